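"""Gene-sharing genome network, Markov clustering and viral-cluster taxonomy.

Genomes (viral populations plus reference genomes) are nodes; an edge is
drawn when the number of protein clusters (PCs) two genomes share is larger
than expected by chance.  Significance is the hypergeometric upper tail
P(X >= c) for c shared PCs out of set sizes a and b in a universe of n PCs;
the similarity score is -log10(P x total pairwise comparisons), and pairs
scoring > 1 are clustered with the Markov clustering (MCL) algorithm at
inflation 2 into approximately genus-level viral clusters (VCs).  Reference
genomes with known lineages carried into a VC vote its taxonomy with
high/medium/low confidence at >=50/30/10% support.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import hypergeom

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class SimilarityEdge:
    genome_a: str
    genome_b: str
    shared: int
    size_a: int
    size_b: int
    p_value: float
    score: float


@dataclass
class TaxonomyCall:
    cluster_id: str
    rank: str
    value: str
    support: float
    tier: str  # high / medium / low / none


def hypergeom_shared_pval(a: int, b: int, c: int, n: int) -> float:
    """P(X >= c) for X ~ Hypergeometric(n, a, b): the chance that two PC
    sets of sizes a and b drawn from n total PCs share at least c members."""
    if not (0 <= c <= min(a, b) <= n) or a > n or b > n:
        raise ValueError(f"inconsistent counts a={a} b={b} c={c} n={n}")
    if c == 0:
        return 1.0
    # survival function computed in log space internally by scipy
    return float(hypergeom.sf(c - 1, n, a, b))


def similarity_score(p_value: float, total_comparisons: int) -> float:
    """Negative logarithmic similarity score, floored at 0.

    -log10(p * C) where C is the number of pairwise comparisons; the
    multiplication is a Bonferroni-style penalty so a score of 1 means the
    shared content is 10x beyond the multiple-testing noise floor.
    """
    corrected = p_value * total_comparisons
    if corrected >= 1.0:
        return 0.0
    return float(-np.log10(corrected))


def build_network(
    memberships: dict[str, set[str]],
    universe_size: int | None = None,
    threshold: float = 1.0,
) -> list[SimilarityEdge]:
    """Score all genome pairs and keep edges with score strictly above ``threshold``.

    ``memberships`` maps genome id -> set of PC ids; the universe defaults to
    the number of distinct PCs observed.  Total comparisons = G(G-1)/2.
    """
    genomes = sorted(memberships)
    if universe_size is None:
        universe_size = len(set().union(*memberships.values())) if memberships else 0
    g = len(genomes)
    total = g * (g - 1) // 2
    edges: list[SimilarityEdge] = []
    for i in range(g):
        for j in range(i + 1, g):
            a_set, b_set = memberships[genomes[i]], memberships[genomes[j]]
            c = len(a_set & b_set)
            if c == 0:
                continue
            p = hypergeom_shared_pval(len(a_set), len(b_set), c, universe_size)
            score = similarity_score(p, max(total, 1))
            if score > threshold:
                edges.append(
                    SimilarityEdge(
                        genomes[i], genomes[j], c, len(a_set), len(b_set), p, score
                    )
                )
    return edges


def negative_control(
    memberships: dict[str, set[str]],
    n_rand: int = 1000,
    seed: int = 0,
    universe_size: int | None = None,
    threshold: float = 1.0,
) -> float:
    """Randomization control for the score threshold.

    For every genome pair whose observed score is <= ``threshold``, the PCs
    in the pair's combined pool are reallocated at random between the two
    genomes (sizes preserved) ``n_rand`` times; returns the maximum score
    seen.  A maximum <= 1 indicates the threshold separates signal from the
    sharing expected among unrelated genomes.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if n_rand <= 0:
        return 0.0
    genomes = sorted(memberships)
    if universe_size is None:
        universe_size = len(set().union(*memberships.values())) if memberships else 0
    g = len(genomes)
    total = max(g * (g - 1) // 2, 1)
    max_score = 0.0
    for i in range(g):
        for j in range(i + 1, g):
            a_set, b_set = memberships[genomes[i]], memberships[genomes[j]]
            c_obs = len(a_set & b_set)
            p = hypergeom_shared_pval(len(a_set), len(b_set), c_obs, universe_size)
            if similarity_score(p, total) > threshold:
                continue
            pool = np.array(sorted(a_set | b_set))
            na = len(a_set)
            for _ in range(n_rand):
                perm = rng.permutation(len(pool))
                ra = set(pool[perm[:na]])
                rb = set(pool[perm[na : na + len(b_set)]])
                c = len(ra & rb)
                p_r = hypergeom_shared_pval(na, len(b_set), c, universe_size)
                s = similarity_score(p_r, total)
                if s > max_score:
                    max_score = s
    return max_score


def mcl(
    edges: list[SimilarityEdge] | list[tuple[str, str, float]],
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-12,
) -> list[set[str]]:
    """Markov clustering of a weighted undirected graph.

    Flow simulation on the column-stochastic transition matrix: alternate
    expansion (matrix squaring) with inflation (elementwise power then
    renormalization) until the matrix stops changing.  Self-loops are added
    with each node's maximum incident edge weight so flow can settle.
    Clusters are the connected components of the converged matrix support;
    isolated nodes come out as singletons.
    """
    triples: list[tuple[str, str, float]] = []
    for e in edges:
        if isinstance(e, SimilarityEdge):
            triples.append((e.genome_a, e.genome_b, e.score))
        else:
            triples.append(e)
    nodes = sorted({n for a, b, _ in triples for n in (a, b)})
    if not nodes:
        return []
    idx = {n: i for i, n in enumerate(nodes)}
    m = len(nodes)
    mat = np.zeros((m, m))
    for a, b, w in triples:
        if w <= 0:
            raise ValueError("edge weights must be positive")
        mat[idx[a], idx[b]] = max(mat[idx[a], idx[b]], w)
        mat[idx[b], idx[a]] = mat[idx[a], idx[b]]
    loops = mat.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(mat, loops)
    mat /= mat.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = mat
        mat = mat @ mat  # expansion
        np.power(mat, inflation, out=mat)  # inflation
        mat[mat < prune] = 0.0
        colsums = mat.sum(axis=0, keepdims=True)
        colsums[colsums == 0] = 1.0
        mat /= colsums
        if prev.shape == mat.shape and np.max(np.abs(mat - prev)) < tol:
            break
    support = csr_matrix((mat + mat.T) > prune)
    _, labels = connected_components(support, directed=False)
    clusters: dict[int, set[str]] = {}
    for node, lab in zip(nodes, labels):
        clusters.setdefault(int(lab), set()).add(node)
    return sorted(clusters.values(), key=lambda s: sorted(s)[0])


def is_near_complete(lineage: str, min_ranks: int = 5) -> bool:
    """A reference lineage is usable for taxonomy when >= ``min_ranks`` of
    its 7 ranks are filled."""
    ranks = [r for r in lineage.split(";") if r.strip()]
    return len(ranks) >= min_ranks


def assign_taxonomy(
    cluster_members: set[str],
    reference_lineages: dict[str, str],
    min_ranks: int = 5,
) -> list[TaxonomyCall]:
    """Taxonomy votes for one viral cluster from its reference members.

    At each rank the support is the fraction of counted references sharing
    the modal value; confidence tiers at >=50% (high), >=30% (medium),
    >=10% (low).  Clusters without usable references get a single ``none``
    call.  When references disagree at a rank, deeper ranks are not called
    (the majority's common ancestor is where the call stops).
    """
    refs = [
        reference_lineages[m].split(";")
        for m in sorted(cluster_members)
        if m in reference_lineages and is_near_complete(reference_lineages[m], min_ranks)
    ]
    cluster_id = sorted(cluster_members)[0]
    if not refs:
        return [TaxonomyCall(cluster_id, "none", "", 0.0, "none")]
    calls: list[TaxonomyCall] = []
    for level, rank in enumerate(RANKS):
        values = [r[level] for r in refs if level < len(r) and r[level].strip()]
        if not values:
            break
        uniq, counts = np.unique(values, return_counts=True)
        order = np.lexsort((uniq, -counts))  # modal value, ties lexicographic
        modal, support = uniq[order[0]], counts[order[0]] / len(refs)
        if support >= 0.5:
            tier = "high"
        elif support >= 0.3:
            tier = "medium"
        elif support >= 0.1:
            tier = "low"
        else:
            tier = "none"
        calls.append(TaxonomyCall(cluster_id, rank, str(modal), float(support), tier))
        if len(uniq) > 1:
            break  # disagreement: stop at the majority's common ancestor
    return calls


def cluster_tier(calls: list[TaxonomyCall]) -> str:
    """Best confidence tier across a cluster's rank calls."""
    order = {"high": 0, "medium": 1, "low": 2, "none": 3}
    return min((c.tier for c in calls), key=order.__getitem__, default="none")


def classify_novelty(
    population_id: str,
    clusters: list[set[str]],
    taxonomy_by_cluster: dict[int, list[TaxonomyCall]],
    reference_ids: set[str],
    public_ids: set[str],
) -> str:
    """Novelty category of one study population.

    ``taxonomy_assigned`` when its VC has any taxonomy call; otherwise
    ``shared_with_public`` when the VC contains a reference or public-soil
    genome; otherwise ``exclusive`` (including unclustered singletons).
    """
    for i, members in enumerate(clusters):
        if population_id in members:
            if len(members) > 1:
                calls = taxonomy_by_cluster.get(i, [])
                if cluster_tier(calls) != "none":
                    return "taxonomy_assigned"
                if members & (reference_ids | public_ids):
                    return "shared_with_public"
            return "exclusive"
    return "exclusive"
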