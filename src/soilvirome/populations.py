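"""Species-level viral population definition and host-bin dereplication.

Viral contigs are clustered greedily (longest first) into populations at
>=95% nucleotide identity over >=85% of the shorter sequence, and a
population enters the analysis set only if its representative is >=10 kb
and/or circular.  Host genome bins are dereplicated at >95% average amino
acid identity (AAI, consumed as a precomputed table), keeping the highest
quality bin per group, where quality = completeness - 4 x contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


@dataclass(frozen=True)
class ContigRecord:
    id: str
    sequence: str
    circular: bool = False
    source: str = "bulk"

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PopulationCluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    ani_threshold: float = 0.95


@dataclass(frozen=True)
class GenomeBin:
    id: str
    contig_ids: tuple[str, ...]
    completeness: float
    contamination: float
    lineage: str = ""


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def estimate_pairwise_identity(
    seq_a: str, seq_b: str, k: int = 16
) -> tuple[float, float]:
    """Estimate nucleotide identity between two sequences.

    Shared ``k``-mers anchor a dominant gap-free diagonal; the overlapping
    span on that diagonal is compared base-by-base.  Returns
    ``(identity, aligned_fraction_of_shorter)``.  Suited to the
    substitution-dominated divergence that separates members of a viral
    population; an exact dynamic-programming aligner is the reference for
    short sequences.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if len(seq_a) < k or len(seq_b) < k:
        # fall back to direct comparison of the overlap
        return _diagonal_identity(seq_a, seq_b, 0)
    return _identity_with_index(_kmer_index(seq_a, k), seq_a, seq_b, k)


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _identity_with_index(
    index: dict[str, list[int]], seq_a: str, seq_b: str, k: int
) -> tuple[float, float]:
    diag_votes: dict[int, int] = {}
    for j in range(len(seq_b) - k + 1):
        for i in index.get(seq_b[j : j + k], ()):
            d = i - j
            diag_votes[d] = diag_votes.get(d, 0) + 1
    if not diag_votes:
        return 0.0, 0.0
    # deterministic: most-voted diagonal, ties to smallest offset
    best = max(sorted(diag_votes), key=lambda d: diag_votes[d])
    return _diagonal_identity(seq_a, seq_b, best)


def _diagonal_identity(seq_a: str, seq_b: str, diag: int) -> tuple[float, float]:
    """Identity over the gap-free overlap of seq_a[i] vs seq_b[i - diag]."""
    a = _encode(seq_a)
    b = _encode(seq_b)
    start_a = max(0, diag)
    start_b = start_a - diag
    span = min(len(a) - start_a, len(b) - start_b)
    if span <= 0:
        return 0.0, 0.0
    matches = int(np.sum(a[start_a : start_a + span] == b[start_b : start_b + span]))
    identity = matches / span
    af = span / min(len(a), len(b))
    return identity, af


def cluster_populations(
    contigs: list[ContigRecord],
    id_thresh: float = 0.95,
    af_thresh: float = 0.85,
) -> list[PopulationCluster]:
    """Greedy longest-first clustering at ``id_thresh`` nucleotide identity.

    Contigs are sorted by length descending (ties by id); each contig joins
    the first cluster whose representative it matches at >= ``id_thresh``
    identity over >= ``af_thresh`` of the shorter sequence, else founds a
    new cluster.  Deterministic; every contig lands in exactly one cluster.
    """
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids")
    k = 16
    ordered = sorted(contigs, key=lambda c: (-c.length, c.id))
    clusters: list[PopulationCluster] = []
    reps: list[ContigRecord] = []
    rep_indexes: list[dict] = []  # k-mer index per representative, built once
    for contig in ordered:
        placed = False
        for cluster, rep, idx in zip(clusters, reps, rep_indexes):
            ident, af = _identity_with_index(idx, rep.sequence, contig.sequence, k)
            if ident >= id_thresh and af >= af_thresh:
                cluster.member_ids.append(contig.id)
                placed = True
                break
        if not placed:
            clusters.append(
                PopulationCluster(
                    representative_id=contig.id,
                    member_ids=[contig.id],
                    ani_threshold=id_thresh,
                )
            )
            reps.append(contig)
            rep_indexes.append(_kmer_index(contig.sequence, k))
    return clusters


def apply_population_criteria(
    clusters: list[PopulationCluster],
    contigs_by_id: dict[str, ContigRecord],
    min_len: int = 10_000,
) -> list[PopulationCluster]:
    """Retain populations whose representative is >= ``min_len`` bp and/or circular."""
    kept = []
    for cl in clusters:
        rep = contigs_by_id[cl.representative_id]
        if rep.length >= min_len or rep.circular:
            kept.append(cl)
    return kept


def detect_circularity(sequence: str, min_overlap: int = 20) -> bool:
    """True iff the sequence carries a terminal exact direct repeat >= ``min_overlap`` bp.

    Circular assemblies present as linear contigs whose ends overlap; an
    exact prefix == suffix match of at least ``min_overlap`` bases is taken
    as evidence of a complete circular genome.
    """
    n = len(sequence)
    if n < 2 * min_overlap:
        return False
    for olap in range(min(n // 2, 500), min_overlap - 1, -1):
        if sequence[:olap] == sequence[-olap:]:
            return True
    return False


def bin_quality(completeness: float, contamination: float) -> float:
    """Bin quality score: completeness - 4 x contamination (both in percent)."""
    return completeness - 4.0 * contamination


def dereplicate_bins(
    aai_matrix: np.ndarray,
    bin_ids: list[str],
    qualities: dict[str, float],
    thresh: float = 0.95,
) -> tuple[list[str], dict[str, str]]:
    """Single-linkage dereplication of genome bins at AAI > ``thresh``.

    Returns ``(representative_ids, member -> representative map)``.  The
    representative of each group is its highest-quality bin (ties broken by
    id, lexicographically smallest wins).
    """
    aai = np.asarray(aai_matrix, dtype=float)
    if aai.shape[0] != aai.shape[1] or aai.shape[0] != len(bin_ids):
        raise ValueError("AAI matrix shape does not match bin ids")
    if not np.allclose(aai, aai.T):
        raise ValueError("AAI matrix must be symmetric")
    adj = csr_matrix(aai > thresh)
    _, labels = connected_components(adj, directed=False)
    rep_map: dict[str, str] = {}
    representatives: list[str] = []
    for lab in np.unique(labels):
        group = [bin_ids[i] for i in np.where(labels == lab)[0]]
        rep = max(sorted(group), key=lambda b: qualities[b])
        representatives.append(rep)
        for b in group:
            rep_map[b] = rep
    return sorted(representatives), rep_map
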