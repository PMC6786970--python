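"""Synthetic soil virus-host communities with planted, machine-readable truth.

The generator emulates the statistical structure the downstream analyses
assume, without simulating reads or assembly:

* hosts get genomes drawn from host-specific order-3 Markov composition
  models (so tetranucleotide signatures are separable) with an embedded
  CRISPR array (repeat + spacers) and a 7-rank lineage;
* viruses are planted with one of four host-link evidence classes — a CRISPR
  protospacer copy (with or without the PAM), host-like composition (emitted
  from the host's Markov model), a shared proviral region (>=2.5 kb covering
  <=90% of a host contig) or a co-binned region (covering >=90% of a short
  host contig) — or left unlinked;
* per-habitat lognormal abundances (palsa / bog / fen, each entity favouring
  one habitat by a multiplicative effect) drive tabular alignment records
  with controlled identity and aligned-fraction noise; a subset of samples
  carries metatranscriptome records in which planted "active" viruses cover
  at least one gene per 10 kb;
* protein-cluster memberships carry planted viral clusters, including
  reference-labelled and public-soil members, over a background PC pool;
* geochemical responses are linear combinations of planted virus/host group
  abundance sums plus Gaussian noise.

Every planted fact is recorded in a :class:`TruthTable`; identical
configuration and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .hostlink import CrisprArray
from .io import GffGene

HABITATS = ("palsa", "bog", "fen")
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_PHYLA = [
    ("d__Bacteria", "p__Acidobacteriota", "c__Acidobacteriae"),
    ("d__Bacteria", "p__Actinobacteriota", "c__Actinomycetia"),
    ("d__Bacteria", "p__Proteobacteria", "c__Alphaproteobacteria"),
    ("d__Bacteria", "p__Proteobacteria", "c__Gammaproteobacteria"),
    ("d__Bacteria", "p__Verrucomicrobiota", "c__Verrucomicrobiae"),
    ("d__Archaea", "p__Halobacteriota", "c__Methanosarcinia"),
    ("d__Archaea", "p__Methanobacteriota", "c__Methanobacteria"),
]

_VIRAL_FAMILIES = ["f__Siphoviridae", "f__Myoviridae", "f__Podoviridae"]


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for the synthetic community (see docs/methods.md)."""

    seed: int = 0
    n_hosts: int = 20
    n_viruses: int = 50
    n_samples_per_habitat: int = 10
    host_genome_len: int = 20_000
    host_short_contig_len: int = 3_000
    viral_contig_len_range: tuple[int, int] = (10_000, 15_000)
    pam_motif: str = "GG"
    spacer_len: int = 32
    n_spacers_per_host: int = 6
    frac_crispr_linked: float = 0.30
    frac_tnf_linked: float = 0.30
    frac_provirus: float = 0.10
    frac_cobinned: float = 0.10
    frac_crispr_no_pam: float = 0.25  # share of CRISPR links planted without the PAM
    provirus_region_len: int = 3_000
    abundance_lognormal_params: tuple[float, float] = (0.0, 1.0)
    habitat_effect_size: float = 4.0
    read_len: int = 150
    reads_per_sample_range: tuple[int, int] = (20_000, 30_000)
    alignment_identity_noise: float = 0.10
    frac_short_alignments: float = 0.05
    n_rna_samples_per_habitat: int = 2
    frac_active: float = 0.5
    n_refseq_like: int = 10
    n_public_like: int = 5
    viral_cluster_size: int = 5
    pcs_per_cluster_pool: int = 25
    pcs_per_genome: int = 18
    background_pcs_per_genome: int = 2
    n_background_pcs: int = 300
    geochem_coefficients: tuple[tuple[float, ...], ...] = (
        (2.0, -1.0, 0.0, 0.0),  # CH4 ~ methanogen hosts - methanotroph hosts
        (0.0, 0.0, -1.5, 2.0),  # d13C-CH4 ~ methanogen/methanotroph viruses
        (1.0, 0.5, 0.5, 0.0),  # DOC
    )
    noise_sd: float = 0.1

    def validate(self) -> None:
        fracs = (
            self.frac_crispr_linked,
            self.frac_tnf_linked,
            self.frac_provirus,
            self.frac_cobinned,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("link fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-9:
            raise ValueError("link-type fractions sum above 1")
        positives = (
            self.n_hosts,
            self.n_viruses,
            self.n_samples_per_habitat,
            self.host_genome_len,
            self.read_len,
            self.spacer_len,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("counts and lengths must be positive")
        if self.viral_contig_len_range[0] > self.viral_contig_len_range[1]:
            raise ValueError("bad viral contig length range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class TruthTable:
    """Planted facts the recovery tests measure against."""

    planted_abundance: pd.DataFrame  # entity x sample true relative abundance
    planted_links: list[dict] = field(default_factory=list)
    planted_clusters: dict[str, str] = field(default_factory=dict)
    planted_taxonomy: dict[str, str] = field(default_factory=dict)
    geochem_model: dict[str, dict[str, float]] = field(default_factory=dict)
    active_viruses: dict[str, bool] = field(default_factory=dict)
    host_groups: dict[str, list[str]] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "planted_abundance": {
                e: {s: float(v) for s, v in row.items()}
                for e, row in self.planted_abundance.iterrows()
            },
            "planted_links": self.planted_links,
            "planted_clusters": self.planted_clusters,
            "planted_taxonomy": self.planted_taxonomy,
            "geochem_model": self.geochem_model,
            "active_viruses": self.active_viruses,
            "host_groups": self.host_groups,
        }


@dataclass
class HostSet:
    genomes: dict[str, dict[str, str]]  # bin id -> contig id -> sequence
    lineages: dict[str, str]
    crispr_arrays: list[CrisprArray]
    bin_quality: pd.DataFrame  # completeness / contamination per bin
    markov_models: dict[str, np.ndarray]
    groups: dict[str, list[str]]  # metabolism group -> bin ids
    aai: pd.DataFrame | None = None  # pairwise AAI table (fractions)


@dataclass
class SyntheticCommunity:
    config: SimulationConfig
    hosts: HostSet
    viral_seqs: dict[str, str]
    genes: list[GffGene]
    alignments: pd.DataFrame
    read_totals: dict[str, int]
    metadata: pd.DataFrame
    pc_membership: dict[str, set[str]]
    reference_lineages: dict[str, str]
    public_ids: set[str]
    truth: TruthTable


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stage,)))


def _random_markov_model(rng: np.random.Generator) -> np.ndarray:
    """Order-3 transition matrix: 64 contexts x 4 next-base probabilities."""
    return rng.dirichlet(np.ones(4), size=64)


def _markov_sequence(model: np.ndarray, length: int, rng: np.random.Generator) -> str:
    cum = np.cumsum(model, axis=1)
    out = np.empty(length, dtype=np.uint8)
    first = rng.integers(0, 4, size=3)
    out[:3] = BASES[first]
    state = int(first[0]) * 16 + int(first[1]) * 4 + int(first[2])
    uniforms = rng.random(length)
    for i in range(3, length):
        nxt = int(np.searchsorted(cum[state], uniforms[i], side="right"))
        nxt = min(nxt, 3)
        out[i] = BASES[nxt]
        state = (state * 4 + nxt) % 64
    return out.tobytes().decode("ascii")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _splice(seq: str, insert: str, pos: int) -> str:
    """Replace seq[pos:pos+len(insert)] with the insert (length preserved)."""
    return seq[:pos] + insert + seq[pos + len(insert) :]


def _lineage_for(index: int) -> str:
    dom, phy, cls = _PHYLA[index % len(_PHYLA)]
    order = f"o__Order{index % 4}"
    fam = f"f__Family{index % 6}"
    genus = f"g__Genus{index}"
    species = f"s__Species{index}"
    return ";".join([dom, phy, cls, order, fam, genus, species])


# ---------------------------------------------------------------------------
# Stage 1: hosts


def generate_host_genomes(config: SimulationConfig) -> HostSet:
    """Host genomes, lineages, CRISPR arrays and a bin-quality table.

    Each host has a main contig (with the CRISPR array embedded in its first
    quarter) and a short contig used for co-binned virus planting.  Archaeal
    hosts are split into methanogen/methanotroph-analog metabolism groups
    used by the geochemistry couplings.
    """
    config.validate()
    rng = _rng(config, 1)
    genomes: dict[str, dict[str, str]] = {}
    lineages: dict[str, str] = {}
    arrays: list[CrisprArray] = []
    models: dict[str, np.ndarray] = {}
    qual_rows = []
    groups: dict[str, list[str]] = {"methanogen": [], "methanotroph": []}
    for h in range(config.n_hosts):
        bin_id = f"host_{h:03d}"
        model = _random_markov_model(rng)
        models[bin_id] = model
        main = _markov_sequence(model, config.host_genome_len, rng)
        short = _markov_sequence(model, config.host_short_contig_len, rng)
        repeat = _random_seq(rng, 30)
        spacers = tuple(
            _random_seq(rng, config.spacer_len) for _ in range(config.n_spacers_per_host)
        )
        cassette = repeat + repeat.join(spacers) + repeat
        pos = int(rng.integers(500, max(501, config.host_genome_len // 4)))
        main = _splice(main, cassette, pos)
        genomes[bin_id] = {f"{bin_id}_c1": main, f"{bin_id}_c2": short}
        lineages[bin_id] = _lineage_for(h)
        arrays.append(
            CrisprArray(
                array_id=f"{bin_id}_array", repeat_seq=repeat, spacers=spacers, source=bin_id
            )
        )
        qual_rows.append(
            {
                "bin_id": bin_id,
                "completeness": float(np.round(rng.uniform(70, 100), 2)),
                "contamination": float(np.round(rng.uniform(0, 8), 2)),
            }
        )
        if lineages[bin_id].startswith("d__Archaea"):
            target = "methanogen" if h % 2 else "methanotroph"
            groups[target].append(bin_id)
    quality = pd.DataFrame(qual_rows).set_index("bin_id")
    # pairwise AAI table consumed by dereplication (genomes are all distinct
    # species here, so values sit well below the 0.95 grouping threshold)
    ids = sorted(genomes)
    aai_vals = rng.uniform(0.5, 0.85, size=(len(ids), len(ids)))
    aai_vals = (aai_vals + aai_vals.T) / 2
    np.fill_diagonal(aai_vals, 1.0)
    aai = pd.DataFrame(np.round(aai_vals, 4), index=ids, columns=ids)
    return HostSet(genomes, lineages, arrays, quality, models, groups, aai)


# ---------------------------------------------------------------------------
# Stage 2: viruses


def generate_viral_contigs(
    config: SimulationConfig, hosts: HostSet
) -> tuple[dict[str, str], list[GffGene], TruthTable]:
    """Viral contigs with planted link evidence, plus gene annotations.

    Link classes are assigned in blocks (CRISPR, TNF, provirus, co-binned,
    unlinked) with hosts cycled across each block; all planted facts are
    recorded in the returned TruthTable (abundances filled in later).
    """
    config.validate()
    rng = _rng(config, 2)
    host_ids = sorted(hosts.genomes)
    n = config.n_viruses
    n_crispr = round(config.frac_crispr_linked * n)
    n_tnf = round(config.frac_tnf_linked * n)
    n_prov = round(config.frac_provirus * n)
    n_cob = round(config.frac_cobinned * n)
    if n_crispr + n_tnf + n_prov + n_cob > n:
        raise ValueError("link-type fractions exceed the virus count")
    kinds = (
        ["crispr"] * n_crispr
        + ["tnf"] * n_tnf
        + ["provirus"] * n_prov
        + ["cobinned"] * n_cob
    )
    kinds += ["unlinked"] * (n - len(kinds))

    viral_seqs: dict[str, str] = {}
    genes: list[GffGene] = []
    truth = TruthTable(planted_abundance=pd.DataFrame())
    lo, hi = config.viral_contig_len_range
    for v, kind in enumerate(kinds):
        vid = f"virus_{v:03d}"
        length = int(rng.integers(lo, hi + 1))
        host = host_ids[v % len(host_ids)] if kind != "unlinked" else None
        if kind == "tnf":
            seq = _markov_sequence(hosts.markov_models[host], length, rng)
        else:
            seq = _markov_sequence(_random_markov_model(rng), length, rng)
        pam_present = True
        if kind == "crispr":
            array = next(a for a in hosts.crispr_arrays if a.source == host)
            spacer = array.spacers[int(rng.integers(len(array.spacers)))]
            pam_present = rng.random() >= config.frac_crispr_no_pam
            insert = spacer + (config.pam_motif if pam_present else "")
            pos = int(rng.integers(100, length - len(insert) - 100))
            seq = _splice(seq, insert, pos)
        elif kind == "provirus":
            main = hosts.genomes[host][f"{host}_c1"]
            # chunk from the second half, clear of the CRISPR cassette
            start = int(rng.integers(len(main) // 2, len(main) - config.provirus_region_len))
            chunk = main[start : start + config.provirus_region_len]
            pos = int(rng.integers(100, length - len(chunk) - 100))
            seq = _splice(seq, chunk, pos)
        elif kind == "cobinned":
            short = hosts.genomes[host][f"{host}_c2"]
            pos = int(rng.integers(100, length - len(short) - 100))
            seq = _splice(seq, short, pos)
        viral_seqs[vid] = seq
        if kind != "unlinked":
            tier = {"crispr": 1 if pam_present else 2, "tnf": 5, "provirus": 3, "cobinned": 4}[
                kind
            ]
            truth.planted_links.append(
                {
                    "virus": vid,
                    "host": host,
                    "evidence": kind,
                    "pam_present": bool(pam_present) if kind == "crispr" else None,
                    "expected_tier": tier,
                }
            )
        genes.extend(_tile_genes(vid, length))
    for link in truth.planted_links:
        assert link["host"] in hosts.genomes
    return viral_seqs, genes, truth


def _tile_genes(contig_id: str, length: int, gene_len: int = 950, gap: int = 50) -> list[GffGene]:
    """Tile ~1-kb genes along a contig; ends are viral hallmark genes and one
    mid-contig gene is a glycoside hydrolase (AMG screen material)."""
    genes = []
    start = 1
    i = 0
    while start + gene_len - 1 <= length:
        genes.append(
            GffGene(
                gene_id=f"{contig_id}_g{i:02d}",
                contig_id=contig_id,
                start=start,
                end=start + gene_len - 1,
                strand="+" if i % 2 == 0 else "-",
                category="other",
            )
        )
        start += gene_len + gap
        i += 1
    if genes:
        genes[0] = dataclasses.replace(genes[0], category="viral_hallmark")
        genes[-1] = dataclasses.replace(genes[-1], category="viral_hallmark")
        if len(genes) > 2:
            mid = len(genes) // 2
            genes[mid] = dataclasses.replace(genes[mid], category="glycoside_hydrolase")
    return genes


# ---------------------------------------------------------------------------
# Stage 3: abundances and alignments


def generate_abundance_and_alignments(
    config: SimulationConfig,
    viral_seqs: dict[str, str],
    hosts: HostSet,
    genes: list[GffGene],
    truth: TruthTable,
) -> tuple[pd.DataFrame, dict[str, int], pd.DataFrame]:
    """Planted abundances, tabular alignment records and sample metadata.

    Every entity (host contig set or viral contig) gets a lognormal baseline
    abundance boosted by ``habitat_effect_size`` in its preferred habitat;
    within a sample, reads are allocated multinomially with probability
    proportional to abundance x entity length, so expected depth tracks
    planted abundance x sample read total.  A configurable share of records
    fails the identity (95%) and aligned-fraction (90%) filters.  RNA
    records are emitted for a subset of samples: planted "active" viruses
    receive reads on every gene; inactive ones on too few genes or none.
    """
    config.validate()
    rng = _rng(config, 3)
    entity_lens: dict[str, int] = {}
    entity_contigs: dict[str, list[tuple[str, int]]] = {}
    for bin_id, contigs in sorted(hosts.genomes.items()):
        entity_contigs[bin_id] = [(c, len(s)) for c, s in sorted(contigs.items())]
        entity_lens[bin_id] = sum(l for _, l in entity_contigs[bin_id])
    for vid, seq in sorted(viral_seqs.items()):
        entity_contigs[vid] = [(vid, len(seq))]
        entity_lens[vid] = len(seq)
    entities = sorted(entity_lens)

    samples = []
    for hab in HABITATS:
        for i in range(config.n_samples_per_habitat):
            samples.append((f"{hab}_{i:02d}", hab, 5 + 5 * i))
    mu, sigma = config.abundance_lognormal_params
    baseline = rng.lognormal(mu, sigma, size=len(entities))
    preferred = [HABITATS[i % 3] for i in range(len(entities))]
    abund = np.empty((len(entities), len(samples)))
    for j, (_, hab, _) in enumerate(samples):
        col = baseline * np.where(
            np.array(preferred) == hab, config.habitat_effect_size, 1.0
        )
        abund[:, j] = col / col.sum()
    planted = pd.DataFrame(abund, index=entities, columns=[s for s, _, _ in samples])
    truth.planted_abundance = planted

    # metagenomic alignments
    records: dict[str, list] = {c: [] for c in io.ALIGNMENT_COLUMNS}
    read_totals: dict[str, int] = {}
    lens = np.array([entity_lens[e] for e in entities], dtype=float)
    for j, (sample_id, hab, depth_cm) in enumerate(samples):
        n_reads = int(rng.integers(*config.reads_per_sample_range))
        read_totals[sample_id] = n_reads
        probs = abund[:, j] * lens
        counts = rng.multinomial(n_reads, probs / probs.sum())
        for e_idx, count in enumerate(counts):
            if count == 0:
                continue
            _emit_reads(
                records,
                rng,
                config,
                entity_contigs[entities[e_idx]],
                count,
                sample_id,
                "dna",
            )

    # metatranscriptomic alignments for a subset of samples
    rna_samples = [
        f"{hab}_{i:02d}"
        for hab in HABITATS
        for i in range(min(config.n_rna_samples_per_habitat, config.n_samples_per_habitat))
    ]
    genes_by_contig: dict[str, list[GffGene]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig_id, []).append(g)
    vids = sorted(viral_seqs)
    for v_idx, vid in enumerate(vids):
        truth.active_viruses[vid] = bool(rng.random() < config.frac_active)
    for sample_id in rna_samples:
        read_totals.setdefault(sample_id, read_totals[sample_id])
        for vid in vids:
            contig_genes = genes_by_contig.get(vid, [])
            required = max(1, -(-len(viral_seqs[vid]) // 10_000))
            if truth.active_viruses[vid]:
                chosen = contig_genes  # every gene transcribed
            elif rng.random() < 0.5 and required > 1:
                chosen = contig_genes[: required - 1]  # below the detection rule
            else:
                chosen = []
            for g in chosen:
                n_g = int(rng.integers(2, 5))
                starts = rng.integers(
                    g.start, max(g.start + 1, g.end - config.read_len + 2), size=n_g
                )
                for st in starts:
                    _append_record(
                        records,
                        read_id=f"rna_{sample_id}_{vid}_{g.gene_id}_{st}",
                        target_id=vid,
                        start=int(st),
                        end=min(int(st) + config.read_len - 1, len(viral_seqs[vid])),
                        read_len=config.read_len,
                        aligned_len=config.read_len,
                        identity=float(np.round(rng.uniform(96, 100), 2)),
                        sample_id=sample_id,
                        dataset="rna",
                    )

    alignments = pd.DataFrame(records)
    metadata = pd.DataFrame(
        {
            "sample_id": [s for s, _, _ in samples],
            "habitat": [h for _, h, _ in samples],
            "depth_cm": [d for _, _, d in samples],
            "read_total": [read_totals[s] for s, _, _ in samples],
            "has_rna": [s in rna_samples for s, _, _ in samples],
        }
    ).set_index("sample_id")
    return alignments, read_totals, metadata


def _emit_reads(records, rng, config, contigs, count, sample_id, dataset):
    lens = np.array([l for _, l in contigs], dtype=float)
    split = rng.multinomial(count, lens / lens.sum()) if len(contigs) > 1 else [count]
    for (contig_id, length), n_c in zip(contigs, split):
        if n_c == 0:
            continue
        max_start = max(1, length - config.read_len + 1)
        starts = rng.integers(1, max_start + 1, size=n_c)
        fail_ident = rng.random(n_c) < config.alignment_identity_noise
        idents = np.where(
            fail_ident, rng.uniform(85, 94.9, n_c), rng.uniform(95, 100, n_c)
        )
        fail_len = rng.random(n_c) < config.frac_short_alignments
        fracs = np.where(fail_len, rng.uniform(0.5, 0.88, n_c), rng.uniform(0.92, 1.0, n_c))
        aligned = np.maximum(1, (fracs * config.read_len).astype(int))
        ends = np.minimum(starts + config.read_len - 1, length)
        prefix = f"{dataset}_{sample_id}_{contig_id}_"
        records["read_id"].extend(prefix + str(i) for i in range(n_c))
        records["target_id"].extend([contig_id] * n_c)
        records["target_start"].extend(starts.tolist())
        records["target_end"].extend(ends.tolist())
        records["read_len"].extend([config.read_len] * n_c)
        records["aligned_len"].extend(aligned.tolist())
        records["pct_identity"].extend(np.round(idents, 2).tolist())
        records["sample_id"].extend([sample_id] * n_c)
        records["dataset"].extend([dataset] * n_c)


def _append_record(records, read_id, target_id, start, end, read_len, aligned_len, identity, sample_id, dataset):
    records["read_id"].append(read_id)
    records["target_id"].append(target_id)
    records["target_start"].append(start)
    records["target_end"].append(end)
    records["read_len"].append(read_len)
    records["aligned_len"].append(aligned_len)
    records["pct_identity"].append(identity)
    records["sample_id"].append(sample_id)
    records["dataset"].append(dataset)


# ---------------------------------------------------------------------------
# Stage 4: protein clusters


def generate_protein_clusters(
    config: SimulationConfig, viral_ids: list[str], truth: TruthTable
) -> tuple[dict[str, set[str]], dict[str, str], set[str]]:
    """PC membership table with planted viral clusters.

    Viruses are partitioned into clusters of ``viral_cluster_size``; members
    of a cluster draw most of their PCs from a cluster-specific pool (strong
    within-cluster sharing) plus a couple of PCs from a large background pool
    (weak cross-cluster sharing).  Reference-like genomes (with 7-rank viral
    lineages) and public-soil-like genomes are planted into the first
    clusters.  Returns (membership, reference lineages, public ids).
    """
    config.validate()
    rng = _rng(config, 4)
    clusters: list[list[str]] = []
    for i in range(0, len(viral_ids), config.viral_cluster_size):
        clusters.append(list(viral_ids[i : i + config.viral_cluster_size]))
    membership: dict[str, set[str]] = {}
    reference_lineages: dict[str, str] = {}
    public_ids: set[str] = set()

    extra_members: dict[int, list[str]] = {ci: [] for ci in range(len(clusters))}
    for r in range(config.n_refseq_like):
        ci = r % len(clusters)
        rid = f"ref_{r:03d}"
        fam = _VIRAL_FAMILIES[ci % len(_VIRAL_FAMILIES)]
        reference_lineages[rid] = (
            f"d__Viruses;p__Uroviricota;c__Caudoviricetes;o__Caudovirales;"
            f"{fam};g__RefGenus{ci};s__RefSpecies{r}"
        )
        truth.planted_taxonomy[rid] = reference_lineages[rid]
        extra_members[ci].append(rid)
    for p in range(config.n_public_like):
        ci = (p * 3 + 1) % len(clusters)
        pid = f"public_{p:03d}"
        public_ids.add(pid)
        extra_members[ci].append(pid)

    for ci, members in enumerate(clusters):
        cluster_id = f"VC_{ci:02d}"
        pool = [f"pc_c{ci:02d}_{k:03d}" for k in range(config.pcs_per_cluster_pool)]
        all_members = list(members) + extra_members[ci]
        for genome in all_members:
            own = rng.choice(len(pool), size=min(config.pcs_per_genome, len(pool)), replace=False)
            bg = rng.choice(
                config.n_background_pcs, size=config.background_pcs_per_genome, replace=False
            )
            membership[genome] = {pool[k] for k in own} | {
                f"pc_bg_{b:03d}" for b in bg
            }
            if genome in members:
                truth.planted_clusters[genome] = cluster_id
    return membership, reference_lineages, public_ids


# ---------------------------------------------------------------------------
# Stage 5: geochemistry


def generate_geochemistry(
    config: SimulationConfig,
    truth: TruthTable,
    hosts: HostSet,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Geochemical responses linearly coupled to planted group abundances.

    Predictors are the planted-abundance sums of four groups (methanogen
    hosts, methanotroph hosts and the viruses linked to each); each response
    is the configured linear combination plus Gaussian noise, alongside
    abiotic columns (depth, pH, moisture, temperature).
    """
    config.validate()
    rng = _rng(config, 5)
    predictors = group_abundance_predictors(truth, hosts)
    # standardize so coefficients mean "response units per predictor s.d."
    # and noise_sd lives on a comparable scale
    z = (predictors - predictors.mean()) / predictors.std().replace(0.0, 1.0)
    responses = ["CH4_porewater", "d13C_CH4", "DOC"]
    out = metadata.copy()
    coeffs = np.asarray(config.geochem_coefficients, dtype=float)
    if coeffs.shape != (len(responses), predictors.shape[1]):
        raise ValueError(
            f"geochem_coefficients must be {len(responses)} x {predictors.shape[1]}"
        )
    for i, resp in enumerate(responses):
        signal = z.to_numpy() @ coeffs[i]
        noise = rng.normal(0.0, config.noise_sd, size=len(signal)) if config.noise_sd else 0.0
        out[resp] = signal + noise
        truth.geochem_model[resp] = dict(zip(predictors.columns, coeffs[i].tolist()))
    hab_ph = {"palsa": 4.0, "bog": 4.2, "fen": 5.7}
    hab_moist = {"palsa": 0.3, "bog": 0.8, "fen": 0.95}
    out["pH"] = [hab_ph[h] + rng.normal(0, 0.1) for h in out["habitat"]]
    out["moisture"] = [
        min(1.0, max(0.0, hab_moist[h] + rng.normal(0, 0.05))) for h in out["habitat"]
    ]
    out["temperature_c"] = 10 - 0.05 * out["depth_cm"] + rng.normal(0, 0.5, len(out))
    truth.host_groups = dict(hosts.groups)
    return out


def group_abundance_predictors(truth: TruthTable, hosts: HostSet) -> pd.DataFrame:
    """Sample x 4 matrix of planted group abundance sums (the geochem predictors)."""
    abund = truth.planted_abundance
    links_by_host: dict[str, list[str]] = {}
    for link in truth.planted_links:
        links_by_host.setdefault(link["host"], []).append(link["virus"])
    cols = {}
    for group in ("methanogen", "methanotroph"):
        bins = hosts.groups.get(group, [])
        viruses = sorted({v for b in bins for v in links_by_host.get(b, [])})
        host_rows = [b for b in bins if b in abund.index]
        cols[f"{group}_hosts"] = (
            abund.loc[host_rows].sum(axis=0) if host_rows else pd.Series(0.0, index=abund.columns)
        )
        virus_rows = [v for v in viruses if v in abund.index]
        cols[f"{group}_viruses"] = (
            abund.loc[virus_rows].sum(axis=0)
            if virus_rows
            else pd.Series(0.0, index=abund.columns)
        )
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Orchestration and writing


def generate_community(config: SimulationConfig) -> SyntheticCommunity:
    """Run all generator stages in order and return the full community."""
    hosts = generate_host_genomes(config)
    viral_seqs, genes, truth = generate_viral_contigs(config, hosts)
    alignments, read_totals, metadata = generate_abundance_and_alignments(
        config, viral_seqs, hosts, genes, truth
    )
    membership, ref_lineages, public_ids = generate_protein_clusters(
        config, sorted(viral_seqs), truth
    )
    metadata = generate_geochemistry(config, truth, hosts, metadata)
    return SyntheticCommunity(
        config=config,
        hosts=hosts,
        viral_seqs=viral_seqs,
        genes=genes,
        alignments=alignments,
        read_totals=read_totals,
        metadata=metadata,
        pc_membership=membership,
        reference_lineages=ref_lineages,
        public_ids=public_ids,
        truth=truth,
    )


def write_community(community: SyntheticCommunity, outdir: str | Path) -> dict[str, Path]:
    """Write the community to disk (FASTA/TSV/GFF3/JSON); deterministic bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "hosts_fasta": outdir / "hosts.fasta",
        "viruses_fasta": outdir / "viruses.fasta",
        "alignments": outdir / "alignments.tsv",
        "genes_gff": outdir / "genes.gff3",
        "crispr": outdir / "crispr_arrays.tsv",
        "pc_membership": outdir / "pc_membership.tsv",
        "metadata": outdir / "metadata.tsv",
        "bin_quality": outdir / "bin_quality.tsv",
        "aai": outdir / "aai_matrix.tsv",
        "lineages": outdir / "host_lineages.tsv",
        "reference_lineages": outdir / "reference_lineages.tsv",
        "truth": outdir / "truth.json",
    }
    host_seqs = {
        cid: seq
        for b in sorted(community.hosts.genomes)
        for cid, seq in sorted(community.hosts.genomes[b].items())
    }
    io.write_fasta(host_seqs, paths["hosts_fasta"])
    io.write_fasta(dict(sorted(community.viral_seqs.items())), paths["viruses_fasta"])
    io.write_alignments(community.alignments, paths["alignments"])
    io.write_gff(community.genes, paths["genes_gff"])
    crispr_rows = [
        {
            "host_id": a.source,
            "repeat_seq": a.repeat_seq,
            "spacer_seq": s,
            "spacer_index": i,
        }
        for a in community.hosts.crispr_arrays
        for i, s in enumerate(a.spacers)
    ]
    pd.DataFrame(crispr_rows).to_csv(paths["crispr"], sep="\t", index=False)
    pc_rows = [
        {"genome_id": g, "pc_id": p}
        for g in sorted(community.pc_membership)
        for p in sorted(community.pc_membership[g])
    ]
    pd.DataFrame(pc_rows).to_csv(paths["pc_membership"], sep="\t", index=False)
    community.metadata.to_csv(paths["metadata"], sep="\t")
    community.hosts.bin_quality.to_csv(paths["bin_quality"], sep="\t")
    community.hosts.aai.to_csv(paths["aai"], sep="\t")
    pd.DataFrame(
        [{"bin_id": b, "lineage": l} for b, l in sorted(community.hosts.lineages.items())]
    ).to_csv(paths["lineages"], sep="\t", index=False)
    ref_rows = [
        {"genome_id": g, "lineage": lin}
        for g, lin in sorted(community.reference_lineages.items())
    ]
    pd.DataFrame(ref_rows).to_csv(paths["reference_lineages"], sep="\t", index=False)
    io.write_json(community.truth.to_jsonable(), paths["truth"])
    return paths
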