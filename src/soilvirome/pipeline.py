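"""End-to-end pipeline orchestration with a run manifest.

Stage order: simulate (optional) -> population dereplication -> abundance
profiling -> activity / AMG annotation -> host linkage -> gene-sharing
network -> ecology statistics.  Each stage reads and writes files under one
output directory; the manifest records the configuration hash, per-file
checksums, timings and the seed, so a rerun with identical inputs is
verifiably identical for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import genes as gn
from . import hostlink as hl
from . import io
from . import network as nw
from . import populations as pop
from . import stats as st
from .simulate import SimulationConfig, generate_community, write_community


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig | None = None
    # mapping / profiling thresholds (named defaults from the study design)
    min_identity: float = 95.0
    min_read_fraction: float = 0.90
    host_min_read_fraction: float = 0.75
    min_breadth: float = 0.70
    host_min_cov: float = 0.25
    min_population_len: int = 10_000
    ani_threshold: float = 0.95
    af_threshold: float = 0.85
    aai_threshold: float = 0.95
    # host linkage
    pam_motif: str = "GG"
    tnf_threshold: float = 1e-3
    min_hit_len: int = 2500
    # network
    inflation: float = 2.0
    score_threshold: float = 1.0
    # statistics
    n_permutations: int = 999

    def __post_init__(self):
        if self.sim is None:
            self.sim = SimulationConfig(seed=self.seed, pam_motif=self.pam_motif)


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(outdir: str | Path) -> list[str]:
    """Schema- and cross-reference checks over the data directory.

    Returns a list of warning/error strings (empty for a clean directory).
    """
    outdir = Path(outdir)
    report: list[str] = []
    data = outdir / "data"
    needed = ["hosts.fasta", "viruses.fasta", "alignments.tsv", "metadata.tsv"]
    for name in needed:
        if not (data / name).exists():
            report.append(f"missing input file: {data / name}")
    if report:
        return report
    hosts = io.read_fasta(data / "hosts.fasta")
    viruses = io.read_fasta(data / "viruses.fasta")
    known = set(hosts) | set(viruses)
    aln = io.read_alignments(data / "alignments.tsv")
    orphans = sorted(set(aln["target_id"]) - known)
    for o in orphans[:20]:
        report.append(f"alignment references unknown contig: {o}")
    try:
        io.read_gff(data / "genes.gff3")
    except ValueError as exc:
        report.append(str(exc))
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "soilvirome 0.1.0",
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
        "outputs": {},
    }

    def record(stage: str, t0: float, written: dict[str, Path]):
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for key, path in written.items():
            manifest["outputs"][f"{stage}/{key}"] = {
                "path": str(path),
                "sha256": _sha256(Path(path)),
            }

    # --- simulate -----------------------------------------------------------
    data = outdir / "data"
    if config.simulate:
        t0 = time.time()
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        community = generate_community(sim_cfg)
        paths = write_community(community, data)
        record("simulate", t0, paths)
    if not (data / "viruses.fasta").exists():
        raise StageError("derep", f"missing FASTA: {data / 'viruses.fasta'}")

    # --- population dereplication ------------------------------------------
    t0 = time.time()
    viral_seqs = io.read_fasta(data / "viruses.fasta")
    contigs = [
        pop.ContigRecord(cid, seq, circular=pop.detect_circularity(seq))
        for cid, seq in viral_seqs.items()
    ]
    clusters = pop.cluster_populations(
        contigs, id_thresh=config.ani_threshold, af_thresh=config.af_threshold
    )
    by_id = {c.id: c for c in contigs}
    retained = pop.apply_population_criteria(clusters, by_id, config.min_population_len)
    pop_rows = [
        {
            "population_id": cl.representative_id,
            "member_id": m,
            "representative": m == cl.representative_id,
        }
        for cl in retained
        for m in cl.member_ids
    ]
    pop_path = outdir / "populations.tsv"
    pd.DataFrame(pop_rows).to_csv(pop_path, sep="\t", index=False)

    aai = pd.read_csv(data / "aai_matrix.tsv", sep="\t", index_col=0)
    qual = pd.read_csv(data / "bin_quality.tsv", sep="\t", index_col=0)
    qualities = {
        b: pop.bin_quality(r["completeness"], r["contamination"])
        for b, r in qual.iterrows()
    }
    reps, rep_map = pop.dereplicate_bins(
        aai.to_numpy(), list(aai.index), qualities, thresh=config.aai_threshold
    )
    derep_path = outdir / "host_representatives.tsv"
    pd.DataFrame(
        [{"bin_id": b, "representative": r} for b, r in sorted(rep_map.items())]
    ).to_csv(derep_path, sep="\t", index=False)
    record("derep", t0, {"populations": pop_path, "host_reps": derep_path})

    # --- abundance profiling ------------------------------------------------
    t0 = time.time()
    aln = io.read_alignments(data / "alignments.tsv")
    metadata = pd.read_csv(data / "metadata.tsv", sep="\t", index_col=0)
    samples = list(metadata.index)
    read_totals = metadata["read_total"].to_dict()
    rep_ids = [cl.representative_id for cl in retained]
    target_lens = {r: len(viral_seqs[r]) for r in rep_ids}
    dna = aln.loc[aln["dataset"] == "dna"]
    viral_cov = ab.coverage_table(
        dna,
        target_lens,
        sample_ids=samples,
        min_identity=config.min_identity,
        min_read_fraction=config.min_read_fraction,
        min_breadth=config.min_breadth,
    )
    viral_otu = ab.normalize_by_reads(viral_cov, read_totals)

    host_seqs = io.read_fasta(data / "hosts.fasta")
    host_bins: dict[str, dict[str, int]] = {}
    for cid, seq in host_seqs.items():
        bin_id = cid.rsplit("_c", 1)[0]
        host_bins.setdefault(bin_id, {})[cid] = len(seq)
    host_bins = {b: cs for b, cs in host_bins.items() if rep_map.get(b, b) == b}
    host_cov = ab.host_coverage_table(
        dna,
        host_bins,
        samples,
        min_identity=config.min_identity,
        min_read_fraction=config.host_min_read_fraction,
        min_cov=config.host_min_cov,
    )
    host_otu = ab.normalize_by_reads(host_cov, read_totals)
    votu_path = outdir / "viral_otu.tsv"
    hotu_path = outdir / "host_otu.tsv"
    viral_otu.data.to_csv(votu_path, sep="\t")
    host_otu.data.to_csv(hotu_path, sep="\t")
    record("profile", t0, {"viral_otu": votu_path, "host_otu": hotu_path})

    # --- activity + AMG annotation -----------------------------------------
    t0 = time.time()
    genes = io.read_gff(data / "genes.gff3")
    genes_by_contig: dict[str, list[io.GffGene]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig_id, []).append(g)
    rna = aln.loc[aln["dataset"] == "rna"]
    rna_filtered = ab.filter_alignments(rna, config.min_identity, config.min_read_fraction)
    rna_samples = sorted(rna_filtered["sample_id"].unique())
    rna_cov = ab.coverage_table(
        rna,
        target_lens,
        sample_ids=rna_samples,
        min_identity=config.min_identity,
        min_read_fraction=config.min_read_fraction,
        min_breadth=0.0,
    )
    calls: list[gn.ActivityCall] = []
    for vid in rep_ids:
        contig_genes = genes_by_contig.get(vid, [])
        if not contig_genes:
            continue
        for sample in rna_samples:
            sub = rna_filtered.loc[
                (rna_filtered["target_id"] == vid) & (rna_filtered["sample_id"] == sample)
            ]
            depth = ab.depth_vector(sub, target_lens[vid])
            cov = {g.gene_id: gn.gene_mean_coverage(depth, g) for g in contig_genes}
            calls.append(gn.detect_active(vid, sample, cov, target_lens[vid]))
    rna_otu = gn.zero_below_detection(rna_cov, calls)
    calls_path = outdir / "activity_calls.tsv"
    pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
        calls_path, sep="\t", index=False
    )
    rna_path = outdir / "rna_otu.tsv"
    rna_otu.data.to_csv(rna_path, sep="\t")

    amg_rows = []
    for vid, contig_genes in sorted(genes_by_contig.items()):
        for g in contig_genes:
            if g.category == gn.GLYCOSIDE_HYDROLASE:
                verdict = gn.amg_context_screen(contig_genes, g)
                amg_rows.append(
                    {"contig_id": vid, "gene_id": g.gene_id, "verdict": verdict}
                )
    amg_path = outdir / "amg_screen.tsv"
    pd.DataFrame(amg_rows).to_csv(amg_path, sep="\t", index=False)
    record(
        "annotate", t0, {"activity": calls_path, "rna_otu": rna_path, "amg": amg_path}
    )

    # --- host linkage -------------------------------------------------------
    t0 = time.time()
    crispr_df = pd.read_csv(data / "crispr_arrays.tsv", sep="\t")
    arrays = [
        hl.CrisprArray(
            array_id=f"{host}_array",
            repeat_seq=grp["repeat_seq"].iloc[0],
            spacers=tuple(grp.sort_values("spacer_index")["spacer_seq"]),
            source=host,
        )
        for host, grp in crispr_df.groupby("host_id")
    ]
    host_genomes: dict[str, dict[str, str]] = {}
    for cid, seq in host_seqs.items():
        host_genomes.setdefault(cid.rsplit("_c", 1)[0], {})[cid] = seq
    lineage_df = pd.read_csv(data / "host_lineages.tsv", sep="\t")
    host_lineages = dict(zip(lineage_df["bin_id"], lineage_df["lineage"]))
    rep_viral_seqs = {r: viral_seqs[r] for r in rep_ids}
    evidence = hl.gather_evidence(
        rep_viral_seqs,
        host_genomes,
        arrays,
        pam_motif=config.pam_motif,
        tnf_threshold=config.tnf_threshold,
    )
    assignments = hl.resolve_all(evidence, host_lineages)
    ev_path = outdir / "link_evidence.tsv"
    pd.DataFrame([dataclasses.asdict(e) for e in evidence]).to_csv(
        ev_path, sep="\t", index=False
    )
    asn_path = outdir / "host_assignments.tsv"
    pd.DataFrame(
        [dataclasses.asdict(a) for a in assignments.values() if a is not None]
    ).to_csv(asn_path, sep="\t", index=False)
    record("hostlink", t0, {"evidence": ev_path, "assignments": asn_path})

    # --- gene-sharing network ----------------------------------------------
    t0 = time.time()
    pc_df = pd.read_csv(data / "pc_membership.tsv", sep="\t")
    membership = {
        g: set(grp["pc_id"]) for g, grp in pc_df.groupby("genome_id")
    }
    edges = nw.build_network(membership, threshold=config.score_threshold)
    vclusters = nw.mcl(edges, inflation=config.inflation)
    ref_df = pd.read_csv(data / "reference_lineages.tsv", sep="\t")
    ref_lineages = dict(zip(ref_df["genome_id"], ref_df["lineage"]))
    taxonomy: dict[int, list[nw.TaxonomyCall]] = {
        i: nw.assign_taxonomy(members, ref_lineages) for i, members in enumerate(vclusters)
    }
    edge_path = outdir / "network_edges.tsv"
    pd.DataFrame([dataclasses.asdict(e) for e in edges]).to_csv(
        edge_path, sep="\t", index=False
    )
    vc_path = outdir / "viral_clusters.tsv"
    pd.DataFrame(
        [
            {"cluster_index": i, "genome_id": g}
            for i, members in enumerate(vclusters)
            for g in sorted(members)
        ]
    ).to_csv(vc_path, sep="\t", index=False)
    tax_path = outdir / "cluster_taxonomy.tsv"
    pd.DataFrame(
        [dataclasses.asdict(c) for calls_ in taxonomy.values() for c in calls_]
    ).to_csv(tax_path, sep="\t", index=False)
    record("network", t0, {"edges": edge_path, "clusters": vc_path, "taxonomy": tax_path})

    # --- ecology statistics -------------------------------------------------
    t0 = time.time()
    seed = _stage_seed(config.seed, "stats")
    votu_sqrt = ab.sqrt_transform(viral_otu)
    bc = st.bray_curtis(votu_sqrt.data)
    habitats = metadata.loc[bc.index, "habitat"].to_numpy()
    results = {
        "permanova": dataclasses.asdict(
            st.permanova(bc, habitats, n_perm=config.n_permutations, seed=seed)
        ),
        "anosim": dataclasses.asdict(
            st.anosim(bc, habitats, n_perm=config.n_permutations, seed=seed)
        ),
        "permdisp": dataclasses.asdict(
            st.permdisp(bc, habitats, n_perm=config.n_permutations, seed=seed)
        ),
    }
    host_bc = st.bray_curtis(ab.sqrt_transform(host_otu).data)
    results["mantel_virus_host"] = dataclasses.asdict(
        st.mantel_spearman(bc, host_bc, n_perm=config.n_permutations, seed=seed)
    )
    mean_curve, _ = st.accumulation_curve(viral_otu.data, n_rand=200, seed=seed)
    results["accumulation_mean"] = mean_curve.tolist()

    virus_lineage = {
        a.viral_population_id: a.lineage
        for a in assignments.values()
        if a is not None and a.lineage
    }
    v_sums = st.lineage_sums(viral_otu.data, virus_lineage, level=2)
    h_sums = st.lineage_sums(host_otu.data, host_lineages, level=2)
    ratios = st.virus_host_ratio(v_sums, h_sums)
    results["virus_host_ratios"] = [dataclasses.asdict(r) for r in ratios]

    # PLS of geochemistry on metabolism group sums
    groups_table = _metabolism_groups(data, assignments)
    predictors = pd.concat(
        [
            st.metabolism_group_sums(host_otu.data, groups_table["hosts"]).T,
            st.metabolism_group_sums(viral_otu.data, groups_table["viruses"]).T,
        ],
        axis=1,
    )
    results["pls"] = {}
    for resp in ("CH4_porewater", "d13C_CH4", "DOC"):
        if resp not in metadata.columns:
            continue
        y = metadata.loc[predictors.index, resp].to_numpy(dtype=float)
        usable = predictors.loc[:, predictors.std(axis=0) > 0]
        ncomp = min(2, max(1, np.linalg.matrix_rank(usable.to_numpy())))
        try:
            model = st.pls_fit(usable, y, n_components=ncomp)
            r, p = st.prediction_r(model)
            results["pls"][resp] = {"r": r, "p": p, "n_components": ncomp}
        except ValueError as exc:
            results["pls"][resp] = {"error": str(exc)}
    stats_path = outdir / "stats_results.json"
    io.write_json(results, stats_path)
    record("stats", t0, {"results": stats_path})

    manifest_path = outdir / "run_manifest.json"
    io.write_json(manifest, manifest_path)
    return manifest


def _metabolism_groups(data: Path, assignments) -> dict[str, dict[str, list[str]]]:
    """Metabolism-defined host groups and the viruses assigned to them."""
    truth = io.read_json(data / "truth.json") if (data / "truth.json").exists() else {}
    host_groups: dict[str, list[str]] = truth.get("host_groups", {})
    lineage_df = pd.read_csv(data / "host_lineages.tsv", sep="\t")
    host_lineages = dict(zip(lineage_df["bin_id"], lineage_df["lineage"]))
    virus_groups: dict[str, list[str]] = {}
    for gname, bins in host_groups.items():
        lineages = {host_lineages[b] for b in bins}
        members = [
            a.viral_population_id
            for a in assignments.values()
            if a is not None
            and any(lin.startswith(a.lineage) and a.lineage for lin in lineages)
        ]
        virus_groups[f"{gname}_viruses"] = sorted(set(members))
    return {
        "hosts": {f"{g}_hosts": bins for g, bins in host_groups.items()},
        "viruses": virus_groups,
    }
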