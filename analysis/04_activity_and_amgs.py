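"""Metatranscriptome activity calls and the AMG genomic-context screen.

A population counts as active in a sample only if transcripts cover at least
one gene per 10 kb of its genome; glycoside hydrolases on viral contigs are
screened for a virus-like genomic context.
"""

from pathlib import Path

import pandas as pd

from soilvirome import abundance as ab
from soilvirome import genes as gn
from soilvirome import io

DATA = Path("scratch/analysis/data")
RESULTS = Path("results")


def main():
    viral_seqs = io.read_fasta(DATA / "viruses.fasta")
    aln = io.read_alignments(DATA / "alignments.tsv")
    genes = io.read_gff(DATA / "genes.gff3")
    by_contig: dict[str, list] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)

    rna = ab.filter_alignments(aln[aln.dataset == "rna"])
    calls = []
    for (vid, sample), group in rna.groupby(["target_id", "sample_id"]):
        depth = ab.depth_vector(group, len(viral_seqs[vid]))
        cov = {g.gene_id: gn.gene_mean_coverage(depth, g) for g in by_contig[vid]}
        calls.append(gn.detect_active(vid, sample, cov, len(viral_seqs[vid])))
    calls_df = pd.DataFrame([c.__dict__ for c in calls])
    calls_df.to_csv(RESULTS / "activity_calls.tsv", sep="\t", index=False)

    amg_rows = [
        {"contig_id": cid, "gene_id": g.gene_id,
         "verdict": gn.amg_context_screen(cgenes, g)}
        for cid, cgenes in sorted(by_contig.items())
        for g in cgenes if g.category == gn.GLYCOSIDE_HYDROLASE
    ]
    amg_df = pd.DataFrame(amg_rows)
    amg_df.to_csv(RESULTS / "amg_screen.tsv", sep="\t", index=False)

    detected = calls_df.groupby("population_id")["detected"].any()
    print(f"{len(calls_df)} activity calls over {calls_df.sample_id.nunique()} "
          f"metatranscriptomes; {detected.sum()}/{len(detected)} populations active somewhere")
    print("AMG screen verdicts:", dict(amg_df.verdict.value_counts()))


if __name__ == "__main__":
    main()
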