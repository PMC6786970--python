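"""Cluster viral contigs into species-level populations and dereplicate host bins.

Populations: greedy 95% nucleotide-identity clustering, retained if the
representative is >=10 kb and/or circular.  Host bins: single-linkage groups
at >95% AAI, keeping the highest completeness - 4 x contamination bin.
"""

from pathlib import Path

import pandas as pd

from soilvirome import io
from soilvirome import populations as pop

DATA = Path("scratch/analysis/data")
RESULTS = Path("results")


def main():
    viral_seqs = io.read_fasta(DATA / "viruses.fasta")
    contigs = [
        pop.ContigRecord(cid, seq, circular=pop.detect_circularity(seq))
        for cid, seq in viral_seqs.items()
    ]
    clusters = pop.cluster_populations(contigs)
    retained = pop.apply_population_criteria(clusters, {c.id: c for c in contigs})
    rows = [
        {"population_id": cl.representative_id, "member_id": m,
         "representative": m == cl.representative_id}
        for cl in retained for m in cl.member_ids
    ]
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "populations.tsv", sep="\t", index=False)

    aai = pd.read_csv(DATA / "aai_matrix.tsv", sep="\t", index_col=0)
    qual = pd.read_csv(DATA / "bin_quality.tsv", sep="\t", index_col=0)
    qualities = {b: pop.bin_quality(r["completeness"], r["contamination"])
                 for b, r in qual.iterrows()}
    reps, rep_map = pop.dereplicate_bins(aai.to_numpy(), list(aai.index), qualities)
    pd.DataFrame(
        [{"bin_id": b, "representative": r} for b, r in sorted(rep_map.items())]
    ).to_csv(RESULTS / "host_representatives.tsv", sep="\t", index=False)

    print(f"{len(contigs)} viral contigs -> {len(clusters)} clusters, "
          f"{len(retained)} populations retained (>=10 kb and/or circular)")
    print(f"{len(rep_map)} host bins -> {len(reps)} representatives after AAI dereplication")


if __name__ == "__main__":
    main()
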