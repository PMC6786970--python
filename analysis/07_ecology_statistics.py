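"""Community statistics and geochemistry prediction on the profiled community.

Bray-Curtis ordination of the square-root OTU table; PERMANOVA/ANOSIM/
PERMDISP across habitats; Mantel virus-vs-host; accumulation curve;
lineage-level virus/host ratios; PLS prediction of porewater geochemistry
from metabolism-group abundances.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from soilvirome import io
from soilvirome import stats as st

DATA = Path("scratch/analysis/data")
RESULTS = Path("results")
SEED = 7


def main():
    votu = pd.read_csv(RESULTS / "viral_otu.tsv", sep="\t", index_col=0)
    hotu = pd.read_csv(RESULTS / "host_otu.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(DATA / "metadata.tsv", sep="\t", index_col=0)
    habitats = meta["habitat"].to_numpy()

    d = st.bray_curtis(np.sqrt(votu))
    out = {
        "permanova": st.permanova(d, habitats, n_perm=999, seed=SEED).__dict__,
        "anosim": st.anosim(d, habitats, n_perm=999, seed=SEED).__dict__,
        "permdisp": st.permdisp(d, habitats, n_perm=999, seed=SEED).__dict__,
        "mantel_virus_host": st.mantel_spearman(
            d, st.bray_curtis(np.sqrt(hotu)), n_perm=999, seed=SEED).__dict__,
    }
    mean_curve, _ = st.accumulation_curve(votu, n_rand=200, seed=SEED)
    out["accumulation_mean"] = mean_curve.tolist()

    asn = pd.read_csv(RESULTS / "host_assignments.tsv", sep="\t")
    virus_lineage = dict(zip(asn["viral_population_id"], asn["lineage"]))
    lineages = pd.read_csv(DATA / "host_lineages.tsv", sep="\t")
    host_lineage = dict(zip(lineages["bin_id"], lineages["lineage"]))
    v_sums = st.lineage_sums(votu, virus_lineage, level=2)
    h_sums = st.lineage_sums(hotu, host_lineage, level=2)
    ratios = st.virus_host_ratio(v_sums, h_sums)
    out["virus_host_ratios"] = [r.__dict__ for r in ratios]

    truth = json.loads((DATA / "truth.json").read_text())
    groups = truth["host_groups"]
    host_pred = st.metabolism_group_sums(hotu, groups).T
    out["pls"] = {}
    for resp in ("CH4_porewater", "d13C_CH4", "DOC"):
        usable = host_pred.loc[:, host_pred.std(axis=0) > 0]
        if usable.shape[1] == 0:
            continue
        ncomp = min(2, int(np.linalg.matrix_rank(usable.to_numpy())))
        model = st.pls_fit(usable, meta.loc[usable.index, resp].to_numpy(), ncomp)
        r, p = st.prediction_r(model)
        out["pls"][resp] = {"r": r, "p": p}

    io.write_json(out, RESULTS / "stats_summary.json")
    print(f"PERMANOVA pseudo-F = {out['permanova']['statistic']:.1f}, "
          f"p = {out['permanova']['p_value']:.4g}")
    print(f"ANOSIM R = {out['anosim']['statistic']:.3f}; "
          f"PERMDISP F = {out['permdisp']['statistic']:.2f}")
    print(f"Mantel (virus vs host) rho = {out['mantel_virus_host']['statistic']:.3f}")
    print(f"{len(ratios)} lineage virus/host ratios; "
          f"PLS r: " + ", ".join(f"{k}={v['r']:.2f}" for k, v in out["pls"].items()))


if __name__ == "__main__":
    main()
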