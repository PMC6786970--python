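"""Community ecology and geochemistry statistics.

Distance-based community comparisons (Bray-Curtis, PCoA, PERMANOVA, ANOSIM,
PERMDISP, Mantel), virus/host abundance summaries and ratios, accumulation
curves, multiple-testing helpers (Bonferroni, exact binomial pervasiveness)
and partial least squares (PLS) prediction of porewater geochemistry from
community abundances.

All permutation tests use the +1-corrected p-value
``(count of permuted statistics >= observed + 1) / (n_permutations + 1)``
and an explicit seed, so every p-value is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import binom, pearsonr, rankdata
from sklearn.cross_decomposition import PLSRegression


@dataclass(frozen=True)
class PermTestResult:
    statistic_name: str
    statistic: float
    n_permutations: int
    p_value: float
    seed: int


# ---------------------------------------------------------------------------
# Distances and ordination


def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples.

    ``matrix`` is entities x samples (the orientation the abundance tables
    use); the result is a symmetric samples x samples DataFrame in [0, 1].
    """
    x = matrix.to_numpy(dtype=float).T
    d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d)  # two all-zero samples: defined as 0 distance
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


def pcoa(dist: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates analysis by Gower double-centering.

    Eigendecomposition of -0.5 * J d^2 J; axes ordered by decreasing
    eigenvalue.  Negative eigenvalues (non-Euclidean distances) are reported
    as-is, with coordinates only for positive axes.
    """
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=dist.index, columns=cols), eigvals


def _check_groups(groups: np.ndarray) -> np.ndarray:
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    return groups


def _perm_pvalue(observed: float, permuted: np.ndarray) -> float:
    return (np.sum(permuted >= observed) + 1) / (len(permuted) + 1)


def permanova(
    dist: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0
) -> PermTestResult:
    """Permutational multivariate ANOVA (pseudo-F) on a distance matrix.

    Partitions the sum of squared distances into among- and within-group
    components; significance by random relabelling of samples.
    """
    groups = _check_groups(np.asarray(groups))
    d2 = dist.to_numpy(dtype=float) ** 2
    n = d2.shape[0]
    labels, inv = np.unique(groups, return_inverse=True)
    k = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(inv_labels: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(k):
            members = inv_labels == g
            ng = members.sum()
            ss_within += d2[np.ix_(members, members)].sum() / (2 * ng)
        ss_among = ss_total - ss_within
        return (ss_among / (k - 1)) / (ss_within / (n - k))

    observed = pseudo_f(inv)
    rng = np.random.default_rng(seed)
    permuted = np.array([pseudo_f(rng.permutation(inv)) for _ in range(n_perm)])
    return PermTestResult("pseudo-F", observed, n_perm, _perm_pvalue(observed, permuted), seed)


def anosim(
    dist: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0
) -> PermTestResult:
    """Analysis of similarities: R from rank dissimilarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; R near 1 means between-group dissimilarities dominate.
    """
    groups = _check_groups(np.asarray(groups))
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    ranks = rankdata(d[iu])
    m = len(ranks)
    _, inv = np.unique(groups, return_inverse=True)

    def r_stat(inv_labels: np.ndarray) -> float:
        within = inv_labels[iu[0]] == inv_labels[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    observed = r_stat(inv)
    rng = np.random.default_rng(seed)
    permuted = np.array([r_stat(rng.permutation(inv)) for _ in range(n_perm)])
    return PermTestResult("ANOSIM R", observed, n_perm, _perm_pvalue(observed, permuted), seed)


def permdisp(
    dist: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0
) -> PermTestResult:
    """Homogeneity of multivariate dispersions.

    Each sample's distance to its group centroid is computed in PCoA space
    (negative-eigenvalue axes subtract, per Anderson's correction); the F
    statistic is a one-way ANOVA on those distances, with significance by
    permuting group labels of the distance-to-centroid values.
    """
    groups = _check_groups(np.asarray(groups))
    d = dist.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    pos = eigvals > 1e-10
    neg = eigvals < -1e-10
    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    labels, inv = np.unique(groups, return_inverse=True)
    z = np.empty(n)
    for g in range(len(labels)):
        members = inv == g
        cr = real[members].mean(axis=0)
        ci = imag[members].mean(axis=0) if imag.size else np.zeros(0)
        d2 = ((real[members] - cr) ** 2).sum(axis=1)
        if imag.size:
            d2 = d2 - ((imag[members] - ci) ** 2).sum(axis=1)
        z[members] = np.sqrt(np.maximum(d2, 0.0))

    def anova_f(inv_labels: np.ndarray) -> float:
        grand = z.mean()
        ss_b = ss_w = 0.0
        for g in range(len(labels)):
            zg = z[inv_labels == g]
            ss_b += len(zg) * (zg.mean() - grand) ** 2
            ss_w += ((zg - zg.mean()) ** 2).sum()
        return (ss_b / (len(labels) - 1)) / (ss_w / (n - len(labels)))

    observed = anova_f(inv)
    rng = np.random.default_rng(seed)
    permuted = np.array([anova_f(rng.permutation(inv)) for _ in range(n_perm)])
    return PermTestResult("PERMDISP F", observed, n_perm, _perm_pvalue(observed, permuted), seed)


def mantel_spearman(
    d1: pd.DataFrame, d2: pd.DataFrame, n_perm: int = 999, seed: int = 0
) -> PermTestResult:
    """Mantel test with Spearman rank correlation of two distance matrices.

    Rows and columns of the second matrix are permuted jointly; one-sided
    (positive association) p-value.
    """
    a = d1.to_numpy(dtype=float)
    b = d2.to_numpy(dtype=float)
    if a.shape != b.shape:
        raise ValueError("distance matrices differ in shape")
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    ra = rankdata(a[iu])

    def spearman_r(mat: np.ndarray) -> float:
        rb = rankdata(mat[iu])
        return float(np.corrcoef(ra, rb)[0, 1])

    observed = spearman_r(b)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        p = rng.permutation(n)
        permuted[i] = spearman_r(b[np.ix_(p, p)])
    return PermTestResult(
        "Mantel rho", observed, n_perm, _perm_pvalue(observed, permuted), seed
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < 3:
        raise ValueError("fewer than 3 complete pairs")
    r, p = pearsonr(x[keep], y[keep])
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Habitat-specific regression with permutation interaction test


@dataclass(frozen=True)
class GroupRegression:
    group: str
    slope: float
    intercept: float
    adj_r2: float
    n: int


def _ols_rss(x: np.ndarray, y: np.ndarray, design: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)


def habitat_regression_anova(
    x, y, groups, n_perm: int = 999, seed: int = 0, min_group_n: int = 3
) -> tuple[list[GroupRegression], PermTestResult]:
    """Per-group linear fits plus a permutation test of slope heterogeneity.

    Fits y ~ x within each group (groups with fewer than ``min_group_n``
    points are excluded) and compares the pooled single-line model with the
    full interaction model (separate slope and intercept per group):
    F = ((RSS_pooled - RSS_inter) / ddf) / (RSS_inter / df_resid),
    with significance from permuting group labels.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    keep_groups = [g for g in np.unique(groups) if np.sum(groups == g) >= min_group_n]
    if len(keep_groups) < 2:
        raise ValueError("need >=2 groups with enough data")
    mask = np.isin(groups, keep_groups)
    x, y, groups = x[mask], y[mask], groups[mask]
    n = len(x)

    fits: list[GroupRegression] = []
    for g in keep_groups:
        sel = groups == g
        xg, yg = x[sel], y[sel]
        design = np.column_stack([np.ones(sel.sum()), xg])
        beta, *_ = np.linalg.lstsq(design, yg, rcond=None)
        resid = yg - design @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yg - yg.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        adj = 1.0 - (1.0 - r2) * (sel.sum() - 1) / max(sel.sum() - 2, 1)
        fits.append(GroupRegression(str(g), float(beta[1]), float(beta[0]), adj, int(sel.sum())))

    _, inv = np.unique(groups, return_inverse=True)
    k = len(keep_groups)
    pooled = np.column_stack([np.ones(n), x])
    rss_pooled = _ols_rss(x, y, pooled)

    def interaction_f(inv_labels: np.ndarray) -> float:
        cols = [np.ones(n), x]
        for g in range(1, k):
            ind = (inv_labels == g).astype(float)
            cols += [ind, ind * x]
        design = np.column_stack(cols)
        rss_full = _ols_rss(x, y, design)
        ddf = 2 * (k - 1)
        df_resid = n - 2 * k
        if rss_full <= 0 or df_resid <= 0:
            return np.inf
        return ((rss_pooled - rss_full) / ddf) / (rss_full / df_resid)

    observed = interaction_f(inv)
    rng = np.random.default_rng(seed)
    permuted = np.array([interaction_f(rng.permutation(inv)) for _ in range(n_perm)])
    result = PermTestResult(
        "interaction F", observed, n_perm, _perm_pvalue(observed, permuted), seed
    )
    return fits, result


# ---------------------------------------------------------------------------
# Richness, ratios and group sums


def accumulation_curve(
    incidence: pd.DataFrame, n_rand: int = 200, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Entity accumulation over randomized sample orderings.

    ``incidence`` is entities x samples (nonzero = detected).  Returns
    ``(mean_curve, traces)`` where ``traces`` is n_rand x n_samples and the
    mean curve averages cumulative richness at each sample count.
    """
    present = incidence.to_numpy() > 0
    n_samples = present.shape[1]
    rng = np.random.default_rng(seed)
    traces = np.empty((n_rand, n_samples), dtype=float)
    for r in range(n_rand):
        order = rng.permutation(n_samples)
        seen = np.zeros(present.shape[0], dtype=bool)
        for pos, s in enumerate(order):
            seen |= present[:, s]
            traces[r, pos] = seen.sum()
    return traces.mean(axis=0), traces


def lineage_key(lineage: str, level: int) -> str | None:
    """Rank-``level`` prefix of a 7-rank lineage (None if unresolved that deep).

    Falls back to the deepest resolved rank above ``level`` when the target
    rank is empty (class-level sums fall back to phylum, etc.).
    """
    ranks = [r.strip() for r in lineage.split(";")]
    ranks = ranks[: level + 1]
    while ranks and not ranks[-1]:
        ranks.pop()
    if not ranks:
        return None
    return ";".join(ranks)


def lineage_sums(
    abundance: pd.DataFrame,
    entity_lineages: dict[str, str],
    level: int = 2,
) -> pd.DataFrame:
    """Sum an entities x samples table by lineage at the given rank level
    (0=domain ... 2=class).  Entities without a resolved lineage are dropped."""
    keys = {
        e: lineage_key(entity_lineages[e], level)
        for e in abundance.index
        if e in entity_lineages
    }
    rows: dict[str, np.ndarray] = {}
    for entity, key in keys.items():
        if key is None:
            continue
        vec = abundance.loc[entity].to_numpy(dtype=float)
        rows[key] = rows.get(key, 0.0) + vec
    return pd.DataFrame(rows, index=abundance.columns).T.sort_index()


@dataclass(frozen=True)
class RatioRecord:
    lineage: str
    mean_ratio: float
    sd_ratio: float
    n_samples: int


def virus_host_ratio(v_sums: pd.DataFrame, h_sums: pd.DataFrame) -> list[RatioRecord]:
    """Per-lineage virus/host abundance ratios across samples.

    The ratio is taken per sample and only where the host sum is positive;
    the mean and (sample, ddof=1) standard deviation are over those samples.
    Lineages never co-observed are skipped.
    """
    records = []
    for lineage in sorted(set(v_sums.index) & set(h_sums.index)):
        v = v_sums.loc[lineage].to_numpy(dtype=float)
        h = h_sums.loc[lineage].to_numpy(dtype=float)
        ok = h > 0
        if not ok.any():
            continue
        ratios = v[ok] / h[ok]
        sd = float(np.std(ratios, ddof=1)) if ok.sum() > 1 else 0.0
        records.append(RatioRecord(lineage, float(ratios.mean()), sd, int(ok.sum())))
    return records


def metabolism_group_sums(
    abundance: pd.DataFrame,
    groups: dict[str, list[str]],
) -> pd.DataFrame:
    """Sum abundances over metabolism-defined entity groups.

    ``groups`` maps group name -> entity ids (an entity may appear in several
    groups and is counted in each); missing entities contribute zero.
    """
    out = {}
    for name in sorted(groups):
        members = [e for e in groups[name] if e in abundance.index]
        if members:
            out[name] = abundance.loc[members].sum(axis=0).to_numpy(dtype=float)
        else:
            out[name] = np.zeros(abundance.shape[1])
    return pd.DataFrame(out, index=abundance.columns).T


# ---------------------------------------------------------------------------
# Multiple testing


def binomial_pervasiveness(k_observed: int, n_tests: int, alpha: float = 0.05) -> float:
    """Exact binomial upper tail P(X >= k) for k significant tests out of n
    at level alpha: are there more significant correlations than the false
    positives expected under a global null?"""
    if not 0 <= k_observed <= n_tests:
        raise ValueError("k must be in [0, n]")
    if k_observed == 0:
        return 1.0
    return float(binom.sf(k_observed - 1, n_tests, alpha))


def bonferroni_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected per-test significance threshold alpha / n."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# Partial least squares


@dataclass
class PlsModel:
    n_components: int
    x_columns: list[str]
    x_weights: np.ndarray
    x_scores: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coefficients: np.ndarray
    fitted: np.ndarray
    y: np.ndarray
    _estimator: PLSRegression


def pls_fit(X: pd.DataFrame, y, n_components: int = 2) -> PlsModel:
    """Fit a PLS regression (NIPALS) of one response on many predictors.

    Predictors are centered and unit-scaled; constant columns are dropped;
    rows with a missing response are removed.  ``n_components`` may not
    exceed the predictor matrix rank.
    """
    y = np.asarray(y, dtype=float)
    keep_rows = ~np.isnan(y)
    X = X.loc[keep_rows]
    y = y[keep_rows]
    keep_cols = X.std(axis=0) > 0
    X = X.loc[:, keep_cols]
    rank = np.linalg.matrix_rank(X.to_numpy() - X.to_numpy().mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds X rank {rank}")
    est = PLSRegression(n_components=n_components, scale=True)
    est.fit(X.to_numpy(), y)
    fitted = est.predict(X.to_numpy()).ravel()
    return PlsModel(
        n_components=n_components,
        x_columns=list(X.columns),
        x_weights=est.x_weights_,
        x_scores=est.x_scores_,
        x_loadings=est.x_loadings_,
        y_loadings=est.y_loadings_,
        coefficients=est.coef_.ravel(),
        fitted=fitted,
        y=y,
        _estimator=est,
    )


def pls_predict(model: PlsModel, X: pd.DataFrame) -> np.ndarray:
    return model._estimator.predict(X[model.x_columns].to_numpy()).ravel()


def prediction_r(model: PlsModel) -> tuple[float, float]:
    """Pearson r (and p) between fitted and observed responses."""
    return pearson(model.fitted, model.y)
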