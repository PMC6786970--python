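"""Coverage-based abundance profiling from read-alignment records.

The chain mirrors the standard metagenomic read-mapping workflow: alignments
are filtered (>=95% identity over >=90% of the read), per-base depth vectors
are accumulated, detection requires breadth >=70% of the contig, the depth
summary is a truncated mean (drop the top and bottom 10% coverage positions),
and per-sample coverages are normalized by sequencing effort so that each
sample is scaled to the all-samples average read total.  Host genome bins use
the same machinery with a 75% read-fraction filter, length-weighted averaging
over contigs and a 0.25x detection floor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AbundanceMatrix:
    """Entities x samples coverage table with one-shot transform flags."""

    data: pd.DataFrame  # index: entity ids, columns: sample ids
    normalized: bool = False
    sqrt_transformed: bool = False

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(self.data.copy(), self.normalized, self.sqrt_transformed)


def filter_alignments(
    records: pd.DataFrame,
    min_identity: float = 95.0,
    min_read_fraction: float = 0.90,
) -> pd.DataFrame:
    """Keep alignments with identity >= ``min_identity`` (percent) covering
    >= ``min_read_fraction`` of the read.  Both boundaries inclusive; row
    order preserved; idempotent."""
    frac = records["aligned_len"] / records["read_len"]
    mask = (records["pct_identity"] >= min_identity) & (frac >= min_read_fraction)
    return records.loc[mask]


def depth_vector(records: pd.DataFrame, target_len: int) -> np.ndarray:
    """Per-position depth (1-based inclusive record coordinates).

    ``depth[i]`` counts the records overlapping position ``i+1``; computed
    with a difference array so it stays linear in target length.
    """
    depth_delta = np.zeros(target_len + 1, dtype=np.int64)
    if len(records):
        starts = records["target_start"].to_numpy(dtype=np.int64) - 1
        ends = records["target_end"].to_numpy(dtype=np.int64)
        if starts.min() < 0 or ends.max() > target_len:
            raise ValueError("alignment coordinates outside target")
        np.add.at(depth_delta, starts, 1)
        np.add.at(depth_delta, ends, -1)
    return np.cumsum(depth_delta[:-1])


def breadth(depth: np.ndarray) -> float:
    """Fraction of positions covered by at least one read."""
    if len(depth) == 0:
        return 0.0
    return float(np.count_nonzero(depth) / len(depth))


def tpmean(depth: np.ndarray, trim: float = 0.10) -> float:
    """Truncated mean depth: drop the floor(trim*L) lowest- and highest-
    coverage positions, then average the rest.

    Robust to anomalously low- or high-coverage regions (e.g. conserved
    repeats or absent islands).  For L < 1/trim nothing is trimmed.
    """
    depth = np.asarray(depth)
    if depth.size == 0:
        raise ValueError("empty depth vector")
    k = math.floor(trim * depth.size)
    ordered = np.sort(depth, kind="stable")
    trimmed = ordered[k : depth.size - k] if k else ordered
    return float(np.mean(trimmed))


def contig_coverage(
    records: pd.DataFrame,
    target_len: int,
    min_breadth: float = 0.70,
    trim: float = 0.10,
) -> float:
    """tpmean coverage of one contig, zeroed when breadth < ``min_breadth``.

    The breadth gate guards against spurious detection driven by reads piling
    on a small region of an otherwise absent contig.
    """
    depth = depth_vector(records, target_len)
    if breadth(depth) < min_breadth:
        return 0.0
    return tpmean(depth, trim=trim)


def coverage_table(
    records: pd.DataFrame,
    target_lengths: dict[str, int],
    sample_ids: list[str] | None = None,
    min_identity: float = 95.0,
    min_read_fraction: float = 0.90,
    min_breadth: float = 0.70,
) -> AbundanceMatrix:
    """Filtered, breadth-gated tpmean coverage for every (target, sample).

    Targets with no passing alignments get coverage 0.  ``sample_ids`` fixes
    the column set (otherwise the samples present in ``records`` are used).
    """
    kept = filter_alignments(records, min_identity, min_read_fraction)
    if sample_ids is None:
        sample_ids = sorted(kept["sample_id"].unique())
    targets = sorted(target_lengths)
    mat = pd.DataFrame(0.0, index=targets, columns=sample_ids)
    for (target, sample), group in kept.groupby(["target_id", "sample_id"], sort=False):
        if target in target_lengths and sample in mat.columns:
            mat.loc[target, sample] = contig_coverage(
                group, target_lengths[target], min_breadth=min_breadth
            )
    return AbundanceMatrix(mat)


def normalize_by_reads(
    matrix: AbundanceMatrix, per_sample_read_totals: dict[str, float]
) -> AbundanceMatrix:
    """Scale each sample by mean(all totals) / its read total.

    A sample with twice the across-sample average read total is multiplied
    by 0.5, bringing every sample to a common sequencing effort.  Refuses to
    normalize twice.
    """
    if matrix.normalized:
        raise ValueError("matrix already normalized")
    totals = np.array([per_sample_read_totals[s] for s in matrix.data.columns], float)
    multipliers = totals.mean() / totals
    out = matrix.data * multipliers
    return AbundanceMatrix(out, normalized=True, sqrt_transformed=matrix.sqrt_transformed)


def sqrt_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Elementwise square root (variance-stabilizing); refuses double application."""
    if matrix.sqrt_transformed:
        raise ValueError("matrix already square-root transformed")
    return AbundanceMatrix(np.sqrt(matrix.data), matrix.normalized, True)


def host_genome_coverage(
    records: pd.DataFrame,
    contig_lengths: dict[str, int],
    min_identity: float = 95.0,
    min_read_fraction: float = 0.75,
    min_cov: float = 0.25,
    trim: float = 0.10,
) -> float:
    """Length-weighted mean tpmean coverage over a bin's contigs in one sample.

    Per-contig coverages (no breadth gate on the host side) are combined as
    sum(len_i * cov_i) / sum(len_i); values below ``min_cov`` are zeroed.
    """
    kept = filter_alignments(records, min_identity, min_read_fraction)
    total_len = 0
    weighted = 0.0
    for contig_id, length in contig_lengths.items():
        sub = kept.loc[kept["target_id"] == contig_id]
        depth = depth_vector(sub, length)
        weighted += length * tpmean(depth, trim=trim)
        total_len += length
    if total_len == 0:
        raise ValueError("bin has no contigs")
    cov = weighted / total_len
    return cov if cov >= min_cov else 0.0


def host_coverage_table(
    records: pd.DataFrame,
    bins: dict[str, dict[str, int]],
    sample_ids: list[str],
    min_identity: float = 95.0,
    min_read_fraction: float = 0.75,
    min_cov: float = 0.25,
) -> AbundanceMatrix:
    """Bin x sample coverage table for host genome bins."""
    mat = pd.DataFrame(0.0, index=sorted(bins), columns=sample_ids)
    contig_to_bin = {c: b for b, contigs in bins.items() for c in contigs}
    records = records.loc[records["target_id"].map(contig_to_bin).notna()]
    for (sample,), group in records.groupby(["sample_id"], sort=False):
        if sample not in mat.columns:
            continue
        for bin_id, contigs in bins.items():
            sub = group.loc[group["target_id"].isin(contigs)]
            if len(sub):
                mat.loc[bin_id, sample] = host_genome_coverage(
                    sub, contigs, min_identity, min_read_fraction, min_cov
                )
    return AbundanceMatrix(mat)
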