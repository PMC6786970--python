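"""Gene-level coverage, metatranscriptome activity detection, and the
auxiliary metabolic gene (AMG) genomic-context screen.

A viral population counts as transcriptionally detected in a sample only if
reads map to at least one gene per 10 kb of its genome (a 20-kb population
needs two positive genes); coverages of undetected populations are zeroed.
Candidate AMGs (glycoside hydrolases on viral contigs) are screened by their
genomic context: bona fide viral carriage requires hallmark viral genes
around the AMG and no other microbial metabolic genes on the contig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import GffGene

VIRAL_HALLMARK = "viral_hallmark"
MICROBIAL_METABOLIC = "microbial_metabolic"
GLYCOSIDE_HYDROLASE = "glycoside_hydrolase"


@dataclass(frozen=True)
class ActivityCall:
    population_id: str
    sample_id: str
    detected: bool
    genes_positive: int
    genes_required: int


def gene_mean_coverage(depth: np.ndarray, gene: GffGene) -> float:
    """Arithmetic mean depth over the gene interval (1-based inclusive)."""
    if gene.start < 1 or gene.end > len(depth) or gene.start > gene.end:
        raise ValueError(f"gene {gene.gene_id} outside depth vector")
    return float(np.mean(depth[gene.start - 1 : gene.end]))


def genes_required_for_detection(total_len_bp: int, window: int = 10_000) -> int:
    """Number of transcribed genes required to call a population active.

    One gene per started 10-kb window of genome, never fewer than one
    (ceiling rule; a 20-kb sequence needs two positive genes).
    """
    if total_len_bp <= 0:
        raise ValueError("population length must be positive")
    return max(1, math.ceil(total_len_bp / window))


def detect_active(
    population_id: str,
    sample_id: str,
    gene_coverages: dict[str, float],
    population_len: int,
) -> ActivityCall:
    """Activity call from per-gene mean transcript coverages."""
    if not gene_coverages:
        raise ValueError(f"population {population_id} has no annotated genes")
    required = genes_required_for_detection(population_len)
    positive = sum(1 for c in gene_coverages.values() if c > 0)
    return ActivityCall(population_id, sample_id, positive >= required, positive, required)


def zero_below_detection(rna_matrix, calls: list[ActivityCall]):
    """Zero RNA coverage of population/sample pairs that failed detection.

    Accepts and returns an :class:`~soilvirome.abundance.AbundanceMatrix`;
    never increases any entry.
    """
    out = rna_matrix.copy()
    for call in calls:
        if not call.detected and call.population_id in out.data.index:
            if call.sample_id in out.data.columns:
                out.data.loc[call.population_id, call.sample_id] = 0.0
    return out


def amg_context_screen(
    genes_on_contig: list[GffGene],
    target_gene: GffGene,
    is_provirus_contig: bool = False,
) -> str:
    """Confidence of viral carriage for a glycoside hydrolase gene.

    ``excluded``: the contig is proviral, or any other microbial metabolic
    gene occurs anywhere on it (possible host contamination).
    ``high``: at least one viral hallmark gene strictly upstream AND one
    strictly downstream of the target (contig coordinates, strand-agnostic).
    ``medium``: otherwise.
    """
    if target_gene.category != GLYCOSIDE_HYDROLASE:
        raise ValueError("target gene is not a glycoside hydrolase")
    if not any(
        g.gene_id == target_gene.gene_id and g.contig_id == target_gene.contig_id
        for g in genes_on_contig
    ):
        raise ValueError("target gene not on the supplied contig")
    if is_provirus_contig:
        return "excluded"
    others = [g for g in genes_on_contig if g.gene_id != target_gene.gene_id]
    if any(g.category == MICROBIAL_METABOLIC for g in others):
        return "excluded"
    upstream = any(
        g.category == VIRAL_HALLMARK and g.end < target_gene.start for g in others
    )
    downstream = any(
        g.category == VIRAL_HALLMARK and g.start > target_gene.end for g in others
    )
    return "high" if upstream and downstream else "medium"
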