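"""Virus-host prediction from CRISPR spacers, nucleotide composition and
shared genomic regions, resolved by evidence priority.

Three independent signals are combined:

1. CRISPR protospacers — a host CRISPR spacer occurring in a viral contig
   with at most one mismatch; finding the protospacer-adjacent motif (PAM)
   on the 3' flank upgrades the link.  The array's repeat sequence, matched
   exactly against host genomes, ties the array (and hence its spacers) to
   a host bin.
2. Tetranucleotide frequency (TNF) — viral and host 4-mer composition
   vectors; the nearest host is a putative host when the mean absolute
   component difference is at most 1e-3.
3. Shared genomic regions — alignments >=2,500 bp at >=70% identity
   (bit score >=50, E <= 1e-3 when supplied externally); a hit covering
   >=90% of a host-bin contig marks a co-binned virus, otherwise a putative
   provirus.

Evidence tiers, most to least confident: (1) CRISPR + PAM, (2) CRISPR,
(3) provirus, (4) co-binned, (5) TNF.  When one virus has several hosts in
its best tier, the assignment falls back to the last common ancestor of the
candidate lineages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TIER_CRISPR_PAM = 1
TIER_CRISPR = 2
TIER_PROVIRUS = 3
TIER_COBINNED = 4
TIER_TNF = 5


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CrisprArray:
    array_id: str
    repeat_seq: str
    spacers: tuple[str, ...]
    source: str  # host bin id or sample id

    def __post_init__(self):
        if not self.spacers:
            raise ValueError("CRISPR array without spacers")
        if len(self.repeat_seq) < 15:
            raise ValueError("CRISPR repeat implausibly short (<15 bp)")


@dataclass(frozen=True)
class SpacerMatch:
    spacer: str
    viral_contig_id: str
    position: int  # 1-based start on the forward strand
    strand: str  # "+" or "-"
    mismatches: int
    pam_found: bool = False


@dataclass(frozen=True)
class SharedRegionHit:
    viral_contig_id: str
    host_contig_id: str
    length: int
    pct_identity: float
    bit_score: float
    e_value: float
    fraction_of_host_contig: float


@dataclass(frozen=True)
class LinkEvidence:
    viral_population_id: str
    host_bin_id: str
    tier: int
    detail: str = ""


@dataclass(frozen=True)
class HostAssignment:
    viral_population_id: str
    lineage: str
    tier: int
    n_evidence: int


# ---------------------------------------------------------------------------
# CRISPR evidence


def _hamming_scan(spacer: str, contig: str, max_mismatch: int) -> list[tuple[int, int]]:
    """All 0-based offsets where the spacer matches with <= max_mismatch."""
    s = np.frombuffer(spacer.encode(), dtype=np.uint8)
    c = np.frombuffer(contig.encode(), dtype=np.uint8)
    if len(c) < len(s):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(c, len(s))
    mism = np.count_nonzero(windows != s, axis=1)
    hits = np.nonzero(mism <= max_mismatch)[0]
    return [(int(i), int(mism[i])) for i in hits]


def find_protospacers(
    spacer: str,
    viral_contig_id: str,
    contig_seq: str,
    max_mismatch: int = 1,
    min_spacer_len: int = 20,
) -> list[SpacerMatch]:
    """Scan both strands of a viral contig for a CRISPR spacer.

    Reports every position with at most ``max_mismatch`` mismatches
    (Hamming distance, no indels).  A spacer longer than the contig simply
    yields no matches.  Spacers below ``min_spacer_len`` are rejected: for
    very short words chance matches swamp the signal.
    """
    spacer = spacer.upper()
    if len(spacer) < min_spacer_len:
        raise ValueError(f"spacer shorter than {min_spacer_len} bp")
    matches = [
        SpacerMatch(spacer, viral_contig_id, pos + 1, "+", mm)
        for pos, mm in _hamming_scan(spacer, contig_seq, max_mismatch)
    ]
    rc = reverse_complement(spacer)
    matches += [
        SpacerMatch(spacer, viral_contig_id, pos + 1, "-", mm)
        for pos, mm in _hamming_scan(rc, contig_seq, max_mismatch)
    ]
    return sorted(matches, key=lambda m: (m.position, m.strand))


def check_pam(match: SpacerMatch, contig_seq: str, motif: str, spacer_len: int) -> bool:
    """True iff ``motif`` lies immediately 3' of the protospacer on the match strand.

    On "+" the motif must follow the protospacer on the forward strand; on
    "-" the protospacer is the reverse complement, so its 3' flank is the
    reverse complement of the bases immediately preceding the match on the
    forward strand.
    """
    motif = motif.upper()
    start0 = match.position - 1
    if match.strand == "+":
        flank = contig_seq[start0 + spacer_len : start0 + spacer_len + len(motif)]
        return flank == motif
    flank = contig_seq[max(0, start0 - len(motif)) : start0]
    return reverse_complement(flank) == motif


def link_repeat_to_host(repeat: str, host_genomes: dict[str, dict[str, str]]) -> list[str]:
    """Host bins whose genome carries the CRISPR repeat exactly (either strand).

    100% identity over the full repeat is required; returns the (possibly
    empty, possibly ambiguous) sorted list of bin ids.
    """
    repeat = repeat.upper()
    rc = reverse_complement(repeat)
    hits = []
    for bin_id, contigs in host_genomes.items():
        for seq in contigs.values():
            if repeat in seq or rc in seq:
                hits.append(bin_id)
                break
    return sorted(hits)


# ---------------------------------------------------------------------------
# Tetranucleotide frequency evidence

_TNF_KMERS = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
_TNF_INDEX = {k: i for i, k in enumerate(_TNF_KMERS)}
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def tnf_vector(sequence: str) -> np.ndarray:
    """256-component tetranucleotide frequency vector (forward strand,
    lexicographic 4-mer order, L1-normalized; windows containing N skipped)."""
    seq = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    codes = _CODE[seq]
    n = len(codes) - 3
    if n <= 0:
        raise ValueError("sequence shorter than 4 bp")
    idx = codes[:n] * 64 + codes[1 : n + 1] * 16 + codes[2 : n + 2] * 4 + codes[3 : n + 3]
    valid = (
        (codes[:n] >= 0)
        & (codes[1 : n + 1] >= 0)
        & (codes[2 : n + 2] >= 0)
        & (codes[3 : n + 3] >= 0)
    )
    counts = np.bincount(idx[valid], minlength=256).astype(float)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid 4-mer windows")
    return counts / total


def tnf_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Mean absolute difference across the 256 4-mer frequencies."""
    return float(np.mean(np.abs(np.asarray(u) - np.asarray(v))))


def nearest_host_by_tnf(
    viral_seq_or_vector,
    host_signatures: dict[str, np.ndarray],
    threshold: float = 1e-3,
) -> str | None:
    """Best-matched host by TNF, or None when no host is within ``threshold``.

    Ties on distance break to the lexicographically smaller host id.
    """
    if isinstance(viral_seq_or_vector, str):
        v = tnf_vector(viral_seq_or_vector)
    else:
        v = np.asarray(viral_seq_or_vector)
    best_id, best_d = None, np.inf
    for host_id in sorted(host_signatures):
        d = tnf_distance(v, host_signatures[host_id])
        if d < best_d:
            best_id, best_d = host_id, d
    return best_id if best_d <= threshold else None


# ---------------------------------------------------------------------------
# Shared-region evidence


def filter_shared_hits(
    hits: list[SharedRegionHit],
    min_bit: float = 50.0,
    max_evalue: float = 1e-3,
    min_identity: float = 70.0,
    min_len: int = 2500,
) -> list[SharedRegionHit]:
    """Keep hits meeting the shared-region confidence thresholds."""
    return [
        h
        for h in hits
        if h.bit_score >= min_bit
        and h.e_value <= max_evalue
        and h.pct_identity >= min_identity
        and h.length >= min_len
    ]


def classify_shared_region(hit: SharedRegionHit, cobinned_fraction: float = 0.90) -> str:
    """``cobinned_link`` when the hit covers >= 90% of the host contig
    (the whole contig was likely binned with the host), else
    ``provirus_link`` (integrated or carried viral region)."""
    return (
        "cobinned_link"
        if hit.fraction_of_host_contig >= cobinned_fraction
        else "provirus_link"
    )


def find_shared_regions(
    viral_seq: str,
    viral_id: str,
    host_contigs: dict[str, str],
    seed_len: int = 64,
    min_len: int = 2500,
    min_identity: float = 70.0,
) -> list[SharedRegionHit]:
    """Discover shared regions internally by exact-seed gap-free extension.

    Exact ``seed_len``-mers shared between virus and host anchor diagonals;
    runs on the same diagonal are merged and the merged span scored
    base-by-base.  Any internal hit passing the length and identity
    thresholds exceeds bit score 50 by construction, so the bit/E-value
    filters are satisfied implicitly.
    """
    hits: list[SharedRegionHit] = []
    index: dict[str, int] = {}
    for i in range(0, len(viral_seq) - seed_len + 1):
        index.setdefault(viral_seq[i : i + seed_len], i)
    for host_contig_id, host_seq in host_contigs.items():
        diags: dict[int, list[int]] = {}
        for j in range(0, len(host_seq) - seed_len + 1, seed_len // 2):
            i = index.get(host_seq[j : j + seed_len])
            if i is not None:
                diags.setdefault(i - j, []).append(j)
        for diag, seeds in diags.items():
            j0, j1 = min(seeds), max(seeds) + seed_len
            # gap-free extension outwards while identity holds locally
            j0, j1 = _extend(viral_seq, host_seq, diag, j0, j1)
            span = j1 - j0
            if span < min_len:
                continue
            a = viral_seq[diag + j0 : diag + j1]
            b = host_seq[j0:j1]
            matches = sum(x == y for x, y in zip(a, b))
            identity = 100.0 * matches / span
            if identity < min_identity:
                continue
            hits.append(
                SharedRegionHit(
                    viral_contig_id=viral_id,
                    host_contig_id=host_contig_id,
                    length=span,
                    pct_identity=identity,
                    bit_score=2.0 * matches,  # >>50 for any retained hit
                    e_value=0.0,
                    fraction_of_host_contig=span / len(host_seq),
                )
            )
    return hits


def _extend(a: str, b: str, diag: int, j0: int, j1: int, max_mismatch_run: int = 10):
    """Extend [j0, j1) on diagonal ``diag`` until a mismatch run ends it."""
    run = 0
    j = j0 - 1
    while j >= 0 and diag + j >= 0:
        run = run + 1 if a[diag + j] != b[j] else 0
        if run > max_mismatch_run:
            break
        j -= 1
    j0 = j + 1 + run
    run = 0
    j = j1
    while j < len(b) and diag + j < len(a):
        run = run + 1 if a[diag + j] != b[j] else 0
        if run > max_mismatch_run:
            break
        j += 1
    j1 = j - run
    return j0, j1


# ---------------------------------------------------------------------------
# Evidence gathering and resolution


def gather_evidence(
    viral_seqs: dict[str, str],
    host_genomes: dict[str, dict[str, str]],
    crispr_arrays: list[CrisprArray],
    pam_motif: str = "GG",
    shared_hits: dict[str, list[SharedRegionHit]] | None = None,
    host_contig_to_bin: dict[str, str] | None = None,
    tnf_threshold: float = 1e-3,
    max_mismatch: int = 1,
) -> list[LinkEvidence]:
    """Collect all virus-host link evidence across the three signals.

    ``shared_hits`` maps virus id -> externally supplied hits; when None,
    shared regions are discovered internally.  All evidence is retained
    (broad host ranges are real); :func:`resolve_host` collapses to one
    assignment per virus.
    """
    evidence: list[LinkEvidence] = []

    # CRISPR: spacer -> virus, repeat -> host
    for array in crispr_arrays:
        host_bins = link_repeat_to_host(array.repeat_seq, host_genomes)
        if not host_bins:
            continue
        for spacer in array.spacers:
            for vid, vseq in viral_seqs.items():
                for m in find_protospacers(spacer, vid, vseq, max_mismatch):
                    pam = check_pam(m, vseq, pam_motif, len(spacer))
                    tier = TIER_CRISPR_PAM if pam else TIER_CRISPR
                    for hb in host_bins:
                        evidence.append(
                            LinkEvidence(vid, hb, tier, f"spacer@{m.position}{m.strand}")
                        )

    # shared regions
    if host_contig_to_bin is None:
        host_contig_to_bin = {
            c: b for b, contigs in host_genomes.items() for c in contigs
        }
    for vid, vseq in viral_seqs.items():
        if shared_hits is not None:
            hits = filter_shared_hits(shared_hits.get(vid, []))
        else:
            all_contigs = {
                c: s for contigs in host_genomes.values() for c, s in contigs.items()
            }
            hits = filter_shared_hits(find_shared_regions(vseq, vid, all_contigs))
        for h in hits:
            kind = classify_shared_region(h)
            tier = TIER_COBINNED if kind == "cobinned_link" else TIER_PROVIRUS
            evidence.append(
                LinkEvidence(vid, host_contig_to_bin[h.host_contig_id], tier, kind)
            )

    # TNF
    host_sigs = {
        b: tnf_vector("".join(contigs[c] for c in sorted(contigs)))
        for b, contigs in host_genomes.items()
    }
    for vid, vseq in viral_seqs.items():
        host = nearest_host_by_tnf(vseq, host_sigs, threshold=tnf_threshold)
        if host is not None:
            evidence.append(LinkEvidence(vid, host, TIER_TNF, "tnf_best_match"))

    return evidence


def lca(lineage_strings: list[str]) -> str:
    """Longest common rank prefix of semicolon-delimited lineages.

    Empty string when even the first rank (domain) differs.
    """
    if not lineage_strings:
        return ""
    split = [s.split(";") for s in lineage_strings]
    common: list[str] = []
    for ranks in zip(*split):
        if len(set(ranks)) == 1:
            common.append(ranks[0])
        else:
            break
    return ";".join(common)


def resolve_host(
    evidence: list[LinkEvidence], host_lineages: dict[str, str]
) -> HostAssignment | None:
    """Collapse one virus's evidence to a single host assignment.

    The lowest-numbered (most confident) tier present wins; several hosts in
    that tier resolve to the last common ancestor of their lineages.  The
    result is invariant to the order of the evidence list.
    """
    if not evidence:
        return None
    vids = {e.viral_population_id for e in evidence}
    if len(vids) != 1:
        raise ValueError("evidence list mixes viral populations")
    best_tier = min(e.tier for e in evidence)
    hosts = sorted({e.host_bin_id for e in evidence if e.tier == best_tier})
    if len(hosts) == 1:
        lineage = host_lineages[hosts[0]]
    else:
        lineage = lca([host_lineages[h] for h in hosts])
    return HostAssignment(vids.pop(), lineage, best_tier, len(evidence))


def resolve_all(
    evidence: list[LinkEvidence], host_lineages: dict[str, str]
) -> dict[str, HostAssignment]:
    """Resolve every virus present in the evidence list."""
    by_virus: dict[str, list[LinkEvidence]] = {}
    for e in evidence:
        by_virus.setdefault(e.viral_population_id, []).append(e)
    return {
        vid: resolve_host(evs, host_lineages) for vid, evs in sorted(by_virus.items())
    }
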