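"""Nucleosome-footprint TSS coverage and normalized correlation against
tissue expression references.

Pipeline for one sample:

1. reduce each read to its strand-aware 5' start;
2. extend 167 bp downstream (3') and keep the central 61 bp
   (1-based offsets 53-113 of the extension) as the "core window";
3. compute per-base depth of core windows;
4. divide depth by the per-100-kb copy ratio (bin count / genome-wide
   median bin count, clamped to [0.1, 10]) to remove CNV bias;
5. accumulate normalized depth over TSS +/- 1 kb per transcript and scale
   to RDPKM (read depth per kilobase per million mapped reads); genes
   average their transcripts;
6. drop genes with RDPKM < 100 or reference log2(mean FPKM) < 0.1, then
   correlate RDPKM with each reference's mean FPKM and normalize the
   Pearson coefficients to sum to 1 (NPCC).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from mcanary.io_formats import (
    AUTOSOMES,
    ExpressionReference,
    FragmentSet,
    PipelineConfig,
    TSSRecord,
)

logger = logging.getLogger("mcanary")

RATIO_CLAMP = (0.1, 10.0)


@dataclass(frozen=True)
class CoreWindow:
    """Central 61 bp of the 167-bp extension from a read's 5' start."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != 61:
            raise ValueError(f"core window must be 61 bp, got {self.end - self.start}")


@dataclass
class BinCopyRatio:
    """Per-100-kb fragment counts and copy ratios, one array per chromosome."""

    bin_size: int
    counts: dict[str, np.ndarray]
    ratios: dict[str, np.ndarray]
    median_count: float

    @property
    def log2_ratios(self) -> dict[str, np.ndarray]:
        return {c: np.log2(r) for c, r in self.ratios.items()}

    def ratio_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        idx = np.asarray(positions, dtype=np.int64) // self.bin_size
        return self.ratios[chrom][idx]


@dataclass
class RDPKMProfile:
    """Per-gene normalized TSS read depth for one sample."""

    rdpkm: dict[str, float]
    total_mapped_reads: int
    window_flank: int
    filtered_gene_set: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for g, v in self.rdpkm.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"RDPKM must be finite and >= 0: {g}={v!r}")
        if not self.filtered_gene_set <= set(self.rdpkm):
            raise ValueError("filtered_gene_set must be a subset of profiled genes")


@dataclass
class NPCCVector:
    """Raw and normalized Pearson correlations against each reference type."""

    r_raw: dict[str, float]
    npcc: dict[str, float]
    n_genes_used: int

    def __post_init__(self) -> None:
        total = sum(self.npcc.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"NPCC values must sum to 1, got {total!r}")


# ---------------------------------------------------------------------------
# Window geometry
# ---------------------------------------------------------------------------


def fragment_5prime_start(chrom_start: int, chrom_end: int, strand: str) -> int:
    """Strand-aware 5' start of a read in 0-based coordinates.

    Forward reads start at their leftmost base; reverse reads start at
    their rightmost base (leftmost + length - 1).
    """
    if strand == "+":
        return chrom_start
    return chrom_end - 1


def nucleosome_core_window(
    start5p: int, strand: str, chrom: str = "", config: PipelineConfig | None = None
) -> CoreWindow | None:
    """Core window from a 5' start, or None if it runs off the chromosome start.

    With the default geometry (167-bp extension, 1-based offsets 53-113) the
    forward window is [start5p+52, start5p+113) and the reverse window is
    its mirror image [start5p-112, start5p-51), both 61 bp.
    """
    cfg = config or PipelineConfig()
    lo = cfg.core_offset_start - 1  # 0-based offset of first core base
    hi = cfg.core_offset_end  # half-open end offset
    if strand == "+":
        start, end = start5p + lo, start5p + hi
    else:
        start, end = start5p - hi + 1, start5p - lo + 1
    if start < 0:
        return None
    return CoreWindow(chrom, start, end)


def core_windows_for_chrom(
    starts5p: np.ndarray, strands: np.ndarray, config: PipelineConfig | None = None
) -> tuple[np.ndarray, np.ndarray, int]:
    """Vectorized core windows; returns (starts, ends, n_dropped).

    Windows extending past the chromosome start are dropped.
    """
    cfg = config or PipelineConfig()
    lo = cfg.core_offset_start - 1
    hi = cfg.core_offset_end
    fwd = strands == "+"
    starts = np.where(fwd, starts5p + lo, starts5p - hi + 1)
    ends = np.where(fwd, starts5p + hi, starts5p - lo + 1)
    ok = starts >= 0
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.debug("dropped %d core windows off chromosome start", n_dropped)
    return starts[ok], ends[ok], n_dropped


def site_depth(
    window_starts: Sequence[int] | np.ndarray,
    window_ends: Sequence[int] | np.ndarray,
    region_start: int,
    region_end: int,
) -> np.ndarray:
    """Per-base depth over [region_start, region_end) via sweep-line.

    depth[p] counts windows covering position region_start + p. Windows are
    clipped to the region.
    """
    if region_end <= region_start:
        raise ValueError("empty region")
    length = region_end - region_start
    diff = np.zeros(length + 1, dtype=np.int64)
    s = np.clip(np.asarray(window_starts, dtype=np.int64) - region_start, 0, length)
    e = np.clip(np.asarray(window_ends, dtype=np.int64) - region_start, 0, length)
    keep = e > s
    np.add.at(diff, s[keep], 1)
    np.add.at(diff, e[keep], -1)
    return np.cumsum(diff[:-1])


# ---------------------------------------------------------------------------
# Copy-ratio normalization
# ---------------------------------------------------------------------------


def bin_copy_ratio(
    fragments: FragmentSet,
    genome: Mapping[str, int],
    bin_size: int = 100_000,
) -> BinCopyRatio:
    """Per-bin 5'-end counts and copy ratios.

    ratio = count / median(count over non-empty autosomal bins), clamped to
    [0.1, 10]. Raises if every bin is empty.
    """
    if len(fragments) == 0:
        raise ValueError("cannot bin an empty fragment set")
    counts: dict[str, np.ndarray] = {}
    for chrom, size in genome.items():
        n_bins = max(1, -(-size // bin_size))
        sub = fragments.for_chrom(chrom)
        c = np.zeros(n_bins, dtype=np.int64)
        if len(sub):
            starts5p = np.where(sub.strands == "+", sub.starts, sub.ends - 1)
            idx = np.clip(starts5p // bin_size, 0, n_bins - 1)
            np.add.at(c, idx, 1)
        counts[chrom] = c
    auto = np.concatenate(
        [counts[c] for c in genome if c in AUTOSOMES] or [np.array([], dtype=np.int64)]
    )
    nonempty = auto[auto > 0]
    if nonempty.size == 0:
        raise ValueError("all autosomal bins are empty")
    med = float(np.median(nonempty))
    ratios = {
        c: np.clip(k / med, RATIO_CLAMP[0], RATIO_CLAMP[1]) for c, k in counts.items()
    }
    return BinCopyRatio(bin_size, counts, ratios, med)


def cnv_normalize_depth(
    depth: np.ndarray, chrom: str, bins: BinCopyRatio, region_start: int = 0
) -> np.ndarray:
    """Divide per-base depth by the linear copy ratio of the containing bin."""
    positions = np.arange(region_start, region_start + len(depth))
    return depth / bins.ratio_at(chrom, positions)


# ---------------------------------------------------------------------------
# RDPKM and NPCC
# ---------------------------------------------------------------------------


def gene_rdpkm(
    normalized_depth: Mapping[str, np.ndarray],
    tss_records: Sequence[TSSRecord],
    total_mapped: int,
    flank: int = 1000,
) -> RDPKMProfile:
    """Accumulate normalized depth over TSS +/- flank per transcript and
    scale to RDPKM; genes average their transcripts.

    RDPKM = (sum of depth over the window) / (window_kb * total_mapped/1e6).
    Transcripts whose window leaves the chromosome are skipped and logged.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    window_kb = 2 * flank / 1000.0
    per_million = total_mapped / 1e6
    per_gene: dict[str, list[float]] = {}
    n_skipped = 0
    for rec in tss_records:
        arr = normalized_depth.get(rec.chrom)
        if arr is None:
            n_skipped += 1
            continue
        lo, hi = rec.tss - flank, rec.tss + flank
        if lo < 0 or hi > len(arr):
            n_skipped += 1
            continue
        acc = float(arr[lo:hi].sum())
        per_gene.setdefault(rec.gene_id, []).append(acc / (window_kb * per_million))
    if n_skipped:
        logger.debug("skipped %d transcripts with off-chromosome TSS windows", n_skipped)
    rdpkm = {g: float(np.mean(v)) for g, v in per_gene.items()}
    return RDPKMProfile(rdpkm, total_mapped, flank)


def filter_genes(
    profile: RDPKMProfile,
    refs: Mapping[str, ExpressionReference],
    rdpkm_min: float = 100.0,
    log2_fpkm_min: float = 0.1,
) -> set[str]:
    """Genes retained for correlation.

    A gene survives iff it is profiled, present in every reference, its
    RDPKM is not < rdpkm_min, and its log2(mean FPKM) is not < log2_fpkm_min
    in every reference (both removals use strict '<').
    """
    fpkm_min = 2.0**log2_fpkm_min
    retained = set()
    for g, v in profile.rdpkm.items():
        if v < rdpkm_min:
            continue
        if any(g not in r.mean_fpkm for r in refs.values()):
            continue
        if any(r.mean_fpkm[g] < fpkm_min for r in refs.values()):
            continue
        retained.add(g)
    if not retained:
        raise ValueError("no genes retained after filtering; correlation undefined")
    return retained


def compute_npcc(
    profile: RDPKMProfile,
    refs: Mapping[str, ExpressionReference],
    retained: set[str] | None = None,
    rdpkm_min: float = 100.0,
    log2_fpkm_min: float = 0.1,
) -> NPCCVector:
    """Pearson r between RDPKM and each reference's mean FPKM over retained
    genes, normalized so the coefficients sum to 1."""
    if retained is None:
        retained = filter_genes(profile, refs, rdpkm_min, log2_fpkm_min)
    genes = sorted(retained)
    if len(genes) < 3:
        raise ValueError(f"need >= 3 retained genes, got {len(genes)}")
    x = np.array([profile.rdpkm[g] for g in genes])
    if np.ptp(x) == 0:
        raise ValueError("RDPKM vector is constant; correlation undefined")
    r_raw = {}
    for t, ref in refs.items():
        y = np.array([ref.mean_fpkm[g] for g in genes])
        if np.ptp(y) == 0:
            raise ValueError(f"reference {t} is constant on retained genes")
        r_raw[t] = float(stats.pearsonr(x, y).statistic)
    total = sum(r_raw.values())
    if abs(total) < 1e-8:
        raise ValueError("NPCC undefined (coefficients cancel)")
    npcc = {t: r / total for t, r in r_raw.items()}
    profile.filtered_gene_set = retained
    return NPCCVector(r_raw, npcc, len(genes))


# ---------------------------------------------------------------------------
# End-to-end per-sample pipeline
# ---------------------------------------------------------------------------


def coverage_profile(
    fragments: FragmentSet,
    tss_records: Sequence[TSSRecord],
    genome: Mapping[str, int],
    config: PipelineConfig | None = None,
) -> RDPKMProfile:
    """Fragments -> CNV-normalized core-window depth -> per-gene RDPKM."""
    cfg = config or PipelineConfig()
    if len(fragments) == 0:
        raise ValueError("empty fragment set")
    bins = bin_copy_ratio(fragments, genome, bin_size=cfg.bin_size)
    normalized: dict[str, np.ndarray] = {}
    for chrom, size in genome.items():
        sub = fragments.for_chrom(chrom)
        if len(sub) == 0:
            normalized[chrom] = np.zeros(size)
            continue
        starts5p = np.where(sub.strands == "+", sub.starts, sub.ends - 1)
        ws, we, _ = core_windows_for_chrom(starts5p, sub.strands, cfg)
        depth = site_depth(ws, we, 0, size)
        normalized[chrom] = cnv_normalize_depth(depth.astype(float), chrom, bins)
    return gene_rdpkm(normalized, tss_records, len(fragments), flank=cfg.tss_flank)


def npcc_pipeline(
    fragments: FragmentSet,
    tss_records: Sequence[TSSRecord],
    refs: Mapping[str, ExpressionReference],
    genome: Mapping[str, int],
    config: PipelineConfig | None = None,
) -> tuple[RDPKMProfile, NPCCVector]:
    """Full per-sample pipeline: fragments -> RDPKM profile -> NPCC vector."""
    cfg = config or PipelineConfig()
    profile = coverage_profile(fragments, tss_records, genome, cfg)
    vec = compute_npcc(
        profile, refs, rdpkm_min=cfg.rdpkm_min, log2_fpkm_min=cfg.log2_fpkm_min
    )
    return profile, vec
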