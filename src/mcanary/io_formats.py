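"""Readers/writers for the external tables and genomic formats of the pipeline.

Internal coordinate convention is 0-based half-open everywhere. SAM input
(1-based) is converted at the boundary; BED is consumed as-is.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

logger = logging.getLogger("mcanary")

#: Canonical chromosome names, in canonical order.
CHROMOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")
AUTOSOMES: tuple[str, ...] = CHROMOSOMES[:22]

CHROM_ORDER: dict[str, int] = {c: i for i, c in enumerate(CHROMOSOMES)}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FragmentRecord:
    """One aligned cfDNA read in genome coordinates (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"fragment end must exceed start: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class FragmentSet:
    """Columnar collection of aligned fragments.

    Stores chrom / start / end / strand as parallel numpy arrays for fast
    per-chromosome slicing. ``genome`` optionally declares chromosome sizes;
    when given, fragments on undeclared chromosomes are dropped (counted in
    ``n_dropped``).
    """

    def __init__(
        self,
        chroms: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        strands: np.ndarray,
        genome: Mapping[str, int] | None = None,
        n_dropped: int = 0,
    ) -> None:
        self.chroms = np.asarray(chroms, dtype=object)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        self.strands = np.asarray(strands, dtype=object)
        self.genome = dict(genome) if genome is not None else None
        self.n_dropped = n_dropped
        n = len(self.chroms)
        if not (len(self.starts) == len(self.ends) == len(self.strands) == n):
            raise ValueError("fragment columns must have equal length")
        if n and np.any(self.ends <= self.starts):
            bad = int(np.argmax(self.ends <= self.starts))
            raise ValueError(f"fragment end <= start at index {bad}")

    @classmethod
    def from_records(
        cls, records: Iterable[FragmentRecord], genome: Mapping[str, int] | None = None
    ) -> "FragmentSet":
        recs = list(records)
        dropped = 0
        if genome is not None:
            kept = [r for r in recs if r.chrom in genome]
            dropped = len(recs) - len(kept)
            recs = kept
        return cls(
            np.array([r.chrom for r in recs], dtype=object),
            np.array([r.start for r in recs], dtype=np.int64),
            np.array([r.end for r in recs], dtype=np.int64),
            np.array([r.strand for r in recs], dtype=object),
            genome=genome,
            n_dropped=dropped,
        )

    def __len__(self) -> int:
        return len(self.chroms)

    def __iter__(self) -> Iterator[FragmentRecord]:
        for c, s, e, st in zip(self.chroms, self.starts, self.ends, self.strands):
            yield FragmentRecord(c, int(s), int(e), st)

    def for_chrom(self, chrom: str) -> "FragmentSet":
        mask = self.chroms == chrom
        return FragmentSet(
            self.chroms[mask],
            self.starts[mask],
            self.ends[mask],
            self.strands[mask],
            genome=self.genome,
        )

    def present_chroms(self) -> list[str]:
        seen = set(self.chroms.tolist())
        return [c for c in CHROMOSOMES if c in seen] + sorted(seen - set(CHROMOSOMES))


def read_fragments(
    path: str | Path,
    format: str = "bed",
    genome: Mapping[str, int] | None = None,
    strand_column: int = 5,
) -> FragmentSet:
    """Read aligned fragments from BED6 or SAM/BAM.

    Parameters
    ----------
    path:
        Input file.
    format:
        ``"bed"`` (0-based half-open; strand in ``strand_column``, default
        BED6 column 6) or ``"sam"`` / ``"bam"``.
    genome:
        Optional chromosome-size map; fragments on undeclared chromosomes
        are dropped and counted in the log.
    strand_column:
        0-based index of the strand column for BED dialects (default 5).

    Strand is required: the downstream 5'-end adjustment is strand-aware.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bed":
        records = _read_bed(path, strand_column)
    elif format in ("sam", "bam"):
        records = _read_sam(path)
    else:
        raise ValueError(f"unknown fragment format {format!r}")
    fs = FragmentSet.from_records(records, genome=genome)
    if fs.n_dropped:
        logger.warning("%s: dropped %d fragments on undeclared chromosomes", path, fs.n_dropped)
    if len(fs) == 0:
        logger.warning("%s: no fragments read", path)
    return fs


def _read_bed(path: Path, strand_column: int) -> list[FragmentRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) <= strand_column:
                raise FormatError(
                    f"{path}:{lineno}: expected strand in column {strand_column + 1}, "
                    f"got {len(fields)} columns"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable coordinates") from exc
            strand = fields[strand_column]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            try:
                records.append(FragmentRecord(chrom, start, end, strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def _read_sam(path: Path) -> list[FragmentRecord]:
    records = []
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_name is None:
                continue
            start = aln.reference_start  # pysam is already 0-based
            end = aln.reference_end
            if end is None:
                end = start + (aln.query_length or 1)
            strand = "-" if aln.is_reverse else "+"
            records.append(FragmentRecord(aln.reference_name, start, end, strand))
    return records


def write_fragments(fragments: FragmentSet, path: str | Path) -> None:
    """Write a FragmentSet as BED6 (name '.', score 0)."""
    with open(path, "w") as fh:
        for c, s, e, st in zip(
            fragments.chroms, fragments.starts, fragments.ends, fragments.strands
        ):
            fh.write(f"{c}\t{s}\t{e}\t.\t0\t{st}\n")


# ---------------------------------------------------------------------------
# TSS annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TSSRecord:
    """Transcription start site of one transcript."""

    gene_id: str
    transcript_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0: {self}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-': {self}")


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a TSS annotation TSV (gene_id, transcript_id, chrom, tss, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str})
    required = {"gene_id", "transcript_id", "chrom", "tss", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    keys = list(zip(df["gene_id"], df["transcript_id"]))
    if len(set(keys)) != len(keys):
        raise FormatError(f"{path}: duplicate (gene_id, transcript_id) pairs")
    return [
        TSSRecord(r.gene_id, r.transcript_id, r.chrom, int(r.tss), r.strand)
        for r in df.itertuples(index=False)
    ]


def write_tss_table(records: Iterable[TSSRecord], path: str | Path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows, columns=["gene_id", "transcript_id", "chrom", "tss", "strand"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Expression references
# ---------------------------------------------------------------------------


@dataclass
class ExpressionReference:
    """Mean-FPKM expression table of one cancer type."""

    cancer_type: str
    mean_fpkm: dict[str, float]

    def __post_init__(self) -> None:
        for gene, v in self.mean_fpkm.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(
                    f"{self.cancer_type}: mean FPKM must be finite and >= 0, "
                    f"got {v!r} for {gene}"
                )

    def genes(self) -> set[str]:
        return set(self.mean_fpkm)


def read_expression_reference(path: str | Path) -> dict[str, ExpressionReference]:
    """Read a TSV with gene_id plus one mean-FPKM column per cancer type."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing gene_id column")
    if df["gene_id"].duplicated().any():
        dups = df["gene_id"][df["gene_id"].duplicated()].tolist()
        raise FormatError(f"{path}: duplicated gene_id rows: {dups[:5]}")
    types = [c for c in df.columns if c != "gene_id"]
    if not types:
        raise FormatError(f"{path}: no cancer-type columns")
    refs = {}
    for t in types:
        col = pd.to_numeric(df[t], errors="coerce")
        if col.isna().any():
            bad = df["gene_id"][col.isna()].tolist()
            raise FormatError(f"{path}: non-numeric FPKM for {t} at genes {bad[:5]}")
        if (col < 0).any():
            raise FormatError(f"{path}: negative FPKM in column {t}")
        refs[t] = ExpressionReference(t, dict(zip(df["gene_id"], col.astype(float))))
    return refs


def write_expression_reference(
    refs: Mapping[str, ExpressionReference], path: str | Path
) -> None:
    genes = sorted(set().union(*(r.genes() for r in refs.values())))
    data = {"gene_id": genes}
    for t, ref in refs.items():
        data[t] = [ref.mean_fpkm.get(g, 0.0) for g in genes]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Z-score tables
# ---------------------------------------------------------------------------


def read_zscore_table(path: str | Path):
    """Read per-subject chromosome z-scores.

    TSV with ``subject_id`` plus columns chr1..chr22, chrX, chrY. chrY may
    be NA (female fetus) and is then recorded as absent.

    Returns a list of ``(subject_id, ChromosomeZScores)``.
    """
    from mcanary.zscore_engine import ChromosomeZScores

    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = ["subject_id"] + [c for c in CHROMOSOMES if c != "chrY"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        vals = {}
        for c in CHROMOSOMES:
            if c not in df.columns:
                continue
            v = getattr(row, c)
            if pd.isna(v):
                if c == "chrY":
                    continue
                raise FormatError(f"{path}: NA z-score for {c} in {row.subject_id}")
            vals[c] = float(v)
        out.append((row.subject_id, ChromosomeZScores(vals)))
    return out


def write_zscore_table(rows, path: str | Path) -> None:
    """Write ``(subject_id, ChromosomeZScores)`` pairs as a TSV (chrY NA when absent)."""
    recs = []
    for sid, z in rows:
        rec = {"subject_id": sid}
        for c in CHROMOSOMES:
            rec[c] = z.get(c, np.nan)
        recs.append(rec)
    pd.DataFrame(recs, columns=["subject_id", *CHROMOSOMES]).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


# ---------------------------------------------------------------------------
# PTM tables
# ---------------------------------------------------------------------------


def read_ptm_table(path: str | Path, markers: tuple[str, ...] | None = None):
    """Read a PTM CSV (subject_id + 7 marker columns) into PTMPanel objects."""
    from mcanary.ptm_panel import PTM_MARKERS, PTMPanel

    markers = markers or PTM_MARKERS
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [m for m in markers if m not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing marker columns {missing}")
    out = []
    for _, row in df.iterrows():
        conc = {m: float(row[m]) for m in markers}
        out.append((str(row["subject_id"]), PTMPanel(conc)))
    return out


def write_ptm_table(rows, path: str | Path) -> None:
    recs = []
    for sid, panel in rows:
        rec = {"subject_id": sid, **panel.concentrations}
        recs.append(rec)
    pd.DataFrame(recs).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


def _default_ptm_cutoffs() -> dict[str, float]:
    from mcanary.ptm_panel import DEFAULT_CUTOFFS

    return dict(DEFAULT_CUTOFFS)


@dataclass
class PipelineConfig:
    """All tunable thresholds and window parameters, defaulting to the
    published operating values."""

    # predictor
    mtop5_cutoff: float = 5.94
    mca_z_threshold: float = 3.0
    mtop5_excluded: tuple[str, ...] = ("chrY", "chr19")
    # TSS window geometry
    extension_length: int = 167
    core_offset_start: int = 53  # 1-based inclusive within the extension
    core_offset_end: int = 113
    tss_flank: int = 1000
    bin_size: int = 100_000
    # gene filters
    rdpkm_min: float = 100.0
    log2_fpkm_min: float = 0.1
    # random forest
    ntree: int = 500
    mtry: int = 5
    seed: int = 0
    # PTM cutoffs
    ptm_cutoffs: dict[str, float] = field(default_factory=_default_ptm_cutoffs)

    def __post_init__(self) -> None:
        for name in ("mtop5_cutoff", "mca_z_threshold", "rdpkm_min", "log2_fpkm_min"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.core_offset_end <= self.core_offset_start:
            raise ValueError("core window offsets out of order")

    @property
    def core_window_length(self) -> int:
        return self.core_offset_end - self.core_offset_start + 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "mtop5_excluded" in data:
            data["mtop5_excluded"] = tuple(data["mtop5_excluded"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["mtop5_excluded"] = list(self.mtop5_excluded)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
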