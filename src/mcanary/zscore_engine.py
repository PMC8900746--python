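"""Per-chromosome z-scores from binned fragment fractions, and the MCA rule.

z_c = (f_c - mu_c) / sigma_c, where f_c is the sample's fraction of
fragments on chromosome c and (mu_c, sigma_c) come from a reference panel
of unaffected samples. The multiple-chromosomal-aneuploidy (MCA) flag is
raised when at least two chromosomes have |z| strictly greater than 3.0.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mcanary.io_formats import CHROMOSOMES, FragmentSet, FormatError


@dataclass
class ChromosomeZScores:
    """Map chromosome -> z for one subject. chrY may be absent (female fetus)."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.values) - set(CHROMOSOMES)
        if unknown:
            raise ValueError(f"unknown chromosomes: {sorted(unknown)}")
        missing = [c for c in CHROMOSOMES if c != "chrY" and c not in self.values]
        if missing:
            raise ValueError(f"missing chromosomes: {missing}")
        for c, v in self.values.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite z for {c}: {v!r}")

    def __getitem__(self, chrom: str) -> float:
        return self.values[chrom]

    def get(self, chrom: str, default=None):
        return self.values.get(chrom, default)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.values

    def items(self):
        return ((c, self.values[c]) for c in CHROMOSOMES if c in self.values)

    def autosomes(self) -> np.ndarray:
        """z-scores of chr1..chr22 in canonical order."""
        return np.array([self.values[c] for c in CHROMOSOMES[:22]])


@dataclass
class ReferencePanel:
    """Per-chromosome mean/sd of fragment fractions across panel samples."""

    mean_fraction: dict[str, float]
    sd_fraction: dict[str, float]
    n_panel: int = 0

    def __post_init__(self) -> None:
        if set(self.mean_fraction) != set(self.sd_fraction):
            raise ValueError("panel mean/sd chromosome sets differ")
        for c, sd in self.sd_fraction.items():
            if not np.isfinite(sd) or sd <= 0:
                raise ValueError(f"panel sd must be > 0 for {c}, got {sd!r}")
        total = sum(self.mean_fraction.values())
        if not np.isclose(total, 1.0, atol=0.05):
            raise ValueError(f"panel mean fractions sum to {total:.4f}, expected ~1")

    @classmethod
    def from_samples(cls, fraction_maps: Iterable[Mapping[str, float]]) -> "ReferencePanel":
        """Estimate the panel from per-sample fraction maps (ddof=1)."""
        maps = list(fraction_maps)
        if len(maps) < 2:
            raise ValueError("panel needs >= 2 samples")
        chroms = [c for c in CHROMOSOMES if all(c in m for m in maps)]
        mean = {}
        sd = {}
        for c in chroms:
            col = np.array([m[c] for m in maps])
            mean[c] = float(col.mean())
            sd[c] = float(col.std(ddof=1))
        return cls(mean, sd, n_panel=len(maps))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReferencePanel":
        df = pd.read_csv(path, sep="\t")
        required = {"chrom", "mean_fraction", "sd_fraction"}
        if not required <= set(df.columns):
            raise FormatError(f"{path}: panel TSV needs columns {sorted(required)}")
        n = int(df["n_panel"].iloc[0]) if "n_panel" in df.columns else 0
        return cls(
            dict(zip(df["chrom"], df["mean_fraction"].astype(float))),
            dict(zip(df["chrom"], df["sd_fraction"].astype(float))),
            n_panel=n,
        )

    def to_tsv(self, path: str | Path) -> None:
        chroms = [c for c in CHROMOSOMES if c in self.mean_fraction]
        pd.DataFrame(
            {
                "chrom": chroms,
                "mean_fraction": [self.mean_fraction[c] for c in chroms],
                "sd_fraction": [self.sd_fraction[c] for c in chroms],
                "n_panel": self.n_panel,
            }
        ).to_csv(path, sep="\t", index=False)


def chromosome_fractions(fragments: FragmentSet) -> dict[str, float]:
    """Fraction of fragments on each of the 24 chromosomes (sums to 1)."""
    n = len(fragments)
    if n == 0:
        raise ValueError("cannot compute fractions of an empty fragment set")
    counts = {c: 0 for c in CHROMOSOMES}
    chroms, per = np.unique(fragments.chroms.astype(str), return_counts=True)
    for c, k in zip(chroms, per):
        if c in counts:
            counts[c] = int(k)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no fragments on canonical chromosomes")
    return {c: counts[c] / total for c in CHROMOSOMES}


def compute_zscores(
    fractions: Mapping[str, float], panel: ReferencePanel
) -> ChromosomeZScores:
    """Standardize per-chromosome fractions against the panel.

    Chromosomes absent from the panel (typically chrY) are skipped and
    recorded as absent in the result.
    """
    z = {}
    for c in CHROMOSOMES:
        if c not in panel.mean_fraction:
            continue
        sd = panel.sd_fraction[c]
        if sd <= 0:
            raise ValueError(f"panel sd is zero for {c}")
        z[c] = (fractions[c] - panel.mean_fraction[c]) / sd
    return ChromosomeZScores(z)


def flag_mca(z: ChromosomeZScores, threshold: float = 3.0) -> bool:
    """Multiple chromosomal aneuploidies: >= 2 chromosomes with |z| strictly > threshold.

    All chromosomes with a defined z participate, including chrX and (when
    present) chrY.
    """
    n_hits = sum(1 for _, v in z.items() if abs(v) > threshold)
    return n_hits >= 2
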