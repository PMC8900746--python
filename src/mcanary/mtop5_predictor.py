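"""The MTOP5Zscores statistic and its cutoff classification.

MTOP5Zscores is the mean of the five largest absolute chromosome z-scores
after excluding chrY and chr19 (chr19 carries a high technical-artifact
rate in unaffected samples). A subject is called positive when the score
strictly exceeds the cutoff (default 5.94).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mcanary.io_formats import CHROM_ORDER
from mcanary.zscore_engine import ChromosomeZScores

DEFAULT_EXCLUDED: tuple[str, ...] = ("chrY", "chr19")
DEFAULT_CUTOFF: float = 5.94


@dataclass
class MTOP5Result:
    score: float
    contributing: list[tuple[str, float]]
    call: str  # "positive" | "negative"
    cutoff_used: float

    def __post_init__(self) -> None:
        if len(self.contributing) != 5:
            raise ValueError("contributing must list exactly 5 chromosomes")
        if self.score < 0:
            raise ValueError("score must be >= 0")


def mtop5zscore(
    z: ChromosomeZScores, excluded: tuple[str, ...] = DEFAULT_EXCLUDED
) -> tuple[float, list[tuple[str, float]]]:
    """Mean of the five largest |z| among non-excluded chromosomes.

    Returns ``(score, contributing)`` with contributing chromosomes in
    descending |z|; ties broken by canonical chromosome order. Requires at
    least 5 scorable chromosomes.
    """
    candidates = [(c, v) for c, v in z.items() if c not in excluded]
    if len(candidates) < 5:
        raise ValueError(
            f"need >= 5 scorable chromosomes after excluding {excluded}, "
            f"got {len(candidates)}"
        )
    ranked = sorted(candidates, key=lambda cv: (-abs(cv[1]), CHROM_ORDER[cv[0]]))
    top5 = ranked[:5]
    score = float(np.mean([abs(v) for _, v in top5]))
    return score, top5


def classify_mtop5(score: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Positive iff score strictly exceeds the cutoff."""
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score!r}")
    return "positive" if score > cutoff else "negative"


def evaluate_subject(
    z: ChromosomeZScores,
    cutoff: float = DEFAULT_CUTOFF,
    excluded: tuple[str, ...] = DEFAULT_EXCLUDED,
) -> MTOP5Result:
    score, top5 = mtop5zscore(z, excluded=excluded)
    return MTOP5Result(score, top5, classify_mtop5(score, cutoff), cutoff)
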