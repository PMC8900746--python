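"""Plasma tumor marker (PTM) screening rule.

A subject is flagged high-risk when at least one marker concentration
strictly exceeds its prespecified clinical cutoff.

The default marker order follows the assay's cutoff list: CA15-3 (28 U/ml),
AFP (500 ng/ml), CEA (5 ng/ml), CA19-9 (37 U/ml), CA125 (36 U/ml),
CYFRA21-1 (3.3 ng/ml), SCC (1.2 ng/ml). Marker names are configuration
data; any 7-marker panel with matching cutoffs is accepted.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np

PTM_MARKERS: tuple[str, ...] = (
    "CA15-3",
    "AFP",
    "CEA",
    "CA19-9",
    "CA125",
    "CYFRA21-1",
    "SCC",
)

DEFAULT_CUTOFFS: dict[str, float] = dict(
    zip(PTM_MARKERS, (28.0, 500.0, 5.0, 37.0, 36.0, 3.3, 1.2))
)


@dataclass
class PTMPanel:
    """Concentrations of exactly 7 plasma tumor markers for one subject."""

    concentrations: dict[str, float]

    def __post_init__(self) -> None:
        if len(self.concentrations) != 7:
            raise ValueError(
                f"PTM panel must have exactly 7 markers, got {len(self.concentrations)}"
            )
        for m, v in self.concentrations.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"concentration must be finite and >= 0: {m}={v!r}")

    def __getitem__(self, marker: str) -> float:
        return self.concentrations[marker]

    def markers(self) -> set[str]:
        return set(self.concentrations)


def flag_ptm_high_risk(
    panel: PTMPanel, cutoffs: Mapping[str, float] | None = None
) -> tuple[bool, list[str]]:
    """Return ``(high_risk, exceeding_markers)``.

    High risk iff any concentration is strictly greater than its cutoff;
    equality is negative.
    """
    cutoffs = dict(cutoffs) if cutoffs is not None else DEFAULT_CUTOFFS
    if panel.markers() != set(cutoffs):
        raise ValueError(
            f"marker mismatch: panel {sorted(panel.markers())} vs "
            f"cutoffs {sorted(cutoffs)}"
        )
    exceeding = [
        m for m in panel.concentrations if panel.concentrations[m] > cutoffs[m]
    ]
    return bool(exceeding), exceeding
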