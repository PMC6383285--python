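"""Editing-level quantification from Sanger chromatogram peak heights.

Base-calling software reports a minor peak at a position only when its
height reaches a fraction (typically 5%) of the major peak's.  The editing
level at a candidate site is minor/(major+minor), so the implied minimum
reportable level is r/(1+r) for a minor/major ratio threshold r — 0.048
for the usual 5% rule.  Peak heights arrive as a CSV table; trace-file
parsing is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "PeakPair",
    "editing_from_peaks",
    "detection_threshold",
    "read_peak_table",
    "quantify_peak_table",
]


@dataclass(frozen=True)
class PeakPair:
    """Major/minor chromatogram peak heights at one candidate site."""

    site: str
    major_base: str
    major_height: float
    minor_base: str
    minor_height: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.major_height <= 0:
            raise ValueError("major peak height must be positive")
        if self.minor_height < 0:
            raise ValueError("minor peak height must be non-negative")

    def normalized(self) -> "PeakPair":
        """Swap bases if the 'minor' peak is taller (with a warning)."""
        if self.minor_height > self.major_height:
            warnings.warn(
                f"{self.site}: minor peak taller than major; swapping bases",
                stacklevel=2,
            )
            return PeakPair(
                site=self.site,
                major_base=self.minor_base,
                major_height=self.minor_height,
                minor_base=self.major_base,
                minor_height=self.major_height,
                label=self.label,
            )
        return self


def detection_threshold(min_minor_ratio: float = 0.05) -> float:
    """Minimum reportable editing level implied by the minor-peak rule."""
    return min_minor_ratio / (1.0 + min_minor_ratio)


def editing_from_peaks(
    peak: PeakPair, min_minor_ratio: float = 0.05
) -> tuple[float, bool]:
    """(editing level, detected) from one peak pair.

    level = minor/(major+minor); detected iff minor >= ratio * major
    (the boundary counts as detected).  Undetected sites still report
    their level, flagged ``detected=False``.
    """
    peak = peak.normalized()
    level = peak.minor_height / (peak.major_height + peak.minor_height)
    detected = peak.minor_height >= min_minor_ratio * peak.major_height
    return level, detected


def read_peak_table(path: str | Path) -> list[PeakPair]:
    """Peak pairs from CSV (site,label,major_base,major_height,minor_base,
    minor_height); the label column is optional."""
    df = pd.read_csv(path)
    needed = ["site", "major_base", "major_height", "minor_base", "minor_height"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"peak table missing column(s): {missing}")
    return [
        PeakPair(
            site=str(r.site),
            major_base=str(r.major_base),
            major_height=float(r.major_height),
            minor_base=str(r.minor_base),
            minor_height=float(r.minor_height),
            label=str(getattr(r, "label", "")),
        )
        for r in df.itertuples()
    ]


def quantify_peak_table(
    peaks: list[PeakPair], min_minor_ratio: float = 0.05
) -> pd.DataFrame:
    """Editing level and detection call for every peak pair."""
    rows = []
    for p in peaks:
        level, detected = editing_from_peaks(p, min_minor_ratio)
        rows.append(
            {
                "site": p.site,
                "label": p.label,
                "editing_level": level,
                "detected": detected,
            }
        )
    return pd.DataFrame(rows)
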