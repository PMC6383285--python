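"""Flanking-sequence context: strand normalization, -1 dinucleotide filter,
and position-frequency-matrix summaries.

Canonical C>U editing is observed on the plus strand as C>T and on the
minus strand as G>A (likewise A>I as A>G / T>C).  All sequence-context
logic operates on the *edited strand*, so minus-strand windows are
reverse-complemented first and positions are reported relative to the
edited base at position 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlankContext",
    "revcomp",
    "edit_class",
    "to_edited_strand",
    "minus_one_filter",
    "build_pfm",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# canonical ref>alt pairs and their editing class / strand
_CANONICAL = {
    ("C", "T"): ("C2U", "plus"),
    ("G", "A"): ("C2U", "minus"),
    ("A", "G"): ("A2I", "plus"),
    ("T", "C"): ("A2I", "minus"),
}


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def edit_class(ref: str, alt: str) -> tuple[str, str] | None:
    """(class, edited strand) for a canonical ref>alt pair, else None."""
    return _CANONICAL.get((ref.upper(), alt.upper()))


@dataclass(frozen=True)
class FlankContext:
    """A flanking window centered on the edited base, on the edited strand."""

    window: str
    edited_strand: str  # "plus" | "minus"
    edit_class: str  # "C2U" | "A2I"

    @property
    def k(self) -> int:
        return len(self.window) // 2

    @property
    def center(self) -> str:
        return self.window[self.k]

    def base_at(self, offset: int) -> str:
        """Base at a position relative to the edited base (0 = edited)."""
        return self.window[self.k + offset]


def to_edited_strand(ref: str, alt: str, plus_strand_window: str) -> FlankContext:
    """Normalize a plus-strand window to the edited strand.

    C>T and A>G windows pass through unchanged; G>A and T>C windows are
    reverse-complemented so the center base becomes C (resp. A).
    """
    window = plus_strand_window.upper()
    if len(window) % 2 != 1:
        raise ValueError("flank window must have odd length")
    cls = edit_class(ref, alt)
    if cls is None:
        raise ValueError(f"non-canonical editing event {ref}>{alt}")
    klass, strand = cls
    center = window[len(window) // 2]
    if center != ref.upper():
        raise ValueError(
            f"window center {center!r} disagrees with site ref {ref!r}"
        )
    if strand == "minus":
        window = revcomp(window)
    return FlankContext(window=window, edited_strand=strand, edit_class=klass)


def minus_one_filter(context: FlankContext) -> bool:
    """APOBEC3 dinucleotide rule: keep a C>U site iff the base immediately
    5' of the edited C (position -1 on the edited strand) is C or T.

    A3G prefers CC, the other APOBEC3s TC; an N at -1 fails (conservative).
    """
    if context.edit_class != "C2U":
        raise ValueError("-1 filter applies to C>U contexts only")
    return context.base_at(-1) in ("C", "T")


def build_pfm(contexts: Iterable[FlankContext | str], k: int | None = None) -> pd.DataFrame:
    """Position frequency matrix over edited-strand windows.

    Rows are positions -k..+k relative to the edited base, columns A/C/G/T.
    Frequencies at each position are computed over non-N observations, so
    every column with at least one observation sums to 1.  An ``n_obs``
    column carries the per-position non-N count.
    """
    windows = [c.window if isinstance(c, FlankContext) else c.upper() for c in contexts]
    if not windows:
        raise ValueError("cannot build a PFM from zero contexts")
    lengths = {len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError("all windows must share the same length")
    width = lengths.pop()
    if k is None:
        k = width // 2
    elif 2 * k + 1 != width:
        raise ValueError(f"windows of length {width} do not match k={k}")

    counts = np.zeros((width, 4), dtype=float)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for w in windows:
        for pos, base in enumerate(w):
            j = base_idx.get(base)
            if j is not None:
                counts[pos, j] += 1
    n_obs = counts.sum(axis=1)
    freqs = np.divide(
        counts, n_obs[:, None], out=np.zeros_like(counts), where=n_obs[:, None] > 0
    )
    pfm = pd.DataFrame(
        freqs, index=pd.RangeIndex(-k, k + 1, name="position"), columns=list("ACGT")
    )
    pfm["n_obs"] = n_obs.astype(int)
    return pfm
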