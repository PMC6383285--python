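"""RNA stem-loop predicate for APOBEC3 editing-site context.

APOBEC3A and APOBEC3G preferentially deaminate cytidines sitting at the
3' end of a short hairpin loop.  This module formalizes that structural
substrate as a deterministic predicate on the flanking-sequence window of
an edited C: the C must be the last (3'-most) base of a tri- or tetra-loop
closed by a stem of at least 2 Watson-Crick base pairs when pairing is
perfect, or at least 4 pair positions when the stem carries exactly one
defect (a single mismatched pair or a single bulged nucleotide on one arm).

Geometry conventions (window indices, ``e`` = center index of the edited C,
``L`` = loop length):

* loop        = ``window[e-L+1 .. e]`` (the edited C closes the loop 3').
* pair *i*    = ``window[e-L-i+1]`` : ``window[e+i]`` for *i* = 1, 2, ...;
  pair 1 is the loop-closing pair.
* a bulge after pair *d* skips one nucleotide on a single arm; pairs
  *i* > *d* are evaluated with that arm shifted outward by one.

Rules (all deliberate, see the package methods note):

* the loop-closing pair (pair 1) must be a true Watson-Crick pair — a
  mismatch there would enlarge the loop;
* the outermost counted pair must be a true pair — terminal defects do not
  extend a stem — hence mismatches live at offsets ``2..stem_len-1`` and
  bulges strictly between counted pairs (offset ``1..stem_len-1``);
* at most one defect per stem;
* G:U wobble pairs are not complementary unless ``wobble=True``;
* any pair involving N never pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

__all__ = [
    "StemLoopCall",
    "stemloop_predicate",
    "enumerate_structures",
    "NO_CALL",
]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class StemLoopCall:
    """Outcome of the stem-loop predicate for one window.

    ``stem_len`` counts paired positions (a bulged nucleotide is not a
    pair position).  ``defect_offset`` is the pair index of a mismatch,
    or for a bulge the index of the last pair before the bulged
    nucleotide, both counted from the loop-closing pair (= 1).
    """

    qualifies: bool
    loop_len: Optional[int] = None
    stem_len: Optional[int] = None
    defect: str = "none"
    defect_offset: Optional[int] = None
    bulge_arm: Optional[str] = None  # "five_prime" | "three_prime"


NO_CALL = StemLoopCall(qualifies=False)


def _is_pair(a: str, b: str, wobble: bool) -> bool:
    if (a, b) in _WC:
        return True
    return wobble and (a, b) in _WOBBLE


def _pair_indices(
    e: int, loop_len: int, i: int, bulge_arm: Optional[str], bulge_after: int
) -> tuple[int, int]:
    """Window indices of the two bases forming stem pair ``i``."""
    five = e - loop_len - i + 1
    three = e + i
    if bulge_arm == "five_prime" and i > bulge_after:
        five -= 1
    elif bulge_arm == "three_prime" and i > bulge_after:
        three += 1
    return five, three


def _pairs_ok(
    window: str,
    e: int,
    loop_len: int,
    i: int,
    wobble: bool,
    bulge_arm: Optional[str] = None,
    bulge_after: int = 0,
) -> Optional[bool]:
    """True/False if pair ``i`` is in-window and (non-)complementary; None if
    either base falls outside the window (the stem cannot extend there)."""
    five, three = _pair_indices(e, loop_len, i, bulge_arm, bulge_after)
    if five < 0 or three >= len(window):
        return None
    return _is_pair(window[five], window[three], wobble)


def _check_window(window: str, k: int = 8) -> int:
    window = window.upper()
    if len(window) % 2 != 1:
        raise ValueError(f"window length must be odd, got {len(window)}")
    e = len(window) // 2
    if e < k:
        raise ValueError(
            f"window too short: need at least {2 * k + 1} nt around the edited base"
        )
    if window[e] != "C":
        raise ValueError(f"center base must be the edited C, got {window[e]!r}")
    return e


def _wc_run(window, e, L, wobble, start=1, bulge_arm=None, bulge_after=0) -> int:
    """Length of the consecutive run of true pairs from pair ``start``."""
    i = start
    while True:
        ok = _pairs_ok(window, e, L, i, wobble, bulge_arm, bulge_after)
        if not ok:
            return i - start
        i += 1


def stemloop_predicate(
    window: str,
    *,
    loop_lengths: Sequence[int] = (3, 4),
    perfect_stem_min: int = 2,
    imperfect_stem_min: int = 4,
    wobble: bool = False,
) -> StemLoopCall:
    """Decide whether the edited C closes a qualifying tri/tetra-loop hairpin.

    Scans each loop length for (a) a perfect stem of >= ``perfect_stem_min``
    consecutive pairs and (b) single-defect stems of >= ``imperfect_stem_min``
    pair positions, and returns the preferred qualifying geometry: perfect
    before defective; shorter loop first; within a category the longest stem;
    mismatch before bulge on ties, then smaller offset, then 5' arm.
    """
    window = window.upper()
    e = _check_window(window)

    candidates: list[tuple[tuple, StemLoopCall]] = []
    for L in loop_lengths:
        r = _wc_run(window, e, L, wobble)
        if r >= perfect_stem_min:
            candidates.append(
                ((0, L, -r, 0, 0, 0), StemLoopCall(True, L, r, "none"))
            )
        # Mismatch: the single non-pairing position must be pair r+1 (the
        # first break in the perfect run); it needs a true pair on both
        # sides, so r >= 1 and at least one pair beyond it.
        if r >= 1 and _pairs_ok(window, e, L, r + 1, wobble) is False:
            r2 = _wc_run(window, e, L, wobble, start=r + 2)
            stem = r + 1 + r2
            if r2 >= 1 and stem >= imperfect_stem_min:
                candidates.append(
                    (
                        (1, L, -stem, 0, r + 1, 0),
                        StemLoopCall(True, L, stem, "mismatch", r + 1),
                    )
                )
        # Bulge: skip one nucleotide on one arm after pair d (1 <= d <= r);
        # pairing resumes shifted and must contribute at least one more pair.
        for arm_rank, arm in ((0, "five_prime"), (1, "three_prime")):
            for d in range(1, r + 1):
                r2 = _wc_run(
                    window, e, L, wobble, start=d + 1, bulge_arm=arm, bulge_after=d
                )
                stem = d + r2
                if r2 >= 1 and stem >= imperfect_stem_min:
                    candidates.append(
                        (
                            (1, L, -stem, 1, d, arm_rank),
                            StemLoopCall(True, L, stem, "bulge", d, arm),
                        )
                    )
    if not candidates:
        return NO_CALL
    candidates.sort(key=lambda t: t[0])
    return candidates[0][1]


def _iter_structures(
    window: str,
    loop_lengths: Sequence[int],
    perfect_stem_min: int,
    imperfect_stem_min: int,
    wobble: bool,
) -> Iterator[StemLoopCall]:
    """Brute-force generator behind :func:`enumerate_structures`.

    Independently of the scanning predicate, test every combination of
    loop length, defect type, defect position and stem length by checking
    each required pair from scratch.
    """
    window = window.upper()
    e = _check_window(window)
    n = len(window)
    max_stem = n  # bounds enforced per-pair via _pairs_ok returning None

    for L in loop_lengths:
        # perfect stems
        for s in range(perfect_stem_min, max_stem):
            if all(_pairs_ok(window, e, L, i, wobble) for i in range(1, s + 1)):
                yield StemLoopCall(True, L, s, "none")
        # one mismatch at interior offset d
        for s in range(imperfect_stem_min, max_stem):
            for d in range(2, s):
                ok = True
                for i in range(1, s + 1):
                    p = _pairs_ok(window, e, L, i, wobble)
                    if p is None or (p is True) != (i != d):
                        ok = False
                        break
                if ok:
                    yield StemLoopCall(True, L, s, "mismatch", d)
        # one bulged nucleotide after pair d on one arm
        for arm in ("five_prime", "three_prime"):
            for s in range(imperfect_stem_min, max_stem):
                for d in range(1, s):
                    ok = True
                    for i in range(1, s + 1):
                        if not _pairs_ok(window, e, L, i, wobble, arm, d):
                            ok = False
                            break
                    if ok:
                        yield StemLoopCall(True, L, s, "bulge", d, arm)


def enumerate_structures(
    window: str,
    *,
    loop_lengths: Sequence[int] = (3, 4),
    perfect_stem_min: int = 2,
    imperfect_stem_min: int = 4,
    wobble: bool = False,
) -> list[StemLoopCall]:
    """Exhaustively enumerate every qualifying hairpin geometry in ``window``.

    Serves as the independent oracle for :func:`stemloop_predicate`:
    ``stemloop_predicate(w).qualifies == bool(enumerate_structures(w))``.
    """
    return list(
        _iter_structures(
            window, loop_lengths, perfect_stem_min, imperfect_stem_min, wobble
        )
    )
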