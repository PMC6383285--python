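"""Stem-loop predicate: hand-checked geometries, oracle equivalence,
boundary behavior and flag semantics."""

import numpy as np
import pytest

from apoedit.stemloop import NO_CALL, enumerate_structures, stemloop_predicate

K = 15


def place(core: str, loop_end_in_core: int, left="T", right="T") -> str:
    """Embed ``core`` in a 31-mer so that core[loop_end_in_core] (the edited
    C) lands at the window center; pads are non-pairing by construction in
    the tests that use them."""
    lpad = left * (K - loop_end_in_core)
    rpad = right * (K - (len(core) - loop_end_in_core - 1))
    w = lpad + core + rpad
    assert len(w) == 2 * K + 1 and w[K] == "C"
    return w


class TestHandCheckedGeometries:
    def test_perfect_triloop_min_stem(self):
        # 5'-G C A A C G C-3': loop AAC ends in the edited C;
        # pair 1 = C:G, pair 2 = G:C -> perfect stem of 2.
        w = place("GCAACGC", 4)
        call = stemloop_predicate(w)
        assert (call.qualifies, call.loop_len, call.stem_len, call.defect) == (
            True, 3, 2, "none")

    def test_tetraloop_with_interior_mismatch(self):
        # 5'-GATC TTAC GCTC-3': loop TTAC; pairs C:G, T:C (mismatch),
        # A:T, G:C -> stem of 4 with one mismatch at offset 2.
        w = place("GATCTTACGCTC", 7, left="A", right="A")
        call = stemloop_predicate(w)
        assert call.qualifies
        assert (call.loop_len, call.stem_len, call.defect, call.defect_offset) == (
            4, 4, "mismatch", 2)

    def test_no_pairing_possible(self):
        assert stemloop_predicate("A" * K + "C" + "A" * K) == NO_CALL

    def test_all_n_window(self):
        w = "N" * K + "C" + "N" * K
        assert not stemloop_predicate(w).qualifies
        assert enumerate_structures(w) == []

    def test_bulge_geometry(self):
        # A planted single-bulge stem must be called as a bulge and be
        # visible to the exhaustive oracle with the same loop length.
        from apoedit.simulate import synth_flank

        rng = np.random.default_rng(5)
        w = synth_flank(rng, True, loop_len=3, stem_len=4, defect="bulge")
        call = stemloop_predicate(w)
        assert call.qualifies and call.defect == "bulge"
        assert call.stem_len >= 4 and call.bulge_arm in ("five_prime", "three_prime")
        # the exhaustive oracle sees the same bulge geometry
        geoms = enumerate_structures(w)
        assert any(
            g.defect == "bulge" and g.loop_len == call.loop_len and g.stem_len >= 4
            for g in geoms
        )


class TestPreferenceOrder:
    def test_perfect_preferred_over_defective(self):
        # A window planted with a perfect stem also admits defective
        # alignments; the call must report the perfect geometry.
        from apoedit.simulate import synth_flank

        rng = np.random.default_rng(7)
        for _ in range(20):
            w = synth_flank(rng, True, loop_len=3, stem_len=3, defect="none")
            assert stemloop_predicate(w).defect == "none"

    def test_maximal_stem_reported(self):
        # perfect stem of 4: GGGC AAC GCCC
        w = place("GGGCAACGCCC", 6)
        call = stemloop_predicate(w)
        assert call.stem_len == 4 and call.defect == "none"
        # oracle lists every sub-stem down to the 2-pair minimum
        lens = {g.stem_len for g in enumerate_structures(w) if g.defect == "none"
                and g.loop_len == 3}
        assert lens == {2, 3, 4}


class TestValidation:
    def test_center_must_be_c(self):
        with pytest.raises(ValueError, match="center"):
            stemloop_predicate("A" * K + "G" + "A" * K)

    def test_window_too_short(self):
        with pytest.raises(ValueError, match="too short"):
            stemloop_predicate("AACAA")

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            stemloop_predicate("A" * 30)


class TestOracleEquivalence:
    def test_random_windows(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(3000):
            w = "".join(rng.choice(bases, 2 * K + 1))
            w = w[:K] + "C" + w[K + 1:]
            assert stemloop_predicate(w).qualifies == bool(enumerate_structures(w)), w

    def test_adversarial_n_and_boundary(self, rng):
        # windows peppered with N and structures forced near the window edge
        bases = np.array(list("ACGTN"))
        for _ in range(500):
            w = "".join(rng.choice(bases, 2 * K + 1))
            w = w[:K] + "C" + w[K + 1:]
            assert stemloop_predicate(w).qualifies == bool(enumerate_structures(w)), w

    def test_wobble_flag_consistency(self, rng):
        bases = np.array(list("ACGT"))
        n_flipped = 0
        for _ in range(500):
            w = "".join(rng.choice(bases, 2 * K + 1))
            w = w[:K] + "C" + w[K + 1:]
            strict = stemloop_predicate(w).qualifies
            wob = stemloop_predicate(w, wobble=True).qualifies
            assert stemloop_predicate(w, wobble=True).qualifies == bool(
                enumerate_structures(w, wobble=True))
            assert wob or not strict  # wobble can only add structures
            n_flipped += wob and not strict
        assert n_flipped > 0  # G:U pairing genuinely changes calls


def test_monotone_in_window_extension(rng):
    """A qualifying call on a window stays qualifying when the window is
    extended outward (more sequence can only add candidate pairs)."""
    from apoedit.simulate import synth_flank

    bases = np.array(list("ACGT"))
    for _ in range(50):
        w = synth_flank(rng, True, loop_len=4, stem_len=2, defect="none", k=K)
        ext = "".join(rng.choice(bases, 4)) + w + "".join(rng.choice(bases, 4))
        assert stemloop_predicate(ext).qualifies
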