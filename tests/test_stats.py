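"""Editing levels, filter cascade pieces, the paired binomial GLM and BH.

The GLM's log odds ratio is cross-checked against an independent
grid-search maximum-likelihood oracle and against Fisher's exact test on
the condition-collapsed table.
"""

import numpy as np
import pytest
from scipy import optimize, stats as sps
from scipy.special import expit

from apoedit.io import EditingSite, SampleObservation, SiteCounts
from apoedit.stats import (
    bh_adjust,
    classify_direction,
    editing_level,
    filter_canonical,
    filter_prevalence,
    glm_condition_test,
    max_editing_level,
    remove_blacklisted,
)
from apoedit.stats import TestResult as SiteTestResult
from apoedit.stats import test_sites as run_site_tests


def site_counts(counts, ref="C", alt="T", pos=100):
    """counts: list of (donor, condition, alt, ref)."""
    site = EditingSite("chr1", pos, ref, alt)
    obs = [
        SampleObservation(f"{d}_{c[0]}", d, c, r_, a_)
        for d, c, a_, r_ in counts
    ]
    return SiteCounts(site=site, observations=obs)


class TestEditingLevel:
    @pytest.mark.parametrize(
        "alt,ref,expected", [(0, 50, 0.0), (5, 95, 0.05), (20, 80, 0.20)]
    )
    def test_levels(self, alt, ref, expected):
        obs = SampleObservation("s", "d", "hypoxia", ref, alt)
        assert editing_level(obs) == pytest.approx(expected)

    def test_zero_coverage_undefined(self):
        obs = SampleObservation("s", "d", "hypoxia", 0, 0)
        with pytest.raises(ZeroDivisionError):
            editing_level(obs)

    def test_zero_coverage_excluded_from_prevalence(self):
        rec = site_counts([("d1", "normoxia", 0, 0), ("d1", "hypoxia", 6, 94)])
        assert max_editing_level(rec) == pytest.approx(0.06)


class TestFilters:
    def test_canonical_classes(self):
        recs = [site_counts([("d1", "hypoxia", 1, 9)], ref=r, alt=a, pos=i + 1)
                for i, (r, a) in enumerate(
                    [("C", "T"), ("G", "A"), ("A", "G"), ("T", "C"),
                     ("C", "G"), ("A", "C")])]
        kept = filter_canonical(recs)
        assert [(r.site.ref, r.site.alt) for r in kept] == [
            ("C", "T"), ("G", "A"), ("A", "G"), ("T", "C")]

    def test_prevalence_any_sample_inclusive(self):
        levels = [0.02, 0.02, 0.051, 0.01, 0.0, 0.0]
        rec = site_counts([
            (f"d{i}", "hypoxia", round(1000 * lv), 1000 - round(1000 * lv))
            for i, lv in enumerate(levels)
        ])
        assert filter_prevalence([rec]) == [rec]

    def test_prevalence_all_below_removed(self):
        rec = site_counts([
            (f"d{i}", "hypoxia", 49, 951) for i in range(3)  # 0.049 each
        ])
        assert filter_prevalence([rec]) == []

    def test_prevalence_boundary_exact(self):
        rec = site_counts([("d1", "hypoxia", 5, 95)])
        assert filter_prevalence([rec]) == [rec]

    def test_blacklist_set_difference(self):
        recs = [site_counts([("d1", "hypoxia", 1, 9)], pos=p) for p in (1, 2, 3)]
        blk = {recs[1].site.key}
        assert [r.site.pos for r in remove_blacklisted(recs, blk)] == [1, 3]
        assert remove_blacklisted(recs, set()) == recs
        assert remove_blacklisted(recs, {r.site.key for r in recs}) == []

    def test_cascade_monotone(self, small_dataset):
        recs = small_dataset.records
        s1 = filter_canonical(recs)
        s2 = remove_blacklisted(s1, small_dataset.blacklist)
        s3 = filter_prevalence(s2)
        keys = [{r.site.key for r in s} for s in (recs, s1, s2, s3)]
        for a, b in zip(keys, keys[1:]):
            assert b <= a


def grid_search_log_or(rec):
    """Independent ML oracle: maximize the binomial log-likelihood over
    (intercept, condition effect, donor offsets) with scipy, no GLM."""
    obs = rec.observations
    donors = sorted({o.donor_id for o in obs})
    cond = np.array([o.condition == "hypoxia" for o in obs], float)
    donor_idx = np.array([donors.index(o.donor_id) for o in obs])
    alt = np.array([o.alt_count for o in obs], float)
    tot = alt + np.array([o.ref_count for o in obs], float)

    def nll(theta):
        b0, b1 = theta[0], theta[1]
        d = np.concatenate([[0.0], theta[2:]])
        p = expit(b0 + b1 * cond + d[donor_idx])
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return -(alt * np.log(p) + (tot - alt) * np.log1p(-p)).sum()

    best = None
    for b1_start in (-2.0, 0.0, 2.0):
        x0 = np.zeros(1 + len(donors))
        x0[1] = b1_start
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
    return best.x[1]


class TestGLM:
    def test_symmetric_counts_null(self):
        rec = site_counts([
            (d, c, 10, 90) for d in ("d1", "d2", "d3")
            for c in ("normoxia", "hypoxia")
        ])
        res = glm_condition_test(rec)
        assert res.log_or == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_three_donor_example_log_or_ln21(self):
        rec = site_counts([
            (d, "hypoxia", 30, 70) for d in ("d1", "d2", "d3")
        ] + [
            (d, "normoxia", 2, 98) for d in ("d1", "d2", "d3")
        ])
        res = glm_condition_test(rec)
        assert res.log_or == pytest.approx(np.log(21), abs=1e-6)
        assert res.p_value < 1e-6
        # independent grid-search ML oracle
        assert grid_search_log_or(rec) == pytest.approx(np.log(21), abs=1e-3)
        # Fisher exact on the collapsed table agrees on significance
        p_fisher = sps.fisher_exact([[90, 210], [6, 294]]).pvalue
        assert p_fisher < 1e-6

    def test_oracle_agreement_on_random_sites(self, rng):
        for _ in range(5):
            counts = []
            for d in ("d1", "d2", "d3"):
                for c in ("normoxia", "hypoxia"):
                    tot = int(rng.integers(50, 200))
                    a = int(rng.integers(5, tot - 5))
                    counts.append((d, c, a, tot - a))
            rec = site_counts(counts)
            res = glm_condition_test(rec)
            assert grid_search_log_or(rec) == pytest.approx(res.log_or, abs=5e-3)

    def test_label_swap_negates_log_or(self):
        counts = [("d1", "hypoxia", 25, 75), ("d1", "normoxia", 10, 90),
                  ("d2", "hypoxia", 30, 70), ("d2", "normoxia", 12, 88)]
        swapped = [
            (d, "normoxia" if c == "hypoxia" else "hypoxia", a, r)
            for d, c, a, r in counts
        ]
        r1 = glm_condition_test(site_counts(counts))
        r2 = glm_condition_test(site_counts(swapped))
        assert r1.log_or == pytest.approx(-r2.log_or, abs=1e-8)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-8)

    def test_donor_relabeling_invariance(self):
        counts = [("d1", "hypoxia", 25, 75), ("d1", "normoxia", 10, 90),
                  ("d2", "hypoxia", 30, 70), ("d2", "normoxia", 12, 88),
                  ("d3", "hypoxia", 20, 80), ("d3", "normoxia", 8, 92)]
        perm = {"d1": "dC", "d2": "dA", "d3": "dB"}
        relabeled = [(perm[d], c, a, r) for d, c, a, r in counts]
        r1 = glm_condition_test(site_counts(counts))
        r2 = glm_condition_test(site_counts(relabeled))
        assert r1.log_or == pytest.approx(r2.log_or, abs=1e-8)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-8)

    def test_separation_haldane_correction(self):
        # zero alt in normoxia everywhere -> collapsed cell empty
        rec = site_counts([
            (d, "hypoxia", 10, 90) for d in ("d1", "d2")
        ] + [
            (d, "normoxia", 0, 100) for d in ("d1", "d2")
        ])
        res = glm_condition_test(rec)
        assert res.separation_corrected
        expected = np.log((20.5 * 200.5) / (180.5 * 0.5))
        assert res.log_or == pytest.approx(expected, abs=1e-9)

    def test_unpaired_input_rejected(self):
        rec = site_counts([("d1", "hypoxia", 5, 95), ("d2", "normoxia", 5, 95)])
        with pytest.raises(ValueError, match="both conditions"):
            glm_condition_test(rec)

    def test_all_zero_coverage_rejected(self):
        rec = site_counts([("d1", "hypoxia", 0, 0), ("d1", "normoxia", 0, 0)])
        with pytest.raises(ValueError, match="coverage"):
            glm_condition_test(rec)

    def test_lrt_flag(self):
        rec = site_counts([
            (d, "hypoxia", 30, 70) for d in ("d1", "d2", "d3")
        ] + [
            (d, "normoxia", 2, 98) for d in ("d1", "d2", "d3")
        ])
        res = glm_condition_test(rec, test="lrt")
        assert res.p_value < 1e-6
        assert res.log_or == pytest.approx(np.log(21), abs=1e-6)


class TestBH:
    def test_single_p(self):
        assert bh_adjust([0.04]) == pytest.approx([0.04])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_q_at_least_p(self, rng):
        p = rng.uniform(size=100)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)


class TestDirection:
    @pytest.mark.parametrize(
        "log_or,q,expected",
        [(1.2, 0.01, "hypoxia_higher"),
         (-1.2, 0.01, "normoxia_higher"),
         (2.0, 0.20, "ns"),
         (0.5, 0.05, "ns")],  # strict q < alpha
    )
    def test_rule(self, log_or, q, expected):
        r = SiteTestResult(("chr1", 1, "C", "T"), log_or, 0.001, q_value=q)
        assert classify_direction([r])[0].direction == expected

    def test_requires_q_values(self):
        r = SiteTestResult(("chr1", 1, "C", "T"), 1.0, 0.01)
        with pytest.raises(ValueError):
            classify_direction([r])


def test_per_class_fdr_family_option():
    recs = []
    for i, (ref, alt) in enumerate([("C", "T")] * 3 + [("A", "G")] * 3):
        recs.append(site_counts(
            [(d, "hypoxia", 30, 70) for d in ("d1", "d2")]
            + [(d, "normoxia", 3, 97) for d in ("d1", "d2")],
            ref=ref, alt=alt, pos=i + 1))
    joint = run_site_tests(recs, fdr_family="joint")
    per = run_site_tests(recs, fdr_family="per_class")
    assert {r.edit_class for r in joint} == {"C2U", "A2I"}
    # identical p-values => BH within 3 vs within 6 gives identical q here
    assert all(r.q_value is not None for r in joint + per)
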