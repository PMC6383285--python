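"""Event-calling statistics: editing levels, prevalence/canonical filters,
blacklist removal, the paired binomial GLM per site, BH FDR and direction
classification.

The per-site test models alt counts as binomial with a logistic link:

    logit p_ij = beta0 + beta1 * [condition_ij == hypoxia] + donor_j

with donor fixed effects absorbing the pairing.  beta1 is the log odds
ratio of editing in hypoxia vs normoxia; a two-sided Wald test (default)
or likelihood-ratio test gives the p-value.  When the condition-collapsed
2x2 table (alt/ref by condition) has an empty cell the fit is replaced by
a Haldane-Anscombe-corrected fit on the collapsed table (0.5 added to all
four cells, donor terms dropped) and the result is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .context import edit_class
from .io import SampleObservation, SiteCounts, SiteKey

__all__ = [
    "TestResult",
    "editing_level",
    "max_editing_level",
    "filter_canonical",
    "filter_prevalence",
    "remove_blacklisted",
    "glm_condition_test",
    "bh_adjust",
    "classify_direction",
    "test_sites",
]


@dataclass(frozen=True)
class TestResult:
    """Per-site differential-editing test result.

    ``log_or`` is the condition coefficient (hypoxia vs normoxia);
    ``direction`` is assigned by :func:`classify_direction` once q-values
    exist.  ``separation_corrected`` marks Haldane-corrected fits.
    """

    site_key: SiteKey
    log_or: float
    p_value: float
    q_value: Optional[float] = None
    direction: str = "ns"
    separation_corrected: bool = False
    edit_class: Optional[str] = None


def editing_level(obs: SampleObservation) -> float:
    """Editing level alt/(ref+alt); undefined at zero coverage."""
    total = obs.ref_count + obs.alt_count
    if total == 0:
        raise ZeroDivisionError("editing level undefined at zero coverage")
    return obs.alt_count / total


def max_editing_level(rec: SiteCounts) -> float:
    """Highest per-sample editing level; zero-coverage samples excluded."""
    levels = [
        editing_level(o)
        for o in rec.observations
        if o.ref_count + o.alt_count > 0
    ]
    return max(levels, default=0.0)


def filter_canonical(records: Iterable[SiteCounts]) -> list[SiteCounts]:
    """Keep only canonical editing classes: C>T/G>A (C>U) and A>G/T>C (A>I)."""
    return [r for r in records if edit_class(r.site.ref, r.site.alt) is not None]


def filter_prevalence(
    records: Iterable[SiteCounts], min_level: float = 0.05
) -> list[SiteCounts]:
    """Keep a site iff any sample reaches ``min_level`` editing (inclusive)."""
    return [r for r in records if max_editing_level(r) >= min_level]


def remove_blacklisted(
    records: Iterable[SiteCounts], blacklist: set[SiteKey]
) -> list[SiteCounts]:
    """Drop sites whose (chrom, pos, ref, alt) key is a known SNP."""
    return [r for r in records if r.site.key not in blacklist]


def _collapsed_2x2(rec: SiteCounts) -> np.ndarray:
    """[[alt_hypoxia, ref_hypoxia], [alt_normoxia, ref_normoxia]]."""
    t = np.zeros((2, 2), dtype=np.int64)
    for o in rec.observations:
        row = 0 if o.condition == "hypoxia" else 1
        t[row, 0] += o.alt_count
        t[row, 1] += o.ref_count
    return t


def glm_condition_test(rec: SiteCounts, test: str = "wald") -> TestResult:
    """Paired binomial GLM test of the condition effect at one site.

    ``test`` is ``'wald'`` (default) or ``'lrt'`` (likelihood ratio against
    the donor-only model).  Requires at least one donor observed under both
    conditions with positive coverage.
    """
    obs = [o for o in rec.observations if o.ref_count + o.alt_count > 0]
    if not obs:
        raise ValueError(f"{rec.site.label}: all-zero coverage")
    by_donor: dict[str, set[str]] = {}
    for o in obs:
        by_donor.setdefault(o.donor_id, set()).add(o.condition)
    if not any(len(c) == 2 for c in by_donor.values()):
        raise ValueError(f"{rec.site.label}: no donor observed under both conditions")

    cls = edit_class(rec.site.ref, rec.site.alt)
    collapsed = _collapsed_2x2(rec)
    if (collapsed == 0).any():
        # Haldane-Anscombe: 0.5 on every collapsed cell, donor terms dropped
        a, b = collapsed[0] + 0.5  # hypoxia alt, ref
        c, d = collapsed[1] + 0.5  # normoxia alt, ref
        beta = float(np.log(a * d / (b * c)))
        se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
        p = float(2 * sps.norm.sf(abs(beta) / se))
        return TestResult(
            site_key=rec.site.key, log_or=beta, p_value=p,
            separation_corrected=True,
            edit_class=cls[0] if cls else None,
        )

    alt = np.array([o.alt_count for o in obs], dtype=float)
    ref = np.array([o.ref_count for o in obs], dtype=float)
    cond = np.array([1.0 if o.condition == "hypoxia" else 0.0 for o in obs])
    donors = sorted({o.donor_id for o in obs})
    cols = [np.ones(len(obs)), cond]
    for d_ in donors[1:]:
        cols.append(np.array([1.0 if o.donor_id == d_ else 0.0 for o in obs]))
    exog = np.column_stack(cols)
    endog = np.column_stack([alt, ref])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        beta = float(fit.params[1])
        if test == "wald":
            p = float(fit.pvalues[1])
        elif test == "lrt":
            null_fit = sm.GLM(
                endog, np.delete(exog, 1, axis=1), family=sm.families.Binomial()
            ).fit()
            lr = 2.0 * (fit.llf - null_fit.llf)
            p = float(sps.chi2.sf(max(lr, 0.0), df=1))
        else:
            raise ValueError(f"unknown test {test!r}")
    return TestResult(
        site_key=rec.site.key, log_or=beta, p_value=p,
        edit_class=cls[0] if cls else None,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_direction(
    results: Sequence[TestResult], alpha: float = 0.05
) -> list[TestResult]:
    """Assign hypoxia_higher / normoxia_higher / ns at FDR < ``alpha``.

    Selection follows the log-odds-ratio sign with strict q < alpha
    (equivalently OR > 1 with FDR < alpha for the hypoxia branch).
    """
    out = []
    for r in results:
        if r.q_value is None:
            raise ValueError("q_values must be assigned before classification")
        if r.q_value < alpha and r.log_or > 0:
            direction = "hypoxia_higher"
        elif r.q_value < alpha and r.log_or < 0:
            direction = "normoxia_higher"
        else:
            direction = "ns"
        out.append(replace(r, direction=direction))
    return out


def test_sites(
    records: Sequence[SiteCounts],
    alpha: float = 0.05,
    test: str = "wald",
    fdr_family: str = "joint",
) -> list[TestResult]:
    """GLM per site, BH across the family, then direction classification.

    ``fdr_family='joint'`` adjusts C>U and A>I events together (default);
    ``'per_class'`` adjusts each editing class separately.
    """
    results = [glm_condition_test(r, test=test) for r in records]
    if fdr_family == "joint":
        groups = {None: list(range(len(results)))}
    elif fdr_family == "per_class":
        groups = {}
        for i, r in enumerate(results):
            groups.setdefault(r.edit_class, []).append(i)
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    adjusted: list[Optional[TestResult]] = [None] * len(results)
    for idx in groups.values():
        qs = bh_adjust([results[i].p_value for i in idx])
        for i, q in zip(idx, qs):
            adjusted[i] = replace(results[i], q_value=float(q))
    return classify_direction(adjusted, alpha=alpha)
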