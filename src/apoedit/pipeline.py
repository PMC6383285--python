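"""The full event-calling cascade and its stage-by-stage report.

Stage order (candidate sites are assumed pre-called upstream):

1. canonical     keep C>T/G>A (C>U) and A>G/T>C (A>I) mismatch classes
2. blacklist     remove known SNPs by (chrom, pos, ref, alt) key
3. prevalence    keep sites with >= 5% editing level in any sample
4. glm_fdr       paired binomial GLM + BH FDR + direction classification;
                 only directionally significant events continue
5. minus_one     C>U events must carry C or T at -1 on the edited strand
                 (A>I events stop after stage 4 and are reported as-is)
6. stemloop      C>U events must sit in exons/UTRs *and* close a
                 qualifying tri/tetra-loop hairpin

Each stage's input is a superset of its output (asserted), and re-running
with identical inputs and config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from . import stats as es
from .context import build_pfm, to_edited_strand
from .io import SiteCounts, SiteKey
from .stemloop import stemloop_predicate

logger = logging.getLogger("apoedit")

__all__ = [
    "PipelineConfig",
    "FilterReport",
    "CascadeResult",
    "apply_manual_filters",
    "run_cascade",
    "summarize_by_class",
]

_STRUCTURE_REGIONS = ("exonic", "UTR5", "UTR3")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable thresholds of the cascade (defaults follow the analysis
    conventions documented per module)."""

    min_editing_level: float = 0.05
    fdr_alpha: float = 0.05
    flank_k: int = 15
    loop_lengths: tuple[int, ...] = (3, 4)
    perfect_stem_min: int = 2
    imperfect_stem_min: int = 4
    wobble: bool = False
    chi2_continuity: bool = False
    sanger_min_minor_ratio: float = 0.05
    glm_test: str = "wald"
    fdr_family: str = "joint"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "loop_lengths" in raw:
            raw["loop_lengths"] = tuple(raw["loop_lengths"])
        return cls(**raw)


@dataclass
class FilterReport:
    """Ordered per-stage in/out counts, with per-direction counts where
    the direction classification applies."""

    stages: list[dict] = field(default_factory=list)

    def add(
        self,
        name: str,
        sites_in: int,
        sites_out: int,
        directions: Optional[dict[str, int]] = None,
    ) -> None:
        if sites_out > sites_in:
            raise AssertionError(
                f"stage {name!r} emitted more sites than it received"
            )
        entry = {"stage": name, "sites_in": sites_in, "sites_out": sites_out}
        if directions is not None:
            entry["directions"] = dict(directions)
        self.stages.append(entry)
        logger.info("stage %-12s in=%d out=%d %s", name, sites_in, sites_out,
                    directions or "")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"stages": self.stages}, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass
class CascadeResult:
    results: pd.DataFrame
    report: FilterReport
    pfm_hypoxia: Optional[pd.DataFrame]
    pfm_normoxia: Optional[pd.DataFrame]
    retained: list[SiteCounts]


def apply_manual_filters(
    sites: Sequence[dict],
    config: PipelineConfig = PipelineConfig(),
) -> pd.DataFrame:
    """The two manual filters on C>U events: -1 C/T, then stem-loop in
    exons/UTRs.

    ``sites`` is a sequence of dicts with keys ``ref``, ``alt``, ``flank``
    (plus-strand window), ``region`` and any identifier columns, which are
    passed through.  Returns a frame with per-site pass/fail columns
    ``minus_one_pass``, ``region_ok``, ``stemloop_qualifies`` and the
    conjunction ``retained``.
    """
    rows = []
    for s in sites:
        ctx = to_edited_strand(s["ref"], s["alt"], s["flank"])
        if ctx.edit_class != "C2U":
            raise ValueError("manual filters apply to C>U events only")
        m1 = ctx.base_at(-1) in ("C", "T")
        region_ok = s.get("region", "unknown") in _STRUCTURE_REGIONS
        call = stemloop_predicate(
            ctx.window,
            loop_lengths=config.loop_lengths,
            perfect_stem_min=config.perfect_stem_min,
            imperfect_stem_min=config.imperfect_stem_min,
            wobble=config.wobble,
        )
        row = dict(s)
        row.update(
            minus_one_pass=m1,
            region_ok=region_ok,
            stemloop_qualifies=call.qualifies,
            loop_len=call.loop_len,
            stem_len=call.stem_len,
            defect=call.defect if call.qualifies else None,
            retained=m1 and region_ok and call.qualifies,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _direction_counts(results: Iterable[es.TestResult]) -> dict[str, int]:
    counts = {"hypoxia_higher": 0, "normoxia_higher": 0}
    for r in results:
        if r.direction in counts:
            counts[r.direction] += 1
    return counts


def run_cascade(
    records: Sequence[SiteCounts],
    blacklist: set[SiteKey],
    config: PipelineConfig = PipelineConfig(),
) -> CascadeResult:
    """Run the full cascade and assemble results, report and PFMs."""
    report = FilterReport()
    n0 = len(records)

    stage1 = es.filter_canonical(records)
    report.add("canonical", n0, len(stage1))

    stage2 = es.remove_blacklisted(stage1, blacklist)
    report.add("blacklist", len(stage1), len(stage2))

    stage3 = es.filter_prevalence(stage2, config.min_editing_level)
    report.add("prevalence", len(stage2), len(stage3))

    results = es.test_sites(
        stage3, alpha=config.fdr_alpha, test=config.glm_test,
        fdr_family=config.fdr_family,
    )
    by_key = {r.site_key: r for r in results}
    significant = [rec for rec in stage3 if by_key[rec.site.key].direction != "ns"]
    report.add(
        "glm_fdr", len(stage3), len(significant),
        _direction_counts(by_key[rec.site.key] for rec in significant),
    )

    cu = [r for r in significant if by_key[r.site.key].edit_class == "C2U"]
    ai = [r for r in significant if by_key[r.site.key].edit_class == "A2I"]

    contexts = {}
    for rec in cu:
        if rec.flank is None:
            raise ValueError(f"{rec.site.label}: flank required for manual filters")
        contexts[rec.site.key] = to_edited_strand(
            rec.site.ref, rec.site.alt, rec.flank
        )

    stage5 = [r for r in cu if contexts[r.site.key].base_at(-1) in ("C", "T")]
    report.add(
        "minus_one", len(cu), len(stage5),
        _direction_counts(by_key[rec.site.key] for rec in stage5),
    )

    stage6 = []
    calls = {}
    for rec in stage5:
        call = stemloop_predicate(
            contexts[rec.site.key].window,
            loop_lengths=config.loop_lengths,
            perfect_stem_min=config.perfect_stem_min,
            imperfect_stem_min=config.imperfect_stem_min,
            wobble=config.wobble,
        )
        calls[rec.site.key] = call
        if call.qualifies and rec.site.region in _STRUCTURE_REGIONS:
            stage6.append(rec)
    report.add(
        "stemloop", len(stage5), len(stage6),
        _direction_counts(by_key[rec.site.key] for rec in stage6),
    )

    retained_keys = {r.site.key for r in stage6}
    stage5_keys = {r.site.key for r in stage5}
    rows = []
    for rec in stage3:
        res = by_key[rec.site.key]
        call = calls.get(rec.site.key)
        rows.append(
            {
                "chrom": rec.site.chrom,
                "pos": rec.site.pos,
                "ref": rec.site.ref,
                "alt": rec.site.alt,
                "gene": rec.site.gene,
                "region": rec.site.region,
                "aa_effect": rec.site.aa_effect,
                "edit_class": res.edit_class,
                "log_or": res.log_or,
                "p_value": res.p_value,
                "q_value": res.q_value,
                "direction": res.direction,
                "separation_corrected": res.separation_corrected,
                "minus_one_pass": rec.site.key in stage5_keys
                if res.edit_class == "C2U" and res.direction != "ns" else pd.NA,
                "stemloop_qualifies": call.qualifies if call else pd.NA,
                "retained": rec.site.key in retained_keys
                if res.edit_class == "C2U" and res.direction != "ns"
                else (res.direction != "ns" if res.edit_class == "A2I" else False),
            }
        )
    results_df = pd.DataFrame(rows)

    def _pfm_for(direction: str) -> Optional[pd.DataFrame]:
        windows = [
            contexts[r.site.key].window
            for r in stage6
            if by_key[r.site.key].direction == direction
        ]
        return build_pfm(windows) if windows else None

    return CascadeResult(
        results=results_df,
        report=report,
        pfm_hypoxia=_pfm_for("hypoxia_higher"),
        pfm_normoxia=_pfm_for("normoxia_higher"),
        retained=stage6 + ai,
    )


def summarize_by_class(
    retained: Sequence[SiteCounts],
) -> pd.DataFrame:
    """Counts and mean editing levels per mutational-impact class.

    UTR sites form their own class regardless of aa_effect; exonic sites
    split into missense / stopgain / synonymous.  Mean levels are computed
    per condition over covered samples.
    """
    rows = []
    for rec in retained:
        if rec.site.region in ("UTR5", "UTR3"):
            cls = "UTR"
        elif rec.site.aa_effect in ("missense", "stopgain", "synonymous"):
            cls = rec.site.aa_effect
        else:
            cls = "other"
        for o in rec.observations:
            if o.ref_count + o.alt_count == 0:
                continue
            rows.append(
                {
                    "class": cls,
                    "condition": o.condition,
                    "level": o.alt_count / (o.ref_count + o.alt_count),
                    "site": rec.site.label,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["class", "n_sites", "mean_level_normoxia", "mean_level_hypoxia"]
        )
    df = pd.DataFrame(rows)
    out = (
        df.pivot_table(index="class", columns="condition", values="level",
                       aggfunc="mean")
        .rename(columns=lambda c: f"mean_level_{c}")
    )
    out["n_sites"] = df.groupby("class")["site"].nunique()
    return out.reset_index()
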