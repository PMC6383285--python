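"""Synthetic paired normoxia/hypoxia editing datasets.

Emulates the study design the downstream analysis assumes: a small donor
cohort sampled under both oxygen conditions, binomial alt-read counts at
each candidate site, hairpin (stem-loop) sequence context planted around
truly edited cytidines, SNP contaminants at ~50%/100% alt fraction in all
samples, and sub-5% noise sites.  Every emitted site carries a truth
label so recall/specificity of the full filter cascade can be measured.

Site classes
------------
``edited_up_hypoxia``   binomial editing, logit shifted by +effect in hypoxia
``edited_up_normoxia``  the same shift applied to the normoxia samples
``snp_het`` / ``snp_hom``  alt fraction ~0.5 / ~1.0 in every sample;
                           these sites appear in the emitted SNP blacklist
``noise``               alt fraction drawn below the 5% prevalence cutoff
``null``                baseline editing, no condition effect

Donor pairing is emulated with per-site donor random intercepts on the
logit scale; flanking windows are i.i.d. uniform A/C/G/T except for
planted hairpins and the -1 dinucleotide of edited sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    EditingSite,
    SampleObservation,
    SiteCounts,
    SiteKey,
    write_blacklist_vcf,
    write_site_table,
)
from .stemloop import StemLoopCall, stemloop_predicate, _pair_indices

__all__ = ["SimConfig", "SimDataset", "synth_flank", "synth_site_counts",
           "synth_dataset", "write_dataset"]

CLASSES = (
    "edited_up_hypoxia",
    "edited_up_normoxia",
    "snp_het",
    "snp_hom",
    "noise",
    "null",
)

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _expit(x: float) -> float:
    return float(1.0 / (1.0 + np.exp(-x)))


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Defaults mirror the emulated study: 3 donors sampled under both
    conditions, per-sample depths of 20-200 reads, ~2% baseline editing
    shifted by +2 logits in the induced condition (giving ~10-30% hypoxia
    editing levels), noise sites strictly below the 5% prevalence cutoff,
    and hairpins planted around every truly edited C.
    """

    n_donors: int = 3
    depth_range: tuple[int, int] = (20, 200)
    n_edited_up_hypoxia: int = 60
    n_edited_up_normoxia: int = 20
    n_snp_het: int = 30
    n_snp_hom: int = 30
    n_noise: int = 40
    n_null: int = 100
    baseline_logit: float = _logit(0.02)
    effect_logit: float = 2.0
    donor_sd: float = 0.3
    planted_stemloop_frac: float = 1.0
    minus_one_c_frac: float = 0.7
    flank_k: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_donors", "n_edited_up_hypoxia", "n_edited_up_normoxia",
            "n_snp_het", "n_snp_hom", "n_noise", "n_null",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must satisfy 0 < low <= high")
        for name in ("planted_stemloop_frac", "minus_one_c_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.donor_sd < 0:
            raise ValueError("donor_sd must be >= 0")


@dataclass
class SimDataset:
    """A generated dataset plus its ground truth."""

    records: list[SiteCounts]
    blacklist: set[SiteKey]
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def synth_flank(
    rng: np.random.Generator,
    plant: bool,
    loop_len: int = 3,
    stem_len: int = 2,
    defect: str = "none",
    *,
    k: int = 15,
    minus_one: Optional[str] = None,
    defect_offset: Optional[int] = None,
    bulge_arm: Optional[str] = None,
    max_tries: int = 500,
) -> str:
    """A 2k+1 window with center C, with or without a planted hairpin.

    ``plant=True`` constructs the requested geometry (loop length 3 or 4,
    stem of ``stem_len`` pairs, optional single mismatch or bulge) and
    resamples the background until the structural predicate reports
    exactly that loop length and defect type, so generator and predicate
    agree by construction.  ``plant=False`` rejection-samples uniform
    windows until the predicate reports no structure.
    """
    if plant:
        if loop_len not in (3, 4):
            raise ValueError("loop_len must be 3 or 4")
        min_stem = 2 if defect == "none" else 4
        if stem_len < min_stem:
            raise ValueError(f"stem_len must be >= {min_stem} for defect={defect!r}")
        if defect not in ("none", "mismatch", "bulge"):
            raise ValueError(f"unknown defect {defect!r}")
    e = k
    for _ in range(max_tries):
        w = list(rng.choice(_BASES, size=2 * k + 1))
        w[e] = "C"
        if plant:
            arm = bulge_arm
            off = defect_offset
            if defect == "mismatch":
                off = off if off is not None else int(rng.integers(2, stem_len))
                if not (2 <= off <= stem_len - 1):
                    raise ValueError("mismatch offset must be interior (2..stem_len-1)")
            elif defect == "bulge":
                off = off if off is not None else int(rng.integers(1, stem_len))
                if not (1 <= off <= stem_len - 1):
                    raise ValueError("bulge offset must be interior (1..stem_len-1)")
                if arm is None:
                    arm = "five_prime" if rng.random() < 0.5 else "three_prime"
            b_arm = arm if defect == "bulge" else None
            b_after = off if defect == "bulge" else 0
            for i in range(1, stem_len + 1):
                five, three = _pair_indices(e, loop_len, i, b_arm, b_after)
                x = str(rng.choice(_BASES))
                w[five] = x
                if defect == "mismatch" and i == off:
                    w[three] = str(rng.choice([b for b in "ACGT" if b != _COMP[x]]))
                else:
                    w[three] = _COMP[x]
        if minus_one is not None:
            w[e - 1] = minus_one
        window = "".join(w)
        call = stemloop_predicate(window)
        if plant:
            if call.qualifies and call.loop_len == loop_len and call.defect == defect:
                return window
        else:
            if not call.qualifies:
                return window
    raise RuntimeError(
        f"flank synthesis failed after {max_tries} tries "
        f"(plant={plant}, loop_len={loop_len}, stem_len={stem_len}, defect={defect})"
    )


def _class_probability(
    rng: np.random.Generator, config: SimConfig, cls: str
) -> tuple[float, float]:
    """(normoxia logit-or-p spec, effect) — see synth_site_counts."""
    if cls == "edited_up_hypoxia":
        return config.baseline_logit, config.effect_logit
    if cls == "edited_up_normoxia":
        return config.baseline_logit, -config.effect_logit
    if cls == "null":
        return config.baseline_logit, 0.0
    raise ValueError(cls)


def synth_site_counts(
    rng: np.random.Generator,
    config: SimConfig,
    cls: str,
    true_effect: Optional[float] = None,
) -> list[SampleObservation]:
    """Donor-paired binomial counts for one site of a given truth class.

    Edited/null classes draw alt ~ Binomial(depth, p) with
    logit p = baseline + donor intercept + effect * [hypoxia]; SNP classes
    use p ~ 0.5 (het) or ~1 (hom) in every sample; noise sites share one
    sub-5% p across samples and conditions.
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    lo, hi = config.depth_range
    donor_eff = rng.normal(0.0, config.donor_sd, size=config.n_donors)
    noise_p = float(rng.uniform(0.0, 0.04)) if cls == "noise" else None
    obs: list[SampleObservation] = []
    for d in range(config.n_donors):
        for cond in ("normoxia", "hypoxia"):
            depth = int(rng.integers(lo, hi + 1))
            if cls == "snp_het":
                p = 0.5
            elif cls == "snp_hom":
                p = 0.998
            elif cls == "noise":
                p = noise_p
            else:
                effect = (
                    true_effect
                    if true_effect is not None
                    else _class_probability(rng, config, cls)[1]
                )
                logit_p = config.baseline_logit + donor_eff[d]
                if cls == "edited_up_hypoxia" and cond == "hypoxia":
                    logit_p += abs(effect)
                elif cls == "edited_up_normoxia" and cond == "normoxia":
                    logit_p += abs(effect)
                p = _expit(logit_p)
            alt = int(rng.binomial(depth, p))
            obs.append(
                SampleObservation(
                    sample_id=f"d{d + 1}_{cond[0].upper()}",
                    donor_id=f"d{d + 1}",
                    condition=cond,
                    ref_count=depth - alt,
                    alt_count=alt,
                )
            )
    return obs


_EDITED_REGIONS = ("exonic", "UTR5", "UTR3")
_OTHER_REGIONS = ("exonic", "UTR5", "UTR3", "intronic", "ncRNA", "intergenic")
_AA_EFFECTS = ("missense", "synonymous", "stopgain")


def synth_dataset(config: SimConfig) -> SimDataset:
    """Generate a full labelled dataset: site/count/flank records, the SNP
    blacklist, and a per-site truth table.  Deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    records: list[SiteCounts] = []
    blacklist: set[SiteKey] = set()
    truth_rows: list[dict] = []
    pos = 1000
    class_counts = (
        ("edited_up_hypoxia", config.n_edited_up_hypoxia),
        ("edited_up_normoxia", config.n_edited_up_normoxia),
        ("snp_het", config.n_snp_het),
        ("snp_hom", config.n_snp_hom),
        ("noise", config.n_noise),
        ("null", config.n_null),
    )
    for cls, n in class_counts:
        for i in range(n):
            edited = cls.startswith("edited")
            if edited:
                region = str(rng.choice(_EDITED_REGIONS, p=[0.6, 0.15, 0.25]))
            else:
                region = str(rng.choice(_OTHER_REGIONS))
            aa = str(rng.choice(_AA_EFFECTS)) if region == "exonic" else "none"
            site = EditingSite(
                chrom="chr1", pos=pos, ref="C", alt="T",
                gene=f"G{pos}", region=region, aa_effect=aa,
            )
            pos += 1000

            planted: Optional[StemLoopCall] = None
            minus_one = None
            if edited:
                minus_one = "C" if rng.random() < config.minus_one_c_frac else "T"
                if rng.random() < config.planted_stemloop_frac:
                    loop_len = int(rng.choice((3, 4)))
                    defect = str(rng.choice(("none", "mismatch", "bulge"),
                                            p=[0.7, 0.15, 0.15]))
                    stem_len = 2 if defect == "none" else 4
                    window = synth_flank(
                        rng, True, loop_len, stem_len, defect,
                        k=config.flank_k, minus_one=minus_one,
                    )
                    planted = stemloop_predicate(window)
                else:
                    window = synth_flank(
                        rng, False, k=config.flank_k, minus_one=minus_one
                    )
            else:
                w = list(rng.choice(_BASES, size=2 * config.flank_k + 1))
                w[config.flank_k] = site.ref
                window = "".join(w)

            effect = (
                config.effect_logit if cls == "edited_up_hypoxia"
                else -config.effect_logit if cls == "edited_up_normoxia"
                else 0.0
            )
            obs = synth_site_counts(rng, config, cls)
            records.append(SiteCounts(site=site, observations=obs, flank=window))
            if cls in ("snp_het", "snp_hom"):
                blacklist.add(site.key)
            truth_rows.append(
                {
                    "site_id": site.label,
                    "chrom": site.chrom,
                    "pos": site.pos,
                    "ref": site.ref,
                    "alt": site.alt,
                    "class": cls,
                    "true_effect_logit": effect,
                    "planted": planted is not None,
                    "loop_len": planted.loop_len if planted else pd.NA,
                    "stem_len": planted.stem_len if planted else pd.NA,
                    "defect": planted.defect if planted else pd.NA,
                }
            )
    truth = pd.DataFrame(truth_rows)
    return SimDataset(records=records, blacklist=blacklist, truth=truth,
                      config=config)


def write_dataset(dataset: SimDataset, outdir: str | Path) -> dict[str, Path]:
    """Write counts.tsv, blacklist.vcf and truth.tsv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "blacklist": outdir / "blacklist.vcf",
        "truth": outdir / "truth.tsv",
    }
    write_site_table(dataset.records, paths["counts"])
    write_blacklist_vcf(dataset.blacklist, paths["blacklist"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
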