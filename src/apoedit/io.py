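"""Readers/writers for site tables, flanks, blacklists and site sets.

Coordinate convention: all positions are 1-based inclusive internally
(matching the field's site notation, e.g. ``1:32231146-CT``); BED input
is converted from 0-based half-open at the boundary.

The site/counts table is a long-format TSV with one row per site x sample:

    chrom pos ref alt sample_id donor_id condition ref_count alt_count
    [gene region aa_effect flank ...]

Unknown columns are preserved as per-site annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

__all__ = [
    "EditingSite",
    "SampleObservation",
    "SiteCounts",
    "SiteKey",
    "CONDITIONS",
    "REGIONS",
    "read_site_table",
    "write_site_table",
    "site_counts_to_frame",
    "extract_flank",
    "read_blacklist",
    "read_site_set",
    "write_blacklist_vcf",
]

SiteKey = tuple[str, int, str, str]

BASES = {"A", "C", "G", "T"}
CONDITIONS = ("normoxia", "hypoxia")
REGIONS = ("exonic", "UTR5", "UTR3", "intronic", "ncRNA", "intergenic", "unknown")
AA_EFFECTS = ("synonymous", "missense", "stopgain", "none")

MANDATORY_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "sample_id", "donor_id", "condition", "ref_count", "alt_count",
]


@dataclass(frozen=True)
class EditingSite:
    """A genomic candidate editing site with optional annotation labels."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    region: str = "unknown"
    aa_effect: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"ref/alt must be A/C/G/T, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.aa_effect is not None and self.aa_effect not in AA_EFFECTS:
            raise ValueError(f"unknown aa_effect {self.aa_effect!r}")

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SampleObservation:
    """Ref/alt read counts for one site in one sample."""

    sample_id: str
    donor_id: str
    condition: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class SiteCounts:
    """One site's donor-paired per-condition observations (plus flank)."""

    site: EditingSite
    observations: list[SampleObservation] = field(default_factory=list)
    flank: Optional[str] = None
    annotations: dict = field(default_factory=dict)

    def is_paired(self) -> bool:
        """True iff every donor appears exactly once per condition."""
        seen = {}
        for o in self.observations:
            key = (o.donor_id, o.condition)
            if key in seen:
                return False
            seen[key] = True
        donors = {o.donor_id for o in self.observations}
        return all(
            (d, c) in seen for d in donors for c in CONDITIONS
        )


def read_site_table(path: str | Path) -> list[SiteCounts]:
    """Parse a long-format site/counts TSV into per-site records."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site table missing mandatory column(s): {missing}")
    for col in ("ref_count", "alt_count"):
        if not pd.api.types.is_integer_dtype(df[col]):
            raise ValueError(f"column {col!r} must be integer-valued")
    extra = [c for c in df.columns if c not in MANDATORY_COLUMNS
             and c not in ("gene", "region", "aa_effect", "flank")]
    records: list[SiteCounts] = []
    for key, grp in df.groupby(["chrom", "pos", "ref", "alt"], sort=False):
        first = grp.iloc[0]
        site = EditingSite(
            chrom=str(key[0]),
            pos=int(key[1]),
            ref=str(key[2]),
            alt=str(key[3]),
            gene=None if "gene" not in grp or pd.isna(first.get("gene")) else str(first["gene"]),
            region=str(first["region"]) if "region" in grp and not pd.isna(first.get("region")) else "unknown",
            aa_effect=None if "aa_effect" not in grp or pd.isna(first.get("aa_effect")) else str(first["aa_effect"]),
        )
        obs = [
            SampleObservation(
                sample_id=str(r.sample_id),
                donor_id=str(r.donor_id),
                condition=str(r.condition),
                ref_count=int(r.ref_count),
                alt_count=int(r.alt_count),
            )
            for r in grp.itertuples()
        ]
        flank = None
        if "flank" in grp.columns and not pd.isna(first.get("flank")):
            flank = str(first["flank"]).upper()
        annotations = {c: first[c] for c in extra}
        records.append(SiteCounts(site=site, observations=obs, flank=flank,
                                  annotations=annotations))
    return records


def site_counts_to_frame(records: Iterable[SiteCounts]) -> pd.DataFrame:
    """Long-format DataFrame mirroring the on-disk TSV layout."""
    rows = []
    for rec in records:
        s = rec.site
        for o in rec.observations:
            row = {
                "chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
                "gene": s.gene, "region": s.region, "aa_effect": s.aa_effect,
                "sample_id": o.sample_id, "donor_id": o.donor_id,
                "condition": o.condition,
                "ref_count": o.ref_count, "alt_count": o.alt_count,
                "flank": rec.flank,
            }
            row.update(rec.annotations)
            rows.append(row)
    return pd.DataFrame(rows)


def write_site_table(records: Iterable[SiteCounts], path: str | Path) -> None:
    site_counts_to_frame(records).to_csv(path, sep="\t", index=False)


def extract_flank(genome, site: EditingSite, k: int = 15) -> str:
    """2k+1 window around ``site`` on the reference plus strand.

    ``genome`` is a FASTA path or an open ``pyfaidx.Fasta``.  Windows
    truncated at contig edges are padded with N; the center base must
    equal ``site.ref`` (a mismatch signals a coordinate-convention bug).
    """
    from pyfaidx import Fasta

    fa = genome if not isinstance(genome, (str, Path)) else Fasta(str(genome))
    if site.chrom not in fa:
        raise KeyError(f"contig {site.chrom!r} absent from genome")
    contig = fa[site.chrom]
    n = len(contig)
    if not (1 <= site.pos <= n):
        raise ValueError(f"position {site.pos} outside contig of length {n}")
    lo = max(0, site.pos - 1 - k)
    hi = min(n, site.pos + k)
    seq = str(contig[lo:hi]).upper()
    window = "N" * (k - (site.pos - 1 - lo)) + seq + "N" * (k - (hi - site.pos))
    center = window[k]
    if center != site.ref:
        raise ValueError(
            f"center base {center!r} at {site.chrom}:{site.pos} disagrees "
            f"with site ref {site.ref!r}"
        )
    return window


def _parse_vcf_sites(path: Path) -> set[SiteKey]:
    keys: set[SiteKey] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 VCF columns")
            chrom, pos, _id, ref, alts = fields[:5]
            try:
                pos_i = int(pos)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer POS {pos!r}") from exc
            for alt in alts.split(","):
                keys.add((chrom, pos_i, ref.upper(), alt.upper()))
    return keys


def read_blacklist(path: str | Path) -> set[SiteKey]:
    """Known-SNP blacklist from a VCF (CHROM/POS/REF/ALT; multi-allelic
    records expanded) or a TSV with chrom/pos/ref/alt columns."""
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    if path.suffix == ".vcf" or head.startswith("##fileformat=VCF"):
        return _parse_vcf_sites(path)
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = ["chrom", "pos", "ref", "alt"]
    if not all(c in df.columns for c in needed):
        raise ValueError(f"TSV blacklist must carry columns {needed}")
    return {
        (str(r.chrom), int(r.pos), str(r.ref).upper(), str(r.alt).upper())
        for r in df.itertuples()
    }


def read_site_set(path: str | Path, *, bed: bool | None = None) -> set[tuple]:
    """Site-position set from BED3 (0-based half-open) or 1-based TSV.

    The convention must be declared via ``bed=True/False`` unless the file
    extension is ``.bed``.  Keys are (chrom, 1-based pos) tuples; BED
    intervals are expanded positionwise.  Duplicates collapse.
    """
    path = Path(path)
    if bed is None:
        if path.suffix == ".bed":
            bed = True
        else:
            raise ValueError(
                "declare the coordinate convention: bed=True (0-based "
                "half-open) or bed=False (1-based positions)"
            )
    keys: set[tuple] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if bed:
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    for pos in range(start + 1, end + 1):
                        keys.add((chrom, pos))
                else:
                    chrom, pos = fields[0], int(fields[1])
                    keys.add((chrom, pos))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable record") from exc
    return keys


def write_blacklist_vcf(keys: Iterable[SiteKey], path: str | Path) -> None:
    """Minimal VCF v4.2 (CHROM POS ID REF ALT QUAL FILTER INFO)."""
    rows = sorted(set(keys))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in rows:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")
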