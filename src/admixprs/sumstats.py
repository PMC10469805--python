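"""GWAS summary statistics: reading, harmonization, and region masking.

Summary statistics are kept in a tab-delimited format with header columns
CHR, POS, EA, OA, BETA, SE, P, EAF (effect allele EA, other allele OA,
effect size BETA on the log odds-ratio scale).  Harmonization aligns each
record to a target genotype panel: effect alleles are matched to the
panel's alternate allele (flipping the sign of BETA where needed), strand
flips are resolved through base complementation, strand-ambiguous A/T and
C/G variants are dropped, and variants rarer than a minor-allele-frequency
floor in the panel are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import GenotypePanel

logger = logging.getLogger(__name__)

SUMSTATS_COLUMNS = ["CHR", "POS", "EA", "OA", "BETA", "SE", "P", "EAF"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _complement(allele: str) -> str | None:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele.upper()))
    except KeyError:
        return None


def is_strand_ambiguous(ea: str, oa: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved without frequencies."""
    return _complement(ea) == oa


@dataclass
class GenomicRegion:
    """Half-open genomic interval [start, end) on one chromosome."""

    chromosome: str
    start: int
    end: int
    inclusive_end: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("region start must be < end")

    @classmethod
    def from_center(
        cls, chromosome: str, center: int, width: int, inclusive_end: bool = False
    ) -> "GenomicRegion":
        half = width // 2
        return cls(chromosome, center - half, center + half, inclusive_end)

    def contains(self, chrom, pos) -> np.ndarray:
        chrom = np.asarray(chrom, dtype=str)
        pos = np.asarray(pos)
        upper = pos <= self.end if self.inclusive_end else pos < self.end
        return (chrom == str(self.chromosome)) & (pos >= self.start) & upper


#: 1 Mb window centered on the APOE signal at chr19:44,908,822 (hg38).
APOE_REGION = GenomicRegion.from_center("19", 44908822, 1_000_000)


@dataclass
class SummaryStatSet:
    """One GWAS's per-variant effect estimates and p-values."""

    gwas_name: str
    records: pd.DataFrame
    build: str = "hg38"
    provenance: str = ""
    drop_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"summary statistics missing columns: {missing}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        r = self.records
        if (r["SE"] <= 0).any():
            raise ValueError("SE must be positive")
        if ((r["P"] <= 0) | (r["P"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        if (r["EA"] == r["OA"]).any():
            raise ValueError("effect allele must differ from other allele")

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"##gwas_name={self.gwas_name}\n")
            fh.write(f"##build={self.build}\n")
            if self.provenance:
                fh.write(f"##provenance={self.provenance}\n")
            self.records.to_csv(fh, sep="\t", index=False)


def read_sumstats(
    path: str,
    column_map: dict[str, str] | None = None,
    or_scale: bool = False,
    sep: str = "\t",
    gwas_name: str | None = None,
    build: str = "hg38",
) -> SummaryStatSet:
    """Parse a delimited summary-statistics file.

    Parameters
    ----------
    column_map : dict
        Maps standard names (CHR, POS, EA, OA, BETA, SE, P, EAF) to the
        source file's headers.  Omitted entries default to the standard
        name itself.  EAF may be absent in the source (filled with NaN).
    or_scale : bool
        When True the effect column holds odds ratios and is converted to
        the log scale.

    Rows with unparseable or out-of-range effect sizes or p-values are
    dropped; counts per drop reason are stored in ``drop_counts`` and
    logged.
    """
    header_meta: dict[str, str] = {}
    with open(path) as fh:
        skip = 0
        for line in fh:
            if line.startswith("##"):
                key, _, val = line[2:].strip().partition("=")
                header_meta[key] = val
                skip += 1
            else:
                break
    df = pd.read_csv(path, sep=sep, skiprows=skip)
    if df.empty:
        raise ValueError(f"empty summary-statistics file: {path}")
    column_map = dict(column_map or {})
    out = {}
    for std in SUMSTATS_COLUMNS:
        src = column_map.get(std, std)
        if src in df.columns:
            out[std] = df[src]
        elif std == "EAF":
            out[std] = np.nan
        else:
            raise ValueError(f"mandatory column '{src}' (for {std}) not found in {path}")
    rec = pd.DataFrame(out)
    rec["CHR"] = rec["CHR"].astype(str).str.removeprefix("chr")
    rec["POS"] = pd.to_numeric(rec["POS"], errors="coerce")
    for col in ("BETA", "SE", "P", "EAF"):
        rec[col] = pd.to_numeric(rec[col], errors="coerce")
    drops: dict[str, int] = {}
    n0 = len(rec)
    ok = rec["POS"].notna() & rec["BETA"].notna() & rec["P"].notna() & rec["SE"].notna()
    drops["unparseable"] = int((~ok).sum())
    rec = rec[ok]
    if or_scale:
        bad = rec["BETA"] <= 0
        drops["nonpositive_or"] = int(bad.sum())
        rec = rec[~bad]
        rec = rec.assign(BETA=np.log(rec["BETA"]))
    bad = (rec["P"] <= 0) | (rec["P"] > 1) | (rec["SE"] <= 0)
    drops["out_of_range"] = int(bad.sum())
    rec = rec[~bad]
    bad = rec["EA"].astype(str) == rec["OA"].astype(str)
    drops["identical_alleles"] = int(bad.sum())
    rec = rec[~bad]
    rec = rec.assign(
        POS=rec["POS"].astype(int),
        EA=rec["EA"].astype(str).str.upper(),
        OA=rec["OA"].astype(str).str.upper(),
    )
    drops = {k: v for k, v in drops.items() if v}
    if drops:
        logger.warning("read_sumstats(%s): dropped rows %s", path, drops)
    ss = SummaryStatSet(
        gwas_name=gwas_name or header_meta.get("gwas_name", "gwas"),
        records=rec.reset_index(drop=True),
        build=header_meta.get("build", build),
        provenance=header_meta.get("provenance", f"read from {path}"),
        drop_counts=drops,
    )
    ss.validate()
    return ss


def harmonize(
    sumstats: SummaryStatSet, panel: GenotypePanel, maf_min: float = 0.01
) -> SummaryStatSet:
    """Align summary statistics to a genotype panel.

    Matching is by (chromosome, position) plus allele reconciliation; the
    output's EA is always the panel's alternate allele (BETA negated when
    the source effect allele was the reference allele), EAF is replaced by
    the panel alternate-allele frequency, and variants whose panel
    minor-allele frequency is strictly below ``maf_min`` are dropped.
    Drop reasons are counted so that retained + dropped = input.
    """
    rec = sumstats.records
    v = panel.variants
    pv = pd.DataFrame(
        {
            "CHR": v["chrom"].astype(str).str.removeprefix("chr"),
            "POS": v["pos"].astype(int),
            "ref": v["ref"].str.upper(),
            "alt": v["alt"].str.upper(),
            "panel_af": v["af"].astype(float),
        }
    )
    merged = rec.reset_index().merge(pv, on=["CHR", "POS"], how="left")

    ea, oa = merged["EA"], merged["OA"]
    ref, alt = merged["ref"], merged["alt"]
    ea_c = ea.map(lambda a: _complement(a) or "?")
    oa_c = oa.map(lambda a: _complement(a) or "?")

    matched = merged["ref"].notna()
    ambiguous_strand = matched & np.array(
        [is_strand_ambiguous(e, o) for e, o in zip(ea, oa)], dtype=bool
    )
    direct = matched & (ea == alt) & (oa == ref)
    flipped = matched & (ea == ref) & (oa == alt)
    comp_direct = matched & (ea_c == alt) & (oa_c == ref)
    comp_flipped = matched & (ea_c == ref) & (oa_c == alt)

    usable = (direct | flipped | comp_direct | comp_flipped) & ~ambiguous_strand
    # A position may host several panel allele pairs; keep only rows with a
    # unique allele-resolved match, never guess.
    match_counts = merged.loc[usable].groupby("index")["index"].transform("size")
    multi = match_counts.index[match_counts > 1]
    usable.loc[multi] = False

    keep = merged[usable].copy()
    negate = (flipped | comp_flipped)[usable]
    keep["BETA"] = np.where(negate, -keep["BETA"], keep["BETA"])
    keep["EA"], keep["OA"] = keep["alt"], keep["ref"]
    keep["EAF"] = keep["panel_af"]

    maf = np.minimum(keep["panel_af"], 1 - keep["panel_af"])
    low_maf = maf < maf_min
    keep = keep[~low_maf]

    dup = keep.duplicated(subset=["CHR", "POS", "EA", "OA"], keep="first")
    keep = keep[~dup]

    n_in = len(rec)
    matched_idx = set(merged.loc[matched, "index"])
    usable_idx = set(merged.loc[usable, "index"])
    ambiguous_idx = set(merged.loc[ambiguous_strand, "index"])
    drops = {
        "unmatched": n_in - len(set(merged.loc[matched, "index"])),
        "strand_ambiguous": len(ambiguous_idx),
        "ambiguous_alleles": len(matched_idx - usable_idx - ambiguous_idx),
        "low_maf": int(low_maf.sum()),
        "duplicate": int(dup.sum()),
    }
    drops = {k: n for k, n in drops.items() if n}
    out = keep[SUMSTATS_COLUMNS].reset_index(drop=True)
    retained = len(out)
    assert retained + sum(drops.values()) == n_in
    if drops:
        logger.info("harmonize(%s): dropped %s", sumstats.gwas_name, drops)
    return replace(
        sumstats,
        records=out,
        drop_counts=drops,
        provenance=sumstats.provenance + f" | harmonized (maf_min={maf_min})",
    )


def exclude_region(sumstats: SummaryStatSet, region: GenomicRegion) -> SummaryStatSet:
    """Remove all records falling inside ``region`` (half-open by default)."""
    rec = sumstats.records
    inside = region.contains(rec["CHR"], rec["POS"])
    n_removed = int(inside.sum())
    logger.info(
        "exclude_region(%s): removed %d records in %s:%d-%d",
        sumstats.gwas_name,
        n_removed,
        region.chromosome,
        region.start,
        region.end,
    )
    return replace(
        sumstats,
        records=rec[~inside].reset_index(drop=True),
        drop_counts={"region_excluded": n_removed},
        provenance=sumstats.provenance
        + f" | region {region.chromosome}:{region.start}-{region.end} excluded",
    )
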