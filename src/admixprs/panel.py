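"""Genotype panel container and VCF input/output.

A :class:`GenotypePanel` holds a samples x variants dosage matrix (expected
alternate-allele counts in [0, 2], ``NaN`` for missing) together with a
variant table.  It is the LD reference for clumping, the allele-frequency
source for harmonization, and the scoring target for PRS construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "af"]


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric-first chromosome ordering ('1' < '2' < ... < 'X')."""
    order = {str(i): i for i in range(1, 23)}
    order.update({"X": 23, "Y": 24, "MT": 25, "M": 25})
    return chrom.astype(str).str.removeprefix("chr").map(lambda c: order.get(c, 26))


@dataclass
class GenotypePanel:
    """Dosage matrix of target individuals with variant annotations.

    Parameters
    ----------
    sample_ids : list of str
    variants : DataFrame with columns chrom, pos, ref, alt, af
        Positions are 1-based; ``af`` is the alternate-allele frequency.
    dosages : ndarray, shape (n_samples, n_variants)
        Alternate-allele dosage in [0, 2]; NaN marks missing genotypes.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing == ["af"]:
            self.variants = self.variants.assign(af=self.empirical_af())
        elif missing:
            raise ValueError(f"variant table missing columns: {missing}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape does not match samples x variants")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or np.nanmax(
                self.dosages, initial=0.0
            ) > 2 + 1e-9:
                raise ValueError("dosages must lie in [0, 2]")
        self._check_sorted()

    def _check_sorted(self) -> None:
        v = self.variants
        key = _chrom_sort_key(v["chrom"])
        for _, grp in v.groupby(key, sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must be sorted within chromosome")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> pd.Series:
        v = self.variants
        return (
            v["chrom"].astype(str)
            + ":"
            + v["pos"].astype(str)
            + ":"
            + v["ref"]
            + ":"
            + v["alt"]
        )

    def empirical_af(self) -> np.ndarray:
        """Alternate-allele frequency from mean dosage / 2, ignoring missing."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def locate(self, chrom: str, pos: int) -> np.ndarray:
        """Indices of variants at (chrom, pos); may be multi-allelic."""
        v = self.variants
        return np.flatnonzero((v["chrom"].astype(str) == str(chrom)) & (v["pos"] == pos))

    # -- I/O -------------------------------------------------------------
    def to_vcf(self, path: str) -> None:
        """Write a minimal text VCF with dosages in the DS FORMAT field."""
        v = self.variants
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
            for chrom in v["chrom"].astype(str).unique():
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.sample_ids)
                + "\n"
            )
            keys = self.variant_keys()
            for j in range(self.n_variants):
                row = v.iloc[j]
                ds = [
                    "." if np.isnan(d) else f"{d:.4g}" for d in self.dosages[:, j]
                ]
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t{keys.iloc[j]}\t{row['ref']}\t"
                    f"{row['alt']}\t.\t.\t.\tDS\t" + "\t".join(ds) + "\n"
                )

    @classmethod
    def from_vcf(cls, path: str) -> "GenotypePanel":
        """Read a VCF; DS field preferred, GT fallback as alt-allele count."""
        from cyvcf2 import VCF

        vcf = VCF(path)
        samples = list(vcf.samples)
        chroms, poss, refs, alts, cols = [], [], [], [], []
        for var in vcf:
            alt = var.ALT[0] if var.ALT else "."
            ds = var.format("DS")
            if ds is not None:
                col = np.asarray(ds, dtype=float).reshape(len(samples))
                col = np.where((col < -0.5) | (col > 2.5), np.nan, col)
            else:
                gt = np.asarray(var.genotype.array())[:, :2]
                col = np.where(gt < 0, np.nan, gt).sum(axis=1).astype(float)
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(alt)
            cols.append(col)
        variants = pd.DataFrame(
            {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
        )
        dosages = (
            np.column_stack(cols) if cols else np.empty((len(samples), 0))
        )
        return cls(sample_ids=samples, variants=variants, dosages=dosages)
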