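"""Clump-and-threshold PRS engine.

Implements the construction of candidate polygenic risk scores from
harmonized GWAS summary statistics and a genotype panel:

* LD as the squared Pearson correlation of dosages (``ld_r2``);
* greedy p-value-ordered clumping within a distance window (``clump``);
* the candidate grid over (r2_max, window_kb, p_threshold) combinations
  (``build_candidate_grid``) — thresholding is applied after clumping;
* additive scoring of individuals with mean imputation of missing
  dosages (``score``).

Models serialize to a PGS-Catalog-style scoring file (chr_name,
chr_position, effect_allele, other_allele, effect_weight).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .sumstats import GenomicRegion, SummaryStatSet, _complement

logger = logging.getLogger(__name__)

#: Clumping grid used for PRS construction: R^2 in {0.1, 0.2, 0.3},
#: distance windows {250, 500, 100} kb, and twelve p-value thresholds.
DEFAULT_R2_GRID = (0.1, 0.2, 0.3)
DEFAULT_WINDOW_GRID_KB = (250, 500, 100)
DEFAULT_P_THRESHOLDS = (
    5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 0.1, 0.2, 0.3, 0.4, 0.5,
)

WEIGHT_COLUMNS = ["chrom", "pos", "effect_allele", "other_allele", "beta"]


@dataclass(frozen=True)
class ClumpParams:
    """Clumping/thresholding parameters for one candidate PRS."""

    r2_max: float
    window_kb: int
    p_threshold: float

    def __post_init__(self) -> None:
        if not 0 < self.r2_max < 1:
            raise ValueError("r2_max must be in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must be in (0, 1]")


@dataclass
class PRSModel:
    """A variant weight list plus construction parameters and reference stats."""

    gwas_name: str
    params: ClumpParams | None
    weights: pd.DataFrame
    reference_mean: float | None = None
    reference_sd: float | None = None
    includes_apoe_region: bool = True
    degenerate: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in WEIGHT_COLUMNS if c not in self.weights.columns]
        if missing:
            raise ValueError(f"weight table missing columns: {missing}")
        self.weights = self.weights.reset_index(drop=True)
        if self.weights.duplicated(subset=["chrom", "pos", "effect_allele"]).any():
            raise ValueError("duplicate variants in weight list")
        if self.reference_sd is not None and self.reference_sd <= 0:
            raise ValueError("reference_sd must be positive")

    @property
    def n_variants(self) -> int:
        return len(self.weights)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"#gwas_name={self.gwas_name}\n")
            if self.params is not None:
                p = self.params
                fh.write(
                    f"#params=r2_max:{p.r2_max},window_kb:{p.window_kb},"
                    f"p_threshold:{p.p_threshold}\n"
                )
            if self.reference_mean is not None:
                fh.write(f"#reference_mean={self.reference_mean!r}\n")
            if self.reference_sd is not None:
                fh.write(f"#reference_sd={self.reference_sd!r}\n")
            fh.write(f"#includes_apoe_region={self.includes_apoe_region}\n")
            out = self.weights.rename(
                columns={
                    "chrom": "chr_name",
                    "pos": "chr_position",
                    "beta": "effect_weight",
                }
            )
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path: str) -> "PRSModel":
        meta: dict[str, str] = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and not line.startswith("#chr"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key] = val
                    skip += 1
                else:
                    break
        df = pd.read_csv(path, sep="\t", skiprows=skip, dtype={"chr_name": str})
        weights = df.rename(
            columns={
                "chr_name": "chrom",
                "chr_position": "pos",
                "effect_weight": "beta",
            }
        )
        params = None
        if "params" in meta:
            kv = dict(item.split(":") for item in meta["params"].split(","))
            params = ClumpParams(
                float(kv["r2_max"]), int(kv["window_kb"]), float(kv["p_threshold"])
            )
        return cls(
            gwas_name=meta.get("gwas_name", "gwas"),
            params=params,
            weights=weights,
            reference_mean=float(meta["reference_mean"])
            if "reference_mean" in meta
            else None,
            reference_sd=float(meta["reference_sd"])
            if "reference_sd" in meta
            else None,
            includes_apoe_region=meta.get("includes_apoe_region", "True") == "True",
        )


@dataclass
class ScoreVector:
    """Per-sample raw and (optionally) standardized PRS values."""

    sample_ids: list[str]
    raw: np.ndarray
    standardized: np.ndarray | None = None
    reference_mean: float | None = None
    reference_sd: float | None = None
    includes_apoe_region: bool | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.sample_ids),):
            raise ValueError("one score per sample required")


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(panel: GenotypePanel, variant_i: int, variant_j: int) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples."""
    x = panel.dosages[:, variant_i]
    y = panel.dosages[:, variant_j]
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        raise ValueError("fewer than 2 complete sample pairs")
    x, y = x[mask], y[mask]
    xc, yc = x - x.mean(), y - y.mean()
    vx, vy = xc @ xc, yc @ yc
    if vx <= 0 or vy <= 0:
        raise ValueError("monomorphic variant")
    r = (xc @ yc) / np.sqrt(vx * vy)
    return float(min(r * r, 1.0))


def _r2_against(panel: GenotypePanel, i: int, js: np.ndarray) -> np.ndarray:
    """r^2 of variant i against each of js; 0 where a variant is constant."""
    D = panel.dosages
    x = D[:, i]
    Y = D[:, js]
    if np.isnan(x).any() or np.isnan(Y).any():
        return np.array([_safe_r2(panel, i, int(j)) for j in js])
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    vx = xc @ xc
    vy = np.einsum("ij,ij->j", Yc, Yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (xc @ Yc) ** 2 / (vx * vy)
    r2[~np.isfinite(r2)] = 0.0
    return np.minimum(r2, 1.0)


def _safe_r2(panel: GenotypePanel, i: int, j: int) -> float:
    try:
        return ld_r2(panel, i, j)
    except ValueError:
        return 0.0


# ---------------------------------------------------------------------------
# Clumping
# ---------------------------------------------------------------------------

def clump(
    sumstats: SummaryStatSet,
    panel: GenotypePanel,
    r2_max: float,
    window_kb: int,
) -> pd.DataFrame:
    """Greedy p-value-ordered LD clumping.

    Candidates are ordered by ascending p-value (ties broken by
    chromosome then position).  The best remaining variant is taken as an
    index SNP, and every other remaining variant on the same chromosome
    within ``window_kb`` kilobases whose r^2 with the index exceeds
    ``r2_max`` is removed from consideration.  Returns the retained
    records (sumstats rows, with the panel column index attached).
    """
    rec = sumstats.records
    v = panel.variants
    key = pd.Series(
        np.arange(len(v)),
        index=pd.MultiIndex.from_arrays(
            [v["chrom"].astype(str).str.removeprefix("chr"), v["pos"].astype(int)]
        ),
    )
    key = key[~key.index.duplicated(keep="first")]
    idx = pd.MultiIndex.from_arrays([rec["CHR"].astype(str), rec["POS"].astype(int)])
    panel_col = key.reindex(idx).to_numpy()
    present = ~np.isnan(panel_col)
    rec = rec[present].assign(panel_col=panel_col[present].astype(int))
    rec = rec.sort_values(
        by=["P", "CHR", "POS"], kind="mergesort"
    ).reset_index(drop=True)

    chrom = rec["CHR"].to_numpy()
    pos = rec["POS"].to_numpy()
    cols = rec["panel_col"].to_numpy()
    active = np.ones(len(rec), dtype=bool)
    kept = np.zeros(len(rec), dtype=bool)
    window = window_kb * 1000

    for i in range(len(rec)):
        if not active[i]:
            continue
        active[i] = False
        kept[i] = True
        near = active & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window)
        js = np.flatnonzero(near)
        if js.size:
            r2 = _r2_against(panel, int(cols[i]), cols[js])
            active[js[r2 > r2_max]] = False

    out = rec[kept].drop(columns="panel_col")
    return out.sort_values(["CHR", "POS"]).reset_index(drop=True)


def build_candidate_grid(
    sumstats: SummaryStatSet,
    panel: GenotypePanel,
    r2_set=DEFAULT_R2_GRID,
    window_set=DEFAULT_WINDOW_GRID_KB,
    p_set=DEFAULT_P_THRESHOLDS,
    includes_apoe_region: bool = True,
) -> list[PRSModel]:
    """One candidate PRSModel per (r2_max, window_kb, p_threshold) combination.

    Clumping is performed once per (r2_max, window_kb) pair; p-value
    thresholding (p <= threshold, inclusive) is applied afterwards to the
    clumped set.  Models with zero variants are flagged degenerate.
    """
    if not (len(r2_set) and len(window_set) and len(p_set)):
        raise ValueError("parameter sets must be nonempty")
    models = []
    for r2_max, window_kb in product(r2_set, window_set):
        clumped = clump(sumstats, panel, r2_max, window_kb)
        for p_thr in p_set:
            sel = clumped[clumped["P"] <= p_thr]
            weights = pd.DataFrame(
                {
                    "chrom": sel["CHR"].astype(str),
                    "pos": sel["POS"].astype(int),
                    "effect_allele": sel["EA"],
                    "other_allele": sel["OA"],
                    "beta": sel["BETA"].astype(float),
                }
            )
            models.append(
                PRSModel(
                    gwas_name=sumstats.gwas_name,
                    params=ClumpParams(r2_max, int(window_kb), p_thr),
                    weights=weights,
                    includes_apoe_region=includes_apoe_region,
                    degenerate=len(weights) == 0,
                )
            )
    return models


def exclude_model_region(model: PRSModel, region: GenomicRegion) -> PRSModel:
    """Drop weight-list variants inside ``region`` (e.g. the APOE window)."""
    w = model.weights
    inside = region.contains(w["chrom"], w["pos"])
    out = replace(
        model,
        weights=w[~inside].reset_index(drop=True),
        includes_apoe_region=False,
        reference_mean=None,
        reference_sd=None,
    )
    out.degenerate = out.n_variants == 0
    return out


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score(panel: GenotypePanel, model: PRSModel) -> ScoreVector:
    """Additive PRS: sum of beta x effect-allele dosage over model variants.

    Model variants are resolved in the panel by (chromosome, position)
    and alleles, handling allele order flips and strand complements as in
    harmonization.  Missing dosages are imputed as 2 x effect-allele
    frequency from the panel.  Variants absent from the panel are skipped
    with a logged count; if more than half are absent a hard error is
    raised.
    """
    v = panel.variants
    pchrom = v["chrom"].astype(str).str.removeprefix("chr").to_numpy()
    ppos = v["pos"].to_numpy()
    pref = v["ref"].str.upper().to_numpy()
    palt = v["alt"].str.upper().to_numpy()
    af = v["af"].to_numpy(dtype=float)

    raw = np.zeros(panel.n_samples)
    n_missing = 0
    for row in model.weights.itertuples(index=False):
        chrom = str(row.chrom).removeprefix("chr")
        cand = np.flatnonzero((pchrom == chrom) & (ppos == row.pos))
        ea = str(row.effect_allele).upper()
        oa = str(row.other_allele).upper()
        ea_c, oa_c = _complement(ea), _complement(oa)
        col = flip = None
        for j in cand:
            if (ea, oa) == (palt[j], pref[j]) or (ea_c, oa_c) == (palt[j], pref[j]):
                col, flip = j, False
                break
            if (ea, oa) == (pref[j], palt[j]) or (ea_c, oa_c) == (pref[j], palt[j]):
                col, flip = j, True
                break
        if col is None:
            n_missing += 1
            continue
        d = panel.dosages[:, col]
        d = np.where(np.isnan(d), 2 * af[col], d)
        if flip:
            d = 2 - d
        raw += row.beta * d

    if model.n_variants and n_missing > 0.5 * model.n_variants:
        raise ValueError(
            f"panel mismatch: {n_missing}/{model.n_variants} model variants absent"
        )
    if n_missing:
        logger.info(
            "score(%s): %d model variants absent from panel", model.gwas_name, n_missing
        )
    return ScoreVector(
        sample_ids=list(panel.sample_ids),
        raw=raw,
        includes_apoe_region=model.includes_apoe_region,
    )
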