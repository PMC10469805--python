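"""Synthetic admixed cohort generator.

Generates the three inputs the PRS pipeline needs, with the statistical
structure of a Hispanic/Latino aging cohort and its discovery GWAS:

* a genotype panel with LD blocks, three-way admixture (European /
  African / Amerindian), background groups with differing
  ancestry-proportion distributions, and an APOE-like locus defined by
  two SNPs from which epsilon-2 / epsilon-4 allele counts derive;
* discovery-GWAS summary statistics of configurable sample size;
* an MCI / cognitive-decline phenotype table with covariates and
  household clustering, the intercept calibrated to a target prevalence
  (about 11% by default).

Genotypes come from block-exchangeable latent Gaussians thresholded to
haplotypes (two per individual), mixing ancestry-specific allele
frequencies per block by sampled local ancestry.  This gives controllable
LD and admixture without external haplotype panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .engine import ScoreVector  # noqa: F401  (re-export convenience)
from .panel import GenotypePanel
from .sumstats import SUMSTATS_COLUMNS, APOE_REGION, SummaryStatSet

ANCESTRY_LABELS = ("european", "african", "amerindian")

# Autosomes used for polygenic LD blocks; chr19 is reserved for the
# APOE-like locus so region masking is clean.
_BLOCK_CHROMS = [str(c) for c in list(range(1, 19)) + [20, 21, 22]]


@dataclass(frozen=True)
class BackgroundGroup:
    """A self-identified background group with its admixture distribution."""

    label: str
    fraction: float
    dirichlet: tuple[float, ...]


#: Six background groups emulating the heterogeneity of a U.S.
#: Hispanic/Latino cohort: Mainland groups (Central American, Mexican,
#: South American) with high Amerindian / low African ancestry, Cuban
#: with high European ancestry, and Caribbean groups (Dominican, Puerto
#: Rican) with high African / low Amerindian ancestry.  Dirichlet
#: parameters are (European, African, Amerindian).
DEFAULT_BACKGROUND_GROUPS = (
    BackgroundGroup("central_american", 0.10, (4.6, 1.5, 3.9)),
    BackgroundGroup("cuban", 0.21, (8.0, 1.0, 1.0)),
    BackgroundGroup("dominican", 0.10, (4.8, 3.7, 1.5)),
    BackgroundGroup("mexican", 0.34, (4.6, 0.8, 4.6)),
    BackgroundGroup("puerto_rican", 0.18, (6.5, 2.5, 1.0)),
    BackgroundGroup("south_american", 0.07, (5.0, 1.0, 4.0)),
)


@dataclass(frozen=True)
class ApoeLocus:
    """Two-SNP APOE-like locus on chr19 (positions of rs429358/rs7412-like
    SNPs, haplotype frequencies, and per-allele log odds ratios)."""

    chromosome: str = "19"
    e4_position: int = 44908684
    e2_position: int = 44908822
    e4_freq: float = 0.12
    e2_freq: float = 0.06
    e4_log_or: float = 0.4
    e2_log_or: float = -0.2


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic cohort.

    ``h2_liability`` is the polygenic fraction of liability variance
    (relative to the logistic residual, variance pi^2/3), excluding the
    APOE and covariate terms.  ``ancestry_fst`` controls ancestry allele
    frequency divergence (Balding-Nichols).
    """

    n_individuals: int = 4000
    n_variants: int = 400
    n_blocks: int = 40
    block_r2: float = 0.5
    n_ancestries: int = 3
    ancestry_fst: float = 0.05
    background_groups: tuple[BackgroundGroup, ...] = DEFAULT_BACKGROUND_GROUPS
    apoe: ApoeLocus = field(default_factory=ApoeLocus)
    n_causal: int = 40
    h2_liability: float = 0.15
    prevalence: float = 0.11
    age_log_or: float = 0.02
    sex_log_or: float = 0.1
    education_log_ors: tuple[float, float, float] = (0.0, -0.1, -0.2)
    cognitive_prs_beta: float = -0.05
    household_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestries == 1 and self.background_groups is DEFAULT_BACKGROUND_GROUPS:
            self.background_groups = (BackgroundGroup("combined", 1.0, (1.0,)),)
        self.validate()

    def validate(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if not 0 <= self.block_r2 < 1:
            raise ValueError("block_r2 must be in [0, 1)")
        if not 0 <= self.h2_liability < 1:
            raise ValueError("h2_liability must be in [0, 1)")
        for g in self.background_groups:
            if len(g.dirichlet) != self.n_ancestries:
                raise ValueError(
                    f"group {g.label}: Dirichlet length != n_ancestries"
                )
            if any(a <= 0 for a in g.dirichlet):
                raise ValueError("Dirichlet parameters must be > 0")
        if self.apoe.e2_freq + self.apoe.e4_freq >= 1:
            raise ValueError("epsilon-2 + epsilon-4 haplotype frequency must be < 1")
        for pos in (self.apoe.e2_position, self.apoe.e4_position):
            if not APOE_REGION.contains([self.apoe.chromosome], [pos])[0]:
                raise ValueError("APOE SNP positions must fall inside the APOE window")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal exceeds n_variants")


@dataclass
class TruthRecord:
    """Ground truth of one simulated panel, for parameter-recovery tests."""

    causal_variants: pd.DataFrame  # chrom, pos, key, beta (per-allele log-OR)
    true_prs: np.ndarray  # per-individual polygenic liability contribution
    ancestry_proportions: pd.DataFrame  # one column per ancestry, rows sum to 1
    apoe_e2_count: np.ndarray
    apoe_e4_count: np.ndarray
    background: np.ndarray

    def validate(self) -> None:
        sums = self.ancestry_proportions.sum(axis=1).to_numpy()
        if np.max(np.abs(sums - 1)) > 1e-9:
            raise ValueError("ancestry proportions must sum to 1")
        for counts in (self.apoe_e2_count, self.apoe_e4_count):
            if not np.isin(counts, [0, 1, 2]).all():
                raise ValueError("APOE allele counts must be in {0, 1, 2}")
        if ((self.apoe_e2_count + self.apoe_e4_count) > 2).any():
            raise ValueError("epsilon-2 + epsilon-4 counts cannot exceed 2")


def _latent_rho(target_r2: float, freq: float) -> float:
    """Latent Gaussian correlation giving binary-allele r^2 = target_r2.

    For thresholded bivariate normals with common frequency ``freq`` the
    allele correlation is (P11 - f^2) / (f (1-f)); solved for the latent
    rho by bisection.
    """
    if target_r2 <= 0:
        return 0.0
    r_target = np.sqrt(target_r2)
    z = stats.norm.ppf(freq)

    def gap(rho: float) -> float:
        p11 = stats.multivariate_normal.cdf(
            [z, z], mean=[0, 0], cov=[[1, rho], [rho, 1]]
        )
        return (p11 - freq**2) / (freq * (1 - freq)) - r_target

    lo, hi = 1e-6, 1 - 1e-6
    if gap(hi) < 0:  # target unattainable at this frequency; saturate
        return hi
    return float(optimize.brentq(gap, lo, hi, xtol=1e-4))


def simulate_panel(config: SimulationConfig) -> tuple[GenotypePanel, TruthRecord]:
    """Generate an admixed genotype panel and its ground truth."""
    if config.n_variants % config.n_blocks:
        raise ValueError("n_variants must be divisible by n_blocks")
    rng = np.random.default_rng(config.seed)
    n, k = config.n_individuals, config.n_ancestries
    m = config.n_variants // config.n_blocks
    nb = config.n_blocks

    # Background groups and per-individual admixture proportions.
    fractions = np.array([g.fraction for g in config.background_groups], dtype=float)
    fractions /= fractions.sum()
    group_idx = rng.choice(len(fractions), size=n, p=fractions)
    Q = np.empty((n, k))
    for gi, g in enumerate(config.background_groups):
        sel = group_idx == gi
        if sel.any():
            Q[sel] = rng.dirichlet(g.dirichlet, size=int(sel.sum()))
    if k == 1:
        Q[:] = 1.0
    background = np.array([config.background_groups[gi].label for gi in group_idx])

    # Ancestry-specific allele frequencies: Balding-Nichols divergence is
    # drawn once per (ancestry, block) and shared by the block's variants
    # (plus a small per-variant jitter), so ancestry frequency differences
    # act like local haplotype background rather than diluting within-block
    # LD away from its target.
    base_block = rng.uniform(0.2, 0.8, size=nb)
    F = config.ancestry_fst
    if k == 1 or F == 0:
        block_anc = np.tile(base_block, (k, 1))
    else:
        a = base_block * (1 - F) / F
        b = (1 - base_block) * (1 - F) / F
        block_anc = np.clip(rng.beta(a, b, size=(k, nb)), 0.02, 0.98)
    jitter = rng.normal(0, 0.02, size=nb * m)
    freqs = np.clip(np.repeat(block_anc, m, axis=1) + jitter, 0.01, 0.99)

    # Local ancestry per haplotype per block.
    Qh = np.repeat(Q, 2, axis=0)  # (2n, k)
    cum = np.cumsum(Qh, axis=1)
    u = rng.random((2 * n, nb))
    anc = (u[:, :, None] > cum[:, None, :]).sum(axis=2)  # (2n, nb)

    # Block-exchangeable latent Gaussians thresholded to haplotypes.
    hap = np.empty((2 * n, nb * m), dtype=np.int8)
    for b in range(nb):
        sl = slice(b * m, (b + 1) * m)
        fbar = float(np.mean(freqs[:, sl]))
        rho = _latent_rho(config.block_r2, fbar)
        shared = rng.standard_normal(2 * n)
        eps = rng.standard_normal((2 * n, m))
        Z = np.sqrt(rho) * shared[:, None] + np.sqrt(1 - rho) * eps
        thresh = stats.norm.ppf(freqs[anc[:, b], sl])  # (2n, m)
        hap[:, sl] = Z < thresh
    dosages = (hap[0::2] + hap[1::2]).astype(float)

    # Variant map: blocks cycle over autosomes (chr19 excluded), 2 Mb
    # apart, 10 kb between variants within a block.
    chroms = np.empty(nb * m, dtype=object)
    pos = np.empty(nb * m, dtype=int)
    for b in range(nb):
        sl = slice(b * m, (b + 1) * m)
        chroms[sl] = _BLOCK_CHROMS[b % len(_BLOCK_CHROMS)]
        start = 1_000_000 + (b // len(_BLOCK_CHROMS)) * 2_000_000
        pos[sl] = start + np.arange(m) * 10_000
    variants = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": "A", "alt": "G"})

    # APOE-like locus: per-haplotype epsilon allele in {e2, e3, e4};
    # generated jointly so no haplotype carries both defining alleles.
    ap = config.apoe
    hap_eps = rng.choice(
        3, size=(2 * n,), p=[ap.e2_freq, 1 - ap.e2_freq - ap.e4_freq, ap.e4_freq]
    )  # 0 = e2, 1 = e3, 2 = e4
    e2_hap = (hap_eps == 0).astype(float)
    e4_hap = (hap_eps == 2).astype(float)
    e2_count = (e2_hap[0::2] + e2_hap[1::2]).astype(int)
    e4_count = (e4_hap[0::2] + e4_hap[1::2]).astype(int)
    apoe_variants = pd.DataFrame(
        {
            "chrom": [ap.chromosome] * 2,
            "pos": [ap.e4_position, ap.e2_position],
            "ref": ["T", "C"],
            "alt": ["C", "T"],  # alt = the epsilon-defining allele
        }
    ).sort_values("pos")
    apoe_cols = {ap.e4_position: e4_count.astype(float), ap.e2_position: e2_count.astype(float)}
    apoe_dos = np.column_stack([apoe_cols[p] for p in apoe_variants["pos"]])

    variants = pd.concat([variants, apoe_variants], ignore_index=True)
    dosages = np.column_stack([dosages, apoe_dos])
    order = np.lexsort(
        (variants["pos"].to_numpy(), variants["chrom"].map(lambda c: int(c)).to_numpy())
    )
    variants = variants.iloc[order].reset_index(drop=True)
    dosages = dosages[:, order]

    sample_ids = [f"S{i:06d}" for i in range(n)]
    panel = GenotypePanel(sample_ids=sample_ids, variants=variants, dosages=dosages)

    # Polygenic truth: n_causal non-APOE variants; effects scaled so the
    # polygenic liability variance matches h2 / (1 - h2) * pi^2 / 3.
    is_apoe = (
        (variants["chrom"] == ap.chromosome)
        & variants["pos"].isin([ap.e2_position, ap.e4_position])
    ).to_numpy()
    candidates = np.flatnonzero(~is_apoe)
    causal_idx = np.sort(rng.choice(candidates, size=config.n_causal, replace=False))
    raw_w = rng.standard_normal(config.n_causal)
    g_raw = dosages[:, causal_idx] @ raw_w
    sd_raw = g_raw.std()
    if config.h2_liability > 0 and sd_raw > 0:
        target_sd = np.sqrt(
            config.h2_liability / (1 - config.h2_liability) * np.pi**2 / 3
        )
        betas = raw_w * target_sd / sd_raw
    else:
        betas = np.zeros(config.n_causal)
    true_prs = dosages[:, causal_idx] @ betas

    keys = panel.variant_keys()
    causal = pd.DataFrame(
        {
            "chrom": variants["chrom"].iloc[causal_idx].to_numpy(),
            "pos": variants["pos"].iloc[causal_idx].to_numpy(),
            "key": keys.iloc[causal_idx].to_numpy(),
            "beta": betas,
        }
    )
    apoe_rows = variants.index[is_apoe]
    apoe_truth = pd.DataFrame(
        {
            "chrom": variants["chrom"].iloc[apoe_rows].to_numpy(),
            "pos": variants["pos"].iloc[apoe_rows].to_numpy(),
            "key": keys.iloc[apoe_rows].to_numpy(),
            "beta": [
                ap.e4_log_or if p == ap.e4_position else ap.e2_log_or
                for p in variants["pos"].iloc[apoe_rows]
            ],
        }
    )
    truth = TruthRecord(
        causal_variants=pd.concat([causal, apoe_truth], ignore_index=True),
        true_prs=true_prs,
        ancestry_proportions=pd.DataFrame(
            Q,
            columns=list(ANCESTRY_LABELS[:k]) if k <= 3 else [f"anc{i}" for i in range(k)],
            index=sample_ids,
        ),
        apoe_e2_count=e2_count,
        apoe_e4_count=e4_count,
        background=background,
    )
    truth.validate()
    return panel, truth


def simulate_sumstats(
    truth: TruthRecord,
    panel: GenotypePanel,
    n_discovery: int,
    seed: int,
    gwas_name: str = "gwas",
) -> SummaryStatSet:
    """Discovery-GWAS summary statistics for every panel variant.

    Effect estimates are true effect + Normal noise with
    SE = 1 / sqrt(2 n f (1 - f)) (f = effect-allele frequency); two-sided
    p-values come from the Wald statistic.  Monomorphic variants are
    excluded with a logged count.  Null variants have true effect 0.
    """
    if n_discovery < 100:
        raise ValueError("n_discovery must be >= 100")
    rng = np.random.default_rng(seed)
    v = panel.variants
    f = panel.empirical_af()
    poly = (f > 0) & (f < 1)
    n_mono = int((~poly).sum())
    if n_mono:
        import logging

        logging.getLogger(__name__).info(
            "simulate_sumstats(%s): excluded %d monomorphic variants",
            gwas_name,
            n_mono,
        )
    true_beta = pd.Series(0.0, index=panel.variant_keys().to_numpy())
    true_beta.loc[truth.causal_variants["key"]] = truth.causal_variants[
        "beta"
    ].to_numpy()
    keep = np.flatnonzero(poly)
    fk = f[keep]
    se = 1.0 / np.sqrt(2 * n_discovery * fk * (1 - fk))
    beta_hat = true_beta.iloc[keep].to_numpy() + rng.standard_normal(keep.size) * se
    z = beta_hat / se
    p = np.maximum(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1))
    rec = pd.DataFrame(
        {
            "CHR": v["chrom"].iloc[keep].astype(str).to_numpy(),
            "POS": v["pos"].iloc[keep].to_numpy(),
            "EA": v["alt"].iloc[keep].to_numpy(),
            "OA": v["ref"].iloc[keep].to_numpy(),
            "BETA": beta_hat,
            "SE": se,
            "P": p,
            "EAF": fk,
        }
    )
    return SummaryStatSet(
        gwas_name=gwas_name,
        records=rec[SUMSTATS_COLUMNS],
        provenance=f"simulated discovery GWAS, n={n_discovery}",
        drop_counts={"monomorphic": n_mono} if n_mono else {},
    )


#: Five discovery GWAS of differing sample size, emulating the
#: heterogeneity of published AD GWAS (two large European-ancestry
#: studies, a biobank, a smaller African-ancestry study, and a
#: mid-size multi-ethnic study), scaled to synthetic effect sizes.
DEFAULT_GWAS_SUITE = (
    ("eur_large", 40_000),
    ("eur_proxy", 80_000),
    ("biobank", 30_000),
    ("afr", 5_000),
    ("multi_ethnic", 15_000),
)


def simulate_gwas_suite(
    truth: TruthRecord,
    panel: GenotypePanel,
    suite=DEFAULT_GWAS_SUITE,
    seed: int = 0,
) -> dict[str, SummaryStatSet]:
    """Simulate one SummaryStatSet per configured discovery GWAS."""
    return {
        name: simulate_sumstats(truth, panel, n_disc, seed=seed + 1000 + i, gwas_name=name)
        for i, (name, n_disc) in enumerate(suite)
    }


class CalibrationError(RuntimeError):
    """Raised when the target prevalence cannot be reached."""


def _calibrate_intercept(eta: np.ndarray, prevalence: float) -> float:
    """Intercept such that mean(expit(b0 + eta)) equals the prevalence."""

    def gap(b0: float) -> float:
        return float(np.mean(expit(b0 + eta)) - prevalence)

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError("target prevalence unattainable given effect sizes")
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


EDUCATION_LEVELS = ("no_hs", "hs", "post_hs")
CENTERS = ("bronx", "chicago", "miami", "san_diego")


def simulate_cohort_phenotypes(
    panel: GenotypePanel,
    truth: TruthRecord,
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate the per-individual phenotype/covariate table.

    MCI comes from a logistic model whose linear predictor is the
    calibrated intercept + polygenic liability + APOE allele effects +
    covariate effects + a shared-household intercept.  Cognitive-change
    scores are linear in the standardized polygenic liability with
    Gaussian noise at the scale of the cohort's printed summary tables.
    """
    rng = np.random.default_rng(config.seed + 101 if seed is None else seed)
    n = panel.n_samples

    age = np.clip(rng.normal(63, 8, n), 50, 90)
    sex = (rng.random(n) < 0.46).astype(int)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=(0.38, 0.21, 0.41))
    center = rng.choice(CENTERS, size=n, p=(0.3, 0.15, 0.3, 0.25))
    time_between = np.clip(rng.normal(7, 1, n), 4, 11)

    # Households of size 1-3 with a shared normal intercept.
    sizes = rng.choice([1, 2, 3], size=n, p=(0.55, 0.3, 0.15))
    hh_ids = np.repeat(np.arange(n), sizes)[:n]
    hh_effects_by_id = rng.normal(0, config.household_sd, size=hh_ids.max() + 1)
    hh = hh_effects_by_id[hh_ids] if config.household_sd > 0 else np.zeros(n)

    edu_eff = dict(zip(EDUCATION_LEVELS, config.education_log_ors))
    eta = (
        truth.true_prs
        + config.apoe.e4_log_or * truth.apoe_e4_count
        + config.apoe.e2_log_or * truth.apoe_e2_count
        + config.age_log_or * (age - 63)
        + config.sex_log_or * sex
        + np.array([edu_eff[e] for e in education])
        + hh
    )
    b0 = _calibrate_intercept(eta, config.prevalence)
    mci = (rng.random(n) < expit(b0 + eta)).astype(int)
    # A small fraction of cases shows a suspect severe deficit (MCI+).
    mci_plus = ((rng.random(n) < 0.13) & (mci == 1)).astype(int)

    prs_sd = truth.true_prs.std()
    z = (truth.true_prs - truth.true_prs.mean()) / prs_sd if prs_sd > 0 else np.zeros(n)
    b = config.cognitive_prs_beta
    cog = {
        "g_factor_change": -0.12 + b * z + rng.normal(0, 0.88, n),
        "word_frequency_change": -0.3 + 2 * b * z + rng.normal(0, 5.4, n),
        "sevlt_recall_change": 0.0 + 2 * b * z + rng.normal(0, 2.95, n),
        "digit_symbol_change": -2.3 + 5 * b * z + rng.normal(0, 7.4, n),
    }

    table = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "mci": mci,
            "mci_plus_flag": mci_plus,
            **cog,
            "age_baseline": age,
            "time_between_visits": time_between,
            "sex": sex,
            "education": education,
            "center": center,
            "apoe_e2_count": truth.apoe_e2_count,
            "apoe_e4_count": truth.apoe_e4_count,
            "background": truth.background,
            "household_id": [f"H{h:06d}" for h in hh_ids],
        }
    )
    anc = truth.ancestry_proportions.reset_index(drop=True)
    for col in anc.columns:
        table[f"anc_{col}"] = anc[col].to_numpy()
    return table


def simulate_kinship_pairs(
    sample_ids: list[str], frac_related: float = 0.05, seed: int = 0
) -> pd.DataFrame:
    """Disjoint related pairs covering about ``frac_related`` of the cohort.

    Kinship values are drawn above the 3rd-degree threshold (0.0442) so
    every listed pair counts as related.
    """
    rng = np.random.default_rng(seed)
    n_pairs = int(round(frac_related * len(sample_ids) / 2))
    chosen = rng.choice(len(sample_ids), size=2 * n_pairs, replace=False)
    ids = np.asarray(sample_ids)
    return pd.DataFrame(
        {
            "id1": ids[chosen[:n_pairs]],
            "id2": ids[chosen[n_pairs:]],
            "kinship": rng.uniform(0.05, 0.25, size=n_pairs),
        }
    )
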