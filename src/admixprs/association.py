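"""PRS-outcome association analysis, power, and model comparison.

Associations of a standardized PRS with MCI (logistic) and with
cognitive-change scores (linear) are estimated by maximum likelihood
with the study covariate set (age at baseline, time between visits, sex,
education, center, genetic PCs, and optionally APOE epsilon-2/epsilon-4
allele counts).  Household clustering is handled with cluster-robust
(sandwich) standard errors rather than random effects.  Also provided:
genetic PCs of the dosage matrix, the Hsieh-type closed-form power of a
logistic regression on a standardized continuous predictor with a
Monte-Carlo counterpart, a paired-bootstrap comparison of Nagelkerke R^2
between two PRSs, and the MCI-control cohort filter used for
biobank-style validation samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

from .panel import GenotypePanel

Z95 = 1.959963984540054  # Phi^-1(0.975)


@dataclass
class AssociationResult:
    """One fitted term: effect estimate with Wald inference and context."""

    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_cases: int | None
    model: dict = field(default_factory=dict)
    coefficients: pd.DataFrame | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _design_matrix(df: pd.DataFrame, terms) -> pd.DataFrame:
    """Design matrix with an intercept; categoricals become indicator
    contrasts against a reference level (education: no-HS-diploma)."""
    cols = {"const": np.ones(len(df))}
    for t in terms:
        s = df[t]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(s.astype(str).unique())
            if t == "education":
                order = [l for l in ("no_hs", "hs", "post_hs") if l in levels]
                levels = order + [l for l in levels if l not in order]
            for lev in levels[1:]:
                cols[f"{t}[{lev}]"] = (s.astype(str) == lev).astype(float)
        else:
            cols[t] = s.to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=df.index)
    return X


def _check_design(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in design matrix")
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError(
            f"collinear design matrix (columns: {list(X.columns)})"
        )


def _wald(res, term, n, n_cases, model_desc) -> AssociationResult:
    est = float(res.params[term])
    se = float(res.bse[term])
    p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else np.nan
    coef = pd.DataFrame(
        {"estimate": res.params, "se": res.bse}
    )
    coef["ci_low"] = coef["estimate"] - Z95 * coef["se"]
    coef["ci_high"] = coef["estimate"] + Z95 * coef["se"]
    coef["p_value"] = 2 * stats.norm.sf(np.abs(coef["estimate"] / coef["se"]))
    return AssociationResult(
        term=term,
        estimate=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        p_value=p,
        n=n,
        n_cases=n_cases,
        model=model_desc,
        coefficients=coef,
    )


def fit_logistic(
    cohort: pd.DataFrame,
    exposure: str,
    covariates=(),
    cluster_var: str | None = None,
    outcome: str = "mci",
) -> AssociationResult:
    """Maximum-likelihood logistic fit of a binary outcome on an exposure.

    Wald estimate, SE, 95% CI (estimate +/- 1.96 SE) and p-value for the
    exposure term; with ``cluster_var`` the SEs are replaced by
    cluster-robust (sandwich) SEs grouped by that variable.
    """
    y = cohort[outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if not np.isin(classes, [0, 1]).all() or classes.size < 2:
        raise ValueError(f"outcome '{outcome}' must be binary with both classes present")
    X = _design_matrix(cohort, [exposure, *covariates])
    _check_design(X)
    model = sm.Logit(y, X)
    try:
        if cluster_var is None:
            res = model.fit(disp=0, maxiter=200)
        else:
            res = model.fit(
                disp=0,
                maxiter=200,
                cov_type="cluster",
                cov_kwds={"groups": cohort[cluster_var].to_numpy()},
            )
    except Exception as exc:  # statsmodels raises several flavors here
        raise ValueError(f"logistic fit failed for '{exposure}': {exc}") from exc
    if not res.mle_retvals.get("converged", True) or not np.isfinite(
        res.params
    ).all() or not np.isfinite(res.bse).all():
        raise ValueError(
            f"logistic fit did not converge (possible separation) for '{exposure}'"
        )
    desc = {
        "outcome": outcome,
        "family": "logistic",
        "exposure": exposure,
        "covariates": list(covariates),
        "cluster_var": cluster_var,
    }
    return _wald(res, exposure, len(y), int(y.sum()), desc)


def fit_linear(
    cohort: pd.DataFrame,
    outcome_name: str,
    exposure: str,
    covariates=(),
    cluster_var: str | None = None,
) -> AssociationResult:
    """Ordinary least squares with optional cluster-robust SEs."""
    y = cohort[outcome_name].to_numpy(dtype=float)
    X = _design_matrix(cohort, [exposure, *covariates])
    _check_design(X)
    model = sm.OLS(y, X)
    if cluster_var is None:
        res = model.fit()
    else:
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": cohort[cluster_var].to_numpy()}
        )
    desc = {
        "outcome": outcome_name,
        "family": "linear",
        "exposure": exposure,
        "covariates": list(covariates),
        "cluster_var": cluster_var,
    }
    return _wald(res, exposure, len(y), None, desc)


def compute_pcs(panel: GenotypePanel, m: int = 5) -> pd.DataFrame:
    """First m principal components of the column-standardized dosages.

    Missing dosages are mean-imputed; zero-variance variants are dropped.
    Components are ordered by decreasing variance explained, with each
    PC's sign fixed so its largest-magnitude variant loading is positive.
    """
    D = panel.dosages.copy()
    mu = np.nanmean(D, axis=0)
    inds = np.where(np.isnan(D))
    D[inds] = np.take(mu, inds[1])
    sd = D.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("zero-variance dosage matrix: no informative variants")
    Xs = (D[:, keep] - mu[keep]) / sd[keep]
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    rank = int((S > S[0] * 1e-9).sum())
    if m > rank:
        raise ValueError(f"m={m} exceeds matrix rank {rank}")
    pcs = U[:, :m] * S[:m]
    for j in range(m):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            pcs[:, j] = -pcs[:, j]
    return pd.DataFrame(
        pcs, columns=[f"PC{j + 1}" for j in range(m)], index=panel.sample_ids
    )


# ---------------------------------------------------------------------------
# Cohort filtering (biobank-style MCI/control definition)
# ---------------------------------------------------------------------------

@dataclass
class FilterSummary:
    n_input: int
    n_removed: int
    n_remaining: int
    n_cases: int
    case_percent: float


def filter_mci_controls(
    cohort: pd.DataFrame, mci_col: str = "mci", dementia_col: str = "dementia"
) -> tuple[pd.DataFrame, FilterSummary]:
    """Biobank case/control filter: cases are individuals with an MCI
    code; individuals *without* MCI but *with* an AD/dementia code are
    excluded so that controls are free of both."""
    mci = cohort[mci_col].astype(bool)
    dem = cohort[dementia_col].astype(bool)
    drop = ~mci & dem
    out = cohort[~drop].reset_index(drop=True)
    n_cases = int(out[mci_col].astype(bool).sum())
    summary = FilterSummary(
        n_input=len(cohort),
        n_removed=int(drop.sum()),
        n_remaining=len(out),
        n_cases=n_cases,
        case_percent=100.0 * n_cases / len(out) if len(out) else np.nan,
    )
    return out, summary


# ---------------------------------------------------------------------------
# Primary analysis and subgroups
# ---------------------------------------------------------------------------

APOE_COUNT_TERMS = ("apoe_e2_count", "apoe_e4_count")


def run_primary_analysis(
    cohort: pd.DataFrame,
    score_sets: dict[str, dict[str, np.ndarray]],
    covariates=(),
    cluster_var: str | None = None,
    sensitivity: bool = True,
) -> pd.DataFrame:
    """Three model blocks per PRS, mirroring the primary results table.

    ``score_sets`` maps PRS name -> {"with_apoe": standardized scores,
    "without_apoe": standardized scores}, aligned to ``cohort`` rows.
    Blocks: (1) APOE-inclusive PRS, unadjusted for APOE allele counts;
    (2) APOE-inclusive PRS adjusted for epsilon-2/epsilon-4 counts (those
    terms reported too); (3) APOE-excluded PRS adjusted for the counts.
    With ``sensitivity`` the full set is re-fitted after removing
    MCI+ (suspect severe deficit) individuals.
    """
    cohort = cohort.reset_index(drop=True)
    blocks = (
        ("prs_with_apoe_unadjusted", "with_apoe", False),
        ("prs_with_apoe_adjusted", "with_apoe", True),
        ("prs_without_apoe_adjusted", "without_apoe", True),
    )
    analyses = [("primary", cohort)]
    if sensitivity:
        if "mci_plus_flag" in cohort.columns:
            analyses.append(("sensitivity", cohort[cohort["mci_plus_flag"] != 1]))
    rows = []
    for analysis, frame in analyses:
        for prs_name, pair in score_sets.items():
            for block, which, adjust in blocks:
                if which not in pair:
                    continue
                scores = np.asarray(pair[which], dtype=float)
                sub = frame.assign(prs=scores[frame.index.to_numpy()] if len(
                    scores
                ) == len(cohort) else scores)
                covs = list(covariates) + (list(APOE_COUNT_TERMS) if adjust else [])
                res = fit_logistic(sub, "prs", covs, cluster_var=cluster_var)
                terms = [("prs", res)]
                if adjust:
                    for t in APOE_COUNT_TERMS:
                        c = res.coefficients.loc[t]
                        terms.append(
                            (
                                t,
                                AssociationResult(
                                    term=t,
                                    estimate=float(c["estimate"]),
                                    se=float(c["se"]),
                                    ci_low=float(c["ci_low"]),
                                    ci_high=float(c["ci_high"]),
                                    p_value=float(c["p_value"]),
                                    n=res.n,
                                    n_cases=res.n_cases,
                                    model=res.model,
                                ),
                            )
                        )
                for term, r in terms:
                    rows.append(
                        {
                            "analysis": analysis,
                            "prs": prs_name,
                            "block": block,
                            "term": term,
                            "estimate": r.estimate,
                            "se": r.se,
                            "or": r.odds_ratio,
                            "or_ci_low": r.or_ci[0],
                            "or_ci_high": r.or_ci[1],
                            "p_value": r.p_value,
                            "n": r.n,
                            "n_cases": r.n_cases,
                        }
                    )
    return pd.DataFrame(rows)


def subgroup_association(
    cohort: pd.DataFrame,
    score: np.ndarray,
    grouping,
    covariates=(),
    cluster_var: str | None = None,
    min_cases: int = 10,
) -> pd.DataFrame:
    """Association within subgroups, without re-standardizing the score.

    ``grouping`` is either ``("background",)`` (one fit per background
    label) or ``("ancestry", name, min_prop)`` (one fit on the subset
    with at least ``min_prop`` of global ancestry ``name``).  Subgroups
    with fewer than ``min_cases`` cases are flagged unstable but still
    reported.
    """
    df = cohort.assign(prs=np.asarray(score, dtype=float))
    if grouping[0] == "background":
        subsets = [(lab, df[df["background"] == lab]) for lab in sorted(df["background"].unique())]
    elif grouping[0] == "ancestry":
        _, name, min_prop = grouping
        col = f"anc_{name}"
        subsets = [(f"{name}>={min_prop}", df[df[col] >= min_prop])]
    else:
        raise ValueError(f"unknown grouping: {grouping!r}")
    rows = []
    for label, sub in subsets:
        n_cases = int(sub["mci"].sum())
        try:
            res = fit_logistic(sub, "prs", covariates, cluster_var=cluster_var)
            rows.append(
                {
                    "subgroup": label,
                    "estimate": res.estimate,
                    "se": res.se,
                    "or": res.odds_ratio,
                    "or_ci_low": res.or_ci[0],
                    "or_ci_high": res.or_ci[1],
                    "p_value": res.p_value,
                    "n": res.n,
                    "n_cases": res.n_cases,
                    "unstable": n_cases < min_cases,
                }
            )
        except ValueError as exc:
            rows.append(
                {
                    "subgroup": label,
                    "estimate": np.nan,
                    "se": np.nan,
                    "or": np.nan,
                    "or_ci_low": np.nan,
                    "or_ci_high": np.nan,
                    "p_value": np.nan,
                    "n": len(sub),
                    "n_cases": n_cases,
                    "unstable": True,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Power
# ---------------------------------------------------------------------------

def power_logistic_continuous(
    n: int, p_event: float, or_per_sd: float, alpha: float = 0.05
) -> float:
    """Hsieh-type closed-form power of a two-sided Wald test for a
    standardized continuous predictor in logistic regression:

        power = Phi( sqrt(n p (1-p)) |ln OR| - z_{1-alpha/2} ).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 < p_event < 1 or not 0 < alpha < 1:
        raise ValueError("p_event and alpha must lie in (0, 1)")
    if or_per_sd <= 0:
        raise ValueError("or_per_sd must be positive")
    z = stats.norm.ppf(1 - alpha / 2)
    ncp = np.sqrt(n * p_event * (1 - p_event)) * abs(np.log(or_per_sd))
    return float(stats.norm.cdf(ncp - z))


def _intercept_for_event_rate(beta: float, p_event: float) -> float:
    """Intercept such that E[expit(b0 + beta X)] = p_event for X ~ N(0,1)."""
    nodes, weights = np.polynomial.hermite.hermgauss(61)
    x = np.sqrt(2) * nodes
    w = weights / np.sqrt(np.pi)

    def gap(b0):
        return float(w @ expit(b0 + beta * x) - p_event)

    return float(optimize.brentq(gap, -30, 30))


def simulate_power_logistic(
    n: int,
    p_event: float,
    or_per_sd: float,
    alpha: float = 0.05,
    n_reps: int = 5000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the same Wald test, by simulation.

    Replicate datasets (X ~ N(0,1), logistic outcome with the intercept
    solved to give the target event rate) are fitted with a vectorized
    two-parameter Newton solver, independent of the closed form.
    """
    rng = np.random.default_rng(seed)
    b1 = np.log(or_per_sd)
    b0 = _intercept_for_event_rate(b1, p_event)
    z_crit = stats.norm.ppf(1 - alpha / 2)
    rejections = []
    done = 0
    while done < n_reps:  # chunked to bound memory at large n
        chunk = min(1000, n_reps - done)
        done += chunk
        x = rng.standard_normal((chunk, n))
        y = (rng.random((chunk, n)) < expit(b0 + b1 * x)).astype(float)
        a = np.full(chunk, b0)
        b = np.zeros(chunk)
        for _ in range(40):
            eta = np.clip(a[:, None] + b[:, None] * x, -30, 30)
            mu = expit(eta)
            w = mu * (1 - mu)
            r = y - mu
            g0 = r.sum(axis=1)
            g1 = (x * r).sum(axis=1)
            h00 = w.sum(axis=1)
            h01 = (w * x).sum(axis=1)
            h11 = (w * x * x).sum(axis=1)
            det = h00 * h11 - h01 * h01
            det = np.where(np.abs(det) < 1e-12, np.nan, det)
            da = (h11 * g0 - h01 * g1) / det
            db = (h00 * g1 - h01 * g0) / det
            a += np.nan_to_num(da)
            b += np.nan_to_num(db)
            if max(np.nanmax(np.abs(da)), np.nanmax(np.abs(db))) < 1e-10:
                break
        se_b = np.sqrt(h00 / det)
        rejections.append(np.abs(b / se_b) > z_crit)
    return float(np.nanmean(np.concatenate(rejections)))


# ---------------------------------------------------------------------------
# Nagelkerke R^2 comparison
# ---------------------------------------------------------------------------

@dataclass
class R2Comparison:
    delta_r2: float
    ci: tuple[float, float]
    p_value: float
    r2_a: float
    r2_b: float
    n_boot: int


def _nagelkerke_pair(y: np.ndarray, X0: np.ndarray, extra: np.ndarray) -> float:
    ll0 = sm.Logit(y, X0).fit(disp=0, maxiter=200).llf
    ll1 = sm.Logit(y, np.column_stack([X0, extra])).fit(disp=0, maxiter=200).llf
    n = len(y)
    p_bar = y.mean()
    ll_null = n * (p_bar * np.log(p_bar) + (1 - p_bar) * np.log(1 - p_bar))
    r2_cs = 1 - np.exp(2 * (ll0 - ll1) / n)
    max_r2 = 1 - np.exp(2 * ll_null / n)
    # Incremental Nagelkerke R^2 of the score over the covariates.
    return float(r2_cs / max_r2)


def compare_r2(
    score_a: np.ndarray,
    score_b: np.ndarray,
    cohort: pd.DataFrame,
    covariates=(),
    n_boot: int = 500,
    seed: int = 0,
    outcome: str = "mci",
) -> R2Comparison:
    """Paired bootstrap of the incremental Nagelkerke R^2 difference
    between two PRSs over the same covariate-only model."""
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    y = cohort[outcome].to_numpy(dtype=float)
    X0 = _design_matrix(cohort, list(covariates)).to_numpy()
    sa = np.asarray(score_a, dtype=float)
    sb = np.asarray(score_b, dtype=float)
    r2a = _nagelkerke_pair(y, X0, sa)
    r2b = _nagelkerke_pair(y, X0, sb)
    delta = r2a - r2b
    rng = np.random.default_rng(seed)
    deltas = []
    n = len(y)
    n_degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            n_degenerate += 1
            continue
        try:
            d = _nagelkerke_pair(yb, X0[idx], sa[idx]) - _nagelkerke_pair(
                yb, X0[idx], sb[idx]
            )
        except Exception:
            n_degenerate += 1
            continue
        deltas.append(d)
    if len(deltas) < n_boot // 2:
        raise ValueError("degenerate bootstrap: too many single-class resamples")
    deltas = np.asarray(deltas)
    ci = (float(np.percentile(deltas, 2.5)), float(np.percentile(deltas, 97.5)))
    p = 2 * min(float(np.mean(deltas <= 0)), float(np.mean(deltas >= 0)))
    return R2Comparison(
        delta_r2=float(delta),
        ci=ci,
        p_value=float(min(p, 1.0)),
        r2_a=float(r2a),
        r2_b=float(r2b),
        n_boot=len(deltas),
    )
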