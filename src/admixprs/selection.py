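"""Internal-validation PRS selection and PRSsum construction.

One PRS per discovery GWAS is chosen by splitting the cohort into k
(default 4) random, distinct subsets of genetically unrelated
individuals, estimating the PRS log odds-ratio for MCI in each subset,
and picking the candidate that minimizes the coefficient of variation
(sample SD / |mean|) of the k estimates.  The selected, standardized
PRSs are then summed without weights into PRSsum, which is itself
re-standardized before association testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import PRSModel, ScoreVector, score
from .panel import GenotypePanel

logger = logging.getLogger(__name__)

#: PLINK-style kinship threshold for 3rd-degree relatedness.
KINSHIP_3RD_DEGREE = 0.0442


@dataclass
class SubsetPartition:
    """Assignment of unrelated individuals to k near-equal subsets."""

    k: int
    assignment: dict[str, int]  # sample id -> subset index
    excluded: frozenset[str]  # dropped as related
    seed: int
    kinship_threshold: float

    def subset_ids(self, s: int) -> list[str]:
        return [i for i, a in self.assignment.items() if a == s]


def partition_unrelated(
    sample_ids: list[str],
    kinship_pairs: pd.DataFrame | None,
    k: int = 4,
    seed: int = 0,
    kinship_threshold: float = KINSHIP_3RD_DEGREE,
) -> SubsetPartition:
    """Greedy maximal unrelated set, randomly split into k subsets.

    ``kinship_pairs`` holds columns id1, id2, kinship; pairs at or below
    the threshold are ignored.  The higher-degree member of each related
    pair is dropped iteratively (ties by sample id, for determinism),
    then the survivors are shuffled with ``seed`` and dealt into k
    subsets whose sizes differ by at most one.
    """
    edges: dict[str, set[str]] = {}
    if kinship_pairs is not None and len(kinship_pairs):
        rel = kinship_pairs[kinship_pairs["kinship"] > kinship_threshold]
        idset = set(sample_ids)
        for a, b in zip(rel["id1"], rel["id2"]):
            if a in idset and b in idset and a != b:
                edges.setdefault(a, set()).add(b)
                edges.setdefault(b, set()).add(a)
    excluded: set[str] = set()
    while edges:
        worst = max(edges, key=lambda i: (len(edges[i]), i))
        excluded.add(worst)
        for other in edges.pop(worst):
            edges[other].discard(worst)
            if not edges[other]:
                del edges[other]
    unrelated = [i for i in sample_ids if i not in excluded]
    if len(unrelated) < k * 30:
        raise ValueError(
            f"insufficient for subset estimation: {len(unrelated)} unrelated "
            f"individuals for k={k}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unrelated))
    assignment = {unrelated[j]: int(i % k) for i, j in enumerate(order)}
    return SubsetPartition(
        k=k,
        assignment=assignment,
        excluded=frozenset(excluded),
        seed=seed,
        kinship_threshold=kinship_threshold,
    )


def coefficient_of_variation(estimates, eps: float = 1e-8) -> float:
    """Sample SD divided by |mean|; +inf when the mean is numerically zero."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("at least 2 estimates required")
    if not np.isfinite(est).all():
        raise ValueError("non-finite estimate")
    mean = est.mean()
    sd = est.std(ddof=1)
    if abs(mean) < eps:
        return float("inf")
    return float(sd / abs(mean))


def standardize(
    scores: ScoreVector, reference: tuple[float, float] | None = None
) -> ScoreVector:
    """Center/scale a score vector: (raw - mean) / sd.

    With ``reference`` omitted, the mean and sample SD are fitted on the
    full supplied sample and stored on the returned vector for later
    external use (e.g. standardizing an external cohort's scores with
    the training cohort's statistics).
    """
    if reference is None:
        if len(scores.raw) < 2:
            raise ValueError("need >= 2 samples to fit standardization")
        mean = float(scores.raw.mean())
        sd = float(scores.raw.std(ddof=1))
    else:
        mean, sd = float(reference[0]), float(reference[1])
    if sd <= 0:
        raise ValueError("zero variance: cannot standardize")
    return replace(
        scores,
        standardized=(scores.raw - mean) / sd,
        reference_mean=mean,
        reference_sd=sd,
    )


def select_best(
    candidates: list[PRSModel],
    panel: GenotypePanel,
    cohort: pd.DataFrame,
    partition: SubsetPartition,
    covariates: tuple[str, ...] = (),
    outcome: str = "mci",
) -> tuple[PRSModel, pd.DataFrame]:
    """Choose the candidate PRS minimizing the CV of subset effect sizes.

    Each candidate is scored on the panel, standardized on the full
    combined sample (storing the reference mean/SD on the model), and the
    MCI association is fitted within each subset separately.  Candidates
    whose fit fails in any subset (or with zero variants) are marked
    degenerate and never selected.  Ties break by fewer variants, then
    lower p-threshold, smaller r2_max, smaller window.
    """
    from .association import fit_logistic

    if not any(not c.degenerate for c in candidates):
        raise ValueError("no non-degenerate candidate PRS")
    cohort = cohort.set_index("sample_id", drop=False)
    rows = []
    fitted: list[PRSModel] = []
    for ci, model in enumerate(candidates):
        entry = {
            "candidate": ci,
            "gwas_name": model.gwas_name,
            "r2_max": model.params.r2_max if model.params else np.nan,
            "window_kb": model.params.window_kb if model.params else np.nan,
            "p_threshold": model.params.p_threshold if model.params else np.nan,
            "n_variants": model.n_variants,
        }
        degenerate = model.degenerate
        betas = [np.nan] * partition.k
        if not degenerate:
            sv = score(panel, model)
            try:
                sv = standardize(sv)
            except ValueError:
                degenerate = True
            else:
                model = replace(
                    model,
                    reference_mean=sv.reference_mean,
                    reference_sd=sv.reference_sd,
                )
                scored = pd.Series(sv.standardized, index=sv.sample_ids)
                for s in range(partition.k):
                    ids = [
                        i for i in partition.subset_ids(s) if i in cohort.index
                    ]
                    sub = cohort.loc[ids].assign(prs=scored.loc[ids].to_numpy())
                    try:
                        res = fit_logistic(sub, "prs", covariates, outcome=outcome)
                        betas[s] = res.estimate
                    except (ValueError, np.linalg.LinAlgError) as exc:
                        logger.info(
                            "candidate %d subset %d fit failed: %s", ci, s, exc
                        )
                        degenerate = True
                        break
        cv = np.nan
        if not degenerate and np.isfinite(betas).all():
            cv = coefficient_of_variation(betas)
            degenerate = not np.isfinite(cv)
        for s, b in enumerate(betas):
            entry[f"beta_subset{s + 1}"] = b
        entry["mean_beta"] = float(np.nanmean(betas)) if np.isfinite(betas).any() else np.nan
        entry["sd_beta"] = (
            float(np.nanstd(betas, ddof=1)) if np.isfinite(betas).all() else np.nan
        )
        entry["cv"] = cv
        entry["degenerate"] = degenerate
        rows.append(entry)
        fitted.append(model)
    report = pd.DataFrame(rows)
    ok = report[~report["degenerate"] & np.isfinite(report["cv"])]
    if ok.empty:
        raise ValueError("all candidate PRSs degenerate; selection impossible")
    ranked = ok.sort_values(
        by=["cv", "n_variants", "p_threshold", "r2_max", "window_kb"],
        kind="mergesort",
    )
    best_idx = int(ranked.iloc[0]["candidate"])
    report["selected"] = report["candidate"] == best_idx
    return fitted[best_idx], report


def prssum(
    selected_scores: list[ScoreVector], restandardize: bool = True
) -> ScoreVector:
    """Unweighted sum of standardized component PRSs.

    All components must be standardized on the same reference sample and
    carry identical sample lists.  The sum is re-standardized before
    association testing (flagged on the result); the APOE-region flag is
    the AND of the components' flags.
    """
    if not selected_scores:
        raise ValueError("no component scores supplied")
    ids = selected_scores[0].sample_ids
    for sv in selected_scores:
        if sv.sample_ids != ids:
            raise ValueError("sample mismatch between component scores")
        if sv.standardized is None:
            raise ValueError("component scores must be standardized first")
    total = np.sum([sv.standardized for sv in selected_scores], axis=0)
    flags = [sv.includes_apoe_region for sv in selected_scores]
    out = ScoreVector(
        sample_ids=list(ids),
        raw=total,
        includes_apoe_region=None if any(f is None for f in flags) else all(flags),
    )
    if restandardize:
        out = standardize(out)
    return out
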