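import numpy as np
import pandas as pd
import pytest

from admixprs import (
    GenotypePanel,
    SimulationConfig,
    simulate_cohort_phenotypes,
    simulate_panel,
    simulate_sumstats,
)
from admixprs.sumstats import SUMSTATS_COLUMNS, SummaryStatSet


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_individuals=1500,
        n_variants=200,
        n_blocks=20,
        block_r2=0.5,
        n_causal=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def panel_truth(small_config):
    return simulate_panel(small_config)


@pytest.fixture(scope="session")
def cohort(panel_truth, small_config):
    panel, truth = panel_truth
    return simulate_cohort_phenotypes(panel, truth, small_config)


@pytest.fixture(scope="session")
def sumstats(panel_truth):
    panel, truth = panel_truth
    return simulate_sumstats(truth, panel, n_discovery=30_000, seed=11, gwas_name="dev")


def random_toy_panel(rng, n_samples=120, max_variants=50, n_chroms=2):
    """A small panel with mixed LD for clumping-oracle comparisons.

    Some variants are noisy copies of a neighbor so that the r2-removal
    branch of clumping is exercised; positions are random within a span
    comparable to the clumping windows.
    """
    n_var = int(rng.integers(10, max_variants + 1))
    f = rng.uniform(0.1, 0.9, size=n_var)
    dos = rng.binomial(2, f, size=(n_samples, n_var)).astype(float)
    for j in range(1, n_var):
        if rng.random() < 0.4:  # correlate with previous variant
            keep = rng.random(n_samples) < rng.uniform(0.5, 0.95)
            dos[:, j] = np.where(keep, dos[:, j - 1], dos[:, j])
    chroms = np.sort(rng.integers(1, n_chroms + 1, size=n_var)).astype(str)
    pos = np.zeros(n_var, dtype=int)
    for c in np.unique(chroms):
        sel = chroms == c
        pos[sel] = np.sort(
            rng.choice(np.arange(1, 700_000, 7), size=int(sel.sum()), replace=False)
        )
    variants = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": "A", "alt": "G"})
    panel = GenotypePanel(
        sample_ids=[f"T{i}" for i in range(n_samples)],
        variants=variants,
        dosages=dos,
    )
    rec = pd.DataFrame(
        {
            "CHR": chroms,
            "POS": pos,
            "EA": "G",
            "OA": "A",
            "BETA": rng.normal(0, 0.1, size=n_var),
            "SE": np.full(n_var, 0.05),
            "P": rng.uniform(1e-9, 1.0, size=n_var),
            "EAF": panel.empirical_af(),
        }
    )
    ss = SummaryStatSet(gwas_name="toy", records=rec[SUMSTATS_COLUMNS])
    return panel, ss


def brute_force_clump(ss, panel, r2_max, window_kb):
    """Independent greedy-clumping oracle: full correlation matrix via
    numpy.corrcoef plus a plain python loop over p-ordered candidates."""
    corr = np.corrcoef(panel.dosages.T)
    rec = ss.records
    keymap = {}
    for j in range(panel.n_variants):
        v = panel.variants.iloc[j]
        keymap.setdefault((str(v["chrom"]), int(v["pos"])), j)
    items = []
    for i in rec.index:
        row = rec.loc[i]
        col = keymap.get((str(row["CHR"]), int(row["POS"])))
        if col is not None:
            items.append((float(row["P"]), str(row["CHR"]), int(row["POS"]), col))
    items.sort()
    removed = set()
    kept = []
    for p, chrom, pos, col in items:
        if col in removed:
            continue
        kept.append((chrom, pos))
        for p2, chrom2, pos2, col2 in items:
            if col2 == col or col2 in removed:
                continue
            if chrom2 != chrom or abs(pos2 - pos) > window_kb * 1000:
                continue
            if corr[col, col2] ** 2 > r2_max:
                removed.add(col2)
        removed.add(col)
    return sorted(kept)
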