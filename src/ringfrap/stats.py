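"""Pairwise comparison of per-cell R_130 between experimental conditions.

The default contrast is a two-sided Welch unequal-variance t test on the
per-cell recovery percentages (the natural test for "mean +/- SE, n cells"
summaries); an exact/Monte-Carlo permutation test of the mean difference
is provided as a small-sample alternative.  Benjamini-Hochberg adjustment
is applied across a table of pairwise contrasts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_LIMIT = 100_000  # enumerate all C(n_a+n_b, n_a) splits up to here


@dataclass
class ConditionComparison:
    condition_a: str
    condition_b: str
    method: str  # welch_t | exact_permutation | mc_permutation
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    adjusted_p: float = float("nan")
    flag: str = ""


def _check_samples(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    return a, b


def welch_t_test(
    sample_a, sample_b, condition_a: str = "A", condition_b: str = "B"
) -> ConditionComparison:
    """Two-sided Welch t test (unequal variances, Welch-Satterthwaite df).

    When both samples have zero variance and equal means the contrast is
    vacuous: statistic 0, p = 1 by convention, flagged.
    """
    a, b = _check_samples(sample_a, sample_b)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return ConditionComparison(
            condition_a, condition_b, "welch_t", 0.0, 1.0, len(a), len(b),
            flag="zero variance in both samples",
        )
    res = sps.ttest_ind(a, b, equal_var=False)
    return ConditionComparison(
        condition_a, condition_b, "welch_t",
        float(res.statistic), float(res.pvalue), len(a), len(b),
    )


def permutation_test(
    sample_a,
    sample_b,
    n_perm: int = 10_000,
    seed: int = 0,
    condition_a: str = "A",
    condition_b: str = "B",
    force_monte_carlo: bool = False,
) -> ConditionComparison:
    """Two-sided permutation test of the absolute mean difference.

    All C(n_a+n_b, n_a) group relabelings are enumerated exactly when
    feasible (<= 100,000); otherwise a seeded Monte-Carlo sample of
    ``n_perm`` permutations is drawn and the add-one (Phipson-Smyth)
    correction applied, so p >= 1/(n_perm + 1).  ``force_monte_carlo``
    skips exact enumeration (useful for validating the sampler).
    """
    a, b = _check_samples(sample_a, sample_b)
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    total = na + nb
    obs = abs(a.mean() - b.mean())
    eps = 1e-12 * (1.0 + obs)
    n_splits = comb(total, na)
    if n_splits <= EXACT_LIMIT and not force_monte_carlo:
        sum_all = pooled.sum()
        count = 0
        for idx in itertools.combinations(range(total), na):
            sa = pooled[list(idx)].sum()
            diff = abs(sa / na - (sum_all - sa) / nb)
            if diff >= obs - eps:
                count += 1
        return ConditionComparison(
            condition_a, condition_b, "exact_permutation",
            float(obs), count / n_splits, na, nb,
        )
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100 in Monte-Carlo mode, got {n_perm}")
    rng = np.random.default_rng(seed % (2**31))
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = abs(perm[:na].mean() - perm[na:].mean())
        if diff >= obs - eps:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return ConditionComparison(
        condition_a, condition_b, "mc_permutation", float(obs), p, na, nb,
    )


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (empty in, empty out)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_conditions(
    per_cell: pd.DataFrame,
    method: str = "welch_t",
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise contrasts of per-cell R_130 with BH adjustment.

    ``per_cell`` needs columns ``condition`` and ``r130_pct``.  ``method``
    is ``welch_t`` or ``permutation``.
    """
    if method not in ("welch_t", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    groups = {c: g["r130_pct"].to_numpy() for c, g in per_cell.groupby("condition")}
    labels = sorted(groups)
    rows = []
    for la, lb in itertools.combinations(labels, 2):
        if method == "welch_t":
            cmp_ = welch_t_test(groups[la], groups[lb], la, lb)
        else:
            cmp_ = permutation_test(
                groups[la], groups[lb], n_perm=n_perm, seed=seed,
                condition_a=la, condition_b=lb,
            )
        rows.append(cmp_)
    adj = adjust_bh([c.p_value for c in rows])
    for c, q in zip(rows, adj):
        c.adjusted_p = float(q)
    return pd.DataFrame(
        {
            "condition_a": [c.condition_a for c in rows],
            "condition_b": [c.condition_b for c in rows],
            "method": [c.method for c in rows],
            "statistic": [c.statistic for c in rows],
            "p_value": [c.p_value for c in rows],
            "adjusted_p": [c.adjusted_p for c in rows],
            "n_a": [c.n_a for c in rows],
            "n_b": [c.n_b for c in rows],
            "flag": [c.flag for c in rows],
        }
    )
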