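"""Cohort-level statistics: rank correlations, rank tests and a
patient-blocked permutation test of the biopsy-level kPL-grade association.

Skewed, small-sample data call for rank methods: Spearman correlation,
the Wilcoxon rank-sum test for unpaired and the signed-rank test for
paired comparisons, with exact permutation null distributions at small n
and tie-corrected normal approximations otherwise.  Approximately normal
quantities use Pearson correlation.

Biopsy-level measurements are clustered within patients.  The dependence
is handled by a permutation F-test: kPL is regressed on patient
indicators plus a numeric-ordinal grade term, the grade's partial F is
the statistic, and the null distribution is built by permuting grade
labels *within* each patient block — which tests the same null (no grade
effect once patient effects are removed) as a linear mixed model or
two-way ordinal ANOVA, without their parametric machinery.  All reported
p-values are two-sided.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("hp13c")

__all__ = ["StatResult", "spearman", "pearson", "rank_sum_test",
           "signed_rank_test", "blocked_grade_test"]

EXACT_N_MAX_SPEARMAN = 8
EXACT_N_MAX_RANKTEST = 10


@dataclass
class StatResult:
    """An estimate with its p-value and method bookkeeping."""

    name: str
    estimate: float
    p_value: float
    n: int
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")
        if self.name in ("spearman_rho", "pearson_r") and \
                not -1.0 - 1e-12 <= self.estimate <= 1.0 + 1e-12:
            raise ValueError("correlation estimate must lie in [-1, 1]")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("constant input: correlation undefined")
    return float(rx @ ry) / denom


def spearman(x, y) -> StatResult:
    """Spearman rank correlation with mid-ranks for ties.

    The p-value is exact (full permutation enumeration of y) for n <= 8
    and otherwise uses the t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 degrees of freedom; both
    are two-sided on |rho|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d samples")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)

    if n <= EXACT_N_MAX_SPEARMAN:
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rank_corr(rx, ry[list(perm)])) >= target:
                count += 1
        p = count / total
        notes = {"p_method": "exact_permutation", "n_perm": total}
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
        notes = {"p_method": "t_approximation"}
    notes["ties"] = "midrank"
    return StatResult("spearman_rho", rho, min(p, 1.0), n, notes)


def pearson(x, y) -> StatResult:
    """Pearson product-moment correlation with the t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d samples")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return StatResult("pearson_r", float(res.statistic), float(res.pvalue),
                      x.size, {"p_method": "t"})


def _exact_two_sided(null: np.ndarray, observed: float) -> float:
    """min(1, 2 * min(P(T <= t), P(T >= t))) over an enumerated null."""
    null = np.asarray(null, dtype=float)
    lo = np.count_nonzero(null <= observed + 1e-12) / null.size
    hi = np.count_nonzero(null >= observed - 1e-12) / null.size
    return min(1.0, 2.0 * min(lo, hi))


def rank_sum_test(a, b) -> StatResult:
    """Wilcoxon rank-sum test (two-sided), mid-ranks for ties.

    Exact: all C(n_a+n_b, n_a) group assignments are enumerated when the
    combined sample size is <= 10; larger samples use the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    combined = np.concatenate([a, b])
    n, na = combined.size, a.size
    ranks = stats.rankdata(combined)
    w = float(ranks[:na].sum())

    if n <= EXACT_N_MAX_RANKTEST:
        null = np.array([ranks[list(c)].sum()
                         for c in itertools.combinations(range(n), na)])
        p = _exact_two_sided(null, w)
        notes = {"p_method": "exact_enumeration", "n_assignments": null.size}
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
        notes = {"p_method": "normal_approximation_tie_corrected"}
    notes["ties"] = "midrank"
    return StatResult("wilcoxon_rank_sum", w, p, n, notes)


def signed_rank_test(diffs) -> StatResult:
    """Wilcoxon signed-rank test (two-sided) on paired differences.

    Zero differences are dropped; at least one nonzero difference is
    required.  Exact sign enumeration (2^n) for n <= 10 nonzero pairs,
    tie-corrected normal approximation otherwise.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 1:
        raise ValueError("all differences are zero: test degenerate")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if n <= EXACT_N_MAX_RANKTEST:
        signs = np.array(list(itertools.product([0, 1], repeat=n)), dtype=float)
        null = signs @ ranks
        p = _exact_two_sided(null, w_plus)
        notes = {"p_method": "exact_enumeration", "n_assignments": null.shape[0]}
    else:
        res = stats.wilcoxon(d, alternative="two-sided", correction=True,
                             method="approx")
        p = float(res.pvalue)
        notes = {"p_method": "normal_approximation_tie_corrected"}
    notes["ties"] = "midrank"
    return StatResult("wilcoxon_signed_rank", w_plus, p, n, notes)


def _block_center(values: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    out = values.astype(float).copy()
    for b in np.unique(blocks):
        m = blocks == b
        out[m] -= out[m].mean()
    return out


def blocked_grade_test(
    biopsy_table: pd.DataFrame,
    n_perm: int = 9999,
    seed: int = 0,
    kpl_col: str = "kpl",
    grade_col: str = "grade",
    patient_col: str = "patient_id",
) -> StatResult:
    """Patient-blocked permutation F-test of the grade effect on kPL.

    Model: kpl ~ patient indicators + numeric grade.  The statistic is the
    partial F for grade; because the patient indicators span the block
    means, it reduces to the regression of block-centered kpl on
    block-centered grade.  The null distribution permutes grade labels
    within each patient block (``n_perm`` draws, seeded) and

        p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

    Requires at least two patients, at least two distinct grades overall,
    and grade variation within at least one patient block.
    """
    df = biopsy_table
    y = df[kpl_col].to_numpy(dtype=float)
    x = df[grade_col].to_numpy(dtype=float)
    blocks = df[patient_col].to_numpy()
    n = y.size
    uniq_blocks = np.unique(blocks)
    if uniq_blocks.size < 2:
        raise ValueError("need >= 2 patients")
    if np.unique(x).size < 2:
        raise ValueError("need >= 2 distinct grades")

    yc = _block_center(y, blocks)
    xc = _block_center(x, blocks)
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("grade is constant within every patient: "
                         "blocked test undefined")
    df_resid = n - uniq_blocks.size - 1
    if df_resid < 1:
        raise ValueError("insufficient residual degrees of freedom")
    syy = float(yc @ yc)

    def partial_f(xc_arr):
        sxy = xc_arr @ yc
        delta = sxy * sxy / sxx            # sxx invariant within-block perms
        rss = np.maximum(syy - delta, 1e-300)
        return delta / (rss / df_resid)

    f_obs = float(partial_f(xc))

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n))
    for b in uniq_blocks:
        m = np.flatnonzero(blocks == b)
        tiled = np.tile(xc[m], (n_perm, 1))
        perms[:, m] = rng.permuted(tiled, axis=1)
    sxy = perms @ yc
    delta = sxy * sxy / sxx
    rss = np.maximum(syy - delta, 1e-300)
    f_perm = delta / (rss / df_resid)

    p = (1.0 + int(np.count_nonzero(f_perm >= f_obs - 1e-12))) / (1.0 + n_perm)
    return StatResult(
        "blocked_permutation_F", f_obs, p, n,
        {"n_perm": n_perm, "seed": seed, "df_resid": df_resid,
         "permutation": "grade within patient blocks"},
    )
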