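"""Differential expression: permutation tests for protein abundances and a
median-of-ratios + permutation stand-in for transcript counts.

Proteins are tested per contrast (e.g. N-/C) with a two-group permutation
test on log2 Mol% — statistic = |difference of group means| — and
Benjamini-Hochberg adjustment. When the number of distinct group-label
assignments is small (<= 10,000, e.g. C(8,4) = 70 for a 4-vs-4 design) the
permutation distribution is enumerated exactly; otherwise it is sampled.
Transcript counts are normalised with median-of-ratios size factors and
tested the same way on log2 normalised counts; a gene is called DE when
p_adj < alpha AND |L2fc| > l2fc_min (defaults 0.05 and 1.0, i.e. fold
change > 2).
"""

from __future__ import annotations

import logging

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import comb
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Enumerate the permutation null exactly when the number of distinct
#: assignments is at most this.
MAX_EXACT_ASSIGNMENTS = 10_000

_TIE_EPS = 1e-12


def log2_fold_change(treatment_values, control_values) -> float:
    """log2(mean(treatment) / mean(control)); both group means must be > 0."""
    t = np.asarray(treatment_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("both groups must be non-empty")
    mt, mc = t.mean(), c.mean()
    if mt <= 0 or mc <= 0:
        raise ValueError("group means must be positive for a log fold change")
    return float(np.log2(mt / mc))


def _assignment_weights(n: int, n_a: int) -> tuple[np.ndarray, np.ndarray]:
    """All C(n, n_a) group-A index sets as mean-weight matrices."""
    combos = np.array(list(combinations(range(n), n_a)), dtype=int)
    w_a = np.zeros((len(combos), n))
    rows = np.repeat(np.arange(len(combos)), n_a)
    w_a[rows, combos.ravel()] = 1.0 / n_a
    w_b = (1.0 - w_a * n_a) / (n - n_a)
    return w_a, w_b


def permutation_test(group_a, group_b, n_perm: int = 10_000,
                     seed: int | None = None) -> float:
    """Two-sided permutation p-value for a difference in group means.

    Statistic: |mean(a) - mean(b)|. p = (1 + #{permuted >= observed}) /
    (1 + #permutations), the add-one estimator that keeps p > 0. Exact
    enumeration when C(n, n_a) <= 10,000, else ``n_perm`` seeded draws.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("permutation test needs >= 2 values per group")
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    n, n_a = pooled.size, a.size
    n_assign = int(comb(n, n_a, exact=True))
    if n_assign <= MAX_EXACT_ASSIGNMENTS:
        w_a, w_b = _assignment_weights(n, n_a)
        stats = np.abs(w_a @ pooled - w_b @ pooled)
        count = int((stats >= obs - _TIE_EPS).sum())
        return (1 + count) / (1 + n_assign)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        stat = abs(perm[:n_a].mean() - perm[n_a:].mean())
        if stat >= obs - _TIE_EPS:
            count += 1
    return (1 + count) / (1 + n_perm)


def permutation_test_matrix(values_a: np.ndarray, values_b: np.ndarray,
                            n_perm: int = 10_000,
                            seed: int | None = None) -> np.ndarray:
    """Row-wise permutation p-values for many features sharing one design.

    ``values_a``/``values_b``: (n_features x n_a) and (n_features x n_b)
    matrices. Same statistic and estimator as :func:`permutation_test`;
    sampled permutations (when needed) are shared across features.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("permutation test needs >= 2 values per group")
    data = np.hstack([a, b])
    n, n_a = data.shape[1], a.shape[1]
    obs = np.abs(a.mean(axis=1) - b.mean(axis=1))
    n_assign = int(comb(n, n_a, exact=True))
    if n_assign <= MAX_EXACT_ASSIGNMENTS:
        w_a, w_b = _assignment_weights(n, n_a)
        stats = np.abs(data @ (w_a - w_b).T)          # features x assignments
        counts = (stats >= obs[:, None] - _TIE_EPS).sum(axis=1)
        return (1 + counts) / (1 + n_assign)
    rng = np.random.default_rng(seed)
    counts = np.zeros(data.shape[0], dtype=int)
    for _ in range(n_perm):
        idx = rng.permutation(n)
        stat = np.abs(data[:, idx[:n_a]].mean(axis=1)
                      - data[:, idx[n_a:]].mean(axis=1))
        counts += stat >= obs - _TIE_EPS
    return (1 + counts) / (1 + n_perm)


def min_attainable_p(n_a: int, n_b: int) -> float:
    """Smallest p the add-one estimator can produce for an exact test."""
    n_assign = int(comb(n_a + n_b, n_a, exact=True))
    n_assign = min(n_assign, MAX_EXACT_ASSIGNMENTS)
    return 2 / (1 + n_assign)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def corrected_raw_threshold(p_values, fdr_target: float) -> float:
    """BH rejection boundary expressed on the raw-p scale.

    The largest p_(i) with p_(i) <= (i/m) * fdr_target; 0.0 when nothing is
    rejected. Features with p_raw at or below the returned cutoff are
    exactly those BH rejects at ``fdr_target``.
    """
    if not 0 < fdr_target < 1:
        raise ValueError("fdr_target must lie in (0, 1)")
    p = np.sort(np.asarray(p_values, dtype=float))
    m = p.size
    if m == 0:
        return 0.0
    bounds = (np.arange(1, m + 1) / m) * fdr_target
    ok = p <= bounds + _TIE_EPS
    if not ok.any():
        return 0.0
    return float(p[np.max(np.nonzero(ok)[0])])


def _contrast_samples(design: pd.DataFrame, group: str,
                      day=None, assay_col: str | None = None) -> list[str]:
    sel = design[design["group"] == group]
    if day is not None and "day" in design.columns:
        sel = sel[sel["day"] == day]
    return sel["sample"].astype(str).tolist()


def protein_de(molpct: pd.DataFrame, design: pd.DataFrame,
               contrast: tuple[str, str] = ("N-", "C"),
               alpha: float = 0.05, p_threshold: float | None = None,
               n_perm: int = 10_000,
               seed: int | None = None) -> pd.DataFrame:
    """Permutation-test differential abundance of proteins for one contrast.

    ``molpct``: protein x sample Mol% matrix (see
    :func:`pamuslink.tmt_quant.molpct_matrix`). Proteins with a nonpositive
    value in any used sample are dropped (log2 undefined) and counted.

    The ``significant`` flag is ``p_adj < alpha`` by default. An exact
    enumeration over few label assignments makes permutation p-values
    coarse (floor 3/71 for 4v4), so the BH tier can be empty by
    construction on small designs; passing ``p_threshold`` instead flags
    ``p_raw < p_threshold`` (the volcano-plot raw-p tier), with p_adj still
    reported.
    """
    treat, ctrl = contrast
    labelled = design.dropna(subset=["tmt_label"]) if "tmt_label" in design else design
    t_samples = [s for s in _contrast_samples(labelled, treat) if s in molpct.columns]
    c_samples = [s for s in _contrast_samples(labelled, ctrl) if s in molpct.columns]
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError(f"contrast {treat}/{ctrl}: need >= 2 samples per group")
    p_min = min_attainable_p(len(t_samples), len(c_samples))
    if p_min > alpha:
        warnings.warn(
            f"contrast {treat}/{ctrl} is under-powered: minimum attainable "
            f"permutation p = {p_min:.3g} exceeds alpha = {alpha}",
            UserWarning, stacklevel=2)
    sub = molpct[t_samples + c_samples]
    ok = (sub > 0).all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("protein DE %s/%s: dropped %d proteins with nonpositive "
                    "Mol%%", treat, ctrl, n_dropped)
    sub = sub[ok]
    tv = sub[t_samples].to_numpy(float)
    cv = sub[c_samples].to_numpy(float)
    l2fc = np.log2(tv.mean(axis=1) / cv.mean(axis=1))
    p_raw = permutation_test_matrix(np.log2(tv), np.log2(cv),
                                    n_perm=n_perm, seed=seed)
    p_adj = bh_adjust(p_raw)
    if p_threshold is None:
        sig = p_adj < alpha
    else:
        sig = p_raw < p_threshold
    return pd.DataFrame({
        "feature": sub.index,
        "contrast": f"{treat}/{ctrl}",
        "l2fc": l2fc,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "significant": sig,
    }).reset_index(drop=True)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference; genes with
    any zero count are excluded from factor estimation)."""
    mat = counts.to_numpy(float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample; "
                         "cannot estimate size factors")
    logs = np.log(mat[positive])
    ref = logs.mean(axis=1)
    sf = np.exp(np.median(logs - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def transcript_de(counts: pd.DataFrame, design: pd.DataFrame,
                  contrast: tuple[str, str] = ("N-", "C"), day=None,
                  alpha: float = 0.05, l2fc_min: float = 1.0,
                  n_perm: int = 10_000, seed: int | None = None) -> pd.DataFrame:
    """Count-based DE: median-of-ratios normalisation, permutation test on
    log2 normalised counts, BH adjustment, and the joint call
    ``p_adj < alpha AND |L2fc| > l2fc_min``.

    Size factors are estimated on the full count matrix; the test uses the
    samples of the requested contrast (optionally restricted to one day).
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    treat, ctrl = contrast
    t_samples = [s for s in _contrast_samples(design, treat, day)
                 if s in counts.columns]
    c_samples = [s for s in _contrast_samples(design, ctrl, day)
                 if s in counts.columns]
    if len(t_samples) < 2 or len(c_samples) < 2:
        raise ValueError(f"contrast {treat}/{ctrl}: need >= 2 replicates per group")
    sf = size_factors(counts)
    norm = counts / sf
    tv = norm[t_samples].to_numpy(float)
    cv = norm[c_samples].to_numpy(float)
    mt, mc = tv.mean(axis=1), cv.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        l2fc = np.log2(mt / mc)
    p_raw = permutation_test_matrix(np.log2(tv + 1.0), np.log2(cv + 1.0),
                                    n_perm=n_perm, seed=seed)
    p_adj = bh_adjust(p_raw)
    sig = (p_adj < alpha) & (np.abs(np.nan_to_num(l2fc, nan=0.0)) > l2fc_min)
    label = f"{treat}/{ctrl}" + (f" day{day}" if day is not None else "")
    return pd.DataFrame({
        "feature": counts.index,
        "contrast": label,
        "l2fc": l2fc,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "significant": sig,
    }).reset_index(drop=True)
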