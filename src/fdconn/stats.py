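"""Permutation tests of male/female connectivity differences.

The comparison runs on the union L of the male and female emerging-link
sets, using each subject's FD weight at those links.  Per merged age group
the two sexes give a |M| x Q and a |B| x Q sample matrix.  The per-link
statistic is the classical two-group one-way ANOVA F

    T_e = ( nM (ybar - m)^2 + nB (xbar - m)^2 ) / ( SSE / (nM + nB - 2) )

and the global statistic is the sum of T_e over the Q links, a
sum-of-F combination suited to Q larger than the sample size.  p-values
come from permutation of the sex labels (exhaustive when the number of
distinct reassignments is small, Monte-Carlo otherwise), and the families
of 7 global / Q local p-values are adjusted by the step-down Holm
procedure to control the familywise error rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .grouping import merged_membership
from .weights import FDWeightMatrix

DEFAULT_N_PERM = 9999
DEFAULT_EXHAUSTIVE_LIMIT = 20_000
_VAR_TOL = 1e-12
#: relative tolerance when ranking permuted statistics against the observed
#: one: mathematically tied relabelings (e.g. mirror partitions) must count
#: as >= despite floating-point rounding
_TIE_REL = 1e-9


def _count_ge(t_perm: np.ndarray, t_obs) -> np.ndarray:
    thresh = t_obs - _TIE_REL * np.maximum(1.0, np.abs(t_obs))
    finite = np.where(np.isinf(t_obs), t_obs, thresh)
    return (t_perm >= finite).sum(axis=0)


@dataclass
class TestResult:
    """One permutation test: observed statistic and (adjusted) p-value."""

    statistic: float
    raw_p: float
    n_permutations: int
    exhaustive: bool
    seed: int | None = None
    adj_p: float | None = None
    label: str = ""


def anova_statistic(y: np.ndarray, x: np.ndarray) -> float:
    """Two-group one-way ANOVA F statistic.

    Degenerate pooled variance: returns 0 when the group means agree and
    +inf when they differ (the sentinel ranks above every finite value in
    a permutation distribution).
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.size == 0 or x.size == 0:
        raise ValueError("both samples must be non-empty")
    if y.size + x.size < 3:
        raise ValueError("need at least 3 observations in total")
    return float(
        _f_statistics(
            np.concatenate([y, x])[:, None],
            np.arange(y.size)[None, :],
            y.size,
        )[0, 0]
    )


def global_statistic(Y: np.ndarray, X: np.ndarray) -> float:
    """Sum of per-link ANOVA F statistics over shared columns."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if Y.shape[1] != X.shape[1]:
        raise ValueError(f"column mismatch: {Y.shape[1]} vs {X.shape[1]}")
    data = np.vstack([Y, X])
    stats = _f_statistics(data, np.arange(Y.shape[0])[None, :], Y.shape[0])
    return float(stats.sum(axis=1)[0])


def _f_statistics(data: np.ndarray, male_idx: np.ndarray, n_m: int) -> np.ndarray:
    """F per (permutation, column) for row-index assignments of the first group.

    ``data`` is (n, Q); ``male_idx`` is (P, n_m) row indices assigned to the
    first group in each of P permutations.  Uses the identity that the
    between-group sum of squares plus the within sum equals the (fixed)
    total sum of squares, so only group sums move across permutations.
    """
    n, q = data.shape
    n_b = n - n_m
    if n_m < 1 or n_b < 1:
        raise ValueError("both groups must be non-empty")
    grand_mean = data.mean(axis=0)
    ss_total = ((data - grand_mean) ** 2).sum(axis=0)
    sum_y = data[male_idx].sum(axis=1)  # (P, Q)
    ybar = sum_y / n_m
    xbar = (data.sum(axis=0) - sum_y) / n_b
    ssb = n_m * (ybar - grand_mean) ** 2 + n_b * (xbar - grand_mean) ** 2
    sse = ss_total - ssb
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (sse / dof)
    degenerate = sse <= _VAR_TOL
    f = np.where(degenerate & (ssb > _VAR_TOL), np.inf, f)
    f = np.where(degenerate & (ssb <= _VAR_TOL), 0.0, f)
    return f


def _assignments(
    n: int, n_m: int, n_perm: int, seed, exhaustive_limit: int
) -> tuple[np.ndarray, bool]:
    """Row-index assignments of the first group: exhaustive or Monte-Carlo."""
    from itertools import combinations

    if comb(n, n_m) <= exhaustive_limit:
        return np.array(list(combinations(range(n), n_m)), dtype=int), True
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, n_m - 1, axis=1)[:, :n_m]
    return idx, False


def permutation_test(
    Y: np.ndarray,
    X: np.ndarray,
    statistic: str = "auto",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
    label: str = "",
) -> TestResult:
    """Two-sample permutation test on the (sum-of-)F statistic.

    1-D samples use the per-link F; 2-D samples the sum over columns
    (``statistic`` may force "anova" or "sum_f").  All label reassignments
    are enumerated when their count is at most ``exhaustive_limit``
    (p = proportion of permuted statistics >= observed, identity included,
    so never 0); otherwise ``n_perm`` Monte-Carlo draws give
    p = (1 + #{T_perm >= T_obs}) / (1 + n_perm).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim == 1:
        X = X[:, None]
    if Y.shape[1] != X.shape[1]:
        raise ValueError("Y and X must share columns")
    if statistic not in ("auto", "anova", "sum_f"):
        raise ValueError(f"unknown statistic {statistic!r}")
    data = np.vstack([Y, X])
    n, n_m = data.shape[0], Y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects in total")
    idx, exhaustive = _assignments(n, n_m, n_perm, seed, exhaustive_limit)
    per_link = _f_statistics(data, idx, n_m)
    t_perm = per_link.sum(axis=1)
    t_obs = float(
        _f_statistics(data, np.arange(n_m)[None, :], n_m).sum(axis=1)[0]
    )
    count = int(_count_ge(t_perm[:, None], np.array([t_obs]))[0])
    if exhaustive:
        raw_p = count / idx.shape[0]
    else:
        raw_p = (1 + count) / (1 + idx.shape[0])
    return TestResult(
        statistic=t_obs,
        raw_p=float(raw_p),
        n_permutations=int(idx.shape[0]),
        exhaustive=exhaustive,
        seed=seed,
        label=label,
    )


def holm_adjust(pvalues) -> np.ndarray:
    """Step-down Holm adjustment (monotone, capped at 1, input order kept)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    # running max enforces step-down monotonicity; cap at 1 commutes with it
    adj_sorted = np.maximum.accumulate(np.minimum((m - np.arange(m)) * p[order], 1.0))
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


@dataclass
class StatDataset:
    """Per-merged-group male/female link-value matrices on the link set L."""

    links: list[tuple[int, int]]
    groups: dict[str, tuple[np.ndarray, np.ndarray]]  # label -> (Y males, X females)
    group_order: list[str]

    @property
    def q(self) -> int:
        return len(self.links)


def build_stat_dataset(
    cohort: list[SubjectRecord],
    subject_matrices: dict[str, FDWeightMatrix | np.ndarray],
    links: list[tuple[int, int]],
) -> StatDataset:
    """Extract each subject's link values (FD weights or thresholded
    correlations) at the links in L, per merged group."""
    membership = merged_membership(cohort)
    labels = sorted({lab for (_, lab) in membership}, key=_band_sort_key)
    rows = np.array([i - 1 for i, _ in links])
    cols = np.array([j - 1 for _, j in links])
    mats = {
        sid: (m.W if isinstance(m, FDWeightMatrix) else np.asarray(m))
        for sid, m in subject_matrices.items()
    }

    def values(subjects):
        if not subjects:
            return np.empty((0, len(links)))
        return np.array([mats[s.subject_id][rows, cols] for s in subjects])

    groups = {
        lab: (values(membership[("M", lab)]), values(membership[("F", lab)]))
        for lab in labels
    }
    return StatDataset(list(links), groups, labels)


def _band_sort_key(label: str):
    try:
        return int(str(label).split("-")[0])
    except ValueError:
        return label


def run_global_analysis(
    dataset: StatDataset,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alpha: float = 0.05,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> pd.DataFrame:
    """One sum-of-F permutation test per merged group, Holm-adjusted jointly.

    Groups with fewer than 2 subjects or an empty sex are skipped with a
    warning.  Returns a table with statistic, raw and adjusted p-values and
    a significance flag at level ``alpha``.
    """
    rng = np.random.default_rng(seed)
    results = []
    for lab in dataset.group_order:
        Y, X = dataset.groups[lab]
        if Y.shape[0] == 0 or X.shape[0] == 0 or Y.shape[0] + X.shape[0] < 3:
            warnings.warn(f"group {lab!r} skipped: too few subjects", stacklevel=2)
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        results.append(
            permutation_test(
                Y, X, "sum_f", n_perm=n_perm, seed=sub_seed,
                exhaustive_limit=exhaustive_limit, label=lab,
            )
        )
    if not results:
        return pd.DataFrame(
            columns=["group", "statistic", "raw_p", "adj_p", "significant"]
        )
    adj = holm_adjust([r.raw_p for r in results])
    for r, a in zip(results, adj):
        r.adj_p = float(a)
    return pd.DataFrame(
        {
            "group": [r.label for r in results],
            "statistic": [r.statistic for r in results],
            "raw_p": [r.raw_p for r in results],
            "adj_p": [r.adj_p for r in results],
            "n_permutations": [r.n_permutations for r in results],
            "exhaustive": [r.exhaustive for r in results],
            "significant": [r.adj_p < alpha for r in results],
        }
    )


def run_local_analysis(
    dataset: StatDataset,
    group: str,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alpha: float = 0.05,
    weak_alpha: float = 0.10,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
) -> pd.DataFrame:
    """Per-link F permutation tests in one merged group, Holm over the Q links.

    A single set of permutations is shared across links (they test the same
    relabelling).  Links are flagged at the ``alpha`` (significant) and
    ``weak_alpha`` (weak evidence) adjusted levels.
    """
    Y, X = dataset.groups[group]
    if Y.shape[0] == 0 or X.shape[0] == 0 or Y.shape[0] + X.shape[0] < 3:
        raise ValueError(f"group {group!r} has too few subjects for testing")
    data = np.vstack([Y, X])
    n, n_m = data.shape[0], Y.shape[0]
    idx, exhaustive = _assignments(n, n_m, n_perm, seed, exhaustive_limit)
    t_perm = _f_statistics(data, idx, n_m)  # (P, Q)
    t_obs = _f_statistics(data, np.arange(n_m)[None, :], n_m)[0]  # (Q,)
    count = _count_ge(t_perm, t_obs)
    if exhaustive:
        raw_p = count / idx.shape[0]
    else:
        raw_p = (1 + count) / (1 + idx.shape[0])
    adj_p = holm_adjust(raw_p)
    return pd.DataFrame(
        {
            "node_i": [i for i, _ in dataset.links],
            "node_j": [j for _, j in dataset.links],
            "statistic": t_obs,
            "raw_p": raw_p,
            "adj_p": adj_p,
            "significant": adj_p < alpha,
            "weak_evidence": adj_p < weak_alpha,
        }
    ).sort_values("adj_p", kind="stable").reset_index(drop=True)
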