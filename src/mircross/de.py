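"""Differential-expression screening for two-group microarray data.

mRNA arrays are normalized by a global lowess (MA-trend) correction in
log2 scale and screened with a SAM-style moderated t statistic
``d_i = (mean_case - mean_control) / (s_i + s0)`` whose false-discovery
rate is estimated from label permutations; a feature is called
differentially expressed when q < 0.05 and fold change > 2.  miRNA
arrays are background-subtracted, quantile-normalized and screened on
fold change alone (FC > 2), matching the weaker evidence the smaller
miRNA designs support.

The fudge factor s0 stabilizes d for low-variance features.  The default
rule takes the median of the per-feature pooled standard errors; the
``percentile_min_cv`` alternative scans s percentiles and picks the one
minimizing the coefficient of variation of the d spread across s bins,
as in the original SAM recipe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

logger = logging.getLogger("mircross")

__all__ = [
    "ExpressionMatrix",
    "DERecord",
    "SAMConfig",
    "lowess_normalize",
    "sam_statistic",
    "pooled_se",
    "permutation_fdr",
    "select_de",
    "mirna_preprocess",
    "de_table",
    "run_de_mrna",
    "run_de_mirna",
]


@dataclass
class ExpressionMatrix:
    """features x samples numeric matrix with case/control labels."""

    values: pd.DataFrame  # rows = features, columns = samples
    group: dict[str, str]  # sample -> "case" | "control"

    def __post_init__(self) -> None:
        unknown = set(self.values.columns) - set(self.group)
        if unknown:
            raise ValueError(f"samples without group labels: {sorted(unknown)}")
        bad = {g for g in self.group.values()} - {"case", "control"}
        if bad:
            raise ValueError(f"group labels must be case/control, got {bad}")
        if not self.case_samples or not self.control_samples:
            raise ValueError("both groups must be nonempty")

    @property
    def case_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.group[s] == "case"]

    @property
    def control_samples(self) -> list[str]:
        return [s for s in self.values.columns if self.group[s] == "control"]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class DERecord:
    """Per-feature differential-expression summary (log2 units)."""

    feature_id: str
    mean_case: float
    mean_control: float
    log2_fc: float
    fold_change: float  # 2**|log2_fc|, >= 1
    direction: Literal["up", "down"]
    d_stat: float
    q_value: float  # NaN in FC-only (miRNA) mode


@dataclass
class SAMConfig:
    n_permutations: int = 1000
    s0_rule: Literal["median_s", "percentile_min_cv"] = "median_s"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def lowess_normalize(matrix: ExpressionMatrix, span: float = 0.4) -> ExpressionMatrix:
    """Global lowess (MA-trend) normalization against a pseudo-reference.

    For each array, M = array - reference and A = (array + reference) / 2
    are formed against the per-feature median array; the lowess fit of M
    on A is subtracted, removing intensity-dependent bias while leaving
    true log-ratios centred where the bulk of features are unchanged.
    Input and output are log2-scale.
    """
    X = matrix.values.to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        raise ValueError("array with zero variance cannot be normalized")
    ref = np.median(X, axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        m = X[:, j] - ref
        a = 0.5 * (X[:, j] + ref)
        fitted = sm_lowess(m, a, frac=span, return_sorted=False)
        out[:, j] = X[:, j] - fitted
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=values, group=dict(matrix.group))


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force all arrays onto the mean sorted-value distribution."""
    X = values.to_numpy(dtype=float)
    order = np.argsort(X, axis=0)
    ranks = np.argsort(order, axis=0)
    target = np.sort(X, axis=0).mean(axis=1)
    return pd.DataFrame(
        target[ranks], index=values.index, columns=values.columns
    )


def mirna_preprocess(
    matrix: ExpressionMatrix,
    background_percentile: float = 2.0,
    epsilon: float = 1e-3,
) -> ExpressionMatrix:
    """Background-subtract, quantile-normalize and log2 raw miRNA intensities.

    Per array, the given intensity percentile (default 2nd) is taken as
    the background constant and subtracted with a small positive floor,
    then arrays are quantile-normalized and log2-transformed.
    """
    X = matrix.values.to_numpy(dtype=float)
    if np.any(X <= 0):
        raise ValueError("raw miRNA intensities must be positive")
    bg = np.percentile(X, background_percentile, axis=0)
    if np.any(bg >= X.max(axis=0)):
        raise ValueError("background estimate >= array maximum")
    sub = np.maximum(X - bg[None, :], epsilon)
    df = pd.DataFrame(sub, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(
        values=np.log2(quantile_normalize(df)), group=dict(matrix.group)
    )


# ---------------------------------------------------------------------------
# SAM statistic and permutation FDR
# ---------------------------------------------------------------------------

def pooled_se(X: np.ndarray, case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Per-feature pooled standard error of the group mean difference."""
    n1, n2 = case.sum(), control.sum()
    x1, x2 = X[:, case], X[:, control]
    ss = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (x2 - x2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))


def _fudge_factor(s: np.ndarray, d_num: np.ndarray, rule: str) -> float:
    if rule == "median_s":
        return float(np.median(s))
    if rule != "percentile_min_cv":
        raise ValueError(f"unknown s0 rule {rule!r}")
    # scan s percentiles; pick the s0 minimizing the CV of the MAD of
    # d across bins of s (Tusher-style stabilization)
    qs = np.percentile(s, np.arange(0, 101, 5))
    bins = np.clip(np.searchsorted(np.percentile(s, np.arange(1, 100)), s), 0, 98)
    best_s0, best_cv = float(np.median(s)), math.inf
    for s0 in qs:
        d = d_num / (s + s0)
        mads = [
            np.median(np.abs(d[bins == b] - np.median(d[bins == b])))
            for b in range(99)
            if np.any(bins == b)
        ]
        mads = np.asarray(mads)
        if mads.mean() == 0:
            continue
        cv = mads.std() / mads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_statistic(
    matrix: ExpressionMatrix, config: SAMConfig | None = None
) -> pd.Series:
    """SAM d statistic: mean difference over (pooled SE + fudge factor s0)."""
    config = config or SAMConfig()
    X = matrix.values.to_numpy(dtype=float)
    case = np.array([matrix.group[s] == "case" for s in matrix.values.columns])
    control = ~case
    if case.sum() < 2 or control.sum() < 2:
        raise ValueError("need >=2 samples per group")
    num = X[:, case].mean(axis=1) - X[:, control].mean(axis=1)
    s = pooled_se(X, case, control)
    s0 = _fudge_factor(s, num, config.s0_rule)
    return pd.Series(num / (s + s0), index=matrix.values.index, name="d_stat")


def _distinct_sign_patterns(n: int, n_case: int, limit: int) -> int:
    return math.comb(n, n_case)


def permutation_fdr(
    matrix: ExpressionMatrix,
    d_stats: pd.Series,
    config: SAMConfig | None = None,
) -> pd.Series:
    """Permutation q-values for the SAM statistic.

    Group labels are permuted ``n_permutations`` times (all distinct
    assignments when fewer exist); for each feature's threshold
    t = |d_i| the q-value is the median permutation count of |d*| >= t
    divided by the observed count of |d| >= t, capped at 1 and made
    monotone non-increasing in |d|.  Deterministic given the seed.
    """
    config = config or SAMConfig()
    rng = np.random.default_rng(config.seed)
    X = matrix.values.to_numpy(dtype=float)
    cols = list(matrix.values.columns)
    case = np.array([matrix.group[s] == "case" for s in cols])
    n, n_case = len(cols), int(case.sum())
    s0 = None

    n_distinct = _distinct_sign_patterns(n, n_case, config.n_permutations)
    if n_distinct < config.n_permutations:
        logger.warning(
            "only %d distinct label permutations exist; using all of them",
            n_distinct,
        )
        from itertools import combinations

        perms = [np.isin(np.arange(n), c) for c in combinations(range(n), n_case)]
    else:
        perms = []
        seen = set()
        while len(perms) < config.n_permutations:
            p = np.zeros(n, dtype=bool)
            p[rng.choice(n, n_case, replace=False)] = True
            key = p.tobytes()
            if key not in seen:
                seen.add(key)
                perms.append(p)

    abs_obs = np.abs(d_stats.to_numpy())
    order = np.argsort(abs_obs)[::-1]  # descending |d|
    sorted_abs = abs_obs[order]
    # observed count of |d| >= t for t = each feature's |d| (ties included)
    obs_counts = np.searchsorted(-sorted_abs, -sorted_abs, side="right")

    perm_counts = np.empty((len(perms), len(abs_obs)), dtype=np.int64)
    for i, p in enumerate(perms):
        num = X[:, p].mean(axis=1) - X[:, ~p].mean(axis=1)
        s = pooled_se(X, p, ~p)
        if s0 is None:
            # fudge factor fixed from the observed statistic's scale
            s_obs = pooled_se(X, case, ~case)
            num_obs = X[:, case].mean(axis=1) - X[:, ~case].mean(axis=1)
            s0 = _fudge_factor(s_obs, num_obs, config.s0_rule)
        d_star = np.sort(np.abs(num / (s + s0)))
        # count of |d*| >= t for each observed threshold
        perm_counts[i] = len(d_star) - np.searchsorted(d_star, sorted_abs, side="left")

    med = np.median(perm_counts, axis=0)
    q_sorted = np.minimum(med / np.maximum(obs_counts, 1), 1.0)
    # enforce monotone non-increasing q in |d| (descending order scan)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return pd.Series(q, index=d_stats.index, name="q_value")


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def de_table(
    matrix: ExpressionMatrix,
    d_stats: pd.Series | None = None,
    q_values: pd.Series | None = None,
) -> list[DERecord]:
    """Assemble per-feature DE records from a (normalized) matrix."""
    case = matrix.case_samples
    control = matrix.control_samples
    mc = matrix.values[case].mean(axis=1)
    mn = matrix.values[control].mean(axis=1)
    records = []
    for fid in matrix.values.index:
        lfc = float(mc[fid] - mn[fid])
        records.append(
            DERecord(
                feature_id=fid,
                mean_case=float(mc[fid]),
                mean_control=float(mn[fid]),
                log2_fc=lfc,
                fold_change=float(2.0 ** abs(lfc)),
                direction="up" if lfc > 0 else "down",
                d_stat=float(d_stats[fid]) if d_stats is not None else math.nan,
                q_value=float(q_values[fid]) if q_values is not None else math.nan,
            )
        )
    return records


def select_de(
    records: list[DERecord],
    fc_cutoff: float = 2.0,
    fdr_cutoff: float | None = 0.05,
) -> tuple[list[DERecord], list[DERecord]]:
    """Split significant records into (up, down) lists.

    With ``fdr_cutoff`` set (mRNA mode) a feature must satisfy
    q < fdr_cutoff AND fold_change > fc_cutoff; with ``fdr_cutoff=None``
    (miRNA mode) the fold-change criterion alone applies.  Both
    inequalities are strict.
    """
    up, down = [], []
    for r in records:
        if r.fold_change <= fc_cutoff:
            continue
        if fdr_cutoff is not None and not (r.q_value < fdr_cutoff):
            continue
        (up if r.direction == "up" else down).append(r)
    return up, down


# ---------------------------------------------------------------------------
# Convenience drivers
# ---------------------------------------------------------------------------

def run_de_mrna(
    matrix: ExpressionMatrix,
    fc_cutoff: float = 2.0,
    fdr_cutoff: float = 0.05,
    sam_config: SAMConfig | None = None,
    normalize: bool = True,
) -> tuple[list[DERecord], list[DERecord], list[DERecord]]:
    """Lowess-normalize, run SAM + permutation FDR, apply the FC/FDR screen.

    Returns (up, down, all_records).
    """
    norm = lowess_normalize(matrix) if normalize else matrix
    d = sam_statistic(norm, sam_config)
    q = permutation_fdr(norm, d, sam_config)
    records = de_table(norm, d, q)
    up, down = select_de(records, fc_cutoff, fdr_cutoff)
    return up, down, records


def run_de_mirna(
    matrix: ExpressionMatrix,
    fc_cutoff: float = 2.0,
    preprocess: bool = True,
    background_percentile: float = 2.0,
) -> tuple[list[DERecord], list[DERecord], list[DERecord]]:
    """Background-correct and normalize raw miRNA arrays, screen on FC alone."""
    norm = (
        mirna_preprocess(matrix, background_percentile) if preprocess else matrix
    )
    records = de_table(norm)
    up, down = select_de(records, fc_cutoff, fdr_cutoff=None)
    return up, down, records
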