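"""Cross-date linear trait models and variety screening statistics.

Four stages operate on the per-plot aggregates and envirotype features:

1. per-date ordinary least squares trait models, grown by greedy forward
   selection of the candidate that maximizes the coefficient of
   determination *averaged across all campaign dates* (averaging across
   dates guards against overfitting any single date; a weather variable may
   enter with exactly one temporal scheme);
2. a one-way ANOVA with Tukey HSD on the residuals of the chosen model,
   with variety as the factor — a screen for genetic signal left
   unexplained by environment and management;
3. a split-plot repeated-measures ANOVA (between: variety; within: time and
   variety x time) with the Greenhouse–Geisser sphericity adjustment, the
   benchmark-protocol analysis;
4. an effect-size partition of the total sum of squares into Environment,
   Management, Variety and Error shares via sequential (Type-I) sums of
   squares in that order.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ["Environment", "Management", "Variety"]


# ---------------------------------------------------------------------------
# OLS with sequential sums of squares
# ---------------------------------------------------------------------------

@dataclass
class OLSFit:
    coef: pd.Series           # includes "intercept"
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float
    sse: float
    sst: float
    df_resid: int
    seq_ss: dict = field(default_factory=dict)   # block name -> sequential SS


def _lstsq_sse(A: np.ndarray, y: np.ndarray):
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return beta, resid, float(resid @ resid)


def fit_ols(X: pd.DataFrame, y, blocks: list[tuple[str, list[str]]] | None = None) -> OLSFit:
    """Least-squares fit of y on X (intercept added) with Type-I block SS.

    ``blocks`` names ordered groups of columns; the sequential SS of a block
    is the drop in SSE when the block joins a model already containing all
    earlier blocks. Default: each column is its own block. Raises on rank
    deficiency and on systems with more parameters than rows.
    """
    y = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    n, p = Xv.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than predictors ({p})")
    A = np.column_stack([np.ones(n), Xv])
    if np.linalg.matrix_rank(A) < p + 1:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    beta, resid, sse = _lstsq_sse(A, y)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    if blocks is None:
        blocks = [(c, [c]) for c in X.columns]
    seq_ss = {}
    cols_so_far: list[str] = []
    prev_sse = sst
    for name, cols in blocks:
        cols_so_far.extend(cols)
        Ak = np.column_stack([np.ones(n), X[cols_so_far].to_numpy(dtype=float)])
        _, _, sse_k = _lstsq_sse(Ak, y)
        seq_ss[name] = prev_sse - sse_k
        prev_sse = sse_k
    return OLSFit(coef=pd.Series(beta, index=["intercept"] + list(X.columns)),
                  fitted=A @ beta, residuals=resid, r2=r2, sse=sse, sst=sst,
                  df_resid=n - p - 1, seq_ss=seq_ss)


# ---------------------------------------------------------------------------
# Forward selection by mean cross-date R^2
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    """A selectable predictor: a single column or an all-or-nothing block.

    ``exclusive_group`` marks mutually exclusive variants (the four temporal
    schemes of one weather variable): once one is selected the others leave
    the pool.
    """
    name: str
    columns: tuple[str, ...]
    exclusive_group: str | None = None

    @property
    def n_params(self) -> int:
        return len(self.columns)


def build_candidates(columns: list[str]) -> list[Candidate]:
    """Candidate set from pipeline column names.

    ``variety:*`` dummies form one block; ``wx:<var>[<scheme>]`` columns are
    scheme variants of one weather variable; everything else is a single
    free predictor.
    """
    cands: list[Candidate] = []
    variety_cols = tuple(c for c in columns if c.startswith("variety:"))
    for c in columns:
        if c.startswith("variety:"):
            continue
        if c.startswith("wx:"):
            var = c[3:].split("[")[0]
            cands.append(Candidate(name=c, columns=(c,), exclusive_group=var))
        else:
            cands.append(Candidate(name=c, columns=(c,)))
    if variety_cols:
        cands.append(Candidate(name="variety", columns=variety_cols))
    return cands


@dataclass
class SelectionResult:
    selected: list[Candidate]
    per_date_r2: dict            # date -> R^2 of the final model
    mean_r2: float
    trace: pd.DataFrame          # step, candidate, mean_r2 after acceptance

    @property
    def selected_names(self) -> list[str]:
        return [c.name for c in self.selected]


def _mean_r2(per_date, columns) -> tuple[float, dict] | None:
    r2s = {}
    for date, (X, y) in per_date.items():
        try:
            if columns:
                fit = fit_ols(X[list(columns)], y, blocks=[("all", list(columns))])
                r2s[date] = fit.r2
            else:
                r2s[date] = 0.0
        except (np.linalg.LinAlgError, ValueError):
            return None
    return float(np.mean(list(r2s.values()))), r2s


def forward_select(per_date: dict, candidates: list[Candidate],
                   tolerance: float = 0.01,
                   max_steps: int | None = None) -> SelectionResult:
    """Greedy forward selection maximizing mean R^2 across dates.

    At each step every remaining candidate is tried on every date's design
    and the one with the best mean R^2 joins the model, provided it improves
    the mean R^2 by more than ``tolerance * n_params(candidate)`` (the
    per-parameter scaling keeps multi-column blocks honest). Ties break by
    candidate declaration order. Candidates whose fit fails on any date are
    skipped with a warning for that step.
    """
    if not per_date:
        raise ValueError("need at least one date")
    if not candidates:
        raise ValueError("candidate set must not be empty")
    pool = list(candidates)
    selected: list[Candidate] = []
    sel_cols: list[str] = []
    current_mean, current_r2s = 0.0, {d: 0.0 for d in per_date}
    trace_rows = []
    step = 0
    while pool and (max_steps is None or step < max_steps):
        best = None
        for cand in pool:
            res = _mean_r2(per_date, sel_cols + list(cand.columns))
            if res is None:
                logger.warning("candidate %s skipped: fit failed on some date", cand.name)
                continue
            mean_r2, r2s = res
            if best is None or mean_r2 > best[0]:
                best = (mean_r2, cand, r2s)
        if best is None:
            break
        mean_r2, cand, r2s = best
        if mean_r2 - current_mean <= tolerance * cand.n_params:
            break
        selected.append(cand)
        sel_cols.extend(cand.columns)
        current_mean, current_r2s = mean_r2, r2s
        pool = [c for c in pool
                if c is not cand
                and (c.exclusive_group is None
                     or c.exclusive_group != cand.exclusive_group)]
        step += 1
        trace_rows.append({"step": step, "candidate": cand.name,
                           "mean_r2": current_mean,
                           **{f"r2[{d}]": r for d, r in current_r2s.items()}})
    trace = pd.DataFrame(trace_rows)
    return SelectionResult(selected=selected, per_date_r2=current_r2s,
                           mean_r2=current_mean, trace=trace)


# ---------------------------------------------------------------------------
# Residual one-way ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class OneWayAnova:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    p: float
    degenerate: bool


@lru_cache(maxsize=128)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def residual_anova_tukey(residuals, varieties, alpha: float = 0.05,
                         compute_pvalues: bool = True):
    """One-way ANOVA by variety on model residuals, plus Tukey HSD.

    Varieties with fewer than two observations are excluded with a warning.
    Returns ``(OneWayAnova, tukey_table)`` where the Tukey table lists each
    pair with its mean difference, the confidence interval
    ``diff +/- q_{1-alpha;k,df} * sqrt(MSE/2 * (1/n_i + 1/n_j))`` built from
    the studentized-range quantile at the pooled degrees of freedom, the
    adjusted p (studentized-range survival function; skipped when
    ``compute_pvalues`` is False — the quadrature is slow and rejection
    only needs the cached quantile) and the significance flag.
    """
    df = pd.DataFrame({"resid": np.asarray(residuals, dtype=float),
                       "variety": np.asarray(varieties, dtype=object)})
    sizes = df.groupby("variety").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("excluding varieties with <2 observations: %s", small)
        df = df[~df["variety"].isin(small)]
    groups = df.groupby("variety")
    k = groups.ngroups
    if k < 2:
        raise ValueError("need at least two varieties with >=2 observations")
    n = len(df)
    grand = df["resid"].mean()
    ss_between = float((groups.size() * (groups["resid"].mean() - grand) ** 2).sum())
    ss_within = float((groups["resid"].apply(lambda s: ((s - s.mean()) ** 2).sum())).sum())
    df_b, df_w = k - 1, n - k
    if ss_within <= 0:
        anova = OneWayAnova(ss_between, ss_within, df_b, df_w,
                            F=float("nan"), p=float("nan"), degenerate=True)
        tukey = pd.DataFrame(columns=["group1", "group2", "meandiff",
                                      "lower", "upper", "q", "p_adj", "reject"])
        return anova, tukey
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    anova = OneWayAnova(ss_between, ss_within, df_b, df_w, F=float(F), p=p,
                        degenerate=False)

    from itertools import combinations

    mse = ss_within / df_w
    labels = np.sort(groups.size().index.to_numpy())
    gmeans = groups["resid"].mean()
    gsizes = groups.size()
    qc = _q_crit(alpha, k, df_w)
    rows = []
    for a, b in combinations(labels, 2):
        diff = float(gmeans[b] - gmeans[a])
        se = float(np.sqrt(mse / 2.0 * (1.0 / gsizes[a] + 1.0 / gsizes[b])))
        q_obs = abs(diff) / se if se > 0 else float("inf")
        rows.append({"group1": a, "group2": b, "meandiff": diff,
                     "lower": diff - qc * se, "upper": diff + qc * se,
                     "q": q_obs, "p_adj": float("nan"),
                     "reject": bool(q_obs > qc)})
    tukey = pd.DataFrame(rows)
    if compute_pvalues and len(tukey):
        tukey["p_adj"] = stats.studentized_range.sf(tukey["q"].to_numpy(),
                                                    k, df_w)
    return anova, tukey


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse–Geisser adjustment
# ---------------------------------------------------------------------------

def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon of a k x k repeated-measures covariance.

    epsilon = (sum lambda)^2 / ((k-1) * sum lambda^2) with lambda the
    eigenvalues of the double-centered covariance; bounded in
    [1/(k-1), 1], and exactly 1 for k = 2.
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    if S.shape != (k, k) or k < 2:
        raise ValueError("covariance must be k x k with k >= 2")
    C = np.eye(k) - np.ones((k, k)) / k
    lam = np.linalg.eigvalsh(C @ S @ C)
    lam = np.clip(lam, 0.0, None)
    denom = (k - 1) * float(np.sum(lam ** 2))
    if denom == 0:
        return 1.0
    eps = float(np.sum(lam)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


@dataclass
class EffectRow:
    ss: float
    df: float
    F: float
    p: float
    p_gg: float


@dataclass
class RMAnovaResult:
    effects: dict            # "variety" | "time" | "variety_x_time" -> EffectRow
    epsilon: float
    n_subjects: int
    k_times: int


def rm_anova_gg(wide: pd.DataFrame, between: pd.Series) -> RMAnovaResult:
    """Split-plot repeated-measures ANOVA with GG-adjusted within-effects.

    ``wide`` holds one row per plot (subject) and one column per campaign
    date; ``between`` gives each plot's variety. The design must be balanced
    (equal replicates per variety). Epsilon comes from the pooled
    within-variety covariance of the repeated measures; the GG-adjusted
    p-values multiply both degrees of freedom of the within-subject F tests
    by epsilon. The between-subjects (variety) test is unaffected by
    sphericity, so its ``p_gg`` equals ``p``.
    """
    Y = wide.to_numpy(dtype=float)
    n, k = Y.shape
    if k < 2:
        raise ValueError("need at least two time points")
    groups = pd.Series(np.asarray(between, dtype=object), index=wide.index)
    counts = groups.value_counts()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: unequal replicates per variety")
    g = len(counts)
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("need at least two replicates per variety")

    grand = Y.mean()
    subj_mean = Y.mean(axis=1)
    time_mean = Y.mean(axis=0)
    glabels = groups.to_numpy()
    uniq = counts.index.to_numpy()
    gmask = {v: glabels == v for v in uniq}
    group_mean = {v: Y[gmask[v]].mean() for v in uniq}
    group_time_mean = {v: Y[gmask[v]].mean(axis=0) for v in uniq}

    ss_total = float(((Y - grand) ** 2).sum())
    ss_subjects = float(k * ((subj_mean - grand) ** 2).sum())
    ss_variety = float(k * r * sum((group_mean[v] - grand) ** 2 for v in uniq))
    ss_subj_err = ss_subjects - ss_variety
    ss_time = float(n * ((time_mean - grand) ** 2).sum())
    ss_interact = float(r * sum(
        ((group_time_mean[v] - group_mean[v] - time_mean + grand) ** 2).sum()
        for v in uniq))
    ss_err_within = ss_total - ss_subjects - ss_time - ss_interact

    df_variety = g - 1
    df_subj_err = g * (r - 1)
    df_time = k - 1
    df_interact = (g - 1) * (k - 1)
    df_err_within = (k - 1) * g * (r - 1)

    # pooled within-variety covariance of the repeated measures
    S = np.zeros((k, k))
    for v in uniq:
        Yv = Y[gmask[v]]
        S += (Yv - Yv.mean(axis=0)).T @ (Yv - Yv.mean(axis=0))
    S /= (n - g)
    eps = gg_epsilon(S)

    def row(ss, df_num, ms_err, df_err, adjust):
        F = (ss / df_num) / ms_err if ms_err > 0 else float("nan")
        p = float(stats.f.sf(F, df_num, df_err)) if np.isfinite(F) else float("nan")
        if adjust and np.isfinite(F):
            p_gg = float(stats.f.sf(F, eps * df_num, eps * df_err))
        else:
            p_gg = p
        return EffectRow(ss=ss, df=df_num, F=float(F), p=p, p_gg=p_gg)

    ms_subj_err = ss_subj_err / df_subj_err
    ms_err_within = ss_err_within / df_err_within
    effects = {
        "variety": row(ss_variety, df_variety, ms_subj_err, df_subj_err, adjust=False),
        "time": row(ss_time, df_time, ms_err_within, df_err_within, adjust=True),
        "variety_x_time": row(ss_interact, df_interact, ms_err_within,
                              df_err_within, adjust=True),
    }
    return RMAnovaResult(effects=effects, epsilon=eps, n_subjects=n, k_times=k)


# ---------------------------------------------------------------------------
# Effect-size partition
# ---------------------------------------------------------------------------

def effect_size_partition(X: pd.DataFrame, y, category_map: dict) -> dict:
    """Percent of total SS per category (Environment, Management, Variety).

    Every non-intercept column of X must map to one of the three
    categories; sequential (Type-I) sums of squares are accumulated in the
    fixed order Environment -> Management -> Variety and the leftover SSE
    becomes the Error share. Percentages sum to 100 up to rounding.
    """
    unmapped = [c for c in X.columns if c not in category_map]
    if unmapped:
        raise ValueError(f"unmapped predictors: {unmapped}")
    bad = {c: v for c, v in category_map.items()
           if c in X.columns and v not in CATEGORY_ORDER}
    if bad:
        raise ValueError(f"unknown categories: {bad}")
    ordered_cols = []
    blocks = []
    for cat in CATEGORY_ORDER:
        cols = [c for c in X.columns if category_map[c] == cat]
        if cols:
            ordered_cols.extend(cols)
            blocks.append((cat, cols))
    fit = fit_ols(X[ordered_cols], y, blocks=blocks)
    out = {cat: 100.0 * fit.seq_ss.get(cat, 0.0) / fit.sst for cat in CATEGORY_ORDER}
    out["Error"] = 100.0 * fit.sse / fit.sst
    return out
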