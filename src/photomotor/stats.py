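"""Assumption-gated repeated-measures statistics and regressions.

The test-selection logic mirrors common physiology practice: normality is
checked with Shapiro-Wilk and equal variance with the Levene test; when
both pass (p > 0.05) the parametric branch runs (one-way repeated-measures
ANOVA, paired t-test), otherwise the nonparametric branch (Friedman ANOVA
on ranks, Wilcoxon signed-rank).  A significant omnibus is followed by a
Student-Newman-Keuls (SNK) stepwise post hoc on ordered means, using the
studentized-range distribution; on the nonparametric branch the same
stepwise scheme runs on rank sums with infinite degrees of freedom.

Regressions: mean Z per bout against 1 cm/s speed bins, and stimulus-trial
habituation (mean response per trial index against trial number), both by
ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as st

from .behavior import BoutSet, SpeedTrace
from .signal_processing import ProcessedSignal

__all__ = [
    "StatResult",
    "RegressionResult",
    "HabituationResult",
    "rm_anova_oneway",
    "snk_posthoc",
    "snk_posthoc_ranks",
    "compare_epoch_windows",
    "paired_group_comparison",
    "bout_window_means",
    "speed_binned_regression",
    "habituation_regression",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    df: tuple | int | None
    n: int
    branch: str  # parametric | nonparametric
    posthoc: pd.DataFrame | None = None
    alpha: float = ALPHA
    assumption_p: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    x_label: str = "x"
    y_label: str = "y"

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")
        if self.n_points < 3:
            raise ValueError("regression needs at least 3 points")

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


class HabituationResult(RegressionResult):
    """Habituation regression with percent change along the fitted line."""

    def percent_change(self, i: int, j: int) -> float:
        """100 * (fit(j) - fit(i)) / fit(i); NaN when fit(i) = 0."""
        fi, fj = self.predict([i, j])
        if fi == 0.0:
            warnings.warn("fitted value at reference trial is zero", stacklevel=2)
            return float("nan")
        return float(100.0 * (fj - fi) / fi)


def rm_anova_oneway(x: np.ndarray) -> tuple[float, int, int, float, float]:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Returns (F, df_conditions, df_error, p, MS_error).  Standard two-way
    decomposition without replication: subject and condition main effects,
    the residual as error.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_total = ((x - grand) ** 2).sum()
    ss_subj = k * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_cond = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_cond
    df_cond = k - 1
    df_err = (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0.0:
        # identical residuals (e.g. all-equal data): no evidence of effect
        return 0.0, df_cond, df_err, 1.0, 0.0
    f = ms_cond / ms_err
    p = float(st.f.sf(f, df_cond, df_err))
    return float(f), df_cond, df_err, p, float(ms_err)


def _snk_stepwise(order_stats, se_for_span, df, k, labels, alpha):
    """Shared SNK stepdown: test ranges widest first; a non-significant
    range blocks every range nested inside it."""
    idx = np.argsort(order_stats)
    sorted_vals = np.asarray(order_stats, dtype=float)[idx]
    rows = []
    blocked = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            q = (sorted_vals[j] - sorted_vals[i]) / se_for_span(span)
            p = float(st.studentized_range.sf(q, span, df)) if q > 0 else 1.0
            sig = (p < alpha) and not blocked[i, j]
            if not sig:
                # block all nested ranges
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        blocked[a, b] = True
            rows.append(
                {
                    "group_a": labels[idx[i]],
                    "group_b": labels[idx[j]],
                    "diff": float(sorted_vals[j] - sorted_vals[i]),
                    "span": span,
                    "q": float(q),
                    "p_value": p,
                    "significant": bool(sig),
                }
            )
    return pd.DataFrame(rows)


def snk_posthoc(
    x: np.ndarray, ms_error: float, df_error: int, labels=None, alpha: float = ALPHA
) -> pd.DataFrame:
    """Student-Newman-Keuls on condition means after RM-ANOVA.

    q = (mean_max - mean_min) / sqrt(MS_error / n) compared against the
    studentized range at the number of means spanned.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    means = x.mean(axis=0)
    if labels is None:
        labels = [f"g{j}" for j in range(k)]
    se = np.sqrt(ms_error / n)
    if se == 0.0:
        se = np.finfo(float).tiny
    return _snk_stepwise(means, lambda span: se, df_error, k, list(labels), alpha)


def snk_posthoc_ranks(x: np.ndarray, labels=None, alpha: float = ALPHA) -> pd.DataFrame:
    """Rank-based SNK after a Friedman omnibus.

    Within-subject ranks are summed per condition; for a comparison
    spanning p ordered conditions, q = (R_max - R_min) /
    sqrt(n * p * (p + 1) / 12), referred to the studentized range with
    infinite degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    ranks = st.rankdata(x, axis=1)
    rank_sums = ranks.sum(axis=0)
    if labels is None:
        labels = [f"g{j}" for j in range(k)]
    se = lambda span: np.sqrt(n * span * (span + 1) / 12.0)
    return _snk_stepwise(rank_sums, se, np.inf, k, list(labels), alpha)


def compare_epoch_windows(
    data,
    labels=None,
    branch: str = "auto",
    alpha: float = ALPHA,
    posthoc: bool = True,
) -> StatResult:
    """Omnibus comparison of window means across repeated measures.

    ``data`` is a subjects x windows matrix (or DataFrame whose columns are
    windows).  With ``branch='auto'`` Shapiro-Wilk per window and Levene
    across windows gate the parametric branch (RM-ANOVA) against the
    nonparametric one (Friedman); either branch can be forced.  A
    significant omnibus triggers the matching SNK post hoc.
    """
    if isinstance(data, pd.DataFrame):
        if labels is None:
            labels = list(data.columns)
        x = data.to_numpy(dtype=float)
    else:
        x = np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("need a subjects x windows matrix")
    incomplete = ~np.all(np.isfinite(x), axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropping {int(incomplete.sum())} subject(s) with missing window means",
            stacklevel=2,
        )
        x = x[~incomplete]
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 complete subjects")
    if k < 2:
        raise ValueError("need at least 2 windows")
    if labels is None:
        labels = [f"w{j}" for j in range(k)]

    assumption_p: dict[str, float] = {}
    if branch == "auto":
        degenerate = any(np.ptp(x[:, j]) == 0.0 for j in range(k))
        if degenerate:
            # Shapiro is undefined on constant data; constant columns are
            # trivially compatible with normality, so only Levene gates
            normal = True
        else:
            sw = [st.shapiro(x[:, j]).pvalue for j in range(k)]
            assumption_p.update({f"shapiro_{labels[j]}": sw[j] for j in range(k)})
            normal = all(p > alpha for p in sw)
        lev = float(st.levene(*x.T, center="mean").pvalue) if np.ptp(x) else 1.0
        assumption_p["levene"] = lev
        branch = "parametric" if (normal and lev > alpha) else "nonparametric"
    if branch not in ("parametric", "nonparametric"):
        raise ValueError(f"unknown branch {branch!r}")

    if branch == "parametric":
        f, df1, df2, p, ms_err = rm_anova_oneway(x)
        ph = (
            snk_posthoc(x, ms_err, df2, labels, alpha)
            if (posthoc and p < alpha)
            else None
        )
        return StatResult(
            "one-way RM ANOVA", f, p, (df1, df2), n, "parametric", ph, alpha, assumption_p
        )
    stat, p = st.friedmanchisquare(*x.T)
    ph = snk_posthoc_ranks(x, labels, alpha) if (posthoc and p < alpha) else None
    return StatResult(
        "Friedman ANOVA on ranks",
        float(stat),
        float(p),
        k - 1,
        n,
        "nonparametric",
        ph,
        alpha,
        assumption_p,
    )


def paired_group_comparison(a, b, alpha: float = ALPHA) -> StatResult:
    """Two dependent groups: paired t-test or Wilcoxon signed-rank.

    Shapiro-Wilk on the paired differences gates the branch.  All-zero
    differences are degenerate: statistic 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return StatResult("paired t-test", 0.0, 1.0, n - 1, n, "parametric")
        warnings.warn(
            "paired differences are a non-zero constant; t statistic is unbounded",
            stacklevel=2,
        )
        return StatResult("paired t-test", float("inf"), 0.0, n - 1, n, "parametric")
    sw = float(st.shapiro(d).pvalue)
    if sw > alpha:
        t, p = st.ttest_rel(a, b)
        return StatResult(
            "paired t-test", float(t), float(p), n - 1, n, "parametric",
            assumption_p={"shapiro_diff": sw},
        )
    w, p = st.wilcoxon(a, b)
    return StatResult(
        "Wilcoxon signed-rank", float(w), float(p), None, n, "nonparametric",
        assumption_p={"shapiro_diff": sw},
    )


def bout_window_means(
    bouts: BoutSet, signal: ProcessedSignal, speed: SpeedTrace
) -> pd.DataFrame:
    """Per-bout mean Z and mean speed over the bout interval [onset, offset)."""
    rows = []
    t_sig = signal.time
    for _, b in bouts.table.iterrows():
        onset, offset = float(b["onset_s"]), float(b["offset_s"])
        in_sig = (t_sig >= onset) & (t_sig < offset)
        in_spd = (speed.time >= onset) & (speed.time < offset) & speed.valid
        if not in_sig.any() or not in_spd.any():
            continue
        rows.append(
            {
                "onset_s": onset,
                "offset_s": offset,
                "mean_z": float(signal.z[in_sig].mean()),
                "mean_speed": float(speed.speed[in_spd].mean()),
            }
        )
    return pd.DataFrame(rows, columns=["onset_s", "offset_s", "mean_z", "mean_speed"])


def speed_binned_regression(
    bouts: BoutSet,
    signal: ProcessedSignal,
    speed: SpeedTrace,
    bin_width: float = 1.0,
) -> RegressionResult:
    """OLS of per-speed-bin mean Z on bin-center speed.

    Each locomotor bout contributes its mean Z and mean speed; bouts are
    sorted into [k, k+1) cm/s bins, Z is averaged per bin, and the bin
    means are regressed on the bin centers.
    """
    per_bout = bout_window_means(bouts, signal, speed)
    if len(per_bout) == 0:
        raise ValueError("no bouts overlap the recording")
    bin_idx = np.floor(per_bout["mean_speed"].to_numpy() / bin_width).astype(int)
    g = per_bout.groupby(bin_idx)["mean_z"].mean()
    if len(g) < 3:
        raise ValueError(f"need >= 3 non-empty speed bins, got {len(g)}")
    centers = (g.index.to_numpy() + 0.5) * bin_width
    fit = st.linregress(centers, g.to_numpy())
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n_points=len(g),
        x_label="speed_bin_center_cms",
        y_label="mean_z",
    )


def habituation_regression(table: pd.DataFrame) -> HabituationResult:
    """OLS of mean stimulus response against trial number.

    ``table`` is tidy with columns mouse, trial_index, value (the
    during-window mean Z).  Values are averaged across mice per trial
    index first, so each trial index contributes one point; percent change
    between trials is read off the fitted line via
    :meth:`HabituationResult.percent_change`.
    """
    needed = {"mouse", "trial_index", "value"}
    if not needed.issubset(table.columns):
        raise ValueError(f"habituation table needs columns {sorted(needed)}")
    per_index = table.groupby("trial_index")["value"].mean()
    if len(per_index) < 3:
        raise ValueError("need >= 3 trial indices with data")
    x = per_index.index.to_numpy(dtype=float)
    y = per_index.to_numpy(dtype=float)
    fit = st.linregress(x, y)
    r2 = float(fit.rvalue**2) if np.ptp(y) > 0 else 0.0
    return HabituationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        p_value=float(fit.pvalue) if np.isfinite(fit.pvalue) else 1.0,
        n_points=len(per_index),
        x_label="trial_index",
        y_label="mean_response_z",
    )
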