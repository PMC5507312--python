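"""Group-level statistics for the cohort analyses.

Unpaired t tests (Welch by default) for endpoint comparisons, the
Mantel-Cox log-rank test for treadmill time-to-exhaustion, a split-plot
(repeated-measures) general linear model for body-weight trajectories with
within-day t tests, box-plot summaries (min, median, max plus quartiles),
per-animal fraction change, and a two-sided Grubbs outlier test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats as sps

__all__ = [
    "GroupComparison", "unpaired_t", "logrank", "logrank_chi2",
    "logrank_permutation_p", "weight_trajectory_model", "boxplot_summary",
    "fraction_change", "grubbs_test", "holm_correction",
]


@dataclass
class GroupComparison:
    """Result of one two-group comparison."""

    estimate: float           # mean difference, or chi-square for log-rank
    p_value: float
    n: tuple[int, int]
    method: str
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _summary(values: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(values)), "sd": float(np.std(values, ddof=1))
        if len(values) > 1 else float("nan"),
        "min": float(np.min(values)), "median": float(np.median(values)),
        "max": float(np.max(values)), "n": int(len(values)),
    }


def unpaired_t(a, b, welch: bool = True) -> GroupComparison:
    """Two-sided unpaired t test (Welch by default, pooled optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    method = "welch_t" if welch else "pooled_t"
    return GroupComparison(
        estimate=float(np.mean(a) - np.mean(b)),
        p_value=float(res.pvalue), n=(len(a), len(b)), method=method,
        summaries={"a": _summary(a), "b": _summary(b)})


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

EXACT_LOGRANK_LIMIT = 8  # per arm; C(16, 8) = 12870 assignments


def _exact_logrank_p(times: np.ndarray, n_a: int) -> tuple[float, float]:
    """Exact two-sided permutation p of the Mantel-Cox statistic.

    Enumerates every assignment of the pooled, fully observed sample into
    arms of size ``n_a`` and ``n - n_a`` with a vectorised suffix-sum
    computation of the hypergeometric-variance chi-square.  Returns
    (chi-square observed, exact p).
    """
    n = len(times)
    order = np.argsort(times, kind="stable")
    sorted_times = times[order]
    # membership matrix over all assignments, in sorted-time order
    combos = np.array(list(itertools.combinations(range(n), n_a)))
    member = np.zeros((len(combos), n), dtype=bool)
    member[np.arange(len(combos))[:, None], combos] = True
    # observed assignment = first n_a indices of the original ordering
    obs = np.zeros(n, dtype=bool)
    obs[order.argsort()[:n_a]] = True  # position of original arm A in sort
    member_obs = obs[None, :]

    def chi(mem: np.ndarray) -> np.ndarray:
        # suffix counts of arm-A members at risk at each sorted event time
        n1 = np.cumsum(mem[:, ::-1], axis=1)[:, ::-1].astype(float)
        o_minus_e = np.zeros(mem.shape[0])
        var = np.zeros(mem.shape[0])
        j = 0
        while j < n:
            # group tied event times
            k = j
            while k + 1 < n and sorted_times[k + 1] == sorted_times[j]:
                k += 1
            nj = float(n - j)
            dj = float(k - j + 1)
            n1j = n1[:, j]
            d1j = mem[:, j:k + 1].sum(axis=1)
            o_minus_e += d1j - dj * n1j / nj
            if nj > 1:
                var += (dj * (n1j / nj) * (1 - n1j / nj)
                        * (nj - dj) / (nj - 1))
            j = k + 1
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(var > 0, o_minus_e ** 2 / var, 0.0)
        return out

    chi_obs = float(chi(member_obs)[0])
    chi_all = chi(member)
    p = float(np.mean(chi_all >= chi_obs - 1e-12))
    return chi_obs, p


def logrank(times_a, times_b, events_a=None, events_b=None,
            method: str = "auto") -> GroupComparison:
    """Mantel-Cox log-rank test on time-to-failure.

    Treadmill exhaustion is the event; by default every failure is
    observed (no censoring).  ``method="auto"`` uses the exact permutation
    distribution of the Mantel-Cox statistic when both arms have at most
    8 fully observed times (the chi-square(1) reference is off by up to
    ~0.03 in p at that size) and the asymptotic chi-square otherwise;
    ``"asymptotic"``/``"exact"`` force a route.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = (np.ones_like(times_a, dtype=int) if events_a is None
                else np.asarray(events_a, dtype=int))
    events_b = (np.ones_like(times_b, dtype=int) if events_b is None
                else np.asarray(events_b, dtype=int))
    flags = []
    if events_a.sum() + events_b.sum() == 0:
        flags.append("degenerate:all_censored")
        return GroupComparison(0.0, 1.0, (len(times_a), len(times_b)),
                               "logrank", flags=flags)
    if (np.array_equal(np.sort(times_a), np.sort(times_b))
            and np.array_equal(np.sort(events_a), np.sort(events_b))):
        # identical samples: chi-square exactly 0
        return GroupComparison(
            0.0, 1.0, (len(times_a), len(times_b)), "logrank",
            summaries={"a": _summary(times_a), "b": _summary(times_b)})

    all_observed = events_a.all() and events_b.all()
    small = (len(times_a) <= EXACT_LOGRANK_LIMIT
             and len(times_b) <= EXACT_LOGRANK_LIMIT)
    use_exact = (method == "exact"
                 or (method == "auto" and small and all_observed))
    if method == "exact" and not (small and all_observed):
        raise ValueError("exact log-rank requires <= 8 fully observed "
                         "times per arm")
    if use_exact:
        pooled = np.concatenate([times_a, times_b])
        chi_obs, p = _exact_logrank_p(pooled, len(times_a))
        return GroupComparison(
            estimate=chi_obs, p_value=p,
            n=(len(times_a), len(times_b)), method="logrank_exact",
            summaries={"a": _summary(times_a), "b": _summary(times_b)},
            flags=flags)
    res = logrank_test(times_a, times_b, event_observed_A=events_a,
                       event_observed_B=events_b)
    return GroupComparison(
        estimate=float(res.test_statistic), p_value=float(res.p_value),
        n=(len(times_a), len(times_b)), method="logrank",
        summaries={"a": _summary(times_a), "b": _summary(times_b)},
        flags=flags)


def logrank_chi2(times: np.ndarray, groups: np.ndarray,
                 events: np.ndarray | None = None) -> float:
    """Vectorised Mantel-Cox chi-square (hypergeometric variance).

    Independent light-weight statistic used by the exhaustive permutation
    oracle; agrees with lifelines on the same data.
    """
    times = np.asarray(times, dtype=float)
    groups = np.asarray(groups, dtype=bool)
    events = (np.ones_like(times, dtype=bool) if events is None
              else np.asarray(events, dtype=bool))
    order = np.argsort(times, kind="stable")
    t, g, e = times[order], groups[order], events[order]
    n = len(t)
    uniq = np.unique(t[e])
    o_minus_e = 0.0
    var = 0.0
    for tj in uniq:
        at_risk = t >= tj
        nj = int(at_risk.sum())
        n1j = int((at_risk & g).sum())
        ev = e & (t == tj)
        dj = int(ev.sum())
        d1j = int((ev & g).sum())
        exp1 = dj * n1j / nj
        o_minus_e += d1j - exp1
        if nj > 1:
            var += dj * (n1j / nj) * (1 - n1j / nj) * (nj - dj) / (nj - 1)
    if var <= 0:
        return 0.0
    return float(o_minus_e ** 2 / var)


def logrank_permutation_p(times_a, times_b, events_a=None, events_b=None,
                          max_per_arm: int = 8) -> float:
    """Exact permutation p of the log-rank statistic (small samples).

    Enumerates every assignment of the pooled sample into the two arms
    (feasible for <= ``max_per_arm`` per arm) and returns the fraction of
    assignments with a chi-square at least the observed one.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    if len(times_a) > max_per_arm or len(times_b) > max_per_arm:
        raise ValueError(f"exhaustive enumeration limited to {max_per_arm} "
                         "per arm")
    events_a = (np.ones_like(times_a) if events_a is None
                else np.asarray(events_a))
    events_b = (np.ones_like(times_b) if events_b is None
                else np.asarray(events_b))
    pooled_t = np.concatenate([times_a, times_b])
    pooled_e = np.concatenate([events_a, events_b]).astype(bool)
    n_a = len(times_a)
    n = len(pooled_t)
    labels = np.zeros(n, dtype=bool)
    labels[:n_a] = True
    observed = logrank_chi2(pooled_t, labels, pooled_e)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n_a):
        lab = np.zeros(n, dtype=bool)
        lab[list(combo)] = True
        stat = logrank_chi2(pooled_t, lab, pooled_e)
        count += stat >= observed - 1e-12
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# Repeated-measures weight model
# ---------------------------------------------------------------------------

def _split_plot_interaction(values: np.ndarray) -> tuple[float, float]:
    """Interaction F and p of a balanced split-plot (groups x days) design.

    ``values`` has shape (n_groups, n_subjects_per_group, n_days); subjects
    are nested in groups, days are the within factor.  Returns the
    group-by-day interaction F tested against the day-by-subject-within-
    group error term.
    """
    a, n, b = values.shape
    grand = values.mean()
    subj_mean = values.mean(axis=2)            # (a, n)
    group_mean = values.mean(axis=(1, 2))      # (a,)
    day_mean = values.mean(axis=(0, 1))        # (b,)
    cell_mean = values.mean(axis=1)            # (a, b)

    ss_day = a * n * np.sum((day_mean - grand) ** 2)
    ss_cells = n * np.sum((cell_mean - grand) ** 2)
    ss_group = n * b * np.sum((group_mean - grand) ** 2)
    ss_inter = ss_cells - ss_group - ss_day
    ss_subj = b * np.sum((subj_mean - group_mean[:, None]) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_within_err = ss_total - ss_cells - ss_subj

    df_inter = (a - 1) * (b - 1)
    df_err = a * (n - 1) * (b - 1)
    ms_inter = ss_inter / df_inter
    ms_err = ss_within_err / df_err
    if ms_err <= 0:
        return 0.0, 1.0
    f = ms_inter / ms_err
    p = float(sps.f.sf(f, df_inter, df_err))
    return float(f), p


def weight_trajectory_model(weights: pd.DataFrame,
                            baseline_day: int = 0) -> dict:
    """Group x day repeated-measures analysis of percent weight change.

    Expects a tidy frame with columns animal, group, day, weight_g.  Weights
    are converted to percent change from ``baseline_day`` per animal (so the
    result is invariant to each animal's absolute scale), then a balanced
    split-plot general linear model tests the group-by-day interaction;
    Welch t tests compare groups within each day.  Animals missing any day
    are dropped listwise with a warning.
    """
    wide = weights.pivot_table(index=["group", "animal"], columns="day",
                               values="weight_g")
    if wide.isna().any().any():
        incomplete = wide.index[wide.isna().any(axis=1)]
        warnings.warn(f"dropping {len(incomplete)} animals with missing "
                      "days (listwise deletion)", stacklevel=2)
        wide = wide.dropna()
    if baseline_day not in wide.columns:
        raise ValueError(f"baseline day {baseline_day} not present")
    pct = 100.0 * (wide.div(wide[baseline_day], axis=0) - 1.0)
    post = pct.drop(columns=[baseline_day])

    group_names = sorted({g for g, _ in post.index})
    if len(group_names) != 2:
        raise ValueError("exactly two groups are required")
    blocks = [post.loc[g].to_numpy() for g in group_names]
    n_min = min(len(b) for b in blocks)
    if any(len(b) != n_min for b in blocks):
        warnings.warn("unbalanced groups: truncating to the smaller group "
                      "for the split-plot model", stacklevel=2)
        blocks = [b[:n_min] for b in blocks]
    values = np.stack(blocks)  # (2, n, days)
    f, p = _split_plot_interaction(values)

    per_day = {}
    for j, day in enumerate(post.columns):
        try:
            per_day[int(day)] = unpaired_t(values[0, :, j], values[1, :, j])
        except ValueError:
            continue
    return {"interaction_F": f, "interaction_p": p,
            "groups": group_names, "n_per_group": n_min,
            "days": [int(d) for d in post.columns],
            "within_day": per_day}


# ---------------------------------------------------------------------------
# Small descriptive helpers
# ---------------------------------------------------------------------------

def boxplot_summary(values) -> dict[str, float]:
    """Min, quartiles, median, max — the panels plot min/median/max."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    return {
        "min": float(np.min(values)),
        "q1": float(np.percentile(values, 25)),
        "median": float(np.median(values)),
        "q3": float(np.percentile(values, 75)),
        "max": float(np.max(values)),
    }


def fraction_change(baseline, followup) -> np.ndarray:
    """(followup - baseline) / baseline, per animal."""
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if baseline.shape != followup.shape:
        raise ValueError("baseline and followup must align")
    if np.any(baseline == 0):
        raise ValueError("zero baseline value: fraction change undefined")
    return (followup - baseline) / baseline


def holm_correction(p_values) -> np.ndarray:
    """Holm step-down adjusted p values (family-wise error control).

    Off by default across the package, matching per-comparison reporting;
    callers opt in where a family of endpoint tests is reported together.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def grubbs_test(values, alpha: float = 0.05) -> int | None:
    """Two-sided Grubbs test; index of the single most extreme outlier or
    None if it does not reach significance at ``alpha``."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 observations")
    mean, sd = values.mean(), values.std(ddof=1)
    if sd == 0:
        return None
    deviations = np.abs(values - mean)
    idx = int(np.argmax(deviations))
    g = deviations[idx] / sd
    t = sps.t.ppf(1 - alpha / (2 * n), n - 2)
    g_crit = ((n - 1) / np.sqrt(n)) * np.sqrt(t ** 2 / (n - 2 + t ** 2))
    return idx if g > g_crit else None
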