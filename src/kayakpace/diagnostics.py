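"""Model validation: sojourn times, geometric goodness of fit, residual RMSE.

Under a time-homogeneous Markov chain the number of consecutive races spent
in one state is geometric; comparing decoded sojourn distributions against
Geometric(p-hat) is the standard check that a hidden *semi*-Markov model is
not needed.  Residual RMSE per PC under the globally decoded state, compared
with each PC's marginal SD, measures how much of the score variation the
state structure explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import FitResult, emission_mean


@dataclass(frozen=True)
class SojournTable:
    """Run lengths of consecutive same-state races, per state."""

    runs: dict[int, list[int]]

    def total_observations(self) -> int:
        return sum(sum(r) for r in self.runs.values())


def sojourn_times(paths) -> SojournTable:
    """Extract maximal same-state runs from decoded paths.

    Runs never merge across athletes: each path contributes its own runs.
    """
    paths = [np.asarray(p, dtype=int) for p in paths]
    if not paths or all(len(p) == 0 for p in paths):
        raise ValueError("need at least one non-empty decoded path")
    runs: dict[int, list[int]] = {}
    for path in paths:
        if len(path) == 0:
            continue
        change = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(path)]])
        for s, e in zip(starts, ends):
            runs.setdefault(int(path[s]), []).append(int(e - s))
    return SojournTable(runs)


@dataclass(frozen=True)
class GeometricGofResult:
    """Chi-square goodness of fit of run lengths to Geometric(p_hat)."""

    p_hat: float
    statistic: float | None
    pvalue: float | None
    df: int | None
    n_runs: int
    sufficient: bool
    message: str = ""


def geometric_gof(run_lengths, min_runs: int = 20, min_expected: float = 5.0) -> GeometricGofResult:
    """Fit Geometric(p-hat) by ML and chi-square test the binned run lengths.

    Support convention: run lengths start at 1 with P(L = l) =
    (1 - p)^(l - 1) p, so the MLE is p-hat = 1 / mean.  Bins are single
    lengths 1, 2, ... with the geometric tail merged from the right until
    every expected count is at least ``min_expected``; degrees of freedom
    are bins - 2 (one for the total, one for the estimated p).  With fewer
    than ``min_runs`` runs an explicit insufficient-data result is
    returned instead of a p-value.
    """
    lengths = np.asarray(list(run_lengths), dtype=int)
    if np.any(lengths < 1):
        raise ValueError("run lengths must be >= 1")
    n = len(lengths)
    if n < min_runs:
        return GeometricGofResult(
            p_hat=float("nan") if n == 0 else 1.0 / lengths.mean(),
            statistic=None,
            pvalue=None,
            df=None,
            n_runs=n,
            sufficient=False,
            message=f"only {n} runs (< {min_runs}); test not performed",
        )
    p_hat = 1.0 / lengths.mean()
    if p_hat >= 1.0:
        # all runs have length 1: the fitted geometric is degenerate at 1
        return GeometricGofResult(
            p_hat=1.0, statistic=0.0, pvalue=1.0, df=0, n_runs=n, sufficient=True,
            message="all runs length 1; fitted geometric is degenerate",
        )
    # expected counts per length, tail merged from the right
    max_len = int(lengths.max())
    support = np.arange(1, max_len + 1)
    pmf = (1.0 - p_hat) ** (support - 1) * p_hat
    tail = (1.0 - p_hat) ** max_len  # P(L > max_len)
    expected = n * np.append(pmf, tail)
    observed = np.append(np.bincount(lengths, minlength=max_len + 1)[1:], 0)
    # merge from the right until all expected >= min_expected
    exp_list = list(expected)
    obs_list = list(observed)
    while len(exp_list) > 2 and exp_list[-1] < min_expected:
        exp_list[-2] += exp_list[-1]
        obs_list[-2] += obs_list[-1]
        exp_list.pop()
        obs_list.pop()
    # merge any remaining sparse interior bins into their right neighbour
    i = 0
    while i < len(exp_list) - 1:
        if exp_list[i] < min_expected:
            exp_list[i + 1] += exp_list[i]
            obs_list[i + 1] += obs_list[i]
            exp_list.pop(i)
            obs_list.pop(i)
        else:
            i += 1
    if len(exp_list) > 1 and exp_list[-1] < min_expected:
        exp_list[-2] += exp_list[-1]
        obs_list[-2] += obs_list[-1]
        exp_list.pop()
        obs_list.pop()
    k = len(exp_list)
    if k < 3:
        return GeometricGofResult(
            p_hat=p_hat, statistic=None, pvalue=None, df=None, n_runs=n,
            sufficient=False,
            message="fewer than 3 usable bins after merging; test not performed",
        )
    obs_arr = np.asarray(obs_list, dtype=float)
    exp_arr = np.asarray(exp_list, dtype=float)
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    statistic = float(np.sum((obs_arr - exp_arr) ** 2 / exp_arr))
    df = k - 2
    pvalue = float(stats.chi2.sf(statistic, df))
    return GeometricGofResult(
        p_hat=p_hat, statistic=statistic, pvalue=pvalue, df=df, n_runs=n,
        sufficient=True,
    )


def residual_rmse(fit: FitResult, sequences) -> pd.DataFrame:
    """Per-PC RMSE of residuals under the globally decoded states.

    The residual at race t is the observed score minus the decoded state's
    covariate-adjusted emission mean.  The marginal SD column gives each
    PC's overall spread for comparison: a model with real state structure
    has RMSE below the marginal SD.
    """
    return residual_rmse_paths(fit.params, fit.decoded, sequences)


def residual_rmse_paths(params, paths, sequences) -> pd.DataFrame:
    """As :func:`residual_rmse`, from explicit parameters and state paths."""
    residuals = []
    observations = []
    for seq, path in zip(sequences, paths, strict=True):
        for t in range(len(seq)):
            m = emission_mean(params, int(path[t]), seq.covariates[t])
            residuals.append(seq.observations[t] - m)
            observations.append(seq.observations[t])
    R = np.asarray(residuals)
    O = np.asarray(observations)
    d = R.shape[1]
    return pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(d)],
            "rmse": np.sqrt(np.mean(R**2, axis=0)),
            "marginal_sd": O.std(axis=0, ddof=0),
        }
    )


def career_summary(sequences, fit: FitResult, records_meta=None) -> pd.DataFrame:
    """Per-race state timeline for every athlete.

    Returns a tidy frame with one row per decoded race: athlete_id,
    race_index (position within the chain unless ``records_meta`` supplies
    true indices/covariate labels), decoded state (1-based) and its
    posterior probability.  ``records_meta``, if given, maps athlete_id to
    a list of (race_index, age_group, event_type) tuples aligned with the
    chain.
    """
    rows = []
    for k, (seq, path, gamma) in enumerate(
        zip(sequences, fit.decoded, fit.posteriors, strict=True)
    ):
        meta = records_meta.get(seq.athlete_id) if records_meta else None
        for t in range(len(seq)):
            row = {
                "athlete_id": seq.athlete_id,
                "race_index": meta[t][0] if meta else t,
                "age_group": meta[t][1] if meta else "",
                "event_type": meta[t][2] if meta else "",
                "state": int(path[t]) + 1,
                "posterior": float(np.clip(gamma[t, int(path[t])], 0.0, 1.0)),
            }
            rows.append(row)
    return pd.DataFrame(rows)


def transition_counts(path: np.ndarray, n_states: int) -> np.ndarray:
    """Observed state-to-state transition counts along one decoded path."""
    C = np.zeros((n_states, n_states), dtype=int)
    p = np.asarray(path, dtype=int)
    np.add.at(C, (p[:-1], p[1:]), 1)
    return C


def modal_state_by_age(timeline: pd.DataFrame) -> pd.DataFrame:
    """Most frequent decoded state per athlete per age group."""
    if timeline.empty or (timeline["age_group"] == "").all():
        return pd.DataFrame(columns=["athlete_id", "age_group", "modal_state"])
    out = (
        timeline[timeline["age_group"] != ""]
        .groupby(["athlete_id", "age_group"])["state"]
        .agg(lambda s: s.mode().iloc[0])
        .reset_index()
        .rename(columns={"state": "modal_state"})
    )
    return out


def plot_timeline(timeline: pd.DataFrame, athlete_id: str, ax=None):
    """Step plot of one athlete's decoded state across their career."""
    import matplotlib.pyplot as plt

    sub = timeline[timeline["athlete_id"] == athlete_id].sort_values("race_index")
    if sub.empty:
        raise ValueError(f"no decoded races for athlete {athlete_id!r}")
    if ax is None:
        _, ax = plt.subplots()
    ax.step(sub["race_index"], sub["state"], where="mid")
    ax.set_yticks(sorted(sub["state"].unique()))
    ax.set_xlabel("race")
    ax.set_ylabel("decoded state")
    ax.set_title(f"athlete {athlete_id}")
    return ax
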