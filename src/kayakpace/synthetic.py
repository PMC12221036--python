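"""Synthetic race-data generator with the structure the analysis assumes.

No race dataset is deposited with the study this package models, so every
pipeline stage is exercised on simulated data: careers that progress
monotonically through age groups, latent pacing states evolving by the
published transition matrices, PC scores drawn from the covariate-dependent
state Gaussians, and raw 50 m split times reconstructed from a smooth shape
library so that the full filter -> normalise -> fPCA -> HMM pipeline can be
round-tripped against known truth.

The shape library lives inside the same cubic B-spline space the fPCA stage
uses: a mean pacing curve rising to its peak early (about 75-80 m for
500 m races, about 100-125 m for 1000 m, with a small late "kick" in the
1000 m shape) and four orthonormal perturbation shapes.  Building the
shapes in-span makes the noise-free score round trip exact up to the
normalisation convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .fpca import BSplineBasis, default_basis
from .hmm import HMMParams
from .race_data import (
    AgeGroup,
    Event,
    EventType,
    Phase,
    RaceRecord,
    records_to_frame,
    segment_grid,
)
from .tables import published_params

MEAN_VELOCITY = {
    Event.W_K1_500: (4.29, 0.23),
    Event.M_K1_1000: (4.80, 0.24),
}

# Mid-segment targets for the mean normalised pacing curve.  500 m: sharp
# early acceleration, peak at the second segment, steady decline (all-out
# profile).  1000 m: peak slightly later, decline to halfway, plateau, then
# a small kick inside the last 250 m (seahorse profile).
_MEAN_TARGETS = {
    Event.W_K1_500: np.array(
        [0.880, 1.060, 1.048, 1.032, 1.016, 1.001, 0.988, 0.974, 0.962, 0.952]
    ),
    Event.M_K1_1000: np.array(
        [
            0.900, 1.050, 1.058, 1.040, 1.020, 1.000, 0.985, 0.975, 0.967,
            0.961, 0.957, 0.955, 0.954, 0.954, 0.955, 0.958, 0.968, 0.977,
            0.974, 0.968,
        ]
    ),
}


@dataclass(frozen=True)
class ShapeLibrary:
    """Mean pacing curve and orthonormal perturbation shapes for one event.

    All functions are B-spline coefficient vectors on ``basis``; the four
    shape rows are orthonormal under the exact L2 inner product, and the
    mean curve's values at the segment midpoints have harmonic mean 1 so a
    zero-score race normalises back onto the mean curve exactly.
    """

    event: Event
    basis: BSplineBasis
    mean_coefs: np.ndarray
    shape_coefs: np.ndarray  # (4, n_basis)


@lru_cache(maxsize=None)
def shape_library(event: Event) -> ShapeLibrary:
    basis = default_basis(float(event.distance_m))
    mid = segment_grid(event)
    D = basis.design(mid)
    mean_coefs, *_ = np.linalg.lstsq(D, _MEAN_TARGETS[event], rcond=None)
    # harmonic mean of midpoint values -> exactly 1 (time-weighted mean of
    # the normalised profile is 1 by the normalisation contract)
    fitted = D @ mean_coefs
    mean_coefs = mean_coefs / (len(fitted) / np.sum(1.0 / fitted))

    # raw perturbation shapes: dropoff (early fast / late slow), mid-race
    # dip vs late surge, and two higher-frequency early/late contrasts;
    # projected into the basis then Gram-Schmidt orthonormalised under G.
    p = event.distance_m
    fine = np.linspace(0.0, float(p), 200)
    u = fine / p
    raw = np.stack(
        [
            np.cos(np.pi * u),
            np.cos(2 * np.pi * u),
            np.sin(2 * np.pi * u),
            np.cos(3 * np.pi * u),
        ]
    )
    Df = basis.design(fine)
    coefs = np.linalg.lstsq(Df, raw.T, rcond=None)[0].T
    G = basis.gram()
    shapes = []
    for c in coefs:
        for s in shapes:
            c = c - (s @ G @ c) * s
        c = c / np.sqrt(c @ G @ c)
        shapes.append(c)
    return ShapeLibrary(
        event=event,
        basis=basis,
        mean_coefs=mean_coefs,
        shape_coefs=np.stack(shapes),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one simulated dataset.

    Defaults mirror the modelled cohorts: 70 athletes for the women's
    event, race-average velocities 4.29 +/- 0.23 m/s (women) or
    4.80 +/- 0.24 m/s (men), the published four-state parameters as truth
    with per-dimension emission SD 0.2, and event-type frequencies of
    0.6 / 0.25 / 0.15 for Domestic / World Cup-Juniors / Champs-Olympics.
    """

    event: Event = Event.W_K1_500
    n_athletes: int = 70
    races_per_athlete: tuple[int, int] = (10, 40)
    sigma: float = 0.2
    include_covariates: bool = True
    params: HMMParams | None = None
    mean_velocity: tuple[float, float] | None = None
    profile_noise_sd: float = 0.01
    event_type_probs: tuple[float, float, float] = (0.6, 0.25, 0.15)
    heat_prob: float = 0.3
    seed: int = 0

    def true_params(self) -> HMMParams:
        if self.params is not None:
            return self.params
        return published_params(
            self.event, sigma=self.sigma, include_covariates=self.include_covariates
        )

    def velocity_distribution(self) -> tuple[float, float]:
        return self.mean_velocity or MEAN_VELOCITY[self.event]


def sample_career(config: SyntheticConfig, athlete_index: int, rng=None):
    """Covariate schedule for one athlete: monotone age progression.

    Returns lists (age_groups, event_types, phases) of equal length.  Age
    groups never regress: two (women) or three (men) sorted cut points,
    drawn beyond the career end so some athletes stay in one group, divide
    the career into consecutive age bands.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1, athlete_index])
        )
    lo, hi = config.races_per_athlete
    T = int(rng.integers(lo, hi + 1))
    groups = (
        [AgeGroup.U18, AgeGroup.U21, AgeGroup.U23, AgeGroup.Open]
        if config.event is Event.M_K1_1000
        else [AgeGroup.U21, AgeGroup.U23, AgeGroup.Open]
    )
    cuts = np.sort(rng.uniform(0, 1.5 * T, size=len(groups) - 1))
    ages = []
    for t in range(T):
        ages.append(groups[int(np.searchsorted(cuts, t, side="right"))])
    tiers = [EventType.Domestic, EventType.WorldCupJuniors, EventType.WorldChampsOlympics]
    event_types = [
        tiers[i] for i in rng.choice(3, size=T, p=config.event_type_probs)
    ]
    phases = []
    for et in event_types:
        if rng.uniform() < config.heat_prob:
            phases.append(Phase.heat)
        else:
            phases.append(Phase.semi if rng.uniform() < 0.4 else Phase.final)
    return ages, event_types, phases


def simulate_states(
    transmat: np.ndarray, startprob: np.ndarray, T: int, rng
) -> np.ndarray:
    """Sample one latent state path from the Markov chain."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    A = np.asarray(transmat, dtype=float)
    n = A.shape[0]
    path = np.empty(T, dtype=int)
    path[0] = rng.choice(n, p=np.asarray(startprob, dtype=float))
    for t in range(1, T):
        path[t] = rng.choice(n, p=A[path[t - 1]])
    return path


def covariate_matrix(params: HMMParams, ages, event_types) -> np.ndarray:
    """0/1 indicator matrix in the model's covariate order."""
    Z = np.zeros((len(ages), params.n_covariates))
    names = list(params.covariate_names)
    for t, (a, e) in enumerate(zip(ages, event_types)):
        if a.value in names:
            Z[t, names.index(a.value)] = 1.0
        if e.value in names:
            Z[t, names.index(e.value)] = 1.0
    return Z


def simulate_scores(
    params: HMMParams, states: np.ndarray, covariates: np.ndarray, rng
) -> np.ndarray:
    """Draw PC-score observations from the state-conditional Gaussians."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    states = np.asarray(states, dtype=int)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    X = np.hstack([np.ones((len(states), 1)), Z])
    means = np.einsum("tq,tdq->td", X, params.coefs[states])
    sds = np.sqrt(params.variances[states])
    return means + sds * rng.standard_normal(means.shape)


def scores_to_splits(
    shapes: ShapeLibrary,
    scores: np.ndarray,
    mean_velocity: float,
    profile_noise_sd: float,
    rng,
    max_tries: int = 100,
) -> tuple[float, ...]:
    """Per-50 m split durations realising one race's planted PC scores.

    The normalised curve mean + sum(score_k * shape_k) is evaluated at the
    segment midpoints, perturbed by iid grid noise, scaled by the race
    mean velocity and inverted to durations.  Draws yielding non-positive
    velocities are resampled (pathological scores eventually raise).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    scores = np.asarray(scores, dtype=float)
    event = shapes.event
    mid = segment_grid(event)
    D = shapes.basis.design(mid)
    base = D @ (shapes.mean_coefs + scores @ shapes.shape_coefs)
    for _ in range(max_tries):
        u = base + profile_noise_sd * rng.standard_normal(len(base))
        if np.all(u > 0.05):
            v = u * mean_velocity
            return tuple(50.0 / v)
    raise ValueError(
        "could not realise a positive velocity profile; scores too extreme"
    )


def generate_dataset(
    config: SyntheticConfig, csv_path=None, truth_path=None
) -> tuple[list[RaceRecord], dict]:
    """Full synthetic dataset plus its truth sidecar.

    Returns (records, truth).  ``truth`` records, per race key
    "athlete_id:race_index", the latent state and planted scores, together
    with the generating parameters and seed so recovery tests can join on
    the filtered data.
    """
    params = config.true_params()
    v_mean, v_sd = config.velocity_distribution()
    shapes = shape_library(config.event)
    records: list[RaceRecord] = []
    races: dict[str, dict] = {}
    for a in range(config.n_athletes):
        athlete_id = f"ath{a:03d}"
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, a]))
        ages, event_types, phases = sample_career(config, a, rng)
        T = len(ages)
        states = simulate_states(params.transmat, params.startprob, T, rng)
        Z = covariate_matrix(params, ages, event_types)
        scores = simulate_scores(params, states, Z, rng)
        for t in range(T):
            v_bar = rng.normal(v_mean, v_sd)
            splits = scores_to_splits(
                shapes, scores[t], v_bar, config.profile_noise_sd, rng
            )
            records.append(
                RaceRecord(
                    athlete_id=athlete_id,
                    race_index=t,
                    event=config.event,
                    age_group=ages[t],
                    event_type=event_types[t],
                    phase=phases[t],
                    split_durations=splits,
                )
            )
            races[f"{athlete_id}:{t}"] = {
                "state": int(states[t]),
                "scores": [float(s) for s in scores[t]],
                "mean_velocity": float(v_bar),
            }
    truth = {
        "seed": config.seed,
        "event": config.event.value,
        "params": params.to_dict(),
        "races": races,
    }
    if csv_path is not None:
        records_to_frame(records).to_csv(csv_path, index=False)
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(truth, fh)
    return records, truth


def simulate_score_sequences(
    params: HMMParams,
    n_athletes: int,
    races_per_athlete: int,
    seed: int,
    covariate_sampler=None,
):
    """Score-level dataset: AthleteSequence chains plus true state paths.

    Bypasses the curve stage for tests and model selection that operate on
    PC scores directly.  ``covariate_sampler(rng, T)`` may supply a (T, c)
    indicator matrix per athlete; by default covariates are all zero.
    """
    from .hmm import AthleteSequence

    sequences = []
    paths = []
    for a in range(n_athletes):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3, a]))
        T = races_per_athlete
        if covariate_sampler is None:
            Z = np.zeros((T, params.n_covariates))
        else:
            Z = covariate_sampler(rng, T)
        states = simulate_states(params.transmat, params.startprob, T, rng)
        scores = simulate_scores(params, states, Z, rng)
        sequences.append(
            AthleteSequence(
                athlete_id=f"ath{a:03d}",
                observations=scores,
                covariates=Z,
                covariate_names=params.covariate_names,
            )
        )
        paths.append(states)
    return sequences, paths
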