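"""Covariate-dependent Gaussian hidden Markov model of PC-score careers.

Each athlete's career is one chain: the hidden state S_t is the pacing-
profile cluster occupied at race t, evolving by a single transition matrix
shared across athletes, and the observation O_t is the 4-vector of
functional-PC scores for that race.  Emissions are Gaussian with diagonal
state-specific covariance and a mean that is linear in race covariates
(age-group and event-type indicators):

    E[O_ti | S_t = j, z_t] = beta_ij0 + sum_k beta_ijk * z_tk

Fitting is multi-sequence EM (Baum-Welch with a weighted-least-squares
M-step for the emission regressions), restarted from many random starting
points; the number of states is selected by AIC.  Decoding is global
(Viterbi).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

_LOG2PI = math.log(2.0 * math.pi)

AGE_COVARIATES = frozenset({"U18", "U21", "U23"})
EVENT_COVARIATES = frozenset({"WorldCupJuniors", "WorldChampsOlympics"})


@dataclass(frozen=True)
class AthleteSequence:
    """One athlete's ordered PC-score observations and covariates.

    ``observations`` is (T, d); ``covariates`` is a (T, c) 0/1 indicator
    matrix in the order of the model's covariate names.  At most one age
    and one event indicator may be set per race.
    """

    athlete_id: str
    observations: np.ndarray
    covariates: np.ndarray
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        obs = np.atleast_2d(np.asarray(self.observations, dtype=float))
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov.reshape(len(obs), -1)
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "covariates", cov)
        if len(obs) < 1:
            raise ValueError("sequence must contain at least one race")
        if len(cov) != len(obs):
            raise ValueError("covariates and observations disagree in length")
        if cov.size and not np.isin(cov, (0.0, 1.0)).all():
            raise ValueError("covariates must be 0/1 indicators")
        if self.covariate_names:
            age_idx = [i for i, n in enumerate(self.covariate_names) if n in AGE_COVARIATES]
            evt_idx = [i for i, n in enumerate(self.covariate_names) if n in EVENT_COVARIATES]
            if age_idx and np.any(cov[:, age_idx].sum(axis=1) > 1):
                raise ValueError("more than one age-group indicator set")
            if evt_idx and np.any(cov[:, evt_idx].sum(axis=1) > 1):
                raise ValueError("more than one event-type indicator set")

    def __len__(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class HMMParams:
    """Parameters of the covariate-dependent Gaussian HMM.

    coefs[j, i, 0] is the intercept for state j, PC dimension i, and
    coefs[j, i, 1 + k] the effect of covariate k; variances[j, i] is the
    state- and dimension-specific emission variance.
    """

    startprob: np.ndarray
    transmat: np.ndarray
    coefs: np.ndarray
    variances: np.ndarray
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "startprob", np.asarray(self.startprob, dtype=float))
        object.__setattr__(self, "transmat", np.asarray(self.transmat, dtype=float))
        object.__setattr__(self, "coefs", np.asarray(self.coefs, dtype=float))
        object.__setattr__(self, "variances", np.asarray(self.variances, dtype=float))
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        n = len(self.startprob)
        if self.transmat.shape != (n, n):
            raise ValueError("transition matrix shape does not match startprob")
        if abs(self.startprob.sum() - 1.0) > 1e-8:
            raise ValueError("initial probabilities must sum to 1")
        if np.any(np.abs(self.transmat.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("every transition-matrix row must sum to 1")
        if self.coefs.shape[0] != n or self.variances.shape[0] != n:
            raise ValueError("emission parameter shapes do not match n_states")
        if self.coefs.shape[2] != 1 + len(self.covariate_names):
            raise ValueError("coefs last axis must be 1 + number of covariates")
        if np.any(self.variances <= 0):
            raise ValueError("emission variances must be positive")

    @property
    def n_states(self) -> int:
        return len(self.startprob)

    @property
    def n_dim(self) -> int:
        return self.coefs.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.coefs.shape[2] - 1

    def n_parameters(self) -> int:
        """Free-parameter count used by AIC.

        (n-1) initial probabilities + n(n-1) transition probabilities
        + n*d*(c+1) emission coefficients + n*d variances.
        """
        n, d, c = self.n_states, self.n_dim, self.n_covariates
        return (n - 1) + n * (n - 1) + n * d * (c + 1) + n * d

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "covariate_names": list(self.covariate_names),
            "startprob": self.startprob.tolist(),
            "transmat": self.transmat.tolist(),
            "coefs": self.coefs.tolist(),
            "variances": self.variances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParams":
        return cls(
            startprob=np.asarray(d["startprob"]),
            transmat=np.asarray(d["transmat"]),
            coefs=np.asarray(d["coefs"]),
            variances=np.asarray(d["variances"]),
            covariate_names=tuple(d["covariate_names"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "HMMParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Emission model


def _design(params: HMMParams, covariates: np.ndarray) -> np.ndarray:
    """(T, 1 + c) regression design from a covariate matrix."""
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[1] != params.n_covariates:
        raise ValueError(
            f"expected {params.n_covariates} covariates, got {Z.shape[1]}"
        )
    return np.hstack([np.ones((Z.shape[0], 1)), Z])


def emission_mean(params: HMMParams, state: int, covariates: np.ndarray) -> np.ndarray:
    """State-conditional mean PC-score vector at covariates z."""
    X = _design(params, np.atleast_2d(np.asarray(covariates, dtype=float)))
    return params.coefs[state] @ X[0]


def mixture_mean(
    params: HMMParams, state_probs: np.ndarray, covariates: np.ndarray
) -> np.ndarray:
    """State-probability-weighted predicted mean PC-score vector."""
    p = np.asarray(state_probs, dtype=float)
    if len(p) != params.n_states:
        raise ValueError("state_probs length does not match n_states")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("state probabilities must sum to 1")
    means = np.stack(
        [emission_mean(params, j, covariates) for j in range(params.n_states)]
    )
    return p @ means


def emission_logdensity(
    params: HMMParams, state: int, observation: np.ndarray, covariates: np.ndarray
) -> float:
    """Log density of one observation under one state's diagonal Gaussian."""
    o = np.asarray(observation, dtype=float)
    m = emission_mean(params, state, covariates)
    v = params.variances[state]
    return float(-0.5 * np.sum(_LOG2PI + np.log(v) + (o - m) ** 2 / v))


def _log_obs_probs(
    params: HMMParams, observations: np.ndarray, design: np.ndarray
) -> np.ndarray:
    """(T, n_states) matrix of emission log densities."""
    # means: (T, n, d) via coefs (n, d, q) x design (T, q)
    means = np.einsum("tq,ndq->tnd", design, params.coefs)
    resid = observations[:, None, :] - means
    v = params.variances[None, :, :]
    return -0.5 * np.sum(_LOG2PI + np.log(v) + resid**2 / v, axis=2)


# ---------------------------------------------------------------------------
# Inference


def _forward_backward_batch(
    startprob: np.ndarray, transmat: np.ndarray, logB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward over a batch of equal-length sequences.

    logB is (m, T, n).  Returns gamma (m, T, n), xi (m, T-1, n, n) and
    loglik (m,).  Per-timestep scaling makes underflow impossible for any
    finite log densities.
    """
    m, T, n = logB.shape
    shift = logB.max(axis=2, keepdims=True)
    B = np.exp(logB - shift)  # in (0, 1], at least one 1 per (seq, t)
    alpha = np.empty((m, T, n))
    c = np.empty((m, T))
    a = startprob[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ transmat) * B[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t, None]
    beta = np.empty((m, T, n))
    beta[:, T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[:, t] = (B[:, t + 1] * beta[:, t + 1]) @ transmat.T / c[:, t + 1, None]
    gamma = alpha * beta
    xi = (
        alpha[:, :-1, :, None]
        * transmat[None, None, :, :]
        * (B[:, 1:] * beta[:, 1:])[:, :, None, :]
        / c[:, 1:, None, None]
    )
    loglik = np.log(c).sum(axis=1) + shift.sum(axis=(1, 2))
    return gamma, xi, loglik


def forward_backward(
    params: HMMParams, seq: AthleteSequence
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact posteriors for one sequence.

    Returns (gamma, xi, loglik): gamma[t, j] = P(S_t = j | O, z), xi[t, i, j]
    = P(S_t = i, S_{t+1} = j | O, z), and the log of the total observation
    likelihood (the sum of the joint over all state paths).
    """
    X = _design(params, seq.covariates)
    logB = _log_obs_probs(params, seq.observations, X)
    gamma, xi, loglik = _forward_backward_batch(
        params.startprob, params.transmat, logB[None]
    )
    return gamma[0], xi[0], float(loglik[0])


def viterbi(params: HMMParams, seq: AthleteSequence) -> np.ndarray:
    """Most probable joint state path; ties break to the lowest state index."""
    X = _design(params, seq.covariates)
    logB = _log_obs_probs(params, seq.observations, X)
    T, n = logB.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.startprob)
        log_A = np.log(params.transmat)
    delta = log_pi + logB[0]
    back = np.zeros((T, n), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + log_A
        back[t] = np.argmax(cand, axis=0)  # argmax takes the lowest index on ties
        delta = cand[back[t], np.arange(n)] + logB[t]
    path = np.empty(T, dtype=int)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def loglikelihood(params: HMMParams, sequences) -> float:
    """Total log-likelihood over independent athlete chains."""
    return sum(forward_backward(params, s)[2] for s in sequences)


# ---------------------------------------------------------------------------
# EM fitting


class DegenerateFitError(RuntimeError):
    """A state starved of posterior mass during EM; the restart is invalid."""


@dataclass
class FitResult:
    """Outcome of a (multi-restart) EM fit."""

    params: HMMParams
    loglik: float
    aic: float
    posteriors: list[np.ndarray]
    decoded: list[np.ndarray]
    n_restarts: int
    seed: int
    best_restart: int
    loglik_history: np.ndarray
    converged: bool
    n_degenerate: int = 0
    restart_logliks: np.ndarray = field(default_factory=lambda: np.empty(0))


def aic(result: FitResult) -> float:
    """Akaike information criterion: -2 loglik + 2 (free parameters)."""
    return -2.0 * result.loglik + 2.0 * result.params.n_parameters()


def _group_by_length(sequences):
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(sequences):
        groups.setdefault(len(s), []).append(i)
    return groups


def _init_params(
    obs: np.ndarray, n_states: int, n_cov: int, cov_names, rng: np.random.Generator
) -> HMMParams:
    """Random but data-anchored starting point for one EM restart.

    Sticky transition matrix (0.85 diagonal, noisy off-diagonal), uniform
    initial distribution, state intercepts at random per-dimension data
    quantiles, zero covariate effects, pooled-SD variances.
    """
    n, d = n_states, obs.shape[1]
    A = np.full((n, n), 0.0)
    for i in range(n):
        off = rng.uniform(0.5, 1.5, size=n)
        off[i] = 0.0
        if n > 1:
            A[i] = 0.15 * off / off.sum()
        A[i, i] = 1.0 - A[i].sum()
    coefs = np.zeros((n, d, 1 + n_cov))
    q = rng.uniform(0.1, 0.9, size=(n, d))
    for i in range(d):
        coefs[:, i, 0] = np.quantile(obs[:, i], q[:, i])
    sd = obs.std(axis=0)
    sd = np.where(sd > 1e-8, sd, 1.0)
    return HMMParams(
        startprob=np.full(n, 1.0 / n),
        transmat=A,
        coefs=coefs,
        variances=np.tile(sd**2, (n, 1)),
        covariate_names=tuple(cov_names),
    )


_VAR_FLOOR = 1e-8


def _em_single(
    sequences,
    params: HMMParams,
    tol: float,
    max_iter: int,
    min_state_weight: float,
) -> tuple[HMMParams, np.ndarray, bool]:
    """One EM run from one starting point.

    Returns (params, loglik history, converged).  Raises
    :class:`DegenerateFitError` if a state's total posterior mass falls
    below ``min_state_weight`` (too few effective observations to fit its
    emission regression).
    """
    n = params.n_states
    d = params.n_dim
    obs_all = np.vstack([s.observations for s in sequences])
    X_all = np.vstack([_design(params, s.covariates) for s in sequences])
    groups = _group_by_length(sequences)
    # per-group stacked observation and design arrays
    stacked = {}
    for T, idx in groups.items():
        O = np.stack([sequences[i].observations for i in idx])
        X = np.stack([_design(params, sequences[i].covariates) for i in idx])
        stacked[T] = (idx, O, X)
    offsets = np.concatenate([[0], np.cumsum([len(s) for s in sequences])])

    history = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        gamma_flat = np.empty((len(obs_all), n))
        first_gammas = []
        xi_sum = np.zeros((n, n))
        gamma_trans_sum = np.zeros(n)
        loglik = 0.0
        for T, (idx, O, X) in stacked.items():
            m = len(idx)
            logB = np.einsum(
                "mtq,ndq->mtnd", X, params.coefs, optimize=True
            )
            logB = O[:, :, None, :] - logB
            v = params.variances[None, None, :, :]
            logB = -0.5 * np.sum(_LOG2PI + np.log(v) + logB**2 / v, axis=3)
            gamma, xi, ll = _forward_backward_batch(
                params.startprob, params.transmat, logB
            )
            loglik += ll.sum()
            first_gammas.append(gamma[:, 0])
            if T > 1:
                xi_sum += xi.sum(axis=(0, 1))
                gamma_trans_sum += gamma[:, :-1].sum(axis=(0, 1))
            for row, i in enumerate(idx):
                gamma_flat[offsets[i] : offsets[i + 1]] = gamma[row]
        history.append(loglik)

        # M-step
        startprob = np.vstack(first_gammas).mean(axis=0)
        startprob = startprob / startprob.sum()
        if gamma_trans_sum.sum() > 0:
            transmat = xi_sum / np.where(
                gamma_trans_sum[:, None] > 0, gamma_trans_sum[:, None], 1.0
            )
            # states never occupied before a transition keep a uniform row
            zero_rows = transmat.sum(axis=1) <= 0
            transmat[zero_rows] = 1.0 / n
            transmat = transmat / transmat.sum(axis=1, keepdims=True)
        else:
            transmat = params.transmat
        total_w = gamma_flat.sum(axis=0)
        if np.any(total_w < min_state_weight):
            raise DegenerateFitError(
                f"state posterior mass {total_w.min():.3g} below "
                f"{min_state_weight:.3g}"
            )
        coefs = np.empty_like(params.coefs)
        variances = np.empty_like(params.variances)
        for j in range(n):
            w = gamma_flat[:, j]
            Xw = X_all * w[:, None]
            XtWX = X_all.T @ Xw
            XtWy = Xw.T @ obs_all
            try:
                b = np.linalg.solve(XtWX, XtWy)
            except np.linalg.LinAlgError:
                b = np.linalg.lstsq(XtWX, XtWy, rcond=None)[0]
            coefs[j] = b.T
            resid = obs_all - X_all @ b
            variances[j] = np.maximum(
                (w[:, None] * resid**2).sum(axis=0) / w.sum(), _VAR_FLOOR
            )
        params = HMMParams(
            startprob=startprob,
            transmat=transmat,
            coefs=coefs,
            variances=variances,
            covariate_names=params.covariate_names,
        )
        if np.isfinite(prev) and loglik - prev < tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = loglik
    return params, np.asarray(history), converged


def em_fit(
    sequences,
    n_states: int,
    n_restarts: int = 200,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    covariate_names: tuple[str, ...] | None = None,
    min_state_mass: float | None = None,
) -> FitResult:
    """Multi-restart EM over independent athlete sequences.

    Each restart runs EM to convergence from a random data-anchored start;
    the restart with the highest final log-likelihood wins.  Restarts in
    which a state starves — total posterior mass below ``min_state_mass``
    (default 1% of all observations, floored at the number of emission
    regressors + 1) — are flagged degenerate and excluded from selection.
    The guard matters: a near-empty state can collapse its variances onto a
    handful of points and inflate the likelihood without describing any
    real cluster, which would otherwise bias AIC towards too many states.
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("need at least one sequence")
    if covariate_names is None:
        covariate_names = tuple(sequences[0].covariate_names)
    n_cov = sequences[0].covariates.shape[1]
    if len(covariate_names) != n_cov:
        covariate_names = tuple(f"z{i + 1}" for i in range(n_cov))
    obs_all = np.vstack([s.observations for s in sequences])
    n_params = (
        (n_states - 1)
        + n_states * (n_states - 1)
        + n_states * obs_all.shape[1] * (n_cov + 1)
        + n_states * obs_all.shape[1]
    )
    if len(obs_all) <= n_params:
        raise ValueError(
            f"{len(obs_all)} observations cannot identify {n_params} parameters"
        )
    if min_state_mass is None:
        min_state_mass = max(n_cov + 2.0, 0.01 * len(obs_all))

    root = np.random.SeedSequence(seed)
    best = None
    restart_logliks = np.full(n_restarts, np.nan)
    n_degenerate = 0
    for r, child in enumerate(root.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        init = _init_params(obs_all, n_states, n_cov, covariate_names, rng)
        try:
            params, history, converged = _em_single(
                sequences, init, tol, max_iter, min_state_mass
            )
        except DegenerateFitError:
            n_degenerate += 1
            continue
        restart_logliks[r] = history[-1]
        if best is None or history[-1] > best[1][-1]:
            best = (params, history, converged, r)
    if best is None:
        raise DegenerateFitError(
            f"all {n_restarts} restarts degenerated with {n_states} states"
        )
    params, history, converged, best_r = best
    posteriors = []
    decoded = []
    loglik = 0.0
    for s in sequences:
        g, _, ll = forward_backward(params, s)
        posteriors.append(g)
        decoded.append(viterbi(params, s))
        loglik += ll
    result = FitResult(
        params=params,
        loglik=loglik,
        aic=0.0,
        posteriors=posteriors,
        decoded=decoded,
        n_restarts=n_restarts,
        seed=seed,
        best_restart=best_r,
        loglik_history=history,
        converged=converged,
        n_degenerate=n_degenerate,
        restart_logliks=restart_logliks,
    )
    result.aic = aic(result)
    return result


def select_n_states(
    sequences,
    candidate_range=range(2, 7),
    n_restarts: int = 20,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[int, dict[int, float]]:
    """Fit every candidate state count and return the AIC minimiser.

    Returns (best n, {n: AIC}).  A candidate whose restarts all degenerate
    is recorded as +inf rather than silently skipped.
    """
    candidates = list(candidate_range)
    if not candidates:
        raise ValueError("candidate_range is empty")
    table: dict[int, float] = {}
    for n in candidates:
        try:
            fit = em_fit(
                sequences, n, n_restarts=n_restarts, seed=seed, tol=tol,
                max_iter=max_iter,
            )
            table[n] = fit.aic
        except DegenerateFitError:
            table[n] = float("inf")
    best = min(table, key=lambda n: (table[n], n))
    return best, table


def align_states(estimated: HMMParams, reference: HMMParams) -> np.ndarray:
    """Permutation mapping estimated state labels onto reference labels.

    Hungarian assignment minimising total distance between emission
    intercepts; perm[j] is the estimated state matched to reference
    state j.
    """
    cost = np.linalg.norm(
        reference.coefs[:, None, :, 0] - estimated.coefs[None, :, :, 0], axis=2
    )
    _, perm = linear_sum_assignment(cost)
    return perm


def permute_states(params: HMMParams, perm: np.ndarray) -> HMMParams:
    """Relabel states by ``perm`` (new state j = old state perm[j])."""
    perm = np.asarray(perm)
    return HMMParams(
        startprob=params.startprob[perm],
        transmat=params.transmat[np.ix_(perm, perm)],
        coefs=params.coefs[perm],
        variances=params.variances[perm],
        covariate_names=params.covariate_names,
    )


# ---------------------------------------------------------------------------
# Model / Results surface


class PacingStateModel:
    """HMM over athlete careers of PC scores, statsmodels-style.

    Parameters
    ----------
    sequences : sequence of AthleteSequence
        One chain per athlete.
    n_states : int
        Number of hidden pacing-profile clusters.
    """

    def __init__(self, sequences, n_states: int = 4):
        self.sequences = list(sequences)
        self.n_states = n_states

    @classmethod
    def from_scores(
        cls, scores_df, n_states: int = 4, covariate_names: tuple[str, ...] = ()
    ) -> "PacingStateModel":
        """Build chains from a tidy scores table.

        ``scores_df`` needs columns athlete_id, race_index, pc1..pc4 and one
        0/1 column per covariate name; rows are grouped by athlete and
        ordered by race_index.
        """
        pc_cols = [c for c in scores_df.columns if c.lower().startswith("pc")]
        seqs = []
        for athlete, grp in scores_df.groupby("athlete_id", sort=True):
            grp = grp.sort_values("race_index")
            seqs.append(
                AthleteSequence(
                    athlete_id=str(athlete),
                    observations=grp[pc_cols].to_numpy(float),
                    covariates=grp[list(covariate_names)].to_numpy(float)
                    if covariate_names
                    else np.zeros((len(grp), 0)),
                    covariate_names=covariate_names,
                )
            )
        return cls(seqs, n_states)

    def fit(
        self,
        n_restarts: int = 200,
        seed: int = 0,
        tol: float = 1e-8,
        max_iter: int = 500,
    ) -> "PacingStateResults":
        fit = em_fit(
            self.sequences,
            self.n_states,
            n_restarts=n_restarts,
            seed=seed,
            tol=tol,
            max_iter=max_iter,
        )
        return PacingStateResults(self, fit)

    def select_n_states(self, candidate_range=range(2, 7), **kw):
        return select_n_states(self.sequences, candidate_range, **kw)


class PacingStateResults:
    """Fitted career HMM: parameters, decoded states, diagnostics hooks."""

    def __init__(self, model: PacingStateModel, fit: FitResult):
        self.model = model
        self.fit_result = fit

    @property
    def params(self) -> HMMParams:
        return self.fit_result.params

    @property
    def loglik(self) -> float:
        return self.fit_result.loglik

    @property
    def aic(self) -> float:
        return self.fit_result.aic

    @property
    def decoded(self) -> list[np.ndarray]:
        return self.fit_result.decoded

    @property
    def posteriors(self) -> list[np.ndarray]:
        return self.fit_result.posteriors

    def predicted_mean(self, state_probs, covariates) -> np.ndarray:
        return mixture_mean(self.params, state_probs, covariates)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Pacing-profile hidden Markov model",
            f"  athletes: {len(self.model.sequences)}   "
            f"races: {sum(len(s) for s in self.model.sequences)}",
            f"  states: {p.n_states}   covariates: "
            f"{', '.join(p.covariate_names) or '(none)'}",
            f"  log-likelihood: {self.loglik:.3f}   AIC: {self.aic:.3f}   "
            f"free parameters: {p.n_parameters()}",
            f"  best of {self.fit_result.n_restarts} restarts "
            f"(#{self.fit_result.best_restart}, seed {self.fit_result.seed}, "
            f"{self.fit_result.n_degenerate} degenerate)",
            "  transition matrix:",
        ]
        for i, row in enumerate(p.transmat):
            lines.append(
                "    from S%d  " % (i + 1)
                + "  ".join(f"{a:6.3f}" for a in row)
            )
        lines.append("  baseline state means (intercepts):")
        header = "    state   " + "  ".join(
            f"PC{i + 1:<6}" for i in range(p.n_dim)
        )
        lines.append(header)
        for j in range(p.n_states):
            lines.append(
                f"    S{j + 1}      "
                + "  ".join(f"{b:7.3f}" for b in p.coefs[j, :, 0])
            )
        return "\n".join(lines)
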