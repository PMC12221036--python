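"""Published four-state model estimates for both events.

These are the reported emission intercepts (per-state mean PC scores at the
baseline covariates: Domestic event, Open age group), the event-type and
age-group effects on those means, and the state transition matrices, for the
Women's K1 500 m and Men's K1 1000 m models.  They serve two roles: worked
examples for the emission machinery, and the default "truth" the synthetic
generator simulates from.

Covariate coding matches the fitted models: indicators for U21, U23 age
groups (plus U18 in the men's event) relative to Open, and for World
Cup/Junior-Worlds and World-Championships/Olympics events relative to
Domestic.

One cell of the men's event-effect table is printed with a malformed
decimal in the source ("-0.0.96", State 4, PC3, World Cup/Juniors); it is
transcribed as -0.096.  One row of the men's transition matrix sums to
1.001 at the printed precision; rows are renormalised on load.
"""

from __future__ import annotations

import numpy as np

from .hmm import HMMParams
from .race_data import Event

WOMENS_COVARIATES = ("U21", "U23", "WorldCupJuniors", "WorldChampsOlympics")
MENS_COVARIATES = ("U18", "U21", "U23", "WorldCupJuniors", "WorldChampsOlympics")

# Per-state mean PC scores at baseline covariates; rows = states, cols = PC1..PC4.
WOMENS_INTERCEPTS = np.array(
    [
        [0.173, 0.230, -0.003, -0.028],
        [-0.418, 0.552, -0.136, 0.168],
        [-0.373, -0.105, 0.070, 0.050],
        [0.063, -0.045, -0.045, -0.039],
    ]
)

MENS_INTERCEPTS = np.array(
    [
        [-0.871, 0.182, -0.126, -0.137],
        [0.979, 0.287, 0.030, -0.068],
        [-0.107, 0.654, 0.080, 0.185],
        [0.118, 0.007, -0.023, 0.030],
    ]
)

# Event-type effects, indexed [state][pc][tier] with tier 0 = World Cup /
# Juniors, tier 1 = World Champs / Olympics (relative to Domestic).
WOMENS_EVENT_EFFECTS = np.array(
    [
        [[-0.570, 0.045], [-0.273, -0.176], [0.190, 0.262], [-0.016, 0.073]],
        [[0.051, 0.246], [-0.045, 0.154], [-0.108, -0.154], [-0.009, -0.012]],
        [[0.363, 0.618], [-0.241, -0.384], [-0.092, 0.037], [-0.012, -0.277]],
        [[0.078, 0.060], [-0.051, -0.047], [0.018, 0.048], [0.014, -0.010]],
    ]
)

MENS_EVENT_EFFECTS = np.array(
    [
        [[0.061, 0.023], [-0.088, -0.119], [0.088, 0.120], [0.084, 0.062]],
        [[0.585, 1.355], [0.285, -0.338], [0.104, 0.647], [-0.664, -0.422]],
        [[0.134, 0.310], [-0.493, 0.404], [-0.193, -0.547], [-0.225, 0.174]],
        [[0.060, 0.424], [-0.082, 0.065], [-0.042, -0.062], [-0.096, -0.047]],
    ]
)

# Age-group effects relative to Open, indexed [state][pc][group]:
# women's groups (U21, U23); men's groups (U18, U21, U23).
WOMENS_AGE_EFFECTS = np.array(
    [
        [[-0.016, -0.024], [-0.098, -0.040], [0.028, -0.055], [0.100, 0.040]],
        [[0.287, -0.384], [0.339, 0.103], [-0.041, -0.277], [-0.160, -0.148]],
        [[0.206, 0.288], [-0.645, 0.200], [0.243, 0.376], [-0.176, -0.280]],
        [[-0.383, -0.136], [0.090, 0.103], [-0.023, -0.010], [0.041, -0.021]],
    ]
)

MENS_AGE_EFFECTS = np.array(
    [
        [
            [1.008, 0.895, 1.216],
            [0.213, -0.029, -0.061],
            [-0.037, 0.008, 0.059],
            [0.124, 0.022, -0.058],
        ],
        [
            [-1.710, -1.656, -1.529],
            [-0.291, -0.410, -0.238],
            [-0.022, 0.238, 0.234],
            [0.326, 0.312, -0.049],
        ],
        [
            [0.285, -0.285, -0.090],
            [-0.231, -0.788, -0.414],
            [-0.258, -0.442, -0.283],
            [-0.217, -0.256, 0.099],
        ],
        [
            [0.538, 0.119, 0.026],
            [-0.728, 0.118, 0.049],
            [0.241, 0.148, -0.052],
            [0.217, 0.049, -0.168],
        ],
    ]
)

WOMENS_TRANSITIONS = np.array(
    [
        [0.976, 0.000, 0.024, 0.000],
        [0.000, 0.917, 0.027, 0.056],
        [0.000, 0.022, 0.853, 0.125],
        [0.026, 0.052, 0.019, 0.903],
    ]
)

MENS_TRANSITIONS = np.array(
    [
        [0.805, 0.081, 0.000, 0.114],
        [0.107, 0.815, 0.078, 0.000],
        [0.064, 0.099, 0.838, 0.000],
        [0.167, 0.234, 0.124, 0.475],
    ]
)


def stationary_distribution(transmat: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix at eigenvalue 1."""
    vals, vecs = np.linalg.eig(transmat.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def published_params(
    event: Event,
    sigma: float = 0.2,
    include_covariates: bool = True,
) -> HMMParams:
    """The reported four-state model as an :class:`HMMParams`.

    Per-state emission SDs are not printed in the main text, so ``sigma``
    fills every state/dimension; the initial distribution, also unprinted,
    is taken as the stationary distribution of the transition matrix.
    With ``include_covariates=False`` only the intercepts (baseline means)
    are loaded.
    """
    if event is Event.W_K1_500:
        intercepts = WOMENS_INTERCEPTS
        age, evt = WOMENS_AGE_EFFECTS, WOMENS_EVENT_EFFECTS
        transmat = WOMENS_TRANSITIONS
        cov_names = WOMENS_COVARIATES
    else:
        intercepts = MENS_INTERCEPTS
        age, evt = MENS_AGE_EFFECTS, MENS_EVENT_EFFECTS
        transmat = MENS_TRANSITIONS
        cov_names = MENS_COVARIATES

    n_states, d = intercepts.shape
    if include_covariates:
        c = len(cov_names)
        coefs = np.zeros((n_states, d, 1 + c))
        coefs[:, :, 0] = intercepts
        n_age = age.shape[2]
        coefs[:, :, 1 : 1 + n_age] = age
        coefs[:, :, 1 + n_age :] = evt
        names = cov_names
    else:
        coefs = intercepts[:, :, None].copy()
        names = ()

    transmat = transmat / transmat.sum(axis=1, keepdims=True)
    return HMMParams(
        startprob=stationary_distribution(transmat),
        transmat=transmat,
        coefs=coefs,
        variances=np.full((n_states, d), float(sigma) ** 2),
        covariate_names=names,
    )
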