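"""Functional PCA of pacing profiles on a B-spline basis.

Discrete normalised segment velocities are smoothed into curves f(x) on the
race distance [0, p] using a clamped B-spline basis, and principal component
eigenfunctions are extracted by solving the covariance eigenproblem in
basis-coefficient space.  All inner products use the exact B-spline Gram
matrix (piecewise Gauss-Legendre, exact for polynomial products), so
eigenfunctions are orthonormal under the true L2 inner product and scores

    beta_k = integral of Phi_k(x) * (f(x) - mean(x)) dx

carry no quadrature error.  A positive first score means the mean-centred
profile resembles the first eigenfunction — in this data a front-loaded
"dropoff" shape; the second maps to a late-race "kick".
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cholesky, eigh, solve_triangular

from .race_data import PacingProfile


@dataclass(frozen=True)
class BSplineBasis:
    """Clamped B-spline basis on [0, domain_length].

    order 4 = cubic.  Interior knots are equally spaced;
    n_basis = order + number of interior knots.
    """

    domain_length: float
    n_basis: int
    order: int = 4

    def __post_init__(self) -> None:
        if self.n_basis < self.order:
            raise ValueError("n_basis must be at least the spline order")
        if self.domain_length <= 0:
            raise ValueError("domain_length must be positive")

    @property
    def n_interior_knots(self) -> int:
        return self.n_basis - self.order

    @property
    def knots(self) -> np.ndarray:
        """Full clamped knot vector."""
        interior = np.linspace(0, self.domain_length, self.n_interior_knots + 2)[1:-1]
        return np.concatenate(
            [
                np.zeros(self.order),
                interior,
                np.full(self.order, self.domain_length),
            ]
        )

    def design(self, x: np.ndarray) -> np.ndarray:
        """Evaluation matrix: design[i, j] = B_j(x_i)."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0) or np.any(x > self.domain_length):
            raise ValueError("evaluation points outside the basis domain")
        return BSpline.design_matrix(
            x, self.knots, self.order - 1, extrapolate=False
        ).toarray()

    def gram(self) -> np.ndarray:
        """Exact Gram matrix G_ij = integral of B_i B_j over the domain.

        Gauss-Legendre per knot span with order nodes integrates the degree
        2(order-1) product polynomials exactly.
        """
        knots = self.knots
        spans = np.unique(knots)
        nodes, weights = np.polynomial.legendre.leggauss(self.order)
        G = np.zeros((self.n_basis, self.n_basis))
        for a, b in zip(spans[:-1], spans[1:]):
            x = 0.5 * (b - a) * nodes + 0.5 * (a + b)
            w = 0.5 * (b - a) * weights
            D = self.design(x)
            G += D.T @ (w[:, None] * D)
        return G

    def evaluate(self, coefs: np.ndarray, x: np.ndarray) -> np.ndarray:
        return self.design(x) @ np.asarray(coefs, dtype=float)

    def to_dict(self) -> dict:
        return {
            "domain_length": self.domain_length,
            "n_basis": self.n_basis,
            "order": self.order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineBasis":
        return cls(**d)


def default_basis(domain_length: float) -> BSplineBasis:
    """Cubic basis sized for the per-race sampling density.

    8 basis functions for 500 m races (10 observed segments), 12 for 1000 m
    (20 segments): full-rank least squares yet smooth.
    """
    n_basis = 8 if domain_length <= 500 else 12
    return BSplineBasis(domain_length=domain_length, n_basis=n_basis)


def smooth_profile(profile: PacingProfile, basis: BSplineBasis) -> np.ndarray:
    """Least-squares B-spline coefficients for one profile."""
    return smooth_values(np.asarray(profile.grid), np.asarray(profile.values), basis)


def smooth_values(
    grid: np.ndarray, values: np.ndarray, basis: BSplineBasis
) -> np.ndarray:
    if basis.n_basis > len(grid):
        raise ValueError(
            f"basis has {basis.n_basis} functions but only {len(grid)} "
            "observation points; the fit would be rank-deficient"
        )
    D = basis.design(grid)
    coefs, _, rank, _ = np.linalg.lstsq(D, values, rcond=None)
    if rank < basis.n_basis:
        raise ValueError("rank-deficient design: reduce n_basis or add points")
    return coefs


@dataclass(frozen=True)
class FPCAModel:
    """Fitted functional PCA: mean curve and orthonormal eigenfunctions.

    ``eigenfunctions`` holds basis coefficients row-wise (K x n_basis);
    ``eigenvalues`` are the score variances, non-increasing; ``varexp`` is
    each component's share of the total variance over the full spectrum.
    """

    basis: BSplineBasis
    mean_coefs: np.ndarray
    eigenfunctions: np.ndarray
    eigenvalues: np.ndarray
    varexp: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenfunctions.shape[0]

    def to_dict(self) -> dict:
        return {
            "basis": self.basis.to_dict(),
            "mean_coefs": self.mean_coefs.tolist(),
            "eigenfunctions": self.eigenfunctions.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "varexp": self.varexp.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FPCAModel":
        return cls(
            basis=BSplineBasis.from_dict(d["basis"]),
            mean_coefs=np.asarray(d["mean_coefs"]),
            eigenfunctions=np.asarray(d["eigenfunctions"]),
            eigenvalues=np.asarray(d["eigenvalues"]),
            varexp=np.asarray(d["varexp"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "FPCAModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fix_signs(eigf: np.ndarray, basis: BSplineBasis) -> np.ndarray:
    """Orient each eigenfunction so its largest-magnitude value is positive."""
    x = np.linspace(0, basis.domain_length, 512)
    D = basis.design(x)
    out = eigf.copy()
    for k in range(out.shape[0]):
        y = D @ out[k]
        if y[np.argmax(np.abs(y))] < 0:
            out[k] = -out[k]
    return out


def fit_fpca(coef_matrix: np.ndarray, basis: BSplineBasis, n_components: int) -> FPCAModel:
    """Eigen-decompose the sample of smoothed curves.

    ``coef_matrix`` is (n_curves x n_basis).  The covariance operator is
    diagonalised through the Cholesky factor of the Gram matrix so that the
    returned eigenfunctions satisfy the L2 orthonormality constraint
    exactly (to floating point).
    """
    C = np.asarray(coef_matrix, dtype=float)
    n_curves = C.shape[0]
    if n_curves < n_components + 1:
        raise ValueError("need at least n_components + 1 curves")
    mean_coefs = C.mean(axis=0)
    Cc = C - mean_coefs
    G = basis.gram()
    L = cholesky(G, lower=True)
    # coefficient covariance mapped to the orthonormalised coordinate system
    S = Cc.T @ Cc / (n_curves - 1)
    M = L.T @ S @ L
    lam, W = eigh(M)
    lam = lam[::-1]
    W = W[:, ::-1]
    lam = np.clip(lam, 0.0, None)
    if n_components > len(lam):
        raise ValueError("n_components exceeds the basis dimension")
    total = lam.sum()
    eigf = solve_triangular(L, W[:, :n_components], lower=True, trans="T").T
    eigf = _fix_signs(eigf, basis)
    varexp = lam[:n_components] / total if total > 0 else np.zeros(n_components)
    return FPCAModel(
        basis=basis,
        mean_coefs=mean_coefs,
        eigenfunctions=eigf,
        eigenvalues=lam[:n_components],
        varexp=varexp,
    )


def compute_scores(model: FPCAModel, coefs: np.ndarray) -> np.ndarray:
    """PC scores of one curve or a stack of curves (rows)."""
    c = np.atleast_2d(np.asarray(coefs, dtype=float))
    if c.shape[1] != model.basis.n_basis:
        raise ValueError("curve is not on the model's basis")
    G = model.basis.gram()
    beta = (c - model.mean_coefs) @ G @ model.eigenfunctions.T
    return beta[0] if np.asarray(coefs).ndim == 1 else beta


def reconstruct(model: FPCAModel, scores: np.ndarray, n_used: int | None = None) -> np.ndarray:
    """Truncated reconstruction: mean + sum over the first n_used scores."""
    scores = np.asarray(scores, dtype=float)
    if n_used is None:
        n_used = model.n_components
    if n_used > model.n_components:
        raise ValueError("n_used exceeds the number of fitted components")
    return model.mean_coefs + scores[:n_used] @ model.eigenfunctions[:n_used]


def variance_explained(model: FPCAModel) -> np.ndarray:
    if model.eigenvalues.sum() <= 0 and model.varexp.sum() <= 0:
        raise ValueError("variance explained undefined: all eigenvalues are zero")
    return model.varexp


class FPCA:
    """Functional-PCA model over a set of pacing profiles.

    Parameters
    ----------
    profiles : sequence of PacingProfile
        Profiles on a common grid.
    basis : BSplineBasis, optional
        Defaults to a cubic basis sized by the race distance.
    """

    def __init__(self, profiles, basis: BSplineBasis | None = None):
        if not profiles:
            raise ValueError("need at least one profile")
        grid = np.asarray(profiles[0].grid)
        domain = grid[-1] + (grid[0] if grid[0] > 0 else 0.0)
        self.basis = basis or default_basis(domain)
        self.grid = grid
        self.values = np.array([p.values for p in profiles], dtype=float)
        D = self.basis.design(grid)
        coefs, _, rank, _ = np.linalg.lstsq(D, self.values.T, rcond=None)
        if rank < self.basis.n_basis:
            raise ValueError("rank-deficient design: reduce n_basis")
        self.coef_matrix = coefs.T

    def fit(self, n_components: int = 4) -> "FPCAResults":
        model = fit_fpca(self.coef_matrix, self.basis, n_components)
        scores = compute_scores(model, self.coef_matrix)
        return FPCAResults(model, scores)


class FPCAResults:
    """Fitted fPCA: the model plus in-sample scores."""

    def __init__(self, model: FPCAModel, scores: np.ndarray):
        self.model = model
        self.scores = scores

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.model.eigenvalues

    @property
    def varexp(self) -> np.ndarray:
        return self.model.varexp

    def transform(self, coefs: np.ndarray) -> np.ndarray:
        return compute_scores(self.model, coefs)

    def summary(self) -> str:
        lines = [
            "Functional PCA",
            f"  basis: order-{self.model.basis.order} B-spline, "
            f"{self.model.basis.n_basis} functions on [0, "
            f"{self.model.basis.domain_length:g}] m",
            f"  curves: {self.scores.shape[0]}",
            "  component   eigenvalue   var.explained   cumulative",
        ]
        cum = 0.0
        for k in range(self.model.n_components):
            cum += self.model.varexp[k]
            lines.append(
                f"  PC{k + 1:<9} {self.model.eigenvalues[k]:>10.5f}"
                f"   {100 * self.model.varexp[k]:>12.2f}%"
                f"   {100 * cum:>9.2f}%"
            )
        return "\n".join(lines)


def plot_components(results: "FPCAResults", ax=None):
    """Plot the mean curve and eigenfunctions of a fitted fPCA."""
    import matplotlib.pyplot as plt

    model = results.model
    if ax is None:
        _, ax = plt.subplots()
    x = np.linspace(0, model.basis.domain_length, 256)
    for k in range(model.n_components):
        ax.plot(
            x,
            model.basis.evaluate(model.eigenfunctions[k], x),
            label=f"PC{k + 1} ({100 * model.varexp[k]:.1f}%)",
        )
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("distance (m)")
    ax.set_ylabel("eigenfunction")
    ax.legend()
    return ax
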