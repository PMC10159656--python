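"""Core data model for matrix-variate Poisson-log normal (MVPLN) mixtures.

An observation is an ``r x p`` count matrix: ``r`` occasions (rows) by ``p``
variables (columns).  Conditional on a latent matrix ``theta``, each count is
Poisson with rate ``exp(theta + log s)`` where ``s`` holds fixed library-size
offsets; ``theta`` is matrix-variate normal with mean ``M``, row covariance
``Phi`` (r x r) and column covariance ``Omega`` (p x p).  Vectorizing the
*transpose* of a matrix (row-major raveling) turns the matrix-variate normal
into an ``rp``-dimensional multivariate normal with covariance
``kron(Phi, Omega)``; every vectorized quantity in this package follows that
convention.

This module provides the container types, the matrix-normal log density,
closed-form unconditional moments, free-parameter counting, the
identifiability normalization of the Kronecker factors, and the complete-data
log-likelihood of the mixture.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .exceptions import DefinitenessError, ValidationError

logger = logging.getLogger(__name__)

#: relative eigenvalue threshold below which an SPD matrix counts as singular
SPD_RTOL = 1e-10
#: diagonal jitter (times trace/dim) applied to near-singular matrices
SPD_JITTER = 1e-8


# ---------------------------------------------------------------------------
# linear-algebra helpers
# ---------------------------------------------------------------------------

def ensure_spd(A: np.ndarray, name: str = "matrix", jitter: bool = True) -> np.ndarray:
    """Validate (and lightly repair) a symmetric positive-definite matrix.

    The input is symmetrized; if its smallest eigenvalue falls below
    ``SPD_RTOL`` times the largest, a diagonal jitter of
    ``SPD_JITTER * trace/dim`` is added (with a logged warning) as long as the
    matrix is only near-singular.  Clearly indefinite input raises
    :class:`DefinitenessError`.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DefinitenessError(f"{name} must be square, got shape {A.shape}")
    A = 0.5 * (A + A.T)
    eig = np.linalg.eigvalsh(A)
    lo, hi = eig[0], eig[-1]
    if hi <= 0:
        raise DefinitenessError(f"{name} is not positive definite (max eigenvalue {hi:.3g})")
    if lo > SPD_RTOL * hi:
        return A
    if lo < -SPD_JITTER * hi:
        raise DefinitenessError(
            f"{name} is not positive definite (eigenvalues in [{lo:.3g}, {hi:.3g}])"
        )
    if not jitter:
        raise DefinitenessError(f"{name} is numerically singular")
    dim = A.shape[0]
    bump = SPD_JITTER * np.trace(A) / dim
    # a couple of escalating attempts; tiny negative eigenvalues may need more
    for _ in range(8):
        A = A + bump * np.eye(dim)
        warnings.warn(f"{name} near-singular; added diagonal jitter {bump:.3g}", stacklevel=2)
        logger.warning("%s near-singular; added diagonal jitter %.3g", name, bump)
        eig = np.linalg.eigvalsh(A)
        if eig[0] > SPD_RTOL * eig[-1]:
            return A
        bump *= 10.0
    raise DefinitenessError(f"{name} could not be regularized to positive definite")


def _chol_logdet(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor (lower) and log-determinant of an SPD matrix."""
    L = np.linalg.cholesky(A)
    return L, 2.0 * float(np.sum(np.log(np.diag(L))))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CountTensor:
    """Observed three-way counts: ``N`` units by ``r`` occasions by ``p`` variables."""

    counts: np.ndarray
    unit_ids: list = None
    occasion_labels: list = None
    variable_labels: list = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ValidationError(f"counts must be a 3-d array, got ndim={c.ndim}")
        if c.size == 0:
            raise ValidationError("counts tensor is empty")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise ValidationError("counts must be integral")
            c = np.round(c).astype(np.int64)
        if (c < 0).any():
            raise ValidationError("counts must be non-negative")
        self.counts = c
        N, r, p = c.shape
        if self.unit_ids is None:
            self.unit_ids = [f"unit{n + 1}" for n in range(N)]
        if self.occasion_labels is None:
            self.occasion_labels = [f"occ{i + 1}" for i in range(r)]
        if self.variable_labels is None:
            self.variable_labels = [f"var{k + 1}" for k in range(p)]
        if len(self.unit_ids) != N:
            raise ValidationError("unit_ids length does not match axis 0")
        if len(self.occasion_labels) != r:
            raise ValidationError("occasion_labels length does not match axis 1")
        if len(self.variable_labels) != p:
            raise ValidationError("variable_labels length does not match axis 2")

    @property
    def N(self) -> int:
        return self.counts.shape[0]

    @property
    def r(self) -> int:
        return self.counts.shape[1]

    @property
    def p(self) -> int:
        return self.counts.shape[2]


@dataclass
class OffsetMatrix:
    """Normalized library sizes shared across units; strictly positive ``r x p``."""

    s: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        if s.ndim != 2:
            raise ValidationError("offsets must be an r x p matrix")
        if not np.all(s > 0):
            raise ValidationError("offsets must be strictly positive")
        self.s = s

    @classmethod
    def ones(cls, r: int, p: int) -> "OffsetMatrix":
        return cls(np.ones((r, p)))

    @property
    def log(self) -> np.ndarray:
        return np.log(self.s)


@dataclass
class ComponentParams:
    """One mixture component: mean matrix ``M`` and SPD factors ``Phi``, ``Omega``."""

    M: np.ndarray
    Phi: np.ndarray
    Omega: np.ndarray

    def __post_init__(self):
        self.M = np.atleast_2d(np.asarray(self.M, dtype=float))
        self.Phi = ensure_spd(np.atleast_2d(self.Phi), "Phi")
        self.Omega = ensure_spd(np.atleast_2d(self.Omega), "Omega")
        r, p = self.M.shape
        if self.Phi.shape != (r, r):
            raise ValidationError(f"Phi shape {self.Phi.shape} incompatible with M {self.M.shape}")
        if self.Omega.shape != (p, p):
            raise ValidationError(
                f"Omega shape {self.Omega.shape} incompatible with M {self.M.shape}"
            )

    @property
    def r(self) -> int:
        return self.M.shape[0]

    @property
    def p(self) -> int:
        return self.M.shape[1]

    def sigma(self) -> np.ndarray:
        """Dense ``kron(Phi, Omega)`` — test/oracle use only."""
        return np.kron(self.Phi, self.Omega)


@dataclass
class MixtureParams:
    """Finite mixture: proportions ``pi`` and a list of component parameters."""

    pi: np.ndarray
    components: list = field(default_factory=list)

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.ndim != 1 or len(self.components) != self.pi.shape[0]:
            raise ValidationError("pi length must equal the number of components")
        if not np.all(self.pi > 0):
            raise ValidationError("all mixing proportions must be positive")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValidationError("mixing proportions must sum to 1")

    @property
    def G(self) -> int:
        return self.pi.shape[0]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def vec_transpose(X: np.ndarray) -> np.ndarray:
    """Row-major vectorization: element ``(i, k)`` lands at position ``i*p + k``.

    This is ``vec`` of the transposed matrix; under it the covariance of a
    vectorized matrix-variate normal is ``kron(Phi, Omega)``.
    """
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValidationError(f"expected a matrix, got ndim={X.ndim}")
    return X.ravel(order="C").copy()


def unvec_transpose(v: np.ndarray, r: int, p: int) -> np.ndarray:
    """Inverse of :func:`vec_transpose`."""
    v = np.asarray(v)
    if v.size != r * p:
        raise ValidationError(f"vector of length {v.size} cannot reshape to {r}x{p}")
    return v.reshape(r, p).copy()


def matnorm_logpdf(X: np.ndarray, params: ComponentParams) -> float:
    """Log density of the matrix-variate normal at ``X``.

    Computed from Cholesky factors of ``Phi`` and ``Omega`` separately; equals
    the ``rp``-dimensional multivariate normal log density of
    ``vec_transpose(X)`` with covariance ``kron(Phi, Omega)``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r, p = params.r, params.p
    if X.shape != (r, p):
        raise ValidationError(f"X shape {X.shape} != ({r}, {p})")
    Lp, ld_phi = _chol_logdet(params.Phi)
    Lo, ld_om = _chol_logdet(params.Omega)
    D = X - params.M
    # tr(Phi^-1 D Omega^-1 D^T) via triangular solves
    A = np.linalg.solve(Lp, D)            # Lp^-1 D
    B = np.linalg.solve(Lo, A.T)          # Lo^-1 D^T Lp^-T
    quad = float(np.sum(B * B))
    return -0.5 * r * p * np.log(2 * np.pi) - 0.5 * p * ld_phi - 0.5 * r * ld_om - 0.5 * quad


def unconditional_moments(params: ComponentParams) -> tuple[np.ndarray, np.ndarray]:
    """Marginal mean and variance of each count cell (unit offsets).

    ``mean = exp(M + Phi_ii Omega_kk / 2)`` and
    ``var = mean + mean^2 (exp(Phi_ii Omega_kk) - 1)``: always overdispersed
    relative to Poisson.
    """
    v = np.outer(np.diag(params.Phi), np.diag(params.Omega))
    mean = np.exp(params.M + 0.5 * v)
    var = mean + mean**2 * (np.exp(v) - 1.0)
    return mean, var


def free_params_count(G: int, r: int, p: int, family: str = "mvpln") -> int:
    """Number of free parameters of a G-component mixture.

    ``mvpln`` uses the Kronecker-structured covariance
    (``(G-1) + G r p + G [r(r+1) + p(p+1)] / 2``); ``mpln`` the unstructured
    ``rp x rp`` covariance.
    """
    if G < 1 or r < 1 or p < 1:
        raise ValidationError("G, r, p must all be >= 1")
    base = (G - 1) + G * r * p
    if family == "mvpln":
        return base + G * (r * (r + 1) + p * (p + 1)) // 2
    if family == "mpln":
        return base + G * r * p * (r * p + 1) // 2
    raise ValidationError(f"unknown family {family!r}")


def identifiability_normalize(
    Phi: np.ndarray, Omega: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale the Kronecker factors so the first diagonal entry of Phi is 1.

    ``Phi`` is divided by its first diagonal element and ``Omega`` multiplied
    by it, leaving ``kron(Phi, Omega)`` unchanged.
    """
    Phi = np.atleast_2d(np.asarray(Phi, dtype=float))
    Omega = np.atleast_2d(np.asarray(Omega, dtype=float))
    a = Phi[0, 0]
    if a <= 0:
        raise DefinitenessError("first diagonal element of Phi must be positive")
    return Phi / a, Omega * a


def poisson_loglik_terms(Y: np.ndarray, theta: np.ndarray, log_s: np.ndarray) -> float:
    """Sum over cells of the Poisson log mass at rate ``exp(theta + log_s)``."""
    lam_log = theta + log_s
    return float(np.sum(-np.exp(lam_log) + Y * lam_log - gammaln(Y + 1.0)))


def complete_data_loglik(
    tensor: CountTensor,
    offsets: OffsetMatrix,
    params: MixtureParams,
    z: np.ndarray,
    thetas: np.ndarray,
) -> float:
    """Complete-data log-likelihood of the mixture.

    Parameters
    ----------
    z : (N, G) hard or soft memberships, rows summing to 1.
    thetas : (N, G, r, p) latent log-rate matrices per unit and component.
    """
    Y = tensor.counts
    N, r, p = Y.shape
    G = params.G
    z = np.asarray(z, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    if z.shape != (N, G):
        raise ValidationError(f"z shape {z.shape} != ({N}, {G})")
    if thetas.shape != (N, G, r, p):
        raise ValidationError(f"thetas shape {thetas.shape} != ({N}, {G}, {r}, {p})")
    if not np.allclose(z.sum(axis=1), 1.0, atol=1e-8):
        raise ValidationError("membership rows must sum to 1")
    log_s = offsets.log
    n_g = z.sum(axis=0)
    total = float(np.sum(n_g * np.log(params.pi)))
    for g, comp in enumerate(params.components):
        for n in range(N):
            w = z[n, g]
            if w == 0.0:
                continue
            th = thetas[n, g]
            total += w * (
                poisson_loglik_terms(Y[n], th, log_s) + matnorm_logpdf(th, comp)
            )
    return total
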