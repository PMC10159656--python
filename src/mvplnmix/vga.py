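"""Variational Gaussian approximation (VGA) EM for MVPLN mixtures.

The posterior of each latent log-rate matrix ``theta_ng`` is approximated by
a matrix-variate Gaussian ``q(theta) = N(xi, Delta, kappa)`` with mean ``xi``
(r x p), row covariance ``Delta`` (r x r) and column covariance ``kappa``
(p x p); the implied vectorized covariance is ``kron(Delta, kappa)``.  The
per-observation evidence lower bound (ELBO) is maximized by coordinate
updates: fixed-point maps for ``Delta`` and ``kappa`` and a damped Newton
step for ``xi``.  Responsibilities replace the intractable marginal with
``exp(ELBO)``, and the M-step has closed-form (flip-flop) updates.

All inner loops are vectorized over observations; the public single-entry
operations are thin wrappers over the batched kernels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp
from sklearn.cluster import KMeans

from .exceptions import DegenerateComponentError, ValidationError
from .model_core import (
    ComponentParams,
    CountTensor,
    MixtureParams,
    OffsetMatrix,
    ensure_spd,
    free_params_count,
    identifiability_normalize,
)

logger = logging.getLogger(__name__)

#: per-observation ELBO is allowed to dip by this much before an update reverts
_ELBO_SLACK = 1e-9


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class VariationalEntry:
    """Variational triplet for one (unit, component) pair."""

    xi: np.ndarray      # (r, p)
    Delta: np.ndarray   # (r, r) SPD
    kappa: np.ndarray   # (p, p) SPD


@dataclass
class VariationalState:
    """Variational triplets for all (unit, component) pairs, stored densely."""

    xi: np.ndarray      # (N, G, r, p)
    Delta: np.ndarray   # (N, G, r, r)
    kappa: np.ndarray   # (N, G, p, p)

    def entry(self, n: int, g: int) -> VariationalEntry:
        return VariationalEntry(self.xi[n, g], self.Delta[n, g], self.kappa[n, g])

    @classmethod
    def initialize(cls, tensor: CountTensor, offsets: OffsetMatrix, G: int,
                   var0: float = 0.1) -> "VariationalState":
        N, r, p = tensor.counts.shape
        xi0 = np.log((tensor.counts + 0.5) / offsets.s)
        xi = np.broadcast_to(xi0[:, None], (N, G, r, p)).copy()
        Delta = np.broadcast_to(var0 * np.eye(r), (N, G, r, r)).copy()
        kappa = np.broadcast_to(var0 * np.eye(p), (N, G, p, p)).copy()
        return cls(xi=xi, Delta=Delta, kappa=kappa)


@dataclass
class FitConfig:
    """Controls for the outer EM loop."""

    max_iter: int = 500
    tol: float = 1e-6
    n_init_runs: int = 100
    seed: int = 1
    restarts: int = 3
    #: importance-sampling draws per (unit, component) for the marginal
    #: log-likelihood estimate used by the information criteria; 0 falls back
    #: to the raw aggregate ELBO (a looser surrogate that can inflate G)
    loglik_samples: int = 300


@dataclass
class FitResult:
    """A converged (or max-iter) fit of one mixture."""

    params: MixtureParams
    responsibilities: np.ndarray   # (N, G)
    map_labels: np.ndarray         # (N,), 1-based
    elbo_trace: np.ndarray
    loglik_proxy: float
    K: int
    criteria: dict
    converged: bool
    n_iter: int
    seed: int
    method: str = "vga"
    diagnostics: dict = field(default_factory=dict)

    @property
    def G(self) -> int:
        return self.params.G


# ---------------------------------------------------------------------------
# batched kernels (one component, all observations)
# ---------------------------------------------------------------------------

class _CompCtx:
    """Precomputed per-component quantities used by the batched kernels."""

    def __init__(self, comp: ComponentParams):
        self.M = comp.M
        self.r, self.p = comp.r, comp.p
        self.Phi_inv = np.linalg.inv(comp.Phi)
        self.Omega_inv = np.linalg.inv(comp.Omega)
        self.logdet_phi = float(np.linalg.slogdet(comp.Phi)[1])
        self.logdet_omega = float(np.linalg.slogdet(comp.Omega)[1])
        self._P = None

    @property
    def P(self) -> np.ndarray:
        # rp x rp prior precision; only materialized for the Newton step
        # (rp is assumed moderate)
        if self._P is None:
            self._P = np.kron(self.Phi_inv, self.Omega_inv)
        return self._P


def _mean_rate(logs, xi, dD, dk):
    """Expected Poisson rate under q: exp(xi + log s + diag products / 2)."""
    return np.exp(xi + logs + 0.5 * dD[..., :, None] * dk[..., None, :])


def _elbo_batch(Y, logs, lgam, xi, Delta, kappa, ctx: _CompCtx) -> np.ndarray:
    """Per-observation ELBO, shape (N,)."""
    r, p = ctx.r, ctx.p
    dD = np.diagonal(Delta, axis1=-2, axis2=-1)
    dk = np.diagonal(kappa, axis1=-2, axis2=-1)
    R = _mean_rate(logs, xi, dD, dk)
    Dm = xi - ctx.M
    quad = np.einsum("ij,njk,kl,nil->n", ctx.Phi_inv, Dm, ctx.Omega_inv, Dm)
    tr_pd = np.einsum("ij,nji->n", ctx.Phi_inv, Delta)
    tr_ok = np.einsum("ij,nji->n", ctx.Omega_inv, kappa)
    sld_d = np.linalg.slogdet(Delta)[1]
    sld_k = np.linalg.slogdet(kappa)[1]
    return (
        -R.sum(axis=(-2, -1))
        + ((xi + logs) * Y).sum(axis=(-2, -1))
        - lgam
        - 0.5 * p * ctx.logdet_phi
        - 0.5 * r * ctx.logdet_omega
        - 0.5 * quad
        - 0.5 * tr_pd * tr_ok
        + 0.5 * p * sld_d
        + 0.5 * r * sld_k
        + 0.5 * r * p
    )


def _delta_candidate(logs, xi, Delta, kappa, ctx: _CompCtx) -> np.ndarray:
    """One application of the fixed-point map for Delta."""
    p = ctx.p
    dD = np.diagonal(Delta, axis1=-2, axis2=-1)
    dk = np.diagonal(kappa, axis1=-2, axis2=-1)
    R = _mean_rate(logs, xi, dD, dk)
    w = (R * dk[..., None, :]).sum(axis=-1)            # (N, r)
    tr_ok = np.einsum("ij,nji->n", ctx.Omega_inv, kappa)
    A = w[..., :, None] * np.eye(ctx.r) + ctx.Phi_inv * tr_ok[..., None, None]
    cand = p * np.linalg.inv(A)
    return 0.5 * (cand + np.swapaxes(cand, -1, -2))


def _kappa_candidate(logs, xi, Delta, kappa, ctx: _CompCtx) -> np.ndarray:
    """One application of the fixed-point map for kappa (roles of axes swapped)."""
    r = ctx.r
    dD = np.diagonal(Delta, axis1=-2, axis2=-1)
    dk = np.diagonal(kappa, axis1=-2, axis2=-1)
    R = _mean_rate(logs, xi, dD, dk)
    w = (R * dD[..., :, None]).sum(axis=-2)            # (N, p)
    tr_pd = np.einsum("ij,nji->n", ctx.Phi_inv, Delta)
    A = w[..., :, None] * np.eye(ctx.p) + ctx.Omega_inv * tr_pd[..., None, None]
    cand = r * np.linalg.inv(A)
    return 0.5 * (cand + np.swapaxes(cand, -1, -2))


def _damped_cov_update(which, Y, logs, lgam, xi, Delta, kappa, ctx, f_old,
                       max_halve: int = 6):
    """Apply a fixed-point candidate with convex-combination damping.

    Where the candidate would lower that observation's ELBO, it is mixed back
    toward the current value (halving the mixing weight); observations that
    never improve keep their current value.  Returns (matrices, elbo).
    """
    old = Delta if which == "delta" else kappa
    cand = (_delta_candidate if which == "delta" else _kappa_candidate)(
        logs, xi, Delta, kappa, ctx
    )
    new = cand.copy()
    t = np.ones(old.shape[0])
    f_new = None
    for _ in range(max_halve):
        if which == "delta":
            f_new = _elbo_batch(Y, logs, lgam, xi, new, kappa, ctx)
        else:
            f_new = _elbo_batch(Y, logs, lgam, xi, Delta, new, ctx)
        bad = f_new < f_old - _ELBO_SLACK
        if not bad.any():
            return new, f_new
        t[bad] *= 0.5
        mix = t[bad][:, None, None]
        new[bad] = (1.0 - mix) * old[bad] + mix * cand[bad]
    # final check; anything still worse reverts
    if which == "delta":
        f_new = _elbo_batch(Y, logs, lgam, xi, new, kappa, ctx)
    else:
        f_new = _elbo_batch(Y, logs, lgam, xi, Delta, new, ctx)
    bad = f_new < f_old - _ELBO_SLACK
    if bad.any():
        new[bad] = old[bad]
        f_new = np.where(bad, f_old, f_new)
    return new, f_new


def _xi_newton_batch(Y, logs, lgam, xi, Delta, kappa, ctx, f_old,
                     max_halve: int = 12):
    """One damped Newton ascent step on vec(xi'), batched over observations."""
    N, r, p = xi.shape
    rp = r * p
    dD = np.diagonal(Delta, axis1=-2, axis2=-1)
    dk = np.diagonal(kappa, axis1=-2, axis2=-1)
    R = _mean_rate(logs, xi, dD, dk)
    Dm = (xi - ctx.M).reshape(N, rp)
    grad = (Y - R).reshape(N, rp) - Dm @ ctx.P      # P symmetric
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite gradient in xi update")
    H = ctx.P[None, :, :] + R.reshape(N, rp)[:, :, None] * np.eye(rp)
    d = np.linalg.solve(H, grad[..., None])[..., 0].reshape(N, r, p)
    step = np.ones(N)
    new = xi + d
    f_new = None
    for _ in range(max_halve):
        f_new = _elbo_batch(Y, logs, lgam, new, Delta, kappa, ctx)
        bad = f_new < f_old - _ELBO_SLACK
        if not bad.any():
            return new, f_new
        step[bad] *= 0.5
        new[bad] = xi[bad] + step[bad][:, None, None] * d[bad]
    f_new = _elbo_batch(Y, logs, lgam, new, Delta, kappa, ctx)
    bad = f_new < f_old - _ELBO_SLACK
    if bad.any():
        new[bad] = xi[bad]
        f_new = np.where(bad, f_old, f_new)
    return new, f_new


# ---------------------------------------------------------------------------
# public single-entry operations
# ---------------------------------------------------------------------------

def _single(fn, Yn, offsets, entry, params):
    Y = np.asarray(Yn, dtype=float)[None]
    logs = offsets.log
    lgam = gammaln(Y + 1.0).sum(axis=(-2, -1))
    ctx = _CompCtx(params)
    xi = np.asarray(entry.xi, dtype=float)[None]
    Delta = np.asarray(entry.Delta, dtype=float)[None]
    kappa = np.asarray(entry.kappa, dtype=float)[None]
    return fn(Y, logs, lgam, xi, Delta, kappa, ctx)


def elbo_observation(Yn, offsets: OffsetMatrix, entry: VariationalEntry,
                     params: ComponentParams) -> float:
    """ELBO contribution of one observation under one component."""
    return float(_single(_elbo_batch, Yn, offsets, entry, params)[0])


def update_Delta(entry: VariationalEntry, Yn, offsets: OffsetMatrix,
                 params: ComponentParams) -> np.ndarray:
    """One (safeguarded) fixed-point application for the row covariance."""
    def run(Y, logs, lgam, xi, Delta, kappa, ctx):
        f_old = _elbo_batch(Y, logs, lgam, xi, Delta, kappa, ctx)
        new, _ = _damped_cov_update("delta", Y, logs, lgam, xi, Delta, kappa, ctx, f_old)
        return new
    out = _single(run, Yn, offsets, entry, params)[0]
    return ensure_spd(out, "Delta")


def update_kappa(entry: VariationalEntry, Yn, offsets: OffsetMatrix,
                 params: ComponentParams) -> np.ndarray:
    """One (safeguarded) fixed-point application for the column covariance."""
    def run(Y, logs, lgam, xi, Delta, kappa, ctx):
        f_old = _elbo_batch(Y, logs, lgam, xi, Delta, kappa, ctx)
        new, _ = _damped_cov_update("kappa", Y, logs, lgam, xi, Delta, kappa, ctx, f_old)
        return new
    out = _single(run, Yn, offsets, entry, params)[0]
    return ensure_spd(out, "kappa")


def update_xi(entry: VariationalEntry, Yn, offsets: OffsetMatrix,
              params: ComponentParams) -> np.ndarray:
    """One damped Newton step on the variational mean."""
    def run(Y, logs, lgam, xi, Delta, kappa, ctx):
        f_old = _elbo_batch(Y, logs, lgam, xi, Delta, kappa, ctx)
        new, _ = _xi_newton_batch(Y, logs, lgam, xi, Delta, kappa, ctx, f_old)
        return new
    return _single(run, Yn, offsets, entry, params)[0]


def responsibilities_from_elbo(pi: np.ndarray, elbos: np.ndarray) -> np.ndarray:
    """Posterior membership weights from per-(n, g) ELBOs, via log-sum-exp."""
    pi = np.asarray(pi, dtype=float)
    elbos = np.atleast_2d(np.asarray(elbos, dtype=float))
    logw = np.log(pi)[None, :] + elbos
    norm = logsumexp(logw, axis=1)
    if not np.all(np.isfinite(norm)):
        raise ValidationError("all-(-inf) responsibility row")
    return np.exp(logw - norm[:, None])


def mstep(tensor: CountTensor, offsets: OffsetMatrix, z: np.ndarray,
          state: VariationalState, params_old: MixtureParams = None) -> MixtureParams:
    """Closed-form M-step given responsibilities and variational parameters.

    ``Phi`` uses the previous iteration's ``Omega`` (flip-flop); ``Omega``
    uses the freshly updated ``Phi``.  Missing ``params_old`` (first step)
    substitutes identity column covariances.
    """
    N, r, p = tensor.counts.shape
    G = z.shape[1]
    n_g = z.sum(axis=0)
    if np.any(n_g < 1e-8):
        raise DegenerateComponentError(
            f"component collapsed: effective sizes {np.round(n_g, 6)}"
        )
    pi = n_g / N
    comps = []
    for g in range(G):
        zg = z[:, g]
        xi_g, Delta_g, kappa_g = state.xi[:, g], state.Delta[:, g], state.kappa[:, g]
        M = np.einsum("n,nij->ij", zg, xi_g) / n_g[g]
        Om_old = params_old.components[g].Omega if params_old is not None else np.eye(p)
        Om_old_inv = np.linalg.inv(Om_old)
        D = xi_g - M
        tr_ok = np.einsum("ij,nji->n", Om_old_inv, kappa_g)
        num_phi = np.einsum("n,nik,kl,njl->ij", zg, D, Om_old_inv, D)
        num_phi += np.einsum("n,nij->ij", zg * tr_ok, Delta_g)
        Phi = ensure_spd(num_phi / (p * n_g[g]), "Phi")
        Phi_inv = np.linalg.inv(Phi)
        tr_pd = np.einsum("ij,nji->n", Phi_inv, Delta_g)
        num_om = np.einsum("n,nik,ij,njl->kl", zg, D, Phi_inv, D)
        num_om += np.einsum("n,nkl->kl", zg * tr_pd, kappa_g)
        Omega = ensure_spd(num_om / (r * n_g[g]), "Omega")
        comps.append(ComponentParams(M=M, Phi=Phi, Omega=Omega))
    return MixtureParams(pi=pi, components=comps)


def init_kmeans(tensor: CountTensor, G: int, n_runs: int = 100,
                seed: int = 1) -> np.ndarray:
    """Hard responsibilities from the best of ``n_runs`` k-means runs.

    Clustering is on ``log(Y + 1)`` flattened to N x rp; the run with the
    lowest within-cluster sum of squares wins.
    """
    N = tensor.N
    if N < G:
        raise ValidationError(f"need N >= G (N={N}, G={G})")
    z = np.zeros((N, G))
    if G == 1:
        z[:, 0] = 1.0
        return z
    X = np.log1p(tensor.counts.reshape(N, -1))
    km = KMeans(n_clusters=G, n_init=n_runs, random_state=seed).fit(X)
    z[np.arange(N), km.labels_] = 1.0
    return z


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------

def _aggregate_elbo(pi, elbos) -> float:
    return float(logsumexp(np.log(pi)[None, :] + elbos, axis=1).sum())


def marginal_loglik_is(tensor: CountTensor, offsets: OffsetMatrix,
                       params: MixtureParams, state: VariationalState,
                       n_samples: int = 300, seed: int = 1) -> float:
    """Importance-sampled mixture log-likelihood using q as proposal.

    The intractable per-component marginal is estimated by self-normalized
    importance sampling with the fitted variational Gaussian as proposal;
    unlike the ELBO it is asymptotically unbiased, which keeps the
    information criteria from rewarding the bound-tightening effect of
    spurious extra components.
    """
    rng = np.random.default_rng([seed, 104729])
    Y = tensor.counts.astype(float)
    N, r, p = Y.shape
    logs = offsets.log
    lgam_full = gammaln(Y + 1.0).sum(axis=(-2, -1))
    logf = np.empty((N, params.G))
    for g, comp in enumerate(params.components):
        ctx = _CompCtx(comp)
        xi, Delta, kappa = state.xi[:, g], state.Delta[:, g], state.kappa[:, g]
        A = np.linalg.cholesky(Delta)
        L = np.linalg.cholesky(kappa)
        Z = rng.standard_normal((n_samples, N, r, p))
        theta = xi[None] + np.einsum("nij,snjk,nlk->snil", A, Z, L)
        logq = (-0.5 * r * p * np.log(2 * np.pi)
                - 0.5 * (p * np.linalg.slogdet(Delta)[1]
                         + r * np.linalg.slogdet(kappa)[1])[None, :]
                - 0.5 * (Z ** 2).sum(axis=(2, 3)))
        lam_log = theta + logs
        pois = (-np.exp(lam_log) + Y * lam_log).sum(axis=(-2, -1)) - lgam_full
        Dm = theta - comp.M
        quad = np.einsum("ij,snjk,kl,snil->sn", ctx.Phi_inv, Dm, ctx.Omega_inv, Dm)
        logprior = -0.5 * (r * p * np.log(2 * np.pi) + p * ctx.logdet_phi
                           + r * ctx.logdet_omega + quad)
        logf[:, g] = logsumexp(pois + logprior - logq, axis=0) - np.log(n_samples)
    return float(logsumexp(np.log(params.pi)[None, :] + logf, axis=1).sum())


def _fit_vga_once(tensor, offsets, G, config, z0):
    Y = tensor.counts.astype(float)
    N, r, p = Y.shape
    logs = offsets.log
    lgam = gammaln(Y + 1.0).sum(axis=(-2, -1))
    state = VariationalState.initialize(tensor, offsets, G)
    params = mstep(tensor, offsets, z0, state, None)
    trace = []
    z = z0
    converged = False
    it = 0
    F = np.empty((N, G))
    for it in range(1, config.max_iter + 1):
        ctxs = [_CompCtx(c) for c in params.components]
        for g in range(G):
            F[:, g] = _elbo_batch(Y, logs, lgam, state.xi[:, g], state.Delta[:, g],
                                  state.kappa[:, g], ctxs[g])
        agg = _aggregate_elbo(params.pi, F)
        trace.append(agg)
        logger.info("iter %d: aggregate ELBO %.6f", it, agg)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-300)
            if rel < config.tol:
                converged = True
                break
        z = responsibilities_from_elbo(params.pi, F)
        if np.any(z.sum(axis=0) < 1e-8):
            raise DegenerateComponentError("component emptied during EM")
        for g in range(G):
            xi_g, D_g, k_g = state.xi[:, g], state.Delta[:, g], state.kappa[:, g]
            f = F[:, g]
            D_g, f = _damped_cov_update("delta", Y, logs, lgam, xi_g, D_g, k_g,
                                        ctxs[g], f)
            k_g, f = _damped_cov_update("kappa", Y, logs, lgam, xi_g, D_g, k_g,
                                        ctxs[g], f)
            xi_g, f = _xi_newton_batch(Y, logs, lgam, xi_g, D_g, k_g, ctxs[g], f)
            state.xi[:, g], state.Delta[:, g], state.kappa[:, g] = xi_g, D_g, k_g
        params = mstep(tensor, offsets, z, state, params)
    # final evaluation with the latest parameters
    ctxs = [_CompCtx(c) for c in params.components]
    for g in range(G):
        F[:, g] = _elbo_batch(Y, logs, lgam, state.xi[:, g], state.Delta[:, g],
                              state.kappa[:, g], ctxs[g])
    z = responsibilities_from_elbo(params.pi, F)
    agg = _aggregate_elbo(params.pi, F)
    if not trace or agg >= trace[-1] - _ELBO_SLACK:
        trace.append(agg)
    norm_comps = []
    for c in params.components:
        Phi, Omega = identifiability_normalize(c.Phi, c.Omega)
        norm_comps.append(ComponentParams(M=c.M, Phi=Phi, Omega=Omega))
    params = MixtureParams(pi=params.pi, components=norm_comps)
    from .selection import information_criteria, map_classify

    K = free_params_count(G, r, p, "mvpln")
    if config.loglik_samples > 0:
        final = marginal_loglik_is(tensor, offsets, params, state,
                                   config.loglik_samples, config.seed)
    else:
        final = trace[-1]
    crit = information_criteria(final, K, N, z)
    return FitResult(
        params=params,
        responsibilities=z,
        map_labels=map_classify(z),
        elbo_trace=np.asarray(trace),
        loglik_proxy=final,
        K=K,
        criteria=crit,
        converged=converged,
        n_iter=it,
        seed=config.seed,
        method="vga",
        diagnostics={"state": state},
    )


def fit_vga(tensor: CountTensor, offsets: OffsetMatrix = None, G: int = 1,
            config: FitConfig = None) -> FitResult:
    """Fit a G-component MVPLN mixture by variational EM.

    Initializes memberships with repeated k-means, sweeps responsibilities,
    the variational triplets and the M-step until the relative change of the
    aggregate ELBO falls below ``config.tol``.  Components that collapse
    trigger a re-initialization (up to ``config.restarts`` extra attempts).
    """
    config = config or FitConfig()
    offsets = offsets if offsets is not None else OffsetMatrix.ones(tensor.r, tensor.p)
    last_err = None
    for attempt in range(config.restarts + 1):
        z0 = init_kmeans(tensor, G, config.n_init_runs, config.seed + attempt)
        try:
            return _fit_vga_once(tensor, offsets, G, config, z0)
        except DegenerateComponentError as err:
            logger.warning("fit attempt %d failed: %s", attempt + 1, err)
            last_err = err
    raise last_err
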