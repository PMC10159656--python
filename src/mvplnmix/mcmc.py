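"""MCMC-EM estimation and the VGA+MCMC hybrid estimator.

The E-step samples each latent log-rate matrix from its conditional
posterior (Poisson likelihood times matrix-variate normal prior) with an
adaptive random-walk Metropolis sampler on the vectorized matrix; posterior
expectations are plugged into the same closed-form M-step algebra as the
variational fit, with the variational second moments replaced by averages
over retained draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .exceptions import SamplerError, ValidationError
from .model_core import (
    ComponentParams,
    CountTensor,
    MixtureParams,
    OffsetMatrix,
    ensure_spd,
    free_params_count,
    identifiability_normalize,
)
from .vga import FitConfig, FitResult, _CompCtx, fit_vga, init_kmeans

logger = logging.getLogger(__name__)


@dataclass
class MCMCConfig:
    """Sampler and EM controls for the MCMC-based fits."""

    B: int = 2000          # total iterations per chain
    W: int = 1000          # retained iterations (post burn-in)
    n_chains: int = 1
    sampler: str = "rwm"
    target_accept: float = None   # default 0.44 scalar / 0.234 multivariate
    init_scale: float = None      # default 2.4 / sqrt(rp)
    seed: int = 1
    rb_responsibilities: bool = False  # Rao-Blackwellize over draws
    em_max_iter: int = 50
    em_tol: float = 1e-6
    n_init_runs: int = 100

    def __post_init__(self):
        if not (1 <= self.W < self.B):
            raise ValidationError("need 1 <= W < B")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if self.sampler != "rwm":
            raise ValidationError(f"unsupported sampler {self.sampler!r}")


@dataclass
class ThetaSamples:
    """Retained posterior draws for one (unit, component) pair."""

    draws: np.ndarray          # (n_draws, r, p)
    mean: np.ndarray           # (r, p)
    acceptance_rate: float


# ---------------------------------------------------------------------------
# batched sampler
# ---------------------------------------------------------------------------

def _log_post_batch(T, Yv, logs_v, mvec, P):
    """Unnormalized log posterior of vec(theta') for a batch, shape (N,)."""
    lam = np.exp(T + logs_v)
    pois = (-lam + T * Yv).sum(axis=1)
    Dm = T - mvec
    return pois - 0.5 * np.einsum("nc,cd,nd->n", Dm, P, Dm)


def _sample_batch(Y, logs, comp: ComponentParams, config: MCMCConfig,
                  rng: np.random.Generator, init=None):
    """Adaptive RWM posterior sampling, vectorized over observations.

    Returns ``(draws, mean, accept_rate)`` with draws of shape
    ``(n_chains * W, N, r, p)``.
    """
    Y = np.asarray(Y, dtype=float)
    N, r, p = Y.shape
    rp = r * p
    ctx = _CompCtx(comp)
    P = ctx.P
    mvec = comp.M.reshape(rp)
    Yv = Y.reshape(N, rp)
    logs_v = np.broadcast_to(logs, (r, p)).reshape(rp)
    target = config.target_accept or (0.44 if rp == 1 else 0.234)
    start = (np.log((Y + 0.5) / np.exp(logs)).reshape(N, rp)
             if init is None else np.asarray(init, float).reshape(N, rp))
    burn = config.B - config.W
    all_draws = []
    total_acc = np.zeros(N)
    for chain in range(config.n_chains):
        T = start.copy()
        if chain > 0:
            T = T + 0.1 * rng.standard_normal((N, rp))
        if config.init_scale is not None:
            scale = np.full(N, config.init_scale)
        else:
            # match the Poisson-curvature posterior scale ~ 1/sqrt(rate)
            curv = np.exp(start + logs_v) + np.diag(P)
            scale = 2.4 / np.sqrt(rp) / np.sqrt(curv.mean(axis=1))
        lp = _log_post_batch(T, Yv, logs_v, mvec, P)
        acc_win = np.zeros(N)
        win = 0
        kept = np.empty((config.W, N, rp))
        n_acc = np.zeros(N)
        for it in range(config.B):
            prop = T + scale[:, None] * rng.standard_normal((N, rp))
            lp_prop = _log_post_batch(prop, Yv, logs_v, mvec, P)
            accept = np.log(rng.random(N)) < lp_prop - lp
            T[accept] = prop[accept]
            lp[accept] = lp_prop[accept]
            acc_win += accept
            win += 1
            if it < burn and win == 25:
                rate = acc_win / win
                scale *= np.exp(2.0 * (rate - target))
                np.clip(scale, 1e-4, 50.0, out=scale)
                acc_win[:] = 0.0
                win = 0
            if it >= burn:
                kept[it - burn] = T
                n_acc += accept
        if np.any(n_acc == 0):
            raise SamplerError("zero acceptance in retained window after adaptation")
        total_acc += n_acc / config.W
        all_draws.append(kept)
    draws = np.concatenate(all_draws, axis=0).reshape(-1, N, r, p)
    return draws, draws.mean(axis=0), total_acc / config.n_chains


def sample_theta_posterior(Yn, offsets: OffsetMatrix, params: ComponentParams,
                           config: MCMCConfig = None,
                           rng: np.random.Generator = None) -> ThetaSamples:
    """Posterior draws of the latent log-rate matrix for one observation."""
    config = config or MCMCConfig()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    Y = np.atleast_2d(np.asarray(Yn, dtype=float))[None]
    draws, mean, acc = _sample_batch(Y, offsets.log, params, config, rng)
    return ThetaSamples(draws=draws[:, 0], mean=mean[0],
                        acceptance_rate=float(acc[0]))


# ---------------------------------------------------------------------------
# plug-in densities and the M-step over draws
# ---------------------------------------------------------------------------

def _plugin_logdens_batch(Y, logs, theta, ctx: _CompCtx):
    """Poisson log mass + matrix-normal log density at theta, shape (N,)."""
    r, p = ctx.r, ctx.p
    lam_log = theta + logs
    pois = (-np.exp(lam_log) + Y * lam_log - gammaln(Y + 1.0)).sum(axis=(-2, -1))
    Dm = theta - ctx.M
    quad = np.einsum("ij,...jk,kl,...il->...", ctx.Phi_inv, Dm, ctx.Omega_inv, Dm)
    return pois - 0.5 * (r * p * np.log(2 * np.pi) + p * ctx.logdet_phi
                         + r * ctx.logdet_omega + quad)


def _mstep_draws(tensor, z, draws, params_old=None):
    """Closed-form M-step with expectations taken over retained draws.

    ``draws[g]`` has shape (S, N, r, p).  Degenerate draw sets (S=1) reduce
    to the plug-in algebra.
    """
    from .exceptions import DegenerateComponentError

    N, r, p = tensor.counts.shape
    G = z.shape[1]
    n_g = z.sum(axis=0)
    if np.any(n_g < 1e-8):
        raise DegenerateComponentError("component collapsed during MCMC-EM")
    comps = []
    for g in range(G):
        zg = z[:, g]
        th = draws[g]                      # (S, N, r, p)
        S = th.shape[0]
        theta_bar = th.mean(axis=0)
        M = np.einsum("n,nij->ij", zg, theta_bar) / n_g[g]
        Om_old = params_old.components[g].Omega if params_old is not None else np.eye(p)
        Om_old_inv = np.linalg.inv(Om_old)
        D = th - M
        num_phi = np.einsum("n,snik,kl,snjl->ij", zg, D, Om_old_inv, D) / S
        Phi = ensure_spd(num_phi / (p * n_g[g]), "Phi")
        Phi_inv = np.linalg.inv(Phi)
        num_om = np.einsum("n,snik,ij,snjl->kl", zg, D, Phi_inv, D) / S
        Omega = ensure_spd(num_om / (r * n_g[g]), "Omega")
        comps.append(ComponentParams(M=M, Phi=Phi, Omega=Omega))
    return MixtureParams(pi=n_g / N, components=comps)


def _finalize(params, z, trace, K, N, converged, n_iter, seed, method, diag):
    from .selection import information_criteria, map_classify

    norm = []
    for c in params.components:
        Phi, Omega = identifiability_normalize(c.Phi, c.Omega)
        norm.append(ComponentParams(M=c.M, Phi=Phi, Omega=Omega))
    params = MixtureParams(pi=params.pi, components=norm)
    final = trace[-1]
    return FitResult(
        params=params,
        responsibilities=z,
        map_labels=map_classify(z),
        elbo_trace=np.asarray(trace),
        loglik_proxy=final,
        K=K,
        criteria=information_criteria(final, K, N, z),
        converged=converged,
        n_iter=n_iter,
        seed=seed,
        method=method,
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def mcmc_em_fit(tensor: CountTensor, offsets: OffsetMatrix = None, G: int = 1,
                config: MCMCConfig = None) -> FitResult:
    """MCMC-EM fit of a G-component MVPLN mixture.

    The E-step samples every (unit, component) posterior; responsibilities
    evaluate the component densities at the posterior means (plug-in) unless
    ``config.rb_responsibilities`` averages over draws.
    """
    if config is not None and not isinstance(config, MCMCConfig):
        config = MCMCConfig(seed=getattr(config, "seed", 1))
    config = config or MCMCConfig()
    offsets = offsets if offsets is not None else OffsetMatrix.ones(tensor.r, tensor.p)
    rng = np.random.default_rng(config.seed)
    Y = tensor.counts.astype(float)
    N, r, p = Y.shape
    logs = offsets.log
    z = init_kmeans(tensor, G, config.n_init_runs, config.seed)
    theta0 = np.log((Y + 0.5) / offsets.s)
    params = _mstep_draws(tensor, z, [theta0[None]] * G, None)
    theta_hat = np.broadcast_to(theta0[:, None], (N, G, r, p)).copy()
    trace = []
    converged = False
    acc_rates = np.zeros(G)
    it = 0
    for it in range(1, config.em_max_iter + 1):
        draws = []
        logd = np.empty((N, G))
        for g, comp in enumerate(params.components):
            dg, mean_g, acc = _sample_batch(Y, logs, comp, config, rng,
                                            init=theta_hat[:, g])
            draws.append(dg)
            theta_hat[:, g] = mean_g
            acc_rates[g] = float(acc.mean())
            ctx = _CompCtx(comp)
            if config.rb_responsibilities:
                per_draw = _plugin_logdens_batch(Y, logs, dg, ctx)  # (S, N)
                logd[:, g] = logsumexp(per_draw, axis=0) - np.log(dg.shape[0])
            else:
                logd[:, g] = _plugin_logdens_batch(Y, logs, theta_hat[:, g], ctx)
        logw = np.log(params.pi)[None, :] + logd
        ll = float(logsumexp(logw, axis=1).sum())
        trace.append(ll)
        logger.info("mcmc-em iter %d: plug-in loglik %.6f", it, ll)
        if len(trace) > 1:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-300)
            if rel < config.em_tol:
                converged = True
                break
        z = np.exp(logw - logsumexp(logw, axis=1)[:, None])
        params = _mstep_draws(tensor, z, draws, params)
    K = free_params_count(G, r, p, "mvpln")
    return _finalize(params, z, trace, K, N, converged, it, config.seed, "mcmc",
                     {"acceptance_rates": acc_rates.copy(), "W": config.W,
                      "theta_hat": theta_hat})


def hybrid_fit(tensor: CountTensor, offsets: OffsetMatrix = None, G: int = 1,
               config: MCMCConfig = None) -> FitResult:
    """Three-step hybrid: VGA fit, fixed memberships, one MCMC refinement.

    Cluster labels come from the VGA step and are returned unchanged; the
    MCMC E-step (initialized at the variational means) and a final M-step
    refine the parameter estimates.
    """
    if config is not None and not isinstance(config, MCMCConfig):
        config = MCMCConfig(seed=getattr(config, "seed", 1))
    config = config or MCMCConfig()
    offsets = offsets if offsets is not None else OffsetMatrix.ones(tensor.r, tensor.p)
    vga_cfg = FitConfig(seed=config.seed, n_init_runs=config.n_init_runs)
    vres = fit_vga(tensor, offsets, G, vga_cfg)
    N, r, p = tensor.counts.shape
    Y = tensor.counts.astype(float)
    logs = offsets.log
    labels = vres.map_labels
    z_hard = np.zeros((N, G))
    z_hard[np.arange(N), labels - 1] = 1.0
    rng = np.random.default_rng(config.seed)
    state = vres.diagnostics.get("state")
    draws = []
    logd = np.empty((N, G))
    acc_rates = np.zeros(G)
    for g, comp in enumerate(vres.params.components):
        init = state.xi[:, g] if state is not None else None
        dg, mean_g, acc = _sample_batch(Y, logs, comp, config, rng, init=init)
        draws.append(dg)
        acc_rates[g] = float(acc.mean())
    params = _mstep_draws(tensor, z_hard, draws, vres.params)
    for g, comp in enumerate(params.components):
        theta_bar = draws[g].mean(axis=0)
        logd[:, g] = _plugin_logdens_batch(Y, logs, theta_bar, _CompCtx(comp))
    logw = np.log(params.pi)[None, :] + logd
    ll = float(logsumexp(logw, axis=1).sum())
    trace = list(vres.elbo_trace) + [ll]
    logger.info("hybrid refinement: ELBO %.4f -> plug-in loglik %.4f",
                vres.loglik_proxy, ll)
    res = _finalize(params, vres.responsibilities, trace, vres.K, N,
                    vres.converged, vres.n_iter + 1, config.seed, "hybrid",
                    {"acceptance_rates": acc_rates, "W": config.W,
                     "vga_loglik_proxy": vres.loglik_proxy})
    # labels are fixed by the VGA step, by construction
    res.map_labels = labels
    return res
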