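"""Synthetic three-way count data.

Generators for MVPLN mixtures and for the independent-Poisson and
independent-negative-binomial competitor mixtures, random SPD covariance
factors, a simplified trimmed-mean-of-M-values (TMM) offset utility, and the
six named benchmark simulation designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import NormalizationError, ValidationError
from .model_core import ComponentParams, CountTensor, OffsetMatrix

LOG_MEAN_LOW = np.log(10.0)
LOG_MEAN_HIGH = np.log(500.0)

#: minimum latent-space distance enforced between component mean matrices so
#: that benchmark designs are well separated (cf. the reference designs'
#: near-perfect recoverability)
MIN_COMPONENT_SEPARATION = 3.5


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass
class SimulationDesign:
    """Fully specified generator for one benchmark setting."""

    name: str
    N: int
    r: int
    p: int
    pi: np.ndarray
    components: list
    family: str = "mvpln"  # mvpln | indep_poisson | indep_negbin
    seed: int = 1

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValidationError("design pi must sum to 1")
        if self.N < self.G or self.G < 1:
            raise ValidationError("need N >= G >= 1")
        if self.family not in ("mvpln", "indep_poisson", "indep_negbin"):
            raise ValidationError(f"unknown family {self.family!r}")

    @property
    def G(self) -> int:
        return self.pi.shape[0]


@dataclass
class LabeledDataset:
    """A simulated dataset with its ground truth attached."""

    tensor: CountTensor
    offsets: OffsetMatrix
    labels: np.ndarray  # 1-based component indices, length N
    design: SimulationDesign = None
    thetas: np.ndarray = None  # (N, r, p) latent draws, mvpln family only


# ---------------------------------------------------------------------------
# random SPD factors
# ---------------------------------------------------------------------------

def random_spd(
    dim: int,
    seed=None,
    diagonal_only: bool = False,
    eig_range: tuple[float, float] = (1.0, 3.0),
) -> np.ndarray:
    """Random SPD matrix with eigenvalues uniform in ``eig_range``.

    The eigenbasis is Haar-distributed (QR of a Gaussian matrix);
    ``diagonal_only`` skips the rotation and returns a diagonal matrix.
    """
    if dim < 1:
        raise ValidationError("dim must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = eig_range
    if not (0 < lo <= hi):
        raise ValidationError("eig_range must satisfy 0 < lo <= hi")
    eigs = rng.uniform(lo, hi, size=dim)
    if diagonal_only:
        return np.diag(eigs)
    Q, R = np.linalg.qr(rng.standard_normal((dim, dim)))
    Q = Q * np.sign(np.diag(R))  # Haar correction
    return (Q * eigs) @ Q.T


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _draw_labels(rng: np.random.Generator, pi: np.ndarray, N: int) -> np.ndarray:
    return rng.choice(len(pi), size=N, p=pi)


def simulate_mvpln_mixture(
    design: SimulationDesign,
    offsets: OffsetMatrix = None,
    rng: np.random.Generator = None,
) -> LabeledDataset:
    """Draw a dataset from an MVPLN mixture design.

    Per unit: component ~ Categorical(pi); latent matrix
    ``theta = M + A Z B`` with ``A A' = Phi``, ``B' B = Omega`` and ``Z`` iid
    standard normal; counts Poisson with rate ``exp(theta + log s)``.
    """
    if design.family != "mvpln":
        raise ValidationError("simulate_mvpln_mixture requires an mvpln design")
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    r, p, N = design.r, design.p, design.N
    offsets = offsets if offsets is not None else OffsetMatrix.ones(r, p)
    if offsets.s.shape != (r, p):
        raise ValidationError("offsets shape does not match design")
    comps = design.components
    A = [np.linalg.cholesky(c.Phi) for c in comps]
    B = [np.linalg.cholesky(c.Omega).T for c in comps]
    labels0 = _draw_labels(rng, design.pi, N)
    Z = rng.standard_normal((N, r, p))
    thetas = np.empty((N, r, p))
    for g in range(design.G):
        idx = labels0 == g
        thetas[idx] = comps[g].M + A[g] @ Z[idx] @ B[g]
    counts = rng.poisson(np.exp(thetas + offsets.log))
    return LabeledDataset(
        tensor=CountTensor(counts),
        offsets=offsets,
        labels=labels0 + 1,
        design=design,
        thetas=thetas,
    )


def simulate_competitor_mixture(
    design: SimulationDesign, rng: np.random.Generator = None
) -> LabeledDataset:
    """Draw from a mixture of independent Poisson or negative-binomial cells.

    Component parameters are dicts: ``{"rates": (r, p)}`` for Poisson or
    ``{"means": (r, p), "dispersions": (r, p)}`` for negative binomial with
    variance ``m + m^2 / dispersion``.
    """
    if design.family not in ("indep_poisson", "indep_negbin"):
        raise ValidationError("competitor design must be indep_poisson or indep_negbin")
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    r, p, N = design.r, design.p, design.N
    labels0 = _draw_labels(rng, design.pi, N)
    counts = np.empty((N, r, p), dtype=np.int64)
    for g, comp in enumerate(design.components):
        idx = labels0 == g
        m = idx.sum()
        if design.family == "indep_poisson":
            rates = np.asarray(comp["rates"], dtype=float)
            if rates.shape != (r, p) or (rates < 0).any():
                raise ValidationError("rates must be a non-negative r x p array")
            counts[idx] = rng.poisson(np.broadcast_to(rates, (m, r, p)))
        else:
            mu = np.asarray(comp["means"], dtype=float)
            phi = np.asarray(comp["dispersions"], dtype=float)
            if mu.shape != (r, p) or phi.shape != (r, p):
                raise ValidationError("means and dispersions must be r x p arrays")
            if (mu < 0).any() or (phi <= 0).any():
                raise ValidationError("negative rates or non-positive dispersions")
            # NB(n=phi, p=phi/(phi+mu)) has mean mu, variance mu + mu^2/phi
            prob = phi / (phi + mu)
            counts[idx] = rng.negative_binomial(
                np.broadcast_to(phi, (m, r, p)), np.broadcast_to(prob, (m, r, p))
            )
    return LabeledDataset(
        tensor=CountTensor(counts),
        offsets=OffsetMatrix.ones(r, p),
        labels=labels0 + 1,
        design=design,
    )


def simulate(design: SimulationDesign, rng: np.random.Generator = None) -> LabeledDataset:
    """Dispatch to the family-appropriate generator."""
    if design.family == "mvpln":
        return simulate_mvpln_mixture(design, rng=rng)
    return simulate_competitor_mixture(design, rng=rng)


# ---------------------------------------------------------------------------
# TMM offsets
# ---------------------------------------------------------------------------

def compute_offsets_tmm(
    tensor: CountTensor, trim_m: float = 0.30, trim_a: float = 0.05
) -> OffsetMatrix:
    """Simplified trimmed-mean-of-M-values library-size normalization.

    The tensor is flattened to an ``N x rp`` matrix (units as genes, the rp
    cells as samples).  The reference sample is the one whose 75th percentile
    of scaled counts is closest to the mean 75th percentile.  For every other
    sample, log2 count ratios (M) and average log2 abundances (A) over genes
    expressed in both are doubly trimmed (30% on M, 5% on A) and averaged with
    inverse-variance precision weights.  The resulting effective library
    sizes are rescaled to geometric mean 1.
    """
    Y = tensor.counts.reshape(tensor.N, -1).astype(float)
    n_samples = Y.shape[1]
    lib = Y.sum(axis=0)
    if (lib == 0).any():
        raise NormalizationError("a sample column is all zero; cannot normalize")
    scaled = Y / lib
    uq = np.array([np.percentile(scaled[Y[:, j] > 0, j], 75) for j in range(n_samples)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        keep = (Y[:, j] > 0) & (Y[:, ref] > 0)
        if not keep.any():
            raise NormalizationError("no genes shared between sample and reference")
        yj, yr = Y[keep, j], Y[keep, ref]
        m = np.log2((yj / lib[j]) / (yr / lib[ref]))
        a = 0.5 * (np.log2(yj / lib[j]) + np.log2(yr / lib[ref]))
        w = 1.0 / ((lib[j] - yj) / (lib[j] * yj) + (lib[ref] - yr) / (lib[ref] * yr))
        lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
        keep2 = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep2.any():
            keep2 = np.ones_like(m, dtype=bool)
        factors[j] = 2 ** (np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2]))
    eff = lib * factors
    eff = eff / np.exp(np.mean(np.log(eff)))
    return OffsetMatrix(eff.reshape(tensor.r, tensor.p))


# ---------------------------------------------------------------------------
# benchmark designs
# ---------------------------------------------------------------------------

def _separated_means(
    rng: np.random.Generator, G: int, r: int, p: int, min_sep: float
) -> list[np.ndarray]:
    """Draw G mean matrices uniform in log-space with pairwise separation."""
    means: list[np.ndarray] = []
    sep = min_sep
    tries = 0
    while len(means) < G:
        cand = rng.uniform(LOG_MEAN_LOW, LOG_MEAN_HIGH, size=(r, p))
        if all(np.linalg.norm(cand - m) >= sep for m in means):
            means.append(cand)
            tries = 0
        else:
            tries += 1
            if tries > 500:  # relax to guarantee termination
                sep *= 0.95
                tries = 0
    return means


def _mvpln_components(
    rng: np.random.Generator, G: int, r: int, p: int, diagonal_only: bool = False
) -> list[ComponentParams]:
    means = _separated_means(rng, G, r, p, MIN_COMPONENT_SEPARATION)
    comps = []
    for M in means:
        Phi = random_spd(r, rng, diagonal_only=diagonal_only, eig_range=(0.5, 1.2))
        Omega = random_spd(p, rng, diagonal_only=diagonal_only, eig_range=(0.1, 0.35))
        comps.append(ComponentParams(M=M, Phi=Phi, Omega=Omega))
    return comps


_DESIGN_TABLE = {
    "sim1": dict(family="mvpln", N=1000, r=2, p=3, pi=[1.0]),
    "sim2": dict(family="mvpln", N=1000, r=2, p=3, pi=[0.79, 0.21]),
    "sim3": dict(family="mvpln", N=1000, r=2, p=3, pi=[0.6, 0.4], diagonal=True),
    "sim4": dict(family="indep_poisson", N=1000, r=2, p=3, pi=[0.45, 0.55]),
    "sim5": dict(family="indep_negbin", N=2000, r=2, p=3, pi=[0.79, 0.21]),
    "sim6": dict(family="mvpln", N=1500, r=2, p=3, pi=[0.125] * 8),
}


def build_benchmark_design(which: str, seed: int = 1, scale: float = 1.0) -> SimulationDesign:
    """Return one of the six named benchmark designs.

    Mixture structure (N, r, p, G, pi) is fixed per design; component
    parameters are drawn reproducibly from ``seed``.  ``scale`` shrinks N
    proportionally for reduced-cost runs.
    """
    if which not in _DESIGN_TABLE:
        raise ValidationError(f"unknown design {which!r}; choose from {sorted(_DESIGN_TABLE)}")
    if not (0 < scale <= 1):
        raise ValidationError("scale must be in (0, 1]")
    spec = _DESIGN_TABLE[which]
    rng = np.random.default_rng([seed, 7919, int(which[-1])])
    G = len(spec["pi"])
    r, p = spec["r"], spec["p"]
    N = max(G, int(round(spec["N"] * scale)))
    if spec["family"] == "mvpln":
        comps = _mvpln_components(rng, G, r, p, diagonal_only=spec.get("diagonal", False))
    elif spec["family"] == "indep_poisson":
        means = _separated_means(rng, G, r, p, MIN_COMPONENT_SEPARATION)
        comps = [{"rates": np.exp(M)} for M in means]
    else:
        means = _separated_means(rng, G, r, p, MIN_COMPONENT_SEPARATION)
        comps = [
            {"means": np.exp(M), "dispersions": rng.uniform(3.0, 10.0, size=(r, p))}
            for M in means
        ]
    return SimulationDesign(
        name=which,
        N=N,
        r=r,
        p=p,
        pi=np.asarray(spec["pi"]),
        components=comps,
        family=spec["family"],
        seed=seed,
    )
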