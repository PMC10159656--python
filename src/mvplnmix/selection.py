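"""Model selection: information criteria, MAP classification, ARI, G-sweep.

Criteria are stored exactly in their conventional printed forms — AIC and
AIC3 are minimized, BIC and ICL (here on the ``2 log L - K log N`` scale) are
maximized — with an explicit direction table used by the sweep driver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

from .exceptions import ValidationError
from .model_core import CountTensor, OffsetMatrix

logger = logging.getLogger(__name__)

#: +1 criteria are maximized, -1 minimized
CRITERIA_DIRECTION = {"AIC": -1, "AIC3": -1, "BIC": +1, "ICL": +1}


def information_criteria(loglik: float, K: int, N: int, z: np.ndarray) -> dict:
    """AIC, BIC, AIC3 and ICL from a maximized log-likelihood (or proxy).

    ``ICL = BIC + 2 * sum_n log z[n, map(n)]``: the entropy term is zero for
    hard responsibilities, negative otherwise.
    """
    if N < 1:
        raise ValidationError("N must be >= 1")
    if K < 0:
        raise ValidationError("K must be >= 0")
    z = np.atleast_2d(np.asarray(z, dtype=float))
    aic = -2.0 * loglik + 2.0 * K
    aic3 = -2.0 * loglik + 3.0 * K
    bic = 2.0 * loglik - K * np.log(N)
    map_idx = z.argmax(axis=1)
    zmap = z[np.arange(z.shape[0]), map_idx]
    with np.errstate(divide="ignore"):
        logz = np.where(zmap > 0, np.log(np.maximum(zmap, 1e-300)), 0.0)
    icl = bic + 2.0 * float(logz.sum())
    return {"AIC": aic, "BIC": bic, "AIC3": aic3, "ICL": icl}


def map_classify(z: np.ndarray) -> np.ndarray:
    """1-based maximum a posteriori labels; ties go to the lowest index."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    return z.argmax(axis=1) + 1


def adjusted_rand_index(a, b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    Returns 1 for identical partitions up to relabeling; the degenerate
    0/0 case (both partitions trivial) is defined as 1.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("label vectors must be 1-d of equal length")
    n = a.size
    if n < 2:
        raise ValidationError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    table = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    sum_cells = comb(table, 2).sum()
    sum_rows = comb(table.sum(axis=1), 2).sum()
    sum_cols = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


@dataclass
class CriteriaReport:
    """All criteria across a sweep of G values, plus per-criterion winners."""

    rows: list = field(default_factory=list)   # dicts: G, K, loglik, AIC/BIC/AIC3/ICL
    chosen: dict = field(default_factory=dict)  # criterion -> G
    errors: dict = field(default_factory=dict)  # G -> error message
    direction: dict = field(default_factory=lambda: dict(CRITERIA_DIRECTION))


def select_model(tensor: CountTensor, offsets: OffsetMatrix = None,
                 G_range=(1, 2, 3, 4, 5), method: str = "vga", config=None):
    """Fit every G in ``G_range`` and pick winners per criterion.

    Returns ``(report, fits, best)`` where ``fits`` maps G to its FitResult
    and ``best`` maps each criterion to the winning FitResult.  A failing G
    is logged and excluded rather than aborting the sweep.  Ties resolve
    toward smaller G.
    """
    from . import mcmc as _mcmc
    from . import vga as _vga

    G_range = sorted(set(int(g) for g in G_range))
    if not G_range:
        raise ValidationError("G_range must be non-empty")
    fitters = {"vga": _vga.fit_vga, "mcmc": _mcmc.mcmc_em_fit, "hybrid": _mcmc.hybrid_fit}
    if method not in fitters:
        raise ValidationError(f"unknown method {method!r}")
    report = CriteriaReport()
    fits = {}
    for G in G_range:
        try:
            res = fitters[method](tensor, offsets, G, config)
        except Exception as err:  # propagate nothing; record and move on
            logger.warning("fit failed for G=%d: %s", G, err)
            report.errors[G] = str(err)
            continue
        fits[G] = res
        report.rows.append({"G": G, "K": res.K, "loglik": res.loglik_proxy,
                            **res.criteria})
    if not fits:
        raise ValidationError("every G in the sweep failed")
    best = {}
    for crit, sign in CRITERIA_DIRECTION.items():
        ordered = sorted(report.rows, key=lambda row: (-sign * row[crit], row["G"]))
        report.chosen[crit] = ordered[0]["G"]
        best[crit] = fits[ordered[0]["G"]]
    return report, fits, best
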