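"""File formats, result serialization and fixture generation.

Canonical interchange is a long-format delimited table with one row per
(unit, occasion, variable, count) triple; a wide N x rp table with
``occasion__variable`` column names is accepted as an alternative dialect.
Axis ordering follows first appearance in the file (the covariance factors
are axis-order dependent, so this ordering is part of the data contract).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .model_core import ComponentParams, CountTensor, MixtureParams, OffsetMatrix
from .simulate import LabeledDataset, build_benchmark_design, simulate
from .vga import FitResult

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
LONG_COLUMNS = ["unit", "occasion", "variable", "count"]


@dataclass
class RunConfig:
    """Resolved configuration of one CLI run."""

    input: str = None
    offsets_mode: str = "ones"       # ones | tmm | file
    offsets_file: str = None
    method: str = "vga"
    G_min: int = 1
    G_max: int = 1
    seed: int = 1
    max_iter: int = 500
    tol: float = 1e-6
    n_init_runs: int = 100
    out_dir: str = "."

    def g_range(self):
        if self.G_max < self.G_min:
            raise ValidationError("empty G range")
        return range(self.G_min, self.G_max + 1)


# ---------------------------------------------------------------------------
# count-tensor I/O
# ---------------------------------------------------------------------------

def _first_appearance(values) -> list:
    return list(pd.unique(values))


def read_count_tensor(path, delimiter: str = "\t") -> CountTensor:
    """Read a long-format (unit, occasion, variable, count) table.

    Every triple must appear exactly once; axes are ordered by first
    appearance.  Wide tables (``occasion__variable`` columns) are detected by
    their header and accepted.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str)
    if df.shape[1] >= 2 and all("__" in c for c in df.columns[1:]):
        return _read_wide(df)
    if df.shape[1] < 4:
        raise ValidationError(
            f"expected 4 columns (unit, occasion, variable, count), got {df.shape[1]}"
        )
    df = df.iloc[:, :4]
    df.columns = LONG_COLUMNS
    if df.isna().any().any():
        raise ValidationError("ragged table: missing fields")
    counts_num = pd.to_numeric(df["count"], errors="coerce")
    if counts_num.isna().any() or not np.allclose(counts_num, counts_num.round()):
        raise ValidationError("non-integer count value in table")
    dup = df.duplicated(subset=["unit", "occasion", "variable"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate triple (unit={row['unit']}, occasion={row['occasion']}, "
            f"variable={row['variable']})"
        )
    units = _first_appearance(df["unit"])
    occs = _first_appearance(df["occasion"])
    vars_ = _first_appearance(df["variable"])
    N, r, p = len(units), len(occs), len(vars_)
    if len(df) != N * r * p:
        raise ValidationError(
            f"incomplete table: {len(df)} rows for {N}x{r}x{p} grid (no implicit zeros)"
        )
    ui = {u: i for i, u in enumerate(units)}
    oi = {o: i for i, o in enumerate(occs)}
    vi = {v: i for i, v in enumerate(vars_)}
    counts = np.zeros((N, r, p), dtype=np.int64)
    counts[
        df["unit"].map(ui).to_numpy(),
        df["occasion"].map(oi).to_numpy(),
        df["variable"].map(vi).to_numpy(),
    ] = counts_num.round().astype(np.int64).to_numpy()
    return CountTensor(counts, unit_ids=units, occasion_labels=occs,
                       variable_labels=vars_)


def _read_wide(df: pd.DataFrame) -> CountTensor:
    units = df.iloc[:, 0].tolist()
    occs, vars_ = [], []
    cells = []
    for col in df.columns[1:]:
        occ, var = col.split("__", 1)
        if occ not in occs:
            occs.append(occ)
        if var not in vars_:
            vars_.append(var)
        cells.append((occ, var))
    r, p = len(occs), len(vars_)
    if len(cells) != r * p or len(set(cells)) != len(cells):
        raise ValidationError("wide table columns do not form a complete occasion/variable grid")
    counts = np.zeros((len(units), r, p), dtype=np.int64)
    for j, (occ, var) in enumerate(cells):
        col = pd.to_numeric(df.iloc[:, j + 1], errors="coerce")
        if col.isna().any() or not np.allclose(col, col.round()):
            raise ValidationError("non-integer count value in table")
        counts[:, occs.index(occ), vars_.index(var)] = col.round().astype(np.int64)
    return CountTensor(counts, unit_ids=units, occasion_labels=occs,
                       variable_labels=vars_)


def write_count_tensor(tensor: CountTensor, path, delimiter: str = "\t") -> None:
    """Write the long-format table (row-major over unit, occasion, variable)."""
    N, r, p = tensor.counts.shape
    rows = {
        "unit": np.repeat(tensor.unit_ids, r * p),
        "occasion": np.tile(np.repeat(tensor.occasion_labels, p), N),
        "variable": np.tile(tensor.variable_labels, N * r),
        "count": tensor.counts.ravel(),
    }
    pd.DataFrame(rows).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# parameter / result serialization
# ---------------------------------------------------------------------------

def params_to_dict(params: MixtureParams) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "G": params.G,
        "pi": params.pi.tolist(),
        "components": [
            {"M": c.M.tolist(), "Phi": c.Phi.tolist(), "Omega": c.Omega.tolist()}
            for c in params.components
        ],
    }


def params_from_dict(d: dict) -> MixtureParams:
    if d.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(f"unsupported params schema {d.get('schema_version')!r}")
    comps = [
        ComponentParams(M=np.array(c["M"]), Phi=np.array(c["Phi"]),
                        Omega=np.array(c["Omega"]))
        for c in d["components"]
    ]
    return MixtureParams(pi=np.array(d["pi"]), components=comps)


def write_fit_result(result: FitResult, out_dir) -> dict:
    """Write params.json, assignments.csv, criteria.csv, elbo_trace.csv, run.log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["params"] = out / "params.json"
    with open(paths["params"], "w") as fh:
        json.dump(
            {**params_to_dict(result.params),
             "loglik_proxy": result.loglik_proxy, "K": result.K,
             "converged": bool(result.converged), "n_iter": int(result.n_iter),
             "seed": int(result.seed), "method": result.method},
            fh, indent=1,
        )
    z = result.responsibilities
    G = z.shape[1]
    assign = pd.DataFrame({"unit_id": np.arange(1, z.shape[0] + 1),
                           "map_label": result.map_labels})
    for g in range(G):
        assign[f"z{g + 1}"] = z[:, g]
    paths["assignments"] = out / "assignments.csv"
    assign.to_csv(paths["assignments"], index=False)
    paths["criteria"] = out / "criteria.csv"
    pd.DataFrame([{"G": G, "K": result.K, "loglik_proxy": result.loglik_proxy,
                   **result.criteria}]).to_csv(paths["criteria"], index=False)
    paths["elbo_trace"] = out / "elbo_trace.csv"
    pd.DataFrame({"iteration": np.arange(1, len(result.elbo_trace) + 1),
                  "elbo": result.elbo_trace}).to_csv(paths["elbo_trace"], index=False)
    paths["log"] = out / "run.log"
    with open(paths["log"], "w") as fh:
        fh.write(f"method={result.method} G={G} converged={result.converged} "
                 f"n_iter={result.n_iter} seed={result.seed}\n")
        for i, v in enumerate(result.elbo_trace, 1):
            fh.write(f"iter {i}: objective {v:.6f}\n")
    return paths


def write_dataset(ds: LabeledDataset, out_dir, stem: str) -> dict:
    """Write one labeled dataset: long TSV plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tsv = out / f"{stem}.tsv"
    write_count_tensor(ds.tensor, tsv)
    sidecar = {
        "labels": np.asarray(ds.labels).tolist(),
        "offsets": ds.offsets.s.tolist(),
    }
    if ds.design is not None:
        d = ds.design
        sidecar["design"] = {
            "name": d.name, "N": d.N, "r": d.r, "p": d.p,
            "pi": d.pi.tolist(), "family": d.family, "seed": d.seed,
        }
    side = out / f"{stem}.json"
    with open(side, "w") as fh:
        json.dump(sidecar, fh)
    return {"tsv": tsv, "sidecar": side}


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixtures(out_dir, scale: float = 1.0, seed: int = 1) -> dict:
    """Materialize the six benchmark designs at reduced scale.

    ``scale`` shrinks N proportionally; the replicate count is
    ``max(3, round(25 * scale))``.  A manifest records every seed so each
    fixture is regenerable bit-exactly.
    """
    if not (0 < scale <= 1):
        raise ValidationError("scale must be in (0, 1]")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_rep = max(3, int(round(25 * scale)))
    manifest = {"scale": scale, "seed": seed, "n_replicates": n_rep, "datasets": []}
    for which in ("sim1", "sim2", "sim3", "sim4", "sim5", "sim6"):
        design = build_benchmark_design(which, seed=seed, scale=scale)
        for rep in range(n_rep):
            rng = np.random.default_rng([seed, rep, int(which[-1])])
            ds = simulate(design, rng=rng)
            stem = f"{which}_rep{rep + 1}"
            paths = write_dataset(ds, out, stem)
            manifest["datasets"].append({
                "design": which, "replicate": rep + 1, "N": design.N,
                "tsv": paths["tsv"].name, "sidecar": paths["sidecar"].name,
            })
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {"manifest": mpath, "n_datasets": len(manifest["datasets"])}


def load_offsets(mode: str, tensor: CountTensor, path=None) -> OffsetMatrix:
    """Resolve an offsets specification: 'ones', 'tmm' or 'file'."""
    from .simulate import compute_offsets_tmm

    if mode == "ones":
        return OffsetMatrix.ones(tensor.r, tensor.p)
    if mode == "tmm":
        return compute_offsets_tmm(tensor)
    if mode == "file":
        if path is None:
            raise ValidationError("offsets mode 'file' requires a path")
        s = np.loadtxt(path)
        return OffsetMatrix(np.atleast_2d(s))
    raise ValidationError(f"unknown offsets mode {mode!r}")
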