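"""File formats for Gaussian sets, tensor grids and result records.

Gaussian sets are stored either as JSON
``{"d": int, "items": [{"mean": [...], "cov": [[...]]}, ...]}``
or as CSV with one row per Gaussian: mean columns ``mu0..mu{d-1}`` followed
by the row-major covariance columns ``cov00, cov01, ...``.  Validation is
strict and error messages carry the offending record index.

Tensor grids are stored as a dense ``.npy`` array (``(*shape, d, d)``)
next to a JSON sidecar ``{"shape": [...], "spacing": [...], "d": int}``.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ball import BallResult
from .curves import CurveSample
from .dti import TensorGrid
from .gaussian import Gaussian
from .scenarios import BenchmarkRatios

__all__ = [
    "read_gaussians_json",
    "write_gaussians_json",
    "read_gaussians_csv",
    "write_gaussians_csv",
    "read_gaussians",
    "read_tensor_grid",
    "write_tensor_grid",
    "curve_sample_records",
    "write_curve_sample",
    "ball_result_to_dict",
    "write_benchmark",
]


def _build_gaussian(rec: dict, d: int, idx: int) -> Gaussian:
    try:
        mean = np.asarray(rec["mean"], dtype=float)
        cov = np.asarray(rec["cov"], dtype=float)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"record {idx}: malformed mean/cov ({exc})") from exc
    if mean.shape != (d,):
        raise ValueError(f"record {idx}: mean has shape {mean.shape}, expected ({d},)")
    if cov.shape != (d, d):
        raise ValueError(f"record {idx}: cov has shape {cov.shape}, expected ({d},{d})")
    if not np.allclose(cov, cov.T, atol=1e-8 * (1 + np.abs(cov).max())):
        raise ValueError(f"record {idx}: covariance is asymmetric beyond tolerance")
    try:
        return Gaussian(mean, cov)
    except ValueError as exc:
        raise ValueError(f"record {idx}: {exc}") from exc


def read_gaussians_json(path: str | Path) -> list[Gaussian]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict) or "d" not in data or "items" not in data:
        raise ValueError("expected an object with keys 'd' and 'items'")
    d = int(data["d"])
    return [_build_gaussian(rec, d, i) for i, rec in enumerate(data["items"])]


def write_gaussians_json(path: str | Path, gaussians: Sequence[Gaussian]) -> None:
    if not gaussians:
        raise ValueError("empty Gaussian set")
    d = gaussians[0].d
    payload = {
        "d": d,
        "items": [
            {"mean": g.mean.tolist(), "cov": g.cov.tolist()} for g in gaussians
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _csv_columns(d: int) -> list[str]:
    return [f"mu{i}" for i in range(d)] + [
        f"cov{i}{j}" for i in range(d) for j in range(d)
    ]


def read_gaussians_csv(path: str | Path) -> list[Gaussian]:
    df = pd.read_csv(path)
    ncol = df.shape[1]
    # d + d^2 columns
    d = int((-1 + np.sqrt(1 + 4 * ncol)) / 2)
    if d + d * d != ncol:
        raise ValueError(f"{ncol} columns do not match d + d^2 for any integer d")
    out = []
    for i, row in df.iterrows():
        vals = row.to_numpy(dtype=float)
        rec = {"mean": vals[:d], "cov": vals[d:].reshape(d, d)}
        out.append(_build_gaussian(rec, d, int(i)))
    return out


def write_gaussians_csv(path: str | Path, gaussians: Sequence[Gaussian]) -> None:
    if not gaussians:
        raise ValueError("empty Gaussian set")
    d = gaussians[0].d
    rows = [np.concatenate([g.mean, g.cov.ravel()]) for g in gaussians]
    pd.DataFrame(rows, columns=_csv_columns(d)).to_csv(path, index=False)


def read_gaussians(path: str | Path) -> list[Gaussian]:
    """Dispatch on extension: ``.json`` or ``.csv``."""
    p = Path(path)
    if p.suffix == ".json":
        return read_gaussians_json(p)
    if p.suffix == ".csv":
        return read_gaussians_csv(p)
    raise ValueError(f"unsupported Gaussian set format {p.suffix!r}")


def write_tensor_grid(prefix: str | Path, grid: TensorGrid) -> None:
    """Write ``<prefix>.npy`` (dense tensors) and ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), grid.covs)
    sidecar = {
        "shape": list(grid.shape),
        "spacing": list(grid.spacing),
        "d": grid.d,
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)
    if grid.means is not None:
        np.save(prefix.parent / (prefix.stem + "_means.npy"), grid.means)


def read_tensor_grid(prefix: str | Path) -> TensorGrid:
    prefix = Path(prefix)
    covs = np.load(prefix.with_suffix(".npy"))
    with open(prefix.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    if list(covs.shape[:-2]) != list(sidecar["shape"]):
        raise ValueError("sidecar shape disagrees with tensor array")
    means_path = prefix.parent / (prefix.stem + "_means.npy")
    means = np.load(means_path) if means_path.exists() else None
    return TensorGrid(covs, tuple(sidecar["spacing"]), means)


def curve_sample_records(sample: CurveSample) -> list[dict]:
    """Flatten a CurveSample to one record per node (step values attach to
    the segment starting at the node; the last node has none)."""
    out = []
    for i, (t, g) in enumerate(zip(sample.ts, sample.points)):
        rec = {
            "t": float(t),
            "mean": g.mean.tolist(),
            "cov": g.cov.tolist(),
            "step_sqrt_jeffreys": float(sample.step_jeffreys[i])
            if i < sample.T
            else None,
        }
        if sample.proj_errors.size:
            rec["proj_error"] = float(sample.proj_errors[i])
        out.append(rec)
    return out


def write_curve_sample(path: str | Path, sample: CurveSample, fmt: str = "json") -> None:
    recs = curve_sample_records(sample)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump({"kind": sample.kind, "T": sample.T, "nodes": recs}, fh, indent=1)
    elif fmt == "csv":
        flat = []
        for rec in recs:
            row = {"t": rec["t"], "step_sqrt_jeffreys": rec["step_sqrt_jeffreys"]}
            if "proj_error" in rec:
                row["proj_error"] = rec["proj_error"]
            for i, m in enumerate(rec["mean"]):
                row[f"mu{i}"] = m
            for i, r_ in enumerate(rec["cov"]):
                for j, c in enumerate(r_):
                    row[f"cov{i}{j}"] = c
            flat.append(row)
        pd.DataFrame(flat).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported format {fmt!r}")


def ball_result_to_dict(res: BallResult) -> dict:
    return {
        "center": {"mean": res.center.mean.tolist(), "cov": res.center.cov.tolist()},
        "center_spd": res.center_spd.tolist(),
        "radius_co": res.radius_co,
        "projection_gap": res.projection_gap,
        "iterations": res.iterations,
    }


def write_benchmark(path: str | Path, ratios: BenchmarkRatios, fmt: str = "json") -> None:
    if fmt == "json":
        payload = {
            "scenario": asdict(ratios.spec),
            "T": ratios.T,
            "reps": ratios.reps,
            "kappa": ratios.kappa,
            "wins": ratios.wins,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    elif fmt == "csv":
        ratios.to_frame().to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported format {fmt!r}")
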