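"""File formats, demo runner and run manifests.

Chains are stored as RFC-4180 CSV with header ``x1..xd`` (one row per
iterate, 0-based row order preserved) or as ``.npy`` arrays.  Sidecar files
are auto-discovered by suffix: ``<stem>.scores.csv|.npy`` for score
evaluations and ``<stem>.gibbs.csv`` for the Gibbs update record (columns
``iter, coord, cond_mean, m1..md``; ``coord`` is 0-based).  All indices in
output files are 0-based.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .control_variates import (
    WeightedSample,
    compute_weights,
    gibbs_cv_matrix,
    scale_weights,
    score_cv_matrix,
)
from .metrics import SignedEmpirical, energy_distance, ksd, star_discrepancy
from .targets import (
    ChainSample,
    GibbsRecord,
    TargetSpec,
    make_gaussian_chain,
    make_truncated_params,
    truncated_gibbs_chain,
)
from .thinning import cube_thin, signed_empirical

logger = logging.getLogger(__name__)

__all__ = [
    "read_chain",
    "write_chain",
    "write_weights",
    "write_subsample",
    "read_subsample",
    "run_demo",
]


def _sidecar(path: Path, kind: str, ext: str) -> Path:
    return path.with_name(path.stem + f".{kind}{ext}")


def _read_table(path: Path, label: str) -> np.ndarray:
    if path.suffix == ".npy":
        arr = np.load(path)
    else:
        try:
            frame = pd.read_csv(path, float_precision="round_trip")
        except Exception as exc:
            raise ValueError(f"[{label}] cannot parse {path}: {exc}") from exc
        bad = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
        if bad:
            raise ValueError(f"[{label}] non-numeric columns in {path}: {bad}")
        arr = frame.to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(arr, dtype=float))


def read_chain(path: str | Path) -> ChainSample:
    """Load a chain plus any score / Gibbs sidecar files next to it."""
    path = Path(path)
    states = _read_table(path, "chain")
    scores = None
    for ext in (".csv", ".npy"):
        sp = _sidecar(path, "scores", ext)
        if sp.exists():
            scores = _read_table(sp, "scores")
            if scores.shape != states.shape:
                raise ValueError(
                    f"[scores] shape {scores.shape} does not match the "
                    f"chain shape {states.shape}"
                )
            break
    gibbs = None
    gp = _sidecar(path, "gibbs", ".csv")
    if gp.exists():
        frame = pd.read_csv(gp, float_precision="round_trip")
        d = states.shape[1]
        mcols = [f"m{i + 1}" for i in range(d)]
        missing = [c for c in ["iter", "coord", "cond_mean", *mcols] if c not in frame]
        if missing:
            raise ValueError(f"[gibbs] {gp} is missing columns {missing}")
        if len(frame) != states.shape[0]:
            raise ValueError(
                f"[gibbs] {len(frame)} records for {states.shape[0]} states"
            )
        gibbs = GibbsRecord(
            coord=frame["coord"].to_numpy(dtype=np.int64),
            cond_mean=frame["cond_mean"].to_numpy(dtype=float),
            all_cond_means=frame[mcols].to_numpy(dtype=float),
        )
    return ChainSample(states=states, scores=scores, gibbs_record=gibbs)


def write_chain(chain: ChainSample, path: str | Path) -> Path:
    """Write a chain (and its sidecars) as CSV or .npy."""
    path = Path(path)
    d = chain.d
    if path.suffix == ".npy":
        np.save(path, chain.states)
        if chain.scores is not None:
            np.save(_sidecar(path, "scores", ".npy"), chain.scores)
    else:
        cols = [f"x{i + 1}" for i in range(d)]
        pd.DataFrame(chain.states, columns=cols).to_csv(path, index=False)
        if chain.scores is not None:
            pd.DataFrame(chain.scores, columns=cols).to_csv(
                _sidecar(path, "scores", ".csv"), index=False
            )
    if chain.gibbs_record is not None:
        rec = chain.gibbs_record
        frame = pd.DataFrame(
            {
                "iter": np.arange(chain.n),
                "coord": rec.coord,
                "cond_mean": rec.cond_mean,
            }
        )
        for i in range(d):
            frame[f"m{i + 1}"] = rec.all_cond_means[:, i]
        frame.to_csv(_sidecar(path, "gibbs", ".csv"), index=False)
    return path


def write_weights(ws: WeightedSample, path: str | Path) -> Path:
    """Weights CSV (index, weight, sign, W) for burn-in diagnostics."""
    path = Path(path)
    n = ws.weights.shape[0]
    frame = pd.DataFrame(
        {
            "index": np.arange(n),
            "weight": ws.weights,
            "sign": ws.signs if ws.signs is not None else np.where(ws.weights < 0, -1.0, 1.0),
            "W": ws.scaled if ws.scaled is not None else np.full(n, np.nan),
        }
    )
    frame.to_csv(path, index=False)
    return path


def write_subsample(res, prefix: str | Path) -> tuple[Path, Path]:
    """Subsample CSV (orig_index, sign, scale) plus JSON diagnostics."""
    prefix = Path(prefix)
    csv_path = prefix.with_suffix(".subsample.csv")
    pd.DataFrame(
        {
            "orig_index": res.indices,
            "sign": res.signs,
            "scale": np.full(res.achieved_size, res.scale),
        }
    ).to_csv(csv_path, index=False)
    meta = {
        "requested_m": res.requested_m,
        "achieved_size": res.achieved_size,
        "omega": res.omega,
        "scale": res.scale,
        "diagnostics": res.diagnostics,
    }
    json_path = prefix.with_suffix(".subsample.json")
    json_path.write_text(json.dumps(meta, indent=2, default=str))
    return csv_path, json_path


def read_subsample(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("orig_index", "sign", "scale") if c not in frame]
    if missing:
        raise ValueError(f"[subsample] {path} is missing columns {missing}")
    return frame


_DEMO_DEFAULTS = {
    "gaussian": {"d": 2, "n": 5000, "m": 50, "cv": "full"},
    "truncnorm": {"d": 10, "n": 100_000, "m": 100, "cv": "gibbs"},
}


def run_demo(name: str, overrides: dict | None = None, seed: int = 0, outdir=".") -> dict:
    """End-to-end synthetic run: target, chain, weights, thinning, metrics.

    Emits chain (+sidecars), weights, subsample files and a manifest JSON
    recording every parameter and seed, and returns the manifest dict.
    """
    if name not in _DEMO_DEFAULTS:
        raise ValueError(f"unknown demo {name!r}; choose from {sorted(_DEMO_DEFAULTS)}")
    cfg = dict(_DEMO_DEFAULTS[name])
    cfg.update({k: v for k, v in (overrides or {}).items() if v is not None})
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    target_seed, chain_seed, thin_seed, metric_seed = rng.integers(2**31, size=4)

    d, n, m = cfg["d"], cfg["n"], cfg["m"]
    if name == "gaussian":
        mean = np.zeros(d)
        cov = 0.5 * np.eye(d) + 0.5  # equicorrelated, unit variance
        target = TargetSpec(mean=mean, cov=cov)
        chain = make_gaussian_chain(target, n, int(chain_seed), mode="iid")
        h = score_cv_matrix(chain, set_kind=cfg["cv"])
        eval_chain = chain
    else:
        target = make_truncated_params(d, int(target_seed))
        chain = truncated_gibbs_chain(target, n, int(chain_seed))
        h, eval_chain = gibbs_cv_matrix(chain)

    chain_path = write_chain(chain, outdir / f"{name}_chain.csv")
    ws = compute_weights(h)
    res = cube_thin(
        eval_chain, h, m, int(thin_seed),
        landing_strategy=cfg.get("landing", "suppression"),
        weights=ws,
    )
    write_weights(scale_weights(ws, m), outdir / f"{name}_weights.csv")
    sub_csv, sub_json = write_subsample(res, outdir / name)

    sub = signed_empirical(res, eval_chain.states)
    ref_stride = max(1, eval_chain.n // 2000)
    ref_states = eval_chain.states[::ref_stride]
    ref = SignedEmpirical(points=ref_states)
    metrics = {
        "energy_distance": energy_distance(ref, sub),
        "star_discrepancy": star_discrepancy(
            ref, sub, n_boxes=1024, seed=int(metric_seed)
        ),
    }
    if eval_chain.scores is not None:
        metrics["ksd"] = ksd(
            eval_chain.states[res.indices],
            eval_chain.scores[res.indices],
            weights=sub.weights,
        )
    manifest = {
        "demo": name,
        "package_version": __version__,
        "config": {k: int(v) if isinstance(v, (int, np.integer)) else v for k, v in cfg.items()},
        "seed": int(seed),
        "derived_seeds": {
            "target": int(target_seed),
            "chain": int(chain_seed),
            "thin": int(thin_seed),
            "metrics": int(metric_seed),
        },
        "omega": res.omega,
        "achieved_size": res.achieved_size,
        "metrics": metrics,
        "files": {
            "chain": str(chain_path),
            "weights": str(outdir / f"{name}_weights.csv"),
            "subsample": str(sub_csv),
            "subsample_meta": str(sub_json),
        },
    }
    (outdir / f"{name}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
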