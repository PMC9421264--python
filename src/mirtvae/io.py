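"""Reading and writing responses, ground truth and fit artifacts.

All artifacts are delimited text: responses as a persons x items CSV with
a header row of item ids and a configurable missing code (``NA`` by
default), matrices via pandas, and a YAML manifest recording the
configuration, seeds and sha256 checksums of every file written.  Data
zeros and missingness are never conflated: a missing cell is the missing
code string, never 0.
"""

from __future__ import annotations

import hashlib
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .encoder import EncoderState
from .estimator import MIRTVAE
from .model import ItemParameters, ResponseData
from .simulate import GroundTruth

MISSING_CODE = "NA"


def read_responses(path, missing_code: str = MISSING_CODE) -> ResponseData:
    """Parse a delimited response table into a :class:`ResponseData`.

    Cells must be ``0``, ``1`` or the missing code; anything else is
    rejected with its row/column location.  Ragged rows are rejected by
    the CSV parser.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    y = np.zeros(df.shape)
    mask = np.ones(df.shape)
    for j, col in enumerate(df.columns):
        for i, cell in enumerate(df[col]):
            cell = cell.strip()
            if cell == missing_code:
                mask[i, j] = 0.0
            elif cell in ("0", "1"):
                y[i, j] = float(cell)
            else:
                raise ValueError(
                    f"invalid response {cell!r} at row {i}, column {col!r}: "
                    f"expected 0, 1 or {missing_code!r}")
    return ResponseData(y=y, mask=mask, item_ids=list(df.columns))


def write_responses(data: ResponseData, path, missing_code: str = MISSING_CODE) -> None:
    cells = np.where(
        data.mask == 1.0,
        data.y.astype(int).astype(str),
        missing_code,
    )
    pd.DataFrame(cells, columns=data.item_ids).to_csv(path, index=False)


def _save(df_or_arr, path: Path) -> None:
    if isinstance(df_or_arr, pd.DataFrame):
        df_or_arr.to_csv(path, index=False)
    else:
        np.savetxt(path, np.atleast_2d(df_or_arr), delimiter=",")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir: Path, config: dict) -> Path:
    """Write ``manifest.yaml`` listing every artifact with its checksum."""
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.rglob("*")
                   if p.is_file() and p.name != "manifest.yaml")
    manifest = {
        "config": config,
        "written": datetime.now(timezone.utc).isoformat(),
        "artifacts": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    path = out_dir / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def write_ground_truth(truth: GroundTruth, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = truth.params
    _save(p.loadings, out / "loadings.csv")
    _save(p.intercepts, out / "intercepts.csv")
    _save(p.guessing, out / "guessing.csv")
    _save(p.upper, out / "upper.csv")
    _save(truth.theta, out / "theta.csv")
    _save(truth.sigma, out / "sigma.csv")
    _save(truth.pattern, out / "pattern.csv")
    write_manifest(out, {"model": p.model, "n_items": p.n_items,
                         "n_factors": p.n_factors})


def read_ground_truth(in_dir) -> GroundTruth:
    d = Path(in_dir)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    model = manifest["config"]["model"]
    load = lambda name: np.loadtxt(d / name, delimiter=",", ndmin=2)
    loadings = load("loadings.csv")
    intercepts = load("intercepts.csv").ravel()
    guessing = load("guessing.csv").ravel()
    upper = load("upper.csv").ravel()
    from .model import unconstrain

    params = ItemParameters(
        loadings=loadings,
        intercepts=intercepts,
        guessing_raw=None if model == "2pl" else unconstrain(np.clip(guessing, 1e-12, 1 - 1e-12)),
        upper_raw=None if model in ("2pl", "3pl") else unconstrain(np.clip(upper, 1e-12, 1 - 1e-12)),
        model=model,
    )
    return GroundTruth(
        params=params,
        theta=load("theta.csv"),
        sigma=load("sigma.csv"),
        pattern=load("pattern.csv"),
    )


def write_fit(est: MIRTVAE, out_dir, seed=None) -> None:
    """Persist a fitted estimator as delimited text plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _save(est.loadings_, out / "loadings.csv")
    _save(est.intercepts_, out / "intercepts.csv")
    _save(est.guessing_, out / "guessing.csv")
    _save(est.upper_asymptote_, out / "upper.csv")
    enc = est.encoder_
    for l, (w, b) in enumerate(zip(enc.weights, enc.biases)):
        _save(w, out / f"encoder_w{l}.csv")
        _save(b, out / f"encoder_b{l}.csv")
    _save(enc.w_mu, out / "encoder_w_mu.csv")
    _save(enc.b_mu, out / "encoder_b_mu.csv")
    _save(enc.w_logvar, out / "encoder_w_logvar.csv")
    _save(enc.b_logvar, out / "encoder_b_logvar.csv")
    rows = [
        {"stage": stage, "window": i + 1, "mean_objective": m}
        for stage, means in est.trace_.windows.items()
        for i, m in enumerate(means)
    ]
    pd.DataFrame(rows, columns=["stage", "window", "mean_objective"]).to_csv(
        out / "trace.csv", index=False)
    write_manifest(out, {
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in est.get_params().items()
                   if not isinstance(v, np.random.Generator)},
        "seed": seed,
        "n_hidden_layers": len(enc.weights),
        "n_iter_per_stage": est.n_iter_per_stage_,
        "success": bool(est.success_),
    })


def read_fit(in_dir) -> MIRTVAE:
    """Rehydrate a fitted estimator from :func:`write_fit` artifacts."""
    d = Path(in_dir)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text())
    cfg = manifest["config"]
    params_cfg = dict(cfg["params"])
    if isinstance(params_cfg.get("hidden_sizes"), list):
        params_cfg["hidden_sizes"] = tuple(params_cfg["hidden_sizes"])
    est = MIRTVAE(**params_cfg)
    load = lambda name: np.loadtxt(d / name, delimiter=",", ndmin=2)
    n_layers = cfg["n_hidden_layers"]
    enc = EncoderState(
        weights=[load(f"encoder_w{l}.csv") for l in range(n_layers)],
        biases=[load(f"encoder_b{l}.csv").ravel() for l in range(n_layers)],
        w_mu=load("encoder_w_mu.csv"),
        b_mu=load("encoder_b_mu.csv").ravel(),
        w_logvar=load("encoder_w_logvar.csv"),
        b_logvar=load("encoder_b_logvar.csv").ravel(),
    )
    from .model import unconstrain

    model = est.model
    loadings = load("loadings.csv")
    guessing = load("guessing.csv").ravel()
    upper = load("upper.csv").ravel()
    item_params = ItemParameters(
        loadings=loadings,
        intercepts=load("intercepts.csv").ravel(),
        guessing_raw=None if model == "2pl" else unconstrain(np.clip(guessing, 1e-12, 1 - 1e-12)),
        upper_raw=None if model in ("2pl", "3pl") else unconstrain(np.clip(upper, 1e-12, 1 - 1e-12)),
        model=model,
    )
    est.item_parameters_ = item_params
    est.encoder_ = enc
    est.loadings_ = item_params.loadings
    est.intercepts_ = item_params.intercepts
    est.guessing_ = item_params.guessing
    est.upper_asymptote_ = item_params.upper
    est.n_iter_per_stage_ = cfg["n_iter_per_stage"]
    est.success_ = cfg["success"]
    est.n_features_in_ = item_params.n_items
    return est
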