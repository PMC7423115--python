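"""Readers, writers and run configuration for the trajectory pipeline.

All interchange formats are plain UTF-8 CSV/JSON with "." as the decimal
separator.  Every JSON artifact carries the hash of the run configuration
that produced it; CSV outputs are covered by a ``run_manifest.json``
written alongside them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exposure import AnnualSeries, ExposureEpisode, JEMEntry
from .lcmm import LCMMFit, LCMMParams, LCMMSpec
from .splines import TimeBasis

__all__ = [
    "read_subjects",
    "read_episodes",
    "read_jem",
    "read_series",
    "write_series",
    "series_to_frame",
    "frame_to_series",
    "fit_to_dict",
    "params_from_dict",
    "posterior_frame",
    "config_hash",
    "write_manifest",
]

_SUBJECT_COLS = ["subject_id", "outcome", "age_index", "stratum", "index_year"]
_EPISODE_COLS = ["subject_id", "exposure_type", "start_year", "end_year", "intensity", "job_code"]
_JEM_COLS = ["job_code", "period_start", "period_end", "probability", "frequency", "intensity"]
_SERIES_COLS = ["subject_id", "t_before_index", "value"]


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def read_subjects(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, _SUBJECT_COLS[:4], path)
    bad = df.index[~df["outcome"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"{path}: outcome must be 0/1 (rows {list(bad[:5])})")
    df["subject_id"] = df["subject_id"].astype(str)
    return df


def read_episodes(path) -> dict[str, list[ExposureEpisode]]:
    df = pd.read_csv(path)
    _require(df, _EPISODE_COLS[:4], path)
    out: dict[str, list[ExposureEpisode]] = {}
    for i, row in df.iterrows():
        try:
            ep = ExposureEpisode(
                int(row["start_year"]),
                int(row["end_year"]),
                float(row.get("intensity", 0.0) or 0.0),
                None if pd.isna(row.get("job_code")) else str(row["job_code"]),
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: row {i}: {err}") from err
        out.setdefault(str(row["subject_id"]), []).append(ep)
    return out


def read_jem(path) -> list[JEMEntry]:
    df = pd.read_csv(path)
    _require(df, _JEM_COLS, path)
    entries = []
    for i, row in df.iterrows():
        try:
            entries.append(
                JEMEntry(
                    str(row["job_code"]),
                    int(row["period_start"]),
                    int(row["period_end"]),
                    float(row["probability"]),
                    float(row["frequency"]),
                    float(row["intensity"]),
                )
            )
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path}: row {i}: {err}") from err
    return entries


def series_to_frame(series: list[AnnualSeries]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": np.repeat([s.subject_id for s in series], [len(s) for s in series]),
            "t_before_index": np.concatenate([s.times for s in series]),
            "value": np.concatenate([s.values for s in series]),
        }
    )


def frame_to_series(df: pd.DataFrame) -> list[AnnualSeries]:
    _require(df, _SERIES_COLS, "series frame")
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        g = grp.sort_values("t_before_index")
        out.append(
            AnnualSeries(str(sid), g["t_before_index"].to_numpy(float), g["value"].to_numpy(float))
        )
    return out


def read_series(path) -> list[AnnualSeries]:
    return frame_to_series(pd.read_csv(path))


def write_series(series: list[AnnualSeries], path) -> None:
    series_to_frame(series).to_csv(path, index=False)


def fit_to_dict(fit: LCMMFit, cfg_hash: str = "") -> dict:
    """JSON-serializable summary of an LCMM fit."""
    p = fit.params
    return {
        "config_hash": cfg_hash,
        "n_classes": p.n_classes,
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "AIC": fit.aic,
        "BIC": fit.bic,
        "converged": bool(fit.converged),
        "criteria": {k: (bool(v) if isinstance(v, (bool, np.bool_)) else float(v))
                     for k, v in fit.criteria.items()},
        "class_probs": p.class_probs.tolist(),
        "params": {
            "xi": p.xi.tolist(),
            "beta": p.beta.tolist(),
            "sigma": p.sigma.tolist(),
            "link_weights": p.link_weights.tolist(),
            "x_scale": p.x_scale.tolist(),
            "sigma_eps": p.sigma_eps,
        },
        "spec": {
            "n_classes": fit.spec.n_classes,
            "link_knots": list(fit.spec.link_knots),
            "link_order": fit.spec.link_order,
            "time_inner_knots": list(fit.spec.time_basis.inner_knots),
            "time_boundary_knots": list(fit.spec.time_basis.boundary_knots),
            "n_starts": fit.spec.n_starts,
            "seed": fit.spec.seed,
        },
    }


def params_from_dict(d: dict) -> tuple[LCMMParams, LCMMSpec]:
    pd_ = d["params"]
    params = LCMMParams(
        np.asarray(pd_["xi"], float),
        np.asarray(pd_["beta"], float),
        np.asarray(pd_["sigma"], float),
        np.asarray(pd_["link_weights"], float),
        np.asarray(pd_["x_scale"], float),
        float(pd_.get("sigma_eps", 1.0)),
    )
    s = d["spec"]
    spec = LCMMSpec(
        n_classes=int(s["n_classes"]),
        time_basis=TimeBasis(tuple(s["time_inner_knots"]), tuple(s["time_boundary_knots"])),
        link_knots=tuple(s["link_knots"]),
        link_order=int(s["link_order"]),
        n_starts=int(s["n_starts"]),
        seed=int(s["seed"]),
    )
    return params, spec


def posterior_frame(fit: LCMMFit) -> pd.DataFrame:
    G = fit.params.n_classes
    df = pd.DataFrame(fit.posterior, columns=[f"p_{g + 1}" for g in range(G)])
    df.insert(0, "subject_id", fit.subject_ids)
    df["modal_class"] = fit.modal_class + 1
    return df


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, config: dict, files: list[str]) -> str:
    """Write run_manifest.json carrying the config hash that covers all
    CSV outputs of the run; returns the hash."""
    h = config_hash(config)
    manifest = {"config_hash": h, "config": config, "files": sorted(files)}
    Path(out_dir, "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return h
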