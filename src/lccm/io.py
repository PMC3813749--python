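"""Readers/writers for waveforms, configurations and result reports.

Time series travel as two-column CSV (``time_s,amplitude``), structured
results as JSON, and human-edited configurations as YAML.  No binary
formats.  Every artifact written by the CLI embeds the seed and a hash of
the configuration that produced it, so runs are reproducible bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .circuits import SourceWaveform
from .inversion import Posterior, connection_nonzero

__all__ = [
    "waveform_to_csv",
    "waveform_from_csv",
    "load_yaml",
    "save_json",
    "config_hash",
    "posterior_report",
]


def waveform_to_csv(wf: SourceWaveform, path: str | Path, metadata: dict | None = None) -> None:
    """Write a waveform as ``time_s,amplitude`` CSV plus a JSON sidecar."""
    path = Path(path)
    # %.17g round-trips float64 exactly through text
    pd.DataFrame({"time_s": wf.t, "amplitude": wf.y}).to_csv(
        path, index=False, float_format="%.17g"
    )
    meta = {"fs_hz": wf.fs, "normalized": wf.normalized}
    if metadata:
        meta.update(metadata)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def waveform_from_csv(path: str | Path) -> SourceWaveform:
    """Read a ``time_s,amplitude`` CSV; the JSON sidecar is optional."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"time_s", "amplitude"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s,amplitude")
    t = df["time_s"].to_numpy(dtype=float)
    y = df["amplitude"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: waveform must be uniformly sampled")
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fs = float(meta.get("fs_hz", 1.0 / dt[0]))
    return SourceWaveform(t=t, y=y, fs=fs, normalized=bool(meta.get("normalized", False)))


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=_jsonify).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def posterior_report(post: Posterior) -> dict:
    """JSON-ready summary: latent means/sds, natural values, evidence, decisions."""
    report = {
        "eta": post.eta.tolist(),
        "sd": post.sd().tolist(),
        "names": post.names,
        "F": post.F,
        "lambda": post.lam,
        "n_iter": post.n_iter,
        "converged": post.converged,
    }
    if post.priors is not None:
        report["natural_values"] = post.naturals()
        decisions = {}
        for p in post.priors:
            if p.reparam == "square":
                decisions[p.name] = connection_nonzero(post, p.name)
        report["nonzero_decisions"] = decisions
    return report
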