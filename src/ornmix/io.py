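"""Configuration files, CSV schemas and run manifests.

Configs are JSON or YAML mappings (chosen by file extension).  Profile
tables use tidy CSV: single-receptor profiles carry columns
``odorant_id, receptor_id, kappa, eta`` (plus optional masking columns
``KM, mu, m``); ensemble profiles carry
``odorant_id, receptor_id, log_kappa_inv, log_eta``.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import OdorantEnsembleProfile
from .masking import MaskedOdorant, MaskingProfile
from .steady_state import SteadyStateProfile

__all__ = [
    "load_config",
    "save_config",
    "write_manifest",
    "profiles_to_frame",
    "frame_to_profiles",
    "ensemble_to_frame",
    "frame_to_ensemble",
]


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=False))


def write_manifest(outdir, experiment: str, config: dict, seed: int,
                   substreams: list[str], runtime_s: float,
                   outputs: list[str]) -> Path:
    """JSON manifest echoing everything needed to reproduce a run."""
    import ornmix

    manifest = {
        "experiment": experiment,
        "config": config,
        "seed": int(seed),
        "substreams": substreams,
        "outputs": outputs,
        "runtime_s": round(runtime_s, 3),
        "versions": {
            "ornmix": ornmix.__version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = Path(outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def profiles_to_frame(profiles: dict) -> pd.DataFrame:
    """{odorant_id: SteadyStateProfile | MaskedOdorant} -> tidy frame."""
    rows = []
    for oid, prof in profiles.items():
        if isinstance(prof, MaskedOdorant):
            rows.append({"odorant_id": oid, "receptor_id": 0,
                         "kappa": prof.receptor.kappa, "eta": prof.receptor.eta,
                         "KM": prof.masking.KM, "mu": prof.masking.mu,
                         "m": prof.masking.m})
        else:
            rows.append({"odorant_id": oid, "receptor_id": 0,
                         "kappa": prof.kappa, "eta": prof.eta})
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> dict:
    out = {}
    masked = {"KM", "mu", "m"} <= set(df.columns)
    for _, row in df.iterrows():
        prof = SteadyStateProfile(float(row["kappa"]), float(row["eta"]))
        if masked and not np.isnan(row["KM"]):
            prof = MaskedOdorant(prof, MaskingProfile(
                KM=float(row["KM"]), mu=float(row["mu"]), m=float(row["m"])))
        out[row["odorant_id"]] = prof
    return out


def ensemble_to_frame(profiles: dict) -> pd.DataFrame:
    """{odorant_id: OdorantEnsembleProfile} -> tidy frame."""
    rows = []
    for oid, prof in profiles.items():
        for r in range(prof.N):
            rows.append({"odorant_id": oid, "receptor_id": r,
                         "log_kappa_inv": prof.log_kappa_inv[r],
                         "log_eta": prof.log_eta[r]})
    return pd.DataFrame(rows)


def frame_to_ensemble(df: pd.DataFrame) -> dict:
    out = {}
    for oid, grp in df.groupby("odorant_id", sort=False):
        grp = grp.sort_values("receptor_id")
        out[oid] = OdorantEnsembleProfile(grp["log_kappa_inv"].to_numpy(),
                                          grp["log_eta"].to_numpy())
    return out
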