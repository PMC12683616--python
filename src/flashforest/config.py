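"""Run configuration and file I/O.

The run configuration is a flat YAML-compatible key-value file.  Every
key has a documented default; unknown keys and out-of-range values are
rejected with all failures reported together.  Tables are CSV throughout;
a metadata record (config, seed, package version) accompanies every run's
outputs so any run is reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .demography import MortalityParams
from .lightning import LightningParams
from .physiology import PhysiologyParams
from .simulate import RunOutputs

__all__ = ["RunConfig", "load_config", "save_config", "write_outputs", "ConfigError"]


class ConfigError(ValueError):
    """Raised with every validation failure collected into one message."""


_DEFAULTS = {
    "width": 200,
    "length": 200,
    "height": 50,
    "years": 600,
    "averaging_years": 50,
    "mode": "none",
    "seed": 0,
    "toroidal": True,
    "species_file": None,
    "forcing_file": None,
    "mortality_file": None,
    "output_dir": "outputs",
    # lightning
    "lam": 12.7,
    "a": -3.0,
    "p_direct": 0.85,
    "d": 0.5,
    "r_max": 25.0,
    "search_radius": 15.0,
    # physiology
    "phi": 0.06,
    "f_below": 0.25,
    "f_wood": 0.45,
    "f_canopy": 0.30,
    "k_ext": 0.5,
    # mortality
    "m0": 0.015,
    "treefall_height_scale": 38.0,
    "treefall_max_prob": 0.0025,
}


@dataclass
class RunConfig:
    """Validated run configuration with defaults for every field."""

    width: int = 200
    length: int = 200
    height: int = 50
    years: int = 600
    averaging_years: int = 50
    mode: str = "none"
    seed: int = 0
    toroidal: bool = True
    species_file: str | None = None
    forcing_file: str | None = None
    mortality_file: str | None = None
    output_dir: str = "outputs"
    lam: float = 12.7
    a: float = -3.0
    p_direct: float = 0.85
    d: float = 0.5
    r_max: float = 25.0
    search_radius: float = 15.0
    phi: float = 0.06
    f_below: float = 0.25
    f_wood: float = 0.45
    f_canopy: float = 0.30
    k_ext: float = 0.5
    m0: float = 0.015
    treefall_height_scale: float = 38.0
    treefall_max_prob: float = 0.0025

    def lightning_params(self) -> LightningParams:
        return LightningParams(
            lam=self.lam if self.mode != "none" else 0.0,
            a=self.a,
            p_direct=self.p_direct,
            d=self.d,
            mode=self.mode,
            r_max=self.r_max,
            search_radius=self.search_radius,
        )

    def physiology_params(self) -> PhysiologyParams:
        return PhysiologyParams(
            phi=self.phi,
            f_below=self.f_below,
            f_wood=self.f_wood,
            f_canopy=self.f_canopy,
            k_ext=self.k_ext,
        )

    def mortality_params(self) -> MortalityParams:
        return MortalityParams(
            m0=self.m0,
            treefall_height_scale=self.treefall_height_scale,
            treefall_max_prob=self.treefall_max_prob,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _validate(raw: dict) -> list[str]:
    errors = []
    unknown = set(raw) - set(_DEFAULTS)
    for k in sorted(unknown):
        errors.append(f"unknown key: {k}")
    merged = {**_DEFAULTS, **{k: v for k, v in raw.items() if k in _DEFAULTS}}
    for k in ("width", "length", "height", "years"):
        v = merged[k]
        if not (isinstance(v, int) and v > 0):
            errors.append(f"{k} must be a positive integer, got {v!r}")
    if merged["mode"] not in ("none", "CLLR", "SSLR"):
        errors.append(f"mode must be none|CLLR|SSLR, got {merged['mode']!r}")
    if isinstance(merged["years"], int) and isinstance(merged["averaging_years"], int):
        if merged["averaging_years"] > merged["years"]:
            errors.append("averaging_years must not exceed years")
    for k, lo, hi in (
        ("p_direct", 0.0, 1.0),
        ("d", 0.0, 1.0),
        ("phi", 1e-9, 0.1),
        ("m0", 0.0, 0.03),
    ):
        v = merged[k]
        if not (isinstance(v, (int, float)) and lo <= v <= hi):
            errors.append(f"{k} must be in [{lo}, {hi}], got {v!r}")
    if not (isinstance(merged["lam"], (int, float)) and merged["lam"] >= 0):
        errors.append(f"lam must be >= 0, got {merged['lam']!r}")
    if merged["mode"] == "SSLR" and merged["species_file"] is not None:
        try:
            cols = pd.read_csv(merged["species_file"], nrows=0).columns
            if "delta_i" not in cols:
                errors.append(
                    "mode SSLR requires a species table with a delta_i column"
                )
        except OSError as exc:
            errors.append(f"species_file unreadable: {exc}")
    return errors


def load_config(path) -> RunConfig:
    """Load and validate a run configuration file.

    An empty file yields the full-default configuration (no lightning,
    200 x 200 m, 600 years).  All validation failures are reported in one
    exception.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a key-value mapping, got {type(raw).__name__}")
    errors = _validate(raw)
    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))
    merged = {**_DEFAULTS, **raw}
    return RunConfig(**merged)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def write_outputs(outputs: RunOutputs, cfg: RunConfig, out_dir, event_log=None) -> dict:
    """Write the run's tables and metadata; returns the paths written.

    Files: annual_state.csv (year, AGB, GPP, N10, N30, N60, ...),
    species_agb.csv, lightning_events.csv (header-only when no strikes),
    run_metadata.json (config, its digest, and the seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["annual"] = out / "annual_state.csv"
    outputs.annual.to_csv(paths["annual"], index=False)

    paths["species_agb"] = out / "species_agb.csv"
    outputs.species_agb.rename("agb_mg_ha").to_csv(paths["species_agb"], index_label="species_id")

    paths["events"] = out / "lightning_events.csv"
    ev = pd.DataFrame(
        event_log or [], columns=["year", "month", "x", "y", "target_species", "n_killed"]
    )
    ev.to_csv(paths["events"], index=False)

    paths["metadata"] = out / "run_metadata.json"
    meta = {
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "summary": {
            **outputs.metrics(),
            "strikes": outputs.strikes,
            "lightning_kills": outputs.lightning_kills,
            "kills_per_strike": outputs.kills_per_strike,
            "deaths_by_cause": outputs.deaths_by_cause,
        },
    }
    paths["metadata"].write_text(json.dumps(meta, indent=2))
    return {k: str(v) for k, v in paths.items()}
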