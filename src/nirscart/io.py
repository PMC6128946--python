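"""File formats: wide-CSV spectra with a JSON sidecar manifest, reference
tables, fit/selection JSON, and YAML/JSON run configuration."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .study import ARM_A_GRID, ARM_B_GRID, PROPERTY_NAMES, SpectraSet, StudyDesign

_META_COLS = ["pony", "joint", "location", "group", "distance_class", "modality",
              "repeat_index"]


def _channel_columns() -> list[str]:
    cols = [f"a_{w:.4f}" for w in ARM_A_GRID]
    cols += [f"b_{w:.4f}" for w in ARM_B_GRID]
    return cols


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """One row per acquisition: metadata columns, then one column per channel
    named by arm and wavelength in um with 4 decimals."""
    meta = spectra.meta.reindex(columns=_META_COLS)
    wide = pd.DataFrame(
        np.concatenate([spectra.arm_a, spectra.arm_b], axis=1),
        columns=_channel_columns(),
    )
    pd.concat([meta.reset_index(drop=True), wide], axis=1).to_csv(path, index=False)


def read_spectra_csv(path) -> SpectraSet:
    df = pd.read_csv(path)
    chan = _channel_columns()
    missing = [c for c in chan if c not in df.columns]
    if missing:
        raise ValueError(
            f"spectra file does not match the study grids ({len(missing)} channels missing)"
        )
    values = df[chan].to_numpy(dtype=float)
    na = ARM_A_GRID.size
    return SpectraSet(
        arm_a=values[:, :na],
        arm_b=values[:, na:],
        meta=df[[c for c in _META_COLS if c in df.columns]].copy(),
    )


def write_manifest(path, design: StudyDesign, seed: int, extra: dict | None = None) -> None:
    manifest = {
        "seed": int(seed),
        "design": {
            "n_repair_ponies": design.n_repair_ponies,
            "n_control_ponies": design.n_control_ponies,
            "joints_per_pony": design.joints_per_pony,
            "locations_per_joint": design.locations_per_joint,
            "n_unreachable": design.n_unreachable,
            "unreachable": sorted(map(list, design.resolve_unreachable())),
        },
        "grids": {
            "arm_a_um": [float(ARM_A_GRID[0]), float(ARM_A_GRID[-1]), float(ARM_A_GRID[1] - ARM_A_GRID[0])],
            "arm_b_um": [float(ARM_B_GRID[0]), float(ARM_B_GRID[-1]), float(ARM_B_GRID[1] - ARM_B_GRID[0])],
        },
        **(extra or {}),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def write_references_csv(references: pd.DataFrame, path) -> None:
    cols = [c for c in references.columns if not c.startswith("latent_")]
    references[cols].to_csv(path, index=False)


def read_references_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [p for p in PROPERTY_NAMES if p not in df.columns]
    if missing:
        raise ValueError(f"reference table missing properties: {missing}")
    return df


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(config: dict, path) -> None:
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(config, indent=1, sort_keys=True))
    else:
        Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
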