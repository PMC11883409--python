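"""Delimited-table schemas, run configuration, and report serialization.

All tables are CSV with a header row followed by a units row (first column
``#units``); times are seconds from adaptation onset, positions metres, forces
newtons, moments newton-metres, gas volumes ml min^-1.  Reading validates the
declared schema (required columns, strictly increasing unique time stamps).
Configuration is YAML with unknown keys rejected; reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["SCHEMAS", "write_table", "read_table", "RunConfig", "load_config",
           "write_report"]

SCHEMAS: dict[str, dict] = {
    "markers": {
        "columns": ["t", "ankle_L_x", "ankle_L_y", "ankle_L_z",
                    "ankle_R_x", "ankle_R_y", "ankle_R_z",
                    "asis_L_y", "asis_R_y"],
        "units": ["s"] + ["m"] * 8,
        "time": "t",
    },
    "forces": {
        "columns": ["t"] + [f"{leg}_{c}" for leg in ("fast", "slow")
                            for c in ("Fx", "Fy", "Fz", "Mx", "My", "Mz")],
        "units": ["s"] + (["N"] * 3 + ["N.m"] * 3) * 2,
        "time": "t",
    },
    "breaths": {
        "columns": ["t", "vo2_ml_min", "vco2_ml_min"],
        "units": ["s", "ml.min-1", "ml.min-1"],
        "time": "t",
    },
    "subjects": {
        "columns": ["id", "mass_kg", "height_m", "leg_length_m", "vo2peak", "gender"],
        "units": ["-", "kg", "m", "m", "ml.kg-1.min-1", "-"],
        "time": None,
    },
    "strides": {
        "columns": ["subject", "t", "duration", "step_length_fast",
                    "step_length_slow", "sla", "mos_fast", "mos_slow",
                    "w_pos_fast", "w_neg_fast", "w_pos_slow", "w_neg_slow", "w_net"],
        "units": ["-", "s", "s", "m", "m", "-", "cm", "cm", "W", "W", "W", "W", "W"],
        "time": None,
    },
    "measures": {
        "columns": ["subject", "measure", "t", "value"],
        "units": ["-", "-", "s", "(measure)"],
        "time": None,
    },
    "epochs": {
        "columns": ["subject", "epoch", "bin", "bin_mid", "sla", "mos_fast",
                    "mos_slow", "w_net", "w_net_metabolic"],
        "units": ["-", "-", "-", "s", "-", "cm", "cm", "W", "W"],
        "time": None,
    },
    "fitness": {
        "columns": ["subject", "vo2peak", "gender", "vo2peak_centered",
                    "delta_sla", "delta_metabolic"],
        "units": ["-", "ml.kg-1.min-1", "-", "ml.kg-1.min-1", "-", "W.kg-1"],
        "time": None,
    },
}


def write_table(df: pd.DataFrame, path, schema_id: str) -> None:
    """CSV writer: header, units row, then data, restricted to the schema."""
    schema = SCHEMAS[schema_id]
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"{schema_id} table missing column(s): {', '.join(missing)}")
    out = df[schema["columns"]]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(",".join(schema["columns"]) + "\n")
        fh.write(",".join(["#units"] + schema["units"][1:]) + "\n")
        out.to_csv(fh, index=False, header=False, float_format="%.10g")


def read_table(path, schema_id: str) -> pd.DataFrame:
    """Validated CSV reader for a declared schema."""
    schema = SCHEMAS[schema_id]
    head = pd.read_csv(path, nrows=0)
    missing = [c for c in schema["columns"] if c not in head.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing column(s): {', '.join(missing)}")
    df = pd.read_csv(path, skiprows=[1])
    tcol = schema["time"]
    if tcol is not None:
        t = df[tcol].to_numpy(float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            kind = "duplicated" if np.any(dt == 0) else "non-monotonic"
            raise ValueError(f"{Path(path).name}: {kind} timestamps in column {tcol!r}")
    return df


_CONFIG_DOC = {
    # every default documented here; unknown keys are rejected on load
    "seed": 0,
    "n_subjects": 17,
    "duration": 1200.0,  # s of adaptation
    "stride_period": 1.1,  # s
    "breath_period": 4.0,  # s
    "belt_speeds": [1.5, 0.5],  # m s^-1 (fast, slow)
    "kinematic_cutoff": 6.0,  # Hz, 4th-order zero-phase Butterworth
    "force_cutoff": 20.0,  # Hz
    "force_threshold": 20.0,  # N, gait-event threshold
    "drift_cutoff": 0.4,  # Hz, CoM complementary-filter crossover
    "metabolic_lag": 180.0,  # s, epoch shift for metabolic data
    "epoch_bin": 3.0,  # s (5.0 also used in the literature)
    "measures": ["sla", "step_length_fast", "step_length_slow", "mos_fast",
                 "mos_slow", "metabolic_rate", "work_net"],
    "replicates": 1,
    "out_dir": "results",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``_CONFIG_DOC`` for defaults)."""

    seed: int = 0
    n_subjects: int = 17
    duration: float = 1200.0
    stride_period: float = 1.1
    breath_period: float = 4.0
    belt_speeds: tuple = (1.5, 0.5)
    kinematic_cutoff: float = 6.0
    force_cutoff: float = 20.0
    force_threshold: float = 20.0
    drift_cutoff: float = 0.4
    metabolic_lag: float = 180.0
    epoch_bin: float = 3.0
    measures: list = field(default_factory=lambda: list(_CONFIG_DOC["measures"]))
    replicates: int = 1
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.kinematic_cutoff <= 0 or self.force_cutoff <= 0:
            raise ValueError("filter cutoffs must be positive")
        if self.epoch_bin <= 0:
            raise ValueError("epoch_bin must be positive")
        self.belt_speeds = tuple(self.belt_speeds)


def load_config(path=None, **overrides) -> RunConfig:
    """Load YAML config; unknown keys raise, omitted keys use defaults."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    unknown = set(raw) - set(_CONFIG_DOC)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**raw)


def write_report(obj, path) -> None:
    """JSON report writer tolerant of numpy scalars and dataclasses."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {k: v for k, v in dataclasses.asdict(o).items()
                    if not isinstance(v, pd.DataFrame)}
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        return str(o)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=default, allow_nan=True))
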