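"""File schemas, table round-trips and run manifests.

All tabular outputs are UTF-8 CSV with a mandatory header row and "." as
the decimal separator.  Every file written by the pipeline starts with a
single ``#`` comment line carrying the master seed and a hash of the
configuration, so a run can be traced back to its inputs; readers skip
comment lines.  Schemas are validated on read: column order is free,
missing columns are an error naming them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from mbondecode.config import RunConfig
from mbondecode.traces import FluorescenceTrace

TRACE_SCHEMA = (
    "fly_id", "mbon_type", "protocol", "phase", "odor", "cs_role",
    "time_s", "fluorescence", "onset_time",
)
AUC_SCHEMA = (
    "fly_id", "mbon_type", "protocol", "phase", "odor", "cs_role",
    "auc", "normalized_auc", "is_responder", "qc_flag",
)
LANE_SCHEMA = (
    "genotype", "temperature", "pair", "reciprocal_id",
    "n_csplus_side", "n_csminus_side",
)


class SchemaError(ValueError):
    """A table is missing required columns; the message lists them."""


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a JSON-serializable config echo."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def traces_to_frame(traces: list[FluorescenceTrace]) -> pd.DataFrame:
    """Long-format trace table: one row per frame."""
    parts = []
    for tr in traces:
        n = tr.times.size
        parts.append(
            pd.DataFrame(
                {
                    "fly_id": np.repeat(tr.fly_id, n),
                    "mbon_type": np.repeat(tr.mbon_type, n),
                    "protocol": np.repeat(tr.protocol, n),
                    "phase": np.repeat(tr.phase, n),
                    "odor": np.repeat(tr.odor, n),
                    "cs_role": np.repeat(tr.cs_role, n),
                    "time_s": tr.times,
                    "fluorescence": tr.values,
                    "onset_time": np.repeat(tr.onset_time, n),
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[FluorescenceTrace]:
    """Rebuild trace objects from a long-format table."""
    validate_schema(df, TRACE_SCHEMA, "trace table")
    traces = []
    key_cols = ["fly_id", "mbon_type", "protocol", "phase", "odor", "cs_role"]
    for key, sub in df.groupby(key_cols, sort=False):
        sub = sub.sort_values("time_s")
        meta = dict(zip(key_cols, key))
        traces.append(
            FluorescenceTrace(
                times=sub["time_s"].to_numpy(float),
                values=sub["fluorescence"].to_numpy(float),
                onset_time=float(sub["onset_time"].iloc[0]),
                **meta,
            )
        )
    return traces


def validate_schema(df: pd.DataFrame, schema: tuple[str, ...], what: str) -> None:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def write_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None,
    cfg_hash: str | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# mbondecode seed={seed} config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path, schema: tuple[str, ...], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    validate_schema(df, schema, what)
    return df


def write_manifest(path: str | Path, config_dict: dict, seed: int) -> str:
    """Write a manifest JSON echoing the configuration; returns its hash."""
    h = config_hash(config_dict)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"seed": seed, "config_hash": h, "config": config_dict}
    path.write_text(json.dumps(payload, indent=2, default=str, sort_keys=True))
    return h


def read_roi_stack(
    stack_path: str | Path, mask_path: str | Path
) -> tuple["np.ndarray", "np.ndarray"]:
    """Read a multi-frame TIFF stack and a single-frame mask image.

    The mask image is binarized (> 0 selects the ROI).
    """
    import tifffile

    stack = np.asarray(tifffile.imread(stack_path))
    mask = np.asarray(tifffile.imread(mask_path)) > 0
    if stack.ndim == 2:
        stack = stack[None]
    return stack, mask


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON) run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise SchemaError(f"config file {path} must contain a mapping")
    return RunConfig.from_dict(data)
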