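"""Readers/writers for trial data and results, plus run configuration.

Trial data travel as long-format comma-separated text with one row per item
per trial: ``observer, condition, trial, order, item_id, x, y, item_class``.
``order`` is 1-based over the selected items; rows with ``order == 0`` are
inventory items that were never selected (inexhaustive designs).  Item
classes are the two-level labels 'A' and 'B'.

Coordinates are stored in the mathematical convention (y up).  Data
recorded in screen coordinates (y down) must be flipped on read
(``y_down=True``) so that the "up"/"down" direction weights keep their
meaning.

Every writer leaves a JSON sidecar recording the package version, seed,
resolved configuration and its hash, so outputs are traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import DataValidationError, InvalidParameterError, build_model

__all__ = [
    "RunConfig",
    "load_config",
    "config_hash",
    "read_trials",
    "write_trials",
    "write_results",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = (
    "observer",
    "condition",
    "trial",
    "order",
    "item_id",
    "x",
    "y",
    "item_class",
)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved hyperparameters of a pipeline run."""

    version: str = "v1.3"
    kappa: float = 20.0
    delta0: float = 20.0
    seed: int = 0
    backend: str = "map"
    n_draws: int = 1000

    def __post_init__(self) -> None:
        build_model(self.version)
        if self.kappa <= 0:
            raise InvalidParameterError("kappa must be positive")
        if self.delta0 <= 0:
            raise InvalidParameterError("delta0 must be positive")
        if self.backend not in ("map", "mcmc"):
            raise InvalidParameterError("backend must be 'map' or 'mcmc'")


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; defaults apply, overrides win, unknown keys fail."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark is not None else ""
            raise DataValidationError(f"malformed config file{line}: {exc}") from exc
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise DataValidationError("config file must contain a mapping")
            data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise DataValidationError(
            f"unknown config keys {sorted(unknown)}; known keys: {sorted(known)}"
        )
    return RunConfig(**data)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Trial tables
# ---------------------------------------------------------------------------

def _validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"missing required columns: {sorted(missing)}")
    bad_class = ~df["item_class"].isin(["A", "B"])
    if bad_class.any():
        rows = df.index[bad_class][:10].tolist()
        raise DataValidationError(
            f"unknown item_class values at rows {rows} "
            f"(expected 'A' or 'B')"
        )
    if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
        raise DataValidationError("non-finite coordinates in trial data")
    for (obs, cond, trial), g in df.groupby(["observer", "condition", "trial"]):
        sel = g[g["order"] > 0]
        orders = np.sort(sel["order"].to_numpy())
        if len(orders) == 0:
            raise DataValidationError(
                f"trial ({obs}, {cond}, {trial}) has no selections"
            )
        if not np.array_equal(orders, np.arange(1, len(orders) + 1)):
            dup = sel[sel["order"].duplicated()].index.tolist()
            raise DataValidationError(
                f"trial ({obs}, {cond}, {trial}): selection order must be "
                f"1..k without gaps or duplicates (offending rows {dup})"
            )
        if g["item_id"].duplicated().any():
            rows = g.index[g["item_id"].duplicated()].tolist()
            raise DataValidationError(
                f"trial ({obs}, {cond}, {trial}): duplicate item ids "
                f"at rows {rows}"
            )
    return df


def read_trials(
    path,
    y_down: bool = False,
    column_map: dict | None = None,
) -> pd.DataFrame:
    """Read and validate a long-format trial table.

    ``column_map`` renames input columns to the required schema;
    ``y_down=True`` declares screen coordinates and flips y to the
    mathematical convention.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    df = _validate_trials(df)
    df = df.copy()
    df["order"] = df["order"].astype(int)
    df["item_id"] = df["item_id"].astype(int)
    df["trial"] = df["trial"].astype(int)
    if y_down:
        df["y"] = -df["y"].astype(float)
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table with deterministic column order."""
    cols = [c for c in REQUIRED_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def _sidecar(path: Path, config: RunConfig | None, seed=None, extra=None) -> None:
    meta = {
        "package": "fomo",
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    if config is not None:
        meta["config"] = asdict(config)
        meta["config_hash"] = config_hash(config)
    if seed is not None:
        meta["seed"] = int(seed)
    if extra:
        meta.update(extra)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )


def write_results(obj, path, config: RunConfig | None = None, seed=None) -> None:
    """Write a results object to delimited text with a metadata sidecar.

    DataFrames go to a single CSV; a fitted :class:`~fomo.inference.Posterior`
    writes ``<stem>_draws.csv``, ``<stem>_summary.csv`` and
    ``<stem>_participant.csv``.  Floats are written at full precision.
    """
    from .inference import Posterior

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False, float_format="%.17g")
        _sidecar(path, config, seed)
    elif isinstance(obj, Posterior):
        stem = path.with_suffix("")
        obj.draws.to_csv(f"{stem}_draws.csv", index=False, float_format="%.17g")
        obj.summary.to_csv(f"{stem}_summary.csv", index=False, float_format="%.17g")
        obj.participant.to_csv(f"{stem}_participant.csv", index=False, float_format="%.17g")
        _sidecar(
            Path(f"{stem}_draws.csv"),
            config,
            obj.seed,
            extra={
                "model_version": obj.version,
                "diagnostics": {
                    k: v
                    for k, v in obj.diagnostics.items()
                    if isinstance(v, (str, int, float, bool))
                },
            },
        )
    else:
        raise InvalidParameterError(
            f"cannot serialise object of type {type(obj).__name__}"
        )
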