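"""CSV/EDF readers and writers plus config and manifest helpers.

Cohort CSV contract: one row per visitor; required columns ``id, p, a, d``;
optional item-level columns ``item_1..item_k`` and demographic columns
(gender, age_group, education, occupation, income_band, seat_position,
travel_mode); UTF-8, header required, decimal point. Numeric values round-
trip at full precision. Unknown columns are preserved.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .eeg import BAND_NAMES, EEGRecording
from .emotions import ValidationError

__all__ = [
    "read_cohort",
    "write_cohort",
    "load_reference_cohort",
    "read_features",
    "write_features",
    "read_eeg_csv",
    "write_eeg_csv",
    "read_eeg_edf",
    "load_yaml_config",
    "config_hash",
    "build_manifest",
]

REQUIRED_COHORT_COLUMNS = ("id", "p", "a", "d")


def read_cohort(path: str | Path, require_scores: bool = True) -> pd.DataFrame:
    """Read a visitor cohort CSV, validating required columns and numerics."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"cohort file {path} is empty") from None
    if df.empty:
        raise ValidationError(f"cohort file {path} contains no visitor rows")
    required = REQUIRED_COHORT_COLUMNS if require_scores else ("id",)
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"cohort file {path} missing column {col!r}")
    for col in ("p", "a", "d"):
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & (df[col].astype(str).str.len() > 0)
        if bad.any() or parsed.isna().any():
            row = int(np.argmax((parsed.isna()).to_numpy()))
            # +2: header line plus 1-based indexing
            raise ValidationError(
                f"non-numeric {col!r} value {df[col].iloc[row]!r} at line {row + 2}"
            )
        df[col] = parsed
    return df


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def load_reference_cohort() -> pd.DataFrame:
    """The bundled 42-visitor reference cohort (published PAD scores with
    printed state and tendency labels), used for validation and examples."""
    with resources.files("padeeg.data").joinpath("reference_cohort.csv").open("rb") as fh:
        return pd.read_csv(fh)


def read_features(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("visitor_id", *BAND_NAMES):
        if col not in df.columns:
            raise ValidationError(f"feature file {path} missing column {col!r}")
    return df


def write_features(features: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    features.to_csv(path, index=False)


def read_eeg_csv(path: str | Path, visitor_id: str | None = None) -> EEGRecording:
    """Read a single-channel EEG CSV with columns time_s, amplitude.

    The sampling rate is inferred from the median sample spacing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "amplitude"):
        if col not in df.columns:
            raise ValidationError(f"EEG file {path} missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError(f"EEG file {path} has fewer than 2 samples")
    dt = float(np.median(np.diff(t)))
    if dt <= 0:
        raise ValidationError(f"EEG file {path} has non-increasing time stamps")
    return EEGRecording(
        visitor_id=visitor_id or path.stem,
        sampling_rate=1.0 / dt,
        samples=df["amplitude"].to_numpy(dtype=float),
    )


def write_eeg_csv(rec: EEGRecording, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(rec.samples.size) / rec.sampling_rate
    pd.DataFrame({"time_s": t, "amplitude": rec.samples}).to_csv(path, index=False)


def read_eeg_edf(path: str | Path, channel: int = 0) -> EEGRecording:
    """Read one channel from an EDF file (requires the optional mne extra)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ValidationError(
            "EDF reading requires the optional 'mne' dependency"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data()[channel]
    return EEGRecording(
        visitor_id=Path(path).stem,
        sampling_rate=float(raw.info["sfreq"]),
        samples=data,
        channel_label=raw.ch_names[channel],
    )


def load_yaml_config(path: str | Path) -> dict[str, Any]:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return cfg


def _canonical_json(obj: Any) -> str:
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)


def config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(_canonical_json(dict(config)).encode()).hexdigest()[:16]


def build_manifest(config: Mapping[str, Any], seed: int) -> dict[str, Any]:
    """Run manifest embedding the seed, config hash and library versions."""
    import sklearn
    import scipy

    from . import __version__

    return {
        "seed": seed,
        "config": dict(config),
        "config_hash": config_hash(config),
        "versions": {
            "padeeg": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
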