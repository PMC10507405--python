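"""End-to-end analysis: score -> classify -> summarize -> features -> train.

`run_pipeline` mirrors the study flow: visitors' PAD scores are classified
to basic emotions and tendencies, cohort descriptives and demographic
profiles are reported, EEG recordings (when present) are reduced to mean
band energies, and SVMs predict tendency from those features. Every output
directory gets a manifest with the seed and config hash so a run can be
reproduced bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .classify import (
    DEFAULT_KERNELS,
    ClassifierReport,
    KernelSpec,
    SplitSpec,
    split_cohort,
    train_and_evaluate,
)
from .eeg import (
    BAND_NAMES,
    BandDefinition,
    band_energies,
    mean_band_energy,
    reject_artifacts,
)
from .emotions import (
    PADScore,
    ValidationError,
    classify_emotion,
    default_emotion_table,
)
from .report import profile_by_group, summarize_dimension, summarize_tendency

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "assign_emotions",
           "extract_features", "DEMOGRAPHIC_ATTRIBUTES"]

DEMOGRAPHIC_ATTRIBUTES = (
    "gender", "age_group", "education", "occupation", "income_band",
    "seat_position", "travel_mode",
)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and the offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class RunConfig:
    """Paths and settings for one end-to-end run.

    Units: time in seconds, frequency in Hz, EEG amplitude device-relative.
    """

    cohort_path: str
    out_dir: str
    eeg_dir: str | None = None
    seed: int = 0
    train_fraction: float = 0.7
    pca_variance: float = 0.95
    kernels: tuple[str, ...] = ("linear", "polynomial", "gaussian", "sigmoid")
    stft_window_s: float = 1.0
    stft_overlap: float = 0.5
    artifact_threshold: float | None = None
    strict_scores: bool = False

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["kernels"] = list(self.kernels)
        return d

    def settings_dict(self) -> dict[str, Any]:
        """Analysis settings only — no filesystem paths, so the config hash
        (and hence the report bundle) is identical wherever the run lives."""
        d = self.to_dict()
        for key in ("cohort_path", "eeg_dir", "out_dir"):
            d.pop(key)
        return d


def assign_emotions(cohort: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Classify each visitor's (p, a, d) to a basic emotion and tendency."""
    table = default_emotion_table()
    states, tendencies, distances = [], [], []
    for _, row in cohort.iterrows():
        score = PADScore(float(row["p"]), float(row["a"]), float(row["d"]),
                         strict=strict)
        a = classify_emotion(score, table)
        states.append(a.emotion_name)
        tendencies.append(a.tendency)
        distances.append(a.distance)
    return cohort.assign(state=states, tendency=tendencies, distance=distances)


def extract_features(
    recordings: Mapping[str, Any],
    window_s: float = 1.0,
    overlap: float = 0.5,
    artifact_threshold: float | None = None,
    bands: BandDefinition | None = None,
) -> pd.DataFrame:
    """Reduce each recording to its mean band energies (one row per visitor)."""
    bands = bands or BandDefinition()
    rows = []
    for vid, rec in recordings.items():
        if artifact_threshold is not None:
            rec, _ = reject_artifacts(rec, artifact_threshold, window_s)
        per_window = band_energies(rec, bands, window_s, overlap)
        mean = mean_band_energy(per_window)
        rows.append({"visitor_id": vid,
                     **{b: getattr(mean, b) for b in BAND_NAMES}})
    return pd.DataFrame(rows)


def _summary_payload(cohort: pd.DataFrame) -> dict[str, Any]:
    payload: dict[str, Any] = {"n": int(len(cohort)), "dimensions": {}}
    for dim in ("p", "a", "d"):
        s = summarize_dimension(cohort[dim].to_numpy(dtype=float))
        payload["dimensions"][dim] = {
            "mean": s.mean, "sd": s.sd, "median": s.median,
            "share_pos": s.share_pos, "share_zero": s.share_zero,
            "share_neg": s.share_neg,
        }
    t = summarize_tendency(cohort["tendency"].tolist())
    payload["tendency"] = {
        "n_positive": t.n_positive, "n_negative": t.n_negative,
        "pct_negative": t.pct_negative,
    }
    return payload


def _summary_text(payload: Mapping[str, Any]) -> str:
    lines = [f"Cohort summary (n = {payload['n']})", ""]
    lines.append(f"{'Dim':<5}{'Mean':>8}{'SD':>8}{'Median':>8}"
                 f"{'>0 %':>8}{'=0 %':>8}{'<0 %':>8}")
    for dim, s in payload["dimensions"].items():
        lines.append(
            f"{dim.upper():<5}{s['mean']:>8.3f}{s['sd']:>8.3f}{s['median']:>8.3f}"
            f"{s['share_pos']:>8.1f}{s['share_zero']:>8.1f}{s['share_neg']:>8.1f}"
        )
    t = payload["tendency"]
    lines += ["", f"Tendency: {t['n_positive']} positive, "
                  f"{t['n_negative']} negative ({t['pct_negative']}% negative)"]
    return "\n".join(lines) + "\n"


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages and write the report bundle to ``out_dir``.

    Returns the in-memory bundle. Any stage error aborts with the stage
    name and the offending input.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        cohort = pio.read_cohort(config.cohort_path)
    except ValidationError as exc:
        raise PipelineError("read_cohort", str(exc)) from exc

    try:
        cohort = assign_emotions(cohort, strict=config.strict_scores)
    except ValidationError as exc:
        raise PipelineError("classify_emotion", str(exc)) from exc

    try:
        summary = _summary_payload(cohort)
    except ValidationError as exc:
        raise PipelineError("cohort_summary", str(exc)) from exc

    profiles: dict[str, Any] = {}
    profile_frames = []
    for attr in DEMOGRAPHIC_ATTRIBUTES:
        if attr not in cohort.columns:
            continue
        prof = profile_by_group(cohort, attr)
        profiles[attr] = {
            "modal_overall": prof.modal_overall,
            "modal_positive": prof.modal_positive,
            "modal_negative": prof.modal_negative,
            "counts": {
                str(cat): {c: int(prof.counts.loc[cat, c])
                           for c in ("positive", "negative", "total")}
                for cat in prof.counts.index
            },
        }
        frame = prof.counts.reset_index().assign(attribute=attr)
        profile_frames.append(frame.rename(columns={attr: "category"}))

    report: ClassifierReport | None = None
    features: pd.DataFrame | None = None
    if config.eeg_dir is not None:
        try:
            eeg_dir = Path(config.eeg_dir)
            recs = {
                p.stem: pio.read_eeg_csv(p)
                for p in sorted(eeg_dir.glob("*.csv"))
            }
            if not recs:
                raise ValidationError(f"no EEG CSV files in {eeg_dir}")
            features = extract_features(
                recs, config.stft_window_s, config.stft_overlap,
                config.artifact_threshold,
            )
        except ValidationError as exc:
            raise PipelineError("eeg_features", str(exc)) from exc

        try:
            merged = cohort.merge(
                features, left_on="id", right_on="visitor_id", how="inner"
            )
            if len(merged) != len(cohort):
                missing = set(cohort["id"]) - set(features["visitor_id"])
                raise ValidationError(
                    f"visitors without EEG features: {sorted(missing)[:5]}"
                )
            labels = merged["tendency"].tolist()
            split = split_cohort(
                labels, SplitSpec(config.train_fraction, True, config.seed)
            )
            kernels = tuple(KernelSpec(k) for k in config.kernels)
            report = train_and_evaluate(
                merged[list(BAND_NAMES)], labels, split, kernels,
                config.pca_variance,
            )
        except ValidationError as exc:
            raise PipelineError("train_svm", str(exc)) from exc

    # --- write bundle (no timestamps: bundles must be reproducible) ---
    pio.write_cohort(cohort, out / "cohort_assigned.csv")
    _write_json(summary, out / "cohort_summary.json")
    (out / "cohort_summary.txt").write_text(_summary_text(summary),
                                            encoding="utf-8")
    if profiles:
        _write_json(profiles, out / "group_profiles.json")
        pd.concat(profile_frames, ignore_index=True)[
            ["attribute", "category", "positive", "negative", "total"]
        ].to_csv(out / "group_profiles.csv", index=False)
    if features is not None:
        pio.write_features(features, out / "features.csv")
    if report is not None:
        _write_json(
            {"rates": report.rates, "accuracy": report.accuracy,
             "n_components": report.n_components,
             "split_sizes": list(report.split_sizes)},
            out / "classifier_report.json",
        )
        (out / "classifier_report.txt").write_text(report.to_text() + "\n",
                                                   encoding="utf-8")
    manifest = pio.build_manifest(config.settings_dict(), config.seed)
    manifest["inputs"] = {
        "cohort": Path(config.cohort_path).name,
        "eeg_dir": Path(config.eeg_dir).name if config.eeg_dir else None,
    }
    _write_json(manifest, out / "manifest.json")

    return {"cohort": cohort, "summary": summary, "profiles": profiles,
            "features": features, "classifier_report": report,
            "manifest": manifest}
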