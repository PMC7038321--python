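"""Trace containers, run configuration, and the end-to-end pipeline.

Canonical trace container is JSONL (one record per measurement with a
ragged ``samples`` array); a long-format CSV
(subject_id, session_id, hand, finger, t_s, force_gf [, label]) is
provided for interoperability.  Encoder logs are written as a one-column
CSV of pulse times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features_classify import (
    ClassifierSpec,
    crossvalidate,
    extract_features,
    feature_matrix,
    FEATURE_GRID_HZ,
)
from .preprocess import preprocess_trace
from .spectral import amplitude_spectrum, assess
from .studies import DEFAULT_VF_THRESHOLDS, repeatability
from .synthcohort import EncoderLog
from .trace import ForceTrace, HoldWindow, ProtocolConfig

logger = logging.getLogger("tremorforce")

__all__ = [
    "RunConfig",
    "FormatError",
    "read_traces",
    "write_traces",
    "write_encoder_csv",
    "read_windows",
    "write_windows",
    "assessments_to_frame",
    "run_pipeline",
]


class FormatError(ValueError):
    """A trace file does not match the expected dialect."""


_TRACE_FIELDS = ("subject_id", "session_id", "hand", "finger", "rate_hz", "samples")
_CSV_COLUMNS = ("subject_id", "session_id", "hand", "finger", "t_s", "force_gf")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Collects the protocol constants, the analysis band, the outlier
    percentile, the validity-threshold sweep and the feature grid; all
    randomness downstream flows from ``seed``.  Unknown keys in a config
    file are rejected.
    """

    target_gf: float = 300.0
    hold_s: float = 3.0
    tolerance_frac: float = 0.2
    rate_hz: float = 40.0
    band_lo_hz: float = 3.5
    band_hi_hz: float = 7.5
    outlier_percentile: float = 1.25
    vf_thresholds: tuple = DEFAULT_VF_THRESHOLDS
    vf_validity_threshold: float = 0.5
    feature_grid: tuple = (3.5, 7.5, 41)
    cv_folds: int = 5
    exclude_thumbs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_lo_hz < self.band_hi_hz < self.rate_hz / 2:
            raise ValueError(
                f"band [{self.band_lo_hz}, {self.band_hi_hz}] Hz must lie inside "
                f"(0, Nyquist={self.rate_hz / 2:g}) Hz"
            )
        if not 0 < self.outlier_percentile < 50:
            raise ValueError("outlier_percentile must be in (0, 50)")
        self.vf_thresholds = tuple(float(t) for t in self.vf_thresholds)
        self.feature_grid = tuple(self.feature_grid)

    @property
    def protocol(self) -> ProtocolConfig:
        return ProtocolConfig(
            target_gf=self.target_gf,
            hold_s=self.hold_s,
            tolerance_frac=self.tolerance_frac,
            rate_hz=self.rate_hz,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["vf_thresholds"] = list(self.vf_thresholds)
        d["feature_grid"] = list(self.feature_grid)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Trace serialization
# ---------------------------------------------------------------------------


def _trace_to_record(tr: ForceTrace) -> dict:
    return {
        "subject_id": tr.subject_id,
        "session_id": tr.session_id,
        "hand": tr.hand,
        "finger": tr.finger,
        "label": tr.label,
        "rate_hz": tr.rate_hz,
        "samples": [round(float(v), 6) for v in tr.samples],
    }


def write_traces(traces: list[ForceTrace], path: str | Path) -> None:
    """Write traces as JSONL (``.jsonl``) or long-format CSV (``.csv``)."""
    path = Path(path)
    if path.suffix == ".jsonl":
        with path.open("w") as fh:
            for tr in traces:
                fh.write(json.dumps(_trace_to_record(tr)) + "\n")
    elif path.suffix == ".csv":
        frames = []
        for tr in traces:
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": tr.subject_id,
                        "session_id": tr.session_id,
                        "hand": tr.hand,
                        "finger": tr.finger,
                        "t_s": np.round(tr.times_s, 6),
                        "force_gf": np.round(tr.samples, 6),
                        "label": tr.label if tr.label is not None else "",
                    }
                )
            )
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    else:
        raise FormatError(f"unsupported trace format {path.suffix!r} (use .jsonl or .csv)")


def _read_traces_jsonl(path: Path) -> list[ForceTrace]:
    traces = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON ({exc})") from exc
            missing = [f for f in _TRACE_FIELDS if f not in rec]
            if missing:
                raise FormatError(f"{path}:{lineno}: missing fields {missing}")
            try:
                traces.append(
                    ForceTrace(
                        subject_id=str(rec["subject_id"]),
                        session_id=str(rec["session_id"]),
                        hand=rec["hand"],
                        finger=rec["finger"],
                        samples=np.asarray(rec["samples"], dtype=float),
                        rate_hz=float(rec["rate_hz"]),
                        label=None if rec.get("label") is None else int(rec["label"]),
                    )
                )
            except (ValueError, TypeError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return traces


def _read_traces_csv(path: Path) -> list[ForceTrace]:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    traces = []
    keys = ["subject_id", "session_id", "hand", "finger"]
    for key, grp in df.groupby(keys, sort=False):
        t = grp["t_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError(f"{path}: non-monotone time for measurement {key}")
        if t.size > 2 and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise FormatError(f"{path}: irregular sampling for measurement {key}")
        label = None
        if "label" in grp.columns:
            lv = grp["label"].iloc[0]
            if pd.notna(lv) and str(lv) != "":
                label = int(float(lv))
        traces.append(
            ForceTrace(
                subject_id=str(key[0]),
                session_id=str(key[1]),
                hand=str(key[2]),
                finger=str(key[3]),
                samples=grp["force_gf"].to_numpy(dtype=float),
                rate_hz=1.0 / dt[0],
                label=label,
            )
        )
    return traces


def read_traces(path: str | Path) -> list[ForceTrace]:
    """Read a JSONL or long-format CSV trace file.

    Malformed rows are reported with their line number (JSONL) or
    measurement key (CSV); an empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        warnings.warn(f"{path} is empty; no traces read", stacklevel=2)
        return []
    if path.suffix == ".jsonl":
        return _read_traces_jsonl(path)
    if path.suffix == ".csv":
        return _read_traces_csv(path)
    raise FormatError(f"unsupported trace format {path.suffix!r} (use .jsonl or .csv)")


def write_encoder_csv(log: EncoderLog, path: str | Path) -> None:
    pd.DataFrame({"pulse_time_s": np.round(log.pulse_times_s, 9)}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Window serialization (preprocessed hold windows + metadata)
# ---------------------------------------------------------------------------


def write_windows(windows: list[tuple[dict, HoldWindow]], path: str | Path) -> None:
    """Write (metadata, window) pairs as JSONL."""
    with Path(path).open("w") as fh:
        for meta, win in windows:
            rec = dict(meta)
            rec["start_index"] = win.start_index
            rec["rate_hz"] = win.rate_hz
            rec["samples"] = [round(float(v), 9) for v in win.samples]
            fh.write(json.dumps(rec) + "\n")


def read_windows(path: str | Path) -> list[tuple[dict, HoldWindow]]:
    out = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rec = json.loads(line)
            try:
                win = HoldWindow(
                    start_index=int(rec.pop("start_index")),
                    samples=np.asarray(rec.pop("samples"), dtype=float),
                    rate_hz=float(rec.pop("rate_hz")),
                )
            except KeyError as exc:
                raise FormatError(f"{path}:{lineno}: missing field {exc}") from exc
            out.append((rec, win))
    return out


def assessments_to_frame(assessments) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": a.subject_id,
                "session_id": a.session_id,
                "hand": a.hand,
                "finger": a.finger,
                "f_d_hz": a.f_d,
                "p_peak": a.p_peak,
                "v_f": a.v_f,
                "valid": a.valid,
            }
            for a in assessments
        ]
    )


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

_CLF_SHORT = {
    "svm": "svm_rbf",
    "nb": "naive_bayes_kernel",
    "dt": "decision_tree",
    "knn": "knn",
}


def run_pipeline(
    config: RunConfig,
    raw_path: str | Path,
    out_dir: str | Path | None = None,
    classifiers: tuple = ("svm", "nb", "dt", "knn"),
) -> dict:
    """Execute the full analysis on a raw trace file.

    Stages: preprocessing (outlier repair, hold-window location,
    band-pass), spectral assessment, feature extraction, and — when both
    class labels are present — the cross-validated classifier benchmark and
    the repeatability threshold sweep.  Artifacts and a manifest (config
    hash, seed, versions) are written to ``out_dir`` when given; rerunning
    with identical config and inputs reproduces them bit-for-bit.

    Any stage failure aborts with the stage name and the offending
    measurement's identifiers.
    """
    traces = read_traces(raw_path)
    if config.exclude_thumbs:
        from .synthcohort import exclude_thumbs as _drop_thumbs

        traces = _drop_thumbs(traces)
    labels_present = any(tr.label is not None for tr in traces)

    assessments = []
    feature_rows = []
    for tr in traces:
        ident = f"{tr.subject_id}/{tr.session_id}/{tr.hand}/{tr.finger}"
        try:
            window = preprocess_trace(
                tr,
                config.protocol,
                lo_hz=config.band_lo_hz,
                hi_hz=config.band_hi_hz,
                percentile=config.outlier_percentile,
            )
        except Exception as exc:
            raise RuntimeError(f"stage=preprocess measurement={ident}: {exc}") from exc
        try:
            a = assess(
                window,
                threshold=config.vf_validity_threshold,
                band=(config.band_lo_hz, config.band_hi_hz),
                subject_id=tr.subject_id,
                session_id=tr.session_id,
                hand=tr.hand,
                finger=tr.finger,
            )
            assessments.append(a)
        except Exception as exc:
            raise RuntimeError(f"stage=spectral measurement={ident}: {exc}") from exc
        try:
            fv = extract_features(amplitude_spectrum(window), label=tr.label)
            feature_rows.append((tr, fv))
        except Exception as exc:
            raise RuntimeError(f"stage=features measurement={ident}: {exc}") from exc

    assessments_df = assessments_to_frame(assessments)
    features_df = pd.DataFrame(
        [fv.values for _, fv in feature_rows],
        columns=[f"f{f:.2f}" for f in FEATURE_GRID_HZ],
    )
    features_df.insert(0, "subject_id", [tr.subject_id for tr, _ in feature_rows])
    features_df["label"] = [
        tr.label if tr.label is not None else "" for tr, _ in feature_rows
    ]

    reports: dict = {}
    try:
        rep = repeatability(assessments, thresholds=config.vf_thresholds)
        reports["repeatability"] = rep
    except Exception as exc:
        raise RuntimeError(f"stage=studies.repeatability: {exc}") from exc

    if labels_present:
        X, y = feature_matrix([fv for _, fv in feature_rows])
        if len(np.unique(y[y >= 0])) == 2:
            Xl, yl = X[y >= 0], y[y >= 0]
            metrics = {}
            for short in classifiers:
                spec = ClassifierSpec(kind=_CLF_SHORT.get(short, short))
                metrics[short] = crossvalidate(
                    Xl, yl, spec, k=config.cv_folds, seed=config.seed
                )
            reports["metrics"] = metrics

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        assessments_df.to_csv(out_dir / "assessments.csv", index=False)
        features_df.to_csv(out_dir / "features.csv", index=False)
        reports["repeatability"].to_dataframe().to_csv(
            out_dir / "repeatability.csv", index=False
        )
        if "metrics" in reports:
            with (out_dir / "metrics.json").open("w") as fh:
                json.dump(
                    {k: v.as_dict() for k, v in reports["metrics"].items()}, fh, indent=2
                )
        import scipy
        import sklearn

        manifest = {
            "config_digest": config.digest(),
            "seed": config.seed,
            "n_traces": len(traces),
            "versions": {
                "tremorforce": __version__,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "assessments": assessments,
        "assessments_df": assessments_df,
        "features_df": features_df,
        "reports": reports,
    }
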