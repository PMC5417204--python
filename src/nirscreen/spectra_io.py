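"""Text-format persistence for spectra tables, sample metadata and models.

Spectra live in a wide CSV: six metadata columns
(``sample_id,batch_id,brand,replicate,side,state``) followed by one column
per wavelength, named by its nm value. Sample metadata is a long CSV with
one row per (sample, component). Models are versioned JSON documents whose
float arrays round-trip exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .authenticate import ClassModel
from .quantify import PLSRModel
from .spectra import QualityClass, SampleRecord, SampleSet, Spectrum, SpectrumState

__all__ = [
    "read_spectra_table",
    "write_spectra_table",
    "read_sample_metadata",
    "write_sample_metadata",
    "apply_metadata",
    "save_model",
    "load_model",
]

_META_COLS = ["sample_id", "batch_id", "brand", "replicate", "side", "state"]

CLASS_MODEL_SCHEMA = "nirscreen.class_model/1"
PLSR_MODEL_SCHEMA = "nirscreen.plsr_model/1"


def _fmt(x: float) -> str:
    return format(float(x), ".9g")


def write_spectra_table(sample_set: SampleSet, path) -> None:
    """Write every scan of every record as one CSV row (deterministic)."""
    path = Path(path)
    grid = sample_set.grid
    header = _META_COLS + [format(w, "g") for w in grid]
    lines = [",".join(header)]
    for rec in sample_set.records:
        for scan in rec.scans:
            rep = scan.meta.get("replicate", "")
            side = scan.meta.get("side", "") or ""
            row = [
                rec.sample_id,
                rec.batch_id,
                rec.brand,
                str(rep),
                str(side),
                scan.state.value,
            ] + [_fmt(v) for v in scan.values]
            lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def read_spectra_table(path) -> SampleSet:
    """Parse a wide spectra CSV back into a SampleSet.

    Wavelength columns are reordered ascending; replicates are grouped
    under their SampleRecord; duplicate (sample_id, replicate, side) keys
    are an error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={c: str for c in _META_COLS[:5]})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"spectra table {path} lacks required columns {missing}")
    wl_cols = [c for c in df.columns if c not in _META_COLS]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column header in {path}: {exc}") from exc
    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    wl_cols = [wl_cols[i] for i in order]
    values = df[wl_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = int(np.argwhere(np.isnan(values))[0][0])
        raise ValueError(f"ragged or non-numeric spectral row {bad + 2} in {path}")

    seen_keys = set()
    records: dict[str, SampleRecord] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        sid = row.sample_id
        rep = row.replicate
        rep = None if pd.isna(rep) or rep == "" else int(float(rep))
        side = row.side
        side = None if (pd.isna(side) or side == "") else str(side)
        key = (sid, rep, side)
        if key in seen_keys:
            raise ValueError(
                f"duplicate scan key (sample_id={sid!r}, replicate={rep}, side={side}) "
                f"at row {i + 2} of {path}"
            )
        seen_keys.add(key)
        meta = {"sample_id": sid}
        if rep is not None:
            meta["replicate"] = rep
        if side is not None:
            meta["side"] = side
        scan = Spectrum(wavelengths, values[i], SpectrumState(row.state), meta)
        if sid not in records:
            records[sid] = SampleRecord(
                sample_id=sid, brand=row.brand, batch_id=row.batch_id, scans=[scan]
            )
        else:
            rec = records[sid]
            if rec.brand != row.brand or rec.batch_id != row.batch_id:
                raise ValueError(f"inconsistent brand/batch for sample {sid!r} in {path}")
            rec.scans.append(scan)
    return SampleSet(list(records.values()), wavelengths)


def write_sample_metadata(sample_set: SampleSet, path) -> None:
    """One row per (sample, component): quality label plus reference %SAPI."""
    path = Path(path)
    lines = ["sample_id,brand,batch_id,quality_class,component,sapi_percent"]
    for rec in sample_set.records:
        for comp, val in rec.sapi_percent.items():
            lines.append(
                f"{rec.sample_id},{rec.brand},{rec.batch_id},"
                f"{rec.quality_class.value},{comp},{_fmt(val)}"
            )
        if not rec.sapi_percent:
            lines.append(
                f"{rec.sample_id},{rec.brand},{rec.batch_id},{rec.quality_class.value},,"
            )
    path.write_text("\n".join(lines) + "\n")


def read_sample_metadata(path) -> pd.DataFrame:
    """Load the metadata CSV, validating quality-class tokens."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "brand": str, "batch_id": str,
                                  "quality_class": str, "component": str})
    required = {"sample_id", "brand", "batch_id", "quality_class", "component", "sapi_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table {path} lacks columns {sorted(missing)}")
    allowed = {qc.value for qc in QualityClass}
    bad = set(df["quality_class"].dropna()) - allowed
    if bad:
        raise ValueError(
            f"unknown quality_class token(s) {sorted(bad)}; allowed: {sorted(allowed)}"
        )
    return df


def apply_metadata(sample_set: SampleSet, metadata: pd.DataFrame) -> SampleSet:
    """Attach quality labels and %SAPI ground truth to matching records.

    Metadata rows without a matching spectrum raise a warning, not an
    error.
    """
    by_id = {rec.sample_id: rec for rec in sample_set.records}
    unmatched = []
    for row in metadata.itertuples(index=False):
        rec = by_id.get(row.sample_id)
        if rec is None:
            unmatched.append(row.sample_id)
            continue
        rec.quality_class = QualityClass(row.quality_class)
        if isinstance(row.component, str) and row.component:
            rec.sapi_percent[row.component] = float(row.sapi_percent)
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} metadata row(s) had no matching spectra "
            f"(e.g. {unmatched[0]!r})",
            stacklevel=2,
        )
    return sample_set


# ---------------------------------------------------------------------------
# Model persistence
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Serialize a ClassModel or PLSRModel as versioned JSON (row-major)."""
    path = Path(path)
    if isinstance(model, ClassModel):
        doc = {
            "schema": CLASS_MODEL_SCHEMA,
            "grid": model.grid.tolist(),
            "projection": model.projection.tolist(),
            "center": model.center.tolist(),
            "mean": model.mean.tolist(),
            "covariance": model.covariance.tolist(),
            "threshold": model.threshold,
            "k": model.k,
            "training_manifest": [list(t) for t in model.training_manifest],
        }
    elif isinstance(model, PLSRModel):
        doc = {
            "schema": PLSR_MODEL_SCHEMA,
            "x_mean": model.x_mean.tolist(),
            "y_mean": model.y_mean,
            "weights": model.weights.tolist(),
            "loadings": model.loadings.tolist(),
            "y_loadings": np.asarray(model.y_loadings).tolist(),
            "coefficients": model.coefficients.tolist(),
            "a": model.a,
            "grid": None if model.grid is None else model.grid.tolist(),
        }
    else:
        raise TypeError(f"cannot serialize model of type {type(model).__name__}")
    path.write_text(json.dumps(doc, indent=1) + "\n")


def load_model(path):
    """Load a model JSON; the schema tag selects the model type."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"cannot parse model file {path}: {exc}") from exc
    schema = doc.get("schema")
    if schema == CLASS_MODEL_SCHEMA:
        return ClassModel(
            grid=np.array(doc["grid"], float),
            projection=np.array(doc["projection"], float),
            center=np.array(doc["center"], float),
            mean=np.array(doc["mean"], float),
            covariance=np.array(doc["covariance"], float),
            threshold=float(doc["threshold"]),
            k=int(doc["k"]),
            training_manifest=[tuple(t) for t in doc["training_manifest"]],
        )
    if schema == PLSR_MODEL_SCHEMA:
        return PLSRModel(
            x_mean=np.array(doc["x_mean"], float),
            y_mean=float(doc["y_mean"]),
            weights=np.array(doc["weights"], float),
            loadings=np.array(doc["loadings"], float),
            y_loadings=np.array(doc["y_loadings"], float),
            coefficients=np.array(doc["coefficients"], float),
            a=int(doc["a"]),
            grid=None if doc.get("grid") is None else np.array(doc["grid"], float),
        )
    raise ValueError(
        f"unsupported model schema {schema!r} in {path}; expected "
        f"{CLASS_MODEL_SCHEMA!r} or {PLSR_MODEL_SCHEMA!r}"
    )
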