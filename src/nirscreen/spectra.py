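"""Core domain types: spectra, sample records and sample sets.

A :class:`Spectrum` is a single wavelength-indexed trace carrying a
processing-state tag so that downstream stages can refuse inputs in the
wrong state (e.g. Mahalanobis matching requires second-derivative spectra).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "SpectrumState",
    "QualityClass",
    "Spectrum",
    "SampleRecord",
    "SampleSet",
]


class SpectrumState(str, Enum):
    """Processing state of a spectrum's values."""

    REFLECTANCE = "reflectance"
    ABSORBANCE = "absorbance"
    SMOOTHED = "smoothed"
    SECOND_DERIVATIVE = "second_derivative"


class QualityClass(str, Enum):
    """Quality label attached to a physical dose."""

    QUALITY_ASSURED = "quality_assured"
    SUBSTANDARD = "substandard"
    FALSIFIED = "falsified"
    DEGRADED = "degraded"
    UNKNOWN = "unknown"


@dataclass
class Spectrum:
    """One wavelength-indexed trace.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelength grid in nm.
    values
        One value per wavelength. Units depend on ``state``:
        reflectance is a fraction of the reference in (0, 1],
        absorbance is -log10(reflectance), derivative states carry
        absorbance per nm^deriv.
    state
        Processing-state tag.
    meta
        Free-form scan metadata (sample_id, replicate, side, ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    state: SpectrumState
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.state = SpectrumState(self.state)
        if self.wavelengths.ndim != 1:
            raise ValueError("wavelengths must be a 1-D vector")
        if self.values.shape != self.wavelengths.shape:
            raise ValueError(
                f"values length {self.values.shape} does not match "
                f"wavelength grid {self.wavelengths.shape}"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.state is SpectrumState.REFLECTANCE and self.values.size:
            if np.any(self.values <= 0):
                bad = self.wavelengths[np.argmax(self.values <= 0)]
                raise ValueError(
                    f"reflectance must be positive; offending wavelength {bad:g} nm"
                )

    def __len__(self) -> int:
        return self.wavelengths.size

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            self.wavelengths.size == other.wavelengths.size
            and np.array_equal(self.wavelengths, other.wavelengths)
        )

    def copy_with(self, values: np.ndarray, state: SpectrumState, **meta) -> "Spectrum":
        """New spectrum on the same grid with updated values/state/meta."""
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return Spectrum(self.wavelengths.copy(), np.asarray(values, float), state, new_meta)


@dataclass
class SampleRecord:
    """One physical dose (or one side of a bilayer tablet).

    ``sapi_percent`` maps component name to percent-of-label content as
    determined by the reference assay; it is ground truth for regression
    and the source of quality labels.
    """

    sample_id: str
    brand: str
    batch_id: str
    quality_class: QualityClass = QualityClass.UNKNOWN
    sapi_percent: dict = field(default_factory=dict)
    scans: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.quality_class = QualityClass(self.quality_class)
        for comp, val in self.sapi_percent.items():
            if val < 0:
                raise ValueError(f"sapi_percent for {comp!r} must be >= 0, got {val}")
        if self.scans:
            grid = self.scans[0].wavelengths
            for s in self.scans[1:]:
                if not np.array_equal(s.wavelengths, grid):
                    raise ValueError(
                        f"scans of sample {self.sample_id!r} are on different grids"
                    )

    @property
    def side(self):
        """Bilayer side shared by all scans, or None."""
        sides = {s.meta.get("side") for s in self.scans}
        if len(sides) == 1:
            return next(iter(sides))
        return None


@dataclass
class SampleSet:
    """A collection of sample records sharing one wavelength grid."""

    records: list
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        seen = set()
        for rec in self.records:
            if rec.sample_id in seen:
                raise ValueError(f"duplicate sample id {rec.sample_id!r}")
            seen.add(rec.sample_id)
            for s in rec.scans:
                if not np.array_equal(s.wavelengths, self.grid):
                    raise ValueError(
                        f"sample {rec.sample_id!r} has a scan off the shared grid"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def brands(self) -> list:
        out = []
        for rec in self.records:
            if rec.brand not in out:
                out.append(rec.brand)
        return out

    def select(self, brand=None, quality_class=None) -> list:
        """Records filtered by brand and/or quality class."""
        recs = self.records
        if brand is not None:
            recs = [r for r in recs if r.brand == brand]
        if quality_class is not None:
            qc = QualityClass(quality_class)
            recs = [r for r in recs if r.quality_class is qc]
        return recs
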