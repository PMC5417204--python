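"""Synthetic NIR spectra libraries with the statistical structure the
screening pipeline assumes.

The forward model is Beer–Lambert: each formulation component has a
Gaussian-band absorbance signature, a dose's absorbance is the
concentration-weighted sum of its component signatures plus baseline terms
(per-sample and per-batch offset/slope) and additive Gaussian noise, and a
scan is the reflectance ``10**(-A)`` of a noisy absorbance realization.

Quality classes:

* quality-assured — every active component drawn near 100 % of label;
* substandard — one designated component drawn in a configured low range;
* falsified — the active components are either absent or replaced by a
  wrong compound whose bands sit away from the genuine ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import QualityClass, SampleRecord, SampleSet, Spectrum, SpectrumState

__all__ = [
    "Band",
    "ComponentSignature",
    "FormulationSpec",
    "NoiseModel",
    "ClassPlan",
    "BrandPlan",
    "LibraryConfig",
    "make_component_signature",
    "simulate_absorbance",
    "simulate_scan_set",
    "generate_bilayer_dose",
    "generate_library",
    "default_grid",
    "config_from_dict",
]

GRID_MIN = 740.0
GRID_MAX = 1060.0


def default_grid(step: float = 1.0) -> np.ndarray:
    """Device wavelength grid: 740–1060 nm inclusive at ``step`` nm."""
    n = int(round((GRID_MAX - GRID_MIN) / step)) + 1
    return GRID_MIN + step * np.arange(n)


@dataclass(frozen=True)
class Band:
    """One Gaussian absorbance band."""

    center: float  # nm
    width: float   # nm, Gaussian sigma
    amplitude: float  # absorbance units at the center


@dataclass
class ComponentSignature:
    """Per-component absorbance fingerprint: a sum of Gaussian bands on a grid."""

    name: str
    bands: tuple
    grid: np.ndarray
    curve: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.bands = tuple(
            b if isinstance(b, Band) else Band(*b) for b in self.bands
        )
        if self.grid.size == 0:
            raise ValueError("signature grid must be non-empty")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("signature grid must be strictly increasing")
        if self.grid[0] < GRID_MIN or self.grid[-1] > GRID_MAX:
            raise ValueError(f"grid must lie within [{GRID_MIN:g}, {GRID_MAX:g}] nm")
        for b in self.bands:
            if b.width <= 0:
                raise ValueError(f"band width must be > 0, got {b.width}")
            if not (GRID_MIN <= b.center <= GRID_MAX):
                raise ValueError(
                    f"band center {b.center} nm outside [{GRID_MIN:g}, {GRID_MAX:g}]"
                )
        curve = np.zeros_like(self.grid)
        for b in self.bands:
            curve += b.amplitude * np.exp(-((self.grid - b.center) ** 2) / (2 * b.width**2))
        self.curve = curve

    def shifted(self, delta_nm: float, name: str | None = None) -> "ComponentSignature":
        """Same bands translated by ``delta_nm`` (clipped to the valid range)."""
        bands = [
            Band(min(max(b.center + delta_nm, GRID_MIN), GRID_MAX), b.width, b.amplitude)
            for b in self.bands
        ]
        return ComponentSignature(name or f"{self.name}+{delta_nm:g}nm", tuple(bands), self.grid)


def make_component_signature(name, bands, grid) -> ComponentSignature:
    """Build a Gaussian-band signature curve(λ) = Σ_b a_b exp(-(λ-c_b)²/2w_b²)."""
    return ComponentSignature(name, tuple(bands), grid)


@dataclass
class FormulationSpec:
    """A brand's formulation: nominal component concentrations, component
    signatures, an excipient signature, and optional bilayer structure."""

    brand: str
    components: dict                 # name -> nominal concentration (1.0 = 100 % of label)
    signatures: dict                 # name -> ComponentSignature
    excipient: ComponentSignature
    bilayer: bool = False
    sides: tuple | None = None       # (frozenset of names, frozenset of names)

    def __post_init__(self) -> None:
        for name, c in self.components.items():
            if c < 0:
                raise ValueError(f"nominal concentration of {name!r} must be >= 0")
            if name not in self.signatures:
                raise ValueError(f"component {name!r} has no signature")
        if self.bilayer:
            if self.sides is None:
                raise ValueError("bilayer formulation requires a side partition")
            a, b = (frozenset(s) for s in self.sides)
            if a | b != set(self.components) or (a & b):
                raise ValueError(
                    "bilayer sides must partition the component set into two disjoint sides"
                )
            self.sides = (a, b)


@dataclass(frozen=True)
class NoiseModel:
    """Scales of the additive disturbances, all in absorbance units
    (slopes per nm)."""

    baseline_offset_sd: float = 0.01
    baseline_slope_sd: float = 3e-5
    batch_effect_sd: float = 0.01
    scan_noise_sd: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("baseline_offset_sd", "baseline_slope_sd", "batch_effect_sd", "scan_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ClassPlan:
    """How many batches and samples of one quality class to generate.

    Samples are spread over the batches round-robin, so ``samples=60,
    batches=23`` gives batch sizes of 2 or 3.
    """

    batches: int = 0
    samples: int = 0

    def __post_init__(self) -> None:
        if self.batches < 0 or self.samples < 0:
            raise ValueError("counts must be >= 0")
        if self.samples > 0 and self.batches == 0:
            raise ValueError("samples requested but zero batches planned")


@dataclass
class BrandPlan:
    """Generation plan for one brand: its formulation plus the quality mix."""

    formulation: FormulationSpec
    quality_assured: ClassPlan = field(default_factory=ClassPlan)
    substandard: ClassPlan = field(default_factory=ClassPlan)
    falsified: ClassPlan = field(default_factory=ClassPlan)
    qa_sapi_range: tuple = (90.0, 110.0)
    substandard_sapi_range: tuple = (66.0, 85.0)
    substandard_component: str | None = None
    falsified_mode: str = "wrong_compound"  # or "absent"
    wrong_shift_nm: float = 60.0
    # Content moves together across components (dose-weight variation):
    # one shared percent-of-label factor per dose instead of independent
    # per-component draws.
    content_correlated: bool = True

    def __post_init__(self) -> None:
        for rng_ in (self.qa_sapi_range, self.substandard_sapi_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"range {rng_} must be ordered low <= high")
        if self.falsified_mode not in ("wrong_compound", "absent"):
            raise ValueError("falsified_mode must be 'wrong_compound' or 'absent'")
        if self.substandard.samples > 0:
            comp = self.substandard_component
            if comp is None or comp not in self.formulation.components:
                raise ValueError("substandard samples need a valid substandard_component")


@dataclass
class LibraryConfig:
    """Full library plan. ``seed`` fixes every source of randomness."""

    brands: list
    noise: NoiseModel = field(default_factory=NoiseModel)
    replicates: int = 3
    base_absorbance: float = 0.1   # constant floor keeping reflectance < 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.brands:
            raise ValueError("at least one brand plan is required")


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def simulate_absorbance(
    formulation: FormulationSpec,
    concentrations: dict,
    baseline: tuple = (0.0, 0.0),
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    components=None,
    signatures: dict | None = None,
    meta: dict | None = None,
) -> Spectrum:
    """Noiseless-or-noisy Beer–Lambert absorbance for one dose.

    ``A(λ) = Σ_i c_i ε_i(λ) + offset + slope·(λ - λ_min) + N(0, noise_sd)``.
    The excipient always contributes with unit concentration. ``components``
    restricts the active set (used for bilayer sides); ``signatures``
    overrides per-component fingerprints (used for wrong-compound
    falsifieds).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    unknown = set(concentrations) - set(formulation.components)
    if unknown:
        raise ValueError(f"concentrations for unknown components: {sorted(unknown)}")
    sigs = dict(formulation.signatures)
    if signatures:
        sigs.update(signatures)
    grid = formulation.excipient.grid
    active = set(formulation.components) if components is None else set(components)
    values = formulation.excipient.curve.copy()
    for name in sorted(active):
        c = concentrations.get(name, 0.0)
        values = values + c * sigs[name].curve
    offset, slope = baseline
    values = values + offset + slope * (grid - grid[0])
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        values = values + rng.normal(0.0, noise_sd, size=grid.size)
    return Spectrum(grid, values, SpectrumState.ABSORBANCE, dict(meta or {}))


def simulate_scan_set(
    absorbance_spectrum: Spectrum,
    scan_noise_sd: float,
    replicates: int,
    rng: np.random.Generator,
) -> list:
    """Triplicate-style reflectance scans: R = 10**-(A + noise) per replicate."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if scan_noise_sd < 0:
        raise ValueError("scan_noise_sd must be >= 0")
    a = absorbance_spectrum.values
    out = []
    for i in range(replicates):
        noisy = a if scan_noise_sd == 0 else a + rng.normal(0.0, scan_noise_sd, size=a.size)
        out.append(
            absorbance_spectrum.copy_with(
                np.power(10.0, -noisy), SpectrumState.REFLECTANCE, replicate=i
            )
        )
    return out


def generate_bilayer_dose(
    formulation: FormulationSpec,
    rng: np.random.Generator,
    concentrations: dict | None = None,
    noise: NoiseModel | None = None,
    replicates: int = 3,
    base_absorbance: float = 0.1,
) -> tuple:
    """Two independent scan sets for a bilayer tablet, one per side.

    Each side's absorbance contains only that side's components (plus the
    shared excipient)."""
    if not formulation.bilayer:
        raise ValueError(f"formulation {formulation.brand!r} is not bilayer")
    noise = noise or NoiseModel()
    conc = concentrations or dict(formulation.components)
    sides = []
    for side_name, comps in zip("AB", formulation.sides):
        offset = base_absorbance + rng.normal(0.0, noise.baseline_offset_sd)
        slope = rng.normal(0.0, noise.baseline_slope_sd)
        a = simulate_absorbance(
            formulation, conc, (offset, slope), 0.0, rng,
            components=comps, meta={"side": side_name},
        )
        scans = simulate_scan_set(a, noise.scan_noise_sd, replicates, rng)
        for s in scans:
            s.meta["side"] = side_name
        sides.append(scans)
    return tuple(sides)


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def _split_round_robin(samples: int, batches: int) -> list:
    base, extra = divmod(samples, batches)
    return [base + (1 if i < extra else 0) for i in range(batches)]


def _draw_concentrations(plan: BrandPlan, qc: QualityClass, rng) -> tuple:
    """(concentration dict, signature overrides) for one sample."""
    form = plan.formulation
    lo, hi = (x / 100.0 for x in plan.qa_sapi_range)
    if plan.content_correlated:
        factor = rng.uniform(lo, hi)
        conc = {name: nom * factor for name, nom in form.components.items()}
    else:
        conc = {name: nom * rng.uniform(lo, hi) for name, nom in form.components.items()}
    overrides = {}
    if qc is QualityClass.SUBSTANDARD:
        slo, shi = (x / 100.0 for x in plan.substandard_sapi_range)
        comp = plan.substandard_component
        conc[comp] = form.components[comp] * rng.uniform(slo, shi)
    elif qc is QualityClass.FALSIFIED:
        if plan.falsified_mode == "absent":
            for name in conc:
                conc[name] = 0.0
        else:
            for name in conc:
                overrides[name] = form.signatures[name].shifted(plan.wrong_shift_nm)
    return conc, overrides


_QC_TAG = {
    QualityClass.QUALITY_ASSURED: "QA",
    QualityClass.SUBSTANDARD: "SS",
    QualityClass.FALSIFIED: "FA",
}


def generate_library(config: LibraryConfig) -> SampleSet:
    """Generate the full sample library described by ``config``.

    Deterministic given ``config.seed``. Batch effects (a shared baseline
    offset/slope) are drawn once per batch; per-sample baselines and
    per-scan noise are drawn independently. Bilayer doses yield two
    records, one per side, each carrying only that side's components.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.brands[0].formulation.excipient.grid
    records = []
    for plan in config.brands:
        form = plan.formulation
        for qc, cls_plan in (
            (QualityClass.QUALITY_ASSURED, plan.quality_assured),
            (QualityClass.SUBSTANDARD, plan.substandard),
            (QualityClass.FALSIFIED, plan.falsified),
        ):
            if cls_plan.samples == 0:
                continue
            tag = _QC_TAG[qc]
            sizes = _split_round_robin(cls_plan.samples, cls_plan.batches)
            idx = 0
            for b, size in enumerate(sizes):
                batch_id = f"{form.brand}-{tag}{b + 1:02d}"
                batch_offset = rng.normal(0.0, config.noise.batch_effect_sd)
                batch_slope = rng.normal(0.0, config.noise.batch_effect_sd / (grid[-1] - grid[0]))
                for _ in range(size):
                    idx += 1
                    sample_id = f"{form.brand}-{tag}-{idx:03d}"
                    conc, overrides = _draw_concentrations(plan, qc, rng)
                    sapi = {
                        name: 100.0 * conc[name] / nom if nom > 0 else 0.0
                        for name, nom in form.components.items()
                    }
                    if qc is QualityClass.FALSIFIED and plan.falsified_mode == "wrong_compound":
                        # wrong compound: none of the stated API is present
                        sapi = {name: 0.0 for name in sapi}
                    offset = (
                        config.base_absorbance
                        + batch_offset
                        + rng.normal(0.0, config.noise.baseline_offset_sd)
                    )
                    slope = batch_slope + rng.normal(0.0, config.noise.baseline_slope_sd)
                    if form.bilayer:
                        for side_name, comps in zip("AB", form.sides):
                            a = simulate_absorbance(
                                form, conc, (offset, slope), 0.0, rng,
                                components=comps, signatures=overrides,
                            )
                            scans = simulate_scan_set(
                                a, config.noise.scan_noise_sd, config.replicates, rng
                            )
                            for s in scans:
                                s.meta.update(sample_id=f"{sample_id}-{side_name}", side=side_name)
                            records.append(
                                SampleRecord(
                                    sample_id=f"{sample_id}-{side_name}",
                                    brand=form.brand,
                                    batch_id=batch_id,
                                    quality_class=qc,
                                    sapi_percent={k: v for k, v in sapi.items() if k in comps},
                                    scans=scans,
                                )
                            )
                    else:
                        a = simulate_absorbance(
                            form, conc, (offset, slope), 0.0, rng, signatures=overrides
                        )
                        scans = simulate_scan_set(
                            a, config.noise.scan_noise_sd, config.replicates, rng
                        )
                        for s in scans:
                            s.meta["sample_id"] = sample_id
                        records.append(
                            SampleRecord(
                                sample_id=sample_id,
                                brand=form.brand,
                                batch_id=batch_id,
                                quality_class=qc,
                                sapi_percent=sapi,
                                scans=scans,
                            )
                        )
    return SampleSet(records, grid)


# ---------------------------------------------------------------------------
# Config documents
# ---------------------------------------------------------------------------

def config_from_dict(doc: dict) -> LibraryConfig:
    """Build a LibraryConfig from a plain (YAML/JSON-loaded) mapping.

    Expected layout::

        seed: 1
        grid: {step: 1.0}
        replicates: 3
        noise: {baseline_offset_sd: ..., baseline_slope_sd: ...,
                batch_effect_sd: ..., scan_noise_sd: ...}
        brands:
          - name: BRAND-A
            components:
              api: {nominal: 1.0,
                    bands: [{center: 900, width: 15, amplitude: 0.8}]}
            excipient_bands: [{center: 800, width: 40, amplitude: 0.5}]
            bilayer: false            # optional; requires `sides`
            sides: [[api], [partner]] # only for bilayer
            quality_assured: {batches: 23, samples: 60}
            falsified: {batches: 3, samples: 22, mode: wrong_compound,
                        shift_nm: 60}
            substandard: {batches: 0, samples: 0, component: api,
                          sapi_range: [66, 85]}
            qa_sapi_range: [90, 110]
    """
    if "seed" not in doc:
        raise ValueError("config must carry an explicit integer `seed`")
    step = float(doc.get("grid", {}).get("step", 1.0))
    grid = default_grid(step)
    noise = NoiseModel(**doc.get("noise", {}))
    brands = []
    for b in doc["brands"]:
        comps, sigs = {}, {}
        for name, spec in b["components"].items():
            comps[name] = float(spec.get("nominal", 1.0))
            bands = [Band(bd["center"], bd["width"], bd["amplitude"]) for bd in spec["bands"]]
            sigs[name] = make_component_signature(name, bands, grid)
        exc_bands = [Band(bd["center"], bd["width"], bd["amplitude"])
                     for bd in b.get("excipient_bands", [])]
        excipient = make_component_signature("excipient", exc_bands, grid)
        form = FormulationSpec(
            brand=b["name"],
            components=comps,
            signatures=sigs,
            excipient=excipient,
            bilayer=bool(b.get("bilayer", False)),
            sides=tuple(map(frozenset, b["sides"])) if b.get("bilayer") else None,
        )
        sub = b.get("substandard", {})
        fal = b.get("falsified", {})
        plan = BrandPlan(
            formulation=form,
            quality_assured=ClassPlan(**{k: int(v) for k, v in b.get("quality_assured", {}).items()}),
            substandard=ClassPlan(batches=int(sub.get("batches", 0)), samples=int(sub.get("samples", 0))),
            falsified=ClassPlan(batches=int(fal.get("batches", 0)), samples=int(fal.get("samples", 0))),
            qa_sapi_range=tuple(b.get("qa_sapi_range", (90.0, 110.0))),
            substandard_sapi_range=tuple(sub.get("sapi_range", (66.0, 85.0))),
            substandard_component=sub.get("component"),
            falsified_mode=fal.get("mode", "wrong_compound"),
            wrong_shift_nm=float(fal.get("shift_nm", 60.0)),
        )
        brands.append(plan)
    return LibraryConfig(
        brands=brands,
        noise=noise,
        replicates=int(doc.get("replicates", 3)),
        base_absorbance=float(doc.get("base_absorbance", 0.1)),
        seed=int(doc["seed"]),
    )
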