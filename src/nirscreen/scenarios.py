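"""Ready-made library configurations for demos, tests and the acceptance
report.

These build generator configs in the *separable regime*: wrong-compound
bands displaced by at least three band-widths from the genuine API bands
and scan noise well below a tenth of the signal amplitude, so falsified
and quality-assured doses form linearly separable clusters in the top-2
PCA plane of their second-derivative spectra.
"""

from __future__ import annotations

from .authenticate import AuthenticateConfig
from .synthetic_data import (
    Band,
    BrandPlan,
    ClassPlan,
    FormulationSpec,
    LibraryConfig,
    NoiseModel,
    default_grid,
    make_component_signature,
)

__all__ = [
    "SEPARABLE_NOISE",
    "SEPARABLE_AUTH",
    "two_api_formulation",
    "monotherapy_formulation",
    "bilayer_formulation",
    "combo_brand_library",
    "monotherapy_library",
    "quantitation_library",
]

# Scan noise two orders below the ~0.5 AU band amplitudes; batch and
# baseline effects are affine in wavelength, which the second-derivative
# pipeline removes exactly.
SEPARABLE_NOISE = NoiseModel(
    baseline_offset_sd=0.02,
    baseline_slope_sd=5e-5,
    batch_effect_sd=0.03,
    scan_noise_sd=2e-4,
)

# Evaluation settings recommended for the separable regime. A 0.999
# chi-square quantile leaves headroom for finite-sample covariance
# estimation with small training batches while falsified doses still sit
# several thresholds out.
SEPARABLE_AUTH = AuthenticateConfig(threshold_quantile=0.999)

def _excipient(grid):
    return make_component_signature(
        "excipient",
        (Band(790.0, 55.0, 0.30), Band(955.0, 80.0, 0.40)),
        grid,
    )


def two_api_formulation(brand: str = "BRAND-A", grid=None) -> FormulationSpec:
    """A fixed-dose combination with two spectrally active APIs."""
    grid = default_grid() if grid is None else grid
    api1 = make_component_signature(
        "api1", (Band(870.0, 10.0, 0.9), Band(925.0, 12.0, 0.6)), grid
    )
    api2 = make_component_signature(
        "api2", (Band(985.0, 11.0, 0.8), Band(1030.0, 10.0, 0.5)), grid
    )
    return FormulationSpec(
        brand=brand,
        components={"api1": 1.0, "api2": 1.0},
        signatures={"api1": api1, "api2": api2},
        excipient=_excipient(grid),
    )


def monotherapy_formulation(brand: str = "BRAND-M", grid=None) -> FormulationSpec:
    """A single-API tablet."""
    grid = default_grid() if grid is None else grid
    api = make_component_signature(
        "api", (Band(880.0, 10.0, 0.9), Band(940.0, 12.0, 0.5)), grid
    )
    return FormulationSpec(
        brand=brand,
        components={"api": 1.0},
        signatures={"api": api},
        excipient=_excipient(grid),
    )


def bilayer_formulation(brand: str = "BRAND-B", grid=None) -> FormulationSpec:
    """A bilayer tablet: one API per side, shared excipient."""
    grid = default_grid() if grid is None else grid
    form = two_api_formulation(brand, grid)
    return FormulationSpec(
        brand=brand,
        components=form.components,
        signatures=form.signatures,
        excipient=form.excipient,
        bilayer=True,
        sides=(frozenset({"api1"}), frozenset({"api2"})),
    )


def combo_brand_library(
    seed: int,
    qa_batches: int = 23,
    qa_samples: int = 60,
    falsified_batches: int = 3,
    falsified_samples: int = 22,
    falsified_mode: str = "wrong_compound",
) -> LibraryConfig:
    """A two-API brand with many quality-assured batches plus falsified
    batches, in the separable regime."""
    plan = BrandPlan(
        formulation=two_api_formulation(),
        quality_assured=ClassPlan(batches=qa_batches, samples=qa_samples),
        falsified=ClassPlan(batches=falsified_batches, samples=falsified_samples),
        falsified_mode=falsified_mode,
        wrong_shift_nm=-60.0,  # > 3 band-widths for every 10-12 nm band
    )
    return LibraryConfig(brands=[plan], noise=SEPARABLE_NOISE, seed=seed)


def monotherapy_library(
    seed: int,
    qa_batches: int = 2,
    qa_samples: int = 36,
    falsified_batches: int = 1,
    falsified_samples: int = 1,
) -> LibraryConfig:
    """A monotherapy brand: few batches, a lone falsified sample."""
    plan = BrandPlan(
        formulation=monotherapy_formulation(),
        quality_assured=ClassPlan(batches=qa_batches, samples=qa_samples),
        falsified=ClassPlan(batches=falsified_batches, samples=falsified_samples),
        falsified_mode="wrong_compound",
        wrong_shift_nm=60.0,
    )
    return LibraryConfig(brands=[plan], noise=SEPARABLE_NOISE, seed=seed)


def quantitation_library(
    seed: int,
    n_samples: int = 30,
    batches: int = 7,
    sapi_range=(66.0, 85.0),
    analyte_visible: bool = True,
    scan_noise_sd: float = 2e-3,
) -> LibraryConfig:
    """A brand whose samples span a wide %SAPI range for one component.

    With ``analyte_visible=False`` the analyte's signature amplitude is
    zero — its content leaves no spectral trace, mimicking an API whose
    reference-standard spectrum is not distinguishable in the tablets.
    All samples are labeled substandard-range on the analyte so the
    generator draws %SAPI across ``sapi_range``.
    """
    grid = default_grid()
    amp = 1.0 if analyte_visible else 0.0
    analyte = make_component_signature(
        "analyte", (Band(900.0, 12.0, 0.9 * amp), Band(960.0, 10.0, 0.5 * amp)), grid
    )
    form = FormulationSpec(
        brand="BRAND-Q",
        components={"analyte": 1.0},
        signatures={"analyte": analyte},
        excipient=_excipient(grid),
    )
    plan = BrandPlan(
        formulation=form,
        substandard=ClassPlan(batches=batches, samples=n_samples),
        substandard_component="analyte",
        substandard_sapi_range=tuple(sapi_range),
    )
    noise = NoiseModel(
        baseline_offset_sd=0.02,
        baseline_slope_sd=5e-5,
        batch_effect_sd=0.03,
        scan_noise_sd=scan_noise_sd,
    )
    return LibraryConfig(brands=[plan], noise=noise, seed=seed)
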