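"""Synthetic LC-UV data with known ground truth.

This module emulates a 30-minute gradient separation of the ten citrus
flavonoids routinely assayed in raw and fermented Fructus Aurantii:
seven glycosides (eriocitrin, neoeriocitrin, narirutin, naringin,
hesperidin, neohesperidin, poncirin), the secondary glycoside
hesperidin-7-O-glucoside, and the aglycones naringenin and hesperetin,
in that elution order.  Naringin is the panel's single-marker reference.

Peaks are Gaussian (exponentially modified Gaussian when an asymmetry
factor is set) with area = response_factor x concentration x
injection_volume, superposed on linear baseline drift and additive white
noise.  Every generated trace carries a ground-truth manifest with the
exact area, apex time and height of each peak, so downstream detection,
integration, calibration and quantification can be tested against truth.

Default per-analyte response factors are chosen so that the marker-relative
correction factors of the simulated instrument equal the panel's accepted
reference values (see ``qamskit.datasets``); retention times are
conventional placements in the 5-26 min window of the gradient, not
measurements.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import exponnorm

from .chromatogram import Chromatogram

__all__ = [
    "ANALYTES",
    "GLYCOSIDES",
    "AGLYCONES",
    "SECONDARY_GLYCOSIDES",
    "MARKER",
    "PeakSpec",
    "SimulationConfig",
    "ManifestEntry",
    "GroundTruthManifest",
    "CohortResult",
    "StandardRun",
    "default_peak_specs",
    "example_ffa_config",
    "example_rfa_config",
    "simulate_chromatogram",
    "simulate_standard_series",
    "simulate_sample_cohort",
]

# Elution order of the ten-analyte panel.
ANALYTES: tuple[str, ...] = (
    "eriocitrin",
    "neoeriocitrin",
    "narirutin",
    "naringin",
    "hesperidin",
    "neohesperidin",
    "hesperidin-7-O-glucoside",
    "poncirin",
    "naringenin",
    "hesperetin",
)
GLYCOSIDES = (
    "eriocitrin",
    "neoeriocitrin",
    "narirutin",
    "naringin",
    "hesperidin",
    "neohesperidin",
    "poncirin",
)
SECONDARY_GLYCOSIDES = ("hesperidin-7-O-glucoside",)
AGLYCONES = ("naringenin", "hesperetin")
MARKER = "naringin"

# Conventional apex placements (min) spanning the 5-26 min gradient window.
DEFAULT_RETENTION_TIMES: dict[str, float] = {
    "eriocitrin": 5.8,
    "neoeriocitrin": 7.1,
    "narirutin": 9.2,
    "naringin": 10.4,
    "hesperidin": 12.6,
    "neohesperidin": 14.3,
    "hesperidin-7-O-glucoside": 16.8,
    "poncirin": 19.5,
    "naringenin": 22.4,
    "hesperetin": 25.2,
}

# Area units per (mg/mL x uL).  Scaled so the marker-relative correction
# factor f_{marker/analyte} = rf_analyte / rf_marker reproduces the panel's
# accepted mean values.
DEFAULT_RESPONSE_FACTORS: dict[str, float] = {
    "eriocitrin": 254.0,
    "neoeriocitrin": 333.0,
    "narirutin": 243.0,
    "naringin": 1000.0,
    "hesperidin": 525.0,
    "neohesperidin": 628.0,
    "hesperidin-7-O-glucoside": 353.0,
    "poncirin": 273.0,
    "naringenin": 563.0,
    "hesperetin": 482.0,
}

# Default mixed-reference-standard concentrations (mg/mL).
STANDARD_CONCENTRATIONS: dict[str, float] = {
    "eriocitrin": 0.050,
    "neoeriocitrin": 0.030,
    "narirutin": 0.060,
    "naringin": 0.400,
    "hesperidin": 0.040,
    "neohesperidin": 0.600,
    "hesperidin-7-O-glucoside": 0.100,
    "poncirin": 0.050,
    "naringenin": 0.020,
    "hesperetin": 0.015,
}

# Extract concentrations (mg/mL) of representative fermented / raw samples.
# Fermented: all ten analytes detectable; raw: glycosides only, the secondary
# glycoside and the two aglycones effectively absent (seven peaks).
EXAMPLE_FFA_CONCENTRATIONS: dict[str, float] = {
    "eriocitrin": 0.035,
    "neoeriocitrin": 0.025,
    "narirutin": 0.040,
    "naringin": 0.220,
    "hesperidin": 0.035,
    "neohesperidin": 0.420,
    "hesperidin-7-O-glucoside": 0.100,
    "poncirin": 0.030,
    "naringenin": 0.012,
    "hesperetin": 0.012,
}
EXAMPLE_RFA_CONCENTRATIONS: dict[str, float] = {
    "eriocitrin": 0.050,
    "neoeriocitrin": 0.024,
    "narirutin": 0.061,
    "naringin": 0.467,
    "hesperidin": 0.038,
    "neohesperidin": 0.533,
    "hesperidin-7-O-glucoside": 0.0,
    "poncirin": 0.044,
    "naringenin": 0.0,
    "hesperetin": 0.0,
}

# Mean contents (mg/g dry weight) of the raw herb used by the cohort
# generator, and fermented/raw mean ratios: fermentation depletes the
# glycosides and produces the secondary glycoside and aglycones.
RAW_MEAN_CONTENTS: dict[str, float] = {
    "eriocitrin": 4.5,
    "neoeriocitrin": 2.2,
    "narirutin": 5.5,
    "naringin": 42.0,
    "hesperidin": 3.4,
    "neohesperidin": 48.0,
    "hesperidin-7-O-glucoside": 0.15,
    "poncirin": 4.0,
    "naringenin": 0.04,
    "hesperetin": 0.02,
}
DEFAULT_FERMENTATION_EFFECT: dict[str, float] = {
    "eriocitrin": 0.72,
    "neoeriocitrin": 0.45,
    "narirutin": 0.68,
    "naringin": 0.45,
    "hesperidin": 0.70,
    "neohesperidin": 0.75,
    "hesperidin-7-O-glucoside": 33.0,
    "poncirin": 0.62,
    "naringenin": 25.0,
    "hesperetin": 40.0,
}

DEFAULT_SAMPLE_MASS_G = 0.5
DEFAULT_EXTRACT_VOLUME_ML = 45.0
DEFAULT_INJECTION_VOLUME_UL = 2.0
DEFAULT_WAVELENGTH_NM = 283
DEFAULT_SEED = 42


@dataclass(frozen=True)
class PeakSpec:
    """Static description of one analyte's chromatographic peak.

    ``response_factor`` is in area units per (mg/mL x uL); ``width_sigma``
    is the Gaussian standard deviation in minutes; ``asymmetry`` >= 0 is
    the exponential tail constant in units of sigma (0 = pure Gaussian).
    """

    analyte_name: str
    retention_time: float
    response_factor: float
    width_sigma: float
    asymmetry: float = 0.0

    def __post_init__(self) -> None:
        if self.retention_time <= 0:
            raise ValueError(f"{self.analyte_name}: retention_time must be > 0")
        if self.width_sigma <= 0:
            raise ValueError(f"{self.analyte_name}: width_sigma must be > 0")
        if self.response_factor <= 0:
            raise ValueError(f"{self.analyte_name}: response_factor must be > 0")
        if self.asymmetry < 0:
            raise ValueError(f"{self.analyte_name}: asymmetry must be >= 0")


def default_peak_specs(asymmetry: float = 0.0) -> list[PeakSpec]:
    """The ten-analyte panel with default retention times and responses.

    Peak widths grow mildly with retention time (0.04 + 0.002 x rt min),
    mimicking gradient-elution band broadening.
    """
    return [
        PeakSpec(
            analyte_name=name,
            retention_time=rt,
            response_factor=DEFAULT_RESPONSE_FACTORS[name],
            width_sigma=0.04 + 0.002 * rt,
            asymmetry=asymmetry,
        )
        for name, rt in DEFAULT_RETENTION_TIMES.items()
    ]


@dataclass
class SimulationConfig:
    """Everything needed to render one chromatogram deterministically."""

    peak_specs: Sequence[PeakSpec] = field(default_factory=default_peak_specs)
    concentrations: Mapping[str, float] = field(
        default_factory=lambda: dict(STANDARD_CONCENTRATIONS)
    )
    injection_volume: float = DEFAULT_INJECTION_VOLUME_UL
    run_length: float = 30.0
    sampling_rate: float = 100.0  # points per minute
    baseline_drift: float = 1.0  # intensity units per minute
    noise_sd: float = 2.0  # additive white-noise SD, intensity units
    seed: int = DEFAULT_SEED
    sample_id: str = "synthetic"

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.injection_volume <= 0:
            raise ValueError("injection_volume must be > 0")
        names = [s.analyte_name for s in self.peak_specs]
        if len(names) != len(set(names)):
            raise ValueError("analyte names within one panel must be unique")
        for spec in self.peak_specs:
            if self.concentrations.get(spec.analyte_name, 0.0) <= 0:
                continue  # absent peaks need not fit the window
            if spec.retention_time - 4 * spec.width_sigma < 0 or (
                spec.retention_time + 4 * spec.width_sigma > self.run_length
            ):
                raise ValueError(
                    f"peak of {spec.analyte_name!r} (rt={spec.retention_time:g} min, "
                    f"sigma={spec.width_sigma:g}) does not fit the "
                    f"{self.run_length:g} min run window"
                )


@dataclass(frozen=True)
class ManifestEntry:
    analyte_name: str
    retention_time: float
    area: float
    apex_time: float
    height: float


@dataclass
class GroundTruthManifest:
    """Exact per-peak truth for one simulated trace, in elution order."""

    entries: list[ManifestEntry]
    seed: int
    injection_volume: float

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.retention_time)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def analytes(self) -> list[str]:
        return [e.analyte_name for e in self.entries]

    def area(self, analyte_name: str) -> float:
        for e in self.entries:
            if e.analyte_name == analyte_name:
                return e.area
        raise KeyError(analyte_name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "analyte": e.analyte_name,
                    "retention_time": e.retention_time,
                    "area": e.area,
                    "apex_time": e.apex_time,
                    "height": e.height,
                }
                for e in self.entries
            ]
        )


def _peak_profile(spec: PeakSpec, t: np.ndarray, area: float) -> np.ndarray:
    """Unit-normalised peak shape scaled to the requested area."""
    if spec.asymmetry < 1e-9:
        z = (t - spec.retention_time) / spec.width_sigma
        return area / (spec.width_sigma * np.sqrt(2 * np.pi)) * np.exp(-0.5 * z * z)
    # exponentially modified Gaussian; K = tau/sigma is the asymmetry factor
    return area * exponnorm.pdf(
        t, spec.asymmetry, loc=spec.retention_time, scale=spec.width_sigma
    )


def _apex_of(spec: PeakSpec, area: float) -> tuple[float, float]:
    """(apex_time, height) of the noiseless component."""
    if spec.asymmetry < 1e-9:
        return spec.retention_time, area / (spec.width_sigma * np.sqrt(2 * np.pi))
    tt = np.linspace(
        spec.retention_time - 2 * spec.width_sigma,
        spec.retention_time + (6 + 4 * spec.asymmetry) * spec.width_sigma,
        4001,
    )
    yy = _peak_profile(spec, tt, area)
    i = int(np.argmax(yy))
    return float(tt[i]), float(yy[i])


def simulate_chromatogram(
    config: SimulationConfig,
) -> tuple[Chromatogram, GroundTruthManifest]:
    """Render one trace and its ground-truth manifest.

    Peak area is ``response_factor x concentration x injection_volume``;
    analytes with zero (or missing) concentration produce no peak and no
    manifest entry.  Identical config (including seed) gives an identical
    trace.
    """
    config.validate()
    n = int(round(config.run_length * config.sampling_rate)) + 1
    t = np.linspace(0.0, config.run_length, n)
    clean = np.zeros_like(t)
    entries: list[ManifestEntry] = []
    for spec in config.peak_specs:
        conc = float(config.concentrations.get(spec.analyte_name, 0.0))
        if conc <= 0:
            continue
        area = spec.response_factor * conc * config.injection_volume
        clean += _peak_profile(spec, t, area)
        apex_time, height = _apex_of(spec, area)
        entries.append(
            ManifestEntry(
                analyte_name=spec.analyte_name,
                retention_time=spec.retention_time,
                area=area,
                apex_time=apex_time,
                height=height,
            )
        )
    trace = clean + config.baseline_drift * t
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        trace = trace + rng.normal(0.0, config.noise_sd, size=t.size)
    chrom = Chromatogram(
        t,
        trace,
        metadata={
            "wavelength_nm": DEFAULT_WAVELENGTH_NM,
            "injection_volume_ul": config.injection_volume,
            "sample_id": config.sample_id,
            "seed": config.seed,
        },
    )
    return chrom, GroundTruthManifest(
        entries=entries, seed=config.seed, injection_volume=config.injection_volume
    )


def example_ffa_config(seed: int = DEFAULT_SEED, **overrides) -> SimulationConfig:
    """Default fermented-sample run: all ten peaks present."""
    kw = dict(
        concentrations=dict(EXAMPLE_FFA_CONCENTRATIONS),
        sample_id="FFA-example",
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


def example_rfa_config(seed: int = DEFAULT_SEED, **overrides) -> SimulationConfig:
    """Default raw-sample run: seven glycoside peaks, aglycones absent."""
    kw = dict(
        concentrations=dict(EXAMPLE_RFA_CONCENTRATIONS),
        sample_id="RFA-example",
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class StandardRun:
    """One mixed-standard injection of a calibration/RCF series."""

    level_index: int
    concentrations: dict[str, float]
    injection_volume: float
    chromatogram: Chromatogram
    manifest: GroundTruthManifest


def _resolve_levels(
    concentration_levels: Sequence[Mapping[str, float]] | Sequence[float],
    base: Mapping[str, float],
) -> list[dict[str, float]]:
    levels: list[dict[str, float]] = []
    for lev in concentration_levels:
        if isinstance(lev, Mapping):
            levels.append({k: float(v) for k, v in lev.items()})
        else:
            levels.append({k: float(lev) * v for k, v in base.items()})
    return levels


def simulate_standard_series(
    peak_specs: Sequence[PeakSpec] | None = None,
    *,
    concentration_levels: Sequence[Mapping[str, float]] | Sequence[float] = (1.0,),
    injection_volumes: Sequence[float] = (DEFAULT_INJECTION_VOLUME_UL,),
    seed: int = DEFAULT_SEED,
    base_concentrations: Mapping[str, float] | None = None,
    noise_sd: float = 0.0,
    baseline_drift: float = 0.0,
    **config_overrides,
) -> list[StandardRun]:
    """One chromatogram per (concentration level, injection volume) pair.

    Levels are either explicit per-analyte concentration mappings or scalar
    multipliers of ``base_concentrations`` (default: the mixed-standard
    recipe).  Areas scale exactly linearly in concentration and volume by
    construction.  Requires at least two levels or two volumes.
    """
    if len(concentration_levels) == 0:
        raise ValueError("concentration_levels must not be empty")
    if len(injection_volumes) == 0:
        raise ValueError("injection_volumes must not be empty")
    if len(concentration_levels) < 2 and len(injection_volumes) < 2:
        raise ValueError("need >= 2 concentration levels or >= 2 injection volumes")
    base = dict(base_concentrations or STANDARD_CONCENTRATIONS)
    levels = _resolve_levels(concentration_levels, base)
    specs = list(peak_specs) if peak_specs is not None else default_peak_specs()
    children = np.random.SeedSequence(seed).spawn(len(levels) * len(injection_volumes))
    runs: list[StandardRun] = []
    i = 0
    for li, conc in enumerate(levels):
        for vol in injection_volumes:
            cfg = SimulationConfig(
                peak_specs=specs,
                concentrations=conc,
                injection_volume=float(vol),
                noise_sd=noise_sd,
                baseline_drift=baseline_drift,
                seed=int(children[i].generate_state(1)[0] % (2**31)),
                sample_id=f"std-L{li}-V{vol:g}",
                **config_overrides,
            )
            chrom, manifest = simulate_chromatogram(cfg)
            runs.append(StandardRun(li, dict(conc), float(vol), chrom, manifest))
            i += 1
    return runs


@dataclass
class CohortResult:
    """Simulated per-sample contents with class labels and true means."""

    contents: pd.DataFrame  # samples x analytes, mg/g
    labels: pd.Series  # "RFA" | "FFA" per sample
    true_means: pd.DataFrame  # class x analyte mean contents


def simulate_sample_cohort(
    n_raw: int,
    n_fermented: int,
    effect_profile: Mapping[str, float] | None = None,
    seed: int = DEFAULT_SEED,
    *,
    cv: float = 0.15,
    raw_means: Mapping[str, float] | None = None,
) -> CohortResult:
    """Draw per-sample analyte contents for a raw-vs-fermented cohort.

    Contents are log-normal around class means with coefficient of
    variation ``cv``.  ``effect_profile`` maps analyte -> fermented/raw
    mean ratio (default: glycosides depleted, secondary glycoside and
    aglycones strongly increased); pass all-ones ratios for a no-signal
    null cohort.
    """
    if n_raw < 3 or n_fermented < 3:
        raise ValueError("need at least 3 samples per class")
    raw = dict(raw_means or RAW_MEAN_CONTENTS)
    effect = dict(DEFAULT_FERMENTATION_EFFECT if effect_profile is None else effect_profile)
    fermented = {a: raw[a] * float(effect.get(a, 1.0)) for a in raw}
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv * cv))

    def draw(means: Mapping[str, float], n: int) -> np.ndarray:
        cols = []
        for a in raw:
            m = means[a]
            if m <= 0:
                cols.append(np.zeros(n))
            else:
                mu = np.log(m) - 0.5 * sigma * sigma
                cols.append(rng.lognormal(mu, sigma, size=n))
        return np.column_stack(cols)

    x_raw = draw(raw, n_raw)
    x_fer = draw(fermented, n_fermented)
    idx = [f"R{i + 1}" for i in range(n_raw)] + [f"FF{i + 1}" for i in range(n_fermented)]
    contents = pd.DataFrame(
        np.vstack([x_raw, x_fer]), index=idx, columns=list(raw.keys())
    )
    labels = pd.Series(["RFA"] * n_raw + ["FFA"] * n_fermented, index=idx, name="class")
    true_means = pd.DataFrame([raw, fermented], index=["RFA", "FFA"])
    return CohortResult(contents=contents, labels=labels, true_means=true_means)


def contents_to_concentrations(
    contents: Mapping[str, float] | pd.Series,
    sample_mass_g: float = DEFAULT_SAMPLE_MASS_G,
    extract_volume_ml: float = DEFAULT_EXTRACT_VOLUME_ML,
) -> dict[str, float]:
    """mg/g dry weight -> mg/mL in the injected extract."""
    if sample_mass_g <= 0 or extract_volume_ml <= 0:
        raise ValueError("sample mass and extract volume must be positive")
    items = contents.items() if hasattr(contents, "items") else contents
    return {a: float(w) * sample_mass_g / extract_volume_ml for a, w in items}
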