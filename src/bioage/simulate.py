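"""Synthetic cohort generator.

Generates cohorts with the statistical structure that biomarker-based
biological-age (BA) estimation assumes:

* each subject's latent BA equals chronological age (CA) plus zero-mean
  Gaussian individual noise (sd ``s_ba``), optionally shifted by a constant
  ``group_shift_delta`` in "disease" groups;
* each biomarker is linear in BA, ``x_j = q_j + k_j * BA + noise``, with
  Gaussian additive noise of sd ``s_j`` (or multiplicative log-normal noise
  for markers such as C-reactive protein that live on a log scale);
* optional missing-completely-at-random masking and multiplicative outlier
  contamination, applied after generation so ground truth is preserved;
* optional exponential survival times whose hazard increases with the
  subject's true age acceleration (dAge = BA - CA).

Every generated table carries hidden columns ``true_ba`` and ``true_dage``
so downstream estimators can be checked against ground truth.

The random stream is laid out so that changing ``missing_rate`` or
``outlier_rate`` never alters the values of unaffected cells: all noise is
drawn first, then contamination masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, PanelError, SchemaError

__all__ = [
    "BiomarkerSpec",
    "GenerativeConfig",
    "PHAGE_MARKERS",
    "kdm8_specs",
    "phage9_specs",
    "generate_controls",
    "generate_disease_group",
    "generate_survival",
    "generate_phage_panel",
]

#: The nine markers of Levine's Phenotypic Age, in its native units
#: (albumin g/L, creatinine umol/L, glucose mmol/L, CRP mg/dL,
#: lymphocyte %, mean cell volume fL, red-cell distribution width %,
#: alkaline phosphatase U/L, white cells 1000 cells/uL).
PHAGE_MARKERS = (
    "albumin",
    "creatinine",
    "glucose",
    "crp",
    "lymphocyte_pct",
    "mcv",
    "rdw",
    "alp",
    "wbc",
)

_TRANSFORM_HINTS = ("none", "log-normal")


@dataclass(frozen=True)
class BiomarkerSpec:
    """Generative law of one biomarker: ``x = intercept + slope * BA + noise``.

    ``noise_sd`` is the sd of additive Gaussian noise for
    ``transform_hint="none"``; for ``"log-normal"`` it is the sd of the
    Gaussian perturbation on the log scale (the linear law then gives the
    median, and the marker stays strictly positive).
    """

    name: str
    intercept: float
    slope: float
    noise_sd: float
    transform_hint: str = "none"

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("biomarker spec field 'name' must be non-empty")
        if self.noise_sd < 0:
            raise ConfigurationError(
                f"biomarker {self.name!r}: field 'noise_sd' must be >= 0, "
                f"got {self.noise_sd}"
            )
        if self.transform_hint not in _TRANSFORM_HINTS:
            raise ConfigurationError(
                f"biomarker {self.name!r}: field 'transform_hint' must be one of "
                f"{_TRANSFORM_HINTS}, got {self.transform_hint!r}"
            )


def kdm8_specs() -> tuple[BiomarkerSpec, ...]:
    """Default 8-biomarker panel mirroring a routine clinical chemistry set.

    Slope signs follow the qualitative age trends of the corresponding real
    markers (creatinine, SBP, BUN, cholesterol and A1c rise with age;
    albumin and resting pulse fall).  Noise sds are set so each marker alone
    resolves age to about +/- 8.5 years (``noise_sd = 8.5 * |slope|``); the
    eight together then resolve BA to about 3 years, which keeps held-out
    recovery of the generative parameters sharp at cohort sizes of a few
    thousand.  Real survey panels are noisier; see the methods note.
    """
    return (
        BiomarkerSpec("creatinine", 0.55, 0.006, 0.051),  # mg/dL
        BiomarkerSpec("albumin", 4.90, -0.008, 0.068),  # g/dL
        BiomarkerSpec("cholesterol", 140.0, 1.0, 8.5),  # mg/dL
        BiomarkerSpec("bun", 9.0, 0.10, 0.85),  # mg/dL
        BiomarkerSpec("sbp", 92.0, 0.50, 4.25),  # mmHg
        BiomarkerSpec("dbp", 66.0, 0.15, 1.275),  # mmHg
        BiomarkerSpec("pulse", 76.0, -0.10, 0.85),  # /min
        BiomarkerSpec("a1c", 4.60, 0.010, 0.085),  # %
    )


def phage9_specs() -> tuple[BiomarkerSpec, ...]:
    """Default nine-marker Phenotypic-Age panel in Levine units.

    CRP is log-normal (its formula term is ln(CRP)); all laws keep markers
    strictly positive over ages 20-80 with wide margin.
    """
    return (
        BiomarkerSpec("albumin", 47.0, -0.05, 1.2),  # g/L
        BiomarkerSpec("creatinine", 60.0, 0.35, 8.0),  # umol/L
        BiomarkerSpec("glucose", 4.60, 0.012, 0.35),  # mmol/L
        BiomarkerSpec("crp", 0.08, 0.003, 0.5, transform_hint="log-normal"),  # mg/dL
        BiomarkerSpec("lymphocyte_pct", 36.0, -0.08, 4.0),  # %
        BiomarkerSpec("mcv", 86.0, 0.06, 3.0),  # fL
        BiomarkerSpec("rdw", 12.2, 0.012, 0.5),  # %
        BiomarkerSpec("alp", 55.0, 0.25, 12.0),  # U/L
        BiomarkerSpec("wbc", 6.5, 0.005, 1.2),  # 1000 cells/uL
    )


@dataclass(frozen=True)
class GenerativeConfig:
    """Parameters of the synthetic cohort.

    ``s_ba`` is the sd (years) of the individual BA-CA noise;
    ``group_shift_delta`` (years) is the constant BA acceleration added in a
    disease group and ignored for controls.
    """

    n_subjects: int
    age_range: tuple[float, float] = (20.0, 80.0)
    female_fraction: float = 0.5
    biomarker_specs: tuple[BiomarkerSpec, ...] = field(default_factory=kdm8_specs)
    s_ba: float = 5.0
    group_shift_delta: float = 0.0
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    outlier_factors: tuple[float, ...] = (3.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError(
                f"field 'n_subjects' must be >= 1, got {self.n_subjects}"
            )
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError(
                f"field 'age_range' must satisfy min < max, got {self.age_range}"
            )
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigurationError(
                f"field 'female_fraction' must lie in [0, 1], got {self.female_fraction}"
            )
        if self.s_ba < 0:
            raise ConfigurationError(f"field 's_ba' must be >= 0, got {self.s_ba}")
        for rate_name in ("missing_rate", "outlier_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"field {rate_name!r} must lie in [0, 1], got {rate}"
                )
        names = [s.name for s in self.biomarker_specs]
        if len(names) != len(set(names)):
            raise ConfigurationError(
                "field 'biomarker_specs' contains duplicate biomarker names"
            )
        if not self.biomarker_specs:
            raise ConfigurationError("field 'biomarker_specs' must be non-empty")


def _generate(config: GenerativeConfig, group: str, shift: float) -> pd.DataFrame:
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    specs = config.biomarker_specs

    ca = rng.uniform(*config.age_range, size=n)
    gender = np.where(rng.random(n) < config.female_fraction, "female", "male")
    ba_noise = rng.normal(0.0, config.s_ba, size=n) if config.s_ba > 0 else np.zeros(n)
    true_ba = ca + ba_noise + shift

    columns: dict[str, np.ndarray] = {}
    for spec in specs:
        level = spec.intercept + spec.slope * true_ba
        noise = rng.normal(0.0, 1.0, size=n)
        if spec.transform_hint == "log-normal":
            if np.any(level <= 0):
                raise DomainError(
                    f"biomarker {spec.name!r}: log-normal law requires a strictly "
                    "positive median; intercept + slope * BA dips below zero"
                )
            values = level * np.exp(spec.noise_sd * noise)
        else:
            values = level + spec.noise_sd * noise
        columns[spec.name] = values

    # Contamination draws are made for every cell regardless of the rates so
    # that raising a rate only adds masked cells, never reshuffles the rest.
    m = len(specs)
    outlier_u = rng.random((n, m))
    factor_idx = rng.integers(0, len(config.outlier_factors), size=(n, m))
    missing_u = rng.random((n, m))

    factors = np.asarray(config.outlier_factors, dtype=float)[factor_idx]
    for j, spec in enumerate(specs):
        vals = columns[spec.name]
        out_mask = outlier_u[:, j] < config.outlier_rate
        vals = np.where(out_mask, vals * factors[:, j], vals)
        vals = np.where(missing_u[:, j] < config.missing_rate, np.nan, vals)
        columns[spec.name] = vals

    df = pd.DataFrame(
        {
            "subject_id": [f"{group}-{i:06d}" for i in range(n)],
            "ca": ca,
            "gender": gender,
            "group": group,
            **columns,
            "true_ba": true_ba,
            "true_dage": true_ba - ca,
        }
    )
    return df


def generate_controls(config: GenerativeConfig) -> pd.DataFrame:
    """Generate a control cohort (no group-level BA shift).

    CA is uniform over ``age_range``; gender is Bernoulli(``female_fraction``);
    ``true_ba = ca + Normal(0, s_ba**2)``; each biomarker follows its spec.
    Fully reproducible from ``config.seed``.
    """
    return _generate(config, "control", 0.0)


def generate_disease_group(config: GenerativeConfig, label: str = "t2d") -> pd.DataFrame:
    """Generate a disease cohort whose true BA gains ``group_shift_delta`` years."""
    if not label:
        raise ConfigurationError("field 'label' must be a non-empty group label")
    return _generate(config, label, config.group_shift_delta)


def generate_survival(
    cohort: pd.DataFrame,
    baseline_hazard: float,
    log_hr_per_year: float,
    censor_time: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach exponential survival times whose hazard rises with true dAge.

    The per-subject hazard is ``baseline_hazard * exp(log_hr_per_year *
    true_dage)`` (a proportional-hazards law with constant baseline);
    follow-up is administratively censored at ``censor_time`` years.
    Returns a copy of ``cohort`` with ``time`` and ``event`` columns.
    """
    if baseline_hazard <= 0:
        raise ConfigurationError(
            f"field 'baseline_hazard' must be > 0, got {baseline_hazard}"
        )
    if censor_time < 0:
        raise ConfigurationError(f"field 'censor_time' must be >= 0, got {censor_time}")
    if "true_dage" not in cohort.columns:
        raise SchemaError("cohort lacks required column 'true_dage'")
    rng = np.random.default_rng(seed)
    dage = cohort["true_dage"].to_numpy(dtype=float)
    hazard = baseline_hazard * np.exp(log_hr_per_year * dage)
    t = rng.exponential(1.0 / hazard)
    event = t <= censor_time
    out = cohort.copy()
    out["time"] = np.where(event, t, censor_time)
    out["event"] = event.astype(int)
    return out


def generate_phage_panel(config: GenerativeConfig) -> pd.DataFrame:
    """Generate a control cohort carrying the nine Phenotypic-Age markers.

    The config's specs must cover all nine markers (Levine units); CRP must
    be log-normal so its log-scale formula term is defined.  All marker
    columns are checked to be strictly positive.
    """
    names = {s.name for s in config.biomarker_specs}
    absent = [m for m in PHAGE_MARKERS if m not in names]
    if absent:
        raise PanelError(
            "phenotypic-age panel is missing markers: " + ", ".join(absent)
        )
    crp_spec = next(s for s in config.biomarker_specs if s.name == "crp")
    if crp_spec.transform_hint != "log-normal":
        config = replace(
            config,
            biomarker_specs=tuple(
                replace(s, transform_hint="log-normal") if s.name == "crp" else s
                for s in config.biomarker_specs
            ),
        )
    df = generate_controls(config)
    for marker in PHAGE_MARKERS:
        vals = df[marker].to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] <= 0):
            raise DomainError(
                f"marker {marker!r} generated non-positive values; tighten its "
                "spec (the Phenotypic Age formula requires positive inputs)"
            )
    return df
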