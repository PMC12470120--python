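"""Synthetic saliva Raman cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: per-subject replicate spectra built from a fixed library of
Lorentzian (or Gaussian) bands on a 400-1600 cm^-1 axis, a cubic
fluorescence-like background, additive Gaussian noise, small rigid
wavenumber miscalibration per replicate, and a clinical covariate table.

Group structure
---------------
* Disease (OSAS) spectra carry multiplicative amplitude effects on a subset
  of bands: elevated lactic acid (920), carotenoids (957), collagen (1030)
  and cholesterol (1444); attenuated protein bands (618, 640, 1548) and the
  saccharide/glycerol/carotene bands (477, 589, 630, 1517) that dominate
  control spectra. The aluminum substrate band (1250) is group-neutral.
* Each subject has a latent severity score that scales the group effect,
  so within-group spectral heterogeneity is correlated across bands.
* Salivary lactate concentration is drawn from per-group lognormals whose
  parameters are solved from the target median and IQR, and is negatively
  coupled to the latent severity: concentrations run *higher* in controls
  even though the spectral 920 band runs higher in disease, reproducing the
  discordance between the spectroscopic and assay readouts.

Everything random flows from the single config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .spectra_io import ClinicalRecord, Cohort, RamanSpectrum, SubjectRecord

# quartile z-score of the standard normal: IQR = 2*sinh(z_q * sigma) * median
_Z_QUARTILE = 0.6744897501960817


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple:
    """Solve lognormal (mu, sigma) from a target median and IQR.

    For X ~ LogNormal(mu, sigma): median = e^mu and
    IQR = e^mu (e^{z sigma} - e^{-z sigma}) = 2 median sinh(z sigma) with
    z the 0.75 normal quantile, so sigma = asinh(iqr / (2 median)) / z.
    """
    if median <= 0 or iqr <= 0:
        raise ConfigError("median and IQR must be positive")
    mu = math.log(median)
    sigma = math.asinh(iqr / (2.0 * median)) / _Z_QUARTILE
    return mu, sigma


@dataclass(frozen=True)
class PeakSpec:
    """One band of the spectral library."""

    center: float            # cm^-1
    width: float             # Gaussian sigma or Lorentzian gamma (HWHM), cm^-1
    base_amplitude: float    # a.u., control-group amplitude
    osas_multiplier: float = 1.0   # >1 elevated in OSAS, <1 elevated in CTR
    shape: str = "lorentzian"

    def __post_init__(self):
        if self.width <= 0 or self.base_amplitude <= 0 or self.osas_multiplier <= 0:
            raise ConfigError("peak width, amplitude and multiplier must be > 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ConfigError(f"unknown peak shape {self.shape!r}")

    def profile(self, x: np.ndarray) -> np.ndarray:
        d = x - self.center
        if self.shape == "gaussian":
            return np.exp(-0.5 * (d / self.width) ** 2)
        return 1.0 / (1.0 + (d / self.width) ** 2)


def default_peak_library() -> list:
    """Saliva band library: centers from the dried-drop fingerprint
    assignments, with group effect directions as observed OSAS vs CTR."""
    up, down = 1.30, 0.78   # OSAS-elevated / CTR-elevated amplitude ratios
    rows = [
        # center width amp   multiplier
        (477.0,  6.0, 2.0, down),   # saccharides
        (505.0,  5.0, 2.0, 1.0),    # methoxy group
        (589.0,  5.0, 2.0, down),   # phosphate of hydroxyapatite
        (618.0,  4.0, 3.0, down),   # C-C twist, proteins
        (630.0,  4.0, 2.0, down),   # glycerol
        (640.0,  4.0, 3.0, down),   # C-S stretch / tyrosine
        (755.0,  5.0, 3.5, 1.0),    # tryptophan
        (825.0,  5.0, 3.0, 1.0),    # phosphodiester
        (853.0,  5.0, 5.0, 1.0),    # tyrosine, proline
        (875.0,  5.0, 3.0, 1.0),    # phospholipids
        (920.0,  5.0, 4.0, 1.35),   # lactic acid / glucose, C-C proline
        (957.0,  5.0, 4.0, up),     # carotenoids
        (1003.0, 4.0, 10.0, 1.0),   # phenylalanine (alignment reference)
        (1030.0, 5.0, 5.0, 1.25),   # phenylalanine of collagen
        (1095.0, 6.0, 3.0, 1.0),    # phosphodioxy / C-N
        (1120.0, 6.0, 2.5, 1.0),    # C-O of ribose
        (1153.0, 6.0, 2.5, 1.0),    # carbohydrates
        (1250.0, 8.0, 1.5, 1.0),    # aluminum substrate band (group-neutral)
        (1308.0, 6.0, 3.0, 1.0),    # C-N aromatic amines
        (1444.0, 9.0, 7.0, 1.20),   # cholesterol / fatty acids
        (1517.0, 6.0, 2.0, down),   # beta-carotene
        (1548.0, 6.0, 5.0, down),   # tryptophan
    ]
    return [
        PeakSpec(center=c, width=w, base_amplitude=a, osas_multiplier=m)
        for c, w, a, m in rows
    ]


@dataclass
class SyntheticCohortConfig:
    """Everything the generator needs; defaults mirror the study conditions.

    Cohort size defaults to 51 OSAS / 34 CTR with 10 replicates per subject;
    AHI severity proportions are 14:14:23 (mild:moderate:severe); lactate
    lognormals are solved from medians/IQRs of 13.23/20.51 uM (OSAS) and
    37.76/54.04 uM (CTR).
    """

    n_osas: int = 51
    n_ctr: int = 34
    replicates_per_subject: int = 10
    peak_library: list = field(default_factory=default_peak_library)
    axis_start: float = 396.0
    axis_step: float = 1.21
    axis_points: int = 1000
    subject_scale_cv: float = 0.15          # lognormal CV of overall intensity
    peak_amplitude_cv: float = 0.25         # per-subject, per-band biological CV
    severity_effect_sd: float = 0.30        # latent severity scaling of effects
    replicate_noise_sd: float = 0.15        # a.u., additive Gaussian per point
    baseline_coefficients_range: tuple = (  # cubic on t in [0, 1]
        (5.0, 15.0), (-6.0, 2.0), (-4.0, 4.0), (-4.0, 4.0)
    )
    wavenumber_jitter_sd: float = 0.3       # cm^-1 rigid shift per replicate
    ahi_proportions: tuple = (14 / 51, 14 / 51, 23 / 51)
    lactate_median_iqr: dict = field(
        default_factory=lambda: {"OSAS": (13.23, 20.51), "CTR": (37.76, 54.04)}
    )
    cortisol_median_iqr: dict = field(
        default_factory=lambda: {"OSAS": (4.5, 3.0), "CTR": (3.2, 2.2)}
    )
    sod3_median_iqr: dict = field(
        default_factory=lambda: {"OSAS": (120.0, 80.0), "CTR": (90.0, 60.0)}
    )
    bmi_mean_sd: dict = field(
        default_factory=lambda: {"OSAS": (31.0, 4.0), "CTR": (27.0, 3.5)}
    )
    latent_coupling: float = 0.55           # severity -> lactate coupling
    seed: int = 0

    def __post_init__(self):
        if self.n_osas < 1 or self.n_ctr < 1 or self.replicates_per_subject < 1:
            raise ConfigError("cohort sizes and replicate count must be >= 1")
        if abs(sum(self.ahi_proportions) - 1.0) > 1e-9:
            raise ConfigError("ahi_proportions must sum to 1")
        if not 0.0 <= self.latent_coupling <= 1.0:
            raise ConfigError("latent_coupling must lie in [0, 1]")
        for name in ("subject_scale_cv", "replicate_noise_sd",
                     "wavenumber_jitter_sd", "severity_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")

    @property
    def axis(self) -> np.ndarray:
        return self.axis_start + self.axis_step * np.arange(self.axis_points)


_AHI_BINS = {"mild": (5.0, 15.0), "moderate": (15.0, 30.0), "severe": (30.0, 60.0)}


def _draw_lognormal(rng, median_iqr: tuple, z: np.ndarray) -> np.ndarray:
    mu, sigma = lognormal_from_median_iqr(*median_iqr)
    return np.exp(mu + sigma * z)


def generate_cohort(config: Optional[SyntheticCohortConfig] = None) -> Cohort:
    """Generate a full synthetic cohort (raw spectra + clinical records).

    The returned :class:`~salivaraman.spectra_io.Cohort` carries a
    ``ground_truth`` table of every planted per-subject parameter.
    """
    config = config or SyntheticCohortConfig()
    rng = np.random.default_rng(config.seed)
    x = config.axis

    centers = np.array([p.center for p in config.peak_library])
    log_mult = np.log(np.array([p.osas_multiplier for p in config.peak_library]))
    amps = np.array([p.base_amplitude for p in config.peak_library])
    profiles = np.vstack([p.profile(x) for p in config.peak_library])

    sigma_scale = math.sqrt(math.log(1.0 + config.subject_scale_cv**2))
    sigma_peak = math.sqrt(math.log(1.0 + config.peak_amplitude_cv**2))

    subjects, truth_rows = [], []
    n_total = config.n_osas + config.n_ctr
    groups = ["OSAS"] * config.n_osas + ["CTR"] * config.n_ctr
    for i in range(n_total):
        group = groups[i]
        sid = f"{'O' if group == 'OSAS' else 'C'}{i + 1:03d}"
        is_osas = group == "OSAS"

        severity = float(rng.normal(0.0, 1.0))
        effect_gain = float(np.clip(1.0 + config.severity_effect_sd * severity, 0.2, 1.8))
        scale = float(rng.lognormal(-0.5 * sigma_scale**2, sigma_scale))
        # CTR spectra sit at the baseline amplitudes; OSAS spectra apply the
        # severity-scaled group multipliers
        eff_log_mult = effect_gain * log_mult if is_osas else np.zeros_like(log_mult)
        # biological composition noise: each band's amplitude varies between
        # subjects independently of group
        bio = rng.normal(-0.5 * sigma_peak**2, sigma_peak, size=log_mult.size)
        subject_amps = amps * np.exp(eff_log_mult + bio) * scale
        clean = subject_amps @ profiles

        # covariates -------------------------------------------------------
        eps = float(rng.normal(0.0, 1.0))
        c = config.latent_coupling
        z_lact = -c * severity + math.sqrt(max(0.0, 1.0 - c**2)) * eps
        lactate = float(_draw_lognormal(rng, config.lactate_median_iqr[group],
                                        np.array(z_lact)))
        cortisol = float(_draw_lognormal(rng, config.cortisol_median_iqr[group],
                                         rng.normal()))
        sod3 = float(_draw_lognormal(rng, config.sod3_median_iqr[group],
                                     rng.normal()))
        bmi_mu, bmi_sd = config.bmi_mean_sd[group]
        bmi = float(np.clip(rng.normal(bmi_mu, bmi_sd), 18.0, 50.0))
        age = float(np.clip(rng.normal(64.0, 12.0), 25.0, 88.0))
        sex = "M" if rng.random() < (0.57 if is_osas else 0.44) else "F"
        smoking = ("non_smoker", "smoker", "former")[
            int(rng.choice(3, p=(0.5, 0.25, 0.25)))
        ]
        if is_osas:
            cls = ("mild", "moderate", "severe")[
                int(rng.choice(3, p=config.ahi_proportions))
            ]
            lo, hi = _AHI_BINS[cls]
            ahi = float(rng.uniform(lo, hi))
            ess = int(np.clip(round(rng.normal(10.0, 4.0)), 0, 24))
        else:
            cls, ahi = None, None
            ess = int(np.clip(round(rng.normal(5.0, 3.0)), 0, 24))

        clinical = ClinicalRecord(
            subject_id=sid, group=group, age=age, sex=sex, ahi=ahi, bmi=bmi,
            ess=ess, smoking=smoking, lactate_uM=lactate,
            cortisol_ng_ml=cortisol, sod3_pg_ml=sod3,
        )

        # replicate spectra ------------------------------------------------
        replicates = []
        truth_base = []
        for rep in range(config.replicates_per_subject):
            jitter = float(rng.normal(0.0, config.wavenumber_jitter_sd))
            # rigid miscalibration: peak pattern displaced by `jitter` on the
            # recorded axis
            if jitter != 0.0:
                signal = np.interp(x - jitter, x, clean, left=clean[0], right=clean[-1])
            else:
                signal = clean
            coeffs = [float(rng.uniform(lo, hi))
                      for lo, hi in config.baseline_coefficients_range]
            t = (x - x[0]) / (x[-1] - x[0])
            base = coeffs[0] + coeffs[1] * t + coeffs[2] * t**2 + coeffs[3] * t**3
            noise = rng.normal(0.0, config.replicate_noise_sd, x.size)
            replicates.append(
                RamanSpectrum(
                    wavenumbers=x.copy(),
                    intensities=signal + base + noise,
                    subject_id=sid,
                    replicate_index=rep + 1,
                    stage="raw",
                )
            )
            truth_base.append({"jitter": jitter, "baseline_coefficients": coeffs})

        subjects.append(SubjectRecord(clinical=clinical, replicates=replicates))
        truth_rows.append(
            {
                "subject_id": sid,
                "group": group,
                "latent_severity": severity,
                "effect_gain": effect_gain if is_osas else 0.0,
                "subject_scale": scale,
                "multiplier_920": float(np.exp(eff_log_mult[np.argmin(np.abs(centers - 920))])),
                "ahi_class": cls,
                "lactate_uM": lactate,
            }
        )

    truth = pd.DataFrame(truth_rows).set_index("subject_id")
    return Cohort(subjects=subjects, ground_truth=truth)


def null_config(config: Optional[SyntheticCohortConfig] = None) -> SyntheticCohortConfig:
    """A copy of `config` with every group effect neutralized.

    Spectral multipliers become 1, the lactate-severity coupling is removed,
    and both groups share the OSAS covariate distributions; group labels are
    retained so type-I calibration can run the full analysis unchanged.
    """
    config = config or SyntheticCohortConfig()
    flat = [replace(p, osas_multiplier=1.0) for p in config.peak_library]
    return replace(
        config,
        peak_library=flat,
        latent_coupling=0.0,
        lactate_median_iqr={g: config.lactate_median_iqr["OSAS"] for g in ("OSAS", "CTR")},
        cortisol_median_iqr={g: config.cortisol_median_iqr["OSAS"] for g in ("OSAS", "CTR")},
        sod3_median_iqr={g: config.sod3_median_iqr["OSAS"] for g in ("OSAS", "CTR")},
        bmi_mean_sd={g: config.bmi_mean_sd["OSAS"] for g in ("OSAS", "CTR")},
    )


def generate_null_cohort(config: Optional[SyntheticCohortConfig] = None) -> Cohort:
    """Generate a cohort with all group effects off (labels retained)."""
    return generate_cohort(null_config(config))


def ground_truth_report(cohort: Cohort) -> pd.DataFrame:
    """Planted per-subject parameters of a generated cohort."""
    if cohort.ground_truth is None:
        raise ConfigError(
            "cohort carries no ground truth (not produced by this generator)"
        )
    return cohort.ground_truth.copy()
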