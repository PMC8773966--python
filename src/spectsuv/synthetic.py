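"""Synthetic cohorts and digital phantoms for the SUVmax analysis pipeline.

No per-lesion data are publicly deposited for this kind of bone SPECT-CT
cohort, so the pipeline is exercised on simulated data whose summary
structure matches the published cohort: 70 female patients, 236 metastatic
and 179 degenerative lesions (one to five per patient per category),
region frequencies from the published localization table, and SUVmax drawn
from truncated-lognormal distributions calibrated by moment matching to
the published mean/sd within the published min/max:

* metastatic:   mean 32.56, sd 16.39, range [10.90, 130.70] g/mL
* degenerative: mean 10.26, sd  4.67, range [ 3.50,  27.00] g/mL

The lognormal family is used because the published SUVmax samples are
right-skewed and reject normality; truncation enforces the printed ranges.

Digital phantoms invert the SUV mapping: prescribed true SUV spheres are
converted to activity concentrations for a given patient so quantification
plus segmentation can be validated end to end, optionally with Gaussian
blur and Poisson counting noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from .quantification import (ActivityVolume, PatientRecord, Sex,
                             TC99M_HALF_LIFE_H, decay_correction,
                             lean_body_mass)

__all__ = [
    "TruncLogNormalParams",
    "CohortConfig",
    "METASTATIC_TARGETS",
    "DEGENERATIVE_TARGETS",
    "REGION_COUNTS",
    "truncated_lognormal_moments",
    "fit_truncated_lognormal",
    "sample_suv",
    "sample_cohort",
    "build_phantom",
]

# Published cohort summaries the generator is calibrated to:
# (mean, sd, min, max) of SUVmax in g/mL per lesion category.
METASTATIC_TARGETS = (32.56, 16.39, 10.90, 130.70)
DEGENERATIVE_TARGETS = (10.26, 4.67, 3.50, 27.00)

# Lesion counts per region (L, T, P, O) per category, from the published
# localization table; used as sampling proportions.
REGION_COUNTS = {
    "metastatic": {"L": 50, "T": 50, "P": 61, "O": 75},
    "degenerative": {"L": 74, "T": 54, "P": 16, "O": 35},
}


@dataclass(frozen=True)
class TruncLogNormalParams:
    """Log-space location/scale and truncation bounds (g/mL)."""

    mu: float
    sigma: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.lo < self.hi:
            raise ValueError("require 0 < lo < hi")


@dataclass
class CohortConfig:
    """Study-design parameters of the simulated cohort.

    Lesion counts and region probabilities reflect the published cohort;
    age, injected activity and injection-to-scan delay follow the published
    mean +/- sd.  Weight/height distributions are generator plumbing (not
    published) and only feed phantom/quantification realism.
    """

    n_patients: int = 70
    n_metastatic: int = 236
    n_degenerative: int = 179
    max_lesions_per_category: int = 5
    age_mean_sd: tuple[float, float] = (59.36, 11.45)          # years
    activity_mean_sd: tuple[float, float] = (673.61, 56.64)    # MBq injected
    delay_mean_sd: tuple[float, float] = (176.32, 34.47)       # minutes
    weight_mean_sd: tuple[float, float] = (70.0, 12.0)         # kg
    weight_bounds: tuple[float, float] = (40.0, 120.0)
    height_mean_sd: tuple[float, float] = (163.0, 7.0)         # cm
    height_bounds: tuple[float, float] = (140.0, 185.0)
    metastatic_targets: tuple[float, float, float, float] = METASTATIC_TARGETS
    degenerative_targets: tuple[float, float, float, float] = (
        DEGENERATIVE_TARGETS)
    seed: int = 0

    def __post_init__(self) -> None:
        for cat, n in (("metastatic", self.n_metastatic),
                       ("degenerative", self.n_degenerative)):
            if n < self.n_patients or n > (self.max_lesions_per_category
                                           * self.n_patients):
                raise ValueError(
                    f"{cat} total {n} infeasible for {self.n_patients} "
                    f"patients with 1..{self.max_lesions_per_category} "
                    "lesions each")

    def region_probs(self, category: str) -> dict[str, float]:
        counts = REGION_COUNTS[category]
        total = sum(counts.values())
        return {r: c / total for r, c in counts.items()}


def truncated_lognormal_moments(mu: float, sigma: float, lo: float,
                                hi: float) -> tuple[float, float]:
    """Mean and sd of a lognormal(mu, sigma) truncated to [lo, hi].

    Closed form: with a = (ln lo - mu)/sigma, b = (ln hi - mu)/sigma and
    Z = Phi(b) - Phi(a),
        E[X^k] = exp(k mu + k^2 sigma^2 / 2)
                 * (Phi(b - k sigma) - Phi(a - k sigma)) / Z.
    """
    a = (math.log(lo) - mu) / sigma
    b = (math.log(hi) - mu) / sigma
    z = stats.norm.cdf(b) - stats.norm.cdf(a)
    if z <= 0:
        raise ValueError("truncation interval has zero mass")

    def raw(k: int) -> float:
        return (math.exp(k * mu + 0.5 * k * k * sigma * sigma)
                * (stats.norm.cdf(b - k * sigma)
                   - stats.norm.cdf(a - k * sigma)) / z)

    m1 = raw(1)
    var = raw(2) - m1 * m1
    return m1, math.sqrt(max(var, 0.0))


def fit_truncated_lognormal(target_mean: float, target_sd: float,
                            lo: float, hi: float,
                            rel_tol: float = 1e-9) -> TruncLogNormalParams:
    """Calibrate (mu, sigma) so the truncated moments hit the targets.

    Solved with a root finder started from the untruncated moment match
    mu = ln m - 0.5 ln(1 + (s/m)^2), sigma^2 = ln(1 + (s/m)^2).
    Raises on failure to reach 1e-6 relative residuals.
    """
    if not lo < target_mean < hi:
        raise ValueError("target mean must lie inside (lo, hi)")
    if target_sd <= 0:
        raise ValueError("target sd must be positive")
    cv2 = (target_sd / target_mean) ** 2
    mu0 = math.log(target_mean) - 0.5 * math.log1p(cv2)
    sigma0 = math.sqrt(math.log1p(cv2))

    def residuals(p):
        mu, log_sigma = p
        m, s = truncated_lognormal_moments(mu, math.exp(log_sigma), lo, hi)
        return [(m - target_mean) / target_mean, (s - target_sd) / target_sd]

    sol = optimize.root(residuals, x0=[mu0, math.log(sigma0)], method="hybr",
                        options={"xtol": 1e-13})
    res = residuals(sol.x)
    if max(abs(r) for r in res) > 1e-6:
        raise RuntimeError(
            f"truncated-lognormal calibration did not converge: "
            f"relative residuals {res}")
    return TruncLogNormalParams(mu=float(sol.x[0]),
                                sigma=float(math.exp(sol.x[1])),
                                lo=lo, hi=hi)


def sample_suv(params: TruncLogNormalParams, n: int,
               rng: np.random.Generator | int) -> np.ndarray:
    """Inverse-CDF draws from the truncated lognormal; all in [lo, hi]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    a = (math.log(params.lo) - params.mu) / params.sigma
    b = (math.log(params.hi) - params.mu) / params.sigma
    u = rng.uniform(stats.norm.cdf(a), stats.norm.cdf(b), size=n)
    x = np.exp(params.mu + params.sigma * stats.norm.ppf(u))
    return np.clip(x, params.lo, params.hi)


def _allocate_lesions(total: int, n_patients: int, cap: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Split ``total`` lesions over patients, each getting 1..cap.

    Multinomial allocation of the surplus above the mandatory one per
    patient, then deterministic rebalancing of any counts clipped at cap.
    """
    counts = np.ones(n_patients, dtype=int)
    surplus = total - n_patients
    counts += rng.multinomial(surplus, np.full(n_patients, 1 / n_patients))
    while counts.max() > cap:
        over = counts > cap
        excess = int((counts[over] - cap).sum())
        counts[over] = cap
        room = cap - counts
        order = rng.permutation(n_patients)
        for i in order:
            if excess == 0:
                break
            take = min(int(room[i]), excess)
            counts[i] += take
            excess -= take
    assert counts.sum() == total and counts.min() >= 1 and counts.max() <= cap
    return counts


def sample_cohort(config: CohortConfig | None = None,
                  seed: int | None = None
                  ) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Simulate patient records and a per-lesion SUVmax table.

    Returns the patient list and a lesion table with columns patient_id,
    lesion_id, category, region, suv_max.  Category totals are met
    exactly; each patient has 1..5 lesions of each category; all draws are
    reproducible under the config (or override) seed.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    met_params = fit_truncated_lognormal(*config.metastatic_targets)
    deg_params = fit_truncated_lognormal(*config.degenerative_targets)

    patients: list[PatientRecord] = []
    base = datetime(2021, 3, 1, 9, 0)
    for i in range(config.n_patients):
        weight = float(np.clip(rng.normal(*config.weight_mean_sd),
                               *config.weight_bounds))
        height = float(np.clip(rng.normal(*config.height_mean_sd),
                               *config.height_bounds))
        age = float(rng.normal(*config.age_mean_sd))
        injected = max(float(rng.normal(*config.activity_mean_sd)), 100.0)
        residual = float(rng.uniform(5.0, 25.0))
        delay_min = max(float(rng.normal(*config.delay_mean_sd)), 30.0)
        measured = base + timedelta(days=i)
        administered = measured + timedelta(minutes=3)
        post = administered + timedelta(minutes=3)
        scan = administered + timedelta(minutes=round(delay_min))
        patients.append(PatientRecord(
            patient_id=f"P{i + 1:03d}", sex=Sex.FEMALE,
            weight_kg=round(weight, 1), height_cm=round(height, 1),
            pre_injection_activity_mbq=round(injected + residual, 2),
            post_injection_activity_mbq=round(residual, 2),
            measured_time=measured, administered_time=administered,
            post_injection_time=post, scan_time=scan,
            age_years=round(age, 1)))

    rows = []
    for category, total, params in (
            ("metastatic", config.n_metastatic, met_params),
            ("degenerative", config.n_degenerative, deg_params)):
        alloc = _allocate_lesions(total, config.n_patients,
                                  config.max_lesions_per_category, rng)
        probs = config.region_probs(category)
        region_codes = list(probs)
        suvs = sample_suv(params, total, rng)
        regions = rng.choice(region_codes, size=total,
                             p=[probs[r] for r in region_codes])
        pos = 0
        for patient, k in zip(patients, alloc):
            for j in range(int(k)):
                rows.append({
                    "patient_id": patient.patient_id,
                    "lesion_id": (f"{patient.patient_id}-"
                                  f"{category[0].upper()}{j + 1}"),
                    "category": category,
                    "region": regions[pos],
                    "suv_max": round(float(suvs[pos]), 2),
                })
                pos += 1
    table = pd.DataFrame(rows)
    return patients, table


def build_phantom(patient: PatientRecord,
                  spheres: list[tuple[tuple[float, float, float],
                                      float, float]],
                  shape: tuple[int, int, int] = (64, 64, 64),
                  spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
                  gain: float = 0.0,
                  blur_fwhm_mm: float = 0.0,
                  background_suv: float = 1.0,
                  half_life_h: float = TC99M_HALF_LIFE_H,
                  rng: np.random.Generator | int | None = None
                  ) -> tuple[ActivityVolume, pd.DataFrame]:
    """Paint true-SUV spheres into an activity volume for ``patient``.

    Each sphere is (center_mm, radius_mm, true_suv).  True SUVs are
    converted to concentrations C = suv * actual_activity(Bq) / (LBM*1000)
    so that running the SUV conversion recovers them.  Optional Gaussian
    blur (FWHM in mm) and Poisson noise (``gain`` counts per Bq/mL; 0
    disables) are applied in that order.  Returns the volume and a truth
    table (center voxel, radius, true SUV).
    """
    if gain < 0:
        raise ValueError("gain must be >= 0")
    corr = decay_correction(patient, half_life_h)
    lbm = patient.lean_body_mass_kg
    suv_to_conc = corr.actual_activity_mbq * 1.0e6 / (lbm * 1000.0)

    grid_suv = np.full(shape, background_suv, dtype=float)
    axes = [np.arange(n) * s for n, s in zip(shape, spacing_mm)]
    painted = np.zeros(shape, dtype=bool)
    truth_rows = []
    for center, radius, true_suv in spheres:
        d2 = ((axes[0][:, None, None] - center[0]) ** 2
              + (axes[1][None, :, None] - center[1]) ** 2
              + (axes[2][None, None, :] - center[2]) ** 2)
        mask = d2 <= radius ** 2
        if not mask.any():
            raise ValueError(f"sphere at {center} lies outside the grid")
        if (mask & painted).any():
            raise ValueError(f"sphere at {center} overlaps a previous one")
        painted |= mask
        grid_suv[mask] = true_suv
        truth_rows.append({
            "center_i": int(round(center[0] / spacing_mm[0])),
            "center_j": int(round(center[1] / spacing_mm[1])),
            "center_k": int(round(center[2] / spacing_mm[2])),
            "radius_mm": radius,
            "true_suv": true_suv,
        })

    conc = grid_suv * suv_to_conc
    if blur_fwhm_mm > 0:
        sigma_vox = [blur_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / s
                     for s in spacing_mm]
        conc = ndimage.gaussian_filter(conc, sigma=sigma_vox)
    if gain > 0:
        rng = np.random.default_rng(rng) if not isinstance(
            rng, np.random.Generator) else rng
        conc = rng.poisson(gain * conc).astype(float) / gain
    vol = ActivityVolume(grid=conc, voxel_spacing_mm=spacing_mm)
    truth = pd.DataFrame(truth_rows, columns=["center_i", "center_j",
                                              "center_k", "radius_mm",
                                              "true_suv"])
    truth = truth.sort_values("true_suv",
                              ascending=False).reset_index(drop=True)
    return vol, truth
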