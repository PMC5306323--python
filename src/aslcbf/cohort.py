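"""Simulation of a longitudinal memory-clinic cohort.

Each subject carries baseline covariates (age, sex, education on the 7-level
Verhage scale, normalized gray-matter volume, visual ratings of medial
temporal atrophy and white-matter hyperintensities, microbleed and lacune
counts) plus baseline perfusion values for the whole brain and five cortical
regions, and a trajectory of MMSE scores over repeated visits.

MMSE follows a linear mixed model with a random intercept and a random slope
on time:

    MMSE_ij = b0 + u0_i + (b_t + u1_i) t_ij + b_c z_i + b_ct z_i t_ij
              + sum_k gamma_k x_ik + e_ij

where z_i is the subject's baseline CBF, standardized over the cohort and
inverted so that higher z means lower perfusion, and u0, u1, e are independent
zero-mean Gaussians.  The generator is the exact twin of the analysis model,
so fitted fixed effects can be compared against the generating coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortConfig", "CBF_COLUMNS", "COHORT_COLUMNS", "simulate_cohort"]

# Baseline CBF measures carried per subject: population mean and SD in
# mL/100 g/min for the uncorrected and PVC-cortical variants.
DEFAULT_CBF_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "cbf_whole_brain": (28.0, 5.6),
    "cbf_frontal": (18.7, 4.7),
    "cbf_parietal": (23.9, 5.9),
    "cbf_prcpcc": (30.2, 6.8),
    "cbf_temporal": (21.8, 5.1),
    "cbf_occipital": (29.1, 7.7),
    "cbf_pvc_cortical": (43.0, 8.7),
    "cbf_pvc_frontal": (43.2, 10.0),
    "cbf_pvc_parietal": (47.3, 10.9),
    "cbf_pvc_prcpcc": (53.8, 11.8),
    "cbf_pvc_temporal": (39.0, 8.3),
    "cbf_pvc_occipital": (48.7, 10.7),
}

CBF_COLUMNS = tuple(DEFAULT_CBF_DISTRIBUTIONS)

COHORT_COLUMNS = (
    "subject_id",
    "visit_time_years",
    "mmse",
    "age_years",
    "sex",
    "education",
    "ngmv_ml",
    "mta",
    "wmh_fazekas",
    "n_microbleeds",
    "n_lacunes",
) + CBF_COLUMNS


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters of the simulated cohort.

    Fixed effects are in MMSE points: ``effect_baseline`` the intercept,
    ``effect_time`` the mean annual change, ``effect_cbf`` the cross-sectional
    effect of one SD lower perfusion, ``effect_cbf_time`` the extra annual
    change per SD lower perfusion.  ``covariate_effects`` maps a covariate
    column to a main-effect coefficient (all zero by default).  Dispersions
    are the SDs of the random intercept, random slope and residual.
    """

    n_subjects: int = 88
    effect_baseline: float = 22.0
    effect_time: float = -2.11
    effect_cbf: float = -0.42
    effect_cbf_time: float = -0.50
    covariate_effects: dict[str, float] = field(default_factory=dict)
    sd_random_intercept: float = 3.0
    sd_random_slope: float = 1.5
    sd_residual: float = 1.5
    visit_count_range: tuple[int, int] = (2, 8)
    mean_visit_interval_years: float = 1.0
    clamp_mmse: bool = False
    measure: str = "cbf_whole_brain"
    cbf_distributions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CBF_DISTRIBUTIONS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        for name in ("sd_random_intercept", "sd_random_slope", "sd_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (dispersion)")
        lo, hi = self.visit_count_range
        if not (2 <= lo <= hi <= 8):
            raise ValueError("visit_count_range must lie within [2, 8]")
        if self.mean_visit_interval_years <= 0:
            raise ValueError("mean_visit_interval_years must be positive")
        if self.measure not in self.cbf_distributions:
            raise ValueError(f"unknown CBF measure {self.measure!r}")
        unknown = set(self.covariate_effects) - set(COHORT_COLUMNS)
        if unknown:
            raise ValueError(f"covariate_effects refer to unknown columns: {sorted(unknown)}")


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Baseline demographics and MRI ratings, drawn independently."""
    age = rng.normal(65.0, 7.0, n)
    sex = rng.integers(0, 2, n)
    education = np.clip(np.rint(rng.normal(5.0, 1.0, n)), 1, 7).astype(int)
    ngmv = rng.normal(715.8, 44.6, n)
    # Visual ratings: mean of two integer 0-4 scores -> 0.5 steps, median 1.5.
    mta = 0.5 * (
        np.clip(np.rint(rng.normal(1.5, 1.0, n)), 0, 4)
        + np.clip(np.rint(rng.normal(1.5, 1.0, n)), 0, 4)
    )
    wmh = rng.choice(4, size=n, p=[0.30, 0.35, 0.20, 0.15])
    # Zero-inflated Poisson counts with median 0.
    microbleeds = np.where(rng.random(n) < 0.70, 0, rng.poisson(1.5, n))
    lacunes = np.where(rng.random(n) < 0.75, 0, rng.poisson(0.7, n))
    return pd.DataFrame(
        {
            "age_years": age,
            "sex": sex,
            "education": education,
            "ngmv_ml": ngmv,
            "mta": mta,
            "wmh_fazekas": wmh,
            "n_microbleeds": microbleeds,
            "n_lacunes": lacunes,
        }
    )


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a long-format visit table from the mixed-model generative twin.

    Visit counts are uniform over ``visit_count_range``; the baseline visit is
    at time 0 and successive gaps are uniform in ``[0.7, 1.3]`` times the mean
    interval.  The standardization of the driving CBF measure uses the
    generated sample itself (mean 0, SD 1, inverted).  With ``clamp_mmse``
    scores are rounded to integers and clipped to [0, 30]; otherwise they are
    returned continuous, which keeps slope-recovery unbiased.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    cov = _draw_covariates(rng, n)
    cbf = {
        name: rng.normal(mu, sd, n).clip(min=1e-3)
        for name, (mu, sd) in config.cbf_distributions.items()
    }

    x = cbf[config.measure]
    sd_x = x.std(ddof=1)
    if sd_x == 0:
        raise ValueError("degenerate CBF draw: zero variance")
    z = (x.mean() - x) / sd_x  # inverted: higher z = lower perfusion

    u0 = rng.normal(0.0, config.sd_random_intercept, n)
    u1 = rng.normal(0.0, config.sd_random_slope, n)
    lo, hi = config.visit_count_range
    n_visits = rng.integers(lo, hi + 1, n)

    cov_term = np.zeros(n)
    for name, coef in config.covariate_effects.items():
        cov_term += coef * cov[name].to_numpy(dtype=float)

    rows: list[pd.DataFrame] = []
    for i in range(n):
        gaps = rng.uniform(0.7, 1.3, n_visits[i] - 1) * config.mean_visit_interval_years
        times = np.concatenate([[0.0], np.cumsum(gaps)])
        eps = rng.normal(0.0, config.sd_residual, n_visits[i])
        mmse = (
            config.effect_baseline
            + u0[i]
            + (config.effect_time + u1[i]) * times
            + config.effect_cbf * z[i]
            + config.effect_cbf_time * z[i] * times
            + cov_term[i]
            + eps
        )
        if config.clamp_mmse:
            mmse = np.clip(np.rint(mmse), 0, 30)
        block = pd.DataFrame({"subject_id": i + 1, "visit_time_years": times, "mmse": mmse})
        for col in cov.columns:
            block[col] = cov[col].iloc[i]
        for name in CBF_COLUMNS:
            block[name] = cbf[name][i]
        rows.append(block)

    table = pd.concat(rows, ignore_index=True)[list(COHORT_COLUMNS)]
    return table
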