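"""Synthetic longitudinal cohort generator.

Emulates a cohort of participants converting from mild cognitive impairment
to Alzheimer's disease over a two-year interval: demographics (age, sex,
education band, APOE e4 allele count), MMSE at baseline and follow-up, and
baseline/follow-up volumes for the 38 canonical hippocampal subfields.

The atrophy model is a linear latent-factor model on percentage volume
change.  For subject ``s`` and subfield ``j``::

    change_pct[s, j] = atrophy_means[j] + loadings[j, :] @ f_s + eps[s, j]

with ``f_s ~ N(0, I)`` standard-normal latent factors shared across
subfields and ``eps ~ N(0, noise_sd^2)`` independent region noise.  The
factors induce blocks of correlated co-atrophy; MMSE percentage decline is
coupled to the first (global) factor so that greater atrophy co-occurs with
greater cognitive decline, as observed in converting cohorts.

All randomness flows through a single ``numpy`` Generator seeded once per
cohort; no global random state is touched.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .labels import (
    CANONICAL_NAMES,
    CANONICAL_ROSTER,
    LEFT_INDICES,
    N_SUBFIELDS,
    RIGHT_INDICES,
    Structure,
)

_PROB_TOL = 1e-12


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Units: ages and education bands as documented per field; MMSE in points
    (0-30); volumes in cubic millimetres; atrophy, decline and noise in
    percent over the follow-up interval.
    """

    n_subjects: int
    seed: int
    age_mean: float
    age_sd: float
    prop_female: float
    apoe_probs: np.ndarray  # P(e4 count = 2, 1, 0)
    education_probs: np.ndarray  # bands <=9, 10-12, 13-16, >16 years
    mmse_baseline_mean: float
    mmse_baseline_sd: float
    mmse_decline_mean: float  # percent
    mmse_decline_sd: float  # percent
    baseline_volume_means: np.ndarray  # mm^3, canonical order
    atrophy_means: np.ndarray  # percent, canonical order
    factor_loadings: np.ndarray  # (38, n_factors), percent per factor SD
    noise_sd: float  # percent
    cognition_coupling: float  # percent MMSE decline per unit of factor 1
    baseline_volume_cv: float = 0.15  # log-normal coefficient of variation

    def __post_init__(self) -> None:
        self.apoe_probs = np.asarray(self.apoe_probs, dtype=float)
        self.education_probs = np.asarray(self.education_probs, dtype=float)
        self.baseline_volume_means = np.asarray(self.baseline_volume_means, dtype=float)
        self.atrophy_means = np.asarray(self.atrophy_means, dtype=float)
        self.factor_loadings = np.atleast_2d(np.asarray(self.factor_loadings, dtype=float))

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise CohortConfigError("n_subjects must be positive")
        for name, probs, k in (
            ("apoe_probs", self.apoe_probs, 3),
            ("education_probs", self.education_probs, 4),
        ):
            if probs.shape != (k,):
                raise CohortConfigError(f"{name} must have length {k}")
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > _PROB_TOL:
                raise CohortConfigError(f"{name} must be non-negative and sum to 1")
        if not 0.0 <= self.prop_female <= 1.0:
            raise CohortConfigError("prop_female must lie in [0, 1]")
        for name, value in (
            ("age_sd", self.age_sd),
            ("mmse_baseline_sd", self.mmse_baseline_sd),
            ("mmse_decline_sd", self.mmse_decline_sd),
            ("noise_sd", self.noise_sd),
            ("baseline_volume_cv", self.baseline_volume_cv),
        ):
            if value <= 0:
                raise CohortConfigError(f"{name} must be strictly positive")
        if self.baseline_volume_means.shape != (N_SUBFIELDS,):
            raise CohortConfigError(
                f"baseline_volume_means must have length {N_SUBFIELDS}"
            )
        if np.any(self.baseline_volume_means <= 0):
            raise CohortConfigError("baseline volumes must be strictly positive")
        if self.atrophy_means.shape != (N_SUBFIELDS,):
            raise CohortConfigError(f"atrophy_means must have length {N_SUBFIELDS}")
        if self.factor_loadings.shape[0] != N_SUBFIELDS:
            raise CohortConfigError(
                f"factor_loadings must have one row per subfield "
                f"({N_SUBFIELDS}); got {self.factor_loadings.shape[0]}"
            )
        if abs(self.cognition_coupling) > self.mmse_decline_sd:
            raise CohortConfigError(
                "cognition_coupling magnitude cannot exceed mmse_decline_sd"
            )
        # Follow-up volumes must stay positive even 6 SD into the left tail
        # of the change distribution, otherwise the configuration is rejected.
        change_sd = np.sqrt(
            np.sum(self.factor_loadings**2, axis=1) + self.noise_sd**2
        )
        worst = self.atrophy_means - 6.0 * change_sd
        if np.any(worst <= -100.0):
            bad = CANONICAL_NAMES[int(np.argmin(worst))]
            raise CohortConfigError(
                f"configuration implies non-positive follow-up volume at -6 SD "
                f"for subfield {bad!r}"
            )

    @property
    def n_factors(self) -> int:
        return self.factor_loadings.shape[1]

    def replace(self, **kwargs) -> "CohortConfig":
        """A copy of the config with the given fields replaced."""
        return dataclasses.replace(self, **kwargs)


@dataclass
class LongitudinalCohort:
    """Per-subject longitudinal measurements at baseline and 2-year follow-up."""

    subject_ids: list[str]
    age: np.ndarray  # years at baseline
    sex: np.ndarray  # 1 = female, 0 = male
    education: np.ndarray  # ordinal band 0-3
    apoe_e4_count: np.ndarray  # 0/1/2 e4 alleles
    mmse_baseline: np.ndarray  # integer points
    mmse_followup: np.ndarray
    volumes_baseline: np.ndarray  # (n, 38) mm^3, canonical column order
    volumes_followup: np.ndarray
    labels: tuple = field(default_factory=lambda: CANONICAL_ROSTER)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def validate(self) -> None:
        n = self.n_subjects
        if len(set(self.subject_ids)) != n:
            raise ValueError("subject_ids must be unique")
        for name in (
            "age",
            "sex",
            "education",
            "apoe_e4_count",
            "mmse_baseline",
            "mmse_followup",
        ):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        for name in ("volumes_baseline", "volumes_followup"):
            arr = getattr(self, name)
            if arr.shape != (n, N_SUBFIELDS):
                raise ValueError(f"{name} must have shape ({n}, {N_SUBFIELDS})")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise ValueError(f"{name} must be finite and strictly positive")
        for name in ("mmse_baseline", "mmse_followup"):
            arr = getattr(self, name)
            if np.any(arr < 0) or np.any(arr > 30):
                raise ValueError(f"{name} must lie in [0, 30]")
        if tuple(self.labels) != CANONICAL_ROSTER:
            raise ValueError("volume columns must follow the canonical roster")

    def covariates(self) -> np.ndarray:
        """The (n, 4) adjustment matrix: age, sex, education band, APOE e4 count."""
        return np.column_stack(
            [self.age, self.sex, self.education, self.apoe_e4_count]
        ).astype(float)


def _mmse_baseline_pmf(mean: float, sd: float):
    """PMF of the rounded, [0, 30]-clipped baseline MMSE score."""
    from scipy.stats import norm

    ks = np.arange(0, 31)
    upper = np.where(ks == 30, np.inf, ks + 0.5)
    lower = np.where(ks == 0, -np.inf, ks - 0.5)
    return ks, norm.cdf((upper - mean) / sd) - norm.cdf((lower - mean) / sd)


def _realized_decline_moments(mu: float, sd: float, b_ks, b_p):
    """Mean/SD of the realized percentage MMSE change under rounding and the
    0-30 score bounds, for a latent normal percent decline N(mu, sd^2)."""
    from scipy.stats import norm

    ks = np.arange(0, 31)
    m1 = m2 = ptot = 0.0
    for b, pb in zip(b_ks, b_p):
        if pb < 1e-14 or b == 0:
            continue
        upper = np.where(ks == 30, np.inf, 100.0 * ((ks + 0.5) / b - 1.0))
        lower = np.where(ks == 0, -np.inf, 100.0 * ((ks - 0.5) / b - 1.0))
        pk = norm.cdf((upper - mu) / sd) - norm.cdf((lower - mu) / sd)
        r = 100.0 * (ks - b) / b
        m1 += pb * (pk @ r)
        m2 += pb * (pk @ (r * r))
        ptot += pb
    m1 /= ptot
    m2 /= ptot
    return m1, float(np.sqrt(max(m2 - m1 * m1, 0.0)))


def _calibrate_decline(config: CohortConfig) -> tuple[float, float]:
    """Latent normal decline parameters whose realized bounded-score moments
    match the configured mmse_decline_mean / mmse_decline_sd.

    The MMSE is an integer score bounded at 30, so clipping and rounding
    shrink the realized change-score SD and shift its mean relative to the
    latent draw; the config targets describe the realized score, and the
    latent parameters are solved by deterministic moment matching.
    """
    from scipy.optimize import root

    b_ks, b_p = _mmse_baseline_pmf(config.mmse_baseline_mean, config.mmse_baseline_sd)

    def gap(theta):
        mu, log_sd = theta
        m, s = _realized_decline_moments(mu, float(np.exp(log_sd)), b_ks, b_p)
        return [m - config.mmse_decline_mean, s - config.mmse_decline_sd]

    sol = root(gap, x0=[config.mmse_decline_mean, np.log(config.mmse_decline_sd)],
               method="hybr")
    if not sol.success:  # pragma: no cover - defensive
        raise CohortConfigError(
            f"could not calibrate MMSE decline parameters: {sol.message}"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def generate_cohort(config: CohortConfig) -> LongitudinalCohort:
    """Draw one synthetic cohort; deterministic for a fixed config + seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    subject_ids = [f"subj{i + 1:05d}" for i in range(n)]
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    sex = (rng.random(n) < config.prop_female).astype(int)
    apoe = rng.choice([2, 1, 0], size=n, p=config.apoe_probs)
    education = rng.choice([0, 1, 2, 3], size=n, p=config.education_probs)

    # Log-normal baseline volumes with the requested mean and CV.
    sigma = np.sqrt(np.log1p(config.baseline_volume_cv**2))
    mu = np.log(config.baseline_volume_means) - 0.5 * sigma**2
    volumes_baseline = np.exp(
        mu[None, :] + sigma * rng.standard_normal((n, N_SUBFIELDS))
    )

    factors = rng.standard_normal((n, config.n_factors))
    eps = rng.normal(0.0, config.noise_sd, size=(n, N_SUBFIELDS))
    change_pct = config.atrophy_means[None, :] + factors @ config.factor_loadings.T + eps
    volumes_followup = volumes_baseline * (1.0 + change_pct / 100.0)

    mmse_baseline = np.clip(
        np.rint(rng.normal(config.mmse_baseline_mean, config.mmse_baseline_sd, size=n)),
        0,
        30,
    ).astype(int)
    lat_mean, lat_sd = _calibrate_decline(config)
    resid_sd = float(np.sqrt(max(lat_sd**2 - config.cognition_coupling**2, 0.0)))
    decline_pct = (
        lat_mean
        + config.cognition_coupling * factors[:, 0]
        + rng.normal(0.0, resid_sd, size=n)
    )
    mmse_followup = np.clip(
        np.rint(mmse_baseline * (1.0 + decline_pct / 100.0)), 0, 30
    ).astype(int)

    cohort = LongitudinalCohort(
        subject_ids=subject_ids,
        age=age,
        sex=sex,
        education=education,
        apoe_e4_count=apoe,
        mmse_baseline=mmse_baseline,
        mmse_followup=mmse_followup,
        volumes_baseline=volumes_baseline,
        volumes_followup=volumes_followup,
    )
    cohort.validate()
    return cohort


def _default_atrophy_means() -> np.ndarray:
    """Per-subfield mean 2-year atrophy (%), hemisphere means −6.35 L / −5.47 R.

    A handful of regions are pinned at values characteristic of converting
    cohorts (worst atrophy in the left fimbria, left presubiculum/subiculum
    head, CA3 body); the remaining entries start from plausible values and
    are shifted uniformly per hemisphere so the hemisphere means are exact.
    """
    means = {}
    base = {
        Structure.CA1: {"body": -5.8, "head": -6.4},
        Structure.CA3: {"body": -7.0, "head": -6.0},
        Structure.CA4: {"body": -6.1, "head": -6.2},
        Structure.DENTATE_GYRUS: {"body": -6.0, "head": -6.6},
        Structure.HATA: {"whole": -5.4},
        Structure.HIPPOCAMPAL_TAIL: {"whole": -5.2},
        Structure.FIMBRIA: {"whole": -8.6},
        Structure.HIPPOCAMPAL_FISSURE: {"whole": -3.4},
        Structure.MOLECULAR_LAYER: {"body": -5.9, "head": -6.3},
        Structure.PARASUBICULUM: {"whole": -4.9},
        Structure.PRESUBICULUM: {"body": -5.6, "head": -7.2},
        Structure.SUBICULUM: {"body": -6.2, "head": -7.1},
    }
    pinned = {
        "CA3 body L": -7.03,
        "CA3 body R": -7.07,
        "Fimbria L": -9.11,
        "Presubiculum head L": -7.99,
        "Subiculum head L": -7.93,
    }
    values = np.empty(N_SUBFIELDS)
    pinned_mask = np.zeros(N_SUBFIELDS, dtype=bool)
    for i, lbl in enumerate(CANONICAL_ROSTER):
        name = lbl.render()
        if name in pinned:
            values[i] = pinned[name]
            pinned_mask[i] = True
        else:
            values[i] = base[lbl.structure][lbl.part.value]
    for idx, target in ((np.array(LEFT_INDICES), -6.35), (np.array(RIGHT_INDICES), -5.47)):
        free = idx[~pinned_mask[idx]]
        deficit = target * len(idx) - values[idx].sum()
        values[free] += deficit / len(free)
        # exact hemisphere mean up to float round-off
        values[free] += (target - values[idx].mean()) * len(idx) / len(free)
    return values


def _default_volume_means() -> np.ndarray:
    """Plausible mean baseline subfield volumes (mm^3), identical L/R."""
    vols = {
        Structure.CA1: {"body": 330.0, "head": 500.0},
        Structure.CA3: {"body": 90.0, "head": 130.0},
        Structure.CA4: {"body": 130.0, "head": 135.0},
        Structure.DENTATE_GYRUS: {"body": 140.0, "head": 150.0},
        Structure.HATA: {"whole": 55.0},
        Structure.HIPPOCAMPAL_TAIL: {"whole": 550.0},
        Structure.FIMBRIA: {"whole": 70.0},
        Structure.HIPPOCAMPAL_FISSURE: {"whole": 160.0},
        Structure.MOLECULAR_LAYER: {"body": 250.0, "head": 320.0},
        Structure.PARASUBICULUM: {"whole": 60.0},
        Structure.PRESUBICULUM: {"body": 160.0, "head": 130.0},
        Structure.SUBICULUM: {"body": 240.0, "head": 170.0},
    }
    return np.array(
        [vols[lbl.structure][lbl.part.value] for lbl in CANONICAL_ROSTER]
    )


def _default_loadings() -> np.ndarray:
    """Default co-atrophy factor structure (percent change per factor SD).

    Four latent factors: a global factor touching every subfield, one factor
    per hemisphere, and one block factor over the CA1-CA3-CA4-dentate gyrus
    axis, mirroring the strongly covarying trisynaptic-circuit block seen in
    subfield co-atrophy data.  The fimbria and hippocampal fissure load far
    more weakly on the shared factors: in converting cohorts the fimbria
    atrophies severely yet stays weakly integrated in the covariance
    network, and the fissure is a CSF space rather than tissue.
    """
    loadings = np.zeros((N_SUBFIELDS, 4))
    ca_dg = {Structure.CA1, Structure.CA3, Structure.CA4, Structure.DENTATE_GYRUS}
    weak = {Structure.FIMBRIA: 0.1, Structure.HIPPOCAMPAL_FISSURE: 0.45}
    for i, lbl in enumerate(CANONICAL_ROSTER):
        scale = weak.get(lbl.structure, 1.0)
        loadings[i, 0] = 2.2 * scale  # global co-atrophy
        if lbl.hemisphere.value == "L":
            loadings[i, 1] = 1.4 * scale
        else:
            loadings[i, 2] = 1.4 * scale
        if lbl.structure in ca_dg:
            loadings[i, 3] = 2.5
    return loadings


def default_config(n_subjects: int = 258, seed: int = 0) -> CohortConfig:
    """Default configuration emulating a 258-subject MCI-to-AD cohort.

    Demographics: age 75.1 +/- 7.17 y, 39.53% female, APOE e4 allele-count
    probabilities (2, 1, 0) = (0.1589, 0.4768, 0.3643), education bands
    (<=9, 10-12, 13-16, >16 y) = (0.0155, 0.1318, 0.4651, 0.3876).  MMSE
    26.40 +/- 1.93 at baseline, declining by -12.9% (SD 13.8) over 2 years.
    Mean subfield atrophy averages -6.35% on the left and -5.47% on the
    right hemisphere.
    """
    config = CohortConfig(
        n_subjects=n_subjects,
        seed=seed,
        age_mean=75.1,
        age_sd=7.17,
        prop_female=0.3953,
        apoe_probs=np.array([0.1589, 0.4768, 0.3643]),
        education_probs=np.array([0.0155, 0.1318, 0.4651, 0.3876]),
        mmse_baseline_mean=26.40,
        mmse_baseline_sd=1.93,
        mmse_decline_mean=-12.9,
        mmse_decline_sd=13.8,
        baseline_volume_means=_default_volume_means(),
        atrophy_means=_default_atrophy_means(),
        factor_loadings=_default_loadings(),
        noise_sd=2.0,
        cognition_coupling=4.0,
    )
    config.validate()
    return config
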