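"""Synthetic cohorts with status-dependent self-report bias.

The generator emulates the statistical structure the correction method
assumes: adolescents and young adults with measured height and weight drawn
from sex/age growth curves, self-reported values that over-report height and
under-report weight most strongly at higher weight status, and psychosocial
covariates correlated with weight status.  It also produces a synthetic LMS
growth-reference fixture so that the whole pipeline is testable without any
external chart download.

Generative scheme (per record):

1. latent height from a sex-specific age curve plus Gaussian spread; latent
   BMI from the LMS reference at the record's age via a Gaussian z-score;
   latent weight = BMI * height^2;
2. self-reported values = latent values plus independent perception noise;
   the *self-reported* weight status (classified from the SR BMI) drives the
   reporting bias, so the correction model's "weight status by self-report"
   dummies are exactly the generative factor;
3. measured weight = SR weight + status/sex-specific under-report + optional
   covariate effects + Gaussian residual; measured height = SR height -
   sex-specific height over-report + Gaussian residual;
4. covariates (body-size estimation, dieting, CES-D, self-esteem, self-rated
   health, puberty) from the latent status and age.

Default bias magnitudes are seeded from reported adolescent self-report
biases (females under-reporting about 1.02 kg at overweight/obesity, males
about 0.19 kg on average); they are illustrative defaults, not a claim of
fidelity to any particular survey.

All randomness flows from a single seed through named, per-variable
``SeedSequence`` children, so adding a new covariate stream does not perturb
existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .correction import (
    FitResult,
    aic_select,
    default_candidate_blocks,
)
from .errors import DataError, DomainError, RangeError
from .growth_reference import (
    ADULT_AGE_MONTHS,
    ADULT_BMI_CUTOFFS,
    GrowthReferenceTable,
    PEDIATRIC_PERCENTILE_CUTOFFS,
    WeightStatus,
)
from .records import AnthropometricRecord

from scipy import stats

__all__ = [
    "SexGrowthParams",
    "SexBiasParams",
    "CovariateParams",
    "SimulationConfig",
    "generate_growth_fixture",
    "generate_cohort",
    "recovery_config",
    "oracle_refit_check",
    "RecoveryReport",
]

_STREAMS = (
    "sex",
    "age",
    "race",
    "parent_ed",
    "sample_weight",
    "height",
    "bmi_z",
    "puberty",
    "bse",
    "dieting",
    "cesd",
    "esteem",
    "health",
    "sr_height",
    "sr_weight",
    "meas_height",
    "meas_weight",
)


def _streams(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SexGrowthParams:
    """Sex-specific anthropometric curves.

    Mean height rises from ``height_at_min_cm`` toward ``height_adult_cm``
    with an exponential approach of time-scale ``plateau_months``; BMI is
    drawn through the LMS reference with z ~ N(bmi_z_mean, bmi_z_sd), which
    puts the cohort slightly above the reference median (typical of recent
    US adolescent samples).
    """

    height_at_min_cm: float
    height_adult_cm: float
    height_sd_cm: float
    plateau_months: float
    bmi_z_mean: float = 0.4
    bmi_z_sd: float = 1.0


@dataclass(frozen=True)
class SexBiasParams:
    """Sex-specific self-report bias.

    ``weight_underreport_kg`` maps the *self-reported* weight status to the
    mean amount by which the self-report falls short of the measured weight;
    ``height_overreport_cm`` is the mean height exaggeration.  ``sr_*_sd``
    are the perception spreads of the self-reports around the latent values;
    ``*_noise_sd`` are the residual spreads of measured given self-reported.
    """

    height_overreport_cm: float
    weight_underreport_kg: dict
    sr_height_sd_cm: float = 1.8
    sr_weight_sd_kg: float = 2.2
    height_noise_sd_cm: float = 1.2
    weight_noise_sd_kg: float = 2.0


@dataclass(frozen=True)
class CovariateParams:
    """Covariate generation and (optional) covariate-driven reporting bias.

    The ``*_weight_effect_kg`` entries add to measured weight given the
    self-report; they default to zero so that the default bias is purely
    status- and sex-dependent, and are switched on by the parameter-recovery
    harness to provide a richer, still correctly specified, linear truth.
    """

    misperception_sd: float = 0.6
    dieting_logit_by_status: dict = field(
        default_factory=lambda: {
            WeightStatus.UW: -4.0,
            WeightStatus.HW: -1.9,
            WeightStatus.OW: -0.7,
            WeightStatus.OB: -0.2,
        }
    )
    dieting_male_logit_offset: float = -1.5
    cesd_mean: float = 11.0
    cesd_sd: float = 7.5
    cesd_status_loading: float = 1.0
    self_esteem_mean: float = 4.1
    self_esteem_sd: float = 0.55
    self_esteem_status_loading: float = -0.08
    self_rated_health_mean: float = 3.9
    self_rated_health_sd: float = 0.85
    self_rated_health_status_loading: float = -0.25
    dieting_weight_effect_kg: float = 0.0
    bse_weight_effect_kg: dict = field(
        default_factory=lambda: {"UW": 0.0, "AboutRight": 0.0, "OW": 0.0}
    )
    puberty_weight_effect_kg: float = 0.0


_DEFAULT_GROWTH = {
    "male": SexGrowthParams(160.0, 176.5, 6.8, 30.0),
    "female": SexGrowthParams(155.0, 163.0, 6.2, 20.0),
}

# Female under-report pinned at 1.02 kg in the overweight/obesity strata;
# male values chosen so the sex-wide mean under-report is of order 0.2 kg.
_DEFAULT_BIAS = {
    "male": SexBiasParams(
        height_overreport_cm=1.2,
        weight_underreport_kg={
            WeightStatus.UW: -0.3,
            WeightStatus.HW: 0.1,
            WeightStatus.OW: 0.5,
            WeightStatus.OB: 0.8,
        },
    ),
    "female": SexBiasParams(
        height_overreport_cm=0.8,
        weight_underreport_kg={
            WeightStatus.UW: -0.3,
            WeightStatus.HW: 0.4,
            WeightStatus.OW: 1.02,
            WeightStatus.OB: 1.02,
        },
    ),
}

_RACE_PROBS = {"White": 0.62, "Hispanic": 0.12, "Black": 0.16, "Asian": 0.045,
               "Other": 0.055}
_PARENT_ED_PROBS = {"HS_or_less": 0.45, "Some_college": 0.21, "College_plus": 0.34}


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a synthetic cohort; deterministic given seed."""

    n: int = 2000
    seed: int = 0
    sex_ratio: float = 0.5  # probability of female
    age_range_months: tuple = (144, 264)
    growth_params: dict = field(default_factory=lambda: dict(_DEFAULT_GROWTH))
    bias_params: dict = field(default_factory=lambda: dict(_DEFAULT_BIAS))
    covariate_params: CovariateParams = field(default_factory=CovariateParams)
    weight_dispersion: float = 0.3  # lognormal sigma of sampling weights
    fixture_seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise DomainError(f"n must be >= 1, got {self.n}")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise DomainError(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")
        lo, hi = self.age_range_months
        if not (lo < hi):
            raise DomainError("age_range_months must be increasing")
        for sex, gp in self.growth_params.items():
            if gp.height_sd_cm <= 0 or gp.bmi_z_sd <= 0:
                raise DomainError(f"SDs must be positive for sex {sex!r}")


# ---------------------------------------------------------------------------
# Growth-reference fixture
# ---------------------------------------------------------------------------

_FIXTURE_SHAPE = {
    # sex -> (M at 144 mo, M at 240 mo, L start, L end, S start, S end)
    "male": (17.8, 23.2, -2.4, -2.0, 0.105, 0.135),
    "female": (18.1, 21.9, -2.2, -1.9, 0.110, 0.140),
}


def generate_growth_fixture(seed: int = 0) -> GrowthReferenceTable:
    """Synthetic monthly LMS reference, ages 144-240 months, both sexes.

    The median BMI curve is smooth, strictly increasing in age and carries a
    small seeded perturbation so tests do not silently depend on an exact
    analytic form; L stays within [-3, 1] and S within [0.05, 0.2].
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ages = np.arange(144, 241, dtype=float)
    f = (ages - ages[0]) / (ages[-1] - ages[0])
    rows = []
    for sex in ("male", "female"):
        m0, m1, l0, l1, s0, s1 = _FIXTURE_SHAPE[sex]
        M = m0 + (m1 - m0) * f**0.85
        # monthly increments are >= 0.04 BMI units; jitter is an order of
        # magnitude smaller, preserving strict monotonicity
        M = M + np.cumsum(rng.normal(0.0, 0.002, size=len(ages)))
        L = np.clip(l0 + (l1 - l0) * f + 0.05 * np.sin(f * np.pi * rng.uniform(1, 2)),
                    -3.0, 1.0)
        S = np.clip(s0 + (s1 - s0) * f + 0.002 * np.sin(f * np.pi * rng.uniform(1, 3)),
                    0.05, 0.2)
        rows.extend(
            (sex, float(a), float(l), float(m), float(s))
            for a, l, m, s in zip(ages, L, M, S)
        )
    return GrowthReferenceTable(rows=tuple(rows))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _lms_arrays(table: GrowthReferenceTable, sexes: np.ndarray,
                ages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    L = np.empty(len(ages))
    M = np.empty(len(ages))
    S = np.empty(len(ages))
    for sex in ("male", "female"):
        mask = sexes == sex
        if not mask.any():
            continue
        tab_ages, tl, tm, ts = table._sex_arrays(sex)
        a = np.clip(ages[mask], tab_ages[0], tab_ages[-1])
        L[mask] = np.interp(a, tab_ages, tl)
        M[mask] = np.interp(a, tab_ages, tm)
        S[mask] = np.interp(a, tab_ages, ts)
    return L, M, S


def _status_vec(bmi: np.ndarray, ages: np.ndarray, sexes: np.ndarray,
                table: GrowthReferenceTable) -> np.ndarray:
    """Vectorised weight-status classification (pediatric + adult routes)."""
    status = np.empty(len(bmi), dtype=int)
    adult = ages >= ADULT_AGE_MONTHS
    lo, mid, hi = ADULT_BMI_CUTOFFS
    status[adult] = np.digitize(bmi[adult], [lo, mid, hi])
    ped = ~adult
    if ped.any():
        L, M, S = _lms_arrays(table, sexes[ped], ages[ped])
        z = np.where(
            L == 0,
            np.log(bmi[ped] / M) / S,
            ((bmi[ped] / M) ** L - 1.0) / (L * S),
        )
        pct = 100.0 * stats.norm.cdf(z)
        status[ped] = np.digitize(pct, list(PEDIATRIC_PERCENTILE_CUTOFFS))
    return status


def generate_cohort(
    config: SimulationConfig,
    table: Optional[GrowthReferenceTable] = None,
) -> list[AnthropometricRecord]:
    """Generate a synthetic cohort with measured values filled in."""
    if table is None:
        table = generate_growth_fixture(config.fixture_seed)
    lo, hi = config.age_range_months
    if lo < table.min_age:
        raise RangeError(
            f"age range starts at {lo} months but the growth reference only "
            f"covers [{table.min_age}, {table.max_age}]"
        )
    if hi > table.max_age and lo < ADULT_AGE_MONTHS and table.max_age < ADULT_AGE_MONTHS:
        raise RangeError(
            f"pediatric ages up to {min(hi, ADULT_AGE_MONTHS)} months are not "
            f"covered by the growth reference (max {table.max_age})"
        )
    n = config.n
    cp = config.covariate_params
    rng = _streams(config.seed)

    female = rng["sex"].random(n) < config.sex_ratio
    sexes = np.where(female, "female", "male")
    ages = rng["age"].integers(lo, hi, size=n).astype(float)

    race = rng["race"].choice(list(_RACE_PROBS), p=list(_RACE_PROBS.values()), size=n)
    parent_ed = rng["parent_ed"].choice(
        list(_PARENT_ED_PROBS), p=list(_PARENT_ED_PROBS.values()), size=n
    )
    sw = rng["sample_weight"].lognormal(0.0, config.weight_dispersion, size=n)
    sw = sw / sw.mean()

    # latent anthropometrics
    height = np.empty(n)
    zmean = np.empty(n)
    zsd = np.empty(n)
    for sex in ("male", "female"):
        mask = sexes == sex
        gp = config.growth_params[sex]
        mean_h = gp.height_adult_cm - (
            gp.height_adult_cm - gp.height_at_min_cm
        ) * np.exp(-(ages[mask] - 144.0) / gp.plateau_months)
        height[mask] = mean_h
        zmean[mask] = gp.bmi_z_mean
        zsd[mask] = gp.bmi_z_sd
    height = height + rng["height"].normal(0.0, 1.0, size=n) * np.array(
        [config.growth_params[s].height_sd_cm for s in sexes]
    )
    z = np.clip(rng["bmi_z"].normal(zmean, zsd), -3.0, 3.0)
    L, M, S = _lms_arrays(table, sexes, ages)
    base = np.maximum(1.0 + L * S * z, 0.2)
    bmi_lat = np.where(L == 0, M * np.exp(S * z), M * base ** (1.0 / L))
    weight = bmi_lat * (height / 100.0) ** 2

    status_lat = _status_vec(bmi_lat, ages, sexes, table)

    # covariates from the latent status
    puberty = np.clip(
        np.rint(
            1.5 + 3.5 * np.clip((ages - 144.0) / 120.0, 0, 1)
            + rng["puberty"].normal(0.0, 0.9, size=n)
        ),
        1, 5,
    ).astype(int)
    coarse = np.clip(status_lat, 0, 2).astype(float)  # OW and OB both "feel" OW
    perceived = coarse + rng["bse"].normal(0.0, cp.misperception_sd, size=n)
    bse = np.where(perceived < 0.5, "UW", np.where(perceived < 1.5, "AboutRight", "OW"))
    logits = np.array(
        [cp.dieting_logit_by_status[WeightStatus(s)] for s in status_lat]
    ) + np.where(female, 0.0, cp.dieting_male_logit_offset)
    dieting = rng["dieting"].random(n) < 1.0 / (1.0 + np.exp(-logits))
    cesd = np.clip(
        rng["cesd"].normal(
            cp.cesd_mean + cp.cesd_status_loading * (status_lat - 1), cp.cesd_sd
        ),
        0, 60,
    )
    esteem = np.clip(
        rng["esteem"].normal(
            cp.self_esteem_mean + cp.self_esteem_status_loading * (status_lat - 1),
            cp.self_esteem_sd,
        ),
        1, 5,
    )
    health = np.clip(
        rng["health"].normal(
            cp.self_rated_health_mean
            + cp.self_rated_health_status_loading * (status_lat - 1),
            cp.self_rated_health_sd,
        ),
        1, 5,
    )

    # self-reports around the latent values
    sr_h = np.empty(n)
    sr_w = np.empty(n)
    for sex in ("male", "female"):
        mask = sexes == sex
        bp = config.bias_params[sex]
        sr_h[mask] = height[mask] + rng["sr_height"].normal(
            0.0, max(bp.sr_height_sd_cm, 1e-12), size=int(mask.sum())
        ) * (bp.sr_height_sd_cm > 0)
        sr_w[mask] = weight[mask] + rng["sr_weight"].normal(
            0.0, max(bp.sr_weight_sd_kg, 1e-12), size=int(mask.sum())
        ) * (bp.sr_weight_sd_kg > 0)
    sr_h = np.maximum(sr_h, 50.0)
    sr_w = np.maximum(sr_w, 15.0)

    sr_bmi = sr_w / (sr_h / 100.0) ** 2
    sr_status = _status_vec(sr_bmi, ages, sexes, table)

    # measured = self-report plus bias plus residual (regression direction)
    under = np.empty(n)
    over = np.empty(n)
    eps_w = np.empty(n)
    eps_h = np.empty(n)
    for sex in ("male", "female"):
        mask = sexes == sex
        bp = config.bias_params[sex]
        under[mask] = np.array(
            [bp.weight_underreport_kg[WeightStatus(s)] for s in sr_status[mask]]
        )
        over[mask] = bp.height_overreport_cm
        eps_w[mask] = rng["meas_weight"].normal(
            0.0, max(bp.weight_noise_sd_kg, 1e-12), size=int(mask.sum())
        ) * (bp.weight_noise_sd_kg > 0)
        eps_h[mask] = rng["meas_height"].normal(
            0.0, max(bp.height_noise_sd_cm, 1e-12), size=int(mask.sum())
        ) * (bp.height_noise_sd_cm > 0)

    bse_eff = np.array([cp.bse_weight_effect_kg.get(b, 0.0) for b in bse])
    meas_w = (
        sr_w
        + under
        + cp.dieting_weight_effect_kg * dieting.astype(float)
        + bse_eff
        + cp.puberty_weight_effect_kg * puberty
        + eps_w
    )
    meas_h = sr_h - over + eps_h
    meas_w = np.maximum(meas_w, 15.0)
    meas_h = np.maximum(meas_h, 50.0)

    width = len(str(n))
    records = [
        AnthropometricRecord(
            id=f"S{i:0{width}d}",
            sex=str(sexes[i]),
            age_months=float(ages[i]),
            sr_height_cm=float(sr_h[i]),
            sr_weight_kg=float(sr_w[i]),
            measured_height_cm=float(meas_h[i]),
            measured_weight_kg=float(meas_w[i]),
            puberty=int(puberty[i]),
            body_size_estimation=str(bse[i]),
            dieting=bool(dieting[i]),
            cesd=float(np.round(cesd[i], 4)),
            self_rated_health=float(np.round(health[i], 4)),
            self_esteem=float(np.round(esteem[i], 4)),
            race_ethnicity=str(race[i]),
            parent_education=str(parent_ed[i]),
            sample_weight=float(np.round(sw[i], 8)),
            sr_weight_status=WeightStatus(int(sr_status[i])),
        )
        for i in range(n)
    ]
    return records


# ---------------------------------------------------------------------------
# Parameter-recovery harness
# ---------------------------------------------------------------------------


def recovery_config(n: int = 10_000, seed: int = 0) -> SimulationConfig:
    """Single-sex (female) configuration with covariate-driven bias switched
    on, used to validate that fitting recovers the generative coefficients.

    Race/ethnicity has no generative effect on measured weight and therefore
    serves as the designated pure-noise block for selection checks.
    """
    cp = CovariateParams(
        dieting_weight_effect_kg=0.45,
        bse_weight_effect_kg={"UW": -0.8, "AboutRight": 0.0, "OW": 1.6},
        puberty_weight_effect_kg=0.12,
    )
    return SimulationConfig(n=n, seed=seed, sex_ratio=1.0, covariate_params=cp)


@dataclass
class RecoveryEntry:
    name: str
    truth: float
    estimate: Optional[float]
    se: Optional[float]
    within: bool


@dataclass
class RecoveryReport:
    """Outcome of one end-to-end parameter-recovery run."""

    entries: list
    noise_block: str
    noise_excluded: bool
    fit: FitResult

    @property
    def all_within(self) -> bool:
        return all(e.within for e in self.entries)


def _expected_weight_coefficients(config: SimulationConfig, sex: str) -> dict:
    """Generative truth of the measured-weight regression, per sex."""
    bp = config.bias_params[sex]
    cp = config.covariate_params
    ref = bp.weight_underreport_kg[WeightStatus.HW]
    expected = {"sr_weight": 1.0}
    for st in (WeightStatus.UW, WeightStatus.OW, WeightStatus.OB):
        expected[f"sr_weight_status[{st.name}]"] = (
            bp.weight_underreport_kg[st] - ref
        )
    if cp.dieting_weight_effect_kg:
        expected["dieting"] = cp.dieting_weight_effect_kg
    bse_ref = cp.bse_weight_effect_kg.get("AboutRight", 0.0)
    for lvl in ("UW", "OW"):
        eff = cp.bse_weight_effect_kg.get(lvl, 0.0) - bse_ref
        if eff:
            expected[f"body_size_estimation[{lvl}]"] = eff
    if cp.puberty_weight_effect_kg:
        expected["puberty"] = cp.puberty_weight_effect_kg
    return expected


def oracle_refit_check(
    config: Optional[SimulationConfig] = None,
    tolerance: float = 3.0,
    noise_block: str = "race_ethnicity",
    table: Optional[GrowthReferenceTable] = None,
) -> RecoveryReport:
    """Generate a cohort, refit the measured-weight model, and compare.

    The cohort must be single-sex (the default recovery configuration is),
    so that the per-sex generative coefficients are identified by a single
    pooled fit.  Every truly generative slope must land within ``tolerance``
    standard errors of its estimate and be retained by selection; the
    designated pure-noise block should be eliminated.
    """
    if config is None:
        config = recovery_config()
    if config.sex_ratio not in (0.0, 1.0):
        raise DataError(
            "oracle_refit_check requires a single-sex cohort "
            "(sex_ratio 0.0 or 1.0) so generative coefficients are identified"
        )
    sex = "female" if config.sex_ratio == 1.0 else "male"
    if table is None:
        table = generate_growth_fixture(config.fixture_seed)
    records = generate_cohort(config, table)
    blocks = [b for b in default_candidate_blocks("weight") if b != "sex"]
    fit = aic_select(blocks, records, "weight", unit_system="metric",
                     growth_ref=table)
    expected = _expected_weight_coefficients(config, sex)
    est = {t.column: t.coefficient for t in fit.model.terms}
    ses = fit.coefficient_ses
    entries = []
    for name, truth in expected.items():
        if name in est:
            e, se = est[name], ses.get(name)
            within = se is not None and abs(e - truth) <= tolerance * se
            entries.append(RecoveryEntry(name, truth, e, se, within))
        else:
            entries.append(RecoveryEntry(name, truth, None, None, False))
    retained = fit.model.provenance.get("blocks_retained", [])
    return RecoveryReport(
        entries=entries,
        noise_block=noise_block,
        noise_excluded=noise_block not in retained,
        fit=fit,
    )
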