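"""Synthetic inputs for exercising the pipeline end to end.

Real runs draw their demographic and mortality inputs from national
statistics and WHO Global Health Estimates tables.  This module
generates structurally identical tables with a known ground truth: an
age pyramid that plateaus in mid-life and contracts at older ages, with
a female surplus at high ages; cardiovascular deaths concentrated in
the oldest bands; and dose–response parameter sets whose slopes are
chosen by the caller, so closed-form expected results exist for every
downstream quantity.

Only the qualitative shape of the demography is emulated — enough for
pipeline invariants, not a statistical model of any real population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from breadsalt import bread_market as bm
from breadsalt import uncertainty_scenarios as us
from breadsalt.cra_mortality import (
    SALT_RELATED_CAUSES,
    DoseResponse,
    MortalityStratum,
)

#: Annual deaths per cause at scale 1.0, shaped after the magnitude of
#: cardiovascular mortality in a mid-size Western European country
#: (tens of thousands of salt-related CVD deaths per year).
DEFAULT_CAUSE_DEATHS: dict[str, float] = {
    "cerebrovascular_disease": 11_100.0,
    "ischaemic_heart_disease": 7_300.0,
    "heart_failure": 4_300.0,
    "aortic_aneurysm": 900.0,
    "pulmonary_embolism": 700.0,
    "rheumatic_heart_disease": 300.0,
    "hypertensive_disease": 2_700.0,
}

#: Default true effective log-RR slopes per g/day salt, by cause.
DEFAULT_BETA_TRUTH: dict[str, float] = {
    "cerebrovascular_disease": 0.040,
    "ischaemic_heart_disease": 0.028,
    "heart_failure": 0.035,
    "aortic_aneurysm": 0.025,
    "pulmonary_embolism": 0.010,
    "rheumatic_heart_disease": 0.010,
    "hypertensive_disease": 0.050,
}

#: Relative age-band population weights, birth to 85+: a plateau through
#: working ages then a decline, before sex-ratio adjustment.
_AGE_POP_WEIGHTS = np.array(
    [4.2, 4.8, 5.2, 5.4, 5.5, 5.6, 5.8, 6.4, 7.0, 7.7, 8.0, 7.8, 7.4, 6.5, 5.6, 4.7, 3.5, 3.0]
)

_GOMPERTZ_RATE = 0.095  # log-slope of CVD mortality per year of age
_MALE_RATE_MULTIPLIER = 1.4
_NB_DISPERSION = 50.0  # negative-binomial size; mild overdispersion


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs for the synthetic population and dose–response generator."""

    seed: int = 0
    n_age_bands: int = 18
    population_total: float = 10_300_000.0
    cause_list: tuple[str, ...] = SALT_RELATED_CAUSES
    total_deaths_scale: float = 1.0
    exposure_mean: float = 7.4
    exposure_sd: float = 0.0
    beta_truth: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETA_TRUTH)
    )
    se_scale: float = 0.25

    def __post_init__(self) -> None:
        if self.n_age_bands < 1:
            raise ValueError("need at least one age band")
        if self.total_deaths_scale < 0:
            raise ValueError("total_deaths_scale must be non-negative")


def _age_bands(n: int) -> list[tuple[int, int | None]]:
    bands: list[tuple[int, int | None]] = [(5 * i, 5 * (i + 1)) for i in range(n - 1)]
    bands.append((5 * (n - 1), None))
    return bands


def _male_fraction(age_mid: float) -> float:
    # slight male surplus at birth shading to a strong female surplus at 85+
    return float(np.clip(0.512 - 0.0019 * max(age_mid - 15.0, 0.0), 0.35, 0.512))


def generate_strata(cfg: SyntheticConfig) -> list[MortalityStratum]:
    """Seeded synthetic age/sex strata with cause-specific death counts.

    Expected death counts follow a Gompertz-like exponential increase
    with age (male excess risk at equal age, but a larger old female
    population), normalised so each cause's expected national total is
    its default magnitude times ``total_deaths_scale``; realised counts
    are negative-binomial draws around those expectations.
    """
    rng = np.random.default_rng(cfg.seed)
    bands = _age_bands(cfg.n_age_bands)
    weights = np.resize(_AGE_POP_WEIGHTS, cfg.n_age_bands)
    weights = weights / weights.sum()

    strata_meta = []  # (band, sex, population, age_mid)
    for (low, high), w in zip(bands, weights):
        mid = low + 2.5 if high is not None else low + 5.0
        band_pop = cfg.population_total * w
        mf = _male_fraction(mid)
        for sex, frac in (("male", mf), ("female", 1.0 - mf)):
            # whole persons, so tables round-trip losslessly through CSV
            strata_meta.append(((low, high), sex, float(round(band_pop * frac)), mid))

    # expected deaths before normalisation: population × Gompertz hazard
    raw = np.array(
        [
            pop
            * np.exp(_GOMPERTZ_RATE * (mid - 70.0))
            * (_MALE_RATE_MULTIPLIER if sex == "male" else 1.0)
            for _, sex, pop, mid in strata_meta
        ]
    )
    raw_total = raw.sum()

    strata = []
    for i, ((low, high), sex, pop, _mid) in enumerate(strata_meta):
        deaths_by_cause = {}
        for cause in cfg.cause_list:
            target = DEFAULT_CAUSE_DEATHS.get(cause, 1_000.0) * cfg.total_deaths_scale
            mu = target * raw[i] / raw_total
            if mu <= 0:
                deaths_by_cause[cause] = 0.0
                continue
            p = _NB_DISPERSION / (_NB_DISPERSION + mu)
            deaths_by_cause[cause] = float(
                rng.negative_binomial(_NB_DISPERSION, p)
            )
        strata.append(
            MortalityStratum(
                age_low=low,
                age_high=high,
                sex=sex,
                population=pop,
                deaths_by_cause=deaths_by_cause,
            )
        )
    return strata


def generate_dose_response(cfg: SyntheticConfig) -> list[DoseResponse]:
    """Direct-pathway dose–response entries with known true slopes.

    One entry per cause: slope from ``beta_truth`` (0 when absent), SE
    ``se_scale × |slope|``, reference exposure at the configured mean.
    """
    return [
        DoseResponse(
            cause=cause,
            pathway="direct",
            beta=cfg.beta_truth.get(cause, 0.0),
            se_beta=cfg.se_scale * abs(cfg.beta_truth.get(cause, 0.0)),
            reference_exposure=cfg.exposure_mean,
        )
        for cause in cfg.cause_list
    ]


@dataclass(frozen=True)
class PolicyFixture:
    """The published Portuguese market constants and scenario battery."""

    market_inputs: bm.MarketInputs
    salt_baseline: bm.SaltBaseline
    total_t_yr: float
    battery: tuple[us.ScenarioSpec, ...]

    @property
    def market_context(self) -> us.MarketContext:
        return us.MarketContext(
            inputs=self.market_inputs,
            bread_share_of_salt=self.salt_baseline.bread_share_of_salt,
            total_t_yr=self.total_t_yr,
        )


def paper_fixture() -> PolicyFixture:
    """Published market constants for the Portuguese bread market (2016).

    Per-capita bread 100.3 g/day and salt 7.4 g/day with an 18.2% bread
    share (national dietary survey); 40,040 t/yr pre-packaged sales of
    which 21,764 t imported; 45% of national production traditional;
    76% voluntary-target compliance; population 10,300,000.  The
    published market total of 376,218 t/yr is pinned directly so the
    decomposition matches the reported figures (the intake-derived
    total is ~0.3% higher).  The battery holds the two counterfactual
    scenarios (extend the statutory 1.4 g/100 g limit to all bread;
    lower the limit to 1.0 g/100 g for all bread) and the ten published
    sensitivity rows.
    """
    inputs = bm.MarketInputs(
        per_capita_bread_g_day=100.3,
        population=10_300_000.0,
        prepackaged_sold_t_yr=40_040.0,
        imported_t_yr=21_764.0,
        traditional_fraction_of_national=0.45,
        bakery_compliance_fraction=0.76,
    )
    baseline = bm.SaltBaseline(
        per_capita_salt_g_day=7.4,
        bread_share_of_salt=0.182,
        per_capita_bread_g_day=100.3,
    )
    share_point = 0.01 * baseline.per_capita_salt_g_day  # ±1 pp of salt via bread
    battery = (
        us.ScenarioSpec(
            label="CF1",
            description="All products <1.4 g salt/100 g bread",
            threshold_g_per_100g=1.4,
        ),
        us.ScenarioSpec(
            label="SA1a",
            description="Voluntary 1.0 g compliance 76% -> 100%",
            threshold_g_per_100g=1.4,
            compliance_fraction=1.0,
        ),
        us.ScenarioSpec(
            label="SA1b",
            description="Voluntary 1.0 g compliance 76% -> 50%",
            threshold_g_per_100g=1.4,
            compliance_fraction=0.5,
        ),
        us.ScenarioSpec(
            label="SA2a",
            description="Urinary-sodium baseline (10.7 g), threshold 1.4",
            threshold_g_per_100g=1.4,
            baseline_salt_g_day=10.7,
        ),
        us.ScenarioSpec(
            label="SA3a-CF1",
            description="1 pp more salt from bread, threshold 1.4",
            threshold_g_per_100g=1.4,
            bread_share_adjustment_g_day=share_point,
        ),
        us.ScenarioSpec(
            label="SA3b-CF1",
            description="1 pp less salt from bread, threshold 1.4",
            threshold_g_per_100g=1.4,
            bread_share_adjustment_g_day=-share_point,
        ),
        us.ScenarioSpec(
            label="SA4a",
            description="1% lower baseline intake, threshold 1.4",
            threshold_g_per_100g=1.4,
            baseline_scale=0.99,
        ),
        us.ScenarioSpec(
            label="CF2",
            description="All products <1.0 g salt/100 g bread",
            threshold_g_per_100g=1.0,
        ),
        us.ScenarioSpec(
            label="SA2b",
            description="Urinary-sodium baseline (10.7 g), threshold 1.0",
            threshold_g_per_100g=1.0,
            baseline_salt_g_day=10.7,
        ),
        us.ScenarioSpec(
            label="SA3a-CF2",
            description="1 pp more salt from bread, threshold 1.0",
            threshold_g_per_100g=1.0,
            bread_share_adjustment_g_day=share_point,
        ),
        us.ScenarioSpec(
            label="SA3b-CF2",
            description="1 pp less salt from bread, threshold 1.0",
            threshold_g_per_100g=1.0,
            bread_share_adjustment_g_day=-share_point,
        ),
        us.ScenarioSpec(
            label="SA4b",
            description="1% lower baseline intake, threshold 1.0",
            threshold_g_per_100g=1.0,
            baseline_scale=0.99,
        ),
    )
    return PolicyFixture(
        market_inputs=inputs,
        salt_baseline=baseline,
        total_t_yr=376_218.0,
        battery=battery,
    )
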