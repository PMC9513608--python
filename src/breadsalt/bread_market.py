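"""Bread-market decomposition and counterfactual salt-reduction scenarios.

The Portuguese bread market is split into three sales segments: imported
pre-packaged bread, nationally produced pre-packaged bread, and loose
bakery bread.  Imported bread and "traditional" bread (a fixed fraction of
national production) are exempt from the statutory salt limit; everything
else is regulated.  A policy scenario caps the salt density (g salt per
100 g bread) of the segments in its scope at a legal threshold, and the
resulting drop in tonnage-weighted mean salt density translates into a
per-capita daily salt-intake reduction.

Because per-segment salt contents are not observed, the module calibrates
them by closure: the regulated segment is split between bakeries already
complying with the voluntary 1.0 g/100 g target and the remainder at the
statutory maximum, and the exempt-segment density is solved so that the
tonnage-weighted mean equals the salt density implied by survey data
(bread's share of total salt intake divided by bread consumption).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import yaml

GRAMS_PER_TONNE = 1e6
DAYS_PER_YEAR = 365.25

#: Calibration guard: an exempt-segment salt density above this value
#: (g per 100 g bread) is treated as physically implausible.
MAX_PLAUSIBLE_DENSITY = 10.0


class Scope(str, enum.Enum):
    """Which market segments a legal salt threshold applies to."""

    ALL_BREAD = "all_bread"
    NON_EXEMPT_ONLY = "non_exempt_only"


class MarketConsistencyError(ValueError):
    """Raised when market inputs violate accounting identities."""


class CalibrationError(ValueError):
    """Raised when the salt-density closure has no plausible solution."""


@dataclass(frozen=True)
class MarketInputs:
    """Observable constants describing the national bread market.

    Parameters
    ----------
    per_capita_bread_g_day
        Mean daily bread consumption, grams per person per day.
    population
        Resident population (persons).
    prepackaged_sold_t_yr
        Annual pre-packaged bread sales, tonnes/year.
    imported_t_yr
        Annual imported (pre-packaged) bread, tonnes/year.
    traditional_fraction_of_national
        Fraction of *nationally produced* bread classified as traditional
        (and hence exempt from the statutory limit).
    bakery_compliance_fraction
        Fraction of regulated production already meeting the voluntary
        1.0 g/100 g target.
    days_per_year
        Year length used to annualise daily consumption.
    """

    per_capita_bread_g_day: float
    population: float
    prepackaged_sold_t_yr: float
    imported_t_yr: float
    traditional_fraction_of_national: float
    bakery_compliance_fraction: float
    days_per_year: float = DAYS_PER_YEAR

    def __post_init__(self) -> None:
        for name in (
            "per_capita_bread_g_day",
            "population",
            "prepackaged_sold_t_yr",
            "imported_t_yr",
            "days_per_year",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.imported_t_yr > self.prepackaged_sold_t_yr:
            raise MarketConsistencyError(
                "imported bread cannot exceed total pre-packaged sales"
            )
        for name in (
            "traditional_fraction_of_national",
            "bakery_compliance_fraction",
        ):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class MarketDecomposition:
    """Annual tonnage of each bread segment, regulated vs exempt."""

    total_t_yr: float
    imported_prepackaged_t_yr: float
    national_prepackaged_t_yr: float
    loose_bakery_t_yr: float
    traditional_t_yr: float
    exempt_t_yr: float
    regulated_t_yr: float

    def share(self, tonnage: float) -> float:
        """Fraction of the total market a tonnage represents."""
        return tonnage / self.total_t_yr

    @property
    def exempt_share(self) -> float:
        return self.share(self.exempt_t_yr)

    @property
    def regulated_share(self) -> float:
        return self.share(self.regulated_t_yr)


@dataclass(frozen=True)
class SaltBaseline:
    """Population salt intake and the share attributable to bread."""

    per_capita_salt_g_day: float
    bread_share_of_salt: float
    per_capita_bread_g_day: float

    def __post_init__(self) -> None:
        if self.per_capita_salt_g_day < 0:
            raise ValueError("salt intake must be non-negative")
        if not 0.0 <= self.bread_share_of_salt <= 1.0:
            raise ValueError("bread share of salt must lie in [0, 1]")

    @property
    def per_capita_bread_salt_g_day(self) -> float:
        """Daily salt from bread, g/person/day."""
        return self.bread_share_of_salt * self.per_capita_salt_g_day

    @property
    def mean_salt_density_g_per_100g(self) -> float:
        """Tonnage-weighted mean salt density implied by the survey data."""
        return implied_salt_density(
            self.bread_share_of_salt,
            self.per_capita_salt_g_day,
            self.per_capita_bread_g_day,
        )


@dataclass(frozen=True)
class SaltScenario:
    """A legal salt threshold, its market scope, and compliance assumptions."""

    threshold_g_per_100g: float
    scope: Scope = Scope.ALL_BREAD
    compliance_fraction: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.threshold_g_per_100g <= 0:
            raise ValueError("threshold must be positive")
        if not 0.0 <= self.compliance_fraction <= 1.0:
            raise ValueError("compliance fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SegmentSalt:
    """Calibrated per-segment salt densities (g per 100 g bread).

    ``segments`` maps segment name -> (market share, salt density,
    exempt flag).  Shares sum to 1; the tonnage-weighted mean density
    equals the calibration target.
    """

    segments: dict[str, tuple[float, float, bool]] = field(default_factory=dict)

    @property
    def mean_density(self) -> float:
        return sum(w * d for w, d, _ in self.segments.values())

    def capped(self, threshold: float, scope: Scope) -> "SegmentSalt":
        """Densities after applying a threshold to the segments in scope."""
        out = {}
        for name, (w, d, exempt) in self.segments.items():
            in_scope = scope is Scope.ALL_BREAD or not exempt
            out[name] = (w, min(d, threshold) if in_scope else d, exempt)
        return SegmentSalt(out)


@dataclass(frozen=True)
class ReductionResult:
    """Per-capita and national salt reduction implied by a scenario."""

    salt_reduction_t_day: float
    salt_reduction_g_capita_day: float
    baseline_intake_g_capita_day: float
    counterfactual_intake_g_capita_day: float
    label: str = ""


def total_annual_bread(
    per_capita_bread_g_day: float,
    population: float,
    days_per_year: float = DAYS_PER_YEAR,
) -> float:
    """Annual national bread consumption in tonnes/year.

    Multiplies per-capita daily intake (g/day) by the population and the
    year length, converting grams to tonnes.
    """
    if per_capita_bread_g_day < 0 or population < 0 or days_per_year < 0:
        raise ValueError("inputs must be non-negative")
    return per_capita_bread_g_day * population * days_per_year / GRAMS_PER_TONNE


def decompose_market(
    inputs: MarketInputs, total_t_yr: float | None = None
) -> MarketDecomposition:
    """Split the annual bread market into segments.

    ``total_t_yr`` overrides the total derived from per-capita intake;
    survey-based intake and trade statistics need not agree exactly, so
    published totals can be supplied directly for parity with reported
    figures.  A discrepancy above 1% triggers a warning.
    """
    derived_total = total_annual_bread(
        inputs.per_capita_bread_g_day, inputs.population, inputs.days_per_year
    )
    if total_t_yr is None:
        total = derived_total
    else:
        total = total_t_yr
        if derived_total > 0 and abs(total - derived_total) / derived_total > 0.01:
            warnings.warn(
                f"supplied total {total:.0f} t/yr differs from the "
                f"intake-derived total {derived_total:.0f} t/yr by more than 1%",
                stacklevel=2,
            )
    if inputs.prepackaged_sold_t_yr > total:
        raise MarketConsistencyError("pre-packaged sales exceed the total market")

    imported = inputs.imported_t_yr
    national_prepackaged = inputs.prepackaged_sold_t_yr - imported
    loose = total - inputs.prepackaged_sold_t_yr
    national_production = total - imported
    traditional = inputs.traditional_fraction_of_national * national_production
    exempt = traditional + imported
    regulated = total - exempt
    return MarketDecomposition(
        total_t_yr=total,
        imported_prepackaged_t_yr=imported,
        national_prepackaged_t_yr=national_prepackaged,
        loose_bakery_t_yr=loose,
        traditional_t_yr=traditional,
        exempt_t_yr=exempt,
        regulated_t_yr=regulated,
    )


def implied_salt_density(
    bread_share_of_salt: float,
    per_capita_salt_g_day: float,
    per_capita_bread_g_day: float,
) -> float:
    """Mean salt density of bread (g/100 g) implied by intake surveys.

    Bread salt per capita is ``share × total salt``; dividing by bread
    consumption and scaling to 100 g gives the market-wide mean density.
    """
    if per_capita_bread_g_day <= 0:
        raise ValueError("bread intake must be positive")
    return (
        bread_share_of_salt * per_capita_salt_g_day / per_capita_bread_g_day * 100.0
    )


def solve_free_density(
    fixed: list[tuple[float, float]], free_weight: float, target_mean: float
) -> float:
    """Solve the closure for one free segment density.

    Given fixed (weight, density) pairs and the weight of the free
    segment, returns the density that makes the weighted mean equal
    ``target_mean``.
    """
    if free_weight <= 0:
        raise CalibrationError("free segment has zero weight; closure undefined")
    fixed_mass = sum(w * d for w, d in fixed)
    density = (target_mean - fixed_mass) / free_weight
    if density < 0 or density > MAX_PLAUSIBLE_DENSITY:
        raise CalibrationError(
            f"closure yields implausible exempt salt density {density:.3f} g/100 g"
        )
    return density


def calibrate_segment_salt(
    decomp: MarketDecomposition,
    mean_density_g_per_100g: float,
    compliance_fraction: float,
    compliant_density: float = 1.0,
    noncompliant_density: float = 1.4,
) -> SegmentSalt:
    """Assign salt densities to market segments by closure.

    The regulated segment is split: ``compliance_fraction`` of it at the
    voluntary-target density (default 1.0 g/100 g) and the remainder at
    the statutory maximum (default 1.4 g/100 g).  The exempt segment's
    density is the free parameter solved so that the tonnage-weighted
    mean equals ``mean_density_g_per_100g``.

    Degenerate markets with no exempt bread are accepted only when the
    fixed regulated densities already reproduce the target mean.
    """
    if mean_density_g_per_100g <= 0:
        raise ValueError("mean salt density must be positive")
    reg_share = decomp.regulated_share
    exempt_share = decomp.exempt_share
    w_compliant = reg_share * compliance_fraction
    w_noncompliant = reg_share * (1.0 - compliance_fraction)
    fixed = [
        (w_compliant, compliant_density),
        (w_noncompliant, noncompliant_density),
    ]
    if exempt_share <= 0:
        fixed_mean = sum(w * d for w, d in fixed)
        if abs(fixed_mean - mean_density_g_per_100g) > 1e-9:
            raise CalibrationError(
                "no exempt segment to absorb the closure residual"
            )
        exempt_density = 0.0
    else:
        exempt_density = solve_free_density(fixed, exempt_share, mean_density_g_per_100g)
    return SegmentSalt(
        {
            "regulated_compliant": (w_compliant, compliant_density, False),
            "regulated_noncompliant": (w_noncompliant, noncompliant_density, False),
            "exempt": (exempt_share, exempt_density, True),
        }
    )


def scenario_reduction(
    decomp: MarketDecomposition,
    segment_salt: SegmentSalt,
    scenario: SaltScenario,
    population: float,
    per_capita_bread_g_day: float,
    baseline_salt_g_day: float = 0.0,
) -> ReductionResult:
    """Salt-intake reduction from capping segment densities at a threshold.

    Each in-scope segment's density drops by ``max(0, density − threshold)``;
    the tonnage-share-weighted sum of those drops, scaled by per-capita
    bread consumption, is the per-capita salt reduction.  National
    tonnes/day follow from the population.
    """
    if population <= 0:
        raise ValueError("population must be positive")
    capped = segment_salt.capped(scenario.threshold_g_per_100g, scenario.scope)
    drop_per_100g = segment_salt.mean_density - capped.mean_density
    g_capita_day = drop_per_100g * per_capita_bread_g_day / 100.0
    t_day = g_capita_day * population / GRAMS_PER_TONNE
    return ReductionResult(
        salt_reduction_t_day=t_day,
        salt_reduction_g_capita_day=g_capita_day,
        baseline_intake_g_capita_day=baseline_salt_g_day,
        counterfactual_intake_g_capita_day=baseline_salt_g_day - g_capita_day,
        label=scenario.label,
    )


def tons_per_day_to_per_capita(tonnes_day: float, population: float) -> float:
    """Convert a national tonnes/day quantity to g/person/day."""
    if population <= 0:
        raise ValueError("population must be positive")
    return tonnes_day * GRAMS_PER_TONNE / population


def load_market_config(path) -> tuple[MarketInputs, SaltBaseline, float | None]:
    """Read market constants from a flat YAML mapping.

    Keys mirror the :class:`MarketInputs` and :class:`SaltBaseline`
    field names; an optional ``total_t_yr`` key pins the market total.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    inputs = MarketInputs(
        per_capita_bread_g_day=float(raw["per_capita_bread_g_day"]),
        population=float(raw["population"]),
        prepackaged_sold_t_yr=float(raw["prepackaged_sold_t_yr"]),
        imported_t_yr=float(raw["imported_t_yr"]),
        traditional_fraction_of_national=float(
            raw["traditional_fraction_of_national"]
        ),
        bakery_compliance_fraction=float(raw["bakery_compliance_fraction"]),
        days_per_year=float(raw.get("days_per_year", DAYS_PER_YEAR)),
    )
    baseline = SaltBaseline(
        per_capita_salt_g_day=float(raw["per_capita_salt_g_day"]),
        bread_share_of_salt=float(raw["bread_share_of_salt"]),
        per_capita_bread_g_day=inputs.per_capita_bread_g_day,
    )
    total = raw.get("total_t_yr")
    return inputs, baseline, (float(total) if total is not None else None)
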