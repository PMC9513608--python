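"""Monte Carlo confidence intervals and the policy-scenario battery.

The deaths-averted estimate is deterministic given its inputs; parameter
uncertainty enters through the dose–response slopes.  Each slope is
drawn independently from a normal on the log-RR scale (mean = point
estimate, sd = its standard error), deaths averted are recomputed per
draw, and the confidence interval is read off the empirical percentiles
of the resulting distribution (linear interpolation between order
statistics).  The central estimate is always the point-parameter value,
so it does not depend on the number of draws or the seed.

Scenario specifications bundle the market-side assumptions (legal
threshold, scope, bakery compliance) with intake-side sensitivity knobs
(alternative baselines, a rescaled baseline, an additive adjustment to
the reduction representing a shifted bread-share of salt), so a whole
battery of counterfactual and sensitivity analyses runs from one
configuration table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from breadsalt import bread_market as bm
from breadsalt import cra_mortality as cra

MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class MonteCarloConfig:
    """Number of draws, seed, and nominal confidence level."""

    n_draws: int = 10_000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_draws < 2:
            raise ValueError("n_draws must be at least 2")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the scenario battery.

    The market-side reduction is recomputed for each spec from its own
    baseline intake, compliance and threshold; ``bread_share_adjustment_g_day``
    then adds a signed per-capita amount to the reduction (the
    operationalisation of moving bread's share of salt intake by a
    percentage point), and ``baseline_scale`` rescales the baseline
    intake before anything else.  ``reduction_t_day_override`` bypasses
    the market model entirely, converting a stated national tonnes/day
    figure instead — useful for replaying published reductions.
    """

    label: str
    threshold_g_per_100g: float
    scope: bm.Scope = bm.Scope.ALL_BREAD
    baseline_salt_g_day: float = 7.4
    compliance_fraction: float = 0.76
    bread_share_adjustment_g_day: float = 0.0
    baseline_scale: float = 1.0
    reduction_t_day_override: float | None = None
    description: str = ""


@dataclass(frozen=True)
class ScenarioResult:
    """Resolved intakes plus the deaths-averted estimate with its CI."""

    label: str
    baseline_g_day: float
    reduction_g_day: float
    counterfactual_g_day: float
    deaths_averted_central: float
    ci_low: float
    ci_high: float
    description: str = ""


@dataclass(frozen=True)
class MarketContext:
    """Market constants shared by every scenario in a battery."""

    inputs: bm.MarketInputs
    bread_share_of_salt: float
    total_t_yr: float | None = None

    def decomposition(self) -> bm.MarketDecomposition:
        return bm.decompose_market(self.inputs, self.total_t_yr)


def sample_dose_response(
    drs: list[cra.DoseResponse], n_draws: int, seed: int
) -> np.ndarray:
    """Draw effective log-RR slopes, shape ``(n_draws, len(drs))``.

    Independent normals per dose–response entry, mean the point slope
    and sd its standard error; reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    betas = np.array([dr.effective_beta for dr in drs])
    ses = np.array([dr.se_beta for dr in drs])
    return rng.normal(loc=betas, scale=ses, size=(n_draws, len(drs)))


def percentile_interval(
    values: np.ndarray, ci_level: float = 0.95
) -> tuple[float, float]:
    """Empirical CI endpoints by linear interpolation of order statistics."""
    alpha = (1.0 - ci_level) / 2.0
    low, high = np.percentile(values, [100 * alpha, 100 * (1 - alpha)], method="linear")
    return float(low), float(high)


def _averted_draws(
    strata: list[cra.MortalityStratum],
    drs: list[cra.DoseResponse],
    shift: float,
    beta_draws: np.ndarray,
) -> np.ndarray:
    """Total deaths averted per draw under a pure mean shift.

    Uses the closed-form impact fraction 1 − exp(β·Δ), which the
    full pipeline reduces to for point exposures (and for untruncated
    equal-variance normal shifts).
    """
    dr_index: list[int] = []
    deaths: list[float] = []
    for stratum in strata:
        for cause, d in stratum.deaths_by_cause.items():
            dr = cra._resolve_dose_response(drs, cause, stratum)
            dr_index.append(drs.index(dr))
            deaths.append(d)
    if not deaths:
        return np.zeros(beta_draws.shape[0])
    deaths_arr = np.asarray(deaths)
    betas = beta_draws[:, dr_index]  # (n_draws, n_cells)
    return (1.0 - np.exp(betas * shift)) @ deaths_arr


def run_monte_carlo(
    strata: list[cra.MortalityStratum],
    drs: list[cra.DoseResponse],
    baseline_g_day: float,
    reduction_g_day: float,
    mc: MonteCarloConfig,
    label: str = "",
    description: str = "",
    beta_draws: np.ndarray | None = None,
) -> ScenarioResult:
    """Central deaths-averted estimate with a percentile Monte Carlo CI.

    The central estimate runs the full comparative-risk-assessment path
    at the point parameters; the CI re-evaluates total deaths averted on
    each sampled parameter vector.  ``beta_draws`` injects a
    pre-computed draw matrix (testing hook); otherwise draws come from
    :func:`sample_dose_response` under the configured seed.
    """
    baseline = cra.ExposureDistribution("point", baseline_g_day, 0.0)
    central = cra.deaths_averted(strata, drs, baseline, -reduction_g_day)
    if beta_draws is None:
        beta_draws = sample_dose_response(drs, mc.n_draws, mc.seed)
    totals = _averted_draws(strata, drs, -reduction_g_day, beta_draws)
    low, high = percentile_interval(totals, mc.ci_level)
    return ScenarioResult(
        label=label,
        baseline_g_day=baseline_g_day,
        reduction_g_day=reduction_g_day,
        counterfactual_g_day=baseline_g_day - reduction_g_day,
        deaths_averted_central=central.deaths_averted_total,
        ci_low=low,
        ci_high=high,
        description=description,
    )


def resolve_scenario(
    spec: ScenarioSpec, market: MarketContext
) -> tuple[float, float]:
    """Resolve a scenario spec to (baseline g/day, reduction g/day).

    The baseline is rescaled first; the market calibration is then
    recomputed from that baseline (so alternative-baseline sensitivity
    analyses carry a proportionally larger bread-salt pool), the
    threshold is applied, and finally the additive bread-share
    adjustment shifts the reduction.  Negative adjusted reductions are
    clipped to zero with a warning.
    """
    baseline = spec.baseline_salt_g_day * spec.baseline_scale
    if baseline < 0:
        raise ValueError("scaled baseline intake is negative")
    pop = market.inputs.population
    if spec.reduction_t_day_override is not None:
        reduction = bm.tons_per_day_to_per_capita(spec.reduction_t_day_override, pop)
    else:
        decomp = market.decomposition()
        density = bm.implied_salt_density(
            market.bread_share_of_salt, baseline, market.inputs.per_capita_bread_g_day
        )
        segment_salt = bm.calibrate_segment_salt(
            decomp, density, spec.compliance_fraction
        )
        scenario = bm.SaltScenario(
            threshold_g_per_100g=spec.threshold_g_per_100g,
            scope=spec.scope,
            compliance_fraction=spec.compliance_fraction,
            label=spec.label,
        )
        result = bm.scenario_reduction(
            decomp,
            segment_salt,
            scenario,
            pop,
            market.inputs.per_capita_bread_g_day,
            baseline_salt_g_day=baseline,
        )
        reduction = result.salt_reduction_g_capita_day
    reduction += spec.bread_share_adjustment_g_day
    if reduction < 0:
        warnings.warn(
            f"scenario {spec.label!r}: adjusted reduction {reduction:.4f} g/day "
            "is negative; clipping to 0",
            stacklevel=2,
        )
        reduction = 0.0
    if baseline - reduction < 0:
        raise ValueError(
            f"scenario {spec.label!r}: counterfactual intake would be negative"
        )
    return baseline, reduction


class BatteryError(RuntimeError):
    """A scenario in the battery failed; carries the failing label."""


def run_battery(
    specs: list[ScenarioSpec],
    strata: list[cra.MortalityStratum],
    drs: list[cra.DoseResponse],
    market: MarketContext,
    mc: MonteCarloConfig,
) -> pd.DataFrame:
    """Run every scenario and return one results row per spec, in order.

    Each scenario draws its parameters from an independent seed stream
    derived from the configured seed, so the battery is reproducible as
    a whole.  Duplicate labels are rejected; any scenario failure aborts
    the battery naming the offending label.
    """
    labels = [s.label for s in specs]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate scenario labels: {sorted(dupes)}")
    seeds = np.random.SeedSequence(mc.seed).generate_state(max(len(specs), 1))
    rows = []
    for spec, seed in zip(specs, seeds):
        try:
            baseline, reduction = resolve_scenario(spec, market)
            res = run_monte_carlo(
                strata,
                drs,
                baseline,
                reduction,
                replace(mc, seed=int(seed % MAX_SEED)),
                label=spec.label,
                description=spec.description,
            )
        except Exception as exc:
            raise BatteryError(f"scenario {spec.label!r} failed: {exc}") from exc
        rows.append(
            {
                "label": res.label,
                "description": res.description,
                "baseline_g_day": res.baseline_g_day,
                "reduction_g_day": res.reduction_g_day,
                "counterfactual_g_day": res.counterfactual_g_day,
                "deaths_averted": res.deaths_averted_central,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label",
            "description",
            "baseline_g_day",
            "reduction_g_day",
            "counterfactual_g_day",
            "deaths_averted",
            "ci_low",
            "ci_high",
        ],
    )


def format_battery(table: pd.DataFrame) -> pd.DataFrame:
    """Round a battery table to reporting precision.

    Intakes to two decimals, deaths and CI endpoints to the nearest
    integer — the convention of published scenario tables.
    """
    out = table.copy()
    for col in ("baseline_g_day", "reduction_g_day", "counterfactual_g_day"):
        out[col] = out[col].round(2)
    for col in ("deaths_averted", "ci_low", "ci_high"):
        out[col] = out[col].round(0).astype(int)
    return out


def load_battery_config(path) -> tuple[list[ScenarioSpec], MonteCarloConfig]:
    """Read a scenario battery from YAML.

    Top-level keys: ``monte_carlo`` (n_draws, seed, ci_level) and
    ``scenarios`` (list of ScenarioSpec field mappings).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    mc_raw = raw.get("monte_carlo", {})
    mc = MonteCarloConfig(
        n_draws=int(mc_raw.get("n_draws", 10_000)),
        seed=int(mc_raw["seed"]),
        ci_level=float(mc_raw.get("ci_level", 0.95)),
    )
    specs = []
    for row in raw["scenarios"]:
        kwargs = dict(row)
        if "scope" in kwargs:
            kwargs["scope"] = bm.Scope(kwargs["scope"])
        specs.append(ScenarioSpec(**kwargs))
    return specs, mc
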