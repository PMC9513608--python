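"""Comparative risk assessment: salt-intake shifts to deaths averted.

Implements the macro-simulation logic of PRIME-style models: for each
age-band × sex stratum and each salt-related cause of death, a potential
impact fraction (PIF) compares the expected relative risk under the
baseline and counterfactual salt-intake distributions,

    PIF = 1 − E_cf[RR(X)] / E_base[RR(X)],

and deaths averted in the stratum are observed deaths × PIF.  Relative
risk is log-linear in salt intake, either directly (log-RR slope per
g/day salt) or mediated through systolic blood pressure (salt→SBP slope
in mmHg per g/day composed with a log-RR slope per mmHg).

Exposure distributions are point masses (the default: a pure mean shift)
or normals truncated at zero; normal expectations use Gauss–Hermite
quadrature, which for the untruncated case must agree with the
log-normal-mean closed form exp(β·(μ−ref) + β²σ²/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy.stats import norm

#: The seven causes of death with an established salt (blood-pressure)
#: dose–response, in conventional reporting order.
SALT_RELATED_CAUSES: tuple[str, ...] = (
    "cerebrovascular_disease",
    "ischaemic_heart_disease",
    "heart_failure",
    "aortic_aneurysm",
    "pulmonary_embolism",
    "rheumatic_heart_disease",
    "hypertensive_disease",
)

SEXES = ("male", "female")

#: Default Gauss–Hermite order for normal-exposure expectations.
DEFAULT_QUAD_ORDER = 64

#: Age cutoff for the premature-mortality aggregate.
UNDER_75 = 75


class ConfigurationError(ValueError):
    """Raised when strata reference a cause with no dose–response."""


@dataclass(frozen=True)
class MortalityStratum:
    """One age-band × sex population cell with cause-specific deaths.

    ``age_high`` is exclusive; ``None`` marks the open terminal band
    (e.g. 85+).
    """

    age_low: int
    age_high: int | None
    sex: str
    population: float
    deaths_by_cause: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.population < 0:
            raise ValueError("population must be non-negative")
        if self.age_high is not None and self.age_high <= self.age_low:
            raise ValueError("age_high must exceed age_low")
        for cause, deaths in self.deaths_by_cause.items():
            if deaths < 0:
                raise ValueError(f"negative death count for {cause}")

    @property
    def is_under_75(self) -> bool:
        return self.age_high is not None and self.age_high <= UNDER_75


@dataclass(frozen=True)
class DoseResponse:
    """Cause-specific log-linear relative-risk slope for salt intake.

    ``pathway`` selects how the effective slope per g/day salt is built:

    * ``direct`` — ``beta`` is the log-RR per g/day salt.
    * ``sbp_mediated`` — the slope is ``sbp_slope × beta_sbp`` where
      ``sbp_slope`` is mmHg systolic blood pressure per g/day salt and
      ``beta_sbp`` the log-RR per mmHg.

    ``se_beta`` is the standard error of the *effective* slope, used for
    parameter uncertainty propagation.  Optional ``age_low``/``age_high``/
    ``sex`` restrict the entry to matching strata; the most specific
    matching entry wins.
    """

    cause: str
    beta: float = 0.0
    se_beta: float = 0.0
    reference_exposure: float = 0.0
    pathway: str = "direct"
    sbp_slope: float = 0.0
    beta_sbp: float = 0.0
    age_low: int | None = None
    age_high: int | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if self.pathway not in ("direct", "sbp_mediated"):
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if self.se_beta < 0:
            raise ValueError("se_beta must be non-negative")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex qualifier must be one of {SEXES}")

    @property
    def effective_beta(self) -> float:
        """Log-RR per g/day salt after pathway composition."""
        if self.pathway == "sbp_mediated":
            return self.sbp_slope * self.beta_sbp
        return self.beta

    def matches(self, stratum: MortalityStratum) -> bool:
        if self.sex is not None and self.sex != stratum.sex:
            return False
        if self.age_low is not None and stratum.age_low < self.age_low:
            return False
        if self.age_high is not None:
            if stratum.age_high is None or stratum.age_high > self.age_high:
                return False
        return True

    @property
    def specificity(self) -> int:
        return sum(q is not None for q in (self.sex, self.age_low, self.age_high))


@dataclass(frozen=True)
class ExposureDistribution:
    """Population salt-intake distribution, g/day.

    ``point`` is a degenerate distribution at ``mean``; ``normal`` is a
    normal truncated at zero (renormalised), which matters only when the
    mean is within a few standard deviations of zero.
    """

    family: str = "point"
    mean: float = 0.0
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("point", "normal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def shifted(self, delta: float) -> "ExposureDistribution":
        """Same distribution with the mean shifted by ``delta``."""
        return ExposureDistribution(self.family, self.mean + delta, self.sd)


@dataclass
class ImpactEstimate:
    """Deaths averted, aggregated several ways, for one exposure shift."""

    deaths_averted_total: float
    by_sex: dict[str, float]
    by_cause: dict[str, float]
    under_75: dict[str, float]
    per_stratum: pd.DataFrame

    def summary(self) -> str:
        lines = [f"Total deaths averted: {self.deaths_averted_total:.1f}"]
        for sex in SEXES:
            lines.append(
                f"  {sex}: {self.by_sex.get(sex, 0.0):.1f} "
                f"(under 75: {self.under_75.get(sex, 0.0):.1f})"
            )
        for cause, v in self.by_cause.items():
            lines.append(f"  {cause}: {v:.1f}")
        return "\n".join(lines)


def relative_risk(exposure: float, dr: DoseResponse, beta: float | None = None) -> float:
    """Relative risk at an exposure level, log-linear in salt intake.

    ``beta`` overrides the dose–response's effective slope (used by the
    Monte Carlo machinery to inject sampled parameters).
    """
    b = dr.effective_beta if beta is None else beta
    return math.exp(b * (exposure - dr.reference_exposure))


def mean_rr(
    dist: ExposureDistribution,
    dr: DoseResponse,
    beta: float | None = None,
    order: int = DEFAULT_QUAD_ORDER,
    truncate_at_zero: bool = True,
) -> float:
    """Expected relative risk over an exposure distribution.

    Point distributions evaluate the RR at the mean.  Normal
    distributions are integrated with probabilists' Gauss–Hermite
    quadrature; with ``truncate_at_zero`` the density is restricted to
    positive intakes and renormalised.  For the untruncated normal the
    result matches the closed form exp(β·(μ−ref) + β²σ²/2).
    """
    b = dr.effective_beta if beta is None else beta
    if dist.family == "point" or dist.sd == 0.0:
        return relative_risk(dist.mean, dr, beta=b)
    nodes, weights = hermegauss(order)
    x = dist.mean + dist.sd * nodes
    f = np.exp(b * (x - dr.reference_exposure))
    w = weights / math.sqrt(2.0 * math.pi)
    if truncate_at_zero:
        mask = x > 0.0
        mass = norm.sf(0.0, loc=dist.mean, scale=dist.sd)
        if mass <= 0.0:
            raise ValueError("truncated normal has no mass above zero")
        return float(np.sum(w[mask] * f[mask]) / mass)
    return float(np.sum(w * f))


def impact_fraction(
    baseline: ExposureDistribution,
    counterfactual: ExposureDistribution,
    dr: DoseResponse,
    beta: float | None = None,
    order: int = DEFAULT_QUAD_ORDER,
) -> float:
    """Potential impact fraction for a shift in the exposure distribution.

    ``1 − E_cf[RR] / E_base[RR]``; positive when the counterfactual
    lowers exposure and the slope is positive, negative (harm) when the
    shift raises expected risk.  For an equal-variance mean shift Δ with
    log-linear RR this reduces exactly to ``1 − exp(β·Δ)``.
    """
    e_base = mean_rr(baseline, dr, beta=beta, order=order)
    e_cf = mean_rr(counterfactual, dr, beta=beta, order=order)
    return 1.0 - e_cf / e_base


def _resolve_dose_response(
    drs: list[DoseResponse], cause: str, stratum: MortalityStratum
) -> DoseResponse:
    candidates = [dr for dr in drs if dr.cause == cause and dr.matches(stratum)]
    if not candidates:
        raise ConfigurationError(
            f"no dose–response for cause {cause!r} in stratum "
            f"({stratum.age_low}, {stratum.age_high}, {stratum.sex})"
        )
    return max(candidates, key=lambda dr: dr.specificity)


def deaths_averted(
    strata: list[MortalityStratum],
    drs: list[DoseResponse],
    baseline: ExposureDistribution,
    shift: float,
    per_stratum_shift: dict[tuple[int, str], float] | None = None,
    beta_overrides: dict[str, float] | None = None,
    order: int = DEFAULT_QUAD_ORDER,
) -> ImpactEstimate:
    """Deaths averted across all strata and causes for an intake shift.

    ``shift`` (g/day, negative for a reduction) moves the baseline
    exposure distribution's mean; ``per_stratum_shift`` keyed by
    ``(age_low, sex)`` overrides it per stratum.  ``beta_overrides``
    (cause → effective slope) lets callers inject sampled parameters.
    """
    rows = []
    for stratum in strata:
        s = shift
        if per_stratum_shift is not None:
            s = per_stratum_shift.get((stratum.age_low, stratum.sex), shift)
        cf = baseline.shifted(s)
        for cause, deaths in stratum.deaths_by_cause.items():
            dr = _resolve_dose_response(drs, cause, stratum)
            beta = None
            if beta_overrides is not None and cause in beta_overrides:
                beta = beta_overrides[cause]
            pif = impact_fraction(baseline, cf, dr, beta=beta, order=order)
            rows.append(
                {
                    "age_low": stratum.age_low,
                    "age_high": stratum.age_high,
                    "sex": stratum.sex,
                    "cause": cause,
                    "deaths": deaths,
                    "pif": pif,
                    "deaths_averted": deaths * pif,
                    "under_75": stratum.is_under_75,
                }
            )
    per_stratum = pd.DataFrame(
        rows,
        columns=[
            "age_low",
            "age_high",
            "sex",
            "cause",
            "deaths",
            "pif",
            "deaths_averted",
            "under_75",
        ],
    )
    if per_stratum.empty:
        total = 0.0
        by_sex = {s: 0.0 for s in SEXES}
        by_cause = {}
        under = {s: 0.0 for s in SEXES}
    else:
        total = float(per_stratum["deaths_averted"].sum())
        by_sex = {
            s: float(per_stratum.loc[per_stratum["sex"] == s, "deaths_averted"].sum())
            for s in SEXES
        }
        by_cause = {
            c: float(g["deaths_averted"].sum())
            for c, g in per_stratum.groupby("cause", sort=False)
        }
        under = {
            s: float(
                per_stratum.loc[
                    (per_stratum["sex"] == s) & per_stratum["under_75"],
                    "deaths_averted",
                ].sum()
            )
            for s in SEXES
        }
    return ImpactEstimate(
        deaths_averted_total=total,
        by_sex=by_sex,
        by_cause=by_cause,
        under_75=under,
        per_stratum=per_stratum,
    )


# ---------------------------------------------------------------------------
# CSV interfaces


def strata_to_frame(strata: list[MortalityStratum]) -> pd.DataFrame:
    """Long-format table: one row per stratum × cause."""
    rows = []
    for st in strata:
        for cause, deaths in st.deaths_by_cause.items():
            rows.append(
                {
                    "age_low": st.age_low,
                    "age_high": "" if st.age_high is None else st.age_high,
                    "sex": st.sex,
                    "population": st.population,
                    "cause": cause,
                    "deaths": deaths,
                }
            )
    return pd.DataFrame(
        rows, columns=["age_low", "age_high", "sex", "population", "cause", "deaths"]
    )


def read_strata_csv(path) -> list[MortalityStratum]:
    """Read strata from a long-format CSV (empty age_high = open band)."""
    df = pd.read_csv(path, dtype={"age_high": "object"})
    strata = []
    for (age_low, age_high, sex), group in df.groupby(
        ["age_low", "age_high", "sex"], sort=False, dropna=False
    ):
        high: int | None
        if pd.isna(age_high) or str(age_high).strip() == "":
            high = None
        else:
            high = int(float(age_high))
        populations = group["population"].unique()
        if len(populations) != 1:
            raise ValueError(
                f"inconsistent population for stratum ({age_low}, {high}, {sex})"
            )
        strata.append(
            MortalityStratum(
                age_low=int(age_low),
                age_high=high,
                sex=str(sex),
                population=float(populations[0]),
                deaths_by_cause={
                    str(r.cause): float(r.deaths) for r in group.itertuples()
                },
            )
        )
    return strata


def write_strata_csv(strata: list[MortalityStratum], path) -> None:
    strata_to_frame(strata).to_csv(path, index=False)


def read_dose_response_csv(path) -> list[DoseResponse]:
    """Read dose–response parameters from CSV.

    Columns: cause, pathway, beta, sbp_slope, beta_sbp, se, reference_exposure
    and optional age_low / age_high / sex qualifiers.  Missing numeric
    fields default to zero.
    """
    df = pd.read_csv(path)

    def _opt_int(v):
        return None if pd.isna(v) else int(v)

    def _num(row, col):
        if col not in row or pd.isna(row[col]):
            return 0.0
        return float(row[col])

    out = []
    for _, row in df.iterrows():
        out.append(
            DoseResponse(
                cause=str(row["cause"]),
                pathway=str(row.get("pathway", "direct")),
                beta=_num(row, "beta"),
                sbp_slope=_num(row, "sbp_slope"),
                beta_sbp=_num(row, "beta_sbp"),
                se_beta=_num(row, "se"),
                reference_exposure=_num(row, "reference_exposure"),
                age_low=_opt_int(row.get("age_low")),
                age_high=_opt_int(row.get("age_high")),
                sex=None if pd.isna(row.get("sex")) else str(row["sex"]),
            )
        )
    return out


def default_dose_response_path() -> Path:
    """Path of the packaged default dose–response parameter file."""
    return Path(__file__).parent / "data" / "dose_response_default.csv"


def load_default_dose_response() -> list[DoseResponse]:
    """Packaged defaults: blood-pressure-mediated slopes per cause.

    Assembled from the comparative-risk-assessment literature (salt→SBP
    trial meta-analyses and prospective SBP→CVD cohort pooling); see the
    methods note for provenance and caveats.
    """
    return read_dose_response_csv(default_dose_response_path())
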