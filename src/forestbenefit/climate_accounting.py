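"""Cumulative climate-benefit accounting.

Per scenario, the cumulative CO₂ uptake is assembled from three components
per 5-year period: the change in forest carbon stocks (living + dead + soil),
the change in the harvested-wood-product pool, and avoided fossil emissions
(RS × harvested carbon).  All ledgers are re-baselined to zero at simulation
start.  The climate benefit of an alternative scenario is its cumulative
uptake minus that of business-as-usual, so a positive benefit means the
alternative removes or avoids more atmospheric carbon.

Because the substitution term is the only place RS enters, and it enters
multiplicatively, every benefit series is exactly affine in RS.  That affine
structure is exploited to deduce the substitution level implied by a reported
benefit without any iteration.

All accounting is in tonnes C; conversion to CO₂ (× 44/12) happens only at
the reporting layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landscape_sim import PERIOD_YEARS, SimOutput
from .substitution import SubstitutionSpec, avoided_emissions
from .wood_products import DEFAULT_PORTFOLIO, ProductPortfolio, run_product_model

__all__ = [
    "ClimateLedger",
    "BenefitSeries",
    "CO2_PER_C",
    "build_ledger",
    "scenario_ledger",
    "climate_benefit",
    "benefit_for",
    "deduce_substitution_level",
    "sign_change_year",
]

CO2_PER_C = 44.0 / 12.0


@dataclass(frozen=True)
class ClimateLedger:
    """Per-period uptake components and their running sum, tonnes C."""

    forest_delta_c: np.ndarray
    hwp_delta_c: np.ndarray
    substitution_c: np.ndarray
    scenario_name: str = ""

    def __post_init__(self) -> None:
        n = len(self.forest_delta_c)
        if len(self.hwp_delta_c) != n or len(self.substitution_c) != n:
            raise ValueError("ledger components differ in length")
        for arr in (self.forest_delta_c, self.hwp_delta_c, self.substitution_c):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite ledger entry")

    @property
    def n_periods(self) -> int:
        return len(self.forest_delta_c)

    @property
    def cumulative_uptake(self) -> np.ndarray:
        return np.cumsum(self.forest_delta_c + self.hwp_delta_c + self.substitution_c)

    @property
    def period_end_years(self) -> np.ndarray:
        return (np.arange(self.n_periods) + 1) * PERIOD_YEARS


@dataclass(frozen=True)
class BenefitSeries:
    """Cumulative-uptake difference of an alternative scenario vs BAU."""

    benefit_c: np.ndarray          # tonnes C, per period end
    alternative: str = ""
    reference: str = "bau"
    rs: float | None = None

    @property
    def n_periods(self) -> int:
        return len(self.benefit_c)

    @property
    def period_end_years(self) -> np.ndarray:
        return (np.arange(self.n_periods) + 1) * PERIOD_YEARS

    @property
    def benefit_co2(self) -> np.ndarray:
        return self.benefit_c * CO2_PER_C

    @property
    def final(self) -> float:
        """Benefit at the simulation horizon, tonnes C."""
        return float(self.benefit_c[-1])

    def at_year(self, year: float) -> float:
        idx = int(round(year / PERIOD_YEARS)) - 1
        if not 0 <= idx < self.n_periods:
            raise ValueError(f"year {year} outside the simulated horizon")
        return float(self.benefit_c[idx])


def build_ledger(
    sim: SimOutput,
    hwp_trajectory: dict[str, np.ndarray] | None = None,
    spec: SubstitutionSpec | float = 0.0,
    portfolio: ProductPortfolio = DEFAULT_PORTFOLIO,
) -> ClimateLedger:
    """Assemble the per-period uptake ledger for one simulated scenario.

    ``hwp_trajectory`` is the output of
    :func:`forestbenefit.wood_products.run_product_model`; it is computed on
    the fly when omitted.  The grids must align.
    """
    if hwp_trajectory is None:
        hwp_trajectory = run_product_model(sim, portfolio)
    total_pool = hwp_trajectory["total_pool"]
    if len(total_pool) != sim.n_periods:
        raise ValueError("simulation and HWP trajectory grids differ")
    forest_delta = np.diff(sim.stock_c, prepend=sim.initial_stock_c)
    hwp_delta = np.diff(total_pool, prepend=0.0)
    subst = avoided_emissions(sim.harvested_c, spec)
    return ClimateLedger(forest_delta, hwp_delta, np.asarray(subst, dtype=float),
                         scenario_name=sim.scenario_name)


def scenario_ledger(sim: SimOutput, rs: float,
                    portfolio: ProductPortfolio = DEFAULT_PORTFOLIO) -> ClimateLedger:
    """Convenience wrapper: ledger for a simulation at a given RS level."""
    return build_ledger(sim, spec=SubstitutionSpec(realized_substitution=rs),
                        portfolio=portfolio)


def climate_benefit(alt: ClimateLedger, bau: ClimateLedger,
                    rs: float | None = None) -> BenefitSeries:
    """Cumulative uptake of the alternative minus that of the reference."""
    if alt.n_periods != bau.n_periods:
        raise ValueError("ledgers live on different period grids")
    return BenefitSeries(
        benefit_c=alt.cumulative_uptake - bau.cumulative_uptake,
        alternative=alt.scenario_name,
        reference=bau.scenario_name,
        rs=rs,
    )


def benefit_for(alt_sim: SimOutput, bau_sim: SimOutput, rs: float,
                portfolio: ProductPortfolio = DEFAULT_PORTFOLIO) -> BenefitSeries:
    """Benefit series of an alternative simulation vs BAU at one RS level."""
    return climate_benefit(scenario_ledger(alt_sim, rs, portfolio),
                           scenario_ledger(bau_sim, rs, portfolio), rs=rs)


def deduce_substitution_level(
    target,
    alt_sim: SimOutput,
    bau_sim: SimOutput,
    year: float | None = None,
    portfolio: ProductPortfolio = DEFAULT_PORTFOLIO,
) -> float:
    """Substitution level required to reproduce a reported climate benefit.

    The benefit at any horizon is affine in RS (the substitution term is the
    only RS-dependent component and is linear in it), so

        RS = (target - benefit@RS=0) / (benefit@RS=1 - benefit@RS=0)

    is an exact solve.  ``target`` is the reported benefit in tonnes C at
    ``year`` (default: the simulation horizon).  Raises when the two arms
    harvest the same cumulative amount at the horizon, in which case the
    benefit is insensitive to RS and the level is unidentifiable.
    """
    b0 = benefit_for(alt_sim, bau_sim, 0.0, portfolio)
    b1 = benefit_for(alt_sim, bau_sim, 1.0, portfolio)
    if year is None:
        y0, y1 = b0.final, b1.final
    else:
        y0, y1 = b0.at_year(year), b1.at_year(year)
    sensitivity = y1 - y0   # = cumulative harvest difference at the horizon
    if abs(sensitivity) < 1e-9 * max(abs(y0), 1.0):
        raise ValueError("RS unidentifiable: scenarios have equal cumulative harvest")
    return (float(target) - y0) / sensitivity


def sign_change_year(series: BenefitSeries, tol: float = 0.0) -> float | None:
    """First period boundary where the benefit turns negative after a
    positive phase.

    Scans for the first period with benefit above ``tol`` and returns the end
    year of the first later period at or below ``-tol`` (the crossing lies at
    that period boundary on the 5-year grid).  Returns ``None`` if the series
    never goes positive or never crosses back within the horizon.
    """
    b = series.benefit_c
    if len(b) == 0:
        raise ValueError("empty benefit series")
    pos = np.nonzero(b > tol)[0]
    if len(pos) == 0:
        return None
    after = b[pos[0]:]
    neg = np.nonzero(after < -tol)[0]
    if len(neg) == 0:
        return None
    return float((pos[0] + neg[0] + 1) * PERIOD_YEARS)
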