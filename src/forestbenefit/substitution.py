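"""Displacement-factor and realized-substitution algebra.

Two currencies are used in the literature for the avoided fossil emissions of
wood use:

* the displacement factor (DF), tonnes fossil C avoided per tonne C in a
  wood product, defined per product and aggregated to a market level as a
  usage-weighted average; and
* the realized substitution level (RS), tonnes fossil C avoided per tonne C
  *harvested*, which folds in the share of the harvest that actually provides
  substitution.

RS is the primary currency here; a DF-plus-share specification is accepted as
an alternate entry path and converted with an explicit product.  Literature
RS presets shipped: 0.42, 0.65 and 1.30 (the three sensitivity levels), 0.53
(the usage-based mean) and the 0.9–1.1 band deduced for high-substitution
studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SubstitutionSpec",
    "RS_PRESETS",
    "aggregate_displacement",
    "mean_literature_rs",
    "avoided_emissions",
    "convert_units",
]

#: shipped realized-substitution presets (ton fossil C avoided / ton C harvested)
RS_PRESETS: dict[str, float] = {
    "low": 0.42,
    "usage_based": 0.53,
    "intermediate": 0.65,
    "deduced_low": 0.9,
    "deduced_high": 1.1,
    "high": 1.30,
}


@dataclass(frozen=True)
class SubstitutionSpec:
    """Substitution assumption: either RS directly, or DF plus share.

    Exactly one entry path must be used.  When ``market_displacement`` and
    ``substituting_share`` are given, RS = DF × share.
    """

    realized_substitution: float | None = None
    market_displacement: float | None = None
    substituting_share: float | None = None

    def __post_init__(self) -> None:
        df_path = self.market_displacement is not None or self.substituting_share is not None
        rs_path = self.realized_substitution is not None
        if rs_path and df_path:
            raise ValueError("give either rs or df+share, not both")
        if not rs_path and not df_path:
            raise ValueError("substitution spec is empty")
        if df_path and (self.market_displacement is None or self.substituting_share is None):
            raise ValueError("df entry path needs both market_displacement and substituting_share")
        if rs_path and self.realized_substitution < 0:
            raise ValueError("realized substitution must be non-negative")
        if df_path:
            if self.market_displacement < 0:
                raise ValueError("displacement factor must be non-negative")
            if not 0.0 <= self.substituting_share <= 1.0:
                raise ValueError("substituting share must lie in [0, 1]")

    @property
    def rs(self) -> float:
        """Realized substitution level, ton fossil C / ton C harvested."""
        if self.realized_substitution is not None:
            return self.realized_substitution
        return self.market_displacement * self.substituting_share

    @classmethod
    def from_scenario_block(cls, block: dict | float | None) -> "SubstitutionSpec":
        """Parse the optional ``substitution:`` block of a scenario config."""
        if block is None:
            return cls(realized_substitution=RS_PRESETS["usage_based"])
        if isinstance(block, (int, float)):
            return cls(realized_substitution=float(block))
        known = {"rs", "df", "share"}
        unknown = set(block) - known
        if unknown:
            raise ValueError(f"unknown substitution keys: {sorted(unknown)}")
        if "rs" in block and ("df" in block or "share" in block):
            raise ValueError("give either rs or df+share, not both")
        if "rs" in block:
            return cls(realized_substitution=float(block["rs"]))
        return cls(market_displacement=float(block["df"]),
                   substituting_share=float(block["share"]))


def aggregate_displacement(product_dfs, usage_weights) -> float:
    """Usage-weighted market-level displacement factor, Σ wᵢ·DFᵢ.

    Weights are each product's share of the total usage of harvested biomass
    and must sum to one.
    """
    dfs = np.asarray(product_dfs, dtype=float)
    w = np.asarray(usage_weights, dtype=float)
    if dfs.shape != w.shape:
        raise ValueError("weights and displacement factors differ in length")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"usage weights must sum to 1 (got {w.sum()!r})")
    if np.any(w < 0):
        raise ValueError("usage weights must be non-negative")
    return float((w * dfs).sum())


def mean_literature_rs(values) -> float:
    """Arithmetic mean of literature RS values.

    RS levels are conventionally quoted to two decimals; the exact mean is
    returned and rounding is left to the reporting layer.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one RS value")
    return float(vals.mean())


def avoided_emissions(harvested_c, spec: SubstitutionSpec | float):
    """Avoided fossil emissions: RS × harvested carbon, tonnes C.

    Accepts a scalar or a per-period array of harvested carbon; a bare float
    is treated as an RS value.  For reduced-harvest comparisons the same term,
    through the scenario difference, accounts for the increased use of
    fossil-based fuels and products.
    """
    rs = spec.rs if isinstance(spec, SubstitutionSpec) else float(spec)
    if rs < 0:
        raise ValueError("realized substitution must be non-negative")
    h = np.asarray(harvested_c, dtype=float)
    if np.any(h < 0):
        raise ValueError("harvested carbon must be non-negative")
    out = rs * h
    return float(out) if out.ndim == 0 else out


def convert_units(df_per_m3: float, conversion: float = 1.3,
                  invert: bool = False) -> float:
    """Convert a substitution level between per-m³-wood and per-ton-C units.

    The forward direction is ``rs = df_per_m3 * conversion``; ``invert=True``
    applies the exact inverse.  The factor's interpretation (m³ per tonne C
    harvested vs its reciprocal) varies between studies, so it is held
    configurable rather than derived.
    """
    if conversion <= 0:
        raise ValueError("conversion factor must be positive")
    if df_per_m3 < 0:
        raise ValueError("substitution level must be non-negative")
    return df_per_m3 / conversion if invert else df_per_m3 * conversion
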