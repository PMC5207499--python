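"""Bloom biomass management arithmetic.

Converts surveyed wet bloom tonnages to dry weight, estimates the total
metal load a collected bloom would carry, costs the disposal options
(landfill vs spreading on arable land), screens tissue concentrations
against international regulatory limits, and checks analytical recovery
against a certified reference material (CRM).

Default moisture fraction for wet Ulva biomass is 0.796; landfill disposal
is costed at €260 per wet tonne and arable-land disposal at €16 per tonne.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "DEFAULT_MOISTURE",
    "LANDFILL_EUR_PER_TONNE",
    "ARABLE_EUR_PER_TONNE",
    "BloomInventory",
    "RegulatoryLimit",
    "CRMRecord",
    "ww_to_dw",
    "metal_load",
    "disposal_cost",
    "screen_limits",
    "crm_check",
]

DEFAULT_MOISTURE = 0.796
LANDFILL_EUR_PER_TONNE = 260.0
ARABLE_EUR_PER_TONNE = 16.0


def ww_to_dw(wet_tonnes: float, moisture_fraction: float = DEFAULT_MOISTURE) -> float:
    """Dry tonnage from wet tonnage: wet × (1 − moisture)."""
    if wet_tonnes < 0:
        raise ValueError("wet tonnage must be >= 0")
    if not 0.0 <= moisture_fraction < 1.0:
        raise ValueError(f"moisture fraction must be in [0, 1), got {moisture_fraction}")
    return wet_tonnes * (1.0 - moisture_fraction)


@dataclass(frozen=True)
class BloomInventory:
    """Wet bloom standing stock at a site, with its dry-weight equivalent."""

    site_id: str
    wet_tonnes: float
    moisture_fraction: float = DEFAULT_MOISTURE

    def __post_init__(self) -> None:
        ww_to_dw(self.wet_tonnes, self.moisture_fraction)  # validates

    @property
    def dry_tonnes(self) -> float:
        return ww_to_dw(self.wet_tonnes, self.moisture_fraction)


def metal_load(dry_tonnes: float, concentration_mg_kg: float) -> float:
    """Total metal mass (kg) in a bloom: dry tonnes × concentration.

    kg = t × 10³ kg t⁻¹ × (mg kg⁻¹) × 10⁻⁶ kg mg⁻¹
    """
    if dry_tonnes < 0 or concentration_mg_kg < 0:
        raise ValueError("tonnage and concentration must be >= 0")
    return dry_tonnes * 1000.0 * concentration_mg_kg * 1e-6


def disposal_cost(wet_tonnes: float, rate_eur_per_tonne: float) -> int:
    """Disposal cost in whole euro (half-away-from-zero rounding)."""
    if wet_tonnes < 0 or rate_eur_per_tonne < 0:
        raise ValueError("tonnage and rate must be >= 0")
    exact = wet_tonnes * rate_eur_per_tonne
    return int(math.floor(exact + 0.5))


@dataclass(frozen=True)
class RegulatoryLimit:
    """A single maximum-limit entry for one metal in one commodity class."""

    jurisdiction: str
    commodity: str
    metal: str
    limit_mg_kg: float
    inorganic_only: bool = False
    basis: str = "dw"
    reference: str = ""

    def __post_init__(self) -> None:
        if self.limit_mg_kg <= 0:
            raise ValueError("limit must be > 0")


def screen_limits(
    concentrations: Mapping[str, float],
    limits: Sequence[RegulatoryLimit],
) -> list[dict]:
    """Screen total tissue concentrations against a set of limits.

    One row per limit entry with ``status`` in {pass, exceed,
    not-regulated}; limits that apply to the inorganic species only are
    flagged ``comparable=False`` because total concentrations overstate the
    regulated fraction (a 'pass'/'exceed' against them is indicative only).
    Metals measured but absent from the limit set are appended as
    ``not-regulated``.
    """
    rows: list[dict] = []
    regulated = set()
    for lim in limits:
        conc = concentrations.get(lim.metal)
        if conc is None:
            continue
        regulated.add(lim.metal)
        rows.append(
            {
                "jurisdiction": lim.jurisdiction,
                "commodity": lim.commodity,
                "metal": lim.metal,
                "concentration_mg_kg": conc,
                "limit_mg_kg": lim.limit_mg_kg,
                "status": "exceed" if conc > lim.limit_mg_kg else "pass",
                "comparable": not lim.inorganic_only,
                "basis": lim.basis,
                "reference": lim.reference,
            }
        )
    for metal, conc in concentrations.items():
        if metal not in regulated:
            rows.append(
                {
                    "jurisdiction": None,
                    "commodity": None,
                    "metal": metal,
                    "concentration_mg_kg": conc,
                    "limit_mg_kg": None,
                    "status": "not-regulated",
                    "comparable": True,
                    "basis": None,
                    "reference": None,
                }
            )
    return rows


@dataclass(frozen=True)
class CRMRecord:
    """Certified/indicative CRM value versus the value found in-house."""

    metal: str
    reported_mean: float
    reported_unc: float
    found_mean: float
    found_unc: float
    certified: bool = True

    def __post_init__(self) -> None:
        if self.reported_mean <= 0 or self.found_mean <= 0:
            raise ValueError("CRM means must be > 0")
        if self.reported_unc < 0 or self.found_unc < 0:
            raise ValueError("CRM uncertainties must be >= 0")


def crm_check(records: Sequence[CRMRecord], k: float = 2.0) -> dict[str, bool]:
    """Recovery check: pass iff |found − reported| ≤ k·√(u_f² + u_r²)."""
    out: dict[str, bool] = {}
    for rec in records:
        tol = k * math.hypot(rec.found_unc, rec.reported_unc)
        out[rec.metal] = abs(rec.found_mean - rec.reported_mean) <= tol
    return out
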