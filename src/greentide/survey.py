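"""Intertidal bloom surveys and their reduction to WFD sub-metrics.

A water body is surveyed by mapping the outer edges of each algal patch
within the Available Intertidal Habitat (AIH) and placing gridded 0.25 m²
quadrats along transects through every patch.  This module holds the survey
data model and the arithmetic that reduces a survey to the five sub-metrics
of the opportunistic-macroalgae assessment tool: percentage cover of the
AIH, affected area (absolute and relative), mean biomass over the AIH and
over the affected area, and the percentage of quadrats with algae entrained
into the sediment.

Units: areas are hectares externally (converted to m² internally), biomass
is g m⁻² wet weight, bloom totals are metric tonnes wet weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "QuadratRecord",
    "SiteGeometry",
    "SiteSurvey",
    "SubMetricValues",
    "compute_affected_area",
    "compute_cover_pct_aih",
    "compute_mean_biomass_aa",
    "compute_mean_biomass_aih",
    "compute_entrained_pct",
    "compute_total_biomass",
    "extract_submetrics",
]

M2_PER_HA = 10_000.0
GRAMS_PER_TONNE = 1_000_000.0


@dataclass(frozen=True)
class QuadratRecord:
    """One sampling quadrat (default 0.25 m²) placed within an algal patch."""

    site_id: str
    patch_id: str
    transect_id: str
    cover_pct: float
    biomass_g_m2: float
    entrained: bool = False
    area_m2: float = 0.25
    quadrat_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.cover_pct <= 100.0:
            raise ValueError(f"cover_pct must be in [0, 100], got {self.cover_pct}")
        if self.biomass_g_m2 < 0.0:
            raise ValueError(f"biomass_g_m2 must be >= 0, got {self.biomass_g_m2}")
        if self.area_m2 <= 0.0:
            raise ValueError(f"area_m2 must be > 0, got {self.area_m2}")


@dataclass(frozen=True)
class SiteGeometry:
    """Mapped geometry of a site: AIH extent and per-patch areas (hectares)."""

    site_id: str
    aih_ha: float
    patch_areas_ha: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.aih_ha <= 0.0:
            raise ValueError(f"aih_ha must be > 0, got {self.aih_ha}")
        for pid, area in self.patch_areas_ha.items():
            if area < 0.0:
                raise ValueError(f"patch {pid!r} has negative area {area}")
        total = sum(self.patch_areas_ha.values())
        if total > self.aih_ha:
            warnings.warn(
                f"site {self.site_id!r}: summed patch area {total:.2f} ha exceeds "
                f"AIH {self.aih_ha:.2f} ha",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SiteSurvey:
    """A site's geometry together with its quadrat records."""

    geometry: SiteGeometry
    quadrats: Sequence[QuadratRecord] = ()

    def __post_init__(self) -> None:
        known = set(self.geometry.patch_areas_ha)
        for q in self.quadrats:
            if q.patch_id not in known:
                raise ValueError(
                    f"quadrat {q.quadrat_id or '?'} references unknown patch "
                    f"{q.patch_id!r}"
                )

    def quadrats_in_patch(self, patch_id: str) -> list[QuadratRecord]:
        return [q for q in self.quadrats if q.patch_id == patch_id]


@dataclass(frozen=True)
class SubMetricValues:
    """The five assessment sub-metrics plus AA expressed relative to AIH."""

    cover_pct_aih: float
    aa_ha: float
    aa_over_aih_pct: float
    biomass_aih_g_m2: float
    biomass_aa_g_m2: float
    entrained_pct: float


def compute_affected_area(geometry: SiteGeometry) -> float:
    """Affected area (AA): total mapped patch area, in hectares."""
    return float(sum(geometry.patch_areas_ha.values()))


def compute_cover_pct_aih(survey: SiteSurvey) -> float:
    """Percentage of the AIH covered by algae.

    Each patch contributes its mapped area weighted by the mean fractional
    cover of its quadrats; a patch of positive area with no quadrats is a
    protocol violation and raises.
    """
    geom = survey.geometry
    covered_ha = 0.0
    for pid, area in geom.patch_areas_ha.items():
        if area == 0.0:
            continue
        quads = survey.quadrats_in_patch(pid)
        if not quads:
            raise ValueError(f"patch {pid!r} has area {area} ha but no quadrats")
        mean_frac = sum(q.cover_pct for q in quads) / len(quads) / 100.0
        covered_ha += area * mean_frac
    return 100.0 * covered_ha / geom.aih_ha


def compute_mean_biomass_aa(survey: SiteSurvey) -> float:
    """Mean wet biomass (g m⁻²) over the affected area: quadrat mean."""
    if not survey.quadrats:
        raise ValueError("cannot compute mean biomass without quadrats")
    return sum(q.biomass_g_m2 for q in survey.quadrats) / len(survey.quadrats)


def compute_mean_biomass_aih(biomass_aa: float, aa_ha: float, aih_ha: float) -> float:
    """Mean biomass diluted over the full AIH, treating area outside patches
    as bare (zero biomass)."""
    if aih_ha <= 0.0:
        raise ValueError(f"aih_ha must be > 0, got {aih_ha}")
    return biomass_aa * aa_ha / aih_ha


def compute_entrained_pct(survey: SiteSurvey) -> float:
    """Percentage of quadrats with algae entrained into the sediment."""
    if not survey.quadrats:
        raise ValueError("cannot compute entrainment without quadrats")
    n_entrained = sum(1 for q in survey.quadrats if q.entrained)
    return 100.0 * n_entrained / len(survey.quadrats)


def compute_total_biomass(spatial_cover_ha: float, mean_biomass_g_m2: float) -> float:
    """Total bloom biomass in metric tonnes wet weight.

    tonnes = cover [ha] × 10⁴ m² ha⁻¹ × biomass [g m⁻²] × 10⁻⁶ t g⁻¹
    """
    if spatial_cover_ha < 0.0 or mean_biomass_g_m2 < 0.0:
        raise ValueError("spatial cover and mean biomass must be >= 0")
    return spatial_cover_ha * M2_PER_HA * mean_biomass_g_m2 / GRAMS_PER_TONNE


def extract_submetrics(survey: SiteSurvey) -> SubMetricValues:
    """Reduce a survey to the five sub-metrics (plus AA/AIH %).

    A survey with no patches (a pristine site) yields all-zero sub-metrics.
    """
    geom = survey.geometry
    aa_ha = compute_affected_area(geom)
    if aa_ha == 0.0 and not survey.quadrats:
        return SubMetricValues(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    cover = compute_cover_pct_aih(survey)
    biomass_aa = compute_mean_biomass_aa(survey)
    biomass_aih = compute_mean_biomass_aih(biomass_aa, aa_ha, geom.aih_ha)
    entrained = compute_entrained_pct(survey)
    return SubMetricValues(
        cover_pct_aih=cover,
        aa_ha=aa_ha,
        aa_over_aih_pct=100.0 * aa_ha / geom.aih_ha,
        biomass_aih_g_m2=biomass_aih,
        biomass_aa_g_m2=biomass_aa,
        entrained_pct=entrained,
    )
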