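"""Ecological Quality Ratio (EQR) scoring and Ecological Status classification.

Each sub-metric value is scored on a 0–1 EQR scale by piecewise-linear
interpolation through a boundary table of six anchors per metric (at EQR
1.0, 0.8, 0.6, 0.4, 0.2 and 0.0).  Within a class band::

    EQR = upper_EQR − (value − lower_bound) / class_width × band_width

with band_width fixed at 0.2.  The overall site EQR is the arithmetic mean
of the contributing sub-metric EQRs, and maps to one of five Ecological
Status classes: High (≥0.8), Good (≥0.6), Moderate (≥0.4), Poor (≥0.2),
Bad (<0.2).

Of the two affected-area criteria (absolute AA in ha, and AA as % of AIH)
only one enters the average; by default the one indicating lesser impact
(the higher EQR), which avoids penalising the same pressure twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from .survey import SiteSurvey, SubMetricValues, extract_submetrics

__all__ = [
    "EQR_ANCHORS",
    "STATUS_CLASSES",
    "BoundaryTable",
    "AssessmentResult",
    "interpolate_eqr",
    "invert_eqr",
    "choose_aa_submetric",
    "final_eqr",
    "classify",
    "screening_decision",
    "assess_site",
]

EQR_ANCHORS: tuple[float, ...] = (1.0, 0.8, 0.6, 0.4, 0.2, 0.0)
STATUS_CLASSES: tuple[str, ...] = ("High", "Good", "Moderate", "Poor", "Bad")

#: EQR lower bound of each status class band.
STATUS_BOUNDS: dict[str, float] = {
    "High": 0.8,
    "Good": 0.6,
    "Moderate": 0.4,
    "Poor": 0.2,
    "Bad": 0.0,
}

METRIC_NAMES = (
    "cover_pct_aih",
    "biomass_aih",
    "biomass_aa",
    "entrained_pct",
    "aa_ha",
    "aa_over_aih_pct",
)


@dataclass(frozen=True)
class BoundaryTable:
    """Anchor values per sub-metric at the fixed EQR anchors 1.0 … 0.0."""

    metrics: Mapping[str, Sequence[float]]
    version: int = 1

    def __post_init__(self) -> None:
        for name, anchors in self.metrics.items():
            vals = list(anchors)
            if len(vals) != 6:
                raise ValueError(f"metric {name!r}: expected 6 anchors, got {len(vals)}")
            if vals[0] != 0:
                raise ValueError(f"metric {name!r}: first anchor must be 0")
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"metric {name!r}: anchors must be non-decreasing")

    def anchors(self, metric: str) -> list[float]:
        try:
            return list(self.metrics[metric])
        except KeyError:
            raise KeyError(f"no boundary anchors for metric {metric!r}") from None


def interpolate_eqr(value: float, anchors: Sequence[float]) -> float:
    """Score a sub-metric value against its six boundary anchors.

    Piecewise-linear between bracketing anchors; values at or above the
    upper-limit anchor clamp to EQR 0.  Continuous and non-increasing.
    """
    anchors = list(anchors)
    if len(anchors) != 6 or any(b < a for a, b in zip(anchors, anchors[1:])):
        raise ValueError("anchor list must hold 6 non-decreasing values")
    if value < 0:
        raise ValueError(f"sub-metric value must be >= 0, got {value}")
    if value >= anchors[-1]:
        return 0.0
    for lo, hi, eqr_hi, eqr_lo in zip(anchors, anchors[1:], EQR_ANCHORS, EQR_ANCHORS[1:]):
        if value <= hi:
            if hi == lo:  # degenerate band: step to the lower EQR
                return eqr_lo
            return eqr_hi - (value - lo) / (hi - lo) * (eqr_hi - eqr_lo)
    return 0.0  # pragma: no cover — clamped above


def invert_eqr(eqr: float, anchors: Sequence[float]) -> float:
    """Metric value that interpolates to the given EQR (inverse of
    :func:`interpolate_eqr` on [0, 1])."""
    if not 0.0 <= eqr <= 1.0:
        raise ValueError(f"EQR must be in [0, 1], got {eqr}")
    anchors = list(anchors)
    for lo, hi, eqr_hi, eqr_lo in zip(anchors, anchors[1:], EQR_ANCHORS, EQR_ANCHORS[1:]):
        if eqr >= eqr_lo:
            return lo + (eqr_hi - eqr) / (eqr_hi - eqr_lo) * (hi - lo)
    return anchors[-1]


def choose_aa_submetric(
    aa_ha: float,
    aa_over_aih_pct: float,
    table: BoundaryTable,
    rule: Literal["lenient", "strict"] = "lenient",
) -> tuple[str, float]:
    """Pick which affected-area criterion enters the final average.

    Only one of absolute AA (ha) and AA/AIH (%) is used.  Under the default
    ``lenient`` rule the criterion with the higher EQR (lesser indicated
    impact) is chosen; ``strict`` takes the lower.  Ties go to ``aa_ha``.
    """
    eqr_abs = interpolate_eqr(aa_ha, table.anchors("aa_ha"))
    eqr_rel = interpolate_eqr(aa_over_aih_pct, table.anchors("aa_over_aih_pct"))
    if rule == "lenient":
        better = eqr_abs >= eqr_rel
    elif rule == "strict":
        better = eqr_abs <= eqr_rel
    else:
        raise ValueError(f"rule must be 'lenient' or 'strict', got {rule!r}")
    return ("aa_ha", eqr_abs) if better else ("aa_over_aih_pct", eqr_rel)


def final_eqr(sub_eqrs: Mapping[str, float]) -> float:
    """Arithmetic mean of the contributing sub-metric EQRs."""
    if not sub_eqrs:
        raise ValueError("no sub-metric EQRs to average")
    vals = list(sub_eqrs.values())
    if any(not 0.0 <= v <= 1.0 for v in vals):
        raise ValueError("every sub-metric EQR must lie in [0, 1]")
    return sum(vals) / len(vals)


def classify(eqr: float) -> str:
    """Map an EQR to its Ecological Status class (boundary value belongs to
    the upper class, e.g. 0.8 → High)."""
    if not 0.0 <= eqr <= 1.0:
        raise ValueError(f"EQR must be in [0, 1], got {eqr}")
    for status, lower in STATUS_BOUNDS.items():
        if eqr >= lower:
            return status
    return "Bad"  # pragma: no cover — Bad bound is 0.0


def screening_decision(aa_over_aih_pct: float) -> bool:
    """True when algal cover strictly exceeds 5% of the AIH, triggering a
    full (biomass) survey."""
    if not 0.0 <= aa_over_aih_pct <= 100.0:
        raise ValueError(f"AA/AIH % must be in [0, 100], got {aa_over_aih_pct}")
    return aa_over_aih_pct > 5.0


@dataclass(frozen=True)
class AssessmentResult:
    """Per-metric EQRs, the combined EQR and the Ecological Status class."""

    site_id: str
    submetrics: SubMetricValues
    sub_eqrs: Mapping[str, float]
    chosen_aa_metric: str
    final_eqr: float
    status: str
    screening_only: bool = False
    aa_rule: str = "lenient"

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "sub_eqrs": dict(self.sub_eqrs),
            "chosen_aa_metric": self.chosen_aa_metric,
            "final_eqr": self.final_eqr,
            "final_eqr_rounded": round(self.final_eqr, 2),
            "status": self.status,
            "screening_only": self.screening_only,
            "aa_rule": self.aa_rule,
            "submetrics": vars(self.submetrics).copy(),
        }


def assess_site(
    survey: SiteSurvey,
    table: BoundaryTable,
    aa_rule: Literal["lenient", "strict"] = "lenient",
) -> AssessmentResult:
    """Run the full assessment: sub-metrics → per-metric EQRs → mean → class.

    Screening-level sites (AA/AIH ≤ 5% and no quadrat data) are scored from
    the cover and affected-area criteria only and flagged ``screening_only``.
    """
    from .survey import compute_affected_area

    geom = survey.geometry
    aa_only = not survey.quadrats and compute_affected_area(geom) > 0.0
    if aa_only:
        # Screening-level survey: patches mapped but no quadrats placed, so
        # only the affected-area criteria are scoreable.
        aa_ha = compute_affected_area(geom)
        nan = float("nan")
        sm = SubMetricValues(nan, aa_ha, 100.0 * aa_ha / geom.aih_ha, nan, nan, nan)
    else:
        sm = extract_submetrics(survey)
    aa_name, aa_eqr = choose_aa_submetric(sm.aa_ha, sm.aa_over_aih_pct, table, aa_rule)

    sub_eqrs: dict[str, float] = {aa_name: aa_eqr}
    screening_only = aa_only
    if not aa_only:
        sub_eqrs["cover_pct_aih"] = interpolate_eqr(
            sm.cover_pct_aih, table.anchors("cover_pct_aih")
        )
        sub_eqrs["biomass_aih"] = interpolate_eqr(
            sm.biomass_aih_g_m2, table.anchors("biomass_aih")
        )
        sub_eqrs["biomass_aa"] = interpolate_eqr(
            sm.biomass_aa_g_m2, table.anchors("biomass_aa")
        )
        sub_eqrs["entrained_pct"] = interpolate_eqr(
            sm.entrained_pct, table.anchors("entrained_pct")
        )
    eqr = final_eqr(sub_eqrs)
    return AssessmentResult(
        site_id=survey.geometry.site_id,
        submetrics=sm,
        sub_eqrs=sub_eqrs,
        chosen_aa_metric=aa_name,
        final_eqr=eqr,
        status=classify(eqr),
        screening_only=screening_only,
        aa_rule=aa_rule,
    )
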