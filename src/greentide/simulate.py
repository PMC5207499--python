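"""Synthetic surveys and metal matrices with known ground truth.

The survey generator works backwards from a target Ecological Status
class: it draws sub-metric EQR targets inside the target class band,
inverts the boundary table to get the corresponding metric values, and
realises them as a quadrat survey with realistic sampling noise
(beta-distributed fractional cover, lognormal biomass, Bernoulli
entrainment).  Because mean biomass over the AIH is tied to biomass over
the affected area by the dilution AA/AIH, it cannot be targeted
independently; the entrainment sub-metric is therefore solved last so the
*expected final EQR* sits at the centre of the target band, which is what
classification recovery depends on.

The metal generator draws per-sample concentrations lognormally around
per-site medians (defaulting to the shipped site-mean table) with a
status-dependent coefficient of variation, emulating the empirical pattern
of higher multivariate dispersion at degraded sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import load_boundary_table, load_metal_site_means, load_site_assessments
from .eqr import (
    STATUS_BOUNDS,
    BoundaryTable,
    classify,
    interpolate_eqr,
    invert_eqr,
)
from .metals import MetalMatrix
from .survey import QuadratRecord, SiteGeometry, SiteSurvey, SubMetricValues

__all__ = [
    "SurveyScenario",
    "SurveyTruth",
    "MetalScenario",
    "MetalTruth",
    "generate_survey",
    "generate_metals",
    "DEFAULT_ESC_CV",
]

#: Status-dependent within-site coefficient of variation for metal draws:
#: dispersion ordering High < Poor < Moderate, as seen in degraded estuaries.
DEFAULT_ESC_CV: dict[str, float] = {
    "High": 0.10,
    "Good": 0.20,
    "Moderate": 0.50,
    "Poor": 0.30,
    "Bad": 0.60,
}


class InfeasibleScenarioError(ValueError):
    """Raised when no survey with expected EQR in the target band exists."""


@dataclass(frozen=True)
class SurveyScenario:
    """Recipe for one synthetic site survey."""

    target_status: str
    site_id: str = "synthetic"
    aih_ha: float | None = None  # derived from the AA criteria when None
    n_patches: int = 3
    transects_per_patch: int = 2
    quadrats_per_transect: int = 12  # protocol minimum is 10
    cover_concentration: float = 150.0  # beta pseudo-count for quadrat cover
    biomass_sigma: float = 0.20  # lognormal sigma of quadrat biomass
    band_margin: float = 0.15  # EQR-target margin, fraction of band width
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.target_status not in STATUS_BOUNDS:
            raise ValueError(f"unknown status class {self.target_status!r}")
        if self.n_patches < 0:
            raise ValueError("n_patches must be >= 0")
        if self.n_patches == 0 and self.target_status != "High":
            raise InfeasibleScenarioError(
                "a survey without patches is pristine and can only target High"
            )
        if self.quadrats_per_transect < 10:
            raise ValueError("protocol requires >= 10 quadrats per transect")
        if not 0.0 < self.band_margin < 0.5:
            raise ValueError("band_margin must be in (0, 0.5)")


@dataclass(frozen=True)
class SurveyTruth:
    """Expected (noise-free) sub-metrics and the status they imply."""

    submetrics: SubMetricValues
    sub_eqrs: Mapping[str, float]
    final_eqr: float
    status: str


def _status_band(status: str) -> tuple[float, float]:
    lo = STATUS_BOUNDS[status]
    return lo, lo + 0.2


def generate_survey(
    scenario: SurveyScenario,
    table: BoundaryTable | None = None,
) -> tuple[SiteSurvey, SurveyTruth]:
    """Generate a reproducible quadrat survey targeting a status class."""
    table = table or load_boundary_table()
    rng = np.random.default_rng(scenario.seed)
    lo, hi = _status_band(scenario.target_status)
    m = scenario.band_margin * (hi - lo)

    if scenario.n_patches == 0:
        geom = SiteGeometry(scenario.site_id, aih_ha=scenario.aih_ha or 100.0)
        survey = SiteSurvey(geometry=geom, quadrats=())
        sm = SubMetricValues(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        eqrs = {k: 1.0 for k in ("cover_pct_aih", "biomass_aih", "biomass_aa",
                                 "entrained_pct", "aa_ha")}
        return survey, SurveyTruth(sm, eqrs, 1.0, "High")

    e_aa, e_cov, e_baa = rng.uniform(lo + m, hi - m, size=3)

    aa_pct = invert_eqr(e_aa, table.anchors("aa_over_aih_pct"))
    if scenario.aih_ha is not None:
        aih_ha = scenario.aih_ha
        aa_ha = aa_pct * aih_ha / 100.0
    else:
        aa_ha = invert_eqr(e_aa, table.anchors("aa_ha"))
        aih_ha = 100.0 * aa_ha / aa_pct

    cover_val = invert_eqr(e_cov, table.anchors("cover_pct_aih"))
    mean_cover_frac = min(cover_val / aa_pct, 0.98)
    cover_val = mean_cover_frac * aa_pct

    biomass_aa = invert_eqr(e_baa, table.anchors("biomass_aa"))
    biomass_aih = biomass_aa * aa_pct / 100.0

    e_cov = interpolate_eqr(cover_val, table.anchors("cover_pct_aih"))
    e_baih = interpolate_eqr(biomass_aih, table.anchors("biomass_aih"))
    e_choice = max(
        interpolate_eqr(aa_ha, table.anchors("aa_ha")),
        interpolate_eqr(aa_pct, table.anchors("aa_over_aih_pct")),
    )
    # entrainment closes the budget so the expected mean sits mid-band
    e_target = (lo + hi) / 2.0
    e_ent = float(np.clip(5.0 * e_target - (e_cov + e_baa + e_baih + e_choice), 0.0, 1.0))
    entrained_pct = invert_eqr(e_ent, table.anchors("entrained_pct"))
    e_ent = interpolate_eqr(entrained_pct, table.anchors("entrained_pct"))

    final = (e_cov + e_baa + e_baih + e_choice + e_ent) / 5.0
    status = classify(final)
    if status != scenario.target_status:
        raise InfeasibleScenarioError(
            f"expected EQR {final:.3f} classifies as {status}, "
            f"not {scenario.target_status} (scenario over-constrained)"
        )

    # realise the survey
    shares = rng.dirichlet(np.full(scenario.n_patches, 5.0))
    patch_areas = {f"P{i+1}": float(aa_ha * s) for i, s in enumerate(shares)}
    geom = SiteGeometry(scenario.site_id, aih_ha=aih_ha, patch_areas_ha=patch_areas)

    kappa = scenario.cover_concentration
    p_ent = entrained_pct / 100.0
    mu = np.log(biomass_aa) - scenario.biomass_sigma**2 / 2.0 if biomass_aa > 0 else None
    quadrats: list[QuadratRecord] = []
    for pid in patch_areas:
        for t in range(scenario.transects_per_patch):
            for q in range(scenario.quadrats_per_transect):
                if 0.0 < mean_cover_frac < 1.0:
                    cov = 100.0 * rng.beta(
                        mean_cover_frac * kappa, (1.0 - mean_cover_frac) * kappa
                    )
                else:
                    cov = 100.0 * mean_cover_frac
                bio = float(rng.lognormal(mu, scenario.biomass_sigma)) if mu is not None else 0.0
                quadrats.append(
                    QuadratRecord(
                        site_id=scenario.site_id,
                        patch_id=pid,
                        transect_id=f"{pid}-T{t+1}",
                        quadrat_id=f"{pid}-T{t+1}-Q{q+1}",
                        cover_pct=float(cov),
                        biomass_g_m2=bio,
                        entrained=bool(rng.random() < p_ent),
                    )
                )
    survey = SiteSurvey(geometry=geom, quadrats=tuple(quadrats))
    sm = SubMetricValues(
        cover_pct_aih=cover_val,
        aa_ha=aa_ha,
        aa_over_aih_pct=aa_pct,
        biomass_aih_g_m2=biomass_aih,
        biomass_aa_g_m2=biomass_aa,
        entrained_pct=entrained_pct,
    )
    eqrs = {
        "cover_pct_aih": e_cov,
        "biomass_aih": e_baih,
        "biomass_aa": e_baa,
        "entrained_pct": e_ent,
        "aa_choice": e_choice,
    }
    return survey, SurveyTruth(sm, eqrs, final, status)


# ---------------------------------------------------------------------------
# metals


@dataclass(frozen=True)
class MetalScenario:
    """Recipe for a synthetic samples × metals matrix.

    ``site_medians`` maps site → metal → lognormal median (mg kg⁻¹ dw);
    ``site_esc`` maps site → status class.  When both are None the shipped
    site-mean table and its published status classes are used.  The
    within-site coefficient of variation is looked up per status class
    (``esc_cv``) unless overridden per site via ``site_cv``.
    """

    site_medians: Mapping[str, Mapping[str, float]] | None = None
    site_esc: Mapping[str, str] | None = None
    esc_cv: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ESC_CV))
    site_cv: Mapping[str, float] | None = None
    samples_per_site: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.samples_per_site < 1:
            raise ValueError("samples_per_site must be >= 1")
        for esc, cv in self.esc_cv.items():
            if cv <= 0:
                raise ValueError(f"CV for {esc!r} must be > 0")


@dataclass(frozen=True)
class MetalTruth:
    medians: pd.DataFrame  # site × metal
    cv: Mapping[str, float]  # site → CV
    esc: Mapping[str, str]


def _default_medians_and_esc() -> tuple[dict, dict]:
    means = load_metal_site_means()  # site × metal
    sites = load_site_assessments()
    esc = dict(zip(sites["site_id"], sites["status"]))
    medians = {s: means.loc[s].to_dict() for s in means.index}
    return medians, {s: esc[s] for s in means.index}


def generate_metals(scenario: MetalScenario) -> tuple[MetalMatrix, MetalTruth]:
    """Draw per-sample metal concentrations lognormally around site medians."""
    if scenario.site_medians is None:
        medians, esc = _default_medians_and_esc()
    else:
        medians = {s: dict(m) for s, m in scenario.site_medians.items()}
        if scenario.site_esc is None:
            raise ValueError("site_esc required when site_medians is given")
        esc = dict(scenario.site_esc)
    missing = set(medians) - set(esc)
    if missing:
        raise ValueError(f"sites without a status class: {sorted(missing)}")

    rng = np.random.default_rng(scenario.seed)
    metals = list(next(iter(medians.values())))
    rows = []
    site_labels = []
    esc_labels = []
    sample_ids = []
    cv_by_site: dict[str, float] = {}
    for site in medians:
        cv = (
            scenario.site_cv[site]
            if scenario.site_cv and site in scenario.site_cv
            else scenario.esc_cv[esc[site]]
        )
        cv_by_site[site] = cv
        sigma = float(np.sqrt(np.log1p(cv * cv)))
        for k in range(scenario.samples_per_site):
            conc = {
                m: float(rng.lognormal(np.log(medians[site][m]), sigma)) for m in metals
            }
            rows.append(conc)
            site_labels.append(site)
            esc_labels.append(esc[site])
            sample_ids.append(f"{site}-{k+1:02d}")
    data = pd.DataFrame(rows, index=sample_ids, columns=metals)
    matrix = MetalMatrix(data=data, site=pd.Series(site_labels), esc=pd.Series(esc_labels))
    truth = MetalTruth(
        medians=pd.DataFrame(medians).T[metals],
        cv=cv_by_site,
        esc=esc,
    )
    return matrix, truth
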