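"""Bundled reference tables.

Small published tables shipped with the package: the sub-metric boundary
anchors, the eight-site assessment summary, per-site metal means and
standard errors, published metal–EQR Spearman coefficients, international
regulatory limits and the BCR-279 CRM comparison.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .eqr import BoundaryTable
from .management import CRMRecord, RegulatoryLimit

__all__ = [
    "load_boundary_table",
    "load_site_assessments",
    "load_metal_site_means",
    "load_metal_site_se",
    "load_eqr_correlations",
    "load_regulatory_limits",
    "load_crm_records",
]


def _path(name: str):
    return resources.files("greentide.data").joinpath(name)


def load_boundary_table(path=None) -> BoundaryTable:
    """The sub-metric boundary anchors (user-overridable YAML)."""
    src = path or _path("boundaries.yaml")
    with open(src) if isinstance(src, (str,)) else src.open() as fh:
        doc = yaml.safe_load(fh)
    return BoundaryTable(metrics=doc["metrics"], version=doc.get("version", 1))


def load_site_assessments() -> pd.DataFrame:
    """Eight-site assessment summary: status, EQR, cover, biomass."""
    with _path("site_assessments.csv").open() as fh:
        return pd.read_csv(fh)


def load_metal_site_means() -> pd.DataFrame:
    """Site × metal mean concentrations (mg kg⁻¹ dw, n = 20 per site)."""
    with _path("metal_site_means.csv").open() as fh:
        df = pd.read_csv(fh, index_col="metal")
    return df.T.rename_axis("site_id")


def load_metal_site_se() -> pd.DataFrame:
    """Site × metal standard errors matching :func:`load_metal_site_means`."""
    with _path("metal_site_se.csv").open() as fh:
        df = pd.read_csv(fh, index_col="metal")
    return df.T.rename_axis("site_id")


def load_eqr_correlations() -> pd.Series:
    """Published metal–EQR Spearman coefficients (MCI row included)."""
    with _path("eqr_correlations.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("metal")["spearman_rho"]


def load_regulatory_limits(path=None) -> list[RegulatoryLimit]:
    """Regulatory maximum-limit entries for toxic elements."""
    src = path or _path("regulatory_limits.yaml")
    with open(src) if isinstance(src, str) else src.open() as fh:
        doc = yaml.safe_load(fh)
    return [
        RegulatoryLimit(
            jurisdiction=e["jurisdiction"],
            commodity=e["commodity"],
            metal=e["metal"],
            limit_mg_kg=float(e["limit"]),
            inorganic_only=bool(e.get("inorganic_only", False)),
            basis=e.get("basis", "dw"),
            reference=e.get("reference", ""),
        )
        for e in doc["limits"]
    ]


def load_crm_records() -> list[CRMRecord]:
    """BCR-279 certified/indicative values vs in-house determinations."""
    with _path("crm_bcr279.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        CRMRecord(
            metal=r.metal,
            reported_mean=r.reported_mean,
            reported_unc=r.reported_unc,
            found_mean=r.found_mean,
            found_unc=r.found_unc,
            certified=bool(r.certified),
        )
        for r in df.itertuples()
    ]
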