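"""CSV readers/writers and JSON reporting.

CSV dialect: comma-separated, UTF-8, ``.`` decimal separator, header row
mandatory.  Validation errors name the offending column and (1-based data)
row.  Rounding happens only here, at the reporting layer; the pipeline
itself runs at full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .eqr import AssessmentResult
from .metals import MetalMatrix
from .survey import QuadratRecord, SiteGeometry, SiteSurvey

__all__ = [
    "RunConfig",
    "read_quadrats",
    "read_geometry",
    "read_metals",
    "write_survey",
    "write_assessment_json",
    "write_correlation_csv",
]

QUADRAT_COLUMNS = [
    "site_id",
    "patch_id",
    "transect_id",
    "quadrat_id",
    "area_m2",
    "cover_pct",
    "biomass_g_m2",
    "entrained",
]
GEOMETRY_COLUMNS = ["site_id", "patch_id", "patch_area_ha", "aih_ha"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved run options shared by the CLI subcommands."""

    aa_rule: str = "lenient"
    n_permutations: int = 9999
    seed: int | None = None
    moisture_fraction: float = 0.796
    boundaries_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, what: str) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax()) + 1
        raise ValueError(f"{what}: non-numeric value in column {col!r} at data row {row}")
    return out


def read_geometry(path) -> dict[str, SiteGeometry]:
    """Read site geometry (one row per patch; aih_ha repeated per site)."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, GEOMETRY_COLUMNS, "geometry")
    _numeric(df, "patch_area_ha", "geometry")
    _numeric(df, "aih_ha", "geometry")
    out: dict[str, SiteGeometry] = {}
    for site_id, grp in df.groupby("site_id", sort=False):
        aih = grp["aih_ha"].unique()
        if len(aih) != 1:
            raise ValueError(f"geometry: site {site_id!r} has inconsistent aih_ha {aih}")
        patches = dict(zip(grp["patch_id"].astype(str), grp["patch_area_ha"].astype(float)))
        out[str(site_id)] = SiteGeometry(str(site_id), float(aih[0]), patches)
    return out


def read_quadrats(path, geometry: dict[str, SiteGeometry]) -> dict[str, SiteSurvey]:
    """Read quadrat records and attach them to their site geometry."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, QUADRAT_COLUMNS, "quadrats")
    for col in ("area_m2", "cover_pct", "biomass_g_m2", "entrained"):
        _numeric(df, col, "quadrats")
    surveys: dict[str, SiteSurvey] = {}
    for site_id, grp in df.groupby("site_id", sort=False):
        sid = str(site_id)
        if sid not in geometry:
            raise ValueError(f"quadrats: site {sid!r} has no geometry")
        quads = tuple(
            QuadratRecord(
                site_id=sid,
                patch_id=str(r.patch_id),
                transect_id=str(r.transect_id),
                quadrat_id=str(r.quadrat_id),
                area_m2=float(r.area_m2),
                cover_pct=float(r.cover_pct),
                biomass_g_m2=float(r.biomass_g_m2),
                entrained=bool(int(r.entrained)),
            )
            for r in grp.itertuples()
        )
        surveys[sid] = SiteSurvey(geometry=geometry[sid], quadrats=quads)
    # sites with geometry but no quadrats are screening-level surveys
    for sid, geom in geometry.items():
        surveys.setdefault(sid, SiteSurvey(geometry=geom, quadrats=()))
    return surveys


def read_metals(path) -> MetalMatrix:
    """Read a tidy metals table (sample_id, site_id, esc_label + metals)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df["sample_id"].duplicated().any() if "sample_id" in df.columns else False:
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"metals: duplicate sample_id {dup!r}")
    return MetalMatrix.from_frame(df)


def write_survey(surveys: dict[str, SiteSurvey], quadrats_path, geometry_path) -> None:
    """Write surveys back to the two-file CSV layout (lossless round-trip)."""
    qrows, grows = [], []
    for sid, sv in surveys.items():
        for pid, area in sv.geometry.patch_areas_ha.items():
            grows.append(
                {"site_id": sid, "patch_id": pid, "patch_area_ha": area,
                 "aih_ha": sv.geometry.aih_ha}
            )
        for q in sv.quadrats:
            qrows.append(
                {"site_id": sid, "patch_id": q.patch_id, "transect_id": q.transect_id,
                 "quadrat_id": q.quadrat_id, "area_m2": q.area_m2,
                 "cover_pct": repr(q.cover_pct), "biomass_g_m2": repr(q.biomass_g_m2),
                 "entrained": int(q.entrained)}
            )
    pd.DataFrame(grows, columns=GEOMETRY_COLUMNS).to_csv(geometry_path, index=False)
    pd.DataFrame(qrows, columns=QUADRAT_COLUMNS).to_csv(quadrats_path, index=False)


def write_assessment_json(results: list[AssessmentResult], path, seed=None) -> None:
    doc = {
        "tool": "greentide",
        "version": __version__,
        "seed": seed,
        "sites": [r.to_dict() for r in results],
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def write_correlation_csv(results, path) -> None:
    """Metal / coefficient / n / p table, mirroring the published layout."""
    df = pd.DataFrame(
        [
            {"metal": r.metal_name, "coefficient": round(r.coefficient, 3),
             "n": r.n, "p_value": round(r.p_value, 4)}
            for r in results
        ]
    )
    df.to_csv(path, index=False)
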