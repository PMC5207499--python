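"""Metal-bioindicator statistics.

Relates Ulva tissue metal concentrations (mg kg⁻¹ dry weight) to the
Ecological Quality Ratio and tests whether metal composition differs among
Ecological Status classes.  The toolkit comprises:

* tie-corrected Spearman rank correlation (average ranks, t or exact
  permutation p-values);
* Fisher z-averaging of correlation coefficients;
* the Metal Content Index (geometric mean over metals);
* per-variable z-score normalisation and Euclidean distance matrices;
* a nested permutational ANOVA (status as fixed factor, site as random
  factor nested in status) on a distance matrix;
* a permutational test of homogeneity of multivariate dispersions
  (distance to group centroid);
* PCA on the correlation matrix;
* per-metal one-way ANOVA with a compact-letter pairwise display.

All stochastic routines take an explicit seed and default to 9999
permutations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "MetalMatrix",
    "CorrelationResult",
    "PermutationTestResult",
    "DispersionResult",
    "PCAResult",
    "site_mean_table",
    "rankdata_average",
    "spearman",
    "fisher_z_mean",
    "metal_content_index",
    "normalize",
    "euclidean_distance_matrix",
    "permanova_nested",
    "permdisp",
    "pca",
    "pearson_matrix",
    "anova_per_metal",
    "compact_letter_display",
]

DEFAULT_N_PERM = 9999


# ---------------------------------------------------------------------------
# containers


@dataclass
class MetalMatrix:
    """Samples × metals concentration table with site and status labels.

    ``data`` holds one row per sample and one numeric column per metal;
    ``site`` and ``esc`` are aligned per-sample labels (ESC = Ecological
    Status class of the sample's site).
    """

    data: pd.DataFrame
    site: pd.Series
    esc: pd.Series

    def __post_init__(self) -> None:
        self.data = pd.DataFrame(self.data)
        self.site = pd.Series(self.site).reset_index(drop=True)
        self.esc = pd.Series(self.esc).reset_index(drop=True)
        self.data = self.data.reset_index(drop=True)
        n = len(self.data)
        if len(self.site) != n or len(self.esc) != n:
            raise ValueError("site/esc labels must align with the sample rows")
        if (self.data.values < 0).any():
            raise ValueError("metal concentrations must be >= 0")
        site_esc = pd.crosstab(self.site, self.esc)
        if ((site_esc > 0).sum(axis=1) > 1).any():
            raise ValueError("each site must map to exactly one status class")

    @property
    def metals(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MetalMatrix":
        """Build from a tidy frame with sample_id, site_id, esc_label columns
        plus one column per metal."""
        meta = {"sample_id", "site_id", "esc_label"}
        missing = meta - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        metal_cols = [c for c in df.columns if c not in meta]
        data = df[metal_cols].astype(float)
        data.index = df["sample_id"].tolist()
        return cls(data=data, site=df["site_id"], esc=df["esc_label"])


@dataclass(frozen=True)
class CorrelationResult:
    metal_name: str
    coefficient: float
    n: int
    p_value: float
    method: str = "spearman"


@dataclass(frozen=True)
class PermutationTestResult:
    terms: tuple[str, ...]
    df: Mapping[str, int]
    ss: Mapping[str, float]
    ms: Mapping[str, float]
    pseudo_f: Mapping[str, float]
    p_perm: Mapping[str, float]
    p_approx: Mapping[str, float]
    n_permutations: int
    seed: int | None


@dataclass(frozen=True)
class DispersionResult:
    groups: tuple[str, ...]
    mean_dispersion: Mapping[str, float]
    se_dispersion: Mapping[str, float]
    f_statistic: float
    p_perm: float
    pairwise_p: Mapping[tuple[str, str], float]
    distances: pd.Series = field(repr=False, default=None)


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame
    scores: pd.DataFrame
    percent_variance: np.ndarray
    eigenvalues: np.ndarray


# ---------------------------------------------------------------------------
# descriptive reductions


def site_mean_table(matrix: MetalMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site mean and standard error of each metal.

    Returns ``(means, ses)`` frames indexed by site (SE = sd/√n with the
    n−1 denominator; NaN for singleton sites).
    """
    grouped = matrix.data.groupby(matrix.site.values)
    means = grouped.mean()
    ses = grouped.sem(ddof=1)
    if (grouped.size() == 0).any():  # pragma: no cover — groupby drops empties
        raise ValueError("empty site group")
    means.index.name = "site_id"
    ses.index.name = "site_id"
    return means, ses


# ---------------------------------------------------------------------------
# correlation


def rankdata_average(x: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties sharing the average of their spanned ranks."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ZeroDivisionError("zero variance")
    return float((xc @ yc) / denom)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    name: str = "",
    p_method: str = "t",
    seed: int | None = None,
) -> CorrelationResult:
    """Tie-corrected Spearman rank correlation.

    Average ranks are assigned to ties and the coefficient is the Pearson
    correlation of the rank vectors.  ``p_method`` is ``"t"`` (two-sided t
    approximation on n−2 df), ``"exact"`` (full permutation enumeration,
    n ≤ 10) or ``"permutation"`` (Monte-Carlo, 9999 draws).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = rankdata_average(x), rankdata_average(y)
    try:
        rho = _pearson_r(rx, ry)
    except ZeroDivisionError:
        raise ValueError("zero variance in ranks; correlation undefined") from None
    rho = max(-1.0, min(1.0, rho))

    if p_method == "t":
        if abs(rho) == 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * _sps.t.sf(abs(t), df=n - 2)
    elif p_method == "exact":
        if n > 10:
            raise ValueError("exact enumeration limited to n <= 10")
        count = 0
        total = 0
        for perm in _permutations(range(n)):
            r = _pearson_r(rx, ry[list(perm)])
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    elif p_method == "permutation":
        rng = np.random.default_rng(seed)
        n_perm = DEFAULT_N_PERM
        count = 0
        for _ in range(n_perm):
            r = _pearson_r(rx, rng.permutation(ry))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return CorrelationResult(name, rho, n, float(p))


def fisher_z_mean(
    correlations: Sequence[float], confidence: float = 0.95
) -> tuple[float, float, float]:
    """Average correlation coefficients on the Fisher z scale.

    Returns ``(mean_r, ci_low, ci_high)``: z = atanh(r) is averaged, a
    normal CI (±z_crit·sd/√n) is formed on the z scale, and all three are
    mapped back with tanh.  A single coefficient returns NaN CI bounds.
    """
    r = np.asarray(correlations, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one coefficient")
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("|r| = 1 present; Fisher z is infinite")
    z = np.arctanh(r)
    mz = z.mean()
    if r.size == 1:
        return float(np.tanh(mz)), float("nan"), float("nan")
    crit = _sps.norm.ppf(0.5 + confidence / 2.0)
    half = crit * z.std(ddof=1) / math.sqrt(r.size)
    return (
        float(np.tanh(mz)),
        float(np.tanh(mz - half)),
        float(np.tanh(mz + half)),
    )


def metal_content_index(concentrations: Sequence[float]) -> float:
    """Metal Content Index: geometric mean of the metal concentrations."""
    c = np.asarray(concentrations, dtype=float)
    if c.size == 0:
        raise ValueError("need at least one concentration")
    if np.any(c <= 0):
        raise ValueError("MCI requires strictly positive concentrations")
    return float(np.exp(np.mean(np.log(c))))


# ---------------------------------------------------------------------------
# multivariate preparation


def normalize(data: pd.DataFrame) -> pd.DataFrame:
    """Per-variable z-scoring (subtract mean, divide by sd with n−1)."""
    df = pd.DataFrame(data).astype(float)
    if len(df) < 2:
        raise ValueError("need at least 2 samples to normalise")
    sd = df.std(ddof=1)
    zero = sd[sd == 0.0]
    if len(zero):
        raise ValueError(f"zero-variance metal(s): {list(zero.index)}")
    return (df - df.mean()) / sd


def euclidean_distance_matrix(data) -> np.ndarray:
    """Pairwise Euclidean distances between sample rows."""
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    sq = (x * x).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# PERMANOVA (nested two-way: ESC fixed, Site random nested in ESC)


def _group_ss(d2: np.ndarray, labels: np.ndarray) -> float:
    """Σ over groups of (within-group pairwise Σd²)/group size."""
    ss = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub.sum() / 2.0 / len(idx)
    return ss


def _nested_stats(
    within_site: np.ndarray,
    between_site: np.ndarray,
    site_sizes: np.ndarray,
    site_esc_idx: np.ndarray,
    ss_total: float,
    n_esc: int,
):
    """Mean squares and pseudo-F for a given assignment of sites to ESC.

    ``between_site[a, b]`` is the summed squared distance over sample pairs
    spanning sites a and b, ``within_site[a]`` the within-site pair sum.
    """
    n_sites = len(site_sizes)
    n = site_sizes.sum()
    # residual: within sites
    ss_res = float((within_site / site_sizes).sum())
    # within-ESC SS pools sites sharing an ESC label
    ss_within_esc = 0.0
    for e in range(n_esc):
        members = np.flatnonzero(site_esc_idx == e)
        size = site_sizes[members].sum()
        tot = within_site[members].sum()
        if len(members) > 1:
            tot += between_site[np.ix_(members, members)].sum() / 2.0
        ss_within_esc += tot / size
    ss_esc = ss_total - ss_within_esc
    ss_site = ss_within_esc - ss_res
    df_esc = n_esc - 1
    df_site = n_sites - n_esc
    df_res = n - n_sites
    ms_esc = ss_esc / df_esc if df_esc else np.nan
    ms_site = ss_site / df_site if df_site else np.nan
    ms_res = ss_res / df_res if df_res else np.nan
    f_esc = ms_esc / ms_site if df_site else np.nan
    f_site = ms_site / ms_res if df_res else np.nan
    return ss_esc, ss_site, ss_res, ms_esc, ms_site, ms_res, f_esc, f_site


def permanova_nested(
    dm: np.ndarray,
    esc: Sequence,
    site: Sequence,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> PermutationTestResult:
    """Nested permutational ANOVA on a distance matrix.

    Partitions the total sum of squared distances into a status (ESC)
    term, a site-within-status term and a residual.  Pseudo-F for ESC is
    MS_ESC/MS_Site(ESC) (sites are the random replicates of status);
    pseudo-F for Site is MS_Site/MS_residual.

    Significance: the ESC term permutes intact site units across status
    labels (holding the number of sites per status); the Site term permutes
    samples across sites within each status class.  An F-distribution
    approximation is reported alongside the permutation p.
    """
    dm = np.asarray(dm, dtype=float)
    esc = np.asarray(esc)
    site = np.asarray(site)
    n = len(esc)
    if dm.shape != (n, n):
        raise ValueError("distance matrix shape must match the label length")
    d2 = dm * dm
    ss_total = d2.sum() / 2.0 / n
    if ss_total == 0.0:
        raise ValueError("all samples identical; SS_total = 0, test undefined")

    sites, site_idx = np.unique(site, return_inverse=True)
    n_sites = len(sites)
    site_sizes = np.bincount(site_idx)
    # ESC label of each site (validated unique in MetalMatrix; re-derive here)
    site_esc = np.empty(n_sites, dtype=object)
    for a in range(n_sites):
        labels = np.unique(esc[site_idx == a])
        if len(labels) != 1:
            raise ValueError(f"site {sites[a]!r} maps to multiple status classes")
        site_esc[a] = labels[0]
    esc_levels, site_esc_idx = np.unique(site_esc, return_inverse=True)
    n_esc = len(esc_levels)
    # a single status class degenerates to a one-way layout: only the
    # site term (MS_site / MS_residual) is testable
    counts = np.bincount(site_esc_idx)
    if n_esc >= 2 and (counts < 2).any():
        warnings.warn(
            "some status class has fewer than 2 sites; the status test has "
            "few permutable units and is weak",
            stacklevel=2,
        )

    # pre-aggregate squared distances at the site level
    within_site = np.zeros(n_sites)
    between_site = np.zeros((n_sites, n_sites))
    for a in range(n_sites):
        ia = np.flatnonzero(site_idx == a)
        within_site[a] = d2[np.ix_(ia, ia)].sum() / 2.0
        for b in range(a + 1, n_sites):
            ib = np.flatnonzero(site_idx == b)
            s = d2[np.ix_(ia, ib)].sum()
            between_site[a, b] = between_site[b, a] = s

    obs = _nested_stats(within_site, between_site, site_sizes, site_esc_idx, ss_total, n_esc)
    ss_esc, ss_site, ss_res, ms_esc, ms_site, ms_res, f_esc, f_site = obs

    rng = np.random.default_rng(seed)

    # ESC term: permute whole sites across ESC labels
    if n_esc >= 2 and np.isfinite(f_esc):
        count_esc = 0
        for _ in range(n_perm):
            perm = rng.permutation(n_sites)
            perm_idx = site_esc_idx[perm]
            f = _nested_stats(
                within_site, between_site, site_sizes, perm_idx, ss_total, n_esc
            )[6]
            if f >= f_esc - 1e-12:
                count_esc += 1
        p_esc = (count_esc + 1) / (n_perm + 1)
    else:
        p_esc = float("nan")

    # Site term: permute samples across sites within each ESC class
    esc_of_sample = site_esc_idx[site_idx]
    if n_sites > n_esc and np.isfinite(f_site):
        count_site = 0
        ss_within_esc = _group_ss(d2, esc_of_sample)  # invariant under these perms
        for _ in range(n_perm):
            perm_site_idx = site_idx.copy()
            for e in range(n_esc):
                members = np.flatnonzero(esc_of_sample == e)
                perm_site_idx[members] = site_idx[members][rng.permutation(len(members))]
            ss_res_p = _group_ss(d2, perm_site_idx)
            ss_site_p = ss_within_esc - ss_res_p
            ms_site_p = ss_site_p / (n_sites - n_esc)
            ms_res_p = ss_res_p / (n - n_sites)
            if ms_site_p / ms_res_p >= f_site - 1e-12:
                count_site += 1
        p_site = (count_site + 1) / (n_perm + 1)
    else:
        p_site = float("nan")

    df = {"esc": n_esc - 1, "site": n_sites - n_esc, "residual": n - n_sites}
    p_approx = {
        "esc": float(_sps.f.sf(f_esc, df["esc"], df["site"])) if df["site"] else np.nan,
        "site": float(_sps.f.sf(f_site, df["site"], df["residual"])),
    }
    return PermutationTestResult(
        terms=("esc", "site", "residual"),
        df=df,
        ss={"esc": ss_esc, "site": ss_site, "residual": ss_res, "total": ss_total},
        ms={"esc": ms_esc, "site": ms_site, "residual": ms_res},
        pseudo_f={"esc": f_esc, "site": f_site},
        p_perm={"esc": p_esc, "site": p_site},
        p_approx=p_approx,
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PERMDISP


def _anova_f(values: np.ndarray, group_idx: np.ndarray, n_groups: int) -> float:
    n = len(values)
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        v = values[group_idx == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    if ss_within == 0.0:
        return np.inf if ss_between > 0 else np.nan
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permdisp(
    data,
    groups: Sequence,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> DispersionResult:
    """Homogeneity of multivariate dispersions under Euclidean distance.

    Each sample's distance to its group centroid is computed in the original
    coordinate space (equivalent to the distance-based formulation when the
    distance is Euclidean).  The overall statistic is the one-way ANOVA F on
    those distances; overall and pairwise p-values come from permuting group
    labels.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    groups = np.asarray(groups)
    levels, gidx = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(gidx)
    if (sizes < 2).any():
        singles = [str(levels[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"singleton group(s): {singles}")

    def dists_to_centroids(perm_gidx: np.ndarray) -> np.ndarray:
        d = np.empty(len(x))
        for g in range(len(levels)):
            idx = perm_gidx == g
            cent = x[idx].mean(axis=0)
            d[idx] = np.linalg.norm(x[idx] - cent, axis=1)
        return d

    dist = dists_to_centroids(gidx)
    f_obs = _anova_f(dist, gidx, len(levels))

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(gidx)
        d = dists_to_centroids(perm)
        if _anova_f(d, perm, len(levels)) >= f_obs - 1e-12:
            count += 1
    p_overall = (count + 1) / (n_perm + 1)

    mean_disp = {}
    se_disp = {}
    for g, lvl in enumerate(levels):
        v = dist[gidx == g]
        mean_disp[str(lvl)] = float(v.mean())
        se_disp[str(lvl)] = float(v.std(ddof=1) / math.sqrt(len(v)))

    pairwise: dict[tuple[str, str], float] = {}
    for a in range(len(levels)):
        for b in range(a + 1, len(levels)):
            sel = (gidx == a) | (gidx == b)
            xs = x[sel]
            gs = (gidx[sel] == b).astype(int)

            def pair_f(g01: np.ndarray) -> float:
                d = np.empty(len(xs))
                for g in (0, 1):
                    idx = g01 == g
                    cent = xs[idx].mean(axis=0)
                    d[idx] = np.linalg.norm(xs[idx] - cent, axis=1)
                return _anova_f(d, g01, 2)

            f_pair = pair_f(gs)
            c = 0
            for _ in range(n_perm):
                perm = rng.permutation(gs)
                if pair_f(perm) >= f_pair - 1e-12:
                    c += 1
            pairwise[(str(levels[a]), str(levels[b]))] = (c + 1) / (n_perm + 1)

    return DispersionResult(
        groups=tuple(str(l) for l in levels),
        mean_dispersion=mean_disp,
        se_dispersion=se_disp,
        f_statistic=float(f_obs),
        p_perm=float(p_overall),
        pairwise_p=pairwise,
        distances=pd.Series(dist, index=groups),
    )


# ---------------------------------------------------------------------------
# PCA and correlation structure


def pca(data: pd.DataFrame) -> PCAResult:
    """PCA of the correlation matrix of a samples × metals table.

    Eigendecomposition of the correlation matrix; percent variance is the
    eigenvalue share of the trace; scores project the z-scored data onto
    the loading vectors.  Loading signs are fixed by making each vector's
    largest-magnitude element positive.
    """
    df = pd.DataFrame(data).astype(float)
    if not np.isfinite(df.values).all():
        raise ValueError("non-finite values in input")
    z = normalize(df)
    corr = np.corrcoef(z.values, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1.0
    pct = 100.0 * eigval / eigval.sum()
    comps = [f"PC{i+1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=df.columns, columns=comps)
    scores = pd.DataFrame(z.values @ eigvec, index=df.index, columns=comps)
    return PCAResult(loadings=loadings, scores=scores, percent_variance=pct, eigenvalues=eigval)


def pearson_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Metal × metal Pearson correlation table (NaN where a variable is
    constant)."""
    df = pd.DataFrame(data).astype(float)
    if len(df) < 3:
        raise ValueError("need at least 3 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(df.values, rowvar=False)
    out = pd.DataFrame(corr, index=df.columns, columns=df.columns)
    np.fill_diagonal(out.values, 1.0)
    return out


# ---------------------------------------------------------------------------
# univariate follow-up


def compact_letter_display(
    levels: Sequence[str],
    means: Mapping[str, float],
    significant: Mapping[tuple[str, str], bool],
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two levels share a letter iff they are *not* significantly different.
    ``significant`` maps unordered level pairs to the test outcome.
    """
    def is_sig(a: str, b: str) -> bool:
        return significant.get((a, b), significant.get((b, a), False))

    order = sorted(levels, key=lambda l: means[l])
    letter_sets: list[set[str]] = [set(order)]
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if not is_sig(a, b):
                continue
            split: list[set[str]] = []
            for s in letter_sets:
                if a in s and b in s:
                    split.extend((s - {a}, s - {b}))
                else:
                    split.append(s)
            # absorb: drop sets contained in another (dedupe exact copies)
            letter_sets = []
            for s in split:
                if any(s < t for t in split) or s in letter_sets or not s:
                    continue
                letter_sets.append(s)
    letter_sets.sort(key=lambda s: min(order.index(l) for l in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {l: "" for l in levels}
    for i, s in enumerate(letter_sets):
        for l in s:
            out[l] += alphabet[i % len(alphabet)]
    return out


def anova_per_metal(
    matrix: MetalMatrix,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA of each metal across sites, with pairwise permutation
    t-tests compressed into compact grouping letters.

    Returns a frame indexed by metal with columns ``F``, ``p`` and
    ``letters`` (site → letter string mapping).
    """
    sites, gidx = np.unique(matrix.site.values, return_inverse=True)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    sizes = np.bincount(gidx)
    if (sizes < 2).any():
        raise ValueError("each site needs at least 2 samples")
    rng = np.random.default_rng(seed)
    rows = []
    for metal in matrix.metals:
        vals = matrix.data[metal].values.astype(float)
        f = _anova_f(vals, gidx, len(sites))
        df1, df2 = len(sites) - 1, len(vals) - len(sites)
        p = float(_sps.f.sf(f, df1, df2))
        means = {str(s): float(vals[gidx == i].mean()) for i, s in enumerate(sites)}
        sig: dict[tuple[str, str], bool] = {}
        for a in range(len(sites)):
            for b in range(a + 1, len(sites)):
                va, vb = vals[gidx == a], vals[gidx == b]
                t_obs = abs(va.mean() - vb.mean())
                pooled = np.concatenate([va, vb])
                count = 0
                for _ in range(n_perm):
                    perm = rng.permutation(pooled)
                    if abs(perm[: len(va)].mean() - perm[len(va):].mean()) >= t_obs - 1e-12:
                        count += 1
                p_pair = (count + 1) / (n_perm + 1)
                sig[(str(sites[a]), str(sites[b]))] = p_pair < alpha
        letters = compact_letter_display([str(s) for s in sites], means, sig)
        rows.append({"metal": metal, "F": float(f), "p": p, "letters": letters})
    return pd.DataFrame(rows).set_index("metal")
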