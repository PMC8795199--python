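"""Technical-validation statistics for a scrubbed radiocarbon table.

Three families of diagnostics:

* **Continental summaries** — raw vs scrubbed date counts, percent kept,
  dated-site counts and mean dates per site, the quick sampling-quality
  table. A "dated site" is a distinct (SiteName, SiteID, Lat, Long) tuple.

* **Spatial sampling bias** — 2D Gaussian kernel-density surfaces of dated
  sites, the same surfaces weighted by dates per site, and their cellwise
  ratio (a relative-risk surface): ratio 1 means dates are proportional to
  sites, >1 over-sampling, <1 under-sampling.

* **Site-vs-date scaling** — standardized major axis (SMA) fits on
  log-log per-unit densities. SMA is the symmetric line fit whose slope
  magnitude is sd(y)/sd(x); both axes carry sampling error here, so an
  ordinary least-squares slope would be attenuated. A slope above 1 means
  unit areas rich in dated sites hold disproportionately many dates.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .records import RecordTable

SITE_KEY_COLUMNS = ["SiteName", "SiteID", "Lat", "Long"]


def _df(table):
    return table.df if isinstance(table, RecordTable) else table


# ---------------------------------------------------------------------------
# site indexing and summary tables

def site_index(table, by_continent: bool = False) -> pd.DataFrame:
    """Distinct site keys with per-site date counts.

    The per-site counts sum to the number of records. With
    ``by_continent=True`` the key additionally includes the continent (two
    continents sharing, say, a blank site key count as two sites).
    """
    df = _df(table)
    cols = (["Continent"] if by_continent else []) + SITE_KEY_COLUMNS
    if df.empty:
        return pd.DataFrame(columns=cols + ["n_dates"])
    out = (df.groupby(cols, dropna=False, sort=False).size()
             .reset_index(name="n_dates"))
    return out


def _round_half_up(x: float, places: int) -> float:
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summary_from_counts(rows: dict, total_dated_sites: int | None = None) -> pd.DataFrame:
    """Summary table from per-continent (raw, scrubbed, dated-site) counts.

    ``rows`` maps continent name -> (raw_dates, scrubbed_dates,
    dated_sites). Percent kept is 100*scrubbed/raw rounded half-up to 1
    decimal; mean dates per site is scrubbed/sites rounded half-up to 2
    decimals (absent when a continent has no dated sites).

    The total row sums the counts, except that ``total_dated_sites`` may be
    given explicitly: site keys are deduplicated within continents, so a
    whole-dataset site count can be smaller than the sum of the
    per-continent counts (identical keys occurring on several continents
    collapse). When the explicit total differs from the row sum the table
    records both (``DatedSites`` vs ``DatedSitesRowSum``).
    """
    out = []
    t_raw = t_scr = t_sites = 0
    for cont, (raw, scr, sites) in rows.items():
        t_raw, t_scr, t_sites = t_raw + raw, t_scr + scr, t_sites + sites
        out.append(_summary_row(cont, raw, scr, sites))
    total_sites = t_sites if total_dated_sites is None else total_dated_sites
    total = _summary_row("Total", t_raw, t_scr, total_sites)
    total["DatedSitesRowSum"] = t_sites
    out.append(total)
    df = pd.DataFrame(out)
    df["DatedSitesRowSum"] = df["DatedSitesRowSum"].fillna(df["DatedSites"]).astype(int)
    return df


def _summary_row(name, raw, scr, sites):
    return {
        "Continent": name,
        "RawDates": int(raw),
        "ScrubbedDates": int(scr),
        "PctKept": _round_half_up(100.0 * scr / raw, 1) if raw else 0.0,
        "DatedSites": int(sites),
        "MeanDatesPerSite": (_round_half_up(scr / sites, 2) if sites else None),
    }


def continent_summary(raw, scrubbed) -> pd.DataFrame:
    """Per-continent summary of a raw/scrubbed table pair.

    The total row's dated-site count is computed over the whole scrubbed
    table (distinct site keys regardless of continent); per-continent rows
    count distinct keys within each continent.
    """
    raw_df, scr_df = _df(raw), _df(scrubbed)
    if raw_df.empty:
        raise ValueError("no records in the raw table")
    continents = list(dict.fromkeys(list(raw_df["Continent"]) + list(scr_df["Continent"])))
    sites = site_index(scr_df, by_continent=True)
    site_counts = (sites.groupby("Continent").size() if not sites.empty
                   else pd.Series(dtype=int))
    rows = {}
    for cont in continents:
        rows[cont] = (
            int((raw_df["Continent"] == cont).sum()),
            int((scr_df["Continent"] == cont).sum()),
            int(site_counts.get(cont, 0)),
        )
    global_sites = len(site_index(scr_df))
    return summary_from_counts(rows, total_dated_sites=global_sites)


# ---------------------------------------------------------------------------
# kernel-density surfaces

@dataclass(frozen=True)
class GridSpec:
    """A regular evaluation lattice: cell centers, inclusive bounds."""

    nx: int
    ny: int
    bounds: tuple  # (xmin, xmax, ymin, ymax)

    def axes(self):
        xmin, xmax, ymin, ymax = self.bounds
        return (np.linspace(xmin, xmax, self.nx),
                np.linspace(ymin, ymax, self.ny))


@dataclass
class DensitySurface:
    """Gridded 2D kernel-density estimate.

    ``z[j, i]`` is the density at ``(x[i], y[j])`` scaled so the surface
    integrates to ``total_weight`` over the plane (up to kernel mass lying
    outside the grid).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    bandwidth: tuple
    total_weight: float

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def integral(self) -> float:
        return float(self.z.sum() * self.cell_area)

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                             "value": self.z.ravel()})


def silverman_bandwidth(values, n_eff=None) -> float:
    """Normal-reference bandwidth for one axis of a 2D product kernel:
    sigma * n^(-1/6)."""
    values = np.asarray(values, float)
    n = len(values) if n_eff is None else n_eff
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 1.0
    if sd == 0:
        sd = 1.0
    return sd * n ** (-1.0 / 6.0)


def kde2d(points, weights=None, bandwidth=None, grid: GridSpec | None = None,
          margin: float = 3.0) -> DensitySurface:
    """Weighted 2D Gaussian product-kernel density on a regular grid.

    ``points`` is (n, 2) of (x, y); ``weights`` default to 1 (the
    unweighted surface). ``bandwidth`` is a per-axis pair; by default the
    normal-reference (Silverman) rule per axis, recorded in the result so a
    figure can be reproduced. Without an explicit grid, a 128x128 lattice
    covering the points plus ``margin`` bandwidths is used.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, float)
    if len(w) != len(pts):
        raise ValueError("weights must match points")
    if bandwidth is None:
        bandwidth = (silverman_bandwidth(pts[:, 0]), silverman_bandwidth(pts[:, 1]))
    hx, hy = float(bandwidth[0]), float(bandwidth[1])
    if hx <= 0 or hy <= 0:
        raise ValueError("bandwidths must be positive")
    if grid is None:
        xmin, xmax = pts[:, 0].min() - margin * hx, pts[:, 0].max() + margin * hx
        ymin, ymax = pts[:, 1].min() - margin * hy, pts[:, 1].max() + margin * hy
        grid = GridSpec(128, 128, (xmin, xmax, ymin, ymax))
    gx, gy = grid.axes()
    # separable kernel: z = Ky @ diag(w) @ Kx^T
    kx = np.exp(-0.5 * ((gx[:, None] - pts[None, :, 0]) / hx) ** 2) / (hx * np.sqrt(2 * np.pi))
    ky = np.exp(-0.5 * ((gy[:, None] - pts[None, :, 1]) / hy) ** 2) / (hy * np.sqrt(2 * np.pi))
    z = ky @ (w[:, None] * kx.T)
    return DensitySurface(gx, gy, z, (hx, hy), float(w.sum()))


@dataclass
class RiskSurface:
    """Cellwise ratio of two unit-mass density surfaces; cells where the
    denominator falls below ``epsilon`` are NaN-masked."""

    x: np.ndarray
    y: np.ndarray
    ratio: np.ndarray
    epsilon: float

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({"x": xx.ravel(), "y": yy.ravel(),
                             "ratio": self.ratio.ravel()})


def risk_surface(weighted: DensitySurface, unweighted: DensitySurface,
                 epsilon: float | None = None) -> RiskSurface:
    """Relative-risk surface: weighted density over unweighted density.

    Both surfaces must share grid and bandwidth; each is normalized to unit
    mass before division, so a ratio of 1 means dates are sampled in
    proportion to sites. ``epsilon`` (denominator floor, default 1% of the
    unweighted surface's maximum) masks cells where the ratio is noise.
    """
    if (weighted.z.shape != unweighted.z.shape
            or not np.allclose(weighted.x, unweighted.x)
            or not np.allclose(weighted.y, unweighted.y)):
        raise ValueError("surfaces must share the same grid")
    if weighted.bandwidth != unweighted.bandwidth:
        raise ValueError("surfaces must share the same bandwidth")
    num = weighted.z / weighted.total_weight
    den = unweighted.z / unweighted.total_weight
    if epsilon is None:
        epsilon = 0.01 * float(den.max())
    ratio = np.where(den >= epsilon, num / np.where(den >= epsilon, den, 1.0), np.nan)
    return RiskSurface(weighted.x, weighted.y, ratio, float(epsilon))


# ---------------------------------------------------------------------------
# per-unit densities and SMA

def density_per_unit(table, layer) -> pd.DataFrame:
    """Site and date densities per administrative unit.

    Records are assigned to units by containment (nearest unit as the
    coastal fallback); densities are counts divided by unit area. Units
    with zero sites are flagged ``included=False`` — log densities are
    undefined there and downstream log-log fits must drop them.
    """
    from .geomask import assign_admin
    from .records import parse_float

    df = _df(table)
    sites = site_index(df)
    site_units: dict = {}
    date_counts: dict = {}
    for rec in sites.to_dict("records"):
        lon, lat = parse_float(rec["Long"]), parse_float(rec["Lat"])
        if lon is None or lat is None:
            continue
        uid = assign_admin((lon, lat), layer).id
        site_units[uid] = site_units.get(uid, 0) + 1
        date_counts[uid] = date_counts.get(uid, 0) + int(rec["n_dates"])
    rows = []
    for u in layer:
        ns, nd = site_units.get(u.id, 0), date_counts.get(u.id, 0)
        rows.append({"unit": u.id, "area": u.area, "n_sites": ns,
                     "n_dates": nd, "site_density": ns / u.area,
                     "date_density": nd / u.area, "included": ns > 0})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SmaFit:
    """Standardized-major-axis line on (already log-transformed) data."""

    slope: float
    intercept: float
    r: float
    n: int


def sma_fit(x, y) -> SmaFit:
    """Fit a standardized major axis line.

    slope = sign(r) * sd(y)/sd(x); the line passes through the centroid.
    Callers fitting log-log density plots pass log10-transformed values.
    Requires n >= 3 and nonzero variance on both axes.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: SMA fit undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = (1.0 if r >= 0 else -1.0) * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    return SmaFit(float(slope), intercept, r, len(x))
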