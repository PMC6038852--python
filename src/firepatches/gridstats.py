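"""Gridded level-2 products: trait maps and the patch-size power law.

The size distribution of fire patches is modelled as N_f = alpha * A_f^-beta.
Per 1-degree cell (or for any catalogue subset) the fit proceeds as in the
self-organized-criticality literature: build the profile histogram of patch
areas in logarithmic bins with a Poisson error sqrt(count) on each bin, then
minimize

    chi2(alpha, beta) = sum_i [ (n_i - m_i(alpha, beta))^2 / n_i ]

over occupied bins, where m_i is the power law *integrated* across bin i
(count space, exact for within-bin curvature). alpha enters linearly and is
profiled out analytically; beta is found by 1-D minimization seeded from a
weighted log-log regression. sigma_beta is read off the chi2 profile at
delta-chi2 = 1 with alpha re-minimized at every beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import optimize

MISSING = float("nan")

GRIDDED_TRAITS = ("par", "si", "d2", "r_sde", "e_sde")


@dataclass
class ProfileHistogram:
    """Counts of patch areas in logarithmic size bins."""

    edges: np.ndarray  # bin edges, ha, len = n_bins + 1
    counts: np.ndarray  # raw counts per bin
    density: np.ndarray  # count / linear bin width (ha^-1)
    errors: np.ndarray  # sqrt(count)

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin centres."""
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "edge_lo_ha": self.edges[:-1],
                "edge_hi_ha": self.edges[1:],
                "count": self.counts,
                "density_per_ha": self.density,
                "poisson_error": self.errors,
            }
        )


@dataclass
class SizeDistributionFit:
    """Power-law fit N_f = alpha * A_f^-beta with its uncertainty."""

    alpha: float
    beta: float
    sigma_beta: float
    chi2: float
    n_fires: int
    bins: ProfileHistogram | None
    converged: bool = True
    message: str = ""


def profile_histogram(areas, bins_per_decade: int = 5) -> ProfileHistogram:
    """Histogram patch areas in logarithmic bins.

    Bin edges are geometric, spanning [min, max] of the data with
    ``bins_per_decade`` bins per factor of 10; each bin carries a Poisson
    error equal to the square root of its count.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("profile_histogram needs at least one area")
    if np.any(areas <= 0):
        raise ValueError("areas must be positive")
    lo, hi = float(areas.min()), float(areas.max())
    if lo == hi:
        hi = lo * (1.0 + 1e-9)
        n_bins = 1
    else:
        n_bins = max(1, int(np.ceil((np.log10(hi) - np.log10(lo)) * bins_per_decade)))
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges[0] = lo  # guard round-off at the data extremes
    edges[-1] = hi
    counts, _ = np.histogram(areas, bins=edges)
    widths = np.diff(edges)
    return ProfileHistogram(
        edges=edges,
        counts=counts.astype(float),
        density=counts / widths,
        errors=np.sqrt(counts),
    )


def _bin_integrals(edges: np.ndarray, beta: float) -> np.ndarray:
    """Integral of A^-beta across each bin."""
    if abs(beta - 1.0) < 1e-10:
        return np.diff(np.log(edges))
    e = 1.0 - beta
    return np.diff(edges**e) / e


def _chi2_profile(edges, counts, occupied):
    """chi2(beta) with alpha profiled out analytically, plus alpha(beta)."""
    n = counts[occupied]

    def alpha_of_beta(beta: float) -> float:
        g = _bin_integrals(edges, beta)[occupied]
        denom = np.sum(g * g / n)
        return float(np.sum(g) / denom) if denom > 0 else 0.0

    def chi2(beta: float) -> float:
        g = _bin_integrals(edges, beta)[occupied]
        a = alpha_of_beta(beta)
        return float(np.sum((n - a * g) ** 2 / n))

    return chi2, alpha_of_beta


def fit_power_law(bins: ProfileHistogram) -> SizeDistributionFit:
    """Fit the power-law exponent to a profile histogram.

    Empty bins are excluded (the Poisson chi2 weight 1/n is undefined at
    n = 0); at least 3 occupied bins are required. Returns a missing fit
    with a diagnostic message when the fit cannot be made.
    """
    occupied = bins.counts >= 1
    n_fires = int(bins.counts.sum())
    if occupied.sum() < 3:
        return SizeDistributionFit(
            MISSING, MISSING, MISSING, MISSING, n_fires, bins,
            converged=False, message="fewer than 3 occupied bins",
        )
    chi2, alpha_of_beta = _chi2_profile(bins.edges, bins.counts, occupied)

    # seed: weighted least squares on log density vs log size
    centers = bins.centers[occupied]
    dens = bins.density[occupied]
    w = bins.counts[occupied]  # relative log-space weights ~ n
    slope = np.polyfit(np.log(centers), np.log(dens), 1, w=np.sqrt(w))[0]
    beta0 = -float(slope)

    res = optimize.minimize_scalar(
        chi2, bounds=(beta0 - 4.0, beta0 + 4.0), method="bounded",
        options={"xatol": 1e-7},
    )
    if not res.success:
        return SizeDistributionFit(
            MISSING, MISSING, MISSING, MISSING, n_fires, bins,
            converged=False, message=f"minimizer failed: {res.message}",
        )
    beta_hat = float(res.x)
    chi2_min = float(res.fun)
    alpha_hat = alpha_of_beta(beta_hat)

    sigma = _sigma_from_profile(chi2, beta_hat, chi2_min)
    if not np.isfinite(sigma):
        return SizeDistributionFit(
            alpha_hat, beta_hat, MISSING, chi2_min, n_fires, bins,
            converged=False, message="delta-chi2 = 1 crossing not bracketed",
        )
    return SizeDistributionFit(alpha_hat, beta_hat, sigma, chi2_min, n_fires, bins)


def _sigma_from_profile(chi2, beta_hat: float, chi2_min: float) -> float:
    """Half-width of the chi2 profile at chi2_min + 1 (mean of both sides)."""
    target = chi2_min + 1.0

    def crossing(direction: float) -> float:
        step = 0.05
        for _ in range(60):
            b = beta_hat + direction * step
            if chi2(b) >= target:
                return optimize.brentq(
                    lambda x: chi2(x) - target, beta_hat, b
                ) if direction > 0 else optimize.brentq(
                    lambda x: chi2(x) - target, b, beta_hat
                )
            step *= 1.5
        return float("nan")

    hi = crossing(+1.0)
    lo = crossing(-1.0)
    return (abs(hi - beta_hat) + abs(beta_hat - lo)) / 2.0


def fit_patch_sizes(areas, bins_per_decade: int = 5) -> SizeDistributionFit:
    """Convenience: profile histogram + power-law fit in one call."""
    return fit_power_law(profile_histogram(areas, bins_per_decade=bins_per_decade))


# ---------------------------------------------------------------------------
# 1-degree gridding
# ---------------------------------------------------------------------------

def _cell_edges(lo: float, hi: float, cell: float) -> np.ndarray:
    first = np.floor(lo / cell) * cell
    last = np.ceil(hi / cell) * cell
    if last <= first:
        last = first + cell
    return np.arange(first, last + cell / 2, cell)


def grid_traits(catalogue: pd.DataFrame, cell_deg: float = 1.0,
                min_area_ha: float = 0.0, min_fires_for_fit: int = 20,
                bins_per_decade: int = 5,
                bounds: tuple[float, float, float, float] | None = None) -> xr.Dataset:
    """Aggregate a patch catalogue onto a regular lat/lon grid.

    Each patch falls in the half-open cell [w, e) x [s, n) containing its
    centre (x_deg, y_deg). Per cell the dataset carries the fire count,
    mean and standard deviation of PAR, SI, D2, R_SDE and E_SDE, and the
    power-law (beta, sigma_beta) for cells with at least
    ``min_fires_for_fit`` patches; all other cells hold NaN.
    """
    df = catalogue
    if min_area_ha > 0:
        df = df[df["area_ha"] >= min_area_ha]
    if bounds is None:
        if len(df) == 0:
            raise ValueError("empty catalogue and no explicit grid bounds")
        bounds = (
            float(df["x_deg"].min()), float(df["y_deg"].min()),
            float(df["x_deg"].max()), float(df["y_deg"].max()),
        )
    west, south, east, north = bounds
    lon_edges = _cell_edges(west, east, cell_deg)
    lat_edges = _cell_edges(south, north, cell_deg)
    lon_centers = (lon_edges[:-1] + lon_edges[1:]) / 2
    lat_centers = (lat_edges[:-1] + lat_edges[1:]) / 2
    shape = (len(lat_centers), len(lon_centers))

    data = {"count": np.zeros(shape, dtype=np.int32)}
    for t in GRIDDED_TRAITS:
        data[f"{t}_mean"] = np.full(shape, np.nan)
        data[f"{t}_std"] = np.full(shape, np.nan)
    data["beta"] = np.full(shape, np.nan)
    data["sigma_beta"] = np.full(shape, np.nan)

    if len(df) > 0:
        ix = np.floor((df["x_deg"].to_numpy() - lon_edges[0]) / cell_deg).astype(int)
        iy = np.floor((df["y_deg"].to_numpy() - lat_edges[0]) / cell_deg).astype(int)
        inside = (ix >= 0) & (ix < shape[1]) & (iy >= 0) & (iy < shape[0])
        sub = df[inside].copy()
        sub["_ix"] = ix[inside]
        sub["_iy"] = iy[inside]
        for (cy, cx), group in sub.groupby(["_iy", "_ix"]):
            data["count"][cy, cx] = len(group)
            for t in GRIDDED_TRAITS:
                if t in group:
                    data[f"{t}_mean"][cy, cx] = group[t].mean()
                    data[f"{t}_std"][cy, cx] = group[t].std(ddof=1) if len(group) > 1 else 0.0
            if len(group) >= min_fires_for_fit:
                fit = fit_patch_sizes(group["area_ha"].to_numpy(),
                                      bins_per_decade=bins_per_decade)
                if fit.converged:
                    data["beta"][cy, cx] = fit.beta
                    data["sigma_beta"][cy, cx] = fit.sigma_beta

    ds = xr.Dataset(
        {k: (("lat", "lon"), v) for k, v in data.items()},
        coords={"lat": lat_centers, "lon": lon_centers},
        attrs={
            "cell_deg": cell_deg,
            "min_fires_for_fit": min_fires_for_fit,
            "bins_per_decade": bins_per_decade,
            "min_area_ha": min_area_ha,
        },
    )
    ds["lat"].attrs.update(units="degrees_north", standard_name="latitude")
    ds["lon"].attrs.update(units="degrees_east", standard_name="longitude")
    ds["count"].attrs["long_name"] = "number of fire patches per cell"
    ds["beta"].attrs["long_name"] = "power-law exponent of the patch size distribution"
    ds["sigma_beta"].attrs["long_name"] = "standard deviation of beta (delta-chi2 = 1)"
    return ds


def compare_grids(grid_a: xr.Dataset, grid_b: xr.Dataset) -> xr.Dataset:
    """Per-cell beta difference and agreement level between two grids.

    agreement N = |beta_a - beta_b| / sqrt(sigma_a^2 + sigma_b^2): the two
    fits are compatible within N standard deviations. Cells missing in
    either grid are missing in the output.
    """
    if (not np.array_equal(grid_a["lat"].values, grid_b["lat"].values)
            or not np.array_equal(grid_a["lon"].values, grid_b["lon"].values)):
        raise ValueError("grid geometries differ; compare requires identical cells")
    diff = grid_a["beta"] - grid_b["beta"]
    pooled = np.sqrt(grid_a["sigma_beta"] ** 2 + grid_b["sigma_beta"] ** 2)
    agreement = np.abs(diff) / pooled
    out = xr.Dataset(
        {"beta_difference": diff, "agreement_sigma": agreement},
        coords={"lat": grid_a["lat"], "lon": grid_a["lon"]},
    )
    out["agreement_sigma"].attrs["long_name"] = (
        "absolute beta difference in units of the pooled standard deviation"
    )
    return out


def write_trait_grid(ds: xr.Dataset, path) -> None:
    """Write a trait grid as NetCDF3 (scipy engine; widely readable)."""
    ds.to_netcdf(path, engine="scipy")


def read_trait_grid(path) -> xr.Dataset:
    ds = xr.open_dataset(path, engine="scipy")
    ds.load()
    ds.close()
    return ds
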