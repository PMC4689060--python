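"""Point-pattern intensity measures for urban point characteristics.

Seven measures are supported downstream: the *simple intensity* (points per
km² of a neighborhood) and Gaussian-kernel intensity surfaces under four
bandwidth regimes — a fixed isotropic bandwidth (default 500 m), an isotropic
bandwidth chosen by Berman–Diggle mean-square-error cross-validation, an
anisotropic bandwidth matrix chosen by least-squares cross-validation, and
residential-density-adaptive rescalings of each pilot bandwidth by the factor
``pilot_density / R_A`` (pilot density 2000 residents/km²).

All coordinates are planar metres; intensities are reported per km².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats
from shapely.geometry import Point, Polygon, box
import shapely

__all__ = [
    "Window",
    "PointPattern",
    "Bandwidth",
    "IntensitySurface",
    "CVResult",
    "simple_intensity",
    "gaussian_kernel_density",
    "kernel_mass",
    "edge_correction",
    "kernel_intensity_surface",
    "bw_fixed",
    "bw_mse_cv",
    "bw_lscv_aniso",
    "adaptive_scale",
]

M2_PER_KM2 = 1e6

# geometric tolerance (metres) for treating a window as an axis-aligned
# rectangle, which unlocks the closed-form Gaussian rectangle mass
_RECT_TOL = 1e-6


@dataclass(frozen=True)
class Window:
    """Study area W: a simple polygon in planar metric coordinates."""

    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise ValueError("window polygon must be a valid non-empty polygon")
        if self.polygon.area <= 0:
            raise ValueError("window area must be positive")

    @classmethod
    def rectangle(cls, width_m: float, height_m: float,
                  origin: tuple[float, float] = (0.0, 0.0)) -> "Window":
        x0, y0 = origin
        return cls(box(x0, y0, x0 + width_m, y0 + height_m))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds

    @property
    def area_km2(self) -> float:
        return self.polygon.area / M2_PER_KM2

    @property
    def is_rectangle(self) -> bool:
        env = self.polygon.envelope
        return abs(env.area - self.polygon.area) < _RECT_TOL * max(env.area, 1.0)

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return shapely.intersects_xy(self.polygon, xy[:, 0], xy[:, 1])


@dataclass(frozen=True)
class PointPattern:
    """Locations of one urban point characteristic inside a window.

    Exact duplicate points are allowed (two playgrounds can share a snapped
    location); NaN coordinates and points outside the window are not.
    """

    kind: str
    points: np.ndarray  # (n, 2) metres
    window: Window

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if np.isnan(pts).any():
            raise ValueError("point pattern contains NaN coordinates")
        if len(pts) and not self.window.contains_points(pts).all():
            raise ValueError("all points must lie inside the window")

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Bandwidth:
    """Kernel bandwidth: isotropic σ (metres) or a full 2×2 SPD matrix (m²)."""

    form: Literal["isotropic", "anisotropic"]
    sigma_m: float | None = None
    Sigma: np.ndarray | None = None
    provenance: str = "fixed"

    def __post_init__(self) -> None:
        if self.form == "isotropic":
            if self.sigma_m is None or self.sigma_m <= 0:
                raise ValueError("isotropic bandwidth requires sigma_m > 0")
        elif self.form == "anisotropic":
            S = np.asarray(self.Sigma, dtype=float)
            if S.shape != (2, 2) or not np.allclose(S, S.T):
                raise ValueError("Sigma must be a symmetric 2x2 matrix")
            ev = np.linalg.eigvalsh(S)
            if ev.min() <= 0:
                raise ValueError("Sigma must be positive definite")
            object.__setattr__(self, "Sigma", S)
        else:
            raise ValueError(f"unknown bandwidth form {self.form!r}")

    @property
    def cov(self) -> np.ndarray:
        if self.form == "isotropic":
            return np.eye(2) * self.sigma_m**2
        return self.Sigma

    @property
    def max_sd_m(self) -> float:
        return float(np.sqrt(np.linalg.eigvalsh(self.cov).max()))

    def scaled(self, factor: float, provenance: str) -> "Bandwidth":
        """Scale linear kernel spread by ``factor`` (covariance by factor²)."""
        if self.form == "isotropic":
            return Bandwidth("isotropic", sigma_m=self.sigma_m * factor,
                             provenance=provenance)
        return Bandwidth("anisotropic", Sigma=self.cov * factor**2,
                         provenance=provenance)


@dataclass
class IntensitySurface:
    """Gridded intensity estimate λ̂(s) in points per km².

    ``values[iy, ix]`` is the estimate at the cell center
    ``(x0 + (ix+0.5)·Δ, y0 + (iy+0.5)·Δ)``; rows run south → north.
    """

    origin: tuple[float, float]
    cell_size_m: float
    values: np.ndarray  # (ny, nx), points / km²
    bandwidth: Bandwidth | None
    kind: str
    edge_corrected: bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> np.ndarray:
        ny, nx = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell_size_m
        ys = y0 + (np.arange(ny) + 0.5) * self.cell_size_m
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def integral_points(self) -> float:
        """∫ λ̂ ds as a point count (midpoint sum over the grid)."""
        cell_km2 = (self.cell_size_m**2) / M2_PER_KM2
        return float(np.nansum(self.values) * cell_km2)

    def value_at(self, x: float, y: float) -> float:
        """Bilinear interpolation of the surface at a point."""
        x0, y0 = self.origin
        d = self.cell_size_m
        fx = (x - x0) / d - 0.5
        fy = (y - y0) / d - 0.5
        ny, nx = self.values.shape
        ix = int(np.clip(np.floor(fx), 0, nx - 2))
        iy = int(np.clip(np.floor(fy), 0, ny - 2))
        tx = float(np.clip(fx - ix, 0.0, 1.0))
        ty = float(np.clip(fy - iy, 0.0, 1.0))
        v = self.values
        return float((1 - tx) * (1 - ty) * v[iy, ix] + tx * (1 - ty) * v[iy, ix + 1]
                     + (1 - tx) * ty * v[iy + 1, ix] + tx * ty * v[iy + 1, ix + 1])


@dataclass
class CVResult:
    """Outcome of a data-driven bandwidth search."""

    bandwidth: Bandwidth
    criterion_grid: list
    criterion_values: np.ndarray
    converged: bool
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# kernel evaluation


def _grid_axes(window: Window, cell_size_m: float):
    xmin, ymin, xmax, ymax = window.bounds
    nx = max(1, int(math.ceil((xmax - xmin) / cell_size_m)))
    ny = max(1, int(math.ceil((ymax - ymin) / cell_size_m)))
    return (xmin, ymin), nx, ny


def _kernel_sum(eval_xy: np.ndarray, pts: np.ndarray, cov: np.ndarray,
                weights: np.ndarray | None = None,
                chunk: int = 4096) -> np.ndarray:
    """Σ_i w_i K_Σ(s − s_i) at each evaluation location, in 1/m²."""
    eval_xy = np.asarray(eval_xy, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return np.zeros(len(eval_xy))
    det = float(np.linalg.det(cov))
    inv = np.linalg.inv(cov)
    a, b, c = inv[0, 0], inv[0, 1], inv[1, 1]
    norm = 1.0 / (2.0 * math.pi * math.sqrt(det))
    out = np.empty(len(eval_xy))
    px, py = pts[:, 0], pts[:, 1]
    for lo in range(0, len(eval_xy), chunk):
        ex = eval_xy[lo:lo + chunk, 0, None] - px[None, :]
        ey = eval_xy[lo:lo + chunk, 1, None] - py[None, :]
        q = a * ex * ex + 2.0 * b * ex * ey + c * ey * ey
        k = np.exp(-0.5 * q)
        if weights is not None:
            k = k * weights[None, :]
        out[lo:lo + chunk] = norm * k.sum(axis=1)
    return out


def gaussian_kernel_density(s, pattern: PointPattern, bw: Bandwidth) -> float:
    """Kernel sum Σ_i K_Σ(s − s_i) at a single location (1/m², uncorrected)."""
    s = np.asarray(s, dtype=float).reshape(1, 2)
    return float(_kernel_sum(s, pattern.points, bw.cov)[0])


def _rect_mass(eval_xy: np.ndarray, cov: np.ndarray,
               bounds: tuple[float, float, float, float]) -> np.ndarray:
    """Closed-form Gaussian mass inside an axis-aligned rectangle."""
    xmin, ymin, xmax, ymax = bounds
    x, y = eval_xy[:, 0], eval_xy[:, 1]
    if abs(cov[0, 1]) < 1e-12 * math.sqrt(cov[0, 0] * cov[1, 1]):
        sx, sy = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
        mx = stats.norm.cdf((xmax - x) / sx) - stats.norm.cdf((xmin - x) / sx)
        my = stats.norm.cdf((ymax - y) / sy) - stats.norm.cdf((ymin - y) / sy)
        return mx * my
    out = np.ones(len(eval_xy))
    max_sd = math.sqrt(float(np.linalg.eigvalsh(cov).max()))
    near = ((x - xmin < 6 * max_sd) | (xmax - x < 6 * max_sd)
            | (y - ymin < 6 * max_sd) | (ymax - y < 6 * max_sd))
    if near.any():
        xn, yn = x[near], y[near]
        # allow_singular: near-degenerate LSCV bandwidths must not crash
        # the mass computation
        mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov,
                                        allow_singular=True)
        ll = np.column_stack([xmin - xn, ymin - yn])
        lr = np.column_stack([xmax - xn, ymin - yn])
        ul = np.column_stack([xmin - xn, ymax - yn])
        ur = np.column_stack([xmax - xn, ymax - yn])
        m = mvn.cdf(ur) - mvn.cdf(ul) - mvn.cdf(lr) + mvn.cdf(ll)
        out[near] = np.clip(np.atleast_1d(m), 0.0, 1.0)
    return out


def kernel_mass(eval_xy: np.ndarray, bw: Bandwidth, window: Window,
                cell_size_m: float = 25.0) -> np.ndarray:
    """Kernel mass m(s) = ∫_W K_Σ(u − s) du retained inside the window.

    Rectangular windows use the closed-form Gaussian rectangle probability;
    general polygons fall back to a midpoint sum over the surface grid.
    Locations further than 6 kernel SDs from the boundary short-circuit to 1.
    """
    eval_xy = np.asarray(eval_xy, dtype=float).reshape(-1, 2)
    cov = bw.cov
    if window.is_rectangle:
        return _rect_mass(eval_xy, cov, window.bounds)
    mass = np.ones(len(eval_xy))
    reach = 6.0 * bw.max_sd_m
    dist_to_edge = shapely.distance(window.polygon.exterior,
                                    shapely.points(eval_xy))
    inner = window.contains_points(eval_xy) & (dist_to_edge > reach)
    todo = ~inner
    if todo.any():
        (x0, y0), nx, ny = _grid_axes(window, cell_size_m)
        xs = x0 + (np.arange(nx) + 0.5) * cell_size_m
        ys = y0 + (np.arange(ny) + 0.5) * cell_size_m
        gx, gy = np.meshgrid(xs, ys)
        cells = np.column_stack([gx.ravel(), gy.ravel()])
        keep = window.contains_points(cells)
        cells = cells[keep]
        vals = _kernel_sum(eval_xy[todo], cells, cov) * cell_size_m**2
        mass[todo] = np.clip(vals, 0.0, 1.0)
    return mass


def edge_correction(s, bw: Bandwidth, window: Window,
                    cell_size_m: float = 25.0,
                    mass_floor: float = 1e-3) -> float:
    """Edge-correction weight w(s) = 1 / m(s) ≥ 1.

    Returns exactly 1.0 when the kernel is fully interior (mass within 1e-3
    of 1). A mass below ``mass_floor`` signals a bandwidth far larger than
    the window and raises.
    """
    s = np.asarray(s, dtype=float).reshape(1, 2)
    if not window.contains_points(s)[0]:
        raise ValueError("edge correction requires a location inside the window")
    m = float(kernel_mass(s, bw, window, cell_size_m)[0])
    if m < mass_floor:
        raise ValueError(
            f"kernel mass {m:.2e} below floor {mass_floor}: bandwidth is far "
            "larger than the window")
    if m > 1.0 - 1e-3:
        return 1.0
    return 1.0 / m


def kernel_intensity_surface(pattern: PointPattern, bw: Bandwidth,
                             cell_size_m: float = 25.0,
                             edge_corrected: bool = True,
                             correction: Literal["per_point", "uniform"] = "per_point",
                             mass_floor: float = 1e-3,
                             eval_mask: np.ndarray | None = None,
                             ) -> IntensitySurface:
    """Edge-corrected kernel intensity surface λ̂(s) in points/km².

    ``correction='per_point'`` (default) weights each kernel by the inverse
    of the mass it retains inside the window, λ̂(s) = Σ_i K_Σ(s − s_i)/m(s_i)
    — this conserves mass exactly (∫_W λ̂ = n). ``'uniform'`` applies the
    weight at the evaluation location instead, λ̂(s) = w(s)·Σ_i K_Σ(s − s_i)
    with w(s) = 1/m(s); it is unbiased for an inhomogeneous Poisson
    intensity but only approximately mass-conserving. With ``eval_mask``
    (boolean, grid-shaped) only the masked cells are computed and the rest
    are NaN — used for per-neighborhood adaptive re-evaluation.
    """
    window = pattern.window
    (x0, y0), nx, ny = _grid_axes(window, cell_size_m)
    surf = IntensitySurface(origin=(x0, y0), cell_size_m=cell_size_m,
                            values=np.full((ny, nx), np.nan),
                            bandwidth=bw, kind=pattern.kind,
                            edge_corrected=edge_corrected)
    centers = surf.cell_centers()
    sel = np.ones(ny * nx, dtype=bool) if eval_mask is None else eval_mask.ravel()
    if not window.is_rectangle:
        sel = sel & window.contains_points(centers)
    pts_eval = centers[sel]

    def _checked_mass(at_xy):
        m = kernel_mass(at_xy, bw, window, cell_size_m)
        low = m < mass_floor
        if low.any():
            raise ValueError(
                "kernel mass below floor at "
                f"{int(low.sum())} locations: bandwidth far larger than window")
        return np.where(m > 1.0 - 1e-3, 1.0, m)

    if edge_corrected and pattern.n and correction == "per_point":
        w_i = 1.0 / _checked_mass(pattern.points)
        dens = _kernel_sum(pts_eval, pattern.points, bw.cov, weights=w_i)
    else:
        dens = _kernel_sum(pts_eval, pattern.points, bw.cov)
        if edge_corrected and pattern.n:
            dens = dens / _checked_mass(pts_eval)
    vals = np.full(ny * nx, np.nan)
    vals[sel] = dens * M2_PER_KM2
    surf.values = vals.reshape(ny, nx)
    return surf


# ---------------------------------------------------------------------------
# simple intensity


def simple_intensity(pattern: PointPattern, region: Polygon) -> float:
    """#{s_i ∈ A} / ν(A): point count per km² of the region.

    Points on the region boundary count as inside.
    """
    area_km2 = region.area / M2_PER_KM2
    if area_km2 <= 0:
        raise ValueError("region must have positive area")
    if pattern.n == 0:
        return 0.0
    inside = shapely.intersects_xy(region, pattern.points[:, 0],
                                   pattern.points[:, 1])
    return float(inside.sum()) / area_km2


# ---------------------------------------------------------------------------
# bandwidth selection


def bw_fixed(sigma_m: float = 500.0) -> Bandwidth:
    """Fixed isotropic bandwidth; the study default is σ_f = 500 m."""
    if sigma_m <= 0:
        raise ValueError("sigma_m must be positive")
    return Bandwidth("isotropic", sigma_m=float(sigma_m), provenance="fixed")


def default_sigma_grid(window: Window, cell_size_m: float = 25.0,
                       n_grid: int = 32) -> np.ndarray:
    """Geometric σ grid from the cell size up to a quarter window diameter."""
    xmin, ymin, xmax, ymax = window.bounds
    diam = math.hypot(xmax - xmin, ymax - ymin)
    return np.geomspace(cell_size_m, diam / 4.0, n_grid)


def mse_cv_criterion(pattern: PointPattern, sigma_m: float,
                     cell_size_m: float = 25.0) -> float:
    """Berman–Diggle style MSE criterion for one candidate σ.

    M(σ) = ∫_W λ̂_σ(s)² ds − 2 Σ_i λ̂_σ,−i(s_i), with λ̂ the uniform
    edge-corrected kernel intensity (1/m² scale internally), the integral a
    midpoint sum on the surface grid, and λ̂_−i the leave-one-out estimate at
    the data points. Minimizing M over σ minimizes the integrated squared
    error of λ̂ up to a constant.
    """
    bw = Bandwidth("isotropic", sigma_m=float(sigma_m), provenance="mse_cv")
    window = pattern.window
    pts = pattern.points
    surf = kernel_intensity_surface(pattern, bw, cell_size_m=cell_size_m)
    lam = np.nan_to_num(surf.values / M2_PER_KM2)
    integral = float((lam**2).sum() * cell_size_m**2)
    # leave-one-out values at the data points, with the same per-point
    # edge-correction weights the surface uses
    mass = kernel_mass(pts, bw, window, cell_size_m)
    mass = np.where(mass > 1.0 - 1e-3, 1.0, np.clip(mass, 1e-12, 1.0))
    w_i = 1.0 / mass
    dens_at_pts = _kernel_sum(pts, pts, bw.cov, weights=w_i)
    self_term = w_i / (2.0 * math.pi * sigma_m**2)
    loo = dens_at_pts - self_term
    return integral - 2.0 * float(loo.sum())


def bw_mse_cv(pattern: PointPattern, sigma_grid: Sequence[float] | None = None,
              cell_size_m: float = 25.0, n_grid: int = 32) -> CVResult:
    """Isotropic bandwidth by MSE cross-validation on a σ grid.

    Ties are broken toward the smaller σ (the grid is ascending and the
    first arg-min wins).
    """
    if pattern.n < 10:
        raise ValueError("MSE cross-validation needs at least 10 points")
    if sigma_grid is None:
        sigma_grid = default_sigma_grid(pattern.window, cell_size_m, n_grid)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if sigma_grid.size == 0:
        raise ValueError("empty sigma grid")
    vals = np.array([mse_cv_criterion(pattern, s, cell_size_m)
                     for s in sigma_grid])
    flat = bool(np.ptp(vals) < 1e-12)
    best = int(np.argmin(vals))
    bw = Bandwidth("isotropic", sigma_m=float(sigma_grid[best]),
                   provenance="mse_cv")
    return CVResult(bandwidth=bw, criterion_grid=list(sigma_grid),
                    criterion_values=vals, converged=not flat)


def _lscv_from_moments(sxx: np.ndarray, sxy: np.ndarray, syy: np.ndarray,
                       n: int, Sigma: np.ndarray) -> float:
    """LSCV(Σ) from precomputed pairwise displacement products (n² each).

    Both closed-form terms share one quadratic form: with q = dᵀΣ⁻¹d,
    φ_Σ(d) ∝ e^(−q/2) and φ_{2Σ}(d) ∝ e^(−q/4) = √(e^(−q/2)).
    """
    det = float(np.linalg.det(Sigma))
    if not math.isfinite(det) or det <= 0:
        return math.inf   # degenerate Σ: worst possible objective
    inv = np.linalg.inv(Sigma)
    a, b, c = inv[0, 0], inv[0, 1], inv[1, 1]
    q = a * sxx + 2.0 * b * sxy + c * syy
    E = np.exp(-0.5 * np.maximum(q, 0.0)).reshape(n, n)
    sqrtE = np.sqrt(E)
    term1 = sqrtE.sum() / (4.0 * math.pi * math.sqrt(det)) / n**2
    np.fill_diagonal(E, 0.0)
    term2 = 2.0 * E.sum() / (2.0 * math.pi * math.sqrt(det)) / (n * (n - 1))
    return float(term1 - term2)


def lscv_objective(pattern: PointPattern, Sigma: np.ndarray) -> float:
    """Least-squares CV objective LSCV(Σ) = ∫ f̂² − (2/n) Σ_i f̂_−i(s_i).

    Uses the closed form for Gaussian kernels: the convolution of two
    Gaussians with covariance Σ is a Gaussian with covariance 2Σ, so
    ∫ f̂² = n⁻² Σ_{i,j} φ_{2Σ}(s_i − s_j).
    """
    pts = pattern.points
    n = len(pts)
    dx = pts[:, None, 0] - pts[None, :, 0]
    dy = pts[:, None, 1] - pts[None, :, 1]
    return _lscv_from_moments((dx * dx).ravel(), (dx * dy).ravel(),
                              (dy * dy).ravel(), n, Sigma)


def _chol_to_sigma(theta: np.ndarray) -> np.ndarray:
    """Log-Cholesky parametrization: θ = (log l11, log l22, l21).

    The log entries are clipped to ±40 so a wandering optimizer cannot
    overflow the covariance into non-finite territory.
    """
    l11 = math.exp(min(max(theta[0], -40.0), 40.0))
    l22 = math.exp(min(max(theta[1], -40.0), 40.0))
    l21 = min(max(theta[2], -1e17), 1e17)
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


def bw_lscv_aniso(pattern: PointPattern, n_starts: int = 6,
                  pilot_sigma_m: float | None = None,
                  tie_tol: float = 0.02) -> CVResult:
    """Anisotropic bandwidth matrix by least-squares cross-validation.

    Minimizes LSCV(Σ) over SPD matrices through an unconstrained
    3-parameter log-Cholesky parametrization with Nelder–Mead from ≥ 5
    deterministic starts (isotropic pilot seed plus scaled / sheared
    variants). LSCV surfaces routinely carry several local minima whose
    objectives differ by well under a percent but whose shapes differ a
    lot; among converged minima within ``tie_tol`` (relative) of the best
    objective, the most-smoothing one (largest |Σ|) is selected — the
    standard guard against spurious small-bandwidth LSCV minima.
    """
    if pattern.n < 10:
        raise ValueError("LSCV needs at least 10 points")
    pts = pattern.points
    if pilot_sigma_m is None:
        # Silverman-style isotropic seed from the marginal SDs
        sd = float(np.sqrt(pts.var(axis=0, ddof=1).mean()))
        pilot_sigma_m = max(sd * pattern.n ** (-1.0 / 6.0), 1e-3)
    lp = math.log(pilot_sigma_m)
    l2 = math.log(2.0)
    starts = [np.array([lp, lp, 0.0]),
              np.array([lp - l2, lp - l2, 0.0]),
              np.array([lp + l2, lp + l2, 0.0]),
              np.array([lp + l2, lp - l2, 0.0]),
              np.array([lp - l2, lp + l2, 0.0]),
              np.array([lp, lp, 0.3 * pilot_sigma_m])]
    while len(starts) < n_starts:
        starts.append(starts[0] + 0.13 * len(starts))
    starts = starts[:max(n_starts, 5)]

    nn = len(pts)
    dx = pts[:, None, 0] - pts[None, :, 0]
    dy = pts[:, None, 1] - pts[None, :, 1]
    sxx, sxy, syy = (dx * dx).ravel(), (dx * dy).ravel(), (dy * dy).ravel()
    fun = lambda th: _lscv_from_moments(sxx, sxy, syy, nn, _chol_to_sigma(th))
    minima = []
    trace = []
    for theta0 in starts:
        # the objective lives on the 1/m² scale, so the f-tolerance must be
        # relative to its magnitude at the start
        fatol = max(abs(fun(theta0)) * 1e-9, 1e-300)
        res = optimize.minimize(
            fun, theta0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": fatol, "maxiter": 1000})
        trace.append({"start": theta0.tolist(), "fun": float(res.fun),
                      "success": bool(res.success)})
        if res.success:
            minima.append((float(res.fun), _chol_to_sigma(res.x)))
    values = np.array([t["fun"] for t in trace])
    if not minima:
        any_best = min(trace, key=lambda t: t["fun"])
        Sigma = _chol_to_sigma(np.asarray(any_best["start"]))
        bw = Bandwidth("anisotropic", Sigma=Sigma, provenance="lscv")
        return CVResult(bandwidth=bw, criterion_grid=[],
                        criterion_values=values, converged=False,
                        diagnostics={"trace": trace})
    best_fun = min(m[0] for m in minima)
    cands = [m for m in minima if m[0] <= best_fun + tie_tol * abs(best_fun)]
    # a kernel spread beyond half the window diameter is indistinguishable
    # from "no structure" and breaks edge correction — drop such plateau
    # minima from the tie-break when an alternative exists
    xmin, ymin, xmax, ymax = pattern.window.bounds
    half_diam = 0.5 * math.hypot(xmax - xmin, ymax - ymin)
    bounded = [m for m in cands
               if math.sqrt(float(np.linalg.eigvalsh(m[1]).max())) <= half_diam]
    if bounded:
        cands = bounded
    fun_sel, Sigma = max(cands, key=lambda m: float(np.linalg.det(m[1])))
    diagnostics = {"trace": trace, "objective": float(fun_sel),
                   "best_objective": float(best_fun)}
    sel_sd = np.sqrt(np.linalg.eigvalsh(Sigma))
    if sel_sd.max() > half_diam or sel_sd.min() < 1.0:
        # degenerate selection — the known LSCV failure mode on gridded or
        # strongly aligned point sets; fall back to the isotropic pilot
        Sigma = np.eye(2) * pilot_sigma_m**2
        diagnostics["degenerate_fallback"] = True
        bw = Bandwidth("anisotropic", Sigma=Sigma,
                       provenance="lscv(isotropic-pilot fallback)")
    else:
        bw = Bandwidth("anisotropic", Sigma=Sigma, provenance="lscv")
    return CVResult(bandwidth=bw, criterion_grid=[],
                    criterion_values=values, converged=True,
                    diagnostics=diagnostics)


def adaptive_scale(pilot: Bandwidth, R_A: float,
                   pilot_density: float = 2000.0,
                   min_density: float = 100.0) -> Bandwidth:
    """Residential-density-adaptive bandwidth σ̃ = (pilot_density / R_A) · σ.

    At the pilot density (2000 residents/km²) the bandwidth is unchanged;
    denser neighborhoods shrink it, sparser ones widen it. R_A is floored at
    ``min_density`` so near-empty neighborhoods cannot blow the bandwidth up
    without bound. Anisotropic pilots scale their covariance by the squared
    factor so the linear kernel spread scales like the isotropic case.
    """
    if R_A <= 0:
        raise ValueError("R_A must be positive")
    R = max(float(R_A), min_density)
    factor = pilot_density / R
    if abs(factor - 1.0) < 1e-12:   # exact pivot: adaptive equals parent
        factor = 1.0
    return pilot.scaled(factor, provenance=f"adaptive({pilot.provenance}, "
                                           f"{factor:.6g})")
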