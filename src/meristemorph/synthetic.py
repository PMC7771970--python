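"""Synthetic shoot apices with full ground truth.

Scenes emulate top-down confocal acquisitions of an Arabidopsis shoot apical
meristem: a spherical-cap dome ringed by a negative-Gaussian-curvature moat,
primordial bumps at golden-angle phyllotactic positions on the outer plateau,
a Lloyd-relaxed Voronoi epidermal tessellation with a controlled
within-meristem cell-area distribution, a cell-wall-stain volume and optional
reporter volumes.

Stage presets encode the doming effect sizes the pipeline must recover:
the domed preset's meristem area is 4.0× the vegetative one's, its cell
number 3.1× (within the three-to-fourfold doming range), and its median cell
area 1.8× (an 80% increase).  Those three ratios are the calibrated ground
truth; all absolute magnitudes are realistic choices for Arabidopsis and
carry no special meaning.

Everything is a pure function of (preset, seed): identical inputs yield
bit-identical scenes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy import ndimage

from .geometry import SurfaceMesh, heightmap_mesh
from .morphometrics import Primordium
from .segmentation import CellSegmentation, triangle_labels_from_vertices
from .volume import VolumeStack

__all__ = [
    "ApexPreset",
    "SyntheticScene",
    "PRESETS",
    "get_preset",
    "generate_apex_scene",
    "make_reporter_field",
    "REPORTER_PATTERNS",
]

REPORTER_PATTERNS = ("pz_patches", "abaxial_primordia", "uniform", "none")


class PrimordiumPlacementError(ValueError):
    """A primordial bump would overlap the summit; refuse to generate."""


@dataclass(frozen=True)
class ApexPreset:
    """Stage/genotype parameters of a synthetic apex.

    ``meristem_cap_area`` (µm²) is the nominal true meristem area — the
    surface area of the dome out to the circle where its Gaussian curvature
    changes sign; ``dome_radius`` is that circle's radius, derived from
    (cap area, dome height) so the three geometry fields cannot disagree.
    ``meristem_cell_count`` and ``median_cell_area`` fix the nominal cell
    number and median cell size inside the meristem region.
    """

    name: str
    dome_height: float                 # µm
    meristem_cap_area: float           # µm², nominal true meristem area
    meristem_cell_count: int           # nominal epidermal cells in the region
    median_cell_area: float            # µm², nominal within-region median
    cell_area_cv: float = 0.18         # multiplicative jitter of cell sizes
                                       # around the radial trend
    n_primordia: int = 2
    divergence_angle: float = 137.5    # degrees (golden angle)
    primordium_radius: float = 7.0     # µm, Gaussian sigma of youngest bump
    primordium_height: float = 5.0     # µm
    primordium_distance: float = 1.1   # bump-center clearance beyond the
                                       # moat, in units of the bump sigma
    noise_sd: float = 2.0              # intensity units, additive Gaussian
    voxel_xy: float = 0.5              # µm
    voxel_z: float = 0.4               # µm (acquisition z step)
    wall_amplitude: float = 100.0
    sheet_amplitude: float = 40.0

    def __post_init__(self):
        if self.dome_height <= 0 or self.meristem_cap_area <= 0:
            raise ValueError("dome_height and meristem_cap_area must be > 0")
        if self.median_cell_area <= 0 or self.meristem_cell_count < 4:
            raise ValueError("invalid cell-size/count parameters")
        if self.n_primordia < 0 or self.primordium_radius <= 0:
            raise ValueError("invalid primordium parameters")
        if self.voxel_xy <= 0 or self.voxel_z <= 0:
            raise ValueError("voxel sizes must be positive")
        if self.meristem_cap_area <= 1.1 * np.pi * self.dome_height ** 2:
            raise ValueError(
                "meristem_cap_area too small for dome_height: a spherical "
                "cap of area A has A = π(σ² + h²), so A must exceed πh²")

    @property
    def dome_radius(self) -> float:
        """Radius (µm) where the dome's Gaussian curvature changes sign."""
        return _DomeProfile.from_cap(self.meristem_cap_area,
                                     self.dome_height).sigma


@dataclass(frozen=True)
class _DomeProfile:
    """Radial height profile: spherical cap, moat, flat outer plateau.

    The cap (radius of curvature R, apex height h above the rim plane) has
    constant Gaussian curvature 1/R² for r < σ; at r = σ it joins, with
    continuous slope, a quadratic moat whose curvature is negative
    throughout (z' <= 0, z'' = const > 0); beyond the moat the surface is a
    flat plateau (K = 0).  The K sign change is therefore sharp and sits
    exactly at σ, and the cap's surface area is exactly π(σ² + h²).
    """

    sigma: float     # cap rim radius, µm
    h: float         # apex height above the rim plane
    R: float         # cap radius of curvature
    delta: float     # moat width, µm
    s0: float        # rim slope dz/dr at σ (negative)
    z_end: float     # plateau height relative to the rim plane (negative)

    @classmethod
    def from_cap(cls, cap_area: float, h: float) -> "_DomeProfile":
        sigma = float(np.sqrt(cap_area / np.pi - h * h))
        R = (sigma * sigma + h * h) / (2 * h)
        s0 = -sigma / (R - h)
        # moat width balancing |K| on both sides of the rim: the quadratic
        # moat has K(σ+) = s0·(−s0/Δ)/(σ(1+s0²)²); setting |K(σ+)| = 1/R²
        # keeps a radius-scale curvature estimator's zero crossing at σ
        # instead of letting a too-sharp moat bleed negative values inward
        delta = s0 * s0 * R * R / (sigma * (1 + s0 * s0) ** 2)
        delta = float(np.clip(delta, 5.0, 0.5 * sigma))
        return cls(sigma, h, R, delta, s0, s0 * delta / 2.0)

    def z(self, r):
        """Height above the plateau-free rim plane (apex at +h)."""
        r = np.asarray(r, dtype=float)
        cap = np.sqrt(np.maximum(self.R ** 2 - np.minimum(r, self.sigma) ** 2,
                                 0.0)) - (self.R - self.h)
        t = np.clip((r - self.sigma) / self.delta, 0.0, 1.0)
        moat = self.s0 * self.delta * (t - 0.5 * t * t)
        return np.where(r <= self.sigma, cap, moat)

    def dz(self, r):
        r = np.asarray(r, dtype=float)
        rc = np.minimum(r, self.sigma * (1 - 1e-12))
        cap = -rc / np.sqrt(np.maximum(self.R ** 2 - rc ** 2, 1e-12))
        t = np.clip((r - self.sigma) / self.delta, 0.0, 1.0)
        moat = self.s0 * (1.0 - t)
        return np.where(r <= self.sigma, cap, moat)

    @property
    def outer_radius(self) -> float:
        """Radius where the moat meets the flat plateau."""
        return self.sigma + self.delta


# target per-cell area as a function of radius inside the region ------------

@dataclass(frozen=True)
class _AreaProfile:
    """Radial target-cell-area profile a(r) inside the dome footprint.

    Two families share one container:

    * power ramp  g = t + (1−t)(r/σ)^p  — right-skewed distributions
      (many small central cells, median <= mean; vegetative-like stages);
    * smooth step g = t + (1−t)·S((r−r0)/w) — a compact small-cell central
      zone inside an enlarged periphery, which can place the median *above*
      the mean (the domed-stage phenotype).
    """

    a_edge: float
    t: float
    sigma: float
    p: float = 1.0
    r0: float = -1.0      # >=0 selects the step family
    w: float = 1.0

    def _g(self, r):
        if self.r0 >= 0:
            s = 0.5 * (1 + np.tanh((np.asarray(r, float) - self.r0) / self.w))
            return self.t + (1 - self.t) * s
        x = np.clip(np.asarray(r, float) / self.sigma, 0, 1)
        return self.t + (1 - self.t) * x ** self.p

    def __call__(self, r):
        return self.a_edge * self._g(r)


def _count_grid(dome: _DomeProfile, npts=4000):
    r = np.linspace(0, dome.sigma, npts)
    w = 2 * np.pi * r * np.hypot(1.0, dome.dz(r))  # surface measure
    w[0] = 0.0
    return r, w


_VORONOI_SPREAD = 0.12  # residual multiplicative size noise of the relaxed
                        # tessellation (log scale), on top of the seeded jitter


def _profile_median(prof: _AreaProfile, r, w, s: float):
    """Count-weighted median cell area predicted by a profile.

    The per-cell areas scatter multiplicatively (seeded lognormal jitter
    plus tessellation noise, combined log-sd ``s``) around the radial
    target, so the predicted median is that of the convolved mixture —
    deflated by e^(s²/2), because the cells must tile a fixed total area
    and the lognormal draws inflate the raw sum by that factor.
    """
    from scipy.stats import norm
    dcount = w / prof._g(r)
    dcount /= dcount.sum()
    la = np.log(prof(np.maximum(r, 1e-9)))
    if s < 1e-6:
        cum = np.cumsum(dcount)
        r_med = np.interp(0.5, cum, r)
        return float(prof(r_med))
    lo, hi = la.min() - 4 * s, la.max() + 4 * s

    def cdf(lx):
        return float(np.sum(dcount * norm.cdf((lx - la) / s)))

    raw = np.exp(brentq(lambda lx: cdf(lx) - 0.5, lo, hi, xtol=1e-8))
    return float(raw * np.exp(-0.5 * s * s))


def _solve_area_profile(cap_area, n_cells, median, dome: _DomeProfile,
                        cv: float = 0.0,
                        family: str | None = None) -> _AreaProfile:
    """Pick a radial profile so n_cells cells with the given median tile the cap.

    The cell count is enforced exactly by seeding; the profile shapes the
    radial gradient so the *median* lands on target.  The count condition
    ∫ dA/a = n fixes a_edge for any shape; the median condition is solved by
    root finding, first over the power family's t, then (for left-skewed
    targets) over the step family's transition radius.
    """
    r, w = _count_grid(dome)
    sigma = dome.sigma
    s = float(np.sqrt(np.log(1 + cv ** 2) + _VORONOI_SPREAD ** 2))

    def finish(t, p=1.0, r0=-1.0, ww=1.0):
        prof = _AreaProfile(1.0, t, sigma, p, r0, ww)
        C = np.trapezoid(w / prof._g(r), r)
        return _AreaProfile(C / n_cells, t, sigma, p, r0, ww)

    def try_power():
        best = None
        for p in (0.35, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.5, 6.0, 8.0):
            f = lambda t: _profile_median(finish(t, p=p), r, w, s) - median
            if f(1e-3) * f(0.999) > 0:
                continue
            t = brentq(f, 1e-3, 0.999, xtol=1e-6)
            prof = finish(t, p=p)
            if prof.a_edge * t < 2.0:       # tiny central cells: reject
                continue
            score = 1.0 / max(t, 1e-6)      # prefer the least extreme gradient
            if best is None or score < best[0]:
                best = (score, prof)
        return None if best is None else best[1]

    def try_step():
        # step family: small-cell core of size t inside an enlarged rim
        for t in (0.45, 0.35, 0.25, 0.18, 0.12, 0.08):
            for wf in (0.12, 0.08):
                ww = wf * sigma
                f = (lambda r0: _profile_median(
                    finish(t, r0=r0, ww=ww), r, w, s) - median)
                grid = np.linspace(0.05 * sigma, 0.9 * sigma, 40)
                vals = np.array([f(g) for g in grid])
                idx = np.where(np.diff(np.sign(vals)) != 0)[0]
                if len(idx) == 0:
                    continue
                r0 = brentq(f, grid[idx[0]], grid[idx[0] + 1], xtol=1e-6)
                prof = finish(t, r0=r0, ww=ww)
                if prof.a_edge * t >= 2.0:
                    return prof
        return None

    # a right-skewed target (median below the mean) belongs to the power
    # family, a left-skewed one to the step family; mixing them makes the
    # realized median respond discontinuously to the target
    mean_area = cap_area / n_cells
    if family is None:
        order = [try_power, try_step] if median <= mean_area \
            else [try_step, try_power]
    elif family == "power":
        order = [try_power]
    else:
        order = [try_step]
    for attempt in order:
        prof = attempt()
        if prof is not None:
            return prof
    raise ValueError(
        "no radial cell-size profile satisfies the preset's "
        "(area, count, median) combination")


# ---------------------------------------------------------------------------

PRESETS: dict[str, ApexPreset] = {
    # vegetative meristem (plants kept in short days)
    "vegetative": ApexPreset(
        name="vegetative", dome_height=12.0, meristem_cap_area=2500.0,
        meristem_cell_count=100, median_cell_area=19.0,
        n_primordia=2, primordium_radius=7.0, primordium_height=5.0),
    # domed transition meristem (~5 long days): 4.0× area, 3.1× cells,
    # 1.8× median cell area relative to vegetative — the recovery targets.
    # The enlarged periphery around a compact small-cell central zone makes
    # the size distribution left-skewed, so its jitter is kept tighter.
    "domed": ApexPreset(
        name="domed", dome_height=26.0, meristem_cap_area=10000.0,
        meristem_cell_count=310, median_cell_area=34.2, cell_area_cv=0.15,
        n_primordia=3, primordium_radius=8.0, primordium_height=8.0),
    # mature inflorescence meristem (~7 long days): smaller than domed,
    # cells back near vegetative size, more/closer primordia
    "inflorescence": ApexPreset(
        name="inflorescence", dome_height=22.0, meristem_cap_area=7000.0,
        meristem_cell_count=330, median_cell_area=19.5,
        n_primordia=4, primordium_radius=7.0, primordium_height=7.0,
        primordium_distance=0.9),
    # florigen-pathway mutant-like stage: lateral expansion without doming
    "ft_tsf_like": ApexPreset(
        name="ft_tsf_like", dome_height=14.0, meristem_cap_area=5000.0,
        meristem_cell_count=200, median_cell_area=21.0,
        n_primordia=2, primordium_radius=7.0, primordium_height=5.0),
    # narrow meristem at unchanged cell size (GA-depleted-like)
    "narrow_meristem": ApexPreset(
        name="narrow_meristem", dome_height=10.0, meristem_cap_area=1500.0,
        meristem_cell_count=60, median_cell_area=19.0,
        n_primordia=2, primordium_radius=6.0, primordium_height=4.0),
}


def get_preset(name: str) -> ApexPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


@dataclass
class SyntheticScene:
    """A generated apex with complete ground truth."""

    params: ApexPreset
    seed: int
    mesh: SurfaceMesh
    true_segmentation: CellSegmentation
    true_region: frozenset[int]
    true_central_cell: int
    true_primordia: list[Primordium]
    true_incipient: list[Primordium]
    wall_stack: VolumeStack
    reporter_stacks: dict[str, VolumeStack]
    sigma: float                      # dome footprint radius, µm
    z_floor: float
    center: tuple[float, float]       # apex axis position (x, y) µm
    zsurf: np.ndarray                 # (ny, nx) analytic surface heights
    cos_slope: np.ndarray             # (ny, nx) cos of surface tilt
    boundary_mask: np.ndarray         # (ny, nx) true cell-boundary pixels
    seeds_xy: np.ndarray              # (n_cells, 2) tessellation seeds
    reporter_footprints: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def grid_spacing(self) -> tuple[float, float]:
        return (self.params.voxel_xy, self.params.voxel_xy)

    def true_region_area(self) -> float:
        areas = self.true_segmentation.cell_areas(self.mesh)
        return float(sum(areas[c] for c in self.true_region))

    def true_median_cell_area(self) -> float:
        areas = self.true_segmentation.cell_areas(self.mesh)
        return float(np.median([areas[c] for c in self.true_region]))


def _primordium_plan(preset: ApexPreset, dome: _DomeProfile, phi0: float):
    """(azimuth_deg, center_radius, bump_sigma, bump_height) per primordium.

    P_1 (youngest, smallest) sits closest past the moat; older bumps are
    larger and farther out, each receding by the divergence angle.
    """
    plan = []
    for k in range(1, preset.n_primordia + 1):
        az = (phi0 - (k - 1) * preset.divergence_angle) % 360.0
        sb = preset.primordium_radius * (1 + 0.30 * (k - 1))
        hb = preset.primordium_height * (1 + 0.35 * (k - 1))
        rr = dome.outer_radius + (preset.primordium_distance
                                  + 0.15 * (k - 1)) * sb
        if rr <= 2.5 * sb:
            raise PrimordiumPlacementError(
                f"primordium {k} (sigma {sb:.1f} µm at radius {rr:.1f} µm) "
                "overlaps the summit")
        plan.append((az, rr, sb, hb))
    return plan


def _render_normal_band(zsurf, pairs, zax, dy, dx):
    """Render 2D weight maps into a volume along surface normals.

    For each voxel the *foot point* — the surface position whose inward
    normal passes through the voxel — is found to first order, and each
    ``(weight2d, (d_min, d_max))`` pair contributes ``weight2d`` at the foot
    point wherever the voxel's normal depth lies in the band.  This renders
    cell walls perpendicular to the surface (anticlinal), not vertical, so
    that band projection along normals recovers them without downhill bias.
    """
    from scipy.ndimage import map_coordinates
    ny, nx = zsurf.shape
    gy, gx = np.gradient(zsurf, dy, dx)
    c = 1.0 / np.sqrt(1.0 + gx * gx + gy * gy)
    iy, ix = np.mgrid[0:ny, 0:nx].astype(np.float64)
    out = np.zeros((len(zax), ny, nx), dtype=np.float32)
    for k, z in enumerate(zax):
        t0 = (zsurf - z) * c
        sy = iy - t0 * c * gy / dy
        sx = ix - t0 * c * gx / dx
        coords = np.stack([sy.ravel(), sx.ravel()])
        zs = map_coordinates(zsurf, coords, order=1,
                             mode="nearest").reshape(ny, nx)
        cs = map_coordinates(c, coords, order=1,
                             mode="nearest").reshape(ny, nx)
        t = (zs - z) * cs
        sl = np.zeros((ny, nx), dtype=np.float32)
        for w2d, (lo, hi) in pairs:
            ws = map_coordinates(w2d, coords, order=1,
                                 mode="nearest").reshape(ny, nx)
            sl += (ws * ((t >= lo) & (t <= hi))).astype(np.float32)
        out[k] = sl
    return out


def _dart_throw(rng, n_target, sample_xy, area_at, max_rounds=300,
                spacing=0.60):
    """Blue-noise seed placement: accept candidates no closer to any
    accepted seed than ``spacing``·sqrt(mean local target area)."""
    accepted = np.empty((0, 2))
    targets = np.empty(0)
    eps = spacing
    rounds = 0
    while len(accepted) < n_target and rounds < max_rounds:
        rounds += 1
        cand = sample_xy(256)
        a_c = area_at(cand)
        for (x, y), a in zip(cand, a_c):
            if len(accepted) >= n_target:
                break
            if len(accepted):
                d2 = (accepted[:, 0] - x) ** 2 + (accepted[:, 1] - y) ** 2
                dmin2 = (eps ** 2) * 0.5 * (targets + a)
                if (d2 < dmin2).any():
                    continue
            accepted = np.vstack([accepted, (x, y)])
            targets = np.append(targets, a)
        if rounds % 40 == 0:
            eps *= 0.92   # relax spacing if saturated
    if len(accepted) < n_target:
        raise RuntimeError("seed placement saturated; preset too dense")
    return accepted


def generate_apex_scene(preset: ApexPreset | str, seed: int,
                        reporters: tuple[str, ...] = ()) -> SyntheticScene:
    """Generate a synthetic apex scene (pure function of its arguments).

    The dome is a spherical cap (constant Gaussian curvature 1/R²) joined at
    its rim circle r = σ to a negative-curvature moat and a flat plateau, so
    the K sign change is sharp and encloses exactly ``meristem_cap_area`` of
    surface; bumps are added at golden-angle positions on the plateau with
    ages increasing with azimuthal recession.  Exactly
    ``meristem_cell_count`` tessellation seeds are placed inside the σ-disc
    — those cells are the ground-truth meristem region — with a radial
    cell-size gradient solved so the region's median cell area matches
    ``median_cell_area``.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    if seed < 0:
        raise ValueError("seed must be >= 0")
    dome = _DomeProfile.from_cap(preset.meristem_cap_area,
                                 preset.dome_height)
    sigma = dome.sigma
    rng = np.random.default_rng([int(seed), 987654321])
    phi0 = float(rng.uniform(0, 360))
    plan = _primordium_plan(preset, dome, phi0)

    dx = dy = preset.voxel_xy
    dz = preset.voxel_z
    # deep enough that a 10 µm normal band below the moat floor stays inside
    z_floor = 12.0 - dome.z_end
    if plan:
        L = max(rr + 1.2 * sb for _, rr, sb, _ in plan) + 4.0
    else:
        L = dome.outer_radius + 8.0
    nx = ny = int(2 * np.ceil(L / dx)) + 1
    cx = cy = (nx - 1) / 2.0 * dx

    xs = np.arange(nx) * dx - cx
    ys = np.arange(ny) * dy - cy
    X, Y = np.meshgrid(xs, ys)

    def surf_rel(xr, yr):
        z = dome.z(np.hypot(xr, yr))
        for az, rr, sb, hb in plan:
            bx = rr * np.cos(np.radians(az))
            by = rr * np.sin(np.radians(az))
            z = z + hb * np.exp(-((xr - bx) ** 2 + (yr - by) ** 2)
                                / (2 * sb ** 2))
        return z

    zrel = surf_rel(X, Y)
    zsurf = zrel + z_floor
    mesh = heightmap_mesh(zsurf, dy, dx)
    vert_areas = mesh.vertex_areas

    gyr, gxr = np.gradient(zrel, dy, dx)
    cos_slope = 1.0 / np.sqrt(1.0 + gxr ** 2 + gyr ** 2)
    metric = 1.0 / cos_slope

    # --- tessellation seeds ------------------------------------------------
    n_in = preset.meristem_cell_count
    median_target = preset.median_cell_area

    from scipy.spatial import cKDTree

    def build_tessellation(profile: _AreaProfile, m_out: float):
        """One tessellation pass.

        ``m_out`` is the radius offset of an explicit ring of outside seeds
        at r = σ + m_out; the rim cell walls then fall halfway between that
        ring and the clamped region rim, which the calibration loop uses to
        pin the ground-truth region area onto the curvature footprint.

        Every pass re-seeds its own RNG identically, so successive passes
        differ only through the profile/ring parameters; that makes the
        measured area and median respond smoothly to the calibration loop
        instead of bouncing with fresh placement noise.
        """
        rng = np.random.default_rng([int(seed), 777000111])
        rgrid = np.linspace(0, sigma, 2000)
        w = 2 * np.pi * rgrid * np.hypot(1.0, dome.dz(rgrid)) / profile(rgrid)
        cdf = np.cumsum(w)
        cdf /= cdf[-1]
        jitter_sd = np.sqrt(np.log(1 + preset.cell_area_cv ** 2))
        a_out = float(profile(sigma))
        spacing_out = np.sqrt(a_out)
        m_rim = float(np.hypot(1.0, dome.s0))
        spacing_rim = np.sqrt(a_out / m_rim)   # 2D row spacing on the rim
        margin = 0.35 * spacing_rim

        # the outermost cells extend to σ but their *seeds* must sit about
        # half a cell inside it; compress the rim band of the radial CDF so
        # seeds are not piled onto the clamp circle (piled seeds make sliver
        # cells that a watershed's minimum-area merge would erase)
        r_squash_lo = sigma - 1.5 * spacing_rim
        r_squash_hi = sigma - 0.55 * spacing_rim

        def sample_region(m):
            r = np.interp(rng.uniform(0, 1, m), cdf, rgrid)
            hi_band = r > r_squash_lo
            r = np.where(
                hi_band,
                r_squash_lo + (r - r_squash_lo)
                * (r_squash_hi - r_squash_lo)
                / max(sigma - r_squash_lo, 1e-9),
                r)
            t = rng.uniform(0, 2 * np.pi, m)
            return np.column_stack([r * np.cos(t), r * np.sin(t)])

        def area_region(p):
            # dart spacing works in the flat 2D plane, but cell areas live on
            # the surface: dividing the target by the metric lets seed rows
            # pack radially tighter on the steep rim, where one surface cell
            # projects to a compressed 2D footprint
            r = np.hypot(p[:, 0], p[:, 1])
            m = np.hypot(1.0, dome.dz(r))
            return profile(r) / m * np.exp(rng.normal(0, jitter_sd, len(r)))

        seeds_in = _dart_throw(rng, n_in, sample_region, area_region)

        # explicit first ring of outside seeds at σ + m_out
        r_ring = sigma + m_out
        spacing_ring = np.sqrt(a_out / float(np.hypot(1.0, dome.dz(r_ring))))
        n_ring = max(int(round(2 * np.pi * r_ring / spacing_ring)), 6)
        ang = (rng.uniform(0, 2 * np.pi)
               + 2 * np.pi * np.arange(n_ring) / n_ring
               + rng.normal(0, 0.05, n_ring))
        ring = np.column_stack([r_ring * np.cos(ang), r_ring * np.sin(ang)])

        # far field: uniform surface density at the rim cell size
        r_far = r_ring + 0.95 * spacing_out
        rpix = np.hypot(X, Y)
        pm = np.where(rpix > r_far, metric, 0.0).ravel()
        pcum = np.cumsum(pm)
        n_far = int(round(pm.sum() * dx * dy / a_out))

        def sample_far(m):
            u = rng.uniform(0, pcum[-1], m)
            idx = np.searchsorted(pcum, u)
            iy, ix = np.unravel_index(np.minimum(idx, len(pm) - 1), (ny, nx))
            jx = rng.uniform(-0.5, 0.5, m) * dx
            jy = rng.uniform(-0.5, 0.5, m) * dy
            return np.column_stack([xs[ix] + jx, ys[iy] + jy])

        def area_far(p):
            ix = np.clip(np.round((p[:, 0] + cx) / dx).astype(int), 0, nx - 1)
            iy = np.clip(np.round((p[:, 1] + cy) / dy).astype(int), 0, ny - 1)
            m = metric[iy, ix]
            return a_out / m * np.exp(rng.normal(0, jitter_sd, len(p)))

        far = _dart_throw(rng, n_far, sample_far, area_far)
        seeds = np.vstack([seeds_in, ring, far])
        out_lo = sigma + min(0.6 * m_out, margin)   # outside clamp radius
        ring_slice = slice(n_in, n_in + n_ring)

        # Density-weighted Lloyd relaxation (3 iterations).  Plain centroidal
        # relaxation drifts toward uniform cell sizes; weighting vertices by
        # 1/a(r)² (the 2D quantizer density whose CVT has cell size ∝ a)
        # preserves the prescribed radial size gradient.  Radial clamps keep
        # region seeds inside the footprint and foreign seeds outside, and the
        # explicit first outside ring is pinned at its radius, so the rim cell
        # walls align with the curvature moat.
        verts = mesh.vertices
        vx = verts[:, 0] - cx
        vy = verts[:, 1] - cy
        vq = np.column_stack([vx, vy, verts[:, 2] - z_floor])
        rv = np.hypot(vx, vy)
        a_v = np.where(rv <= sigma, profile(rv), a_out)
        lloyd_w = vert_areas / a_v ** 2
        for _ in range(3):
            pts3 = np.column_stack([
                seeds[:, 0], seeds[:, 1],
                surf_rel(seeds[:, 0], seeds[:, 1])])
            lab = cKDTree(pts3).query(vq)[1]
            wsum = np.bincount(lab, weights=lloyd_w, minlength=len(seeds))
            sx = np.bincount(lab, weights=lloyd_w * vx, minlength=len(seeds))
            sy = np.bincount(lab, weights=lloyd_w * vy, minlength=len(seeds))
            nz_mask = wsum > 0
            seeds[nz_mask, 0] = sx[nz_mask] / wsum[nz_mask]
            seeds[nz_mask, 1] = sy[nz_mask] / wsum[nz_mask]
            r = np.hypot(seeds[:, 0], seeds[:, 1])
            rin = np.minimum(r[:n_in], sigma - margin)
            rout = np.maximum(r[n_in:], out_lo)
            scale_in = np.where(r[:n_in] > 0,
                                rin / np.maximum(r[:n_in], 1e-9), 1.0)
            scale_out = rout / np.maximum(r[n_in:], 1e-9)
            seeds[:n_in] *= scale_in[:, None]
            seeds[n_in:] *= scale_out[:, None]
            # the calibration ring stays at its exact radius
            r_now = np.hypot(seeds[ring_slice, 0], seeds[ring_slice, 1])
            seeds[ring_slice] *= (r_ring / np.maximum(r_now, 1e-9))[:, None]
            np.clip(seeds[:, 0], xs[1], xs[-2], out=seeds[:, 0])
            np.clip(seeds[:, 1], ys[1], ys[-2], out=seeds[:, 1])

        pts3 = np.column_stack([seeds[:, 0], seeds[:, 1],
                                surf_rel(seeds[:, 0], seeds[:, 1])])
        vlab = cKDTree(pts3).query(vq)[1] + 1
        return seeds, np.asarray(vlab, dtype=np.int64)

    def measure(seg_):
        areas_ = seg_.cell_areas(mesh)
        reg = [areas_[c] for c in range(1, n_in + 1) if c in areas_]
        return float(np.sum(reg)), float(np.median(reg))

    # calibration loop (deterministic, <=3 passes): the ring offset pins the
    # measured region area on the nominal cap area, and the median target is
    # corrected for the residual tessellation bias
    a_nom = preset.meristem_cap_area
    rim_metric = float(np.hypot(1.0, dome.s0))
    target = median_target
    profile = _solve_area_profile(a_nom, n_in, target, dome,
                                  cv=preset.cell_area_cv)
    m_out = 0.35 * np.sqrt(float(profile(sigma)))
    seeds = vlab = seg = None
    for _pass in range(6):
        seeds, vlab = build_tessellation(profile, m_out)
        tri = triangle_labels_from_vertices(mesh.faces, vlab)
        seg = CellSegmentation(tri, vlab)
        a_meas, med_meas = measure(seg)
        area_err = a_meas / a_nom - 1.0
        med_err = med_meas / median_target - 1.0
        if abs(area_err) <= 0.015 and abs(med_err) <= 0.03:
            break
        # boundary offset implied by the area error, halved per Voronoi midpoint
        shift = (a_meas - a_nom) / (2 * np.pi * sigma * rim_metric)
        m_out = float(np.clip(m_out - 2.0 * shift,
                              0.1, 3.0 * np.sqrt(float(profile(sigma)))))
        if med_meas > 0:
            # damped multiplicative correction, re-solved within the same
            # profile family (switching families mid-loop makes the median
            # response discontinuous and the loop oscillate)
            adj = float(np.clip(
                target * (median_target / med_meas) ** 0.8,
                0.3 * median_target, 3.0 * median_target))
            fam = "step" if profile.r0 >= 0 else "power"
            for adj_try in (adj, 0.5 * (adj + target)):
                try:
                    profile = _solve_area_profile(a_nom, n_in, adj_try, dome,
                                                  cv=preset.cell_area_cv,
                                                  family=fam)
                    target = adj_try
                    break
                except ValueError:
                    continue  # infeasible; keep the current profile

    true_region = frozenset(range(1, n_in + 1))
    central = int(vlab[np.argmax(mesh.vertices[:, 2])])
    if central not in true_region:
        # summit vertex fell into a non-region cell (should not happen for
        # sane presets); take the region seed nearest the axis instead
        central = int(1 + np.argmin(np.hypot(seeds[:n_in, 0],
                                             seeds[:n_in, 1])))

    # --- true primordium / incipient catalogues ---------------------------
    prims = []
    for k, (az, rr, sb, hb) in enumerate(plan, start=1):
        bx, by = rr * np.cos(np.radians(az)), rr * np.sin(np.radians(az))
        prims.append(Primordium(
            id=f"P_{k}",
            centroid=np.array([bx + cx, by + cy,
                               float(surf_rel(bx, by)) + z_floor]),
            azimuth=az, age_rank=k))
    incip = []
    for nft in (1, 2):
        az = (phi0 + nft * preset.divergence_angle) % 360.0
        bx, by = sigma * np.cos(np.radians(az)), sigma * np.sin(np.radians(az))
        incip.append(Primordium(
            id=f"i_{nft}",
            centroid=np.array([bx + cx, by + cy,
                               float(surf_rel(bx, by)) + z_floor]),
            azimuth=az, age_rank=-nft))

    # --- wall-stain volume -------------------------------------------------
    lab_img = vlab.reshape(ny, nx)
    boundary = np.zeros((ny, nx), dtype=bool)
    boundary[:, 1:] |= lab_img[:, 1:] != lab_img[:, :-1]
    boundary[1:, :] |= lab_img[1:, :] != lab_img[:-1, :]
    d_b = ndimage.distance_transform_edt(~boundary, sampling=(dy, dx))

    nzv = int(np.ceil((zsurf.max() + 1.2) / dz)) + 1
    zax = np.arange(nzv) * dz
    wall2d = preset.wall_amplitude * np.exp(-d_b ** 2 / (2 * 0.5 ** 2))
    sheet2d = np.full_like(wall2d, preset.sheet_amplitude)
    vol = _render_normal_band(
        zsurf, [(sheet2d, (0.0, 1.0)), (wall2d, (0.0, 4.0))], zax, dy, dx)
    if preset.noise_sd > 0:
        vol = vol + rng.normal(0, preset.noise_sd, vol.shape).astype(np.float32)
    wall_stack = VolumeStack(vol, (dz, dy, dx))

    scene = SyntheticScene(
        params=preset, seed=int(seed), mesh=mesh, true_segmentation=seg,
        true_region=true_region, true_central_cell=central,
        true_primordia=prims, true_incipient=incip,
        wall_stack=wall_stack, reporter_stacks={},
        sigma=float(sigma), z_floor=z_floor, center=(cx, cy),
        zsurf=zsurf, cos_slope=cos_slope, boundary_mask=boundary,
        seeds_xy=seeds + np.array([cx, cy]),
    )
    for name in reporters:
        scene.reporter_stacks[name] = make_reporter_field(scene, name)
    return scene


def make_reporter_field(
    scene: SyntheticScene,
    pattern: str,
    band: tuple[float, float] = (2.0, 10.0),
    amplitude: float = 100.0,
    noise_sd: float | None = None,
) -> VolumeStack:
    """Render a reporter-expression volume for a scene.

    The signal's support is a depth band below the surface (measured along
    the surface normal, default 2–10 µm).  Patterns: ``pz_patches`` (patches
    at the incipient-primordium positions on the meristem flank, like a
    GA-biosynthesis reporter), ``abaxial_primordia`` (domains on the outer
    flank of each primordium, like a GA-catabolism reporter), ``uniform``,
    and ``none`` (all-zero, no noise).
    """
    if pattern not in REPORTER_PATTERNS:
        raise ValueError(
            f"unknown reporter pattern {pattern!r}; "
            f"choose from {REPORTER_PATTERNS}")
    preset = scene.params
    dz, dy, dx = scene.wall_stack.voxel_size
    nzv, ny, nx = scene.wall_stack.shape
    if noise_sd is None:
        noise_sd = preset.noise_sd
    if pattern == "none":
        return VolumeStack(
            np.zeros((nzv, ny, nx), dtype=np.float32), (dz, dy, dx))

    cx, cy = scene.center
    xs = np.arange(nx) * dx - cx
    ys = np.arange(ny) * dy - cy
    X, Y = np.meshgrid(xs, ys)

    if pattern == "uniform":
        w2d = np.ones((ny, nx), dtype=np.float32)
        footprint = np.ones((ny, nx), dtype=bool)
    elif pattern == "pz_patches":
        w2d = np.zeros((ny, nx), dtype=np.float32)
        footprint = np.zeros((ny, nx), dtype=bool)
        sp = 0.5 * preset.primordium_radius
        for p in scene.true_incipient:
            bx, by = p.centroid[0] - cx, p.centroid[1] - cy
            d2 = (X - bx) ** 2 + (Y - by) ** 2
            w2d += np.exp(-d2 / (2 * sp ** 2)).astype(np.float32)
            footprint |= d2 <= (2 * sp) ** 2
    else:  # abaxial_primordia
        w2d = np.zeros((ny, nx), dtype=np.float32)
        footprint = np.zeros((ny, nx), dtype=bool)
        for p in scene.true_primordia:
            az = np.radians(p.azimuth)
            rr = np.hypot(p.centroid[0] - cx, p.centroid[1] - cy)
            sb = preset.primordium_radius
            bx = (rr + 0.8 * sb) * np.cos(az)
            by = (rr + 0.8 * sb) * np.sin(az)
            d2 = (X - bx) ** 2 + (Y - by) ** 2
            w2d += np.exp(-d2 / (2 * (0.8 * sb) ** 2)).astype(np.float32)
            footprint |= d2 <= (1.6 * sb) ** 2

    zax = np.arange(nzv) * dz
    vol = amplitude * _render_normal_band(
        scene.zsurf, [(w2d.astype(np.float64), tuple(band))], zax, dy, dx)
    # ground-truth support volume (same foot-point geometry as the signal)
    foot_vol = _render_normal_band(
        scene.zsurf, [(footprint.astype(np.float64), tuple(band))],
        zax, dy, dx) >= 0.5
    if noise_sd and noise_sd > 0:
        rng = np.random.default_rng(
            [scene.seed, 271828, REPORTER_PATTERNS.index(pattern)])
        vol = vol + rng.normal(0, noise_sd, vol.shape).astype(np.float32)
    scene.reporter_footprints[pattern] = foot_vol
    return VolumeStack(vol, (dz, dy, dx))
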