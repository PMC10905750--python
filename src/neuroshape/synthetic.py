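"""Synthetic neuromast rosettes with known ground truth.

A neuromast is a rosette of radially arranged epithelial cells: central
flask-shaped hair cells (HC) whose bodies sit apically, surrounded by
taller columnar support cells (SC) that lean inward as the rosette
converges at its apical center.  This module generates 3D multichannel
volumes of such rosettes — membrane and nuclear channels, marker
channels, boundary/nucleus probability maps standing in for trained
model inference — together with voxel-level ground-truth labels and a
per-cell truth table, so that every downstream analysis stage can be
exercised and scored without any imaging data.

Two parametric shape families are used.  HC-like cells are solids of
revolution with a beta-function radius profile (wide basal body,
narrow apical neck; the widest cross-section lies below mid-height).
SC-like cells are tapered elliptical columns with an apical inward
lean; a "concave" variant adds a strong sideways bow that makes the
cell crescent-shaped and therefore *not* star-shaped about its
centroid — these cells exercise the reconstruction-error QC downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage
from skimage.segmentation import find_boundaries

from .core import LabeledVolume, wrap_angle_deg

__all__ = [
    "MarkerSpec",
    "SynthConfig",
    "GroundTruth",
    "PlacementError",
    "GenerationError",
    "HC_FACTORS",
    "SC_FACTORS",
    "SC_CONCAVE_FACTORS",
    "make_cell_shape",
    "generate_neuromast",
]

GOLDEN_ANGLE_DEG = 137.50776405003785


class PlacementError(ValueError):
    """Raised when the requested cells cannot be placed without overlap."""


class GenerationError(RuntimeError):
    """Raised when a parametric mesh fails its closure checks."""


@dataclass(frozen=True)
class MarkerSpec:
    """One fluorescent reporter: who expresses it and where it localizes.

    ``population`` selects the truth-positive cells: ``central`` (HC-like),
    ``dorsoventral`` (DV-subtype SCs) or ``peripheral`` (outer-ring SCs).
    ``offset_sd`` is the s.d. of a per-organ multiplicative brightness
    offset, emulating organ-to-organ reporter intensity variation.
    """

    name: str
    population: str
    localization: str
    offset_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.population not in ("central", "dorsoventral", "peripheral"):
            raise ValueError(f"unknown population {self.population!r}")
        if self.localization not in ("nuclear", "cytoplasmic"):
            raise ValueError(f"unknown localization {self.localization!r}")


DEFAULT_MARKERS = (
    MarkerSpec("dv_nls", "dorsoventral", "nuclear", 0.2),
    MarkerSpec("periph_nls", "peripheral", "nuclear", 0.2),
    MarkerSpec("central_cyto", "central", "cytoplasmic", 0.2),
)


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic rosette.

    Defaults describe the emulated tissue: ~23% hair cells, 16% of cells
    strongly concave, anisotropic voxels of 0.22 x 0.05 x 0.05 um (z, y,
    x) and a ~20 um organ radius.  ``noise_sd`` is additive Gaussian
    noise on the unit intensity scale of every channel.
    """

    n_cells: int = 40
    hc_fraction: float = 0.23
    polarity: str = "parallel"
    organ_radius_um: float = 20.0
    voxel_size_um: tuple[float, float, float] = (0.22, 0.05, 0.05)
    noise_sd: float = 0.05
    marker_spec: tuple[MarkerSpec, ...] = DEFAULT_MARKERS
    concave_fraction: float = 0.16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.hc_fraction <= 1.0:
            raise ValueError("hc_fraction must be in [0, 1]")
        if not 0.0 <= self.concave_fraction <= 1.0:
            raise ValueError("concave_fraction must be in [0, 1]")
        if self.hc_fraction + self.concave_fraction > 1.0 + 1e-12:
            raise ValueError("hc_fraction + concave_fraction must be <= 1")
        if self.polarity not in ("parallel", "perpendicular"):
            raise ValueError("polarity must be 'parallel' or 'perpendicular'")
        if self.organ_radius_um <= 0:
            raise ValueError("organ_radius_um must be positive")
        vz, vy, vx = self.voxel_size_um
        if min(vz, vy, vx) <= 0:
            raise ValueError("voxel sizes must be positive")
        if vz < max(vy, vx) - 1e-12:
            raise ValueError("voxel z-spacing must be >= xy-spacing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Volumes plus per-cell truth for one generated rosette."""

    cell_labels: LabeledVolume
    nucleus_labels: LabeledVolume
    truth_table: pd.DataFrame
    channels: dict[str, np.ndarray]
    probability_maps: dict[str, np.ndarray]
    config: SynthConfig
    organ_index: int = 0


# Family-mean shape factors, micrometres.  HC: solid of revolution with a
# beta radius profile peaking at alpha/(alpha+beta) of the height; SC:
# tapered elliptical column.  ``bow_um`` is a sideways (azimuthal)
# mid-height bow; ``lean_um`` an apical inward lean.
HC_FACTORS = {"height": 11.0, "body_radius": 2.0, "neck_ratio": 0.55, "aspect": 1.0}
SC_FACTORS = {"height": 19.0, "radius": 1.7, "taper": 0.75, "bow_um": 0.5, "lean_um": 1.4}
SC_CONCAVE_FACTORS = {
    "height": 19.0,
    "radius": 1.7,
    "taper": 0.80,
    "bow_um": 3.6,
    "lean_um": 1.4,
}

_HC_ALPHA, _HC_BETA = 1.2, 2.2  # beta-profile exponents; peak at ~0.35 height

_FACTOR_RANGES = {
    "height": (4.0, 40.0),
    "body_radius": (0.8, 8.0),
    "neck_ratio": (0.2, 0.95),
    "aspect": (0.5, 2.0),
    "radius": (0.8, 8.0),
    "taper": (0.3, 1.2),
    "bow_um": (0.0, 5.0),
    "lean_um": (0.0, 5.0),
}


def _check_factors(factors: dict) -> None:
    for k, v in factors.items():
        lo, hi = _FACTOR_RANGES[k]
        if not lo <= v <= hi:
            raise ValueError(f"shape factor {k}={v} outside [{lo}, {hi}]")


def _profile(cell_type: str, factors: dict):
    """Return (height, fn) where fn(t) -> (a, b, cx, cy) for t in [0, 1].

    ``a``/``b`` are the elliptical cross-section semi-axes and
    ``(cx, cy)`` the in-plane centre offset of the section at
    normalized height ``t`` (0 = basal, 1 = apical).
    """
    _check_factors(factors)
    if cell_type == "HC":
        h = factors["height"]
        rb, nr, asp = factors["body_radius"], factors["neck_ratio"], factors["aspect"]
        tpk = _HC_ALPHA / (_HC_ALPHA + _HC_BETA)
        peak = tpk**_HC_ALPHA * (1 - tpk) ** _HC_BETA

        def fn(t):
            t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
            g = t**_HC_ALPHA * (1.0 - t) ** _HC_BETA / peak
            # ellipsoidal end-rounding keeps the surface smooth at the poles
            e = np.sqrt(np.clip(4.0 * t * (1.0 - t), 0.0, 1.0))
            rho = rb * (nr + (1.0 - nr) * g) * e
            z = np.zeros_like(rho)
            return rho, asp * rho, z, z

        return h, fn
    if cell_type in ("SC", "SC-concave"):
        h = factors["height"]
        r, taper = factors["radius"], factors["taper"]
        bow, lean = factors["bow_um"], factors["lean_um"]

        def fn(t):
            t = np.clip(np.asarray(t, dtype=float), 0.0, 1.0)
            # superelliptical rounding: near-cylindrical wall, rounded ends
            e = np.sqrt(np.clip(1.0 - np.abs(1.0 - 2.0 * t) ** 4, 0.0, 1.0))
            rho = r * (1.0 + (taper - 1.0) * t) * e
            cx = lean * t  # apical lean along local +x (inward when placed)
            cy = bow * 4.0 * t * (1.0 - t)  # sideways mid-height bow
            return rho, rho, cx, cy

        return h, fn
    raise ValueError(f"unknown cell type {cell_type!r}")


def make_cell_shape(
    cell_type: str,
    shape_factors: dict | None = None,
    mesh_resolution: int = 48,
) -> trimesh.Trimesh:
    """Build a closed triangulated surface for one cell.

    ``cell_type`` is ``"HC"``, ``"SC"`` or ``"SC-concave"``;
    ``shape_factors`` defaults to the family mean.  ``mesh_resolution``
    sets the azimuthal vertex count (and the number of height levels).
    The HC family is star-shaped about its centroid; the concave SC
    variant is crescent-like and deliberately is not.
    """
    if shape_factors is None:
        shape_factors = {
            "HC": HC_FACTORS,
            "SC": SC_FACTORS,
            "SC-concave": SC_CONCAVE_FACTORS,
        }[cell_type]
    if mesh_resolution < 8:
        raise ValueError("mesh_resolution must be >= 8")
    h, fn = _profile(cell_type, shape_factors)
    n_lev = mesh_resolution + 1
    n_az = mesh_resolution
    # cosine spacing packs rings near the rounded ends; the exact poles
    # collapse to the apex vertices
    j = np.arange(1, n_lev + 1)
    t = (1.0 - np.cos(np.pi * j / (n_lev + 1))) / 2.0
    a, b, cx, cy = fn(t)
    psi = 2.0 * np.pi * np.arange(n_az) / n_az
    cos_p, sin_p = np.cos(psi), np.sin(psi)

    verts = np.empty((n_lev * n_az + 2, 3))
    for j in range(n_lev):
        base = j * n_az
        verts[base : base + n_az, 0] = cx[j] + a[j] * cos_p
        verts[base : base + n_az, 1] = cy[j] + b[j] * sin_p
        verts[base : base + n_az, 2] = t[j] * h
    i_bot = n_lev * n_az
    i_top = i_bot + 1
    _, _, cx0, cy0 = fn(0.0)
    _, _, cx1, cy1 = fn(1.0)
    verts[i_bot] = (float(cx0), float(cy0), 0.0)
    verts[i_top] = (float(cx1), float(cy1), h)

    faces = []
    for j in range(n_lev - 1):
        for k in range(n_az):
            k1 = (k + 1) % n_az
            v00, v01 = j * n_az + k, j * n_az + k1
            v10, v11 = (j + 1) * n_az + k, (j + 1) * n_az + k1
            faces.append((v00, v11, v10))
            faces.append((v00, v01, v11))
    for k in range(n_az):
        k1 = (k + 1) % n_az
        faces.append((i_bot, k1, k))
        faces.append((i_top, (n_lev - 1) * n_az + k, (n_lev - 1) * n_az + k1))

    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    if not mesh.is_watertight:
        raise GenerationError(
            f"generated {cell_type} mesh is not watertight "
            f"(resolution {mesh_resolution})"
        )
    return mesh


# ---------------------------------------------------------------------------
# placement


def _sunflower(n: int, r_disk: float) -> np.ndarray:
    """Deterministic phyllotaxis layout of n points in a disk (xy)."""
    i = np.arange(n)
    r = r_disk * np.sqrt((i + 0.5) / n)
    th = np.radians(GOLDEN_ANGLE_DEG) * i
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


@dataclass
class _PlacedCell:
    label: int
    cell_type: str  # HC | SC | SC-concave
    subtype: str  # DV | peripheral | other
    xy: np.ndarray  # basal-axis position, um
    angle_deg: float  # position angle about the organ centre
    phi_local_deg: float  # rotation of the local frame about z
    base_z: float
    factors: dict


def _layout(config: SynthConfig, rng: np.random.Generator) -> list[_PlacedCell]:
    n = config.n_cells
    n_hc = int(round(n * config.hc_fraction))
    n_sc = n - n_hc
    n_concave = min(int(round(n * config.concave_fraction)), n_sc)

    hc_r = HC_FACTORS["body_radius"]
    sc_r = SC_FACTORS["radius"]
    lean = SC_FACTORS["lean_um"]
    bow_c = SC_CONCAVE_FACTORS["bow_um"]

    # central HC disk sized for ~2-radius spacing under phyllotaxis
    spacing_hc = 2.0 * hc_r * 1.05
    r_disk = spacing_hc * math.sqrt(max(n_hc, 1)) / 1.77 if n_hc > 1 else 0.0
    r_mid = r_disk + hc_r + sc_r + lean + 0.4
    n_out = int(math.ceil(n_sc * 0.6))
    n_mid = n_sc - n_out
    if n_mid > 0:
        need_mid = 2.0 * sc_r + (bow_c if n_concave else 0.0) + 0.3
        r_mid = max(r_mid, n_mid * need_mid / (2.0 * math.pi))
    r_out = r_mid + 2.0 * sc_r + 0.5
    if n_out > 0:
        need_out = 2.0 * sc_r + 0.4
        r_out = max(r_out, n_out * need_out / (2.0 * math.pi))
    if r_out + sc_r > config.organ_radius_um:
        raise PlacementError(
            f"cannot place {n} cells ({n_hc} HC, {n_sc} SC) within organ radius "
            f"{config.organ_radius_um} um: outer ring would need "
            f"{r_out + sc_r:.1f} um"
        )

    sc_h = SC_FACTORS["height"]
    hc_base = 1.0 + 0.30 * sc_h
    placed: list[_PlacedCell] = []
    label = 1

    def jitter_factors(base: dict) -> dict:
        out = {}
        for k, v in base.items():
            if k in ("neck_ratio", "taper", "aspect"):
                f = float(np.clip(rng.normal(1.0, 0.04), 0.9, 1.1))
            else:
                f = float(np.clip(rng.normal(1.0, 0.07), 0.85, 1.15))
            lo, hi = _FACTOR_RANGES[k]
            out[k] = float(np.clip(v * f, lo, hi))
        return out

    for xy in _sunflower(n_hc, r_disk):
        ang = math.degrees(math.atan2(xy[1], xy[0])) if np.hypot(*xy) > 1e-9 else 0.0
        placed.append(
            _PlacedCell(label, "HC", "other", np.asarray(xy, float),
                        wrap_angle_deg(ang), wrap_angle_deg(ang + 180.0),
                        hc_base, jitter_factors(HC_FACTORS))
        )
        label += 1

    # DV poles sit at +-90 deg in parallel organs and 0/180 in
    # perpendicular ones (the organ is rotated 90 deg in the image frame)
    dv_axis = 90.0 if config.polarity == "parallel" else 0.0

    ring_members: list[tuple[float, int, bool]] = []  # (radius, count, outer?)
    if n_mid > 0:
        ring_members.append((r_mid, n_mid, False))
    if n_out > 0:
        ring_members.append((r_out, n_out, True))

    sc_cells: list[_PlacedCell] = []
    for r_ring, count, is_outer in ring_members:
        phase = float(rng.uniform(0.0, 360.0 / count))
        for i in range(count):
            ang = wrap_angle_deg(-180.0 + phase + 360.0 * i / count
                                 + float(rng.normal(0.0, 0.03 * 360.0 / count)))
            rr = r_ring * float(np.clip(rng.normal(1.0, 0.02), 0.95, 1.05))
            xy = np.array([rr * math.cos(math.radians(ang)),
                           rr * math.sin(math.radians(ang))])
            if is_outer:
                subtype = "peripheral"
            else:
                d_dv = min(
                    abs(wrap_angle_deg(ang - dv_axis)),
                    abs(wrap_angle_deg(ang - dv_axis + 180.0)),
                )
                subtype = "DV" if d_dv <= 45.0 else "other"
            sc_cells.append(
                _PlacedCell(0, "SC", subtype, xy, ang,
                            wrap_angle_deg(ang + 180.0), 1.0, {})
            )

    # concave cells drawn preferentially from the middle ring, mirroring
    # curved cells found midway between centre and periphery
    mid_first = sorted(range(len(sc_cells)),
                       key=lambda i: (sc_cells[i].subtype == "peripheral", i))
    concave_idx = set(mid_first[:n_concave])
    for i, cell in enumerate(sc_cells):
        base = SC_CONCAVE_FACTORS if i in concave_idx else SC_FACTORS
        cell.cell_type = "SC-concave" if i in concave_idx else "SC"
        cell.factors = jitter_factors(base)
        cell.label = label
        label += 1
        placed.append(cell)

    # gross-overlap guard on xy footprints
    for i in range(len(placed)):
        for j in range(i + 1, len(placed)):
            ci, cj = placed[i], placed[j]
            ri = ci.factors.get("body_radius", ci.factors.get("radius", 1.0))
            rj = cj.factors.get("body_radius", cj.factors.get("radius", 1.0))
            if np.hypot(*(ci.xy - cj.xy)) < 0.80 * (ri + rj):
                raise PlacementError(
                    f"cells {ci.label} and {cj.label} of {n} requested would "
                    "overlap; increase organ_radius_um or reduce n_cells"
                )
    return placed


# ---------------------------------------------------------------------------
# painting


def _nucleus_params(cell: _PlacedCell):
    """Nucleus (t-centre, t half-extent, lateral semi-axis) inside the cell.

    The nucleus is an ellipsoid whose sections follow the cell's own
    (possibly bowed) axis, so curved cells carry curved nuclei that
    still sit strictly inside the cell.
    """
    h, fn = _profile(cell.cell_type, cell.factors)
    tn, dz_frac = 0.42, 0.18
    ts = np.linspace(tn - dz_frac, tn + dz_frac, 9)
    a, b, _, _ = fn(ts)
    s_lat = 0.8 * float(np.min(np.minimum(a, b)))
    s_lat = max(s_lat, 0.3)
    return tn, dz_frac, s_lat


def _paint(config: SynthConfig, placed: list[_PlacedCell], shape):
    vz, vy, vx = config.voxel_size_um
    cells = np.zeros(shape, dtype=np.int32)
    nucs = np.zeros(shape, dtype=np.int32)
    zc = np.arange(shape[0]) * vz
    yc = np.arange(shape[1]) * vy
    xc = np.arange(shape[2]) * vx
    x0 = xc[-1] / 2.0
    y0 = yc[-1] / 2.0

    for cell in placed:
        h, fn = _profile(cell.cell_type, cell.factors)
        tt = np.linspace(0, 1, 33)
        a, b, cx, cy = fn(tt)
        r_max = float(np.max(np.maximum(a, b) + np.hypot(cx, cy))) + 0.2
        wx, wy = x0 + cell.xy[0], y0 + cell.xy[1]
        phi = math.radians(cell.phi_local_deg)
        ex = np.array([math.cos(phi), math.sin(phi)])
        ey = np.array([-math.sin(phi), math.cos(phi)])

        iz = slice(max(0, int((cell.base_z) / vz)),
                   min(shape[0], int((cell.base_z + h) / vz) + 2))
        iy = slice(max(0, int((wy - r_max) / vy)),
                   min(shape[1], int((wy + r_max) / vy) + 2))
        ix = slice(max(0, int((wx - r_max) / vx)),
                   min(shape[2], int((wx + r_max) / vx) + 2))
        z = zc[iz][:, None, None]
        y = yc[iy][None, :, None]
        x = xc[ix][None, None, :]
        t = (z - cell.base_z) / h
        xl = (x - wx) * ex[0] + (y - wy) * ex[1]
        yl = (x - wx) * ey[0] + (y - wy) * ey[1]
        a_t, b_t, cx_t, cy_t = fn(t)
        with np.errstate(divide="ignore", invalid="ignore"):
            # zero radius at the rounded tips: division yields inf, outside
            inside = (
                ((xl - cx_t) / a_t) ** 2 + ((yl - cy_t) / b_t) ** 2 <= 1.0
            ) & ((t >= 0.0) & (t <= 1.0))
        sub = cells[iz, iy, ix]
        sub[inside & (sub == 0)] = cell.label
        cells[iz, iy, ix] = sub

        tn, dz_frac, s_lat = _nucleus_params(cell)
        axial = 1.0 - ((t - tn) / dz_frac) ** 2
        sect = s_lat * np.sqrt(np.clip(axial, 0.0, 1.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            nuc = (
                ((xl - cx_t) ** 2 + (yl - cy_t) ** 2)
                <= sect**2
            ) & (axial > 0.0)
        nsub = nucs[iz, iy, ix]
        nsub[nuc & (cells[iz, iy, ix] == cell.label)] = cell.label
        nucs[iz, iy, ix] = nsub
    return cells, nucs


def _blur_sigma_vox(sigma_um: float, voxel: tuple[float, float, float]):
    return tuple(sigma_um / v for v in voxel)


def generate_neuromast(
    config: SynthConfig, seed: int | None = None, organ_index: int = 0
) -> GroundTruth:
    """Generate one rosette with ground truth.

    All randomness flows from a single stream seeded by
    ``(seed, organ_index)`` (``seed`` defaults to ``config.seed``), so an
    identical call is bit-identical.  Raises :class:`PlacementError` when
    the organ radius cannot accommodate ``n_cells``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng([int(seed), int(organ_index)])
    placed = _layout(config, rng)

    vz, vy, vx = config.voxel_size_um
    margin = 4.0
    half_xy = config.organ_radius_um + margin
    heights = [c.base_z + _profile(c.cell_type, c.factors)[0] for c in placed]
    lz = max(heights) + 1.5
    shape = (
        int(math.ceil(lz / vz)) + 1,
        2 * int(math.ceil(half_xy / vy)),
        2 * int(math.ceil(half_xy / vx)),
    )
    cells, nucs = _paint(config, placed, shape)

    present = set(np.unique(cells)) - {0}
    missing = [c.label for c in placed if c.label not in present]
    if missing:
        raise PlacementError(f"{len(missing)} cells painted no voxels: {missing}")

    # channels: blurred indicators on a unit intensity scale, plus noise
    sig_mem = _blur_sigma_vox(0.25, config.voxel_size_um)
    sig_nuc = _blur_sigma_vox(0.35, config.voxel_size_um)
    boundary = find_boundaries(cells, connectivity=1, mode="thick").astype(np.float32)
    membrane = ndimage.gaussian_filter(boundary, sig_mem)
    membrane /= max(membrane.max(), 1e-9)
    nuclear = ndimage.gaussian_filter((nucs > 0).astype(np.float32), sig_nuc)
    nuclear /= max(nuclear.max(), 1e-9)

    def noisy(x):
        if config.noise_sd > 0:
            x = x + config.noise_sd * rng.standard_normal(x.shape, dtype=np.float32)
        return x

    channels = {
        "membrane": noisy(membrane.copy()),
        "nuclear": noisy(nuclear.copy()),
    }
    probability_maps = {
        "boundary": np.clip(noisy(membrane.copy()), 0.0, 1.0),
        "nucleus": np.clip(noisy(nuclear.copy()), 0.0, 1.0),
    }

    pop_of = {"central": lambda c: c.cell_type == "HC",
              "dorsoventral": lambda c: c.subtype == "DV",
              "peripheral": lambda c: c.subtype == "peripheral"}
    marker_flags: dict[str, dict[int, bool]] = {}
    for spec in config.marker_spec:
        gain = float(max(1.0 + rng.normal(0.0, spec.offset_sd), 0.2))
        vol = np.full(shape, 0.05, dtype=np.float32)
        flags = {}
        is_pos = pop_of[spec.population]
        mask_src = nucs if spec.localization == "nuclear" else cells
        for cell in placed:
            flags[cell.label] = bool(is_pos(cell))
            if flags[cell.label]:
                vol[mask_src == cell.label] = gain
        channels[spec.name] = noisy(vol)
        marker_flags[spec.name] = flags

    # truth table
    rows = []
    vvox = vz * vy * vx
    idx = {c.label: c for c in placed}
    coms = ndimage.center_of_mass(np.ones_like(cells), cells, sorted(present))
    xy_by_label = {}
    for lab, com in zip(sorted(present), coms):
        xy_by_label[lab] = (com[2] * vx, com[1] * vy, com[0] * vz)
    cx0 = np.mean([xy_by_label[l][0] for l in sorted(present)])
    cy0 = np.mean([xy_by_label[l][1] for l in sorted(present)])
    rr = {l: math.hypot(xy_by_label[l][0] - cx0, xy_by_label[l][1] - cy0)
          for l in sorted(present)}
    r_max = max(rr.values()) if rr else 1.0
    for lab in sorted(present):
        c = idx[lab]
        row = {
            "label": lab,
            "type": "HC" if c.cell_type == "HC" else "SC",
            "subtype": c.subtype,
            "concave": c.cell_type == "SC-concave",
            "x_um": xy_by_label[lab][0],
            "y_um": xy_by_label[lab][1],
            "z_um": xy_by_label[lab][2],
            "angle_deg": c.angle_deg,
            "d_true": rr[lab] / r_max if r_max > 0 else 0.0,
            "volume_um3": float(np.sum(cells == lab)) * vvox,
        }
        for k, v in c.factors.items():
            row[f"factor_{k}"] = v
        for name, flags in marker_flags.items():
            row[f"{name}_positive"] = flags[lab]
        rows.append(row)
    truth = pd.DataFrame(rows).set_index("label", drop=False)

    gt = GroundTruth(
        cell_labels=LabeledVolume(cells, config.voxel_size_um),
        nucleus_labels=LabeledVolume(nucs, config.voxel_size_um),
        truth_table=truth,
        channels=channels,
        probability_maps=probability_maps,
        config=config,
        organ_index=organ_index,
    )
    return gt
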