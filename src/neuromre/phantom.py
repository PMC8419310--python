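"""Digital brain-slice phantoms with known viscoelastic ground truth.

A phantom is a stack of coronal slices on a regular grid. Each pixel carries a
true shear wave speed ``c`` (m/s, stiffness surrogate) and a true loss angle
``phi`` (rad, fluidity surrogate: 0 = elastic solid, pi/2 = fluid). The brain
parenchyma is an ellipse per slice, embedded in a coupling medium; ventricles
are fluid-like inclusions; lesions are of two kinds mirroring contrast-MRI
phenotypes: large diffuse blobs near the ventricles (blood-brain-barrier
leakage visualised by gadolinium) and small focal discs (iron-oxide
nanoparticle accumulation).

Default geometry follows the acquisition this emulates: 7 coronal slices of
0.8 mm, 90 x 60 in-plane matrix at 0.18 x 0.18 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._seeds import STAGE_PHANTOM, child_rng

DEFAULT_GRID = (7, 60, 90)  # (slices, rows, cols)
DEFAULT_SPACING_MM = (0.8, 0.18, 0.18)  # (dz, dy, dx)

#: Baseline tissue truth (m/s, rad) used by the default spec factory.
TISSUE_C, TISSUE_PHI = 3.15, 0.69
GD_C, GD_PHI = 3.28, 0.85
VSOP_C, VSOP_PHI = 3.03, 0.91

ATLAS_LABELS = {
    1: "cerebral_cortex",
    2: "cerebral_nuclei",
    3: "brain_stem",
    4: "fiber_tracts",
}


@dataclass(frozen=True)
class Ellipse:
    """In-plane ellipse on one or more contiguous slices."""

    center_rc: tuple[float, float]
    semi_axes_rc: tuple[float, float]
    slice_range: tuple[int, int]  # inclusive (s0, s1)

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        ns, nr, nc = grid_shape
        out = np.zeros(grid_shape, dtype=bool)
        rr, cc = np.ogrid[:nr, :nc]
        cy, cx = self.center_rc
        ay, ax = self.semi_axes_rc
        if ay <= 0 or ax <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        inplane = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
        s0, s1 = self.slice_range
        s0, s1 = max(0, s0), min(ns - 1, s1)
        out[s0 : s1 + 1] = inplane
        return out


@dataclass(frozen=True)
class LesionFocus:
    """Disc- or streak-shaped lesion on one or more slices.

    Circular by default; ``semi_axes_rc`` makes it an in-plane ellipse
    (elongated streaks mimic tract-associated lesions)."""

    center_src: tuple[int, float, float]  # (slice, row, col)
    radius_px: float
    kind: str  # 'gd' | 'vsop'
    c_true: float
    phi_true: float
    n_slices: int = 1  # extends from center slice downward through n slices
    semi_axes_rc: tuple[float, float] | None = None

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        if self.kind not in ("gd", "vsop"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        s, r, c = self.center_src
        axes = self.semi_axes_rc or (self.radius_px, self.radius_px)
        ell = Ellipse((r, c), axes, (int(s), int(s) + self.n_slices - 1))
        return ell.mask(grid_shape)


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one phantom; identical spec+seed is bit-reproducible."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    pixel_spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    brain_geometry: tuple[Ellipse, ...] = ()   # one per slice; default built if empty
    ventricle_geometry: tuple[Ellipse, ...] = ()
    lesion_foci: tuple[LesionFocus, ...] = ()
    region_truth: dict = field(default_factory=lambda: {
        "background": (3.0, 0.25),
        "brain": (TISSUE_C, TISSUE_PHI),
        "ventricle": (1.0, 1.35),
    })
    density_rho: float = 1000.0  # kg/m^3, soft-tissue convention
    seed: int = 0


@dataclass
class Phantom:
    """Rasterised ground truth: property maps plus the masks that made them."""

    c_true: np.ndarray
    phi_true: np.ndarray
    brain: np.ndarray
    ventricles: np.ndarray
    gd_truth: np.ndarray
    vsop_truth: np.ndarray
    atlas: np.ndarray
    spec: PhantomSpec

    @property
    def pixel_spacing_mm(self) -> tuple[float, float, float]:
        return self.spec.pixel_spacing_mm

    @property
    def density_rho(self) -> float:
        return self.spec.density_rho


def _default_brain(grid_shape) -> tuple[Ellipse, ...]:
    """Per-slice brain ellipses, tapering toward the first and last slice."""
    ns, nr, nc = grid_shape
    out = []
    half = max((ns - 1) / 2.0, 0.5)
    for s in range(ns):
        t = (s - (ns - 1) / 2.0) / (half + 1.0)
        scale = math.sqrt(max(1.0 - 0.45 * t * t, 0.1))
        out.append(Ellipse(
            center_rc=((nr - 1) / 2.0, (nc - 1) / 2.0),
            semi_axes_rc=(0.38 * nr * scale, 0.42 * nc * scale),
            slice_range=(s, s),
        ))
    return tuple(out)


def _default_ventricles(grid_shape) -> tuple[Ellipse, ...]:
    ns, nr, nc = grid_shape
    s0, s1 = max(0, ns // 2 - 1), min(ns - 1, ns // 2 + 1)
    dy = 0.20 * nr  # dorsal lateral ventricles
    out = []
    for side in (-1.0, 1.0):
        out.append(Ellipse(
            center_rc=((nr - 1) / 2.0 - dy, (nc - 1) / 2.0 + side * 0.12 * nc),
            semi_axes_rc=(max(1.5, 0.05 * nr), max(1.5, 0.04 * nc)),
            slice_range=(s0, s1),
        ))
    return tuple(out)


def default_phantom_spec(
    seed: int = 0,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
    pixel_spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM,
    n_gd: int = 2,
    n_vsop: int = 4,
    vsop_radius_range: tuple[float, float] = (2.0, 4.0),
    vsop_shape: str = "disc",
    gd_radius_frac_range: tuple[float, float] = (0.09, 0.13),
    placement_margin_px: float = 0.0,
    tissue_c: float = TISSUE_C,
    tissue_phi: float = TISSUE_PHI,
    gd_c: float = GD_C,
    gd_phi: float = GD_PHI,
    vsop_c: float = VSOP_C,
    vsop_phi: float = VSOP_PHI,
) -> PhantomSpec:
    """Build a randomised but reproducible phantom spec.

    Gd lesions are large blobs placed near the ventricles; VSOP foci are small
    discs (radius 2-4 px) scattered in the parenchyma.
    """
    rng = child_rng(seed, STAGE_PHANTOM)
    ns, nr, nc = grid_shape
    brain = _default_brain(grid_shape)
    vents = _default_ventricles(grid_shape)

    foci: list[LesionFocus] = []

    def _separated(s, r, c, radius):
        """Keep lesion territories apart when a placement margin is set."""
        for f in foci:
            span = range(int(f.center_src[0]), int(f.center_src[0]) + f.n_slices)
            if int(s) not in span:
                continue
            need = radius + f.radius_px + 1.5 * placement_margin_px
            if np.hypot(r - f.center_src[1], c - f.center_src[2]) < need:
                return False
        return True

    # Gd blobs: near ventricles, radius ~ 10% of rows, spanning 2 slices.
    for _ in range(n_gd):
        v = vents[rng.integers(len(vents))]
        lo = max(v.slice_range[0] - 1, 0)
        hi = max(min(v.slice_range[1] + 1, ns - 1), lo)
        radius = float(rng.uniform(*gd_radius_frac_range) * nr)

        def _inside_brain(s0, n_sl, r, c):
            """Project (r, c) into the tightest safe ellipse of the slice span."""
            for sl in range(s0, min(s0 + n_sl, ns)):
                e = brain[sl]
                ey, ex = e.center_rc
                ay = max(e.semi_axes_rc[0] - radius - 1, 1.0)
                ax = max(e.semi_axes_rc[1] - radius - 1, 1.0)
                q = ((r - ey) / ay) ** 2 + ((c - ex) / ax) ** 2
                if q > 1.0:
                    f = 1.0 / np.sqrt(q)
                    r = ey + (r - ey) * f
                    c = ex + (c - ex) * f
            return r, c

        s, r, c = lo, *(_inside_brain(lo, 2, 0.35 * nr, 0.38 * nc))
        for _try in range(100):
            st = int(rng.integers(lo, hi + 1))
            n_sl = min(2, ns - st)
            rt = float(np.clip(v.center_rc[0] + rng.normal(0, 0.06 * nr),
                               0.30 * nr, 0.70 * nr))
            ct = float(np.clip(v.center_rc[1] + rng.normal(0, 0.08 * nc),
                               0.30 * nc, 0.70 * nc))
            rt, ct = _inside_brain(st, n_sl, rt, ct)
            if _separated(st, rt, ct, radius):
                s, r, c = st, rt, ct
                break
        foci.append(LesionFocus((s, r, c), radius, "gd", gd_c, gd_phi,
                                n_slices=min(2, ns - s)))
    # VSOP foci: small discs scattered in the parenchyma ('disc'), elongated
    # streaks ('tract'), or commissural bands spanning the brain width at
    # mid-height ('band'). Placement keeps each focus plus margin away from
    # the brain boundary and the ventricles.
    if vsop_shape not in ("disc", "tract", "band"):
        raise ValueError(f"unknown vsop_shape {vsop_shape!r}")
    for _ in range(n_vsop):
        s = int(rng.integers(min(1, ns - 1), ns))
        ell = brain[s]
        cy, cx = ell.center_rc
        ay, ax = ell.semi_axes_rc
        if vsop_shape in ("tract", "band"):
            ry = float(rng.uniform(2.0, 3.0))
            if vsop_shape == "band":
                # full-width band inscribed in the brain ellipse, slightly
                # ventral of the ventricles
                dr = float(rng.uniform(0.0, 3.0))
                rx = 0.96 * ax * math.sqrt(max(1 - ((dr + ry) / ay) ** 2, 0.0))
                r, c = cy + dr, cx
            else:
                rx = float(rng.uniform(9.0, 15.0))
                half = max(ax - rx - placement_margin_px, 1.0)
                r = float(cy + rng.uniform(-2.0, 2.0))
                c = float(rng.uniform(cx - half, cx + half))
            foci.append(LesionFocus((s, r, c), max(ry, rx), "vsop",
                                    vsop_c, vsop_phi, semi_axes_rc=(ry, rx)))
            continue
        radius = float(rng.uniform(*vsop_radius_range))
        m_b = radius + placement_margin_px          # clearance from brain edge
        m_v = radius + 2 + placement_margin_px / 2  # clearance from ventricles
        ay_in, ax_in = max(ay - m_b, 1.0), max(ax - m_b, 1.0)

        def _clear_of_ventricles(r, c):
            for v in vents:
                vy, vx = v.center_rc
                vry, vrx = v.semi_axes_rc
                if ((r - vy) / (vry + m_v)) ** 2 + ((c - vx) / (vrx + m_v)) ** 2 <= 1.0:
                    return False
            return True

        r, c = cy + 0.6 * ay_in, cx  # fallback: ventral mid-parenchyma
        for _try in range(200):
            rt = float(rng.uniform(cy - ay_in, cy + ay_in))
            ct = float(rng.uniform(cx - ax_in, cx + ax_in))
            if (((rt - cy) / ay_in) ** 2 + ((ct - cx) / ax_in) ** 2 <= 1.0
                    and _clear_of_ventricles(rt, ct)
                    and _separated(s, rt, ct, radius)):
                r, c = rt, ct
                break
        foci.append(LesionFocus((s, r, c), radius, "vsop", vsop_c, vsop_phi))

    truth = {"background": (3.0, 0.25), "brain": (tissue_c, tissue_phi),
             "ventricle": (1.0, 1.35)}
    return PhantomSpec(grid_shape=grid_shape, pixel_spacing_mm=pixel_spacing_mm,
                       brain_geometry=brain, ventricle_geometry=vents,
                       lesion_foci=tuple(foci), region_truth=truth, seed=seed)


def _make_atlas(brain: np.ndarray, ventricles: np.ndarray) -> np.ndarray:
    """Toy anatomical parcellation of the brain mask into four labelled regions."""
    from scipy import ndimage

    ns, nr, nc = brain.shape
    atlas = np.zeros(brain.shape, dtype=np.int16)
    for s in range(ns):
        sl = brain[s]
        if not sl.any():
            continue
        dist = ndimage.distance_transform_edt(sl)
        rows = np.arange(nr)[:, None] * np.ones((1, nc))
        cortex = sl & (dist <= 4)
        interior = sl & ~cortex
        rmid = rows[sl].mean()
        fiber = interior & (np.abs(rows - rmid) <= 0.08 * nr)
        stem = interior & ~fiber & (rows > rmid)
        nuclei = interior & ~fiber & ~stem
        atlas[s][cortex] = 1
        atlas[s][nuclei] = 2
        atlas[s][stem] = 3
        atlas[s][fiber] = 4
    atlas[ventricles] = 0
    return atlas


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterise a spec into ground-truth property maps and masks.

    Raises ``ValueError`` for lesions extending outside the brain or for
    non-positive true wave speeds.
    """
    spec = _with_default_geometry(spec)
    for name, (c, phi) in spec.region_truth.items():
        if c <= 0:
            raise ValueError(f"non-positive c_true for region {name!r}")
        if not (0 <= phi < math.pi / 2):
            raise ValueError(f"phi_true out of [0, pi/2) for region {name!r}")

    gs = spec.grid_shape
    brain = np.zeros(gs, dtype=bool)
    for ell in spec.brain_geometry:
        brain |= ell.mask(gs)
    ventricles = np.zeros(gs, dtype=bool)
    for ell in spec.ventricle_geometry:
        ventricles |= ell.mask(gs)
    if (ventricles & ~brain).any():
        raise ValueError("ventricles must lie inside the brain")

    c_bg, phi_bg = spec.region_truth["background"]
    c_tis, phi_tis = spec.region_truth["brain"]
    c_ven, phi_ven = spec.region_truth["ventricle"]
    c_true = np.full(gs, c_bg, dtype=np.float64)
    phi_true = np.full(gs, phi_bg, dtype=np.float64)
    c_true[brain] = c_tis
    phi_true[brain] = phi_tis

    gd = np.zeros(gs, dtype=bool)
    vsop = np.zeros(gs, dtype=bool)
    for focus in spec.lesion_foci:
        if focus.c_true <= 0:
            raise ValueError("lesion c_true must be positive")
        m = focus.mask(gs)
        if (m & ~brain).any():
            raise ValueError(f"lesion focus at {focus.center_src} extends outside the brain")
        c_true[m] = focus.c_true
        phi_true[m] = focus.phi_true
        if focus.kind == "gd":
            gd |= m
        else:
            vsop |= m

    c_true[ventricles] = c_ven
    phi_true[ventricles] = phi_ven
    gd &= ~ventricles
    vsop &= ~ventricles

    atlas = _make_atlas(brain, ventricles)
    return Phantom(c_true=c_true, phi_true=phi_true, brain=brain,
                   ventricles=ventricles, gd_truth=gd, vsop_truth=vsop,
                   atlas=atlas, spec=spec)


def _with_default_geometry(spec: PhantomSpec) -> PhantomSpec:
    if not spec.brain_geometry:
        spec = replace(spec, brain_geometry=_default_brain(spec.grid_shape))
    return spec


def uniform_phantom_spec(
    c: float,
    phi: float,
    grid_shape=DEFAULT_GRID,
    pixel_spacing_mm=DEFAULT_SPACING_MM,
    full_field: bool = True,
) -> PhantomSpec:
    """Spec for a homogeneous phantom (no ventricles, no lesions).

    With ``full_field`` the 'brain' fills the whole grid, which is the clean
    configuration for oracle tests against analytic plane waves.
    """
    ns, nr, nc = grid_shape
    if full_field:
        geom = tuple(Ellipse(((nr - 1) / 2.0, (nc - 1) / 2.0), (10.0 * nr, 10.0 * nc), (s, s))
                     for s in range(ns))
    else:
        geom = _default_brain(grid_shape)
    truth = {"background": (c, phi), "brain": (c, phi), "ventricle": (c, phi)}
    return PhantomSpec(grid_shape=grid_shape, pixel_spacing_mm=pixel_spacing_mm,
                       brain_geometry=geom, region_truth=truth)
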