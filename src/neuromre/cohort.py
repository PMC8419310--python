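"""Synthetic cohorts: paired baseline/EAE sessions with known effect sizes.

Each animal gets a phantom pair sharing one lesion geometry: the baseline
phantom carries the animal's healthy viscoelasticity, the EAE phantom applies
region-specific softening. Default effect sizes are the group statistics the
analysis is meant to recover: healthy tissue shear wave speed 3.15 +- 0.11 m/s
between animals, with EAE softening of -5.85% in unremarkable parenchyma
("rest of the brain"), -9.76% in Gd-enhancing (BBB-leakage) lesions and
-16.81% in VSOP-accumulation lesions. Fluidity (loss angle, 0.69 +- 0.03 rad
whole-brain; elevated in lesions) is left unchanged by EAE, reflecting the
null fluidity effect the analysis should report.

Lesion geometry is randomised per animal; per-animal softening percentages are
deterministic by default (``*_pct_sd = 0``) and can be given between-animal
spread for power studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._seeds import STAGE_COHORT, child_rng
from .contrast import ContrastImagePair, simulate_contrast_pair
from .phantom import (DEFAULT_GRID, DEFAULT_SPACING_MM, GD_C, GD_PHI, TISSUE_C,
                      TISSUE_PHI, VSOP_C, VSOP_PHI, LesionFocus, Phantom,
                      PhantomSpec, default_phantom_spec, make_phantom)
from .waves import EDGE_SOURCES, PAPER_FREQUENCIES_HZ, WaveField, simulate_wavefield


@dataclass(frozen=True)
class CohortSpec:
    n_animals: int = 19
    baseline_c_mean: float = TISSUE_C       # m/s, between-animal mean
    baseline_c_sd: float = 0.11             # m/s, between-animal sd
    eae_global_pct: float = -5.85           # % change of non-lesion parenchyma
    gd_region_pct: float = -9.76            # % change inside Gd lesions
    vsop_region_pct: float = -16.81         # % change inside VSOP lesions
    phi_baseline_mean: float = TISSUE_PHI   # rad
    phi_sd: float = 0.03                    # rad, between-animal
    #: session-level fluidity drift at the EAE timepoint: small mean shift and
    #: the extra dispersion implied by the reported group sds
    #: (0.69 +- 0.03 baseline vs 0.70 +- 0.06 EAE, not significant)
    phi_eae_shift: float = 0.01
    phi_eae_jitter_sd: float = 0.052        # sqrt(0.06^2 - 0.03^2)
    noise_sigma: float = 0.01               # complex noise sd on wave images (a.u.)
    seed: int = 0
    # optional between-animal spread of the regional percent changes
    eae_global_pct_sd: float = 0.0
    gd_region_pct_sd: float = 0.0
    vsop_region_pct_sd: float = 0.0
    # lesion baseline contrast relative to tissue (group means of the regions)
    gd_baseline_c: float = GD_C
    vsop_baseline_c: float = VSOP_C
    gd_phi: float = GD_PHI
    vsop_phi: float = VSOP_PHI
    #: the mechanically altered territory extends this many pixels beyond the
    #: imaging-visible lesion core (inflammation halo, ~half a shear
    #: wavelength), at both timepoints; contrast images see the core only
    soften_halo_px: int = 12
    vsop_radius_px: tuple[float, float] = (2.0, 4.0)
    vsop_shape: str = "disc"  # 'disc' (focal) or 'tract' (elongated streaks)
    gd_radius_frac: tuple[float, float] = (0.09, 0.13)
    # imaging / simulation configuration
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    pixel_spacing_mm: tuple[float, float, float] = DEFAULT_SPACING_MM
    frequencies_hz: tuple[float, ...] = PAPER_FREQUENCIES_HZ
    sources: tuple[str, ...] = EDGE_SOURCES
    solver_refine: int = 2
    n_gd: int = 2
    n_vsop: int = 4
    gd_enhancement_pct: float = 30.0
    vsop_drop_pct: float = 40.0
    contrast_noise_sigma: float = 1.0

    def __post_init__(self):
        if self.n_animals < 2:
            raise ValueError("a paired cohort needs at least 2 animals")
        for name in ("baseline_c_sd", "phi_sd", "eae_global_pct_sd",
                     "gd_region_pct_sd", "vsop_region_pct_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("eae_global_pct", "gd_region_pct", "vsop_region_pct"):
            if getattr(self, name) <= -100:
                raise ValueError(f"{name} must be > -100")


@dataclass
class AnimalSession:
    """Paired baseline/EAE data for one animal."""

    animal_id: str
    phantom_baseline: Phantom
    phantom_eae: Phantom
    wavefield_baseline: WaveField | None
    wavefield_eae: WaveField | None
    gd_pair: ContrastImagePair
    vsop_pair: ContrastImagePair
    truth: dict = field(default_factory=dict)


def _scaled_spec(base: PhantomSpec, c_scale: float, phi_shift: float) -> PhantomSpec:
    """Scale tissue/lesion speeds of a phantom spec and shift loss angles."""
    truth = dict(base.region_truth)
    c_tis, phi_tis = truth["brain"]
    truth["brain"] = (c_tis * c_scale, phi_tis + phi_shift)
    foci = [LesionFocus(f.center_src, f.radius_px, f.kind, f.c_true * c_scale,
                        f.phi_true + phi_shift, f.n_slices, f.semi_axes_rc)
            for f in base.lesion_foci]
    return replace(base, region_truth=truth, lesion_foci=tuple(foci))


def _euclidean_dilate(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """In-plane isotropic (Euclidean) dilation, slice by slice."""
    from scipy import ndimage

    if radius_px <= 0 or not mask.any():
        return mask.copy()
    out = np.zeros_like(mask)
    for s in range(mask.shape[0]):
        if mask[s].any():
            d = ndimage.distance_transform_edt(~mask[s])
            out[s] = d <= radius_px
    return out


def _lesion_territories(ph: Phantom, halo_px: int):
    """Softened territories: lesion cores dilated isotropically by the
    inflammation halo, clipped to parenchyma."""
    parench = ph.brain & ~ph.ventricles
    t_gd = _euclidean_dilate(ph.gd_truth, halo_px) & parench
    t_vsop = _euclidean_dilate(ph.vsop_truth, halo_px) & parench
    return t_gd, t_vsop


def _apply_eae(ph_b: Phantom, spec: CohortSpec, c_vals: dict, pcts: dict) -> Phantom:
    """EAE phantom: baseline copy with region-specific softening applied.

    Non-lesion parenchyma softens by pct_rest, Gd territories by pct_gd, VSOP
    territories by pct_vsop (VSOP wins where territories overlap). Loss angles
    get only a session-level drift (null fluidity effect within the reported
    dispersion)."""
    import copy

    ph_e = copy.deepcopy(ph_b)
    parench = ph_e.brain & ~ph_e.ventricles
    t_gd, t_vsop = _lesion_territories(ph_e, spec.soften_halo_px)
    ph_e.c_true[parench] = c_vals["tissue"] * (1 + pcts["rest"] / 100.0)
    ph_e.c_true[t_gd] = c_vals["gd"] * (1 + pcts["gd"] / 100.0)
    ph_e.c_true[t_vsop] = c_vals["vsop"] * (1 + pcts["vsop"] / 100.0)
    ph_e.phi_true[parench] = np.clip(
        ph_e.phi_true[parench] + pcts["phi_drift"], 0.0, 1.45)
    return ph_e


def make_cohort(spec: CohortSpec, simulate_waves: bool = True) -> list[AnimalSession]:
    """Generate a full paired cohort.

    Per animal: baseline tissue speed drawn from
    ``Normal(baseline_c_mean, baseline_c_sd)`` (lesion speeds co-scaled so the
    lesion/tissue ratio is preserved), loss angle from
    ``Normal(phi_baseline_mean, phi_sd)``; EAE speeds multiply the baseline by
    ``1 + pct/100`` with the class-specific percentage. The truth record keeps
    every drawn value plus the regional means of the rasterised maps.
    Deterministic under (spec, spec.seed); animals use independent substreams,
    so growing the cohort does not reshuffle earlier animals.
    """
    sessions = []
    for a in range(spec.n_animals):
        rng = child_rng(spec.seed, STAGE_COHORT, a)
        c_a = float(rng.normal(spec.baseline_c_mean, spec.baseline_c_sd))
        if c_a <= 0:
            raise ValueError("drew a non-positive baseline wave speed; "
                             "check baseline_c_mean/sd")
        phi_a = float(np.clip(rng.normal(spec.phi_baseline_mean, spec.phi_sd),
                              0.0, 1.45))
        pct_rest = float(rng.normal(spec.eae_global_pct, spec.eae_global_pct_sd))
        pct_gd = float(rng.normal(spec.gd_region_pct, spec.gd_region_pct_sd))
        pct_vsop = float(rng.normal(spec.vsop_region_pct, spec.vsop_region_pct_sd))
        phi_drift = float(rng.normal(spec.phi_eae_shift, spec.phi_eae_jitter_sd))

        geo_seed = int(rng.integers(0, 2**31 - 1))
        base_geom = default_phantom_spec(
            seed=geo_seed, grid_shape=spec.grid_shape,
            pixel_spacing_mm=spec.pixel_spacing_mm,
            n_gd=spec.n_gd, n_vsop=spec.n_vsop,
            vsop_radius_range=spec.vsop_radius_px,
            vsop_shape=spec.vsop_shape,
            gd_radius_frac_range=spec.gd_radius_frac,
            placement_margin_px=spec.soften_halo_px,
            tissue_c=spec.baseline_c_mean, tissue_phi=spec.phi_baseline_mean,
            gd_c=spec.gd_baseline_c, gd_phi=spec.gd_phi,
            vsop_c=spec.vsop_baseline_c, vsop_phi=spec.vsop_phi)

        scale = c_a / spec.baseline_c_mean
        shift = phi_a - spec.phi_baseline_mean
        ph_b = make_phantom(_scaled_spec(base_geom, scale, shift))
        # extend lesion values over the softened territory (core + halo)
        c_vals = {"tissue": c_a, "gd": spec.gd_baseline_c * scale,
                  "vsop": spec.vsop_baseline_c * scale}
        t_gd, t_vsop = _lesion_territories(ph_b, spec.soften_halo_px)
        ph_b.c_true[t_gd] = c_vals["gd"]
        ph_b.phi_true[t_gd] = spec.gd_phi + shift
        ph_b.c_true[t_vsop] = c_vals["vsop"]
        ph_b.phi_true[t_vsop] = spec.vsop_phi + shift
        ph_e = _apply_eae(ph_b, spec, c_vals,
                          {"rest": pct_rest, "gd": pct_gd, "vsop": pct_vsop,
                           "phi_drift": phi_drift})

        wf_b = wf_e = None
        if simulate_waves:
            wseed_b = int(rng.integers(0, 2**31 - 1))
            wseed_e = int(rng.integers(0, 2**31 - 1))
            wf_b = simulate_wavefield(ph_b, spec.frequencies_hz, spec.sources,
                                      spec.noise_sigma, wseed_b,
                                      refine=spec.solver_refine)
            wf_e = simulate_wavefield(ph_e, spec.frequencies_hz, spec.sources,
                                      spec.noise_sigma, wseed_e,
                                      refine=spec.solver_refine)

        cseed = int(rng.integers(0, 2**31 - 1))
        gd_pair = simulate_contrast_pair(ph_e, "t1_gbca",
                                         spec.gd_enhancement_pct,
                                         spec.contrast_noise_sigma, cseed)
        vsop_pair = simulate_contrast_pair(ph_e, "t2star_vsop",
                                           spec.vsop_drop_pct,
                                           spec.contrast_noise_sigma, cseed + 1)

        parench = ph_b.brain & ~ph_b.ventricles
        rest = parench & ~t_gd & ~t_vsop

        def _means(ph):
            return {
                "whole_brain": float(ph.c_true[parench].mean()),
                "rest": float(ph.c_true[rest].mean()),
                "gd": float(ph.c_true[t_gd].mean()) if t_gd.any() else np.nan,
                "vsop": float(ph.c_true[t_vsop].mean()) if t_vsop.any() else np.nan,
            }

        truth = {
            "baseline_c": c_a, "phi": phi_a, "phi_drift": phi_drift,
            "pct_rest": pct_rest, "pct_gd": pct_gd, "pct_vsop": pct_vsop,
            "regional_mean_c_baseline": _means(ph_b),
            "regional_mean_c_eae": _means(ph_e),
            "territory_gd": t_gd, "territory_vsop": t_vsop,
        }
        sessions.append(AnimalSession(
            animal_id=f"m{a:03d}", phantom_baseline=ph_b, phantom_eae=ph_e,
            wavefield_baseline=wf_b, wavefield_eae=wf_e,
            gd_pair=gd_pair, vsop_pair=vsop_pair, truth=truth))
    return sessions
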