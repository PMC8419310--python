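"""Lesion-mask construction, set algebra, slice resampling and incidence maps.

The mask pipeline mirrors the contrast-MRI workflow: percent signal-intensity
change maps yield Gd-enhancement masks; post/pre signal ratios yield VSOP
hypointensity masks; VSOP masks are dilated (two pixels by default, to buffer
single-pixel artifacts at the coarser elastography resolution); overlap
between the two classes is disregarded so each mask marks areas seen by one
modality only; ventricles are removed because shear waves do not propagate in
fluid; finally masks can be resampled along the slice axis onto a
finer-sliced reference atlas grid.

Incidence maps report, per voxel, the percentage of animals whose mask covers
that voxel; regional incidence reports the percentage of animals whose mask
touches an atlas region at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .contrast import ContrastImagePair

#: reference atlas slicing: 215 coronal slices spanning 20.8 mm, so that the
#: 7 x 0.8 mm acquisition footprint maps onto ~58 atlas slices
ATLAS_N_SLICES = 215
ATLAS_SPAN_MM = 20.8

MASK_STATES = ("raw", "dilated", "exclusive", "final")

#: in-plane 4-connected structuring element used for mask dilation
CROSS_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class LesionMaskSet:
    """Gd / VSOP / ventricle / brain masks with an explicit processing state."""

    gd: np.ndarray
    vsop: np.ndarray
    ventricles: np.ndarray
    brain: np.ndarray
    state: str = "raw"
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if self.state not in MASK_STATES:
            raise ValueError(f"unknown state {self.state!r}")
        shapes = {m.shape for m in (self.gd, self.vsop, self.ventricles, self.brain)}
        if len(shapes) != 1:
            raise ValueError("all masks must share one grid")
        if self.state in ("exclusive", "final") and (self.gd & self.vsop).any():
            raise ValueError("exclusive/final mask sets must have disjoint gd and vsop")
        if self.state == "final":
            if ((self.gd | self.vsop) & self.ventricles).any():
                raise ValueError("final masks must not contain ventricle voxels")
            if ((self.gd | self.vsop) & ~self.brain).any():
                raise ValueError("final masks must lie inside the brain")


@dataclass
class IncidenceMap:
    percent: np.ndarray  # float, [0, 100]
    n_animals: int
    modality: str


def percent_change_si(pair: ContrastImagePair, brain: np.ndarray) -> np.ndarray:
    """Percent signal-intensity change map, 100 * (post - pre) / pre.

    Positive values are enhancement (hyperintense post-contrast). Restricted
    to the brain: NaN outside and at invalid (pre <= 0) pixels.
    """
    brain = np.asarray(brain, dtype=bool)
    out = np.full(pair.pre.shape, np.nan)
    ok = brain & (pair.pre > 0)
    out[ok] = 100.0 * (pair.post[ok] - pair.pre[ok]) / pair.pre[ok]
    return out


def _remove_small(mask: np.ndarray, min_size_px: int) -> np.ndarray:
    """Drop connected components smaller than min_size_px, slice-wise."""
    if min_size_px <= 1:
        return mask
    out = np.zeros_like(mask)
    for s in range(mask.shape[0]):
        lab, n = ndimage.label(mask[s], structure=CROSS_2D)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        keep = np.flatnonzero(sizes >= min_size_px)
        keep = keep[keep > 0]
        out[s] = np.isin(lab, keep)
    return out


def gd_mask_from_change(change_map: np.ndarray, threshold_pct: float = 15.0,
                        min_size_px: int = 5) -> np.ndarray:
    """Threshold a percent-change map into a Gd-enhancement mask."""
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive")
    mask = np.nan_to_num(change_map, nan=-np.inf) >= threshold_pct
    return _remove_small(mask, min_size_px)


def vsop_mask_from_hypointensity(pair: ContrastImagePair, brain: np.ndarray,
                                 ratio_threshold: float = 0.8,
                                 min_size_px: int = 5) -> np.ndarray:
    """Post/pre ratio thresholding into a VSOP hypointensity mask.

    A threshold of 0 (or below) is unsatisfiable for positive signals and
    yields an empty mask; thresholds >= 1 would mark unenhanced tissue and are
    rejected.
    """
    if ratio_threshold >= 1:
        raise ValueError("ratio_threshold must be < 1")
    brain = np.asarray(brain, dtype=bool)
    if ratio_threshold <= 0:
        return np.zeros(pair.pre.shape, dtype=bool)
    ok = brain & (pair.pre > 0)
    ratio = np.full(pair.pre.shape, np.inf)
    ratio[ok] = pair.post[ok] / pair.pre[ok]
    return _remove_small(ratio <= ratio_threshold, min_size_px)


def dilate_mask(mask: np.ndarray, pixels: int,
                brain: np.ndarray | None = None) -> np.ndarray:
    """In-plane morphological dilation, ``pixels`` iterations of a 4-connected
    cross; slices are treated independently (anisotropic voxels). Optionally
    clipped to the brain."""
    if pixels < 0:
        raise ValueError("pixels must be >= 0")
    out = np.asarray(mask, dtype=bool).copy()
    if pixels > 0:
        for s in range(out.shape[0]):
            out[s] = ndimage.binary_dilation(out[s], structure=CROSS_2D,
                                             iterations=pixels)
    if brain is not None:
        out &= np.asarray(brain, dtype=bool)
    return out


def make_exclusive(mask_set: LesionMaskSet) -> LesionMaskSet:
    """Mutual exclusion then ventricle removal; advances state to ``final``.

    Voxels marked by both modalities are disregarded in both masks, so each
    final mask marks areas seen exclusively by one contrast agent.
    """
    if mask_set.state != "dilated":
        raise ValueError("make_exclusive expects a 'dilated' mask set "
                         f"(got {mask_set.state!r})")
    overlap = mask_set.gd & mask_set.vsop
    gd = mask_set.gd & ~overlap & ~mask_set.ventricles & mask_set.brain
    vsop = mask_set.vsop & ~overlap & ~mask_set.ventricles & mask_set.brain
    return replace(mask_set, gd=gd, vsop=vsop, state="final",
                   provenance=mask_set.provenance
                   + ["mutual_exclusion", "ventricle_removal"])


def build_mask_set(gd_pair: ContrastImagePair, vsop_pair: ContrastImagePair,
                   brain: np.ndarray, ventricles: np.ndarray,
                   gd_threshold_pct: float = 15.0,
                   vsop_ratio_threshold: float = 0.8,
                   min_size_px: int = 5,
                   vsop_dilation_px: int = 2) -> LesionMaskSet:
    """Full mask pipeline: threshold -> dilate VSOP -> exclusion -> ventricles."""
    change = percent_change_si(gd_pair, brain)
    gd = gd_mask_from_change(change, gd_threshold_pct, min_size_px) & brain
    vsop = vsop_mask_from_hypointensity(vsop_pair, brain,
                                        vsop_ratio_threshold, min_size_px)
    vsop = dilate_mask(vsop, vsop_dilation_px, brain=brain)
    ms = LesionMaskSet(gd=gd, vsop=vsop, ventricles=ventricles, brain=brain,
                       state="dilated",
                       provenance=[f"gd_threshold_{gd_threshold_pct}",
                                   f"vsop_ratio_{vsop_ratio_threshold}",
                                   f"min_size_{min_size_px}",
                                   f"vsop_dilated_{vsop_dilation_px}"])
    return make_exclusive(ms)


def resample_slices(image: np.ndarray, source_slice_mm: float,
                    n_target: int = ATLAS_N_SLICES,
                    target_span_mm: float = ATLAS_SPAN_MM,
                    method: str = "linear",
                    fill=0.0) -> np.ndarray:
    """Resample the slice axis onto a reference atlas grid.

    The source stack (n_source slices of ``source_slice_mm``) is centred in
    the atlas span; target slices whose centre falls outside the source
    footprint are set to ``fill``. In-plane sampling is unchanged. Masks must
    use ``method='nearest'``.
    """
    if method not in ("nearest", "linear"):
        raise ValueError("method must be 'nearest' or 'linear'")
    if source_slice_mm <= 0 or target_span_mm <= 0 or n_target < 1:
        raise ValueError("incompatible resampling geometry")
    ns = image.shape[0]
    src_span = ns * source_slice_mm
    dz_t = target_span_mm / n_target
    z0 = (target_span_mm - src_span) / 2.0
    centers = (np.arange(n_target) + 0.5) * dz_t
    # continuous source slice coordinate of each target centre
    coord = (centers - z0) / source_slice_mm - 0.5
    inside = (centers >= z0) & (centers < z0 + src_span)
    out = np.full((n_target,) + image.shape[1:], fill, dtype=
                  image.dtype if method == "nearest" else float)
    if method == "nearest":
        idx = np.clip(np.round(coord).astype(int), 0, ns - 1)
        out[inside] = image[idx[inside]]
    else:
        lo = np.clip(np.floor(coord).astype(int), 0, ns - 1)
        hi = np.clip(lo + 1, 0, ns - 1)
        t = np.clip(coord - lo, 0.0, 1.0)
        vals = (1 - t)[:, None, None] * image[lo] + t[:, None, None] * image[hi]
        out[inside] = vals[inside]
    return out


def incidence_map(masks: list[np.ndarray], modality: str) -> IncidenceMap:
    """Voxelwise percentage of animals with a mask at each voxel."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError("masks must share one grid")
    count = np.zeros(masks[0].shape, dtype=float)
    for m in masks:
        count += np.asarray(m, dtype=bool)
    return IncidenceMap(percent=100.0 * count / len(masks),
                        n_animals=len(masks), modality=modality)


def regional_incidence(masks: list[np.ndarray], atlas: np.ndarray,
                       label_names: dict[int, str]) -> pd.DataFrame:
    """Per-region percentage of animals whose mask intersects the region.

    Mirrors the tabulated incidence report: one row per anatomical label,
    values rounded to one decimal.
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    labels_present = set(np.unique(atlas)) - {0}
    unknown = labels_present - set(label_names)
    if unknown:
        raise ValueError(f"atlas contains unknown labels {sorted(unknown)}")
    rows = []
    for lab, name in label_names.items():
        region = atlas == lab
        n_hit = sum(bool((np.asarray(m, dtype=bool) & region).any()) for m in masks)
        rows.append({"anatomical_label": name,
                     "incidence_pct": round(100.0 * n_hit / len(masks), 1)})
    return pd.DataFrame(rows)
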