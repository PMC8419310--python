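"""Synthetic contrast-agent image pairs.

Two modalities mirror the study design: ``t1_gbca`` (gadolinium-based contrast
agent; blood-brain-barrier leakage appears *hyper*intense on post-contrast
T1-weighted images) and ``t2star_vsop`` (very small superparamagnetic iron
oxide particles; accumulation appears *hypo*intense on post-contrast
T2*-weighted images). Pre and post images share the grid; the post image
differs from the pre image only inside the corresponding lesion class, so
noiseless percent-change and ratio maps are exact by construction.

Magnitude MR noise is Rician: the noisy signal is the modulus of the true
signal plus complex Gaussian noise, hence nonnegative and positively biased
at low SNR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import STAGE_CONTRAST, child_rng
from .phantom import Phantom

MODALITIES = ("t1_gbca", "t2star_vsop")

#: noiseless tissue signal levels (arbitrary units)
SI_TISSUE = 100.0
SI_BACKGROUND = 20.0
SI_VENTRICLE = {"t1_gbca": 60.0, "t2star_vsop": 130.0}


@dataclass
class ContrastImagePair:
    pre: np.ndarray
    post: np.ndarray
    modality: str
    pixel_spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.pre.shape != self.post.shape:
            raise ValueError("pre and post images must share the grid")
        if (self.pre < 0).any() or (self.post < 0).any():
            raise ValueError("signal intensities must be nonnegative")


def rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Rician-corrupted magnitude signal |S + n1 + i n2|, n ~ N(0, sigma)."""
    if sigma <= 0:
        return signal.copy()
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(signal + n1, n2)


def simulate_contrast_pair(phantom: Phantom, modality: str,
                           enhancement_pct: float = 30.0,
                           noise_sigma: float = 0.0,
                           seed: int = 0) -> ContrastImagePair:
    """Simulate a pre/post contrast pair for one phantom.

    ``enhancement_pct`` is the percent SI increase inside Gd lesions for
    ``t1_gbca``, or the percent SI *drop* inside VSOP foci for
    ``t2star_vsop`` (e.g. 40 means post/pre = 0.6 on the foci). The pre image
    is a smooth tissue baseline with a gentle reproducible shading field, so
    ratio-based maps are exact while absolute SI varies across the slice as in
    real coils.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    if enhancement_pct <= 0:
        raise ValueError("enhancement_pct must be positive "
                         "(a drop is still expressed as a positive percentage)")
    rng = child_rng(seed, STAGE_CONTRAST)
    gs = phantom.brain.shape
    pre = np.full(gs, SI_BACKGROUND, dtype=float)
    pre[phantom.brain] = SI_TISSUE
    pre[phantom.ventricles] = SI_VENTRICLE[modality]
    # low-frequency multiplicative shading (+-8%), deterministic under seed
    from scipy import ndimage
    shading = ndimage.gaussian_filter(rng.standard_normal(gs), sigma=(0, 8, 8))
    smax = np.abs(shading).max()
    if smax > 0:
        pre = pre * (1.0 + 0.08 * shading / smax)

    post = pre.copy()
    if modality == "t1_gbca":
        post[phantom.gd_truth] = pre[phantom.gd_truth] * (1 + enhancement_pct / 100.0)
    else:
        post[phantom.vsop_truth] = pre[phantom.vsop_truth] * (1 - enhancement_pct / 100.0)
        if (post < 0).any():
            raise ValueError("drop percentage exceeds 100%")

    pre_n = rician(pre, noise_sigma, rng)
    post_n = rician(post, noise_sigma, rng)
    return ContrastImagePair(pre=pre_n, post=post_n, modality=modality,
                             pixel_spacing_mm=phantom.pixel_spacing_mm)
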