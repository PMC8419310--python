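"""Multifrequency inversion of shear-wave fields.

Two estimators act on the same multifrequency displacement data:

* **Stiffness** — shear wave speed ``c`` (m/s) by multifrequency wavenumber
  analysis: each wave image is decomposed into directional components in the
  Fourier domain, the local wavenumber of every component is measured
  unwrap-free as ``|Im(grad u / u)|``, converted to a speed ``omega/k`` and the
  speeds are averaged across frequencies/directions/components with
  amplitude^p weights.

* **Fluidity** — loss angle ``phi`` (rad) of the complex shear modulus by
  Laplacian-based direct multifrequency inversion:
  ``phi = arccos( -sum_j Re(Lap u_j . conj u_j) / sum_j |Lap u_j||u_j| )``,
  exact for any field obeying the homogeneous Helmholtz equation, since there
  ``Lap u = -k^2 u`` and ``arg(k^2) = phi``.

Both estimators are invariant to rescaling the field by a nonzero complex
constant. Validity is tracked explicitly: pixels with vanishing amplitude,
vanishing denominators, or within a configurable margin of the mask boundary
are flagged invalid rather than propagated as NaN.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .waves import WaveField

_EPS = 1e-12


@dataclass(frozen=True)
class InversionConfig:
    n_directions: int = 8
    bandpass_k_min: float | None = None  # rad/m; None -> derived from frequencies
    bandpass_k_max: float | None = None
    amplitude_weight_power: float = 2.0
    smoothing_sigma_px: float = 1.0
    #: smoothing before the Laplacian: the 5-point stencil amplifies white
    #: noise as k^4, so the loss angle needs its own regularisation (exact for
    #: locally homogeneous Helmholtz fields); kept as small as noise
    #: robustness allows because wider kernels mix fluidity across nearby
    #: regions of different phi
    phi_smoothing_sigma_px: float = 1.5
    density_rho: float = 1000.0
    edge_margin_px: int = 2
    weight_rel_threshold: float = 1e-3  # valid if weight > this x mean weight
    #: plausible parenchymal wave speeds; sets the per-frequency radial band
    #: and the wavenumber plausibility gate
    c_expected_range: tuple[float, float] = (1.5, 5.0)
    #: normalise the field by its Gaussian-smoothed amplitude envelope before
    #: directional filtering, so attenuation does not smear the spectrum and
    #: low-amplitude regions are not drowned by filter leakage; weights still
    #: use the original amplitude. 0 disables the normalisation.
    flatten_sigma_px: float = 4.0

    def __post_init__(self):
        if self.n_directions < 1:
            raise ValueError("n_directions must be >= 1")
        if self.edge_margin_px < 0:
            raise ValueError("edge_margin_px must be >= 0")
        if (self.bandpass_k_min is not None and self.bandpass_k_max is not None
                and not self.bandpass_k_min < self.bandpass_k_max):
            raise ValueError("bandpass_k_min must be < bandpass_k_max")

    def bandpass(self, frequencies_hz) -> tuple[float, float]:
        """Radial band (rad/m) bracketing plausible wavenumbers for a set of
        drive frequencies, with a 20% guard on either side. For a single
        frequency this is the per-frequency band the stiffness inversion
        applies; a sharp band keeps strongly damped (spectrally broadened)
        waves from dragging the local phase gradient."""
        c_lo, c_hi = self.c_expected_range
        w_min = 2 * math.pi * min(frequencies_hz)
        w_max = 2 * math.pi * max(frequencies_hz)
        k_min = self.bandpass_k_min if self.bandpass_k_min is not None \
            else 0.8 * w_min / c_hi
        k_max = self.bandpass_k_max if self.bandpass_k_max is not None \
            else 1.2 * w_max / c_lo
        return k_min, k_max


@dataclass
class ParameterMaps:
    """Stiffness and fluidity maps with a shared validity mask."""

    c_map: np.ndarray          # m/s
    phi_map: np.ndarray        # rad
    valid_mask: np.ndarray     # bool
    pixel_spacing_mm: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)


def directional_filter(image: np.ndarray, n_directions: int,
                       pixel_spacing_mm: tuple[float, float],
                       bandpass: tuple[float, float] | None = None,
                       ) -> list[np.ndarray]:
    """Split a complex wave image into directional components.

    Angular windows are raised-cosine lobes centred at ``2 pi j / n`` with
    full-width-at-half-maximum ``2 pi / n``; for n >= 2 they form a partition
    of unity, so the sum over sectors (without the radial band) reconstructs
    the input exactly. ``n_directions=1`` is the identity window. ``bandpass``
    is an optional radial pass band in rad/m.

    The image is mirror-padded to twice its size before the FFT to suppress
    wraparound ringing from non-periodic fields; padding is cropped off after
    filtering, and cancels exactly in the sum over sectors.
    """
    if n_directions < 1:
        raise ValueError("n_directions must be >= 1")
    u = np.asarray(image, dtype=complex)
    if u.ndim != 2:
        raise ValueError("directional_filter expects a 2D image")
    nr0, nc0 = u.shape
    py, px = nr0 // 2, nc0 // 2
    u = np.pad(u, ((py, py), (px, px)), mode="reflect")
    nr, nc = u.shape
    dy, dx = (s * 1e-3 for s in pixel_spacing_mm)
    ky = 2 * math.pi * np.fft.fftfreq(nr, d=dy)[:, None]
    kx = 2 * math.pi * np.fft.fftfreq(nc, d=dx)[None, :]
    kmag = np.hypot(ky, kx)
    theta = np.arctan2(ky, kx)

    radial = np.ones_like(kmag)
    if bandpass is not None:
        k_min, k_max = bandpass
        radial = ((kmag >= k_min) & (kmag <= k_max)).astype(float)

    U = np.fft.fft2(u)
    out = []
    n = n_directions
    for j in range(n):
        if n == 1:
            ang = np.ones_like(kmag)
        else:
            delta = np.angle(np.exp(1j * (theta - 2 * math.pi * j / n)))
            ang = np.where(np.abs(delta) <= 2 * math.pi / n,
                           np.cos(n * delta / 4.0) ** 2, 0.0)
        filtered = np.fft.ifft2(U * ang * radial)
        out.append(filtered[py:py + nr0, px:px + nc0])
    return out


def estimate_wavenumber(image: np.ndarray,
                        pixel_spacing_mm: tuple[float, float],
                        smoothing_sigma_px: float = 1.0,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Local wavenumber (rad/m) and amplitude of a complex wave image.

    The phase gradient is computed unwrap-free from the argument of the
    ratio of neighbouring samples, ``arg(u[i+1] conj(u[i-1])) / 2h`` — the
    discrete realisation of ``Im(grad u / u)`` that is exact for plane waves
    (including attenuated ones) and immune to 2-pi wrapping. Each gradient
    component is Gaussian-smoothed and the wavenumber is the vector norm.
    Pixels whose amplitude is below machine tolerance get k=0 and zero
    amplitude, so that amplitude weighting removes them instead of
    propagating NaN.
    """
    u = np.asarray(image, dtype=complex)
    if u.ndim != 2:
        raise ValueError("estimate_wavenumber expects a 2D image")
    dy, dx = (s * 1e-3 for s in pixel_spacing_mm)
    if dy <= 0 or dx <= 0:
        raise ValueError("pixel spacing must be positive")
    amp = np.abs(u)
    tiny = amp < _EPS
    py = np.zeros(u.shape)
    px = np.zeros(u.shape)
    py[1:-1, :] = np.angle(u[2:, :] * np.conj(u[:-2, :])) / (2 * dy)
    py[0, :] = np.angle(u[1, :] * np.conj(u[0, :])) / dy
    py[-1, :] = np.angle(u[-1, :] * np.conj(u[-2, :])) / dy
    px[:, 1:-1] = np.angle(u[:, 2:] * np.conj(u[:, :-2])) / (2 * dx)
    px[:, 0] = np.angle(u[:, 1] * np.conj(u[:, 0])) / dx
    px[:, -1] = np.angle(u[:, -1] * np.conj(u[:, -2])) / dx
    py = np.where(tiny, 0.0, py)
    px = np.where(tiny, 0.0, px)
    if smoothing_sigma_px > 0:
        py = ndimage.gaussian_filter(py, smoothing_sigma_px)
        px = ndimage.gaussian_filter(px, smoothing_sigma_px)
    k = np.hypot(py, px)
    amp = np.where(tiny, 0.0, amp)
    return k, amp


def _iter_images(wavefield: WaveField):
    nf, ncomp, ns = wavefield.components.shape[:3]
    for fi in range(nf):
        omega = 2 * math.pi * wavefield.frequencies_hz[fi]
        for ci in range(ncomp):
            for si in range(ns):
                yield omega, si, wavefield.components[fi, ci, si]


def invert_stiffness(wavefield: WaveField, config: InversionConfig = InversionConfig(),
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude-weighted multifrequency wave-speed map.

    Returns ``(c_map, total_weight)``; validity thresholding on the weight is
    left to :func:`invert` so both inversions share one mask.
    """
    if len(wavefield.frequencies_hz) == 0:
        raise ValueError("wavefield has no frequencies")
    ns, nr, nc = wavefield.grid_shape
    num = np.zeros((ns, nr, nc))
    den = np.zeros((ns, nr, nc))
    spacing2d = wavefield.pixel_spacing_mm[1:]
    for omega, si, img in _iter_images(wavefield):
        if not np.all(np.isfinite(img)):
            raise ValueError("wave image contains non-finite values")
        band = config.bandpass([omega / (2 * math.pi)])  # per-frequency band
        a0 = np.abs(img)
        if config.flatten_sigma_px > 0 and a0.max() > 0:
            env = ndimage.gaussian_filter(a0, config.flatten_sigma_px)
            work = img / np.maximum(env, 1e-9 * env.max())
        else:
            work = img
        comps = directional_filter(work, config.n_directions, spacing2d, bandpass=band)
        # per-frequency plausibility gate on the local wavenumber: contributions
        # implying speeds far outside the expected physiological range are
        # filter leakage or phase-singularity spikes, not waves
        c_lo, c_hi = config.c_expected_range
        k_lo, k_hi = 0.8 * omega / c_hi, 1.2 * omega / c_lo
        for comp in comps:
            k, amp = estimate_wavenumber(comp, spacing2d, config.smoothing_sigma_px)
            if config.flatten_sigma_px > 0:
                amp = amp * a0  # directional share times true local amplitude
            w = amp ** config.amplitude_weight_power
            w = np.where((k >= k_lo) & (k <= k_hi), w, 0.0)
            ok = k > _EPS
            num[si][ok] += (w * (omega / np.maximum(k, _EPS)))[ok]
            den[si][ok] += w[ok]
    c_map = np.where(den > 0, num / np.maximum(den, _EPS), 0.0)
    return c_map, den


def invert_loss_angle(wavefield: WaveField, config: InversionConfig = InversionConfig(),
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Laplacian-based multifrequency loss-angle map.

    Returns ``(phi_map, denominator)``; the accumulated denominator plays the
    role of a confidence weight (it vanishes where the field carries no
    curvature information).
    """
    if len(wavefield.frequencies_hz) == 0:
        raise ValueError("wavefield has no frequencies")
    ns, nr, nc = wavefield.grid_shape
    num = np.zeros((ns, nr, nc))
    den = np.zeros((ns, nr, nc))
    dy, dx = (s * 1e-3 for s in wavefield.pixel_spacing_mm[1:])
    for _omega, si, img in _iter_images(wavefield):
        if not np.all(np.isfinite(img)):
            raise ValueError("wave image contains non-finite values")
        u = img
        if config.phi_smoothing_sigma_px > 0:
            u = (ndimage.gaussian_filter(u.real, config.phi_smoothing_sigma_px)
                 + 1j * ndimage.gaussian_filter(u.imag, config.phi_smoothing_sigma_px))
        lap = np.zeros_like(u)
        lap[1:-1, :] += (u[2:, :] - 2 * u[1:-1, :] + u[:-2, :]) / dy**2
        lap[:, 1:-1] += (u[:, 2:] - 2 * u[:, 1:-1] + u[:, :-2]) / dx**2
        num[si] += np.real(lap * np.conj(u))
        den[si] += np.abs(lap) * np.abs(u)
    ratio = np.where(den > _EPS, -num / np.maximum(den, _EPS), np.nan)
    phi = np.arccos(np.clip(ratio, -1.0, 1.0))
    phi = np.where(np.isfinite(phi), phi, 0.0)
    return np.clip(phi, 0.0, math.pi), den


def invert(wavefield: WaveField, config: InversionConfig = InversionConfig(),
           brain_mask: np.ndarray | None = None) -> ParameterMaps:
    """Joint inversion with shared validity handling and provenance.

    ``brain_mask`` (optional, bool) restricts validity; the configured edge
    margin is eroded off the mask because wavenumber and Laplacian estimates
    degrade at tissue boundaries.
    """
    c_map, w_c = invert_stiffness(wavefield, config)
    phi_map, w_phi = invert_loss_angle(wavefield, config)
    valid = (w_c > config.weight_rel_threshold * float(w_c.mean())) \
        & (w_phi > _EPS) & (c_map > 0)
    if brain_mask is not None:
        mask = np.asarray(brain_mask, dtype=bool)
        if mask.shape != valid.shape:
            raise ValueError("brain mask shape does not match wavefield grid")
        if config.edge_margin_px > 0:
            eroded = np.zeros_like(mask)
            for s in range(mask.shape[0]):
                eroded[s] = ndimage.binary_erosion(
                    mask[s], iterations=config.edge_margin_px, border_value=0)
            mask = eroded
        valid &= mask
    elif config.edge_margin_px > 0:
        eroded = np.zeros_like(valid)
        for s in range(valid.shape[0]):
            eroded[s] = ndimage.binary_erosion(
                valid[s], iterations=config.edge_margin_px, border_value=0)
        valid = eroded
    if not valid.any():
        raise ValueError("inversion produced no valid pixels "
                         "(all weights below threshold)")
    digest = hashlib.sha256(np.ascontiguousarray(wavefield.components).tobytes())
    prov = {"config": config.__dict__ | {}, "input_sha256": digest.hexdigest()}
    return ParameterMaps(c_map=c_map, phi_map=phi_map, valid_mask=valid,
                         pixel_spacing_mm=wavefield.pixel_spacing_mm,
                         provenance=prov)
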