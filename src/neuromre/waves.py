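"""Shear-wave forward models: analytic plane waves and an FDFD Helmholtz solver.

Conventions
-----------
Time-harmonic fields ``u(x) e^{-i omega t}``. For a medium with phase speed
``c`` (m/s) and loss angle ``phi`` (rad) the complex wavenumber is

    k = (omega / c) * (1 + i tan(phi / 2)),

so ``Re(k) = omega / c`` (the ground-truth phase speed is what a wavenumber
inversion estimates) and ``Im(k) > 0`` attenuates the wave along its
propagation direction. The complex shear modulus consistent with
``k^2 = rho omega^2 / G`` is ``G = rho c^2 cos^2(phi/2) e^{-i phi}``; its
phase magnitude equals the loss angle.

The heterogeneous forward model solves, slice by slice,

    div(G(x) grad u) + rho omega^2 u = 0

on a 2D grid by second-order finite differences, with boundary excitation on
configurable edge segments (Dirichlet lines) and a graded perfectly-matched
layer at the domain edge. An optional grid-refinement factor controls
numerical dispersion independently of the imaging grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu

from ._seeds import STAGE_WAVES, child_rng
from .phantom import Phantom

PAPER_FREQUENCIES_HZ = (1000.0, 1100.0, 1200.0, 1300.0, 1400.0)

EDGE_SOURCES = ("left", "right", "top", "bottom")


class SolverError(RuntimeError):
    """Raised when the FDFD solve does not satisfy its residual tolerance."""


def complex_wavenumber(c: float | np.ndarray, phi: float | np.ndarray,
                       freq_hz: float) -> np.ndarray:
    """Complex wavenumber (rad/m) with Re(k)=omega/c and attenuation from phi."""
    c = np.asarray(c, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    if np.any(~np.isfinite(c)) or np.any(c <= 0):
        raise ValueError("wave speed must be finite and positive")
    if np.any((phi < 0) | (phi >= math.pi / 2)):
        raise ValueError("loss angle must lie in [0, pi/2)")
    omega = 2 * math.pi * freq_hz
    return (omega / c) * (1.0 + 1j * np.tan(phi / 2.0))


def shear_modulus(c, phi, rho: float) -> np.ndarray:
    """Complex shear modulus G with |arg G| = phi, consistent with k^2 = rho w^2/G."""
    c = np.asarray(c, dtype=float)
    phi = np.asarray(phi, dtype=float)
    return rho * c**2 * np.cos(phi / 2.0) ** 2 * np.exp(-1j * phi)


def simulate_plane_wave(c: float, phi: float, freq_hz: float,
                        direction: tuple[float, float],
                        grid_shape: tuple[int, int],
                        pixel_spacing_mm: tuple[float, float] = (0.18, 0.18),
                        ) -> np.ndarray:
    """Analytic attenuated plane wave u(x) = exp(i k (d . x)) on a 2D grid.

    ``direction`` is an in-plane (dy, dx) vector (normalised internally);
    coordinates are in metres. Serves as the closed-form oracle for both the
    forward solver and the inversions.
    """
    d = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(d)
    if not np.isfinite(nrm) or nrm == 0:
        raise ValueError("direction must be a nonzero vector")
    d = d / nrm
    k = complex(complex_wavenumber(c, phi, freq_hz))
    nr, nc = grid_shape
    dy, dx = (s * 1e-3 for s in pixel_spacing_mm)
    yy = np.arange(nr)[:, None] * dy
    xx = np.arange(nc)[None, :] * dx
    proj = d[0] * yy + d[1] * xx
    return np.exp(1j * k * proj)


@dataclass
class WaveField:
    """Complex displacement images, one per (frequency, component, slice)."""

    frequencies_hz: tuple[float, ...]
    components: np.ndarray  # complex, shape (n_freq, n_comp, slices, rows, cols)
    pixel_spacing_mm: tuple[float, float, float]
    amplitude_units: str = "a.u."

    def __post_init__(self):
        self.components = np.asarray(self.components)
        if self.components.ndim != 5:
            raise ValueError("components must have shape (freq, comp, slice, row, col)")
        if self.components.shape[0] != len(self.frequencies_hz):
            raise ValueError("one image stack per frequency required")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.components.shape[2:]


def _pml_stretch(n: int, pml: int, h: float, omega: float, c_ref: float) -> np.ndarray:
    """1D complex coordinate-stretch factors s(x) = 1 + i sigma/omega."""
    sigma = np.zeros(n)
    if pml > 0:
        sigma_max = 3.0 * c_ref * math.log(1e4) / (2.0 * pml * h)
        t = np.arange(1, pml + 1) / pml
        sigma[:pml] = sigma_max * t[::-1] ** 2
        sigma[n - pml:] = sigma_max * t**2
    return 1.0 + 1j * sigma / omega


def _upsample_nearest(a: np.ndarray, factor: int, n_out: int, axis: int) -> np.ndarray:
    idx = np.clip(np.round(np.arange(n_out) / factor).astype(int), 0, a.shape[axis] - 1)
    return np.take(a, idx, axis=axis)


def solve_helmholtz_slice(G: np.ndarray, rho: float, freq_hz: float,
                          pixel_spacing_mm: tuple[float, float],
                          source: str = "left",
                          pml_px: int = 10,
                          refine: int = 1,
                          residual_tol: float = 1e-8) -> np.ndarray:
    """Solve div(G grad u) + rho omega^2 u = 0 on one slice.

    The wave is excited by a unit Dirichlet line one PML-width in from the
    ``source`` edge; all four edges carry a graded absorbing (PML) layer. With
    ``refine`` > 1 the PDE is discretised on an ``refine``-times finer grid
    (reducing numerical dispersion) and sampled back onto the imaging grid.
    """
    if source not in EDGE_SOURCES:
        raise ValueError(f"unknown source {source!r}")
    if freq_hz <= 0 or not np.isfinite(freq_hz):
        raise ValueError("frequency must be positive")
    G = np.asarray(G, dtype=complex)
    nr0, nc0 = G.shape
    q = int(refine)
    nr, nc = (nr0 - 1) * q + 1, (nc0 - 1) * q + 1
    if q > 1:
        G = _upsample_nearest(_upsample_nearest(G, q, nr, 0), q, nc, 1)
    hy, hx = (s * 1e-3 / q for s in pixel_spacing_mm)
    omega = 2 * math.pi * freq_hz
    pml = pml_px * q

    c_ref = float(np.median(np.sqrt(np.abs(G) / rho)))
    sy = _pml_stretch(nr, pml, hy, omega, c_ref)
    sx = _pml_stretch(nc, pml, hx, omega, c_ref)
    # half-node stretch factors and moduli
    sy_h = 0.5 * (sy[:-1] + sy[1:])
    sx_h = 0.5 * (sx[:-1] + sx[1:])
    Gy = 0.5 * (G[:-1, :] + G[1:, :])  # at (i+1/2, j)
    Gx = 0.5 * (G[:, :-1] + G[:, 1:])  # at (i, j+1/2)

    idx = np.arange(nr * nc).reshape(nr, nc)
    rows, cols, vals = [], [], []
    diag = np.full((nr, nc), rho * omega**2, dtype=complex)

    # y-direction couplings
    cy = (Gy / sy_h[:, None]) / (hy**2)
    cy_up = cy / sy[1:, None]      # contribution in the equation at node i+1
    cy_dn = cy / sy[:-1, None]     # at node i
    # x-direction couplings
    cx = (Gx / sx_h[None, :]) / (hx**2)
    cx_rt = cx / sx[None, 1:]
    cx_lf = cx / sx[None, :-1]

    # equation at (i, j):  cy_dn[i]*(u[i+1]-u[i]) - cy_up[i-1]*(u[i]-u[i-1]) + ... + rho w^2 u = 0
    ii = idx[:-1, :].ravel()
    jj = idx[1:, :].ravel()
    rows += [ii, ii, jj, jj]
    cols += [jj, ii, ii, jj]
    vals += [cy_dn.ravel(), -cy_dn.ravel(), cy_up.ravel(), -cy_up.ravel()]
    ii = idx[:, :-1].ravel()
    jj = idx[:, 1:].ravel()
    rows += [ii, ii, jj, jj]
    cols += [jj, ii, ii, jj]
    vals += [cx_lf.ravel(), -cx_lf.ravel(), cx_rt.ravel(), -cx_rt.ravel()]
    rows.append(idx.ravel())
    cols.append(idx.ravel())
    vals.append(diag.ravel())

    A = coo_matrix((np.concatenate(vals),
                    (np.concatenate(rows), np.concatenate(cols))),
                   shape=(nr * nc, nr * nc)).tocsr()

    # Dirichlet source line; the outer boundary is left natural (zero-flux),
    # which is exact for fields grazing the PML and reflection-free in tandem
    # with the absorbing layer.
    dir_mask = np.zeros((nr, nc), dtype=bool)
    rhs_val = np.zeros((nr, nc), dtype=complex)
    src_line = np.zeros((nr, nc), dtype=bool)
    if source == "left":
        src_line[:, pml] = True
    elif source == "right":
        src_line[:, nc - 1 - pml] = True
    elif source == "top":
        src_line[pml, :] = True
    else:
        src_line[nr - 1 - pml, :] = True
    dir_mask |= src_line
    rhs_val[src_line] = 1.0

    free = ~dir_mask.ravel()
    fixed = dir_mask.ravel()
    b = -(A[:, fixed] @ rhs_val.ravel()[fixed])
    A_ff = A[free][:, free]
    b_f = b[free]
    u = rhs_val.ravel().astype(complex)
    lu = splu(A_ff.tocsc())
    u_f = lu.solve(b_f)
    res = np.linalg.norm(A_ff @ u_f - b_f) / max(np.linalg.norm(b_f), 1e-300)
    if not np.isfinite(res) or res > residual_tol:
        raise SolverError(f"FDFD solve failed: relative residual {res:.3e}")
    u[free] = u_f
    return u.reshape(nr, nc)[::q, ::q]


def simulate_wavefield(phantom: Phantom,
                       frequencies_hz=PAPER_FREQUENCIES_HZ,
                       sources=EDGE_SOURCES,
                       noise_sigma: float = 0.0,
                       seed: int = 0,
                       refine: int = 2,
                       pml_px: int = 10) -> WaveField:
    """Simulate multifrequency wave images through a phantom.

    Per frequency and slice, fields excited from each configured edge are
    superposed (>= 4 directions by default), the superposition is normalised to
    unit median amplitude inside the brain, and complex Gaussian noise of
    standard deviation ``noise_sigma`` (per real/imag channel, in those
    amplitude units) is added. Deterministic for fixed (phantom spec, seed).
    """
    freqs = tuple(float(f) for f in frequencies_hz)
    if len(freqs) == 0:
        raise ValueError("at least one frequency required")
    if any(f <= 0 for f in freqs):
        raise ValueError("frequencies must be positive")
    ns, nr, nc = phantom.c_true.shape
    out = np.zeros((len(freqs), 1, ns, nr, nc), dtype=complex)
    rng = child_rng(seed, STAGE_WAVES)
    spacing2d = phantom.pixel_spacing_mm[1:]
    for fi, f in enumerate(freqs):
        for s in range(ns):
            G = shear_modulus(phantom.c_true[s], phantom.phi_true[s],
                              phantom.density_rho)
            u = np.zeros((nr, nc), dtype=complex)
            for src in sources:
                u += solve_helmholtz_slice(G, phantom.density_rho, f, spacing2d,
                                           source=src, pml_px=pml_px, refine=refine)
            scale = np.median(np.abs(u)[phantom.brain[s]]) if phantom.brain[s].any() \
                else np.median(np.abs(u))
            if scale > 0:
                u = u / scale
            if noise_sigma > 0:
                u = u + noise_sigma * (rng.standard_normal((nr, nc))
                                       + 1j * rng.standard_normal((nr, nc)))
            out[fi, 0, s] = u
    return WaveField(frequencies_hz=freqs, components=out,
                     pixel_spacing_mm=phantom.pixel_spacing_mm)
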