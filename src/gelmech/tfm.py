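"""Fourier-transform traction cytometry (FTTC).

A cell pulling on the surface of a soft elastic gel displaces fiducial
beads embedded near the surface.  Treating the gel as a semi-infinite,
incompressible elastic half-space loaded tangentially at its surface, the
displacement field u is the convolution of the traction field f with the
Boussinesq Green's tensor; in Fourier space the convolution becomes a
per-wavevector 2×2 multiply,

    ũ(k) = G̃(k) · f̃(k),
    G̃(k) = 2(1+ν)/(E·k³) · [[(1−ν)k² + ν·ky²,   −ν·kx·ky],
                             [−ν·kx·ky,   (1−ν)k² + ν·kx²]],

so the traction is recovered by inverting G̃ mode by mode.  The inversion
amplifies high-frequency noise, so a 0th-order Tikhonov scheme is used:

    f̃ = (G̃ᵀG̃ + λ²I)⁻¹ G̃ᵀ ũ,

with λ = 0 giving the plain inverse.  The k = 0 (DC) mode of both maps is
set to zero, which enforces zero net force and zero mean displacement.

Also provided: single-pass PIV (normalized cross-correlation with
parabolic subpixel refinement) to estimate the displacement field from a
stressed/relaxed bead-image pair, and summary statistics (total force,
mean and peak traction stress) over a cell mask.

Coordinate convention: row-major grids, x = columns increasing rightward,
y = rows increasing downward; vector components are expressed in the same
frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import match_template

__all__ = [
    "ElasticHalfSpace",
    "DisplacementField",
    "TractionField",
    "FTTCParams",
    "TractionSummary",
    "BeadImagePair",
    "greens_tensor_fourier",
    "forward_displacement",
    "reconstruct_traction",
    "estimate_displacement",
    "traction_summaries",
    "lambda_grid_search",
    "read_vector_field",
    "write_vector_field",
]


@dataclass(frozen=True)
class ElasticHalfSpace:
    """Substrate elasticity: Young's modulus E (Pa), Poisson ratio ν."""

    E: float
    poisson: float = 0.5

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be > 0")
        if not 0.0 <= self.poisson <= 0.5:
            raise ValueError("poisson must lie in [0, 0.5]")


@dataclass
class DisplacementField:
    """Regular-grid surface displacement (meters); spacing in meters/step."""

    spacing: float
    ux: np.ndarray
    uy: np.ndarray

    def __post_init__(self) -> None:
        self.ux = np.asarray(self.ux, dtype=float)
        self.uy = np.asarray(self.uy, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.ux.shape != self.uy.shape or self.ux.ndim != 2:
            raise ValueError("ux and uy must be equal-shape 2D arrays")
        if not (np.all(np.isfinite(self.ux)) and np.all(np.isfinite(self.uy))):
            raise ValueError("displacement values must be finite")

    @property
    def grid(self) -> tuple:
        return self.ux.shape


@dataclass
class TractionField:
    """Regular-grid surface traction stress (Pa); spacing in meters/step."""

    spacing: float
    fx: np.ndarray
    fy: np.ndarray

    def __post_init__(self) -> None:
        self.fx = np.asarray(self.fx, dtype=float)
        self.fy = np.asarray(self.fy, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.fx.shape != self.fy.shape or self.fx.ndim != 2:
            raise ValueError("fx and fy must be equal-shape 2D arrays")
        if not (np.all(np.isfinite(self.fx)) and np.all(np.isfinite(self.fy))):
            raise ValueError("traction values must be finite")

    @property
    def grid(self) -> tuple:
        return self.fx.shape

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.fx, self.fy)


@dataclass(frozen=True)
class FTTCParams:
    """Inversion controls: Tikhonov λ (m/Pa), zero-pad factor, window."""

    lambda_reg: float = 0.0
    pad_factor: int = 2
    window: str = "none"

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.pad_factor < 1 or int(self.pad_factor) != self.pad_factor:
            raise ValueError("pad_factor must be an integer >= 1")
        if self.window not in ("none", "hann"):
            raise ValueError("window must be 'none' or 'hann'")


@dataclass(frozen=True)
class TractionSummary:
    """Mask statistics of a traction field.

    ``total_force`` integrates |f| over the mask (Σ|f|·spacing², newtons);
    ``total_stress`` is the un-integrated sum of stress magnitudes (Pa),
    emitted alongside because "total traction" is reported both ways in
    the literature.
    """

    total_force: float
    total_stress: float
    mean_stress: float
    max_stress: float
    mask_area: float


@dataclass
class BeadImagePair:
    """Stressed (cell attached) / relaxed (cell released) bead images."""

    image_stressed: np.ndarray
    image_relaxed: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.image_stressed = np.asarray(self.image_stressed, dtype=float)
        self.image_relaxed = np.asarray(self.image_relaxed, dtype=float)
        if self.image_stressed.shape != self.image_relaxed.shape:
            raise ValueError("bead images must have equal shapes")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


# ---------------------------------------------------------------------------
# Green's tensor and the forward/inverse maps
# ---------------------------------------------------------------------------

def greens_tensor_fourier(kx: float, ky: float,
                          substrate: ElasticHalfSpace) -> np.ndarray:
    """Boussinesq half-space Green's tensor at one wavevector (m/Pa).

    Symmetric 2×2; entries scale as 1/E.  Raises at k = 0 — the DC mode is
    handled by the field-level maps (set to zero).
    """
    k2 = kx * kx + ky * ky
    if k2 == 0.0:
        raise ValueError("Green's tensor is singular at k = 0 (DC handled by caller)")
    k = np.sqrt(k2)
    nu, E = substrate.poisson, substrate.E
    pref = 2.0 * (1.0 + nu) / (E * k**3)
    return pref * np.array([
        [(1.0 - nu) * k2 + nu * ky * ky, -nu * kx * ky],
        [-nu * kx * ky, (1.0 - nu) * k2 + nu * kx * kx],
    ])


def _greens_grids(ny: int, nx: int, spacing: float, substrate: ElasticHalfSpace):
    """Vectorised Green's tensor entries on the FFT frequency grid.

    Returns (G11, G12, G22) with the DC entry set to 0.
    """
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing)
    KX, KY = np.meshgrid(kx, ky)
    K2 = KX**2 + KY**2
    K2[0, 0] = 1.0  # placeholder; DC zeroed below
    K = np.sqrt(K2)
    nu, E = substrate.poisson, substrate.E
    pref = 2.0 * (1.0 + nu) / (E * K**3)
    G11 = pref * ((1.0 - nu) * K2 + nu * KY**2)
    G22 = pref * ((1.0 - nu) * K2 + nu * KX**2)
    G12 = pref * (-nu * KX * KY)
    G11[0, 0] = G12[0, 0] = G22[0, 0] = 0.0
    return G11, G12, G22


def _pad(a: np.ndarray, pad_factor: int) -> np.ndarray:
    ny, nx = a.shape
    if pad_factor == 1:
        return a
    out = np.zeros((ny * pad_factor, nx * pad_factor), dtype=a.dtype)
    out[:ny, :nx] = a
    return out


def forward_displacement(traction: TractionField,
                         substrate: ElasticHalfSpace,
                         pad_factor: int = 1) -> DisplacementField:
    """Surface displacement produced by a traction field (forward model).

    FFT → per-mode multiply by the Green's tensor → inverse FFT.  The DC
    mode is zeroed (zero-mean displacement).  Linear in the traction.
    """
    ny, nx = traction.grid
    fx = _pad(traction.fx, pad_factor)
    fy = _pad(traction.fy, pad_factor)
    G11, G12, G22 = _greens_grids(*fx.shape, traction.spacing, substrate)
    Fx, Fy = np.fft.fft2(fx), np.fft.fft2(fy)
    Ux = G11 * Fx + G12 * Fy
    Uy = G12 * Fx + G22 * Fy
    ux = np.real(np.fft.ifft2(Ux))[:ny, :nx]
    uy = np.real(np.fft.ifft2(Uy))[:ny, :nx]
    return DisplacementField(traction.spacing, ux, uy)


def reconstruct_traction(displacement: DisplacementField,
                         substrate: ElasticHalfSpace,
                         params: FTTCParams = FTTCParams()) -> TractionField:
    """Tikhonov-regularised FTTC inversion of a displacement field.

    Per wavevector solves f̃ = (G̃ᵀG̃ + λ²I)⁻¹ G̃ᵀ ũ with an explicit
    symmetric 2×2 inverse; λ = 0 reduces to f̃ = G̃⁻¹ũ.  The DC traction is
    set to zero (zero net force).  Optional zero padding (``pad_factor``)
    softens the periodic-boundary artefact of the FFT convolution; an
    optional Hann window tapers the displacement before padding.
    """
    ny, nx = displacement.grid
    ux, uy = displacement.ux, displacement.uy
    if params.window == "hann":
        wy = np.hanning(ny)[:, None]
        wx = np.hanning(nx)[None, :]
        w = wy * wx
        ux, uy = ux * w, uy * w
    ux = _pad(ux, params.pad_factor)
    uy = _pad(uy, params.pad_factor)
    G11, G12, G22 = _greens_grids(*ux.shape, displacement.spacing, substrate)
    Uxf, Uyf = np.fft.fft2(ux), np.fft.fft2(uy)
    lam2 = params.lambda_reg**2
    # A = G^T G + lambda^2 I  (G symmetric)
    A11 = G11 * G11 + G12 * G12 + lam2
    A12 = G12 * (G11 + G22)
    A22 = G22 * G22 + G12 * G12 + lam2
    b1 = G11 * Uxf + G12 * Uyf
    b2 = G12 * Uxf + G22 * Uyf
    det = A11 * A22 - A12 * A12
    det[0, 0] = 1.0  # DC zeroed below
    Fx = (A22 * b1 - A12 * b2) / det
    Fy = (A11 * b2 - A12 * b1) / det
    Fx[0, 0] = Fy[0, 0] = 0.0
    fx = np.real(np.fft.ifft2(Fx))[:ny, :nx]
    fy = np.real(np.fft.ifft2(Fy))[:ny, :nx]
    return TractionField(displacement.spacing, fx, fy)


def lambda_grid_search(displacement: DisplacementField,
                       substrate: ElasticHalfSpace,
                       truth: TractionField,
                       lambdas: Sequence[float],
                       pad_factor: int = 2,
                       support: np.ndarray | None = None):
    """Testing helper: pick the λ minimising L2 error against a known truth.

    Returns (best_lambda, errors). Intended for synthetic-data studies only —
    real data has no ground truth and λ must be chosen by the user.
    """
    mag = truth.magnitude
    if support is None:
        support = mag >= 0.05 * mag.max()
    norm = np.sqrt(np.sum(truth.fx[support] ** 2 + truth.fy[support] ** 2))
    errors = []
    for lam in lambdas:
        rec = reconstruct_traction(
            displacement, substrate,
            FTTCParams(lambda_reg=lam, pad_factor=pad_factor))
        err = np.sqrt(np.sum((rec.fx[support] - truth.fx[support]) ** 2
                             + (rec.fy[support] - truth.fy[support]) ** 2))
        errors.append(err / norm)
    errors = np.asarray(errors)
    return float(lambdas[int(np.argmin(errors))]), errors


# ---------------------------------------------------------------------------
# PIV displacement estimation from bead images
# ---------------------------------------------------------------------------

def estimate_displacement(pair: BeadImagePair,
                          window_px: int = 16,
                          overlap: float = 0.5,
                          search_margin: int | None = None,
                          peak_ratio_threshold: float = 1.1) -> DisplacementField:
    """Single-pass PIV between the relaxed and stressed bead images.

    Each interrogation window of the relaxed (reference) image is matched
    against a search region of the stressed image by normalized
    cross-correlation; the correlation peak gives the bead displacement,
    refined to subpixel precision by a 3-point parabolic fit along each
    axis (skipped when the match is numerically exact, where the
    displacement is exactly integer).  Vectors whose primary/secondary
    correlation-peak ratio falls below ``peak_ratio_threshold`` are flagged
    spurious and replaced by the median of their neighbours.
    """
    if window_px < 8:
        raise ValueError("window_px must be >= 8")
    img_r = pair.image_relaxed
    img_s = pair.image_stressed
    H, W = img_r.shape
    if window_px > min(H, W):
        raise ValueError("window larger than image")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    if search_margin is None:
        search_margin = window_px // 2
    step = max(int(round(window_px * (1.0 - overlap))), 1)
    m = search_margin
    rows = range(m, H - window_px - m + 1, step)
    cols = range(m, W - window_px - m + 1, step)
    rows = list(rows)
    cols = list(cols)
    if not rows or not cols:
        raise ValueError("image too small for window + search margin")
    vy = np.zeros((len(rows), len(cols)))
    vx = np.zeros((len(rows), len(cols)))
    ok = np.ones((len(rows), len(cols)), dtype=bool)

    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            tmpl = img_r[r:r + window_px, c:c + window_px]
            search = img_s[r - m:r + window_px + m, c - m:c + window_px + m]
            if tmpl.std() == 0 or search.std() == 0:
                ok[i, j] = False
                continue
            corr = match_template(search, tmpl)
            pk = np.unravel_index(np.argmax(corr), corr.shape)
            peak = corr[pk]
            # second peak outside a 3x3 exclusion zone around the primary
            masked = corr.copy()
            r0, c0 = pk
            masked[max(r0 - 1, 0):r0 + 2, max(c0 - 1, 0):c0 + 2] = -np.inf
            second = masked.max()
            if second > 0 and peak / max(second, 1e-12) < peak_ratio_threshold:
                ok[i, j] = False
            dy = pk[0] - m
            dx = pk[1] - m
            if peak < 1.0 - 1e-7:  # subpixel refinement of an inexact match
                dy += _parabolic_offset(corr, pk, axis=0)
                dx += _parabolic_offset(corr, pk, axis=1)
            vy[i, j], vx[i, j] = dy, dx

    # replace spurious vectors by the median of their neighbourhood
    if not ok.all():
        med_y = ndimage.median_filter(vy, size=3, mode="nearest")
        med_x = ndimage.median_filter(vx, size=3, mode="nearest")
        vy[~ok] = med_y[~ok]
        vx[~ok] = med_x[~ok]

    ps = pair.pixel_size
    return DisplacementField(spacing=step * ps, ux=vx * ps, uy=vy * ps)


def _parabolic_offset(corr: np.ndarray, peak, axis: int) -> float:
    """Vertex offset of the parabola through the peak and its axis neighbours."""
    idx = list(peak)
    if idx[axis] == 0 or idx[axis] == corr.shape[axis] - 1:
        return 0.0
    b = corr[tuple(idx)]
    idx[axis] -= 1
    a = corr[tuple(idx)]
    idx[axis] += 2
    c = corr[tuple(idx)]
    denom = a - 2.0 * b + c
    if denom == 0.0:
        return 0.0
    return float(0.5 * (a - c) / denom)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def traction_summaries(traction: TractionField, mask: np.ndarray) -> TractionSummary:
    """Total/mean/max traction stress over a mask (e.g. the cell footprint)."""
    mask = np.asarray(mask)
    if mask.shape != traction.grid:
        raise ValueError("mask must match the traction grid")
    sel = mask > 0
    if not sel.any():
        raise ValueError("empty mask")
    mag = traction.magnitude[sel]
    area_per_cell = traction.spacing**2
    return TractionSummary(
        total_force=float(mag.sum() * area_per_cell),
        total_stress=float(mag.sum()),
        mean_stress=float(mag.mean()),
        max_stress=float(mag.max()),
        mask_area=float(sel.sum() * area_per_cell),
    )


# ---------------------------------------------------------------------------
# Vector-field file I/O (CSV with x_m, y_m and either u or f columns)
# ---------------------------------------------------------------------------

def write_vector_field(path, field) -> None:
    """Write a displacement or traction field as a tidy CSV grid table."""
    if isinstance(field, DisplacementField):
        c1, c2, a1, a2 = "ux_m", "uy_m", field.ux, field.uy
    elif isinstance(field, TractionField):
        c1, c2, a1, a2 = "fx_pa", "fy_pa", field.fx, field.fy
    else:
        raise TypeError("expected DisplacementField or TractionField")
    ny, nx = a1.shape
    ys, xs = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    pd.DataFrame({
        "x_m": xs.ravel() * field.spacing,
        "y_m": ys.ravel() * field.spacing,
        c1: a1.ravel(),
        c2: a2.ravel(),
    }).to_csv(path, index=False)


def read_vector_field(path):
    """Read a CSV grid table back into a Displacement- or TractionField."""
    df = pd.read_csv(path)
    xs = np.unique(df["x_m"].to_numpy())
    ys = np.unique(df["y_m"].to_numpy())
    nx, ny = xs.size, ys.size
    if len(df) != nx * ny:
        raise ValueError("vector field file is not a complete regular grid")
    dxs = np.diff(xs)
    if nx > 1 and not np.allclose(dxs, dxs[0], rtol=1e-6):
        raise ValueError("x coordinates are not equally spaced")
    spacing = float(dxs[0]) if nx > 1 else float(np.diff(ys)[0])
    df = df.sort_values(["y_m", "x_m"])
    if {"ux_m", "uy_m"} <= set(df.columns):
        return DisplacementField(spacing,
                                 df["ux_m"].to_numpy().reshape(ny, nx),
                                 df["uy_m"].to_numpy().reshape(ny, nx))
    if {"fx_pa", "fy_pa"} <= set(df.columns):
        return TractionField(spacing,
                             df["fx_pa"].to_numpy().reshape(ny, nx),
                             df["fy_pa"].to_numpy().reshape(ny, nx))
    raise ValueError("expected ux_m/uy_m or fx_pa/fy_pa columns")
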