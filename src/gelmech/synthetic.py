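"""Seeded synthetic-data generators with known ground truth.

Every pipeline stage in this package has a matching generator here that
produces the inputs the instrument would have produced, bundled with the
parameters used to make them.  Recovery of those parameters by the
analysis code is the package's core validation loop.

All randomness flows from one ``numpy.random.default_rng(seed)`` per
scene; identical (parameters, seed) pairs are bit-identical.  Noise is
additive Gaussian with the stated SD; SD = 0 reproduces the analytic
forward model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import draw

from .afm import (CoordinateKind, ForceSegment, ProbeSpec, SegmentLabel,
                  hertz_force)
from .images import QuantImage, RegionMask
from .tfm import (BeadImagePair, DisplacementField, ElasticHalfSpace,
                  TractionField, forward_displacement)

__all__ = [
    "SyntheticScene",
    "gen_hertz_curve",
    "gen_viscoelastic_segments",
    "gen_traction_scene",
    "gen_cell_image",
    "render_beads",
]


@dataclass
class SyntheticScene:
    """A generated input bundled with the ground truth that produced it."""

    kind: str
    ground_truth: dict
    seed: int
    payload: dict


# ---------------------------------------------------------------------------
# AFM force curves
# ---------------------------------------------------------------------------

def gen_hertz_curve(
    E: float,
    R: float = 10e-6,
    poisson: float = 0.5,
    max_indent: float = 1e-6,
    n_samples: int = 500,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
    pre_contact_fraction: float = 0.25,
    approach_speed: float = 2e-6,
    raw: bool = False,
    probe: ProbeSpec | None = None,
    contact_height: float = 0.0,
) -> SyntheticScene:
    """Spherical-indenter approach curve following the Hertz law.

    The indentation sweeps from −``pre_contact_fraction``·max_indent
    (tip above the surface, zero force) to ``max_indent`` at constant
    approach speed.  Noise is Gaussian with SD = ``noise_sd_frac`` × the
    local noiseless force.  With ``raw=True`` the payload additionally
    carries the (time, height, deflection) triplet an instrument records,
    built with the given probe spring constant, for exercising the raw
    conversion path.
    """
    if min(E, R, max_indent, n_samples) <= 0:
        raise ValueError("parameters must be positive")
    if max_indent >= R:
        raise ValueError("max_indent must be << R for Hertz validity")
    rng = np.random.default_rng(seed)
    delta = np.linspace(-pre_contact_fraction * max_indent, max_indent, n_samples)
    time = (delta - delta[0]) / approach_speed
    force = hertz_force(delta, E, R, poisson)
    if noise_sd_frac > 0:
        force = force + rng.normal(0.0, 1.0, force.shape) * noise_sd_frac * np.abs(force)
    curve = ForceSegment(SegmentLabel.APPROACH, time, delta, force,
                         CoordinateKind.INDENTATION)
    payload = {"curve": curve}
    if raw:
        if probe is None:
            probe = ProbeSpec(spring_constant=0.3, tip_radius=R)
        deflection = force / probe.spring_constant
        height = contact_height + delta + deflection
        payload["raw"] = {"time": time, "height": height,
                          "deflection": deflection, "probe": probe,
                          "contact_height": contact_height}
    gt = {"E": E, "R": R, "poisson": poisson, "max_indent": max_indent,
          "contact_point": 0.0, "noise_sd_frac": noise_sd_frac, "seed": seed}
    return SyntheticScene("force_curve", gt, seed, payload)


def gen_viscoelastic_segments(
    tan_delta: float = 0.1,
    f0: float = 10.0,
    amp: float = 10e-9,
    hold_s: float = 60.0,
    relax_fraction: float = 0.4,
    tau_s: float = 5.0,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
    F0: float = 1e-8,
    force_amp: float = 2e-9,
    osc_s: float = 0.4,
    sample_rate: float = 5000.0,
    baseline_offset: float = 0.0,
    approach_s: float = 0.0,
    indent_depth: float = 1e-6,
) -> SyntheticScene:
    """Pause (stress-relaxation hold) + oscillation segments.

    The hold follows a standard-linear-solid decay
    F(t) = F0·((1−relax_fraction) + relax_fraction·e^(−t/τ)); the
    oscillation is a phase-lagged sinusoid whose force leads the
    indentation by arctan(tan_delta).  Defaults mirror a 10 Hz, 10 nm
    microrheology segment and a 60 s relaxation hold.  ``approach_s`` > 0
    prepends a baseline + linear ramp (with optional ``baseline_offset``)
    for exercising the alignment steps of the relaxation pipeline.
    """
    if not 0.0 <= relax_fraction <= 1.0:
        raise ValueError("relax_fraction must lie in [0, 1]")
    if tan_delta < 0:
        raise ValueError("tan_delta must be >= 0")
    if min(hold_s, osc_s, sample_rate) <= 0 or approach_s < 0:
        raise ValueError("durations and sample_rate must be positive")
    rng = np.random.default_rng(seed)
    dt_hold = max(hold_s / 2000.0, 1e-4)

    t_hold = np.arange(0.0, hold_s + dt_hold / 2, dt_hold)
    f_hold = F0 * ((1.0 - relax_fraction)
                   + relax_fraction * np.exp(-t_hold / tau_s))
    if approach_s > 0:
        n_app = max(int(approach_s / dt_hold), 4)
        t_app = np.linspace(-approach_s, -dt_hold, n_app)
        f_app = np.where(t_app < -approach_s / 2, 0.0,
                         F0 * (t_app + approach_s / 2) / (approach_s / 2))
        t_full = np.concatenate([t_app, t_hold]) + approach_s
        f_full = np.concatenate([f_app, f_hold])
    else:
        t_full, f_full = t_hold, f_hold
    f_full = f_full + baseline_offset
    if noise_sd_frac > 0:
        f_full = f_full + rng.normal(0.0, noise_sd_frac * F0, f_full.shape)
    pause = ForceSegment(SegmentLabel.PAUSE, t_full,
                         np.full_like(t_full, indent_depth), f_full,
                         CoordinateKind.INDENTATION)

    n_osc = int(osc_s * sample_rate)
    t_osc = np.arange(n_osc) / sample_rate
    phase = np.arctan(tan_delta)
    pos = indent_depth + amp * np.sin(2.0 * np.pi * f0 * t_osc)
    frc = (F0 * (1.0 - relax_fraction)
           + force_amp * np.sin(2.0 * np.pi * f0 * t_osc + phase))
    if noise_sd_frac > 0:
        pos = pos + rng.normal(0.0, noise_sd_frac * amp, pos.shape)
        frc = frc + rng.normal(0.0, noise_sd_frac * force_amp, frc.shape)
    osc = ForceSegment(SegmentLabel.OSCILLATION, t_osc, pos, frc,
                       CoordinateKind.INDENTATION)

    gt = {"tan_delta": tan_delta, "f0": f0, "amp": amp, "F0": F0,
          "relax_fraction": relax_fraction, "tau_s": tau_s, "hold_s": hold_s,
          "energy_dissipation_pct":
              float(relax_fraction * (1.0 - np.exp(-hold_s / tau_s)) * 100.0),
          "baseline_offset": baseline_offset, "seed": seed}
    return SyntheticScene("relaxation_oscillation", gt, seed,
                          {"pause": pause, "oscillation": osc})


# ---------------------------------------------------------------------------
# Traction scenes
# ---------------------------------------------------------------------------

def render_beads(shape, positions: np.ndarray, spot_sd: float = 1.0,
                 amplitude: float = 1.0) -> np.ndarray:
    """Render Gaussian bead spots (SD in px) at subpixel positions (row, col)."""
    img = np.zeros(shape)
    half = int(np.ceil(4 * spot_sd))
    ax = np.arange(-half, half + 1)
    for r, c in positions:
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < shape[0] and 0 <= ci < shape[1]):
            continue
        dy = (ax + ri - r)[:, None]
        dx = (ax + ci - c)[None, :]
        stamp = amplitude * np.exp(-(dy**2 + dx**2) / (2.0 * spot_sd**2))
        r0, r1 = max(ri - half, 0), min(ri + half + 1, shape[0])
        c0, c1 = max(ci - half, 0), min(ci + half + 1, shape[1])
        img[r0:r1, c0:c1] += stamp[r0 - (ri - half):stamp.shape[0] - ((ri + half + 1) - r1),
                                   c0 - (ci - half):stamp.shape[1] - ((ci + half + 1) - c1)]
    return img


def gen_traction_scene(
    patches: Sequence[dict],
    grid: tuple = (64, 64),
    spacing: float = 1e-6,
    substrate: ElasticHalfSpace = ElasticHalfSpace(E=12e3),
    noise_sd_frac: float = 0.0,
    render_bead_images: bool = False,
    pixel_size: float | None = None,
    bead_density: float = 0.02,
    bead_spot_sd: float = 1.0,
    pad_factor: int = 2,
    seed: int = 0,
) -> SyntheticScene:
    """Ground-truth Gaussian traction patches and their displacement field.

    Each patch is ``{"center": (x_m, y_m), "sd": m, "peak_pa": Pa,
    "direction": (dx, dy)}``; the direction is normalised internally.
    Displacement comes from the half-space forward model; optional noise
    is Gaussian with SD = ``noise_sd_frac`` × max |u|.  With
    ``render_bead_images=True`` a stressed/relaxed bead-image pair is
    rendered: beads scattered uniformly, advected by the (bilinear-
    interpolated) displacement field in the stressed frame.
    """
    ny, nx = grid
    rng = np.random.default_rng(seed)
    ys = np.arange(ny)[:, None] * spacing
    xs = np.arange(nx)[None, :] * spacing
    fx = np.zeros(grid)
    fy = np.zeros(grid)
    import warnings
    for p in patches:
        cx, cy = p["center"]
        sd = p["sd"]
        if sd < spacing:
            warnings.warn("patch sd below grid spacing: aliasing likely",
                          RuntimeWarning)
        d = np.asarray(p["direction"], dtype=float)
        d = d / np.linalg.norm(d)
        g = p["peak_pa"] * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * sd**2))
        fx += g * d[0]
        fy += g * d[1]
    truth = TractionField(spacing, fx, fy)
    disp = forward_displacement(truth, substrate, pad_factor=pad_factor)
    ux, uy = disp.ux, disp.uy
    umax = max(np.abs(ux).max(), np.abs(uy).max(), 1e-30)
    if noise_sd_frac > 0:
        ux = ux + rng.normal(0.0, noise_sd_frac * umax, ux.shape)
        uy = uy + rng.normal(0.0, noise_sd_frac * umax, uy.shape)
    noisy = DisplacementField(spacing, ux, uy)
    payload = {"traction": truth, "displacement": noisy,
               "displacement_clean": disp}
    if render_bead_images:
        if pixel_size is None:
            pixel_size = spacing / 4.0
        H = int(round(ny * spacing / pixel_size))
        W = int(round(nx * spacing / pixel_size))
        n_beads = int(bead_density * H * W)
        pos = rng.uniform([0, 0], [H - 1, W - 1], size=(n_beads, 2))
        # bilinear displacement (meters) at bead positions, in grid coords
        coords = pos * pixel_size / spacing
        dr = ndimage.map_coordinates(disp.uy, coords.T, order=1) / pixel_size
        dc = ndimage.map_coordinates(disp.ux, coords.T, order=1) / pixel_size
        relaxed = render_beads((H, W), pos, bead_spot_sd)
        stressed = render_beads((H, W), pos + np.column_stack([dr, dc]),
                                bead_spot_sd)
        payload["beads"] = BeadImagePair(stressed, relaxed, pixel_size)
    gt = {"patches": list(patches), "grid": grid, "spacing": spacing,
          "E": substrate.E, "poisson": substrate.poisson,
          "noise_sd_frac": noise_sd_frac, "seed": seed}
    return SyntheticScene("traction_scene", gt, seed, payload)


# ---------------------------------------------------------------------------
# Cell images
# ---------------------------------------------------------------------------

def _rotated_bar(center_rc, length_px: float, width_px: float,
                 angle: float, shape) -> tuple:
    """Pixel indices of a filled rotated rectangle (bar)."""
    L, w = length_px / 2.0, width_px / 2.0
    ca, sa = np.cos(angle), np.sin(angle)
    corners = np.array([[-L, -w], [L, -w], [L, w], [-L, w]])
    rot = corners @ np.array([[ca, sa], [-sa, ca]])
    rows = rot[:, 1] + center_rc[0]
    cols = rot[:, 0] + center_rc[1]
    return draw.polygon(rows, cols, shape=shape)


def gen_cell_image(
    nc_ratio: float = 2.0,
    nucleus_axes_um: tuple = (8.0, 6.0),
    cell_axes_um: tuple = (25.0, 18.0),
    fa_lengths_um: Sequence[float] = (),
    stripe_anisotropy: float = 1.0,
    stripe_period_um: float = 2.0,
    pixel_size_um: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SyntheticScene:
    """Synthetic immunofluorescence scene with exact ground truth.

    Payload channels (all :class:`QuantImage`, pixel size in µm):

    * ``yap`` — uniform nuclear intensity ``nc_ratio`` and cytoplasmic 1.0,
      so the area-normalised N/C ratio equals ``nc_ratio`` exactly in the
      noiseless limit;
    * ``fa`` — rotated bars of the requested physical lengths (3 px wide);
    * ``actin`` — oriented sinusoidal stripe texture blended with smoothed
      noise; ``stripe_anisotropy`` = 1 gives pure parallel stripes.

    Masks: elliptical ``nucleus`` and ``cell`` (nucleus concentric,
    strictly inside the cell).
    """
    if nc_ratio <= 0:
        raise ValueError("nc_ratio must be > 0")
    if (nucleus_axes_um[0] >= cell_axes_um[0]
            or nucleus_axes_um[1] >= cell_axes_um[1]):
        raise ValueError("nucleus must fit inside the cell")
    if not 0.0 <= stripe_anisotropy <= 1.0:
        raise ValueError("stripe_anisotropy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ps = pixel_size_um
    ax, ay = cell_axes_um[0] / ps, cell_axes_um[1] / ps
    H = int(np.ceil(2.6 * ay))
    W = int(np.ceil(2.6 * ax))
    cy, cx = H / 2.0, W / 2.0
    yy = np.arange(H)[:, None] - cy
    xx = np.arange(W)[None, :] - cx
    cell = (xx / ax) ** 2 + (yy / ay) ** 2 <= 1.0
    nax, nay = nucleus_axes_um[0] / ps, nucleus_axes_um[1] / ps
    nucleus = (xx / nax) ** 2 + (yy / nay) ** 2 <= 1.0

    yap = np.zeros((H, W))
    yap[cell] = 1.0
    yap[nucleus] = nc_ratio
    if noise_sd > 0:
        yap = np.clip(yap + rng.normal(0.0, noise_sd, yap.shape), 0.0, None)

    fa = np.zeros((H, W))
    angles = rng.uniform(0.0, np.pi, size=len(fa_lengths_um))
    # place bars on a coarse grid of slots so they never touch
    slot = max(int(max(fa_lengths_um) / ps) + 6, 8) if fa_lengths_um else 8
    slots = [(r + slot // 2, c + slot // 2)
             for r in range(2, H - slot, slot)
             for c in range(2, W - slot, slot)]
    if len(slots) < len(fa_lengths_um):
        raise ValueError("too many focal adhesions for the image size")
    order = rng.permutation(len(slots))
    for i, (length_um, ang) in enumerate(zip(fa_lengths_um, angles)):
        rr, cc = _rotated_bar(slots[order[i]], length_um / ps, 3.0, ang, (H, W))
        fa[rr, cc] = 1.0
    if noise_sd > 0:
        fa = np.clip(fa + rng.normal(0.0, noise_sd, fa.shape), 0.0, None)

    theta = rng.uniform(0.0, np.pi)
    period_px = stripe_period_um / ps
    phase_field = (xx * np.cos(theta) + yy * np.sin(theta)) * 2.0 * np.pi / period_px
    stripes = 0.5 + 0.5 * np.sin(phase_field)
    rough = ndimage.gaussian_filter(rng.uniform(0.0, 1.0, (H, W)), 1.0)
    rough = (rough - rough.min()) / max(rough.max() - rough.min(), 1e-12)
    actin = stripe_anisotropy * stripes + (1.0 - stripe_anisotropy) * rough
    if noise_sd > 0:
        actin = np.clip(actin + rng.normal(0.0, noise_sd, actin.shape), 0.0, None)

    payload = {
        "yap": QuantImage(yap, ps, "yap"),
        "fa": QuantImage(fa, ps, "p-fak"),
        "actin": QuantImage(actin, ps, "actin"),
        "nucleus_mask": RegionMask(nucleus.astype(int)),
        "cell_mask": RegionMask(cell.astype(int)),
    }
    gt = {"nc_ratio": nc_ratio, "fa_lengths_um": list(fa_lengths_um),
          "stripe_anisotropy": stripe_anisotropy, "stripe_angle": float(theta),
          "nucleus_axes_um": tuple(nucleus_axes_um),
          "cell_axes_um": tuple(cell_axes_um),
          "pixel_size_um": ps, "noise_sd": noise_sd, "seed": seed}
    return SyntheticScene("cell_image", gt, seed, payload)
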