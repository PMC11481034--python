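"""AFM force-curve mechanics.

Turns force-spectroscopy segments acquired with a spherical probe into the
three mechanical readouts used to characterise soft hydrogels:

* Young's modulus from a Hertz fit of the approach segment,
* loss tangent tan(δ) from a small-amplitude oscillation segment
  (lock-in amplitude/phase estimation at the drive frequency),
* energy dissipation from constant-indentation stress-relaxation holds.

All quantities are SI internally (m, N, Pa, s). File readers convert from
declared column units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "SegmentLabel",
    "CoordinateKind",
    "ForceSegment",
    "ProbeSpec",
    "HertzFit",
    "OscillationResult",
    "RelaxationResult",
    "InputError",
    "NoContactError",
    "InsufficientDataError",
    "NonPhysicalError",
    "DegenerateCurveError",
    "hertz_force",
    "preprocess_raw_curve",
    "detect_contact_point",
    "fit_hertz",
    "oscillation_loss_tangent",
    "process_relaxation",
    "energy_dissipation",
]


class InputError(ValueError):
    """Malformed input (mismatched lengths, non-increasing time, bad units)."""


class NoContactError(RuntimeError):
    """Contact detection found no force rise above the baseline noise."""


class InsufficientDataError(RuntimeError):
    """Too few samples for the requested fit."""


class NonPhysicalError(RuntimeError):
    """Result outside the physically admissible range (e.g. phase lag ≥ π/2)."""


class DegenerateCurveError(RuntimeError):
    """Relaxation curve without a positive peak force."""


class SegmentLabel(str, Enum):
    APPROACH = "approach"
    PAUSE = "pause"
    OSCILLATION = "oscillation"
    RETRACT = "retract"


class CoordinateKind(str, Enum):
    """What the ``position`` array of a :class:`ForceSegment` means."""

    HEIGHT = "height"          # raw piezo height
    INDENTATION = "indentation"  # tip-sample indentation depth


@dataclass
class ForceSegment:
    """One labeled segment of a force curve.

    Parameters
    ----------
    label : SegmentLabel
        Which phase of the ramp this segment belongs to.
    time : ndarray, seconds
        Strictly increasing sample times.
    position : ndarray, meters
        Piezo height or indentation depth; ``coordinate`` says which.
    force : ndarray, newtons
    coordinate : CoordinateKind
    """

    label: SegmentLabel
    time: np.ndarray
    position: np.ndarray
    force: np.ndarray
    coordinate: CoordinateKind = CoordinateKind.HEIGHT

    def __post_init__(self) -> None:
        self.label = SegmentLabel(self.label)
        self.coordinate = CoordinateKind(self.coordinate)
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        n = self.time.size
        if n < 2:
            raise InputError("segment needs at least 2 samples")
        if self.position.size != n or self.force.size != n:
            raise InputError("time/position/force arrays must have equal length")
        if not np.all(np.diff(self.time) > 0):
            raise InputError("time must be strictly increasing")


@dataclass(frozen=True)
class ProbeSpec:
    """Cantilever + tip metadata: spring constant k (N/m) and sphere radius R (m)."""

    spring_constant: float
    tip_radius: float
    geometry: str = "sphere"

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise InputError("spring_constant must be > 0")
        if self.tip_radius <= 0:
            raise InputError("tip_radius must be > 0")
        if self.geometry != "sphere":
            raise InputError("only spherical probes are supported")


@dataclass(frozen=True)
class HertzFit:
    """Result of a spherical Hertz fit: E (Pa), contact point (m), residual (N)."""

    youngs_modulus: float
    contact_point: float
    poisson_ratio: float
    rms_residual: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.youngs_modulus < 0:
            raise NonPhysicalError("youngs_modulus must be >= 0")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise InputError("poisson_ratio must lie in [0, 0.5]")


@dataclass(frozen=True)
class OscillationResult:
    """Lock-in estimate of an oscillation segment at the drive frequency."""

    frequency: float
    indentation_amplitude: float
    force_amplitude: float
    phase_lag: float
    loss_tangent: float


@dataclass
class RelaxationResult:
    """Averaged, normalized stress-relaxation hold.

    ``normalized_force[0]`` is 1.0 by construction; ``time`` starts at 0 at
    the instant of peak force (t0, F0).
    """

    t0: float
    F0: float
    time: np.ndarray
    normalized_force: np.ndarray
    n_curves: int = 1


def hertz_force(delta: np.ndarray, E: float, R: float, poisson: float = 0.5) -> np.ndarray:
    """Spherical (paraboloidal) Hertz contact law.

    F(δ) = (4/3) · E/(1−ν²) · √R · δ^{3/2} for δ > 0, else 0.
    Valid for indentations small compared with the tip radius.
    """
    delta = np.asarray(delta, dtype=float)
    d = np.clip(delta, 0.0, None)
    return (4.0 / 3.0) * E / (1.0 - poisson**2) * np.sqrt(R) * d**1.5


def preprocess_raw_curve(
    time: Sequence[float],
    height: Sequence[float],
    deflection: Sequence[float],
    probe: ProbeSpec,
    contact_height: float | None = None,
) -> ForceSegment:
    """Convert raw (height, deflection) data into a force segment.

    Force is Hooke's law on the cantilever, ``F = k · deflection``.  If the
    contact height is known, position becomes indentation,
    ``δ = (height − height_at_contact) − deflection``; otherwise the raw
    height is kept and flagged as such.
    """
    time = np.asarray(time, dtype=float)
    height = np.asarray(height, dtype=float)
    deflection = np.asarray(deflection, dtype=float)
    if not (time.size == height.size == deflection.size):
        raise InputError("time/height/deflection arrays must have equal length")
    if not np.all(np.diff(time) > 0):
        raise InputError("time must be strictly increasing")
    force = probe.spring_constant * deflection
    if contact_height is None:
        return ForceSegment(SegmentLabel.APPROACH, time, height, force,
                            CoordinateKind.HEIGHT)
    indentation = (height - contact_height) - deflection
    return ForceSegment(SegmentLabel.APPROACH, time, indentation, force,
                        CoordinateKind.INDENTATION)


def detect_contact_point(
    curve: ForceSegment,
    baseline_fraction: float = 0.2,
    threshold_sd: float = 5.0,
) -> float:
    """Threshold-based contact point of an approach segment.

    The baseline mean and SD are estimated from the first ``baseline_fraction``
    of samples; the contact point is the position where the force first
    exceeds mean + ``threshold_sd``·SD (with an absolute floor for noiseless
    data).  Baseline-relative thresholding makes the result invariant under a
    constant force offset.
    """
    if not 0 < baseline_fraction < 1:
        raise InputError("baseline_fraction must lie in (0, 1)")
    n = curve.force.size
    nb = max(int(round(baseline_fraction * n)), 2)
    base = curve.force[:nb]
    mu, sd = float(np.mean(base)), float(np.std(base))
    scale = max(np.max(np.abs(curve.force - mu)), 1.0)
    thresh = mu + max(threshold_sd * sd, 1e-12 * scale)
    above = np.nonzero(curve.force > thresh)[0]
    if above.size == 0:
        raise NoContactError("no force rise above baseline threshold")
    return float(curve.position[above[0]])


def _hertz_lsq(delta: np.ndarray, force: np.ndarray, R: float, poisson: float):
    """Closed-form linear LSQ of E at fixed contact point. Returns (E, rms)."""
    basis = (4.0 / 3.0) / (1.0 - poisson**2) * np.sqrt(R) * np.clip(delta, 0.0, None) ** 1.5
    denom = float(basis @ basis)
    if denom == 0.0:
        return 0.0, float(np.sqrt(np.mean(force**2)))
    E = float(basis @ force) / denom
    resid = force - E * basis
    return E, float(np.sqrt(np.mean(resid**2)))


def fit_hertz(
    curve: ForceSegment,
    probe: ProbeSpec,
    poisson_ratio: float = 0.5,
    fit_contact: bool = True,
    contact_point: float | None = None,
) -> HertzFit:
    """Fit the spherical Hertz model to an approach segment.

    The curve must be in indentation coordinates (``position`` = indentation
    depth relative to a provisional contact at 0).  By default the contact
    point is a free parameter of the fit, optimised by bounded scalar search
    with E solved in closed form at each candidate; pass ``fit_contact=False``
    (optionally with an explicit ``contact_point``) to pin it.
    """
    if curve.coordinate is not CoordinateKind.INDENTATION:
        raise InputError("fit_hertz requires indentation coordinates; "
                         "run preprocess_raw_curve with a contact height first")
    delta = curve.position
    force = curve.force

    def n_post(c: float) -> int:
        return int(np.count_nonzero(delta > c))

    if contact_point is not None:
        c0 = float(contact_point)
        fit_contact = False
    else:
        c0 = 0.0

    if fit_contact:
        lo, hi = float(delta.min()), float(delta.max())
        span = hi - lo

        def cost(c: float) -> float:
            return _hertz_lsq(delta - c, force, probe.tip_radius, poisson_ratio)[1]

        res = optimize.minimize_scalar(
            cost, bounds=(lo, hi - 0.05 * span), method="bounded",
            options={"xatol": 1e-6 * span},
        )
        c0 = float(res.x)
        # fall back to the pinned origin if the search did not help
        if cost(0.0) <= res.fun and n_post(0.0) >= 5:
            c0 = 0.0

    if n_post(c0) < 5:
        raise InsufficientDataError("fewer than 5 post-contact samples")
    E, rms = _hertz_lsq(delta - c0, force, probe.tip_radius, poisson_ratio)
    clamped = False
    if E < 0:
        warnings.warn("negative fitted modulus clamped to zero", RuntimeWarning)
        E, clamped = 0.0, True
        rms = float(np.sqrt(np.mean(force[delta > c0] ** 2)))
    return HertzFit(E, c0, poisson_ratio, rms, clamped)


def _lockin(t: np.ndarray, y: np.ndarray, f0: float):
    """LSQ sinusoid fit at f0 with linear-drift removal.

    Model y = a·sin(ωt) + b·cos(ωt) + c + d·t.  Returns (amplitude, phase)
    with y ≈ A·sin(ωt + φ).
    """
    w = 2.0 * np.pi * f0
    X = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = coef[0], coef[1]
    return float(np.hypot(a, b)), float(np.arctan2(b, a))


def oscillation_loss_tangent(curve: ForceSegment, drive_frequency: float) -> OscillationResult:
    """Loss tangent from a small-amplitude oscillation segment.

    Amplitude and phase of indentation and force are estimated by
    least-squares sinusoid fits (a lock-in) at the drive frequency after
    linear detrending; the loss tangent is tan of the force–indentation
    phase lag.  For small oscillations about an operating indentation the
    linearised contact stiffness carries the loss angle of the complex
    modulus, so this phase lag is tan(δ) = G″/G′.
    """
    if curve.label is not SegmentLabel.OSCILLATION:
        raise InputError("expected an oscillation segment")
    t = curve.time - curve.time[0]
    duration = float(t[-1])
    if duration * drive_frequency < 2.0:
        raise InsufficientDataError("need at least 2 full oscillation periods")
    amp_d, ph_d = _lockin(t, curve.position, drive_frequency)
    amp_f, ph_f = _lockin(t, curve.force, drive_frequency)
    lag = (ph_f - ph_d + np.pi) % (2.0 * np.pi) - np.pi
    if lag < 0.0:
        if lag > -1e-6:
            lag = 0.0
        else:
            raise NonPhysicalError(f"force lags indentation (phase {lag:.3g} rad)")
    if lag >= np.pi / 2:
        raise NonPhysicalError(f"phase lag {lag:.3g} rad >= pi/2")
    return OscillationResult(
        frequency=float(drive_frequency),
        indentation_amplitude=amp_d,
        force_amplitude=amp_f,
        phase_lag=float(lag),
        loss_tangent=float(np.tan(lag)),
    )


def _prepare_relaxation(curve: ForceSegment):
    """Single-curve pipeline: baseline-align, locate (t0, F0), shift, crop, normalize."""
    f = curve.force.copy()
    t = curve.time
    i_max = int(np.argmax(f))
    # pre-hold baseline = samples before the force maximum ramp; use the first
    # 10% of pre-peak samples as the quiescent baseline estimate
    if i_max > 0:
        nb = max(i_max // 10, 1)
        baseline = float(np.mean(f[:nb]))
    else:
        baseline = None
    if baseline is not None and baseline < 0:
        f = f - baseline
    elif baseline is None and f[0] < 0:
        f = f - min(0.0, float(f[0]))
    i_max = int(np.argmax(f))
    t0 = float(t[i_max])
    F0 = float(f[i_max])
    if F0 <= 0:
        raise DegenerateCurveError("peak force F0 must be > 0")
    # crop to the constant-indentation hold: from the peak to the end of the
    # segment (retract data is excluded upstream by segment label)
    tt = t[i_max:] - t0
    ff = f[i_max:] / F0
    return t0, F0, tt, ff


def process_relaxation(curves: Sequence[ForceSegment]) -> RelaxationResult:
    """Average stress-relaxation pipeline.

    Per curve: align to zero force if the baseline is negative; find the
    force maximum (t0, F0); shift time so the peak sits at 0; crop to the
    constant-indentation hold; normalise by F0.  The per-curve results are
    then linearly interpolated onto the time grid of the first curve,
    cropped to the shortest common hold duration, and averaged pointwise.
    """
    if len(curves) == 0:
        raise InputError("need at least one relaxation curve")
    prepared = [_prepare_relaxation(c) for c in curves]
    t_common = prepared[0][2]
    t_end = min(p[2][-1] for p in prepared)
    t_common = t_common[t_common <= t_end + 1e-15]
    stack = np.vstack([np.interp(t_common, p[2], p[3]) for p in prepared])
    mean_curve = stack.mean(axis=0)
    mean_curve[0] = 1.0  # exact by construction; guard interpolation round-off
    t0 = float(np.mean([p[0] for p in prepared]))
    F0 = float(np.mean([p[1] for p in prepared]))
    return RelaxationResult(t0=t0, F0=F0, time=t_common,
                            normalized_force=mean_curve, n_curves=len(curves))


def energy_dissipation(result: RelaxationResult) -> float:
    """Energy dissipation (%) of a normalized relaxation hold.

    On the normalized averaged signal the peak is 1 by construction, so the
    dissipation is (1 − F_norm(t_max)) × 100, the relative force drop over
    the hold.
    """
    return float((1.0 - result.normalized_force[-1]) * 100.0)


# ---------------------------------------------------------------------------
# Delimited-text force-curve I/O (columns: time_s, position_m, force_N, segment)
# ---------------------------------------------------------------------------

def read_force_curve(path, coordinate: CoordinateKind = CoordinateKind.INDENTATION):
    """Read one force curve (TSV/CSV, sniffed) into labeled segments."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    required = {"time_s", "position_m", "force_N", "segment"}
    if not required <= set(df.columns):
        raise InputError(f"force-curve file needs columns {sorted(required)}")
    segments = []
    for label, grp in df.groupby("segment", sort=False):
        segments.append(ForceSegment(
            SegmentLabel(label), grp["time_s"].to_numpy(),
            grp["position_m"].to_numpy(), grp["force_N"].to_numpy(),
            coordinate))
    return segments


def write_force_curve(path, segments: Sequence[ForceSegment], sep: str = "\t") -> None:
    """Write labeled segments to a delimited text file."""
    import pandas as pd

    frames = [pd.DataFrame({"time_s": s.time, "position_m": s.position,
                            "force_N": s.force, "segment": s.label.value})
              for s in segments]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
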