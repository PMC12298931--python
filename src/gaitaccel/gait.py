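"""Gait-cycle segmentation, time normalization and per-phase statistics.

A gait cycle runs from one foot contact of a leg to the next; stance ends at
toe-off.  Cycles are normalized to a 0-100% grid anchored at the *average*
toe-off percentage: stance (contact -> toe-off) and swing (toe-off -> next
contact) are linearly resampled onto the grid segments on either side of the
anchor, so the stance/swing boundary of every cycle lands on the same grid
point before averaging.  Ensemble curves are reported as mean +/- sample SD
across cycles, and phase statistics (Pearson r, RMSE between two channels
over a %-cycle window) as per-cycle values summarized mean +/- SD.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal as _signal

from .errors import DetectionError, InvalidInputError

__all__ = [
    "GaitEvents",
    "GaitCycleEnsemble",
    "PhaseStats",
    "detect_gait_events",
    "normalize_to_gait_cycle",
    "ensemble_stats",
    "phase_component_stats",
]


@dataclass
class GaitEvents:
    """Foot-contact and toe-off times [s] for one leg."""

    foot_contacts: np.ndarray
    toe_offs: np.ndarray
    side: str = "right"

    def __post_init__(self):
        self.foot_contacts = np.sort(np.asarray(self.foot_contacts, dtype=float))
        self.toe_offs = np.sort(np.asarray(self.toe_offs, dtype=float))
        if len(self.foot_contacts) >= 2:
            for to in self.toe_offs:
                k = np.searchsorted(self.foot_contacts, to)
                if k == 0 or k == len(self.foot_contacts):
                    continue  # outside the contact span; tolerated and unused
        for name, arr in (("foot_contacts", self.foot_contacts), ("toe_offs", self.toe_offs)):
            if len(arr) > 1 and np.any(np.diff(arr) <= 0):
                raise InvalidInputError(f"{name} must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        """Complete contact-to-contact cycles containing a toe-off."""
        return len(self._cycles())

    def _cycles(self) -> list[tuple[float, float, float]]:
        """(contact, toe_off, next_contact) triples for complete cycles."""
        out = []
        for c0, c1 in zip(self.foot_contacts[:-1], self.foot_contacts[1:]):
            inside = self.toe_offs[(self.toe_offs > c0) & (self.toe_offs < c1)]
            if len(inside) == 1:
                out.append((float(c0), float(inside[0]), float(c1)))
        return out


@dataclass
class GaitCycleEnsemble:
    """Cycle-normalized multi-channel curves: 0-100% grid, mean +/- SD."""

    grid: np.ndarray                # (G,) percent of gait cycle
    mean: np.ndarray                # (G, C)
    sd: np.ndarray                  # (G, C)
    cycles: np.ndarray              # (K, G, C) individual normalized cycles
    toe_off_pct: float              # average stance/swing boundary
    channel_names: list = field(default_factory=list)

    @property
    def n_cycles(self) -> int:
        return self.cycles.shape[0]


@dataclass
class PhaseStats:
    """Correlation / RMSE between two channels over a %-cycle window."""

    phase: str
    window: tuple
    r_mean: float
    r_sd: float
    rmse_mean: float
    rmse_sd: float
    n_cycles: int
    r_per_cycle: np.ndarray = None
    rmse_per_cycle: np.ndarray = None


def _parabolic_refine(x: np.ndarray, i: int) -> float:
    """Sub-sample extremum location via 3-point parabola around index i."""
    if i <= 0 or i >= len(x) - 1:
        return float(i)
    denom = x[i - 1] - 2.0 * x[i] + x[i + 1]
    if denom == 0.0:
        return float(i)
    return i + 0.5 * (x[i - 1] - x[i + 1]) / denom


def detect_gait_events(
    gyro_sagittal,
    dt: float,
    t0: float = 0.0,
    side: str = "right",
    freq_band: tuple = (0.5, 2.0),
    search_frac: float = 0.25,
    height_frac: float = 0.5,
) -> GaitEvents:
    """Heel-strike / toe-off candidates from the sagittal angular velocity.

    The shank's sagittal angular-velocity waveform has a dominant mid-swing
    peak flanked by two troughs: the one before it marks toe-off, the one
    after it the next foot contact.  The signal is auto-oriented so the
    swing peak is positive; troughs are searched within ``search_frac`` of a
    cycle on either side of each accepted peak and refined to sub-sample
    precision.  Externally annotated events, when available, should be
    preferred over this heuristic.
    """
    x = np.asarray(gyro_sagittal, dtype=float)
    if x.ndim != 1:
        raise InvalidInputError("gyro_sagittal must be 1-D")
    n = len(x)
    if n < 8:
        raise DetectionError("record too short for event detection")
    xd = x - x.mean()
    if np.max(np.abs(xd)) < 1e-9:
        raise DetectionError("no periodicity detected (constant input); annotate manually")

    # dominant frequency of the oscillation
    spec = np.abs(np.fft.rfft(xd * np.hanning(n)))
    freqs = np.fft.rfftfreq(n, d=dt)
    mask = (freqs >= 0.2) & (freqs <= 5.0)
    if not np.any(mask) or np.max(spec[mask]) <= 0:
        raise DetectionError("no periodicity detected; annotate manually")
    f0 = float(freqs[mask][np.argmax(spec[mask])])
    if not (freq_band[0] <= f0 <= freq_band[1]):
        raise DetectionError(
            f"dominant frequency {f0:.2f} Hz outside {freq_band} Hz; annotate manually"
        )
    period = 1.0 / f0 / dt  # samples per cycle

    if -xd.min() > xd.max():
        xd = -xd  # orient the mid-swing peak positive

    peaks, _ = _signal.find_peaks(
        xd, height=height_frac * xd.max(), distance=max(int(0.7 * period), 1)
    )
    if len(peaks) < 1:
        raise DetectionError("no swing peaks found; annotate manually")

    win = max(int(round(search_frac * period)), 2)
    contacts, toe_offs = [], []
    for p in peaks:
        lo = p - win
        if lo >= 0:
            seg = xd[lo : p + 1]
            i = lo + int(np.argmin(seg))
            toe_offs.append(t0 + dt * _parabolic_refine(xd, i))
        hi = p + win
        if hi < n:
            seg = xd[p : hi + 1]
            i = p + int(np.argmin(seg))
            contacts.append(t0 + dt * _parabolic_refine(xd, i))
    if len(contacts) < 1 and len(toe_offs) < 1:
        raise DetectionError("no events recovered; annotate manually")
    return GaitEvents(foot_contacts=np.array(contacts), toe_offs=np.array(toe_offs), side=side)


def normalize_to_gait_cycle(
    t,
    channels,
    events: GaitEvents,
    n_points: int = 101,
    channel_names: Optional[Sequence[str]] = None,
) -> GaitCycleEnsemble:
    """Resample each cycle onto the 0-100% grid anchored at average toe-off.

    ``channels`` is (N,) or (N, C) sampled at times ``t``.  Stance maps to
    [0, toe_off_pct] and swing to [toe_off_pct, 100] by linear interpolation,
    so cycle boundaries land exactly on 0% and 100% and every cycle's
    toe-off sample lands on the anchor grid point.
    """
    t = np.asarray(t, dtype=float)
    ch = np.asarray(channels, dtype=float)
    if ch.ndim == 1:
        ch = ch[:, None]
    if len(t) != len(ch):
        raise InvalidInputError("t and channels must have equal length")
    cycles = [
        c for c in events._cycles() if c[0] >= t[0] - 1e-9 and c[2] <= t[-1] + 1e-9
    ]
    if not cycles:
        raise InvalidInputError("no complete gait cycle (contact -> contact) in the record")

    to_pcts = [100.0 * (to - c0) / (c1 - c0) for c0, to, c1 in cycles]
    to_pct = float(np.mean(to_pcts))
    grid = np.linspace(0.0, 100.0, n_points)

    out = np.empty((len(cycles), n_points, ch.shape[1]))
    for k, (c0, to, c1) in enumerate(cycles):
        stance = grid <= to_pct
        times = np.empty(n_points)
        times[stance] = c0 + (grid[stance] / to_pct) * (to - c0)
        times[~stance] = to + ((grid[~stance] - to_pct) / (100.0 - to_pct)) * (c1 - to)
        for c in range(ch.shape[1]):
            out[k, :, c] = np.interp(times, t, ch[:, c])

    mean, sd = ensemble_stats(out)
    return GaitCycleEnsemble(
        grid=grid,
        mean=mean,
        sd=sd,
        cycles=out,
        toe_off_pct=to_pct,
        channel_names=list(channel_names) if channel_names else [],
    )


def ensemble_stats(cycles) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD (n-1) across cycles.

    ``cycles`` is a sequence of equally shaped arrays or a stacked array with
    the cycle axis first.  With a single cycle the SD is reported as zero
    (with a warning) rather than undefined.
    """
    arr = np.asarray(cycles, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("empty cycle list")
    mean = arr.mean(axis=0)
    if arr.shape[0] < 2:
        _warnings.warn("single cycle: SD reported as 0", stacklevel=2)
        sd = np.zeros_like(mean)
    else:
        sd = arr.std(axis=0, ddof=1)
    return mean, sd


def phase_component_stats(
    cycles_a,
    cycles_b,
    phase_window: tuple = (0.0, 100.0),
    grid: Optional[np.ndarray] = None,
    phase: str = "custom",
) -> PhaseStats:
    """Pearson r and RMSE between two cycle-normalized channels in a window.

    ``cycles_a`` and ``cycles_b`` are (K, G) stacks of normalized cycles on a
    shared grid (default 0-100% at (G-1)/100 steps).  Statistics are computed
    per cycle inside ``phase_window`` (percent, inclusive) and summarized as
    mean +/- sample SD across cycles.  A constant channel within the window
    makes the correlation undefined for that cycle; it is reported as NaN
    with a warning and excluded from the summary.
    """
    a = np.atleast_2d(np.asarray(cycles_a, dtype=float))
    b = np.atleast_2d(np.asarray(cycles_b, dtype=float))
    if a.shape != b.shape:
        raise InvalidInputError(f"cycle stacks differ in shape: {a.shape} vs {b.shape}")
    g = np.linspace(0.0, 100.0, a.shape[1]) if grid is None else np.asarray(grid, dtype=float)
    lo, hi = phase_window
    mask = (g >= lo) & (g <= hi)
    if not np.any(mask):
        raise InvalidInputError(f"empty phase window {phase_window}")

    r_vals = np.empty(a.shape[0])
    rmse_vals = np.empty(a.shape[0])
    for k in range(a.shape[0]):
        xa, xb = a[k, mask], b[k, mask]
        rmse_vals[k] = float(np.sqrt(np.mean((xa - xb) ** 2)))
        if np.ptp(xa) == 0.0 or np.ptp(xb) == 0.0:
            _warnings.warn(
                f"cycle {k}: constant channel in window; correlation undefined",
                stacklevel=2,
            )
            r_vals[k] = np.nan
        else:
            r_vals[k] = float(np.corrcoef(xa, xb)[0, 1])

    ok = np.isfinite(r_vals)
    r_mean = float(np.mean(r_vals[ok])) if np.any(ok) else float("nan")
    r_sd = float(np.std(r_vals[ok], ddof=1)) if ok.sum() > 1 else 0.0
    rmse_sd = float(np.std(rmse_vals, ddof=1)) if len(rmse_vals) > 1 else 0.0
    return PhaseStats(
        phase=phase,
        window=(float(lo), float(hi)),
        r_mean=r_mean,
        r_sd=r_sd,
        rmse_mean=float(np.mean(rmse_vals)),
        rmse_sd=rmse_sd,
        n_cycles=a.shape[0],
        r_per_cycle=r_vals,
        rmse_per_cycle=rmse_vals,
    )
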