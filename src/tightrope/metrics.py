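"""Posturographic indicators computed from simulated trajectories.

Sway ranges are reported as ±2·SD of the angle over the analysis window
(in degrees; the CoP range in mm), pulse statistics describe the
intermittency of each controller (duty cycle, pulse rate, mean pulse
duration), and the spectral analysis uses a Welch estimate.  Unless noted
otherwise every statistic excludes the initial ``discard`` seconds of the
run (start-up transient).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal

from .simulator import Trajectory

#: Welch PSD settings: decimate to 100 Hz (anti-aliased), Hann window,
#: 40 s segments, 50% overlap -> 0.025 Hz resolution.
PSD_RATE = 100.0
PSD_SEGMENT_S = 40.0

#: band searched for the coronal resonant peak, Hz
ML_PEAK_BAND = (0.1, 2.0)


@dataclass(frozen=True)
class PulseStats:
    """Intermittency statistics of one controller."""

    duty: float  # % of time in the on-phase
    rate: float  # pulses per second
    mean_duration: float  # ms

    def __post_init__(self) -> None:
        if not (0.0 <= self.duty <= 100.0) or self.rate < 0:
            raise ValueError("invalid pulse statistics")


@dataclass(frozen=True)
class SummaryStats:
    """The consolidated indicator set of one run (or the mean over runs)."""

    R_ap: float  # sagittal sway range ±2 SD, deg
    R_ml: float  # coronal sway range ±2 SD, deg
    R_cop: float  # CoP range ±2 SD, mm
    sd_Gap: float  # N m
    sd_TsTap: float  # N m
    sd_Gml: float  # N m
    sd_Tml: float  # N m
    sd_dxp: float  # m
    corr_ap_ml: float
    corr_qap_Tap: float
    corr_qml_dxp: float
    pulse_ap: PulseStats
    pulse_ml: PulseStats
    psd_peak_ml: float  # Hz
    fell: bool
    fall_time: Optional[float]  # s

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# elementary indicators


def _post_discard(series: np.ndarray, dt: float, discard: float) -> np.ndarray:
    out = np.asarray(series)[int(round(discard / dt)):]
    if out.size == 0:
        raise ValueError("no samples left after discarding the transient")
    return out


def sway_range(series: np.ndarray, dt: float, discard: float = 0.0) -> float:
    """±range of an angular series as 2·SD, converted to degrees."""
    x = _post_discard(series, dt, discard)
    return math.degrees(2.0 * float(np.std(x)))


def pulse_statistics(
    on_flags: np.ndarray, dt: float, discard: float = 0.0
) -> PulseStats:
    """Duty cycle, pulse rate and mean pulse duration of an on/off series.

    A pulse is a maximal run of consecutive on samples; runs touching the
    window edges count as pulses.
    """
    flags = _post_discard(np.asarray(on_flags, dtype=bool), dt, discard)
    n = flags.size
    window = n * dt
    duty = 100.0 * flags.sum() / n
    if not flags.any():
        return PulseStats(duty=0.0, rate=0.0, mean_duration=0.0)
    padded = np.concatenate(([False], flags, [False])).astype(np.int8)
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    durations = (ends - starts) * dt
    return PulseStats(
        duty=float(duty),
        rate=len(starts) / window,
        mean_duration=float(durations.mean() * 1000.0),
    )


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Standard Pearson coefficient; raises on degenerate inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(np.corrcoef(x, y)[0, 1])


def power_spectrum(
    series: np.ndarray, fs: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Welch PSD of a sway series.

    The series is anti-alias decimated to ~100 Hz first; segments are 40 s
    Hann windows with 50% overlap (0.025 Hz resolution), enough to localize
    a 0.3–0.4 Hz peak.
    """
    x = np.asarray(series, dtype=float)
    factor = max(int(round(fs / PSD_RATE)), 1)
    if factor > 1:
        x = signal.decimate(x, factor, zero_phase=True)
        fs = fs / factor
    nperseg = min(int(round(PSD_SEGMENT_S * fs)), x.size)
    if nperseg < 16:
        raise ValueError("series too short for a spectral estimate")
    return signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                        noverlap=nperseg // 2)


def peak_frequency(
    freqs: np.ndarray, psd: np.ndarray, band: Tuple[float, float] = ML_PEAK_BAND
) -> float:
    """Frequency of maximum PSD within ``band`` (Hz)."""
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValueError("band contains no frequency bins")
    return float(freqs[mask][np.argmax(psd[mask])])


def detect_fall(traj: Trajectory, threshold: Optional[float] = None) -> Optional[float]:
    """Earliest time (s) at which either sway angle exceeds ``threshold``
    or any sample is non-finite; ``None`` if the run never falls."""
    thr = traj.config.fall_threshold if threshold is None else threshold
    bad = (
        (np.abs(traj.q_ap) > thr)
        | (np.abs(traj.q_ml) > thr)
        | ~np.isfinite(traj.q_ap)
        | ~np.isfinite(traj.q_ml)
        | ~np.isfinite(traj.qd_ap)
        | ~np.isfinite(traj.qd_ml)
    )
    idx = np.flatnonzero(bad)
    if idx.size:
        return float(traj.t[idx[0]])
    if traj.aborted:  # diverged numerically right at the recorded horizon
        return float(traj.t[-1])
    return None


# ---------------------------------------------------------------------------
# consolidated summary


def _summarize_one(traj: Trajectory) -> SummaryStats:
    cfg = traj.config
    dt, disc = cfg.dt, cfg.warmup_discard
    fall_time = detect_fall(traj)

    def cut(a):
        return _post_discard(a, dt, disc)

    q_ap, q_ml = cut(traj.q_ap), cut(traj.q_ml)
    ts_tap = cut(traj.T_s + traj.T_ap)

    def corr_or_nan(x, y):
        try:
            return pearson_correlation(x, y)
        except ValueError:
            return float("nan")  # undefined (e.g. zero-variance) flagged as NaN

    freqs, psd = power_spectrum(q_ml, fs=1.0 / dt)
    return SummaryStats(
        R_ap=sway_range(traj.q_ap, dt, disc),
        R_ml=sway_range(traj.q_ml, dt, disc),
        R_cop=2.0 * float(np.std(cut(traj.y_cop))) * 1000.0,
        sd_Gap=float(np.std(cut(traj.G_ap))),
        sd_TsTap=float(np.std(ts_tap)),
        sd_Gml=float(np.std(cut(traj.G_ml))),
        sd_Tml=float(np.std(cut(traj.T_ml))),
        sd_dxp=float(np.std(cut(traj.dx_p))),
        corr_ap_ml=corr_or_nan(q_ap, q_ml),
        corr_qap_Tap=corr_or_nan(q_ap, cut(traj.T_ap)),
        corr_qml_dxp=corr_or_nan(q_ml, cut(traj.dx_p)),
        pulse_ap=pulse_statistics(traj.on_ap, dt, disc),
        pulse_ml=pulse_statistics(traj.on_ml, dt, disc),
        psd_peak_ml=peak_frequency(freqs, psd),
        fell=fall_time is not None,
        fall_time=fall_time,
    )


def summarize(trajs: Union[Trajectory, Sequence[Trajectory]]) -> SummaryStats:
    """Per-run indicators, averaged across runs (Monte-Carlo replication).

    Correlations and SDs are computed per run and then averaged; the fall
    flag is true if any run fell (earliest fall time reported).
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("need at least one trajectory")
    singles = [_summarize_one(tr) for tr in trajs]
    if len(singles) == 1:
        return singles[0]

    def mean(attr):
        return float(np.mean([getattr(s, attr) for s in singles]))

    def mean_pulse(attr):
        ps = [getattr(s, attr) for s in singles]
        return PulseStats(
            duty=float(np.mean([p.duty for p in ps])),
            rate=float(np.mean([p.rate for p in ps])),
            mean_duration=float(np.mean([p.mean_duration for p in ps])),
        )

    fall_times = [s.fall_time for s in singles if s.fall_time is not None]
    return SummaryStats(
        R_ap=mean("R_ap"), R_ml=mean("R_ml"), R_cop=mean("R_cop"),
        sd_Gap=mean("sd_Gap"), sd_TsTap=mean("sd_TsTap"),
        sd_Gml=mean("sd_Gml"), sd_Tml=mean("sd_Tml"), sd_dxp=mean("sd_dxp"),
        corr_ap_ml=mean("corr_ap_ml"),
        corr_qap_Tap=mean("corr_qap_Tap"),
        corr_qml_dxp=mean("corr_qml_dxp"),
        pulse_ap=mean_pulse("pulse_ap"),
        pulse_ml=mean_pulse("pulse_ml"),
        psd_peak_ml=mean("psd_peak_ml"),
        fell=any(s.fell for s in singles),
        fall_time=min(fall_times) if fall_times else None,
    )
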