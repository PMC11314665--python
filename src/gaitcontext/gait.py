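"""Lower-back (L5) accelerometer gait analysis.

Three stages:

1. **Bout segmentation** — walking is separated from rest by thresholding
   the moving standard deviation of the acceleration magnitude (window
   0.5 s); nearby active periods are merged and short ones discarded.
2. **Gait-event detection** — within each bout the vertical channel is
   detrended, integrated, and differentiated with Gaussian-derivative
   (continuous wavelet) smoothing.  Initial contacts (heel strikes) are
   the local minima of the once-differentiated signal — equivalently,
   minima of the Gaussian-smoothed vertical acceleration; final contacts
   (toe-offs) are the local maxima of the twice-differentiated signal.
   The smoothing scale adapts to the dominant step frequency found as
   the spectral peak in the 1.4-3 Hz locomotor band.
3. **Temporal characteristics** — from the validated, alternating IC/FC
   sequence: step time (consecutive ICs), stride time (alternate ICs),
   stance time (IC to the next-but-one FC), swing = stride - stance.
   For each series we report mean, standard deviation and asymmetry.

Asymmetry is the absolute difference between the means of the
even-indexed and odd-indexed elements of a series.  A single lumbar
sensor cannot label steps left/right, so alternating indices act as a
proxy for the two sides; for a perfectly symmetric gait the two means
coincide and asymmetry is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.signal import find_peaks

G = 9.80665  # standard gravity, m/s^2

LOCOMOTOR_BAND = (1.4, 3.0)  # plausible step-frequency range, Hz


@dataclass
class AccelSignal:
    """Uniformly sampled tri-axial acceleration from a lower-back sensor.

    Channels follow the anatomical convention: vertical (V),
    anteroposterior (AP), mediolateral (ML), all in m/s^2.
    """

    timestamps: np.ndarray
    vertical: np.ndarray
    anteroposterior: np.ndarray
    mediolateral: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.vertical = np.asarray(self.vertical, dtype=float)
        self.anteroposterior = np.asarray(self.anteroposterior, dtype=float)
        self.mediolateral = np.asarray(self.mediolateral, dtype=float)
        n = self.timestamps.size
        if not (self.vertical.size == self.anteroposterior.size == self.mediolateral.size == n):
            raise ValueError("all channels must have the same length")
        if n < 2:
            raise ValueError("signal needs at least 2 samples")
        dt = np.diff(self.timestamps)
        if dt.min() <= 0:
            raise ValueError("timestamps must be strictly increasing")
        if (dt.max() - dt.min()) > 1e-6 * dt.mean() + 1e-9:
            raise ValueError("non-uniform sampling")

    @property
    def fs(self) -> float:
        """Sample rate in Hz."""
        return 1.0 / float(np.mean(np.diff(self.timestamps)))

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def magnitude(self) -> np.ndarray:
        return np.sqrt(
            self.vertical**2 + self.anteroposterior**2 + self.mediolateral**2
        )

    def slice(self, start: float, end: float) -> "AccelSignal":
        sel = (self.timestamps >= start) & (self.timestamps <= end)
        return AccelSignal(
            self.timestamps[sel],
            self.vertical[sel],
            self.anteroposterior[sel],
            self.mediolateral[sel],
        )


@dataclass(frozen=True)
class WalkingBout:
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("bout end must be after start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class BoutConfig:
    """Bout-segmentation parameters.

    ``activity_threshold`` is on the moving STD of the acceleration
    magnitude, in m/s^2 (default 0.05 g); quiet standing with typical
    sensor noise sits well below it, walking well above.
    """

    activity_threshold: float = 0.05 * G
    window: float = 0.5  # moving-STD window, s
    merge_gap: float = 0.3  # merge active periods closer than this, s
    min_duration: float = 3.0  # discard shorter bouts, s


@dataclass
class EventConfig:
    """Gait-event detection parameters.

    ``smooth_scale`` is the Gaussian smoothing sigma in units of the
    estimated step period; ``step_band`` bounds the spectral search for
    the dominant step frequency; ``min_step_fraction`` sets the minimum
    admissible spacing between same-type events as a fraction of the
    estimated step period.
    """

    smooth_scale: float = 0.05
    step_band: tuple[float, float] = LOCOMOTOR_BAND
    min_step_fraction: float = 0.6
    prominence_fraction: float = 0.25
    fc_refractory_scale: float = 2.5  # x smoothing sigma, after each IC


@dataclass
class GaitEvents:
    """Validated initial/final-contact times (seconds), alternating."""

    ic_times: np.ndarray
    fc_times: np.ndarray

    def __post_init__(self) -> None:
        self.ic_times = np.asarray(self.ic_times, dtype=float)
        self.fc_times = np.asarray(self.fc_times, dtype=float)
        for name, t in (("ic", self.ic_times), ("fc", self.fc_times)):
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"{name}_times must be strictly ascending")


@dataclass
class TemporalGaitStats:
    """Mean / STD / asymmetry for step, stance and swing times (seconds)."""

    step_mean: float
    step_std: float
    step_asymmetry: float
    stance_mean: float
    stance_std: float
    stance_asymmetry: float
    swing_mean: float
    swing_std: float
    swing_asymmetry: float
    n_steps: int = 0
    series: dict = field(default_factory=dict, repr=False)

    def as_row(self) -> dict[str, float]:
        return {
            "step_mean": self.step_mean,
            "step_std": self.step_std,
            "step_asy": self.step_asymmetry,
            "stance_mean": self.stance_mean,
            "stance_std": self.stance_std,
            "stance_asy": self.stance_asymmetry,
            "swing_mean": self.swing_mean,
            "swing_std": self.swing_std,
            "swing_asy": self.swing_asymmetry,
        }


def moving_std(x: np.ndarray, window_samples: int) -> np.ndarray:
    """Centred moving standard deviation via two uniform filters."""
    w = max(int(window_samples), 1)
    m = uniform_filter1d(x, w, mode="nearest")
    m2 = uniform_filter1d(x * x, w, mode="nearest")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def detect_bouts(signal: AccelSignal, config: BoutConfig = BoutConfig()) -> list[WalkingBout]:
    """Segment walking bouts out of a free-living acceleration trace."""
    if signal.duration < 1.0:
        raise ValueError("need at least 1 s of data")
    fs = signal.fs
    activity = moving_std(signal.magnitude(), round(config.window * fs))
    active = activity > config.activity_threshold
    t = signal.timestamps

    intervals: list[list[float]] = []
    in_run = False
    start = 0.0
    for i, a in enumerate(active):
        if a and not in_run:
            in_run, start = True, t[i]
        elif not a and in_run:
            in_run = False
            intervals.append([start, t[i - 1]])
    if in_run:
        intervals.append([start, t[-1]])

    merged: list[list[float]] = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] < config.merge_gap:
            merged[-1][1] = iv[1]
        else:
            merged.append(iv)
    return [
        WalkingBout(s, e) for s, e in merged if (e - s) >= config.min_duration
    ]


def estimate_step_frequency(
    vertical: np.ndarray, fs: float, band: tuple[float, float] = LOCOMOTOR_BAND
) -> float:
    """Dominant step frequency: spectral peak of the vertical channel
    within the locomotor band (Hz)."""
    v = vertical - vertical.mean()
    n = v.size
    spec = np.abs(np.fft.rfft(v * np.hanning(n))) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any() or spec[sel].max() == 0:
        return float(np.mean(band))
    return float(freqs[sel][np.argmax(spec[sel])])


def _enforce_alternation(
    ic: np.ndarray, ic_strength: np.ndarray, fc: np.ndarray, fc_strength: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Keep the strongest event in every same-type run so the merged
    sequence alternates IC, FC, IC, FC, ... starting with an IC."""
    events = [(t, 0, s) for t, s in zip(ic, ic_strength)] + [
        (t, 1, s) for t, s in zip(fc, fc_strength)
    ]
    events.sort()
    # drop leading FCs: a stride is anchored at an initial contact
    while events and events[0][1] == 1:
        events.pop(0)
    kept: list[tuple[float, int, float]] = []
    for ev in events:
        if kept and kept[-1][1] == ev[1]:
            if ev[2] > kept[-1][2]:
                kept[-1] = ev
        else:
            kept.append(ev)
    ic_out = np.array([t for t, k, _ in kept if k == 0])
    fc_out = np.array([t for t, k, _ in kept if k == 1])
    return ic_out, fc_out


def detect_gait_events(
    signal: AccelSignal,
    bout: Optional[WalkingBout] = None,
    config: EventConfig = EventConfig(),
) -> GaitEvents:
    """Detect initial/final contacts in one walking bout.

    The vertical channel is mean-detrended, integrated, then
    differentiated with a Gaussian-derivative kernel (scale adapted to
    the dominant step frequency).  ICs are the minima of the result;
    differentiating once more, FCs are the maxima.  The merged sequence
    is validated to alternate IC, FC, IC, FC, ...
    """
    seg = signal if bout is None else signal.slice(bout.start, bout.end)
    fs = seg.fs
    f_step = estimate_step_frequency(seg.vertical, fs, config.step_band)
    step_period = 1.0 / f_step
    if seg.duration < 3.0 * step_period:
        raise ValueError(
            f"bout of {seg.duration:.2f} s too short for ~{step_period:.2f} s steps"
        )
    v = seg.vertical - seg.vertical.mean()
    if np.allclose(v, 0.0):
        return GaitEvents(np.array([]), np.array([]))
    sigma = max(config.smooth_scale * step_period * fs, 1.0)  # samples
    integ = cumulative_trapezoid(v, dx=1.0 / fs, initial=0.0)
    # d/dt with Gaussian-derivative smoothing; the 1/fs step cancels in
    # peak positions but keeps amplitudes in physical units
    y1 = gaussian_filter1d(integ, sigma, order=1) * fs
    y2 = gaussian_filter1d(integ, sigma, order=2) * fs * fs
    distance = max(round(config.min_step_fraction * step_period * fs), 1)

    def _peaks(x: np.ndarray, dist: int) -> tuple[np.ndarray, np.ndarray]:
        span = float(x.max() - x.min())
        if span == 0.0:
            return np.array([], dtype=int), np.array([])
        idx, props = find_peaks(
            x, distance=dist, prominence=config.prominence_fraction * span / 2
        )
        return idx, props["prominences"]

    ic_idx, ic_prom = _peaks(-y1, distance)
    # FC candidates are all local maxima ranked by height: the refractory
    # filter and alternation enforcement below do the pruning, so a strong
    # spurious maximum right after a heel strike (whose shoulder also
    # flattens the true peak's prominence) cannot shadow the true toe-off
    fc_idx, _ = find_peaks(y2, distance=2)
    fc_prom = y2[fc_idx]
    t = seg.timestamps
    ic_t = t[ic_idx]
    fc_t = t[fc_idx]
    # refractory window: the twice-differentiated signal rings just after
    # each heel strike, but a toe-off cannot occur that early in stance
    refractory = config.fc_refractory_scale * sigma / fs
    if ic_t.size:
        since_ic = fc_t[:, None] - ic_t[None, :]
        since_ic[since_ic < 0] = np.inf
        keep = since_ic.min(axis=1) > refractory
        fc_t, fc_prom = fc_t[keep], fc_prom[keep]
    ic, fc = _enforce_alternation(ic_t, ic_prom, fc_t, fc_prom)
    return GaitEvents(ic, fc)


def _asymmetry(series: np.ndarray) -> float:
    """|mean of even-indexed - mean of odd-indexed| elements."""
    if series.size < 2:
        return 0.0
    return float(abs(series[0::2].mean() - series[1::2].mean()))


def _summary(series: np.ndarray) -> tuple[float, float, float]:
    if series.size == 0:
        return float("nan"), float("nan"), float("nan")
    return float(series.mean()), float(series.std(ddof=0)), _asymmetry(series)


def compute_temporal_stats(events: GaitEvents) -> TemporalGaitStats:
    """Temporal gait characteristics from validated IC/FC events.

    With ICs t_1 < t_2 < ... and FCs interleaved one per step:

    * step_k   = t_{k+1} - t_k
    * stride_k = t_{k+2} - t_k
    * stance_k = (FC following IC_{k+1}) - t_k
    * swing_k  = stride_k - stance_k   (exact by construction)
    """
    ic = events.ic_times
    fc = events.fc_times
    if ic.size < 4:
        raise ValueError(f"need >= 4 initial contacts, got {ic.size}")
    if fc.size == 0:
        raise ValueError("need interleaved final contacts")

    steps = np.diff(ic)
    strides = ic[2:] - ic[:-2]

    # stance_k: the first FC after IC_{k+1}, minus IC_k
    stances = []
    for k in range(ic.size - 1):
        nxt = fc[fc > ic[k + 1]]
        if nxt.size == 0:
            break
        stances.append(nxt[0] - ic[k])
    stances = np.array(stances)
    n = min(stances.size, strides.size)
    stances_n = stances[:n]
    swings = strides[:n] - stances_n

    step_m, step_s, step_a = _summary(steps)
    stance_m, stance_s, stance_a = _summary(stances_n)
    swing_m, swing_s, swing_a = _summary(swings)
    return TemporalGaitStats(
        step_mean=step_m,
        step_std=step_s,
        step_asymmetry=step_a,
        stance_mean=stance_m,
        stance_std=stance_s,
        stance_asymmetry=stance_a,
        swing_mean=swing_m,
        swing_std=swing_s,
        swing_asymmetry=swing_a,
        n_steps=int(steps.size),
        series={"step": steps, "stride": strides[:n], "stance": stances_n, "swing": swings},
    )


def analyze_signal(
    signal: AccelSignal,
    bout_config: BoutConfig = BoutConfig(),
    event_config: EventConfig = EventConfig(),
) -> list[tuple[WalkingBout, TemporalGaitStats]]:
    """Full per-bout pipeline: segment, detect events, summarize."""
    out = []
    for bout in detect_bouts(signal, bout_config):
        events = detect_gait_events(signal, bout, event_config)
        if events.ic_times.size < 4:
            continue
        out.append((bout, compute_temporal_stats(events)))
    return out


def read_accel_csv(path, time_col: str = "time", cols: tuple[str, str, str] = ("v", "ap", "ml")) -> AccelSignal:
    """Read an acceleration CSV with columns time + vertical/AP/ML (m/s^2)."""
    import pandas as pd

    df = pd.read_csv(path)
    return AccelSignal(
        df[time_col].to_numpy(),
        df[cols[0]].to_numpy(),
        df[cols[1]].to_numpy(),
        df[cols[2]].to_numpy(),
    )


def write_accel_csv(signal: AccelSignal, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "time": signal.timestamps,
            "v": signal.vertical,
            "ap": signal.anteroposterior,
            "ml": signal.mediolateral,
        }
    ).to_csv(path, index=False)
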