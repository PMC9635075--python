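"""The 61 per-movement LA features.

Every function takes plain arrays and returns a ``dict`` of named values;
``compute_movement_features`` assembles the full registry block for one
segmented event. Values that are undefined for a segment (zero variance,
missing previous movement, too-short window, unextractable gravity) are NaN
and stay NaN through aggregation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import integrate, signal, stats

from ..types import MovementEvent
from .lyapunov import largest_lyapunov_exponent

GRAVITY_M_S2 = 9.80665

#: minimum separation between the two dominant spectral peaks (Hz)
DOM_FREQ_SEPARATION_HZ = 0.5
#: cross-correlation peaks must exceed this fraction of the global maximum
PEAK_FRACTION = 0.25
#: look-back / look-ahead horizon for recent-movement features (s)
RECENT_WINDOW_S = 90.0

WAVELET = "db4"
WAVELET_LEVELS = 3


def stat_features(vm: np.ndarray) -> dict:
    """Moment statistics of the vector-magnitude slice (>= 3 samples)."""
    vm = np.asarray(vm, dtype=float)
    n = len(vm)
    mean = float(np.mean(vm))
    dev = vm - mean
    m2 = float(np.mean(dev**2)) if np.ptp(vm) > 0 else 0.0
    out = {
        "stat.mean": mean,
        "stat.sd": float(np.sqrt(m2 * n / (n - 1))) if n > 1 else 0.0,
        "stat.max": float(np.max(vm)),
        "stat.min": float(np.min(vm)),
        "stat.rms": float(np.sqrt(np.mean(vm**2))),
        "stat.range": float(np.ptp(vm)),
    }
    if m2 == 0.0 or n < 4:
        out["stat.skewness"] = float("nan")
        out["stat.kurtosis"] = float("nan")
    else:
        # adjusted Fisher-Pearson skewness; bias-corrected excess kurtosis
        g1 = float(np.mean(dev**3)) / m2**1.5
        g2 = float(np.mean(dev**4)) / m2**2 - 3.0
        out["stat.skewness"] = g1 * np.sqrt(n * (n - 1)) / (n - 2)
        out["stat.kurtosis"] = ((n + 1) * g2 + 6.0) * (n - 1) / ((n - 2) * (n - 3))
    return out


def _psd(vm: np.ndarray, fs: float):
    """Averaged-periodogram (Welch) PSD of the mean-removed slice.

    Segments of up to 2 s with 50% overlap and a Hann window; slices shorter
    than 1 s are symmetrically padded first. Implemented directly with rfft
    (numerically equivalent to the scipy reference, which is what the tests
    compare against) because movement slices are short and many.
    """
    vm = np.asarray(vm, dtype=float)
    min_len = int(np.ceil(fs))
    if len(vm) < min_len:
        vm = np.pad(vm, (0, min_len - len(vm)), mode="symmetric")
    nperseg = min(len(vm), int(round(2 * fs)))
    step = max(1, nperseg // 2)
    win = signal.windows.hann(nperseg, sym=False)
    scale = 1.0 / (fs * float(np.sum(win**2)))
    n_segs = (len(vm) - nperseg) // step + 1
    starts = np.arange(n_segs) * step
    segs = vm[starts[:, None] + np.arange(nperseg)]
    segs = segs - segs.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(segs * win, axis=1)) ** 2 * scale
    if nperseg % 2 == 0:
        spec[:, 1:-1] *= 2.0
    else:
        spec[:, 1:] *= 2.0
    psd = spec.mean(axis=0)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs[1:], psd[1:]  # drop the DC bin


FREQ_KEYS = (
    "freq.dom_freq_1",
    "freq.dom_freq_2",
    "freq.power_dom_1",
    "freq.power_dom_2",
    "freq.power_dom1_over_total",
    "freq.med_freq",
    "freq.mean_freq",
    "freq.total_power",
    "freq.spectral_edge_95",
    "freq.bandwidth",
)


def frequency_features(vm: np.ndarray, fs: float) -> dict:
    """Spectral features of the movement's vector magnitude."""
    vm = np.asarray(vm, dtype=float)
    if np.ptp(vm) == 0:
        return {k: float("nan") for k in FREQ_KEYS}
    freqs, psd = _psd(vm, fs)
    total = float(psd.sum())
    if total <= 0:
        return {k: float("nan") for k in FREQ_KEYS}

    i1 = int(np.argmax(psd))
    dom1, p1 = float(freqs[i1]), float(psd[i1])

    # second dominant peak: highest local maximum at least 0.5 Hz from dom1
    interior = np.arange(1, len(psd) - 1)
    is_peak = (psd[interior] >= psd[interior - 1]) & (psd[interior] >= psd[interior + 1])
    candidates = interior[is_peak & (np.abs(freqs[interior] - dom1) >= DOM_FREQ_SEPARATION_HZ)]
    if candidates.size:
        i2 = candidates[np.argmax(psd[candidates])]
        dom2, p2 = float(freqs[i2]), float(psd[i2])
    else:
        dom2, p2 = float("nan"), float("nan")

    cum = np.cumsum(psd) / total
    med_freq = float(np.interp(0.5, cum, freqs))
    edge95 = float(np.interp(0.95, cum, freqs))
    mean_freq = float(np.sum(freqs * psd) / total)
    bandwidth = float(np.sqrt(np.sum((freqs - mean_freq) ** 2 * psd) / total))
    return {
        "freq.dom_freq_1": dom1,
        "freq.dom_freq_2": dom2,
        "freq.power_dom_1": p1,
        "freq.power_dom_2": p2,
        "freq.power_dom1_over_total": p1 / total,
        "freq.med_freq": med_freq,
        "freq.mean_freq": mean_freq,
        "freq.total_power": total,
        "freq.spectral_edge_95": edge95,
        "freq.bandwidth": bandwidth,
    }


def wavelet_features(vm: np.ndarray) -> dict:
    """Wavelet band energies and entropy (orthogonal DWT, periodized).

    The per-band energy of an orthogonal DWT partitions the signal energy
    (Parseval), so band energies sum to the total squared signal. Entropy is
    the Shannon entropy (nats) of the normalized band-energy distribution
    over [approx, detail_3, detail_2, detail_1].
    """
    vm = np.asarray(vm, dtype=float)
    min_len = 2**WAVELET_LEVELS
    if len(vm) < min_len:
        vm = np.pad(vm, (0, min_len - len(vm)), mode="symmetric")
    with warnings.catch_warnings():
        # short segments see boundary effects at the deepest level; with
        # periodized orthogonal decomposition energy is still conserved
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(vm, WAVELET, mode="periodization", level=WAVELET_LEVELS)
    approx = float(np.sum(coeffs[0] ** 2))
    # coeffs[1] is the coarsest detail; report wave_energy_k with k=1 finest
    details = [float(np.sum(c**2)) for c in coeffs[1:]]  # [d3, d2, d1]
    d3, d2, d1 = details
    bands = np.array([approx, d3, d2, d1])
    total = bands.sum()
    if total > 0:
        p = bands / total
        nz = p[p > 0]
        entropy = float(-np.sum(nz * np.log(nz)))
        rel = bands / total
    else:
        entropy = 0.0
        rel = np.zeros(4)
    return {
        "sc.wave_approx": approx,
        "sc.wave_energy_1": d1,
        "sc.wave_energy_2": d2,
        "sc.wave_energy_3": d3,
        "sc.wave_entropy": entropy,
        "sc.rel_energy_1": float(rel[3]),
        "sc.rel_energy_2": float(rel[2]),
        "sc.rel_energy_3": float(rel[1]),
    }


def axis_correlation_features(axes: np.ndarray) -> dict:
    """Pearson correlations between axis pairs over the segment."""
    axes = np.asarray(axes, dtype=float)
    out = {}
    for key, (i, j) in {"cc.corr_xy": (0, 1), "cc.corr_xz": (0, 2), "cc.corr_yz": (1, 2)}.items():
        a, b = axes[:, i], axes[:, j]
        if len(a) < 3 or np.std(a) == 0 or np.std(b) == 0:
            out[key] = float("nan")
        else:
            out[key] = float(np.corrcoef(a, b)[0, 1])
    return out


#: inclination change above which the movement is flagged as a roll (deg)
ROLL_ANGLE_DEG = 30.0
#: gravity magnitude below which orientation is unreliable (g)
MIN_GRAVITY_G = 0.5


def inclination_features(gravity: np.ndarray, fs: float) -> dict:
    """Change of the inclination angle of the low-pass gravity vector.

    Inclination is measured against the device vertical (the +z axis). The
    rate is the net change over the segment duration; the max rate is taken
    over 0.5-s sub-windows.
    """
    g = np.asarray(gravity, dtype=float)
    keys = ("ang.incl_angle_change", "ang.angle_rate_change", "ang.max_angle_rate", "ang.roll_flag")
    mag = np.linalg.norm(g, axis=1)
    if np.min(mag) < MIN_GRAVITY_G:
        return {k: float("nan") for k in keys}
    cos_incl = np.clip(g[:, 2] / mag, -1.0, 1.0)
    angle = np.degrees(np.arccos(cos_incl))
    change = float(abs(angle[-1] - angle[0]))
    duration = len(g) / fs
    rate = change / duration
    w = max(1, int(round(0.5 * fs)))
    if len(angle) > w:
        max_rate = float(np.max(np.abs(angle[w:] - angle[:-w])) / (w / fs))
    else:
        max_rate = rate
    return {
        "ang.incl_angle_change": change,
        "ang.angle_rate_change": rate,
        "ang.max_angle_rate": max_rate,
        "ang.roll_flag": 1.0 if change >= ROLL_ANGLE_DEG else 0.0,
    }


def gravity_change_features(gravity: np.ndarray) -> dict:
    """Per-axis absolute change of the low-pass gravity component (g)."""
    g = np.asarray(gravity, dtype=float)
    if np.min(np.linalg.norm(g, axis=1)) < MIN_GRAVITY_G:
        return {k: float("nan") for k in ("cga.grav_change_x", "cga.grav_change_y", "cga.grav_change_z")}
    delta = np.abs(g[-1] - g[0])
    return {
        "cga.grav_change_x": float(delta[0]),
        "cga.grav_change_y": float(delta[1]),
        "cga.grav_change_z": float(delta[2]),
    }


def median_crossing_features(vm: np.ndarray, duration_s: float) -> dict:
    """Sign changes of vm about its median; normalized per second."""
    vm = np.asarray(vm, dtype=float)
    s = np.sign(vm - np.median(vm))
    s = s[s != 0]
    count = int(np.sum(s[1:] != s[:-1])) if len(s) > 1 else 0
    return {
        "mc.num_med_crossings": float(count),
        "mc.num_med_crossings_norm": count / duration_s if duration_s > 0 else float("nan"),
    }


def velocity_distance_features(axes: np.ndarray, fs: float, detrend: bool = True) -> dict:
    """Velocity/distance estimates by trapezoidal integration.

    Acceleration (g) is converted to m/s^2 and integrated per axis; linear
    drift is removed from the velocity unless ``detrend=False`` (useful for
    analytic checks on unfiltered inputs).
    """
    a = np.asarray(axes, dtype=float) * GRAVITY_M_S2
    dt = 1.0 / fs
    v = integrate.cumulative_trapezoid(a, dx=dt, initial=0.0, axis=0)
    if detrend and len(v) > 2:
        v = signal.detrend(v, axis=0, type="linear")
    speed = np.linalg.norm(v, axis=1)
    disp = np.linalg.norm(np.trapezoid(v, dx=dt, axis=0))
    path = float(np.trapezoid(speed, dx=dt))
    jerk = np.diff(a, axis=0) * fs
    jerk_mag = np.linalg.norm(jerk, axis=1) if len(jerk) else np.zeros(1)
    return {
        "vd.peak_velocity": float(np.max(speed)),
        "vd.mean_velocity": float(np.mean(speed)),
        "vd.velocity_rms": float(np.sqrt(np.mean(speed**2))),
        "vd.displacement": float(disp),
        "vd.path_length": path,
        "vd.jerk_rms": float(np.sqrt(np.mean(jerk_mag**2))),
        "vd.jerk_peak": float(np.max(jerk_mag)),
    }


def movement_timing_features(event: MovementEvent, sleep_period: tuple) -> dict:
    s0, s1 = sleep_period
    fs = event.sampling_rate_hz
    onset_h = (event.start_idx - s0) / fs / 3600.0
    period_len = (s1 - s0) / fs
    return {
        "time.duration_s": event.duration_s,
        "time.onset_hours": onset_h,
        "time.night_fraction": (event.start_idx - s0) / (s1 - s0),
        "time.offset_hours": (event.end_idx - s0) / fs / 3600.0,
    }


def _norm_xcorr(a: np.ndarray, b: np.ndarray):
    """Full normalized cross-correlation of equal-length (zero-padded) slices."""
    n = max(len(a), len(b))
    a = np.pad(a, (0, n - len(a)))
    b = np.pad(b, (0, n - len(b)))
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return None, None
    c = signal.correlate(a, b, mode="full") / denom
    lags = signal.correlation_lags(n, n, mode="full")
    return c, lags


def _peak_stats(c: np.ndarray, lags: np.ndarray, fs: float):
    """(max, n_peaks, |lag| of peak closest to zero in s) of a correlation curve."""
    cmax = float(np.max(c))
    interior = np.arange(1, len(c) - 1)
    is_peak = (c[interior] > c[interior - 1]) & (c[interior] >= c[interior + 1])
    peaks = interior[is_peak & (c[interior] > PEAK_FRACTION * cmax)]
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(c))])
    closest = peaks[np.argmin(np.abs(lags[peaks]))]
    return cmax, float(len(peaks)), float(abs(lags[closest]) / fs)


RRM_KEYS = (
    "rrm.time_since_prev",
    "rrm.max_cross_corr",
    "rrm.max_cross_cov",
    "rrm.num_cross_corr_peaks",
    "rrm.num_cross_cov_peaks",
    "rrm.close_cross_corr_peak",
    "rrm.close_cross_cov_peak",
    "rrm.move_next_90s",
    "rrm.dom_freq_last_90s",
    "rrm.corr_with_prev",
    "rrm.consistency_score",
)


def recent_movement_features(
    event: MovementEvent,
    prev_event: MovementEvent | None,
    limb_events: list,
    vm_trace: np.ndarray,
    sleep_period: tuple,
) -> dict:
    """Relationship of a movement to the recent same-limb movement history.

    Cross-correlation compares the raw vm slices (shorter one zero-padded);
    cross-covariance compares the mean-removed slices. Peaks are local maxima
    above 25% of the global maximum. ``move_next_90s`` flags any same-limb
    event starting within 90 s after this event ends; ``dom_freq_last_90s``
    is the dominant frequency of the preceding 90 s of the filtered vector
    magnitude (clipped at sleep onset). For the first movement of the night
    all previous-referenced values are NaN.
    """
    fs = event.sampling_rate_hz
    out = {k: float("nan") for k in RRM_KEYS}

    out["rrm.move_next_90s"] = float(
        any(
            e.start_idx > event.start_idx
            and (e.start_idx - event.end_idx) / fs <= RECENT_WINDOW_S
            and e.start_idx >= event.end_idx
            for e in limb_events
        )
    )

    s0 = sleep_period[0]
    win_start = max(s0, event.start_idx - int(RECENT_WINDOW_S * fs))
    window = vm_trace[win_start : event.start_idx]
    if len(window) >= 2 * fs:
        out["rrm.dom_freq_last_90s"] = frequency_features(window, fs)["freq.dom_freq_1"]

    if prev_event is None:
        return out

    out["rrm.time_since_prev"] = (event.start_idx - prev_event.end_idx) / fs

    cur, prv = event.vm, prev_event.vm
    c, lags = _norm_xcorr(cur, prv)
    if c is not None:
        cmax, npk, close = _peak_stats(c, lags, fs)
        out["rrm.max_cross_corr"] = cmax
        out["rrm.num_cross_corr_peaks"] = npk
        out["rrm.close_cross_corr_peak"] = close
    cv, lags_cv = _norm_xcorr(cur - np.mean(cur), prv - np.mean(prv))
    if cv is not None:
        cmax, npk, close = _peak_stats(cv, lags_cv, fs)
        out["rrm.max_cross_cov"] = cmax
        out["rrm.num_cross_cov_peaks"] = npk
        out["rrm.close_cross_cov_peak"] = close

    n = min(len(cur), len(prv))
    if n >= 3 and np.std(cur[:n]) > 0 and np.std(prv[:n]) > 0:
        out["rrm.corr_with_prev"] = float(np.corrcoef(cur[:n], prv[:n])[0, 1])
    if not np.isnan(out["rrm.max_cross_corr"]):
        ratio = min(event.duration_s, prev_event.duration_s) / max(
            event.duration_s, prev_event.duration_s
        )
        out["rrm.consistency_score"] = out["rrm.max_cross_corr"] * ratio
    return out


#: low-pass cutoff separating gravity from movement (Hz)
GRAVITY_CUTOFF_HZ = 0.25
#: context padding around an event when estimating gravity locally (s)
GRAVITY_PAD_S = 6.0


def gravity_slice(
    data: np.ndarray, fs: float, start: int, end: int, cutoff_hz: float = GRAVITY_CUTOFF_HZ
) -> np.ndarray:
    """Low-pass gravity estimate over [start, end), filtered with local context.

    Filtering a padded slice instead of the whole night is numerically
    equivalent away from the trace edges and much cheaper for short events.
    """
    from ..detection import lowpass

    pad = int(GRAVITY_PAD_S * fs)
    a, b = max(0, start - pad), min(len(data), end + pad)
    g = lowpass(data[a:b], fs, cutoff_hz)
    return g[start - a : start - a + (end - start)]


@dataclass
class MovementContext:
    """Per-trace context shared by all movements of one limb-night."""

    fs: float
    sleep_period: tuple
    vm_filtered: np.ndarray  # high-pass vector magnitude, full trace
    raw_data: np.ndarray | None = None  # (n, 3) unfiltered trace for gravity
    gravity: np.ndarray | None = None  # optional precomputed full-trace estimate
    limb_events: list = field(default_factory=list)  # ordered same-limb events

    def gravity_for(self, event: MovementEvent) -> np.ndarray:
        if self.gravity is not None:
            return self.gravity[event.start_idx : event.end_idx]
        return gravity_slice(self.raw_data, self.fs, event.start_idx, event.end_idx)


def compute_movement_features(event: MovementEvent, ctx: MovementContext) -> dict:
    """Assemble the full 61-feature block for one segmented ankle movement."""
    vm = event.vm
    out = {}
    out.update(stat_features(vm))
    out.update(frequency_features(vm, ctx.fs))
    out.update(wavelet_features(vm))
    out["sc.lyapunov_exp"] = largest_lyapunov_exponent(vm)
    out.update(axis_correlation_features(event.axes))
    grav = ctx.gravity_for(event)
    out.update(inclination_features(grav, ctx.fs))
    out.update(gravity_change_features(grav))
    out.update(median_crossing_features(vm, event.duration_s))
    prev = (
        ctx.limb_events[event.prev_index]
        if event.prev_index is not None and event.prev_index >= 0
        else None
    )
    out.update(
        recent_movement_features(event, prev, ctx.limb_events, ctx.vm_filtered, ctx.sleep_period)
    )
    out.update(velocity_distance_features(event.axes, ctx.fs))
    out.update(movement_timing_features(event, ctx.sleep_period))
    return out
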