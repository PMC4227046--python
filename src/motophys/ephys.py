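"""Per-cell passive and spike-shape measurements from current-clamp sweeps.

Definitions follow standard intracellular practice for neonatal motoneuron
slice recordings: resting potential as the pre-pulse baseline mean; spikes as
overshooting voltage peaks; spike threshold as the voltage where dV/dt first
exceeds 10 mV/ms on the upstroke; input conductance as the inverse slope of
the steady-state I-V relation over small 500 ms pulses; spike amplitude and
width at half amplitude on the average of 30 brief-pulse trials; and the AHP
relaxation time constant from a mono-exponential fit. Liquid junction
potential is not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .errors import AnalysisError, NoSpikeError, ValidationError
from .synthgen import ProtocolSet, Sweep

#: dV/dt criterion for the spiking threshold (mV/ms)
DVDT_CRITERION = 10.0
#: boxcar width for derivative smoothing (s)
DERIV_SMOOTH = 0.2e-3
#: baseline window before current onset for the resting potential (s)
BASELINE_WINDOW = 0.200
#: steady-state averaging window at the end of each I-V pulse (s)
IV_STEADY_WINDOW = 0.100


@dataclass
class SpikeTrain:
    """Detected spikes of one sweep."""

    peak_times: np.ndarray                 # s
    peak_indices: np.ndarray
    threshold_times: np.ndarray = field(default_factory=lambda: np.array([]))
    threshold_voltages: np.ndarray = field(default_factory=lambda: np.array([]))

    def __len__(self) -> int:
        return len(self.peak_times)

    @property
    def instantaneous_frequencies(self) -> np.ndarray:
        """Inverse inter-spike intervals (Hz), one per ISI."""
        if len(self.peak_times) < 2:
            return np.array([])
        return 1.0 / np.diff(self.peak_times)


@dataclass
class CellFeatures:
    """The measured per-cell intrinsic-property vector."""

    cell_id: str = ""
    genotype: str = ""
    V_rest: float = np.nan          # mV
    G_in: float = np.nan            # nS
    rheobase: float = np.nan        # nA
    V_threshold: float = np.nan     # mV
    delta_V: float = np.nan         # mV
    recruitment_current: float = np.nan  # nA
    derecruitment_current: float = np.nan  # nA
    ap_amplitude: float = np.nan    # mV
    ap_halfwidth: float = np.nan    # ms
    ahp_tau: float = np.nan         # ms
    pattern: str = ""               # immediate | delayed
    mmo_present: bool = False
    gain: float = np.nan            # Hz/nA; nan when no primary range exists
    f_half_second: float = np.nan   # Hz


def _current_onset_index(sweep: Sweep) -> int:
    nz = np.flatnonzero(np.abs(sweep.current) > 1e-9)
    if nz.size == 0:
        raise AnalysisError("sweep carries no current injection")
    return int(nz[0])


def resting_potential(sweep: Sweep) -> float:
    """Mean voltage over the 200 ms preceding current onset (mV)."""
    onset = _current_onset_index(sweep)
    n_base = int(round(BASELINE_WINDOW / sweep.dt))
    if onset < n_base:
        raise AnalysisError(
            f"baseline window unavailable: {onset * sweep.dt * 1e3:.0f} ms "
            f"before onset, need {BASELINE_WINDOW * 1e3:.0f} ms")
    return float(np.mean(sweep.voltage[onset - n_base:onset]))


def detect_spikes(sweep: Sweep, min_overshoot: float = 0.0,
                  with_thresholds: bool = False,
                  min_prominence: float = 10.0) -> SpikeTrain:
    """Overshooting voltage peaks separated by at least 1 ms.

    A peak must also be a prominent event (default 10 mV) so that baseline
    noise riding on a depolarized plateau is never mistaken for a spike. An
    empty train is a valid result (subthreshold sweep). When
    ``with_thresholds`` is set, the dV/dt threshold crossing is located for
    every spike and recorded in the train.
    """
    distance = max(1, int(round(1e-3 / sweep.dt)))
    peaks, _ = signal.find_peaks(sweep.voltage, height=min_overshoot,
                                 distance=distance, prominence=min_prominence)
    train = SpikeTrain(peak_times=peaks * sweep.dt, peak_indices=peaks)
    if with_thresholds and peaks.size:
        t_times, t_volts = [], []
        for k in range(peaks.size):
            idx, volt = _threshold_crossing(sweep, k, train)
            t_times.append(idx * sweep.dt)
            t_volts.append(volt)
        train.threshold_times = np.asarray(t_times)
        train.threshold_voltages = np.asarray(t_volts)
    return train


def _smoothed_derivative(v: np.ndarray, dt: float) -> np.ndarray:
    """Central-difference dV/dt (mV/ms) after a 0.2 ms boxcar."""
    width = max(1, int(round(DERIV_SMOOTH / dt)))
    if width > 1:
        kernel = np.ones(width) / width
        v = np.convolve(v, kernel, mode="same")
    dv = np.gradient(v, dt * 1e3)
    return dv


def _threshold_crossing(sweep: Sweep, spike_index: int, train: SpikeTrain):
    peaks = train.peak_indices
    peak = int(peaks[spike_index])
    start = int(peaks[spike_index - 1]) if spike_index > 0 else 0
    dv = _smoothed_derivative(sweep.voltage[start:peak + 1], sweep.dt)
    # walk back from the peak through the upstroke run where dV/dt >= criterion
    i = peak - start - 1
    if i < 0 or dv[i] < DVDT_CRITERION:
        # the sample right before the peak can sit at the corner; step in
        while i >= 0 and dv[i] < DVDT_CRITERION:
            i -= 1
        if i < 0:
            raise AnalysisError("dV/dt never reached the threshold criterion")
    while i > 0 and dv[i - 1] >= DVDT_CRITERION:
        i -= 1
    return start + i, float(sweep.voltage[start + i])


def spike_threshold(sweep: Sweep, spike_index: int = 0,
                    train: SpikeTrain | None = None) -> float:
    """Voltage at the first upstroke sample where dV/dt >= 10 mV/ms (mV)."""
    if train is None:
        train = detect_spikes(sweep)
    if len(train) <= spike_index:
        raise NoSpikeError("requested spike not present in the sweep")
    _, volt = _threshold_crossing(sweep, spike_index, train)
    return volt


def input_conductance(iv: ProtocolSet) -> float:
    """Inverse slope of the steady-state I-V line (nS).

    Steady-state deflection per sweep is the mean over the last 100 ms of the
    pulse; sweeps at the same amplitude (the 10 repeats) are averaged before
    the least-squares line of V on I.
    """
    if iv.descriptor != "IV_STEPS":
        raise ValidationError("input_conductance needs an IV_STEPS protocol")
    by_amp: dict[float, list[float]] = {}
    for sweep in iv.sweeps:
        onset = _current_onset_index(sweep)
        on = np.flatnonzero(np.abs(sweep.current) > 1e-9)
        off = int(on[-1]) + 1
        n_ss = int(round(IV_STEADY_WINDOW / sweep.dt))
        amp = float(sweep.current[onset])
        v_ss = float(np.mean(sweep.voltage[off - n_ss:off]))
        by_amp.setdefault(round(amp, 6), []).append(v_ss)
    if len(by_amp) < 3:
        raise ValidationError("need at least 3 distinct I-V amplitudes")
    amps = np.array(sorted(by_amp))
    v = np.array([np.mean(by_amp[a]) for a in amps])
    slope, _ = np.polyfit(amps, v, 1)  # mV per nA
    if abs(slope) < 1e-12:
        raise AnalysisError("singular I-V fit")
    return 1000.0 / slope


def average_aligned(protocol: ProtocolSet) -> tuple[Sweep, int]:
    """Average single-spike trials aligned on the spike peak sample.

    Returns the averaged sweep and the common peak index. Trials whose peak
    is more than 5 ms away from the median peak time are rejected.
    """
    if not protocol.sweeps:
        raise ValidationError("no sweeps to average")
    peaks = []
    for sweep in protocol.sweeps:
        train = detect_spikes(sweep)
        if len(train) != 1:
            raise AnalysisError(
                f"sweep {sweep.sweep_index} has {len(train)} spikes, expected exactly 1")
        peaks.append(int(train.peak_indices[0]))
    peaks = np.asarray(peaks)
    med = int(np.median(peaks))
    dt = protocol.sweeps[0].dt
    if np.any(np.abs(peaks - med) * dt > 5e-3):
        raise AnalysisError("trials misaligned beyond 5 ms tolerance")
    p_min = int(peaks.min())
    n = min(s.voltage.size - (p - p_min) for s, p in zip(protocol.sweeps, peaks))
    stack = np.stack([
        s.voltage[p - p_min: p - p_min + n]
        for s, p in zip(protocol.sweeps, peaks)
    ])
    avg_v = stack.mean(axis=0)
    ref = protocol.sweeps[0]
    cur = ref.current[peaks[0] - p_min: peaks[0] - p_min + n]
    return Sweep(dt=dt, voltage=avg_v, current=cur, protocol_id=ref.protocol_id), p_min


def ap_shape(single_aps: ProtocolSet) -> tuple[float, float]:
    """(amplitude mV, half-width ms) of the averaged single action potential.

    Amplitude is peak minus pre-pulse baseline; half-width is the time the
    averaged waveform spends at or above baseline + amplitude/2, with linear
    interpolation at the two half-level crossings.
    """
    avg, peak = average_aligned(single_aps)
    baseline = resting_potential(avg)
    amp = float(avg.voltage[peak] - baseline)
    half = baseline + amp / 2.0
    v = avg.voltage
    above = v >= half
    left = peak
    while left > 0 and above[left - 1]:
        left -= 1
    right = peak
    while right < v.size - 1 and above[right + 1]:
        right += 1
    # sub-sample interpolation of the crossing on each flank
    t_left = left - (v[left] - half) / (v[left] - v[left - 1]) if left > 0 else left
    t_right = right + (v[right] - half) / (v[right] - v[right + 1]) \
        if right < v.size - 1 else right
    return amp, float((t_right - t_left) * avg.dt * 1e3)


def fit_ahp(avg_sweep: Sweep, peak_index: int | None = None,
            baseline: float | None = None) -> float:
    """AHP relaxation time constant (ms) by mono-exponential least squares.

    The model is V(t) = baseline - A * exp(-(t - t_trough)/tau) fitted from
    the post-spike trough until the voltage has recovered to within 5% of the
    trough depth, or the next stimulus, whichever comes first.
    """
    v, dt = avg_sweep.voltage, avg_sweep.dt
    if peak_index is None:
        train = detect_spikes(avg_sweep)
        if len(train) == 0:
            raise NoSpikeError("no spike found for AHP fit")
        peak_index = int(train.peak_indices[0])
    if baseline is None:
        baseline = resting_potential(avg_sweep)
    search = v[peak_index:]
    trough_rel = int(np.argmin(search))
    trough = peak_index + trough_rel
    depth = baseline - v[trough]
    if depth <= 0.5:
        raise AnalysisError("no AHP trough after the spike")
    # fit window: trough -> recovery to 5% of depth (or next current step/end)
    rec = np.flatnonzero(v[trough:] >= baseline - 0.05 * depth)
    stop = trough + (int(rec[0]) if rec.size else v.size - trough)
    nxt = np.flatnonzero(np.abs(avg_sweep.current[trough:]) > 1e-9)
    if nxt.size:
        stop = min(stop, trough + int(nxt[0]))
    if stop - trough < 5:
        raise AnalysisError("AHP recovery window too short to fit")
    t = (np.arange(trough, stop) - trough) * dt * 1e3  # ms
    y = v[trough:stop]

    def model(tt, a, tau):
        return baseline - a * np.exp(-tt / tau)

    try:
        popt, _ = optimize.curve_fit(
            model, t, y, p0=(depth, max(t[-1] / 3.0, 1.0)), maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise AnalysisError(f"AHP fit did not converge: {exc}") from exc
    return float(popt[1])
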