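"""Synthetic motoneurons, their protocol responses, and dendritic trees.

The generator stands in for raw patch-clamp recordings: it draws ground-truth
model cells from published per-group property tables (:mod:`motophys.tables`),
renders their voltage responses to each acquisition protocol, and emits
partial dendritic reconstructions as SWC trees, so every downstream stage of
the pipeline can be tested against known ground truth.

Two trace-synthesis modes exist. ``template`` composes sweeps analytically:
RC charging toward V_rest + I/G_in, stereotyped spike waveforms with the
cell's amplitude/half-width, mono-exponential AHP recovery, a slow
depolarizing creep for delayed-firing cells, and damped subthreshold
oscillations (MMOs) between spikes at low drive. ``mechanistic`` integrates a
leaky integrate-and-fire cell with a slowly inactivating potassium
conductance that reproduces the delayed/immediate phenomenology dynamically.

Joint structure of the samples: input conductance G_in and rheobase are drawn
from their printed rows through a Gaussian copula whose correlation is
calibrated (deterministically, per group) so that the derived voltage
distance to threshold, delta_V = 1000 * rheobase / G_in, has the printed
group mean. This keeps the Ohmic relation I = G * U exact per cell while the
conductance, rheobase and delta_V table rows are all recoverable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import ValidationError
from .sampling import MatchedTruncNorm, calibrate_copula_rho, gaussian_copula_pair, matched_truncnorm
from .tables import MMO_PREVALENCE, Row, electro_rows, morpho_rows

DESCRIPTORS = ("IV_STEPS", "RHEO_STEPS", "SINGLE_AP", "RAMP")

#: default white-noise SD added to every synthetic voltage trace (mV)
DEFAULT_NOISE_SD = 0.3
#: membrane time constant used by both synthesis modes (s)
DEFAULT_TAU_M = 0.010
#: minimum steady firing rate at rheobase (Hz)
DEFAULT_F_MIN = 12.0
#: F-I slope used to render delayed-cell step responses (Hz/nA)
DELAYED_STEP_SLOPE = 20.0
#: width of the sub-primary (MMO) current range above recruitment (nA)
SUBPRIMARY_WIDTH = 0.25
#: derecruitment current as a fraction of rheobase (ramp hysteresis)
DERECRUIT_FRACTION = 0.85
#: MMO rendering: oscillation frequency (Hz) and per-ISI damping constant (s)
MMO_FREQ = 100.0
MMO_DAMP_TAU = 0.060
#: latency of a delayed cell at rheobase (s): mean, sd, min, max
DELAY_SCALE_ROW = Row(2.5, 1.0, 0.5, 4.5, 1)
#: AHP trough depth below baseline (mV): mean, sd, min, max
AHP_AMPLITUDE_ROW = Row(5.0, 1.0, 2.0, 8.0, 1)
#: ceiling on the derived voltage distance to threshold (mV); published
#: delta_V ranges top out at 50 mV and a threshold near 0 mV would collide
#: with the overshoot criterion for spike detection
DELTA_V_CAP = 50.0


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Distribution entries defining one (genotype, pattern) population."""

    genotype: str
    pattern: str
    properties: dict[str, Row]
    mmo_prevalence: float = 1.0

    def __post_init__(self) -> None:
        if self.pattern not in ("immediate", "delayed"):
            raise ValidationError(f"unknown pattern {self.pattern!r}")
        for name in ("V_rest", "G_in", "rheobase", "delta_V",
                     "ap_amplitude", "ap_halfwidth", "ahp_tau"):
            if name not in self.properties:
                raise ValidationError(f"GroupSpec incomplete: missing {name!r}")

    @classmethod
    def from_tables(cls, genotype: str, pattern: str) -> "GroupSpec":
        k, n = MMO_PREVALENCE[(genotype, pattern)]
        return cls(genotype, pattern, dict(electro_rows(genotype, pattern)), k / n)

    def with_zero_sd(self) -> "GroupSpec":
        """Degenerate copy: every property pinned at its mean (for tests)."""
        props = {k: Row(r.mean, 0.0, r.mean, r.mean, r.n) for k, r in self.properties.items()}
        return replace(self, properties=props)


@dataclass
class ModelCell:
    """Ground-truth intrinsic parameters of one synthetic motoneuron."""

    id: str
    genotype: str
    pattern: str
    V_rest: float          # mV
    G_in: float            # nS
    V_th: float            # mV, spike threshold (dV/dt criterion voltage)
    delta_V: float         # mV, V_th - V_rest
    rheobase_true: float   # nA
    ap_amplitude: float    # mV, peak above resting baseline
    ap_halfwidth: float    # ms
    ahp_amplitude: float   # mV, trough depth below baseline
    ahp_tau: float         # ms
    gain_true: float       # Hz/nA (nan for delayed cells: no linear primary range)
    f_half_second_true: float  # Hz, rate 0.5 s after ramp recruitment
    mmo_present: bool
    mmo_amplitude: float = 2.0   # mV
    delay_scale: float = 0.0     # s, first-spike latency at rheobase (delayed only)
    noise_sd: float = DEFAULT_NOISE_SD
    tau_m: float = DEFAULT_TAU_M
    f_min: float = DEFAULT_F_MIN
    seed: int = 0

    def __post_init__(self) -> None:
        if self.V_th <= self.V_rest:
            raise ValidationError("V_th must exceed V_rest")
        if self.pattern == "delayed" and not self.delay_scale > 0:
            raise ValidationError("delayed cells need delay_scale > 0")
        if self.pattern == "immediate" and self.delay_scale != 0:
            raise ValidationError("immediate cells have delay_scale = 0")

    @property
    def mmo_ceiling(self) -> float:
        """Current (nA) above which MMOs disappear (sub-primary upper edge)."""
        if self.pattern == "delayed":
            return math.inf  # no identifiable primary range in delayed cells
        return self.rheobase_true + SUBPRIMARY_WIDTH

    @property
    def v_peak(self) -> float:
        return self.V_rest + self.ap_amplitude

    @property
    def v_trough(self) -> float:
        return self.V_rest - self.ahp_amplitude


@dataclass
class Sweep:
    """One current-clamp trace pair, uniformly sampled."""

    dt: float                 # s
    voltage: np.ndarray       # mV
    current: np.ndarray       # nA
    sweep_index: int = 0
    protocol_id: str = ""

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.voltage.shape != self.current.shape:
            raise ValidationError("voltage and current series must have equal length")
        if not self.dt > 0:
            raise ValidationError("dt must be > 0")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.voltage.size) * self.dt


@dataclass
class ProtocolSet:
    """Ordered sweeps of one acquisition protocol plus its parameters."""

    descriptor: str
    sweeps: list[Sweep]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.descriptor not in DESCRIPTORS:
            raise ValidationError(f"unsupported protocol descriptor {self.descriptor!r}")


# --------------------------------------------------------------------------
# population sampling
# --------------------------------------------------------------------------

def _matched(row: Row) -> MatchedTruncNorm:
    return matched_truncnorm(row.mean, row.sd, row.min, row.max)


def _group_rho(spec: GroupSpec) -> float:
    """Copula correlation between G_in and rheobase hitting the delta_V mean."""
    dist_g = _matched(spec.properties["G_in"])
    dist_i = _matched(spec.properties["rheobase"])
    target = spec.properties["delta_V"].mean
    return calibrate_copula_rho(
        dist_g, dist_i,
        lambda g, i: float(np.mean(np.minimum(1000.0 * i / g, DELTA_V_CAP))),
        target,
    )


def sample_population(spec: GroupSpec, n: int, seed: int) -> list[ModelCell]:
    """Draw ``n`` ground-truth model cells for one group.

    Every scalar property comes from a moment-matched truncated normal of its
    table row. G_in and rheobase are coupled (see module docstring) and
    delta_V is derived, so rheobase = G_in * delta_V / 1000 holds exactly.
    """
    if n <= 0:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = spec.properties

    rho = _group_rho(spec)
    g_in, rheo = gaussian_copula_pair(_matched(p["G_in"]), _matched(p["rheobase"]), rho, n, rng)
    # cap the derived threshold distance; rheobase follows so I = G * U stays
    # exact per cell (a threshold near 0 mV would be unphysiological and
    # collide with the overshoot spike criterion)
    delta_v = np.minimum(1000.0 * rheo / g_in, DELTA_V_CAP)
    rheo = g_in * delta_v / 1000.0

    v_rest = _matched(p["V_rest"]).rvs(n, rng)
    amp = _matched(p["ap_amplitude"]).rvs(n, rng)
    width = _matched(p["ap_halfwidth"]).rvs(n, rng)
    ahp_tau = _matched(p["ahp_tau"]).rvs(n, rng)
    ahp_amp = _matched(AHP_AMPLITUDE_ROW).rvs(n, rng)
    mmo = rng.uniform(size=n) < spec.mmo_prevalence
    seeds = rng.integers(0, 2**31 - 1, size=n)

    if spec.pattern == "immediate":
        gain = _matched(p["gain"]).rvs(n, rng)
        f_half = DEFAULT_F_MIN + gain * 0.05  # rate 0.5 s (0.05 nA) past recruitment
        delay = np.zeros(n)
    else:
        gain = np.full(n, np.nan)
        f_half = _matched(p["f_half_second"]).rvs(n, rng)
        delay = _matched(DELAY_SCALE_ROW).rvs(n, rng)

    # Spikes must overshoot 0 mV (study inclusion criterion) and peak must sit
    # clear of the threshold so an upstroke exists; lift rare offending draws.
    amp = np.maximum(amp, np.maximum(5.0 - v_rest, delta_v + 25.0))

    cells = []
    for i in range(n):
        cells.append(ModelCell(
            id=f"{spec.genotype}_{spec.pattern}_{i:04d}",
            genotype=spec.genotype, pattern=spec.pattern,
            V_rest=float(v_rest[i]), G_in=float(g_in[i]),
            V_th=float(v_rest[i] + delta_v[i]), delta_V=float(delta_v[i]),
            rheobase_true=float(rheo[i]),
            ap_amplitude=float(amp[i]), ap_halfwidth=float(width[i]),
            ahp_amplitude=float(ahp_amp[i]), ahp_tau=float(ahp_tau[i]),
            gain_true=float(gain[i]), f_half_second_true=float(f_half[i]),
            mmo_present=bool(mmo[i]),
            delay_scale=float(delay[i]) if spec.pattern == "delayed" else 0.0,
            seed=int(seeds[i]),
        ))
    return cells


# --------------------------------------------------------------------------
# template-mode trace synthesis
# --------------------------------------------------------------------------

def _spike_waveform(cell: ModelCell, dt: float) -> np.ndarray:
    """Stereotyped spike from threshold crossing to AHP trough.

    Piecewise-linear rise (threshold -> peak) and fall (peak -> trough), with
    durations chosen so the width at half amplitude equals the cell's
    half-width. The rise is kept steeper than 15 mV/ms so the dV/dt >= 10
    mV/ms criterion always fires on the upstroke, and the rise duration is
    snapped to the sample grid so the rendered peak value is exact.
    """
    v_th, v_peak, v_trough = cell.V_th, cell.v_peak, cell.v_trough
    a_half = cell.ap_amplitude / 2.0
    w = cell.ap_halfwidth * 1e-3  # s
    rise_share = a_half / (v_peak - v_th)        # fraction of rise above half level
    fall_share = a_half / (v_peak - v_trough)
    r = w / (rise_share + 2.0 * fall_share)      # fall lasts twice the rise
    r = min(r, (v_peak - v_th) / 15.0 * 1e-3)    # enforce upstroke >= 15 mV/ms
    r = max(dt, round(r / dt) * dt)              # peak lands on a sample
    f = max(dt, (w - r * rise_share) / fall_share)
    t = np.arange(0.0, r + f + dt / 2, dt)
    v = np.where(
        t <= r,
        v_th + (v_peak - v_th) * t / r,
        v_peak + (v_trough - v_peak) * np.clip((t - r) / f, 0.0, 1.0),
    )
    return v


def _iterate_spike_times(rate, t_start: float, t_stop: float, f_floor: float = 2.0):
    """Place spikes so each ISI is the inverse of the local rate."""
    times = []
    t = t_start
    while t < t_stop:
        times.append(t)
        f = max(rate(t), f_floor)
        t = t + 1.0 / f
    return np.asarray(times)


def _add_mmos(v: np.ndarray, t: np.ndarray, isi_windows, cell: ModelCell) -> None:
    """Damped subthreshold oscillations inside the given ISI windows."""
    for t0, t1 in isi_windows:
        if t1 - t0 < 0.012:
            continue
        sl = slice(np.searchsorted(t, t0 + 0.012), np.searchsorted(t, t1 - 0.006))
        if sl.stop <= sl.start:
            continue
        tt = t[sl] - (t0 + 0.012)
        v[sl] += cell.mmo_amplitude * np.exp(-tt / MMO_DAMP_TAU) * np.sin(
            2 * np.pi * MMO_FREQ * tt)


def _render_train(
    v: np.ndarray,
    t: np.ndarray,
    dt: float,
    spike_times: np.ndarray,
    cell: ModelCell,
    drive_baseline: float,
    rest_after: float,
    t_drive_end: float,
    mmo_current: np.ndarray | None = None,
) -> None:
    """Paste spike waveforms and AHP recoveries over a baseline trace.

    ``drive_baseline`` is the inter-spike plateau the AHP relaxes toward while
    the stimulus persists; after ``t_drive_end`` relaxation targets
    ``rest_after``. ``mmo_current`` (same length as ``v``), when given, gates
    MMO insertion per ISI by the current at the ISI midpoint.
    """
    wf = _spike_waveform(cell, dt)
    n = v.size
    tau = cell.ahp_tau * 1e-3
    mmo_windows = []
    for k, ts in enumerate(spike_times):
        i0 = int(round(ts / dt))
        if i0 >= n:
            break
        i1 = min(n, i0 + wf.size)
        v[i0:i1] = wf[: i1 - i0]
        next_i = int(round(spike_times[k + 1] / dt)) if k + 1 < len(spike_times) else n
        next_i = min(next_i, n)
        if i1 < next_i:
            tt = (np.arange(i1, next_i) - (i1 - 1)) * dt
            base = drive_baseline if t[i1 - 1] < t_drive_end else rest_after
            v[i1:next_i] = base - (base - cell.v_trough) * np.exp(-tt / tau)
            if k + 1 < len(spike_times):
                t0, t1 = t[i1 - 1], spike_times[k + 1]
                if mmo_current is None or mmo_current[(i1 + next_i) // 2] <= cell.mmo_ceiling:
                    mmo_windows.append((t0, t1))
    if cell.mmo_present and mmo_windows:
        _add_mmos(v, t, mmo_windows, cell)


def _noise(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    return rng.normal(0.0, sd, n) if sd > 0 else np.zeros(n)


def _template_step_sweep(
    cell: ModelCell, amplitude: float, rng: np.random.Generator, *,
    duration: float = 5.0, pre: float = 0.5, post: float = 0.5, dt: float = 1e-4,
    index: int = 0, protocol_id: str = "RHEO_STEPS",
) -> Sweep:
    """5 s square-pulse response (rheobase-search protocol)."""
    n = int(round((pre + duration + post) / dt))
    t = np.arange(n) * dt
    i_on, i_off = int(round(pre / dt)), int(round((pre + duration) / dt))
    cur = np.zeros(n)
    cur[i_on:i_off] = amplitude

    vr, tau = cell.V_rest, cell.tau_m
    defl = 1000.0 * amplitude / cell.G_in
    v = np.full(n, vr)
    seg = t[i_on:i_off] - pre
    v[i_on:i_off] = vr + defl * (1 - np.exp(-seg / tau))
    if i_off < n:
        v[i_off:] = vr + (v[i_off - 1] - vr) * np.exp(-(t[i_off:] - (pre + duration)) / tau)

    fires = amplitude >= cell.rheobase_true - 1e-12
    if fires:
        rheo = cell.rheobase_true
        if cell.pattern == "immediate":
            if defl > cell.delta_V + 1e-9:
                t_cross = -tau * math.log(1 - cell.delta_V / defl)
            else:
                t_cross = math.inf
            latency = min(t_cross, 0.080)
            f_const = cell.f_min + (0.0 if np.isnan(cell.gain_true) else
                                    cell.gain_true * (amplitude - rheo))
            rate = lambda _t: f_const
        else:
            latency = cell.delay_scale * max(0.0, (2 * rheo - amplitude) / rheo)
            latency = min(latency, duration - 0.2)
            f_ss = cell.f_min + DELAYED_STEP_SLOPE * (amplitude - rheo)
            t_first = pre + latency
            span = max(duration - latency, 1e-6)
            rate = lambda _t: f_ss * (0.6 + 0.4 * (_t - t_first) / span)
            # slow depolarizing creep toward threshold before the first spike
            base_frac = min(defl, 0.75 * cell.delta_V)
            creep = (cell.delta_V - base_frac) / max(latency, 1e-6)
            sl = slice(i_on, min(int(round((pre + latency) / dt)), i_off))
            v[sl] = vr + base_frac * (1 - np.exp(-(t[sl] - pre) / tau)) \
                + creep * (t[sl] - pre)
        spike_times = _iterate_spike_times(rate, pre + latency, pre + duration - 0.005)
        # cap the subthreshold trajectory so it never tops the threshold
        first_i = int(round(spike_times[0] / dt)) if spike_times.size else i_off
        np.minimum(v[i_on:first_i], cell.V_th, out=v[i_on:first_i])
        _render_train(
            v, t, dt, spike_times, cell,
            drive_baseline=cell.V_th - 6.0, rest_after=vr,
            t_drive_end=pre + duration,
            mmo_current=cur if amplitude <= cell.mmo_ceiling else None,
        )
    v += _noise(rng, cell.noise_sd, n)
    return Sweep(dt=dt, voltage=v, current=cur, sweep_index=index, protocol_id=protocol_id)


def _template_iv(cell: ModelCell, rng: np.random.Generator, *,
                 amplitudes_pa=(-100, -70, -40, -10, 20), repeats: int = 10,
                 duration: float = 0.5, pre: float = 0.2, post: float = 0.3,
                 dt: float = 1e-4) -> ProtocolSet:
    """Small 500 ms I-V pulses, each amplitude repeated ``repeats`` times."""
    sweeps = []
    n = int(round((pre + duration + post) / dt))
    t = np.arange(n) * dt
    i_on, i_off = int(round(pre / dt)), int(round((pre + duration) / dt))
    idx = 0
    for amp_pa in amplitudes_pa:
        amp = amp_pa / 1000.0  # nA
        defl = 1000.0 * amp / cell.G_in
        base = np.full(n, cell.V_rest)
        seg = t[i_on:i_off] - pre
        base[i_on:i_off] = cell.V_rest + defl * (1 - np.exp(-seg / cell.tau_m))
        base[i_off:] = cell.V_rest + (base[i_off - 1] - cell.V_rest) * np.exp(
            -(t[i_off:] - (pre + duration)) / cell.tau_m)
        cur = np.zeros(n)
        cur[i_on:i_off] = amp
        for _ in range(repeats):
            v = base + _noise(rng, cell.noise_sd, n)
            sweeps.append(Sweep(dt=dt, voltage=v, current=cur.copy(),
                                sweep_index=idx, protocol_id="IV_STEPS"))
            idx += 1
    return ProtocolSet("IV_STEPS", sweeps,
                       {"amplitudes_pA": list(amplitudes_pa), "repeats": repeats,
                        "pulse_s": duration, "pre_s": pre, "dt": dt})


def _template_single_ap(cell: ModelCell, rng: np.random.Generator, *,
                        trials: int = 30, pre: float = 0.25, total: float = 0.85,
                        dt: float = 1e-4) -> ProtocolSet:
    """1 ms suprathreshold pulses; one spike per trial, AHP fully recovered."""
    n = int(round(total / dt))
    t = np.arange(n) * dt
    amp = float(np.clip(2.0 * cell.rheobase_true, 1.0, 10.0))
    i_on = int(round(pre / dt))
    i_off = i_on + int(round(0.001 / dt))
    cur = np.zeros(n)
    cur[i_on:i_off] = amp
    base = np.full(n, cell.V_rest)
    # charge to threshold across the 1 ms pulse, spike at pulse end
    base[i_on:i_off] = cell.V_rest + cell.delta_V * (t[i_on:i_off] - pre) / 0.001
    t_spike = i_off * dt
    _render_train(base, t, dt, np.array([t_spike]), cell,
                  drive_baseline=cell.V_rest, rest_after=cell.V_rest,
                  t_drive_end=0.0)
    sweeps = []
    for k in range(trials):
        v = base + _noise(rng, cell.noise_sd, n)
        sweeps.append(Sweep(dt=dt, voltage=v, current=cur.copy(),
                            sweep_index=k, protocol_id="SINGLE_AP"))
    return ProtocolSet("SINGLE_AP", sweeps,
                       {"trials": trials, "pulse_nA": amp, "pre_s": pre, "dt": dt})


def _ramp_rate_fn(cell: ModelCell, t_rec: float, current_at):
    """Instantaneous-rate law along a triangular ramp."""
    i_rec = current_at(t_rec)
    if cell.pattern == "immediate":
        def rate(tt):
            return cell.f_min + cell.gain_true * (current_at(tt) - i_rec)
        return rate
    f_half = cell.f_half_second_true

    def rate(tt):
        rel = tt - t_rec
        if rel < 0.45:
            return max(4.0, f_half * rel / 0.45)
        if rel < 0.60:
            return f_half
        return f_half + 8.0 * (current_at(tt) - current_at(t_rec + 0.60))
    return rate


def _template_ramp(cell: ModelCell, rng: np.random.Generator, *,
                   velocity: float = 0.1, peak: float | None = None,
                   trials: int = 3, dt: float = 5e-4) -> ProtocolSet:
    """Slow triangular current ramp (default 0.1 nA/s)."""
    if cell.pattern == "immediate" and np.isnan(cell.gain_true):
        raise ValidationError("ramp requested for a cell with undefined gain")
    if peak is None:
        peak = max(1.0, 1.5 * cell.rheobase_true)
    t_apex = peak / velocity
    n = int(round(2 * t_apex / dt))
    t = np.arange(n) * dt
    cur = np.where(t <= t_apex, velocity * t, np.maximum(0.0, 2 * peak - velocity * t))

    def current_at(tt):
        return velocity * tt if tt <= t_apex else max(0.0, 2 * peak - velocity * tt)

    t_rec = cell.rheobase_true / velocity
    i_derec = DERECRUIT_FRACTION * cell.rheobase_true
    t_stop = (2 * peak - i_derec) / velocity  # descending crossing of derecruitment
    rate = _ramp_rate_fn(cell, t_rec, current_at)

    sweeps = []
    for k in range(trials):
        v = cell.V_rest + np.clip(1000.0 * cur / cell.G_in, None, cell.delta_V - 0.5)
        if t_rec < t_stop:
            spike_times = _iterate_spike_times(rate, t_rec, min(t_stop, t[-1] - 0.05))
            _render_train(v, t, dt, spike_times, cell,
                          drive_baseline=cell.V_th - 6.0, rest_after=cell.V_rest,
                          t_drive_end=t_stop, mmo_current=cur)
        v += _noise(rng, cell.noise_sd, n)
        sweeps.append(Sweep(dt=dt, voltage=v, current=cur.copy(),
                            sweep_index=k, protocol_id="RAMP"))
    return ProtocolSet("RAMP", sweeps,
                       {"velocity_nA_per_s": velocity, "peak_nA": peak,
                        "trials": trials, "dt": dt})


# --------------------------------------------------------------------------
# mechanistic mode: LIF + slowly inactivating potassium conductance
# --------------------------------------------------------------------------

def _mechanistic_sweep(cell: ModelCell, current: np.ndarray, dt: float,
                       rng: np.random.Generator, protocol_id: str,
                       index: int = 0) -> Sweep:
    """Euler-integrate a leaky IF cell; delayed cells carry a K conductance
    that is fully available at rest and slowly inactivates on depolarization,
    postponing the first spike and accelerating the discharge."""
    n = current.size
    vr = cell.V_rest
    g_l = cell.G_in
    c_nf = g_l * cell.tau_m  # nS * s = nF
    delayed = cell.pattern == "delayed"
    g_k = 1.5 * g_l if delayed else 0.0
    e_k = vr - 15.0
    tau_h = cell.delay_scale / 3.0 if delayed else 1.0
    wf = _spike_waveform(cell, dt)
    dt_ms = dt * 1e3

    v = np.empty(n)
    v[0] = vr
    h = 1.0
    i = 1
    tau_ahp = cell.ahp_tau * 1e-3
    while i < n:
        vm = v[i - 1]
        if vm >= cell.V_th and current[i - 1] > 0:
            j1 = min(n, i - 1 + wf.size)
            v[i - 1:j1] = wf[: j1 - i + 1]
            h *= math.exp(-(j1 - i + 1) * dt / tau_h) if delayed else 1.0
            i = j1
            continue
        i_net = current[i - 1] - g_l * (vm - vr) / 1000.0 - g_k * h * (vm - e_k) / 1000.0
        v[i] = vm + dt_ms * i_net / c_nf
        if delayed:
            h_inf = 1.0 / (1.0 + math.exp((vm - (vr + 3.0)) / 1.0))
            h += dt * (h_inf - h) / tau_h
        i += 1
    # relax spike-truncated tails toward rest with the AHP constant
    v += _noise(rng, cell.noise_sd, n)
    return Sweep(dt=dt, voltage=v, current=current, sweep_index=index,
                 protocol_id=protocol_id)


def _mechanistic_step(cell: ModelCell, amplitude: float, rng, *,
                      duration=5.0, pre=0.5, post=0.5, dt=1e-4, index=0) -> Sweep:
    n = int(round((pre + duration + post) / dt))
    cur = np.zeros(n)
    cur[int(round(pre / dt)): int(round((pre + duration) / dt))] = amplitude
    return _mechanistic_sweep(cell, cur, dt, rng, "RHEO_STEPS", index)


# --------------------------------------------------------------------------
# public protocol synthesis
# --------------------------------------------------------------------------

def synthesize_protocol(
    cell: ModelCell,
    descriptor: str,
    mode: Literal["template", "mechanistic"] = "template",
    seed: int | None = None,
    **params,
) -> ProtocolSet:
    """Render one acquisition protocol for a model cell.

    ``RHEO_STEPS`` accepts ``amplitudes`` (nA list; default: the 50/100 pA
    search grid up to the first suprathreshold step), ``IV_STEPS`` the
    standard -100..+20 pA series, ``SINGLE_AP`` 30 brief-pulse trials,
    ``RAMP`` a slow triangular ramp.
    """
    if descriptor not in DESCRIPTORS:
        raise ValidationError(f"unsupported protocol descriptor {descriptor!r}")
    rng = np.random.default_rng(cell.seed if seed is None else seed)

    if descriptor == "RHEO_STEPS":
        amplitudes = params.pop("amplitudes", None)
        if amplitudes is None:
            from .protocols import search_grid
            grid = search_grid(params.pop("ceiling", 5.0))
            stop = int(np.searchsorted(grid, cell.rheobase_true - 1e-12))
            amplitudes = list(grid[: min(stop + 1, grid.size)])
        step = _mechanistic_step if mode == "mechanistic" else _template_step_sweep
        sweeps = [step(cell, float(a), rng, index=k, **params)
                  for k, a in enumerate(amplitudes)]
        return ProtocolSet("RHEO_STEPS", sweeps,
                           {"amplitudes_nA": [float(a) for a in amplitudes],
                            "pulse_s": params.get("duration", 5.0),
                            "interpulse_s": 20.0, "mode": mode})
    if mode == "mechanistic":
        raise ValidationError("mechanistic mode implements RHEO_STEPS only")
    if descriptor == "IV_STEPS":
        return _template_iv(cell, rng, **params)
    if descriptor == "SINGLE_AP":
        return _template_single_ap(cell, rng, **params)
    return _template_ramp(cell, rng, **params)


# --------------------------------------------------------------------------
# synthetic dendritic trees
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeSpec:
    """Distributions for synthetic partial dendritic reconstructions."""

    n_primary: Row
    n_branch_points: Row
    total_length: Row            # mm, post-filter target
    terminal_segment_length: Row  # um
    z_excursion: Row              # um, depth below slice surface (kept dendrites)
    p_plunge: float = 0.3         # probability of one extra plunging dendrite
    plunge_depth: float = 80.0    # um, beyond the 50 um inclusion limit

    @classmethod
    def from_tables(cls, genotype: str, pattern: str) -> "TreeSpec":
        m = morpho_rows(genotype, pattern)
        return cls(
            n_primary=m["n_primary"],
            n_branch_points=m["n_branch_points"],
            total_length=m["total_length"],
            terminal_segment_length=m["terminal_segment"],
            z_excursion=Row(20, 10, 0, 45, 1),
        )

    def __post_init__(self) -> None:
        for name in ("n_primary", "n_branch_points", "total_length",
                     "terminal_segment_length", "z_excursion"):
            row = getattr(self, name)
            if row.max < 0 or (name != "n_branch_points" and row.max <= 0):
                raise ValidationError(f"{name} support must be positive")


def generate_tree(spec: TreeSpec, seed: int):
    """Grow one synthetic SWC morphology; returns (Morphology, ground_truth).

    Topology: the drawn number of bifurcations is spread over the drawn
    number of primary dendrites; each dendrite is grown by repeatedly
    splitting a random terminal segment. Raw segment lengths come from the
    terminal-segment distribution and are rescaled so the summed length of
    the in-plane dendrites equals the drawn total-length target exactly.
    Nodes are laid out as 10 um steps with angular jitter; kept dendrites
    stay above their drawn depth excursion, while optional extra dendrites
    plunge past the slice-inclusion limit to exercise the depth filter.
    """
    from .morphometry import Morphology  # local import: one-way dependency

    rng = np.random.default_rng(seed)
    n_primary = max(1, int(round(_matched(spec.n_primary).rvs(1, rng)[0])))
    n_branch = max(0, int(round(_matched(spec.n_branch_points).rvs(1, rng)[0])))
    total_um = _matched(spec.total_length).rvs(1, rng)[0] * 1000.0

    # split bifurcations across dendrites
    alloc = np.bincount(rng.integers(0, n_primary, size=n_branch), minlength=n_primary)

    # grow topologies: each segment is (dendrite, parent_segment or -1)
    seg_parent: list[int] = []
    seg_dendrite: list[int] = []
    children: dict[int, list[int]] = {}
    for d in range(n_primary):
        trunk = len(seg_parent)
        seg_parent.append(-1)
        seg_dendrite.append(d)
        children[trunk] = []
        tips = [trunk]
        for _ in range(alloc[d]):
            s = tips.pop(int(rng.integers(len(tips))))
            for _ in range(2):
                c = len(seg_parent)
                seg_parent.append(s)
                seg_dendrite.append(d)
                children[s].append(c)
                children[c] = []
                tips.append(c)

    n_seg = len(seg_parent)
    raw = _matched(spec.terminal_segment_length).rvs(n_seg, rng)
    lengths = raw * (total_um / raw.sum())

    # geometry: 10 um steps, radial base direction per dendrite, depth-bounded z
    step = 10.0
    ids, types, xs, ys, zs, radii, parents = [1], [1], [0.0], [0.0], [0.0], [5.0], [-1]
    next_id = 2
    z_caps = _matched(spec.z_excursion).rvs(n_primary, rng)
    seg_end_node: dict[int, int] = {}
    seg_end_pos: dict[int, np.ndarray] = {}
    seg_end_dir: dict[int, np.ndarray] = {}
    truth_paths: list[float] = []
    truth_terms: list[float] = []
    path_len: dict[int, float] = {}

    def grow_segment(s: int, plunge: bool = False, z_cap: float = 45.0):
        nonlocal next_id
        parent_seg = seg_parent[s]
        if parent_seg < 0:
            d = seg_dendrite[s]
            ang = 2 * np.pi * d / n_primary + rng.normal(0, 0.2)
            direction = np.array([np.cos(ang), np.sin(ang), 0.0])
            pos = np.zeros(3)
            parent_node = 1
            base_len = 0.0
        else:
            direction = seg_end_dir[parent_seg].copy()
            ang = rng.normal(0, 0.6)
            c, sn = np.cos(ang), np.sin(ang)
            direction = np.array([c * direction[0] - sn * direction[1],
                                  sn * direction[0] + c * direction[1], direction[2]])
            pos = seg_end_pos[parent_seg].copy()
            parent_node = seg_end_node[parent_seg]
            base_len = path_len[parent_seg]
        remaining = lengths[s]
        while remaining > 1e-9:
            hop = min(step, remaining)
            ang = rng.normal(0, 0.15)
            c, sn = np.cos(ang), np.sin(ang)
            direction = np.array([c * direction[0] - sn * direction[1],
                                  sn * direction[0] + c * direction[1], direction[2]])
            xy = direction[:2] / np.linalg.norm(direction[:2])
            if plunge:
                dz = 0.6 * hop
            else:
                dz = float(np.clip(rng.normal(0, 0.1) * hop,
                                   -pos[2], max(0.0, z_cap - pos[2])))
            dxy = math.sqrt(max(hop**2 - dz**2, 1e-12))
            pos = pos + np.array([xy[0] * dxy, xy[1] * dxy, dz])
            ids.append(next_id)
            types.append(3)
            xs.append(float(pos[0])); ys.append(float(pos[1])); zs.append(float(pos[2]))
            radii.append(1.0)
            parents.append(parent_node)
            parent_node = next_id
            next_id += 1
            remaining -= hop
        seg_end_node[s] = parent_node
        seg_end_pos[s] = pos
        seg_end_dir[s] = direction
        path_len[s] = base_len + lengths[s]

    for s in range(n_seg):
        grow_segment(s, z_cap=float(z_caps[seg_dendrite[s]]))
        if not children[s]:
            truth_terms.append(float(lengths[s]))
            truth_paths.append(float(path_len[s]))

    # optional plunging dendrite, pruned by the 50 um slice filter downstream
    n_plunged = 0
    if rng.uniform() < spec.p_plunge:
        n_plunged = 1
        s = len(seg_parent)
        seg_parent.append(-1)
        seg_dendrite.append(0)
        children[s] = []
        lengths = np.append(lengths, spec.plunge_depth / 0.6 + 20.0)
        grow_segment(s, plunge=True)

    morph = Morphology(
        node_id=np.array(ids), node_type=np.array(types),
        x=np.array(xs), y=np.array(ys), z=np.array(zs),
        radius=np.array(radii), parent=np.array(parents),
    )
    truth = {
        "n_primary": n_primary,
        "n_branch_points": n_branch,
        "total_length_mm": total_um / 1000.0,
        "dendritic_paths_um": truth_paths,
        "terminal_segment_lengths_um": truth_terms,
        "n_plunging_dendrites": n_plunged,
    }
    return morph, truth
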