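"""Acquisition-protocol logic: rheobase search, pattern classification,
ramp/F-I analysis and mixed-mode-oscillation detection.

The rheobase search walks 5 s square pulses up a 50 pA grid (100 pA above
0.9 nA) until at least one action potential fires. The firing pattern is read
from the rheobase sweep: delayed cells start seconds after pulse onset with
an accelerating discharge, immediate cells fire from onset at constant rate.
Slow triangular ramps (0.1 nA/s) yield the recruitment/derecruitment
currents, the frequency reached 0.5 s after recruitment, the F-I curve and -
when a linear primary range exists above the sub-primary (MMO) region - its
slope, the gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import ephys
from .errors import AnalysisError, NoSpikeError, ValidationError
from .synthgen import ModelCell, ProtocolSet, Sweep, synthesize_protocol

#: first-spike latency above which a rheobase discharge is delayed (s)
LATENCY_CUTOFF = 0.500
#: fallback latency requiring an accelerating discharge as well (s)
LATENCY_FALLBACK = 0.200
#: minimum oscillation prominence counted as an MMO (mV)
MMO_PROMINENCE = 1.0
#: an ISI "contains MMOs" when it holds at least this many oscillations
MMO_PER_ISI = 2
#: the cell is MMO-positive when that happens in at least this many ISIs
MMO_MIN_ISIS = 2
#: search ceiling for the rheobase grid (nA)
RHEOBASE_CEILING = 5.0


def search_grid(ceiling: float = RHEOBASE_CEILING) -> np.ndarray:
    """The experimental step grid: 50 pA steps to 0.9 nA, 100 pA beyond."""
    fine = np.arange(0.05, 0.9001, 0.05)
    coarse = np.arange(1.0, ceiling + 1e-9, 0.1)
    return np.round(np.concatenate([fine, coarse]), 3)


@dataclass
class MMOResult:
    present: bool
    count: int                       # total oscillations across ISIs
    per_isi: list[int] = field(default_factory=list)
    isi_end_currents: list[float] = field(default_factory=list)  # nA, at ISI end


@dataclass
class FICurve:
    """Per-spike (current, instantaneous frequency) points of a ramp."""

    currents: np.ndarray             # nA at the closing spike of each ISI
    frequencies: np.ndarray          # Hz
    phases: np.ndarray               # "ascending" | "descending"
    boundary_current: float = np.nan  # sub-primary/primary separation (nA)
    gain: float = np.nan             # Hz/nA on the ascending primary range


@dataclass
class RampResult:
    recruitment_current: float       # nA
    derecruitment_current: float     # nA
    f_half_second: float             # Hz
    mmo_present: bool
    ficurve: FICurve


def rheobase_search(
    source: ModelCell | ProtocolSet,
    ceiling: float = RHEOBASE_CEILING,
    mode: str = "template",
    **sweep_params,
) -> tuple[float, Sweep]:
    """Minimal tested current eliciting at least one spike, plus that sweep.

    Accepts either a model cell (sweeps are synthesized on demand, mirroring
    the acquisition loop) or a pre-recorded RHEO_STEPS protocol whose sweeps
    are scanned in order of amplitude.
    """
    if isinstance(source, ProtocolSet):
        if source.descriptor != "RHEO_STEPS":
            raise ValidationError("rheobase_search needs a RHEO_STEPS protocol")
        order = np.argsort([np.max(s.current) for s in source.sweeps])
        for k in order:
            sweep = source.sweeps[k]
            if len(ephys.detect_spikes(sweep)) >= 1:
                return float(np.max(sweep.current)), sweep
        raise NoSpikeError("no sweep of the protocol elicited a spike")

    cell = source
    proto = synthesize_protocol(cell, "RHEO_STEPS", mode=mode,
                                ceiling=ceiling, **sweep_params)
    for sweep in proto.sweeps:
        if len(ephys.detect_spikes(sweep)) >= 1:
            return float(np.max(sweep.current)), sweep
    raise NoSpikeError(f"no spike up to the {ceiling} nA search ceiling")


def classify_pattern(rheobase_sweep: Sweep, spikes: ephys.SpikeTrain | None = None,
                     latency_cutoff: float = LATENCY_CUTOFF,
                     latency_fallback: float = LATENCY_FALLBACK) -> str:
    """Immediate vs delayed firing, judged on the rheobase sweep.

    Delayed iff the first-spike latency exceeds the cutoff, or exceeds the
    fallback latency with a rising instantaneous-frequency trend (Theil-Sen
    slope of f against time > 0, needing at least 3 spikes).
    """
    if spikes is None:
        spikes = ephys.detect_spikes(rheobase_sweep)
    if len(spikes) == 0:
        raise NoSpikeError("cannot classify a sweep without spikes")
    onset = ephys._current_onset_index(rheobase_sweep) * rheobase_sweep.dt
    latency = float(spikes.peak_times[0]) - onset
    if latency > latency_cutoff:
        return "delayed"
    if latency > latency_fallback and len(spikes) >= 3:
        f = spikes.instantaneous_frequencies
        t = spikes.peak_times[1:]
        slope = stats.theilslopes(f, t)[0]
        if slope > 0:
            return "delayed"
    return "immediate"


def detect_mmos(sweep: Sweep, spikes: ephys.SpikeTrain | None = None,
                threshold: float | None = None,
                prominence: float = MMO_PROMINENCE) -> MMOResult:
    """Count subthreshold oscillations inside inter-spike intervals.

    Within each ISI - excluding 10 ms after the preceding spike and 5 ms
    before the next threshold crossing - local maxima with at least the given
    prominence and a peak voltage below the measured spiking threshold are
    counted on a lightly smoothed trace (2.5 ms boxcar; MMOs live around
    50-150 Hz, far below the smoothing corner, while single-sample recording
    noise is suppressed). The cell is flagged MMO-positive when >= 2
    oscillations occur in each of >= 2 ISIs.
    """
    from scipy.signal import find_peaks

    if spikes is None:
        spikes = ephys.detect_spikes(sweep, with_thresholds=True)
    if len(spikes) < 2:
        return MMOResult(False, 0)
    if threshold is None:
        if spikes.threshold_voltages.size == 0:
            spikes = ephys.detect_spikes(sweep, with_thresholds=True)
        threshold = float(np.median(spikes.threshold_voltages))
    width = max(1, int(round(2.5e-3 / sweep.dt)))
    v = np.convolve(sweep.voltage, np.ones(width) / width, mode="same")
    dt = sweep.dt
    per_isi: list[int] = []
    end_currents: list[float] = []
    for k in range(len(spikes) - 1):
        i0 = int(spikes.peak_indices[k]) + int(round(0.010 / dt))
        if spikes.threshold_times.size:
            i1 = int(round(spikes.threshold_times[k + 1] / dt)) - int(round(0.005 / dt))
        else:
            i1 = int(spikes.peak_indices[k + 1]) - int(round(0.005 / dt))
        if i1 - i0 < 3:
            per_isi.append(0)
            end_currents.append(float(sweep.current[int(spikes.peak_indices[k + 1])]))
            continue
        seg = v[i0:i1]
        peaks, props = find_peaks(seg, prominence=prominence)
        n_osc = int(np.sum(seg[peaks] < threshold))
        per_isi.append(n_osc)
        end_currents.append(float(sweep.current[int(spikes.peak_indices[k + 1])]))
    counts = np.asarray(per_isi)
    present = bool(np.sum(counts >= MMO_PER_ISI) >= MMO_MIN_ISIS)
    return MMOResult(present, int(counts.sum()), per_isi, end_currents)


def segment_ranges(ficurve: FICurve, mmo: MMOResult) -> float:
    """Sub-primary/primary boundary current (nA) from the last MMO ISI.

    Returns nan when MMOs are absent everywhere (the whole ascending
    discharge is primary). When MMOs persist into the last ascending ISI,
    there is no primary range: the boundary equals the largest ascending
    current and the caller gets no gain.
    """
    asc = ficurve.phases == "ascending"
    if not np.any(asc):
        return np.nan
    counts = np.asarray(mmo.per_isi, dtype=float)
    ends = np.asarray(mmo.isi_end_currents, dtype=float)
    if counts.size == 0 or not np.any(counts >= MMO_PER_ISI):
        return np.nan
    return float(ends[counts >= MMO_PER_ISI][-1])


def _ramp_apex_index(sweep: Sweep) -> int:
    return int(np.argmax(sweep.current))


def analyze_ramp(ramp: ProtocolSet, threshold: float | None = None) -> RampResult:
    """Recruitment/derecruitment, frequency at +0.5 s, F-I curve and gain.

    Recruitment current is the injected current at the first ascending-phase
    spike, averaged across the (nominally three) trials; derecruitment is the
    current at the last descending-phase spike. ``f_half_second`` is the
    instantaneous frequency of the ISI containing the time 0.5 s after the
    first spike. The gain is the least-squares slope of frequency against
    current over the ascending primary range, absent if no primary range is
    identified.
    """
    if ramp.descriptor != "RAMP":
        raise ValidationError("analyze_ramp needs a RAMP protocol")
    if len(ramp.sweeps) < 3:
        import warnings
        warnings.warn(f"only {len(ramp.sweeps)} ramp trials; proceeding", stacklevel=2)

    recruits, derecruits, f_halves = [], [], []
    fi_currents, fi_freqs, fi_phases = [], [], []
    mmo_counts, mmo_ends = [], []
    any_mmo = []
    got_ascending = False
    for sweep in ramp.sweeps:
        spikes = ephys.detect_spikes(sweep)
        if len(spikes) == 0:
            continue
        apex = _ramp_apex_index(sweep)
        idx = spikes.peak_indices
        ascending = idx <= apex
        if not np.any(ascending):
            continue
        got_ascending = True
        first = int(idx[ascending][0])
        recruits.append(float(sweep.current[first]))
        desc = idx > apex
        if np.any(desc):
            derecruits.append(float(sweep.current[int(idx[desc][-1])]))
        # ISI containing t_first + 0.5 s
        t_half = spikes.peak_times[0] + 0.5
        isis = np.diff(spikes.peak_times)
        pos = int(np.searchsorted(spikes.peak_times, t_half))
        if 1 <= pos <= isis.size:
            f_halves.append(1.0 / isis[pos - 1])
        # F-I points: frequency of each ISI at the current of its closing spike
        f = spikes.instantaneous_frequencies
        closing = idx[1:]
        fi_currents.append(sweep.current[closing])
        fi_freqs.append(f)
        fi_phases.append(np.where(closing <= apex, "ascending", "descending"))
        mmo = detect_mmos(sweep, spikes, threshold=threshold)
        any_mmo.append(mmo.present)
        asc_isi = closing <= apex
        mmo_counts.extend(np.asarray(mmo.per_isi)[asc_isi].tolist())
        mmo_ends.extend(np.asarray(mmo.isi_end_currents)[asc_isi].tolist())

    if not got_ascending:
        raise NoSpikeError("no ascending-phase spikes on any ramp trial")

    fic = FICurve(
        currents=np.concatenate(fi_currents),
        frequencies=np.concatenate(fi_freqs),
        phases=np.concatenate(fi_phases),
    )
    mmo_all = MMOResult(any(any_mmo), int(np.sum(mmo_counts)), mmo_counts, mmo_ends)
    boundary = segment_ranges(fic, mmo_all)
    fic.boundary_current = boundary

    asc = fic.phases == "ascending"
    sel = asc if np.isnan(boundary) else asc & (fic.currents > boundary)
    max_asc = fic.currents[asc].max()
    # a primary range narrower than 0.05 nA is not identifiable as linear
    if (np.any(sel) and (np.isnan(boundary) or boundary < max_asc)
            and sel.sum() >= 3 and np.ptp(fic.currents[sel]) >= 0.05):
        slope, _ = np.polyfit(fic.currents[sel], fic.frequencies[sel], 1)
        fic.gain = float(slope)

    return RampResult(
        recruitment_current=float(np.mean(recruits)),
        derecruitment_current=float(np.mean(derecruits)) if derecruits else np.nan,
        f_half_second=float(np.mean(f_halves)) if f_halves else np.nan,
        mmo_present=bool(any(any_mmo)),
        ficurve=fic,
    )


def measure_cell(cell: ModelCell, *, seed: int | None = None,
                 include: tuple[str, ...] = ("steps", "iv", "single_ap", "ramp"),
                 mode: str = "template") -> ephys.CellFeatures:
    """Run the full protocol battery on a model cell and assemble features."""
    feats = ephys.CellFeatures(cell_id=cell.id, genotype=cell.genotype)
    base_seed = cell.seed if seed is None else seed

    if "steps" in include:
        rheo, sweep = rheobase_search(cell, mode=mode, seed=base_seed)
        feats.rheobase = rheo
        feats.V_rest = ephys.resting_potential(sweep)
        spikes = ephys.detect_spikes(sweep, with_thresholds=True)
        feats.V_threshold = float(spikes.threshold_voltages[0])
        feats.delta_V = feats.V_threshold - feats.V_rest
        feats.pattern = classify_pattern(sweep, spikes)
        feats.mmo_present = detect_mmos(sweep, spikes).present
    if "iv" in include:
        iv = synthesize_protocol(cell, "IV_STEPS", seed=base_seed + 1)
        feats.G_in = ephys.input_conductance(iv)
    if "single_ap" in include:
        aps = synthesize_protocol(cell, "SINGLE_AP", seed=base_seed + 2)
        feats.ap_amplitude, feats.ap_halfwidth = ephys.ap_shape(aps)
        avg, peak = ephys.average_aligned(aps)
        feats.ahp_tau = ephys.fit_ahp(avg, peak)
    if "ramp" in include:
        ramp = synthesize_protocol(cell, "RAMP", seed=base_seed + 3)
        res = analyze_ramp(ramp)
        feats.recruitment_current = res.recruitment_current
        feats.derecruitment_current = res.derecruitment_current
        feats.f_half_second = res.f_half_second
        feats.gain = res.ficurve.gain
        feats.mmo_present = feats.mmo_present or res.mmo_present
    return feats
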