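"""Electrophysiological feature extraction, per-e-type statistics, and
heuristic e-type classification.

The registry implements the features used as optimization constraints:
spike timing/count features on depolarizing steps and resting-potential /
input-resistance features on the hyperpolarizing step.  Undefined features
(e.g. ISI statistics on a trace with fewer than 3 spikes) are flagged
``defined=False`` — never silently zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .simulator import VoltageTrace

__all__ = [
    "SpikeTrain",
    "FeatureValue",
    "FeatureStatistics",
    "FEATURE_NAMES",
    "SPIKE_THRESHOLD",
    "detect_spikes",
    "extract_features",
    "aggregate_statistics",
    "classify_etype",
]

SPIKE_THRESHOLD = -20.0  # mV, upward crossing

FEATURE_NAMES = (
    "spike_count",
    "time_to_first_spike",
    "mean_ISI",
    "ISI_values",
    "adaptation_index",
    "AP_amplitude_mean",
    "AHP_depth_mean",
    "voltage_base",
    "steady_state_voltage",
    "voltage_deflection",
    "input_resistance",
)

# sd floor convention: keeps z-scores finite when experimental sd collapses
SD_FLOOR_REL = 0.05
SD_FLOOR_ABS = 1e-3


@dataclass
class SpikeTrain:
    spike_times: np.ndarray  # ms, strictly increasing
    detection_threshold: float = SPIKE_THRESHOLD

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")
        self.spike_times = t

    @property
    def n(self) -> int:
        return int(self.spike_times.size)


@dataclass
class FeatureValue:
    name: str
    protocol_amplitude: float
    value: float | np.ndarray | None
    defined: bool = True

    def __post_init__(self) -> None:
        if self.defined and self.value is None:
            raise ValueError("defined feature must carry a value")
        if not self.defined:
            self.value = None


@dataclass
class FeatureStatistics:
    """Pooled mean ± sd per (feature, amplitude) with observation counts."""

    stats: dict[tuple[str, float], tuple[float, float, int]] = field(default_factory=dict)

    def mean(self, name: str, amp: float) -> float:
        return self.stats[(name, amp)][0]

    def sd(self, name: str, amp: float) -> float:
        return self.stats[(name, amp)][1]

    def keys(self):
        return self.stats.keys()


def detect_spikes(
    trace: VoltageTrace,
    threshold: float = SPIKE_THRESHOLD,
    rearm_margin: float = 10.0,
) -> SpikeTrain:
    """Upward threshold crossings; one spike per crossing until the voltage
    recrosses downward.

    A Schmitt-trigger re-arm level (``threshold − rearm_margin``) guards
    against double counts when an action potential's axo-somatic shoulder
    dips briefly below threshold mid-spike; genuine inter-spike intervals
    repolarize far below it.
    """
    v = trace.voltage
    above = v > threshold
    idx = np.nonzero(~above[:-1] & above[1:])[0] + 1
    if rearm_margin > 0 and idx.size > 1:
        rearm = threshold - rearm_margin
        kept = [idx[0]]
        for i in idx[1:]:
            if np.min(v[kept[-1]:i]) < rearm:
                kept.append(i)
        idx = np.array(kept)
    return SpikeTrain(trace.time[idx], threshold)


def _spike_windows(trace: VoltageTrace, train: SpikeTrain) -> list[tuple[int, int]]:
    """Index window [crossing, next crossing or end) for each spike."""
    t = trace.time
    idx = np.searchsorted(t, train.spike_times)
    bounds = list(idx) + [t.size]
    return [(bounds[i], bounds[i + 1]) for i in range(len(idx))]


def adaptation_index(isis: np.ndarray) -> float:
    """Mean over consecutive ISI pairs of (ISI_{k+1}-ISI_k)/(ISI_{k+1}+ISI_k);
    positive for accommodating (lengthening) trains."""
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        raise ValueError("adaptation index needs at least 2 ISIs")
    return float(np.mean((isis[1:] - isis[:-1]) / (isis[1:] + isis[:-1])))


def extract_features(
    trace: VoltageTrace,
    feature_list: list[str] | tuple[str, ...] = FEATURE_NAMES,
    threshold: float = SPIKE_THRESHOLD,
) -> list[FeatureValue]:
    unknown = set(feature_list) - set(FEATURE_NAMES)
    if unknown:
        raise KeyError(f"unknown feature name(s): {sorted(unknown)}")

    t, v = trace.time, trace.voltage
    amp = trace.protocol_amplitude
    on, off = trace.stim_start, trace.stim_end
    train = detect_spikes(trace, threshold)
    stim_mask = (train.spike_times >= on) & (train.spike_times <= off)
    spikes = train.spike_times[stim_mask]
    isis = np.diff(spikes)

    base_mask = (t >= on - 50.0) & (t < on)
    v_base = float(np.mean(v[base_mask])) if base_mask.any() else float(v[0])
    ss_mask = (t >= off - 0.1 * (off - on)) & (t <= off)
    v_ss = float(np.mean(v[ss_mask]))

    out: list[FeatureValue] = []
    for name in feature_list:
        if name == "spike_count":
            out.append(FeatureValue(name, amp, float(spikes.size)))
        elif name == "time_to_first_spike":
            if spikes.size:
                out.append(FeatureValue(name, amp, float(spikes[0] - on)))
            else:
                out.append(FeatureValue(name, amp, None, defined=False))
        elif name == "mean_ISI":
            if isis.size >= 2:
                out.append(FeatureValue(name, amp, float(np.mean(isis))))
            else:
                out.append(FeatureValue(name, amp, None, defined=False))
        elif name == "ISI_values":
            if isis.size >= 2:
                out.append(FeatureValue(name, amp, isis.copy()))
            else:
                out.append(FeatureValue(name, amp, None, defined=False))
        elif name == "adaptation_index":
            if isis.size >= 2:
                out.append(FeatureValue(name, amp, adaptation_index(isis)))
            else:
                out.append(FeatureValue(name, amp, None, defined=False))
        elif name == "AP_amplitude_mean":
            if spikes.size:
                amps = []
                windows = _spike_windows(trace, SpikeTrain(spikes, threshold))
                for lo, hi in windows:
                    amps.append(v[lo:hi].max() - v[lo])
                out.append(FeatureValue(name, amp, float(np.mean(amps))))
            else:
                out.append(FeatureValue(name, amp, None, defined=False))
        elif name == "AHP_depth_mean":
            if spikes.size:
                depths = []
                windows = _spike_windows(trace, SpikeTrain(spikes, threshold))
                for lo, hi in windows:
                    depths.append(v[lo] - v[lo:hi].min())
                out.append(FeatureValue(name, amp, float(np.mean(depths))))
            else:
                out.append(FeatureValue(name, amp, None, defined=False))
        elif name == "voltage_base":
            out.append(FeatureValue(name, amp, v_base))
        elif name == "steady_state_voltage":
            out.append(FeatureValue(name, amp, v_ss))
        elif name == "voltage_deflection":
            out.append(FeatureValue(name, amp, v_ss - v_base))
        elif name == "input_resistance":
            if amp < 0:
                out.append(FeatureValue(name, amp, (v_ss - v_base) / amp))  # MΩ
            else:
                out.append(FeatureValue(name, amp, None, defined=False))
    return out


def floored_sd(sd: float, mean: float) -> float:
    return max(sd, SD_FLOOR_REL * abs(mean), SD_FLOOR_ABS)


def aggregate_statistics(
    trace_collections: list[list[VoltageTrace]],
    feature_list: list[str] | tuple[str, ...] | None = None,
    apply_sd_floor: bool = True,
) -> FeatureStatistics:
    """Pool features across cells into per-(feature, amplitude) mean ± sd.

    ``trace_collections`` holds one trace list per cell.  Undefined values are
    excluded from n; a (feature, amplitude) undefined in every trace is
    omitted with a warning.  Sample sd (n−1); the sd floor keeps z-scores
    finite for degenerate pools.
    """
    feature_list = tuple(feature_list or [f for f in FEATURE_NAMES if f != "ISI_values"])
    pooled: dict[tuple[str, float], list[float]] = {}
    seen: set[tuple[str, float]] = set()
    for traces in trace_collections:
        for trace in traces:
            for fv in extract_features(trace, feature_list):
                key = (fv.name, fv.protocol_amplitude)
                seen.add(key)
                if fv.defined and np.isscalar(fv.value):
                    pooled.setdefault(key, []).append(float(fv.value))

    stats = {}
    for key in sorted(seen):
        vals = pooled.get(key, [])
        if not vals:
            warnings.warn(f"feature {key} undefined in every trace; omitted", stacklevel=2)
            continue
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        if apply_sd_floor:
            sd = floored_sd(sd, mean)
        stats[key] = (mean, sd, len(vals))
    return FeatureStatistics(stats)


def classify_etype(
    cell_traces: list[VoltageTrace],
    burst_threshold: float = 0.4,
    adaptation_threshold: float = 0.01,
    threshold: float = SPIKE_THRESHOLD,
) -> str:
    """Classify a cell's step responses as cAC / bAC / cNAC.

    Uses the lowest suprathreshold amplitude with ≥4 spikes — accommodation
    and bursting are assessed near rheobase, where they are most expressed.
    Burst index b = first ISI / mean(later ISIs): b < ``burst_threshold`` →
    bAC (initial doublet/burst).  Otherwise an adaptation index above
    ``adaptation_threshold`` (progressively lengthening ISIs) → cAC, else
    cNAC.  Returns ``"unclassifiable"`` when no trace has ≥4 spikes.
    """
    best: np.ndarray | None = None
    best_amp = np.inf
    for trace in cell_traces:
        if trace.protocol_amplitude <= 0:
            continue
        train = detect_spikes(trace, threshold)
        s = train.spike_times
        s = s[(s >= trace.stim_start) & (s <= trace.stim_end)]
        if s.size >= 4 and trace.protocol_amplitude < best_amp:
            best = s
            best_amp = trace.protocol_amplitude
    if best is None:
        return "unclassifiable"
    isis = np.diff(best)
    b = isis[0] / np.mean(isis[1:])
    if b < burst_threshold:
        return "bAC"
    return "cAC" if adaptation_index(isis) > adaptation_threshold else "cNAC"
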