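"""Muscle-mechanics features from force-time traces.

Extracts the standard intact-preparation readouts: baseline-subtracted
maximum force per stimulation frequency, the force-frequency curve
(1-200 Hz protocol), single-twitch activation (t10-t100) and relaxation
(t100-t10) kinetics with linearly interpolated 10% crossings, and the
elliptical cross-sectional area of the larval trunk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ForceTrace:
    """A force-time series for one stimulation at one frequency."""

    time: np.ndarray          # ms, strictly increasing
    force: np.ndarray         # mN
    stim_frequency: float     # Hz
    sarcomere_length_state: str = "optimal"   # slack | optimal
    fish_id: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force", f)
        if t.size != f.size or t.size < 20:
            raise ValueError("trace needs >= 20 matching samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(f))):
            raise ValueError("trace contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.sarcomere_length_state not in ("slack", "optimal"):
            raise ValueError("sarcomere_length_state must be 'slack' or 'optimal'")


@dataclass(frozen=True)
class TwitchKinetics:
    t_activation: Optional[float]   # ms, 10% force -> peak
    t_relaxation: Optional[float]   # ms, peak -> 10% force
    peak_force: float               # mN above baseline
    baseline: float                 # mN


@dataclass(frozen=True)
class ForceFrequencyCurve:
    frequencies: tuple    # Hz, ascending
    max_forces: tuple     # mN, baseline-subtracted
    state: str


@dataclass(frozen=True)
class CrossSection:
    widths: tuple   # mm x3
    depths: tuple   # mm x3
    csa: float      # mm^2


def _baseline(trace: ForceTrace, pre_fraction: float = 0.1) -> float:
    """Pre-stimulus baseline: median of the first ``pre_fraction`` of samples."""
    n = max(2, int(round(pre_fraction * trace.force.size)))
    return float(np.median(trace.force[:n]))


def max_force(trace: ForceTrace, pre_fraction: float = 0.1) -> float:
    """Baseline-subtracted maximum force of the trace.

    A peak at either trace boundary is logged as possible truncation.
    """
    b = _baseline(trace, pre_fraction)
    i = int(np.argmax(trace.force))
    if i in (0, trace.force.size - 1):
        logger.warning("force peak at trace boundary (t=%.1f ms): possible truncation",
                       trace.time[i])
    return float(trace.force[i] - b)


def force_frequency(traces: Sequence[ForceTrace]) -> ForceFrequencyCurve:
    """Max force by ascending stimulation frequency for one preparation state."""
    if not traces:
        raise ValueError("no traces")
    states = {t.sarcomere_length_state for t in traces}
    if len(states) > 1:
        raise ValueError("traces mix slack and optimal sarcomere-length states")
    freqs = [t.stim_frequency for t in traces]
    if len(set(freqs)) != len(freqs):
        raise ValueError("duplicate stimulation frequency in one state")
    order = np.argsort(freqs)
    return ForceFrequencyCurve(
        frequencies=tuple(float(freqs[i]) for i in order),
        max_forces=tuple(max_force(traces[i]) for i in order),
        state=states.pop())


def _cross_time(t: np.ndarray, f: np.ndarray, i: int, level: float) -> float:
    """Linear-interpolated time where f crosses ``level`` between i and i+1."""
    if f[i + 1] == f[i]:
        return float(t[i])
    return float(t[i] + (level - f[i]) / (f[i + 1] - f[i]) * (t[i + 1] - t[i]))


def twitch_kinetics(trace: ForceTrace, pre_fraction: float = 0.1) -> TwitchKinetics:
    """t10-t100 activation and t100-t10 relaxation times of a single twitch.

    Both 10% thresholds are relative to the baseline-subtracted peak, so the
    result is invariant to baseline offsets and force rescaling.  Undefined
    phases (no 10% crossing on the rise, or no decay to 10% within the
    trace) are returned as None.
    """
    b = _baseline(trace, pre_fraction)
    f = trace.force - b
    t = trace.time
    ipk = int(np.argmax(f))
    peak = float(f[ipk])
    thr = 0.1 * peak
    t_act = None
    if peak > 0:
        for i in range(ipk - 1, -1, -1):
            if f[i] < thr <= f[i + 1]:
                t_act = float(t[ipk] - _cross_time(t, f, i, thr))
                break
            if f[i] >= thr and i == 0:
                break
    t_rel = None
    if peak > 0:
        for i in range(ipk, f.size - 1):
            if f[i] >= thr > f[i + 1]:
                t_rel = float(_cross_time(t, f, i, thr) - t[ipk])
                break
    if t_act is None or t_rel is None:
        logger.warning("twitch kinetics partly undefined (act=%s, rel=%s)", t_act, t_rel)
    return TwitchKinetics(t_activation=t_act, t_relaxation=t_rel,
                          peak_force=peak, baseline=b)


def ellipse_csa(widths: Sequence[float], depths: Sequence[float]) -> CrossSection:
    """Elliptical trunk cross-section from three width and depth measurements.

    csa = pi * (mean width / 2) * (mean depth / 2)
    """
    widths = tuple(float(w) for w in widths)
    depths = tuple(float(d) for d in depths)
    if len(widths) != 3 or len(depths) != 3:
        raise ValueError("need exactly three widths and three depths")
    if min(widths + depths) <= 0:
        raise ValueError("all width/depth measurements must be positive")
    csa = float(np.pi * (np.mean(widths) / 2.0) * (np.mean(depths) / 2.0))
    return CrossSection(widths=widths, depths=depths, csa=csa)


# ---------------------------------------------------------------------------
# I/O

def read_trace_csv(path, stim_frequency: float = 1.0,
                   state: str = "optimal", **labels) -> ForceTrace:
    """Read a trace CSV (time_ms, force_mN)."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    return ForceTrace(time=df["time_ms"].to_numpy(float),
                      force=df["force_mN"].to_numpy(float),
                      stim_frequency=stim_frequency,
                      sarcomere_length_state=state, **labels)


def features_to_frame(traces: Sequence[ForceTrace],
                      csa: Optional[CrossSection] = None):
    """Per-trace feature table: max force, kinetics, optional CSA-normalized force."""
    import pandas as pd

    rows = []
    for tr in traces:
        kin = twitch_kinetics(tr)
        fmax = max_force(tr)
        row = {"fish_id": tr.fish_id, "genotype": tr.genotype,
               "stim_frequency_hz": tr.stim_frequency,
               "state": tr.sarcomere_length_state,
               "max_force_mN": fmax,
               "t_activation_ms": kin.t_activation,
               "t_relaxation_ms": kin.t_relaxation}
        if csa is not None:
            row["csa_mm2"] = csa.csa
            row["specific_force_mN_per_mm2"] = fmax / csa.csa
        rows.append(row)
    return pd.DataFrame(rows)
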