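"""Voltage-clamp trace analysis for microtransplanted synaptic membranes.

Oocytes carrying human synaptic receptors are clamped (default -80 mV) and
perfused with GABA (inhibitory, GABA-A receptors) or kainate (excitatory,
AMPA receptors).  This module extracts agonist-response amplitudes from raw
current traces, applies quality control (signal-to-noise >= 3 and
repeatable responses), and forms the electrophysiological E/I ratio:
kainate/GABA amplitude per oocyte, averaged per subject over at least three
oocytes.

Conventions: inward currents are negative; amplitudes are stored signed and
ratios use magnitudes.  The baseline is taken from the pre-application
segment; a linear trend fitted there is extrapolated under the response so
that slow drift does not bias the peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import median_abs_deviation

__all__ = [
    "CurrentTrace",
    "ResponseMeasure",
    "OocyteRecording",
    "SubjectEI",
    "measure_response",
    "qc_recording",
    "oocyte_ei",
    "subject_ei",
    "potentiation_index",
]


@dataclass(frozen=True)
class CurrentTrace:
    """Uniformly sampled current trace with one agonist-application window."""

    time: np.ndarray       # s
    current: np.ndarray    # nA
    window: tuple[float, float]   # (t_on, t_off) of agonist application
    agonist: str = "GABA"  # "GABA" | "kainate" | "AMPA+CTZ"
    clamp_voltage: float = -80.0  # mV

    def __post_init__(self) -> None:
        if self.time.shape != self.current.shape or self.time.ndim != 1:
            raise ValueError("time and current must be matching 1D arrays")
        dt = np.diff(self.time)
        if dt.size == 0 or dt.min() <= 0:
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")
        t_on, t_off = self.window
        if not t_on < t_off:
            raise ValueError("application window must satisfy t_on < t_off")
        if t_on < self.time[0] or t_off > self.time[-1]:
            raise ValueError("application window outside trace span")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class ResponseMeasure:
    amplitude: float    # nA, signed (inward negative)
    baseline: float     # nA
    noise_sd: float     # nA, robust (MAD-scaled) pre-application noise
    snr: float
    qc_pass: bool
    agonist: str = ""


@dataclass
class OocyteRecording:
    """All agonist applications recorded from one oocyte."""

    oocyte_id: str
    subject_id: str
    traces: list[CurrentTrace] = field(default_factory=list)


@dataclass(frozen=True)
class SubjectEI:
    oocyte_ratios: tuple[float, ...]
    mean_ei: float
    n_oocytes: int


def measure_response(trace: CurrentTrace, deactivation_margin: float = 5.0,
                     min_baseline: float = 0.5,
                     smooth_s: float = 0.1) -> ResponseMeasure:
    """Measure the agonist-response amplitude of one trace.

    Baseline is the median of the pre-application segment (>= 0.5 s
    required).  A linear trend fitted to that segment is subtracted from the
    whole trace; the amplitude is the extremum of the lightly smoothed
    residual within [t_on, t_off + deactivation_margin].  QC passes when the
    signal-to-noise ratio is at least 3 and the response shows activation
    (excursion beyond 3x noise inside the window) and deactivation (decay
    back toward baseline afterwards).
    """
    t, i = trace.time, trace.current
    t_on, t_off = trace.window
    pre = t < t_on
    if pre.sum() < 2 or (t_on - t[0]) < min_baseline:
        raise ValueError("need at least 0.5 s of pre-application baseline")
    baseline = float(np.median(i[pre]))
    slope, intercept = np.polyfit(t[pre], i[pre], 1)
    corrected = i - (slope * t + intercept)
    noise = float(median_abs_deviation(corrected[pre], scale="normal"))

    k = max(1, int(round(smooth_s / trace.dt)))
    smoothed = ndimage.uniform_filter1d(corrected, size=k, mode="nearest")

    win = (t >= t_on) & (t <= t_off + deactivation_margin)
    seg = smoothed[win]
    idx = int(np.argmax(np.abs(seg)))
    amplitude = float(seg[idx])

    if noise > 0:
        snr = abs(amplitude) / noise
    else:
        snr = float("inf") if abs(amplitude) > 0 else 0.0

    during = (t >= t_on) & (t <= t_off)
    activated = bool(np.any(np.abs(smoothed[during]) > 3 * noise)) if noise > 0 \
        else bool(np.any(np.abs(smoothed[during]) > 0))
    tail = smoothed[t > t_off]
    if tail.size:
        tail_level = float(np.abs(tail[-max(1, k):]).mean())
        deactivated = tail_level < max(3 * noise, 0.5 * abs(amplitude))
    else:
        deactivated = False

    qc = bool(snr >= 3 and activated and deactivated)
    return ResponseMeasure(amplitude=amplitude, baseline=baseline,
                           noise_sd=noise, snr=snr, qc_pass=qc,
                           agonist=trace.agonist)


def qc_recording(measures: list[ResponseMeasure], min_snr: float = 3.0,
                 max_cv: float = 0.3) -> bool:
    """QC an oocyte: every response has SNR >= 3 and repeats are consistent.

    Repeat applications of the same agonist must agree within a coefficient
    of variation of ``max_cv`` (population CV on amplitude magnitudes).
    """
    if not measures:
        return False
    if any(m.snr < min_snr for m in measures):
        return False
    by_agonist: dict[str, list[float]] = {}
    for m in measures:
        by_agonist.setdefault(m.agonist, []).append(abs(m.amplitude))
    for amps in by_agonist.values():
        if len(amps) >= 2:
            mean = float(np.mean(amps))
            if mean == 0:
                return False
            cv = float(np.std(amps)) / mean  # population SD
            if cv > max_cv:
                return False
    return True


def oocyte_ei(kainate: ResponseMeasure, gaba: ResponseMeasure) -> float:
    """Per-oocyte electrophysiological E/I: |kainate| / |GABA| amplitude."""
    if not (kainate.qc_pass and gaba.qc_pass):
        raise ValueError("both responses must pass QC to form an E/I ratio")
    if gaba.amplitude == 0:
        raise ValueError("GABA amplitude must be non-zero")
    return abs(kainate.amplitude) / abs(gaba.amplitude)


def subject_ei(ratios: list[float] | np.ndarray) -> SubjectEI:
    """Subject-level E/I: arithmetic mean over >= 3 QC-passing oocytes.

    The subject mean is the experimental unit carried into group statistics.
    """
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) < 3:
        raise ValueError("subject-level E/I requires at least 3 oocytes "
                         "(triplicate rule)")
    return SubjectEI(oocyte_ratios=ratios, mean_ei=float(np.mean(ratios)),
                     n_oocytes=len(ratios))


def potentiation_index(pre: ResponseMeasure, post: ResponseMeasure) -> float:
    """Amplitude ratio post/pre for modulator assays (e.g., concanavalin A)."""
    if pre.amplitude == 0:
        raise ValueError("pre-modulator amplitude must be non-zero")
    return abs(post.amplitude) / abs(pre.amplitude)
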