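"""Trans-mitral inflow-pattern classification.

The mitral inflow during one diastole normally shows two waves: the early
diastolic E wave and the atrial-contraction A wave, separated by diastasis.
As heart rate rises, diastasis shrinks and the two waves first partially
merge (EA-half-separation) and finally collapse into a single lobe
(EA-fusion).  For correlation analyses the trichotomy is coded numerically
as 1 = EA-separation, 2 = EA-half-separation, 3 = EA-fusion.

Qualitative definitions are made operational with two explicit rules:

* **fusion** — the filling trace has a single local maximum;
* **separation** — two maxima whose inter-peak minimum is at most
  ``sep_threshold`` (default 5%) of the smaller peak;
* **half-separation** — everything in between.

Classification is applied to the velocity trace at the mitral-annulus row
(s = 0) of the map, matching where pulse-wave Doppler samples the inflow.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io import VelocityMap

DEFAULT_MIN_PROMINENCE = 0.10
DEFAULT_SEP_THRESHOLD = 0.05


class PatternLabel(enum.Enum):
    """Inflow-morphology trichotomy with its numeric coding."""

    EA_SEPARATION = 1
    EA_HALF_SEPARATION = 2
    EA_FUSION = 3

    @property
    def code(self) -> int:
        return self.value

    @classmethod
    def from_code(cls, code: int) -> "PatternLabel":
        return cls(int(code))


@dataclass
class WaveFeatures:
    """Detected filling-wave peaks and the valley between them.

    ``peak_times`` (ms) and ``peak_velocities`` (m/s) list the retained
    maxima in time order (E first, then A when both are present).
    ``inter_peak_min`` is defined only when two peaks were found.
    """

    peak_times: np.ndarray
    peak_velocities: np.ndarray
    inter_peak_min: float | None
    e_peak: float
    a_peak: float | None
    diastasis_estimate: float | None  # ms; time the trace spends near zero between E and A


def extract_wave_features(
    trace: np.ndarray,
    dt: float = 1.0,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
) -> WaveFeatures:
    """Detect E/A peaks in one diastolic velocity trace.

    Local maxima below ``min_prominence`` of the global filling peak are
    discarded; if more than two remain, the two tallest are kept (ordered
    in time).  When two peaks remain, the earlier is E and the later is A,
    and the minimum of the trace between them is reported together with a
    diastasis estimate (time spent below the separation threshold).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1 or len(trace) < 3:
        raise ValueError("trace must be a 1-D series with >= 3 samples")
    vmax = float(np.max(trace))
    if vmax <= 0:
        raise ValueError("no filling wave: trace has no positive velocity")
    floor = min_prominence * vmax
    idx, _ = find_peaks(trace, height=floor)
    if len(idx) == 0:
        # a wave clipped at the window edge has no interior local maximum
        k = int(np.argmax(trace))
        if trace[k] >= floor:
            idx = np.array([k])
        else:
            raise ValueError("no filling wave: no peak above prominence floor")
    if len(idx) > 2:
        keep = np.sort(idx[np.argsort(trace[idx])[-2:]])
        idx = keep
    times = idx * dt
    vels = trace[idx]
    if len(idx) == 2:
        lo, hi = idx
        valley = float(np.min(trace[lo : hi + 1]))
        smaller = float(min(vels))
        below = trace[lo : hi + 1] <= DEFAULT_SEP_THRESHOLD * smaller
        diastasis = float(np.count_nonzero(below)) * dt
        return WaveFeatures(
            peak_times=times,
            peak_velocities=vels,
            inter_peak_min=valley,
            e_peak=float(vels[0]),
            a_peak=float(vels[1]),
            diastasis_estimate=diastasis,
        )
    return WaveFeatures(
        peak_times=times,
        peak_velocities=vels,
        inter_peak_min=None,
        e_peak=float(vels[0]),
        a_peak=None,
        diastasis_estimate=None,
    )


def classify_pattern(
    features: WaveFeatures,
    sep_threshold: float = DEFAULT_SEP_THRESHOLD,
) -> PatternLabel:
    """Apply the two-threshold rule to detected wave features."""
    if features.a_peak is None:
        return PatternLabel.EA_FUSION
    assert features.inter_peak_min is not None
    smaller = min(features.e_peak, features.a_peak)
    if features.inter_peak_min <= sep_threshold * smaller:
        return PatternLabel.EA_SEPARATION
    return PatternLabel.EA_HALF_SEPARATION


def classify_trace(
    trace: np.ndarray,
    dt: float = 1.0,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    sep_threshold: float = DEFAULT_SEP_THRESHOLD,
) -> PatternLabel:
    """Feature extraction + classification for one diastolic trace."""
    return classify_pattern(
        extract_wave_features(trace, dt=dt, min_prominence=min_prominence),
        sep_threshold=sep_threshold,
    )


def classify_map(
    vmap: VelocityMap,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    sep_threshold: float = DEFAULT_SEP_THRESHOLD,
) -> PatternLabel:
    """Per-animal label from the mitral-annulus trace of a velocity map.

    Each complete cycle is classified independently; the modal label wins,
    with ties broken toward the higher (more merged) code.
    """
    base = vmap.base_trace()
    starts = [c for c in vmap.cycle_starts if c < vmap.n_time]
    if len(starts) >= 2:
        windows = list(zip(starts[:-1], starts[1:]))
    else:
        windows = [(0, vmap.n_time)]
    labels = [
        classify_trace(
            base[c0:c1], dt=vmap.dt,
            min_prominence=min_prominence, sep_threshold=sep_threshold,
        )
        for c0, c1 in windows
    ]
    counts = Counter(labels)
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0].code))
    return best[0]
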