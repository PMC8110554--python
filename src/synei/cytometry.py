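"""Flow-cytometry-style size gating of synaptosome-like particles.

Events are diameter-calibrated particles from P2 fractions.  The analysis
gate keeps particles of 1-3 µm (synaptosome-sized, boundaries inclusive);
gated events are classified as small (below the 2 µm calibration bin),
medium (within a half-width ``delta`` of 2 µm) or large (above it), and the
large/small proportion ratio summarizes the size distribution per subject.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "gate_by_size",
    "classify_sizes",
    "large_small_ratio",
    "percent_reduction",
]


def gate_by_size(events: pd.DataFrame, lo: float = 1.0, hi: float = 3.0,
                 cap: int | None = None,
                 diameter_col: str = "diameter") -> pd.DataFrame:
    """Retain events with lo <= diameter <= hi; optionally cap at ``cap``.

    The cap mirrors analyzing a fixed number of in-gate events (first
    ``cap`` events in acquisition order).
    """
    d = events[diameter_col]
    if (d <= 0).any():
        raise ValueError("diameters must be positive")
    gated = events[(d >= lo) & (d <= hi)]
    if cap is not None:
        gated = gated.head(cap)
    return gated


def classify_sizes(gated: pd.DataFrame, delta: float = 0.1,
                   diameter_col: str = "diameter") -> dict[str, float]:
    """Proportions (%) of gated events in small/medium/large size classes.

    medium is a calibration-bead bin of half-width ``delta`` around 2 µm;
    small is everything in the gate below it, large everything above.  The
    three classes partition the gate, so proportions sum to 100% whenever
    any events are gated.
    """
    d = gated[diameter_col].to_numpy(dtype=float)
    n = d.size
    if n == 0:
        return {"small": float("nan"), "medium": float("nan"),
                "large": float("nan"), "n": 0}
    medium = np.abs(d - 2.0) <= delta
    small = (~medium) & (d < 2.0)
    large = (~medium) & (d > 2.0)
    return {
        "small": float(small.sum()) / n * 100.0,
        "medium": float(medium.sum()) / n * 100.0,
        "large": float(large.sum()) / n * 100.0,
        "n": int(n),
    }


def large_small_ratio(proportions: dict[str, float]) -> float:
    """Large-to-small class ratio; inf/nan-flagged when small is empty."""
    small, large = proportions["small"], proportions["large"]
    if small == 0:
        return float("inf") if large > 0 else float("nan")
    return large / small


def percent_reduction(control_mean: float, group_mean: float) -> float:
    """Percent reduction of a group mean relative to the control mean."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (control_mean - group_mean) / control_mean
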