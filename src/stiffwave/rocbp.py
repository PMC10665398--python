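"""Rate of change in systolic blood pressure (ROC_BP) around skin incision.

The pre-incision sBP is the median of the 10 heartbeats immediately before
the incision; the post-incision sBP is the maximum beat sBP within a
window after the incision (default 120 s).  ROC_BP is reported as the
percent change (post/pre - 1) * 100; the raw ratio is also kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_POST_WINDOW_S = 120.0
N_PRE_BEATS = 10


@dataclass
class RocBpResult:
    pre_sbp_mmhg: float
    post_sbp_mmhg: float
    rocbp_pct: float

    @property
    def ratio(self) -> float:
        """Raw post/pre sBP ratio."""
        return self.post_sbp_mmhg / self.pre_sbp_mmhg


def compute_rocbp(
    beat_time_s: np.ndarray,
    sbp_mmhg: np.ndarray,
    incision_time_s: float,
    post_window_s: float = DEFAULT_POST_WINDOW_S,
    n_pre_beats: int = N_PRE_BEATS,
) -> RocBpResult:
    """Percent sBP change from the pre-incision median to the post maximum.

    Requires at least ``n_pre_beats`` beats strictly before the incision
    (the median is over the last such beats) and at least one beat in
    (incision, incision + post_window].
    """
    t = np.asarray(beat_time_s, dtype=float)
    sbp = np.asarray(sbp_mmhg, dtype=float)
    if t.size != sbp.size:
        raise ValueError("beat time and sBP arrays must have equal length")
    pre_idx = np.flatnonzero(t < incision_time_s)
    if pre_idx.size < n_pre_beats:
        raise ValueError(
            f"need >= {n_pre_beats} beats before the incision, "
            f"got {pre_idx.size}")
    pre = float(np.median(sbp[pre_idx[-n_pre_beats:]]))
    if pre <= 0:
        raise ValueError("pre-incision sBP must be positive")
    post_mask = (t > incision_time_s) & (t <= incision_time_s + post_window_s)
    if not post_mask.any():
        raise ValueError("empty post-incision window")
    post = float(np.max(sbp[post_mask]))
    return RocBpResult(pre, post, (post / pre - 1.0) * 100.0)
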