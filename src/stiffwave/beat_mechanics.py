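"""Per-beat vascular stiffness and viscosity estimation.

The arterial wall is modeled as a spring-damper (mechanical impedance)
system driven by transmural pressure and observed through vessel-wall
displacement.  Arterial pressure Pb(t) plays the role of force and the
photoplethysmogram (PPG) amplitude Pl(t), expressed in percent of full
scale, the role of displacement.  Within one heartbeat, with t0 the beat
onset ("the starting time of the change"), the model is

    dPb(t) = K * dPl(t) + B * dPl_dot(t)

where dX(t) = X(t) - X(t0) and Pl_dot is the first time derivative of the
PPG amplitude.  K (mmHg/%) is the vascular stiffness and B (mmHg*s/%) the
vascular viscosity.  One (K, B) pair is estimated per heartbeat by least
squares; beats with a coefficient of determination below 0.95 or a
negative K or B are excluded from analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Default coefficient-of-determination cutoff for accepting a beat.
DEFAULT_R2_MIN = 0.95


@dataclass
class WaveformRecord:
    """Time-aligned arterial pressure / PPG samples with beat onsets.

    Attributes
    ----------
    time_s : strictly increasing sample times, seconds.
    abp_mmhg : arterial blood pressure Pb(t) per sample.
    ppg_pct : PPG amplitude Pl(t) per sample, percent of full scale.
    sample_rate_hz : nominal sampling rate.
    beat_onsets : strictly increasing sample indices, one per beat onset t0.
    k_true, b_true : optional generator ground truth (synthetic data only).
    """

    time_s: np.ndarray
    abp_mmhg: np.ndarray
    ppg_pct: np.ndarray
    sample_rate_hz: float
    beat_onsets: np.ndarray
    k_true: float | None = None
    b_true: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.abp_mmhg = np.asarray(self.abp_mmhg, dtype=float)
        self.ppg_pct = np.asarray(self.ppg_pct, dtype=float)
        self.beat_onsets = np.asarray(self.beat_onsets, dtype=int)
        n = self.time_s.size
        if not (self.abp_mmhg.size == n and self.ppg_pct.size == n):
            raise ValueError("time, ABP and PPG arrays must have equal length")
        if n >= 2 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("sample times must be strictly increasing")
        if self.beat_onsets.size:
            if np.any((self.beat_onsets < 0) | (self.beat_onsets >= n)):
                raise ValueError("beat onsets out of array bounds")
            if np.any(np.diff(self.beat_onsets) <= 0):
                raise ValueError("beat onsets must be strictly increasing")


@dataclass
class BeatSegment:
    """One heartbeat's difference series relative to its own onset sample."""

    t0_index: int
    t0_s: float
    dPb: np.ndarray   # Pb(t) - Pb(t0), mmHg
    dPl: np.ndarray   # Pl(t) - Pl(t0), %
    dPl_dot: np.ndarray  # Pl_dot(t) - Pl_dot(t0), %/s


@dataclass
class BeatEstimate:
    """Per-beat stiffness/viscosity estimate with validity flag."""

    beat_time_s: float
    k: float
    b: float
    r_squared: float
    valid: bool
    reason: str | None = None


@dataclass
class KSeries:
    """Per-beat K time series of valid beats only."""

    beat_time_s: np.ndarray
    k: np.ndarray
    exclusion_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beat_time_s = np.asarray(self.beat_time_s, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.beat_time_s.size != self.k.size:
            raise ValueError("time and K arrays must have equal length")
        if self.beat_time_s.size >= 2 and not np.all(np.diff(self.beat_time_s) > 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.k.size)


def differentiate_ppg(ppg_pct: np.ndarray, sample_rate_hz: float) -> np.ndarray:
    """First time derivative of the PPG amplitude, %/s.

    Central finite differences at interior samples, one-sided at the two
    edges (``numpy.gradient`` convention, second-order accurate inside).
    """
    ppg_pct = np.asarray(ppg_pct, dtype=float)
    if ppg_pct.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if not np.all(np.isfinite(ppg_pct)):
        raise ValueError("non-finite PPG samples")
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    return np.gradient(ppg_pct, 1.0 / sample_rate_hz)


def segment_beats(waveform: WaveformRecord) -> list[BeatSegment]:
    """Split a waveform record into per-beat difference segments.

    Each segment covers the half-open interval [onset_i, onset_{i+1}) and
    its difference series are taken against the segment's own onset sample,
    so dPb, dPl and dPl_dot are exactly zero at the first sample.  Segments
    with fewer than 3 samples are skipped with a logged warning.
    """
    onsets = waveform.beat_onsets
    if onsets.size < 2:
        logger.warning("fewer than 2 beat onsets: no segments produced")
        return []
    pl_dot = differentiate_ppg(waveform.ppg_pct, waveform.sample_rate_hz)
    segments: list[BeatSegment] = []
    for i0, i1 in zip(onsets[:-1], onsets[1:]):
        if i1 - i0 < 3:
            logger.warning("segment at sample %d has <3 samples; skipped", i0)
            continue
        sl = slice(i0, i1)
        segments.append(
            BeatSegment(
                t0_index=int(i0),
                t0_s=float(waveform.time_s[i0]),
                dPb=waveform.abp_mmhg[sl] - waveform.abp_mmhg[i0],
                dPl=waveform.ppg_pct[sl] - waveform.ppg_pct[i0],
                dPl_dot=pl_dot[sl] - pl_dot[i0],
            )
        )
    return segments


def fit_beat(segment: BeatSegment, r2_min: float = DEFAULT_R2_MIN) -> BeatEstimate:
    """Least-squares fit of the spring-damper model for one beat.

    (k, b) minimize sum(dPb - k*dPl - b*dPl_dot)^2 with no intercept: all
    three difference series vanish at t0 by construction, so the model
    passes through the origin.  R^2 = 1 - SSR/SST with SST taken about the
    mean of dPb.  A rank-deficient design (dPl and dPl_dot collinear or
    all zero) or an SST of zero yields an invalid estimate with a reason.
    """
    X = np.column_stack([segment.dPl, segment.dPl_dot])
    y = segment.dPb
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    k, b = float(coef[0]), float(coef[1])
    if rank < 2:
        return BeatEstimate(segment.t0_s, k, b, float("nan"), False,
                            reason="rank_deficient")
    ssr = float(np.sum((y - X @ coef) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return BeatEstimate(segment.t0_s, k, b, float("nan"), False,
                            reason="zero_variance")
    r2 = 1.0 - ssr / sst
    valid, reason = True, None
    if r2 < r2_min:
        valid, reason = False, "low_r_squared"
    elif k < 0 or b < 0:
        valid, reason = False, "negative_coefficient"
    return BeatEstimate(segment.t0_s, k, b, r2, valid, reason=reason)


def filter_estimates(
    estimates: list[BeatEstimate],
    r2_min: float = DEFAULT_R2_MIN,
    exclude_rule: str = "either",
) -> KSeries:
    """Apply the exclusion filters and assemble the valid-beat K series.

    Retains beats with R^2 >= ``r2_min`` and non-negative coefficients,
    preserving order; exclusion counts by reason are recorded on the
    result.  ``exclude_rule`` selects how the negative-coefficient rule is
    read: ``"either"`` (default) drops a beat if K or B is negative,
    ``"both"`` only if both are.
    """
    if exclude_rule not in ("either", "both"):
        raise ValueError("exclude_rule must be 'either' or 'both'")
    times, ks = [], []
    counts: dict[str, int] = {}

    def _excl(reason: str) -> None:
        counts[reason] = counts.get(reason, 0) + 1

    for est in estimates:
        if not np.isfinite(est.r_squared):
            _excl(est.reason or "degenerate")
            continue
        if est.r_squared < r2_min:
            _excl("low_r_squared")
            continue
        neg = (est.k < 0 or est.b < 0) if exclude_rule == "either" \
            else (est.k < 0 and est.b < 0)
        if neg:
            _excl("negative_coefficient")
            continue
        times.append(est.beat_time_s)
        ks.append(est.k)
    return KSeries(np.array(times), np.array(ks), exclusion_counts=counts)


def estimate_k_series(
    waveform: WaveformRecord,
    r2_min: float = DEFAULT_R2_MIN,
    exclude_rule: str = "either",
) -> tuple[KSeries, list[BeatEstimate]]:
    """Segment, fit and filter in one call; returns the K series and all
    per-beat estimates (including excluded ones)."""
    estimates = [fit_beat(seg, r2_min=r2_min) for seg in segment_beats(waveform)]
    return filter_estimates(estimates, r2_min=r2_min, exclude_rule=exclude_rule), estimates
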