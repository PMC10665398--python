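"""MEC_K detection: the minimum evoked current of the vascular stiffness value.

A session delivers a ladder of tetanic stimuli (50 Hz, 5 s; 10 mA up to
80 mA in 10-mA steps) while per-beat vascular stiffness K is monitored.
For each stimulus the pre-stimulus K is the median over the 10 s before
onset and the post-stimulus K is the maximum over the 20 s after the
stimulus; a stimulus "responds" when K rises by at least 5% of the
pre-stimulus value.  MEC_K is the lowest intensity from which every
subsequent stimulus also responds; an isolated sub-threshold response
followed by a non-response is rejected as noise, and a session whose
80-mA stimulus fails the 5% criterion is classified out of range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beat_mechanics import KSeries

#: Sentinel for sessions with no >=5% K rise even at the top intensity.
OUT_OF_RANGE = "OOR"

DEFAULT_THRESHOLD = 0.05
DEFAULT_PRE_WINDOW_S = 10.0
DEFAULT_POST_WINDOW_S = 20.0


@dataclass
class StimulusEvent:
    onset_s: float
    intensity_ma: int
    duration_s: float = 5.0
    frequency_hz: float = 50.0  # metadata only

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class StimulusResponse:
    """Pre/post K summary for one stimulus."""

    intensity_ma: int
    pre_k: float
    post_k: float
    rise: float          # (post_k / pre_k) - 1
    responded: bool      # rise >= threshold


@dataclass
class MecResult:
    meck_ma: int | str   # intensity in mA, or OUT_OF_RANGE
    responses: list[StimulusResponse] = field(default_factory=list)
    rejected_as_noise: list[int] = field(default_factory=list)

    @property
    def out_of_range(self) -> bool:
        return self.meck_ma == OUT_OF_RANGE


def evaluate_stimulus(
    kseries: KSeries,
    event: StimulusEvent,
    pre_window_s: float = DEFAULT_PRE_WINDOW_S,
    post_window_s: float = DEFAULT_POST_WINDOW_S,
    threshold: float = DEFAULT_THRESHOLD,
    anchor: str = "offset",
) -> StimulusResponse:
    """Summarize the K response to one stimulus.

    pre_k is the median K over [onset - pre_window, onset) and post_k the
    maximum K over (ref, ref + post_window], where ref is the stimulus
    offset (end of the train, default) or its onset (``anchor="onset"``).
    Windows are closed on the side away from the stimulus and open at the
    stimulus boundary.
    """
    if anchor not in ("offset", "onset"):
        raise ValueError("anchor must be 'offset' or 'onset'")
    t = kseries.beat_time_s
    pre_mask = (t >= event.onset_s - pre_window_s) & (t < event.onset_s)
    if not pre_mask.any():
        raise ValueError(
            f"empty pre-stimulus window for stimulus at {event.onset_s} s")
    ref = event.offset_s if anchor == "offset" else event.onset_s
    post_mask = (t > ref) & (t <= ref + post_window_s)
    if not post_mask.any():
        raise ValueError(
            f"empty post-stimulus window for stimulus at {event.onset_s} s")
    pre_k = float(np.median(kseries.k[pre_mask]))
    post_k = float(np.max(kseries.k[post_mask]))
    rise = post_k / pre_k - 1.0
    return StimulusResponse(
        intensity_ma=event.intensity_ma,
        pre_k=pre_k,
        post_k=post_k,
        rise=rise,
        responded=rise >= threshold,
    )


def _check_ladder(responses: list[StimulusResponse]) -> None:
    intensities = [r.intensity_ma for r in responses]
    if not responses:
        raise ValueError("no stimulus responses")
    expected = list(range(10, 10 * len(responses) + 10, 10))
    if intensities != expected:
        raise ValueError(
            f"stimulus ladder must be 10 mA steps from 10 mA without gaps; "
            f"got {intensities}")


def detect_meck(responses: list[StimulusResponse], rule: str = "suffix") -> MecResult:
    """Determine MEC_K from an ordered ladder of stimulus responses.

    ``rule="suffix"`` (default): MEC_K is the smallest intensity i such
    that every tested intensity >= i responded; any responded intensity
    below it is rejected as noise.  This unifies the pairwise
    noise-rejection sentence with the out-of-range rule under the premise
    that a genuine response is monotone in intensity.

    ``rule="pairwise"``: the literal local reading — a responded intensity
    whose immediate successor did not respond is rejected as noise, and
    MEC_K is the lowest surviving responded intensity.

    Under both rules a non-responding top intensity classifies the session
    as OUT_OF_RANGE.
    """
    if rule not in ("suffix", "pairwise"):
        raise ValueError("rule must be 'suffix' or 'pairwise'")
    _check_ladder(responses)
    responded = [r.responded for r in responses]
    intensities = [r.intensity_ma for r in responses]

    if not responded[-1]:
        rejected = [i for i, resp in zip(intensities, responded) if resp]
        return MecResult(OUT_OF_RANGE, responses, rejected)

    if rule == "suffix":
        start = len(responded)
        while start > 0 and responded[start - 1]:
            start -= 1
        meck = intensities[start]
        rejected = [i for i, resp
                    in zip(intensities[:start], responded[:start]) if resp]
    else:
        meck = None
        rejected = []
        for j, (i, resp) in enumerate(zip(intensities, responded)):
            if not resp:
                continue
            if j + 1 < len(responded) and not responded[j + 1]:
                rejected.append(i)
            elif meck is None:
                meck = i
        assert meck is not None  # last intensity responded, so one survives
    return MecResult(meck, responses, rejected)


def detect_meck_from_series(
    kseries: KSeries,
    events: list[StimulusEvent],
    pre_window_s: float = DEFAULT_PRE_WINDOW_S,
    post_window_s: float = DEFAULT_POST_WINDOW_S,
    threshold: float = DEFAULT_THRESHOLD,
    rule: str = "suffix",
    anchor: str = "offset",
) -> MecResult:
    """Evaluate every stimulus of a session and run MEC_K detection."""
    responses = [
        evaluate_stimulus(kseries, ev, pre_window_s=pre_window_s,
                          post_window_s=post_window_s, threshold=threshold,
                          anchor=anchor)
        for ev in sorted(events, key=lambda e: e.onset_s)
    ]
    return detect_meck(responses, rule=rule)
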