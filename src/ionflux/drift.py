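"""Drift-corrected voltage differences via the paired-regression procedure.

A single ion-selective electrode drifts slowly, so the raw voltage at one
position is meaningless on its own.  Moving the electrode between two
positions and comparing three consecutive loops cancels any drift that is
linear over the ~30 s window: an ordinary least-squares line is fitted
jointly through the first and third loops (same position), a second line
with the *same slope* is fitted through the middle loop (other position),
and the voltage difference dV = V(position 0) - V(position 1) is the
vertical distance between the two parallel lines.  Only samples after the
start-fit time of each loop enter the fits, allowing the electrode's
exponential response to settle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EstimateError
from .segmentation import PositionSegment

logger = logging.getLogger("ionflux")


@dataclass(frozen=True)
class DvEstimate:
    """One drift-corrected voltage difference, centred on one loop.

    Sign convention: dV = V(position 0) - V(position 1).  ``V0``/``V1`` are
    the two parallel regression lines evaluated at the middle loop's midpoint
    time; ``slope`` is their shared drift slope in mV/s.
    """

    center_segment_index: int
    time_s: float
    dV: float  # mV
    V0: float  # mV
    V1: float  # mV
    slope: float  # mV / s
    n_points_used: int
    channel: str = "ise1_mV"


def _fit_window(seg: PositionSegment, start_fit: float, channel: str):
    sl = seg.samples[seg.samples["local_time_s"] >= start_fit]
    if len(sl) == 0:
        raise EstimateError(
            f"segment {seg.index}: no samples at local time >= {start_fit} s"
        )
    return sl["time_s"].to_numpy(), sl[channel].to_numpy()


def segment_voltage(
    seg: PositionSegment, start_fit: float, channel: str = "ise1_mV"
) -> float:
    """Mean channel voltage (mV) over samples with local time >= start_fit."""
    _, v = _fit_window(seg, start_fit, channel)
    return float(np.mean(v))


def dv_triple(
    prev: PositionSegment,
    mid: PositionSegment,
    next: PositionSegment,
    start_fit: float,
    channel: str = "ise1_mV",
) -> DvEstimate:
    """Drift-corrected dV from three consecutive loops.

    ``prev`` and ``next`` must share a position that differs from ``mid``'s,
    and none of the three may be truncated or span a reposition event.
    Raises :class:`EstimateError` when the triple is unusable.
    """
    if prev.position_index != next.position_index:
        raise EstimateError(
            f"segments {prev.index}/{next.index}: outer positions differ"
        )
    if mid.position_index == prev.position_index:
        raise EstimateError(
            f"segment {mid.index}: middle position equals outer position"
        )
    for seg in (prev, mid, next):
        if seg.truncated:
            raise EstimateError(f"segment {seg.index} is truncated")
        if seg.spans_reposition:
            raise EstimateError(f"segment {seg.index} spans a reposition event")

    t_prev, v_prev = _fit_window(prev, start_fit, channel)
    t_mid, v_mid = _fit_window(mid, start_fit, channel)
    t_next, v_next = _fit_window(next, start_fit, channel)
    t_out = np.concatenate([t_prev, t_next])
    v_out = np.concatenate([v_prev, v_next])
    if len(t_out) < 2 or len(t_mid) < 2:
        raise EstimateError("need >= 2 points per fitted line")

    # OLS through the pooled outer loops, parameterised about the middle
    # loop's midpoint time for conditioning (t is large in absolute seconds)
    t_ref = mid.midpoint_time
    tc = t_out - np.mean(t_out)
    b = float(np.dot(tc, v_out - np.mean(v_out)) / np.dot(tc, tc))
    alpha_outer = float(np.mean(v_out) + b * (t_ref - np.mean(t_out)))
    # middle line constrained to the same slope
    alpha_mid = float(np.mean(v_mid - b * (t_mid - t_ref)))

    offset = alpha_outer - alpha_mid
    dV = offset if mid.position_index == 1 else -offset
    if mid.position_index == 1:
        V0, V1 = alpha_outer, alpha_mid
    else:
        V0, V1 = alpha_mid, alpha_outer
    if not np.isfinite(dV):
        raise EstimateError("non-finite dV estimate")
    return DvEstimate(
        center_segment_index=mid.index,
        time_s=t_ref,
        dV=dV,
        V0=V0,
        V1=V1,
        slope=b,
        n_points_used=len(t_out) + len(t_mid),
        channel=channel,
    )


def dv_series(
    segments: list[PositionSegment],
    start_fit: float,
    channel: str = "ise1_mV",
) -> list[DvEstimate]:
    """Sliding-window dV estimates, one per interior usable segment.

    Unusable triples (wrong position pattern, truncated, spanning a
    reposition) are skipped with a logged reason; the first and last
    segments never yield an estimate.
    """
    if len(segments) < 3:
        logger.warning("fewer than 3 segments: no dV estimates possible")
        return []
    estimates = []
    for i in range(1, len(segments) - 1):
        try:
            estimates.append(
                dv_triple(segments[i - 1], segments[i], segments[i + 1],
                          start_fit, channel)
            )
        except EstimateError as exc:
            logger.warning("skipping triple centred on segment %d: %s", i, exc)
    return estimates
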