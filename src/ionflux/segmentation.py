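"""Splitting a recording into position loops.

Segmentation is driven by the recorded position channel rather than nominal
loop arithmetic, so it tolerates the timing jitter of acquisition hardware
(loops slightly longer than their nominal duration).  Samples strictly
between the two plateau levels (possible after resampling) are assigned to
the following segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .errors import SegmentationError
from .io import Recording

#: A sample counts as "at" a level when within this fraction of scan_distance.
LEVEL_TOLERANCE = 0.10


@dataclass
class PositionSegment:
    """One position loop: samples plus segment-local time and flags."""

    index: int
    position_index: int  # 0 (near tissue) or 1 (scan_distance away)
    samples: pd.DataFrame  # time_s, local_time_s, <voltage channels>
    truncated: bool = False
    spans_reposition: bool = False

    @property
    def midpoint_time(self) -> float:
        t = self.samples["time_s"].to_numpy()
        return float((t[0] + t[-1]) / 2.0)


def _is_reposition_event(text: str) -> bool:
    return "reposition" in text.lower()


def segment(rec: Recording, acq: AcquisitionConfig) -> list[PositionSegment]:
    """Partition ``rec`` into position loops.

    The position column must show exactly two plateau levels (0 and
    scan_distance, tolerance +-10% of scan_distance).  A final segment
    shorter than the loop duration is flagged ``truncated`` (and excluded
    from dV analysis downstream); segments overlapping a reposition event
    mark are flagged ``spans_reposition``.
    """
    pos = rec.samples["position_um"].to_numpy()
    d_um = acq.scan_distance * 1e6
    tol = LEVEL_TOLERANCE * d_um
    near0 = np.abs(pos) <= tol
    near1 = np.abs(pos - d_um) <= tol
    intermediate = ~(near0 | near1)
    if np.any(intermediate):
        # isolated transition samples are tolerated; a plateau is not
        run = 0
        for flag in intermediate:
            run = run + 1 if flag else 0
            if run >= 3:
                raise SegmentationError(
                    "position channel shows more than two plateau levels "
                    f"(expected 0 and {d_um:g} um within +-{tol:g} um)"
                )
    level = np.where(near1, 1, 0)
    if np.any(intermediate):  # assign transition samples to the following segment
        idx = np.arange(len(pos))
        determined = ~intermediate
        # for each intermediate sample, take the next determined level
        nxt = np.full(len(pos), -1)
        last = level[determined][-1]
        for i in range(len(pos) - 1, -1, -1):
            if determined[i]:
                last = level[i]
            nxt[i] = last
        level = nxt

    # runs of constant level, chunked into loop-sized segments
    boundaries = np.flatnonzero(np.diff(level) != 0) + 1
    run_starts = np.concatenate(([0], boundaries))
    run_ends = np.concatenate((boundaries, [len(pos)]))
    n_loop = acq.n_samples_per_loop

    segments: list[PositionSegment] = []
    for start, end in zip(run_starts, run_ends):
        length = end - start
        is_final_run = end == len(pos)
        if length < n_loop // 2 and not is_final_run:
            raise SegmentationError(
                "position oscillates faster than half a loop duration "
                f"(run of {length} samples at sample {start})"
            )
        for chunk_start in range(start, end, n_loop):
            chunk_end = min(chunk_start + n_loop, end)
            sl = rec.samples.iloc[chunk_start:chunk_end]
            t = sl["time_s"].to_numpy()
            df = pd.DataFrame({"time_s": t, "local_time_s": t - t[0]})
            for ch in rec.channels:
                df[ch] = sl[ch].to_numpy()
            seg = PositionSegment(
                index=len(segments),
                position_index=int(level[chunk_start]),
                samples=df,
                truncated=(chunk_end - chunk_start) < n_loop,
            )
            segments.append(seg)

    for t_ev, text in rec.events:
        if _is_reposition_event(text):
            for seg in segments:
                ts = seg.samples["time_s"].to_numpy()
                if ts[0] <= t_ev <= ts[-1]:
                    seg.spans_reposition = True

    total = sum(len(s.samples) for s in segments)
    assert total == len(rec.samples), "segments must partition the samples"
    return segments
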