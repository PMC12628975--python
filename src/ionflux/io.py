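"""Reading and writing the ASCII recording and analysis-output files.

Recording dialect (UTF-8, LF line endings, tab separated, diffable):

.. code-block:: text

    #IONFLUX-RECORDING	1
    #key=value                      (acquisition metadata, one per line)
    #EVENT	<time_s>	<free text>  (event marks, sorted by time)
    #COLUMNS	time_s	position_um	ise1_mV	[ise2_mV]	[volt1_mV]	[volt2_mV]
    <tab separated data rows, fixed decimal places>

Numbers are written with fixed precision (time 1e-5 s, position 1e-4 um,
voltages 1e-6 mV = 1 nV) so a write -> read -> write cycle is byte identical.

The analysis output is a TSV with one header row; its column set follows the
channel/buffer/event configuration and tops out at 15 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError

MAGIC = "#IONFLUX-RECORDING\t1"

#: Data columns of a recording in storage order; the first three are mandatory.
RECORDING_COLUMNS = ("time_s", "position_um", "ise1_mV", "ise2_mV", "volt1_mV", "volt2_mV")
_MANDATORY = RECORDING_COLUMNS[:3]
_COLUMN_FMT = {"time_s": "%.5f", "position_um": "%.4f"}  # voltages default to %.6f

#: Full 15-column analysis output in fixed order.
ANALYSIS_COLUMNS = (
    "time_min", "position_index",
    "V1_mV", "dV1_mV", "conc1_mM", "flux1_nmol_m2_s", "flux1_buffercorr",
    "V2_mV", "dV2_mV", "conc2_mM", "flux2_nmol_m2_s", "flux2_buffercorr",
    "volt1_mV", "volt2_mV", "event_mark",
)


@dataclass
class Recording:
    """A uniformly sampled multichannel recording plus event marks.

    ``samples`` holds time (s), electrode position as displacement along the
    scan axis (um, 0 = position 0) and 1-4 voltage channels (mV).  ``events``
    is a time-sorted list of ``(time_s, text)`` marks.
    """

    meta: dict[str, str]
    samples: pd.DataFrame
    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self):
        cols = list(self.samples.columns)
        for c in _MANDATORY:
            if c not in cols:
                raise ParseError(f"recording lacks mandatory column {c!r}")
        bad = [c for c in cols if c not in RECORDING_COLUMNS]
        if bad:
            raise ParseError(f"unknown recording column(s) {bad}")
        t = self.samples["time_s"].to_numpy()
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ParseError("time column not strictly increasing", line=i + 2)
            step = np.median(dt)
            if np.any(np.abs(dt - step) > step):
                raise ParseError("time column not uniform to within one sample interval")
        self.events = sorted(self.events, key=lambda e: e[0])

    @property
    def channels(self) -> list[str]:
        """Active voltage channels, in storage order."""
        return [c for c in RECORDING_COLUMNS[2:] if c in self.samples.columns]


def write_recording(rec: Recording, path) -> None:
    """Write ``rec`` to ``path`` in the dialect documented above."""
    lines = [MAGIC]
    for key, value in rec.meta.items():
        lines.append(f"#{key}={value}")
    for t, text in rec.events:
        lines.append(f"#EVENT\t{t:.5f}\t{text}")
    cols = ["time_s", "position_um"] + rec.channels
    lines.append("#COLUMNS\t" + "\t".join(cols))
    fmts = [_COLUMN_FMT.get(c, "%.6f") for c in cols]
    arr = rec.samples[cols].to_numpy()
    for row in arr:
        lines.append("\t".join(f % v for f, v in zip(fmts, row)))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_recording(path) -> Recording:
    """Parse a recording file; raises :class:`ParseError` with a line number."""
    with open(path, encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    if not raw or raw[0] != MAGIC:
        raise ParseError("missing recording magic line", line=1)
    meta: dict[str, str] = {}
    events: list[tuple[float, str]] = []
    cols: list[str] | None = None
    data_start = None
    for i, line in enumerate(raw[1:], start=2):
        if line.startswith("#EVENT\t"):
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("malformed #EVENT line", line=i)
            events.append((float(parts[1]), "\t".join(parts[2:])))
        elif line.startswith("#COLUMNS\t"):
            cols = line.split("\t")[1:]
            data_start = i
            break
        elif line.startswith("#"):
            if "=" not in line:
                raise ParseError("malformed header line (expected key=value)", line=i)
            key, _, value = line[1:].partition("=")
            meta[key] = value
        else:
            raise ParseError("data row before #COLUMNS line", line=i)
    if cols is None:
        raise ParseError("no #COLUMNS line found")
    for c in _MANDATORY:
        if c not in cols:
            raise ParseError(f"missing mandatory column {c!r}", line=data_start)
    try:
        samples = pd.read_csv(
            path, sep="\t", comment=None, names=cols, skiprows=data_start,
            dtype=float, engine="c",
        )
    except ValueError as exc:
        raise ParseError(f"cannot parse data block: {exc}") from exc
    return Recording(meta=meta, samples=samples, events=events)


def analysis_columns(
    ise2: bool = False, buffer: bool = False,
    volt1: bool = False, volt2: bool = False, events: bool = False,
) -> list[str]:
    """Column set of the analysis file for a given configuration.

    Base 6 columns for ISE channel 1, +1 buffer-corrected flux column per
    active ISE channel when buffer correction is on, +4 for ISE channel 2,
    +1 per auxiliary voltage channel, +1 event column; 15 at maximum.
    """
    cols = list(ANALYSIS_COLUMNS[:6])
    if buffer:
        cols.append("flux1_buffercorr")
    if ise2:
        cols += ["V2_mV", "dV2_mV", "conc2_mM", "flux2_nmol_m2_s"]
        if buffer:
            cols.append("flux2_buffercorr")
    if volt1:
        cols.append("volt1_mV")
    if volt2:
        cols.append("volt2_mV")
    if events:
        cols.append("event_mark")
    return cols


@dataclass
class AnalysisOutput:
    """Per-measurement analysis rows in the fixed 15-column order (subset)."""

    table: pd.DataFrame

    def __post_init__(self):
        cols = list(self.table.columns)
        order = [c for c in ANALYSIS_COLUMNS if c in cols]
        if cols != order or len(cols) < 6:
            raise ValueError(
                f"analysis columns must be an ordered subset of {ANALYSIS_COLUMNS} "
                f"starting with the 6 base columns; got {cols}"
            )


def write_analysis(out: AnalysisOutput, path) -> None:
    """Write the analysis table as a TSV with one header row."""
    df = out.table.copy()
    for c in df.columns:
        if c == "position_index":
            df[c] = df[c].map(lambda v: "%d" % v)
        elif c != "event_mark":
            df[c] = df[c].map(lambda v: "%.6f" % v)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
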