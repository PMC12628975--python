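"""Ion-flux calculation from drift-corrected voltage differences.

Two formalisms are provided.  The chemical-potential method converts dV
directly into a flux,

    J = C u ((58/|z|) / slope_cal) (dV / dx),

using the bath concentration C, the ionic mobility u and only the *slope* of
the calibration curve — which makes it insensitive to electrode drift and to
any constant amplifier gain (including inverting amplifiers, which simply
make slope_cal negative).  The diffusion-gradient method back-calculates the
concentrations at both positions through the full calibration line and
applies Fick's law, J = D dC/dx.  Because the diffusion coefficient is
derived from the mobility through the Einstein relation, the two methods
agree exactly in the small-gradient limit; they diverge when the local
concentration departs from the bath value, which the chemical-potential
method can absorb by substituting the measured position-1 concentration for
the bath concentration (``use_position1_conc``).

Sign convention: J > 0 is net influx into the tissue, J < 0 efflux.  With
dV = V(position 0) - V(position 1) and a non-inverting cation electrode, an
efflux raises the concentration at position 0, so dV > 0 maps to J < 0; the
sign flip is applied once, here.

For H+ fluxes in buffered solutions, part of the acid flux travels as
protonated buffer HA rather than free H+; the correction either scales the
chemical-potential flux by (r + 1) with the flux-ratio r, or adds the Fick
flux of HA computed from the protonated-buffer concentrations at the two
positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, voltage_to_concentration
from .config import AcquisitionConfig, GeometrySpec
from .constants import NERNST_SLOPE_IDEAL_MV
from .drift import DvEstimate, dv_series, segment_voltage
from .errors import ConfigError
from .io import AnalysisOutput, Recording, analysis_columns
from .segmentation import segment
from .species import BufferSpecies, IonSpecies, diffusion_coefficient, lookup_ion

_METHODS = ("chemical_potential", "diffusion_gradient")


@dataclass(frozen=True)
class FluxConfig:
    """Everything the flux calculation needs beyond the dV estimates.

    ``bath_conc`` is in mol m^-3 (numerically mM) and is required by the
    chemical-potential method unless ``use_position1_conc`` substitutes the
    measured position-1 concentration.  Buffer correction is only meaningful
    for H+ measurements and is refused for other ions.
    """

    method: str
    ion: IonSpecies
    bath_conc: float | None = None
    use_position1_conc: bool = False
    geometry: GeometrySpec = GeometrySpec()
    scan_distance: float = 50e-6  # m
    scan_angle: float = 0.0  # degrees
    buffer: BufferSpecies | None = None
    buffer_conc_mM: float | None = None

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ConfigError(f"method must be one of {_METHODS}")
        if (
            self.method == "chemical_potential"
            and not self.use_position1_conc
            and (self.bath_conc is None or not self.bath_conc > 0)
        ):
            raise ConfigError("chemical_potential requires bath_conc > 0")
        if self.buffer is not None:
            if self.buffer_conc_mM is None or not self.buffer_conc_mM > 0:
                raise ConfigError("buffer correction requires buffer_conc_mM > 0")
            if self.ion.name != "H+":
                raise ConfigError(
                    "buffer correction applies only to H+ measurements "
                    f"(ion is {self.ion.name})"
                )


def corrected_distance(
    geom: GeometrySpec, scan_distance: float, scan_angle: float = 0.0
) -> float:
    """Effective dx (m) referencing the flux to the tissue surface.

    The surface-normal displacement is d = scan_distance * cos(angle).  For
    curved tissues the steady-state field decays with distance, so the
    equivalent planar distance is

    - cylinder (radius a): dx = a ln(r1 / r0)
    - sphere:              dx = a^2 (r1 - r0) / (r0 r1)

    with r0 = a + gap0 and r1 = r0 + d; both tend to d as a grows (flat
    limit).
    """
    d = scan_distance * math.cos(math.radians(scan_angle))
    if not d > 0:
        raise ConfigError("normal displacement must be > 0")
    if geom.shape == "flat":
        return d
    a = geom.radius
    if a is None:
        raise ConfigError(f"{geom.shape} geometry requires a radius")
    r0 = a + geom.gap0
    r1 = r0 + d
    if geom.shape == "cylinder":
        return a * math.log(r1 / r0)
    return a**2 * (r1 - r0) / (r0 * r1)


def flux_chemical_potential(
    dv: DvEstimate, cfg: FluxConfig, cal: CalibrationCurve
) -> float:
    """Chemical-potential flux (mol m^-2 s^-1, influx-positive) from one dV."""
    dx = corrected_distance(cfg.geometry, cfg.scan_distance, cfg.scan_angle)
    if cfg.use_position1_conc:
        c_eff = float(voltage_to_concentration(cal, dv.V1))  # mol m^-3
    else:
        c_eff = cfg.bath_conc
    slope_ratio = (NERNST_SLOPE_IDEAL_MV / abs(cfg.ion.z)) / cal.slope
    return -c_eff * cfg.ion.u * slope_ratio * (dv.dV * 1e-3) / dx


def flux_diffusion_gradient(
    dv: DvEstimate, cfg: FluxConfig, cal: CalibrationCurve
) -> float:
    """Fick's-law flux from the back-calculated concentrations at both positions."""
    dx = corrected_distance(cfg.geometry, cfg.scan_distance, cfg.scan_angle)
    c0 = float(voltage_to_concentration(cal, dv.V0))  # mol m^-3 (== mM)
    c1 = float(voltage_to_concentration(cal, dv.V1))
    D = diffusion_coefficient(cfg.ion)
    return -D * (c0 - c1) / dx


def buffer_ratio(
    buf: BufferSpecies, C_buf_mM: float, pH: float, u_H: float | None = None
) -> float:
    """Ratio r of protonated-buffer flux to free-H+ flux.

    r = (u_HA / u_H+) * C * 1e-3 * 10^pK * (10^pH / (10^pK + 10^pH))^2,
    with the buffer's total concentration C in mM (the 1e-3 factor converts
    to molar).  r -> 0 as C -> 0.
    """
    if not C_buf_mM > 0:
        raise ConfigError("buffer concentration must be > 0")
    if u_H is None:
        u_H = lookup_ion("H+").u
    frac = 10.0**pH / (10.0**buf.pK + 10.0**pH)
    return (buf.u_HA / u_H) * C_buf_mM * 1e-3 * 10.0**buf.pK * frac**2


def correct_flux_chemical(J_H: float, r: float) -> float:
    """Total acid flux J_total = (r + 1) J_H+ for the chemical-potential method."""
    if r < 0:
        raise ConfigError("buffer flux ratio r must be >= 0")
    return (r + 1.0) * J_H


def protonated_conc(buf: BufferSpecies, C_buf_mM: float, pH: float) -> float:
    """Protonated-buffer concentration [HA] = C 10^pK / (10^pH + 10^pK), mM."""
    return C_buf_mM * 10.0**buf.pK / (10.0**pH + 10.0**buf.pK)


def correct_flux_fick(
    J_H: float,
    buf: BufferSpecies,
    C_buf_mM: float,
    pH0: float,
    pH1: float,
    dx: float,
) -> float:
    """Total acid flux for the Fick method: J_H plus the HA Fick flux.

    The HA flux uses the same influx-positive sign convention, so an acid
    efflux ([HA] higher at position 0) adds a same-signed contribution.
    """
    ha0 = protonated_conc(buf, C_buf_mM, pH0)  # mM == mol m^-3
    ha1 = protonated_conc(buf, C_buf_mM, pH1)
    J_HA = -buf.D_HA * (ha0 - ha1) / dx
    return J_H + J_HA


def _pH_from_conc_mM(c_mM: float) -> float:
    """pH from an H+ concentration in mM: pH = -log10(c * 1e-3 M)."""
    return 3.0 - math.log10(c_mM)


def compute_flux_series(
    estimates: list[DvEstimate], cfg: FluxConfig, cal: CalibrationCurve
) -> pd.DataFrame:
    """Per-triple concentrations and fluxes for one ISE channel.

    Columns: time_s, dV_mV, conc0_mM, conc1_mM, J (mol m^-2 s^-1) and, when
    buffer correction is configured, J_buffercorr.
    """
    rows = []
    dx = corrected_distance(cfg.geometry, cfg.scan_distance, cfg.scan_angle)
    for dv in estimates:
        c0 = float(voltage_to_concentration(cal, dv.V0))
        c1 = float(voltage_to_concentration(cal, dv.V1))
        if cfg.method == "chemical_potential":
            J = flux_chemical_potential(dv, cfg, cal)
        else:
            J = flux_diffusion_gradient(dv, cfg, cal)
        row = {
            "time_s": dv.time_s, "dV_mV": dv.dV,
            "conc0_mM": c0, "conc1_mM": c1, "J": J,
        }
        if cfg.buffer is not None:
            pH0, pH1 = _pH_from_conc_mM(c0), _pH_from_conc_mM(c1)
            if cfg.method == "chemical_potential":
                r = buffer_ratio(cfg.buffer, cfg.buffer_conc_mM, (pH0 + pH1) / 2.0)
                row["J_buffercorr"] = correct_flux_chemical(J, r)
            else:
                row["J_buffercorr"] = correct_flux_fick(
                    J, cfg.buffer, cfg.buffer_conc_mM, pH0, pH1, dx
                )
        rows.append(row)
    return pd.DataFrame(rows)


def acquisition_from_meta(
    meta: dict, cfg: FluxConfig, start_fit: float = 5.0
) -> AcquisitionConfig:
    """Rebuild the acquisition timing from recording metadata.

    Falls back to the flux configuration's scan parameters and the package
    defaults for keys absent from the header.
    """
    return AcquisitionConfig(
        sample_interval=float(meta.get("sample_interval_s", 0.01)),
        loop_duration=float(meta.get("loop_duration_s", 10.0)),
        scan_distance=float(meta.get("scan_distance_um", cfg.scan_distance * 1e6)) * 1e-6,
        scan_angle=float(meta.get("scan_angle_deg", cfg.scan_angle)),
        manipulator_side=meta.get("manipulator_side", "left"),
        start_fit=start_fit,
    )


def analyse(
    rec: Recording,
    cals: CalibrationCurve | dict[str, CalibrationCurve],
    cfg: FluxConfig,
    start_fit: float = 5.0,
) -> AnalysisOutput:
    """Full pipeline: segment, dV series, concentrations, fluxes, output table.

    ``cals`` is either the channel-1 curve or a mapping
    ``{"ise1_mV": curve, "ise2_mV": curve}``; a second curve is mandatory
    when the recording carries a second ISE channel.  Rows are indexed by
    the middle loop of each dV triple; per-loop voltages/concentrations give
    the alternating position-0/position-1 concentration trace, event marks
    are merged onto the loop containing them.
    """
    if isinstance(cals, CalibrationCurve):
        cals = {"ise1_mV": cals}
    if "ise1_mV" not in cals:
        raise ConfigError("missing calibration for ISE channel 1")
    ise2 = "ise2_mV" in rec.samples.columns
    if ise2 and "ise2_mV" not in cals:
        raise ConfigError(
            "recording has an active second ISE channel but no calibration "
            "was supplied for it"
        )
    acq = acquisition_from_meta(rec.meta, cfg, start_fit)
    segments = segment(rec, acq)

    channels = ["ise1_mV"] + (["ise2_mV"] if ise2 else [])
    series = {}
    est_by_seg: dict[str, dict[int, DvEstimate]] = {}
    for ch in channels:
        ests = dv_series(segments, start_fit, ch)
        series[ch] = compute_flux_series(ests, cfg, cals[ch])
        est_by_seg[ch] = {e.center_segment_index: e for e in ests}

    # rows follow channel 1's usable triples
    volt1 = "volt1_mV" in rec.samples.columns
    volt2 = "volt2_mV" in rec.samples.columns
    has_events = len(rec.events) > 0
    buffer_on = cfg.buffer is not None
    cols = analysis_columns(ise2=ise2, buffer=buffer_on,
                            volt1=volt1, volt2=volt2, events=has_events)
    rows = []
    for e1 in est_by_seg["ise1_mV"].values():
        seg = segments[e1.center_segment_index]
        ch1 = series["ise1_mV"]
        r1 = ch1[ch1["time_s"] == e1.time_s].iloc[0]
        v1 = segment_voltage(seg, start_fit, "ise1_mV")
        row = {
            "time_min": e1.time_s / 60.0,
            "position_index": seg.position_index,
            "V1_mV": v1,
            "dV1_mV": e1.dV,
            "conc1_mM": float(voltage_to_concentration(cals["ise1_mV"], v1)),
            "flux1_nmol_m2_s": r1["J"] * 1e9,
        }
        if buffer_on:
            row["flux1_buffercorr"] = r1["J_buffercorr"] * 1e9
        if ise2:
            e2 = est_by_seg["ise2_mV"].get(e1.center_segment_index)
            if e2 is None:
                continue
            ch2 = series["ise2_mV"]
            r2 = ch2[ch2["time_s"] == e2.time_s].iloc[0]
            v2 = segment_voltage(seg, start_fit, "ise2_mV")
            row["V2_mV"] = v2
            row["dV2_mV"] = e2.dV
            row["conc2_mM"] = float(voltage_to_concentration(cals["ise2_mV"], v2))
            row["flux2_nmol_m2_s"] = r2["J"] * 1e9
            if buffer_on:
                row["flux2_buffercorr"] = r2["J_buffercorr"] * 1e9
        for name, col in (("volt1_mV", volt1), ("volt2_mV", volt2)):
            if col:
                row[name] = segment_voltage(seg, start_fit, name)
        if has_events:
            ts = seg.samples["time_s"].to_numpy()
            marks = [text for t, text in rec.events if ts[0] <= t <= ts[-1]]
            row["event_mark"] = "; ".join(marks)
        rows.append(row)
    table = pd.DataFrame(rows, columns=cols)
    return AnalysisOutput(table=table)


def flux_config_from_dict(d: dict) -> FluxConfig:
    """Build a :class:`FluxConfig` from a plain mapping (YAML analysis config).

    Layout: method, ion, bath_conc_mM, use_position1_conc, geometry {shape,
    radius_um, gap0_um}, scan {distance_um, angle_deg}, buffer {name, conc_mM,
    solution_pH}.
    """
    from .species import lookup_buffer

    geo_d = d.get("geometry", {})
    radius = geo_d.get("radius_um")
    geom = GeometrySpec(
        shape=geo_d.get("shape", "flat"),
        radius=None if radius is None else float(radius) * 1e-6,
        gap0=float(geo_d.get("gap0_um", 0.0)) * 1e-6,
    )
    scan_d = d.get("scan", {})
    buffer = None
    buffer_conc = None
    if "buffer" in d and d["buffer"]:
        buf_d = d["buffer"]
        buffer = lookup_buffer(buf_d["name"], float(buf_d.get("solution_pH", 7.0)))
        buffer_conc = float(buf_d["conc_mM"])
    bath = d.get("bath_conc_mM")
    return FluxConfig(
        method=d.get("method", "chemical_potential"),
        ion=lookup_ion(d["ion"]),
        bath_conc=None if bath is None else float(bath),
        use_position1_conc=bool(d.get("use_position1_conc", False)),
        geometry=geom,
        scan_distance=float(scan_d.get("distance_um", 50.0)) * 1e-6,
        scan_angle=float(scan_d.get("angle_deg", 0.0)),
        buffer=buffer,
        buffer_conc_mM=buffer_conc,
    )
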