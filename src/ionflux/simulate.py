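"""Physics-based generator of synthetic self-referencing-electrode recordings.

The electrode dwells 10 s at each of two positions (first loop stationary at
position 0, then alternating), sampling every 10 ms.  A steady-state diffusion
field around the tissue, driven by a piecewise-constant source flux, sets the
ideal Nernstian electrode voltage; the measured signal adds a first-order
exponential sensor lag, a linear drift and i.i.d. Gaussian noise.  Because the
field has a closed form, every run carries exact per-loop ground truth
(flux, concentrations at both positions, drift-free dV), which is what makes
parameter-recovery testing of the analysis pipeline possible.

Sign conventions: the scenario's ``true_flux`` is positive for *efflux* out of
the tissue (it raises the concentration near the surface), whereas the
analyser reports fluxes positive for *influx*; a recovered flux therefore
matches ``-true_flux``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AcquisitionConfig, GeometrySpec
from .errors import ScenarioError
from .io import Recording
from .species import IonSpecies, diffusion_coefficient

#: Default unstirred-layer thickness (m): the quiescent film over which the
#: diffusion profile develops; concentrations relax to bulk beyond it.
DEFAULT_UNSTIRRED_LAYER = 500e-6


@dataclass(frozen=True)
class ElectrodeModel:
    """Electrode response: Nernstian line, first-order lag, drift, noise.

    slope/intercept are the *measured* calibration line (mV per decade and mV
    at 1 mM), so an inverting amplifier is modelled by a negative slope; tau
    is the exponential response time constant (s); drift in mV/min; noise_sd
    in mV (the default reflects a 30 uV system noise floor).
    """

    slope: float = 58.0
    intercept: float = 0.0
    tau: float = 0.5
    drift: float = 0.0
    noise_sd: float = 0.03

    def __post_init__(self):
        if self.tau < 0 or self.noise_sd < 0:
            raise ScenarioError("tau and noise_sd must be >= 0")
        if self.slope == 0:
            raise ScenarioError("electrode slope must be nonzero")


@dataclass(frozen=True)
class SimulationScenario:
    """Complete description of one synthetic experiment.

    ``true_flux`` is either a constant (mol m^-2 s^-1, efflux-positive) or a
    piecewise-constant schedule as ``[(t_start_s, J), ...]`` applied from each
    start time onward (the diffusion field tracks it quasi-statically).
    """

    ion: IonSpecies
    bulk_conc: float  # mol m^-3 (numerically mM)
    true_flux: float | tuple | list = 0.0
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    electrode: ElectrodeModel = field(default_factory=ElectrodeModel)
    unstirred_layer: float = DEFAULT_UNSTIRRED_LAYER
    n_loops: int = 4
    seed: int = 0

    def __post_init__(self):
        if not self.bulk_conc > 0:
            raise ScenarioError("bulk_conc must be > 0")
        if self.n_loops < 3:
            raise ScenarioError("n_loops must be >= 3 (dV needs a triple)")
        if not self.unstirred_layer > 0:
            raise ScenarioError("unstirred_layer must be > 0")

    def flux_at(self, t) -> np.ndarray:
        """Source flux at time(s) ``t`` (efflux-positive)."""
        t = np.asarray(t, dtype=float)
        if np.isscalar(self.true_flux) or isinstance(self.true_flux, (int, float)):
            return np.full(t.shape, float(self.true_flux))
        starts = np.array([s for s, _ in self.true_flux], dtype=float)
        values = np.array([v for _, v in self.true_flux], dtype=float)
        idx = np.searchsorted(starts, t, side="right") - 1
        if np.any(idx < 0):
            raise ScenarioError("piecewise flux schedule must start at or before t=0")
        return values[idx]


@dataclass
class GroundTruth:
    """Exact per-loop quantities of a simulated run.

    ``true_flux`` keeps the scenario's efflux-positive sign; ``true_dv_mV`` is
    the drift- and noise-free dV = V(position 0) - V(position 1) implied by
    the concentration field and the electrode slope.
    """

    loop_time: np.ndarray  # loop midpoint, s
    position_index: np.ndarray  # 0 or 1
    true_flux: np.ndarray  # mol m^-2 s^-1, efflux-positive
    conc0: np.ndarray  # mol m^-3 at position 0
    conc1: np.ndarray  # mol m^-3 at position 1
    true_dv_mV: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "loop_time_s": self.loop_time,
            "position_index": self.position_index,
            "true_flux_mol_m2_s": self.true_flux,
            "conc0_mM": self.conc0,
            "conc1_mM": self.conc1,
            "true_dv_mV": self.true_dv_mV,
        })


def position_waveform(acq: AcquisitionConfig, n_loops: int) -> np.ndarray:
    """Electrode displacement time series in um along the scan axis.

    The first loop stays at position 0; subsequent loops alternate between
    position 1 (scan_distance) and position 0, with instantaneous transitions
    at loop boundaries.  Length = n_loops * n_samples_per_loop.
    """
    n = acq.n_samples_per_loop
    loop_idx = np.arange(n_loops * n) // n
    return (loop_idx % 2) * acq.scan_distance * 1e6


def concentration_field(
    geom: GeometrySpec,
    ion: IonSpecies,
    bulk: float,
    J_surface,
    distance_from_surface,
    unstirred_layer: float = DEFAULT_UNSTIRRED_LAYER,
) -> np.ndarray | float:
    """Steady-state concentration (mol m^-3) at a distance from the surface.

    Solves the zero-divergence diffusion profile for a constant surface flux
    ``J_surface`` (efflux-positive) inside an unstirred layer of thickness L,
    with c = bulk outside the layer:

    - flat:      c(x) = bulk + (J/D) (L - x)
    - cylinder:  c(r) = bulk + (J a / D) ln(R / r),   r = a + x, R = a + L
    - sphere:    c(r) = bulk + (J a^2 / D) (1/r - 1/R)

    All forms reduce to bulk when J = 0; a flux strong enough to drive the
    concentration non-positive raises :class:`ScenarioError`.
    """
    x = np.asarray(distance_from_surface, dtype=float)
    if np.any(x < 0):
        raise ScenarioError("distance from surface must be >= 0")
    J = np.asarray(J_surface, dtype=float)
    D = diffusion_coefficient(ion)
    L = unstirred_layer
    if geom.shape == "flat":
        c = bulk + (J / D) * np.clip(L - x, 0.0, None)
    else:
        a = geom.radius
        r = a + x
        R = a + L
        inside = r <= R
        if geom.shape == "cylinder":
            c = bulk + (J * a / D) * np.where(inside, np.log(R / r), 0.0)
        else:  # sphere
            c = bulk + (J * a**2 / D) * np.where(inside, 1.0 / r - 1.0 / R, 0.0)
    if np.any(c <= 0):
        raise ScenarioError(
            "source flux too strong: concentration driven to <= 0 within the layer"
        )
    return c if c.ndim else float(c)


def _first_order_lag(v_ideal: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """Exact exponential relaxation toward a sample-wise constant target."""
    if tau == 0:
        return v_ideal.copy()
    decay = math.exp(-dt / tau)
    out = np.empty_like(v_ideal)
    out[0] = v_ideal[0]
    for k in range(1, len(v_ideal)):
        out[k] = v_ideal[k] + (out[k - 1] - v_ideal[k]) * decay
    return out


def simulate(sc: SimulationScenario) -> tuple[Recording, GroundTruth]:
    """Run the scenario; returns the Recording and its exact ground truth.

    Seeded runs are bit-reproducible: the only randomness is the Gaussian
    voltage noise drawn from ``numpy.random.default_rng(sc.seed)``.
    """
    acq = sc.acquisition
    n = acq.n_samples_per_loop
    n_total = sc.n_loops * n
    dt = acq.sample_interval
    t = np.arange(n_total) * dt
    pos_um = position_waveform(acq, sc.n_loops)
    pos_idx = (np.arange(n_total) // n) % 2

    # surface-normal distance of the tip at each sample
    x = sc.geometry.gap0 + pos_idx * acq.normal_displacement
    J_t = sc.flux_at(t)
    c = concentration_field(
        sc.geometry, sc.ion, sc.bulk_conc, J_t, x, sc.unstirred_layer
    )
    v_ideal = sc.electrode.intercept + sc.electrode.slope * np.log10(c)
    v = _first_order_lag(v_ideal, dt, sc.electrode.tau)
    v = v + sc.electrode.drift * (t / 60.0)
    if sc.electrode.noise_sd > 0:
        rng = np.random.default_rng(sc.seed)
        v = v + rng.normal(0.0, sc.electrode.noise_sd, n_total)

    samples = pd.DataFrame(
        {"time_s": t, "position_um": pos_um, "ise1_mV": v}
    )
    meta = {
        "ion": sc.ion.name,
        "bulk_conc_mM": repr(sc.bulk_conc),
        "electrode_slope_mV_per_decade": repr(sc.electrode.slope),
        "electrode_intercept_mV": repr(sc.electrode.intercept),
        "electrode_tau_s": repr(sc.electrode.tau),
        "electrode_drift_mV_per_min": repr(sc.electrode.drift),
        "electrode_noise_sd_mV": repr(sc.electrode.noise_sd),
        "sample_interval_s": repr(dt),
        "loop_duration_s": repr(acq.loop_duration),
        "scan_distance_um": repr(acq.scan_distance * 1e6),
        "scan_angle_deg": repr(acq.scan_angle),
        "manipulator_side": acq.manipulator_side,
        "geometry_shape": sc.geometry.shape,
        "geometry_radius_um": repr((sc.geometry.radius or 0) * 1e6),
        "geometry_gap0_um": repr(sc.geometry.gap0 * 1e6),
        "unstirred_layer_um": repr(sc.unstirred_layer * 1e6),
        "n_loops": repr(sc.n_loops),
        "seed": repr(sc.seed),
    }
    rec = Recording(meta=meta, samples=samples, events=[])

    # per-loop ground truth, flux evaluated at the loop midpoint
    loop_mid = (np.arange(sc.n_loops) + 0.5) * acq.loop_duration
    J_loop = sc.flux_at(loop_mid)
    c0 = concentration_field(
        sc.geometry, sc.ion, sc.bulk_conc, J_loop, sc.geometry.gap0,
        sc.unstirred_layer,
    )
    c1 = concentration_field(
        sc.geometry, sc.ion, sc.bulk_conc, J_loop,
        sc.geometry.gap0 + acq.normal_displacement, sc.unstirred_layer,
    )
    truth = GroundTruth(
        loop_time=loop_mid,
        position_index=(np.arange(sc.n_loops) % 2),
        true_flux=np.asarray(J_loop, dtype=float),
        conc0=np.asarray(c0, dtype=float),
        conc1=np.asarray(c1, dtype=float),
        true_dv_mV=sc.electrode.slope * np.log10(np.asarray(c0) / np.asarray(c1)),
    )
    return rec, truth


def scenario_from_dict(d: dict) -> SimulationScenario:
    """Build a scenario from a plain mapping (the YAML scenario-file layout).

    Recognised keys: ion, bulk_conc_mM, true_flux (number or [[t_s, J], ...]),
    n_loops, seed, unstirred_layer_um, and nested acquisition
    {sample_interval_s, loop_duration_s, scan_distance_um, scan_angle_deg,
    manipulator_side, start_fit_s}, geometry {shape, radius_um, gap0_um},
    electrode {slope_mV_per_decade, intercept_mV, tau_s, drift_mV_per_min,
    noise_sd_mV}.  Fluxes are in mol m^-2 s^-1, efflux-positive.
    """
    from .species import lookup_ion

    acq_d = d.get("acquisition", {})
    acq = AcquisitionConfig(
        sample_interval=float(acq_d.get("sample_interval_s", 0.01)),
        loop_duration=float(acq_d.get("loop_duration_s", 10.0)),
        scan_distance=float(acq_d.get("scan_distance_um", 50.0)) * 1e-6,
        scan_angle=float(acq_d.get("scan_angle_deg", 0.0)),
        manipulator_side=acq_d.get("manipulator_side", "left"),
        start_fit=float(acq_d.get("start_fit_s", 5.0)),
    )
    geo_d = d.get("geometry", {})
    radius = geo_d.get("radius_um")
    geom = GeometrySpec(
        shape=geo_d.get("shape", "flat"),
        radius=None if radius is None else float(radius) * 1e-6,
        gap0=float(geo_d.get("gap0_um", 0.0)) * 1e-6,
    )
    el_d = d.get("electrode", {})
    electrode = ElectrodeModel(
        slope=float(el_d.get("slope_mV_per_decade", 58.0)),
        intercept=float(el_d.get("intercept_mV", 0.0)),
        tau=float(el_d.get("tau_s", 0.5)),
        drift=float(el_d.get("drift_mV_per_min", 0.0)),
        noise_sd=float(el_d.get("noise_sd_mV", 0.03)),
    )
    flux = d.get("true_flux", 0.0)
    if isinstance(flux, (list, tuple)) and flux and isinstance(flux[0], (list, tuple)):
        flux = [(float(t), float(j)) for t, j in flux]
    else:
        flux = float(flux)
    return SimulationScenario(
        ion=lookup_ion(d["ion"]),
        bulk_conc=float(d["bulk_conc_mM"]),
        true_flux=flux,
        acquisition=acq,
        geometry=geom,
        electrode=electrode,
        unstirred_layer=float(d.get("unstirred_layer_um", 500.0)) * 1e-6,
        n_loops=int(d.get("n_loops", 4)),
        seed=int(d.get("seed", 0)),
    )
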