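"""Ion and pH-buffer species tables.

The tables ship as editable TSV files under ``ionflux/data``.  Mobilities are
limiting ionic mobilities u = lambda0 / (|z| F); the diffusion coefficient is
always *derived* from u through the Einstein relation so that the
chemical-potential and Fick flux formalisms are mutually consistent (tabulated
D values for buffers are kept separately because the protonated species is
neutral and has no electrophoretic mobility in the same sense).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .constants import EINSTEIN_VOLTAGE
from .errors import BufferValidityError, UnknownSpeciesError

#: Polyprotic buffers are only trusted within this many pH units of the
#: tabulated pK (their other dissociations would otherwise interfere).
POLYPROTIC_PH_TOLERANCE = 0.25


@dataclass(frozen=True)
class IonSpecies:
    """An ion with signed valency ``z`` and mobility ``u`` (m^2 V^-1 s^-1)."""

    name: str
    z: int
    u: float

    def __post_init__(self):
        if self.z == 0:
            raise ValueError(f"{self.name}: valency must be nonzero")
        if not self.u > 0:
            raise ValueError(f"{self.name}: mobility must be positive")


@dataclass(frozen=True)
class BufferSpecies:
    """A pH buffer: pK plus transport constants of the protonated form HA."""

    name: str
    pK: float
    u_HA: float
    D_HA: float
    is_polyprotic: bool

    def __post_init__(self):
        if not self.u_HA > 0 or not self.D_HA > 0:
            raise ValueError(f"{self.name}: u_HA and D_HA must be positive")
        if not 0 < self.pK < 14:
            raise ValueError(f"{self.name}: pK must lie in (0, 14)")


def _data_lines(filename: str):
    text = resources.files("ionflux.data").joinpath(filename).read_text()
    for raw in text.splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            yield line.split("\t")


def _load_ions() -> dict[str, IonSpecies]:
    table = {}
    for name, z, u in _data_lines("ions.tsv"):
        table[name] = IonSpecies(name=name, z=int(z), u=float(u))
    return table


def _load_buffers() -> dict[str, BufferSpecies]:
    table = {}
    for name, pK, u_HA, D_HA, poly in _data_lines("buffers.tsv"):
        table[name] = BufferSpecies(
            name=name,
            pK=float(pK),
            u_HA=float(u_HA),
            D_HA=float(D_HA),
            is_polyprotic=poly.lower() in ("yes", "true", "1"),
        )
    return table


ION_TABLE: dict[str, IonSpecies] = _load_ions()
BUFFER_TABLE: dict[str, BufferSpecies] = _load_buffers()


def lookup_ion(name: str) -> IonSpecies:
    """Return the tabulated :class:`IonSpecies` for ``name`` (e.g. ``"K+"``)."""
    try:
        return ION_TABLE[name]
    except KeyError:
        raise UnknownSpeciesError(
            f"unknown ion {name!r}; available: {', '.join(sorted(ION_TABLE))}"
        ) from None


def diffusion_coefficient(species: IonSpecies) -> float:
    """Diffusion coefficient in m^2 s^-1 via the Einstein relation.

    D = u * V_T / |z| with the thermal voltage V_T = 0.058 V / ln 10, matching
    the 58 mV/decade ideal electrode slope used throughout the package.
    """
    return species.u * EINSTEIN_VOLTAGE / abs(species.z)


def lookup_buffer(name: str, solution_pH: float) -> BufferSpecies:
    """Return the tabulated buffer, validating polyprotic pH applicability.

    Polyprotic organic-acid buffers are tabulated with a single pK and are
    refused when ``|solution_pH - pK|`` exceeds 0.25 pH units, because their
    neighbouring dissociations would otherwise contribute.
    """
    try:
        buf = BUFFER_TABLE[name]
    except KeyError:
        raise UnknownSpeciesError(
            f"unknown buffer {name!r}; available: {', '.join(sorted(BUFFER_TABLE))}"
        ) from None
    if buf.is_polyprotic and abs(solution_pH - buf.pK) > POLYPROTIC_PH_TOLERANCE:
        raise BufferValidityError(
            f"{name} is polyprotic: it may only be used within "
            f"{POLYPROTIC_PH_TOLERANCE} pH units of its tabulated pK "
            f"{buf.pK} (got pH {solution_pH})"
        )
    return buf
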