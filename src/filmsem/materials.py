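"""Material and beam data model plus per-material electron-physics quantities.

The transport engine consumes three single-electron quantities, all standard
in low-voltage SEM Monte-Carlo work:

* the Berger–Seltzer mean ionization potential ``J(Z)``,
* the total screened-Rutherford elastic cross-section ``sigma(Z, E)``,
* the Joy–Luo modified Bethe stopping power, which remains positive and
  finite down to the transport cutoff (0.05 keV) where the plain Bethe
  formula turns over.

Units are keV for energy and nm for length throughout the public API;
densities are g/cm^3 with conversions applied inside the formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

AVOGADRO = 6.02214076e23  # 1/mol
#: Lowest electron energy (keV) at which the physics formulas are evaluated.
ENERGY_FLOOR_KEV = 0.05
#: Highest supported beam energy (keV).
ENERGY_CEIL_KEV = 30.0


@dataclass(frozen=True)
class Element:
    """A chemical element as the scattering formulas see it."""

    symbol: str
    Z: int
    atomic_mass: float  # g/mol

    def __post_init__(self) -> None:
        if not isinstance(self.Z, (int, np.integer)) or self.Z < 1:
            raise DomainError(f"atomic number must be a positive integer, got {self.Z!r}")
        if self.atomic_mass <= self.Z * 0.9:
            raise DomainError(
                f"atomic mass {self.atomic_mass} g/mol implausible for Z={self.Z}"
            )


@dataclass(frozen=True)
class Material:
    """A (possibly compound) material defined by mass density and weight fractions."""

    name: str
    density: float  # g/cm^3
    composition: tuple[tuple[Element, float], ...]

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise DomainError(f"density must be positive, got {self.density}")
        if not self.composition:
            raise DomainError("material needs at least one element")
        total = 0.0
        for elem, w in self.composition:
            if not 0.0 < w <= 1.0:
                raise DomainError(
                    f"weight fraction of {elem.symbol} must be in (0, 1], got {w}"
                )
            total += w
        if abs(total - 1.0) > 1e-9:
            raise DomainError(
                f"weight fractions of {self.name!r} sum to {total!r}, not 1 "
                "(renormalize explicitly; silent renormalization is refused)"
            )

    @property
    def elements(self) -> tuple[Element, ...]:
        return tuple(e for e, _ in self.composition)

    @property
    def weight_fractions(self) -> tuple[float, ...]:
        return tuple(w for _, w in self.composition)


@dataclass(frozen=True)
class Layer:
    """One slab of the film stack."""

    material: Material
    thickness: float  # nm

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise DomainError(f"layer thickness must be positive, got {self.thickness}")


@dataclass(frozen=True)
class FilmStack:
    """Ordered stack of layers; the first layer is the beam-entry side."""

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise DomainError("a film stack needs at least one layer")

    @property
    def total_thickness(self) -> float:
        return float(sum(l.thickness for l in self.layers))

    def boundaries(self) -> np.ndarray:
        """Depths (nm) of the lower face of each layer, measured from the top."""
        return np.cumsum([l.thickness for l in self.layers])


@dataclass(frozen=True)
class BeamSpec:
    """Electron-beam and scan parameters.

    Defaults are the imaging conditions used throughout this package's
    reference configuration: 4 kV, 3 nm spot, 31.3 pA, a 1280x1024 frame
    scanned in 40 s.
    """

    voltage: float = 4.0  # kV
    spot_diameter: float = 3.0  # nm (FWHM for a Gaussian profile)
    current: float = 31.3  # pA
    image_width: int = 1280  # px
    image_height: int = 1024  # px
    frame_time: float = 40.0  # s

    def __post_init__(self) -> None:
        if not 0.1 <= self.voltage <= ENERGY_CEIL_KEV:
            raise DomainError(
                f"beam voltage {self.voltage} kV outside supported range "
                f"[0.1, {ENERGY_CEIL_KEV}] kV"
            )
        for name in ("spot_diameter", "current", "frame_time"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.image_width < 1 or self.image_height < 1:
            raise DomainError("image dimensions must be at least 1 px")


# --- built-in element and material library -------------------------------

SILICON = Element("Si", 14, 28.0855)
NITROGEN = Element("N", 7, 14.007)
NICKEL = Element("Ni", 28, 58.6934)
GOLD = Element("Au", 79, 196.96657)

#: Elements available for user-defined materials in configuration files.
ELEMENTS: dict[str, Element] = {
    e.symbol: e
    for e in (
        Element("H", 1, 1.008),
        Element("C", 6, 12.011),
        NITROGEN,
        Element("O", 8, 15.999),
        Element("Al", 13, 26.9815),
        SILICON,
        Element("P", 15, 30.9738),
        Element("S", 16, 32.06),
        Element("Ti", 22, 47.867),
        Element("Cr", 24, 51.9961),
        Element("Fe", 26, 55.845),
        NICKEL,
        Element("Cu", 29, 63.546),
        Element("Pd", 46, 106.42),
        Element("Ag", 47, 107.8682),
        Element("Pt", 78, 195.084),
        GOLD,
    )
}

# "SiN" membranes are amorphous silicon nitride; Si3N4 stoichiometry is
# assumed for the weight fractions, with the membrane's bulk density.
SIN = Material("SiN", 3.12, ((SILICON, 0.6006), (NITROGEN, 0.3994)))
NI = Material("Ni", 8.9, ((NICKEL, 1.0),))
AU = Material("Au", 19.3, ((GOLD, 1.0),))

MATERIALS: dict[str, Material] = {m.name: m for m in (SIN, NI, AU)}


def get_material(name: str) -> Material:
    """Look up a built-in material by (case-insensitive) name."""
    for key, mat in MATERIALS.items():
        if key.lower() == name.lower():
            return mat
    raise DomainError(f"unknown material {name!r}; built-ins: {sorted(MATERIALS)}")


def coated_film_stack(
    sin_thickness: float = 50.0,
    ni_thickness: float = 15.0,
    au_thickness: float = 10.0,
) -> FilmStack:
    """The metal-coated SiN membrane: SiN entry layer, Ni, then Au at the bottom.

    The imaging film uses a 50-nm membrane; the transport benchmarks in this
    package use 60 nm (pass ``sin_thickness=60``).
    """
    return FilmStack(
        (
            Layer(SIN, sin_thickness),
            Layer(NI, ni_thickness),
            Layer(AU, au_thickness),
        )
    )


# --- physics quantities ---------------------------------------------------


def mean_ionization_potential(Z: int) -> float:
    """Berger–Seltzer mean ionization potential J (keV) for atomic number Z."""
    if not isinstance(Z, (int, np.integer)):
        raise DomainError(f"Z must be an integer, got {Z!r}")
    if Z < 1:
        raise DomainError(f"Z must be >= 1, got {Z}")
    if Z < 13:
        return 11.5 * Z * 1e-3
    return (9.76 * Z + 58.5 * Z ** (-0.19)) * 1e-3


def screening_parameter(Z: int, energy):
    """Screening parameter alpha of the screened-Rutherford cross-section."""
    energy = np.asarray(energy, dtype=float)
    return 3.4e-3 * Z ** 0.67 / energy


def _check_energy(energy, upper: float | None = None) -> np.ndarray:
    e = np.asarray(energy, dtype=float)
    if np.any(e <= ENERGY_FLOOR_KEV):
        raise DomainError(
            f"energy must exceed the {ENERGY_FLOOR_KEV} keV validity floor"
        )
    if upper is not None and np.any(e > upper):
        raise DomainError(f"energy must be <= {upper} keV")
    return e


def elastic_cross_section(Z: int, energy):
    """Total screened-Rutherford elastic cross-section (cm^2).

    ``sigma = 5.21e-21 (Z/E)^2 * 4 pi / (alpha (1 + alpha)) * ((E+511)/(E+1024))^2``
    with E in keV.  The relativistic factor uses the 511/1024 keV constants
    (one fixed convention; some codes use 1022).
    """
    e = _check_energy(energy)
    alpha = screening_parameter(Z, e)
    rel = ((e + 511.0) / (e + 1024.0)) ** 2
    sigma = 5.21e-21 * (Z / e) ** 2 * (4.0 * np.pi / (alpha * (1.0 + alpha))) * rel
    return sigma if sigma.shape else float(sigma)


def browning_cross_section(Z: int, energy):
    """Empirical Mott-fit total elastic cross-section (cm^2), Browning's
    parametrization:

    ``sigma = 3.0e-18 Z^1.7 / (E + 0.005 Z^1.7 sqrt(E) + 0.0007 Z^2 / sqrt(E))``

    with E in keV.  Fits phase-shift (Mott) cross-sections over 0.1-30 keV
    and, unlike screened Rutherford, does not blow up for heavy elements at
    a few keV; this is the transport engine's default elastic model.
    """
    e = _check_energy(energy)
    z17 = float(Z) ** 1.7
    sigma = 3.0e-18 * z17 / (e + 0.005 * z17 * np.sqrt(e) + 0.0007 * Z ** 2 / np.sqrt(e))
    return sigma if sigma.shape else float(sigma)


_CROSS_SECTIONS = {
    "screened_rutherford": elastic_cross_section,
    "browning": browning_cross_section,
}


def partial_inverse_mfps(
    material: Material, energy, model: str = "screened_rutherford"
) -> np.ndarray:
    """Per-element inverse elastic mean free paths (1/nm).

    Row i corresponds to element i of the material's composition; columns
    follow the shape of ``energy``.  Summing over rows gives the total
    inverse mean free path.
    """
    try:
        sigma_fn = _CROSS_SECTIONS[model]
    except KeyError:
        raise DomainError(
            f"unknown elastic model {model!r}; choose from {sorted(_CROSS_SECTIONS)}"
        ) from None
    e = _check_energy(energy)
    rows = []
    for elem, w in material.composition:
        n_i = AVOGADRO * material.density * w / elem.atomic_mass  # atoms/cm^3
        rows.append(n_i * np.asarray(sigma_fn(elem.Z, e)) * 1e-7)
    return np.array(rows)


def elastic_mfp(material: Material, energy, model: str = "screened_rutherford"):
    """Elastic mean free path (nm) for a compound material."""
    inv = partial_inverse_mfps(material, energy, model=model).sum(axis=0)
    out = 1.0 / inv
    return out if out.shape else float(out)


def stopping_power(material: Material, energy):
    """Joy–Luo modified Bethe stopping power (keV/nm), positive for all
    energies in (0.05, 30] keV."""
    e = _check_energy(energy, upper=ENERGY_CEIL_KEV)
    total = np.zeros_like(e)
    for elem, w in material.composition:
        J = mean_ionization_potential(elem.Z)
        k = 0.731 + 0.0688 * math.log10(elem.Z)
        total = total + (w * elem.Z / elem.atomic_mass) * np.log(
            1.166 * (e + k * J) / J
        )
    out = 7.85e4 * (material.density / e) * total * 1e-7  # keV/cm -> keV/nm
    return out if out.shape else float(out)
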