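"""Liquid junction potential via the Henderson equation.

The junction potential between the pipette filling solution and the bath
arises from unequal ionic mobilities across the liquid–liquid boundary.
The Henderson approximation gives, for pipette (P) against bath (B),

    E = (RT/F) * [Σ z_i u_i (c_i^B − c_i^P)] / [Σ z_i² u_i (c_i^B − c_i^P)]
        * ln( Σ z_i² u_i c_i^P / Σ z_i² u_i c_i^B )

where u_i is the ionic mobility relative to K⁺ (λ°_molar / (z² λ°_K)),
z_i the valence and c_i the concentration. E is the potential of the bath
relative to the pipette; the value reported here is the pipette potential
relative to the bath (the sign convention in which whole-cell potentials
would be corrected by *adding* the junction potential).

The built-in relative-mobility table follows the standard junction
potential literature (limiting molar conductivities at 25 °C, scaled to
K⁺ = 1); every entry can be overridden per species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IonSpecies",
    "SolutionSpec",
    "MOBILITY_TABLE",
    "henderson_junction_potential",
    "k_gluconate_internal",
    "standard_acsf",
]

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: Relative ionic mobilities u = λ°_molar / (z² λ°_K), λ°_K = 73.5 S cm²/mol.
MOBILITY_TABLE: dict[str, float] = {
    "K": 1.0,
    "Na": 0.682,
    "Li": 0.56,
    "Cs": 1.05,
    "H": 4.76,
    "Mg": 0.361,
    "Ca": 0.4045,
    "Ba": 0.4332,
    "Cl": 1.0388,
    "Br": 1.063,
    "F": 0.753,
    "HCO3": 0.605,
    "H2PO4": 0.449,
    "SO4": 0.544,
    "gluconate": 0.33,
    "HEPES": 0.30,
    "acetate": 0.556,
    "methanesulfonate": 0.66,
    "ATP": 0.24,
    "GTP": 0.24,
}

_DEFAULT_VALENCE = {
    "K": 1, "Na": 1, "Li": 1, "Cs": 1, "H": 1, "Mg": 2, "Ca": 2, "Ba": 2,
    "Cl": -1, "Br": -1, "F": -1, "HCO3": -1, "H2PO4": -1, "SO4": -2,
    "gluconate": -1, "HEPES": -1, "acetate": -1, "methanesulfonate": -1,
    "ATP": -2, "GTP": -2,
}


@dataclass
class IonSpecies:
    name: str
    valence: int
    mobility: float  # relative to K+
    concentration: float  # mM

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.name}: concentration must be >= 0")
        if self.valence != 0 and self.mobility == 0:
            raise ValueError(f"{self.name}: charged species requires nonzero mobility")


@dataclass
class SolutionSpec:
    """A list of dissolved ionic species with a temperature."""

    species: list[IonSpecies]
    temperature_c: float = 33.0

    def __post_init__(self) -> None:
        for sp in self.species:
            if sp.valence == 0 and sp.mobility != 0:
                warnings.warn(
                    f"{sp.name}: zero valence with nonzero mobility; "
                    "neutral species do not contribute to the junction potential",
                    stacklevel=2,
                )

    @classmethod
    def from_concentrations(
        cls, concentrations: dict[str, float], temperature_c: float = 33.0,
        mobility_overrides: dict[str, float] | None = None,
    ) -> "SolutionSpec":
        """Build from {ion name: mM} using the built-in mobility table."""
        over = mobility_overrides or {}
        species = []
        for name, conc in concentrations.items():
            if name not in MOBILITY_TABLE and name not in over:
                raise KeyError(f"no mobility table entry for ion '{name}'")
            species.append(
                IonSpecies(
                    name=name,
                    valence=_DEFAULT_VALENCE.get(name, 0),
                    mobility=over.get(name, MOBILITY_TABLE.get(name, 0.0)),
                    concentration=conc,
                )
            )
        return cls(species, temperature_c)

    def charged(self) -> list[IonSpecies]:
        return [s for s in self.species if s.valence != 0 and s.concentration > 0]


def henderson_junction_potential(pipette: SolutionSpec, bath: SolutionSpec) -> float:
    """Henderson liquid junction potential of pipette relative to bath, mV.

    Temperature is taken from the pipette spec (the two should agree).
    """
    if not pipette.charged() and not bath.charged():
        raise ValueError("all-neutral solutions: junction potential undefined")
    temp_k = pipette.temperature_c + 273.15
    rt_f_mv = GAS_CONSTANT * temp_k / FARADAY * 1e3

    conc_p = {s.name: s.concentration for s in pipette.charged()}
    conc_b = {s.name: s.concentration for s in bath.charged()}
    props: dict[str, tuple[int, float]] = {}
    for s in list(pipette.charged()) + list(bath.charged()):
        if s.name in props and not np.isclose(props[s.name][1], s.mobility):
            raise ValueError(f"{s.name}: inconsistent mobility between solutions")
        props[s.name] = (s.valence, s.mobility)

    num = den = sum_p = sum_b = 0.0
    for name, (z, u) in props.items():
        cp = conc_p.get(name, 0.0)
        cb = conc_b.get(name, 0.0)
        d = cb - cp
        num += z * u * d
        den += z * z * u * d
        sum_p += z * z * u * cp
        sum_b += z * z * u * cb
    if sum_p <= 0 or sum_b <= 0:
        raise ValueError("each solution must contain charged species")
    if den == 0.0:
        return 0.0
    bath_minus_pip = rt_f_mv * (num / den) * np.log(sum_p / sum_b)
    return float(-bath_minus_pip)


# ---------------------------------------------------------------------------
# recipe helpers (fully dissociated salts; HEPES half-anionic at pH 7.4,
# which sits at its pKa; titrant cations ignored as in common practice)

def k_gluconate_internal(temperature_c: float = 33.0) -> SolutionSpec:
    """K-gluconate whole-cell internal: K-gluconate 135, NaCl 10, HEPES 10,
    MgCl2 1, Na2ATP 2, GTP 0.3 (mM)."""
    return SolutionSpec.from_concentrations(
        {
            "K": 135.0,
            "gluconate": 135.0,
            "Na": 10.0 + 4.0,
            "Cl": 10.0 + 2.0,
            "HEPES": 5.0,
            "Mg": 1.0,
            "ATP": 2.0,
            "GTP": 0.3,
        },
        temperature_c=temperature_c,
    )


def standard_acsf(temperature_c: float = 33.0) -> SolutionSpec:
    """Standard recording aCSF: NaCl 123, KCl 4, CaCl2 1, MgSO4 1,
    NaHCO3 26, NaH2PO4 1.25 (mM)."""
    return SolutionSpec.from_concentrations(
        {
            "Na": 123.0 + 26.0 + 1.25,
            "Cl": 123.0 + 4.0 + 2.0,
            "K": 4.0,
            "Ca": 1.0,
            "Mg": 1.0,
            "SO4": 1.0,
            "HCO3": 26.0,
            "H2PO4": 1.25,
        },
        temperature_c=temperature_c,
    )
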