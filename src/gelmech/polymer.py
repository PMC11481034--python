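"""Hydrogel polymer-network characterisation.

Swelling and degradation arithmetic plus the hydrogel mesh size ξ by three
routes:

* **mechanical** — ξ from the shear modulus via rubber elasticity,
  ξ = (G·N_A / (R·T))^(−1/3);
* **swelling** — Flory–Rehner/Peppas–Merrill: the molecular weight between
  crosslinks M̄c from equilibrium swelling thermodynamics, then
  n = 2·M̄c/Mr, r̄0 = l·√Cn·√n, ξ = ν₂ₛ^(−1/3)·r̄0;
* **combined** — M̄c from the measured shear modulus together with the
  volumetric swelling ratio Q = ν₂ᵣ/ν₂ₛ:
  1/M̄c = G·Q^(1/3)/(R·T·C₂ᵣ) + 2/M̄n.

Defaults are for PEG networks swollen in water: repeat-unit mass Mr = 44
g/mol, backbone bond length l = 0.146 nm, characteristic ratio Cn = 4.0,
specific volume ν̄ = 0.89 cm³/g, water molar volume V₁ = 18 cm³/mol, and
Flory interaction parameter χ = 0.426.  User-facing units follow lab
convention (cm³/g, g/cm³, nm); conversions to SI are internal to each
function.

Note the combined-route expression is implemented with a *positive*
chain-end term +2/M̄n, exactly as used here; some literature variants
subtract that term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "AVOGADRO",
    "GravimetricSample",
    "DegradationSeries",
    "PolymerParams",
    "MechanicalState",
    "MeshResult",
    "UnphysicalResultError",
    "water_sorption",
    "mass_loss",
    "shear_from_youngs",
    "mesh_size_mechanical",
    "mc_from_swelling",
    "mc_from_mechanics_swelling",
    "swelling_ratio",
    "mesh_size_from_mc",
    "mesh_size_pipeline",
]

GAS_CONSTANT = 8.314          # J mol^-1 K^-1
AVOGADRO = 6.02214076e23      # mol^-1


class UnphysicalResultError(ValueError):
    """A parameter set produced a non-positive 1/M̄c (no physical network)."""


@dataclass(frozen=True)
class GravimetricSample:
    """Hydrogel masses: m0 post-formation, mt after time t (grams)."""

    m0: float
    mt: float

    def __post_init__(self) -> None:
        if self.m0 <= 0:
            raise ValueError("m0 must be > 0")
        if self.mt < 0:
            raise ValueError("mt must be >= 0")


@dataclass(frozen=True)
class DegradationSeries:
    """Initial swollen mass Mi and (time_h, Mt) samples during degradation."""

    Mi: float
    samples: tuple

    def __post_init__(self) -> None:
        if self.Mi <= 0:
            raise ValueError("Mi must be > 0")
        times = [s[0] for s in self.samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        if any(s[1] < 0 for s in self.samples):
            raise ValueError("masses must be >= 0")


@dataclass
class PolymerParams:
    """Polymer/solvent parameter set for the swelling-based mesh size.

    Attributes
    ----------
    Mn_bar : number-average molecular weight of the precursor polymer, g/mol.
    Mr : repeat-unit molecular mass, g/mol (44 for PEG).
    bond_length_l : average backbone bond length, nm (0.146 for PEG).
    Cn : characteristic ratio (4.0 for PEG).
    nu_bar : specific volume of amorphous polymer, cm³/g (0.89 for PEG).
    V1 : molar volume of the solvent, cm³/mol (18 for water).
    chi : Flory polymer–solvent interaction parameter (0.426 for PEG–water).
    nu2_r, nu2_s : polymer volume fraction before swelling / at swelling
        equilibrium, dimensionless in (0, 1].
    C2_r : polymer mass concentration in solution before crosslinking, g/cm³.
    """

    Mn_bar: float
    nu2_r: float
    nu2_s: float
    Mr: float = 44.0
    bond_length_l: float = 0.146
    Cn: float = 4.0
    nu_bar: float = 0.89
    V1: float = 18.0
    chi: float = 0.426
    C2_r: float | None = None

    def __post_init__(self) -> None:
        for name in ("Mn_bar", "nu2_r", "nu2_s", "Mr", "bond_length_l",
                     "Cn", "nu_bar", "V1", "chi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.C2_r is not None and self.C2_r <= 0:
            raise ValueError("C2_r must be > 0")
        if not self.nu2_s < 1:
            raise ValueError("nu2_s must be < 1")
        if self.nu2_s > self.nu2_r:
            import warnings
            warnings.warn("nu2_s > nu2_r: gel appears to deswell", RuntimeWarning)


@dataclass
class MechanicalState:
    """Measured elasticity: Young's modulus E (Pa), Poisson ratio, T (K)."""

    E: float
    poisson: float = 0.5
    T: float = 310.15

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be > 0")
        if not -1 < self.poisson <= 0.5:
            raise ValueError("poisson must lie in (-1, 0.5]")
        if self.T <= 0:
            raise ValueError("T must be > 0")

    @property
    def G(self) -> float:
        return shear_from_youngs(self.E, self.poisson)


@dataclass(frozen=True)
class MeshResult:
    """Mesh size by one route. Mc_bar/n_repeats/r0 stay None on the mechanical route."""

    method: str
    xi: float
    Mc_bar: float | None = None
    n_repeats: float | None = None
    r0: float | None = None


def water_sorption(sample: GravimetricSample) -> float:
    """Water sorption in percent: (mt − m0)/m0 × 100. Negative = deswelling."""
    return (sample.mt - sample.m0) / sample.m0 * 100.0


def mass_loss(series: DegradationSeries) -> np.ndarray:
    """Percent mass lost at each timepoint: (Mi − Mt)/Mi × 100."""
    Mt = np.array([s[1] for s in series.samples], dtype=float)
    return (series.Mi - Mt) / series.Mi * 100.0


def shear_from_youngs(E: float, poisson: float = 0.5) -> float:
    """Shear modulus of an isotropic elastic solid, G = E / (2(1+ν))."""
    if E <= 0:
        raise ValueError("E must be > 0")
    if not -1 < poisson <= 0.5:
        raise ValueError("poisson must lie in (-1, 0.5]")
    return E / (2.0 * (1.0 + poisson))


def mesh_size_mechanical(G: float, T: float = 310.15) -> float:
    """Mesh size (nm) from rubber elasticity: ξ = (G·N_A/(R·T))^(−1/3).

    G·N_A/(R·T) is a crosslink number density in m⁻³; its inverse cube
    root is the characteristic inter-crosslink distance, returned in nm.
    """
    if G <= 0 or T <= 0:
        raise ValueError("G and T must be > 0")
    xi_m = (G * AVOGADRO / (GAS_CONSTANT * T)) ** (-1.0 / 3.0)
    return xi_m * 1e9


def mc_from_swelling(params: PolymerParams) -> float:
    """M̄c (g/mol) from equilibrium swelling (Flory–Rehner/Peppas–Merrill).

    1/M̄c = 2/M̄n − [ (ν̄/V₁)·(ln(1−ν₂ₛ) + ν₂ₛ + χ·ν₂ₛ²) ]
                    / { ν₂ᵣ·[ (ν₂ₛ/ν₂ᵣ)^(1/3) − ½·(ν₂ₛ/ν₂ᵣ) ] }
    """
    p = params
    mixing = np.log(1.0 - p.nu2_s) + p.nu2_s + p.chi * p.nu2_s**2
    phi = p.nu2_s / p.nu2_r
    elastic = p.nu2_r * (phi ** (1.0 / 3.0) - 0.5 * phi)
    inv_mc = 2.0 / p.Mn_bar - (p.nu_bar / p.V1) * mixing / elastic
    if inv_mc <= 0:
        raise UnphysicalResultError("1/Mc <= 0: parameter set has no physical network")
    return 1.0 / inv_mc


def swelling_ratio(nu2_r: float, nu2_s: float) -> float:
    """Water-induced volumetric swelling ratio Q = ν₂ᵣ/ν₂ₛ."""
    if nu2_r <= 0 or nu2_s <= 0:
        raise ValueError("volume fractions must be > 0")
    return nu2_r / nu2_s


def mc_from_mechanics_swelling(
    G: float, Q: float, T: float, C2_r: float, Mn_bar: float
) -> float:
    """M̄c (g/mol) from shear modulus + swelling ratio (combined route).

    1/M̄c,E = G·Q^(1/3) / (R·T·C₂ᵣ) + 2/M̄n, with C₂ᵣ supplied in g/cm³
    and converted internally to g/m³ so the first term carries mol/g.
    """
    if min(G, Q, T, C2_r, Mn_bar) <= 0:
        raise ValueError("all inputs must be > 0")
    c2r_si = C2_r * 1e6  # g/cm^3 -> g/m^3
    inv_mc = G * Q ** (1.0 / 3.0) / (GAS_CONSTANT * T * c2r_si) + 2.0 / Mn_bar
    if inv_mc <= 0:
        raise UnphysicalResultError("1/Mc <= 0")
    return 1.0 / inv_mc


def mesh_size_from_mc(Mc_bar: float, params: PolymerParams,
                      method: str = "swelling") -> MeshResult:
    """Mesh size from M̄c via chain statistics.

    n = 2·M̄c/Mr repeating units per crosslinked chain;
    r̄0 = l·√Cn·√n is the unperturbed end-to-end distance (nm);
    ξ = ν₂ₛ^(−1/3)·r̄0 dilates it to the swollen state.
    """
    if Mc_bar <= 0:
        raise ValueError("Mc_bar must be > 0")
    p = params
    n = 2.0 * Mc_bar / p.Mr
    r0 = p.bond_length_l * np.sqrt(p.Cn) * np.sqrt(n)
    xi = p.nu2_s ** (-1.0 / 3.0) * r0
    return MeshResult(method=method, xi=float(xi), Mc_bar=float(Mc_bar),
                      n_repeats=float(n), r0=float(r0))


def mesh_size_pipeline(
    method: str,
    params: PolymerParams | None = None,
    mech: MechanicalState | None = None,
) -> MeshResult:
    """Dispatch the full mesh-size chain for one of the three routes.

    ``mechanical`` needs only ``mech``; ``swelling`` needs only ``params``;
    ``combined`` needs both plus ``params.C2_r``.
    """
    if method == "mechanical":
        if mech is None:
            raise ValueError("mechanical route needs a MechanicalState")
        return MeshResult(method="mechanical",
                          xi=mesh_size_mechanical(mech.G, mech.T))
    if method == "swelling":
        if params is None:
            raise ValueError("swelling route needs PolymerParams")
        return mesh_size_from_mc(mc_from_swelling(params), params, "swelling")
    if method == "combined":
        if params is None or mech is None or params.C2_r is None:
            raise ValueError("combined route needs PolymerParams (with C2_r) "
                             "and a MechanicalState")
        Q = swelling_ratio(params.nu2_r, params.nu2_s)
        mc = mc_from_mechanics_swelling(mech.G, Q, mech.T, params.C2_r,
                                        params.Mn_bar)
        return mesh_size_from_mc(mc, params, "combined")
    raise ValueError(f"unknown method {method!r}")
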