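"""Membrane transport mechanisms of the duct epithelium.

Every mechanism is expressed as a per-unit-area molar flux law.  Channels
(ENaC, CFTR, CaCC, Maxi-K, basolateral K) use the Goldman–Hodgkin–Katz
current form.  The NaK-ATPase uses a saturating 3:2 kinetic form.  The
electroneutral carriers (NHE, AE) and the electrogenic Na⁺–2HCO₃⁻
cotransporter (NBC) use thermodynamically consistent saturating rate laws
that vanish exactly at electrochemical equilibrium.  Water crosses
aquaporin-bearing membranes proportionally to the osmotic gradient, and the
tight junction passes Na⁺, K⁺ and Cl⁻ with GHK kinetics driven by the
transepithelial potential.

Sign conventions
----------------
All species fluxes are reported positive *into the outside compartment*
(i.e. out of the cell for membrane mechanisms, lumen → interstitium for the
paracellular pathway).  ``FluxResult.current`` is the carried charge
current, ``F · Σ z_N · flux_N``, in the same direction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .constants import FARADAY, IDX, KA_BUFFER, RT_F, SPECIES, Z, ion_vector, ph_to_conc

__all__ = [
    "MembraneEnvironment",
    "FluxResult",
    "CellTypeParams",
    "KineticConstants",
    "BathParams",
    "BufferParams",
    "TransporterParams",
    "default_params",
    "load_params",
    "save_params",
    "nernst",
    "ghk_flux",
    "channel_flux",
    "nak_atpase_flux",
    "nhe_flux",
    "ae_flux",
    "nbc_flux",
    "exchanger_fluxes",
    "water_flux",
    "paracellular_flux",
    "buffer_rate",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class CellTypeParams:
    """Transport coefficients of one duct cell type (per µm² of membrane).

    Channel permeabilities are in nm/s, carrier rate coefficients in
    zmol s⁻¹ µm⁻², the pump density in zmol s⁻¹ µm⁻² (cycles), water
    permeabilities in µm³ s⁻¹ µm⁻² mM⁻¹ and tight-junction permeabilities
    in nm/s per µm² of apical membrane.
    """

    # apical
    p_enac: float = 0.0
    p_cftr: float = 0.0
    p_cacc: float = 0.0
    p_maxik: float = 0.0
    g_nhe_a: float = 0.0
    g_ae_a: float = 0.0
    g_nbc_a: float = 0.0
    lp_aqp_a: float = 0.0
    # basolateral
    r_nak: float = 0.0
    p_k_b: float = 0.0
    g_nhe_b: float = 0.0
    g_ae_b: float = 0.0
    g_nbc_b: float = 0.0
    lp_aqp_b: float = 0.0
    # tight junction (per µm² apical membrane)
    p_tj_na: float = 0.0
    p_tj_k: float = 0.0
    p_tj_cl: float = 0.0
    # fixed intracellular impermeant osmolyte concentration at the resting
    # volume; the impermeant *amount* of a cell is this value times its
    # resting volume and stays constant thereafter.
    impermeant_mm: float = 90.0
    # intracellular carbonic-anhydrase-assisted buffer rate, s⁻¹
    k_buffer: float = 1.0

    def scaled(self, factor: float) -> "CellTypeParams":
        """All transport coefficients multiplied by ``factor``.

        Used for the global time-scaling of transport rates; impermeant
        content and equilibria are untouched.
        """
        out = copy.copy(self)
        for name in (
            "p_enac", "p_cftr", "p_cacc", "p_maxik", "g_nhe_a", "g_ae_a",
            "g_nbc_a", "lp_aqp_a", "r_nak", "p_k_b", "g_nhe_b", "g_ae_b",
            "g_nbc_b", "lp_aqp_b", "p_tj_na", "p_tj_k", "p_tj_cl",
            "k_buffer",
        ):
            setattr(out, name, getattr(out, name) * factor)
        return out


@dataclass
class KineticConstants:
    """Half-saturation constants of the carriers and the pump (mM)."""

    nak_km_na: float = 40.0
    nak_km_k: float = 1.5
    #: ENaC self-inhibition by luminal Na⁺: the open probability scales as
    #: km/(km + [Na]_L), making absorption quasi-zeroth-order over most of
    #: the duct (measured ENaC saturates at a few tens of mM).
    enac_km_na: float = 15.0
    nhe_km_na: float = 15.0
    nhe_km_h: float = 10.0 ** (-4.2)   # pK 7.2, in mM
    ae_km_cl: float = 30.0
    ae_km_hco3: float = 10.0
    nbc_km_na: float = 30.0
    nbc_km_hco3: float = 10.0
    #: Na⁺ : HCO3⁻ coupling of the NBC per membrane.  1:2 (net charge −1)
    #: favours uptake; the basolateral 1:3 form (net −2, the renal NBCe1
    #: stoichiometry) runs outward at physiological potentials and gives
    #: the cell a self-limiting bicarbonate exit.
    nbc_n_apical: float = 2.0
    nbc_n_basolateral: float = 3.0
    #: HCO3⁻:Cl⁻ permeability ratio of the anion channels (CFTR, CaCC).
    p_hco3_ratio: float = 0.3


@dataclass
class BathParams:
    """The fixed interstitial reservoir bathing all basolateral membranes."""

    na: float = 140.0
    k: float = 5.0
    cl: float = 110.0
    hco3: float = 25.0
    ph: float = 7.4
    #: non-ionic osmolytes (glucose, proteins ...), mM
    impermeant_mm: float = 13.7

    def concentrations(self) -> np.ndarray:
        return ion_vector(self.na, self.k, self.cl, self.hco3,
                          ph_to_conc(self.ph))

    def osmolarity(self) -> float:
        return float(self.concentrations().sum() + self.impermeant_mm)


@dataclass
class BufferParams:
    """CO2/HCO3 buffering: dissolved CO2 per compartment and the luminal
    hydration rate constant k_p."""

    ka: float = KA_BUFFER
    co2_cell: float = 1.2      # mM, equilibrated with tissue pCO2
    co2_interstitium: float = 1.2
    #: Dissolved CO2 assumed for the luminal compartment.  Final saliva is
    #: substantially CO2-depleted relative to plasma, which is what permits
    #: its alkaline pH at modest bicarbonate levels.
    co2_lumen: float = 0.10
    k_lumen: float = 0.1056    # s⁻¹


@dataclass
class TransporterParams:
    """Full parameter set: one block per cell type plus shared constants."""

    cells: dict = field(default_factory=dict)   # {"ID": CellTypeParams, "SD": ...}
    kinetics: KineticConstants = field(default_factory=KineticConstants)
    bath: BathParams = field(default_factory=BathParams)
    buffer: BufferParams = field(default_factory=BufferParams)
    #: Global factor applied to every transport coefficient and buffer rate.
    #: Scaling it by s while scaling time by 1/s leaves steady states fixed.
    time_scale: float = 1.0

    def cell_params(self, cell_type: str) -> CellTypeParams:
        p = self.cells[cell_type]
        if self.time_scale != 1.0:
            p = p.scaled(self.time_scale)
        return p

    def k_lumen_effective(self) -> float:
        return self.buffer.k_lumen * self.time_scale


def default_params() -> TransporterParams:
    """Calibrated parameter set for the mouse parotid duct.

    The striated duct absorbs Na⁺ (ENaC + NaK-ATPase), secretes K⁺
    (Maxi-K) and reabsorbs Cl⁻ mostly paracellularly; it is apically
    water-tight.  The intercalated duct carries CaCC and apical AQP5, no
    ENaC, and secretes a small amount of water.  Coefficients were fitted
    by hand against measured mouse final-saliva composition at basal flow.
    """
    sd = CellTypeParams(
        p_enac=1.8,
        p_cftr=0.12,
        p_cacc=0.0,
        p_maxik=0.75,
        g_nhe_a=2.0,
        g_ae_a=4.0,
        g_nbc_a=16.0,
        lp_aqp_a=0.0,
        r_nak=85.0,
        p_k_b=0.16,
        g_nhe_b=0.7,
        g_ae_b=5.0,
        g_nbc_b=30.0,
        lp_aqp_b=0.02,
        p_tj_na=0.005,
        p_tj_k=0.007,
        p_tj_cl=0.12,
        impermeant_mm=92.0,
        k_buffer=0.45,
    )
    iden = CellTypeParams(
        p_enac=0.0,
        p_cftr=0.0,
        p_cacc=0.06,
        p_maxik=0.003,
        g_nhe_a=1.0,
        g_ae_a=0.0,
        g_nbc_a=0.0,
        lp_aqp_a=0.00035,
        r_nak=18.0,
        p_k_b=0.25,
        g_nhe_b=4.5,
        g_ae_b=5.8,
        g_nbc_b=4.4,
        lp_aqp_b=0.02,
        p_tj_na=0.05,
        p_tj_k=0.05,
        p_tj_cl=0.1,
        impermeant_mm=113.5,
        k_buffer=2.5,
    )
    return TransporterParams(cells={"ID": iden, "SD": sd})


def save_params(params: TransporterParams, path) -> None:
    """Write a parameter set to a YAML file."""
    doc = {
        "cells": {name: asdict(p) for name, p in params.cells.items()},
        "kinetics": asdict(params.kinetics),
        "bath": asdict(params.bath),
        "buffer": asdict(params.buffer),
        "time_scale": params.time_scale,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path) -> TransporterParams:
    """Read a parameter set from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return TransporterParams(
        cells={name: CellTypeParams(**blk) for name, blk in doc["cells"].items()},
        kinetics=KineticConstants(**doc.get("kinetics", {})),
        bath=BathParams(**doc.get("bath", {})),
        buffer=BufferParams(**doc.get("buffer", {})),
        time_scale=doc.get("time_scale", 1.0),
    )


# ---------------------------------------------------------------------------
# Flux primitives
# ---------------------------------------------------------------------------

@dataclass
class MembraneEnvironment:
    """Concentrations and potential across one membrane patch.

    ``v`` is the potential of the inside relative to the outside, mV.
    """

    inside: np.ndarray
    outside: np.ndarray
    v: float = 0.0
    area: float = 1.0
    temperature: float = 310.0


@dataclass
class FluxResult:
    """Per-species molar fluxes (zmol/s, positive into the outside
    compartment), osmotic water flux (µm³/s) and carried charge current."""

    fluxes: np.ndarray
    water: float = 0.0
    current: float = None

    def __post_init__(self):
        if self.current is None:
            self.current = FARADAY * float(np.dot(Z, self.fluxes))

    def __add__(self, other: "FluxResult") -> "FluxResult":
        return FluxResult(self.fluxes + other.fluxes, self.water + other.water)


def nernst(inside, outside, z) -> float:
    """Nernst equilibrium potential (mV) of a species across a membrane."""
    inside = np.asarray(inside, dtype=float)
    outside = np.asarray(outside, dtype=float)
    if np.any(inside <= 0) or np.any(outside <= 0):
        raise ValueError("Nernst potential requires positive concentrations")
    return RT_F / z * np.log(outside / inside)


def ghk_flux(p, z, c_in, c_out, v):
    """GHK flux density out of the inside compartment, zmol s⁻¹ µm⁻².

    ``p`` is the permeability in nm/s, ``v`` the inside-minus-outside
    potential in mV.  Vectorises over any argument.
    """
    phi = z * np.asarray(v, dtype=float) / RT_F
    small = np.abs(phi) < 1e-8
    phi_safe = np.where(small, 1.0, phi)
    denom = -np.expm1(-phi_safe)
    full = phi_safe * (c_in - c_out * np.exp(-phi_safe)) / denom
    # second-order accurate small-phi expansion of the same expression
    lin = (c_in - c_out) + phi * (c_in + c_out) / 2.0
    return p * np.where(small, lin, full)


_CHANNEL_SPECIES = {
    "Na": ("Na",),
    "K": ("K",),
    "Cl": ("Cl", "HCO3"),
}


def channel_flux(env: MembraneEnvironment, conductance, species,
                 p_hco3_ratio: float = 0.0) -> FluxResult:
    """Flux through a GHK channel selective for ``species``.

    ``species`` is the primary permeant ion ("Na", "K" or "Cl"); anion
    channels additionally pass HCO3⁻ at ``p_hco3_ratio`` times the Cl⁻
    permeability (CFTR and CaCC share this behaviour).
    """
    if conductance < 0:
        raise ValueError("channel permeability must be non-negative")
    if species not in _CHANNEL_SPECIES:
        raise ValueError(f"unknown channel species {species!r}")
    fluxes = np.zeros(len(SPECIES))
    perms = {species: conductance}
    if species == "Cl" and p_hco3_ratio:
        perms["HCO3"] = conductance * p_hco3_ratio
    for name, p in perms.items():
        i = IDX[name]
        fluxes[i] = env.area * ghk_flux(p, Z[i], env.inside[i],
                                        env.outside[i], env.v)
    return FluxResult(fluxes)


def nak_atpase_flux(env: MembraneEnvironment, density,
                    km_na: float = 11.0, km_k: float = 1.5) -> FluxResult:
    """3 Na⁺ out : 2 K⁺ in pump, saturating in internal Na⁺ and external K⁺."""
    if density < 0:
        raise ValueError("pump density must be non-negative")
    na_i = env.inside[IDX["Na"]]
    k_o = env.outside[IDX["K"]]
    rate = density * env.area * (na_i / (na_i + km_na)) ** 3 \
        * (k_o / (k_o + km_k)) ** 2
    fluxes = np.zeros(len(SPECIES))
    fluxes[IDX["Na"]] = 3.0 * rate
    fluxes[IDX["K"]] = -2.0 * rate
    return FluxResult(fluxes)


def _nhe_rate(g, na_i, h_i, na_o, h_o, km_na, km_h):
    """Saturating Na⁺/H⁺ exchange rate, positive = Na⁺ in / H⁺ out."""
    num = na_o * h_i - na_i * h_o
    den = (na_o + km_na) * (h_i + km_h) + (na_i + km_na) * (h_o + km_h)
    return g * num / den


def _ae_rate(g, cl_i, b_i, cl_o, b_o, km_cl, km_b):
    """Saturating Cl⁻/HCO3⁻ exchange rate, positive = Cl⁻ in / HCO3⁻ out."""
    num = cl_o * b_i - cl_i * b_o
    den = (cl_o + km_cl) * (b_i + km_b) + (cl_i + km_cl) * (b_o + km_b)
    return g * num / den


def _nbc_rate(g, na_i, b_i, na_o, b_o, v, km_na, km_b, n=2.0):
    """Electrogenic 1 Na⁺ : n HCO3⁻ cotransport, positive = inward.

    Carries net charge 1−n inward per translocation; the membrane
    potential enters through a symmetric Eyring factor so the rate
    vanishes exactly at electrochemical equilibrium.
    """
    z = 1.0 - n
    phi = np.asarray(v, dtype=float) / RT_F
    e = np.exp(np.clip(-z * phi / 2.0, -50, 50))
    num = na_o * b_o ** n * e - na_i * b_i ** n / e
    den = (na_o + km_na) * (b_o + km_b) ** n + (na_i + km_na) * (b_i + km_b) ** n
    return g * num / den


def nhe_flux(env: MembraneEnvironment, g, km_na=15.0, km_h=10 ** -4.2) -> FluxResult:
    """Electroneutral Na⁺/H⁺ exchanger (1:1)."""
    r = env.area * _nhe_rate(g, env.inside[IDX["Na"]], env.inside[IDX["H"]],
                             env.outside[IDX["Na"]], env.outside[IDX["H"]],
                             km_na, km_h)
    fluxes = np.zeros(len(SPECIES))
    fluxes[IDX["Na"]] = -r
    fluxes[IDX["H"]] = r
    return FluxResult(fluxes)


def ae_flux(env: MembraneEnvironment, g, km_cl=30.0, km_b=10.0) -> FluxResult:
    """Electroneutral Cl⁻/HCO3⁻ anion exchanger (1:1)."""
    r = env.area * _ae_rate(g, env.inside[IDX["Cl"]], env.inside[IDX["HCO3"]],
                            env.outside[IDX["Cl"]], env.outside[IDX["HCO3"]],
                            km_cl, km_b)
    fluxes = np.zeros(len(SPECIES))
    fluxes[IDX["Cl"]] = -r
    fluxes[IDX["HCO3"]] = r
    return FluxResult(fluxes)


def nbc_flux(env: MembraneEnvironment, g, km_na=30.0, km_b=10.0,
             n: float = 2.0) -> FluxResult:
    """Electrogenic Na⁺–nHCO3⁻ cotransporter (net charge 1−n)."""
    r = env.area * _nbc_rate(g, env.inside[IDX["Na"]], env.inside[IDX["HCO3"]],
                             env.outside[IDX["Na"]], env.outside[IDX["HCO3"]],
                             env.v, km_na, km_b, n)
    fluxes = np.zeros(len(SPECIES))
    fluxes[IDX["Na"]] = -r
    fluxes[IDX["HCO3"]] = -n * r
    return FluxResult(fluxes)


def exchanger_fluxes(env: MembraneEnvironment, densities: dict,
                     kinetics: KineticConstants | None = None) -> FluxResult:
    """Combined NHE + AE + NBC flux for one membrane.

    ``densities`` maps any of {"nhe", "ae", "nbc"} to a rate coefficient.
    """
    kin = kinetics or KineticConstants()
    for name, g in densities.items():
        if g < 0:
            raise ValueError("carrier densities must be non-negative")
        if name not in ("nhe", "ae", "nbc"):
            raise ValueError(f"unknown carrier {name!r}")
    total = FluxResult(np.zeros(len(SPECIES)))
    if densities.get("nhe"):
        total = total + nhe_flux(env, densities["nhe"],
                                 kin.nhe_km_na, kin.nhe_km_h)
    if densities.get("ae"):
        total = total + ae_flux(env, densities["ae"],
                                kin.ae_km_cl, kin.ae_km_hco3)
    if densities.get("nbc"):
        total = total + nbc_flux(env, densities["nbc"],
                                 kin.nbc_km_na, kin.nbc_km_hco3,
                                 kin.nbc_n_apical)
    return total


def water_flux(osm_inside, osm_outside, permeability, area):
    """Osmotic water flux, µm³/s, positive = water leaves the cell."""
    if permeability < 0 or np.any(np.asarray(area) < 0):
        raise ValueError("water permeability and area must be non-negative")
    return permeability * area * (np.asarray(osm_outside) - np.asarray(osm_inside))


def paracellular_flux(lumen: np.ndarray, interstitium: np.ndarray, v_te,
                      tj_permeabilities: dict, area: float = 1.0) -> FluxResult:
    """Tight-junction GHK flux, lumen → interstitium positive.

    ``v_te`` is the transepithelial potential V_A − V_B (interstitium minus
    lumen); only Na⁺, K⁺ and Cl⁻ may have nonzero permeability.
    """
    fluxes = np.zeros(len(SPECIES))
    for name, p in tj_permeabilities.items():
        if name not in ("Na", "K", "Cl"):
            if p:
                raise ValueError(
                    f"tight junction is impermeable to {name}")
            continue
        if p < 0:
            raise ValueError("tight-junction permeability must be non-negative")
        i = IDX[name]
        # potential of the lumen relative to the interstitium is −v_te
        fluxes[i] = area * ghk_flux(p, Z[i], lumen[i], interstitium[i], -v_te)
    return FluxResult(fluxes)


def buffer_rate(conc: np.ndarray, k: float, co2: float,
                ka: float = KA_BUFFER) -> np.ndarray:
    """Mass-action CO2 hydration source terms, mM/s per species.

    R = k (CO2 − [H][HCO3]/Ka); H⁺ and HCO3⁻ receive equal rates.
    """
    if k < 0:
        raise ValueError("buffer rate constant must be non-negative")
    r = k * (co2 - conc[..., IDX["H"]] * conc[..., IDX["HCO3"]] / ka)
    rates = np.zeros(np.shape(conc))
    rates[..., IDX["H"]] = r
    rates[..., IDX["HCO3"]] = r
    return rates
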