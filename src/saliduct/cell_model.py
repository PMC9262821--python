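"""Single duct-cell dynamics: ion balances, volume and membrane potentials.

A cell's state variables are the amounts (moles) of the five ion species
and the cell volume; concentrations are derived on demand, so conservation
under volume change is exact.  The apical and basolateral membrane
potentials are not state variables: membrane charging is far faster than
every other process, so the potentials are treated as algebraic
constraints and solved at every right-hand-side evaluation from the
requirement that no net charge accumulates in the cell or in its adjacent
lumen (the transcellular current returns through the tight junction).

This module is the readable single-cell reference implementation; the
simulator uses an equivalent vectorised path and is cross-checked against
it in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import SPECIES, conc_to_ph
from . import transporters as tr

__all__ = [
    "CellState",
    "CellEnvironment",
    "osmolarity",
    "cell_fluxes",
    "cell_rhs",
    "membrane_potentials",
    "PotentialSolveError",
]


class PotentialSolveError(RuntimeError):
    """Raised when the charge-balance constraint cannot be solved."""


@dataclass
class CellState:
    """One duct cell's instantaneous state."""

    concentrations: np.ndarray       # mM, SPECIES order
    volume: float                    # µm³
    v_a: float = -60.0               # apical membrane potential, mV (cell − lumen)
    v_b: float = -60.0               # basolateral potential, mV (cell − interstitium)
    cell_type: str = "SD"
    impermeant: float = 0.0          # fixed intracellular osmolyte amount, zmol

    @property
    def moles(self) -> np.ndarray:
        return self.concentrations * self.volume

    @property
    def ph(self) -> float:
        return float(conc_to_ph(self.concentrations[SPECIES.index("H")]))

    @property
    def transepithelial(self) -> float:
        """V_A − V_B: interstitium minus lumen potential."""
        return self.v_a - self.v_b

    def osmolarity(self) -> float:
        return osmolarity(self.concentrations, self.impermeant / self.volume)


@dataclass
class CellEnvironment:
    """What one cell sees: its apical strips and the interstitial bath."""

    strips: list                     # list[(segment id, area µm², conc array)]
    interstitium: np.ndarray         # mM
    basal_area: float
    bath_impermeant: float = 0.0     # mM, non-ionic interstitial osmolytes
    lumen_impermeant: float = 0.0    # mM, luminal protein


def osmolarity(conc, impermeant_mm: float = 0.0) -> float:
    """Total osmolarity: Σ species + impermeant, mM."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0) or impermeant_mm < 0:
        raise ValueError("osmolarity requires non-negative entries")
    return float(conc.sum() + impermeant_mm)


def cell_fluxes(state: CellState, env: CellEnvironment,
                params: tr.TransporterParams):
    """Evaluate every membrane mechanism at the cell's current potentials.

    Returns a dict of FluxResult keyed by mechanism, with apical
    mechanisms summed over strips.  Apical fluxes are positive into the
    lumen, basolateral fluxes positive into the interstitium and
    paracellular fluxes positive lumen → interstitium.
    """
    p = params.cell_params(state.cell_type)
    kin = params.kinetics
    conc = state.concentrations
    out = {}

    def zero():
        return tr.FluxResult(np.zeros(len(SPECIES)))

    apical = {
        "enac": zero(), "cftr": zero(), "cacc": zero(), "maxik": zero(),
        "nhe_a": zero(), "ae_a": zero(), "nbc_a": zero(),
    }
    para = zero()
    water_apical = 0.0
    osm_c = state.osmolarity()
    for _seg, area, lconc in env.strips:
        e = tr.MembraneEnvironment(conc, lconc, v=state.v_a, area=area)
        # ENaC self-inhibition by luminal Na
        p_enac = p.p_enac * kin.enac_km_na / (
            kin.enac_km_na + lconc[tr.IDX["Na"]])
        apical["enac"] = apical["enac"] + tr.channel_flux(e, p_enac, "Na")
        apical["cftr"] = apical["cftr"] + tr.channel_flux(
            e, p.p_cftr, "Cl", kin.p_hco3_ratio)
        apical["cacc"] = apical["cacc"] + tr.channel_flux(
            e, p.p_cacc, "Cl", kin.p_hco3_ratio)
        apical["maxik"] = apical["maxik"] + tr.channel_flux(e, p.p_maxik, "K")
        apical["nhe_a"] = apical["nhe_a"] + tr.nhe_flux(
            e, p.g_nhe_a, kin.nhe_km_na, kin.nhe_km_h)
        apical["ae_a"] = apical["ae_a"] + tr.ae_flux(
            e, p.g_ae_a, kin.ae_km_cl, kin.ae_km_hco3)
        apical["nbc_a"] = apical["nbc_a"] + tr.nbc_flux(
            e, p.g_nbc_a, kin.nbc_km_na, kin.nbc_km_hco3, kin.nbc_n_apical)
        osm_l = osmolarity(lconc, env.lumen_impermeant)
        water_apical += tr.water_flux(osm_c, osm_l, p.lp_aqp_a, area)
        para = para + tr.paracellular_flux(
            lconc, env.interstitium, state.transepithelial,
            {"Na": p.p_tj_na, "K": p.p_tj_k, "Cl": p.p_tj_cl}, area)
    out.update(apical)
    out["paracellular"] = para

    eb = tr.MembraneEnvironment(conc, env.interstitium, v=state.v_b,
                                area=env.basal_area)
    out["nak"] = tr.nak_atpase_flux(eb, p.r_nak, kin.nak_km_na, kin.nak_km_k)
    out["k_b"] = tr.channel_flux(eb, p.p_k_b, "K")
    out["nhe_b"] = tr.nhe_flux(eb, p.g_nhe_b, kin.nhe_km_na, kin.nhe_km_h)
    out["ae_b"] = tr.ae_flux(eb, p.g_ae_b, kin.ae_km_cl, kin.ae_km_hco3)
    out["nbc_b"] = tr.nbc_flux(eb, p.g_nbc_b, kin.nbc_km_na,
                               kin.nbc_km_hco3, kin.nbc_n_basolateral)

    osm_i = osmolarity(env.interstitium, env.bath_impermeant)
    water_basal = tr.water_flux(osm_c, osm_i, p.lp_aqp_b, env.basal_area)
    out["water"] = tr.FluxResult(np.zeros(len(SPECIES)),
                                 water=water_apical + water_basal)
    out["water"].water_apical = water_apical
    out["water"].water_basal = water_basal
    return out


_APICAL = ("enac", "cftr", "cacc", "maxik", "nhe_a", "ae_a", "nbc_a")
_BASOLATERAL = ("nak", "k_b", "nhe_b", "ae_b", "nbc_b")


def cell_rhs(state: CellState, env: CellEnvironment,
             params: tr.TransporterParams):
    """Time derivatives of the cell's ion amounts (zmol/s) and volume (µm³/s).

    The potentials stored in ``state`` are used as-is; solve them first
    with :func:`membrane_potentials`.
    """
    fx = cell_fluxes(state, env, params)
    dmoles = np.zeros(len(SPECIES))
    for name in _APICAL + _BASOLATERAL:
        dmoles -= fx[name].fluxes          # positive mechanism flux leaves the cell
    p = params.cell_params(state.cell_type)
    dmoles += tr.buffer_rate(state.concentrations, p.k_buffer,
                             params.buffer.co2_cell,
                             params.buffer.ka) * state.volume
    dvolume = -fx["water"].water
    return dmoles, dvolume


def _currents(state: CellState, env: CellEnvironment,
              params: tr.TransporterParams):
    """(apical, basolateral, paracellular) currents at the stored potentials."""
    fx = cell_fluxes(state, env, params)
    i_a = sum(fx[m].current for m in _APICAL)
    i_b = sum(fx[m].current for m in _BASOLATERAL)
    i_p = fx["paracellular"].current
    return i_a, i_b, i_p


def membrane_potentials(state: CellState, env: CellEnvironment,
                        params: tr.TransporterParams,
                        v_init=None, tol: float = 1e-12,
                        max_iter: int = 100):
    """Solve the quasi-steady charge-balance constraint for (V_A, V_B).

    Constraints: the net current out of the cell vanishes (apical +
    basolateral), and the transcellular current into the lumen returns
    through the tight junction.  A damped Newton iteration on
    (V_cell, V_lumen) relative to the grounded interstitium; raises
    :class:`PotentialSolveError` if the system is degenerate or no
    solution exists in the ±150 mV bracket.
    """
    p = params.cell_params(state.cell_type)
    electro = (p.p_enac + p.p_cftr + p.p_cacc + p.p_maxik + p.g_nbc_a
               + p.r_nak + p.p_k_b + p.g_nbc_b)
    if electro == 0:
        raise PotentialSolveError(
            "all electrogenic conductances are zero; potentials undefined")

    if v_init is None:
        v_c, v_l = -60.0, -5.0
    else:
        v_c, v_l = v_init

    def residual(v_c, v_l):
        state.v_a = v_c - v_l
        state.v_b = v_c
        i_a, i_b, i_p = _currents(state, env, params)
        # cell charge balance and lumen charge balance
        return np.array([i_a + i_b, i_a - i_p]), max(
            abs(i_a), abs(i_b), abs(i_p), 1e-30)

    stall, best = 0, np.inf
    scale_ref = 0.0              # largest current seen; a solution where
    for _ in range(max_iter):    # every current vanishes is judged by it
        f, scale = residual(v_c, v_l)
        scale_ref = max(scale_ref, scale)
        err = np.max(np.abs(f)) / scale_ref
        # accept either full convergence or a round-off-limited stall
        stall = stall + 1 if err > 0.5 * best else 0
        best = min(best, err)
        if err <= tol or (stall >= 4 and err <= 1e-9):
            state.v_a, state.v_b = v_c - v_l, v_c
            return state.v_a, state.v_b
        h = 1e-3
        f_c, _ = residual(v_c + h, v_l)
        f_l, _ = residual(v_c, v_l + h)
        jac = np.column_stack([(f_c - f) / h, (f_l - f) / h])
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError as exc:
            raise PotentialSolveError(f"singular current Jacobian: {exc}")
        step = np.clip(step, -25.0, 25.0)
        v_c += step[0]
        v_l += step[1]
        if not (-150.0 <= v_c <= 150.0 and -150.0 <= v_l <= 150.0):
            raise PotentialSolveError(
                "no charge-balance root in the ±150 mV bracket; "
                f"state: conc={state.concentrations}, w={state.volume}, "
                f"v_c={v_c:.1f}, v_l={v_l:.1f}")
    raise PotentialSolveError(
        f"potential solve did not converge; residual {f} at "
        f"v_c={v_c:.2f}, v_l={v_l:.2f}")
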