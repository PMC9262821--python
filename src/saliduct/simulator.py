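"""Whole-duct simulation: cells + branched lumen as one stiff ODE system.

The state vector stacks, in order: per-cell ion amounts (zmol), per-cell
volumes (µm³) and per-segment luminal concentrations (mM).  Membrane
potentials are algebraic: at every right-hand-side evaluation a vectorised
damped-Newton solve finds, for every cell simultaneously, the cell and
local-lumen potentials at which (i) no net current leaves the cell and
(ii) the transcellular current returns through the tight junction.

Integration uses the BDF method with a hand-built Jacobian sparsity
pattern (cells couple to their apical segments; segments couple to their
parents and, through the quasi-steady water flow, to every upstream
water-secreting cell).
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .constants import FARADAY, IDX, SPECIES, Z, conc_to_ph
from . import transporters as tr
from .transporters import TransporterParams, default_params
from .geometry import (CellGeometry, DuctGeometry, LumenSegment,
                       SpatialStats, generate_synthetic_duct)
from .lumen_model import LumenNetwork
from .primary_saliva import PrimarySaliva, unstimulated_composition
from .cell_model import PotentialSolveError

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "DuctSystem",
    "build_geometry",
    "run_to_steady_state",
    "run_stimulation",
    "flow_sweep",
    "build_simplified",
    "simplify_geometry",
]

_NS = len(SPECIES)
_EPS = 1e-12


# ---------------------------------------------------------------------------
# Configuration and results
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Everything needed to run one duct simulation."""

    geometry: DuctGeometry
    params: TransporterParams = field(default_factory=default_params)
    boundary: PrimarySaliva = field(default_factory=unstimulated_composition)
    atol: float = 1e-10
    rtol: float = 1e-9
    t_end: float = 20000.0
    dt_out: float = 100.0
    mode: str = "full"               # "full" | "simplified"

    def __post_init__(self):
        if self.atol <= 0 or self.rtol <= 0:
            raise ValueError("solver tolerances must be positive")
        if self.t_end <= 0:
            raise ValueError("end time must be positive")


@dataclass
class SimulationResult:
    """Time series of a duct simulation."""

    time: np.ndarray
    cell_conc: np.ndarray            # (nt, ncell, 5) mM
    cell_volume: np.ndarray          # (nt, ncell)
    cell_va: np.ndarray              # (nt, ncell) mV
    cell_vb: np.ndarray
    lumen_conc: np.ndarray           # (nt, nseg, 5)
    flow: np.ndarray                 # (nt, nseg) µm³/s
    outlet_conc: np.ndarray          # (nt, 5)
    outlet_flow: np.ndarray          # (nt,)
    steady: bool
    system: "DuctSystem"
    y_final: np.ndarray
    wall_time: float = 0.0

    @property
    def final_saliva(self) -> dict:
        """Outlet ('final saliva') composition at the last output time."""
        c = self.outlet_conc[-1]
        return {
            "Na": c[IDX["Na"]], "K": c[IDX["K"]], "Cl": c[IDX["Cl"]],
            "HCO3": c[IDX["HCO3"]], "pH": float(conc_to_ph(c[IDX["H"]])),
            "flow": float(self.outlet_flow[-1]),
        }

    def transepithelial(self, t_index: int = -1) -> np.ndarray:
        """Per-cell V_A − V_B at an output time."""
        return self.cell_va[t_index] - self.cell_vb[t_index]

    def profile_frame(self):
        """Final-time spatial profile as a pandas DataFrame."""
        import pandas as pd
        sys = self.system
        return pd.DataFrame({
            "x": sys.net.x,
            "duct_type": sys.net.duct_type,
            "flow": self.flow[-1],
            **{name: self.lumen_conc[-1, :, i]
               for i, name in enumerate(SPECIES)},
        })


# ---------------------------------------------------------------------------
# Geometry helper
# ---------------------------------------------------------------------------

def build_geometry(stats: SpatialStats | None = None, n_acini: int = 4,
                   seed: int = 0, dx: float = 1.0) -> DuctGeometry:
    """Synthetic duct geometry in canonical simulator form."""
    from .geometry import discretise_centreline
    tree, cells = generate_synthetic_duct(stats, n_acini, seed, dx)
    segments = discretise_centreline(tree, dx)
    return DuctGeometry(segments=segments, cells=cells)


# ---------------------------------------------------------------------------
# The assembled ODE system
# ---------------------------------------------------------------------------

class DuctSystem:
    """Vectorised duct model over a fixed geometry and parameter set."""

    def __init__(self, geom: DuctGeometry, params: TransporterParams,
                 boundary: PrimarySaliva):
        self.geom = geom
        self.params = params
        self.boundary = boundary
        self.net = LumenNetwork(geom)
        cells = geom.cells
        self.n_cell = len(cells)
        self.n_seg = self.net.n
        self.ny = self.n_cell * (_NS + 1) + self.n_seg * _NS

        self.ab = np.array([c.basal_area for c in cells])
        self.aa = np.array([c.apical_area for c in cells])
        self.w0 = np.array([c.volume for c in cells])
        self.cell_type = np.array([c.cell_type for c in cells])

        # per-cell transport coefficients (time scaling folded in)
        names = ("p_enac", "p_cftr", "p_cacc", "p_maxik", "g_nhe_a",
                 "g_ae_a", "g_nbc_a", "lp_aqp_a", "r_nak", "p_k_b",
                 "g_nhe_b", "g_ae_b", "g_nbc_b", "lp_aqp_b", "p_tj_na",
                 "p_tj_k", "p_tj_cl", "impermeant_mm", "k_buffer")
        per_type = {t: params.cell_params(t) for t in set(self.cell_type)}
        for name in names:
            vals = np.array([getattr(per_type[t], name) for t in self.cell_type])
            setattr(self, name, vals)
        self.impermeant = self.impermeant_mm * self.w0      # zmol, fixed

        # strips
        sc, ss, sa = [], [], []
        for c in cells:
            for seg, area in c.strips:
                sc.append(c.index)
                ss.append(seg)
                sa.append(area)
        self.strip_cell = np.array(sc, dtype=int)
        self.strip_seg = np.array(ss, dtype=int)
        self.strip_area = np.array(sa)
        self.n_strip = len(sa)

        kin = params.kinetics
        self.kin = kin
        self.bath_conc = params.bath.concentrations()
        self.bath_osm = params.bath.osmolarity()
        self.buffer = params.buffer
        self.k_lumen = params.k_lumen_effective()

        self.q_leaf_weight = np.zeros(self.n_seg)
        for s in geom.segments:
            if s.is_leaf:
                self.q_leaf_weight[s.index] = getattr(s, "inflow_weight", 1.0)

        # warm-start cache for the potential solve
        self._v_c = np.full(self.n_cell, -60.0)
        self._v_l = np.full(self.n_cell, -5.0)
        electro = (self.p_enac + self.p_cftr + self.p_cacc + self.p_maxik
                   + self.g_nbc_a + self.r_nak + self.p_k_b + self.g_nbc_b
                   + self.p_tj_na + self.p_tj_k + self.p_tj_cl)
        self.inert = electro == 0.0

    # -- state packing ----------------------------------------------------

    #: cold-start intracellular guess: a generic polarised epithelial cell.
    #: Starting cells at the interstitial composition instead puts K⁺ at its
    #: equilibrium across the K channels and can trap the solution in a
    #: depolarised, pump-defeated fixed point.
    INIT_CELL = np.array([25.0, 120.0, 40.0, 12.0, 5.0e-5])

    def initial_state(self) -> np.ndarray:
        """Cold start: polarised cells, lumen at primary saliva."""
        conc_c = np.tile(self.INIT_CELL, (self.n_cell, 1))
        w = self.w0.copy()
        conc_l = np.tile(self.boundary.composition, (self.n_seg, 1))
        return self.pack(conc_c * w[:, None], w, conc_l)

    def pack(self, moles, w, conc_l) -> np.ndarray:
        return np.concatenate([np.ravel(moles), np.ravel(w), np.ravel(conc_l)])

    def unpack(self, y):
        nc = self.n_cell
        moles = y[: nc * _NS].reshape(nc, _NS)
        w = y[nc * _NS: nc * (_NS + 1)]
        conc_l = y[nc * (_NS + 1):].reshape(self.n_seg, _NS)
        return moles, w, conc_l

    def atol_vector(self, atol: float) -> np.ndarray:
        """Absolute tolerances scaled to 1 mM worth of each state."""
        scale = np.concatenate([
            np.repeat(self.w0, _NS), self.w0, np.ones(self.n_seg * _NS)])
        return atol * scale

    # -- membrane rate evaluation -----------------------------------------

    def _rates(self, conc_c, conc_l, v_c, v_l):
        """All membrane fluxes at given potentials.

        Returns a dict with per-strip fluxes into the lumen, per-strip
        paracellular fluxes (lumen → interstitium), per-cell basolateral
        fluxes into the interstitium, water fluxes, and the three per-cell
        currents used by the charge-balance solve.
        """
        kin = self.kin
        sc, ssg = self.strip_cell, self.strip_seg
        area = self.strip_area
        cc = np.maximum(conc_c, _EPS)
        cl = np.maximum(conc_l, _EPS)
        ccs = cc[sc]                     # per-strip cell concentrations
        cls = cl[ssg]                    # per-strip lumen concentrations
        v_a = (v_c - v_l)[sc]

        into_lumen = np.zeros((self.n_strip, _NS))
        # channels (GHK), flux out of cell = into lumen; ENaC open
        # probability is reduced by luminal Na (self-inhibition)
        p_enac_eff = self.p_enac[sc] * kin.enac_km_na \
            / (kin.enac_km_na + cls[:, IDX["Na"]])
        into_lumen[:, IDX["Na"]] += area * tr.ghk_flux(
            p_enac_eff, 1.0, ccs[:, IDX["Na"]], cls[:, IDX["Na"]], v_a)
        p_anion = self.p_cftr[sc] + self.p_cacc[sc]
        into_lumen[:, IDX["Cl"]] += area * tr.ghk_flux(
            p_anion, -1.0, ccs[:, IDX["Cl"]], cls[:, IDX["Cl"]], v_a)
        into_lumen[:, IDX["HCO3"]] += area * tr.ghk_flux(
            p_anion * kin.p_hco3_ratio, -1.0,
            ccs[:, IDX["HCO3"]], cls[:, IDX["HCO3"]], v_a)
        into_lumen[:, IDX["K"]] += area * tr.ghk_flux(
            self.p_maxik[sc], 1.0, ccs[:, IDX["K"]], cls[:, IDX["K"]], v_a)
        # apical carriers; rates positive into the cell
        r = area * tr._nhe_rate(self.g_nhe_a[sc],
                                ccs[:, IDX["Na"]], ccs[:, IDX["H"]],
                                cls[:, IDX["Na"]], cls[:, IDX["H"]],
                                kin.nhe_km_na, kin.nhe_km_h)
        into_lumen[:, IDX["Na"]] -= r
        into_lumen[:, IDX["H"]] += r
        r = area * tr._ae_rate(self.g_ae_a[sc],
                               ccs[:, IDX["Cl"]], ccs[:, IDX["HCO3"]],
                               cls[:, IDX["Cl"]], cls[:, IDX["HCO3"]],
                               kin.ae_km_cl, kin.ae_km_hco3)
        into_lumen[:, IDX["Cl"]] -= r
        into_lumen[:, IDX["HCO3"]] += r
        r = area * tr._nbc_rate(self.g_nbc_a[sc],
                                ccs[:, IDX["Na"]], ccs[:, IDX["HCO3"]],
                                cls[:, IDX["Na"]], cls[:, IDX["HCO3"]],
                                v_a, kin.nbc_km_na, kin.nbc_km_hco3,
                                kin.nbc_n_apical)
        into_lumen[:, IDX["Na"]] -= r
        into_lumen[:, IDX["HCO3"]] -= kin.nbc_n_apical * r

        # paracellular (lumen → interstitium), potential of lumen is v_l
        para = np.zeros((self.n_strip, _NS))
        for name, p in (("Na", self.p_tj_na), ("K", self.p_tj_k),
                        ("Cl", self.p_tj_cl)):
            i = IDX[name]
            para[:, i] = area * tr.ghk_flux(
                p[sc], Z[i], cls[:, i], self.bath_conc[i], v_l[sc])

        # basolateral, flux out of cell = into interstitium
        into_bath = np.zeros((self.n_cell, _NS))
        into_bath[:, IDX["K"]] += self.ab * tr.ghk_flux(
            self.p_k_b, 1.0, cc[:, IDX["K"]], self.bath_conc[IDX["K"]], v_c)
        na_i = cc[:, IDX["Na"]]
        pump = self.r_nak * self.ab \
            * (na_i / (na_i + kin.nak_km_na)) ** 3 \
            * (self.bath_conc[IDX["K"]]
               / (self.bath_conc[IDX["K"]] + kin.nak_km_k)) ** 2
        into_bath[:, IDX["Na"]] += 3.0 * pump
        into_bath[:, IDX["K"]] -= 2.0 * pump
        r = self.ab * tr._nhe_rate(self.g_nhe_b,
                                   cc[:, IDX["Na"]], cc[:, IDX["H"]],
                                   self.bath_conc[IDX["Na"]],
                                   self.bath_conc[IDX["H"]],
                                   kin.nhe_km_na, kin.nhe_km_h)
        into_bath[:, IDX["Na"]] -= r
        into_bath[:, IDX["H"]] += r
        r = self.ab * tr._ae_rate(self.g_ae_b,
                                  cc[:, IDX["Cl"]], cc[:, IDX["HCO3"]],
                                  self.bath_conc[IDX["Cl"]],
                                  self.bath_conc[IDX["HCO3"]],
                                  kin.ae_km_cl, kin.ae_km_hco3)
        into_bath[:, IDX["Cl"]] -= r
        into_bath[:, IDX["HCO3"]] += r
        r = self.ab * tr._nbc_rate(self.g_nbc_b,
                                   cc[:, IDX["Na"]], cc[:, IDX["HCO3"]],
                                   self.bath_conc[IDX["Na"]],
                                   self.bath_conc[IDX["HCO3"]],
                                   v_c, kin.nbc_km_na, kin.nbc_km_hco3,
                                   kin.nbc_n_basolateral)
        into_bath[:, IDX["Na"]] -= r
        into_bath[:, IDX["HCO3"]] -= kin.nbc_n_basolateral * r

        # currents
        i_a = np.zeros(self.n_cell)
        np.add.at(i_a, sc, FARADAY * (into_lumen @ Z))
        i_p = np.zeros(self.n_cell)
        np.add.at(i_p, sc, FARADAY * (para @ Z))
        i_b = FARADAY * (into_bath @ Z)
        return {
            "into_lumen": into_lumen, "para": para, "into_bath": into_bath,
            "i_a": i_a, "i_b": i_b, "i_p": i_p,
        }

    def _water(self, conc_c, w, conc_l):
        """Per-strip water into the lumen and per-cell water into the bath."""
        osm_c = np.maximum(conc_c, _EPS).sum(axis=1) + self.impermeant / w
        osm_l = (np.maximum(conc_l, _EPS).sum(axis=1)
                 + self.boundary.protein_mm)
        w_lumen = (self.lp_aqp_a[self.strip_cell] * self.strip_area
                   * (osm_l[self.strip_seg] - osm_c[self.strip_cell]))
        w_bath = self.lp_aqp_b * self.ab * (self.bath_osm - osm_c)
        return w_lumen, w_bath

    # -- charge-balance potentials ----------------------------------------

    def solve_potentials(self, conc_c, conc_l, tol=1e-13, max_iter=120):
        """Vectorised damped Newton for (V_cell, V_lumen) of every cell."""
        v_c = self._v_c.copy()
        v_l = self._v_l.copy()
        active = ~self.inert
        if not np.any(active):
            return v_c * 0.0, v_l * 0.0

        def res(v_c, v_l):
            rates = self._rates(conc_c, conc_l, v_c, v_l)
            f1 = rates["i_a"] + rates["i_b"]
            f2 = rates["i_a"] - rates["i_p"]
            scale = np.maximum.reduce([
                np.abs(rates["i_a"]), np.abs(rates["i_b"]),
                np.abs(rates["i_p"])])
            return f1, f2, np.maximum(scale, 1e-30)

        h = 1e-3
        stall = 0
        prev_err = np.inf
        scale_ref = np.zeros(self.n_cell)   # largest current seen per cell
        for it in range(max_iter):
            f1, f2, scale = res(v_c, v_l)
            scale_ref = np.maximum(scale_ref, scale)
            err = np.maximum(np.abs(f1), np.abs(f2)) / scale_ref
            worst = float(np.max(err[active]))
            if worst <= tol:
                break
            # accept a round-off-limited solution that has stopped improving
            stall = stall + 1 if worst > 0.5 * prev_err else 0
            prev_err = min(prev_err, worst)
            if stall >= 4 and worst <= 1e-9:
                break
            g1, g2, _ = res(v_c + h, v_l)
            k1, k2, _ = res(v_c, v_l + h)
            j11 = (g1 - f1) / h
            j12 = (k1 - f1) / h
            j21 = (g2 - f2) / h
            j22 = (k2 - f2) / h
            det = j11 * j22 - j12 * j21
            det = np.where(np.abs(det) < 1e-300, np.nan, det)
            dc = -(f1 * j22 - f2 * j12) / det
            dl = -(j11 * f2 - j21 * f1) / det
            dc = np.clip(np.nan_to_num(dc), -25.0, 25.0)
            dl = np.clip(np.nan_to_num(dl), -25.0, 25.0)
            v_c = np.where(active, v_c + dc, 0.0)
            v_l = np.where(active, v_l + dl, 0.0)
            if np.any(np.abs(v_c) > 200) or np.any(np.abs(v_l) > 200):
                raise PotentialSolveError(
                    "potential solve diverged beyond ±200 mV")
        else:
            bad = np.argmax(err)
            raise PotentialSolveError(
                f"charge balance not converged (cell {bad}, rel err "
                f"{err[bad]:.2e})")
        self._v_c, self._v_l = v_c, v_l
        return v_c, v_l

    # -- full right-hand side ---------------------------------------------

    def rhs(self, t, y):
        moles, w, conc_l = self.unpack(y)
        w = np.maximum(w, 1e-6)
        conc_c = moles / w[:, None]
        v_c, v_l = self.solve_potentials(conc_c, conc_l)
        rates = self._rates(conc_c, conc_l, v_c, v_l)
        w_lumen, w_bath = self._water(conc_c, w, conc_l)

        # cells
        dmoles = -rates["into_bath"]
        np.subtract.at(dmoles, self.strip_cell, rates["into_lumen"])
        # intracellular CO2 buffering (vectorised mass action)
        r_buf = self.k_buffer * (
            self.buffer.co2_cell
            - np.maximum(conc_c[:, IDX["H"]], _EPS)
            * np.maximum(conc_c[:, IDX["HCO3"]], _EPS) / self.buffer.ka)
        dmoles[:, IDX["H"]] += r_buf * w
        dmoles[:, IDX["HCO3"]] += r_buf * w
        dw = -(w_bath.copy())
        np.subtract.at(dw, self.strip_cell, w_lumen)

        # lumen
        j_sec = np.zeros((self.n_seg, _NS))
        np.add.at(j_sec, self.strip_seg,
                  rates["into_lumen"] - rates["para"])
        water_sec = np.zeros(self.n_seg)
        np.add.at(water_sec, self.strip_seg, w_lumen)
        q_leaf = self.q_leaf_weight * self.boundary.flow(t)
        v_out = self.net.update_flows(q_leaf, water_sec)
        dconc_l = self.net.rhs(conc_l, v_out, j_sec,
                               self.boundary.composition, q_leaf,
                               self.k_lumen, self.buffer.co2_lumen,
                               self.buffer.ka)
        return self.pack(dmoles, dw, dconc_l)

    def flows(self, t, y):
        """Instantaneous per-segment volumetric flow for a packed state."""
        moles, w, conc_l = self.unpack(y)
        w = np.maximum(w, 1e-6)
        conc_c = moles / w[:, None]
        w_lumen, _ = self._water(conc_c, w, conc_l)
        water_sec = np.zeros(self.n_seg)
        np.add.at(water_sec, self.strip_seg, w_lumen)
        q_leaf = self.q_leaf_weight * self.boundary.flow(t)
        return self.net.update_flows(q_leaf, water_sec)

    # -- Jacobian sparsity --------------------------------------------------

    def jac_sparsity(self) -> sparse.csr_matrix:
        nc, ns = self.n_cell, self.n_seg
        rows, cols = [], []

        def couple(r_idx, c_idx):
            r_idx = np.asarray(r_idx, dtype=int)
            c_idx = np.asarray(c_idx, dtype=int)
            rr, cc = np.meshgrid(r_idx, c_idx, indexing="ij")
            rows.append(rr.ravel())
            cols.append(cc.ravel())

        def cell_block(c):
            return np.concatenate([np.arange(c * _NS, (c + 1) * _NS),
                                   [nc * _NS + c]])

        def seg_block(s):
            base = nc * (_NS + 1)
            return np.arange(base + s * _NS, base + (s + 1) * _NS)

        strips_of_cell = {}
        for c, s in zip(self.strip_cell, self.strip_seg):
            strips_of_cell.setdefault(int(c), []).append(int(s))
        for c, segs in strips_of_cell.items():
            cb = cell_block(c)
            sb = np.concatenate([seg_block(s) for s in segs])
            local = np.concatenate([cb, sb])
            couple(local, local)

        # advection: segment <- parents (and itself)
        for s in self.geom.segments:
            sb = seg_block(s.index)
            couple(sb, sb)
            for up in s.upstream:
                couple(sb, seg_block(up))

        # quasi-steady flow: a segment's advection depends on every
        # upstream cell through its water flux
        upstream_cells = [set() for _ in range(ns)]
        cells_of_seg = {}
        for c, s in zip(self.strip_cell, self.strip_seg):
            cells_of_seg.setdefault(int(s), set()).add(int(c))
        for s in self.geom.segments:
            acc = set(cells_of_seg.get(s.index, ()))
            for up in s.upstream:
                acc |= upstream_cells[up]
            upstream_cells[s.index] = acc
            sb = seg_block(s.index)
            for c in acc:
                couple(sb, cell_block(c))

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        data = np.ones(len(rows), dtype=np.int8)
        m = sparse.coo_matrix((data, (rows, cols)),
                              shape=(self.ny, self.ny))
        m.sum_duplicates()
        return m.tocsr()


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def _integrate(system: DuctSystem, y0, t_span, config: SimulationConfig,
               dt_out=None):
    dt_out = dt_out or config.dt_out
    t_eval = np.arange(t_span[0], t_span[1] + 0.5 * dt_out, dt_out)
    sol = solve_ivp(system.rhs, t_span, y0, method="BDF",
                    t_eval=t_eval, rtol=config.rtol,
                    atol=system.atol_vector(config.atol),
                    jac_sparsity=system.jac_sparsity())
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return sol


def _collect(system: DuctSystem, sol, steady: bool,
             wall: float) -> SimulationResult:
    nt = len(sol.t)
    nc, ns = system.n_cell, system.n_seg
    cell_conc = np.empty((nt, nc, _NS))
    cell_volume = np.empty((nt, nc))
    cell_va = np.empty((nt, nc))
    cell_vb = np.empty((nt, nc))
    lumen_conc = np.empty((nt, ns, _NS))
    flow = np.empty((nt, ns))
    for k in range(nt):
        moles, w, conc_l = system.unpack(sol.y[:, k])
        w = np.maximum(w, 1e-6)
        conc_c = moles / w[:, None]
        cell_conc[k] = conc_c
        cell_volume[k] = w
        lumen_conc[k] = conc_l
        v_c, v_l = system.solve_potentials(conc_c, conc_l)
        cell_va[k] = v_c - v_l
        cell_vb[k] = v_c
        flow[k] = system.flows(sol.t[k], sol.y[:, k])
    outlet = system.net.n - 1
    return SimulationResult(
        time=sol.t, cell_conc=cell_conc, cell_volume=cell_volume,
        cell_va=cell_va, cell_vb=cell_vb, lumen_conc=lumen_conc, flow=flow,
        outlet_conc=lumen_conc[:, outlet, :], outlet_flow=flow[:, outlet],
        steady=steady, system=system, y_final=sol.y[:, -1], wall_time=wall)


def run_to_steady_state(config: SimulationConfig,
                        max_time: float = 60000.0) -> SimulationResult:
    """Integrate with constant inflow until the duct equilibrates.

    Runs to the configured horizon (default 20,000 s of model time) and
    extends in chunks if the relative state change still exceeds 1e-8/s.
    """
    boundary = replace(config.boundary, m=1.0)
    system = DuctSystem(config.geometry, config.params, boundary)
    t0 = _time.perf_counter()
    y = system.initial_state()
    t_end = config.t_end
    sol = _integrate(system, y, (0.0, t_end), config)
    while True:
        resid = _steady_residual(system, sol.y[:, -1], t_end)
        if resid < 1e-8 or t_end >= max_time:
            break
        sol = _integrate(system, sol.y[:, -1], (t_end, t_end + 10000.0),
                         config)
        t_end += 10000.0
    wall = _time.perf_counter() - t0
    return _collect(system, sol, resid < 1e-8, wall)


def _steady_residual(system: DuctSystem, y, t) -> float:
    dy = system.rhs(t, y)
    scale = np.maximum(np.abs(y), system.atol_vector(1.0))
    return float(np.max(np.abs(dy) / scale))


def run_stimulation(config: SimulationConfig, m: float,
                    t_off: float = 400.0, recovery: float = 400.0,
                    steady: SimulationResult | None = None,
                    dt_out: float = 10.0) -> SimulationResult:
    """Transient response to a sigmoid-stimulated primary-saliva flow.

    Starts from the unstimulated steady state and integrates over
    [0, t_off + recovery]; the state at t = 400 s is the conventional
    'stimulated' reporting point.
    """
    if steady is None:
        steady = run_to_steady_state(config)
    boundary = replace(config.boundary, m=m, t_on=0.0, t_off=t_off)
    system = DuctSystem(config.geometry, config.params, boundary)
    system._v_c = steady.system._v_c.copy()
    system._v_l = steady.system._v_l.copy()
    t0 = _time.perf_counter()
    sol = _integrate(system, steady.y_final, (0.0, t_off + recovery),
                     config, dt_out=dt_out)
    wall = _time.perf_counter() - t0
    return _collect(system, sol, False, wall)


def flow_sweep(config: SimulationConfig, multipliers,
               steady: SimulationResult | None = None,
               record_at: float = 400.0):
    """Final-saliva composition as a function of the flow multiplier.

    Returns a pandas DataFrame with one row per multiplier, recorded at
    ``record_at`` seconds after stimulation onset.
    """
    import pandas as pd
    if steady is None:
        steady = run_to_steady_state(config)
    rows = []
    for m in multipliers:
        if m < 1:
            raise ValueError("flow multipliers must be >= 1")
        if m == 1:
            res, k = steady, -1
        else:
            res = run_stimulation(config, m, t_off=record_at + 1.0,
                                  recovery=0.0, steady=steady)
            k = int(np.argmin(np.abs(res.time - record_at)))
        c = res.outlet_conc[k]
        rows.append({
            "m": m, "flow": res.outlet_flow[k],
            "Na": c[IDX["Na"]], "K": c[IDX["K"]], "Cl": c[IDX["Cl"]],
            "HCO3": c[IDX["HCO3"]], "pH": float(conc_to_ph(c[IDX["H"]])),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-compartment simplification
# ---------------------------------------------------------------------------

def simplify_geometry(geom: DuctGeometry) -> DuctGeometry:
    """Aggregate all ID cells (and all SD cells) into single compartments.

    The two lumen compartments keep the total lumen volume and the total
    duct length of their region; membrane areas and cell volumes are
    summed.  Transport coefficients are per unit area, so the same
    parameter set drives the simplified model.
    """
    segs = geom.segments
    ids = [s for s in segs if s.duct_type == "ID"]
    sds = [s for s in segs if s.duct_type == "SD"]
    if not ids or not sds:
        raise ValueError("simplification needs both ID and SD regions")
    n_leaves = sum(1 for s in segs if s.is_leaf)

    def lump(region, index, length, upstream, leaf):
        vol = sum(s.volume for s in region)
        area = vol / length
        seg = LumenSegment(
            index=index, length=length, radius=float(np.sqrt(area / np.pi)),
            duct_type=region[0].duct_type, upstream=upstream,
            x=float(np.mean([s.x for s in region])), is_leaf=leaf)
        return seg

    id_len = max(s.x + s.length / 2 for s in ids) - \
        min(s.x - s.length / 2 for s in ids)
    sd_len = max(s.x + s.length / 2 for s in sds) - \
        min(s.x - s.length / 2 for s in sds)
    seg_id = lump(ids, 0, id_len, [], True)
    seg_id.inflow_weight = float(n_leaves)
    seg_sd = lump(sds, 1, sd_len, [0], False)

    def lump_cells(cells, cell_type, index, seg_index):
        group = [c for c in cells if c.cell_type == cell_type]
        a_a = sum(c.apical_area for c in group)
        return CellGeometry(
            index=index, cell_type=cell_type, apical_area=a_a,
            basal_area=sum(c.basal_area for c in group),
            volume=sum(c.volume for c in group),
            strips=[(seg_index, a_a)])

    cell_id = lump_cells(geom.cells, "ID", 0, 0)
    cell_sd = lump_cells(geom.cells, "SD", 1, 1)
    return DuctGeometry(segments=[seg_id, seg_sd], cells=[cell_id, cell_sd])


def build_simplified(config: SimulationConfig) -> SimulationConfig:
    """Configuration of the two-compartment model equivalent to ``config``."""
    return replace(config, geometry=simplify_geometry(config.geometry),
                   mode="simplified")
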