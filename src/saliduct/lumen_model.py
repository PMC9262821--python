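"""1-D upwind advection of the luminal fluid over the branched segment tree.

Each lumen segment is a well-mixed compartment of fixed volume A·Δx.  Axial
diffusion and hydrostatic pressure are neglected; the volumetric flow field
is quasi-steady (it re-equilibrates instantly along the duct, transit time
being far shorter than cellular timescales), so at any instant the flow
out of a segment equals the sum of its upstream inflows plus all water
secreted into the lumen up to and including that segment.

The upwind scheme makes the advective influx of a segment use its
upstream segments' concentrations; junction segments sum the advected
fluxes of all their parents, which conserves mass exactly (the scheme
telescopes to a discrete ledger: d/dt Σ moles = inflow − outflow +
secretion).

Sign convention: the per-segment source term ``j_sec`` is positive for
secretion *into* the lumen, so the balance reads
d(moles_i)/dt = in − out + j_sec_i.  (Transport written with the opposite
flux orientation merely flips the sign of J; the physics — Na⁺ removal by
ENaC lowers luminal Na⁺ — fixes the direction used here.)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import transporters as tr
from .geometry import DuctGeometry

__all__ = ["LumenNetwork", "BoundaryInflow", "update_flows", "lumen_rhs"]


@dataclass
class BoundaryInflow:
    """Primary-saliva inflow at the leaf segments."""

    concentrations: np.ndarray        # mM, shared by all leaves
    q_per_leaf: float                 # µm³/s at each leaf

    def validate(self):
        if self.q_per_leaf <= 0:
            raise ValueError("boundary inflow must be positive")


class LumenNetwork:
    """Precomputed static arrays of the segment tree plus flow/advection ops."""

    def __init__(self, geom: DuctGeometry):
        segs = geom.segments
        n = len(segs)
        self.n = n
        self.length = np.array([s.length for s in segs])
        self.radius = np.array([s.radius for s in segs])
        self.area = np.array([s.area for s in segs])
        self.lateral = np.array([s.lateral_per_length * s.length for s in segs])
        self.volume = self.area * self.length
        self.x = np.array([s.x for s in segs])
        self.is_leaf = np.array([s.is_leaf for s in segs])
        self.duct_type = np.array([s.duct_type for s in segs])
        self.leaf_idx = np.nonzero(self.is_leaf)[0]

        # parent pairs for vectorised junction sums
        src, dst = [], []
        for s in segs:
            for up in s.upstream:
                if up >= s.index:
                    raise ValueError("segments are not topologically ordered")
                src.append(up)
                dst.append(s.index)
        self.par_src = np.array(src, dtype=int)
        self.par_dst = np.array(dst, dtype=int)

        # chains of single-parent segments for fast flow accumulation
        self.chains = []           # list[(head_parents, ndarray of indices)]
        chain, head_parents = [], []
        for s in segs:
            single = len(s.upstream) == 1 and s.upstream[0] == s.index - 1 \
                and chain and chain[-1] == s.index - 1
            if not single:
                if chain:
                    self.chains.append((head_parents, np.array(chain)))
                chain, head_parents = [], list(s.upstream)
            chain.append(s.index)
        if chain:
            self.chains.append((head_parents, np.array(chain)))

    # -- flow field -------------------------------------------------------

    def update_flows(self, q_leaf: np.ndarray, water_in: np.ndarray):
        """Volumetric flow out of every segment, µm³/s.

        ``q_leaf`` is the boundary inflow per segment (nonzero at leaves),
        ``water_in`` the transepithelial water secreted into each segment.
        """
        src = q_leaf + water_in
        v_out = np.empty(self.n)
        for head_parents, idx in self.chains:
            base = sum(v_out[p] for p in head_parents)
            v_out[idx] = base + np.cumsum(src[idx])
        if np.any(v_out[self.leaf_idx] < 0):
            raise ValueError("negative incoming flow: backflow not supported")
        return v_out

    # -- advection --------------------------------------------------------

    def rhs(self, conc: np.ndarray, v_out: np.ndarray, j_sec: np.ndarray,
            boundary_conc: np.ndarray, q_leaf: np.ndarray,
            k_buffer: float = 0.0, co2: float = 0.0,
            ka: float = tr.KA_BUFFER):
        """d[N]/dt for every segment (mM/s).

        ``j_sec`` is the total molar source into each segment (zmol/s,
        secretion positive), already including paracellular removal.
        """
        if np.any(v_out < -1e-12):
            raise ValueError("negative flow: backflow not supported")
        adv_in = np.zeros_like(conc)
        if len(self.par_src):
            np.add.at(adv_in, self.par_dst,
                      v_out[self.par_src, None] * conc[self.par_src])
        adv_in[self.leaf_idx] += q_leaf[self.leaf_idx, None] * boundary_conc
        dconc = (adv_in - v_out[:, None] * conc + j_sec) / self.volume[:, None]
        if k_buffer > 0:
            dconc += tr.buffer_rate(conc, k_buffer, co2, ka)
        return dconc


def update_flows(geom: DuctGeometry, boundary: BoundaryInflow,
                 water_fluxes: np.ndarray | None = None) -> np.ndarray:
    """Per-segment volumetric flow for a geometry and boundary inflow."""
    boundary.validate()
    net = LumenNetwork(geom)
    q_leaf = np.where(net.is_leaf, boundary.q_per_leaf, 0.0)
    if water_fluxes is None:
        water_fluxes = np.zeros(net.n)
    return net.update_flows(q_leaf, np.asarray(water_fluxes, dtype=float))


def lumen_rhs(geom: DuctGeometry, conc: np.ndarray, j_sec: np.ndarray,
              water_in: np.ndarray, boundary: BoundaryInflow,
              k_buffer: float = 0.0, co2: float = 0.0) -> np.ndarray:
    """Convenience wrapper: flows + advection in one call."""
    boundary.validate()
    net = LumenNetwork(geom)
    q_leaf = np.where(net.is_leaf, boundary.q_per_leaf, 0.0)
    v_out = net.update_flows(q_leaf, np.asarray(water_in, dtype=float))
    return net.rhs(np.asarray(conc, dtype=float), v_out,
                   np.asarray(j_sec, dtype=float),
                   boundary.concentrations, q_leaf, k_buffer, co2)
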