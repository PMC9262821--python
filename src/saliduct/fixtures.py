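"""Deterministic test fixtures: tiny ducts, inert parameter sets and the
full reference configuration.

Every fixture regenerates bit-identically from its (name, seed) pair; no
fixture is stored on disk.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

from .geometry import DuctGeometry, SpatialStats
from .transporters import TransporterParams, default_params
from .primary_saliva import PrimarySaliva, unstimulated_composition

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]


@dataclass
class Fixture:
    """A named, reproducible test configuration."""

    name: str
    geometry: DuctGeometry
    params: TransporterParams
    boundary: PrimarySaliva
    notes: str = ""


def _inert_params() -> TransporterParams:
    p = default_params()
    for cell in p.cells.values():
        for name in ("p_enac", "p_cftr", "p_cacc", "p_maxik", "g_nhe_a",
                     "g_ae_a", "g_nbc_a", "lp_aqp_a", "r_nak", "p_k_b",
                     "g_nhe_b", "g_ae_b", "g_nbc_b", "lp_aqp_b",
                     "p_tj_na", "p_tj_k", "p_tj_cl"):
            setattr(cell, name, 0.0)
        cell.k_buffer = 0.0
    p.buffer = copy.copy(p.buffer)
    p.buffer.k_lumen = 0.0
    return p


FIXTURE_NAMES = ("inert-duct", "single-SD-cell", "two-branch-junction",
                 "mini-duct", "paper-default")


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Build one of the named fixtures.

    * ``inert-duct`` — a single short branch pair with every transporter
      density zero; the duct must leave the saliva untouched.
    * ``single-SD-cell`` — one SD cell on a straight 5 µm duct.
    * ``two-branch-junction`` — two ID branches merging into one SD.
    * ``mini-duct`` — a 4-cell duct (2 ID + 2 SD) for fast transients.
    * ``paper-default`` — the full 4-acinus reference geometry.
    """
    from .simulator import build_geometry

    if name == "inert-duct":
        stats = SpatialStats(id_length=10.0, sd_length=10.0,
                             id_cell_length=5.0, sd_cell_length=5.0, cv=0.0)
        geom = build_geometry(stats, n_acini=1, seed=seed)
        return Fixture(name, geom, _inert_params(), unstimulated_composition(),
                       "all transporter densities zero; outlet == inlet")
    if name == "single-SD-cell":
        # a lone SD cell: one ID stub feeds a 5 µm SD carrying one cell
        stats = SpatialStats(id_length=2.0, sd_length=5.0,
                             id_cell_length=2.0, sd_cell_length=5.0, cv=0.0)
        geom = build_geometry(stats, n_acini=1, seed=seed)
        params = default_params()
        # silence the stub ID cell so only the SD cell transports
        for fname in ("p_cacc", "p_maxik", "g_nhe_a", "g_ae_a", "g_nbc_a",
                      "lp_aqp_a", "r_nak", "p_k_b", "g_nhe_b", "g_ae_b",
                      "g_nbc_b", "lp_aqp_b", "p_tj_na", "p_tj_k", "p_tj_cl"):
            setattr(params.cells["ID"], fname, 0.0)
        params.cells["ID"].k_buffer = 0.0
        return Fixture(name, geom, params, unstimulated_composition(),
                       "one active SD cell; ID stub inert")
    if name == "two-branch-junction":
        stats = SpatialStats(id_length=10.0, sd_length=10.0, cv=0.0)
        geom = build_geometry(stats, n_acini=2, seed=seed)
        return Fixture(name, geom, default_params(),
                       unstimulated_composition(),
                       "junction flow must equal the sum of branch flows")
    if name == "mini-duct":
        stats = SpatialStats(id_length=10.0, sd_length=10.0, cv=0.0)
        geom = build_geometry(stats, n_acini=1, seed=seed)
        return Fixture(name, geom, default_params(),
                       unstimulated_composition(),
                       "4 cells (2 ID + 2 SD); fast transient checks")
    if name == "paper-default":
        geom = build_geometry(SpatialStats(), n_acini=4, seed=seed)
        return Fixture(name, geom, default_params(),
                       unstimulated_composition(),
                       "full 4-acinus reference duct")
    raise ValueError(f"unknown fixture {name!r}")
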