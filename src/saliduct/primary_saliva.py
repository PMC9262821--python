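"""Primary-saliva boundary condition.

The acinus is not modelled mechanistically; its output — the ionic
composition and volumetric flow of the primary saliva — is the duct's
upstream boundary condition.  At rest the composition is Na⁺ 136.9,
K⁺ 6.9, Cl⁻ 115.4, HCO₃⁻ 28.4 mM at pH 7.11 with 10.4 mM impermeant
digestive protein (osmolarity 298 mM, electroneutral).  Stimulated flow
follows a sigmoid ramp

    Q(t) = Q_basal (m − 1) / (1 + exp(0.1 (t − 50))) + Q_basal

inside the stimulation window and returns to Q_basal outside it.  At high
flow the composition is held constant; an optional mode raises osmolarity
linearly with the flow multiplier (to 330 mM at m = 4), mimicking the
acinar model's low-stimulation behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import ion_vector, ph_to_conc

__all__ = [
    "PrimarySaliva",
    "sigmoid_flow",
    "unstimulated_composition",
    "stimulated_composition",
]

#: Basal primary-saliva inflow per acinus (µm³/s); four acini give the
#: 417 µm³/s total primary inflow of the reference gland.
Q_BASAL_PER_ACINUS = 104.25

#: Basal secretion per acinar cell (µm³/s).
Q_BASAL_PER_CELL = 11.91


@dataclass
class PrimarySaliva:
    """Primary-saliva composition and flow protocol."""

    composition: np.ndarray = field(
        default_factory=lambda: ion_vector(
            Na=136.9, K=6.9, Cl=115.4, HCO3=28.4, H=ph_to_conc(7.11)))
    protein_mm: float = 10.4          # impermeant digestive protein
    q_basal: float = Q_BASAL_PER_ACINUS   # per leaf (per acinus)
    m: float = 1.0                    # flow-rate multiplier during stimulation
    t_on: float = 0.0
    t_off: float = 400.0

    def osmolarity(self) -> float:
        return float(self.composition.sum() + self.protein_mm)

    def charge_imbalance(self) -> float:
        """Σ cations − Σ anions, mM (≈0 for an electroneutral secretion)."""
        na, k, cl, hco3, h = self.composition
        return float(na + k + h - cl - hco3)

    def flow(self, t) -> np.ndarray:
        """Volumetric inflow per acinus at time ``t`` (s)."""
        return sigmoid_flow(t, self.m, self.q_basal, self.t_on, self.t_off)


def sigmoid_flow(t, m: float, q_basal: float,
                 t_on: float = 0.0, t_off: float = 400.0):
    """Stimulated flow protocol (µm³/s); ``q_basal`` outside [t_on, t_off]."""
    if m < 1:
        raise ValueError("flow multiplier m must be >= 1")
    if q_basal <= 0:
        raise ValueError("q_basal must be positive")
    t = np.asarray(t, dtype=float)
    # rising sigmoid with its half-rise point 50 s after onset; the flow
    # plateaus at m·Q_basal and drops back to Q_basal at switch-off
    tau = t - t_on
    arg = np.clip(-0.1 * (tau - 50.0), -500.0, 500.0)
    q = q_basal * (m - 1.0) / (1.0 + np.exp(arg)) + q_basal
    on = (t >= t_on) & (t < t_off)
    out = np.where(on, q, q_basal)
    return out if out.shape else float(out)


def unstimulated_composition() -> PrimarySaliva:
    """The resting primary saliva."""
    return PrimarySaliva()


def stimulated_composition(m: float, mode: str = "constant") -> PrimarySaliva:
    """Primary saliva during stimulation at flow multiplier ``m``.

    ``mode="constant"`` (default, the high-flow assumption) keeps the
    resting composition.  ``mode="linear_osmolarity"`` scales the ionic
    concentrations so osmolarity rises linearly from 297 mM at m = 1 to
    330 mM at m = 4.
    """
    if m < 1:
        raise ValueError("flow multiplier m must be >= 1")
    base = unstimulated_composition()
    base.m = m
    if mode == "constant":
        return base
    if mode != "linear_osmolarity":
        raise ValueError(f"unknown composition mode {mode!r}")
    target_osm = 297.0 + 11.0 * (m - 1.0)
    ionic = base.osmolarity() - base.protein_mm
    factor = (target_osm - base.protein_mm) / ionic
    return replace(base, composition=base.composition * factor)
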