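"""Physical constants and species bookkeeping.

Model units
-----------
length        µm
volume        µm³
time          s
concentration mM  (1 mM = 1 zmol/µm³, 1 zmol = 1e-21 mol)
amount        zmol
potential     mV
permeability  nm/s   (1 nm/s × 1 mM × 1 µm² = 1 zmol/s)
water perm.   µm³ s⁻¹ µm⁻² mM⁻¹ (lumped osmotic permeability)

With these choices concentration × volume gives amount directly and
permeability × concentration × area gives molar flux directly.
"""

from __future__ import annotations

import numpy as np

#: Gas constant × temperature / Faraday at 310 K, in mV.
RT_F = 26.7

#: Faraday constant, C/mol.  Currents appear only in ratios (charge-balance
#: residuals), so the absolute scale is irrelevant to the solution.
FARADAY = 96485.33212

#: Modelled ion species, in storage order.
SPECIES = ("Na", "K", "Cl", "HCO3", "H")

#: Valence of each species, aligned with SPECIES.
Z = np.array([1.0, 1.0, -1.0, -1.0, 1.0])

#: Index of each species in SPECIES order.
IDX = {name: i for i, name in enumerate(SPECIES)}

#: Apparent equilibrium constant of CO2 + H2O <-> H+ + HCO3- in mM
#: (pK' = 6.1 on the molar scale; [H][HCO3]/[CO2] with all three in mM).
KA_BUFFER = 10.0 ** (-3.1)


def ion_vector(Na=0.0, K=0.0, Cl=0.0, HCO3=0.0, H=0.0) -> np.ndarray:
    """Build a concentration vector (mM) in canonical species order."""
    return np.array([Na, K, Cl, HCO3, H], dtype=float)


def ph_to_conc(ph: float) -> float:
    """[H+] in mM for a given pH."""
    return 10.0 ** (-ph) * 1e3


def conc_to_ph(h_mm) -> float:
    """pH for a given [H+] in mM."""
    return -np.log10(np.asarray(h_mm) * 1e-3)
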