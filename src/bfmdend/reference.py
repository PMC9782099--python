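"""Reference production-scale results for the single-spacer BFM dendrimer model.

Published values for generation 4 and 5 systems at three volume
fractions each, obtained from long (up to 1e8-step) production runs with
the distance-dependent bond-energy table of the original model
parameterisation.  Lengths are in lattice units; D in lattice units² per
step.  Desk-scale athermal runs of this package are compared against
these numbers in the regression suite.
"""

from __future__ import annotations

__all__ = ["REFERENCE_SYSTEMS", "MEAN_BRANCH_DISTANCE_DILUTE",
           "RG_ANGSTROM_DILUTE", "RCE_OVER_RG"]

#: rows: (G, phi, Rg, Rce, A, phi_over, D*1e6)
REFERENCE_SYSTEMS: tuple[dict, ...] = (
    {"G": 4, "phi": 0.041, "Rg": 12.9, "Rce": 14.8, "A": 0.048,
     "phi_over": 0.109, "D1e6": 8.8},
    {"G": 4, "phi": 0.079, "Rg": 12.6, "Rce": 14.5, "A": 0.048,
     "phi_over": 0.115, "D1e6": 2.8},
    {"G": 4, "phi": 0.171, "Rg": 11.7, "Rce": 13.5, "A": 0.054,
     "phi_over": 0.143, "D1e6": 2.8},
    {"G": 5, "phi": 0.048, "Rg": 16.0, "Rce": 17.7, "A": 0.028,
     "phi_over": 0.128, "D1e6": 0.35},
    {"G": 5, "phi": 0.090, "Rg": 15.6, "Rce": 17.4, "A": 0.037,
     "phi_over": 0.138, "D1e6": 0.35},
    {"G": 5, "phi": 0.202, "Rg": 14.1, "Rce": 15.7, "A": 0.048,
     "phi_over": 0.184, "D1e6": 0.43},
)

#: mean bonded branching-point distance in the dilute regime (lattice units)
MEAN_BRANCH_DISTANCE_DILUTE = 5.2

#: Rg of the most dilute systems mapped to Å via the 1.45 Å lattice unit
RG_ANGSTROM_DILUTE = {4: 18.9, 5: 23.2}

#: concentration-independent Rce/Rg ratios per generation
RCE_OVER_RG = {4: 1.15, 5: 1.11}
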