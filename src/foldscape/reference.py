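"""Reference catalog for the talin R3(IVVI) conformational space.

Published long-timescale magnetic-tweezers measurements at the coexistence
force (F_0.5 ≈ 8.5 pN) partition the conformational space of the talin R3(IVVI)
domain into six states (roman numerals i–vi) built from nine conformations
(capital letters). Each conformation is fingerprinted, relative to the natively
folded form F, by its mean extension offset Δz and its excess extension
variance Δσ²; each directed transition by its mean waiting time.

These tables parameterise the default synthetic-trajectory scenario and the
state-region classifier. Values are in nm, nm² and seconds.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "CONFORMATION_TABLE",
    "TRANSITION_TABLE",
    "REFERENCE_LC_NM",
    "COEXISTENCE_FORCE_PN",
    "PSF_SD_NM",
    "ISOMERIZATION_RATE_PER_S",
    "conformation_table",
    "transition_table",
]

#: Contour-length increment of the fully unfolded conformation, nm.
REFERENCE_LC_NM = 42.5

#: Coexistence force of the native two-state dynamics, pN.
COEXISTENCE_FORCE_PN = 8.5

#: Gaussian point-spread function of the bead-tracking measurement, nm.
PSF_SD_NM = 0.85

#: Force-independent cis→trans isomerization rate of proline 881, 1/s.
ISOMERIZATION_RATE_PER_S = 0.0017

# (state region, conformation label, Δz nm, Δσ² nm², unstructured L_c nm)
CONFORMATION_TABLE = [
    ("i", "F", 0.0, 0.0, 0.0),
    ("i", "U", 18.2, 5.8, 42.5),
    ("iii", "I", 5.4, 0.16, 1.3),
    ("iv", "H", 15.6, 2.8, 22.6),
    ("v", "L1", 3.3, 0.6, 4.4),
    ("v", "L2", 7.6, 3.4, 24.9),
    ("v", "L3", 14.9, 4.6, 33.7),
    ("vi", "M1", 7.45, 2.8, 26.7),
    ("vi", "M2", 14.3, 2.8, 25.2),
]

# (state region, from, to, mean transition time s, events). "U2"/"F2" denote
# the unfolded/folded conformations of the trans-proline isomer (state ii),
# which shares the F/U extension levels but a shifted folding equilibrium.
TRANSITION_TABLE = [
    ("i", "F", "U", 1.4, 522_721),
    ("i", "U", "F", 1.3, 522_721),
    ("ii", "U", "U2", 1372.5, 152),
    ("ii", "F2", "U2", 0.07, 1504),
    ("ii", "U2", "F2", 3.2, 1505),
    ("ii", "U2", "U", 63.4, 154),
    ("iii", "U", "I", 6135.0, 11),
    ("iii", "F", "I", 12504.0, 2),
    ("iii", "I", "U", 7.8, 12),
    ("iii", "I", "F", 6.5, 4),
    ("iv", "U", "H", 1251.8, 108),
    ("iv", "H", "U", 96.3, 108),
    ("v", "U", "L3", 2153.4, 57),
    ("v", "L3", "L2", 0.09, 1985),
    ("v", "L2", "L1", 0.42, 12_298),
    ("v", "L1", "L2", 0.37, 12_298),
    ("v", "L2", "L3", 2.52, 1985),
    ("v", "L3", "U", 270.4, 57),
    ("vi", "U", "M2", 1744.0, 79),
    ("vi", "M1", "M2", 0.91, 15_980),
    ("vi", "M2", "M1", 0.25, 15_981),
    ("vi", "M2", "U", 122.0, 79),
]


def conformation_table() -> pd.DataFrame:
    """Conformation catalog as a DataFrame (one row per conformation)."""
    return pd.DataFrame(
        CONFORMATION_TABLE,
        columns=["state", "label", "delta_z_nm", "delta_var_nm2", "unstructured_Lc_nm"],
    )


def transition_table() -> pd.DataFrame:
    """Directed mean transition times as a DataFrame (one row per edge)."""
    return pd.DataFrame(
        TRANSITION_TABLE,
        columns=["state", "from_label", "to_label", "mean_time_s", "n_events"],
    )
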