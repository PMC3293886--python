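"""Default study conditions for the synthetic generator and drivers.

Values describe a Col-0 × Ri-0-like RIL family of 160 quasi-homozygous
lines phenotyped for five base phenological traits (days; FRR derived,
dimensionless) in a 3-block greenhouse design.  Broad-sense heritabilities
and genetic correlations mirror control-condition estimates typical of
such families; fitness surfaces are moderate directional/quadratic
coefficients with the sign structure of the seed-production analysis
(stronger selection for earliness under water stress, weaker and partly
reversed selection under competition).  Baseline fitness W0 is total
silique length in mm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import FitnessSurface
from .traits import (
    CONTROL,
    INTENSE_COMPETITION,
    MODERATE_COMPETITION,
    MODERATE_WATER,
    SEVERE_WATER,
)

N_LINES = 160
N_BLOCKS = 3

TRAIT_MEANS = {"GERM": 3.5, "BT": 25.0, "INT": 5.0, "FLO": 20.0, "RP": 30.0}
GENETIC_SDS = {"GERM": 0.8, "BT": 4.0, "INT": 1.5, "FLO": 4.0, "RP": 4.0}
H2_TARGET = {"GERM": 0.20, "BT": 0.51, "INT": 0.26, "FLO": 0.30, "RP": 0.25}

_BASE = ["GERM", "BT", "INT", "FLO", "RP"]
GENETIC_CORR = pd.DataFrame(
    np.array(
        [
            #  GERM    BT    INT    FLO    RP
            [1.00, 0.04, 0.06, -0.20, -0.15],
            [0.04, 1.00, -0.28, 0.11, -0.04],
            [0.06, -0.28, 1.00, 0.06, 0.10],
            [-0.20, 0.11, 0.06, 1.00, 0.63],
            [-0.15, -0.04, 0.10, 0.63, 1.00],
        ]
    ),
    index=_BASE,
    columns=_BASE,
)

#: Mean shifts of the stress treatments relative to control (days): stress
#: delays flowering slightly and shortens the reproductive phase.
TREATMENT_SHIFTS = {
    MODERATE_WATER: {"FLO": -3.0},
    SEVERE_WATER: {"FLO": -6.0},
    MODERATE_COMPETITION: {"INT": 0.5, "FLO": -2.0, "RP": -2.0},
    INTENSE_COMPETITION: {"INT": 1.0, "FLO": -4.0, "RP": -4.0},
}

W0 = {  # baseline silique production, mm
    CONTROL: 1000.0,
    MODERATE_WATER: 650.0,
    SEVERE_WATER: 300.0,
    MODERATE_COMPETITION: 750.0,
    INTENSE_COMPETITION: 550.0,
}

#: Experiment-A fitness surfaces (b on the β scale, g on the γ scale).
SURFACES = {
    CONTROL: FitnessSurface(
        w0=W0[CONTROL],
        linear={"GERM": -0.11, "BT": -0.17, "INT": -0.09, "FLO": -0.10, "RP": 0.10},
        quadratic={"INT": -0.05, "FLO": 0.15, "RP": -0.09},
        noise_sd=0.9 * W0[CONTROL],
    ),
    MODERATE_WATER: FitnessSurface(
        w0=W0[MODERATE_WATER],
        linear={"GERM": -0.19, "BT": -0.64, "INT": -0.26, "FLO": -0.10},
        quadratic={"BT": 0.13},
        noise_sd=0.6 * W0[MODERATE_WATER],
    ),
    SEVERE_WATER: FitnessSurface(
        w0=W0[SEVERE_WATER],
        linear={"GERM": -0.36, "BT": -1.0, "INT": -0.45, "FLO": -0.35},
        quadratic={"BT": 0.25},
        noise_sd=0.55 * W0[SEVERE_WATER],
    ),
    MODERATE_COMPETITION: FitnessSurface(
        w0=W0[MODERATE_COMPETITION],
        linear={"GERM": -0.15, "BT": -0.26, "INT": -0.12, "FLO": 0.05, "RP": -0.05},
        quadratic={"BT": 0.08},
        noise_sd=0.8 * W0[MODERATE_COMPETITION],
    ),
    INTENSE_COMPETITION: FitnessSurface(
        w0=W0[INTENSE_COMPETITION],
        linear={"GERM": -0.11, "BT": -0.24, "INT": -0.19, "FLO": 0.20, "RP": -0.10},
        quadratic={"BT": 0.10, "FLO": -0.15},
        noise_sd=0.85 * W0[INTENSE_COMPETITION],
    ),
}

#: LNS fitness surfaces per treatment intensity: directional selection for
#: earliness grading up with water-stress intensity — weak under the mild
#: intensities (watering stopped late, most plants finish their cycle) and
#: strong under the two most severe ones; competition neutral (selection on
#: unmeasured traits dominates there).
LNS_SURFACES = {
    "control": FitnessSurface(w0=1000.0, linear={}, noise_sd=300.0),
    "W1": FitnessSurface(w0=800.0, linear={"GERM": -0.02, "BT": -0.08}, noise_sd=280.0),
    "W2": FitnessSurface(w0=650.0, linear={"GERM": -0.05, "BT": -0.20}, noise_sd=250.0),
    "W3": FitnessSurface(w0=450.0, linear={"GERM": -0.12, "BT": -0.60}, noise_sd=200.0),
    "W4": FitnessSurface(w0=300.0, linear={"GERM": -0.20, "BT": -1.10}, noise_sd=150.0),
    "C1": FitnessSurface(w0=800.0, linear={}, noise_sd=280.0),
    "C2": FitnessSurface(w0=700.0, linear={}, noise_sd=260.0),
    "C3": FitnessSurface(w0=600.0, linear={}, noise_sd=240.0),
    "C4": FitnessSurface(w0=500.0, linear={}, noise_sd=220.0),
}

#: Small per-block micro-environment offsets (days) applied to every trait
#: table; block 1 is the reference.
BLOCK_EFFECTS = {
    1: {},
    2: {"GERM": 0.1, "BT": 0.4, "INT": 0.1, "FLO": 0.3, "RP": 0.3},
    3: {"GERM": -0.1, "BT": -0.3, "INT": -0.1, "FLO": -0.2, "RP": -0.4},
}
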