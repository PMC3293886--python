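"""Trait and treatment vocabulary shared across the package.

Seven phenological traits span the annual life cycle of a selfing plant
such as *Arabidopsis thaliana*:

* ``GERM`` — germination timing (days from sowing to cotyledon opening)
* ``BT``   — bolting time (days from germination to inflorescence emergence)
* ``INT``  — interval between bolting and anthesis (days)
* ``ANT``  — time to anthesis (days); by construction ``ANT = BT + INT``
* ``FLO``  — flowering duration (days from first flower to last flower)
* ``RP``   — reproductive period duration (days from first flower to last
  mature fruit)
* ``FRR``  — flowering-to-reproductive-period ratio, ``FLO / RP``
  (dimensionless)

``ANT`` and ``FRR`` are deterministic functions of the other traits, so the
multivariate generator draws the five *base* traits and derives the other
two, and polynomial selection-gradient models exclude ``ANT`` (it would be
perfectly collinear with ``BT`` and ``INT``).

Fitness (``FITNESS``) is total silique (fruit) length in millimetres, a
standard seed-production proxy in selfing annuals.
"""

from __future__ import annotations

import re

TRAITS: tuple[str, ...] = ("GERM", "BT", "INT", "ANT", "FLO", "RP", "FRR")

#: Traits drawn directly by the generator; ANT and FRR are derived.
BASE_TRAITS: tuple[str, ...] = ("GERM", "BT", "INT", "FLO", "RP")

#: Traits admissible in polynomial selection-gradient regressions
#: (ANT integrates BT and INT and is therefore excluded).
GRADIENT_TRAITS: tuple[str, ...] = ("GERM", "BT", "INT", "FLO", "RP", "FRR")

FITNESS = "FITNESS"

# Seed-production experiment ("experiment A"): five treatments, three
# randomized blocks (flats) each.
CONTROL = "control"
MODERATE_WATER = "moderate water stress"
SEVERE_WATER = "severe water stress"
MODERATE_COMPETITION = "moderate competition"
INTENSE_COMPETITION = "intense competition"

EXPERIMENT_A_TREATMENTS: tuple[str, ...] = (
    CONTROL,
    MODERATE_WATER,
    SEVERE_WATER,
    MODERATE_COMPETITION,
    INTENSE_COMPETITION,
)

#: Treatments in which watering stops before fruit maturation; plants often
#: die before the last fruit matures, so RP (and hence FRR) is unobservable.
WATER_STRESS_TREATMENTS: frozenset[str] = frozenset({MODERATE_WATER, SEVERE_WATER})

# Laboratory-natural-selection (LNS) treatment intensities: a shared control
# plus four water-stress intensities (W1 mild .. W4 severe) and four
# interspecific-competition intensities (C1 .. C4).
LNS_WATER_INTENSITIES: tuple[str, ...] = ("control", "W1", "W2", "W3", "W4")
LNS_COMPETITION_INTENSITIES: tuple[str, ...] = ("control", "C1", "C2", "C3", "C4")
LNS_TREATMENTS: tuple[str, ...] = (
    "control", "W1", "W2", "W3", "W4", "C1", "C2", "C3", "C4",
)

_WATER_INTENSITY_RE = re.compile(r"W[1-4]\Z")


def is_water_stress(treatment: str) -> bool:
    """True if *treatment* is a water-stress condition (experiment-A label
    or LNS intensity W1–W4), under which RP and FRR are structurally
    missing."""
    return treatment in WATER_STRESS_TREATMENTS or bool(
        _WATER_INTENSITY_RE.match(treatment)
    )


def observable_traits(treatment: str) -> tuple[str, ...]:
    """Traits measurable under *treatment* (drops RP/FRR under water stress)."""
    if is_water_stress(treatment):
        return tuple(t for t in TRAITS if t not in ("RP", "FRR"))
    return TRAITS
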