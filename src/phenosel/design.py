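"""Greenhouse experimental layouts.

Two designs are modelled:

* the seed-production experiment ("experiment A"): 5 treatments × 3 flats,
  each flat a 13×13 grid (0.28 m side, plants 2.5 cm apart) holding one
  replicate of each of 160 RILs plus two replicates of each parent
  (164 plants); the four corners and one random position are empty;
* the LNS phenotyping experiment: per stress type, 3 randomized blocks each
  holding 4 seeds × 25 populations × 4 generations, the 160 G0 RILs and
  5 replicates of each parent (570 plants per block, 1,710 total), laid out
  on 9 arrays of 66 wells with 24 empty positions per block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .family import PARENT_IDS
from .traits import (
    EXPERIMENT_A_TREATMENTS,
    INTENSE_COMPETITION,
    MODERATE_COMPETITION,
)

EMPTY = "EMPTY"

GRID_SIDE = 13
FLAT_SIDE_M = 0.28
FLAT_AREA_M2 = FLAT_SIDE_M**2

N_RILS_DEFAULT = 160
PLANTS_PER_FLAT = GRID_SIDE * GRID_SIDE - 5  # 164

#: Neighbouring competitor seeds per focal plant in the two competition
#: treatments of experiment A.
COMPETITOR_SEEDS = {MODERATE_COMPETITION: 4, INTENSE_COMPETITION: 8}

# LNS phenotyping block structure
LNS_N_POPULATIONS = 25          # 5 populations × 5 treatment intensities
LNS_N_GENERATIONS = 4           # G1..G4 (G0 enters as the 160-RIL reference)
LNS_SEEDS_PER_POP_GEN = 4       # per block
LNS_PARENT_REPLICATES = 5       # per parent per block
LNS_N_BLOCKS = 3
LNS_ARRAYS_PER_BLOCK = 9
LNS_WELLS_PER_ARRAY = 66
LNS_EMPTY_PER_BLOCK = 24


@dataclass
class DesignLayout:
    """Tabular experiment layout: one row per position (plant or EMPTY)."""

    table: pd.DataFrame
    flat_side_m: float = FLAT_SIDE_M

    @property
    def n_plants(self) -> int:
        return int((self.table["line_id"] != EMPTY).sum())

    def plants(self) -> pd.DataFrame:
        return self.table[self.table["line_id"] != EMPTY].reset_index(drop=True)


def build_design_a(
    ril_ids: list[str] | None = None,
    seed: int | np.random.Generator = 0,
) -> DesignLayout:
    """Layout of the seed-production experiment.

    Each of the 5 treatments has 3 flats; each flat is an independent
    randomization of 160 RILs + 2 replicates of each parent on a 13×13 grid
    with the four corners plus one random interior position left empty.
    Competitor seed counts are 4 (moderate) and 8 (intense competition)
    around every focal plant, 0 elsewhere.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if ril_ids is None:
        ril_ids = [f"RIL{i + 1:03d}" for i in range(N_RILS_DEFAULT)]
    occupants = list(ril_ids) + [p for p in PARENT_IDS for _ in range(2)]
    if len(occupants) != PLANTS_PER_FLAT:
        raise ValueError(
            f"flat holds {PLANTS_PER_FLAT} plants; got {len(occupants)} occupants"
        )

    corners = [(0, 0), (0, GRID_SIDE - 1), (GRID_SIDE - 1, 0), (GRID_SIDE - 1, GRID_SIDE - 1)]
    all_cells = [(r, c) for r in range(GRID_SIDE) for c in range(GRID_SIDE)]
    interior = [rc for rc in all_cells if rc not in corners]

    rows = []
    for treatment in EXPERIMENT_A_TREATMENTS:
        n_comp = COMPETITOR_SEEDS.get(treatment, 0)
        for block in (1, 2, 3):
            extra_empty = interior[rng.integers(len(interior))]
            empties = set(corners) | {extra_empty}
            cells = [rc for rc in all_cells if rc not in empties]
            order = rng.permutation(len(occupants))
            for (r, c), k in zip(cells, order):
                rows.append((treatment, block, r, c, occupants[k], n_comp))
            for r, c in sorted(empties):
                rows.append((treatment, block, r, c, EMPTY, 0))

    table = pd.DataFrame(
        rows,
        columns=["treatment", "block", "row", "col", "line_id", "n_competitor_seeds"],
    )
    return DesignLayout(table=table)


def build_design_lns_phenotyping(
    populations: list[tuple[str, int]] | None = None,
    ril_ids: list[str] | None = None,
    generations: tuple[int, ...] = (1, 2, 3, 4),
    seed: int | np.random.Generator = 0,
) -> DesignLayout:
    """Layout of the LNS phenotyping experiment for one stress type.

    Parameters
    ----------
    populations
        The 25 (treatment intensity, population id) combinations followed
        for this stress type.  Defaults to 5 populations in each of
        ``control`` and four unnamed intensities ``I1..I4``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if ril_ids is None:
        ril_ids = [f"RIL{i + 1:03d}" for i in range(N_RILS_DEFAULT)]
    if populations is None:
        populations = [
            (intensity, p)
            for intensity in ("control", "I1", "I2", "I3", "I4")
            for p in range(1, 6)
        ]
    if len(populations) != LNS_N_POPULATIONS:
        raise ValueError(f"expected {LNS_N_POPULATIONS} populations")

    rows = []
    for block in range(1, LNS_N_BLOCKS + 1):
        entries: list[tuple[str, str | None, int | None, int | None]] = []
        # 4 seeds per population × generation
        for intensity, pop in populations:
            for gen in generations:
                for _ in range(LNS_SEEDS_PER_POP_GEN):
                    entries.append((f"POP:{intensity}:{pop}", intensity, pop, gen))
        # one replicate per RIL for the G0 reference
        for line in ril_ids:
            entries.append((line, None, None, 0))
        # parental replicates
        for parent in PARENT_IDS:
            for _ in range(LNS_PARENT_REPLICATES):
                entries.append((parent, None, None, None))
        entries += [(EMPTY, None, None, None)] * LNS_EMPTY_PER_BLOCK

        n_wells = LNS_ARRAYS_PER_BLOCK * LNS_WELLS_PER_ARRAY
        if len(entries) != n_wells:
            raise AssertionError("block does not fill its arrays exactly")
        order = rng.permutation(len(entries))
        for pos, k in enumerate(order):
            line_id, intensity, pop, gen = entries[k]
            rows.append(
                (
                    block,
                    pos // LNS_WELLS_PER_ARRAY + 1,
                    pos % LNS_WELLS_PER_ARRAY + 1,
                    line_id,
                    intensity,
                    pop,
                    gen,
                )
            )

    table = pd.DataFrame(
        rows,
        columns=["block", "array", "well", "line_id", "treatment_intensity", "population", "generation"],
    )
    return DesignLayout(table=table)


def experiment_a_density(rounded: bool = True) -> float:
    """Plant density of an experiment-A flat (plants/m²); rounded to the
    nearest hundred by default, as conventionally reported."""
    d = PLANTS_PER_FLAT / FLAT_AREA_M2
    return round(d, -2) if rounded else d


def lns_founding_density(census: int = 160, rounded: bool = True) -> float:
    """Seed density at the founding of an LNS population (seeds/m²);
    rounded to the nearest ten by default."""
    d = census / FLAT_AREA_M2
    return round(d, -1) if rounded else d
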