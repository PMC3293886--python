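"""Shared builders for the test suite: single-trait families and
replicated block designs with a known generative fitness surface."""

from __future__ import annotations

import numpy as np
import pandas as pd

import phenosel as ps


def corr_identity(traits) -> pd.DataFrame:
    k = len(traits)
    return pd.DataFrame(np.eye(k), index=traits, columns=traits)


def single_trait_family(rng, n_lines=160, h2=0.5, mean=25.0, sd=4.0, trait="BT"):
    return ps.make_ril_family(
        n_lines,
        {trait: mean},
        {trait: sd},
        corr_identity([trait]),
        {trait: h2},
        seed=rng,
    )


def replicated_design(family, n_blocks=3, treatment="control") -> ps.DesignLayout:
    rows = [
        (treatment, b, line)
        for b in range(1, n_blocks + 1)
        for line in family.line_ids
    ]
    return ps.DesignLayout(pd.DataFrame(rows, columns=["treatment", "block", "line_id"]))


def surface_table(rng, b=0.0, g=0.0, noise_sd=0.0, h2=0.5, n_lines=160,
                  n_blocks=3, treatment="control", trait="BT", w0=1000.0):
    """One treatment, n_lines × n_blocks plants, fitness from a single-trait
    surface with linear coefficient b and γ-scale curvature g."""
    fam = single_trait_family(rng, n_lines=n_lines, h2=h2, trait=trait)
    design = replicated_design(fam, n_blocks=n_blocks, treatment=treatment)
    table = ps.simulate_phenotypes(fam, design, seed=rng)
    surf = ps.FitnessSurface(
        w0=w0, linear={trait: b} if b else {}, quadratic={trait: g} if g else {},
        noise_sd=noise_sd * w0,
    )
    return ps.simulate_fitness(table, surf, seed=rng)


def null_lns_dataset(rng, family, intensities=("control", "I1", "I2", "I3", "I4"),
                     n_pops=5, generations=(1, 2, 3, 4)):
    """Fully null LNS phenotyping data: every population × generation sample
    is 12 uniform draws from the founding family (no drift, no selection,
    no block or generation effects)."""
    base = [t for t in family.traits if t in ("GERM", "BT", "INT", "FLO", "RP")]
    resid = family.residual_sd.reindex(base).to_numpy()
    geno = family.genotypic_values.loc[family.ril_ids, base].to_numpy()
    n_lines = len(geno)
    rows = []
    for intensity in intensities:
        for pop in range(1, n_pops + 1):
            for gen in generations:
                for block in (1, 2, 3):
                    pick = rng.integers(n_lines, size=4)
                    vals = geno[pick] + rng.standard_normal((4, len(base))) * resid
                    for v in vals:
                        rows.append([intensity, pop, gen, block] + list(v))
    return pd.DataFrame(
        rows, columns=["treatment_intensity", "population", "generation", "block"] + base
    )


def null_g0_data(rng, family):
    return ps.simulate_g0_block_data(family, rng=rng)
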