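"""Synthetic phenotype and fitness tables.

``simulate_phenotypes`` turns a RIL family plus an experiment layout into a
tidy per-plant phenotype table (genotypic value + treatment shift + block
effect + residual noise, with the identity traits ANT and FRR derived and
RP/FRR blanked under water stress).  ``simulate_fitness`` fills the FITNESS
column from a linear+quadratic fitness surface on within-treatment
standardized traits:

    W(z) = W0 * (1 + Σ_k b_k z_k + ½ Σ_k g_k z_k²) + noise,  truncated at 0,

so the generative ``b`` and ``g`` live on the same scale as the directional
gradient β and the (doubled) quadratic coefficient γ that the selection
analysis estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignLayout
from .family import RILFamily, _derive_identity_traits
from .traits import BASE_TRAITS, FITNESS, is_water_stress


@dataclass
class FitnessSurface:
    """Linear + quadratic fitness surface on standardized traits.

    ``linear[k]`` is the directional coefficient b_k and ``quadratic[k]``
    the γ-scale curvature g_k (the surface uses ``½ g_k z_k²`` so that the
    doubled quadratic regression coefficient recovers g_k).
    """

    w0: float = 1000.0
    linear: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def traits(self) -> list[str]:
        return sorted(set(self.linear) | set(self.quadratic))

    def relative_fitness(self, z: pd.DataFrame | dict[str, np.ndarray]) -> np.ndarray:
        """Expected relative fitness at standardized trait values *z*.

        Missing (NaN) trait values contribute 0, i.e. are treated as being
        at the trait mean.
        """
        if isinstance(z, dict):
            z = pd.DataFrame(z)
        w = np.ones(len(z))
        for k, b in self.linear.items():
            w = w + b * np.nan_to_num(z[k].to_numpy(dtype=float))
        for k, g in self.quadratic.items():
            w = w + 0.5 * g * np.nan_to_num(z[k].to_numpy(dtype=float)) ** 2
        return w


def simulate_phenotypes(
    family: RILFamily,
    design: DesignLayout,
    treatment_shifts: dict[str, dict[str, float]] | None = None,
    block_effects: dict[int, dict[str, float]] | None = None,
    seed: int | np.random.Generator = 0,
    round_germ: bool = False,
) -> pd.DataFrame:
    """Simulate a tidy per-plant phenotype table from a layout.

    Each plant's base-trait value is its line's genotypic value plus the
    treatment shift, the block effect and independent Gaussian residual
    noise with the family's per-trait residual SD.  ANT and FRR are then
    derived from the realized base traits, and RP/FRR are set missing for
    water-stress treatments.  Germination is continuous by default;
    ``round_germ`` rounds it to whole days (daily monitoring).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    treatment_shifts = treatment_shifts or {}
    block_effects = block_effects or {}

    plants = design.plants().copy()
    unknown = set(plants["line_id"]) - set(family.line_ids)
    if unknown:
        raise ValueError(f"design references unknown lines: {sorted(unknown)[:5]}")

    base = [t for t in family.traits if t in BASE_TRAITS]
    geno = family.genotypic_values.loc[plants["line_id"], base].to_numpy()
    resid_sd = family.residual_sd.reindex(base).to_numpy()
    noise = rng.standard_normal(geno.shape) * resid_sd
    values = geno + noise

    for j, trait in enumerate(base):
        if "treatment" in plants:
            shift = plants["treatment"].map(
                lambda tr: treatment_shifts.get(tr, {}).get(trait, 0.0)
            )
            values[:, j] += shift.to_numpy(dtype=float)
        beff = plants["block"].map(lambda b: block_effects.get(b, {}).get(trait, 0.0))
        values[:, j] += beff.to_numpy(dtype=float)

    out = plants.reset_index(drop=True)
    out.insert(0, "plant_id", np.arange(1, len(out) + 1))
    for j, trait in enumerate(base):
        out[trait] = values[:, j]
    if round_germ and "GERM" in out:
        out["GERM"] = np.round(out["GERM"])
    _derive_identity_traits(out)

    if "treatment" in out:
        ws = out["treatment"].map(is_water_stress)
    elif "treatment_intensity" in out:
        ws = out["treatment_intensity"].fillna("").map(is_water_stress)
    else:
        ws = pd.Series(False, index=out.index)
    for trait in ("RP", "FRR"):
        if trait in out:
            out.loc[ws, trait] = np.nan
    return out


def simulate_fitness(
    table: pd.DataFrame,
    surface: FitnessSurface | dict[str, FitnessSurface],
    seed: int | np.random.Generator = 0,
    group: str = "treatment",
) -> pd.DataFrame:
    """Fill the FITNESS column from a fitness surface.

    Traits are standardized within each *group* level (default: treatment)
    before the surface is evaluated; realized fitness is
    ``max(0, W0·w(z) + noise)``.  *surface* may be a single surface or a
    per-group mapping.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = table.copy()
    out[FITNESS] = np.nan

    for level, idx in out.groupby(group, sort=False).groups.items():
        surf = surface[level] if isinstance(surface, dict) else surface
        missing = [k for k in surf.traits() if k not in out.columns]
        if missing:
            raise ValueError(f"surface traits absent from table: {missing}")
        sub = out.loc[idx]
        z = {}
        for k in surf.traits():
            x = sub[k].astype(float)
            sd = x.std(ddof=1)
            z[k] = ((x - x.mean()) / sd).to_numpy() if sd > 0 else np.zeros(len(x))
        w = surf.relative_fitness(pd.DataFrame(z, index=sub.index))
        fit = surf.w0 * w + rng.standard_normal(len(sub)) * surf.noise_sd
        fit = np.clip(fit, 0.0, None)
        if np.all(fit == 0):
            warnings.warn(
                f"all realized fitness is 0 in group {level!r}; "
                "relative fitness is undefined downstream",
                RuntimeWarning,
                stacklevel=2,
            )
        out.loc[idx, FITNESS] = fit
    return out
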