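"""Forward-in-time simulator of the laboratory-natural-selection design.

Populations of selfing inbred lines are propagated through discrete,
non-overlapping generations at fixed census (160 seeds per flat).  Each
generation: every individual expresses a phenotype (line genotypic value
plus environmental noise), receives realized fitness from the treatment's
fitness surface evaluated at the standardized phenotype (truncated at 0),
and the next generation is a multinomial draw of *census* offspring with
probabilities proportional to per-line summed fitness.  Selfing means
offspring inherit the parental line exactly — no recombination, so a line
lost from a population never reappears.

Standardization of phenotypes uses the founding family's phenotypic
moments as a fixed reference across generations, so a surface's b/g keep
their meaning throughout a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .family import RILFamily, _derive_identity_traits, family_phenotypic_moments
from .simulate import FitnessSurface
from .traits import BASE_TRAITS


@dataclass
class ExperimentalPopulation:
    population_id: str
    treatment: str
    generation: int
    counts: np.ndarray  # per-line founder counts, aligned with line_ids
    line_ids: list[str]

    @property
    def census(self) -> int:
        return int(self.counts.sum())

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class PopulationTrajectory:
    population_id: str
    treatment: str
    generations: list[ExperimentalPopulation] = field(default_factory=list)
    trait_means: list[dict[str, float]] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)

    def counts_matrix(self) -> np.ndarray:
        return np.vstack([g.counts for g in self.generations])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.generations:
            for line, c in zip(g.line_ids, g.counts):
                if c > 0:
                    rows.append((self.population_id, self.treatment, g.generation, line, int(c)))
        return pd.DataFrame(
            rows, columns=["population", "treatment", "generation", "line_id", "count"]
        )


def found_population(
    family: RILFamily,
    treatment: str,
    census: int | None = None,
    population_id: str = "P1",
    weights: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ExperimentalPopulation:
    """Found a G0 population: one seed of every RIL by default.

    A non-default *census* requires explicit *weights* (multinomial draw);
    otherwise a census differing from the number of RILs is an error.
    """
    lines = family.ril_ids
    n = len(lines)
    if census is None:
        census = n
    if census == n and weights is None:
        counts = np.ones(n, dtype=np.int64)
    elif weights is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        p = np.asarray(weights, dtype=float)
        counts = rng.multinomial(census, p / p.sum())
    else:
        raise ValueError(
            f"census {census} ≠ number of lines {n}: pass explicit weights to override"
        )
    return ExperimentalPopulation(
        population_id=population_id,
        treatment=treatment,
        generation=0,
        counts=counts,
        line_ids=lines,
    )


def _line_fitness(
    pop: ExperimentalPopulation,
    family: RILFamily,
    surface: FitnessSurface,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float]:
    """Summed realized fitness per line and the population mean fitness."""
    traits = surface.traits()
    mean, sd = family_phenotypic_moments(family)
    counts = pop.counts
    alive = counts > 0
    idx = np.repeat(np.arange(len(counts))[alive], counts[alive])
    geno = family.genotypic_values.loc[pop.line_ids].iloc[idx][
        [t for t in traits if t in BASE_TRAITS]
    ]
    n_ind = len(geno)
    z = pd.DataFrame(index=np.arange(n_ind))
    for t in traits:
        if t not in geno.columns:  # derived traits are outside the simulator's surface space
            raise ValueError(f"surface trait {t!r} is not a base trait of the family")
        noise = rng.standard_normal(n_ind) * float(family.residual_sd.get(t, 0.0))
        z[t] = (geno[t].to_numpy() + noise - float(mean[t])) / float(sd[t])
    w = surface.relative_fitness(z)
    fitness = surface.w0 * w + rng.standard_normal(len(w)) * surface.noise_sd
    fitness = np.clip(fitness, 0.0, None)
    per_line = np.bincount(idx, weights=fitness, minlength=len(counts))
    return per_line, float(fitness.mean())


def advance_generation(
    pop: ExperimentalPopulation,
    family: RILFamily,
    surface: FitnessSurface,
    rng: np.random.Generator | int = 0,
    census: int | None = None,
) -> tuple[ExperimentalPopulation, float]:
    """One generation of selfing + fitness-proportional seed sampling.

    Returns the next-generation population and the parental mean realized
    fitness.  Raises if total realized fitness is zero (extinction).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if pop.census == 0:
        raise ValueError("population is empty")
    census = pop.census if census is None else census
    per_line, mean_fit = _line_fitness(pop, family, surface, rng)
    total = per_line.sum()
    if total <= 0:
        raise RuntimeError(
            f"population {pop.population_id} went extinct at generation {pop.generation}"
        )
    counts = rng.multinomial(census, per_line / total)
    nxt = ExperimentalPopulation(
        population_id=pop.population_id,
        treatment=pop.treatment,
        generation=pop.generation + 1,
        counts=counts,
        line_ids=pop.line_ids,
    )
    return nxt, mean_fit


def _population_trait_means(pop: ExperimentalPopulation, family: RILFamily) -> dict[str, float]:
    g = family.genotypic_values.loc[pop.line_ids]
    w = pop.counts / pop.census
    return {t: float(g[t].to_numpy() @ w) for t in family.traits}


def run_lns(
    family: RILFamily,
    treatments: list[str],
    n_populations: int,
    n_generations: int,
    surfaces: dict[str, FitnessSurface],
    seed: int = 0,
) -> list[PopulationTrajectory]:
    """Run independent replicate trajectories for each treatment intensity.

    Each population gets its own independent random stream spawned from the
    master seed, so trajectories are reproducible individually and jointly.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be ≥ 1")
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(treatments) * n_populations)
    trajectories = []
    k = 0
    for treatment in treatments:
        surface = surfaces[treatment]
        for p in range(1, n_populations + 1):
            rng = np.random.default_rng(streams[k])
            k += 1
            pop = found_population(family, treatment, population_id=f"{treatment}:{p}")
            traj = PopulationTrajectory(population_id=f"{treatment}:{p}", treatment=treatment)
            traj.generations.append(pop)
            traj.trait_means.append(_population_trait_means(pop, family))
            for _ in range(n_generations):
                pop, mean_fit = advance_generation(pop, family, surface, rng)
                traj.generations.append(pop)
                traj.trait_means.append(_population_trait_means(pop, family))
                traj.mean_fitness.append(mean_fit)
            trajectories.append(traj)
    return trajectories


def expected_response(
    family: RILFamily, surface: FitnessSurface, trait: str
) -> float:
    """Breeder's-equation prediction of the per-generation change in the
    population mean of *trait* (trait units).

    For Gaussian standardized phenotypes the selection differential is
    ``S_t = Σ_k b_k ρ_P(t,k) / (1 + ½ Σ_k g_k)`` (quadratic terms shift
    mean fitness but not the covariance), and the genetic response is
    ``Δz̄ = H²_t · S_t · sd_P(t)``.  Ignores the truncation of fitness at 0
    and fitness noise (both mean-preserving at realistic settings).
    """
    mean, sd = family_phenotypic_moments(family)
    if trait not in mean.index:
        raise KeyError(f"{trait!r} is not a base trait of the family")
    traits = [t for t in surface.traits()]
    # phenotypic correlations between trait and each surface trait
    g = family.genotypic_values[[c for c in mean.index]]
    cov_g = g.cov()
    resid = family.residual_sd.reindex(mean.index).fillna(0.0)
    cov_p = cov_g + np.diag(resid**2)
    cov_p = pd.DataFrame(cov_p, index=mean.index, columns=mean.index)
    mean_w = 1.0 + 0.5 * sum(surface.quadratic.get(k, 0.0) for k in traits)
    s = 0.0
    for k in traits:
        b = surface.linear.get(k, 0.0)
        if b == 0.0:
            continue
        rho = float(cov_p.loc[trait, k] / (sd[trait] * sd[k]))
        s += b * rho
    s /= mean_w
    h2 = float(family.h2_target.get(trait, 0.0))
    return h2 * s * float(sd[trait])


def simulate_g0_block_data(
    family: RILFamily,
    block_effects: dict[int, dict[str, float]] | None = None,
    n_blocks: int = 3,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Phenotype the G0 reference: one replicate of every RIL per block,
    grown in common-garden (control) conditions."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    block_effects = block_effects or {}
    base = [t for t in family.traits if t in BASE_TRAITS]
    rows = []
    for block in range(1, n_blocks + 1):
        geno = family.genotypic_values.loc[family.ril_ids, base]
        noise = rng.standard_normal(geno.shape) * family.residual_sd.reindex(base).to_numpy()
        vals = geno.to_numpy() + noise
        for t_i, t in enumerate(base):
            vals[:, t_i] += block_effects.get(block, {}).get(t, 0.0)
        for i, line in enumerate(geno.index):
            rows.append([block, line] + list(vals[i]))
    out = pd.DataFrame(rows, columns=["block", "line_id"] + base)
    _derive_identity_traits(out)
    return out


def sample_phenotyping(
    trajectories: list[PopulationTrajectory],
    family: RILFamily,
    generations: tuple[int, ...] = (1, 2, 3, 4),
    seeds_per_block: int = 4,
    n_blocks: int = 3,
    block_effects: dict[int, dict[str, float]] | None = None,
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Common-garden phenotyping sample of the evolved populations.

    For every population × generation, ``seeds_per_block`` seeds are drawn
    per block in proportion to the population's line composition and
    phenotyped under control conditions (12 plants per combination at the
    default 4 × 3).  RP/FRR are not blanked here: phenotyping is done in a
    watered common garden regardless of the selective treatment.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    block_effects = block_effects or {}
    base = [t for t in family.traits if t in BASE_TRAITS]
    resid = family.residual_sd.reindex(base).to_numpy()
    rows = []
    for traj in trajectories:
        for gen in generations:
            pop = traj.generations[gen]
            p = pop.counts / pop.census
            for block in range(1, n_blocks + 1):
                draw = rng.choice(len(p), size=seeds_per_block, p=p)
                geno = family.genotypic_values.loc[pop.line_ids].iloc[draw][base]
                vals = geno.to_numpy() + rng.standard_normal(geno.shape) * resid
                for t_i, t in enumerate(base):
                    vals[:, t_i] += block_effects.get(block, {}).get(t, 0.0)
                for i, line in enumerate(geno.index):
                    rows.append(
                        [traj.population_id, traj.treatment, gen, block, line] + list(vals[i])
                    )
    out = pd.DataFrame(
        rows,
        columns=["population", "treatment_intensity", "generation", "block", "line_id"] + base,
    )
    _derive_identity_traits(out)
    return out
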