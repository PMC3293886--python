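"""End-to-end pipeline drivers.

``run_experiment_a`` chains the seed-production stages: synthesize (or
load) a per-plant phenotype/fitness table, run phenotypic and genotypic
selection analyses, heritabilities, correlation matrices and the
genetic-constraint scan, and return (optionally write) report tables.
``run_lns_pipeline`` chains the experimental-evolution stages: forward
simulation, common-garden phenotyping sample, and the repeated
theoretical-G0 ANOVA with the 95% criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import defaults
from .design import build_design_a
from .evolve import run_lns, sample_phenotyping, simulate_g0_block_data
from .family import make_ril_family
from .io import write_phenotypes
from .quantgen import (
    correlation_matrices,
    detect_genetic_constraints,
    estimate_heritability,
)
from .resample import repeated_g0_significance
from .selection import (
    selection_differential,
    selection_gradients,
    selection_table,
    sequential_bonferroni,
    standardize_and_relativize,
)
from .traits import EXPERIMENT_A_TREATMENTS, GRADIENT_TRAITS, TRAITS


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | None = None
    n_lines: int = defaults.N_LINES
    levels: tuple[str, ...] = ("phenotypic", "genotypic")
    alpha: float = 0.05
    n_repeats: int = 500
    lns_treatments: tuple[str, ...] = ("control", "W1", "W2", "W3", "W4")
    lns_n_populations: int = 5
    lns_n_generations: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set an explicit seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("levels", "lns_treatments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def make_default_family(n_lines: int = defaults.N_LINES, seed: int = 0, include_parents: bool = True):
    return make_ril_family(
        n_lines=n_lines,
        trait_means=defaults.TRAIT_MEANS,
        genetic_sds=defaults.GENETIC_SDS,
        genetic_corr=defaults.GENETIC_CORR,
        h2_target=defaults.H2_TARGET,
        seed=seed,
        include_parents=include_parents,
    )


def simulate_experiment_a(config: PipelineConfig) -> pd.DataFrame:
    """Synthesize the full experiment-A phenotype/fitness table."""
    from .simulate import simulate_fitness, simulate_phenotypes

    rng = np.random.default_rng(config.seed)
    family = make_default_family(config.n_lines, seed=rng, include_parents=True)
    design = build_design_a(ril_ids=family.ril_ids, seed=rng)
    table = simulate_phenotypes(
        family,
        design,
        treatment_shifts=defaults.TREATMENT_SHIFTS,
        block_effects=defaults.BLOCK_EFFECTS,
        seed=rng,
    )
    return simulate_fitness(table, defaults.SURFACES, seed=rng)


def run_experiment_a(
    config: PipelineConfig, table: pd.DataFrame | None = None
) -> dict[str, object]:
    """Selection, heritability, correlation and constraint reports.

    Returns a dict with keys ``table``, ``selection`` (tidy S/β/γ report
    with Holm flags), ``heritability``, ``correlations`` (per treatment)
    and ``constraints``.
    """
    if table is None:
        table = simulate_experiment_a(config)
    treatments = [t for t in EXPERIMENT_A_TREATMENTS if t in set(table["treatment"])]
    if not treatments:
        raise ValueError("no recognized treatments in table")

    selection_frames = []
    constraint_rows = []
    correlations = {}
    for level in config.levels:
        std = standardize_and_relativize(table, level=level)
        estimates = []
        for trait in [t for t in TRAITS if t in table.columns]:
            estimates.extend(selection_differential(std, trait))
        grads = selection_gradients(std)
        estimates.extend(grads)
        report = selection_table(estimates)
        # Holm flags within treatment at k = number of phenological traits
        k = len([t for t in TRAITS if t in table.columns])
        for col, flag in (("p_S", "sig_S"), ("p_beta", "sig_beta"), ("p_gamma", "sig_gamma")):
            report[flag] = False
            for trt in treatments:
                mask = report["treatment"] == trt
                report.loc[mask, flag] = sequential_bonferroni(
                    report.loc[mask, col].to_numpy(), k=k, alpha=config.alpha
                )
        selection_frames.append(report)

        if level == "genotypic":
            for trt in treatments:
                corr = correlation_matrices(table, treatment=trt)
                correlations[trt] = corr
                est_trt = [e for e in grads if e.treatment == trt]
                constraints = detect_genetic_constraints(
                    est_trt, corr.genotypic, corr.genotypic_p, alpha=config.alpha
                )
                for c in constraints:
                    constraint_rows.append({"treatment": trt, **c})

    herit_rows = []
    for trt in treatments:
        for trait in [t for t in TRAITS + ("FITNESS",) if t in table.columns]:
            sub = table[table["treatment"] == trt]
            if sub[trait].notna().sum() == 0:
                continue
            h = estimate_heritability(table, trait, treatment=trt)
            herit_rows.append(
                {"treatment": trt, "trait": trait, "H2": h.H2, "F": h.F, "p": h.p}
            )

    out = {
        "table": table,
        "selection": pd.concat(selection_frames, ignore_index=True),
        "heritability": pd.DataFrame(herit_rows),
        "correlations": correlations,
        "constraints": pd.DataFrame(
            constraint_rows,
            columns=["treatment", "trait_i", "trait_j", "beta_i", "beta_j", "r_g"],
        ),
    }
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_phenotypes(table, out_dir / "experiment_a_phenotypes.csv")
        out["selection"].to_csv(out_dir / "selection_report.csv", index=False, na_rep="NA")
        out["heritability"].to_csv(out_dir / "heritability_report.csv", index=False, na_rep="NA")
        out["constraints"].to_csv(out_dir / "constraints.csv", index=False, na_rep="NA")
        for trt, corr in correlations.items():
            slug = trt.replace(" ", "_")
            corr.phenotypic.to_csv(out_dir / f"corr_phenotypic_{slug}.csv", na_rep="NA")
            corr.genotypic.to_csv(out_dir / f"corr_genotypic_{slug}.csv", na_rep="NA")
    return out


def run_lns_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Forward-simulate the LNS experiment and run the resampled-G0 tests.

    Returns trajectories, the phenotyping sample, the G0 block data and a
    per-trait report table (factor × p95/verdict).
    """
    rng_seed = np.random.SeedSequence(config.seed)
    sim_seed, pheno_seed, g0_seed, test_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in rng_seed.spawn(4)
    )
    family = make_default_family(config.n_lines, seed=sim_seed, include_parents=False)
    trajectories = run_lns(
        family,
        treatments=list(config.lns_treatments),
        n_populations=config.lns_n_populations,
        n_generations=config.lns_n_generations,
        surfaces=defaults.LNS_SURFACES,
        seed=sim_seed,
    )
    pheno = sample_phenotyping(
        trajectories, family, block_effects=defaults.BLOCK_EFFECTS, rng=pheno_seed
    )
    g0 = simulate_g0_block_data(
        family, block_effects=defaults.BLOCK_EFFECTS, rng=g0_seed
    )

    rows = []
    reports = {}
    for trait in [t for t in GRADIENT_TRAITS if t in pheno.columns]:
        rep = repeated_g0_significance(
            g0, pheno, trait, n_repeats=config.n_repeats, seed=test_seed,
            alpha=config.alpha,
        )
        reports[trait] = rep
        for factor in rep.p95.index:
            rows.append(
                {
                    "trait": trait,
                    "factor": factor,
                    "p95": rep.p95[factor],
                    "significant": bool(rep.verdict[factor]),
                }
            )
    report_table = pd.DataFrame(rows)

    out = {
        "family": family,
        "trajectories": trajectories,
        "phenotyping": pheno,
        "g0_block_data": g0,
        "reports": reports,
        "report_table": report_table,
    }
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        traj = pd.concat([t.to_frame() for t in trajectories], ignore_index=True)
        traj.to_csv(out_dir / "lns_trajectories.csv", index=False)
        write_phenotypes(pheno, out_dir / "lns_phenotyping.csv")
        report_table.to_csv(out_dir / "lns_report.csv", index=False, na_rep="NA")
    return out
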