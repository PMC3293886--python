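"""Quantitative genetics of the RIL phenotype tables.

* Broad-sense heritability per trait × treatment from the mean squares of
  the two-way (block + genotype) ANOVA:
  ``σ̂²_G = (MS_G − MS_E) / r`` and ``H² = σ̂²_G / (σ̂²_G + MS_E)``,
  clamped at 0, with r the number of replicates per line (3 blocks).
* The treatment × genotype GLM
  ``Y = μ + treatment + block(treatment) + genotype + treatment×genotype + ε``
  on Box-Cox-transformed responses, with model selection by AIC (a
  simpler model is retained when it lies within 2 points of the minimum).
* Pairwise Pearson correlations at the individual (phenotypic) and
  line-mean (genotypic) level.
* Genetic-constraint detection: two traits are jointly constrained when
  directional selection on both opposes their genetic correlation
  (β_i · β_j · r_g < 0, all three significant).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._linmod import dummies, interaction, sequential_anova
from .selection import SelectionEstimate
from .transform import boxcox_transform
from .traits import TRAITS


@dataclass
class HeritabilityEstimate:
    trait: str
    treatment: str | None
    H2: float
    MS_genotype: float
    MS_error: float
    r: float
    F: float
    p: float


@dataclass
class AnovaReport:
    anova: pd.DataFrame
    aic: dict[str, float]
    retained: tuple[str, ...]
    boxcox_lambda: float
    boxcox_shift: float


@dataclass
class CorrelationMatrices:
    treatment: str | None
    phenotypic: pd.DataFrame
    phenotypic_p: pd.DataFrame
    genotypic: pd.DataFrame
    genotypic_p: pd.DataFrame


def estimate_heritability(
    table: pd.DataFrame,
    trait: str,
    treatment: str | None = None,
    block_col: str = "block",
) -> HeritabilityEstimate:
    """MS-based broad-sense heritability for one trait in one treatment.

    Fits ``y = μ + block + genotype + ε`` (all fixed) and converts the
    genotype and error mean squares into an among-line variance component.
    With unbalanced replication r is the standard effective replicate
    number ``(N − Σ n_i²/N) / (a − 1)``.
    """
    sub = table
    if treatment is not None:
        sub = sub[sub["treatment"] == treatment]
    d = sub[[block_col, "line_id", trait]].dropna()
    if d[block_col].nunique() < 2:
        raise ValueError("need at least 2 blocks (replicates per line) to estimate MS_error")
    if d["line_id"].nunique() < 2:
        raise ValueError("need at least 2 lines")

    y = d[trait].to_numpy(dtype=float)
    anova, rss, df_resid = sequential_anova(
        y, [("block", dummies(d[block_col])), ("genotype", dummies(d["line_id"]))]
    )
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom: MS_error inestimable")
    ms_g = float(anova.loc["genotype", "mean_sq"])
    ms_e = rss / df_resid
    counts = d["line_id"].value_counts().to_numpy(dtype=float)
    n_tot = counts.sum()
    a = len(counts)
    r = (n_tot - (counts**2).sum() / n_tot) / (a - 1)

    sigma2_g = max((ms_g - ms_e) / r, 0.0)
    h2 = sigma2_g / (sigma2_g + ms_e) if (sigma2_g + ms_e) > 0 else 1.0
    return HeritabilityEstimate(
        trait=trait,
        treatment=treatment,
        H2=min(h2, 1.0),
        MS_genotype=ms_g,
        MS_error=ms_e,
        r=r,
        F=float(anova.loc["genotype", "F"]),
        p=float(anova.loc["genotype", "p"]),
    )


def fit_treatment_genotype_model(
    table: pd.DataFrame, trait: str, transform: bool = True
) -> AnovaReport:
    """Treatment × genotype GLM with AIC term selection.

    Candidate models form the marginality-respecting ladder
    intercept → +treatment → +block(treatment) → +genotype →
    +treatment×genotype; the retained model has the fewest terms among
    those within 2 AIC points of the minimum.  The report carries the
    Type-I ANOVA of the retained model.
    """
    d = table[["treatment", "block", "line_id", trait]].dropna()
    if d["treatment"].nunique() < 2 or d["line_id"].nunique() < 2:
        raise ValueError("need ≥ 2 treatments and ≥ 2 genotypes")
    y = d[trait].to_numpy(dtype=float)
    lam, shift = np.nan, 0.0
    if transform:
        y, lam, shift = boxcox_transform(y)

    trt = dummies(d["treatment"])
    blk = dummies(d["treatment"].astype(str) + "/" + d["block"].astype(str))
    gen = dummies(d["line_id"])
    inter = interaction(trt, gen)
    ladder: list[tuple[tuple[str, ...], list[tuple[str, np.ndarray]]]] = [
        ((), []),
        (("treatment",), [("treatment", trt)]),
        (("treatment", "block(treatment)"), [("treatment", trt), ("block(treatment)", blk)]),
        (
            ("treatment", "block(treatment)", "genotype"),
            [("treatment", trt), ("block(treatment)", blk), ("genotype", gen)],
        ),
        (
            ("treatment", "block(treatment)", "genotype", "treatment:genotype"),
            [
                ("treatment", trt),
                ("block(treatment)", blk),
                ("genotype", gen),
                ("treatment:genotype", inter),
            ],
        ),
    ]

    n = len(y)
    aic: dict[str, float] = {}
    fits = {}
    for names, terms in ladder:
        if terms:
            anova, rss, df_resid = sequential_anova(y, terms)
            k = n - df_resid  # rank of the mean structure
        else:
            rss = float(((y - y.mean()) ** 2).sum())
            k = 1
            anova = pd.DataFrame(columns=["df", "sum_sq", "mean_sq", "F", "p"])
        label = " + ".join(names) if names else "intercept"
        aic[label] = n * np.log(rss / n) + 2 * (k + 1)
        fits[label] = (names, anova)

    best = min(aic.values())
    # fewest-terms model within 2 AIC points of the minimum
    candidates = [lbl for lbl in aic if aic[lbl] <= best + 2.0]
    retained_label = min(candidates, key=lambda lbl: len(fits[lbl][0]))
    names, anova = fits[retained_label]
    return AnovaReport(
        anova=anova, aic=aic, retained=names, boxcox_lambda=lam, boxcox_shift=shift
    )


def correlation_matrices(
    table: pd.DataFrame,
    treatment: str | None = None,
    traits: tuple[str, ...] | None = None,
    min_pairs: int = 4,
) -> CorrelationMatrices:
    """Phenotypic (individual-level) and genotypic (line-mean) Pearson
    correlation matrices with two-sided p-values; cells with fewer than
    *min_pairs* complete pairs are NA."""
    sub = table
    if treatment is not None:
        sub = sub[sub["treatment"] == treatment]
    if traits is None:
        traits = tuple(t for t in TRAITS if t in sub.columns and sub[t].notna().any())

    pheno = sub[list(traits)]
    geno = sub.groupby("line_id", sort=False)[list(traits)].mean()

    def _pairwise(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        k = len(traits)
        r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
        p = pd.DataFrame(np.zeros((k, k)), index=traits, columns=traits)
        np.fill_diagonal(p.values, 0.0)
        for a, b in combinations(traits, 2):
            d = df[[a, b]].dropna()
            if len(d) < min_pairs:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            res = stats.pearsonr(d[a], d[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
        return r, p

    rp, pp = _pairwise(pheno)
    rg, pg = _pairwise(geno)
    return CorrelationMatrices(
        treatment=treatment,
        phenotypic=rp,
        phenotypic_p=pp,
        genotypic=rg,
        genotypic_p=pg,
    )


def detect_genetic_constraints(
    estimates: list[SelectionEstimate] | pd.DataFrame,
    genotypic_r: pd.DataFrame,
    genotypic_p: pd.DataFrame,
    alpha: float = 0.05,
) -> list[dict]:
    """Flag trait pairs whose genetic correlation opposes joint selection.

    A pair (i, j) is constrained iff β_i, β_j and r_g(i, j) are all
    significant at *alpha* and ``β_i · β_j · r_g(i, j) < 0`` — selection in
    the same direction with an antagonistic correlation, or in opposite
    directions with a positive one.  The rule is symmetric in (i, j).
    """
    if isinstance(estimates, list):
        est = pd.DataFrame(
            [(e.trait, e.beta, e.p_beta) for e in estimates],
            columns=["trait", "beta", "p_beta"],
        ).set_index("trait")
    else:
        est = estimates.set_index("trait") if "trait" in estimates.columns else estimates

    flagged = []
    for i, j in combinations(est.index, 2):
        if i not in genotypic_r.index or j not in genotypic_r.columns:
            raise KeyError(f"trait pair ({i}, {j}) absent from the correlation matrix")
        bi, pi = est.loc[i, "beta"], est.loc[i, "p_beta"]
        bj, pj = est.loc[j, "beta"], est.loc[j, "p_beta"]
        rg, prg = genotypic_r.loc[i, j], genotypic_p.loc[i, j]
        if any(pd.isna(v) for v in (bi, bj, rg, pi, pj, prg)):
            continue
        if pi < alpha and pj < alpha and prg < alpha and bi * bj * rg < 0:
            flagged.append(
                {"trait_i": i, "trait_j": j, "beta_i": bi, "beta_j": bj, "r_g": rg}
            )
    return flagged
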