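"""Significance machinery for the LNS phenotyping data.

The initial generation G0 was grown as one replicate of each of the 160
RILs per block, not as 12-plant populations, so it is not directly
comparable to the evolved-population samples.  "Theoretical" G0
populations bridge the gap: per block, 25 disjoint sub-populations of 4
RILs are drawn without replacement; sub-populations are concatenated one
per block into 25 pseudo-populations of 12 under the constraint that no
RIL appears twice within a population; the pseudo-populations are randomly
partitioned five-per-treatment-intensity.  The five-factor ANOVA

    Y = μ + block + generation + treatment intensity
        + generation×treatment intensity
        + population(treatment intensity)
        + population(treatment intensity)×generation + ε

(Box-Cox-transformed response) is then fitted with F-tests over the
denominators implied by expected mean squares for population as a random
factor: treatment intensity over MS[population(intensity)], generation and
the generation×intensity interaction over MS[population(intensity)×
generation], and block and the population terms over the residual.

Because the construction is stochastic, it is repeated (500 times by
default) and a factor is declared significant only when at least 95% of
its P-values fall below 0.05; the 95th percentile of the P-value
distribution is reported per factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from ._linmod import dummies, interaction, sequential_anova
from .transform import boxcox_transform

FACTORS = (
    "block",
    "generation",
    "treatment_intensity",
    "generation:treatment_intensity",
    "population(treatment_intensity)",
    "population(treatment_intensity):generation",
)

#: F-test denominator per factor ("residual" or another factor's MS)
DENOMINATORS = {
    "block": "residual",
    "generation": "population(treatment_intensity):generation",
    "treatment_intensity": "population(treatment_intensity)",
    "generation:treatment_intensity": "population(treatment_intensity):generation",
    "population(treatment_intensity)": "residual",
    "population(treatment_intensity):generation": "residual",
}


@dataclass
class TheoreticalG0Set:
    """25 pseudo-populations of 12 G0 individuals each.

    ``members`` has one row per individual: population id, treatment
    intensity, block and line id.
    """

    members: pd.DataFrame
    n_restarts: int = 0
    n_redraws: int = 0


def construct_theoretical_g0(
    g0_block_data: pd.DataFrame,
    population_labels: list[tuple[str, object]] | None = None,
    rng: np.random.Generator | int = 0,
    n_populations: int = 25,
    sub_size: int = 4,
    max_restarts: int = 1000,
    max_redraws: int = 50,
) -> TheoreticalG0Set:
    """Assemble theoretical G0 populations from per-block RIL records.

    Parameters
    ----------
    g0_block_data
        One row per (block, line) G0 individual; needs columns ``block``
        and ``line_id`` (trait columns are carried along by the caller).
    population_labels
        The 25 real (treatment intensity, population id) combinations the
        pseudo-populations are mapped onto; defaults to 5 populations in
        each of ``control, I1..I4``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if population_labels is None:
        population_labels = [
            (i, p) for i in ("control", "I1", "I2", "I3", "I4") for p in range(1, 6)
        ]
    if len(population_labels) != n_populations:
        raise ValueError("population_labels must have one entry per pseudo-population")

    blocks = sorted(g0_block_data["block"].unique())
    lines_by_block = {
        b: g0_block_data.loc[g0_block_data["block"] == b, "line_id"].unique()
        for b in blocks
    }
    need = n_populations * sub_size
    for b, lines in lines_by_block.items():
        if len(lines) < need:
            raise ValueError(
                f"block {b!r} has {len(lines)} distinct lines; {need} required"
            )

    n_redraws = 0
    total_restarts = 0
    while True:
        subpops = {
            b: rng.permutation(lines_by_block[b])[:need].reshape(n_populations, sub_size)
            for b in blocks
        }
        assignment = _match_subpops(subpops, blocks, n_populations, rng, max_restarts)
        if assignment is not None:
            restarts_used = assignment[1]
            total_restarts += restarts_used
            pops = assignment[0]
            break
        total_restarts += max_restarts
        n_redraws += 1
        if n_redraws > max_redraws:
            raise RuntimeError(
                f"theoretical-G0 matching unsatisfiable after {n_redraws} redraws "
                f"({total_restarts} restarts)"
            )

    label_order = rng.permutation(len(population_labels))
    rows = []
    for p_idx, per_block in enumerate(pops):
        intensity, pop_id = population_labels[label_order[p_idx]]
        for b, lines in zip(blocks, per_block):
            for line in lines:
                rows.append((pop_id, intensity, b, line))
    members = pd.DataFrame(
        rows, columns=["population", "treatment_intensity", "block", "line_id"]
    )
    return TheoreticalG0Set(members=members, n_restarts=total_restarts, n_redraws=n_redraws)


def _match_subpops(subpops, blocks, n_populations, rng, max_restarts):
    """Greedy randomized matching of one sub-population per block into
    populations without duplicated lines; returns (populations, restarts)
    or None when every restart failed."""
    first = blocks[0]
    for restart in range(max_restarts):
        pops = [[subpops[first][i]] for i in range(n_populations)]
        used_sets = [set(subpops[first][i]) for i in range(n_populations)]
        ok = True
        for b in blocks[1:]:
            avail = list(rng.permutation(n_populations))
            chosen = [-1] * n_populations
            for i in range(n_populations):
                pick = next(
                    (j for j in avail if not (set(subpops[b][j]) & used_sets[i])), None
                )
                if pick is None:
                    ok = False
                    break
                chosen[i] = pick
                avail.remove(pick)
            if not ok:
                break
            for i in range(n_populations):
                pops[i].append(subpops[b][chosen[i]])
                used_sets[i] |= set(subpops[b][chosen[i]])
        if ok:
            return pops, restart
    return None


def theoretical_g0_rows(
    g0_block_data: pd.DataFrame, tg0: TheoreticalG0Set
) -> pd.DataFrame:
    """Materialize the G0 pseudo-population records (generation 0) by
    joining the member list back onto the phenotyped G0 individuals."""
    merged = tg0.members.merge(g0_block_data, on=["block", "line_id"], how="left")
    merged.insert(0, "generation", 0)
    return merged


def fit_lns_anova(
    table: pd.DataFrame, trait: str, transform: bool = True
) -> pd.DataFrame:
    """Five-factor ANOVA of one trait with mixed-model F denominators.

    *table* needs columns ``block, generation, treatment_intensity,
    population`` and the trait.  Uses exact balanced-design sums of squares
    when every population×generation×block cell has the same count, and a
    sequential least-squares decomposition otherwise.  Returns a DataFrame
    indexed by factor with df, sum_sq, mean_sq, den_term, F and p.
    """
    cols = ["block", "generation", "treatment_intensity", "population", trait]
    d = table[cols].dropna()
    if d.empty:
        raise ValueError("no complete records for trait " + trait)
    y = d[trait].to_numpy(dtype=float)
    if transform:
        y, _, _ = boxcox_transform(y)

    blk = np.asarray(pd.Categorical(d["block"]).codes, dtype=np.int64)
    gen = np.asarray(pd.Categorical(d["generation"]).codes, dtype=np.int64)
    intensity = np.asarray(pd.Categorical(d["treatment_intensity"]).codes, dtype=np.int64)
    pop_fac = pd.Categorical(
        d["treatment_intensity"].astype(str) + "/" + d["population"].astype(str)
    )
    pop = np.asarray(pop_fac.codes, dtype=np.int64)
    n_b, n_g, n_i, n_p = blk.max() + 1, gen.max() + 1, intensity.max() + 1, pop.max() + 1

    # intensity of each population (nesting map)
    int_of_pop = np.zeros(n_p, dtype=int)
    int_of_pop[pop] = intensity

    cell = (pop * n_g + gen) * n_b + blk
    counts = np.bincount(cell, minlength=n_p * n_g * n_b)
    balanced = counts.min() == counts.max() and counts.min() > 0

    if balanced:
        ss, df = _balanced_lns_ss(y, blk, gen, intensity, pop, int_of_pop, n_b, n_g, n_i, n_p)
    else:
        ss, df = _unbalanced_lns_ss(y, blk, gen, intensity, pop)

    out = pd.DataFrame({"df": pd.Series(df), "sum_sq": pd.Series(ss)})
    out = out.loc[list(FACTORS) + ["residual"]]
    out["mean_sq"] = out["sum_sq"] / out["df"].replace(0, np.nan)
    fvals, pvals, dens = [], [], []
    for factor in FACTORS:
        den = DENOMINATORS[factor]
        ms_den = out.loc[den, "mean_sq"]
        df_den = out.loc[den, "df"]
        if out.loc[factor, "df"] < 1 or not np.isfinite(ms_den) or ms_den <= 0:
            fvals.append(np.nan)
            pvals.append(np.nan)
        else:
            f = out.loc[factor, "mean_sq"] / ms_den
            fvals.append(f)
            pvals.append(stats.f.sf(f, out.loc[factor, "df"], df_den))
        dens.append(den)
    out.loc[list(FACTORS), "den_term"] = dens
    out.loc[list(FACTORS), "F"] = fvals
    out.loc[list(FACTORS), "p"] = pvals
    return out


def _balanced_lns_ss(y, blk, gen, intensity, pop, int_of_pop, n_b, n_g, n_i, n_p):
    n = len(y)
    m = y.mean()

    def level_means(codes, k):
        cnt = np.bincount(codes, minlength=k).astype(float)
        return np.bincount(codes, weights=y, minlength=k) / cnt, cnt

    m_b, c_b = level_means(blk, n_b)
    m_g, c_g = level_means(gen, n_g)
    m_i, c_i = level_means(intensity, n_i)
    gi = gen * n_i + intensity
    m_gi, c_gi = level_means(gi, n_g * n_i)
    m_p, c_p = level_means(pop, n_p)
    pg = pop * n_g + gen
    m_pg, c_pg = level_means(pg, n_p * n_g)

    ss = {
        "block": float(c_b @ (m_b - m) ** 2),
        "generation": float(c_g @ (m_g - m) ** 2),
        "treatment_intensity": float(c_i @ (m_i - m) ** 2),
    }
    # interaction deviations
    gi_g = np.repeat(np.arange(n_g), n_i)
    gi_i = np.tile(np.arange(n_i), n_g)
    dev_gi = m_gi - m_g[gi_g] - m_i[gi_i] + m
    ss["generation:treatment_intensity"] = float(c_gi @ dev_gi**2)
    dev_p = m_p - m_i[int_of_pop]
    ss["population(treatment_intensity)"] = float(c_p @ dev_p**2)
    pg_p = np.repeat(np.arange(n_p), n_g)
    pg_g = np.tile(np.arange(n_g), n_p)
    pg_gi = pg_g * n_i + int_of_pop[pg_p]
    dev_pg = m_pg - m_p[pg_p] - m_gi[pg_gi] + m_i[int_of_pop[pg_p]]
    ss["population(treatment_intensity):generation"] = float(c_pg @ dev_pg**2)

    ss_tot = float(((y - m) ** 2).sum())
    ss["residual"] = max(ss_tot - sum(ss.values()), 0.0)

    df = {
        "block": n_b - 1,
        "generation": n_g - 1,
        "treatment_intensity": n_i - 1,
        "generation:treatment_intensity": (n_g - 1) * (n_i - 1),
        "population(treatment_intensity)": n_p - n_i,
        "population(treatment_intensity):generation": (n_p - n_i) * (n_g - 1),
    }
    df["residual"] = n - 1 - sum(df.values())
    return ss, df


def _unbalanced_lns_ss(y, blk, gen, intensity, pop):
    d_b, d_g, d_i, d_p = dummies(blk), dummies(gen), dummies(intensity), dummies(pop)
    terms = [
        ("block", d_b),
        ("generation", d_g),
        ("treatment_intensity", d_i),
        ("generation:treatment_intensity", interaction(d_g, d_i)),
        ("population(treatment_intensity)", d_p),
        ("population(treatment_intensity):generation", interaction(d_p, d_g)),
    ]
    anova, rss, df_resid = sequential_anova(y, terms)
    ss = dict(anova["sum_sq"])
    ss["residual"] = rss
    df = {k: int(v) for k, v in anova["df"].items()}
    df["residual"] = df_resid
    return ss, df


@dataclass
class ResamplingReport:
    """Distribution of per-factor P-values over repeated theoretical-G0
    constructions, with the 95%-criterion verdict."""

    trait: str
    pvalues: pd.DataFrame  # n_repeats × factors
    p95: pd.Series
    verdict: pd.Series
    n_repeats: int
    alpha: float = 0.05


def empirical_p95(p: np.ndarray) -> float:
    """95th percentile with the convention that ``p95 < 0.05`` holds iff at
    least 95% of the values are below 0.05 (order statistic at rank
    ``ceil(0.95 n)``)."""
    p = np.sort(np.asarray(p, dtype=float))
    n = len(p)
    return float(p[int(np.ceil(0.95 * n)) - 1])


def repeated_g0_significance(
    g0_block_data: pd.DataFrame,
    g1_g4_data: pd.DataFrame,
    trait: str,
    n_repeats: int = 500,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    transform: bool = True,
) -> ResamplingReport:
    """Repeat the theoretical-G0 construction and the five-factor ANOVA.

    Each repeat draws a fresh G0 set, merges it with the fixed G1–G4
    phenotyping records and refits the ANOVA (Box-Cox refitted on the
    pooled data of the repeat).  A factor is significant when ≥ 95% of its
    P-values fall below 0.05.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be ≥ 2")
    if n_repeats < 100:
        warnings.warn(
            "fewer than 100 repeats: the 95%-criterion verdict is unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = (
        g1_g4_data[["treatment_intensity", "population"]]
        .drop_duplicates()
        .itertuples(index=False, name=None)
    )
    labels = list(labels)
    cols = ["generation", "block", "treatment_intensity", "population", trait]
    fixed = g1_g4_data[cols]

    records = np.empty((n_repeats, len(FACTORS)))
    for r in range(n_repeats):
        tg0 = construct_theoretical_g0(
            g0_block_data, population_labels=labels, rng=rng,
            n_populations=len(labels),
        )
        g0_rows = theoretical_g0_rows(g0_block_data, tg0)[cols]
        pooled = pd.concat([g0_rows, fixed], ignore_index=True)
        anova = fit_lns_anova(pooled, trait, transform=transform)
        records[r] = anova.loc[list(FACTORS), "p"].to_numpy()

    pvals = pd.DataFrame(records, columns=list(FACTORS))
    p95 = pvals.apply(lambda c: empirical_p95(c.to_numpy()))
    verdict = (pvals < alpha).mean() >= 0.95
    return ResamplingReport(
        trait=trait, pvalues=pvals, p95=p95, verdict=verdict, n_repeats=n_repeats, alpha=alpha
    )


def tukey_letters(
    group_means,
    mse: float,
    df_error: int,
    n_per_group,
    alpha: float = 0.05,
) -> dict:
    """Compact letter display from Tukey's studentized-range test.

    Groups sharing a letter do not differ significantly at *alpha*.
    ``n_per_group`` may be a scalar (balanced) or a per-group mapping/array
    (Tukey–Kramer).  Returns ``{group: letters}``.
    """
    means = pd.Series(group_means, dtype=float)
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if df_error < 1:
        raise ValueError("df_error must be ≥ 1")
    n = pd.Series(n_per_group, index=means.index, dtype=float) if np.ndim(n_per_group) else pd.Series(
        float(n_per_group), index=means.index
    )
    q = studentized_range.ppf(1 - alpha, k, df_error)

    order = means.sort_values().index
    m = means[order].to_numpy()
    nn = n[order].to_numpy()

    def sig(i: int, j: int) -> bool:
        se = np.sqrt(mse / 2.0 * (1.0 / nn[i] + 1.0 / nn[j]))
        return abs(m[i] - m[j]) > q * se

    # maximal runs of mutually non-significant groups along the mean order
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and all(not sig(a, j + 1) for a in range(i, j + 1)):
            j += 1
        if not intervals or intervals[-1][1] < j or intervals[-1][0] > i:
            if not any(lo <= i and j <= hi for lo, hi in intervals):
                intervals.append((i, j))

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for letter_idx, (lo, hi) in enumerate(intervals):
        for g in order[lo : hi + 1]:
            letters[g] += alphabet[letter_idx % len(alphabet)]
    return {g: letters[g] for g in means.index}
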