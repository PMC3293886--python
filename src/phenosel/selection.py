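"""Lande–Arnold selection analysis.

Within each treatment, traits are standardized to mean 0 / SD 1 (sample,
n−1 denominator) and fitness is divided by its treatment mean, giving
relative fitness w.  The standardized selection differential S of a trait
is the slope of the simple regression of w on z — numerically identical to
cov(w, z) because var(z) = 1 — and captures total (direct plus indirect)
selection.  Directional gradients β and quadratic coefficients γ come from
one multiple polynomial regression of w on all z_k and z_k² (no
cross-products); the raw quadratic coefficient and its SE are doubled so
that γ estimates the curvature of the individual fitness surface
(stabilizing when γ < 0, disruptive when γ > 0).  ANT is excluded from the
polynomial model because it is the sum of BT and INT.

The genotypic level repeats the analysis on line means within treatment,
which removes environmental covariance between trait and fitness.
Multiplicity within a treatment is controlled with a Holm step-down
(sequential Bonferroni) rule at k = 7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traits import FITNESS, GRADIENT_TRAITS, TRAITS

#: condition-number threshold above which a gradient design is rejected
_COND_MAX = 1e8


@dataclass
class SelectionEstimate:
    """Per trait × treatment × level selection estimates.

    ``S``/``beta``/``gamma`` and their SEs and p-values are filled by
    :func:`selection_differential` and :func:`selection_gradients`; unfilled
    components are NaN.
    """

    trait: str
    treatment: str
    level: str
    n: int
    S: float = np.nan
    se_S: float = np.nan
    p_S: float = np.nan
    beta: float = np.nan
    se_beta: float = np.nan
    p_beta: float = np.nan
    gamma: float = np.nan
    se_gamma: float = np.nan
    p_gamma: float = np.nan
    r2: float = np.nan


def standardize_and_relativize(
    table: pd.DataFrame,
    level: str = "phenotypic",
    treatment_col: str = "treatment",
    traits: tuple[str, ...] = TRAITS,
) -> pd.DataFrame:
    """Standardize traits and relativize fitness within each treatment.

    Returns a copy of the table (collapsed to line means within treatment
    at the genotypic level) with added columns ``z_<trait>`` and ``w``.
    Standardization uses the complete cases of each trait separately; the
    sample (n−1) SD is used so that the regression-slope/covariance
    identity for S holds exactly.
    """
    if level not in ("phenotypic", "genotypic"):
        raise ValueError("level must be 'phenotypic' or 'genotypic'")
    present = [t for t in traits if t in table.columns]

    if level == "genotypic":
        cols = present + ([FITNESS] if FITNESS in table.columns else [])
        table = (
            table.groupby([treatment_col, "line_id"], sort=False)[cols]
            .mean()
            .reset_index()
        )

    out = table.copy()
    out.attrs["level"] = level
    for treatment, idx in out.groupby(treatment_col, sort=False).groups.items():
        sub = out.loc[idx]
        if FITNESS in out.columns:
            fit = sub[FITNESS].astype(float)
            if fit.notna().sum() < 3:
                raise ValueError(f"treatment {treatment!r}: fewer than 3 fitness records")
            mean_fit = fit.mean()
            if not mean_fit > 0:
                raise ValueError(f"treatment {treatment!r}: mean fitness is not positive")
            out.loc[idx, "w"] = fit / mean_fit
        for trait in present:
            x = sub[trait].astype(float)
            if x.notna().sum() == 0:
                out.loc[idx, f"z_{trait}"] = np.nan
                continue
            sd = x.std(ddof=1)
            if not sd > 0:
                raise ValueError(
                    f"trait {trait!r} has zero variance in treatment {treatment!r}"
                )
            out.loc[idx, f"z_{trait}"] = (x - x.mean()) / sd
    return out


def selection_differential(
    std_table: pd.DataFrame,
    trait: str,
    treatment_col: str = "treatment",
) -> list[SelectionEstimate]:
    """Standardized selection differential S per treatment.

    S is the OLS slope of w on the standardized trait; its SE and p-value
    come from the simple regression t-test.
    """
    zcol = f"z_{trait}"
    if zcol not in std_table.columns:
        raise KeyError(f"table is not standardized for trait {trait!r}")
    level = std_table.attrs.get("level", "phenotypic")
    results = []
    for treatment, sub in std_table.groupby(treatment_col, sort=False):
        d = sub[[zcol, "w"]].dropna()
        n = len(d)
        if n == 0:
            continue
        if n < 3:
            raise ValueError(f"treatment {treatment!r}: n = {n} < 3 for trait {trait!r}")
        z = d[zcol].to_numpy()
        w = d["w"].to_numpy()
        res = stats.linregress(z, w)
        results.append(
            SelectionEstimate(
                trait=trait,
                treatment=treatment,
                level=level,
                n=n,
                S=res.slope,
                se_S=res.stderr,
                p_S=res.pvalue,
            )
        )
    return results


def _polynomial_design(
    sub: pd.DataFrame, traits: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    zcols = [f"z_{t}" for t in traits]
    d = sub[zcols + ["w"]].dropna()
    z = d[zcols].to_numpy()
    cols = ["const"] + [f"b_{t}" for t in traits] + [f"q_{t}" for t in traits]
    X = np.column_stack([np.ones(len(d)), z, z**2])
    return X, d["w"].to_numpy(), cols


def selection_gradients(
    std_table: pd.DataFrame,
    traits: tuple[str, ...] | None = None,
    treatment_col: str = "treatment",
) -> list[SelectionEstimate]:
    """Directional (β) and quadratic (γ) selection gradients per treatment.

    One multiple regression of w on all z_k and z_k² per treatment; γ and
    its SE are twice the raw quadratic coefficient and SE (which leaves the
    t statistic, hence the p-value, unchanged).  Traits that are entirely
    missing in a treatment (RP/FRR under water stress) are dropped from
    that treatment's model.
    """
    if traits is None:
        traits = tuple(t for t in GRADIENT_TRAITS if f"z_{t}" in std_table.columns)
    if "ANT" in traits:
        raise ValueError("ANT integrates BT and INT and cannot enter the polynomial model")
    level = std_table.attrs.get("level", "phenotypic")

    results: list[SelectionEstimate] = []
    for treatment, sub in std_table.groupby(treatment_col, sort=False):
        avail = [t for t in traits if sub[f"z_{t}"].notna().any()]
        X, w, cols = _polynomial_design(sub, avail)
        n, p = X.shape
        if n <= p:
            raise ValueError(f"treatment {treatment!r}: n = {n} too small for {p} terms")
        if np.linalg.cond(X) > _COND_MAX:
            raise ValueError(
                f"treatment {treatment!r}: collinear polynomial design for traits {avail}"
            )
        coef, _, _, _ = np.linalg.lstsq(X, w, rcond=None)
        resid = w - X @ coef
        rss = float(resid @ resid)
        tss = float(((w - w.mean()) ** 2).sum())
        df = n - p
        sigma2 = rss / df
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        tvals = coef / se
        pvals = 2 * stats.t.sf(np.abs(tvals), df)
        r2 = 1 - rss / tss if tss > 0 else np.nan

        for t in avail:
            ib = cols.index(f"b_{t}")
            iq = cols.index(f"q_{t}")
            results.append(
                SelectionEstimate(
                    trait=t,
                    treatment=treatment,
                    level=level,
                    n=n,
                    beta=coef[ib],
                    se_beta=se[ib],
                    p_beta=pvals[ib],
                    gamma=2 * coef[iq],
                    se_gamma=2 * se[iq],
                    p_gamma=pvals[iq],
                    r2=r2,
                )
            )
    return results


def compare_treatments(
    std_table: pd.DataFrame,
    treatment_a: str,
    treatment_b: str,
    traits: tuple[str, ...] | None = None,
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """ANCOVA-style comparison of selection between two treatments.

    Pools the two (already within-treatment standardized/relativized)
    tables and fits one polynomial regression with a treatment indicator
    and trait×treatment, trait²×treatment interactions.  A significant
    linear (quadratic) interaction for a trait indicates that directional
    (stabilizing/disruptive) selection differs between the treatments.

    Returns a DataFrame indexed by trait with the interaction coefficient
    estimates and p-values.
    """
    sub_a = std_table[std_table[treatment_col] == treatment_a]
    sub_b = std_table[std_table[treatment_col] == treatment_b]
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise ValueError("both treatments must be present in the table")

    if traits is None:
        traits = tuple(
            t
            for t in GRADIENT_TRAITS
            if f"z_{t}" in std_table.columns
            and sub_a[f"z_{t}"].notna().any()
            and sub_b[f"z_{t}"].notna().any()
        )
    avail_a = {t for t in traits if sub_a[f"z_{t}"].notna().any()}
    avail_b = {t for t in traits if sub_b[f"z_{t}"].notna().any()}
    if avail_a != avail_b:
        raise ValueError(
            f"trait sets differ between treatments: {sorted(avail_a ^ avail_b)}"
        )

    zcols = [f"z_{t}" for t in traits]
    pooled = pd.concat([sub_a, sub_b], ignore_index=True)
    d = pooled[zcols + ["w", treatment_col]].dropna()
    g = (d[treatment_col] == treatment_b).to_numpy(dtype=float)
    z = d[zcols].to_numpy()
    X = np.column_stack(
        [np.ones(len(d)), g, z, z**2, z * g[:, None], (z**2) * g[:, None]]
    )
    w = d["w"].to_numpy()
    coef, _, _, _ = np.linalg.lstsq(X, w, rcond=None)
    resid = w - X @ coef
    df = len(d) - X.shape[1]
    if df < 1:
        raise ValueError("insufficient data for the pooled interaction model")
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    pvals = 2 * stats.t.sf(np.abs(coef / np.where(se > 0, se, np.inf)), df)

    k = len(traits)
    rows = {}
    for j, t in enumerate(traits):
        ilin = 2 + 2 * k + j
        iquad = 2 + 3 * k + j
        rows[t] = {
            "delta_beta": coef[ilin],
            "p_linear_interaction": pvals[ilin],
            "delta_gamma": 2 * coef[iquad],
            "p_quadratic_interaction": pvals[iquad],
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def sequential_bonferroni(
    p_values, k: int | None = None, alpha: float = 0.05
) -> np.ndarray:
    """Holm step-down (sequential Bonferroni) significance flags.

    The i-th smallest p-value (1-based) is compared with ``alpha/(k−i+1)``;
    testing stops at the first failure.  ``k`` defaults to the number of
    p-values but may be larger (e.g. k = 7 for the seven phenological
    traits when fewer are testable).  Flags are returned in input order;
    NaN p-values are never significant.
    """
    p = np.asarray(p_values, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if k is None:
        k = int(finite.sum())
    if finite.sum() > k:
        raise ValueError("more p-values than k")
    flags = np.zeros(len(p), dtype=bool)
    order = np.argsort(np.where(finite, p, np.inf))
    for rank, idx in enumerate(order[: int(finite.sum())], start=1):
        if p[idx] <= alpha / (k - rank + 1):
            flags[idx] = True
        else:
            break
    return flags


def selection_table(estimates: list[SelectionEstimate]) -> pd.DataFrame:
    """Assemble estimates into a tidy report table (one row per
    trait × treatment × level), merging S rows with β/γ rows."""
    df = pd.DataFrame([vars(e) for e in estimates])
    if df.empty:
        return df
    agg = {
        c: "first" if c == "n" else "mean"
        for c in df.columns
        if c not in ("trait", "treatment", "level")
    }
    merged = (
        df.groupby(["level", "treatment", "trait"], sort=False)
        .agg({k: (lambda s: s.dropna().iloc[0] if s.notna().any() else np.nan) for k in agg})
        .reset_index()
    )
    return merged
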