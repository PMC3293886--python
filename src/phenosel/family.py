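"""Recombinant-inbred-line (RIL) families.

A RIL family is a set of quasi-homozygous lines: replicate plants of a line
are genetically identical, so the phenotype of a plant decomposes as

    phenotype = genotypic value (line) + environment (block, treatment)
                + residual noise,

and broad-sense heritability H² is the among-line share of phenotypic
variance, ``H² = σ²_G / (σ²_G + σ²_E)``.  The family object stores per-line
genotypic trait values, the among-line (genetic) correlation structure that
generated them, the targeted H² per trait and the residual standard
deviation implied by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traits import BASE_TRAITS

PARENT_IDS = ("Col-0", "Ri-0")


@dataclass
class RILFamily:
    """A set of inbred lines with known genotypic trait values.

    Attributes
    ----------
    genotypic_values
        DataFrame, one row per line (index = line id), one column per trait.
    genetic_corr
        Among-line correlation matrix used to generate the values
        (traits × traits, symmetric, unit diagonal, PSD).
    h2_target
        Per-trait broad-sense heritability in [0, 1].
    residual_sd
        Per-trait environmental standard deviation implied by
        ``h2_target`` and the among-line SDs.
    parent_ids
        Ids of parental accessions included in the family (may be empty).
    """

    genotypic_values: pd.DataFrame
    genetic_corr: pd.DataFrame
    h2_target: pd.Series
    residual_sd: pd.Series
    parent_ids: tuple[str, ...] = field(default=())

    @property
    def line_ids(self) -> list[str]:
        return list(self.genotypic_values.index)

    @property
    def ril_ids(self) -> list[str]:
        return [i for i in self.line_ids if i not in self.parent_ids]

    @property
    def traits(self) -> list[str]:
        return list(self.genotypic_values.columns)

    @property
    def n_lines(self) -> int:
        return len(self.genotypic_values)

    def __post_init__(self) -> None:
        if self.genotypic_values.index.has_duplicates:
            raise ValueError("line ids must be unique")
        _validate_corr(self.genetic_corr.to_numpy())
        h2 = self.h2_target
        if ((h2 < 0) | (h2 > 1)).any():
            raise ValueError("h2_target must lie in [0, 1]")


def _validate_corr(corr: np.ndarray, tol: float = 1e-8) -> None:
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=tol):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=tol):
        raise ValueError("correlation matrix must have unit diagonal")
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -tol:
        raise ValueError(
            f"correlation matrix is not positive semidefinite "
            f"(smallest eigenvalue {eigmin:.3e})"
        )


def make_ril_family(
    n_lines: int,
    trait_means: dict[str, float] | pd.Series,
    genetic_sds: dict[str, float] | pd.Series,
    genetic_corr: pd.DataFrame | np.ndarray,
    h2_target: dict[str, float] | pd.Series,
    seed: int | np.random.Generator,
    include_parents: bool = False,
) -> RILFamily:
    """Draw a quasi-homozygous RIL family.

    Genotypic values are multivariate normal with the requested means,
    among-line SDs and correlation matrix.  If the trait set includes the
    derived traits ``ANT`` or ``FRR`` they are overridden by their defining
    identities (``ANT = BT + INT``, ``FRR = FLO / RP``) so that every
    downstream table satisfies them exactly.  The per-trait residual SD is
    ``sd_G * sqrt((1 - H²) / H²)``, which makes the realized broad-sense
    heritability match ``h2_target`` in expectation.

    Parameters
    ----------
    n_lines
        Number of RILs (≥ 2), excluding parents.
    include_parents
        If True, two parental accessions are appended with genotypic values
        equal to the trait means.
    seed
        Integer seed or an existing :class:`numpy.random.Generator`.
    """
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    means = pd.Series(trait_means, dtype=float)
    sds = pd.Series(genetic_sds, dtype=float).reindex(means.index)
    h2 = pd.Series(h2_target, dtype=float).reindex(means.index)
    if sds.isna().any() or h2.isna().any():
        raise ValueError("genetic_sds and h2_target must cover every trait in trait_means")
    if ((h2 < 0) | (h2 > 1)).any():
        raise ValueError("h2_target must lie in [0, 1]")
    bad = (h2 == 0) & (sds > 0)
    if bad.any():
        raise ValueError(
            "h2_target = 0 with positive genetic SD implies infinite residual SD "
            f"for: {', '.join(means.index[bad])}"
        )

    traits = list(means.index)
    corr = pd.DataFrame(np.asarray(genetic_corr, dtype=float), index=traits, columns=traits)
    _validate_corr(corr.to_numpy())

    # residual sd; h2==0 only allowed with sd==0 (degenerate trait)
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = sds * np.sqrt((1.0 - h2) / h2)
    resid = resid.where(~((h2 == 0) & (sds == 0)), 0.0).fillna(0.0)

    # draw via eigen factor (tolerant of semidefinite matrices)
    vals, vecs = np.linalg.eigh(corr.to_numpy())
    factor = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None)))
    z = rng.standard_normal((n_lines, len(traits))) @ factor.T
    geno = means.to_numpy() + z * sds.to_numpy()

    ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    parents: tuple[str, ...] = ()
    if include_parents:
        parents = PARENT_IDS
        geno = np.vstack([geno, np.tile(means.to_numpy(), (2, 1))])
        ids = ids + list(parents)

    gv = pd.DataFrame(geno, index=pd.Index(ids, name="line_id"), columns=traits)
    _derive_identity_traits(gv)

    return RILFamily(
        genotypic_values=gv,
        genetic_corr=corr,
        h2_target=h2,
        residual_sd=resid,
        parent_ids=parents,
    )


def _derive_identity_traits(df: pd.DataFrame) -> None:
    """Create/enforce ANT = BT + INT and FRR = FLO / RP in place whenever
    the constituent traits are present."""
    cols = set(df.columns)
    if {"BT", "INT"} <= cols:
        df["ANT"] = df["BT"] + df["INT"]
    if {"FLO", "RP"} <= cols:
        df["FRR"] = df["FLO"] / df["RP"]


def family_phenotypic_moments(family: RILFamily) -> tuple[pd.Series, pd.Series]:
    """Expected phenotypic mean and SD per base trait.

    The phenotypic variance of a trait is the among-line variance of the
    genotypic values plus the squared residual SD.  Used as the fixed
    standardization reference by the forward simulator.
    """
    traits = [t for t in family.traits if t in BASE_TRAITS]
    g = family.genotypic_values[traits]
    mean = g.mean()
    var = g.var(ddof=1) + family.residual_sd.reindex(traits) ** 2
    return mean, np.sqrt(var)
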