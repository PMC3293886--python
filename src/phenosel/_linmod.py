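"""Internal least-squares helpers: sequential (Type I) ANOVA on ordered
term blocks.  Rank-deficient dummy codings are handled through the
numerical rank reported by the QR-based solver, so callers may pass full
(non-contrast) indicator matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def dummies(codes: pd.Series | np.ndarray) -> np.ndarray:
    """Full one-hot indicator matrix for a categorical vector."""
    codes = pd.Categorical(codes)
    n = len(codes)
    out = np.zeros((n, len(codes.categories)))
    out[np.arange(n), codes.codes] = 1.0
    return out


def interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise products of two indicator matrices."""
    return (a[:, :, None] * b[:, None, :]).reshape(len(a), -1)


def sequential_anova(
    y: np.ndarray, terms: list[tuple[str, np.ndarray]]
) -> tuple[pd.DataFrame, float, int]:
    """Type-I ANOVA for ordered term blocks (intercept implied).

    Returns ``(table, rss, df_resid)`` where the table has one row per term
    with df, sum_sq, mean_sq, F and p (F against the residual mean square).
    """
    n = len(y)
    X = np.ones((n, 1))
    rss_prev = float(((y - y.mean()) ** 2).sum())
    rank_prev = 1
    rows = []
    for name, block in terms:
        X = np.hstack([X, block])
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        rss = float(resid @ resid)
        df = int(rank - rank_prev)
        rows.append((name, df, max(rss_prev - rss, 0.0)))
        rss_prev, rank_prev = rss, int(rank)
    df_resid = n - rank_prev
    ms_resid = rss_prev / df_resid if df_resid > 0 else np.nan

    table = pd.DataFrame(rows, columns=["term", "df", "sum_sq"]).set_index("term")
    table["mean_sq"] = table["sum_sq"] / table["df"].replace(0, np.nan)
    table["F"] = table["mean_sq"] / ms_resid
    table["p"] = stats.f.sf(table["F"], table["df"], df_resid)
    return table, rss_prev, df_resid
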