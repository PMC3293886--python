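"""Box-Cox preprocessing for the linear-model stages.

λ is chosen by profile maximum likelihood on the grid [−2, 2] in steps of
0.05; λ = 0 is the log transform.  When the minimum of the data is ≤ 0 a
location shift of ``1 − min(y)`` is applied first.  The ANOVA/GLM stages
transform their response this way to meet normality/homoscedasticity
assumptions; the selection analyses deliberately do not (they operate on
relative fitness and standardized traits).
"""

from __future__ import annotations

import numpy as np

LAMBDA_GRID = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.05), 2)


def boxcox_transform(values) -> tuple[np.ndarray, float, float]:
    """Box-Cox transform with grid-profile-ML λ.

    Returns ``(transformed, lambda, shift)``.  Raises on constant input
    (the likelihood is flat and the transform meaningless).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1:
        raise ValueError("expected a 1-d array")
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    if np.ptp(y) == 0:
        raise ValueError("constant input: Box-Cox transform undefined")
    shift = 0.0
    if y.min() <= 0:
        shift = 1.0 - y.min()
    ys = y + shift
    # vectorized profile log-likelihood over the grid:
    # llf(λ) = (λ − 1) Σ log y − (n/2) log σ²_λ
    n = len(ys)
    logy = np.log(ys)
    sum_logy = logy.sum()
    nonzero = LAMBDA_GRID != 0
    lams = LAMBDA_GRID[nonzero]
    trans = (ys[:, None] ** lams - 1.0) / lams
    var = trans.var(axis=0)
    llf = np.full(len(LAMBDA_GRID), -np.inf)
    llf[nonzero] = (lams - 1.0) * sum_logy - 0.5 * n * np.log(var)
    izero = np.flatnonzero(~nonzero)
    if izero.size:
        llf[izero[0]] = -sum_logy - 0.5 * n * np.log(logy.var())
    lam = float(LAMBDA_GRID[int(np.argmax(llf))])
    if lam == 0.0:
        out = np.log(ys)
    else:
        out = (ys**lam - 1.0) / lam
    return out, lam, shift
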