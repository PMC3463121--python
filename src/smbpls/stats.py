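"""Small statistical primitives shared across the package."""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

from .exceptions import DegenerateInputError


def objective_value(t: np.ndarray, u: np.ndarray) -> float:
    """Sample covariance of two centered score vectors: ``t . u / (K - 1)``.

    This is the quantity the (sparse) multi-block PLS component maximizes —
    the covariance between the super score summarizing the input blocks and
    the response score.
    """
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    if t.shape != u.shape:
        raise DegenerateInputError(f"score length mismatch: {t.shape} vs {u.shape}")
    k = t.size
    if k < 2:
        raise DegenerateInputError("covariance needs at least 2 samples")
    return float(t @ u) / (k - 1)


def correlation_pvalue(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with its two-sided Student-t p-value.

    The test statistic is ``r * sqrt((K - 2) / (1 - r^2))`` referred to a
    Student t distribution with ``K - 2`` degrees of freedom, the classical
    exact null test for a bivariate-normal correlation.

    Returns
    -------
    (r, p)
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DegenerateInputError("correlation inputs must be 1-D of equal length")
    k = a.size
    if k < 3:
        raise DegenerateInputError("correlation test needs at least 3 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    r = float(np.corrcoef(a, b)[0, 1])
    r = max(-1.0, min(1.0, r))
    if 1.0 - r * r <= 0.0:
        return r, 0.0
    tstat = r * np.sqrt((k - 2) / (1.0 - r * r))
    p = 2.0 * float(_st.t.sf(abs(tstat), df=k - 2))
    return r, min(1.0, p)
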