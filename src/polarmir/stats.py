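"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries (untestable hypotheses) are passed through as NaN and do
    not count toward the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is positive, decreasing and convex on (0, inf), so Newton
    from ``0.5 + 1/y`` converges monotonically.  Returns ``inf`` for
    y <= 0 (no finite solution).
    """
    if y <= 0:
        return np.inf
    if y > 1e7:  # trigamma(x) ~ 1/x^2 + ... for small x
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = polygamma(1, x)
        step = (tri - y) / polygamma(2, x)
        x -= step
        if x <= 0:
            x = 1e-8
        if abs(step) < tol * x:
            break
    return float(x)
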