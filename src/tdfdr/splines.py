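"""Natural cubic spline basis (truncated-power construction).

A natural cubic spline with K knots is linear beyond the boundary knots and
spans K basis functions including the constant.  ``natural_cubic_basis``
returns the K-1 non-constant columns, so ``df`` columns require K = df + 1
knots, placed at evenly spaced quantiles of the data (boundary knots at the
extremes).  df = 1 degenerates to the identity (linear adjustment).
"""

from __future__ import annotations

import numpy as np

__all__ = ["natural_cubic_basis"]


def natural_cubic_basis(x: np.ndarray, df: int = 4) -> np.ndarray:
    """Basis matrix (len(x) x df, no intercept) of a natural cubic spline."""
    x = np.asarray(x, dtype=float).ravel()
    if df < 1:
        raise ValueError("df must be >= 1")
    if df >= x.size:
        raise ValueError(f"spline df={df} must be < n={x.size}")
    if df == 1:
        return x[:, None]
    knots = np.unique(np.quantile(x, np.linspace(0.0, 1.0, df + 1)))
    if knots.size < 3:  # too many ties: fall back to linear
        return x[:, None]
    K = knots.size

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - knots[K - 1], 0.0, None) ** 3
        return num / (knots[K - 1] - knots[k])

    dK2 = d(K - 2)
    cols = [x] + [d(k) - dK2 for k in range(K - 2)]
    return np.column_stack(cols)
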