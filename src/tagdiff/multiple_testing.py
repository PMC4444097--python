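"""Benjamini–Yekutieli false-discovery-rate control.

The BY step-up procedure controls the FDR under arbitrary dependence
among the p-values by inflating the Benjamini–Hochberg thresholds with
the harmonic number c(m) = sum_{k=1..m} 1/k:

    q_(i) = min_{j >= i} min(1, p_(j) * m * c(m) / j)

Tags sharing a p-value share a q-value.  The adjustment itself is
delegated to statsmodels' ``multipletests`` (method ``fdr_by``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["FDRResult", "benjamini_yekutieli", "DEFAULT_FDR_CAP"]

DEFAULT_FDR_CAP = 0.001


@dataclass(frozen=True)
class FDRResult:
    q_values: np.ndarray
    threshold: float
    rejected: np.ndarray


def benjamini_yekutieli(p_values, threshold: float = DEFAULT_FDR_CAP) -> FDRResult:
    """BY-adjusted q-values and the q <= threshold rejection mask.

    Input order is preserved: ``q_values[i]`` corresponds to
    ``p_values[i]``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        empty = np.array([], dtype=float)
        return FDRResult(empty, threshold, np.array([], dtype=bool))
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    _, q, _, _ = multipletests(p, method="fdr_by", is_sorted=False)
    q = np.minimum(q, 1.0)
    return FDRResult(q_values=q, threshold=threshold, rejected=q <= threshold)
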