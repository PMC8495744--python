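"""Shared statistical helpers for UCE-vs-control comparisons."""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

__all__ = ["control_ttest", "paired_control_ttest", "bh_fdr"]


def control_ttest(value: float, control_values) -> tuple[float, float, float | None]:
    """Two-sided t-test of one observed statistic against N control-set values.

    Returns ``(control_mean, control_sd, p_value)``.  The observed value is
    itself one draw from the null when the sets are exchangeable, so the
    standard error includes the extra ``+1`` variance term (prediction
    form): ``t = (value - mean) / (sd * sqrt(1 + 1/N))`` with ``N - 1``
    degrees of freedom.  With a single control set no p-value can be
    computed and ``None`` is returned.
    """
    c = np.asarray(control_values, dtype=float)
    n = c.size
    if n == 0:
        raise ValueError("no control values")
    mean = float(c.mean())
    if n < 2:
        return mean, float("nan"), None
    sd = float(c.std(ddof=1))
    if sd == 0.0:
        return mean, sd, 1.0 if value == mean else 0.0
    t = (value - mean) / (sd * math.sqrt(1.0 + 1.0 / n))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return mean, sd, p


def paired_control_ttest(values, control_means) -> float | None:
    """Two-sided paired t-test of per-cell observed values vs control means."""
    v = np.asarray(values, dtype=float)
    c = np.asarray(control_means, dtype=float)
    mask = np.isfinite(v) & np.isfinite(c)
    v, c = v[mask], c[mask]
    if v.size < 2:
        return None
    res = sps.ttest_rel(v, c)
    return float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, bounded below by p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return sps.false_discovery_control(p, method="bh")
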