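"""Shared statistical primitives: signed-z Stouffer combination and BH adjustment."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# Two-sided p-values are clipped before the normal-quantile transform so that
# perfectly monotone toy inputs (p == 0) do not produce infinite z-scores.
P_FLOOR = 1e-300
P_CEIL = 1.0 - 1e-16


def stouffer_signed(p_values, signs) -> tuple[float, float]:
    """Combine two-sided p-values with Stouffer's method, carrying effect signs.

    Each study contributes z_i = sign_i * Phi^-1(1 - p_i / 2); the combined
    statistic is Z = sum(z_i) / sqrt(k) with equal weights, and the combined
    p-value is the two-sided normal tail 2 * (1 - Phi(|Z|)).

    Parameters
    ----------
    p_values : array-like of two-sided per-study p-values in (0, 1].
    signs : array-like of effect directions; only the sign is used, zero
        contributes a zero z-score.

    Returns
    -------
    (z, p) : combined Z statistic and two-sided combined p-value.
    """
    p = np.clip(np.asarray(p_values, dtype=float), P_FLOOR, P_CEIL)
    s = np.sign(np.asarray(signs, dtype=float))
    if p.size == 0:
        raise ValueError("stouffer_signed requires at least one study")
    z_i = s * stats.norm.isf(p / 2.0)
    z = float(z_i.sum() / np.sqrt(p.size))
    p_comb = float(np.clip(2.0 * stats.norm.sf(abs(z)), P_FLOOR, 1.0))
    return z, p_comb


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
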