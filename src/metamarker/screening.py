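"""Per-metabolite two-group screening and shared rank-test / FDR kernels.

The initial screen compares each metabolite's abundances between cases and
controls with the two-sided Mann-Whitney U test and controls the false
discovery rate with the Benjamini-Yekutieli step-up procedure (valid under
arbitrary dependence between metabolites).  The same rank test and the
Benjamini-Hochberg variant are reused by the autoencoder anomaly stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_prep import MetabolomicMatrix

#: largest per-group size at which the exact U distribution is used (untied data)
EXACT_MAX_N = 8


def mann_whitney(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
    exact_max_n: int = EXACT_MAX_N,
) -> tuple[float, float]:
    """Mann-Whitney U test of ``x`` vs ``y``.

    Uses the exact permutation distribution when both groups are small
    (min(n, m) <= ``exact_max_n``) and there are no ties, and the normal
    approximation with tie and continuity correction otherwise.

    Returns ``(U, p)`` where U counts (x > y) pairs plus half the ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def adjust_benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_benjamini_yekutieli(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli adjusted p-values (BH times the harmonic factor c(m))."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


_ADJUST = {"bh": adjust_benjamini_hochberg, "by": adjust_benjamini_yekutieli}


def screen_metabolites(
    m: MetabolomicMatrix, correction: str = "by", alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided Mann-Whitney screen of every metabolite, with FDR control.

    Returns one row per metabolite: ``metabolite``, ``u`` (case-vs-control U
    statistic), ``p``, ``p_adj`` (by the chosen correction, default
    Benjamini-Yekutieli), ``direction`` (sign of case median minus control
    median) and ``significant`` (``p_adj`` < ``alpha``).
    """
    if correction not in _ADJUST:
        raise ValueError(f"correction must be one of {sorted(_ADJUST)}")
    if np.isnan(m.values).any():
        raise ValueError("screen requires an imputed matrix")
    if m.case_mask.sum() < 2 or m.control_mask.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    case = m.values[m.case_mask]
    ctrl = m.values[m.control_mask]
    stats_u = np.empty(m.n_metabolites)
    pvals = np.empty(m.n_metabolites)
    direction = np.empty(m.n_metabolites)
    for j in range(m.n_metabolites):
        stats_u[j], pvals[j] = mann_whitney(case[:, j], ctrl[:, j])
        direction[j] = np.sign(np.median(case[:, j]) - np.median(ctrl[:, j]))
    p_adj = _ADJUST[correction](pvals)
    return pd.DataFrame(
        {
            "metabolite": m.metabolite_ids,
            "u": stats_u,
            "p": pvals,
            "p_adj": p_adj,
            "direction": direction.astype(int),
            "significant": p_adj < alpha,
        }
    )
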