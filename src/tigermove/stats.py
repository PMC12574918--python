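"""Small statistical primitives shared across modules.

The one-sample Wilcoxon signed-rank test used to compare observed
per-node network metrics against random-network null means is authored
here so its small-sample behaviour is explicit: the exact two-sided tail
is computed by convolving the signed-rank-sum distribution when n <= 12,
and a normal approximation with continuity correction is used above
that.  Zero differences are dropped; if every difference is zero the
comparison is degenerate and p = 1 is returned with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

__all__ = ["WilcoxonResult", "wilcoxon_signed_rank", "akaike_weights"]

EXACT_MAX_N = 12


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_used: int  # non-zero differences entering the test
    method: str  # "exact" | "normal" | "degenerate"
    degenerate: bool


def _exact_two_sided_p(ranks2: np.ndarray, w2_obs: float) -> float:
    """Exact two-sided tail of W+ by distribution convolution.

    ``ranks2`` are the (tie-averaged) ranks doubled so they are integers
    even with .5 average ranks; ``w2_obs`` is the doubled observed W+.
    Under H0 each rank is added with probability 1/2, so the pmf of the
    doubled rank sum follows from a 0/1 convolution over ranks.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    mean2 = total / 2.0
    # two-sided: sum probability of outcomes at least as far from the mean
    dev = abs(w2_obs - mean2)
    support = np.arange(total + 1)
    p = counts[np.abs(support - mean2) >= dev - 1e-9].sum()
    return min(1.0, float(p))


def wilcoxon_signed_rank(
    x,
    mu: float = 0.0,
    exact_max_n: int = EXACT_MAX_N,
) -> WilcoxonResult:
    """One-sample two-sided Wilcoxon signed-rank test of ``x`` against ``mu``."""
    d = np.asarray(x, dtype=float) - mu
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0, "degenerate", True)
    ranks = sp_stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(ranks * 2).astype(int)
        p = _exact_two_sided_p(ranks2, 2 * w_plus)
        return WilcoxonResult(w_plus, p, n, "exact", False)
    mean = n * (n + 1) / 4.0
    # variance with tie correction
    tie_term = 0.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return WilcoxonResult(w_plus, 1.0, n, "degenerate", True)
    dev = abs(w_plus - mean)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)  # continuity-corrected
    p = 2.0 * sp_stats.norm.sf(z)
    return WilcoxonResult(w_plus, min(1.0, float(p)), n, "normal", False)


def akaike_weights(aic) -> tuple[np.ndarray, np.ndarray]:
    """Return (delta_aic, weights) for a vector of AIC values.

    delta_i = AIC_i - min AIC; w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2).
    Weights are invariant to adding any constant to all AICs.
    """
    aic = np.asarray(aic, dtype=float)
    if aic.size == 0:
        raise ValueError("empty AIC vector")
    delta = aic - aic.min()
    rel = np.exp(-delta / 2.0)
    return delta, rel / rel.sum()
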