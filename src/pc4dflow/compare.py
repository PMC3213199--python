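"""Method-agreement statistics for paired flow measurements.

Agreement between a test series (e.g. stroke volumes from the 4D pipeline)
and a reference series (e.g. direct 2D through-plane flow) is summarized by:

* ordinary least-squares regression of test on reference (slope, intercept, r^2);
* Bland-Altman percent bias: mean +/- SD of per-pair percent differences.
  The reported default uses the reference value as denominator (the reference
  method defines truth); the classical pair-mean-denominator variant is also
  computed and included;
* a paired two-sided Wilcoxon signed-rank test. Conventions (they differ
  across packages, so they are fixed here): zero differences are dropped,
  tied absolute differences receive mid-ranks, the null distribution is exact
  for n <= 25 (computed by convolution over the signed-rank generating
  function) and a normal approximation with continuity correction is used
  above. The two-sided p-value is P(|W - mu| >= |w_obs - mu|) under the
  symmetric null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError

EXACT_WILCOXON_MAX_N = 25


@dataclass
class AgreementReport:
    """Regression + Bland-Altman + Wilcoxon summary of two paired series."""

    n: int
    slope: float
    intercept: float
    r_squared: float
    bias_percent_mean: float
    bias_percent_sd: float
    bias_percent_mean_pairmean: float
    bias_percent_sd_pairmean: float
    wilcoxon_statistic: float
    wilcoxon_p_two_sided: float
    all_differences_zero: bool = False
    bias_denominator: str = "reference"

    def to_dict(self) -> dict:
        return {k: (v if not isinstance(v, (np.floating, np.integer)) else float(v))
                for k, v in self.__dict__.items()}


def wilcoxon_signed_rank(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, int]:
    """Paired two-sided Wilcoxon signed-rank test.

    Returns ``(W_plus, p_two_sided, n_used)`` where ``W_plus`` is the sum of
    ranks of positive differences x - y after dropping zeros and mid-ranking
    ties. Exact null distribution for n <= 25; normal approximation with
    continuity correction above. If every difference is zero the test is
    degenerate and ``(0.0, 1.0, 0)`` is returned by convention.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0

    if n <= EXACT_WILCOXON_MAX_N:
        # Mid-ranks are multiples of 1/2: work on doubled integer ranks.
        r2 = np.round(2 * ranks).astype(int)
        pmf = np.zeros(r2.sum() + 1)
        pmf[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(pmf)
            shifted[r:] = pmf[: pmf.size - r]
            pmf = 0.5 * (pmf + shifted)
        support = np.arange(pmf.size) / 2.0
        dev = abs(w_plus - mu)
        p = float(pmf[np.abs(support - mu) >= dev - 1e-9].sum())
    else:
        sigma = np.sqrt(np.sum(ranks**2) / 4.0)
        dev = abs(w_plus - mu)
        z = max(dev - 0.5, 0.0) / sigma  # continuity correction
        p = float(2.0 * stats.norm.sf(z))
    return w_plus, min(p, 1.0), n


def agreement(reference, test) -> AgreementReport:
    """Full agreement analysis of ``test`` against ``reference``.

    Both inputs are equal-length sequences (n >= 3) of positive reference
    values and their paired test measurements.
    """
    ref = np.asarray(reference, dtype=float)
    tst = np.asarray(test, dtype=float)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise ParameterError("reference and test must be equal-length 1-D sequences")
    n = ref.size
    if n < 3:
        raise ParameterError(f"need at least 3 pairs, got {n}")
    if np.any(ref <= 0):
        raise ParameterError("reference values must be positive (percent-bias denominator)")
    if np.ptp(ref) == 0:
        raise ParameterError("reference values are constant: regression undefined")

    fit = stats.linregress(ref, tst)
    d_ref = 100.0 * (tst - ref) / ref
    pair_mean = (tst + ref) / 2.0
    d_mean = 100.0 * (tst - ref) / pair_mean

    w, p, n_used = wilcoxon_signed_rank(tst, ref)
    return AgreementReport(
        n=n,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        bias_percent_mean=float(d_ref.mean()),
        bias_percent_sd=float(d_ref.std(ddof=1)),
        bias_percent_mean_pairmean=float(d_mean.mean()),
        bias_percent_sd_pairmean=float(d_mean.std(ddof=1)),
        wilcoxon_statistic=w,
        wilcoxon_p_two_sided=p,
        all_differences_zero=(n_used == 0),
    )
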