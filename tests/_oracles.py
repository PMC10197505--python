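"""Independent oracles used by the test suite.

Everything here is deliberately written without reference to the package
internals: plain enumeration, resampling, and normal-orthant integration,
so the tests cross-check two independent routes to the same quantity.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal, norm

R, N = "recall", "no_recall"


def fuse_historical(r1: str, r2: str, arb: str | None, policy: bool,
                    historical_final: str | None = None):
    """Hand enumeration of the human double-reading decision.

    Returns (final, arbitrated). Cases: agreed no-recall is final; agreed
    recall is final unless the site arbitrates agreed recalls; disagreement
    goes to the arbitration opinion, falling back to the recorded final.
    """
    if (r1, r2) == (N, N):
        return N, False
    if (r1, r2) == (R, R):
        if not policy:
            return R, False
        return (arb if arb is not None else historical_final), True
    return (arb if arb is not None else historical_final), True


def fuse_with_ai(r1: str, ai: str, arb: str | None, r2: str):
    """Hand enumeration of double reading with the AI as second reader."""
    if r1 == ai:
        return r1, False
    return (arb if arb is not None else r2), True


def bootstrap_ratio_ci(k1: int, n1: int, k0: int, n0: int,
                       n_rep: int = 100_000, seed: int = 0):
    """Parametric bootstrap 95% CI for (k1/n1)/(k0/n0), two independent
    binomials resampled at their observed proportions."""
    rng = np.random.default_rng(seed)
    a = rng.binomial(n1, k1 / n1, n_rep) / n1
    b = rng.binomial(n0, k0 / n0, n_rep) / n0
    keep = (a > 0) & (b > 0)
    ratios = a[keep] / b[keep]
    return tuple(np.quantile(ratios, [0.025, 0.975]))


def orthant3(t: np.ndarray, corr: np.ndarray) -> float:
    """P(Z1<=t1, Z2<=t2, Z3<=t3) for a standard trivariate normal."""
    return float(multivariate_normal(mean=np.zeros(3), cov=corr,
                                     allow_singular=True).cdf(t))


def orthant2(t1: float, t2: float, rho: float) -> float:
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(multivariate_normal(mean=[0, 0], cov=cov,
                                     allow_singular=True).cdf([t1, t2]))


def dr_recall_probability(p1: float, p2: float, p_arb: float,
                          rho_hh: float) -> float:
    """Exact P(double-reading final = recall) under the latent-threshold
    model with equicorrelated human readers (agreed recalls not arbitrated).

    recall iff (r1 and r2) or (exactly one of r1, r2) and arbitrator.
    """
    t1, t2, t3 = norm.ppf([p1, p2, p_arb])
    corr = np.full((3, 3), rho_hh)
    np.fill_diagonal(corr, 1.0)
    both = orthant2(t1, t2, rho_hh)
    tri = orthant3(np.array([t1, t2, t3]), corr)
    p_r1_yes_r2_no_arb = orthant2(t1, t3, rho_hh) - tri
    p_r2_yes_r1_no_arb = orthant2(t2, t3, rho_hh) - tri
    return both + p_r1_yes_r2_no_arb + p_r2_yes_r1_no_arb
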