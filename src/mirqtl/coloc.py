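"""Single-causal-variant Bayesian colocalization via Wakefield approximate
Bayes factors.

Two association signals over a shared locus are compared under five
hypotheses: H0 no association, H1/H2 association in one study only, H3 two
distinct causal variants, H4 one shared causal variant. Per-SNP evidence is
the Wakefield log-ABF; per-hypothesis sums over causal-SNP configurations
are accumulated in log space.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import logsumexp

from .containers import ColocResult

__all__ = ["wakefield_labf", "coloc_abf"]

DEFAULT_SD_QUANT = 0.15  # prior effect SD, quantitative trait (phenotype-SD units)
DEFAULT_SD_CC = 0.2  # case-control traits, log-odds scale


def wakefield_labf(
    beta: np.ndarray | float, se: np.ndarray | float, sd_prior: float = DEFAULT_SD_QUANT
) -> np.ndarray | float:
    """Wakefield log approximate Bayes factor for one SNP.

    With V = se^2, W = sd_prior^2, r = W/(V+W), z = beta/se:
    lABF = 0.5*log(1 - r) + z^2 * r / 2.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    V = se**2
    W = sd_prior**2
    r = W / (V + W)
    z2 = (beta / se) ** 2
    out = 0.5 * np.log1p(-r) + z2 * r / 2.0
    return float(out) if out.ndim == 0 else out


def coloc_abf(
    beta1: np.ndarray,
    se1: np.ndarray,
    beta2: np.ndarray,
    se2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    sd_prior1: float = DEFAULT_SD_QUANT,
    sd_prior2: float = DEFAULT_SD_QUANT,
) -> ColocResult:
    """Posterior probabilities PP0..PP4 for a locus pair.

    Inputs must already be intersected and allele-harmonized so row i of
    both studies is the same SNP with the same effect allele.
    """
    beta1 = np.atleast_1d(np.asarray(beta1, dtype=float))
    beta2 = np.atleast_1d(np.asarray(beta2, dtype=float))
    se1 = np.atleast_1d(np.asarray(se1, dtype=float))
    se2 = np.atleast_1d(np.asarray(se2, dtype=float))
    k = len(beta1)
    if k == 0:
        raise ValueError("empty SNP intersection")
    if not (len(beta2) == len(se1) == len(se2) == k):
        raise ValueError("study vectors must have equal length")

    l1 = np.atleast_1d(wakefield_labf(beta1, se1, sd_prior1))
    l2 = np.atleast_1d(wakefield_labf(beta2, se2, sd_prior2))
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)

    lh0 = 0.0
    lh1 = np.log(p1) + s1
    lh2 = np.log(p2) + s2
    lh4 = np.log(p12) + s12
    # H3: sum over i != j of ABF1_i * ABF2_j = S1*S2 - S12
    diff = s12 - (s1 + s2)
    if diff >= 0.0:
        if k > 1 and diff > 1e-12:
            warnings.warn("negative H3 configuration mass; clamped to 0")
        lh3 = -np.inf
    else:
        lh3 = np.log(p1) + np.log(p2) + s1 + s2 + np.log1p(-np.exp(diff))
    if k == 1:
        lh3 = -np.inf

    lall = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lall - logsumexp(lall))
    pp = pp / pp.sum()
    return ColocResult(
        pp0=float(pp[0]), pp1=float(pp[1]), pp2=float(pp[2]),
        pp3=float(pp[3]), pp4=float(pp[4]),
        n_snps=k, p1=p1, p2=p2, p12=p12,
    )
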