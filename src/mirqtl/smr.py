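"""Summary-based Mendelian randomization (SMR) with the HEIDI heterogeneity
test, including the two-molecular-trait mediation variant.

SMR estimates the effect b_xy of an exposure (miRNA abundance) on an outcome
(trait, transcript or protein) at the exposure's top cis SNP from the two
sets of summary statistics: b_xy = b_zy / b_zx. The SMR test statistic is
T = z_zx^2 z_zy^2 / (z_zx^2 + z_zy^2) ~ chi2(1) under the null. HEIDI asks
whether b_xy is constant across SNPs in LD with the top SNP: heterogeneity
(p < 0.05) indicates linkage of two distinct causal variants rather than a
single shared one (causality or pleiotropy).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .containers import SmrResult

__all__ = [
    "smr_test",
    "heidi_test",
    "smr_two_molecular",
    "HEIDI_P_EXPOSURE",
    "HEIDI_R2_RANGE",
    "HEIDI_MAX_SNPS",
]

HEIDI_P_EXPOSURE = 1.57e-3  # exposure-significance eligibility (|z| > 3.16)
HEIDI_R2_RANGE = (0.05, 0.9)  # r2 with the top SNP
HEIDI_MAX_SNPS = 20
DEFAULT_INSTRUMENT_P = 5e-8


def smr_test(
    b_zx: float, se_zx: float, b_zy: float, se_zy: float
) -> tuple[float, float, float, float]:
    """(b_xy, se_xy, T_smr, p_smr) at one instrument SNP.

    b_xy = b_zy / b_zx; T = z1^2 z2^2 / (z1^2 + z2^2) referred to chi2(1);
    se_xy by the delta method.
    """
    if b_zx == 0:
        raise ValueError("b_zx = 0: no instrument")
    if se_zx <= 0 or se_zy <= 0:
        raise ValueError("standard errors must be positive")
    z1 = b_zx / se_zx
    z2 = b_zy / se_zy
    b_xy = b_zy / b_zx
    if z2 == 0:
        t_smr, p = 0.0, 1.0
    else:
        t_smr = (z1**2 * z2**2) / (z1**2 + z2**2)
        p = float(stats.chi2.sf(t_smr, df=1))
    if b_zy == 0:
        se_xy = abs(se_zy / b_zx)
    else:
        se_xy = abs(b_xy) * math.sqrt(
            se_zy**2 / b_zy**2 + se_zx**2 / b_zx**2
        )
    return b_xy, se_xy, t_smr, p


def _bxy_cov(
    b_zx: np.ndarray,
    se_zx: np.ndarray,
    b_zy: np.ndarray,
    se_zy: np.ndarray,
    R: np.ndarray,
) -> np.ndarray:
    """Delta-method covariance of the per-SNP Wald ratios b_zy/b_zx.

    Exposure and outcome studies are treated as independent samples, so the
    cross term vanishes:
    cov(bxy_i, bxy_j) = r_ij [ se_zy_i se_zy_j / (b_zx_i b_zx_j)
                             + b_zy_i b_zy_j se_zx_i se_zx_j / (b_zx_i^2 b_zx_j^2) ].
    """
    inv_bzx = 1.0 / b_zx
    term_y = np.outer(se_zy * inv_bzx, se_zy * inv_bzx)
    gy = b_zy * se_zx * inv_bzx**2
    term_x = np.outer(gy, gy)
    return R * (term_y + term_x)


def heidi_test(
    b_zx: np.ndarray,
    se_zx: np.ndarray,
    b_zy: np.ndarray,
    se_zy: np.ndarray,
    R: np.ndarray,
    top: int | None = None,
    p_exposure_max: float = HEIDI_P_EXPOSURE,
    r2_range: tuple[float, float] = HEIDI_R2_RANGE,
    max_snps: int = HEIDI_MAX_SNPS,
) -> tuple[float, int, str]:
    """(p_heidi, n_snps_used, reason).

    SNP eligibility besides the top SNP: exposure p below
    ``p_exposure_max`` and r2 with the top SNP within ``r2_range``; at most
    ``max_snps`` SNPs, strongest exposure signals first. With fewer than 3
    eligible SNPs p is NaN with a reason code.

    The statistic sums the squared standardized differences
    d_i = b_xy(i) - b_xy(top); its null distribution (a correlated
    chi-square sum with weights from the eigenvalues of the correlation
    matrix of d) is approximated by a two-moment Satterthwaite match.
    """
    b_zx = np.asarray(b_zx, dtype=float)
    se_zx = np.asarray(se_zx, dtype=float)
    b_zy = np.asarray(b_zy, dtype=float)
    se_zy = np.asarray(se_zy, dtype=float)
    m = len(b_zx)
    z_zx = b_zx / se_zx
    if top is None:
        top = int(np.argmax(np.abs(z_zx)))
    p_exp = stats.chi2.sf(z_zx**2, df=1)
    r2_top = R[top] ** 2
    eligible = (
        (np.arange(m) != top)
        & (p_exp < p_exposure_max)
        & (r2_top >= r2_range[0])
        & (r2_top <= r2_range[1])
        & (b_zx != 0)
    )
    idx = np.flatnonzero(eligible)
    if idx.size > max_snps:
        idx = idx[np.argsort(p_exp[idx], kind="mergesort")[:max_snps]]
    if idx.size < 3:
        return float("nan"), int(idx.size), "fewer_than_3_eligible_snps"

    sel = np.concatenate([[top], idx])
    pos_top = 0
    V = _bxy_cov(b_zx[sel], se_zx[sel], b_zy[sel], se_zy[sel], R[np.ix_(sel, sel)])
    bxy = b_zy[sel] / b_zx[sel]
    d = bxy[1:] - bxy[pos_top]
    k = len(d)
    # cov(d_i, d_j) = V_ij - V_i0 - V_j0 + V_00
    Vd = V[1:, 1:] - V[1:, [0]] - V[[0], 1:] + V[0, 0]
    sd_d = np.sqrt(np.clip(np.diag(Vd), 1e-300, None))
    stat = float(np.sum((d / sd_d) ** 2))
    corr_d = Vd / np.outer(sd_d, sd_d)
    lam = np.linalg.eigvalsh((corr_d + corr_d.T) / 2)
    lam = np.clip(lam, 0.0, None)
    s1, s2 = lam.sum(), float(np.sum(lam**2))
    if s1 <= 0 or s2 <= 0:
        return 1.0, k, ""
    scale = s2 / s1
    df = s1**2 / s2
    p = float(stats.chi2.sf(stat / scale, df=df))
    return p, k, ""


def smr_two_molecular(
    exposure: dict,
    outcome: dict,
    R: np.ndarray,
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
    instrument_p_max: float = DEFAULT_INSTRUMENT_P,
    smr_alpha: float = 0.05,
    heidi_alpha: float = 0.05,
) -> SmrResult:
    """SMR + HEIDI between two molecular traits with a mediation verdict.

    ``exposure``/``outcome`` are dicts with keys ``snp`` (ids), ``b``,
    ``se``, aligned row-for-row with each other and with the LD matrix
    ``R``. The top SNP is the exposure's strongest signal and must pass the
    instrument threshold. Mediation = SMR p < ``smr_alpha`` and HEIDI
    p >= ``heidi_alpha``; an uncomputable HEIDI p yields verdict False with
    the reason recorded.
    """
    b_zx = np.asarray(exposure["b"], dtype=float)
    se_zx = np.asarray(exposure["se"], dtype=float)
    b_zy = np.asarray(outcome["b"], dtype=float)
    se_zy = np.asarray(outcome["se"], dtype=float)
    snps = np.asarray(exposure["snp"], dtype=object)
    z_zx = b_zx / se_zx
    top = int(np.argmax(np.abs(z_zx)))
    p_top = float(stats.chi2.sf(z_zx[top] ** 2, df=1))
    if p_top > instrument_p_max:
        raise ValueError(
            f"top exposure SNP p={p_top:.3g} fails instrument threshold "
            f"{instrument_p_max:.3g}"
        )
    b_xy, se_xy, t_smr, p_smr = smr_test(
        b_zx[top], se_zx[top], b_zy[top], se_zy[top]
    )
    p_heidi, n_heidi, reason = heidi_test(b_zx, se_zx, b_zy, se_zy, R, top=top)
    mediation = bool(
        p_smr < smr_alpha and (not math.isnan(p_heidi)) and p_heidi >= heidi_alpha
    )
    return SmrResult(
        exposure_id=exposure_id,
        outcome_id=outcome_id,
        top_snp=str(snps[top]),
        b_xy=b_xy,
        se_xy=se_xy,
        t_smr=t_smr,
        p_smr=p_smr,
        p_heidi=p_heidi,
        n_snps_heidi=n_heidi,
        heidi_reason=reason,
        mediation=mediation,
    )
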