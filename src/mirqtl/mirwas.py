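"""FUSION-style miRNA-wide association (miRWAS).

Per miRNA: a cis-heritability gate (single-component REML on the cis genomic
relationship matrix, likelihood-ratio p against h2 = 0 with the boundary
chi-square mixture null), sparse expression weight models (top1 / lasso /
elastic net, selected by cross-validated R2), the LD-aware weighted-z
association with a GWAS, and the four-criteria causal screen:

(1) miRWAS FDR < 0.05, (2) coloc PP.H4 > 0.5, (3) SMR p < 0.05,
(4) HEIDI p >= 0.05.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import TwasModel, VariantPanel

__all__ = [
    "estimate_cis_h2",
    "fit_weight_models",
    "twas_associate",
    "causal_screen",
]


def _standardize(G: np.ndarray) -> np.ndarray:
    sd = G.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic SNP among cis SNPs; filter first")
    return (G - G.mean(axis=0)) / sd


def estimate_cis_h2(G: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """REML estimate of cis SNP heritability and its LRT p-value.

    Model: y ~ N(mu, sigma2 * (h2 * K + (1 - h2) * I)) with K = Z Z'/m on
    standardized dosages. Working in the eigenbasis of the centered K, the
    restricted likelihood is profiled over sigma2 and maximized over h2 on
    [0, 1 - 1e-6] by bounded scalar optimization. The p-value uses the
    0.5*chi2(0) + 0.5*chi2(1) boundary mixture.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    if m < 2:
        raise ValueError("need at least 2 cis SNPs")
    if n < 100:
        raise ValueError("need n >= 100 samples for a stable REML fit")
    Z = _standardize(G)
    K = Z @ Z.T / m
    # restrict to the orthogonal complement of the intercept
    yc = y - y.mean()
    Kc = K - K.mean(axis=0)[None, :] - K.mean(axis=1)[:, None] + K.mean()
    lam, U = np.linalg.eigh((Kc + Kc.T) / 2)
    # drop the ~zero eigenvalue direction corresponding to the intercept
    order = np.argsort(lam)
    lam, U = lam[order[1:]], U[:, order[1:]]
    lam = np.clip(lam, 0.0, None)
    ys = U.T @ yc
    nr = len(ys)  # n - 1 restricted contrasts

    def neg_restricted_ll(h2: float) -> float:
        v = h2 * lam + (1.0 - h2)
        sigma2 = float(np.sum(ys**2 / v)) / nr
        return 0.5 * (np.sum(np.log(v)) + nr * math.log(max(sigma2, 1e-300)) + nr)

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, 1.0 - 1e-6), method="bounded",
        options={"xatol": 1e-6},
    )
    h2_hat = float(res.x)
    ll1 = -neg_restricted_ll(h2_hat)
    ll0 = -neg_restricted_ll(0.0)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = 0.5 * float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    if not res.success:
        warnings.warn("REML optimizer did not converge; boundary estimate returned")
    return h2_hat, p


def _cv_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss = np.sum((y_true - y_true.mean()) ** 2)
    if ss <= 0:
        return 0.0
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / float(ss)


def fit_weight_models(
    panel_cis: VariantPanel,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    h2: float = float("nan"),
    h2_p: float = float("nan"),
    feature_id: str = "feature",
    n_alphas: int = 20,
) -> TwasModel:
    """Fit top1 / lasso / elastic-net weights and pick the best by CV R2.

    Weights live on the standardized-dosage scale (so they pair with an LD
    correlation matrix in the association step). For lasso and elastic net
    (mixing 0.5) the penalty is the grid value maximizing out-of-fold R2;
    the model's cv_r2 is that maximum. Ties go to top1 (the simplest). If
    every model's cv_r2 is <= 0 the model label is 'none' and the miRNA is
    excluded from association.
    """
    from sklearn.linear_model import ElasticNet, Lasso
    from sklearn.model_selection import KFold

    G = _standardize(panel_cis.dosage)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean()
    n, m = G.shape
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(G))

    # --- top1: weight = marginal beta of the most significant cis SNP
    marg = G.T @ yc / n
    top_idx = int(np.argmax(np.abs(marg)))
    w_top1 = np.zeros(m)
    w_top1[top_idx] = marg[top_idx]
    pred = np.empty(n)
    for tr, te in splits:
        b = G[tr].T @ (y[tr] - y[tr].mean()) / len(tr)
        j = int(np.argmax(np.abs(b)))
        pred[te] = y[tr].mean() + b[j] * G[te, j]
    cv = {"top1": _cv_r2(y, pred)}

    # --- lasso / elastic net over a shared alpha grid (log-spaced down from
    # the smallest penalty that zeroes every coefficient)
    alpha_max = float(np.max(np.abs(G.T @ yc))) / n
    alphas = np.geomspace(alpha_max, alpha_max * 1e-3, n_alphas)
    weights = {"top1": w_top1}
    for name, l1_ratio in (("lasso", 1.0), ("enet", 0.5)):
        grid = alphas / l1_ratio
        preds = np.zeros((len(grid), n))
        for tr, te in splits:
            ytr = y[tr] - y[tr].mean()
            for a_i, a in enumerate(grid):
                est = (
                    Lasso(alpha=a, max_iter=5000)
                    if l1_ratio == 1.0
                    else ElasticNet(alpha=a, l1_ratio=l1_ratio, max_iter=5000)
                )
                est.fit(G[tr], ytr)
                preds[a_i, te] = y[tr].mean() + est.predict(G[te])
        r2s = np.array([_cv_r2(y, preds[a_i]) for a_i in range(len(grid))])
        best = int(np.argmax(r2s))
        cv[name] = float(r2s[best])
        est = (
            Lasso(alpha=grid[best], max_iter=5000)
            if l1_ratio == 1.0
            else ElasticNet(alpha=grid[best], l1_ratio=l1_ratio, max_iter=5000)
        )
        est.fit(G, yc)
        weights[name] = est.coef_.copy()

    best_model = max(cv, key=lambda k: (cv[k], k == "top1"))
    if cv[best_model] <= 0:
        best_model = "none"
        warnings.warn(f"{feature_id}: no model with positive cv R2; excluded")
    w = weights.get(best_model, np.zeros(m))
    return TwasModel(
        feature_id=feature_id,
        h2_cis=h2,
        h2_p=h2_p,
        model=best_model,
        snp_id=panel_cis.snp_id.copy(),
        a1=panel_cis.alt.copy(),
        a2=panel_cis.ref.copy(),
        weights=w,
        cv_r2=cv,
    )


def twas_associate(
    model: TwasModel, z_gwas: np.ndarray, R: np.ndarray, ridge: float = 1e-3
) -> tuple[float, float]:
    """Weighted-z association: z = w'z / sqrt(w'Rw), two-sided normal p.

    ``z_gwas`` must be aligned to ``model.snp_id`` with matching effect
    alleles. A non-positive quadratic form (numerical) is ridge-regularized
    on the diagonal with a warning.
    """
    w = np.asarray(model.weights, dtype=float)
    z_gwas = np.asarray(z_gwas, dtype=float)
    if model.model == "none" or not np.any(w != 0):
        raise ValueError("model has no usable weights")
    denom = float(w @ R @ w)
    if denom <= 0:
        warnings.warn("non-positive w'Rw; ridge-regularizing the LD matrix")
        denom = float(w @ (R + ridge * np.eye(len(w))) @ w)
    z = float(w @ z_gwas) / math.sqrt(denom)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return z, p


def causal_screen(
    mirwas: pd.DataFrame,
    coloc: pd.DataFrame,
    smr: pd.DataFrame,
    fdr_max: float = 0.05,
    pp4_min: float = 0.5,
    smr_p_max: float = 0.05,
    heidi_p_min: float = 0.05,
) -> pd.DataFrame:
    """Conjunction of the four causal criteria per (miRNA, trait).

    Inputs are keyed by columns ``mirna`` and ``trait``: ``mirwas`` carries
    z/p/fdr, ``coloc`` carries pp4, ``smr`` carries smr_p and heidi_p.
    Strict inequalities follow the rule: fdr < 0.05, pp4 > 0.5,
    smr_p < 0.05, heidi_p >= 0.05. A pair missing any component gets
    causal=False with a reason code.
    """
    out = mirwas.merge(coloc, on=["mirna", "trait"], how="left").merge(
        smr, on=["mirna", "trait"], how="left"
    )
    reasons = []
    flags = []
    for row in out.itertuples():
        reason = []
        if pd.isna(row.fdr) or not (row.fdr < fdr_max):
            reason.append("mirwas_fdr")
        if pd.isna(row.pp4) or not (row.pp4 > pp4_min):
            reason.append("coloc_pp4")
        if pd.isna(row.smr_p) or not (row.smr_p < smr_p_max):
            reason.append("smr_p")
        if pd.isna(row.heidi_p) or not (row.heidi_p >= heidi_p_min):
            reason.append("heidi_p")
        flags.append(not reason)
        reasons.append(",".join(reason))
    out["causal"] = flags
    out["reason"] = reasons
    return out
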