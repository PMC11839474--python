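"""cis-miR-QTL scan: window construction, additive linear-model scan,
Storey q-values and per-QTL variance explained.

The scan regresses normalized log2 miRNA abundance on SNP dosage plus
covariates (batch, PMI, RIN, age, sex, diagnosis, study, platform, genetic
PCs and expression SVs). By Frisch-Waugh-Lovell, expression and dosages are
residualized on the covariates once and the per-SNP coefficient, exact
small-sample t statistic (n - p - 1 df) and two-sided p follow from the
simple regression of the residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, MirnaAnnotation, VariantPanel
from .expression_qc import _drop_collinear, residualize

__all__ = [
    "CisWindow",
    "build_cis_windows",
    "drop_high_vif",
    "scan_cis",
    "storey_pi0",
    "storey_qvalues",
    "variance_explained",
]


@dataclass
class CisWindow:
    mature_id: str
    regions: list = field(default_factory=list)  # (chrom, start, end), merged

    def contains(self, chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos <= e for c, s, e in self.regions)


def _merge_regions(regions: list) -> list:
    out: list = []
    for chrom, start, end in sorted(regions):
        if out and out[-1][0] == chrom and start <= out[-1][2] + 1:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], end))
        else:
            out.append((chrom, start, end))
    return out


def build_cis_windows(
    annotation: MirnaAnnotation, pad: int = 500_000
) -> list[CisWindow]:
    """Per mature miRNA, the union of padded precursor intervals.

    Each precursor contributes [start - pad, end + pad] clamped at 1;
    overlapping regions (precursors closer than 2*pad) are merged so a SNP in
    the shared padding is tested only once for the miRNA.
    """
    windows = []
    for mid, grp in annotation.table.groupby("mature_id", sort=True):
        regions = [
            (str(r.chrom), max(1, int(r.start) - pad), int(r.end) + pad)
            for r in grp.itertuples()
        ]
        windows.append(CisWindow(mature_id=mid, regions=_merge_regions(regions)))
    return windows


def drop_high_vif(X: np.ndarray, vif_max: float = 500.0) -> tuple[np.ndarray, list]:
    """Iteratively drop the non-intercept column with the largest VIF > bound.

    Mirrors allowing the scan to run despite near-collinearity (e.g. genetic
    PCs vs genotyping platform) while keeping the design invertible.
    Column 0 is assumed to be the intercept and is never dropped.
    """
    X = np.asarray(X, dtype=float)
    keep = list(range(X.shape[1]))
    dropped: list = []
    while len(keep) > 1:
        sub = X[:, keep]
        vifs = np.zeros(len(keep))
        for j in range(1, len(keep)):
            y = sub[:, j]
            others = np.delete(sub, j, axis=1)
            coef, *_ = np.linalg.lstsq(others, y, rcond=None)
            resid = y - others @ coef
            tss = np.sum((y - y.mean()) ** 2)
            if tss <= 0:
                vifs[j] = np.inf
                continue
            r2 = 1.0 - resid @ resid / tss
            vifs[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
        worst = int(np.argmax(vifs))
        if vifs[worst] <= vif_max:
            break
        dropped.append(keep[worst])
        del keep[worst]
    if dropped:
        warnings.warn(f"dropped {len(dropped)} covariate column(s) with VIF > {vif_max}")
    return X[:, keep], dropped


def scan_cis(
    panel: VariantPanel,
    expr: ExpressionMatrix,
    covars: np.ndarray | None,
    windows: list[CisWindow],
    vif_max: float = 500.0,
) -> pd.DataFrame:
    """Additive-model scan of every SNP-miRNA pair within the cis windows.

    Returns all tested pairs (not only significant ones) with per-dosage-unit
    beta, se, t, two-sided p (t distribution, n - p - 1 df) and n. SNPs that
    are monomorphic within the analysis samples are skipped and counted in
    ``df.attrs['n_monomorphic_skipped']``.
    """
    if not np.array_equal(panel.sample_id, expr.sample_id):
        raise ValueError("panel and expression samples must be aligned")
    n = panel.n_samples
    if covars is None:
        X = np.ones((n, 1))
    else:
        X = np.asarray(covars, dtype=float)
        if X.shape[0] != n:
            raise ValueError("covariate rows must match samples")
        if not np.allclose(X[:, 0], 1.0):
            X = np.column_stack([np.ones(n), X])
        X, _ = _drop_collinear(X)
        X, _ = drop_high_vif(X, vif_max)
    p_cov = X.shape[1]
    dof = n - p_cov - 1
    if dof <= 0:
        raise ValueError("not enough samples for the covariate model")

    mono = panel.dosage.std(axis=0) == 0
    G_res = residualize(panel.dosage, X)
    Y_res = residualize(expr.values, X)
    gss = np.einsum("ij,ij->j", G_res, G_res)

    feat_idx = {f: j for j, f in enumerate(expr.feature_id)}
    rows = []
    n_mono_skipped = 0
    for w in windows:
        j = feat_idx.get(w.mature_id)
        if j is None:
            continue
        in_win = np.zeros(panel.n_snps, dtype=bool)
        for chrom, start, end in w.regions:
            in_win |= (panel.chrom == chrom) & (panel.pos >= start) & (panel.pos <= end)
        snp_sel = np.flatnonzero(in_win & ~mono)
        n_mono_skipped += int((in_win & mono).sum())
        if snp_sel.size == 0:
            continue
        y = Y_res[:, j]
        yss = y @ y
        g = G_res[:, snp_sel]
        gy = y @ g
        denom = gss[snp_sel]
        beta = gy / denom
        rss = np.maximum(yss - beta * gy, 0.0)
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / denom)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, 0.0)
        p = np.where(se > 0, 2.0 * stats.t.sf(np.abs(t), df=dof), 1.0)
        rows.append(
            pd.DataFrame(
                {
                    "mirna": w.mature_id,
                    "snp": panel.snp_id[snp_sel],
                    "chrom": panel.chrom[snp_sel],
                    "pos": panel.pos[snp_sel],
                    "a1": panel.alt[snp_sel],
                    "a2": panel.ref[snp_sel],
                    "beta": beta,
                    "se": se,
                    "t": t,
                    "p": np.clip(p, np.finfo(float).tiny, 1.0),
                    "n": n,
                }
            )
        )
    if not rows:
        out = pd.DataFrame(
            columns=["mirna", "snp", "chrom", "pos", "a1", "a2", "beta", "se", "t", "p", "n"]
        )
    else:
        out = pd.concat(rows, ignore_index=True)
    out.attrs["n_monomorphic_skipped"] = n_mono_skipped
    out.attrs["dof"] = dof
    return out


def _natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (truncated-power form, linear beyond
    boundary knots)."""
    x = np.asarray(x, dtype=float)
    k = np.asarray(knots, dtype=float)
    km = k[-1]

    def d(j):
        num = np.maximum(x - k[j], 0.0) ** 3 - np.maximum(x - km, 0.0) ** 3
        return num / (km - k[j])

    cols = [x]
    for j in range(len(k) - 2):
        cols.append(d(j) - d(len(k) - 2))
    return np.column_stack([np.ones_like(x)] + cols)


def storey_pi0(
    p: np.ndarray, lambdas: np.ndarray | None = None
) -> float:
    """Storey pi0: spline-smoothed pi0(lambda) evaluated at the largest lambda."""
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    m = len(p)
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    # natural cubic smoother with interior knots at the lambda tertiles (~3 df)
    knots = np.quantile(lambdas, [0.0, 1 / 3, 2 / 3, 1.0])
    B = _natural_spline_basis(lambdas, knots)
    coef, *_ = np.linalg.lstsq(B, pi0_l, rcond=None)
    pi0_hat = float((_natural_spline_basis(np.array([lambdas[-1]]), knots) @ coef)[0])
    return float(np.clip(pi0_hat, 1.0 / m, 1.0))


def storey_qvalues(
    p: np.ndarray | list, lambdas: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values over the full set of tests.

    q_(i) = min_{j: p_(j) >= p_(i)} pi0 * m * p_(j) / j. With fewer than 100
    p-values the pi0 estimate is unstable, so pi0 falls back to 1 (plain
    Benjamini-Hochberg) with a warning.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    if m < 100:
        warnings.warn("fewer than 100 p-values; using pi0 = 1 (BH)")
        pi0 = 1.0
    else:
        pi0 = storey_pi0(p, lambdas)
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, pi0


def variance_explained(
    expr_resid: np.ndarray, dosage: np.ndarray, pcs: np.ndarray | None = None
) -> float:
    """Fraction of residual expression variance explained by one SNP.

    Fits residualized expression on SNP dosage plus genetic PCs and reports
    Var(beta * dosage) / Var(outcome).
    """
    y = np.asarray(expr_resid, dtype=float)
    vy = y.var()
    if vy <= 0:
        return 0.0
    cols = [np.ones_like(y), np.asarray(dosage, dtype=float)]
    if pcs is not None and pcs.size:
        cols.append(np.asarray(pcs, dtype=float))
    X = np.column_stack(cols)
    X, dropped = _drop_collinear(X)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    if 1 in dropped:  # dosage column itself collinear/constant
        return 0.0
    beta = coef[1]
    return float((beta * np.asarray(dosage)).var() / vy)
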