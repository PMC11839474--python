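"""miRNA count QC: abundance filtering, dedup, TMM/log2 normalization,
outlier removal, surrogate variables and residualization.

The normalization pipeline follows the small-RNA convention: trimmed mean of
M-values (TMM) scale factors, then log2 counts-per-million. The log transform
uses a prior of 0.5 on the CPM scale, log2(CPM + 0.5), which makes a sample's
normalized values exactly invariant to uniform rescaling of its counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MirnaAnnotation

__all__ = [
    "rpm",
    "filter_low_expression",
    "dedup_multi_precursor",
    "tmm_norm_factors",
    "normalize_log2",
    "remove_outlier_samples_batch",
    "remove_outlier_samples_pca",
    "estimate_surrogate_variables",
    "residualize",
    "build_design",
]


def rpm(em: ExpressionMatrix) -> np.ndarray:
    """Reads-per-million matrix from raw counts."""
    if em.tag != "counts":
        raise ValueError("rpm expects raw counts")
    lib = em.library_size
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    return em.values / lib[:, None] * 1e6


def filter_low_expression(
    em: ExpressionMatrix, min_rpm: float = 1.0, min_frac: float = 0.5
) -> ExpressionMatrix:
    """Keep features with RPM >= min_rpm in >= min_frac of samples.

    Both thresholds are inclusive, so a feature at exactly 1 RPM in exactly
    half the samples survives.
    """
    r = rpm(em)
    frac = np.mean(r >= min_rpm, axis=0)
    keep = np.flatnonzero(frac >= min_frac)
    return em.subset_features(keep)


def dedup_multi_precursor(
    em: ExpressionMatrix, annotation: MirnaAnnotation | None = None
) -> ExpressionMatrix:
    """Collapse duplicate mature ids, keeping the highest-total-count row.

    Features are expected to carry a ``mature_id`` (and ``precursor_id``)
    column in ``feature_meta``; when absent the feature id itself is the
    mature id and the matrix is returned unchanged. Ties are broken by the
    lexicographically smallest precursor id, with a warning.
    """
    meta = em.feature_meta
    if meta is None or "mature_id" not in meta.columns:
        return em
    totals = em.values.sum(axis=0)
    prec = meta.get("precursor_id", pd.Series([""] * em.n_features)).to_numpy(dtype=object)
    mature = meta["mature_id"].to_numpy(dtype=object)
    keep: list[int] = []
    for mid in pd.unique(mature):
        idx = np.flatnonzero(mature == mid)
        best_total = totals[idx].max()
        best = idx[totals[idx] == best_total]
        if len(best) > 1:
            order = np.argsort(prec[best].astype(str))
            warnings.warn(
                f"total-count tie for {mid}; keeping precursor {prec[best[order[0]]]}"
            )
            keep.append(int(best[order[0]]))
        else:
            keep.append(int(best[0]))
    keep.sort()
    out = em.subset_features(keep)
    out.feature_id = out.feature_meta["mature_id"].to_numpy(dtype=object)
    return out


def tmm_norm_factors(
    counts: np.ndarray,
    lib: np.ndarray | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    ref_sample: int | None = None,
) -> np.ndarray:
    """Trimmed-mean-of-M-values scale factors (samples in rows).

    The reference sample is the one whose 75th count percentile (as a
    fraction of library size) is closest to the across-sample mean of that
    quantity. Per sample, M and A values versus the reference are computed
    over features expressed in both; the middle (1 - 2*logratio_trim) of M
    and (1 - 2*sum_trim) of A are retained by rank; the factor is 2 to the
    plain mean of the retained M values (the unweighted trimmed mean, so a
    sample's factor is exactly invariant to uniform rescaling of its
    counts). Factors are rescaled so their log-mean is zero.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[0]
    if lib is None:
        lib = counts.sum(axis=1)
    if np.any(lib <= 0):
        raise ValueError("zero library size")
    if ref_sample is None:
        f75 = np.array([np.quantile(counts[i] / lib[i], 0.75) for i in range(n)])
        ref_sample = int(np.argmin(np.abs(f75 - f75.mean())))

    ref = counts[ref_sample]
    nref = lib[ref_sample]
    log_factors = np.zeros(n)
    for i in range(n):
        if i == ref_sample:
            continue
        obs = counts[i]
        ok = (obs > 0) & (ref > 0) & (obs < lib[i]) & (ref < nref)
        if not ok.any():
            continue
        po, pr = obs[ok] / lib[i], ref[ok] / nref
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        ng = m.size
        lo_m = int(np.floor(ng * logratio_trim)) + 1
        hi_m = ng + 1 - lo_m
        lo_a = int(np.floor(ng * sum_trim)) + 1
        hi_a = ng + 1 - lo_a
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any():
            continue
        f = float(np.mean(m[keep]))
        if np.isfinite(f):
            log_factors[i] = f
    log_factors -= log_factors.mean()
    return 2.0**log_factors


def normalize_log2(em: ExpressionMatrix, prior: float = 0.5) -> ExpressionMatrix:
    """TMM-normalized log2 CPM: log2(count / (lib * factor) * 1e6 + prior)."""
    if em.tag != "counts":
        raise ValueError("normalize_log2 expects raw counts")
    lib = em.library_size
    if np.any(lib <= 0):
        raise ValueError("sample with all-zero counts")
    factors = tmm_norm_factors(em.values, lib)
    cpm = em.values / (lib * factors)[:, None] * 1e6
    out = ExpressionMatrix(
        sample_id=em.sample_id,
        feature_id=em.feature_id,
        values=np.log2(cpm + prior),
        tag="log2",
        library_size=lib,
        feature_meta=em.feature_meta,
    )
    return out


def remove_outlier_samples_batch(
    metrics: pd.DataFrame,
    batch: pd.Series,
    n_sd: float = 5.0,
    min_batch: int = 3,
    max_iter: int = 50,
) -> list:
    """Iteratively drop samples > n_sd from their batch mean on any metric.

    Repeats until no sample is dropped. A batch that would fall below
    ``min_batch`` retained samples stops iterating with a warning.
    """
    retained = list(metrics.index)
    frozen_batches: set = set()
    for _ in range(max_iter):
        dropped: list = []
        cur = metrics.loc[retained]
        cur_batch = batch.loc[retained]
        for b, grp in cur.groupby(cur_batch, observed=True):
            if b in frozen_batches:
                continue
            if len(grp) < min_batch:
                warnings.warn(f"batch {b} below {min_batch} samples; not iterating")
                frozen_batches.add(b)
                continue
            mu, sd = grp.mean(), grp.std(ddof=1)
            z = (grp - mu).abs() / sd.replace(0.0, np.inf)
            bad = grp.index[(z > n_sd).any(axis=1)]
            if len(grp) - len(bad) < min_batch:
                warnings.warn(f"batch {b} would fall below {min_batch}; stopping it")
                frozen_batches.add(b)
                continue
            dropped.extend(bad)
        if not dropped:
            break
        retained = [s for s in retained if s not in set(dropped)]
    return retained


def _top_pcs(values: np.ndarray, k: int = 2) -> np.ndarray:
    x = values - values.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    return u[:, :k] * s[:k]


def remove_outlier_samples_pca(
    em: ExpressionMatrix, n_sd: float = 4.0, iterate: bool = False
) -> tuple[list, np.ndarray]:
    """Drop samples > n_sd from the mean of PC1 or PC2 of normalized values.

    Single pass by default (the miRNA convention); set ``iterate`` for the
    repeat-until-stable variant used for proteomic matrices. Returns the
    retained sample ids and the post-removal PCs (recomputed once).
    """
    if em.tag != "log2":
        raise ValueError("pca outlier removal expects normalized log2 values")
    idx = np.arange(em.n_samples)
    while True:
        pcs = _top_pcs(em.values[idx], k=2)
        mu, sd = pcs.mean(axis=0), pcs.std(axis=0, ddof=1)
        ok = (np.abs(pcs - mu) <= n_sd * sd).all(axis=1)
        if ok.all() or not iterate:
            idx = idx[ok]
            break
        idx = idx[ok]
    final_pcs = _top_pcs(em.values[idx], k=2)
    return list(em.sample_id[idx]), final_pcs


def build_design(covars: pd.DataFrame, add_intercept: bool = True) -> np.ndarray:
    """Numeric design matrix: dummy-coded categoricals plus an intercept."""
    num = covars.select_dtypes(include=[np.number])
    cat = covars.select_dtypes(exclude=[np.number])
    parts = [num.to_numpy(dtype=float)] if num.shape[1] else []
    if cat.shape[1]:
        parts.append(pd.get_dummies(cat, drop_first=True).to_numpy(dtype=float))
    X = np.column_stack(parts) if parts else np.empty((len(covars), 0))
    if add_intercept:
        X = np.column_stack([np.ones(len(covars)), X])
    return X


def _drop_collinear(X: np.ndarray, tol: float = 1e-10) -> tuple[np.ndarray, list]:
    """Remove columns that are linearly dependent on earlier ones (QR pivot)."""
    from scipy.linalg import qr

    if X.shape[1] == 0:
        return X, []
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    rank = int(np.sum(diag > tol * max(diag[0], 1.0)))
    keep = sorted(piv[:rank])
    dropped = sorted(set(range(X.shape[1])) - set(keep))
    if dropped:
        warnings.warn(f"dropped {len(dropped)} collinear covariate column(s): {dropped}")
    return X[:, keep], dropped


def residualize(values: np.ndarray, covars: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``values`` on the covariate matrix.

    Collinear covariate columns are dropped with a warning; residuals are
    orthogonal to the retained covariate space to numerical precision.
    """
    values = np.asarray(values, dtype=float)
    X, _ = _drop_collinear(np.asarray(covars, dtype=float))
    if X.shape[1] == 0:
        return values.copy()
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ coef


def estimate_surrogate_variables(
    log2_values: np.ndarray, known_covars: np.ndarray, n_sv: int = 15
) -> np.ndarray:
    """Surrogate variables by residual SVD.

    Known covariates are regressed out of the expression matrix; the SVs are
    the top ``n_sv`` left singular vectors of the residual, each scaled to
    unit sample variance. They are orthogonal to the known-covariate column
    space by construction.
    """
    X, _ = _drop_collinear(np.asarray(known_covars, dtype=float))
    n = log2_values.shape[0]
    if n_sv >= n - X.shape[1]:
        raise ValueError(
            f"n_sv={n_sv} too large for n={n} samples and rank-{X.shape[1]} covariates"
        )
    resid = residualize(log2_values, X)
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    sv = u[:, :n_sv]
    sv = sv / sv.std(axis=0, ddof=1)
    return sv
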