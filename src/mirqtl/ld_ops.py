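"""LD computation, greedy clumping to index miR-QTLs, and stepwise
conditional analysis for independent signals."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ClumpResult, VariantPanel
from .expression_qc import _drop_collinear

__all__ = ["ld_r2", "ld_matrix", "clump", "conditional_scan"]


def ld_r2(panel: VariantPanel, snp_i: str, snp_j: str) -> float:
    """Composite LD: squared Pearson correlation of the dosage vectors.

    Returns NaN for a monomorphic SNP (undefined correlation).
    """
    gi = panel.dosage[:, panel.index_of(snp_i)]
    gj = panel.dosage[:, panel.index_of(snp_j)]
    if gi.std() == 0 or gj.std() == 0:
        return float("nan")
    r = np.corrcoef(gi, gj)[0, 1]
    return float(r * r)


def ld_matrix(panel: VariantPanel, snps: list | np.ndarray | None = None) -> np.ndarray:
    """Pairwise dosage correlation matrix over the requested SNPs."""
    if snps is None:
        G = panel.dosage
    else:
        idx = [panel.index_of(s) for s in snps]
        G = panel.dosage[:, idx]
    sd = G.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic SNP in LD matrix request")
    R = np.corrcoef(G, rowvar=False)
    if R.ndim == 0:  # single SNP
        R = np.array([[1.0]])
    return (R + R.T) / 2


def clump(
    records: pd.DataFrame,
    panel: VariantPanel,
    r2_max: float = 0.5,
    radius_kb: float = 250.0,
    p_max: float | None = None,
) -> list[ClumpResult]:
    """Greedy LD clumping of one miRNA's significant miR-QTLs.

    Repeatedly takes the remaining SNP with the smallest p as the next index
    and absorbs remaining SNPs with r2 >= r2_max AND distance <= radius_kb.
    Ties on p are broken by the smaller genomic position. Index SNPs are
    mutually non-absorbable under the rule; membership partitions the input.
    """
    if records.empty:
        return []
    rec = records.copy()
    if p_max is not None:
        rec = rec[rec["p"] <= p_max]
        if rec.empty:
            return []
    rec = rec.sort_values(["p", "pos"], kind="mergesort").reset_index(drop=True)
    idx_in_panel = np.array([panel.index_of(s) for s in rec["snp"]])
    G = panel.dosage[:, idx_in_panel]
    sd = G.std(axis=0)
    Gc = (G - G.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    n = G.shape[0]
    radius_bp = radius_kb * 1000.0

    remaining = list(range(len(rec)))
    results = []
    while remaining:
        i = remaining[0]  # smallest p (ties already broken by position)
        members, m_r2, m_dist = [], [], []
        keep = []
        gi = Gc[:, i]
        for j in remaining[1:]:
            dist = abs(int(rec.at[j, "pos"]) - int(rec.at[i, "pos"]))
            same_chrom = rec.at[j, "chrom"] == rec.at[i, "chrom"]
            r2 = (gi @ Gc[:, j] / n) ** 2 if sd[i] > 0 and sd[j] > 0 else 0.0
            if same_chrom and r2 >= r2_max and dist <= radius_bp:
                members.append(rec.at[j, "snp"])
                m_r2.append(float(r2))
                m_dist.append(dist)
            else:
                keep.append(j)
        results.append(
            ClumpResult(
                index_snp=rec.at[i, "snp"],
                index_p=float(rec.at[i, "p"]),
                members=members,
                member_r2=m_r2,
                member_dist_bp=m_dist,
            )
        )
        remaining = keep
    return results


def conditional_scan(
    y: np.ndarray,
    panel: VariantPanel,
    covars: np.ndarray | None,
    index_snps: list,
    threshold: float,
) -> list:
    """Stepwise conditional analysis over index SNPs ranked by p.

    The independent list starts with the top-ranked index SNP. Each round
    refits every remaining index SNP with the current independent set as
    extra covariates; with more than one SNP still significant at
    ``threshold`` the best-ranked one is added and the round repeats; with
    exactly one, it is added and the procedure stops; with none it stops.
    A candidate collinear with the current set is skipped with a warning.
    """
    if not index_snps:
        raise ValueError("need at least one index SNP")
    y = np.asarray(y, dtype=float)
    n = len(y)
    base = np.ones((n, 1)) if covars is None else np.asarray(covars, dtype=float)
    if base.ndim == 1:
        base = base[:, None]
    if not np.allclose(base[:, 0], 1.0):
        base = np.column_stack([np.ones(n), base])

    independent = [index_snps[0]]
    remaining = list(index_snps[1:])
    while remaining:
        X_ind = np.column_stack(
            [panel.dosage[:, panel.index_of(s)] for s in independent]
        )
        X_base = np.column_stack([base, X_ind])
        X_base, _ = _drop_collinear(X_base)
        sig: list = []
        for s in remaining:
            g = panel.dosage[:, panel.index_of(s)]
            X = np.column_stack([X_base, g])
            rank_before = np.linalg.matrix_rank(X_base)
            if np.linalg.matrix_rank(X) == rank_before:
                warnings.warn(f"SNP {s} collinear with conditional set; skipped")
                continue
            dof = n - X.shape[1]
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            sigma2 = resid @ resid / dof
            xtx_inv_last = np.linalg.pinv(X.T @ X)[-1, -1]
            se = np.sqrt(sigma2 * xtx_inv_last)
            p = 2.0 * stats.t.sf(abs(coef[-1] / se), df=dof) if se > 0 else 1.0
            if p <= threshold:
                sig.append(s)
        if not sig:
            break
        # best-ranked = earliest in the original p-ordered list
        best = min(sig, key=remaining.index)
        independent.append(best)
        remaining.remove(best)
        if len(sig) == 1:
            break
    return independent
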