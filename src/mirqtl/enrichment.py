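"""Regulatory-region enrichment, cross-study sharing statistics and
positional characterization of index miR-QTLs.

Enrichment uses the Cochran-Mantel-Haenszel test over MAF strata
((0-0.1), [0.1-0.2), [0.2-0.5] by default) of 2x2 tables (miR-QTL yes/no x
interval overlap yes/no). Sharing between studies uses the Storey pi1
replication statistic and a Yates-corrected 2x2 chi-squared test of eMiR
overlap.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cis_qtl import storey_pi0

__all__ = [
    "overlap_flags",
    "build_stratified_tables",
    "cmh_test",
    "sharing_chi2",
    "pi1",
    "position_stats",
    "MAF_STRATA",
]

MAF_STRATA = [(0.0, 0.1), (0.1, 0.2), (0.2, 0.5)]


def overlap_flags(
    chrom: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame
) -> np.ndarray:
    """True where a SNP position lies in any interval (1-based inclusive)."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    flags = np.zeros(len(pos), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return flags
    for c, grp in intervals.groupby("chrom", sort=False):
        # merge to sorted disjoint intervals, then locate by binary search
        g = grp.sort_values("start")
        starts, ends = [], []
        for s, e in zip(g["start"].astype(int), g["end"].astype(int)):
            if ends and s <= ends[-1] + 1:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        starts_a = np.asarray(starts)
        ends_a = np.asarray(ends)
        sel = chrom == str(c)
        if not sel.any():
            continue
        j = np.searchsorted(starts_a, pos[sel], side="right") - 1
        ok = (j >= 0) & (pos[sel] <= ends_a[np.clip(j, 0, None)])
        flags[np.flatnonzero(sel)[ok]] = True
    return flags


def build_stratified_tables(
    maf: np.ndarray,
    is_qtl: np.ndarray,
    in_interval: np.ndarray,
    strata: list[tuple[float, float]] | None = None,
) -> list[np.ndarray]:
    """Per-MAF-stratum 2x2 tables [[qtl&in, qtl&out], [non&in, non&out]]."""
    if strata is None:
        strata = MAF_STRATA
    maf = np.asarray(maf, dtype=float)
    is_qtl = np.asarray(is_qtl, dtype=bool)
    in_interval = np.asarray(in_interval, dtype=bool)
    tables = []
    for i, (lo, hi) in enumerate(strata):
        last = i == len(strata) - 1
        sel = (maf >= lo) & ((maf <= hi) if last else (maf < hi))
        a = int(np.sum(sel & is_qtl & in_interval))
        b = int(np.sum(sel & is_qtl & ~in_interval))
        c = int(np.sum(sel & ~is_qtl & in_interval))
        d = int(np.sum(sel & ~is_qtl & ~in_interval))
        tables.append(np.array([[a, b], [c, d]]))
    return tables


def cmh_test(tables: list[np.ndarray]) -> tuple[float, tuple[float, float], float]:
    """Mantel-Haenszel common OR, 95% CI and CMH p over strata.

    OR_MH = sum(a_k d_k / n_k) / sum(b_k c_k / n_k); the chi-squared test is
    run without continuity correction; the CI uses the Robins-Breslow-
    Greenland variance. A zero denominator yields a +inf sentinel with a
    warning.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    arr = [np.asarray(t, dtype=float) for t in tables]
    if not any(t.sum() > 0 for t in arr):
        raise ValueError("need at least one stratum with nonzero margins")
    denom = sum(t[0, 1] * t[1, 0] / t.sum() for t in arr if t.sum() > 0)
    if denom == 0:
        warnings.warn("zero discordant-cell denominator; OR is +inf")
        return float("inf"), (float("inf"), float("inf")), 0.0
    st = StratifiedTable([t for t in arr if t.sum() > 0])
    or_mh = float(st.oddsratio_pooled)
    ci = tuple(float(x) for x in st.oddsratio_pooled_confint(alpha=0.05))
    res = st.test_null_odds(correction=False)
    return or_mh, ci, float(res.pvalue)


def sharing_chi2(
    both_tested: int, emirs_a: int, emirs_b: int, shared: int
) -> tuple[float, float]:
    """Chi-squared test of eMiR sharing between two studies.

    Reconstructs the 2x2 table (shared, a-only, b-only, neither) from the
    printed counts and applies the test of independence with Yates
    continuity correction. Symmetric in the two studies' roles.
    """
    if shared > min(emirs_a, emirs_b) or max(emirs_a, emirs_b) > both_tested:
        raise ValueError("inconsistent counts")
    a = shared
    b = emirs_a - shared
    c = emirs_b - shared
    d = both_tested - emirs_a - emirs_b + shared
    if min(a, b, c, d) < 0:
        raise ValueError("negative reconstructed cell")
    table = np.array([[a, b], [c, d]])
    x2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(x2), float(p)


def pi1(replication_p: np.ndarray) -> float:
    """Storey pi1 = 1 - pi0 over replication p-values of discovery top hits."""
    p = np.asarray(replication_p, dtype=float)
    if len(p) < 50:
        raise ValueError("need at least 50 replication p-values for pi1")
    return float(np.clip(1.0 - storey_pi0(p), 0.0, 1.0))


def position_stats(
    index_qtls: pd.DataFrame, annotation, genomic_orientation: bool = False
) -> dict:
    """Positional summary of index miR-QTLs relative to their precursors.

    Each index QTL (columns: mirna, snp, chrom, pos, p) is classified as
    within a precursor, upstream, downstream, or ambiguous (miRNAs with
    multiple precursors whose orientations disagree; excluded and counted).
    Upstream/downstream follows the miRNA gene's transcriptional orientation
    unless ``genomic_orientation`` is set. Reports the exact two-sided
    binomial test of upstream vs downstream counts (minimum-likelihood rule
    at p=0.5) and the Spearman correlation of |distance to the nearest TSS|
    with the association p-value (average ranks for ties).
    """
    n_up = n_down = n_within = n_ambig = 0
    dists, pvals = [], []
    for row in index_qtls.itertuples():
        prec = annotation.precursors_of(row.mirna)
        prec = prec[prec["chrom"].astype(str) == str(row.chrom)]
        if prec.empty:
            n_ambig += 1
            continue
        inside = (prec["start"] <= row.pos) & (row.pos <= prec["end"])
        if inside.any():
            n_within += 1
            continue
        labels = set()
        tss_dists = []
        for pr in prec.itertuples():
            if genomic_orientation or pr.strand == "+":
                up = row.pos < pr.start
                tss = pr.start if pr.strand == "+" or genomic_orientation else pr.end
            else:
                up = row.pos > pr.end
                tss = pr.end
            labels.add("up" if up else "down")
            tss_dists.append(abs(int(row.pos) - int(tss)))
        if len(labels) > 1:
            n_ambig += 1
            continue
        if labels.pop() == "up":
            n_up += 1
        else:
            n_down += 1
        dists.append(min(tss_dists))
        pvals.append(row.p)
    n_tested = n_up + n_down
    binom_p = (
        float(stats.binomtest(n_up, n_tested, 0.5, alternative="two-sided").pvalue)
        if n_tested
        else float("nan")
    )
    if len(dists) >= 3:
        rho, rho_p = stats.spearmanr(dists, pvals)
    else:
        rho, rho_p = float("nan"), float("nan")
    return {
        "n_upstream": n_up,
        "n_downstream": n_down,
        "n_within": n_within,
        "n_ambiguous": n_ambig,
        "binomial_p": binom_p,
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
    }
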