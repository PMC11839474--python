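"""Genomic classification of miRNAs (intragenic/intergenic, clusters),
host-gene correlation, and the predicted-target protein-QTL sharing
workflow."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MirnaAnnotation, VariantPanel
from .smr import smr_two_molecular

__all__ = [
    "classify_intragenic",
    "assign_clusters",
    "host_correlation",
    "filter_target_table",
    "target_pqtl_share",
    "HOST_BIOTYPES",
]

# biotypes whose same-strand overlap makes a miRNA intragenic; miRNA genes
# themselves never count as hosts
HOST_BIOTYPES = {"protein_coding", "lncRNA", "lincRNA", "snoRNA", "snRNA", "scaRNA"}


def classify_intragenic(
    annotation: MirnaAnnotation,
    genes: pd.DataFrame,
    host_biotypes: set | None = None,
) -> pd.DataFrame:
    """Per precursor: intragenic (with host id) or intergenic.

    Intragenic requires >= 1 bp overlap AND matching strand with a gene of an
    eligible biotype other than a miRNA gene. All hosts are recorded; the
    primary host is the one with the longest overlap.
    """
    if host_biotypes is None:
        host_biotypes = HOST_BIOTYPES
    rows = []
    for pr in annotation.table.itertuples():
        cand = genes[
            (genes["chrom"].astype(str) == str(pr.chrom))
            & (genes["strand"] == pr.strand)
            & (genes["biotype"].isin(host_biotypes))
            & (genes["start"] <= pr.end)
            & (genes["end"] >= pr.start)
        ]
        if cand.empty:
            rows.append(
                {
                    "mature_id": pr.mature_id,
                    "precursor_id": pr.precursor_id,
                    "classification": "intergenic",
                    "host_gene": "",
                    "all_hosts": "",
                }
            )
            continue
        ov = np.minimum(cand["end"], pr.end) - np.maximum(cand["start"], pr.start) + 1
        primary = cand.iloc[int(np.argmax(ov.to_numpy()))]["gene_id"]
        rows.append(
            {
                "mature_id": pr.mature_id,
                "precursor_id": pr.precursor_id,
                "classification": "intragenic",
                "host_gene": primary,
                "all_hosts": ",".join(cand["gene_id"].astype(str)),
            }
        )
    return pd.DataFrame(rows)


def assign_clusters(precursors: pd.DataFrame, gap_max: int = 10_000) -> pd.Series:
    """Single-linkage clustering of precursors within ``gap_max`` of each
    other on a chromosome; singletons get their own labels.

    The inter-miRNA distance is the gap between precursor intervals; chains
    are transitive (A-B and B-C near implies one cluster of three).
    """
    df = precursors.sort_values(["chrom", "start"]).copy()
    labels = {}
    cluster_n = 0
    for chrom, grp in df.groupby("chrom", sort=False):
        prev_end = None
        for pr in grp.itertuples():
            gap = None if prev_end is None else pr.start - prev_end - 1
            if prev_end is None or gap >= gap_max:
                cluster_n += 1
            labels[pr.precursor_id] = f"cluster_{cluster_n}"
            prev_end = max(prev_end, pr.end) if prev_end is not None else pr.end
    return precursors["precursor_id"].map(labels)


def host_correlation(
    mirna_resid: pd.DataFrame,
    transcript_resid: pd.DataFrame,
    pairs: list[tuple[str, str]],
    n_background: int = 1000,
    seed: int = 0,
    min_overlap: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Spearman correlation of intragenic miRNA/host-transcript residuals.

    Per pair: Spearman rho and p over the shared samples (pairs with fewer
    than ``min_overlap`` shared samples are skipped). Set level: a two-sided
    rank-sum test of intragenic-pair correlations against correlations of
    ``n_background`` random miRNA-transcript pairings.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for mir, gene in pairs:
        if mir not in mirna_resid.columns or gene not in transcript_resid.columns:
            continue
        common = mirna_resid.index.intersection(transcript_resid.index)
        if len(common) < min_overlap:
            continue
        rho, p = stats.spearmanr(
            mirna_resid.loc[common, mir], transcript_resid.loc[common, gene]
        )
        rows.append({"mirna": mir, "gene": gene, "rho": float(rho), "p": float(p)})
    per_pair = pd.DataFrame(rows)
    if per_pair.empty:
        return per_pair, float("nan")
    common = mirna_resid.index.intersection(transcript_resid.index)
    mir_cols = list(mirna_resid.columns)
    gene_cols = list(transcript_resid.columns)
    bg = np.empty(n_background)
    mr = mirna_resid.loc[common]
    tr = transcript_resid.loc[common]
    for i in range(n_background):
        m = mir_cols[rng.integers(len(mir_cols))]
        g = gene_cols[rng.integers(len(gene_cols))]
        bg[i], _ = stats.spearmanr(mr[m], tr[g])
    _, set_p = stats.mannwhitneyu(per_pair["rho"], bg, alternative="two-sided")
    return per_pair, float(set_p)


def filter_target_table(
    targets: pd.DataFrame,
    targetscan_score_max: float = -0.2,
    rna22_p_max: float = 0.05,
) -> pd.DataFrame:
    """Apply source-specific filters to a predicted-target table.

    Columns: mirna, gene, source ('targetscan'|'rna22'), score. TargetScan
    rows keep cumulative weighted context++ score < -0.2 (more negative =
    stronger targeting); RNA22 rows keep prediction p < 0.05.
    """
    ts = targets[
        (targets["source"] == "targetscan") & (targets["score"] < targetscan_score_max)
    ]
    r22 = targets[(targets["source"] == "rna22") & (targets["score"] < rna22_p_max)]
    return (
        pd.concat([ts, r22], ignore_index=True)
        .drop_duplicates(["mirna", "gene"])
        .reset_index(drop=True)
    )


def target_pqtl_share(
    mir_qtls: pd.DataFrame,
    protein: pd.DataFrame,
    panel: VariantPanel,
    targets: pd.DataFrame,
    protein_coords: pd.DataFrame | None = None,
    covars: np.ndarray | None = None,
    fdr_max: float = 0.05,
    cis_kb: float = 500.0,
    miss_max: float = 0.5,
) -> pd.DataFrame:
    """Test miR-QTL SNPs against predicted-target protein abundance.

    Only (index miR-QTL SNP, predicted-target protein) pairs are tested;
    proteins with > 50% missing samples are excluded. FDR (BH) is applied
    across all tests run. Shared pairs are labeled cis (within ``cis_kb``
    on the same chromosome) or trans otherwise when protein coordinates are
    supplied.
    """
    from statsmodels.stats.multitest import multipletests

    from .expression_qc import _drop_collinear

    t_by_mir = targets.groupby("mirna")["gene"].apply(set).to_dict()
    rows = []
    n = len(protein.index)
    keep_prot = [
        c for c in protein.columns if protein[c].isna().mean() <= miss_max
    ]
    base = np.ones((n, 1)) if covars is None else np.asarray(covars, dtype=float)
    if not np.allclose(base[:, 0], 1.0):
        base = np.column_stack([np.ones(n), base])
    base, _ = _drop_collinear(base)

    for q in mir_qtls.itertuples():
        genes = t_by_mir.get(q.mirna, set()) & set(keep_prot)
        if not genes:
            continue
        g = panel.dosage[:, panel.index_of(q.snp)]
        for gene in sorted(genes):
            yv = protein[gene].to_numpy(dtype=float)
            ok = ~np.isnan(yv)
            if ok.sum() < 30:
                continue
            X = np.column_stack([base[ok], g[ok]])
            dof = ok.sum() - X.shape[1]
            coef, *_ = np.linalg.lstsq(X, yv[ok], rcond=None)
            resid = yv[ok] - X @ coef
            sigma2 = resid @ resid / dof
            se = float(np.sqrt(sigma2 * np.linalg.pinv(X.T @ X)[-1, -1]))
            p = 2.0 * float(stats.t.sf(abs(coef[-1] / se), df=dof)) if se > 0 else 1.0
            rows.append(
                {
                    "mirna": q.mirna,
                    "snp": q.snp,
                    "chrom": str(q.chrom),
                    "pos": int(q.pos),
                    "gene": gene,
                    "beta": float(coef[-1]),
                    "se": se,
                    "p": p,
                    "n": int(ok.sum()),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out["shared"] = out["fdr"] < fdr_max
    if protein_coords is not None:
        coords = protein_coords.set_index("gene_id")
        labels = []
        for r in out.itertuples():
            if r.gene not in coords.index:
                labels.append("unknown")
                continue
            g = coords.loc[r.gene]
            if str(g["chrom"]) != r.chrom:
                labels.append("trans")
            else:
                dist = max(int(g["start"]) - r.pos, r.pos - int(g["end"]), 0)
                labels.append("cis" if dist <= cis_kb * 1000 else "trans")
        out["cis_trans"] = labels
    return out
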