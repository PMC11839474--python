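"""Readers/writers for every file the pipeline touches, plus variant QC.

Internal coordinates are 1-based inclusive everywhere; BED (0-based
half-open) is converted at this boundary. All readers are strict on their
documented schemas and fail loudly otherwise.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, MirnaAnnotation, VariantPanel

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "filter_variants",
    "hwe_chi2_p",
    "read_intervals",
    "write_intervals",
    "read_mirna_annotation",
    "read_summary_stats",
    "read_counts",
    "write_counts",
    "read_covariates",
    "write_covariates",
    "harmonize_alleles",
]

_NT = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# VCF


def write_genotypes(panel: VariantPanel, path: str | Path) -> None:
    """Write the panel as an uncompressed VCF 4.2 with a DS FORMAT field."""
    path = Path(path)
    order = np.lexsort((panel.pos, panel.chrom.astype(str)))
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in pd.unique(panel.chrom[order]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in panel.sample_id)
            + "\n"
        )
        for j in order:
            ds = panel.dosage[:, j]
            cells = []
            for d in ds:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    hard = int(round(d))
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(hard, 0), 2)]
                    cells.append(f"{gt}:{d:.6g}")
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_id[j]}\t"
                f"{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def read_genotypes(path: str | Path) -> VariantPanel:
    """Read biallelic SNPs from a VCF into a :class:`VariantPanel`.

    Dosages come from the DS field when present, else from the GT allele
    sum. Multiallelic and indel records are skipped and counted in
    ``panel.n_skipped``. Records are sorted by (chrom, pos).
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    n_skipped = 0
    for v in vcf:
        alts = v.ALT
        if len(alts) != 1 or len(v.REF) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        if v.REF not in _NT or alts[0] not in _NT:
            n_skipped += 1
            continue
        ds = None
        try:
            arr = v.format("DS")
        except KeyError:
            arr = None
        if arr is not None:
            ds = np.asarray(arr, dtype=float).reshape(-1)
        else:
            gt = np.asarray(v.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            ds = gt.sum(axis=1)
        rows.append(ds)
        meta.append((v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS, v.REF, alts[0]))
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} multiallelic/indel record(s)")
    if not meta:
        raise ValueError(f"no biallelic SNP records in {path}")
    snp_id, chrom, pos, ref, alt = (np.asarray(x, dtype=object) for x in zip(*meta))
    dosage = np.column_stack(rows)
    order = np.lexsort((pos.astype(int), chrom.astype(str)))
    return VariantPanel(
        snp_id=snp_id[order],
        chrom=chrom[order],
        pos=pos[order].astype(np.int64),
        ref=ref[order],
        alt=alt[order],
        dosage=dosage[:, order],
        sample_id=samples,
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# Variant QC


def hwe_chi2_p(n_hom_ref: np.ndarray, n_het: np.ndarray, n_hom_alt: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg chi-squared p-value (1 df) from hard-call counts."""
    n_hom_ref = np.asarray(n_hom_ref, dtype=float)
    n_het = np.asarray(n_het, dtype=float)
    n_hom_alt = np.asarray(n_hom_alt, dtype=float)
    n = n_hom_ref + n_het + n_hom_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n_hom_alt + n_het) / (2 * n)
        q = 1.0 - p
        e0, e1, e2 = n * q**2, 2 * n * p * q, n * p**2
        x2 = np.zeros_like(n)
        for obs, exp in ((n_hom_ref, e0), (n_het, e1), (n_hom_alt, e2)):
            term = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1.0), 0.0)
            x2 = x2 + term
    return stats.chi2.sf(x2, df=1)


def filter_variants(
    panel: VariantPanel,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-8,
    miss_max: float = 0.05,
) -> VariantPanel:
    """MAF / HWE / missingness filters; HWE on rounded hard calls.

    Surviving missing dosages are mean-imputed so downstream linear algebra
    sees a complete matrix.
    """
    if not (0.0 <= maf_min <= 0.5 and 0.0 <= hwe_p_min <= 1.0 and 0.0 <= miss_max <= 1.0):
        raise ValueError("QC thresholds outside valid ranges")
    maf = panel.maf
    miss = panel.missingness
    hard = np.round(panel.dosage)
    valid = ~np.isnan(hard)
    n0 = np.sum((hard == 0) & valid, axis=0)
    n1 = np.sum((hard == 1) & valid, axis=0)
    n2 = np.sum((hard == 2) & valid, axis=0)
    hwe_p = hwe_chi2_p(n0, n1, n2)
    keep = (maf >= maf_min) & (hwe_p >= hwe_p_min) & (miss <= miss_max)
    if not keep.any():
        raise ValueError(
            f"no variants survive QC (maf>={maf_min}, hwe_p>={hwe_p_min}, "
            f"miss<={miss_max})"
        )
    out = panel.subset_snps(keep)
    if np.isnan(out.dosage).any():
        col_mean = np.nanmean(out.dosage, axis=0)
        idx = np.where(np.isnan(out.dosage))
        out.dosage[idx] = np.take(col_mean, idx[1])
    return out


# ---------------------------------------------------------------------------
# Intervals (BED), annotation, summary stats


def read_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED file into internal 1-based inclusive intervals."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "bed_start", "bed_end"],
        dtype={0: str},
    )
    if (df["bed_start"] > df["bed_end"]).any():
        raise ValueError("BED interval with start > end")
    out = pd.DataFrame(
        {"chrom": df["chrom"], "start": df["bed_start"] + 1, "end": df["bed_end"]}
    )
    if (out["start"] > out["end"]).any():
        raise ValueError("zero-length BED interval")
    return out


def write_intervals(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write internal 1-based inclusive intervals as 0-based half-open BED."""
    bed = pd.DataFrame(
        {
            "chrom": intervals["chrom"],
            "start": intervals["start"] - 1,
            "end": intervals["end"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_mirna_annotation(path: str | Path) -> MirnaAnnotation:
    """Read the miRNA coordinate table (TSV; GFF-like columns).

    Required columns: mature_id, precursor_id, chrom, start, end, strand;
    optional: arm, cluster. Coordinates are 1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "arm" not in df.columns:
        df["arm"] = ""
    if "cluster" not in df.columns:
        df["cluster"] = ""
    return MirnaAnnotation(table=df)


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a GWAS/QTL summary-statistic TSV.

    Columns: snp, chrom, pos, a1 (effect allele), a2, and at least one of
    (beta, se) or z; p and n optional. z is filled from beta/se when absent
    and checked for consistency (1e-6) when both are present.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snp", "a1", "a2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summary stats missing columns: {sorted(missing)}")
    for col in ("a1", "a2"):
        df[col] = df[col].astype(str).str.upper()
        bad = ~df[col].isin(sorted(_NT))
        if bad.any():
            raise ValueError(f"non-single-nucleotide alleles in column {col}")
    if "se" in df.columns and (df["se"] <= 0).any():
        raise ValueError("non-positive standard errors")
    if "z" not in df.columns:
        if not {"beta", "se"} <= set(df.columns):
            raise ValueError("need z or beta+se")
        df["z"] = df["beta"] / df["se"]
    elif {"beta", "se"} <= set(df.columns):
        resid = np.abs(df["z"] - df["beta"] / df["se"])
        if np.nanmax(resid.to_numpy(), initial=0.0) > 1e-6:
            raise ValueError("z inconsistent with beta/se beyond 1e-6")
    if "p" not in df.columns:
        df["p"] = 2.0 * stats.norm.sf(np.abs(df["z"]))
    return df


# ---------------------------------------------------------------------------
# Counts / covariates TSV


def read_counts(path: str | Path, tag: str = "counts") -> ExpressionMatrix:
    """Read a samples x features matrix TSV (first column = sample id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        sample_id=df.index.to_numpy(dtype=object),
        feature_id=df.columns.to_numpy(dtype=object),
        values=df.to_numpy(dtype=float),
        tag=tag,
    )


def write_counts(em: ExpressionMatrix, path: str | Path) -> None:
    em.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_covariates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_covariates(covars: pd.DataFrame, path: str | Path) -> None:
    covars.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Allele harmonization


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize_alleles(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    on: str = "pos",
    drop_ambiguous: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two summary-stat tables on shared variants.

    ``on`` is 'pos' (match on chrom+pos) or 'snp' (match on id). When the
    effect alleles are swapped between tables, table b's z/beta signs are
    flipped. Strand-ambiguous A/T and C/G SNPs are dropped with a warning,
    as are variants whose allele pairs do not match under either orientation.
    Returns the two tables aligned row-for-row.
    """
    key = ["chrom", "pos"] if on == "pos" else ["snp"]
    a = stats_a.drop_duplicates(key).set_index(key)
    b = stats_b.drop_duplicates(key).set_index(key)
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no shared variants to harmonize")
    a = a.loc[common].reset_index()
    b = b.loc[common].reset_index()

    amb = np.array(
        [_is_ambiguous(x, y) for x, y in zip(a["a1"], a["a2"])]
    ) | np.array([_is_ambiguous(x, y) for x, y in zip(b["a1"], b["a2"])])
    same = (a["a1"].to_numpy() == b["a1"].to_numpy()) & (
        a["a2"].to_numpy() == b["a2"].to_numpy()
    )
    swapped = (a["a1"].to_numpy() == b["a2"].to_numpy()) & (
        a["a2"].to_numpy() == b["a1"].to_numpy()
    )
    keep = (same | swapped) & (~amb if drop_ambiguous else True)
    n_amb = int((amb & (same | swapped)).sum()) if drop_ambiguous else 0
    n_mismatch = int((~(same | swapped)).sum())
    if n_amb:
        warnings.warn(f"dropped {n_amb} strand-ambiguous SNP(s)")
    if n_mismatch:
        warnings.warn(f"dropped {n_mismatch} SNP(s) with irreconcilable alleles")
    a = a.loc[keep].reset_index(drop=True)
    b = b.loc[keep].reset_index(drop=True)
    flip = swapped[keep]
    for col in ("z", "beta"):
        if col in b.columns:
            b.loc[flip, col] = -b.loc[flip, col]
    b.loc[flip, ["a1", "a2"]] = b.loc[flip, ["a2", "a1"]].to_numpy()
    return a, b
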