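"""In-memory containers shared across the pipeline.

Coordinate convention: 1-based inclusive everywhere (as in VCF/GFF).
BED files are converted at the I/O boundary (see :mod:`mirqtl.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantPanel",
    "ExpressionMatrix",
    "MirnaAnnotation",
    "SimTruth",
    "CausalEffect",
    "MediationLink",
    "ClumpResult",
    "ColocResult",
    "SmrResult",
    "TwasModel",
]


@dataclass
class VariantPanel:
    """SNP metadata plus a samples x SNPs dosage matrix.

    ``dosage`` entries are in [0, 2] (additive alt-allele dose); NaN marks a
    missing genotype prior to QC. ``maf`` is always recomputed from the
    dosages, so it cannot drift from the matrix.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray  # (n_samples, n_snps)
    sample_id: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if self.dosage.shape != (len(self.sample_id), len(self.snp_id)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_id)} samples x {len(self.snp_id)} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency per SNP, ignoring missing entries."""
        return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.alt_freq
        return np.minimum(p, 1.0 - p)

    @property
    def missingness(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosage), axis=0)

    def index_of(self, snp: str) -> int:
        idx = np.flatnonzero(self.snp_id == snp)
        if idx.size == 0:
            raise KeyError(f"SNP {snp!r} not in panel")
        return int(idx[0])

    def subset_snps(self, mask_or_idx) -> "VariantPanel":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return VariantPanel(
            snp_id=self.snp_id[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            dosage=self.dosage[:, idx],
            sample_id=self.sample_id,
            n_skipped=self.n_skipped,
        )

    def subset_samples(self, sample_ids) -> "VariantPanel":
        order = {s: i for i, s in enumerate(self.sample_id)}
        idx = np.array([order[s] for s in sample_ids], dtype=int)
        return VariantPanel(
            snp_id=self.snp_id,
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[idx],
            sample_id=np.asarray(list(sample_ids), dtype=object),
            n_skipped=self.n_skipped,
        )


VALID_TAGS = ("counts", "rpm", "log2")


@dataclass
class ExpressionMatrix:
    """Samples x features expression values with a value tag.

    ``tag`` is one of ``counts`` (raw non-negative integers), ``rpm``
    (reads per million) or ``log2`` (normalized log2 counts per million).
    ``feature_meta`` optionally carries per-feature annotation (e.g. the
    mature/precursor mapping used by dedup).
    """

    sample_id: np.ndarray
    feature_id: np.ndarray
    values: np.ndarray  # (n_samples, n_features)
    tag: str
    library_size: np.ndarray | None = None
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.feature_id = np.asarray(self.feature_id, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.tag not in VALID_TAGS:
            raise ValueError(f"unknown value tag {self.tag!r}")
        if self.values.shape != (len(self.sample_id), len(self.feature_id)):
            raise ValueError("values shape does not match sample/feature ids")
        if self.tag == "counts" and np.nanmin(self.values, initial=0) < 0:
            raise ValueError("raw counts must be non-negative")
        if self.library_size is None and self.tag == "counts":
            self.library_size = self.values.sum(axis=1)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_id, columns=self.feature_id)

    def subset_features(self, keep_idx) -> "ExpressionMatrix":
        keep_idx = np.asarray(keep_idx, dtype=int)
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.iloc[keep_idx].reset_index(drop=True)
        return ExpressionMatrix(
            sample_id=self.sample_id,
            feature_id=self.feature_id[keep_idx],
            values=self.values[:, keep_idx],
            tag=self.tag,
            library_size=self.library_size,
            feature_meta=meta,
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        order = {s: i for i, s in enumerate(self.sample_id)}
        idx = np.array([order[s] for s in sample_ids], dtype=int)
        lib = None if self.library_size is None else self.library_size[idx]
        return ExpressionMatrix(
            sample_id=np.asarray(list(sample_ids), dtype=object),
            feature_id=self.feature_id,
            values=self.values[idx],
            tag=self.tag,
            library_size=lib,
            feature_meta=self.feature_meta,
        )


@dataclass
class MirnaAnnotation:
    """Mature-miRNA -> precursor coordinate table.

    One row per (mature, precursor) pair; a mature id may map to several
    precursors (roughly 9% of brain-expressed miRNAs do). Coordinates are
    1-based inclusive, strand '+'/'-'.
    """

    table: pd.DataFrame  # columns: mature_id, precursor_id, chrom, start, end, strand, arm, cluster

    REQUIRED = ("mature_id", "precursor_id", "chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation missing columns: {missing}")
        t = self.table
        if (t["start"] > t["end"]).any():
            bad = t.loc[t["start"] > t["end"], "precursor_id"].tolist()
            raise ValueError(f"coordinate inversion (start > end) for {bad}")
        if not t["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        if t.duplicated(["mature_id", "precursor_id"]).any():
            raise ValueError("duplicate (mature_id, precursor_id) rows")

    def precursors_of(self, mature_id: str) -> pd.DataFrame:
        return self.table[self.table["mature_id"] == mature_id]

    @property
    def mature_ids(self) -> np.ndarray:
        return self.table["mature_id"].unique()


@dataclass
class CausalEffect:
    feature_id: str
    snp_id: str
    beta: float  # per-dosage-unit effect on log2 expression
    var_frac: float  # fraction of (residual) expression variance explained


@dataclass
class MediationLink:
    trait_id: str
    feature_id: str
    beta_med: float  # trait effect per unit log2 expression


@dataclass
class SimTruth:
    """Planted ground truth for a simulated dataset."""

    causal_map: list = field(default_factory=list)  # CausalEffect
    mediation_map: list = field(default_factory=list)  # MediationLink
    scenario: dict = field(default_factory=dict)  # locus/feature -> scenario label
    seed: int = 0
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for ce in self.causal_map:
            if not (0.0 <= ce.var_frac < 1.0):
                raise ValueError(f"variance fraction {ce.var_frac} outside [0, 1)")
        if not self.features:
            self.features = sorted({ce.feature_id for ce in self.causal_map})

    def validate_against(self, panel: VariantPanel) -> None:
        snps = set(panel.snp_id.tolist())
        for ce in self.causal_map:
            if ce.snp_id not in snps:
                raise ValueError(f"causal SNP {ce.snp_id} absent from panel")

    def causal_for(self, feature_id: str) -> list:
        return [ce for ce in self.causal_map if ce.feature_id == feature_id]


@dataclass
class ClumpResult:
    index_snp: str
    index_p: float
    members: list  # member snp ids (excluding the index)
    member_r2: list
    member_dist_bp: list


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    p1: float
    p2: float
    p12: float

    def as_dict(self) -> dict:
        return {
            "pp0": self.pp0, "pp1": self.pp1, "pp2": self.pp2,
            "pp3": self.pp3, "pp4": self.pp4, "n_snps": self.n_snps,
            "p1": self.p1, "p2": self.p2, "p12": self.p12,
        }


@dataclass
class SmrResult:
    exposure_id: str
    outcome_id: str
    top_snp: str
    b_xy: float
    se_xy: float
    t_smr: float
    p_smr: float
    p_heidi: float  # NaN when not computable
    n_snps_heidi: int
    heidi_reason: str = ""
    mediation: bool | None = None


@dataclass
class TwasModel:
    feature_id: str
    h2_cis: float
    h2_p: float
    model: str  # 'top1' | 'lasso' | 'enet' | 'none'
    snp_id: np.ndarray
    a1: np.ndarray  # effect allele of each weight (alt allele of panel)
    a2: np.ndarray
    weights: np.ndarray  # on the standardized-dosage scale
    cv_r2: dict = field(default_factory=dict)
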