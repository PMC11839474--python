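"""Synthetic genotype / miRNA-count / GWAS data with planted ground truth.

The generator mirrors the statistical structure the downstream stages assume:
LD-structured diploid dosages with a realistic MAF spectrum, negative-binomial
small-RNA counts whose log2-scale means carry planted cis-SNP effects plus
batch and hidden-factor structure, and GWAS z-scores drawn from the
multivariate normal implied by the LD matrix under mediated, pleiotropic,
linkage or null scenarios.

All randomness flows through one ``numpy.random.Generator`` passed or seeded
explicitly; a fixed seed fixes every output bit-for-bit.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .containers import (
    CausalEffect,
    ExpressionMatrix,
    MediationLink,
    SimTruth,
    VariantPanel,
)

__all__ = [
    "simulate_genotypes",
    "simulate_mirna_counts",
    "simulate_covariates",
    "simulate_gwas_summary",
    "simulate_annotations",
]

# non-strand-ambiguous ref/alt pairs only, so harmonization never drops
# simulated SNPs
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]

LN2 = math.log(2.0)


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    block_size: int = 10,
    within_block_r: float = 0.0,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
    chrom: str = "1",
    start_pos: int = 1_000_000,
    spacing: int = 3_000,
) -> VariantPanel:
    """Draw an LD-blocked diploid dosage panel.

    Haplotypes within an LD block share a latent uniform: each haplotype
    copies the block uniform with probability ``sqrt(within_block_r)`` and
    draws a fresh uniform otherwise; the allele is the uniform thresholded at
    the SNP's frequency. Two SNPs in a block then have haplotypic Pearson
    correlation ~ ``within_block_r`` (exactly r when their frequencies
    coincide). Dosage is the sum of two independent haplotypes, which
    preserves the correlation. SNPs in different blocks are independent.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not (0.0 <= within_block_r < 1.0):
        raise ValueError("within_block_r must be in [0, 1)")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be contained in (0, 0.5]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    block_size = min(max(int(block_size), 1), n_snps)
    if within_block_r == 0.0:
        block_size = n_snps  # blocks are irrelevant without LD; one pass

    n_hap = 2 * n_samples
    rho = math.sqrt(within_block_r)
    freqs = np.empty(n_snps)
    haplos = np.empty((n_hap, n_snps), dtype=np.int8)

    for b_start in range(0, n_snps, block_size):
        b_end = min(b_start + block_size, n_snps)
        width = b_end - b_start
        if within_block_r > 0:
            f_block = rng.uniform(lo, hi)
            f = np.clip(f_block + rng.uniform(-0.02, 0.02, size=width), lo, hi)
            u_shared = rng.uniform(size=(n_hap, 1))
            copy = rng.uniform(size=(n_hap, width)) < rho
            u = np.where(copy, u_shared, rng.uniform(size=(n_hap, width)))
        else:
            f = rng.uniform(lo, hi, size=width)
            u = rng.uniform(size=(n_hap, width))
        freqs[b_start:b_end] = f
        haplos[:, b_start:b_end] = u < f

    dosage = (haplos[0::2] + haplos[1::2]).astype(float)
    pos = start_pos + spacing * np.arange(n_snps, dtype=np.int64)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_snps)
    ref = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    alt = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)
    snp_id = np.array([f"rs{100000 + i}" for i in range(n_snps)], dtype=object)
    return VariantPanel(
        snp_id=snp_id,
        chrom=np.array([chrom] * n_snps, dtype=object),
        pos=pos,
        ref=ref,
        alt=alt,
        dosage=dosage,
        sample_id=np.array([f"S{i:04d}" for i in range(n_samples)], dtype=object),
    )


def _count_noise_log2_var(mu: float, dispersion: float) -> float:
    """Approximate log2-scale variance added by NB counting noise.

    Delta method on log2(count): Var ~ (1/mu + dispersion) / ln(2)^2.
    """
    return (1.0 / max(mu, 1e-8) + dispersion) / LN2**2


def simulate_mirna_counts(
    panel: VariantPanel,
    truth: SimTruth,
    n_batches: int = 4,
    libsize_range: tuple[float, float] = (3e6, 6e6),
    dispersion: float = 0.05,
    seed: int | np.random.Generator = 0,
    n_hidden: int = 3,
    sigma_log2: float = 0.5,
    batch_sd: float = 0.3,
    factor_sd: float = 0.3,
    baseline_range: tuple[float, float] = (5.0, 9.0),
) -> tuple[ExpressionMatrix, SimTruth, pd.DataFrame]:
    """Negative-binomial miRNA counts with planted cis effects.

    The log2-CPM mean per (sample, feature) is baseline + sum(beta * dosage)
    + batch offset + k hidden-factor loadings + N(0, sigma^2); counts are
    drawn NB with Var = mu + mu^2 * dispersion at the sample's library size.

    Where a :class:`CausalEffect` specifies a nonzero ``var_frac``, ``beta``
    is rescaled so that Var(beta * dosage) is that fraction of the variance
    the QTL scan sees after covariates and SVs absorb batch/factor structure
    (log-scale noise plus the expected counting noise); the realized beta is
    written back into the returned truth. Batch assignments and nuisance
    covariates are returned as a covariate table.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    truth.validate_against(panel)
    features = list(truth.features)
    n, m = panel.n_samples, len(features)
    if m == 0:
        raise ValueError("truth declares no features")
    per_feature = {}
    for ce in truth.causal_map:
        per_feature.setdefault(ce.feature_id, []).append(ce)
    for fid, ces in per_feature.items():
        if sum(ce.var_frac for ce in ces) >= 1.0:
            raise ValueError(f"variance fractions for {fid} sum to >= 1")

    lib = rng.uniform(*libsize_range, size=n)
    batch = rng.integers(0, n_batches, size=n)
    batch_eff = rng.normal(0.0, batch_sd, size=(n_batches, m))
    scores = rng.normal(size=(n, n_hidden))
    loadings = rng.normal(0.0, factor_sd, size=(n_hidden, m))
    baseline = rng.uniform(*baseline_range, size=m)
    noise = rng.normal(0.0, sigma_log2, size=(n, m))

    log2cpm = baseline[None, :] + batch_eff[batch] + scores @ loadings + noise

    feat_idx = {f: j for j, f in enumerate(features)}
    new_causal = []
    for ce in truth.causal_map:
        j = feat_idx[ce.feature_id]
        g = panel.dosage[:, panel.index_of(ce.snp_id)]
        vg = g.var()
        if vg <= 0:
            warnings.warn(f"monomorphic causal SNP {ce.snp_id}; effect dropped")
            new_causal.append(CausalEffect(ce.feature_id, ce.snp_id, 0.0, 0.0))
            continue
        if ce.var_frac > 0:
            mu_bar = lib.mean() * 2.0 ** baseline[j] / 1e6
            v_nongen = sigma_log2**2 + _count_noise_log2_var(mu_bar, dispersion)
            beta = math.copysign(
                math.sqrt(ce.var_frac / (1.0 - ce.var_frac) * v_nongen / vg),
                ce.beta if ce.beta != 0 else 1.0,
            )
        else:
            beta = ce.beta
        log2cpm[:, j] += beta * g
        new_causal.append(CausalEffect(ce.feature_id, ce.snp_id, beta, ce.var_frac))

    mu = lib[:, None] * 2.0**log2cpm / 1e6
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts = rng.poisson(lam).astype(float)
    else:
        counts = rng.poisson(mu).astype(float)

    covars = simulate_covariates(panel.sample_id, batch, rng)
    # library size = the sample's total mapped reads, of which the simulated
    # features are only a part; do not let it default to the feature row sum
    em = ExpressionMatrix(
        sample_id=panel.sample_id,
        feature_id=np.array(features, dtype=object),
        values=counts,
        tag="counts",
        library_size=lib,
    )
    out_truth = SimTruth(
        causal_map=new_causal,
        mediation_map=list(truth.mediation_map),
        scenario=dict(truth.scenario),
        seed=truth.seed,
        features=features,
    )
    return em, out_truth, covars


def simulate_covariates(
    sample_id: np.ndarray, batch: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Nuisance covariates in the shape of a postmortem brain study."""
    n = len(sample_id)
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "batch": [f"b{b}" for b in batch],
            "pmi_hours": np.clip(rng.normal(7.0, 3.0, size=n), 1.0, None),
            "rin": np.clip(rng.normal(5.5, 1.0, size=n), 2.1, 10.0),
            "age_death": np.clip(rng.normal(89.0, 6.0, size=n), 66.0, 108.0),
            "sex": rng.choice(["F", "M"], size=n, p=[0.63, 0.37]),
            "diagnosis": rng.choice(["normal", "impaired"], size=n),
            "study": rng.choice(["ROS", "MAP"], size=n),
            "platform": rng.choice(["wgs", "chip"], size=n, p=[0.7, 0.3]),
        }
    ).set_index("sample_id")


def simulate_gwas_summary(
    panel: VariantPanel,
    truth: SimTruth,
    scenario: str,
    n_gwas: int,
    seed: int | np.random.Generator = 0,
    trait_id: str = "trait",
    feature_id: str | None = None,
    pleiotropy_effect: float = 0.1,
    linkage_r2: tuple[float, float] = (0.3, 0.9),
    linkage_effect: float = 0.1,
    ld_ridge: float = 1e-6,
) -> pd.DataFrame:
    """GWAS z-scores from the MVN implied by panel LD and the scenario.

    z ~ N(R @ lambda, R) where lambda carries the non-centrality at the causal
    SNP(s): lambda_c = b * sqrt(n_gwas * 2 f (1-f)) for a per-allele effect b
    in phenotype-SD units (phenotype variance 1).

    * ``mediated``: the trait's causal SNP is the miRNA's causal SNP with
      b = beta_qtl * beta_mediation taken from the truth tables.
    * ``pleiotropy``: same SNP, independent effect size.
    * ``linkage``: a distinct SNP whose r2 with the exposure SNP lies in
      ``linkage_r2``.
    * ``null``: lambda = 0.
    """
    if scenario not in ("mediated", "pleiotropy", "linkage", "null"):
        raise ValueError(f"unknown scenario {scenario!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    G = panel.dosage
    sd = G.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("panel contains monomorphic SNPs; filter before simulating GWAS")
    R = np.corrcoef(G, rowvar=False)
    R = (R + R.T) / 2 + ld_ridge * np.eye(panel.n_snps)

    lam = np.zeros(panel.n_snps)
    if scenario != "null":
        causal = truth.causal_map
        if feature_id is not None:
            causal = [ce for ce in causal if ce.feature_id == feature_id]
        if not causal:
            raise ValueError("scenario requires a causal SNP in the truth table")
        ce = causal[0]
        c_idx = panel.index_of(ce.snp_id)
        f = panel.alt_freq[c_idx]
        if scenario == "mediated":
            med = [ml for ml in truth.mediation_map if ml.feature_id == ce.feature_id]
            if not med:
                raise ValueError("mediated scenario requires a mediation link in the truth")
            b = ce.beta * med[0].beta_med
            t_idx = c_idx
        elif scenario == "pleiotropy":
            b, t_idx = pleiotropy_effect, c_idx
        else:  # linkage
            r2_with_causal = R[c_idx] ** 2
            eligible = np.flatnonzero(
                (r2_with_causal >= linkage_r2[0])
                & (r2_with_causal <= linkage_r2[1])
                & (np.arange(panel.n_snps) != c_idx)
            )
            if eligible.size == 0:
                raise ValueError(
                    f"no SNP with r2 in {linkage_r2} of exposure SNP {ce.snp_id}"
                )
            t_idx = int(rng.choice(eligible))
            b = linkage_effect
        lam[t_idx] = b * math.sqrt(n_gwas * 2.0 * f * (1.0 - f))

    L = np.linalg.cholesky(R)
    z = R @ lam + L @ rng.standard_normal(panel.n_snps)
    f_all = panel.alt_freq
    se = 1.0 / np.sqrt(2.0 * f_all * (1.0 - f_all) * n_gwas)
    from scipy import stats

    return pd.DataFrame(
        {
            "snp": panel.snp_id,
            "chrom": panel.chrom,
            "pos": panel.pos,
            "a1": panel.alt,  # effect allele
            "a2": panel.ref,
            "beta": z * se,
            "se": se,
            "z": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
            "n": n_gwas,
        }
    )


def simulate_annotations(
    panel: VariantPanel,
    qtl_snps: set,
    target_or: float,
    strata: list[tuple[float, float]] | None = None,
    seed: int | np.random.Generator = 0,
    base_rates: list[float] | None = None,
) -> pd.DataFrame:
    """Interval set with a stratum-constant odds ratio of covering QTL SNPs.

    Within each MAF stratum, non-QTL SNPs are interval members with the
    stratum's base rate and QTL SNPs with the rate implied by ``target_or``.
    Returns merged 1-based inclusive intervals covering the member SNPs
    (single-base intervals, so non-members are never swept in).
    """
    if target_or <= 0:
        raise ValueError("target_or must be > 0")
    if not qtl_snps:
        raise ValueError("qtl_snps must be non-empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if strata is None:
        strata = [(0.0, 0.1), (0.1, 0.2), (0.2, 0.5)]
    if base_rates is None:
        base_rates = [0.25, 0.30, 0.35][: len(strata)]

    maf = panel.maf
    is_qtl = np.isin(panel.snp_id, list(qtl_snps))
    member = np.zeros(panel.n_snps, dtype=bool)
    for (lo_s, hi_s), p0 in zip(strata, base_rates):
        in_s = (maf >= lo_s) & (maf < hi_s) if hi_s < 0.5 else (maf >= lo_s) & (maf <= 0.5)
        odds1 = target_or * p0 / (1.0 - p0)
        p1 = odds1 / (1.0 + odds1)
        u = rng.uniform(size=panel.n_snps)
        member |= in_s & np.where(is_qtl, u < p1, u < p0)

    rows = [
        {"chrom": c, "start": int(p), "end": int(p)}
        for c, p in zip(panel.chrom[member], panel.pos[member])
    ]
    return (
        pd.DataFrame(rows, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
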