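"""End-to-end orchestration: one synthetic study from genotypes and counts
through QC, cis scan, heritability gate, weights, miRWAS, coloc and
SMR/HEIDI to the four-criteria causal screen.

These drivers are what the replicate-level tests and the acceptance script
run; they exercise every stage on data whose ground truth is known.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cis_qtl, coloc, expression_qc, mirwas, simulate, smr
from .containers import CausalEffect, MediationLink, MirnaAnnotation, SimTruth

__all__ = [
    "simulate_study",
    "scan_study",
    "mixed_scan_study",
    "causal_screen_replicate",
]


def simulate_study(
    seed: int,
    n_samples: int = 604,
    n_snps: int = 60,
    block_size: int = 6,
    within_block_r: float = 0.8,
    n_features: int = 1,
    n_null_features: int = 19,
    var_frac: float = 0.15,
    causal_block: int = 0,
    dispersion: float = 0.01,
    sigma_log2: float = 0.5,
):
    """One cis locus: LD panel + miRNA counts with planted causal SNPs.

    The first ``n_features`` miRNAs carry the causal SNP (mid-block, so
    HEIDI always has in-block LD partners); ``n_null_features`` additional
    miRNAs are pure noise, giving normalization and surrogate-variable
    estimation a realistic multi-feature matrix. Returns
    (panel, counts, truth, covars).
    """
    rng = np.random.default_rng(seed)
    panel = simulate.simulate_genotypes(
        n_samples, n_snps, block_size=block_size, within_block_r=within_block_r,
        maf_range=(0.1, 0.5), seed=rng,
    )
    causal_idx = causal_block * block_size + block_size // 2
    causal = [
        CausalEffect(f"miR-{k}", str(panel.snp_id[causal_idx]), 1.0, var_frac)
        for k in range(n_features)
    ]
    truth = SimTruth(
        causal_map=causal,
        mediation_map=[MediationLink("trait", f"miR-{k}", -0.25) for k in range(n_features)],
        scenario={},
        seed=seed,
        features=[f"miR-{k}" for k in range(n_features + n_null_features)],
    )
    counts, truth, covars = simulate.simulate_mirna_counts(
        panel, truth, dispersion=dispersion, sigma_log2=sigma_log2, seed=rng
    )
    return panel, counts, truth, covars


def _annotation_for_panel(panel, features, pad_center: int | None = None) -> MirnaAnnotation:
    """Place each feature's precursor at the panel's center so the 500-kb cis
    window covers the whole simulated locus."""
    center = int(np.median(panel.pos)) if pad_center is None else pad_center
    rows = [
        {
            "mature_id": f, "precursor_id": f"{f}-prec", "chrom": str(panel.chrom[0]),
            "start": center, "end": center + 80, "strand": "+", "arm": "5p", "cluster": "",
        }
        for f in features
    ]
    return MirnaAnnotation(table=pd.DataFrame(rows))


def scan_study(panel, counts, covars, n_sv: int = 5):
    """Normalize, estimate SVs and run the covariate-adjusted cis scan."""
    log2 = expression_qc.normalize_log2(counts)
    X_known = expression_qc.build_design(covars)
    sv = expression_qc.estimate_surrogate_variables(log2.values, X_known, n_sv=n_sv)
    X = np.column_stack([X_known, sv])
    ann = _annotation_for_panel(panel, list(log2.feature_id))
    windows = cis_qtl.build_cis_windows(ann)
    res = cis_qtl.scan_cis(panel, log2, X, windows)
    return res, log2, X


def mixed_scan_study(
    seed: int,
    n_true: int = 200,
    n_null: int = 200,
    n_samples: int = 604,
    block_size: int = 10,
    within_block_r: float = 0.8,
    var_frac: float = 0.04,
    n_sv: int = 15,
    q_thresh: float = 0.01,
) -> dict:
    """Mixed null/alternative study: power, empirical FDR and recovered
    variance fractions at the q-value threshold.

    Each feature owns one LD block of ``block_size`` SNPs as its cis window;
    the first ``n_true`` features carry a causal SNP (mid-block) explaining
    ``var_frac`` of residual expression variance, the rest are null. False
    positives are significant pairs in null features' windows (every SNP in
    a causal feature's block tags the planted signal through LD).
    """
    rng = np.random.default_rng(seed)
    n_feat = n_true + n_null
    n_snps = n_feat * block_size
    panel = simulate.simulate_genotypes(
        n_samples, n_snps, block_size=block_size, within_block_r=within_block_r,
        maf_range=(0.1, 0.5), seed=rng,
    )
    features = [f"m{k:04d}" for k in range(n_feat)]
    causal = [
        CausalEffect(
            features[k],
            str(panel.snp_id[k * block_size + block_size // 2]),
            1.0,
            var_frac,
        )
        for k in range(n_true)
    ]
    truth = SimTruth(causal_map=causal, features=features, seed=seed)
    counts, truth, covars = simulate.simulate_mirna_counts(
        panel, truth, dispersion=0.01, seed=rng
    )
    log2 = expression_qc.normalize_log2(counts)
    X_known = expression_qc.build_design(covars)
    sv = expression_qc.estimate_surrogate_variables(log2.values, X_known, n_sv=n_sv)
    X = np.column_stack([X_known, sv])

    windows = [
        cis_qtl.CisWindow(
            features[k],
            [(
                str(panel.chrom[0]),
                int(panel.pos[k * block_size]),
                int(panel.pos[min((k + 1) * block_size, n_snps) - 1]),
            )],
        )
        for k in range(n_feat)
    ]
    res = cis_qtl.scan_cis(panel, log2, X, windows)
    res["q"], pi0 = cis_qtl.storey_qvalues(res["p"].to_numpy())

    causal_by_feature = {ce.feature_id: ce for ce in truth.causal_map}
    sig = res[res["q"] < q_thresh]
    n_false = int((~sig["mirna"].isin(causal_by_feature)).sum())
    fdr_hat = n_false / max(len(sig), 1)
    truth_pairs = res.set_index(["mirna", "snp"])
    detected = 0
    vfs = []
    resid = expression_qc.residualize(log2.values, X)
    feat_col = {f: j for j, f in enumerate(log2.feature_id)}
    for ce in truth.causal_map:
        row = truth_pairs.loc[(ce.feature_id, ce.snp_id)]
        detected += row["q"] < q_thresh
        g = panel.dosage[:, panel.index_of(ce.snp_id)]
        vfs.append(
            cis_qtl.variance_explained(resid[:, feat_col[ce.feature_id]], g)
        )
    return {
        "power": detected / n_true,
        "empirical_fdr": fdr_hat,
        "n_significant": int(len(sig)),
        "pi0": pi0,
        "variance_fractions": np.asarray(vfs),
        "median_vf": float(np.median(vfs)),
    }


def causal_screen_replicate(
    seed: int,
    scenario: str,
    n_gwas: int = 50_000,
    n_samples: int = 604,
    var_frac: float = 0.15,
    h2_gate_p: float = 0.01,
) -> dict:
    """Run one miRNA x trait through the full four-criteria screen.

    ``scenario`` is 'mediated', 'linkage' or 'null' and controls how the
    GWAS summary statistics are generated against the planted miR-QTL.
    Returns the merged screen row as a dict (plus ground-truth labels).
    """
    rng = np.random.default_rng(seed)
    panel, counts, truth, covars = simulate_study(
        int(rng.integers(2**31 - 1)), n_samples=n_samples, var_frac=var_frac,
        n_null_features=99,
    )
    scan, log2, X = scan_study(panel, counts, covars)
    scan = scan[scan["mirna"] == "miR-0"].reset_index(drop=True)

    # expression residual for the heritability gate / weights
    y_resid = expression_qc.residualize(log2.values[:, 0], X)
    h2, h2_p = mirwas.estimate_cis_h2(panel.dosage, y_resid)
    out = {
        "scenario": scenario,
        "h2": h2,
        "h2_p": h2_p,
        "gated_out": h2_p >= h2_gate_p,
    }
    if out["gated_out"]:
        out.update(causal=False, reason="h2_gate")
        return out

    model = mirwas.fit_weight_models(
        panel, y_resid, seed=int(rng.integers(2**31 - 1)), h2=h2, h2_p=h2_p,
        feature_id="miR-0",
    )
    gwas = simulate.simulate_gwas_summary(
        panel, truth,
        scenario=scenario if scenario != "null" else "null",
        n_gwas=n_gwas, seed=rng, linkage_r2=(0.3, 0.9),
    )
    if model.model == "none":
        out.update(causal=False, reason="no_model")
        return out

    # align scan and GWAS rows to model SNPs (same panel, same alleles)
    scan_idx = scan.set_index("snp").loc[model.snp_id]
    gwas_idx = gwas.set_index("snp").loc[model.snp_id]
    R = np.corrcoef(panel.dosage, rowvar=False)
    z, p = mirwas.twas_associate(model, gwas_idx["z"].to_numpy(), R)
    cres = coloc.coloc_abf(
        scan_idx["beta"].to_numpy(), scan_idx["se"].to_numpy(),
        gwas_idx["beta"].to_numpy(), gwas_idx["se"].to_numpy(),
    )
    sres = smr.smr_two_molecular(
        {"snp": model.snp_id, "b": scan_idx["beta"].to_numpy(),
         "se": scan_idx["se"].to_numpy()},
        {"snp": model.snp_id, "b": gwas_idx["beta"].to_numpy(),
         "se": gwas_idx["se"].to_numpy()},
        R,
        exposure_id="miR-0", outcome_id="trait",
        instrument_p_max=1e-4,
    )
    screen = mirwas.causal_screen(
        pd.DataFrame([{"mirna": "miR-0", "trait": "trait", "z": z, "p": p, "fdr": p}]),
        pd.DataFrame([{"mirna": "miR-0", "trait": "trait", "pp4": cres.pp4}]),
        pd.DataFrame([
            {"mirna": "miR-0", "trait": "trait",
             "smr_p": sres.p_smr, "heidi_p": sres.p_heidi}
        ]),
    )
    row = screen.iloc[0]
    out.update(
        causal=bool(row["causal"]), reason=row["reason"], twas_z=z, twas_p=p,
        pp4=cres.pp4, pp3=cres.pp3, smr_p=sres.p_smr, heidi_p=sres.p_heidi,
        model=model.model,
    )
    return out
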