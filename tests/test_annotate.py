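"""Intragenic/intergenic classification, miRNA clusters, host-gene
correlation and the predicted-target protein association workflow."""

import numpy as np
import pandas as pd
import pytest

from mirqtl import annotate, simulate
from mirqtl.containers import MirnaAnnotation


def _genes(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "biotype", "chrom", "start", "end", "strand"]
    )


def _ann(rows):
    return MirnaAnnotation(
        table=pd.DataFrame(
            rows,
            columns=["mature_id", "precursor_id", "chrom", "start", "end", "strand"],
        )
    )


class TestIntragenic:
    def test_same_strand_overlap_is_intragenic(self):
        ann = _ann([("m", "p", "1", 5000, 5100, "+")])
        genes = _genes([("HOST", "protein_coding", "1", 1000, 9000, "+")])
        out = annotate.classify_intragenic(ann, genes)
        assert out.loc[0, "classification"] == "intragenic"
        assert out.loc[0, "host_gene"] == "HOST"

    def test_opposite_strand_overlap_is_intergenic(self):
        ann = _ann([("m", "p", "1", 5000, 5100, "+")])
        genes = _genes([("G", "protein_coding", "1", 1000, 9000, "-")])
        out = annotate.classify_intragenic(ann, genes)
        assert out.loc[0, "classification"] == "intergenic"

    def test_mirna_gene_overlap_does_not_count(self):
        ann = _ann([("m", "p", "1", 5000, 5100, "+")])
        genes = _genes([("MIRGENE", "miRNA", "1", 4000, 6000, "+")])
        out = annotate.classify_intragenic(ann, genes)
        assert out.loc[0, "classification"] == "intergenic"

    def test_primary_host_is_longest_overlap(self):
        ann = _ann([("m", "p", "1", 5000, 5100, "+")])
        genes = _genes([
            ("SHORT", "protein_coding", "1", 5090, 9000, "+"),
            ("LONG", "protein_coding", "1", 1000, 9000, "+"),
        ])
        out = annotate.classify_intragenic(ann, genes)
        assert out.loc[0, "host_gene"] == "LONG"
        assert set(out.loc[0, "all_hosts"].split(",")) == {"SHORT", "LONG"}


class TestClusters:
    def _prec(self, rows):
        return pd.DataFrame(rows, columns=["precursor_id", "chrom", "start", "end"])

    def test_close_precursors_share_cluster(self):
        df = self._prec([("a", "1", 1000, 1100), ("b", "1", 6000, 6100)])
        labels = annotate.assign_clusters(df, gap_max=10_000)
        assert labels.iloc[0] == labels.iloc[1]

    def test_distant_precursors_split(self):
        df = self._prec([("a", "1", 1000, 1100), ("b", "1", 16_200, 16_300)])
        labels = annotate.assign_clusters(df, gap_max=10_000)
        assert labels.iloc[0] != labels.iloc[1]

    def test_transitive_chain_is_one_cluster(self):
        df = self._prec([
            ("a", "1", 1000, 1100),
            ("b", "1", 6100, 6200),
            ("c", "1", 11_200, 11_300),
        ])
        labels = annotate.assign_clusters(df, gap_max=10_000)
        assert len(set(labels)) == 1

    def test_permutation_invariant(self):
        df = self._prec([
            ("a", "1", 1000, 1100),
            ("b", "1", 6100, 6200),
            ("c", "2", 500, 600),
        ])
        l1 = annotate.assign_clusters(df)
        l2 = annotate.assign_clusters(df.iloc[[2, 0, 1]].reset_index(drop=True))
        m1 = {r: l1[df.index[df["precursor_id"] == r][0]] for r in "abc"}
        grouping1 = m1["a"] == m1["b"], m1["a"] == m1["c"]
        df2 = df.iloc[[2, 0, 1]].reset_index(drop=True)
        m2 = {r: l2[df2.index[df2["precursor_id"] == r][0]] for r in "abc"}
        grouping2 = m2["a"] == m2["b"], m2["a"] == m2["c"]
        assert grouping1 == grouping2 == (True, False)


class TestHostCorrelation:
    def test_monotone_transform_gives_rho_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        mir = pd.DataFrame({"m1": x}, index=[f"s{i}" for i in range(50)])
        tr = pd.DataFrame({"g1": np.exp(x)}, index=mir.index)
        per_pair, _ = annotate.host_correlation(mir, tr, [("m1", "g1")],
                                                n_background=50)
        assert per_pair.loc[0, "rho"] == pytest.approx(1.0)

    def test_null_pairs_set_level_calibrated(self):
        nonsig = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            mir = pd.DataFrame(
                rng.normal(size=(60, 10)),
                index=[f"s{i}" for i in range(60)],
                columns=[f"m{j}" for j in range(10)],
            )
            tr = pd.DataFrame(
                rng.normal(size=(60, 10)),
                index=mir.index, columns=[f"g{j}" for j in range(10)],
            )
            pairs = [(f"m{j}", f"g{j}") for j in range(10)]
            _, set_p = annotate.host_correlation(mir, tr, pairs,
                                                 n_background=200, seed=rep)
            nonsig += set_p >= 0.05
        assert nonsig >= 18  # >= 90%

    def test_planted_positive_coupling_detected(self):
        sig = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            n, m = 100, 40
            base = rng.normal(size=(n, m))
            mir = pd.DataFrame(base, index=[f"s{i}" for i in range(n)],
                               columns=[f"m{j}" for j in range(m)])
            tr_vals = rng.normal(size=(n, m))
            for j in range(12):  # ~30% of pairs positively coupled
                tr_vals[:, j] = 0.8 * base[:, j] + 0.6 * tr_vals[:, j]
            tr = pd.DataFrame(tr_vals, index=mir.index,
                              columns=[f"g{j}" for j in range(m)])
            pairs = [(f"m{j}", f"g{j}") for j in range(m)]
            _, set_p = annotate.host_correlation(mir, tr, pairs,
                                                 n_background=200, seed=rep)
            sig += set_p < 0.05
        assert sig >= 16  # >= 80%


class TestTargetTable:
    def test_source_specific_filters(self):
        t = pd.DataFrame({
            "mirna": ["m"] * 4,
            "gene": ["g1", "g2", "g3", "g4"],
            "source": ["targetscan", "targetscan", "rna22", "rna22"],
            "score": [-0.5, -0.1, 0.01, 0.2],
        })
        out = annotate.filter_target_table(t)
        assert sorted(out["gene"]) == ["g1", "g3"]


class TestTargetPqtlShare:
    def _setup(self, seed=0, couple=True):
        rng = np.random.default_rng(seed)
        panel = simulate.simulate_genotypes(400, 10, within_block_r=0.0,
                                            maf_range=(0.2, 0.5), seed=seed)
        g = panel.dosage[:, 4]
        prot = pd.DataFrame(
            rng.normal(size=(400, 3)),
            index=panel.sample_id, columns=["P1", "P2", "P3"],
        )
        if couple:
            prot["P1"] = prot["P1"] + 0.4 * g
        qtls = pd.DataFrame([
            {"mirna": "m", "snp": str(panel.snp_id[4]), "chrom": "1",
             "pos": int(panel.pos[4]), "p": 1e-9}
        ])
        targets = pd.DataFrame({
            "mirna": ["m", "m"], "gene": ["P1", "P2"],
            "source": ["targetscan"] * 2, "score": [-0.5, -0.5],
        })
        return panel, prot, qtls, targets

    def test_planted_trans_effect_detected(self):
        panel, prot, qtls, targets = self._setup(couple=True)
        coords = pd.DataFrame([
            {"gene_id": "P1", "chrom": "2", "start": 1, "end": 1000},
            {"gene_id": "P2", "chrom": "1", "start": int(panel.pos[4]) + 100_000,
             "end": int(panel.pos[4]) + 101_000},
        ])
        out = annotate.target_pqtl_share(qtls, prot, panel, targets,
                                         protein_coords=coords)
        row = out[out["gene"] == "P1"].iloc[0]
        assert row["shared"]
        assert row["cis_trans"] == "trans"
        row2 = out[out["gene"] == "P2"].iloc[0]
        assert row2["cis_trans"] == "cis"

    def test_null_coupling_rarely_significant(self):
        panel, prot, qtls, targets = self._setup(seed=1, couple=False)
        out = annotate.target_pqtl_share(qtls, prot, panel, targets)
        assert out["shared"].sum() == 0

    def test_high_missingness_protein_excluded(self):
        panel, prot, qtls, targets = self._setup(couple=True)
        prot.loc[prot.index[:250], "P1"] = np.nan  # > 50% missing
        out = annotate.target_pqtl_share(qtls, prot, panel, targets)
        assert "P1" not in set(out.get("gene", pd.Series(dtype=object)))
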