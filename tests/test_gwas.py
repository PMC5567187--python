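"""Double-hit integration: GWAS filtering, overlap test, candidate table."""

import math

import numpy as np
import pandas as pd
import pytest
from oracles import hypergeom_upper_tail_exact

from doublehit import (
    GwasSimConfig,
    candidate_filter,
    double_hit_overlap,
    filter_gwas,
    probe_snp_colocalization,
    simulate_gwas,
    table1_fixture,
)


class TestFilterGwas:
    def test_all_above_threshold_gives_empty(self):
        snps = pd.DataFrame({"rsid": ["rs1"], "gwas_p": [0.5], "gene_symbol": ["A"]})
        kept, genes = filter_gwas(snps)
        assert kept.empty and genes == set()

    def test_boundary_p_excluded(self):
        snps = pd.DataFrame({"rsid": ["rs1", "rs2"], "gwas_p": [0.05, 0.049999],
                             "gene_symbol": ["A", "B"]})
        kept, genes = filter_gwas(snps)
        assert genes == {"B"}

    def test_counts_by_construction(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i % 25}" for i in range(40)] + [f"H{i}" for i in range(60)]
        p = np.concatenate([rng.uniform(0.0001, 0.049, 40), rng.uniform(0.06, 1.0, 60)])
        snps = pd.DataFrame({"rsid": [f"rs{i}" for i in range(100)],
                             "gwas_p": p, "gene_symbol": genes})
        kept, unique_genes = filter_gwas(snps)
        assert len(kept) == 40
        assert len(unique_genes) == 25

    def test_blacklisted_genes_dropped(self):
        snps = pd.DataFrame({"rsid": ["rs1", "rs2"], "gwas_p": [0.01, 0.01],
                             "gene_symbol": ["SPUR1", "GOOD"]})
        _, genes = filter_gwas(snps, blacklist={"spur1"})
        assert genes == {"GOOD"}


class TestDoubleHitOverlap:
    def test_disjoint_sets(self):
        res = double_hit_overlap({"A", "B"}, {"C", "D"}, M=100)
        assert res["x"] == 0 and res["p"] == 1.0

    def test_full_overlap_single_term(self):
        # M=20, K=N=x=10: p = 1/C(20,10)
        genes = {f"G{i}" for i in range(10)}
        res = double_hit_overlap(genes, genes, M=20)
        assert res["p"] == pytest.approx(1 / math.comb(20, 10), rel=1e-9)

    def test_matches_enumeration_oracle(self):
        gwas = {f"G{i}" for i in range(8)}
        dmp = {f"G{i}" for i in range(5, 12)}
        res = double_hit_overlap(gwas, dmp, M=30)
        assert res["p"] == pytest.approx(
            hypergeom_upper_tail_exact(30, 8, 7, res["x"]), abs=1e-12)

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            double_hit_overlap({"A", "B"}, {"C"}, M=2)

    def test_planted_double_hit_is_significant(self):
        universe = [f"G{i:04d}" for i in range(800)]
        risk = universe[:25]
        snps = simulate_gwas(GwasSimConfig(n_snps=1500, seed=0), universe, risk_genes=risk)
        _, gwas_genes = filter_gwas(snps)
        dmp_genes = set(g.upper() for g in universe[:60])  # risk genes all differentially methylated
        res = double_hit_overlap(gwas_genes, dmp_genes, M=len(universe))
        assert res["p"] < 0.01


class TestCandidateFilter:
    def test_published_table_worked_example(self):
        snps, dmp = table1_fixture()
        out = candidate_filter(snps, dmp)
        assert len(out) == 30
        assert out["gene_symbol"].nunique() == 26
        hyper = out.loc[out["direction"] == "hyper", "gene_symbol"].nunique()
        hypo = out.loc[out["direction"] == "hypo", "gene_symbol"].nunique()
        assert (hyper, hypo) == (8, 18)

    def test_distractors_each_violate_one_rule_and_are_excluded(self):
        snps, dmp = table1_fixture(include_distractors=True)
        out = candidate_filter(snps, dmp)
        assert len(out) == 30
        assert not out["gene_symbol"].str.startswith("DSTGENE").any()
        # every distractor fails for its labelled reason and only that one
        reasons = snps.loc[snps["distractor_reason"] != "", "distractor_reason"]
        assert reasons.nunique() == len(reasons)

    def test_dlg1_row_details(self):
        snps, dmp = table1_fixture()
        out = candidate_filter(snps, dmp)
        row = out.loc[(out["gene_symbol"] == "DLG1") & (out["rsid"] == "rs74674649")].iloc[0]
        assert row["gwas_p"] == pytest.approx(6.01e-4)
        assert row["cadd"] == pytest.approx(28.2)
        assert row["probe_id"] == "cg12594803"
        assert row["t_stat"] < 0
        assert row["min_p_for_gene"] == pytest.approx(6.01e-4)

    def test_min_p_for_gene_covers_unfiltered_snps(self):
        snps = pd.DataFrame({
            "rsid": ["rs1", "rs2"],
            "chromosome": ["1", "1"],
            "position": [100, 200],
            "gwas_p": [0.04, 0.001],
            "func_class": ["exonic", "intronic"],
            "consequence": ["nonsynonymous", "none"],
            "cadd": [20.0, np.nan],
            "gene_symbol": ["A", "A"],
        })
        dmp = pd.DataFrame({"gene": ["A"], "probe_id": ["cg1"], "p_bh": [0.01],
                            "t_stat": [2.0]})
        out = candidate_filter(snps, dmp)
        assert len(out) == 1  # intronic SNP filtered out of the candidates...
        assert out.iloc[0]["min_p_for_gene"] == pytest.approx(0.001)  # ...but counted here

    def test_rows_satisfy_every_predicate(self):
        snps, dmp = table1_fixture(include_distractors=True)
        out = candidate_filter(snps, dmp)
        sig_genes = set(dmp.loc[dmp["p_bh"] < 0.05, "gene"])
        assert (out["gwas_p"] < 0.05).all()
        assert out["location"].isin(["exonic", "splicing"]).all()
        assert out["consequence"].isin(["nonsynonymous", "stopgain"]).all()
        assert (out["cadd"] > 15).all()
        assert out["gene_symbol"].isin(sig_genes).all()
        # candidates are a subset of the nominal GWAS filter output
        kept, _ = filter_gwas(snps)
        assert set(out["rsid"]) <= set(kept["rsid"])

    def test_duplicated_genes_make_gene_count_smaller(self):
        snps, dmp = table1_fixture()
        out = candidate_filter(snps, dmp)
        dup = out["gene_symbol"].value_counts()
        assert set(dup[dup > 1].index) == {"DLG1", "GGA1", "IGHMBP2", "PRR5-ARHGAP8"}
        assert out["gene_symbol"].nunique() < len(out)


class TestColocalization:
    def test_snp_inside_cpg_site_reported(self):
        snps = pd.DataFrame({"rsid": ["rs1"], "chromosome": ["chr1"], "position": [1001],
                             "gwas_p": [0.01]})
        probes = pd.DataFrame({"chromosome": ["1"], "position": [1000]},
                              index=pd.Index(["cgX"], name="probe_id"))
        hits = probe_snp_colocalization(snps, probes)
        assert len(hits) == 1  # position 1001 is the G of the 2-bp CpG at 1000
        assert hits.iloc[0]["probe_id"] == "cgX"

    def test_fixture_has_zero_colocalizations(self):
        snps, dmp = table1_fixture()
        probes = dmp.set_index("probe_id")[["chromosome", "position"]]
        assert probe_snp_colocalization(snps, probes).empty

    def test_empty_inputs_and_window(self):
        assert probe_snp_colocalization(pd.DataFrame(), pd.DataFrame()).empty
        snps = pd.DataFrame({"rsid": ["rs1"], "chromosome": ["1"], "position": [990]})
        probes = pd.DataFrame({"chromosome": ["1"], "position": [1000]},
                              index=pd.Index(["cgX"], name="probe_id"))
        assert probe_snp_colocalization(snps, probes, window=0).empty
        assert len(probe_snp_colocalization(snps, probes, window=10)) == 1


class TestSimulateGwas:
    def test_deterministic_given_seed(self):
        universe = [f"G{i}" for i in range(50)]
        a = simulate_gwas(GwasSimConfig(seed=9), universe)
        b = simulate_gwas(GwasSimConfig(seed=9), universe)
        pd.testing.assert_frame_equal(a, b)

    def test_no_exonic_snps_means_no_candidates(self):
        universe = [f"G{i}" for i in range(50)]
        snps = simulate_gwas(GwasSimConfig(frac_exonic=0.0, seed=1), universe)
        dmp = pd.DataFrame({"gene": universe, "probe_id": [f"cg{i}" for i in range(50)],
                            "p_bh": [0.001] * 50, "t_stat": [1.0] * 50})
        out = candidate_filter(snps, dmp)
        assert out.empty

    def test_consequence_only_for_coding_classes(self):
        universe = [f"G{i}" for i in range(50)]
        snps = simulate_gwas(GwasSimConfig(seed=2), universe)
        coding = snps["func_class"].isin(["exonic", "splicing"])
        assert (snps.loc[~coding, "consequence"] == "none").all()
        assert snps.loc[~coding, "cadd"].isna().all()

    def test_null_config_overlap_calibrated(self):
        # no risk genes: double-hit overlap p behaves like a null test
        universe = [f"G{i:04d}" for i in range(400)]
        rng = np.random.default_rng(0)
        ps = []
        for seed in range(60):
            snps = simulate_gwas(GwasSimConfig(n_snps=400, n_risk_genes=0, seed=seed),
                                 universe)
            _, gwas_genes = filter_gwas(snps)
            dmp_genes = set(rng.choice(universe, 40, replace=False))
            if gwas_genes:
                ps.append(double_hit_overlap(gwas_genes, dmp_genes, M=400)["p"])
        ps = np.asarray(ps)
        # discrete but near-continuous: rejection rate at 0.05 within noise
        assert np.mean(ps < 0.05) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / len(ps))
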