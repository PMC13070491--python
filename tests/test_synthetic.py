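"""Generator contracts: construction, planted effects, determinism."""

import numpy as np
import pandas as pd
import pytest

from gliostate import synthetic as syn


class TestGenomeModel:
    def test_default_construction(self):
        model = syn.build_genome_model(22, 250, 13)
        assert model.n_genes == 22 * 250 + 13
        assert model.chromosomes[:3] == ["chr1", "chr2", "chr3"]
        assert model.genes.loc[model.genes["mito"], "chromosome"].eq("chrM").all()

    def test_positions_strictly_increasing_within_chromosome(self):
        model = syn.build_genome_model(5, 210, 3, cnv_chromosomes=None)
        for chrom in model.chromosomes:
            pos = model.genes["position"].to_numpy()[model.genes_on(chrom)]
            assert (np.diff(pos) > 0).all()

    def test_too_few_genes_for_cnv_window_rejected(self):
        with pytest.raises(ValueError, match="202"):
            syn.build_genome_model(22, 100, 13, cnv_chromosomes=("chr7",))

    def test_cnv_chromosome_absent_rejected(self):
        with pytest.raises(ValueError, match="chr7"):
            syn.build_genome_model(5, 250, 13, cnv_chromosomes=("chr7",))


class TestSimulateDataset:
    def test_zero_malignant_fraction_yields_no_malignant_truth(self, small_model):
        cfg = syn.SimConfig(
            n_samples=1, cells_per_sample=100, malignant_fraction=0.0, seed=3
        )
        with pytest.warns(UserWarning, match="ignored"):
            _, truth = syn.simulate_dataset(small_model, cfg)
        assert not truth["is_malignant"].any()

    def test_same_seed_bitwise_identical(self, small_model):
        cfg = syn.SimConfig(n_samples=1, cells_per_sample=120, seed=5)
        a1, t1 = syn.simulate_dataset(small_model, cfg)
        a2, t2 = syn.simulate_dataset(small_model, cfg)
        assert (a1.X != a2.X).nnz == 0
        pd.testing.assert_frame_equal(t1, t2)

    def test_planted_cnv_ratio_matches_group_mean_oracle(self, small_dataset, small_model):
        # double ratio (target chrom vs neutral chrom, malignant vs nonmalignant)
        # isolates the planted multiplicative shift from composition effects
        adata, truth, cfg = small_dataset
        X = adata.X.toarray().astype(float)
        cpm = X / X.sum(1, keepdims=True)
        mal = truth["is_malignant"].to_numpy()
        nonmal = (~mal) & (truth["cell_type"] != "doublet").to_numpy()
        ref = small_model.genes_on("chr9")  # carries no signature or CNV

        def double_ratio(chrom):
            idx = small_model.genes_on(chrom)
            num = cpm[mal][:, idx].mean() / cpm[mal][:, ref].mean()
            den = cpm[nonmal][:, idx].mean() / cpm[nonmal][:, ref].mean()
            return num / den

        assert double_ratio("chr7") == pytest.approx(2**0.4, rel=0.06)
        assert double_ratio("chr10") == pytest.approx(2**-0.5, rel=0.06)

    def test_nonmalignant_marginals_invariant_to_cnv_spec(self, small_model):
        # planted shifts touch malignant cells only, so the nonmalignant
        # per-gene mean is unchanged in expectation (sampling noise aside)
        base = dict(n_samples=1, cells_per_sample=600, seed=9)
        a1, t1 = syn.simulate_dataset(small_model, syn.SimConfig(**base))
        a2, t2 = syn.simulate_dataset(
            small_model,
            syn.SimConfig(**base, cnv_spec={"chr7": (1.5, 1.0), "chr10": (-2.0, 1.0)}),
        )
        for chrom in ("chr7", "chr10", "chr9"):
            idx = small_model.genes_on(chrom)
            means = []
            for a, t in ((a1, t1), (a2, t2)):
                nonmal = ((~t["is_malignant"]) & (t["cell_type"] != "doublet")).to_numpy()
                means.append(a.X.toarray()[nonmal][:, idx].mean())
            assert means[0] == pytest.approx(means[1], rel=0.05)

    def test_doublet_expected_library_size_sums_parents(self, small_model):
        cfg = syn.SimConfig(
            n_samples=1, cells_per_sample=2000, doublet_rate=0.3, seed=21
        )
        adata, truth = syn.simulate_dataset(small_model, cfg)
        totals = np.asarray(adata.X.sum(axis=1)).ravel()
        is_doub = truth["is_doublet"].to_numpy()
        ratio = totals[is_doub].mean() / totals[~is_doub].mean()
        assert ratio == pytest.approx(2.0, rel=0.06)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError, match="malignant_fraction"):
            syn.SimConfig(malignant_fraction=1.5)
        with pytest.raises(ValueError, match="fraction"):
            syn.SimConfig(cnv_spec={"chr7": (0.4, 2.0)})


class TestTruthTable:
    def test_write_read_round_trip(self, small_dataset, tmp_path):
        _, truth, _ = small_dataset
        truth = truth.reset_index()
        path = tmp_path / "truth.tsv"
        syn.write_truth(truth, path)
        back = syn.read_truth(path)
        pd.testing.assert_frame_equal(back, truth)

    def test_empty_truth_header_only(self, tmp_path):
        empty = pd.DataFrame(
            columns=[
                "barcode", "sample", "cell_type", "is_malignant",
                "state", "cycling", "is_doublet",
            ]
        )
        path = tmp_path / "truth.tsv"
        syn.write_truth(empty, path)
        assert path.read_text().strip() == "\t".join(empty.columns)

    def test_barcode_order_preserved(self, small_dataset, tmp_path):
        adata, truth, _ = small_dataset
        path = tmp_path / "truth.tsv"
        syn.write_truth(truth.reset_index(), path)
        back = syn.read_truth(path)
        assert list(back["barcode"]) == list(adata.obs_names)

    def test_state_fractions_sum_to_one_per_sample(self, small_dataset):
        _, truth, _ = small_dataset
        fr = syn.sample_true_state_fractions(truth.reset_index())
        np.testing.assert_allclose(fr[list(syn.NEFTEL_STATES)].sum(axis=1), 1.0)


class TestPKPDTables:
    def test_everolimus_tumor_unbound_forced_below_lloq(self):
        pk, _ = syn.simulate_pkpd_tables(n_patients=12, seed=4, lloq=0.1)
        tumor = pk[
            (pk["drug"] == "everolimus")
            & pk["compartment"].isin(["enhancing", "non-enhancing"])
        ]
        assert ((tumor["total_nM"] * tumor["fraction_unbound"]) < 0.1).all()

    def test_zero_variability_gives_arm_geometric_mean(self):
        params = {
            "ribociclib": {
                "ref_dose": 400.0,
                "fu": {c: 0.3 for c in syn.COMPARTMENTS},
                "total_gm": {c: 1000.0 for c in syn.COMPARTMENTS},
                "cv": 0.0,
            }
        }
        arms = ({"ribociclib": 400},)
        pk, _ = syn.simulate_pkpd_tables(
            n_patients=5, dose_arms=arms, pk_params=params, seed=0,
            force_everolimus_tumor_below_lloq=False,
        )
        assert (pk["total_nM"] == 1000.0).all()

    def test_empty_dose_arms_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            syn.simulate_pkpd_tables(n_patients=2, dose_arms=())

    def test_negative_concentration_parameters_rejected(self):
        params = {
            "ribociclib": {
                "ref_dose": 400.0,
                "fu": {c: 0.3 for c in syn.COMPARTMENTS},
                "total_gm": {c: -5.0 for c in syn.COMPARTMENTS},
                "cv": 0.0,
            }
        }
        with pytest.raises(ValueError, match="negative"):
            syn.simulate_pkpd_tables(
                n_patients=2, dose_arms=({"ribociclib": 400},), pk_params=params
            )

    def test_planted_ihc_decrease_detectable_by_paired_test(self):
        # Monte-Carlo: with a planted 30% mean Ki-67 decrease the paired
        # t-test should reject far more often than alpha
        from gliostate.stats import paired_ttest

        rejections = 0
        n_rep = 50
        for rep in range(n_rep):
            _, ihc = syn.simulate_pkpd_tables(n_patients=20, seed=1000 + rep)
            ki = ihc[ihc["marker"] == "Ki-67"]
            res = paired_ttest(ki["pre_pct"], ki["post_pct"])
            rejections += res.p_value < 0.05
        assert rejections / n_rep > 0.8
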