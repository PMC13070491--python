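"""CNV smoothing, Viterbi decoding vs enumeration, malignancy rule."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gliostate import cnv as cnvm
from gliostate import synthetic as syn


def viterbi_brute_force(values, params):
    """Independent oracle: score every 3^L path, return the best."""
    values = np.asarray(values, dtype=float)
    T = params.transition_matrix()
    mu = np.asarray(params.means)
    best_path, best_ll = None, -np.inf
    for path in itertools.product(range(3), repeat=len(values)):
        ll = np.log(1.0 / 3.0)
        for t, s in enumerate(path):
            ll += -((values[t] - mu[s]) ** 2) / (2 * params.sigma**2)
            if t > 0:
                ll += np.log(T[path[t - 1], s])
        if ll > best_ll + 1e-12:
            best_ll, best_path = ll, path
    return np.array(best_path)


class TestSmoothing:
    def test_constant_matrix_gives_zero_profile(self, tiny_adata):
        adata = tiny_adata(
            np.full((5, 12), 3), chromosomes=["chr1"] * 6 + ["chr2"] * 6
        )
        prof = cnvm.build_cnv_profile(adata, adata.obs_names[:2], window=3)
        np.testing.assert_allclose(prof.smoothed, 0.0, atol=1e-12)

    def test_window_one_is_identity_on_centered_track(self, tiny_adata):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 20, size=(6, 10))
        adata = tiny_adata(counts)
        p1 = cnvm.build_cnv_profile(adata, adata.obs_names[:3], window=1)
        # recompute the centered track by hand
        X = counts.astype(float)
        cpm = np.log2(X / X.sum(1, keepdims=True) * 1e4 + 1)
        centered = np.clip(cpm - cpm[:3].mean(0), -3, 3)
        centered -= centered.mean(1, keepdims=True)
        np.testing.assert_allclose(p1.smoothed, centered, atol=1e-6)

    def test_planted_gain_raises_smoothed_chr7_vs_neutral(self, small_dataset, small_model):
        adata, truth, _ = small_dataset
        nonmal = truth.index[
            (~truth["is_malignant"]) & (truth["cell_type"] != "doublet")
        ]
        prof = cnvm.build_cnv_profile(adata, nonmal)
        mal_rows = prof.barcodes.get_indexer(truth.index[truth["is_malignant"]])
        chr7 = prof.smoothed[mal_rows][:, prof.chromosome_slice("chr7")].mean()
        chr9 = prof.smoothed[mal_rows][:, prof.chromosome_slice("chr9")].mean()
        chr10 = prof.smoothed[mal_rows][:, prof.chromosome_slice("chr10")].mean()
        assert chr7 > chr9 + 0.1
        assert chr10 < chr9 - 0.1

    def test_reference_cells_profile_mean_near_zero(self, small_dataset):
        adata, truth, _ = small_dataset
        ref = truth.index[truth["cell_type"] == "oligodendrocytes"]
        prof = cnvm.build_cnv_profile(adata, ref)
        rows = prof.barcodes.get_indexer(ref)
        for chrom in prof.chromosomes:
            m = prof.smoothed[rows][:, prof.chromosome_slice(chrom)].mean()
            assert abs(m) < 0.02

    def test_short_chromosome_warns_and_truncates(self, tiny_adata):
        adata = tiny_adata(np.ones((3, 8), dtype=int))
        with pytest.warns(UserWarning, match="truncated"):
            prof = cnvm.build_cnv_profile(adata, adata.obs_names[:1], window=101)
        assert prof.smoothed.shape == (3, 8)

    def test_empty_reference_rejected(self, tiny_adata):
        adata = tiny_adata(np.ones((3, 8), dtype=int))
        with pytest.raises(ValueError, match="reference"):
            cnvm.build_cnv_profile(adata, [])


class TestViterbi:
    def test_matches_exhaustive_enumeration_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            L = rng.integers(2, 9)
            params = cnvm.HMMParams(
                means=tuple(np.sort(rng.normal(0, 0.3, 3))),
                sigma=float(rng.uniform(0.05, 0.4)),
                stay_prob=float(rng.uniform(0.5, 0.999)),
            )
            values = rng.normal(0, 0.4, L)
            fast = cnvm.viterbi_decode(values, params)[0]
            slow = viterbi_brute_force(values, params)
            np.testing.assert_array_equal(fast, slow)

    def test_all_zero_profile_decodes_neutral(self):
        path = cnvm.viterbi_decode(np.zeros(50), cnvm.HMMParams())[0]
        assert (path == cnvm.STATE_NEUTRAL).all()

    def test_stay_probability_near_one_gives_constant_path(self):
        values = np.concatenate([np.full(5, 0.2), np.full(5, -0.2)])
        path = cnvm.viterbi_decode(
            values, cnvm.HMMParams(stay_prob=1 - 1e-12)
        )[0]
        assert len(set(path.tolist())) == 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            cnvm.HMMParams(means=(0.2, 0.0, -0.2))
        with pytest.raises(ValueError, match="sigma"):
            cnvm.HMMParams(sigma=0.0)
        with pytest.raises(ValueError, match="stay_prob"):
            cnvm.HMMParams(stay_prob=1.0)


class TestAlteredFractions:
    def _profile_with_states(self, states, chroms):
        n_cells, n_genes = states.shape
        gene_order = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n_genes)],
                "chromosome": chroms,
                "position": np.arange(n_genes),
            }
        )
        return cnvm.CNVProfile(
            smoothed=np.zeros_like(states, dtype=np.float32),
            barcodes=pd.Index([f"c{i}" for i in range(n_cells)]),
            gene_order=gene_order,
            states=states.astype(np.int8),
        )

    def test_all_gain_gives_fraction_one(self):
        states = np.full((2, 10), cnvm.STATE_GAIN)
        prof = self._profile_with_states(states, ["chr7"] * 10)
        gain, loss = cnvm.chromosome_altered_fraction(prof)
        assert (gain["chr7"] == 1.0).all()
        assert (loss["chr7"] == 0.0).all()

    def test_partial_gain_arithmetic(self):
        states = np.full((1, 100), cnvm.STATE_NEUTRAL)
        states[0, :30] = cnvm.STATE_GAIN
        prof = self._profile_with_states(states, ["chr7"] * 100)
        gain, _ = cnvm.chromosome_altered_fraction(prof)
        assert gain.loc["c0", "chr7"] == pytest.approx(0.30)

    def test_matches_naive_tally_oracle_on_random_matrix(self):
        rng = np.random.default_rng(5)
        chroms = ["chr1"] * 40 + ["chr2"] * 60
        states = rng.integers(0, 3, size=(20, 100))
        prof = self._profile_with_states(states, chroms)
        gain, loss = cnvm.chromosome_altered_fraction(prof)
        for ci, cell in enumerate(prof.barcodes):
            for chrom, sl in (("chr1", slice(0, 40)), ("chr2", slice(40, 100))):
                row = states[ci, sl]
                assert gain.loc[cell, chrom] == pytest.approx(
                    (row == cnvm.STATE_GAIN).mean()
                )
                assert loss.loc[cell, chrom] == pytest.approx(
                    (row == cnvm.STATE_LOSS).mean()
                )

    def test_fractions_require_decoded_states(self, tiny_adata):
        adata = tiny_adata(np.ones((2, 6), dtype=int))
        prof = cnvm.build_cnv_profile(adata, adata.obs_names[:1], window=1)
        with pytest.raises(ValueError, match="states"):
            cnvm.chromosome_altered_fraction(prof)


class TestMalignancyRule:
    def _call(self, label, gain7, loss10, threshold=0.25):
        labels = pd.Series([label], index=["c0"])
        gain = pd.DataFrame({"chr7": [gain7]}, index=["c0"])
        loss = pd.DataFrame({"chr10": [loss10]}, index=["c0"])
        return cnvm.classify_malignant_cells(labels, gain, loss, threshold)["c0"]

    @pytest.mark.parametrize(
        "label,gain7,loss10,expected",
        [
            ("malignant-candidate", 0.30, 0.0, "malignant"),
            ("malignant-candidate", 0.0, 0.30, "malignant"),
            ("malignant-candidate", 0.10, 0.10, "unresolved"),
            ("neurons", 0.30, 0.0, "unresolved"),
            ("neurons", 0.10, 0.10, "nonmalignant"),
        ],
    )
    def test_concordance_rule_branches(self, label, gain7, loss10, expected):
        assert self._call(label, gain7, loss10) == expected

    def test_threshold_boundary_strict(self):
        # exactly 25% altered is NOT an event
        assert self._call("malignant-candidate", 0.25, 0.25) == "unresolved"
        assert self._call("neurons", 0.25, 0.25) == "nonmalignant"

    def test_missing_fraction_rejected(self):
        labels = pd.Series(["neurons"], index=["c0"])
        gain = pd.DataFrame({"chr7": [np.nan]}, index=["c0"])
        loss = pd.DataFrame({"chr10": [0.0]}, index=["c0"])
        with pytest.raises((KeyError, ValueError)):
            cnvm.classify_malignant_cells(labels, gain, loss)


class TestSampleFilter:
    def _calls(self, n_malignant, sample="S1"):
        calls = pd.Series(
            ["malignant"] * n_malignant + ["nonmalignant"] * 5,
            index=[f"c{i}" for i in range(n_malignant + 5)],
        )
        labels = pd.Series(sample, index=calls.index)
        return calls, labels

    def test_24_malignant_cells_excluded(self):
        calls, labels = self._calls(24)
        assert cnvm.filter_samples_by_malignant_count(calls, labels) == []

    def test_25_malignant_cells_retained(self):
        calls, labels = self._calls(25)
        assert cnvm.filter_samples_by_malignant_count(calls, labels) == ["S1"]

    def test_zero_malignant_cells_excluded(self):
        calls, labels = self._calls(0)
        assert cnvm.filter_samples_by_malignant_count(calls, labels) == []
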