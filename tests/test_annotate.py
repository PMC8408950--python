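"""Unit tests for marker peaks, embedding, aggregation, scores and origin calls."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from amulet.annotate import (
    MarkerPeakSet,
    PeakCountMatrix,
    _fit_distance_mixture,
    association_scores,
    classify_and_annotate,
    find_marker_peaks,
    knn_aggregate,
    singlet_mean_profiles,
    svd_embedding,
)


def toy_counts(n_peaks=30, n_cells=320, seed=0, planted_peak=0, planted_type="A"):
    """Two types (160 cells each); ``planted_peak`` accessible only in A."""
    rng = np.random.default_rng(seed)
    labels = {}
    arr = rng.poisson(1.0, size=(n_peaks, n_cells))
    barcodes = [f"c{i}" for i in range(n_cells)]
    for i, b in enumerate(barcodes):
        labels[b] = "A" if i < n_cells // 2 else "B"
    arr[planted_peak] = 0
    arr[planted_peak, : n_cells // 2] = rng.poisson(3.0, size=n_cells // 2) + 1
    peaks = [("chr1", i * 1000, i * 1000 + 500) for i in range(n_peaks)]
    return PeakCountMatrix(peaks=peaks, barcodes=barcodes, counts=sp.csr_matrix(arr)), labels


class TestPeakCountMatrix:
    def test_shape_validation(self):
        with pytest.raises(ValueError, match="shape"):
            PeakCountMatrix(
                peaks=[("chr1", 0, 10)], barcodes=["a", "b"], counts=sp.csr_matrix((1, 1))
            )

    def test_mtx_round_trip(self, tmp_path):
        from scipy.io import mmwrite

        from amulet.annotate import read_peak_count_matrix

        pcm, _ = toy_counts(n_peaks=5, n_cells=160)
        mmwrite(str(tmp_path / "m.mtx"), pcm.counts)
        with open(tmp_path / "peaks.bed", "w") as fh:
            for c, s, e in pcm.peaks:
                fh.write(f"{c}\t{s}\t{e}\n")
        with open(tmp_path / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(pcm.barcodes) + "\n")
        loaded = read_peak_count_matrix(
            tmp_path / "m.mtx", tmp_path / "peaks.bed", tmp_path / "barcodes.tsv"
        )
        assert loaded.peaks == pcm.peaks
        assert loaded.barcodes == pcm.barcodes
        assert (loaded.counts != pcm.counts).nnz == 0


class TestFindMarkerPeaks:
    def test_planted_marker_found(self):
        pcm, labels = toy_counts()
        markers = find_marker_peaks(pcm, labels, top_n=5, min_cells=100)
        assert 0 in markers.peak_indices("A")
        # and ranked first: perfect separation gives the smallest p
        assert markers.tables["A"].iloc[0]["peak_index"] == 0

    def test_uniform_peak_excluded(self):
        pcm, labels = toy_counts()
        markers = find_marker_peaks(pcm, labels, top_n=5, min_cells=100)
        table = markers.tables["A"]
        uniform = table[table["peak_index"] != 0]
        assert (uniform["adjusted_p"] > 0.05).all()

    def test_small_type_absent(self):
        pcm, labels = toy_counts(n_cells=640)
        # carve a third type with 149 cells out of B, leaving B with 171
        for i, b in enumerate(pcm.barcodes):
            if 320 <= i < 469:
                labels[b] = "C"
        markers = find_marker_peaks(pcm, labels, min_cells=150)
        assert "C" not in markers.cell_types
        assert "A" in markers.cell_types

    def test_fewer_than_two_types_fails(self):
        pcm, labels = toy_counts()
        labels = {b: "A" for b in labels}
        with pytest.raises(ValueError, match=">= 2 cell types"):
            find_marker_peaks(pcm, labels, min_cells=100)

    def test_top_n_limit(self):
        pcm, labels = toy_counts()
        markers = find_marker_peaks(pcm, labels, top_n=3, min_cells=100)
        assert all(len(t) <= 3 for t in markers.tables.values())


class TestSvdEmbedding:
    def test_rank_one_matrix(self):
        u = np.outer(np.arange(1, 11), np.ones(8))
        with pytest.warns(UserWarning, match="reduced"):
            emb = svd_embedding(sp.csr_matrix(u), n_components=50, tf_scale=False)
        var = emb.var(axis=0)
        assert var[0] >= var.sum() * 0.999

    def test_duplicated_cells_identical(self):
        rng = np.random.default_rng(0)
        arr = rng.poisson(1.0, size=(20, 10))
        arr[:, 5] = arr[:, 3]
        emb = svd_embedding(sp.csr_matrix(arr), n_components=5)
        np.testing.assert_allclose(emb[3], emb[5], atol=1e-10)

    def test_reproducible(self):
        rng = np.random.default_rng(1)
        arr = sp.csr_matrix(rng.poisson(1.0, size=(40, 30)))
        e1 = svd_embedding(arr, n_components=10, random_state=7)
        e2 = svd_embedding(arr, n_components=10, random_state=7)
        np.testing.assert_array_equal(e1, e2)


class TestKnnAggregate:
    def make_markers(self, idx):
        tables = {
            "A": pd.DataFrame(
                {"peak_index": idx, "adjusted_p": 0.0, "avg_logFC": 1.0}
            )
        }
        return MarkerPeakSet(tables=tables)

    def test_k_zero_is_identity(self):
        pcm, _ = toy_counts(n_peaks=10, n_cells=160)
        emb = svd_embedding(pcm, n_components=5)
        markers = self.make_markers(np.arange(10))
        agg = knn_aggregate(pcm, emb, markers, k=0)
        np.testing.assert_array_equal(agg, pcm.counts.toarray().T)

    def test_identical_cells_aggregation_is_identity(self):
        arr = np.tile(np.arange(6)[:, None], (1, 20))
        pcm = PeakCountMatrix(
            peaks=[("chr1", i, i + 1) for i in range(6)],
            barcodes=[f"c{i}" for i in range(20)],
            counts=sp.csr_matrix(arr),
        )
        emb = np.zeros((20, 3))
        agg = knn_aggregate(pcm, emb, self.make_markers(np.arange(6)), k=5)
        np.testing.assert_allclose(agg, arr.T)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(3)
        n_cells, n_peaks, k = 200, 12, 7
        arr = rng.poisson(2.0, size=(n_peaks, n_cells))
        pcm = PeakCountMatrix(
            peaks=[("chr1", i, i + 1) for i in range(n_peaks)],
            barcodes=[f"c{i}" for i in range(n_cells)],
            counts=sp.csr_matrix(arr),
        )
        emb = rng.normal(size=(n_cells, 4))
        agg = knn_aggregate(pcm, emb, self.make_markers(np.arange(n_peaks)), k=k)
        # oracle: all-pairs distances, take k+1 nearest including self
        d = np.linalg.norm(emb[:, None, :] - emb[None, :, :], axis=2)
        for i in range(n_cells):
            nn = np.argsort(d[i], kind="stable")[: k + 1]
            np.testing.assert_allclose(agg[i], arr[:, nn].mean(axis=1))

    def test_k_too_large(self):
        pcm, _ = toy_counts(n_peaks=5, n_cells=160)
        emb = np.zeros((160, 2))
        with pytest.raises(ValueError, match="smaller"):
            knn_aggregate(pcm, emb, self.make_markers(np.arange(5)), k=160)


class TestAssociationScores:
    def make_profiles(self, agg, types=("A",), per_type=None):
        per_type = per_type or {t: len(agg[0]) // len(types) for t in types}
        tables = {}
        start = 0
        for t in types:
            tables[t] = pd.DataFrame(
                {
                    "peak_index": np.arange(start, start + per_type[t]),
                    "adjusted_p": 0.0,
                    "avg_logFC": 1.0,
                }
            )
            start += per_type[t]
        markers = MarkerPeakSet(tables=tables)
        barcodes = [f"c{i}" for i in range(len(agg))]
        return association_scores(np.asarray(agg, dtype=float), markers, barcodes)

    def test_max_value_scores_one(self):
        prof = self.make_profiles([[0.0], [1.0], [5.0]])
        assert prof.peak_scores[2, 0] == 1.0

    def test_scores_in_unit_interval(self):
        rng = np.random.default_rng(0)
        prof = self.make_profiles(rng.normal(size=(50, 4)))
        assert (prof.peak_scores > 0).all()
        assert (prof.peak_scores <= 1).all()

    def test_constant_peak_scores_one_everywhere(self):
        prof = self.make_profiles([[2.0], [2.0], [2.0]])
        assert (prof.peak_scores == 1.0).all()

    def test_type_summary_is_mean(self):
        prof = self.make_profiles(
            [[1.0, 2.0, 10.0, 20.0], [2.0, 1.0, 20.0, 10.0]],
            types=("A", "B"),
            per_type={"A": 2, "B": 2},
        )
        np.testing.assert_allclose(
            prof.type_scores["A"].to_numpy(), prof.peak_scores[:, :2].mean(axis=1)
        )

    def test_own_type_scores_higher_in_separated_sample(self):
        from amulet.simulate import SyntheticSpec, make_synthetic_sample
        from amulet.annotate import find_marker_peaks, knn_aggregate, svd_embedding

        spec = SyntheticSpec.toy(
            n_nuclei=400, depth=1_500, n_peaks=1_200, markers_per_type=80,
            n_repeat_hotspots=0, artifact_rate=0.0, seed=13,
        )
        s = make_synthetic_sample(spec)
        pcm = PeakCountMatrix(
            peaks=spec.peak_regions(), barcodes=s.barcodes, counts=s.peak_counts
        )
        markers = find_marker_peaks(pcm, s.labels, top_n=50, min_cells=80)
        emb = svd_embedding(pcm, n_components=20)
        agg = knn_aggregate(pcm, emb, markers, k=15)
        prof = association_scores(agg, markers, pcm.barcodes)
        own = []
        for b in pcm.barcodes:
            t = s.labels[b]
            row = prof.type_scores.loc[b]
            own.append(row[t] == row.max())
        assert np.mean(own) > 0.95


class TestMixtureFit:
    def test_recovers_bimodal_means(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.5, 0.05, 60), rng.normal(5.0, 0.5, 60)])
        gm = _fit_distance_mixture(x)
        means = np.sort(gm.means_.ravel())
        assert abs(means[0] - 0.5) / 0.5 < 0.1
        assert abs(means[-1] - 5.0) / 5.0 < 0.1


class TestClassifyAndAnnotate:
    def make_inputs(self, n_singlets=40, n_mult=12, seed=0):
        """Synthetic profiles: 2 types over 4 marker peaks (2 each)."""
        rng = np.random.default_rng(seed)
        barcodes, labels, scores = [], {}, []
        for i in range(n_singlets):
            t = "A" if i % 2 == 0 else "B"
            b = f"s{i}"
            barcodes.append(b)
            labels[b] = t
            base = np.array([0.9, 0.9, 0.3, 0.3]) if t == "A" else np.array([0.3, 0.3, 0.9, 0.9])
            scores.append(np.clip(base + rng.normal(0, 0.02, 4), 0.01, 1.0))
        mult_bcs = []
        for i in range(n_mult):
            b = f"m{i}"
            barcodes.append(b)
            labels[b] = "A"
            if i < n_mult // 2:  # homotypic A+A: close to A singlet profile
                base = np.array([0.95, 0.95, 0.3, 0.3])
            else:  # heterotypic A+B
                base = np.array([0.92, 0.92, 0.92, 0.92])
            scores.append(np.clip(base + rng.normal(0, 0.02, 4), 0.01, 1.0))
            mult_bcs.append(b)
        tables = {
            "A": pd.DataFrame({"peak_index": [0, 1], "adjusted_p": 0.0, "avg_logFC": 1.0}),
            "B": pd.DataFrame({"peak_index": [2, 3], "adjusted_p": 0.0, "avg_logFC": 1.0}),
        }
        markers = MarkerPeakSet(tables=tables)
        from amulet.annotate import AssociationProfiles

        scores = np.array(scores)
        type_scores = pd.DataFrame(
            {"A": scores[:, :2].mean(axis=1), "B": scores[:, 2:].mean(axis=1)},
            index=barcodes,
        )
        profiles = AssociationProfiles(
            barcodes=barcodes,
            peak_scores=scores,
            type_scores=type_scores,
            marker_peaks=markers,
        )
        return profiles, labels, mult_bcs

    def test_classification_and_origins(self):
        profiles, labels, mult_bcs = self.make_inputs()
        calls = classify_and_annotate(profiles, labels, mult_bcs)
        assert len(calls) == len(mult_bcs)
        by_bc = calls.set_index("barcode")
        for i, b in enumerate(mult_bcs):
            if i < len(mult_bcs) // 2:
                assert by_bc.loc[b, "type_class"] == "homotypic"
                assert by_bc.loc[b, "origin1"] == "A"
            else:
                assert by_bc.loc[b, "type_class"] == "heterotypic"
                assert {by_bc.loc[b, "origin1"], by_bc.loc[b, "origin2"]} == {"A", "B"}

    def test_exact_singlet_profile_is_homotypic(self):
        profiles, labels, mult_bcs = self.make_inputs()
        sing = singlet_mean_profiles(profiles, labels, mult_bcs)
        # overwrite one multiplet's profile with the A singlet mean: distance 0
        idx = profiles.barcodes.index(mult_bcs[0])
        profiles.peak_scores[idx] = sing.loc["A"].to_numpy()
        profiles.type_scores.iloc[idx, 0] = profiles.peak_scores[idx][:2].mean()
        profiles.type_scores.iloc[idx, 1] = profiles.peak_scores[idx][2:].mean()
        calls = classify_and_annotate(profiles, labels, mult_bcs)
        row = calls[calls["barcode"] == mult_bcs[0]].iloc[0]
        assert row["distance_to_top_singlet"] == pytest.approx(0.0, abs=1e-12)
        assert row["type_class"] == "homotypic"

    def test_single_multiplet_homotypic_with_warning(self):
        profiles, labels, mult_bcs = self.make_inputs()
        with pytest.warns(UserWarning, match="single multiplet"):
            calls = classify_and_annotate(profiles, labels, mult_bcs[:1])
        assert calls.iloc[0]["type_class"] == "homotypic"

    def test_every_multiplet_gets_one_call(self):
        profiles, labels, mult_bcs = self.make_inputs(n_mult=10)
        calls = classify_and_annotate(profiles, labels, mult_bcs)
        assert sorted(calls["barcode"]) == sorted(mult_bcs)
        n_het = (calls["type_class"] == "heterotypic").sum()
        n_hom = (calls["type_class"] == "homotypic").sum()
        assert n_het + n_hom == len(mult_bcs)

    def test_no_multiplets_fails(self):
        profiles, labels, _ = self.make_inputs()
        with pytest.raises(ValueError, match="no multiplets"):
            classify_and_annotate(profiles, labels, [])
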