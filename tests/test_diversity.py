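"""Feature tables, dissimilarity metrics, PCoA, rarefaction, overlap and
per-site uniqueness."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import dice, pdist, squareform

from chemocart.diversity import (
    DiversityParams,
    FeatureTable,
    build_feature_table,
    dataset_overlap,
    distance_matrix,
    location_uniqueness,
    pcoa,
    rarefaction_curve,
)
from chemocart.io import SampleMetadata, ValidationError
from chemocart.processing import ConsensusFeature

from conftest import random_spectrum


def meta(sample_id: str, site: str = "PAP") -> SampleMetadata:
    return SampleMetadata(sample_id=sample_id, site_code=site, latitude=0.0, longitude=0.0)


def table_from_matrix(mat, feature_ids=None, samples=None, sites=None) -> FeatureTable:
    mat = np.asarray(mat, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{j}" for j in range(mat.shape[1])]
    sites = sites or ["PAP"] * len(samples)
    metadata = {s: meta(s, site) for s, site in zip(samples, sites)}
    return FeatureTable(matrix=pd.DataFrame(mat, index=feature_ids, columns=samples), metadata=metadata)


class TestBuildFeatureTable:
    def test_toy_matrix_entries(self):
        features = [
            ConsensusFeature("f1", 500.0, np.array([[100.0, 1.0]]), ["a"], {"s1": 2.0, "s2": 3.0}),
            ConsensusFeature("f2", 600.0, np.array([[100.0, 1.0]]), ["b"], {"s1": 1.0}),
            ConsensusFeature("f3", 700.0, np.array([[100.0, 1.0]]), ["c"], {"s2": 5.0}),
        ]
        table = build_feature_table(features, [meta("s1"), meta("s2")])
        assert table.matrix.loc["f1", "s2"] == 3.0
        assert table.matrix.loc["f2", "s2"] == 0.0  # zero-filled where absent
        assert table.matrix.loc["f3", "s1"] == 0.0

    def test_orphan_sample_raises_with_ids(self):
        features = [ConsensusFeature("f1", 500.0, np.array([[100.0, 1.0]]), ["a"], {"ghost": 1.0})]
        with pytest.raises(ValidationError, match="ghost"):
            build_feature_table(features, [meta("s1")])

    def test_column_sums_reproduce_planted_abundance_totals(self):
        from chemocart import simulate
        from chemocart.processing import NetworkingParams, apply_standard_filters, cluster_spectra

        config = simulate.GeneratorConfig(n_scaffolds=4, samples_per_site=1, rng_seed=5).noise_free()
        planted, truth = simulate.generate_spectral_families(config)
        spectra, metadata, truth = simulate.generate_collection(planted, truth, config)
        params = NetworkingParams()
        features, _ = cluster_spectra([apply_standard_filters(s, params) for s in spectra], params)
        table = build_feature_table(features, metadata)
        expected = {}
        for f in truth.features.values():
            for sid, ab in f.per_sample_abundance.items():
                expected[sid] = expected.get(sid, 0.0) + ab
        for sid in table.sample_ids:
            assert table.matrix[sid].sum() == pytest.approx(expected.get(sid, 0.0), rel=1e-9)

    def test_biom_json_roundtrip(self, tmp_path):
        table = table_from_matrix([[1.0, 0.0], [0.5, 2.0]])
        table.to_biom_json(tmp_path / "t.biom.json")
        back = FeatureTable.from_biom_json(tmp_path / "t.biom.json")
        pd.testing.assert_frame_equal(back.matrix, table.matrix)


class TestDistanceMatrix:
    def test_identical_samples_at_zero_distance(self):
        t = table_from_matrix([[1.0, 1.0], [2.0, 2.0]])
        for metric in ("bray_curtis", "binary_jaccard"):
            d = distance_matrix(t, metric)
            assert d.iloc[0, 1] == 0.0
            assert (np.diag(d.values) == 0).all()

    def test_disjoint_presence_at_distance_one(self):
        t = table_from_matrix([[1.0, 0.0], [0.0, 2.0]])
        for metric in ("bray_curtis", "binary_jaccard"):
            assert distance_matrix(t, metric).iloc[0, 1] == 1.0

    def test_bray_curtis_hand_value(self):
        t = table_from_matrix(np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]))
        d = distance_matrix(t, "bray_curtis")
        assert d.iloc[0, 1] == pytest.approx(4 / 12, abs=1e-12)

    def test_all_zero_sample_rules(self):
        t = table_from_matrix([[1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        d = distance_matrix(t, "bray_curtis")
        assert d.iloc[0, 1] == 1.0  # empty vs non-empty
        assert d.iloc[1, 2] == 0.0  # empty vs empty

    def test_metric_axioms_and_range(self, rng):
        mat = rng.lognormal(0, 1, size=(12, 6)) * (rng.random((12, 6)) < 0.6)
        t = table_from_matrix(mat)
        for metric in ("bray_curtis", "binary_jaccard"):
            d = distance_matrix(t, metric).values
            assert np.allclose(d, d.T)
            assert (d >= 0).all() and (d <= 1).all()

    def test_binary_bray_curtis_equals_sorensen_dice(self, rng):
        """On presence/absence data Bray-Curtis reduces to the Sorensen
        formula — cross-checked against scipy's dice dissimilarity."""
        mat = (rng.random((20, 5)) < 0.5).astype(float)
        mat[0, :] = 1.0  # no all-zero samples
        t = table_from_matrix(mat)
        d = distance_matrix(t, "bray_curtis")
        for i, j in itertools.combinations(range(5), 2):
            expected = dice(mat[:, i] > 0, mat[:, j] > 0)
            assert d.iloc[i, j] == pytest.approx(expected, abs=1e-12)


class TestPCoA:
    def test_identical_samples_coincide(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        res = pcoa(d)
        np.testing.assert_allclose(
            res.coordinates.iloc[0].values, res.coordinates.iloc[1].values, atol=1e-9
        )

    def test_collinear_points_give_single_axis_and_exact_distances(self):
        d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        res = pcoa(d)
        assert res.coordinates.shape[1] == 1
        emb = squareform(pdist(res.coordinates.values))
        np.testing.assert_allclose(emb, d, atol=1e-9)

    def test_euclidean_cloud_distances_reconstructed(self, rng):
        points = rng.normal(size=(5, 3))
        d = squareform(pdist(points))
        res = pcoa(d)
        emb = squareform(pdist(res.coordinates.values))
        np.testing.assert_allclose(emb, d, atol=1e-9)

    def test_axis_ordering_and_sign_convention(self, rng):
        points = rng.normal(size=(8, 4)) * np.array([5.0, 2.0, 1.0, 0.3])
        d = squareform(pdist(points))
        res = pcoa(d)
        eig = res.eigenvalues
        assert all(eig[i] >= eig[i + 1] - 1e-12 for i in range(len(eig) - 1))
        for k in range(res.coordinates.shape[1]):
            col = res.coordinates.values[:, k]
            nz = np.nonzero(np.abs(col) > 1e-12)[0]
            assert col[nz[0]] > 0
        assert res.proportion_explained.sum() == pytest.approx(1.0)

    def test_non_symmetric_input_rejected(self):
        with pytest.raises(ValidationError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [0.5, 0.0]]))

    def test_agrees_with_independent_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        mat = rng.lognormal(0, 1, size=(15, 7))
        t = table_from_matrix(mat)
        d = distance_matrix(t, "bray_curtis")
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, ids=d.index))
        n_pos = ours.coordinates.shape[1]
        np.testing.assert_allclose(
            sorted(ours.eigenvalues, reverse=True)[:n_pos],
            sorted(theirs.eigvals, reverse=True)[:n_pos],
            atol=1e-8,
        )
        # embeddings agree up to axis sign
        np.testing.assert_allclose(
            np.abs(ours.coordinates.values[:, :3]),
            np.abs(theirs.samples.values[:, :3]),
            atol=1e-8,
        )


class TestRarefaction:
    def test_full_depth_equals_total_richness_with_zero_sd(self, rng):
        mat = (rng.random((30, 6)) < 0.4).astype(float)
        t = table_from_matrix(mat)
        curve = rarefaction_curve(t, DiversityParams(rng_seed=1))
        last = curve.iloc[-1]
        assert last["depth"] == 6
        assert last["mean_richness"] == float((mat.sum(axis=1) > 0).sum())
        assert last["sd_richness"] == 0.0

    def test_full_depth_is_seed_independent(self, rng):
        mat = (rng.random((30, 5)) < 0.4).astype(float)
        t = table_from_matrix(mat)
        values = {
            rarefaction_curve(t, DiversityParams(rng_seed=s)).iloc[-1]["mean_richness"]
            for s in range(5)
        }
        assert len(values) == 1

    def test_depth_one_matches_exhaustive_enumeration(self):
        mat = np.array(
            [[1, 0, 0, 1], [1, 1, 0, 0], [0, 0, 1, 0], [0, 1, 1, 1], [1, 0, 0, 0]], dtype=float
        )
        t = table_from_matrix(mat)
        exact = np.mean([(mat[:, j] > 0).sum() for j in range(4)])
        curve = rarefaction_curve(
            t, DiversityParams(rarefaction_iterations=4000, rarefaction_depths=[1], rng_seed=0)
        )
        assert curve.iloc[0]["mean_richness"] == pytest.approx(exact, abs=0.05)

    def test_curve_nondecreasing_for_many_seeds(self, rng):
        mat = (rng.random((40, 8)) < 0.3).astype(float)
        t = table_from_matrix(mat)
        for seed in range(20):
            curve = rarefaction_curve(t, DiversityParams(rng_seed=seed))
            means = curve["mean_richness"].values
            assert (np.diff(means) >= -1e-9).all()

    def test_depth_beyond_sample_count_rejected(self):
        t = table_from_matrix([[1.0, 1.0]])
        with pytest.raises(ValidationError, match="depth"):
            rarefaction_curve(t, DiversityParams(rarefaction_depths=[3]))


def _features_for(spectra):
    return [ConsensusFeature(s.spectrum_id, s.precursor_mz, s.peaks, ["m"] * 3) for s in spectra]


class TestDatasetOverlap:
    def _tables(self, feats_by_label):
        tables, features = [], []
        for label, feats in feats_by_label.items():
            mat = pd.DataFrame(
                1.0, index=[f.feature_id for f in feats], columns=[f"{label}_s1"]
            )
            t = FeatureTable(matrix=mat, metadata={f"{label}_s1": meta(f"{label}_s1")},
                             dataset_label=label)
            tables.append(t)
            features.append(feats)
        return tables, features

    def test_identical_datasets_fully_overlap(self, rng):
        spectra = [random_spectrum(rng) for _ in range(6)]
        fa = _features_for(spectra)
        fb = [ConsensusFeature("b" + f.feature_id, f.consensus_precursor_mz,
                               f.representative_peaks, ["m"] * 3) for f in fa]
        tables, features = self._tables({"A": fa, "B": fb})
        result = dataset_overlap(tables, features)
        assert result["focal_percent_unique"] == 0.0
        assert result["unique_counts"] == {"A": 0, "B": 0}

    def test_partial_overlap_counts(self, rng):
        a, b, c, d = (random_spectrum(rng, precursor=300.0 + 70 * i) for i in range(4))
        fa = _features_for([a, b, c])
        fb = _features_for([b, c, d])
        for f in fb:
            f.feature_id = "B" + f.feature_id
        tables, features = self._tables({"A": fa, "B": fb})
        result = dataset_overlap(tables, features)
        assert result["unique_counts"]["A"] == 1
        assert result["unique_counts"]["B"] == 1
        assert result["shared_groups"] == 2
        assert result["focal_percent_unique"] == pytest.approx(100 / 3)

    def test_planted_sharing_recovered_within_binomial_tolerance(self, default_config):
        from chemocart import simulate
        from dataclasses import replace

        config = replace(default_config, rng_seed=12)
        datasets, shared_ids = simulate.generate_multidataset(
            ["cyano", "actino", "lichen", "sponge", "freshwater"], 0.15, config
        )
        tables, features = [], []
        for label, (planted, _) in datasets.items():
            feats = _features_for(planted)
            mat = pd.DataFrame(1.0, index=[f.feature_id for f in feats], columns=[f"{label}_s1"])
            tables.append(FeatureTable(matrix=mat, metadata={f"{label}_s1": meta(f"{label}_s1")},
                                       dataset_label=label))
            features.append(feats)
        result = dataset_overlap(tables, features, focal=0)
        focal_label = result["focal"]
        n_total = result["focal_total_features"]
        planted_unique = n_total - len(shared_ids[focal_label])
        # spectral matching recovers the planted unique set exactly here
        assert result["focal_unique_features"] == planted_unique
        # and the planted sharing regime (~15% of scaffolds shared) puts the
        # unique fraction near 85% within binomial tolerance
        p = planted_unique / n_total
        assert result["focal_percent_unique"] / 100 == pytest.approx(p, abs=1e-9)
        assert abs(p - 0.85) <= 3 * np.sqrt(0.15 * 0.85 / n_total) + 0.05


class TestLocationUniqueness:
    def test_hand_enumeration(self):
        mat = np.array([[1, 0], [1, 1], [0, 1], [0, 1]], dtype=float)
        t = table_from_matrix(mat, feature_ids=["f1", "f2", "f3", "f4"],
                              samples=["sA", "sB"], sites=["A", "B"])
        result = location_uniqueness(t).set_index("site")
        assert result.loc["A", "unique_features"] == 1
        assert result.loc["A", "percent_of_all"] == pytest.approx(25.0)
        assert result.loc["B", "unique_features"] == 2
        assert result.loc["B", "percent_of_all"] == pytest.approx(50.0)
        assert result.loc["__shared__", "percent_of_all"] == pytest.approx(25.0)

    def test_cosmopolitan_features_leave_all_sites_at_zero(self):
        mat = np.ones((5, 3))
        t = table_from_matrix(mat, samples=["s0", "s1", "s2"], sites=["A", "B", "C"])
        result = location_uniqueness(t)
        site_rows = result[result["site"] != "__shared__"]
        assert (site_rows["percent_of_all"] == 0.0).all()

    def test_percentages_sum_to_one_hundred(self, rng):
        mat = (rng.random((60, 10)) < 0.3).astype(float)
        mat[0, 0] = 1.0
        sites = [f"S{j % 4}" for j in range(10)]
        t = table_from_matrix(mat, samples=[f"s{j}" for j in range(10)], sites=sites)
        result = location_uniqueness(t)
        assert result["percent_of_all"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_planted_endemicity_recovered_at_zero_noise(self):
        from chemocart import simulate
        from chemocart.processing import NetworkingParams, apply_standard_filters, cluster_spectra

        patterns = [
            (1, 0, 0, 0, 0, 0, 0, 0),  # endemic to HI
            (0, 0, 0, 0, 0, 0, 1, 0),  # endemic to PAL
            (1, 1, 0, 0, 0, 0, 0, 0),  # shared
        ]
        config = simulate.GeneratorConfig(
            n_scaffolds=6, analogs_per_scaffold_mean=0.0, samples_per_site=1,
            site_assignment=patterns, rng_seed=2,
        ).noise_free()
        planted, truth = simulate.generate_spectral_families(config)
        spectra, metadata, truth = simulate.generate_collection(planted, truth, config)
        params = NetworkingParams()
        features, _ = cluster_spectra([apply_standard_filters(s, params) for s in spectra], params)
        table = build_feature_table(features, metadata)
        result = location_uniqueness(table).set_index("site")
        assert result.loc["HI", "unique_features"] == 2
        assert result.loc["PAL", "unique_features"] == 2
        assert result.loc["__shared__", "unique_features"] == 2
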