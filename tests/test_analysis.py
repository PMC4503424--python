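"""Allocation index, centroid decoder, statistical dependence and
exclusivity probing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adsyn.analysis import (CentroidDecoder, allocation_index,
                            assign_super_category, decode, decoder_error,
                            exclusivity_counts, fit_centroid_decoder,
                            network_size_curves, statistical_dependence)
from adsyn.datasets import CategorySpec, Dataset, make_dataset_B
from conftest import make_probe_model


def _labelled_dataset(patterns, labels, n_categories):
    patterns = np.asarray(patterns, dtype=np.uint8)
    cats = [CategorySpec(str(c), np.arange(patterns.shape[1]),
                         int((np.asarray(labels) == c).sum()),
                         float((np.asarray(labels) == c).mean()))
            for c in range(n_categories)]
    return Dataset(name="t", patterns=patterns, labels=labels,
                   categories=cats, active_per_pattern=0)


class TestAllocationIndex:
    def test_published_worked_example(self):
        """Ten neurons, 100 firings split 18/32/50 -> shares .18/.32/.50."""
        # one input line per category; ten neurons all fire to every line
        patterns = np.repeat(np.eye(3, dtype=np.uint8),
                             [18, 32, 50], axis=0)
        labels = np.repeat([0, 1, 2], [18, 32, 50])
        ds = _labelled_dataset(patterns, labels, 3)
        model = make_probe_model(np.ones((10, 3)), np.ones((10, 3)),
                                 theta=1.0)
        rep = allocation_index(model, ds)
        assert rep.total_firings == 1000
        assert rep.shares == pytest.approx([0.18, 0.32, 0.50])

    def test_single_selective_neuron(self):
        patterns = np.eye(3, dtype=np.uint8)
        ds = _labelled_dataset(patterns, [0, 1, 2], 3)
        model = make_probe_model([[1, 0, 0]], [[1.0, 0, 0]], theta=0.5)
        rep = allocation_index(model, ds)
        assert rep.shares == pytest.approx([1.0, 0.0, 0.0])
        assert rep.neuron_shares == pytest.approx([1.0, 0.0, 0.0])
        assert rep.n_responding == 1

    def test_degenerate_when_nothing_fires(self):
        patterns = np.eye(3, dtype=np.uint8)
        ds = _labelled_dataset(patterns, [0, 1, 2], 3)
        model = make_probe_model([[1, 0, 0]], [[1.0, 0, 0]], theta=99.0)
        rep = allocation_index(model, ds)
        assert rep.degenerate
        assert rep.total_firings == 0
        assert rep.n_responding == 0
        assert rep.shares == pytest.approx(np.zeros(3))
        assert rep.neuron_shares == pytest.approx(np.zeros(3))

    def test_shares_normalized_and_supers_aggregate(self):
        ds = make_dataset_B("B1", 5)
        rng = np.random.default_rng(0)
        c = (rng.random((40, 390)) < 0.08).astype(np.uint8)
        model = make_probe_model(c, np.full((40, 390), 0.3), theta=0.8)
        rep = allocation_index(model, ds)
        assert rep.shares.sum() == pytest.approx(1.0)
        assert (rep.shares >= 0).all()
        assert rep.super_shares == pytest.approx(
            rep.shares.reshape(3, 3).sum(axis=1))


class TestCentroidDecoder:
    def test_disjoint_signatures_decode_perfectly(self):
        X = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        y = np.array([0, 0, 1, 1])
        dec = fit_centroid_decoder(X, y)
        assert decoder_error(dec, X, y) == 0.0
        assert decode(dec, [0, 1]) == 1

    def test_tie_goes_to_lowest_category_index(self):
        dec = fit_centroid_decoder(np.array([[0.0, 0.0], [1.0, 1.0]]),
                                   np.array([0, 1]))
        # (1, 0) is exactly equidistant from both centroids
        assert decode(dec, [1.0, 0.0]) == 0

    def test_matches_sklearn_nearest_centroid(self):
        from sklearn.neighbors import NearestCentroid
        rng = np.random.default_rng(3)
        X = rng.normal(size=(120, 7))
        y = rng.integers(0, 4, 120)
        Xt = rng.normal(size=(50, 7))
        ours = fit_centroid_decoder(X, y).predict(Xt)
        ref = NearestCentroid().fit(X, y).predict(Xt)
        assert (ours == ref).all()

    def test_unseen_category_rejected(self):
        dec = fit_centroid_decoder(np.eye(2), np.array([0, 1]))
        with pytest.raises(ValueError, match="unseen"):
            decoder_error(dec, np.eye(2), np.array([0, 2]))


class TestStatisticalDependence:
    def test_independent_fair_coins_are_zero(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        assert statistical_dependence(X) == pytest.approx(0.0, abs=1e-12)

    def test_perfectly_correlated_coins_are_one_bit(self):
        X = np.array([[0, 0], [1, 1]])
        assert statistical_dependence(X) == pytest.approx(1.0)

    def test_explicit_frequencies(self):
        # same multiset expressed by weights instead of multiplicity
        X = np.array([[0, 0], [1, 1], [1, 0]])
        w = np.array([0.25, 0.25, 0.5])
        Xm = np.array([[0, 0], [1, 1], [1, 0], [1, 0]])
        assert statistical_dependence(X, w) == pytest.approx(
            statistical_dependence(Xm))
        with pytest.raises(ValueError, match="sum to 1"):
            statistical_dependence(X, np.array([0.5, 0.5, 0.5]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_non_negative_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        X = (rng.random((rng.integers(2, 30), rng.integers(1, 6))) < 0.4)
        dep = statistical_dependence(X.astype(np.uint8))
        p = X.mean(axis=0)
        mask = (p > 0) & (p < 1)
        marginal = -(p[mask] * np.log2(p[mask])
                     + (1 - p[mask]) * np.log2(1 - p[mask])).sum()
        assert -1e-9 <= dep <= marginal + 1e-9


class TestSizeCurves:
    def test_full_pool_collapses_repeats(self):
        ds = make_dataset_B("B1", 5)
        test = make_dataset_B("B1", 6)
        rng = np.random.default_rng(1)
        c = (rng.random((12, 390)) < 0.08).astype(np.uint8)
        model = make_probe_model(c, np.full((12, 390), 0.35), theta=0.8)
        cur = network_size_curves(model, ds, test, sizes=(12,),
                                  n_repeats=50, seed=0)
        assert cur.loc[0, "n_repeats"] == 1
        assert cur.loc[0, "error_se"] == 0.0

    def test_oversized_subset_rejected(self):
        ds = make_dataset_B("B1", 5)
        model = make_probe_model(np.ones((4, 390)), np.ones((4, 390)),
                                 theta=0.8)
        with pytest.raises(ValueError, match="exceeds"):
            network_size_curves(model, ds, ds, sizes=(5,))

    def test_firing_representation_option(self):
        ds = make_dataset_B("B1", 5)
        test = make_dataset_B("B1", 6)
        rng = np.random.default_rng(1)
        c = (rng.random((15, 390)) < 0.08).astype(np.uint8)
        model = make_probe_model(c, np.full((15, 390), 0.35), theta=0.8)
        a = network_size_curves(model, ds, test, sizes=(8,), n_repeats=5,
                                seed=3, decoder_inputs="firing")
        b = network_size_curves(model, ds, test, sizes=(8,), n_repeats=5,
                                seed=3, decoder_inputs="excitation")
        # same subsets, same dependence; decoding differs in general
        assert a.loc[0, "dependence"] == b.loc[0, "dependence"]
        with pytest.raises(ValueError, match="decoder_inputs"):
            network_size_curves(model, ds, test, sizes=(8,),
                                decoder_inputs="analog")


class TestExclusivity:
    def _b1(self):
        return make_dataset_B("B1", 9)

    def test_constructed_exclusive_and_shared_neurons(self):
        ds = self._b1()
        srm = ds.subregions
        n1 = np.zeros(390)
        n1[srm.lines_of(1, 1)[:10]] = 0.3   # inside category A exclusive
        n2 = np.zeros(390)
        n2[srm.lines_of(3, 7)[:10]] = 0.3   # triple overlap of G, H, J
        c = (np.vstack([n1, n2]) > 0).astype(np.uint8)
        model = make_probe_model(c, np.vstack([n1, n2]), theta=0.8)
        rep = exclusivity_counts(model, ds, probe_theta=2.4)
        assert rep.category_exclusive[0] == 1        # neuron 1 -> A only
        assert rep.category_nonexclusive[6:9].tolist() == [1, 1, 1]
        assert rep.cross_super_firers == 0
        # neuron 1 straddles no sub-region boundary: exclusive to I-1
        idx = rep.subregion_ids.index((1, 1))
        assert rep.subregion_exclusive[idx] == 1
        # neuron 2 fires only the III-7 probe among sub-regions
        idx7 = rep.subregion_ids.index((3, 7))
        assert rep.subregion_exclusive[idx7] == 1

    def test_super_category_assignment(self):
        ds = self._b1()
        srm = ds.subregions
        rows = []
        for sc in (1, 2, 3):
            v = np.zeros(390)
            v[srm.lines_of(sc, 1)[:10]] = 0.5
            rows.append(v)
        rows.append(np.zeros(390))           # silent neuron -> unassigned
        c = (np.vstack(rows) > 0).astype(np.uint8)
        model = make_probe_model(c, np.vstack(rows), theta=0.8)
        assert assign_super_category(model, ds).tolist() == [1, 2, 3, 0]

    def test_requires_subregion_map(self):
        from adsyn.datasets import make_dataset_A
        model = make_probe_model(np.ones((2, 80)), np.ones((2, 80)),
                                 theta=3.0)
        with pytest.raises(ValueError, match="sub-region"):
            exclusivity_counts(model, make_dataset_A(1))
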