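"""Presence thresholds, coverage fractions, sharing classes, singletons
and the Poisson detection-miss probability."""

import math

import numpy as np
import pandas as pd
import pytest

import txturn
from txturn.presence import PresenceMatrix, singleton_presence


def _toy_counts(cols: dict, taxa=None):
    counts = pd.DataFrame(cols)
    taxa = taxa or {s: s for s in counts.columns}
    samples = pd.DataFrame(
        {"taxon": [taxa[s] for s in counts.columns], "tissue": "x",
         "replicate": 0},
        index=pd.Index(list(counts.columns), name="sample_id"))
    return txturn.CountMatrix(counts=counts, samples=samples)


def _full_mask(n):
    return txturn.CommonGenomeMask(np.ones(n, dtype=bool), (), 1)


class TestBinarize:
    @pytest.mark.parametrize("count,tau,expected", [
        (0, 1, 0), (10, 10, 1), (99, 100, 0), (1, 1, 1), (100, 100, 1)])
    def test_at_least_semantics(self, count, tau, expected):
        cm = _toy_counts({"A": [count], "B": [0]})
        pm = txturn.binarize(cm, tau, _full_mask(1))
        assert pm.values.iloc[0]["A"] == expected

    def test_invalid_tau(self):
        cm = _toy_counts({"A": [1]})
        with pytest.raises(ValueError):
            txturn.binarize(cm, 0, _full_mask(1))

    def test_mask_restriction(self):
        cm = _toy_counts({"A": [5, 5, 5]})
        mask = txturn.CommonGenomeMask(np.array([True, False, True]), (), 1)
        pm = txturn.binarize(cm, 1, mask)
        assert pm.n_windows == 2

    def test_tissue_aggregation_before_threshold(self):
        # two tissues of the same taxon with 1 read each: present at tau=2
        cm = _toy_counts({"s1": [1], "s2": [1]}, taxa={"s1": "T", "s2": "T"})
        pm = txturn.binarize(cm, 2, _full_mask(1))
        assert pm.values.iloc[0]["T"] == 1

    def test_threshold_monotonicity(self, small_dataset, small_mask):
        fracs = []
        for tau in (1, 10, 100):
            pm = txturn.binarize(small_dataset.counts, tau, small_mask)
            fracs.append(txturn.coverage_fraction(pm))
        for lo, hi in zip(fracs[1:], fracs[:-1]):
            assert (lo <= hi + 1e-12).all()


class TestCoverageFraction:
    def test_direct_ratio_and_union_bound(self):
        vals = pd.DataFrame({"A": [1, 1, 1, 1, 1, 0, 0, 0, 0, 0],
                             "B": [0, 0, 0, 0, 0, 1, 1, 0, 0, 0]})
        pm = PresenceMatrix(values=vals, tau=1)
        frac = txturn.coverage_fraction(pm)
        assert frac["A"] == 0.5
        assert frac["B"] == 0.2
        assert frac["union"] == 0.7
        assert frac["union"] >= frac.drop("union").max()

    def test_empty_mask_errors(self):
        pm = PresenceMatrix(values=pd.DataFrame({"A": []}, dtype=np.int8), tau=1)
        with pytest.raises(ValueError):
            txturn.coverage_fraction(pm)


class TestClassifySharing:
    def test_class_definitions(self):
        rows = np.zeros((3, 10), dtype=np.int8)
        rows[0, 0] = 1          # single
        rows[1, :] = 1          # all
        rows[2, :5] = 1         # intermediate
        pm = PresenceMatrix(values=pd.DataFrame(rows, columns=[f"t{i}" for i in range(10)]), tau=1)
        prof = txturn.classify_sharing(pm)
        assert list(prof.per_window["sharing_class"]) == ["single", "all",
                                                          "intermediate"]

    def test_partition_identity(self, small_presence):
        prof = txturn.classify_sharing(small_presence)
        n_expressed = int((small_presence.values.sum(axis=1) > 0).sum())
        assert int(prof.class_counts.sum()) == n_expressed

    def test_single_taxon_errors(self):
        pm = PresenceMatrix(values=pd.DataFrame({"A": [1, 0]}), tau=1)
        with pytest.raises(ValueError):
            txturn.classify_sharing(pm)

    def test_all_class_enriched_for_high_coverage(self, small_dataset,
                                                  small_mask):
        """The conserved high-expression core makes all-taxa windows richer
        in >=100-read coverage than single-taxon windows."""
        pms = {tau: txturn.binarize(small_dataset.counts, tau, small_mask)
               for tau in (1, 10, 100)}
        prof = txturn.classify_sharing(pms[1], {10: pms[10], 100: pms[100]})
        tab = prof.by_threshold
        frac100_all = tab.loc["all", 100] / tab.loc["all", 1]
        frac100_single = tab.loc["single", 100] / max(tab.loc["single", 1], 1)
        assert frac100_all > frac100_single


class TestTaxonSpecificHighExpression:
    @pytest.mark.parametrize("counts,expected_hit", [
        ([60, 0, 0], True),    # high and exclusive
        ([60, 1, 0], False),   # present elsewhere
        ([50, 0, 0], False),   # strict > boundary
    ])
    def test_exclusivity_and_threshold(self, counts, expected_hit):
        taxa = ["A", "B", "C"]
        cm = _toy_counts({t: [c] for t, c in zip(taxa, counts)})
        pm = txturn.binarize(cm, 1, _full_mask(1))
        hits = txturn.taxon_specific_high_expression(cm, pm, min_reads=50)
        assert (len(hits["A"]) == 1) == expected_hit


class TestSingletons:
    def test_redetection_flags(self):
        cm = _toy_counts({"a": [1, 1, 0], "b": [3, 0, 5]})
        rep = txturn.singleton_redetection(cm)
        row = rep.per_sample.loc["a"]
        assert row["n_singletons"] == 2
        assert row["n_redetected"] == 1    # window 0 seen in b
        assert row["n_unique"] == 1        # window 1 unique
        assert rep.dataset_unique_windows["a"] == [1]

    def test_no_singletons(self):
        cm = _toy_counts({"a": [0, 2], "b": [0, 2]})
        rep = txturn.singleton_redetection(cm)
        assert (rep.per_sample["n_singletons"] == 0).all()
        assert (rep.per_sample["frac_unique"] == 0.0).all()

    def test_singleton_presence_matrix(self):
        cm = _toy_counts({"A": [1, 2, 0]})
        pm = singleton_presence(cm, _full_mask(3))
        assert list(pm.values["A"]) == [1, 0, 0]


class TestDetectionMissProbability:
    def test_poisson_zero_class(self):
        assert txturn.detection_miss_probability(1, 1) == pytest.approx(
            math.exp(-1))
        assert txturn.detection_miss_probability(1, 9) == pytest.approx(
            math.exp(-9))
        assert txturn.detection_miss_probability(0, 5) == 1.0

    def test_collapsibility_and_monotonicity(self):
        assert txturn.detection_miss_probability(0.7, 4) == pytest.approx(
            txturn.detection_miss_probability(2.8, 1))
        probs = [txturn.detection_miss_probability(lam, 2)
                 for lam in (0.5, 1.0, 2.0)]
        assert probs == sorted(probs, reverse=True)

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            txturn.detection_miss_probability(-1, 1)
        with pytest.raises(ValueError):
            txturn.detection_miss_probability(1, 0)

    def test_simulated_zero_fraction_matches(self, small_dataset):
        """In the simulator, transcribed windows at total mean m are missed
        at rate exp(-m): spot-check via a fresh tiny model with lambda*d=1."""
        model = txturn.TurnoverModel(n_windows=20_000, seed=3,
                                     lognorm_mu=0.0, lognorm_sigma=0.0,
                                     depth=1.0, n_tissues=1,
                                     core_fraction=0.0)
        ds = txturn.simulate_dataset(model)
        pres = ds.true_presence.iloc[:, 0].to_numpy().astype(bool)
        counts = ds.counts.counts.iloc[:, 0].to_numpy()
        zero_frac = (counts[pres] == 0).mean()
        n = pres.sum()
        se = np.sqrt(math.exp(-1) * (1 - math.exp(-1)) / n)
        assert abs(zero_frac - math.exp(-1)) < 3 * se
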