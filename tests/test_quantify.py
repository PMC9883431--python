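import numpy as np
import pandas as pd
import pytest

import zegselect as z
from zegselect.locus_model import AlleleKind
from zegselect.quantify import (
    AlleleCallTable,
    QuantifyError,
    kind_of_key,
)
from zegselect.readproc import ReadCall


def _call(key):
    return ReadCall(category=kind_of_key(key), allele_key=key)


def _table(rows, ki_bit=None):
    """rows: {embryo: {allele_key: count}}"""
    counts = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    return AlleleCallTable(counts=counts, ki_bit=ki_bit)


class TestTabulate:
    def test_empty_input(self):
        table = z.tabulate({})
        assert table.counts.empty

    def test_counts_conserve_reads(self):
        calls = {
            "e1": [_call("WT")] * 7 + [_call("del3@108")] * 3,
            "e2": [_call("WT")] * 5,
        }
        table = z.tabulate(calls)
        assert int(table.totals.sum()) == 15
        assert table.counts.loc["e1", "del3@108"] == 3

    def test_hand_tallied_mixed_fixture(self):
        """20 reads tallied by hand across categories and embryos."""
        calls = {
            "e1": (
                [_call("WT")] * 6
                + [_call("del2@109")] * 4
                + [_call("HDR[101]")] * 2
                + [_call("OTHER_SUB")]
            ),
            "e2": [_call("WT")] * 3 + [_call("insA@110")] * 4,
        }
        table = z.tabulate(calls, ki_bit=2)
        assert table.counts.loc["e1"].to_dict() == {
            "WT": 6, "del2@109": 4, "HDR[101]": 2, "OTHER_SUB": 1, "insA@110": 0,
        }
        assert table.counts.loc["e2", "insA@110"] == 4
        # column order: WT, HDR, indels by global count, OTHER
        assert table.allele_keys[0] == "WT"
        assert table.allele_keys[-1] == "OTHER_SUB"
        assert table.allele_keys[2:4] == ["del2@109", "insA@110"]


class TestFilterMinReads:
    def test_boundary_99_dropped_100_kept(self):
        table = _table({"lo": {"WT": 99}, "hi": {"WT": 100}})
        filtered, dropped = z.filter_min_reads(table, min_total=100)
        assert dropped == ["lo"]
        assert filtered.embryos == ["hi"]
        assert filtered.dropped_embryos == ("lo",)

    def test_zero_threshold_is_identity(self):
        table = _table({"a": {"WT": 5}, "b": {"WT": 0}})
        filtered, dropped = z.filter_min_reads(table, min_total=0)
        assert dropped == [] and filtered.embryos == ["a", "b"]

    def test_surviving_rows_unchanged(self):
        table = _table({"a": {"WT": 150, "del1@9": 30}, "b": {"WT": 20}})
        filtered, _ = z.filter_min_reads(table, min_total=100)
        pd.testing.assert_series_equal(filtered.counts.loc["a"], table.counts.loc["a"])


class TestSef:
    def test_single_allele_fraction(self):
        table = _table({"e": {"HDR[1]": 5, "WT": 95}}, ki_bit=0)
        assert z.sef(table, "e", "KI") == pytest.approx(0.05)

    def test_all_indels_sums_indel_and_imperfect_columns(self):
        table = _table(
            {"e": {"WT": 80, "del2@5": 10, "insA@7": 5, "HDR[10]+del1@3": 5}},
            ki_bit=0,
        )
        assert z.sef(table, "e", "all_indels") == pytest.approx(0.20)

    def test_zero_count_selector(self):
        table = _table({"e": {"WT": 10}})
        assert z.sef(table, "e", "del5@3") == 0.0

    def test_unknown_embryo_errors(self):
        with pytest.raises(QuantifyError):
            z.sef(_table({"e": {"WT": 1}}), "nope", "WT")

    def test_category_fractions_partition_unity(self, small_experiment):
        _, result = small_experiment
        table = result.tables["WE"]
        for e in table.embryos:
            ki = z.sef(table, e, "KI")
            indels = z.sef(table, e, "all_indels")
            wt = z.sef(table, e, "WT")
            other = z.sef(table, e, "OTHER_SUB")
            hdr_no_ki = sum(
                z.sef(table, e, k)
                for k in table.allele_keys
                if kind_of_key(k) is AlleleKind.HDR
                and k not in z.quantify._selector_columns(table, "KI")
            )
            assert ki + indels + wt + other + hdr_no_ki == pytest.approx(1.0)


class TestAverageSef:
    def test_unweighted_mean(self):
        table = _table({"a": {"del1@9": 1, "WT": 99}, "b": {"del1@9": 3, "WT": 97}})
        assert z.average_sef(table, "del1@9") == pytest.approx(0.02)

    def test_empty_subset_errors(self):
        with pytest.raises(QuantifyError, match="empty"):
            z.average_sef(_table({"a": {"WT": 1}}), "WT", embryos=[])

    def test_mean_of_ratios_differs_from_pooled_ratio(self):
        """Skewed depths: averaging per-embryo SEFs is not the pooled SEF."""
        table = _table({"deep": {"del1@9": 500, "WT": 500}, "shallow": {"del1@9": 0, "WT": 10}})
        mean_of_ratios = z.average_sef(table, "del1@9")
        pooled = table.counts["del1@9"].sum() / table.counts.values.sum()
        assert mean_of_ratios == pytest.approx(0.25)
        assert mean_of_ratios != pytest.approx(pooled)


class TestTopIndels:
    def test_fewer_than_n_returns_all(self):
        table = _table({"e": {"del1@9": 5, "del2@9": 3, "insA@9": 1, "WT": 91}})
        assert len(z.top_indels(table, n=10)) == 3

    def test_n_one_returns_argmax(self):
        table = _table({"e": {"del1@9": 5, "del2@9": 8, "WT": 87}})
        assert z.top_indels(table, n=1) == ["del2@9"]

    def test_tie_broken_by_key_order(self):
        table = _table({"e": {"del2@9": 5, "del1@9": 5, "WT": 90}})
        assert z.top_indels(table, n=1) == ["del1@9"]


class TestFrequencyClasses:
    def test_class_assignment_with_strict_outer_bounds(self):
        # average SEFs: 0.64% (low), exactly 1% (middle), 5.96% (high)
        table = _table(
            {
                "e": {"a": 64, "b": 100, "c": 596, "WT": 9240},
            }
        )
        classes = z.frequency_classes(table, ["a", "b", "c"])
        assert classes["a"] == "<1%"
        assert classes["b"] == "1-5%"
        assert classes["c"] == ">5%"

    def test_bounds_must_increase(self):
        with pytest.raises(QuantifyError):
            z.frequency_classes(_table({"e": {"WT": 1}}), [], bounds=(0.05, 0.01))


class TestIncorporationByDistance:
    def test_single_marker_reads(self, lqts):
        # all HDR reads carry only the 1-bp marker (vector position 0)
        table = _table({"e": {"HDR[1000]": 10, "WT": 90}}, ki_bit=2)
        df = z.incorporation_by_distance(table, lqts)
        by_dist = df.set_index("distance_bp")["mean_incorporation"]
        assert by_dist[1] == pytest.approx(0.10)
        assert by_dist[3] == 0.0 and by_dist[5] == 0.0 and by_dist[6] == 0.0

    def test_equals_count_weighted_column_means(self, lqts):
        table = _table(
            {"e1": {"HDR[1100]": 4, "HDR[1010]": 4, "WT": 92},
             "e2": {"HDR[1100]": 10, "WT": 90}},
            ki_bit=2,
        )
        df = z.incorporation_by_distance(table, lqts)
        by_dist = df.set_index("distance_bp")["mean_incorporation"]
        # marker 0 (1 bp): e1 8/100, e2 10/100 -> 0.09
        assert by_dist[1] == pytest.approx(0.09)
        # marker 1 (3 bp): e1 4/100, e2 10/100 -> 0.07
        assert by_dist[3] == pytest.approx(0.07)

    def test_recovers_distance_decay_from_simulation(self, lqts):
        """Configured tract decay is recovered as monotone decreasing
        incorporation rates when averaged over enough mosaic embryos."""
        params = z.SimulationParams(
            n_embryos=500, mean_ki_fraction=0.2, dirichlet_concentration=50.0, seed=21
        )
        spectrum = z.default_spectrum(lqts, params)
        rows = {}
        for i in range(params.n_embryos):
            profile = z.simulate_embryo_profile(params, i, spectrum)
            rows[profile.embryo_id] = {
                k: int(round(f * 10_000)) for k, f in profile.frequencies.items()
            }
        table = _table(rows, ki_bit=lqts.ki_marker_index)
        df = z.incorporation_by_distance(table, lqts)
        rates = df["mean_incorporation"].to_numpy()  # ordered by distance
        assert (np.diff(rates) < 0).all()
        # and close to the configured marginals of the tract model
        from zegselect.synthetic_data import hdr_pattern_weights

        weights = hdr_pattern_weights(lqts, params.tract_p_max, params.tract_decay_bp)
        order = np.argsort([z.marker_distance(m, lqts) for m in lqts.markers])
        expected = np.array(
            [
                params.mean_ki_fraction
                * sum(w for bits, w in weights.items() if bits[i])
                for i in order
            ]
        )
        assert np.allclose(rates, expected, atol=0.04)


class TestCrisprStat:
    def test_pure_wildtype_zero_percent(self):
        peaks = z.PeakTable(intensities={200: 100.0}, wt_length=200)
        assert z.crispr_stat_estimate(peaks) == 0.0

    def test_even_split_fifty_percent(self):
        peaks = z.PeakTable(intensities={200: 50.0, 195: 50.0}, wt_length=200)
        assert z.crispr_stat_estimate(peaks) == pytest.approx(50.0)

    def test_zero_intensity_errors(self):
        peaks = z.PeakTable(intensities={200: 0.0}, wt_length=200)
        with pytest.raises(QuantifyError):
            z.crispr_stat_estimate(peaks)

    def test_estimate_non_increasing_in_blur(self, lqts):
        spectrum = z.default_spectrum(lqts, z.SimulationParams())
        del1 = next(k for k in spectrum.by_key if k.startswith("del1@"))
        profile = z.EmbryoProfile("e", {"WT": 0.6, del1: 0.4})
        sigmas = [0.0, 0.5, 1.0, 1.5, 2.0]
        ests = [
            z.crispr_stat_estimate(
                z.simulate_fragment_peaks(profile, lqts, spectrum, s)
            )
            for s in sigmas
        ]
        assert ests[0] == pytest.approx(40.0)
        assert all(a >= b - 1e-9 for a, b in zip(ests, ests[1:]))
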