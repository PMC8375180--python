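"""Feature aggregation, region scoring, imputation, matrix assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from xcnv.core import CNVRecord, CNVType
from xcnv.features import (
    FEATURE_SCHEMA,
    FeatureMatrix,
    GeneScoreTable,
    RegionSet,
    ScoreTrack,
    aggregate_positional,
    build_feature_matrix,
    cdts_feature,
    column_minima,
    gene_score,
    impute_missing,
    region_fraction,
    universal_features,
)
from xcnv.popfreq import AFDatabase, AFEntry
from xcnv.core import Interval


def track(pairs, name="t"):
    return ScoreTrack(name, {("1", p): v for p, v in pairs})


def cnv(start, end, cnv_type="loss"):
    return CNVRecord("1", start, end, cnv_type)


class TestAggregatePositional:
    def test_mean_over_covered_positions(self):
        t = track([(100, 2.0), (200, 4.0), (900, 99.0)])
        assert aggregate_positional(cnv(50, 300), t) == 3.0

    def test_no_covered_position_is_missing(self):
        assert math.isnan(aggregate_positional(cnv(50, 60), track([(100, 2.0)])))

    def test_single_position_identity(self):
        assert aggregate_positional(cnv(90, 110), track([(100, 7.5)])) == 7.5

    def test_total_denominator_mode(self):
        t = track([(100, 2.0), (200, 4.0)])
        got = aggregate_positional(cnv(1, 100_0), t, denominator="total")
        assert got == pytest.approx(6.0 / 1000)

    def test_matches_per_base_loop_on_dense_track(self):
        rng = np.random.default_rng(0)
        pos_scores = [(p, float(rng.normal())) for p in range(1, 501)]
        t = track(pos_scores)
        c = cnv(101, 350)
        oracle = np.mean([v for p, v in pos_scores if c.start <= p <= c.end])
        assert aggregate_positional(c, t) == pytest.approx(oracle)

    def test_invariant_to_input_order(self):
        pairs = [(300, 1.0), (100, 5.0), (200, 3.0)]
        assert aggregate_positional(cnv(1, 400), track(pairs)) == \
               aggregate_positional(cnv(1, 400), track(list(reversed(pairs))))


class TestGeneScore:
    table = GeneScoreTable("pLI", [("1", 100, 200, "A", 0.1), ("1", 300, 400, "B", 0.99)])

    def test_max_mode(self):
        assert gene_score(cnv(50, 500), self.table, "max") == 0.99

    def test_mean_mode(self):
        assert gene_score(cnv(50, 500), self.table, "mean") == pytest.approx(0.545)

    def test_no_overlap_missing(self):
        assert math.isnan(gene_score(cnv(1000, 2000), self.table))

    def test_single_gene_same_either_mode(self):
        assert gene_score(cnv(50, 250), self.table, "max") == 0.1
        assert gene_score(cnv(50, 250), self.table, "mean") == 0.1


class TestRegionFraction:
    def test_overlap_fraction(self):
        rs = RegionSet("PLS", [("1", 101, 350)])
        assert region_fraction(cnv(101, 1100), rs) == pytest.approx(0.25)

    def test_no_overlap_zero(self):
        rs = RegionSet("PLS", [("1", 5000, 6000)])
        assert region_fraction(cnv(1, 1000), rs) == 0.0

    def test_literal_mode_is_length_ratio(self):
        rs = RegionSet("PLS", [("1", 200, 699)])  # 500 bp element
        assert region_fraction(cnv(1, 1000), rs, mode="length_ratio") == pytest.approx(2.0)

    def test_bounded_and_merge_invariant(self):
        whole = RegionSet("PLS", [("1", 101, 400)])
        split = RegionSet("PLS", [("1", 101, 250), ("1", 251, 400)])
        overlapping = RegionSet("PLS", [("1", 101, 300), ("1", 200, 400)])
        c = cnv(1, 1000)
        want = region_fraction(c, whole)
        assert region_fraction(c, split) == pytest.approx(want)
        assert region_fraction(c, overlapping) == pytest.approx(want)
        assert 0.0 <= want <= 1.0


class TestCDTS:
    thresholds = {1: -2.0, 5: -1.0}

    def test_all_below(self):
        t = track([(100, -3.0), (200, -2.5)], name="CDTS")
        assert cdts_feature(cnv(1, 300), t, 1, self.thresholds) == 1.0

    def test_none_below(self):
        t = track([(100, 0.0), (200, 1.0)], name="CDTS")
        assert cdts_feature(cnv(1, 300), t, 1, self.thresholds) == 0.0

    def test_fractional_count(self):
        pairs = [(i * 10, -3.0 if i <= 3 else 0.0) for i in range(1, 11)]
        t = track(pairs, name="CDTS")
        assert cdts_feature(cnv(1, 200), t, 1, self.thresholds) == pytest.approx(0.3)

    def test_unknown_percentile_rejected(self):
        t = track([(100, 0.0)], name="CDTS")
        with pytest.raises(ValueError):
            cdts_feature(cnv(1, 200), t, 10, self.thresholds)

    def test_no_coverage_missing(self):
        t = track([(10_000, 0.0)], name="CDTS")
        assert math.isnan(cdts_feature(cnv(1, 200), t, 1, self.thresholds))


class TestUniversalFeatures:
    db = AFDatabase(
        entries=[AFEntry(Interval("1", 1, 10_000), CNVType.LOSS, 0.02)],
        group_sizes={"NFE": 100},
    )

    def test_loss_af_lands_in_loss_column(self):
        assert universal_features(cnv(1, 10_000, "loss"), self.db) == (10_000, 0.0, 0.0, 0.02)

    def test_gain_without_match(self):
        assert universal_features(cnv(1, 10_000, "gain"), self.db) == (10_000, 1.0, 0.0, 0.0)

    def test_type_encoding_differs(self):
        g = universal_features(cnv(1, 500, "gain"), None)
        l = universal_features(cnv(1, 500, "loss"), None)
        assert g[1] != l[1] and g[0] == l[0]


def fm_from(data: pd.DataFrame) -> FeatureMatrix:
    full = pd.DataFrame(0.0, index=data.index, columns=FEATURE_SCHEMA)
    for c in data.columns:
        full[c] = data[c]
    return FeatureMatrix(data=full, mask=full.isna())


class TestImputation:
    def test_train_time_minimum(self):
        m = fm_from(pd.DataFrame({"CADD": [0.2, np.nan, 0.5]}))
        out = impute_missing(m)
        assert list(out.data["CADD"]) == [0.2, 0.2, 0.5]
        assert not out.mask.any().any()

    def test_fully_observed_unchanged_and_idempotent(self):
        m = fm_from(pd.DataFrame({"CADD": [0.2, 0.3]}))
        out = impute_missing(m)
        pd.testing.assert_frame_equal(out.data, m.data)
        again = impute_missing(out)
        pd.testing.assert_frame_equal(again.data, out.data)

    def test_predict_time_uses_training_minima(self):
        train = fm_from(pd.DataFrame({"CADD": [0.4, 0.9]}))
        batch = fm_from(pd.DataFrame({"CADD": [np.nan, 0.1]}))
        out = impute_missing(batch, reference=train)
        assert list(out.data["CADD"]) == [0.4, 0.1]

    def test_all_missing_column_errors_with_name(self):
        m = fm_from(pd.DataFrame({"CADD": [np.nan, np.nan]}))
        with pytest.raises(ValueError, match="CADD"):
            column_minima(m)

    def test_schema_enforced(self):
        bad = pd.DataFrame({"CADD": [1.0]})
        with pytest.raises(ValueError):
            FeatureMatrix(data=bad, mask=bad.isna())


class TestBuildFeatureMatrix:
    def test_schema_shape(self, toy_bundle):
        fm = build_feature_matrix([], toy_bundle)
        assert fm.data.shape == (0, 30)
        assert list(fm.data.columns) == FEATURE_SCHEMA

    def test_group_sizes_sum_to_thirty(self):
        from xcnv.features import FEATURE_GROUPS

        sizes = {k: len(v) for k, v in FEATURE_GROUPS.items()}
        assert sizes == {"universal": 4, "coding": 13, "noncoding": 8, "genome_wide": 5}

    def test_duplicate_cnv_identical_rows(self, toy_bundle, loss_record):
        fm = build_feature_matrix([loss_record, loss_record], toy_bundle)
        pd.testing.assert_series_equal(fm.data.iloc[0], fm.data.iloc[1], check_names=False)

    def test_missing_source_named(self, toy_bundle, loss_record):
        del toy_bundle.tracks["CADD"]
        with pytest.raises(ValueError, match="CADD"):
            build_feature_matrix([loss_record], toy_bundle)

    def test_gene_count_feature(self, toy_bundle, loss_record):
        fm = build_feature_matrix([loss_record], toy_bundle)
        assert fm.data.loc[0, "n_coding_genes"] == 2.0
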