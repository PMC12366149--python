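"""Feature harmonization: normalization, missingness, pre-selection."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_call
from svmeta.features import (
    FeatureMatrix,
    basic_feature_matrix,
    build_feature_matrix,
    correlation_select,
    default_feature_registry,
    normalize_metric,
)
from svmeta.merge import merge_calls
from svmeta.types import SequencingStats, SVType

STATS = SequencingStats(mean_coverage=35.0, read_length=150.0)


@pytest.mark.parametrize(
    "value, kind, expected",
    [
        (70.0, "coverage", 2.0),
        (15.0, "read_length", 0.1),
        (0.7, "none", 0.7),
    ],
)
def test_normalize_metric(value, kind, expected):
    assert normalize_metric(value, kind, STATS) == pytest.approx(expected)


def test_registry_column_counts_match_model_design():
    # 34 caller metrics + svlen for deletions; 35 + svlen for insertions
    assert len(default_feature_registry(SVType.DEL).column_names()) == 35
    assert len(default_feature_registry(SVType.INS).column_names()) == 36


def test_unsupported_caller_rejected_by_registry():
    from svmeta.features import FeatureRegistry

    with pytest.raises(ValueError, match="not allowed"):
        FeatureRegistry(
            svtype=SVType.INS, entries=(("lumpy", "qual", "none"),)
        )


def _two_caller_setup():
    a = make_call(id="a", caller="manta", metrics={"qual": 120.0, "paired_read_support": 70.0})
    b = make_call(id="b", caller="delly", pos=900_000, end=901_000, svlen=1001,
                  metrics={"paired_read_support": 35.0})
    calls = {"manta": [a], "delly": [b]}
    consensus = merge_calls(calls)
    return calls, consensus


def test_absent_caller_yields_missing_never_zero():
    calls, consensus = _two_caller_setup()
    registry = default_feature_registry(SVType.DEL)
    fm = build_feature_matrix(consensus, calls, registry, STATS)
    row_a = fm.df.iloc[[i for i, c in enumerate(consensus) if ("manta", "a") in c.members][0]]
    assert row_a["manta.qual"] == pytest.approx(120.0)
    assert row_a["manta.paired_read_support"] == pytest.approx(70.0 / 35.0)
    assert np.isnan(row_a["delly.paired_read_support"])  # absent caller -> NaN


def test_metric_reported_as_none_stays_missing():
    calls, consensus = _two_caller_setup()
    registry = default_feature_registry(SVType.DEL)
    fm = build_feature_matrix(consensus, calls, registry, STATS)
    row_b = fm.df.iloc[[i for i, c in enumerate(consensus) if ("delly", "b") in c.members][0]]
    assert np.isnan(row_b["delly.split_read_support"])


def test_unlisted_registry_caller_warns():
    calls, consensus = _two_caller_setup()
    registry = default_feature_registry(SVType.DEL)
    with pytest.warns(UserWarning, match="absent from inputs"):
        build_feature_matrix(consensus, {"manta": calls["manta"]}, registry, STATS)


def test_basic_matrix_is_svlen_plus_presence_flags():
    calls, consensus = _two_caller_setup()
    bm = basic_feature_matrix(consensus, calls, SVType.DEL)
    assert len(bm.df.columns) == 7  # svlen + six deletion callers
    assert set(bm.df.columns) == {
        "svlen", "presence_breakdancer", "presence_delly", "presence_lumpy",
        "presence_manta", "presence_pindel", "presence_tardis",
    }
    presence = bm.df.filter(like="presence_")
    assert set(np.unique(presence.to_numpy())) <= {0.0, 1.0}


def test_coverage_scale_invariance_is_exact():
    """Multiplying coverage-kind raw metrics and mean coverage by the same
    factor leaves the feature matrix bit-identical."""
    calls, consensus = _two_caller_setup()
    registry = default_feature_registry(SVType.DEL)
    fm1 = build_feature_matrix(consensus, calls, registry, STATS)

    scaled = {
        caller: [
            make_call(
                id=c.id, caller=c.caller, pos=c.pos, end=c.end, svlen=c.svlen,
                metrics={
                    k: (None if v is None else v * 2.0)
                    if any(e == (c.caller, k, "coverage") for e in registry.entries)
                    else v
                    for k, v in c.metrics.items()
                },
            )
            for c in cs
        ]
        for caller, cs in calls.items()
    }
    consensus2 = merge_calls(scaled)
    stats2 = SequencingStats(mean_coverage=70.0, read_length=150.0)
    fm2 = build_feature_matrix(consensus2, scaled, registry, stats2)
    pd.testing.assert_frame_equal(fm1.df, fm2.df)


def test_tsv_round_trip(tmp_path):
    calls, consensus = _two_caller_setup()
    registry = default_feature_registry(SVType.DEL)
    fm = build_feature_matrix(consensus, calls, registry, STATS,
                              labels=[True] * len(consensus))
    path = tmp_path / "features.tsv"
    fm.to_tsv(path)
    back = FeatureMatrix.from_tsv(path)
    pd.testing.assert_frame_equal(fm.df, back.df)
    assert back.labels.tolist() == [True] * len(consensus)
    assert back.registry_hash == fm.registry_hash
    assert back.stats == fm.stats


class TestCorrelationSelect:
    def _matrix(self, df, labels):
        return FeatureMatrix(df=df, labels=pd.Series(labels, index=df.index))

    def test_duplicated_column_keeps_exactly_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        labels = x + rng.normal(size=100) > 0
        df = pd.DataFrame({"a": x, "a_copy": x, "b": rng.normal(size=100)})
        kept = correlation_select(self._matrix(df, labels), r_threshold=0.9)
        assert sum(c in kept for c in ("a", "a_copy")) == 1
        assert "b" in kept

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"const": np.ones(50), "x": rng.normal(size=50)})
        kept = correlation_select(self._matrix(df, rng.random(50) > 0.5))
        assert kept == ["x"]

    def test_independent_features_all_retained(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.normal(size=(500, 10)), columns=[f"f{i}" for i in range(10)]
        )
        labels = rng.random(500) > 0.5
        kept = correlation_select(self._matrix(df, labels), r_threshold=0.9)
        assert kept == list(df.columns)

    def test_all_constant_warns_and_returns_empty(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.zeros(10)})
        with pytest.warns(UserWarning, match="constant"):
            assert correlation_select(self._matrix(df, [True, False] * 5)) == []

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=200)
        df = pd.DataFrame({
            "a": x, "near_a": x + rng.normal(scale=0.05, size=200),
            "b": rng.normal(size=200),
        })
        labels = pd.Series(x > 0, index=df.index)
        kept = correlation_select(self._matrix(df, labels))
        perm = rng.permutation(len(df))
        df2 = df.iloc[perm]
        kept2 = correlation_select(FeatureMatrix(df=df2, labels=labels.iloc[perm]))
        assert kept == kept2
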