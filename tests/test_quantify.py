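"""Cascade quantification: worked examples, invariants, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from junctiso import (
    CascadeQuantifier,
    JunctionCounts,
    aggregate_by_tissue,
    cascade_fractions,
    cterm_fractions,
    e8_variant_fractions,
    nterm_fractions,
    quantify_samples,
)

from conftest import TP63_C_COUNTS, TP63_C_EXPECTED, TP73_C_COUNTS, TP73_C_EXPECTED


class TestWorkedExamples:
    def test_tp63_four_level_cascade(self, tp63):
        got = cterm_fractions(TP63_C_COUNTS, tp63)
        assert got == pytest.approx(TP63_C_EXPECTED, abs=1e-12)
        assert sum(got.values()) == pytest.approx(100.0, abs=1e-9)

    def test_tp73_two_level_cascade(self, tp73):
        got = cterm_fractions(TP73_C_COUNTS, tp73)
        assert got == pytest.approx(TP73_C_EXPECTED, abs=1e-12)
        assert sum(got.values()) == pytest.approx(100.0, abs=1e-9)


class TestNTerminal:
    def test_tp63_testis_like_split(self, tp63):
        got = nterm_fractions({"E3-E4": 96.0, "E3p-E4": 4.0}, tp63)
        assert got == pytest.approx({"TA": 96.0, "dN": 4.0})

    def test_tp73_single_nonzero_branch(self, tp73):
        got = nterm_fractions({"E3-E4": 0.0, "E3p-E4": 0.0, "E3a-E4": 100.0}, tp73)
        assert got == pytest.approx({"TA": 0.0, "dN": 0.0, "I3a": 100.0})

    def test_equal_counts_split_evenly(self, tp63):
        got = nterm_fractions({"E3-E4": 7.0, "E3p-E4": 7.0}, tp63)
        assert got == pytest.approx({"TA": 50.0, "dN": 50.0})


class TestE8Variant:
    def test_seventy_thirty(self, tp63):
        got = e8_variant_fractions({"E8-E9": 70.0, "E8-E9:E8s": 30.0}, tp63)
        assert got == pytest.approx({"E8": 70.0, "E8s": 30.0})

    def test_zero_counts_are_na(self, tp63):
        got = e8_variant_fractions({}, tp63)
        assert all(math.isnan(v) for v in got.values())

    def test_single_read(self, tp63):
        got = e8_variant_fractions({"E8-E9": 1.0}, tp63)
        assert got == pytest.approx({"E8": 100.0, "E8s": 0.0})


class TestNASemantics:
    def test_zero_root_gives_all_na(self, tp73):
        got = cterm_fractions({}, tp73)
        assert all(math.isnan(v) for v in got.values())

    def test_zero_nonroot_denominator_blanks_only_that_subtree(self, tp63):
        # gamma vs non-gamma defined, but nothing to split non-gamma with
        got = cterm_fractions({"E10-E11a": 30.0, "E10-E11": 70.0}, tp63)
        assert got["gamma"] == pytest.approx(30.0)
        assert all(math.isnan(got[k]) for k in ("delta", "beta", "alpha"))

    def test_zero_parent_mass_keeps_children_at_zero(self, tp63):
        got = cterm_fractions({"E10-E11a": 10.0}, tp63)
        assert got == pytest.approx(
            {"gamma": 100.0, "delta": 0.0, "beta": 0.0, "alpha": 0.0}
        )

    def test_partial_flag_in_fraction_table(self, tp63):
        jc_partial = JunctionCounts(
            "p", 10**6, raw={"E10-E11a": 30.0, "E10-E11": 70.0}
        )
        jc_allna = JunctionCounts("q", 10**6, raw={})
        table = quantify_samples([jc_partial, jc_allna], tp63, termini=["C"])
        df = table.data
        assert df[df.unit_id == "p"]["partial"].all()
        # fully undefined terminus is NA but not "partial"
        assert not df[df.unit_id == "q"]["partial"].any()
        assert df[df.unit_id == "q"]["pct"].isna().all()


# -- invariants --------------------------------------------------------------

_counts6 = st.lists(
    st.floats(0, 1e6, allow_nan=False, allow_infinity=False), min_size=6, max_size=6
)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(values=_counts6)
def test_nonna_leaves_sum_to_hundred_or_less(values):
    from junctiso import build_tp63_model

    model = build_tp63_model()
    uids = ["E10-E11a", "E10-E11", "E11-E14", "E11-E12", "E12-E14", "E12-E13"]
    got = cterm_fractions(dict(zip(uids, values)), model)
    finite = [v for v in got.values() if not math.isnan(v)]
    if len(finite) == len(got):
        assert sum(finite) == pytest.approx(100.0, abs=1e-6)
    elif finite:
        assert sum(finite) <= 100.0 + 1e-6


@settings(max_examples=100, deadline=None, derandomize=True)
@given(values=_counts6, c=st.floats(1e-6, 1e6, allow_nan=False, allow_infinity=False))
def test_scale_invariance(values, c):
    from junctiso import build_tp63_model

    model = build_tp63_model()
    uids = ["E10-E11a", "E10-E11", "E11-E14", "E11-E12", "E12-E14", "E12-E13"]
    base = cterm_fractions(dict(zip(uids, values)), model)
    scaled = cterm_fractions(dict(zip(uids, [v * c for v in values])), model)
    for k in base:
        if math.isnan(base[k]):
            assert math.isnan(scaled[k])
        else:
            assert scaled[k] == pytest.approx(base[k], abs=1e-6)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    values=st.lists(st.floats(0.1, 1e4), min_size=6, max_size=6),
    bump=st.floats(0.1, 1e4),
    which=st.integers(0, 5),
)
def test_branch_monotonicity(values, bump, which):
    """Raising one branch junction weakly raises every leaf under it and
    weakly lowers all other leaves."""
    from junctiso import build_tp63_model

    model = build_tp63_model()
    uids = ["E10-E11a", "E10-E11", "E11-E14", "E11-E12", "E12-E14", "E12-E13"]
    under = {
        "E10-E11a": {"gamma"},
        "E10-E11": {"delta", "beta", "alpha"},
        "E11-E14": {"delta"},
        "E11-E12": {"beta", "alpha"},
        "E12-E14": {"beta"},
        "E12-E13": {"alpha"},
    }
    base = cterm_fractions(dict(zip(uids, values)), model)
    bumped_counts = dict(zip(uids, values))
    bumped_counts[uids[which]] += bump
    bumped = cterm_fractions(bumped_counts, model)
    for leaf in base:
        if leaf in under[uids[which]]:
            assert bumped[leaf] >= base[leaf] - 1e-9
        else:
            assert bumped[leaf] <= base[leaf] + 1e-9


# -- sklearn surface ---------------------------------------------------------


class TestCascadeQuantifier:
    def test_transform_matches_function(self, tp63):
        X = pd.DataFrame([TP63_C_COUNTS, {k: 2 * v for k, v in TP63_C_COUNTS.items()}])
        est = CascadeQuantifier(model="TP63", terminus="C").fit()
        out = est.transform(X)
        assert list(out.columns) == est.leaves_
        for col, exp in TP63_C_EXPECTED.items():
            assert out[col].iloc[0] == pytest.approx(exp)
            assert out[col].iloc[1] == pytest.approx(exp)  # scale invariant

    def test_clone_and_params_round_trip(self):
        est = CascadeQuantifier(model="TP73", terminus="N")
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_rejects_negative_counts(self, tp63):
        est = CascadeQuantifier(model="TP63", terminus="C").fit()
        X = pd.DataFrame([{**TP63_C_COUNTS, "E10-E11a": -1.0}])
        with pytest.raises(ValueError, match="non-negative"):
            est.transform(X)

    def test_feature_names_out(self):
        est = CascadeQuantifier(model="TP63", terminus="C").fit()
        assert set(est.get_feature_names_out()) == set(TP63_C_EXPECTED)


# -- tissue aggregation ------------------------------------------------------


def _sample(sid, alpha_reads, beta_reads):
    return JunctionCounts(
        sid, 10**6,
        raw={"E10-E11": alpha_reads + beta_reads, "E11-E12": alpha_reads + beta_reads,
             "E12-E13": alpha_reads, "E12-E14": beta_reads},
    )


class TestAggregateByTissue:
    def test_mean_over_samples(self, tp73):
        table = quantify_samples(
            [_sample("a", 80, 20), _sample("b", 60, 40)], tp73, termini=["C"]
        )
        out = aggregate_by_tissue(table, {"a": "lung", "b": "lung"})
        piv = out.pivot("C")
        assert piv.loc["lung", "alpha"] == pytest.approx(70.0)
        assert piv.loc["lung", "beta"] == pytest.approx(30.0)

    def test_na_samples_are_skipped_with_n_reported(self, tp73):
        empty = JunctionCounts("c", 10**6, raw={})
        table = quantify_samples([_sample("a", 60, 40), empty], tp73, termini=["C"])
        out = aggregate_by_tissue(table, {"a": "lung", "c": "lung"})
        row = out.data[(out.data.isoform == "alpha")].iloc[0]
        assert row["pct"] == pytest.approx(60.0)
        assert row["n_samples"] == 1

    def test_all_na_tissue_is_na(self, tp73):
        empty = JunctionCounts("c", 10**6, raw={})
        table = quantify_samples([empty], tp73, termini=["C"])
        out = aggregate_by_tissue(table, {"c": "lung"})
        assert out.data["pct"].isna().all()
        assert (out.data["n_samples"] == 0).all()

    def test_unannotated_sample_raises(self, tp73):
        table = quantify_samples([_sample("a", 60, 40)], tp73, termini=["C"])
        with pytest.raises(KeyError, match="a"):
            aggregate_by_tissue(table, {})
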