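import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matlm import (
    AnnotationTable,
    SampleTable,
    ValidationError,
    ZSpec,
    ZVariable,
    bin_numeric,
    build_x,
    build_z,
    per_level_effects,
)

CARBON_EDGES = [40, 45, 50, 55, 60, 65, 70]


class TestBinNumeric:
    def test_half_open_bins_match_printed_notation(self):
        # "40 <= Total Carbon < 45" and the open-topped "70 <= Total Carbon"
        assert bin_numeric([44], CARBON_EDGES)[0] == "[40,45)"
        assert bin_numeric([45], CARBON_EDGES)[0] == "[45,50)"
        assert bin_numeric([70], CARBON_EDGES)[0] == "[70,inf)"
        assert bin_numeric([93], CARBON_EDGES)[0] == "[70,inf)"

    def test_value_below_first_edge_is_an_error(self):
        with pytest.raises(ValidationError, match="below"):
            bin_numeric([39], CARBON_EDGES)

    def test_closed_top_rejects_overflow(self):
        with pytest.raises(ValidationError):
            bin_numeric([70], CARBON_EDGES, open_upper=False)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=40, max_value=200, allow_nan=False))
    def test_partition_every_value_gets_exactly_one_bin(self, v):
        labels = bin_numeric([v], CARBON_EDGES)
        assert len(labels) == 1
        lo = float(labels[0][1:].split(",")[0])
        hi_txt = labels[0].split(",")[1][:-1]
        assert lo <= v
        if hi_txt != "inf":
            assert v < float(hi_txt)


@pytest.fixture
def samples():
    df = pd.DataFrame(
        {
            "group": ["control", "case", "case", "control"],
            "fish_oil": ["no", "yes", "no", "yes"],
            "age": [50.0, 61.0, 47.0, 58.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return SampleTable(df, {"group": "categorical", "fish_oil": "categorical",
                            "age": "continuous"})


class TestBuildX:
    def test_two_binary_covariates_with_intercept(self, samples):
        X = build_x(samples, ["group", "fish_oil"], intercept=True)
        assert X.values.shape == (4, 3)
        assert X.column_labels == ["intercept", "group:control", "fish_oil:yes"]
        np.testing.assert_array_equal(X.values[:, 0], 1.0)

    def test_reference_level_override(self, samples):
        X = build_x(samples, ["group"], references={"group": "control"})
        assert X.column_labels == ["intercept", "group:case"]
        np.testing.assert_array_equal(X.values[:, 1], [0, 1, 1, 0])

    def test_continuous_covariate(self, samples):
        X = build_x(samples, ["age"])
        assert X.values.shape == (4, 2)
        np.testing.assert_array_equal(X.values[:, 1], samples.column("age"))

    def test_unknown_reference_level(self, samples):
        with pytest.raises(ValidationError, match="banana"):
            build_x(samples, ["group"], references={"group": "banana"})

    def test_confounded_covariates_raise_rank_error(self):
        df = pd.DataFrame(
            {"a": ["x", "y", "x", "y"], "b": ["u", "v", "u", "v"]},
            index=[f"s{i}" for i in range(4)],
        )
        t = SampleTable(df, {"a": "categorical", "b": "categorical"})
        with pytest.raises(ValidationError, match="rank"):
            build_x(t, ["a", "b"])


@pytest.fixture
def annotations():
    rng = np.random.default_rng(7)
    carbon = rng.integers(40, 80, size=30)
    db = rng.integers(3, 12, size=30)
    sub = np.where(db >= 6, "poly", "mono")
    df = pd.DataFrame(
        {"total_carbon": carbon, "double_bonds": db, "subclass": sub},
        index=[f"met{j}" for j in range(30)],
    )
    return AnnotationTable(
        df,
        {"total_carbon": "continuous", "double_bonds": "continuous",
         "subclass": "categorical"},
    )


class TestBuildZ:
    def test_unadjusted_is_cell_means(self, annotations):
        Z = build_z(annotations, ZSpec([ZVariable("subclass")], "unadjusted"))
        assert Z.values.shape == (30, 2)
        assert set(Z.values.ravel()) <= {0.0, 1.0}
        np.testing.assert_array_equal(Z.values.sum(axis=1), 1.0)
        # columns sum to category counts
        counts = annotations.column("subclass").value_counts()
        for lab, col in zip(Z.column_labels, Z.values.T):
            assert col.sum() == counts[lab.split(":", 1)[1]]

    def test_adjusted_column_count_is_cellmeans_plus_reference(self, annotations):
        spec = ZSpec(
            [
                ZVariable("total_carbon", CARBON_EDGES),
                ZVariable("double_bonds", [3, 6, 9]),
            ],
            "adjusted",
        )
        Z = build_z(annotations, spec)
        # 7 carbon bins (cell means) + (3 - 1) reference-coded db bins
        assert Z.values.shape[1] == 9
        assert np.linalg.matrix_rank(Z.values) == 9
        assert Z.coding == {"total_carbon": "cell_means", "double_bonds": "reference"}
        assert Z.reference_levels["double_bonds"] == "[3,6)"

    def test_single_level_gives_column_of_ones(self):
        df = pd.DataFrame({"cls": ["tg"] * 5}, index=[f"m{j}" for j in range(5)])
        Z = build_z(AnnotationTable(df, {"cls": "categorical"}),
                    ZSpec([ZVariable("cls")], "unadjusted"))
        np.testing.assert_array_equal(Z.values, np.ones((5, 1)))

    def test_empty_bin_dropped_with_warning(self, annotations, caplog):
        # no metabolite has carbon >= 100
        spec = ZSpec([ZVariable("total_carbon", [40, 100])], "unadjusted")
        with caplog.at_level(logging.WARNING, logger="matlm"):
            Z = build_z(annotations, spec)
        assert Z.values.shape[1] == 1
        assert any("empty level" in r.message for r in caplog.records)

    def test_unadjusted_requires_single_variable(self):
        with pytest.raises(ValidationError):
            ZSpec([ZVariable("a"), ZVariable("b")], "unadjusted")

    def test_decreasing_edges_rejected(self):
        with pytest.raises(ValidationError):
            ZVariable("total_carbon", [50, 40])


def test_per_level_effects_restores_reference_row(annotations):
    Z = build_z(
        annotations,
        ZSpec([ZVariable("total_carbon", CARBON_EDGES),
               ZVariable("double_bonds", [3, 6, 9])], "adjusted"),
    )
    inf = pd.DataFrame(
        {
            "x_label": ["fish_oil:yes"] * 9,
            "z_label": Z.column_labels,
            "effect": np.arange(9.0),
            "se": np.full(9, 0.1),
        }
    )
    levels = per_level_effects(inf, Z)
    ref = levels[(levels.z_label == "double_bonds:[3,6)")]
    assert len(ref) == 1
    assert ref.iloc[0].effect == 0.0 and ref.iloc[0].se == 0.0
    assert set(levels.z_label) == {
        "double_bonds:[3,6)", "double_bonds:[6,9)", "double_bonds:[9,inf)"
    }
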