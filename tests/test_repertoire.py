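"""Call-type taxonomy, classification tree and repertoire proportions."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from calltag.exceptions import ClassificationError
from calltag.reference import (
    default_repertoire,
    deployment_summary,
    repertoire_proportions,
)
from calltag.repertoire import (
    BroadTypeClassifier,
    CallFeatures,
    TaxonomyWarning,
    assign_subtype,
    classify_broad,
    classify_calls,
    features_for_label,
    label_to_broad,
    proportional_use,
)


class TestBroadClassification:
    def test_low_first_harmonic_tonal(self):
        assert classify_broad(CallFeatures(1500.0, "tonal")) == "LF tonal"

    def test_high_first_harmonic_tonal(self):
        assert classify_broad(CallFeatures(3000.0, "tonal")) == "HF tonal"

    def test_paired_sequence_beats_everything(self):
        f = CallFeatures(500.0, "pulsed", in_paired_sequence=True)
        assert classify_broad(f) == "paired burst"

    def test_heterogeneous_segments_are_complex(self):
        f = CallFeatures(500.0, "tonal", n_segments=2,
                         segment_structures=("pulsed", "tonal"))
        assert classify_broad(f) == "complex"

    def test_homogeneous_segments_are_not_complex(self):
        f = CallFeatures(500.0, "tonal", n_segments=2,
                         segment_structures=("tonal", "tonal"))
        assert classify_broad(f) == "LF tonal"

    def test_single_pulse_and_pulsed(self):
        assert classify_broad(CallFeatures(400.0, "single_pulse")) == "pulse"
        assert classify_broad(CallFeatures(400.0, "pulsed")) == "LF pulsed"

    def test_unknown_structure_is_other(self):
        assert classify_broad(CallFeatures(400.0, "unstructured")) == "other"

    def test_missing_feature_named_in_error(self):
        with pytest.raises(ClassificationError, match="structure"):
            classify_broad(CallFeatures(400.0, None))

    def test_pure_function_idempotent(self):
        f = CallFeatures(1500.0, "tonal")
        assert classify_broad(f) == classify_broad(f)


class TestSubtypeAssignment:
    def test_consistent_hint_accepted(self):
        lab = assign_subtype("LF tonal", "bop")
        assert (lab.broad_type, lab.subtype) == ("LF tonal", "bop")

    def test_absent_hint_falls_back_to_other(self):
        assert assign_subtype("LF pulsed", None).subtype == "other"

    def test_conflicting_hint_warns_and_resolves(self):
        with pytest.warns(TaxonomyWarning):
            lab = assign_subtype("HF tonal", "whup")
        assert lab.broad_type == "HF tonal" and lab.subtype is None
        with pytest.warns(TaxonomyWarning):
            lab2 = assign_subtype("LF tonal", "whup")
        assert lab2.subtype == "other"

    def test_thwop_variants_fold_into_thwop(self):
        lab = assign_subtype("LF pulsed", "thwop variant 2")
        assert lab.subtype == "thwop" and lab.variant == "variant 2"


class TestClassifierEstimator:
    def test_predict_matches_rule(self):
        feats = [CallFeatures(1500.0, "tonal"), CallFeatures(2500.0, "tonal"),
                 CallFeatures(300.0, "pulsed")]
        clf = BroadTypeClassifier().fit()
        assert list(clf.predict(feats)) == ["LF tonal", "HF tonal", "LF pulsed"]

    def test_sklearn_clone_and_dataframe_input(self):
        clf = clone(BroadTypeClassifier()).fit()
        df = pd.DataFrame(
            {"first_harmonic_hz": [900.0], "structure": ["tonal"],
             "n_segments": [1], "in_paired_sequence": [False]}
        )
        assert clf.predict(df)[0] == "LF tonal"

    def test_simulator_labels_classify_to_their_own_broad_type(self):
        rng = np.random.default_rng(0)
        for label in default_repertoire("adult"):
            f = features_for_label(label, rng)
            assert classify_broad(f) == label_to_broad(label)


class TestProportions:
    def frame(self, counts, col="adult"):
        rows = []
        for (broad, sub), n in counts.items():
            for _ in range(n):
                rows.append({"broad_type": broad, "subtype": sub, "age_class": col})
        return pd.DataFrame(rows)

    def test_simple_counts(self):
        df = self.frame({("LF tonal", "bop"): 2, ("LF pulsed", "whup"): 1,
                         ("LF pulsed", "knock"): 1})
        sub, broad = proportional_use(df)
        assert sub["adult"]["LF tonal bop"] == pytest.approx(0.5)
        assert sub["adult"]["LF pulsed whup"] == pytest.approx(0.25)
        assert broad["adult"]["LF pulsed"] == pytest.approx(0.5)

    def test_columns_sum_to_one(self):
        df = pd.concat(
            [self.frame({("LF tonal", "bop"): 3, ("pulse", None): 2}, "adult"),
             self.frame({("LF pulsed", "snort"): 4}, "calf")],
            ignore_index=True,
        )
        sub, broad = proportional_use(df)
        assert np.allclose(sub.sum(axis=0), 1.0, atol=1e-9)
        assert np.allclose(broad.sum(axis=0), 1.0, atol=1e-9)

    def test_adding_calls_never_decreases_their_share(self):
        base = {("LF tonal", "bop"): 2, ("LF pulsed", "whup"): 3}
        sub1, _ = proportional_use(self.frame(base))
        base[("LF tonal", "bop")] += 4
        sub2, _ = proportional_use(self.frame(base))
        assert sub2["adult"]["LF tonal bop"] > sub1["adult"]["LF tonal bop"]

    def test_classify_calls_end_to_end(self):
        df = pd.DataFrame(
            {
                "first_harmonic_hz": [1500.0, 2500.0, 300.0],
                "structure": ["tonal", "tonal", "pulsed"],
                "n_segments": [1, 1, 1],
                "in_paired_sequence": [False, False, False],
                "analyst_subtype_hint": ["bop", None, "knock"],
                "age_class": ["adult", "adult", "calf"],
            }
        )
        out = classify_calls(df)
        assert list(out["broad_type"]) == ["LF tonal", "HF tonal", "LF pulsed"]
        assert list(out["subtype"]) == ["bop", None, "knock"]


class TestPlot:
    def test_stacked_proportion_plot_covers_unit_interval(self):
        df = pd.DataFrame(
            {"broad_type": ["LF tonal", "LF pulsed", "LF pulsed"],
             "subtype": ["bop", "whup", None], "age_class": ["adult"] * 3}
        )
        _, broad = proportional_use(df)
        from calltag.repertoire import plot_broad_proportions

        ax = plot_broad_proportions(broad)
        heights = sum(p.get_height() for p in ax.patches)
        assert heights == pytest.approx(1.0)


class TestReferenceTables:
    def test_deployment_totals(self):
        table = deployment_summary()
        assert int(table["n_focal_calls"].sum()) == 982
        assert int((table["n_focal_calls"] > 0).sum()) == 13

    def test_published_proportion_columns(self):
        table = repertoire_proportions()
        assert table["adult"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table["group2_calf"].sum() == pytest.approx(1.0, abs=1e-9)
        assert table["group5_calf"].sum() == pytest.approx(1.0, abs=1e-9)
        # source table prints a column that undersums; defaults renormalize
        props = default_repertoire("calf")
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)
        adult = default_repertoire("adult")
        assert sum(adult.values()) == pytest.approx(1.0, abs=1e-12)
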