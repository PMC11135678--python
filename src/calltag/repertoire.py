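"""Hierarchical call-type taxonomy and proportional repertoire use.

Humpback whale non-song social calls are organized here on two levels: broad
call types separable by objective structural features (tonal vs pulsed
structure, a 2 kHz first-harmonic threshold, multi-component structure,
production in paired sequences), and named subtypes within the two
low-frequency broad types. Subtype identities (bop vs grunt, whup vs thwop,
...) are graded and are assigned by analyst consensus, not by an automatic
rule: this module validates analyst subtype hints against the taxonomy and
falls back to an "other" subtype when a hint is absent or inconsistent.

Broad types:

* **HF tonal** — tonal call whose first harmonic reaches 2 kHz or above.
* **LF tonal** — tonal call with first harmonic below 2 kHz throughout.
  Subtypes: bop, grunt.
* **LF pulsed** — call built from rapid broadband pulses; always low
  frequency. Subtypes: whup, thwop, knock, squelch, snort, squish,
  pseudo-thwop.
* **complex** — heterogeneous components (e.g. pulsed then tonal) joined
  without a temporal gap.
* **pulse** — a single short broadband pulse.
* **paired burst** — short pulses or pulsed calls produced in a paired
  sequence, associated with coordinated bottom feeding.
* **other** — anything that fits none of the above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import ClassificationError

__all__ = [
    "BROAD_TYPES",
    "SUBTYPES",
    "CallFeatures",
    "CallTypeLabel",
    "TaxonomyWarning",
    "BroadTypeClassifier",
    "classify_broad",
    "assign_subtype",
    "classify_calls",
    "proportional_use",
    "label_to_broad",
    "features_for_label",
    "plot_broad_proportions",
]

BROAD_TYPES = (
    "HF tonal",
    "LF tonal",
    "LF pulsed",
    "complex",
    "pulse",
    "paired burst",
    "other",
)

#: subtypes permitted within each broad type; broad types absent from this
#: mapping carry no subtype level
SUBTYPES: dict[str, frozenset[str]] = {
    "LF tonal": frozenset({"bop", "grunt"}),
    "LF pulsed": frozenset(
        {"whup", "thwop", "knock", "squelch", "snort", "squish", "pseudo-thwop"}
    ),
}

#: calf structural variants folded into an existing subtype
_VARIANT_HINTS = {
    "thwop variant 1": ("thwop", "variant 1"),
    "thwop variant 2": ("thwop", "variant 2"),
}

FIRST_HARMONIC_THRESHOLD_HZ = 2000.0


class TaxonomyWarning(UserWarning):
    """An analyst subtype hint conflicts with the assigned broad type."""


@dataclass
class CallFeatures:
    """Objective structural features of one call, as scored by an analyst."""

    first_harmonic_hz: float
    structure: str  # tonal | pulsed | single_pulse
    n_segments: int = 1
    in_paired_sequence: bool = False
    analyst_subtype_hint: str | None = None
    segment_structures: tuple[str, ...] = ()

    def __post_init__(self):
        if self.first_harmonic_hz is not None and self.first_harmonic_hz <= 0:
            raise ClassificationError("first_harmonic_hz must be positive")
        if self.n_segments < 1:
            raise ClassificationError("n_segments must be >= 1")


@dataclass(frozen=True)
class CallTypeLabel:
    broad_type: str
    subtype: str | None = None
    variant: str | None = None


def classify_broad(features: CallFeatures) -> str:
    """Assign the broad call type from structural features.

    Decision order: paired sequence membership, then multi-component
    heterogeneity (complex), then single pulses, then pulsed calls (always
    low frequency), then the 2 kHz first-harmonic split for tonal calls.
    """
    if features.in_paired_sequence is None:
        raise ClassificationError("missing feature: in_paired_sequence")
    if features.in_paired_sequence:
        return "paired burst"
    if features.n_segments > 1 and len(set(features.segment_structures)) > 1:
        return "complex"
    if features.structure is None:
        raise ClassificationError("missing feature: structure")
    if features.structure == "single_pulse":
        return "pulse"
    if features.structure == "pulsed":
        return "LF pulsed"
    if features.structure == "tonal":
        if features.first_harmonic_hz is None:
            raise ClassificationError("missing feature: first_harmonic_hz")
        if features.first_harmonic_hz < FIRST_HARMONIC_THRESHOLD_HZ:
            return "LF tonal"
        return "HF tonal"
    return "other"


def assign_subtype(broad_type: str, hint: str | None) -> CallTypeLabel:
    """Attach a subtype to a broad type, validating the analyst hint.

    Within LF tonal and LF pulsed an absent or taxonomy-inconsistent hint
    resolves to the "other" subtype (with a :class:`TaxonomyWarning` on
    conflict); broad types without a subtype level pass through unchanged.
    """
    if broad_type not in BROAD_TYPES:
        raise ClassificationError(f"unknown broad type {broad_type!r}")
    variant = None
    if hint is not None:
        hint = hint.strip().lower()
        if hint in _VARIANT_HINTS:
            hint, variant = _VARIANT_HINTS[hint]
    allowed = SUBTYPES.get(broad_type)
    if allowed is None:
        if hint is not None and any(hint in subs for subs in SUBTYPES.values()):
            warnings.warn(
                f"subtype hint {hint!r} is inconsistent with broad type "
                f"{broad_type!r}; dropping it",
                TaxonomyWarning,
                stacklevel=2,
            )
        return CallTypeLabel(broad_type, None, None)
    if hint is None or hint in ("", "other"):
        return CallTypeLabel(broad_type, "other", None)
    if hint in allowed:
        return CallTypeLabel(broad_type, hint, variant)
    warnings.warn(
        f"subtype hint {hint!r} is inconsistent with broad type "
        f"{broad_type!r}; resolving to 'other'",
        TaxonomyWarning,
        stacklevel=2,
    )
    return CallTypeLabel(broad_type, "other", None)


class BroadTypeClassifier(ClassifierMixin, BaseEstimator):
    """Rule-based broad-call-type classifier.

    A stateless decision tree over structural features; ``fit`` only records
    the class set so the estimator composes with scikit-learn tooling.
    ``predict`` accepts a sequence of :class:`CallFeatures` or a DataFrame
    with the feature columns.
    """

    def fit(self, X=None, y=None):
        self.classes_ = np.asarray(BROAD_TYPES, dtype=object)
        return self

    def predict(self, X):
        if not hasattr(self, "classes_"):
            self.fit()
        feats = _as_features(X)
        return np.asarray([classify_broad(f) for f in feats], dtype=object)


def _as_features(X) -> list[CallFeatures]:
    if isinstance(X, pd.DataFrame):
        out = []
        for row in X.itertuples(index=False):
            seg = getattr(row, "segment_structures", ()) or ()
            if isinstance(seg, float):  # NaN from a CSV round trip
                seg = ()
            if isinstance(seg, str):
                seg = tuple(s for s in seg.split("+") if s)
            hint = getattr(row, "analyst_subtype_hint", None)
            if isinstance(hint, float) and np.isnan(hint):
                hint = None
            out.append(
                CallFeatures(
                    first_harmonic_hz=getattr(row, "first_harmonic_hz"),
                    structure=getattr(row, "structure"),
                    n_segments=int(getattr(row, "n_segments", 1)),
                    in_paired_sequence=bool(getattr(row, "in_paired_sequence", False)),
                    analyst_subtype_hint=hint,
                    segment_structures=tuple(seg),
                )
            )
        return out
    return list(X)


def classify_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Classify every row of a call table; adds broad_type/subtype/variant."""
    feats = _as_features(calls)
    labels = [assign_subtype(classify_broad(f), f.analyst_subtype_hint) for f in feats]
    out = calls.copy()
    out["broad_type"] = [lab.broad_type for lab in labels]
    out["subtype"] = [lab.subtype for lab in labels]
    out["variant"] = [lab.variant for lab in labels]
    return out


def proportional_use(
    calls: pd.DataFrame, by: str = "age_class"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportional repertoire use per group of the ``by`` column.

    Returns ``(subtype_table, broad_table)``: rows are (broad type, subtype)
    pairs or broad types, columns are the grouping levels, and every column
    sums to 1. Empty columns are omitted.
    """
    if by not in calls.columns:
        raise KeyError(f"grouping column {by!r} not in call table")
    labeled = calls.dropna(subset=["broad_type"])
    sub_key = labeled["broad_type"].str.cat(
        labeled["subtype"].fillna(""), sep=" ", join="left"
    ).str.strip()
    sub_counts = pd.crosstab(sub_key, labeled[by])
    broad_counts = pd.crosstab(labeled["broad_type"], labeled[by])
    sub_counts = sub_counts.loc[:, sub_counts.sum(axis=0) > 0]
    broad_counts = broad_counts.loc[:, broad_counts.sum(axis=0) > 0]
    return sub_counts / sub_counts.sum(axis=0), broad_counts / broad_counts.sum(axis=0)


# ---------------------------------------------------------------------------
# label helpers used by the synthetic-scene generator

_LABEL_TO_BROAD = {
    "hf_tonal": "HF tonal",
    "lf_tonal_other": "LF tonal",
    "lf_pulsed_other": "LF pulsed",
    "paired_burst": "paired burst",
    "complex": "complex",
    "pulse": "pulse",
    "other": "other",
}


def label_to_broad(label: str) -> str:
    """Broad type for a simulator repertoire label."""
    if label in _LABEL_TO_BROAD:
        return _LABEL_TO_BROAD[label]
    for broad, subs in SUBTYPES.items():
        if label in subs:
            return broad
    raise KeyError(f"unknown repertoire label {label!r}")


def features_for_label(label: str, rng: np.random.Generator) -> CallFeatures:
    """Synthesize analyst-style features consistent with a repertoire label.

    Used by the scene generator so that its annotation tables can be pushed
    through the classification tree; classification of these features always
    returns the label's own broad type.
    """
    broad = label_to_broad(label)
    hint = label if any(label in subs for subs in SUBTYPES.values()) else None
    if broad == "HF tonal":
        f0 = float(rng.uniform(2200.0, 3200.0))
        return CallFeatures(f0, "tonal", analyst_subtype_hint=hint)
    if broad == "LF tonal":
        f0 = float(rng.uniform(150.0, 900.0))
        return CallFeatures(f0, "tonal", analyst_subtype_hint=hint)
    if broad == "LF pulsed":
        f0 = float(rng.uniform(80.0, 600.0))
        return CallFeatures(f0, "pulsed", analyst_subtype_hint=hint)
    if broad == "pulse":
        return CallFeatures(float(rng.uniform(100.0, 800.0)), "single_pulse")
    if broad == "paired burst":
        return CallFeatures(
            float(rng.uniform(100.0, 600.0)), "pulsed", in_paired_sequence=True
        )
    if broad == "complex":
        return CallFeatures(
            float(rng.uniform(150.0, 900.0)),
            "tonal",
            n_segments=2,
            segment_structures=("pulsed", "tonal"),
        )
    # "other": unstructured, defeats every earlier branch
    return CallFeatures(float(rng.uniform(200.0, 1500.0)), "unstructured")


def plot_broad_proportions(broad_table: pd.DataFrame, ax=None):
    """Stacked-bar plot of broad-type proportions per column."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 + broad_table.shape[1], 4))
    bottom = np.zeros(broad_table.shape[1])
    for broad in broad_table.index:
        vals = broad_table.loc[broad].to_numpy(dtype=float)
        ax.bar(broad_table.columns.astype(str), vals, bottom=bottom, label=broad)
        bottom += vals
    ax.set_ylabel("proportion of calls")
    ax.legend(fontsize=8)
    return ax
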