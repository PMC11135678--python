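"""Bundled reference tables from a published multi-tag humpback whale study.

Two small tables ship with the package:

* ``deployment_summary`` — per-individual tag deployment metadata for seven
  Gulf of Maine groups (2006-2009): deployment date, group, analysis duration
  and focal-call count for each tagged whale.
* ``repertoire_proportions`` — proportional use of call subtypes by adults and
  by each of three calves, on the package's two-level call taxonomy.

They serve as realistic defaults for the synthetic-scene generator (repertoire
draws, group compositions) and as inputs for summary arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "deployment_summary",
    "repertoire_proportions",
    "default_repertoire",
    "summary_statistics",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("calltag.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def deployment_summary() -> pd.DataFrame:
    """Per-individual deployment summary (one row per tagged whale)."""
    return _read("deployment_summary.csv")


def repertoire_proportions() -> pd.DataFrame:
    """Subtype-level proportional repertoire use for adults and three calves.

    Columns ``adult``, ``group2_calf``, ``group5_calf``, ``group6_calf`` hold
    the proportions as published; the ``group6_calf`` column sums to 0.965
    due to rounding in the source table and is renormalized by
    :func:`default_repertoire` before use in simulation.
    """
    return _read("repertoire_proportions.csv")


def default_repertoire(age_class: str = "adult") -> dict[str, float]:
    """Default subtype proportions for the simulator, normalized to sum to 1.

    ``adult`` uses the pooled adult column; ``calf`` uses the best-sampled
    calf (the group-6 calf, 302 calls).
    """
    table = repertoire_proportions()
    column = {"adult": "adult", "calf": "group6_calf"}.get(age_class)
    if column is None:
        raise KeyError(f"unknown age class {age_class!r}")
    props = table.set_index("label")[column]
    props = props[props > 0]
    props = props / props.sum()
    return props.to_dict()


def summary_statistics() -> dict[str, float]:
    """Arithmetic summaries of the deployment table.

    Returns the total focal-call count, the share contributed by group 6,
    the total browsed time (summed per individual, in minutes) and the
    number of individuals with at least one focal call.
    """
    table = deployment_summary()
    total = int(table["n_focal_calls"].sum())
    group6 = int(table.loc[table["group"] == 6, "n_focal_calls"].sum())
    return {
        "total_focal_calls": total,
        "group6_focal_calls": group6,
        "group6_share_pct": 100.0 * group6 / total,
        "total_browsing_min": float(table["analysis_duration_min"].sum()),
        "n_vocal_individuals": int((table["n_focal_calls"] > 0).sum()),
    }
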