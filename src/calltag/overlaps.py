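"""Counting temporally overlapping focal calls within a group.

Overlap avoidance is a core feature of vocal turn-taking; an overlap
instance here is an unordered pair of focal calls from two different
individuals in the same group whose time spans strictly intersect
(spans [a, b) and [c, d) with a < d and c < b; a shared endpoint is not an
overlap). Three mutually overlapping calls therefore yield three pairwise
instances; an alternative event-cluster counting (one merged event per
connected component of the pairwise overlap graph) is available behind a
flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = ["OverlapInstance", "count_overlaps"]

logger = logging.getLogger("calltag")


@dataclass(frozen=True)
class OverlapInstance:
    group_id: str
    call_a: str
    call_b: str
    caller_a: str
    caller_b: str
    overlap_s: float
    involves_calf: bool


def count_overlaps(
    calls: pd.DataFrame, mode: str = "pairs"
) -> tuple[list[OverlapInstance], pd.DataFrame]:
    """Find all overlap instances among focal calls, per group.

    ``calls`` needs caller_id, group_id, t_start_s, t_end_s and (optionally)
    focal_label and age_class columns; rows not labeled focal, and rows
    without a caller, are excluded (with a logged count). Returns the
    instances and a per-group summary (instances, instances involving a
    calf). ``mode="clusters"`` instead counts connected components of the
    pairwise overlap graph that span more than one caller.
    """
    df = calls.copy()
    if "focal_label" in df.columns:
        df = df[df["focal_label"] == "focal"]
    n_missing = int(df["caller_id"].isna().sum()) if "caller_id" in df.columns else len(df)
    if "caller_id" not in df.columns:
        raise KeyError("call table lacks caller_id")
    if n_missing:
        logger.info("excluding %d calls without caller_id from overlap count", n_missing)
        df = df.dropna(subset=["caller_id"])
    if "group_id" not in df.columns:
        df = df.assign(group_id="all")
    ages = {}
    if "age_class" in df.columns:
        ages = df.drop_duplicates("caller_id").set_index("caller_id")["age_class"].to_dict()
    instances: list[OverlapInstance] = []
    summaries = []
    for group_id, grp in df.groupby("group_id", sort=True):
        grp = grp.sort_values("t_start_s").reset_index(drop=True)
        starts = grp["t_start_s"].to_numpy()
        ends = grp["t_end_s"].to_numpy()
        callers = grp["caller_id"].astype(str).to_numpy()
        ids = (
            grp["call_id"].astype(str).to_numpy()
            if "call_id" in grp.columns
            else grp.index.astype(str).to_numpy()
        )
        pairs = []
        for i in range(len(grp)):
            for j in range(i + 1, len(grp)):
                if starts[j] >= ends[i]:
                    break  # sorted by onset: no later call can overlap call i
                if callers[i] == callers[j]:
                    continue
                ov = min(ends[i], ends[j]) - starts[j]
                if ov > 0:
                    pairs.append((i, j, ov))
        group_instances = [
            OverlapInstance(
                group_id=str(group_id),
                call_a=ids[i],
                call_b=ids[j],
                caller_a=callers[i],
                caller_b=callers[j],
                overlap_s=float(ov),
                involves_calf=(
                    ages.get(callers[i]) == "calf" or ages.get(callers[j]) == "calf"
                ),
            )
            for i, j, ov in pairs
        ]
        if mode == "clusters":
            group_instances = _merge_clusters(group_instances, pairs, ids)
        elif mode != "pairs":
            raise ValueError(f"unknown overlap counting mode {mode!r}")
        instances.extend(group_instances)
        summaries.append(
            {
                "group_id": group_id,
                "n_instances": len(group_instances),
                "n_involving_calf": sum(x.involves_calf for x in group_instances),
            }
        )
    return instances, pd.DataFrame(summaries)


def _merge_clusters(instances, pairs, ids):
    """Collapse pairwise instances into one per overlap event cluster."""
    parent = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, _ in pairs:
        parent[find(i)] = find(j)
    clusters: dict = {}
    for inst, (i, j, _) in zip(instances, pairs):
        root = find(i)
        keep = clusters.get(root)
        if keep is None or inst.overlap_s > keep.overlap_s:
            clusters[root] = inst
    return list(clusters.values())
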