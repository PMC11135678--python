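"""Cross-tag call matching and relative-level caller assignment.

When every whale in a small group carries a tag, a call reaches every tag
but is loudest on the tag of the whale that produced it. Detections from
synchronized tags are first bundled into per-call groups by temporal
overlap (with an onset tolerance for clock slop), then each bundle is
labeled by relative received level:

* a call seen on only one tag is **focal** to that tag's whale;
* with multiple tags, the highest-level member is focal and the rest
  nonfocal, provided the two highest levels differ by at least ``delta_db``
  (default 1 dB);
* otherwise the levels are too similar to call and every member is
  **indeterminate** (caller "undetermined") — such calls may come from a
  distant untagged whale or from animals swimming very close together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import AmbiguityError, InvalidParameterError

__all__ = [
    "Detection",
    "MatchedCall",
    "FocalAssigner",
    "match_across_tags",
    "assign_focal",
    "assign_calls",
    "cross_validate_with_manual",
]

UNDETERMINED = "undetermined"


@dataclass
class Detection:
    """One call as seen on one tag."""

    tag_id: str
    whale_id: str
    t_start_s: float
    t_end_s: float
    rl_db: float
    index: int = -1  # row in the source table, for traceability

    def __post_init__(self):
        if not self.t_end_s > self.t_start_s:
            raise InvalidParameterError("detection must have t_end_s > t_start_s")
        if not np.isfinite(self.rl_db):
            raise InvalidParameterError("detection rl_db must be finite")

    def overlaps(self, other: "Detection") -> bool:
        return self.t_start_s < other.t_end_s and other.t_start_s < self.t_end_s


@dataclass
class MatchedCall:
    """The cross-tag bundle for one acoustic event."""

    call_id: str
    members: list[Detection]
    labels: dict[str, str] = field(default_factory=dict)  # tag_id -> label
    caller_id: str = UNDETERMINED


def _as_detections(per_tag: dict[str, pd.DataFrame]) -> list[Detection]:
    dets = []
    for tag_id, df in per_tag.items():
        for i, row in enumerate(df.itertuples(index=False)):
            dets.append(
                Detection(
                    tag_id=tag_id,
                    whale_id=str(getattr(row, "whale_id", tag_id)),
                    t_start_s=float(row.t_start_s),
                    t_end_s=float(row.t_end_s),
                    rl_db=float(row.rl_db),
                    index=i,
                )
            )
    dets.sort(key=lambda d: (d.t_start_s, d.tag_id))
    return dets


def match_across_tags(
    per_tag: dict[str, pd.DataFrame] | list[Detection],
    tolerance_s: float = 0.1,
) -> list[MatchedCall]:
    """Bundle detections from different tags into per-call groups.

    Greedy in onset order: a detection joins the existing bundle containing
    the nearest-onset member it temporally matches (span overlap, or onset
    difference within ``tolerance_s``) among bundles with no member from its
    own tag; otherwise it opens a new bundle — so two acoustic events that
    overlap in time yield two bundles, each with at most one member per tag.
    Two detections on the *same* tag with coincident spans (both endpoints
    within 1 ms) at the same level (within 0.1 dB) are duplicate annotations
    of one event and raise :class:`AmbiguityError`; distinct events that
    merely coincide in time differ in level on a given tag.
    """
    if tolerance_s < 0:
        raise InvalidParameterError("tolerance_s must be >= 0")
    dets = _as_detections(per_tag) if isinstance(per_tag, dict) else sorted(
        per_tag, key=lambda d: (d.t_start_s, d.tag_id)
    )
    _check_duplicates(dets)
    done: list[MatchedCall] = []
    active: list[MatchedCall] = []
    n_created = 0
    max_dur = max((d.t_end_s - d.t_start_s for d in dets), default=0.0)
    for d in dets:
        # a bundle whose last member started more than one call-duration plus
        # the tolerance ago can never match a future detection: retire it
        horizon = d.t_start_s - (max_dur + tolerance_s)
        still = []
        for b in active:
            (done if b.members[-1].t_start_s < horizon else still).append(b)
        active = still
        best, best_gap = None, np.inf
        for b in active:
            if any(m.tag_id == d.tag_id for m in b.members):
                continue
            matches = [
                m
                for m in b.members
                if m.overlaps(d) or abs(d.t_start_s - m.t_start_s) <= tolerance_s
            ]
            if not matches:
                continue
            gap = min(abs(d.t_start_s - m.t_start_s) for m in matches)
            if gap < best_gap:
                best, best_gap = b, gap
        if best is not None:
            best.members.append(d)
        else:
            active.append(MatchedCall(call_id=f"call_{n_created:05d}", members=[d]))
            n_created += 1
    bundles = sorted(done + active, key=lambda b: b.members[0].t_start_s)
    for k, b in enumerate(bundles):
        b.call_id = f"call_{k:05d}"
    return bundles


def _check_duplicates(dets: list[Detection]) -> None:
    """Raise on near-coincident same-tag detections (duplicate annotations)."""
    by_tag: dict[str, Detection] = {}
    for d in dets:  # onset-sorted; only the previous same-tag span can collide
        prev = by_tag.get(d.tag_id)
        if (
            prev is not None
            and abs(prev.t_start_s - d.t_start_s) < 1e-3
            and abs(prev.t_end_s - d.t_end_s) < 1e-3
            and abs(prev.rl_db - d.rl_db) < 0.1
        ):
            raise AmbiguityError(
                f"tag {d.tag_id!r}: detections at {prev.t_start_s:.3f}s and "
                f"{d.t_start_s:.3f}s annotate the same span",
                collisions=[(prev, d)],
            )
        if prev is None or d.t_end_s > prev.t_end_s:
            by_tag[d.tag_id] = d
    return None


def assign_focal(
    matched: MatchedCall, delta_db: float = 1.0, strategy: str = "top_two"
) -> MatchedCall:
    """Label a bundle's members focal / nonfocal / indeterminate.

    ``top_two`` applies the level criterion to the gap between the two
    highest member levels; ``all_pairs`` demands every pair of members be
    separated by ``delta_db`` before any focal label is given.
    """
    if delta_db <= 0:
        raise InvalidParameterError("delta_db must be positive")
    if not matched.members:
        raise InvalidParameterError("bundle has no members")
    if len(matched.members) == 1:
        m = matched.members[0]
        matched.labels = {m.tag_id: "focal"}
        matched.caller_id = m.whale_id
        return matched
    rls = np.asarray([m.rl_db for m in matched.members])
    order = np.argsort(rls)[::-1]
    if strategy == "top_two":
        separable = rls[order[0]] - rls[order[1]] >= delta_db
    elif strategy == "all_pairs":
        separable = np.all(np.diff(np.sort(rls)) >= delta_db)
    else:
        raise InvalidParameterError(f"unknown strategy {strategy!r}")
    if separable:
        top = matched.members[order[0]]
        matched.labels = {
            m.tag_id: ("focal" if m is top else "nonfocal") for m in matched.members
        }
        matched.caller_id = top.whale_id
    else:
        matched.labels = {m.tag_id: "indeterminate" for m in matched.members}
        matched.caller_id = UNDETERMINED
    return matched


class FocalAssigner(BaseEstimator):
    """Match detections across tags and assign focal labels.

    Parameters
    ----------
    tolerance_s : onset tolerance for cross-tag matching (s).
    delta_db : minimum level gap for a confident focal label (dB).
    strategy : "top_two" (gap between the two loudest members) or
        "all_pairs" (every pairwise gap must exceed ``delta_db``).
    """

    def __init__(self, tolerance_s: float = 0.1, delta_db: float = 1.0,
                 strategy: str = "top_two"):
        self.tolerance_s = tolerance_s
        self.delta_db = delta_db
        self.strategy = strategy

    def transform(self, per_tag: dict[str, pd.DataFrame]) -> pd.DataFrame:
        """Return the unified labeled call table (one row per member)."""
        bundles = match_across_tags(per_tag, self.tolerance_s)
        rows = []
        for b in bundles:
            assign_focal(b, self.delta_db, self.strategy)
            for m in b.members:
                rows.append(
                    {
                        "call_id": b.call_id,
                        "tag_id": m.tag_id,
                        "whale_id": m.whale_id,
                        "t_start_s": m.t_start_s,
                        "t_end_s": m.t_end_s,
                        "rl_db": m.rl_db,
                        "focal_label": b.labels[m.tag_id],
                        "caller_id": b.caller_id,
                        "source_row": m.index,
                    }
                )
        return pd.DataFrame(rows)


def assign_calls(
    per_tag: dict[str, pd.DataFrame],
    tolerance_s: float = 0.1,
    delta_db: float = 1.0,
    strategy: str = "top_two",
) -> pd.DataFrame:
    """Functional wrapper over :class:`FocalAssigner`."""
    return FocalAssigner(tolerance_s, delta_db, strategy).transform(per_tag)


def cross_validate_with_manual(
    primary: pd.DataFrame, manual: pd.DataFrame, tolerance_s: float = 0.5
) -> dict:
    """Reconcile two selection tables for the same tag.

    Selections are paired greedily by nearest onset when spans overlap or
    onsets differ by at most ``tolerance_s``; the report lists selections
    present in only one source. Labels are never mutated.
    """
    a = primary.sort_values("t_start_s").reset_index(drop=True)
    b = manual.sort_values("t_start_s").reset_index(drop=True)
    used_b: set[int] = set()
    only_a = []
    for i, row in a.iterrows():
        gaps = []
        for j, other in b.iterrows():
            if j in used_b:
                continue
            overlap = row.t_start_s < other.t_end_s and other.t_start_s < row.t_end_s
            gap = abs(row.t_start_s - other.t_start_s)
            if overlap or gap <= tolerance_s:
                gaps.append((gap, j))
        if gaps:
            used_b.add(min(gaps)[1])
        else:
            only_a.append(i)
    only_b = [j for j in b.index if j not in used_b]
    return {
        "n_primary": len(a),
        "n_manual": len(b),
        "n_matched": len(a) - len(only_a),
        "only_in_primary": a.loc[only_a].to_dict("records"),
        "only_in_manual": b.loc[only_b].to_dict("records"),
        "n_discrepancies": len(only_a) + len(only_b),
    }
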