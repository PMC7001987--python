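"""Social graph and dataset recommendations.

Users own datasets, favorite datasets, and follow other (public) users.
Recommendations are the union of three sources: datasets similar to a
user's own data, datasets similar to their favorites, and datasets owned
by users they follow.  Private datasets still drive the engine for their
owner — a user can find data similar to an unpublished dataset — but are
never surfaced to anyone else.  Users can filter recommendations to keep
only primary-data or only metadata similarities; follow-based items are
not similarity edges and pass through the filter unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .coverage import DatasetRecord
from .network import SimilarityEdge

__all__ = ["SocialGraph", "Recommendation", "recommend"]

REASON_OWNED = "similar_to_owned"
REASON_FAVORITE = "similar_to_favorite"
REASON_FOLLOWED = "from_followed_user"

FILTERS = ("all", "primary_only", "metadata_only")


class PermissionError_(PermissionError):
    """Visibility rule violation (private dataset or private user)."""


@dataclass
class SocialGraph:
    """Users, ownership, favorites and follows."""

    users: dict[str, bool] = field(default_factory=dict)  # user_id -> public
    owns: dict[str, set[str]] = field(default_factory=dict)
    favorites: dict[str, set[str]] = field(default_factory=dict)
    follows: dict[str, set[str]] = field(default_factory=dict)

    def add_user(self, user_id: str, public: bool = True) -> None:
        self.users.setdefault(user_id, public)
        self.owns.setdefault(user_id, set())
        self.favorites.setdefault(user_id, set())
        self.follows.setdefault(user_id, set())

    def _require_user(self, user_id: str) -> None:
        if user_id not in self.users:
            raise KeyError(f"unknown user {user_id!r}")

    def owner_of(self, dataset_id: str) -> str | None:
        for user, datasets in self.owns.items():
            if dataset_id in datasets:
                return user
        return None

    def visible_to(self, user_id: str, record: DatasetRecord) -> bool:
        """Public datasets are visible to all; private only to their owner."""
        return record.public or record.dataset_id in self.owns.get(user_id, set())

    def own(self, user_id: str, dataset_id: str) -> None:
        self._require_user(user_id)
        self.owns[user_id].add(dataset_id)

    def favorite(self, user_id: str, record: DatasetRecord) -> None:
        """Idempotent; favoriting an inaccessible private dataset is refused."""
        self._require_user(user_id)
        if not self.visible_to(user_id, record):
            raise PermissionError_(
                f"{user_id} cannot favorite private dataset {record.dataset_id}"
            )
        self.favorites[user_id].add(record.dataset_id)

    def follow(self, user_id: str, target_user: str) -> None:
        """Idempotent; only public accounts may be followed."""
        self._require_user(user_id)
        self._require_user(target_user)
        if not self.users[target_user]:
            raise PermissionError_(f"user {target_user!r} is private and cannot be followed")
        self.follows[user_id].add(target_user)

    # -- persistence: one JSON document -----------------------------------
    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "users": self.users,
            "owns": {u: sorted(d) for u, d in self.owns.items()},
            "favorites": {u: sorted(d) for u, d in self.favorites.items()},
            "follows": {u: sorted(d) for u, d in self.follows.items()},
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh, indent=1)
        return doc

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "SocialGraph":
        if not isinstance(source, dict):
            with open(source) as fh:
                source = json.load(fh)
        return cls(
            users=dict(source["users"]),
            owns={u: set(d) for u, d in source["owns"].items()},
            favorites={u: set(d) for u, d in source["favorites"].items()},
            follows={u: set(d) for u, d in source["follows"].items()},
        )


@dataclass(frozen=True)
class Recommendation:
    """One suggested dataset with its provenance."""

    user_id: str
    dataset_id: str
    reasons: frozenset[str]
    by_primary: bool = False
    by_metadata: bool = False


def _edge_passes(edge: SimilarityEdge, filter_: str) -> bool:
    if filter_ == "primary_only":
        return edge.by_primary
    if filter_ == "metadata_only":
        return edge.by_metadata
    return True


def recommend(
    graph: SocialGraph,
    edges: Iterable[SimilarityEdge],
    records: Mapping[str, DatasetRecord],
    user_id: str,
    filter: str = "all",
) -> list[Recommendation]:
    """Per-user recommendations from similarity edges and the social graph.

    The output excludes the user's own and already-favorited datasets and
    never exposes another user's private dataset.  Results are ordered by
    reason count (descending), then dataset id — deterministic.
    """
    if filter not in FILTERS:
        raise ValueError(f"filter must be one of {FILTERS}")
    graph._require_user(user_id)
    owned = graph.owns.get(user_id, set())
    faved = graph.favorites.get(user_id, set())

    # adjacency from similarity edges
    neighbors: dict[str, list[SimilarityEdge]] = {}
    for edge in edges:
        neighbors.setdefault(edge.dataset_id_a, []).append(edge)
        neighbors.setdefault(edge.dataset_id_b, []).append(edge)

    found: dict[str, dict] = {}

    def consider(dataset_id: str, reason: str, edge: SimilarityEdge | None) -> None:
        if dataset_id in owned or dataset_id in faved:
            return
        rec = records.get(dataset_id)
        if rec is None or not graph.visible_to(user_id, rec):
            return
        entry = found.setdefault(
            dataset_id, {"reasons": set(), "by_primary": False, "by_metadata": False}
        )
        entry["reasons"].add(reason)
        if edge is not None:
            entry["by_primary"] |= edge.by_primary
            entry["by_metadata"] |= edge.by_metadata

    for seed_set, reason in ((owned, REASON_OWNED), (faved, REASON_FAVORITE)):
        for seed in seed_set:
            for edge in neighbors.get(seed, []):
                if not _edge_passes(edge, filter):
                    continue
                other = edge.dataset_id_b if edge.dataset_id_a == seed else edge.dataset_id_a
                consider(other, reason, edge)

    # follow-based items bypass the similarity filter (not similarity edges)
    for followed in graph.follows.get(user_id, set()):
        for dataset_id in graph.owns.get(followed, set()):
            consider(dataset_id, REASON_FOLLOWED, None)

    recs = [
        Recommendation(
            user_id=user_id,
            dataset_id=did,
            reasons=frozenset(entry["reasons"]),
            by_primary=entry["by_primary"],
            by_metadata=entry["by_metadata"],
        )
        for did, entry in found.items()
    ]
    recs.sort(key=lambda r: (-len(r.reasons), r.dataset_id))
    return recs
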