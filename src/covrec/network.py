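"""The dataset similarity network and its exploratory views.

Every dataset is compared pair-wise against all others from the same
assembly and experiment type, independently by primary data (predicted
ontology classes intersect) and by annotated metadata (shared key parent
classes).  The resulting edges feed three views: a collapsed
force-directed graph (datasets with the same annotated cell type and
target merge into one node whose size is the member count), a
hierarchical-clustering dendrogram, and a PCA projection fit on a
reference cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .classify import ClassifierModel, ClassPrediction, predict_classes, primary_similarity
from .coverage import DatasetProfile, DatasetRecord
from .ontology import InteractionTable, OntologySet, metadata_similarity

__all__ = [
    "SimilarityEdge",
    "NetworkGraph",
    "compare_all",
    "add_dataset",
    "build_network",
    "layout_force_directed",
    "Dendrogram",
    "hierarchical_dendrogram",
    "PCAModel",
    "fit_pca",
    "write_edges",
    "read_edges",
]


@dataclass(frozen=True)
class SimilarityEdge:
    """Unordered similar pair; flags say which comparison route fired."""

    dataset_id_a: str
    dataset_id_b: str
    by_primary: bool
    by_metadata: bool

    def __post_init__(self) -> None:
        if self.dataset_id_a == self.dataset_id_b:
            raise ValueError("self-edges are not stored")
        if not (self.by_primary or self.by_metadata):
            raise ValueError("an edge must be similar by at least one route")
        if self.dataset_id_a > self.dataset_id_b:  # canonical order
            a, b = self.dataset_id_b, self.dataset_id_a
            object.__setattr__(self, "dataset_id_a", a)
            object.__setattr__(self, "dataset_id_b", b)

    @property
    def pair(self) -> frozenset[str]:
        return frozenset({self.dataset_id_a, self.dataset_id_b})


def _predictions_for(
    dataset_id: str,
    profiles: Mapping[str, DatasetProfile],
    records: Mapping[str, DatasetRecord],
    models: Mapping[tuple[str, str, str], ClassifierModel],
) -> dict[str, ClassPrediction]:
    """Predictions per metadata field for one dataset, where models exist."""
    rec = records[dataset_id]
    profile = profiles.get(dataset_id)
    preds: dict[str, ClassPrediction] = {}
    if profile is None:
        return preds
    for fld in ("cell_type", "target"):
        if fld == "target" and rec.target is None:
            continue
        model = models.get((rec.assembly, rec.experiment_type, fld))
        if model is None or model.feature_class != profile.feature_class:
            continue
        preds[fld] = predict_classes(model, profile)
    return preds


def _compare_pair(
    id_a: str,
    id_b: str,
    preds: Mapping[str, dict[str, ClassPrediction]],
    records: Mapping[str, DatasetRecord],
    config: OntologySet,
    interactions: InteractionTable,
) -> SimilarityEdge | None:
    by_primary = bool(preds.get(id_a)) and bool(preds.get(id_b)) and primary_similarity(
        preds[id_a], preds[id_b]
    )
    verdict = metadata_similarity(records[id_a], records[id_b], config, interactions)
    if by_primary or verdict.similar:
        return SimilarityEdge(id_a, id_b, by_primary, verdict.similar)
    return None


def compare_all(
    profiles: Mapping[str, DatasetProfile],
    records: Mapping[str, DatasetRecord],
    models: Mapping[tuple[str, str, str], ClassifierModel],
    config: OntologySet,
    interactions: InteractionTable | None = None,
) -> set[SimilarityEdge]:
    """All pairwise similarity edges within (assembly, experiment type) groups.

    ``models`` is keyed by (assembly, experiment_type, metadata_field);
    missing models simply disable the primary route for that group.
    Datasets without a profile are compared by metadata only (warning).
    """
    interactions = interactions if interactions is not None else InteractionTable()
    for did in records:
        if did not in profiles:
            warnings.warn(f"dataset {did}: no profile; metadata-only comparison")
    groups: dict[tuple[str, str], list[str]] = {}
    for did, rec in records.items():
        groups.setdefault((rec.assembly, rec.experiment_type), []).append(did)
    edges: set[SimilarityEdge] = set()
    for members in groups.values():
        preds = {d: _predictions_for(d, profiles, records, models) for d in members}
        members = sorted(members)
        for i, id_a in enumerate(members):
            for id_b in members[i + 1 :]:
                edge = _compare_pair(id_a, id_b, preds, records, config, interactions)
                if edge is not None:
                    edges.add(edge)
    return edges


def add_dataset(
    edges: set[SimilarityEdge],
    new_id: str,
    profiles: Mapping[str, DatasetProfile],
    records: Mapping[str, DatasetRecord],
    models: Mapping[tuple[str, str, str], ClassifierModel],
    config: OntologySet,
    interactions: InteractionTable | None = None,
) -> set[SimilarityEdge]:
    """Incrementally integrate one dataset: compare it only against members
    of its own (assembly, experiment type) group.  Agrees with a full
    recompute by construction (checked in tests)."""
    interactions = interactions if interactions is not None else InteractionTable()
    rec = records[new_id]
    group = [
        d
        for d, r in records.items()
        if d != new_id and (r.assembly, r.experiment_type) == (rec.assembly, rec.experiment_type)
    ]
    preds = {d: _predictions_for(d, profiles, records, models) for d in [new_id, *group]}
    out = set(edges)
    for other in group:
        edge = _compare_pair(new_id, other, preds, records, config, interactions)
        if edge is not None:
            out.add(edge)
    return out


@dataclass
class NetworkGraph:
    """Collapsed network: one node per annotated (cell type, target) group."""

    graph: nx.Graph
    coordinates: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def total_datasets(self) -> int:
        return sum(d["size"] for _, d in self.graph.nodes(data=True))

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = nx.node_link_data(self.graph, edges="links")
        for node in doc["nodes"]:
            if node["id"] in self.coordinates:
                node["x"], node["y"] = map(float, self.coordinates[node["id"]])
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh, indent=1)
        return doc


def build_network(
    edges: Iterable[SimilarityEdge], records: Mapping[str, DatasetRecord]
) -> NetworkGraph:
    """Collapse datasets into (cell type, target) groups.

    Node size is the member count; an inter-group edge exists iff any
    member pair is similar, with source flags OR-ed over member pairs.
    """
    g = nx.Graph()
    group_of: dict[str, str] = {}
    for did, rec in records.items():
        key = f"{rec.cell_type}|{rec.target or '-'}"
        group_of[did] = key
        if key not in g:
            g.add_node(key, cell_type=rec.cell_type, target=rec.target, members=[], size=0)
        g.nodes[key]["members"].append(did)
        g.nodes[key]["size"] += 1
    for edge in edges:
        ga, gb = group_of[edge.dataset_id_a], group_of[edge.dataset_id_b]
        if ga == gb:
            continue
        if g.has_edge(ga, gb):
            g.edges[ga, gb]["by_primary"] |= edge.by_primary
            g.edges[ga, gb]["by_metadata"] |= edge.by_metadata
        else:
            g.add_edge(ga, gb, by_primary=edge.by_primary, by_metadata=edge.by_metadata)
    return NetworkGraph(graph=g)


def layout_force_directed(
    network: NetworkGraph, seed: int = 0, iterations: int = 200
) -> dict[str, tuple[float, float]]:
    """Fruchterman-Reingold layout; deterministic for a fixed seed."""
    if network.graph.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty network")
    pos = nx.spring_layout(network.graph, seed=seed, iterations=iterations)
    coords = {node: (float(xy[0]), float(xy[1])) for node, xy in pos.items()}
    network.coordinates = coords
    return coords


@dataclass
class Dendrogram:
    """Average-linkage merge tree over datasets."""

    ids: tuple[str, ...]
    linkage_matrix: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def to_newick(self, path: str | Path | None = None) -> str:
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, list(self.ids))
        newick = str(tree).strip()
        if path is not None:
            Path(path).write_text(newick + "\n")
        return newick


def _profile_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation on log2(TPM+1) rows; constant rows -> max."""
    X = np.log2(np.asarray(matrix, dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    D = 1.0 - corr
    D[np.isnan(D)] = 1.0
    np.fill_diagonal(D, 0.0)
    return np.clip((D + D.T) / 2.0, 0.0, 2.0)


def hierarchical_dendrogram(
    matrix: np.ndarray,
    ids: Sequence[str],
    selected_features: np.ndarray | None = None,
) -> Dendrogram:
    """Average-linkage clustering of dataset profiles.

    ``matrix`` is datasets x features TPM; distance is 1 - Pearson on
    log2(TPM+1), restricted to ``selected_features`` when given (the
    classifier's filtered feature space).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 2:
        raise ValueError("dendrogram requires at least 2 datasets")
    if len(ids) != matrix.shape[0]:
        raise ValueError("one id per dataset row required")
    if selected_features is not None:
        matrix = matrix[:, np.asarray(selected_features)]
    D = _profile_distance_matrix(matrix)
    Z = linkage(squareform(D, checks=False), method="average")
    return Dendrogram(ids=tuple(ids), linkage_matrix=Z)


@dataclass
class PCAModel:
    """PCA transform frozen on a reference cohort; projection never refits."""

    pca: PCA
    n_features: int
    log_transform: bool = True

    def project(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        single = data.ndim == 1
        if single:
            data = data[None, :]
        if data.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {data.shape[1]}"
            )
        X = np.log2(data + 1.0) if self.log_transform else data
        coords = self.pca.transform(X)
        return coords[0] if single else coords


def fit_pca(
    reference_matrix: np.ndarray, n_components: int = 2, log_transform: bool = True
) -> PCAModel:
    """Fit a PCA on the reference cohort (datasets x features)."""
    X = np.asarray(reference_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("reference matrix must have >=2 datasets and >=2 features")
    Xt = np.log2(X + 1.0) if log_transform else X
    pca = PCA(n_components=n_components, random_state=0).fit(Xt)
    return PCAModel(pca=pca, n_features=X.shape[1], log_transform=log_transform)


# ---------------------------------------------------------------------------
# edge serialization


def write_edges(edges: Iterable[SimilarityEdge], path: str | Path) -> None:
    doc = [
        {
            "a": e.dataset_id_a,
            "b": e.dataset_id_b,
            "by_primary": e.by_primary,
            "by_metadata": e.by_metadata,
        }
        for e in sorted(edges, key=lambda e: (e.dataset_id_a, e.dataset_id_b))
    ]
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_edges(path: str | Path) -> set[SimilarityEdge]:
    with open(path) as fh:
        doc = json.load(fh)
    return {SimilarityEdge(d["a"], d["b"], d["by_primary"], d["by_metadata"]) for d in doc}
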