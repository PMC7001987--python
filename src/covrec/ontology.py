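"""Ontology-driven categorical metadata comparison.

Cell/tissue terms are compared through a BRENDA-like anatomy ontology,
protein targets through a GO-like process ontology plus a custom
histone-modification ontology that groups marks by where they are enriched
in the genome (e.g. H3K4me3 under both "at active promoters" and "at poised
promoters").  Each ontology carries a hand-picked set of *key parent
classes* (e.g. "cardiovascular system"); two annotations are similar when
they share at least one key parent.  Transcription-factor target pairs must
additionally show protein-protein interaction evidence in a STRING-like
edge table.  Free text is normalized onto ontology terms with fuzzy
(Levenshtein-ratio) matching so clerical variants still resolve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import obonet

__all__ = [
    "Ontology",
    "InteractionTable",
    "OntologySet",
    "MetadataVerdict",
    "load_ontology",
    "fuzzy_score",
    "is_transcription_factor",
    "targets_similar",
    "metadata_similarity",
]

DEFAULT_FUZZY_THRESHOLD = 90.0
DEFAULT_STRING_CUTOFF = 0.4  # "medium confidence" convention


class OntologyError(ValueError):
    """Structural problem in an ontology (cycle, unknown key class)."""


class TermLookupError(KeyError):
    """Term id not present in the ontology."""


def _parse_synonym(raw: str) -> str:
    # OBO synonym line payload: "text" SCOPE [xrefs]
    if raw.startswith('"'):
        end = raw.find('"', 1)
        if end > 0:
            return raw[1:end]
    return raw


class Ontology:
    """DAG of terms linked by is_a edges, with designated key parent classes.

    Edges run child -> parent.  ``key_classes`` is the manually curated
    subset of term ids whose descendants are treated as mutually similar.
    """

    def __init__(
        self,
        terms: Mapping[str, str],
        is_a_edges: Iterable[tuple[str, str]],
        key_classes: Iterable[str] = (),
        synonyms: Mapping[str, Sequence[str]] | None = None,
        name: str = "ontology",
    ):
        self.name = name
        self.terms = dict(terms)  # id -> primary name
        self.synonyms = {t: list(s) for t, s in (synonyms or {}).items()}
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent in is_a_edges:
            for t in (child, parent):
                if t not in self.terms:
                    raise OntologyError(f"edge references unknown term {t!r}")
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"is_a graph contains a cycle: {cycle}")
        self._graph = g
        self.key_classes = frozenset(key_classes)
        missing = self.key_classes - self.terms.keys()
        if missing:
            raise OntologyError(f"key classes absent from ontology: {sorted(missing)}")
        # lowercase name/synonym -> term id; collisions resolved to smallest id
        vocab: dict[str, str] = {}
        for tid in sorted(self.terms):
            for label in [self.terms[tid], *self.synonyms.get(tid, [])]:
                vocab.setdefault(label.lower(), tid)
        self._vocab = vocab

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Transitive is_a closure of ``term_id``, excluding the term itself."""
        if term_id not in self.terms:
            raise TermLookupError(f"{term_id!r} not in ontology {self.name!r}")
        return frozenset(nx.descendants(self._graph, term_id))

    def key_parents(self, term_id: str) -> frozenset[str]:
        """Key classes among the term and its ancestors.

        A term that is itself a key class reports itself, so identical
        annotations are always similar.
        """
        return (self.ancestors(term_id) | {term_id}) & self.key_classes

    def fuzzy_match(
        self, query: str, threshold: float = DEFAULT_FUZZY_THRESHOLD
    ) -> tuple[str, float] | None:
        """Resolve free text onto a term id.

        Exact (case-insensitive) name or synonym matches short-circuit at
        score 100; otherwise the highest-scoring vocabulary entry at or
        above ``threshold`` wins, ties broken by smallest term id.  Returns
        ``(term_id, score)`` or None.
        """
        if not query or not query.strip():
            raise ValueError("empty query")
        q = query.strip().lower()
        if q in self._vocab:
            return self._vocab[q], 100.0
        best: tuple[float, str] | None = None
        for label, tid in self._vocab.items():
            score = fuzzy_score(q, label)
            if score < threshold:
                continue
            if best is None or score > best[0] or (score == best[0] and tid < best[1]):
                best = (score, tid)
        if best is None:
            return None
        return best[1], best[0]


def fuzzy_score(a: str, b: str) -> float:
    """Normalized Levenshtein similarity on [0, 100] (case-insensitive)."""
    a, b = a.lower(), b.lower()
    if a == b:
        return 100.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 100.0 * (1.0 - dist / max(len(a), len(b)))


def load_ontology(
    path: str | Path, key_class_ids: Iterable[str] = (), name: str | None = None
) -> Ontology:
    """Load an OBO 1.2 file, keeping is_a edges, names and synonyms."""
    graph = obonet.read_obo(str(path))
    terms: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    edges: list[tuple[str, str]] = []
    for node, data in graph.nodes(data=True):
        terms[node] = data.get("name", node)
        syns = [_parse_synonym(s) for s in data.get("synonym", [])]
        if syns:
            synonyms[node] = syns
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent))
    return Ontology(
        terms,
        edges,
        key_classes=key_class_ids,
        synonyms=synonyms,
        name=name or Path(path).stem,
    )


class InteractionTable:
    """Symmetric protein-protein interaction edges with confidence scores."""

    def __init__(self, edges: Iterable[tuple[str, str, float]] = ()):
        self._scores: dict[frozenset[str], float] = {}
        for a, b, score in edges:
            self.add(a, b, score)

    def add(self, a: str, b: str, score: float) -> None:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"interaction score {score} outside [0, 1]")
        key = frozenset({a.lower(), b.lower()})
        self._scores[key] = max(score, self._scores.get(key, 0.0))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionTable":
        """3-column TSV: protein_a, protein_b, score."""
        table = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ValueError(f"{path}: line {lineno}: expected 3 columns")
                table.add(fields[0], fields[1], float(fields[2]))
        return table

    def __len__(self) -> int:
        return len(self._scores)

    def score(self, a: str, b: str) -> float:
        return self._scores.get(frozenset({a.lower(), b.lower()}), 0.0)

    def has_interaction(self, a: str, b: str, cutoff: float = DEFAULT_STRING_CUTOFF) -> bool:
        return self.score(a, b) >= cutoff


@dataclass
class OntologySet:
    """The ontologies and thresholds one comparison run uses.

    ``target_ontologies`` typically holds a GO-like ontology (for protein
    targets) and the histone-modification ontology.  ``tf_classes`` names
    the key classes in the GO-like ontology that define transcription
    factors.
    """

    cell_type_ontology: Ontology
    target_ontologies: tuple[Ontology, ...] = ()
    tf_classes: frozenset[str] = frozenset()
    fuzzy_threshold: float = DEFAULT_FUZZY_THRESHOLD
    string_cutoff: float = DEFAULT_STRING_CUTOFF


@dataclass(frozen=True)
class MetadataVerdict:
    """Categorical similarity decision for one dataset pair."""

    similar: bool
    cell_type_shared_classes: frozenset[str]
    target_shared_classes: frozenset[str] | None  # None = target not applicable
    tf_interaction_checked: bool = False


def _match_target(term: str, config: OntologySet) -> tuple[Ontology, str] | None:
    """First target ontology that resolves the term (GO-like searched first)."""
    for onto in config.target_ontologies:
        hit = onto.fuzzy_match(term, config.fuzzy_threshold)
        if hit is not None:
            return onto, hit[0]
    return None


def is_transcription_factor(target_term: str, config: OntologySet) -> bool:
    """True iff the term resolves to a TF-defining key class.

    TF-defining classes live in the GO-like target ontology; histone marks
    resolve in the histone ontology and are therefore never TFs.  Unmatched
    free text degrades to False with a warning.
    """
    match = _match_target(target_term, config)
    if match is None:
        warnings.warn(f"target term {target_term!r} matched no ontology; treating as non-TF")
        return False
    onto, tid = match
    return bool(onto.key_parents(tid) & config.tf_classes)


def targets_similar(
    target_a: str,
    target_b: str,
    config: OntologySet,
    interactions: InteractionTable,
) -> tuple[bool, frozenset[str], bool]:
    """Decide protein-target similarity.

    Non-TF pairs (histone marks, other proteins) are similar iff they share
    a key parent class in any target ontology.  TF pairs must share a key
    parent AND show an interaction edge at or above the configured cutoff.
    Returns (similar, shared key classes, whether the interaction table was
    consulted).
    """
    match_a = _match_target(target_a, config)
    match_b = _match_target(target_b, config)
    if match_a is None or match_b is None:
        for term, match in ((target_a, match_a), (target_b, match_b)):
            if match is None:
                warnings.warn(f"target term {term!r} matched no ontology; not similar")
        return False, frozenset(), False
    shared: frozenset[str] = frozenset()
    for onto in config.target_ontologies:
        if match_a[0] is onto and match_b[0] is onto:
            shared = shared | (onto.key_parents(match_a[1]) & onto.key_parents(match_b[1]))
    if not shared:
        return False, shared, False
    both_tf = is_transcription_factor(target_a, config) and is_transcription_factor(
        target_b, config
    )
    if both_tf:
        # STRING lookup uses canonical matched names
        name_a = match_a[0].terms[match_a[1]]
        name_b = match_b[0].terms[match_b[1]]
        return interactions.has_interaction(name_a, name_b, config.string_cutoff), shared, True
    return True, shared, False


def metadata_similarity(
    rec_a, rec_b, config: OntologySet, interactions: InteractionTable | None = None
) -> MetadataVerdict:
    """Categorical metadata comparison of two dataset records.

    Records must already be scoped to the same assembly and experiment
    type (the caller compares a dataset only against others from the same
    organism and technique).  Similar requires: cell types sharing a key
    parent class, and — where both records carry targets — similar targets.
    Unmatched terms degrade to "not similar" with a warning so one bad
    record cannot block a batch comparison.
    """
    interactions = interactions if interactions is not None else InteractionTable()
    onto = config.cell_type_ontology
    cell_shared: frozenset[str] = frozenset()
    hit_a = onto.fuzzy_match(rec_a.cell_type, config.fuzzy_threshold)
    hit_b = onto.fuzzy_match(rec_b.cell_type, config.fuzzy_threshold)
    if hit_a is None or hit_b is None:
        for rec, hit in ((rec_a, hit_a), (rec_b, hit_b)):
            if hit is None:
                warnings.warn(
                    f"cell type {rec.cell_type!r} ({rec.dataset_id}) matched no term"
                )
        return MetadataVerdict(False, cell_shared, None)
    cell_shared = onto.key_parents(hit_a[0]) & onto.key_parents(hit_b[0])
    cells_ok = bool(cell_shared)

    if rec_a.target is None and rec_b.target is None:
        return MetadataVerdict(cells_ok, cell_shared, None)
    if rec_a.target is None or rec_b.target is None:
        # applicability mismatch: one assay has a target, the other does not
        return MetadataVerdict(False, cell_shared, frozenset())
    tgt_ok, tgt_shared, tf_checked = targets_similar(
        rec_a.target, rec_b.target, config, interactions
    )
    return MetadataVerdict(cells_ok and tgt_ok, cell_shared, tgt_shared, tf_checked)
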