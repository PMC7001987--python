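"""Seed-reproducible synthetic cohorts, ontologies and coverage tracks.

Real deployments of this kind of engine sit on tens of thousands of
consortium datasets; everything here emulates the *statistical structure*
those pipelines assume — cohorts of TPM profiles whose classes are
separable at a set of planted discriminative features, toy is_a ontologies
with designated key parent classes, random protein-interaction tables and
small bedGraph tracks — so every other module is testable without any
download.  All generators are deterministic given their seed.

The log-normal cohort model: each feature f has a baseline log2 level
drawn once; a member of class c adds ``mean_shift`` (in within-class SD
units) at that class's signal features, plus N(0, noise_sd) noise, and the
row is exponentiated and renormalized to the TPM scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .coverage import GenomicInterval, DatasetRecord, TPM_TOTAL
from .ontology import InteractionTable, Ontology, OntologySet

__all__ = [
    "ClassSpec",
    "CohortSpec",
    "generate_cohort",
    "generate_toy_ontology",
    "generate_interactions",
    "generate_track",
    "toy_anatomy_ontology",
    "histone_mark_ontology",
    "go_like_ontology",
    "TimecourseVignette",
    "timecourse_vignette",
]


@dataclass(frozen=True)
class ClassSpec:
    """One planted class: its annotation term and its discriminative features."""

    term: str  # cell-type annotation written into the records
    n_members: int
    signal_features: tuple[int, ...]
    mean_shift: float = 3.0  # in within-class SD units

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("each class needs at least one member")
        if self.mean_shift < 0:
            raise ValueError("mean_shift must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort with planted class structure."""

    n_features: int
    classes: tuple[ClassSpec, ...]
    noise_sd: float = 1.0
    fraction_mislabeled: float = 0.0
    seed: int = 0
    assembly: str = "toy1"
    experiment_type: str = "RNA-seq"
    baseline_log2: float = 5.0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not self.classes:
            raise ValueError("at least one class required")
        if not 0.0 <= self.fraction_mislabeled <= 1.0:
            raise ValueError("fraction_mislabeled must be in [0, 1]")
        for cls in self.classes:
            if any(i < 0 or i >= self.n_features for i in cls.signal_features):
                raise ValueError("signal feature index out of range")

    @property
    def n_datasets(self) -> int:
        return sum(c.n_members for c in self.classes)


def generate_cohort(spec: CohortSpec) -> tuple[np.ndarray, list[DatasetRecord]]:
    """Draw a (datasets x features) TPM matrix and matching records.

    Mislabeled records (an exact count, round(fraction * n)) keep their
    true coverage signal but are annotated with another class's term —
    planting pairs that are similar by primary data only.
    """
    rng = np.random.default_rng(spec.seed)
    baseline = spec.baseline_log2 + rng.normal(0.0, 1.0, size=spec.n_features)
    rows, records, class_of = [], [], []
    i = 0
    for c_idx, cls in enumerate(spec.classes):
        mu = baseline.copy()
        mu[list(cls.signal_features)] += cls.mean_shift * spec.noise_sd
        for _ in range(cls.n_members):
            log2x = mu + rng.normal(0.0, spec.noise_sd, size=spec.n_features)
            rows.append(np.exp2(log2x))
            records.append(
                DatasetRecord(
                    dataset_id=f"ds{i:04d}",
                    experiment_id=f"exp{i:04d}",
                    assembly=spec.assembly,
                    experiment_type=spec.experiment_type,
                    cell_type=cls.term,
                    owner="generator",
                )
            )
            class_of.append(c_idx)
            i += 1
    matrix = np.vstack(rows)
    matrix = TPM_TOTAL * matrix / matrix.sum(axis=1, keepdims=True)

    n = spec.n_datasets
    k = int(np.floor(spec.fraction_mislabeled * n + 0.5))
    if k > 0 and len(spec.classes) > 1:
        flip = rng.choice(n, size=k, replace=False)
        for j in flip:
            wrong = spec.classes[(class_of[j] + 1) % len(spec.classes)]
            rec = records[j]
            records[j] = DatasetRecord(
                dataset_id=rec.dataset_id,
                experiment_id=rec.experiment_id,
                assembly=rec.assembly,
                experiment_type=rec.experiment_type,
                cell_type=wrong.term,
                target=rec.target,
                owner=rec.owner,
                public=rec.public,
            )
    return matrix, records


def generate_toy_ontology(depth: int, branching: int, key_level: int = 1) -> Ontology:
    """Balanced is_a tree; nodes at ``key_level`` are the key classes.

    ``depth`` counts levels (root is level 0), so depth=3, branching=2
    gives 7 terms with 2 key classes at level 1.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    if not 0 < key_level < depth:
        raise ValueError("key_level must be between 1 and depth-1")
    terms: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    keys: list[str] = []
    level_nodes = [["T:root"]]
    terms["T:root"] = "root"
    for level in range(1, depth):
        new_nodes = []
        for parent in level_nodes[-1]:
            for b in range(branching):
                tid = f"{parent}.{b}"
                terms[tid] = f"term {tid[2:]}"
                edges.append((tid, parent))
                new_nodes.append(tid)
                if level == key_level:
                    keys.append(tid)
        level_nodes.append(new_nodes)
    return Ontology(terms, edges, key_classes=keys, name="toy-tree")


def generate_interactions(
    terms: Sequence[str], density: float, seed: int = 0
) -> InteractionTable:
    """Random symmetric interaction table over ``terms``.

    Each unordered pair is present with probability ``density`` (0 and 1
    are exact), with a confidence score in [0.5, 1.0].
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    table = InteractionTable()
    terms = sorted(set(terms))
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            if rng.random() < density or density == 1.0:
                table.add(a, b, 0.5 + 0.5 * float(rng.random()))
    return table


def generate_track(
    intervals: Sequence[GenomicInterval | tuple],
    values: Sequence[float],
    path: str | Path,
) -> Path:
    """Write a bedGraph with the given per-interval constant values.

    Intervals must not overlap within a chromosome (a coverage track
    assigns one value per base).
    """
    ivs = [
        iv if isinstance(iv, GenomicInterval) else GenomicInterval(iv[0], iv[1], iv[2], f"iv{i}")
        for i, iv in enumerate(intervals)
    ]
    if len(ivs) != len(values):
        raise ValueError("one value per interval required")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom_ivs in by_chrom.values():
        chrom_ivs.sort(key=lambda iv: iv.start)
        for prev, cur in zip(chrom_ivs, chrom_ivs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping track intervals {prev.chrom}:{prev.start}-{prev.end} "
                    f"and {cur.chrom}:{cur.start}-{cur.end}"
                )
    path = Path(path)
    with open(path, "w") as fh:
        for iv, val in zip(ivs, values):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{val}\n")
    return path


# ---------------------------------------------------------------------------
# hand-built domain fixtures


def toy_anatomy_ontology() -> Ontology:
    """Small anatomy DAG with organ-system-level key classes."""
    terms = {
        "BT:root": "anatomical entity",
        "BT:cardio": "cardiovascular system",
        "BT:neuro": "neurological system",
        "BT:stem": "stem cell",
        "BT:heart": "heart",
        "BT:cm": "cardiomyocyte",
        "BT:brain": "brain",
        "BT:neuron": "neuron",
        "BT:esc": "embryonic stem cell",
    }
    edges = [
        ("BT:cardio", "BT:root"),
        ("BT:neuro", "BT:root"),
        ("BT:stem", "BT:root"),
        ("BT:heart", "BT:cardio"),
        ("BT:cm", "BT:heart"),
        ("BT:brain", "BT:neuro"),
        ("BT:neuron", "BT:neuro"),
        ("BT:esc", "BT:stem"),
    ]
    synonyms = {"BT:cm": ["cardiac muscle cell"], "BT:esc": ["hESC", "ES cell"]}
    return Ontology(
        terms,
        edges,
        key_classes=["BT:cardio", "BT:neuro", "BT:stem"],
        synonyms=synonyms,
        name="toy-anatomy",
    )


def histone_mark_ontology() -> Ontology:
    """Histone-modification DAG grouping marks by enrichment location.

    H3K4me3 carries two parents — "at active promoters" and "at poised
    promoters" — so target prediction is genuinely multi-label.
    """
    terms = {
        "HM:root": "histone modification",
        "HM:actpro": "at active promoters",
        "HM:poispro": "at poised promoters",
        "HM:actenh": "at active enhancers",
        "HM:repr": "at repressed regions",
        "HM:h3k4me3": "H3K4me3",
        "HM:h3k27ac": "H3K27ac",
        "HM:h3k4me1": "H3K4me1",
        "HM:h3k27me3": "H3K27me3",
        "HM:h3k9me3": "H3K9me3",
    }
    edges = [
        ("HM:actpro", "HM:root"),
        ("HM:poispro", "HM:root"),
        ("HM:actenh", "HM:root"),
        ("HM:repr", "HM:root"),
        ("HM:h3k4me3", "HM:actpro"),
        ("HM:h3k4me3", "HM:poispro"),
        ("HM:h3k27ac", "HM:actpro"),
        ("HM:h3k27ac", "HM:actenh"),
        ("HM:h3k4me1", "HM:actenh"),
        ("HM:h3k27me3", "HM:repr"),
        ("HM:h3k9me3", "HM:repr"),
    ]
    return Ontology(
        terms,
        edges,
        key_classes=["HM:actpro", "HM:poispro", "HM:actenh", "HM:repr"],
        name="histone-marks",
    )


def go_like_ontology() -> Ontology:
    """Minimal molecular-function DAG whose TF key class tags known factors."""
    terms = {
        "GO:root": "molecular function",
        "GO:tf": "DNA-binding transcription factor activity",
        "GO:enz": "chromatin modifying enzyme activity",
        "GO:gata4": "GATA4",
        "GO:nanog": "NANOG",
        "GO:pou5f1": "POU5F1",
        "GO:tbx5": "TBX5",
        "GO:ezh2": "EZH2",
    }
    edges = [
        ("GO:tf", "GO:root"),
        ("GO:enz", "GO:root"),
        ("GO:gata4", "GO:tf"),
        ("GO:nanog", "GO:tf"),
        ("GO:pou5f1", "GO:tf"),
        ("GO:tbx5", "GO:tf"),
        ("GO:ezh2", "GO:enz"),
    ]
    synonyms = {"GO:pou5f1": ["OCT4"]}
    return Ontology(
        terms,
        edges,
        key_classes=["GO:tf", "GO:enz"],
        synonyms=synonyms,
        name="go-like",
    )


def default_ontology_set() -> OntologySet:
    """The standard toy configuration: anatomy + (GO-like, histone) targets."""
    return OntologySet(
        cell_type_ontology=toy_anatomy_ontology(),
        target_ontologies=(go_like_ontology(), histone_mark_ontology()),
        tf_classes=frozenset({"GO:tf"}),
    )


# ---------------------------------------------------------------------------
# differentiation time-course preset


@dataclass
class TimecourseVignette:
    """A stem-to-cardiac differentiation cohort plus 4 user timepoints.

    The reference cohort holds ``n_per_class`` stem-like and cardiac-like
    RNA-seq datasets.  The four timepoint datasets (days 0, 2, 4 and 30)
    interpolate linearly between the two class centroids in log space, and
    are all annotated by their uploader with the stem-cell term — so late
    timepoints can only be linked to cardiac data through primary
    (coverage-predicted) similarity.
    """

    matrix: np.ndarray
    records: list[DatasetRecord]
    timecourse_matrix: np.ndarray
    timecourse_records: list[DatasetRecord]
    days: tuple[int, ...]
    ontologies: OntologySet = field(repr=False)
    stem_class: str = "BT:stem"
    cardiac_class: str = "BT:cardio"

    @property
    def stem_ids(self) -> list[str]:
        return [r.dataset_id for r in self.records if r.cell_type == "embryonic stem cell"]

    @property
    def cardiac_ids(self) -> list[str]:
        return [r.dataset_id for r in self.records if r.cell_type != "embryonic stem cell"]


def timecourse_vignette(
    seed: int = 0,
    n_per_class: int = 100,
    n_features: int = 1500,
    n_signal: int = 60,
    mean_shift: float = 3.0,
    days: tuple[int, ...] = (0, 2, 4, 30),
) -> TimecourseVignette:
    """Build the differentiation vignette.

    ``n_per_class`` defaults to 100 so the reference cohort clears the
    minimum-cohort training gate.  Timepoint noise is half the cohort
    noise, keeping the interpolation path tight around the centroid line.
    """
    if n_features < 2 * n_signal:
        raise ValueError("n_features must be at least 2 * n_signal")
    rng = np.random.default_rng(seed)
    sig_a = tuple(range(0, n_signal))
    sig_b = tuple(range(n_signal, 2 * n_signal))
    spec = CohortSpec(
        n_features=n_features,
        classes=(
            ClassSpec("embryonic stem cell", n_per_class, sig_a, mean_shift),
            ClassSpec("heart", n_per_class, sig_b, mean_shift),
        ),
        noise_sd=1.0,
        seed=int(rng.integers(2**31 - 1)),
    )
    matrix, records = generate_cohort(spec)

    baseline = spec.baseline_log2 + np.random.default_rng(spec.seed).normal(
        0.0, 1.0, size=n_features
    )
    mu_a, mu_b = baseline.copy(), baseline.copy()
    mu_a[list(sig_a)] += mean_shift * spec.noise_sd
    mu_b[list(sig_b)] += mean_shift * spec.noise_sd

    tc_rows, tc_records = [], []
    max_day = max(days)
    for day in days:
        t = day / max_day
        log2x = (1 - t) * mu_a + t * mu_b + rng.normal(0.0, 0.5 * spec.noise_sd, n_features)
        tc_rows.append(np.exp2(log2x))
        tc_records.append(
            DatasetRecord(
                dataset_id=f"tc_day{day:02d}",
                experiment_id=f"tc_day{day:02d}",
                assembly=spec.assembly,
                experiment_type=spec.experiment_type,
                cell_type="embryonic stem cell",
                owner="uploader",
                public=False,
            )
        )
    tc = np.vstack(tc_rows)
    tc = TPM_TOTAL * tc / tc.sum(axis=1, keepdims=True)
    return TimecourseVignette(
        matrix=matrix,
        records=records,
        timecourse_matrix=tc,
        timecourse_records=tc_records,
        days=tuple(days),
        ontologies=default_ontology_set(),
    )
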