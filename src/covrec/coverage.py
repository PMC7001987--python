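"""Feature coverage extraction and TPM profiles.

Datasets enter the system as genome-wide read coverage tracks (bigWig, or
bedGraph as a text fallback).  Coverage is summed over fixed, ordered lists
of genomic features (promoters, gene bodies, transcripts, enhancers), then
converted to transcripts-per-million (TPM): per-feature coverage rates
(sum / length) rescaled so each dataset's profile sums to 10^6.  Only the
TPM profile and the metadata record are retained downstream; raw coverage
is discarded after featurization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_CLASSES",
    "GenomicInterval",
    "FeatureSet",
    "DatasetProfile",
    "DatasetRecord",
    "BedGraphTrack",
    "load_feature_set",
    "write_feature_set",
    "extract_counts",
    "compute_tpm",
    "build_profile",
    "write_profile_matrix",
    "read_profile_matrix",
    "write_records",
    "read_records",
]

FEATURE_CLASSES = ("promoter", "gene_body", "transcript", "enhancer")

TPM_TOTAL = 1_000_000.0


class CoverageError(ValueError):
    """Malformed track or feature input."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with a unique name."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise CoverageError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FeatureSet:
    """Ordered feature list; ordering defines the profile vector index."""

    assembly: str
    feature_class: str
    intervals: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise CoverageError(
                f"unknown feature class {self.feature_class!r}; "
                f"expected one of {FEATURE_CLASSES}"
            )
        names = [iv.name for iv in self.intervals]
        if len(set(names)) != len(names):
            raise CoverageError("duplicate feature names in feature set")

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def names(self) -> list[str]:
        return [iv.name for iv in self.intervals]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self.intervals], dtype=float)


@dataclass(frozen=True)
class DatasetRecord:
    """User-annotated metadata for one dataset.

    An *experiment* describes a single biological sample and groups one or
    more datasets (replicates, or the same replicate on different
    assemblies).  ``target`` is experiment-type specific (e.g. a ChIP
    antibody target) and legitimately absent for assays such as RNA-seq.
    """

    dataset_id: str
    experiment_id: str
    assembly: str
    experiment_type: str
    cell_type: str
    target: str | None = None
    owner: str = "anonymous"
    public: bool = True


@dataclass(frozen=True)
class DatasetProfile:
    """One dataset's TPM vector over a named feature set."""

    dataset_id: str
    experiment_id: str
    assembly: str
    experiment_type: str
    feature_class: str
    tpm: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        tpm = np.asarray(self.tpm, dtype=float)
        object.__setattr__(self, "tpm", tpm)
        if np.any(tpm < 0):
            raise CoverageError("TPM values must be non-negative")
        total = tpm.sum()
        if total > 0 and abs(total - TPM_TOTAL) > 1e-6 * TPM_TOTAL:
            raise CoverageError(f"TPM vector sums to {total}, expected {TPM_TOTAL}")

    @property
    def degenerate(self) -> bool:
        """True for zero-signal datasets (excluded from classifier training)."""
        return float(self.tpm.sum()) == 0.0


def load_feature_set(path: str | Path, feature_class: str, assembly: str) -> FeatureSet:
    """Read a BED3/BED4+ file into a FeatureSet.

    Column 4 is used as the feature name when present; otherwise names are
    synthesized as ``chrom:start-end``.  Coordinates are BED 0-based
    half-open and preserved as such.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise CoverageError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise CoverageError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) >= 4 and fields[3] else f"{chrom}:{start}-{end}"
            try:
                intervals.append(GenomicInterval(chrom, start, end, name))
            except CoverageError as exc:
                raise CoverageError(f"{path}: line {lineno}: {exc}") from exc
    return FeatureSet(assembly=assembly, feature_class=feature_class, intervals=tuple(intervals))


def write_feature_set(features: FeatureSet, path: str | Path) -> None:
    """Export a FeatureSet as BED4 (round-trips through load_feature_set)."""
    with open(path, "w") as fh:
        for iv in features.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


class BedGraphTrack:
    """In-memory coverage track parsed from a 4-column bedGraph file.

    Intervals are half-open; bases not covered by any interval have value 0.
    """

    def __init__(self, regions: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._regions = dict(regions)

    @classmethod
    def from_file(cls, path: str | Path) -> "BedGraphTrack":
        try:
            df = pd.read_csv(
                path,
                sep=r"\s+",
                header=None,
                comment="#",
                names=["chrom", "start", "end", "value"],
                dtype={"chrom": str},
            )
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise CoverageError(f"cannot parse bedGraph {path}: {exc}") from exc
        if df.isna().any().any():
            raise CoverageError(f"malformed bedGraph {path}: missing fields")
        if (df["value"] < 0).any():
            raise CoverageError(f"negative coverage values in {path}")
        if (df["start"] >= df["end"]).any():
            raise CoverageError(f"empty or inverted interval in {path}")
        regions = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            regions[str(chrom)] = (
                sub["start"].to_numpy(dtype=np.int64),
                sub["end"].to_numpy(dtype=np.int64),
                sub["value"].to_numpy(dtype=float),
            )
        return cls(regions)

    def chroms(self) -> list[str]:
        return list(self._regions)

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end); 0 for absent chromosomes."""
        if chrom not in self._regions:
            return 0.0
        starts, ends, values = self._regions[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if hi <= lo:
            return 0.0
        s, e, v = starts[lo:hi], ends[lo:hi], values[lo:hi]
        overlap = np.minimum(e, end) - np.maximum(s, start)
        return float(np.sum(overlap.clip(min=0) * v))


def _open_track(track):
    """Accept a BedGraphTrack, an open pyBigWig handle, or a file path."""
    if isinstance(track, BedGraphTrack):
        return track, False
    if hasattr(track, "chroms") and hasattr(track, "values"):  # pyBigWig handle
        return track, True
    path = Path(track)
    if path.suffix.lower() in {".bw", ".bigwig"}:
        import pyBigWig

        try:
            return pyBigWig.open(str(path)), True
        except RuntimeError as exc:
            raise CoverageError(f"cannot open bigWig {path}: {exc}") from exc
    return BedGraphTrack.from_file(path), False


def extract_counts(track, features: FeatureSet) -> np.ndarray:
    """Per-feature summed coverage: count_i = Σ_{b in [start_i, end_i)} value(b).

    ``track`` may be a bigWig path, an open pyBigWig handle, a bedGraph path,
    or a :class:`BedGraphTrack`.  Features on chromosomes absent from the
    track yield 0; features overhanging chromosome ends are clipped to the
    available data.  Strand is ignored (coverage tracks are unstranded).
    """
    handle, is_bigwig = _open_track(track)
    counts = np.zeros(len(features), dtype=float)
    if is_bigwig:
        chrom_sizes = handle.chroms()
        for i, iv in enumerate(features.intervals):
            size = chrom_sizes.get(iv.chrom)
            if not size:
                continue
            start, end = min(iv.start, size), min(iv.end, size)
            if end <= start:
                continue
            vals = handle.values(iv.chrom, start, end, numpy=True)
            vals = np.nan_to_num(vals, nan=0.0)
            if np.any(vals < 0):
                raise CoverageError(f"negative coverage at {iv.chrom}:{start}-{end}")
            counts[i] = float(vals.sum())
    else:
        for i, iv in enumerate(features.intervals):
            counts[i] = handle.interval_sum(iv.chrom, iv.start, iv.end)
    return counts


def compute_tpm(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Length-normalized TPM: rate_i = counts_i / lengths_i, rescaled to 10^6.

    All-zero counts give an all-zero vector (degenerate dataset).  TPM is
    invariant to global rescaling of the input coverage.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise CoverageError("counts and lengths must have identical shape")
    if np.any(lengths <= 0):
        raise CoverageError("feature lengths must be positive")
    if np.any(counts < 0):
        raise CoverageError("coverage counts must be non-negative")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        return np.zeros_like(rates)
    return TPM_TOTAL * rates / total


def build_profile(record: DatasetRecord, track, features: FeatureSet) -> DatasetProfile:
    """Featurize one dataset: extract counts, convert to TPM, drop raw coverage."""
    if record.assembly != features.assembly:
        raise CoverageError(
            f"assembly mismatch: record {record.assembly!r} vs "
            f"feature set {features.assembly!r}"
        )
    counts = extract_counts(track, features)
    tpm = compute_tpm(counts, features.lengths)
    return DatasetProfile(
        dataset_id=record.dataset_id,
        experiment_id=record.experiment_id,
        assembly=record.assembly,
        experiment_type=record.experiment_type,
        feature_class=features.feature_class,
        tpm=tpm,
    )


# ---------------------------------------------------------------------------
# serialization: TSV profile matrix (rows = features, columns = datasets)
# with a JSON sidecar of DatasetRecords


def write_profile_matrix(
    profiles: Sequence[DatasetProfile], features: FeatureSet, path: str | Path
) -> None:
    data = {p.dataset_id: p.tpm for p in profiles}
    df = pd.DataFrame(data, index=features.names)
    df.index.name = "feature"
    df.to_csv(path, sep="\t")


def read_profile_matrix(path: str | Path) -> pd.DataFrame:
    """Profile matrix as DataFrame (rows = features, columns = dataset ids)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_records(records: Iterable[DatasetRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(r) for r in records], fh, indent=1)


def read_records(path: str | Path) -> list[DatasetRecord]:
    with open(path) as fh:
        return [DatasetRecord(**d) for d in json.load(fh)]
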