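"""Binned genomic tracks and feature sets, with bedGraph/BED text I/O.

All coordinates are 0-based half-open throughout the package.  A
:class:`BinnedTrack` stores one fixed-width value vector per chromosome;
bin *i* of a chromosome covers ``[i*w, (i+1)*w)`` (the final bin is
implicitly truncated at the chromosome end).  Features carry a class
label and an *anchor* base pair: the transcription start site for
promoters (strand-aware) and the interval midpoint for everything else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence

import numpy as np

PROMOTER_CLASS = "promoter"

#: canonical feature class labels used across the pipeline
FEATURE_CLASSES = ("promoter", "enhancer", "PRE", "origin", "random", "transcript")


class TrackIOError(ValueError):
    """Raised for malformed track or feature files."""


def n_bins(chrom_length: int, bin_width: int) -> int:
    return math.ceil(chrom_length / bin_width)


@dataclass
class BinnedTrack:
    """Fixed-width binned signal over a declared genome.

    Parameters
    ----------
    bin_width
        Bin size in bp.
    chrom_lengths
        Ordered mapping of chromosome name to length in bp; the ordering
        defines output order for all writers.
    values
        Mapping of chromosome name to a float vector of length
        ``ceil(length / bin_width)``.
    """

    bin_width: int
    chrom_lengths: Dict[str, int]
    values: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if not self.values:
            self.values = {
                c: np.zeros(n_bins(length, self.bin_width))
                for c, length in self.chrom_lengths.items()
            }
        for chrom, length in self.chrom_lengths.items():
            vec = np.asarray(self.values[chrom], dtype=float)
            expect = n_bins(length, self.bin_width)
            if vec.shape != (expect,):
                raise ValueError(
                    f"{chrom}: expected {expect} bins, got {vec.shape}"
                )
            self.values[chrom] = vec

    @property
    def chromosomes(self) -> List[str]:
        return list(self.chrom_lengths)

    def bin_capacity(self, chrom: str, i: int) -> int:
        """bp actually covered by bin *i* (smaller for the last bin)."""
        w = self.bin_width
        return min((i + 1) * w, self.chrom_lengths[chrom]) - i * w

    def all_values(self) -> np.ndarray:
        """Concatenation of every chromosome's bins (declaration order)."""
        return np.concatenate([self.values[c] for c in self.chrom_lengths])

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values()))

    def same_geometry(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.chrom_lengths == other.chrom_lengths
        )

    def copy_with(self, values: Mapping[str, np.ndarray]) -> "BinnedTrack":
        return BinnedTrack(self.bin_width, dict(self.chrom_lengths), dict(values))

    def assert_finite(self) -> None:
        for chrom, vec in self.values.items():
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite values on {chrom}")


@dataclass(frozen=True)
class Feature:
    """A classed genomic interval with an anchor point."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    class_label: str = "random"
    name: str = ""
    anchor: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.anchor < 0:
            object.__setattr__(self, "anchor", default_anchor(
                self.start, self.end, self.strand, self.class_label))

    @property
    def oriented(self) -> int:
        """+1 for forward/unstranded, -1 for reverse."""
        return -1 if self.strand == "-" else 1


def default_anchor(start: int, end: int, strand: str, class_label: str) -> int:
    """TSS for promoters (start for '+', end-1 for '-'); midpoint otherwise."""
    if class_label == PROMOTER_CLASS:
        return end - 1 if strand == "-" else start
    return (start + end) // 2


class FeatureSet:
    """Ordered collection of :class:`Feature` with a per-class index."""

    def __init__(self, features: Iterable[Feature],
                 chrom_lengths: Mapping[str, int] | None = None):
        self.features: List[Feature] = list(features)
        self.chrom_lengths = dict(chrom_lengths) if chrom_lengths else None
        if self.chrom_lengths is not None:
            for f in self.features:
                if f.chrom not in self.chrom_lengths:
                    raise TrackIOError(f"feature on undeclared chromosome {f.chrom}")
                if f.end > self.chrom_lengths[f.chrom]:
                    raise TrackIOError(
                        f"feature {f.chrom}:{f.start}-{f.end} beyond chromosome end")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __getitem__(self, i: int) -> Feature:
        return self.features[i]

    def by_class(self, class_label: str) -> "FeatureSet":
        return FeatureSet(
            (f for f in self.features if f.class_label == class_label),
            self.chrom_lengths,
        )

    @property
    def classes(self) -> List[str]:
        seen: Dict[str, None] = {}
        for f in self.features:
            seen.setdefault(f.class_label, None)
        return list(seen)


def concat_feature_sets(sets: Sequence["FeatureSet"]) -> "FeatureSet":
    if not sets:
        raise ValueError("nothing to concatenate")
    return FeatureSet((f for s in sets for f in s), sets[0].chrom_lengths)


# ---------------------------------------------------------------------------
# chrom.sizes


def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column TSV of chromosome name and length."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise TrackIOError(f"{path}:{lineno}: expected 'name length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path, bin_width: int,
                  chrom_lengths: Mapping[str, int]) -> BinnedTrack:
    """Read a bedGraph file into a :class:`BinnedTrack`.

    Each bin's value is the coverage-length-weighted sum of intervals over
    the bin, divided by the bin's capacity in bp; uncovered bins are 0.
    Intervals may arrive unsorted but must not overlap.
    """
    track = BinnedTrack(bin_width, dict(chrom_lengths))
    w = bin_width
    covered: Dict[str, list] = {c: [] for c in chrom_lengths}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise TrackIOError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom not in chrom_lengths:
                raise TrackIOError(f"{path}:{lineno}: undeclared chromosome {chrom}")
            if e > chrom_lengths[chrom] or s < 0 or s >= e:
                raise TrackIOError(
                    f"{path}:{lineno}: interval [{s},{e}) outside {chrom}")
            covered[chrom].append((s, e))
            vec = track.values[chrom]
            for i in range(s // w, math.ceil(e / w)):
                overlap = min(e, (i + 1) * w) - max(s, i * w)
                vec[i] += v * overlap / track.bin_capacity(chrom, i)
    for chrom, ivals in covered.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise TrackIOError(
                    f"{path}: overlapping intervals on {chrom}: "
                    f"[{s1},{e1}) and [{s2},{e2})")
    return track


def write_bedgraph(track: BinnedTrack, path, suppress_zeros: bool = False) -> None:
    """Write a track as bedGraph, merging runs of equal values.

    By default zero-valued intervals are written explicitly so that
    ``read_bedgraph(write_bedgraph(t))`` is an exact round trip; pass
    ``suppress_zeros=True`` for a sparse file.
    """
    track.assert_finite()
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom in track.chrom_lengths:
            vec = track.values[chrom]
            length = track.chrom_lengths[chrom]
            if vec.size == 0:
                continue
            # boundaries of runs of equal values
            change = np.flatnonzero(np.diff(vec)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [vec.size]))
            for b0, b1 in zip(starts, ends):
                v = vec[b0]
                if suppress_zeros and v == 0.0:
                    continue
                fh.write(f"{chrom}\t{b0 * w}\t{min(b1 * w, length)}\t{v:.17g}\n")


# ---------------------------------------------------------------------------
# BED


def read_bed(path, class_label: str,
             chrom_lengths: Mapping[str, int] | None = None) -> FeatureSet:
    """Read BED3/BED6 features of one class; anchors follow the class rule."""
    feats: List[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise TrackIOError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                chrom, s, e = parts[0], int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise TrackIOError(f"{path}:{lineno}: {exc}") from None
            name = parts[3] if len(parts) > 3 else f"{class_label}_{lineno}"
            strand = parts[5] if len(parts) > 5 else "."
            if strand not in ("+", "-", "."):
                raise TrackIOError(f"{path}:{lineno}: bad strand {strand!r}")
            if s < 0 or s >= e:
                raise TrackIOError(f"{path}:{lineno}: bad interval [{s},{e})")
            feats.append(Feature(chrom, s, e, strand, class_label, name))
    return FeatureSet(feats, chrom_lengths)


def write_bed(features: Sequence[Feature] | FeatureSet, path) -> None:
    """Write features as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\n")
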