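"""Genomic coordinate conventions and fragment-level interaction records.

All coordinates are 0-based half-open (BED convention). The restriction
fragment map is the coordinate unit of every interaction statement: a
promoter "bait" fragment and a distal "other-end" fragment are identified
by integer fragment ids, and SNPs are assigned to fragments by the same
point-to-fragment rule used for sequencing reads in capture Hi-C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomicInterval",
    "FragmentMap",
    "GeneModel",
    "Interaction",
    "AnnotationSet",
    "digest_genome",
]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def __len__(self) -> int:
        return self.end - self.start


class FragmentMap:
    """Ordered, non-overlapping restriction fragments tiling each chromosome.

    Fragments carry unique integer ids (position in the global ordering by
    default). Within a chromosome they must be sorted, non-overlapping and
    contiguous: each fragment's end equals the next fragment's start, so the
    map is an exact partition of the digested range.
    """

    def __init__(self, intervals: list[GenomicInterval], ids: list[int] | None = None):
        if ids is None:
            ids = list(range(len(intervals)))
        if len(ids) != len(intervals):
            raise ValueError("ids and intervals must have equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("fragment ids must be unique")
        self._intervals: dict[int, GenomicInterval] = dict(zip(ids, intervals))
        # per-chromosome sorted arrays for O(log n) point lookup
        self._chrom_starts: dict[str, np.ndarray] = {}
        self._chrom_ends: dict[str, np.ndarray] = {}
        self._chrom_ids: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for fid, iv in zip(ids, intervals):
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, fid))
        for chrom, rows in by_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            if np.any(ends[:-1] != starts[1:]):
                i = int(np.argmax(ends[:-1] != starts[1:]))
                raise ValueError(
                    f"fragments on {chrom} are not contiguous near position {ends[i]}"
                )
            self._chrom_starts[chrom] = starts
            self._chrom_ends[chrom] = ends
            self._chrom_ids[chrom] = np.array([r[2] for r in rows])

    def __len__(self) -> int:
        return len(self._intervals)

    def __contains__(self, fid: int) -> bool:
        return fid in self._intervals

    @property
    def fragment_ids(self) -> list[int]:
        return list(self._intervals)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._chrom_starts)

    def fragment(self, fid: int) -> GenomicInterval:
        return self._intervals[fid]

    def assign(self, chrom: str, pos: int) -> int | None:
        """Fragment id containing ``pos`` (half-open), or None if untiled."""
        starts = self._chrom_starts.get(chrom)
        if starts is None:
            return None
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0 or pos >= self._chrom_ends[chrom][i]:
            return None
        return int(self._chrom_ids[chrom][i])

    def assign_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized ``assign``; -1 marks positions outside the tiled range."""
        positions = np.asarray(positions)
        out = np.full(positions.shape, -1, dtype=np.int64)
        starts = self._chrom_starts.get(chrom)
        if starts is None:
            return out
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < self._chrom_ends[chrom][np.clip(idx, 0, None)])
        out[ok] = self._chrom_ids[chrom][idx[ok]]
        return out

    def intervals_in_order(self) -> list[tuple[int, GenomicInterval]]:
        out: list[tuple[int, GenomicInterval]] = []
        for chrom in self._chrom_starts:
            for fid in self._chrom_ids[chrom]:
                out.append((int(fid), self._intervals[int(fid)]))
        return out


def digest_genome(
    chrom_lengths: dict[str, int], cut_sites: dict[str, list[int]] | None = None
) -> FragmentMap:
    """Partition each chromosome at the given cut positions.

    Cut sites must be strictly inside (0, length), sorted and unique; the
    resulting fragments tile the chromosome exactly (cuts + 1 fragments).
    """
    cut_sites = cut_sites or {}
    intervals: list[GenomicInterval] = []
    for chrom, length in chrom_lengths.items():
        cuts = list(cut_sites.get(chrom, []))
        if sorted(set(cuts)) != cuts:
            raise ValueError(f"cut sites on {chrom} must be sorted and unique")
        for c in cuts:
            if not (0 < c < length):
                raise ValueError(
                    f"cut site {c} outside (0, {length}) on chromosome {chrom}"
                )
        bounds = [0, *cuts, length]
        for a, b in zip(bounds[:-1], bounds[1:]):
            intervals.append(GenomicInterval(chrom, a, b))
    return FragmentMap(intervals)


@dataclass
class GeneModel:
    """A gene body with its TSS and the baited promoter fragment(s)."""

    gene_id: str
    body: GenomicInterval
    strand: str
    tss: int
    promoter_fragment_ids: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (self.body.start <= self.tss < self.body.end):
            raise ValueError(
                f"TSS {self.tss} outside gene body [{self.body.start}, {self.body.end})"
                f" for {self.gene_id}"
            )

    @classmethod
    def from_coords(
        cls,
        gene_id: str,
        chrom: str,
        start: int,
        end: int,
        strand: str,
        tss: int | None = None,
        fragment_map: FragmentMap | None = None,
        extra_promoter_fragments: set[int] | None = None,
    ) -> "GeneModel":
        if tss is None:
            tss = start if strand == "+" else end - 1
        promoter: set[int] = set(extra_promoter_fragments or ())
        if fragment_map is not None:
            fid = fragment_map.assign(chrom, tss)
            if fid is not None:
                promoter.add(fid)
        return cls(gene_id, GenomicInterval(chrom, start, end), strand, tss,
                   frozenset(promoter))


@dataclass(frozen=True)
class Interaction:
    """A significant bait/other-end fragment interaction call."""

    bait_fragment_id: int
    other_end_fragment_id: int
    score: float

    def __post_init__(self) -> None:
        if self.bait_fragment_id == self.other_end_fragment_id:
            raise ValueError("bait and other-end fragments must differ")


class AnnotationSet:
    """A named union of genomic intervals with point-in-union membership.

    Input intervals may overlap; they are merged at construction so that a
    point covered by several of them is counted once.
    """

    def __init__(self, name: str, intervals: list[GenomicInterval]):
        self.name = name
        self.intervals = list(intervals)
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, spans in by_chrom.items():
            spans.sort()
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._merged[chrom] = (
                np.array([m[0] for m in merged]),
                np.array([m[1] for m in merged]),
            )

    def contains(self, chrom: str, pos: int) -> bool:
        got = self._merged.get(chrom)
        if got is None:
            return False
        starts, ends = got
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def contains_many(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions)
        got = self._merged.get(chrom)
        if got is None:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = got
        idx = np.searchsorted(starts, positions, side="right") - 1
        return (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
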