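"""In-silico restriction digest of a genome and fragment lookup.

The digest tiles every chromosome into half-open restriction fragments
``[start, end)`` with globally unique integer ids, strictly increasing in
(chromosome order, coordinate).  Because ids are dense per chromosome,
``|id_i - id_j| == 1`` means genomic adjacency, which downstream filters
(self-ligation, undigested-neighbour collapsing) rely on.  Chromosome
boundaries break adjacency by construction: the first id of each chromosome
is offset so ids on different chromosomes are never consecutive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .enzyme import RestrictionEnzyme, reverse_complement


@dataclass(frozen=True)
class RestrictionFragment:
    """One restriction fragment: half-open interval plus its global id."""

    chrom: str
    start: int
    end: int
    fragment_id: int

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def __len__(self) -> int:
        return self.end - self.start


class FragmentMap:
    """Per-chromosome restriction-fragment tiling with O(log n) lookup."""

    def __init__(
        self,
        enzyme: RestrictionEnzyme | None,
        chrom_sizes: Mapping[str, int],
        internal_cuts: Mapping[str, Iterable[int]],
    ) -> None:
        self.enzyme = enzyme
        self.chroms: list[str] = list(chrom_sizes)
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self._starts: dict[str, np.ndarray] = {}
        self._offsets: dict[str, int] = {}
        offset = 0
        for chrom in self.chroms:
            size = self.chrom_sizes[chrom]
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
            cuts = np.asarray(sorted(set(internal_cuts.get(chrom, ()))), dtype=np.int64)
            if cuts.size and (cuts[0] <= 0 or cuts[-1] >= size):
                raise ValueError(f"cut positions outside (0, {size}) on {chrom}")
            self._starts[chrom] = np.concatenate(([0], cuts))
            self._offsets[chrom] = offset
            # +1 gap between chromosomes keeps ids on different chromosomes
            # from ever being adjacent (|Δid| == 1 implies same chromosome).
            offset += cuts.size + 1 + 1
        self._total = offset

    # -- digest ----------------------------------------------------------

    @classmethod
    def from_genome(
        cls, genome: Mapping[str, str], enzyme: RestrictionEnzyme
    ) -> "FragmentMap":
        """Digest ``genome`` (mapping name -> sequence) with ``enzyme``."""
        sizes: dict[str, int] = {}
        cuts: dict[str, list[int]] = {}
        for chrom, seq in genome.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {chrom!r} has empty sequence")
            sizes[chrom] = len(seq)
            cuts[chrom] = enzyme.cut_positions(seq)
        return cls(enzyme, sizes, cuts)

    # -- queries ---------------------------------------------------------

    def n_fragments(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self._starts[chrom])
        return sum(len(s) for s in self._starts.values())

    def locate(self, chrom: str, pos: int) -> int:
        """Fragment id of the fragment with ``start <= pos < end``."""
        if chrom not in self._starts:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(
                f"position {pos} outside [0, {self.chrom_sizes[chrom]}) on {chrom}"
            )
        idx = int(np.searchsorted(self._starts[chrom], pos, side="right")) - 1
        return self._offsets[chrom] + idx

    def chrom_of(self, fragment_id: int) -> str:
        for chrom in self.chroms:
            off = self._offsets[chrom]
            if off <= fragment_id < off + len(self._starts[chrom]):
                return chrom
        raise KeyError(f"unknown fragment id {fragment_id}")

    def fragment(self, fragment_id: int) -> RestrictionFragment:
        chrom = self.chrom_of(fragment_id)
        idx = fragment_id - self._offsets[chrom]
        starts = self._starts[chrom]
        start = int(starts[idx])
        end = (
            int(starts[idx + 1])
            if idx + 1 < len(starts)
            else self.chrom_sizes[chrom]
        )
        return RestrictionFragment(chrom, start, end, fragment_id)

    def fragments(self, chrom: str | None = None) -> Iterator[RestrictionFragment]:
        chroms = [chrom] if chrom is not None else self.chroms
        for c in chroms:
            starts = self._starts[c]
            ends = np.concatenate((starts[1:], [self.chrom_sizes[c]]))
            off = self._offsets[c]
            for i, (s, e) in enumerate(zip(starts, ends)):
                yield RestrictionFragment(c, int(s), int(e), off + i)

    def fragment_ids(self, chrom: str) -> np.ndarray:
        """Global ids of all fragments on ``chrom`` in coordinate order."""
        off = self._offsets[chrom]
        return np.arange(off, off + len(self._starts[chrom]), dtype=np.int64)

    def starts(self, chrom: str) -> np.ndarray:
        return self._starts[chrom].copy()

    def ends(self, chrom: str) -> np.ndarray:
        return np.concatenate((self._starts[chrom][1:], [self.chrom_sizes[chrom]]))

    def midpoints(self, chrom: str) -> np.ndarray:
        return (self.starts(chrom) + self.ends(chrom)) / 2.0

    def fragment_sequence(self, genome: Mapping[str, str], fragment_id: int) -> str:
        frag = self.fragment(fragment_id)
        return genome[frag.chrom][frag.start:frag.end].upper()

    # -- serialisation ---------------------------------------------------

    def to_bed(self, path) -> None:
        """Write the map as BED4 (chrom, start, end, fragment_id)."""
        with open(path, "w") as fh:
            for frag in self.fragments():
                fh.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\t{frag.fragment_id}\n")

    @classmethod
    def from_bed(cls, path, enzyme: RestrictionEnzyme | None = None) -> "FragmentMap":
        sizes: dict[str, int] = {}
        cuts: dict[str, list[int]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("track", "#")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                start, end = int(start), int(end)
                if chrom not in cuts:
                    cuts[chrom] = []
                if start > 0:
                    cuts[chrom].append(start)
                sizes[chrom] = max(sizes.get(chrom, 0), end)
        return cls(enzyme, sizes, cuts)


def digest_genome(genome: Mapping[str, str], enzyme: RestrictionEnzyme) -> FragmentMap:
    """In-silico digest: cut every chromosome at each site occurrence.

    Boundaries are ``occurrence_start + cut_offset`` for every occurrence of
    the recognition sequence on either strand, deduplicated and sorted, plus
    the chromosome limits.
    """
    return FragmentMap.from_genome(genome, enzyme)


@dataclass
class SequenceIndex:
    """Exact-match lookup from fragment sequence to (fragment_id, strand).

    Stands in for alignment of digested sub-reads: each unambiguous fragment
    sequence and its reverse complement key the fragment id with orientation
    ``"+"`` / ``"-"``.  Fragments shorter than ``min_length`` and sequences
    occurring for more than one fragment are excluded (recorded, not errors).
    """

    lookup: dict[str, tuple[int, str]]
    ambiguous: set[int] = field(default_factory=set)
    too_short: set[int] = field(default_factory=set)

    def assign(self, piece: str) -> tuple[int, str] | None:
        return self.lookup.get(piece.upper())


def build_sequence_index(
    fmap: FragmentMap, genome: Mapping[str, str], min_length: int = 1
) -> SequenceIndex:
    """Index every eligible fragment sequence (both orientations)."""
    seen: dict[str, tuple[int, str]] = {}
    ambiguous_keys: set[str] = set()
    ambiguous_ids: set[int] = set()
    too_short: set[int] = set()
    for frag in fmap.fragments():
        seq = genome[frag.chrom][frag.start:frag.end].upper()
        if len(seq) < min_length:
            too_short.add(frag.fragment_id)
            continue
        rc = reverse_complement(seq)
        for key, orient in ((seq, "+"), (rc, "-")):
            if key in ambiguous_keys:
                ambiguous_ids.add(frag.fragment_id)
                continue
            prev = seen.get(key)
            if prev is None:
                seen[key] = (frag.fragment_id, orient)
            elif prev[0] != frag.fragment_id:
                # same sequence for two different fragments: drop both
                ambiguous_keys.add(key)
                ambiguous_ids.update((prev[0], frag.fragment_id))
                del seen[key]
            # palindromic fragment (rc == seq, same id): keep '+' entry
    # a fragment ambiguous under one key is removed entirely
    if ambiguous_ids:
        seen = {k: v for k, v in seen.items() if v[0] not in ambiguous_ids}
    return SequenceIndex(seen, ambiguous_ids, too_short)
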