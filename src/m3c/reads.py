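"""Decompose viewpoint-primed concatemer reads into fragment chains.

Each merged single-end read is a concatemer of ligated restriction
fragments primed from the viewpoint (bait) fragment.  Processing mirrors an
alignment-based pipeline at desk scale: the read is fragmented in-silico at
every recognition-site occurrence (same cut convention as the genome
digest), each piece is assigned to a genomic fragment by exact sequence
lookup in either orientation, and the resulting ordered chain is passed
through the viewpoint / self-ligation / continuous-fragment filters before
any contact counting.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .enzyme import RestrictionEnzyme
from .fragment_map import SequenceIndex


@dataclass(frozen=True)
class SequenceRead:
    read_id: str
    sequence: str


@dataclass(frozen=True)
class FragmentChain:
    """One retained read as an ordered list of non-viewpoint fragment ids.

    ``members`` excludes the viewpoint fragment and everything removed by
    the self-ligation, continuous-fragment and duplicate filters;
    ``orientations`` is parallel to ``members``.
    """

    read_id: str
    viewpoint_id: int
    members: tuple[int, ...]
    orientations: tuple[str, ...]


# rejection / drop categories
OFF_TARGET = "off_target"
EMPTY_AFTER_FILTER = "empty_after_filter"
RETAINED = "retained"
SELF_LIGATION = "self_ligation"
CONTINUOUS = "continuous"
DUPLICATE = "duplicate"
UNASSIGNED = "unassigned"
SHORT_PIECE = "short_piece"


@dataclass
class ProcessingStats:
    """Read- and member-level accounting for one processed library.

    Invariant: ``reads_in == retained + off_target + empty_after_filter``.
    """

    reads_in: int = 0
    retained: int = 0
    off_target: int = 0
    empty_after_filter: int = 0
    member_drops: dict[str, int] = field(
        default_factory=lambda: {
            SELF_LIGATION: 0,
            CONTINUOUS: 0,
            DUPLICATE: 0,
            UNASSIGNED: 0,
            SHORT_PIECE: 0,
        }
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("reads_in", self.reads_in),
            (RETAINED, self.retained),
            (OFF_TARGET, self.off_target),
            (EMPTY_AFTER_FILTER, self.empty_after_filter),
        ] + [(f"member_{k}", v) for k, v in self.member_drops.items()]
        return pd.DataFrame(rows, columns=["category", "count"])


def split_read(sequence: str, enzyme: RestrictionEnzyme) -> list[str]:
    """Cut a read at every recognition occurrence (both strands).

    Uses the same ``occurrence_start + cut_offset`` convention as the genome
    digest, so pieces of a concatemer line up with genomic restriction
    fragments.  Concatenating the pieces reproduces the read.
    """
    seq = sequence.upper()
    cuts = enzyme.cut_positions(seq)
    bounds = [0] + cuts + [len(seq)]
    return [seq[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def assign_fragments(
    pieces: Sequence[str],
    index: SequenceIndex,
    min_length: int = 1,
    stats: ProcessingStats | None = None,
) -> list[tuple[int, str]]:
    """Map read pieces to (fragment_id, orientation) by exact lookup.

    Pieces shorter than ``min_length`` or absent from the index are skipped
    (counted in ``stats`` when given); order of the rest is preserved.
    """
    assigned: list[tuple[int, str]] = []
    for piece in pieces:
        if len(piece) < min_length:
            if stats is not None:
                stats.member_drops[SHORT_PIECE] += 1
            continue
        hit = index.assign(piece)
        if hit is None:
            if stats is not None:
                stats.member_drops[UNASSIGNED] += 1
            continue
        assigned.append(hit)
    return assigned


def build_chain(
    read_id: str,
    assigned: Sequence[tuple[int, str]],
    viewpoint_id: int,
    self_ligation_window: int = 1,
    stats: ProcessingStats | None = None,
) -> FragmentChain | None:
    """Apply the viewpoint and artifact filters to one assigned read.

    Filter order:

    1. reject as off-target unless the first assigned fragment is the
       viewpoint;
    2. drop members within ``self_ligation_window`` fragments of the
       viewpoint (undigested / self-ligated bait products);
    3. collapse runs of consecutive members that are genomically adjacent
       (``|id_i - id_{i+1}| <= 1``, undigested neighbours), keeping the
       first of each run;
    4. drop exact duplicate members, keeping the first occurrence.

    Returns ``None`` for rejected reads (off-target or empty after
    filtering); rejections are categorised counts, not errors.
    """
    if not assigned or assigned[0][0] != viewpoint_id:
        if stats is not None:
            stats.off_target += 1
        return None

    members = [(fid, ori) for fid, ori in assigned[1:]]

    kept: list[tuple[int, str]] = []
    for fid, ori in members:
        if abs(fid - viewpoint_id) <= self_ligation_window:
            if stats is not None:
                stats.member_drops[SELF_LIGATION] += 1
            continue
        kept.append((fid, ori))

    def collapse_adjacent(items: list[tuple[int, str]]) -> list[tuple[int, str]]:
        # collapse adjacency runs to their first member, repeating until no
        # two consecutive retained members are genomically adjacent
        # (removing a run can bring a new adjacent pair together)
        while True:
            out: list[tuple[int, str]] = []
            prev_fid: int | None = None
            dropped = 0
            for fid, ori in items:
                adjacent = prev_fid is not None and abs(fid - prev_fid) <= 1
                prev_fid = fid
                if adjacent:
                    dropped += 1
                    continue
                out.append((fid, ori))
            if stats is not None:
                stats.member_drops[CONTINUOUS] += dropped
            if dropped == 0:
                return out
            items = out

    collapsed = collapse_adjacent(kept)

    seen: set[int] = set()
    final: list[tuple[int, str]] = []
    for fid, ori in collapsed:
        if fid in seen:
            if stats is not None:
                stats.member_drops[DUPLICATE] += 1
            continue
        seen.add(fid)
        final.append((fid, ori))
    # deduplication can itself bring an adjacent pair together
    final = collapse_adjacent(final)

    if not final:
        if stats is not None:
            stats.empty_after_filter += 1
        return None
    if stats is not None:
        stats.retained += 1
    return FragmentChain(
        read_id,
        viewpoint_id,
        tuple(f for f, _ in final),
        tuple(o for _, o in final),
    )


def process_library(
    reads: Iterable[SequenceRead],
    enzyme: RestrictionEnzyme,
    index: SequenceIndex,
    viewpoint_id: int,
    self_ligation_window: int = 1,
    min_piece_length: int = 1,
    deduplicate: bool = False,
) -> tuple[list[FragmentChain], ProcessingStats]:
    """Run split → assign → filter over a whole library.

    ``deduplicate`` optionally removes PCR-duplicate chains, i.e. chains
    with an identical (viewpoint, members) tuple (off by default).
    """
    stats = ProcessingStats()
    chains: list[FragmentChain] = []
    seen_chains: set[tuple[int, tuple[int, ...]]] = set()
    for read in reads:
        stats.reads_in += 1
        pieces = split_read(read.sequence, enzyme)
        assigned = assign_fragments(pieces, index, min_piece_length, stats)
        chain = build_chain(
            read.read_id, assigned, viewpoint_id, self_ligation_window, stats
        )
        if chain is None:
            continue
        if deduplicate:
            key = (chain.viewpoint_id, chain.members)
            if key in seen_chains:
                continue
            seen_chains.add(key)
        chains.append(chain)
    return chains, stats


def merge_overlapping(r1: str, r2: str, min_overlap: int = 20) -> str | None:
    """Naive exact-overlap merge of a read pair (convenience plumbing).

    ``r2`` must be given on the same strand as ``r1``.  Returns ``None``
    when no exact suffix/prefix overlap of at least ``min_overlap`` exists.
    """
    max_ov = min(len(r1), len(r2))
    for ov in range(max_ov, min_overlap - 1, -1):
        if r1[-ov:] == r2[:ov]:
            return r1 + r2[ov:]
    return None


# -- I/O ---------------------------------------------------------------


def read_fastq(path) -> Iterator[SequenceRead]:
    """Iterate reads from a FASTQ file (gzip allowed)."""
    from Bio import SeqIO

    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield SequenceRead(rec.id, str(rec.seq))


def write_chains(chains: Iterable[FragmentChain], path) -> None:
    """Chains as TSV: read_id, viewpoint_id, member ids, orientations."""
    with open(path, "w") as fh:
        fh.write("read_id\tviewpoint_id\tmembers\torientations\n")
        for c in chains:
            fh.write(
                f"{c.read_id}\t{c.viewpoint_id}\t"
                f"{','.join(map(str, c.members))}\t{','.join(c.orientations)}\n"
            )


def read_chains(path) -> list[FragmentChain]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    chains = []
    for row in df.itertuples(index=False):
        members = tuple(int(x) for x in row.members.split(","))
        orients = tuple(row.orientations.split(","))
        chains.append(
            FragmentChain(row.read_id, int(row.viewpoint_id), members, orients)
        )
    return chains
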