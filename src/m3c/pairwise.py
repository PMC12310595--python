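"""Viewpoint-anchored pairwise interaction profiles with CPM-in-cis.

The pairwise profile is the classic 4C-style view of a multi-contact
library: per restriction fragment, how many reads connect it to the
viewpoint.  ``first_only`` counts only the initial digested fragment behind
the viewpoint of each read; ``all_members`` counts every distinct member.
Normalisation is counts-per-million *in cis*: the scale factor is
1e6 / (total counts on the viewpoint's chromosome), and trans fragments are
scaled by the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd

from .fragment_map import FragmentMap
from .reads import FragmentChain

CountMode = Literal["first_only", "all_members"]


@dataclass
class ViewpointProfile:
    viewpoint_id: int
    counts: dict[int, int] = field(default_factory=dict)
    normalized: dict[int, float] = field(default_factory=dict)
    cis_total: int = 0


def count_pairwise(
    chains: Iterable[FragmentChain], mode: CountMode = "first_only"
) -> ViewpointProfile:
    """Tally viewpoint contacts per fragment over retained chains.

    All chains must share a viewpoint.  ``first_only`` increments the first
    member once per chain; ``all_members`` increments each distinct member
    once per chain.  An empty collection yields an empty profile.
    """
    if mode not in ("first_only", "all_members"):
        raise ValueError(f"unknown mode {mode!r}")
    counts: dict[int, int] = {}
    viewpoint_id: int | None = None
    for chain in chains:
        if viewpoint_id is None:
            viewpoint_id = chain.viewpoint_id
        elif chain.viewpoint_id != viewpoint_id:
            raise ValueError("chains do not share a viewpoint")
        targets = (
            chain.members[:1] if mode == "first_only" else set(chain.members)
        )
        for fid in targets:
            counts[fid] = counts.get(fid, 0) + 1
    return ViewpointProfile(viewpoint_id if viewpoint_id is not None else -1, counts)


def cpm_cis_normalize(
    profile: ViewpointProfile, fmap: FragmentMap, drop_trans: bool = False
) -> ViewpointProfile:
    """Fill ``normalized`` with counts-per-million-in-cis values.

    cis = fragments on the viewpoint's chromosome.  Every fragment's value
    is ``count * 1e6 / cis_total``; trans fragments get the same factor
    (or are dropped with ``drop_trans``).  A zero cis total maps everything
    to zero.
    """
    if profile.viewpoint_id < 0 or not profile.counts:
        profile.normalized = {}
        profile.cis_total = 0
        return profile
    vp_chrom = fmap.chrom_of(profile.viewpoint_id)
    cis_ids = set(map(int, fmap.fragment_ids(vp_chrom)))
    cis_total = sum(c for f, c in profile.counts.items() if f in cis_ids)
    profile.cis_total = cis_total
    if cis_total == 0:
        profile.normalized = {f: 0.0 for f in profile.counts}
        return profile
    scale = 1_000_000 / cis_total
    profile.normalized = {
        f: c * scale
        for f, c in profile.counts.items()
        if not (drop_trans and f not in cis_ids)
    }
    return profile


def profile_to_bedgraph(
    profile: ViewpointProfile,
    fmap: FragmentMap,
    path,
    track_name: str | None = "m3c_profile",
) -> None:
    """Write nonzero normalized values as a coordinate-sorted bedGraph."""
    records = []
    for fid, value in profile.normalized.items():
        if value == 0:
            continue
        frag = fmap.fragment(fid)
        records.append((frag.chrom, frag.start, frag.end, value))
    records.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        if track_name is not None:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


def window_counts(
    profile: ViewpointProfile, fmap: FragmentMap, k: int = 30
) -> pd.DataFrame:
    """Raw counts pooled over fixed windows of ``k`` fragments.

    Export table for external differential statistics on the viewpoint's
    chromosome; one row per window of k consecutive fragments.
    """
    vp_chrom = fmap.chrom_of(profile.viewpoint_id)
    ids = fmap.fragment_ids(vp_chrom)
    starts = fmap.starts(vp_chrom)
    ends = fmap.ends(vp_chrom)
    rows = []
    for w0 in range(0, len(ids), k):
        w_ids = ids[w0 : w0 + k]
        count = sum(profile.counts.get(int(f), 0) for f in w_ids)
        rows.append(
            (vp_chrom, int(starts[w0]), int(ends[min(w0 + k, len(ids)) - 1]), count)
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])
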