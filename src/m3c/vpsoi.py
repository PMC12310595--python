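"""VP-SOI association analysis for three-way chromatin interactions.

Given a viewpoint (VP) and a second site of interest (SOI), reads are
partitioned into a *positive* set (contain the VP and at least one fragment
in the SOI) and a *negative* set (contain the VP but no SOI fragment).  For
every genomic bin, the fraction of positive reads touching the bin is
compared against a resampled null built from the negative set: each
iteration draws as many negative reads as there are positive reads and
removes one randomly chosen fragment from each drawn read, the removed
fragment standing in for the SOI fragment that every positive read carries.
Across iterations (default 1,000) the per-bin mean and standard deviation
of the null define a z-score; bins with z at or beyond the threshold are
called cooperative (enriched) or competitive (depleted), otherwise random.

Because a read enters the positive set in proportion to how many ligated
fragments it carries, the default resampling draws negative reads with
probability proportional to their member count (size-biased, still without
replacement) before the single-fragment removal; this makes the null match
the positive set's residual fragment cardinality under independence.
Uniform sampling is available via ``weighting="uniform"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .fragment_map import FragmentMap
from .multiway import BinGrid
from .reads import FragmentChain

LABEL_COOPERATIVE = "cooperative"
LABEL_RANDOM = "random"
LABEL_COMPETITIVE = "competitive"
LABEL_EXCLUDED = "excluded"

#: sentinel text used in tabular output when negative_sd == 0
POS_INF = "+inf"
NEG_INF = "-inf"


@dataclass(frozen=True)
class VPSOIConfig:
    viewpoint_id: int
    soi: tuple[str, int, int]  # chrom, start, end (half-open)
    grid: BinGrid
    n_iterations: int = 1000
    seed: int = 0
    z_threshold: float = 2.0
    allow_replacement: bool = False
    weighting: Literal["cardinality", "uniform"] = "cardinality"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")


@dataclass
class ReadPartition:
    positive: list[FragmentChain]
    negative: list[FragmentChain]


@dataclass
class VPSOIResult:
    """Per-bin association table plus run metadata."""

    table: pd.DataFrame
    config: VPSOIConfig
    n_positive: int
    n_negative: int
    metadata: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["z"] = [
            (POS_INF if np.isposinf(z) else NEG_INF if np.isneginf(z)
             else "" if np.isnan(z) else f"{z:.4f}")
            for z in df["z"]
        ]
        df.to_csv(path, sep="\t", index=False)

    def run_metadata(self) -> dict:
        return {
            "viewpoint_id": self.config.viewpoint_id,
            "soi": list(self.config.soi),
            "n_iterations": self.config.n_iterations,
            "seed": self.config.seed,
            "z_threshold": self.config.z_threshold,
            "weighting": self.config.weighting,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            **self.metadata,
        }


def _in_soi(fid: int, fmap: FragmentMap, soi: tuple[str, int, int]) -> bool:
    frag = fmap.fragment(fid)
    chrom, start, end = soi
    return frag.chrom == chrom and start <= frag.midpoint < end


def partition_reads(
    chains: Iterable[FragmentChain], fmap: FragmentMap, config: VPSOIConfig
) -> ReadPartition:
    """Split chains into SOI-positive and SOI-negative sets.

    Membership is by fragment midpoint falling inside the SOI interval.
    The SOI must not contain the viewpoint fragment itself.
    """
    vp = fmap.fragment(config.viewpoint_id)
    chrom, start, end = config.soi
    if vp.chrom == chrom and start <= vp.midpoint < end:
        raise ValueError("SOI interval overlaps the viewpoint fragment")
    positive, negative = [], []
    for chain in chains:
        if any(_in_soi(f, fmap, config.soi) for f in chain.members):
            positive.append(chain)
        else:
            negative.append(chain)
    return ReadPartition(positive, negative)


def excluded_bins(fmap: FragmentMap, config: VPSOIConfig) -> np.ndarray:
    """Boolean mask of bins overlapping the viewpoint fragment or the SOI."""
    g = config.grid
    mask = np.zeros(g.n_bins, dtype=bool)
    vp = fmap.fragment(config.viewpoint_id)
    intervals = [(vp.chrom, vp.start, vp.end), config.soi]
    for chrom, start, end in intervals:
        if chrom != g.chrom:
            continue
        for i in range(g.n_bins):
            b0, b1 = g.bin_bounds(i)
            if start < b1 and b0 < end:
                mask[i] = True
    return mask


def _chain_bin_arrays(
    chains: Sequence[FragmentChain], fmap: FragmentMap, grid: BinGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Flatten member bins of chains into ragged arrays for fast resampling.

    Returns (flat_bins, flat_singleton, offsets, n_members, presence):

    - flat_bins[offsets[r]:offsets[r]+n_members[r]] are read r's member bin
      indices (-1 for members outside the window);
    - flat_singleton marks members whose bin is touched exactly once within
      their read (removing such a member empties that bin for the read);
    - presence is the (n_reads, n_bins) 0/1 matrix of bin occupancy.
    """
    n_bins = grid.n_bins
    n_members = np.array([len(c.members) for c in chains], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(n_members)[:-1]))
    flat_bins = np.empty(int(n_members.sum()), dtype=np.int64)
    flat_singleton = np.zeros(int(n_members.sum()), dtype=bool)
    presence = np.zeros((len(chains), n_bins), dtype=np.uint8)
    pos = 0
    for r, chain in enumerate(chains):
        bins = []
        for fid in chain.members:
            frag = fmap.fragment(fid)
            b = grid.bin_of(frag.chrom, frag.midpoint)
            bins.append(-1 if b is None else b)
        arr = np.array(bins, dtype=np.int64)
        flat_bins[pos : pos + len(arr)] = arr
        valid = arr[arr >= 0]
        if valid.size:
            uniq, counts = np.unique(valid, return_counts=True)
            presence[r, uniq] = 1
            singles = set(uniq[counts == 1])
            for k, b in enumerate(arr):
                if b >= 0 and b in singles:
                    flat_singleton[pos + k] = True
        pos += len(arr)
    return flat_bins, flat_singleton, offsets, n_members, presence


def positive_profile(
    partition: ReadPartition, fmap: FragmentMap, config: VPSOIConfig
) -> np.ndarray:
    """Per-bin fraction of positive reads touching the bin."""
    if not partition.positive:
        raise ValueError("no VP-SOI co-occurring reads (empty positive set)")
    *_, presence = _chain_bin_arrays(partition.positive, fmap, config.grid)
    return presence.sum(axis=0, dtype=np.float64) / len(partition.positive)


def resample_negative_profile(
    partition: ReadPartition, fmap: FragmentMap, config: VPSOIConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Resampled null profile: per-bin (mean, population sd) over iterations.

    Each iteration draws ``len(positive)`` negative reads (without
    replacement unless ``allow_replacement``) and removes one uniformly
    chosen member from each drawn read before tallying per-bin presence
    frequencies.  The RNG is fully determined by ``config.seed``.
    """
    n_pos = len(partition.positive)
    n_neg = len(partition.negative)
    if n_pos == 0:
        raise ValueError("no VP-SOI co-occurring reads (empty positive set)")
    if n_neg < n_pos and not config.allow_replacement:
        raise ValueError(
            f"negative set ({n_neg} reads) smaller than positive set "
            f"({n_pos} reads); enable allow_replacement to sample anyway"
        )
    flat_bins, flat_singleton, offsets, n_members, presence = _chain_bin_arrays(
        partition.negative, fmap, config.grid
    )
    rng = np.random.default_rng(config.seed)
    if config.weighting == "cardinality":
        weights = n_members.astype(np.float64)
    else:
        weights = np.ones(n_neg, dtype=np.float64)
    prob = weights / weights.sum()

    n_bins = config.grid.n_bins
    acc = np.zeros(n_bins)
    acc_sq = np.zeros(n_bins)
    presence_f = presence.astype(np.int64)
    for _ in range(config.n_iterations):
        if config.allow_replacement:
            idx = rng.choice(n_neg, size=n_pos, replace=True, p=prob)
        else:
            # Efraimidis-Spirakis exponential keys == successive weighted
            # sampling without replacement; O(n) per iteration.
            keys = rng.exponential(size=n_neg) / weights
            idx = np.argpartition(keys, n_pos - 1)[:n_pos]
        tallies = presence_f[idx].sum(axis=0)
        # remove one uniformly chosen member per drawn read; presence in a
        # bin changes only when the removed member was its sole occupant
        u = (rng.random(n_pos) * n_members[idx]).astype(np.int64)
        g = offsets[idx] + u
        removed_bins = flat_bins[g]
        lone = flat_singleton[g]
        if lone.any():
            np.subtract.at(tallies, removed_bins[lone], 1)
        freq = tallies / n_pos
        acc += freq
        acc_sq += freq * freq
    mean = acc / config.n_iterations
    var = np.maximum(acc_sq / config.n_iterations - mean * mean, 0.0)
    return mean, np.sqrt(var)


def compute_zscores(
    positive_freq: np.ndarray,
    negative_mean: np.ndarray,
    negative_sd: np.ndarray,
    fmap: FragmentMap,
    config: VPSOIConfig,
) -> pd.DataFrame:
    """Per-bin z-scores and cooperative/random/competitive labels.

    ``z = (positive_freq - negative_mean) / negative_sd``.  Where the null
    sd is zero the z-score is undefined: equal frequencies are labelled
    random (z = NaN), otherwise the label follows the sign with z reported
    as +/- infinity.  Bins overlapping the viewpoint or SOI are excluded.
    """
    g = config.grid
    excl = excluded_bins(fmap, config)
    diff = positive_freq - negative_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / negative_sd
    z = np.where(negative_sd == 0, np.where(diff > 0, np.inf,
                 np.where(diff < 0, -np.inf, np.nan)), z)
    labels = np.full(g.n_bins, LABEL_RANDOM, dtype=object)
    labels[z >= config.z_threshold] = LABEL_COOPERATIVE
    labels[z <= -config.z_threshold] = LABEL_COMPETITIVE
    labels[excl] = LABEL_EXCLUDED
    bounds = [g.bin_bounds(i) for i in range(g.n_bins)]
    return pd.DataFrame(
        {
            "chrom": g.chrom,
            "start": [b[0] for b in bounds],
            "end": [b[1] for b in bounds],
            "positive_freq": positive_freq,
            "negative_mean": negative_mean,
            "negative_sd": negative_sd,
            "z": z,
            "label": labels,
        }
    )


def run_vpsoi(
    chains: Iterable[FragmentChain], fmap: FragmentMap, config: VPSOIConfig
) -> VPSOIResult:
    """Full VP-SOI analysis: partition, profiles, resampled null, z-scores."""
    partition = partition_reads(chains, fmap, config)
    pos_freq = positive_profile(partition, fmap, config)
    neg_mean, neg_sd = resample_negative_profile(partition, fmap, config)
    table = compute_zscores(pos_freq, neg_mean, neg_sd, fmap, config)
    return VPSOIResult(
        table,
        config,
        n_positive=len(partition.positive),
        n_negative=len(partition.negative),
    )
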