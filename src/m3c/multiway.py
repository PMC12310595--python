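"""Three-way (viewpoint-anchored) contact matrices.

Every retained chain contributes unordered pairs of its non-viewpoint
members; each pair co-occurring with the viewpoint is one three-way
contact.  ``first_two`` uses only the first two digested fragments
following the viewpoint; ``all_triples`` enumerates every unordered pair
of distinct members per read.  Fragments are assigned to fixed-size bins
by midpoint over an analysis window; raw matrices are integer counts,
normalisation rescales to a grand total of 1,000,000 interactions
(each unordered pair counted once), and subtraction of two normalized
matrices gives a differential heatmap.  Interaction loops are bin pairs
whose *raw* contact frequency reaches a threshold (default >= 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .fragment_map import FragmentMap
from .reads import FragmentChain

MatrixMode = Literal["first_two", "all_triples"]


@dataclass(frozen=True)
class BinGrid:
    """Fixed-resolution binning of one analysis window.

    Half-open bins ``[start + i*res, start + (i+1)*res)``; the last bin is
    clipped to the window end.
    """

    chrom: str
    window_start: int
    window_end: int
    resolution: int

    def __post_init__(self) -> None:
        if self.window_end <= self.window_start:
            raise ValueError("empty analysis window")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")

    @property
    def n_bins(self) -> int:
        return math.ceil((self.window_end - self.window_start) / self.resolution)

    def bin_of(self, chrom: str, pos: float) -> int | None:
        """Bin index of a position, or None outside the window."""
        if chrom != self.chrom or not self.window_start <= pos < self.window_end:
            return None
        return int((pos - self.window_start) // self.resolution)

    def bin_bounds(self, i: int) -> tuple[int, int]:
        start = self.window_start + i * self.resolution
        return start, min(start + self.resolution, self.window_end)


@dataclass
class ContactMatrix:
    """Symmetric binned co-occurrence matrix anchored at one viewpoint."""

    grid: BinGrid
    values: np.ndarray
    kind: Literal["raw", "normalized", "difference"] = "raw"
    meta: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        """Grand total counting each unordered bin pair once."""
        upper = np.triu(self.values)
        return float(upper.sum())


def _member_bins(
    chain: FragmentChain, grid: BinGrid, fmap: FragmentMap
) -> list[int | None]:
    bins = []
    for fid in chain.members:
        frag = fmap.fragment(fid)
        bins.append(grid.bin_of(frag.chrom, frag.midpoint))
    return bins


def build_threeway_matrix(
    chains: Iterable[FragmentChain],
    grid: BinGrid,
    fmap: FragmentMap,
    mode: MatrixMode = "first_two",
) -> ContactMatrix:
    """Accumulate the raw three-way matrix over filtered chains.

    Chains with fewer than two members contribute nothing (counted as
    skipped in the matrix metadata); pairs with either fragment outside the
    window are skipped; two fragments in the same bin increment the
    diagonal once.
    """
    if mode not in ("first_two", "all_triples"):
        raise ValueError(f"unknown mode {mode!r}")
    n = grid.n_bins
    values = np.zeros((n, n), dtype=np.int64)
    skipped_chains = 0
    skipped_pairs = 0
    used_chains = 0
    for chain in chains:
        if len(chain.members) < 2:
            skipped_chains += 1
            continue
        used_chains += 1
        bins = _member_bins(chain, grid, fmap)
        if mode == "first_two":
            pairs = [(bins[0], bins[1])]
        else:
            pairs = [
                (bins[i], bins[j])
                for i in range(len(bins))
                for j in range(i + 1, len(bins))
            ]
        for bi, bj in pairs:
            if bi is None or bj is None:
                skipped_pairs += 1
                continue
            if bi == bj:
                values[bi, bi] += 1
            else:
                values[bi, bj] += 1
                values[bj, bi] += 1
    return ContactMatrix(
        grid,
        values,
        "raw",
        {
            "mode": mode,
            "chains_used": used_chains,
            "chains_skipped": skipped_chains,
            "pairs_skipped": skipped_pairs,
        },
    )


def normalize_matrix_total(matrix: ContactMatrix) -> ContactMatrix:
    """Rescale a raw matrix so unordered-pair totals sum to 1,000,000.

    A zero matrix maps to a zero matrix.
    """
    if matrix.kind != "raw":
        raise ValueError("normalization expects a raw matrix")
    total = matrix.total
    scale = 0.0 if total == 0 else 1_000_000 / total
    return ContactMatrix(
        matrix.grid,
        matrix.values.astype(float) * scale,
        "normalized",
        dict(matrix.meta, raw_total=total),
    )


def subtract_matrices(a: ContactMatrix, b: ContactMatrix) -> ContactMatrix:
    """Entrywise ``a - b`` of two normalized matrices on the same grid."""
    if a.grid != b.grid:
        raise ValueError("matrices are on different grids")
    if a.kind != "normalized" or b.kind != "normalized":
        raise ValueError("subtraction expects normalized matrices")
    return ContactMatrix(
        a.grid,
        a.values - b.values,
        "difference",
        {"minuend": a.meta, "subtrahend": b.meta},
    )


def call_loops(
    matrix: ContactMatrix, threshold: int = 5
) -> list[tuple[int, int, int]]:
    """Off-diagonal bin pairs with raw contact frequency >= threshold.

    Returns upper-triangle ``(bin_i, bin_j, count)`` sorted by descending
    count, then by (i, j).  The diagonal is excluded.
    """
    if matrix.kind != "raw":
        raise ValueError("loop calling uses raw contact frequencies")
    iu, ju = np.triu_indices(matrix.grid.n_bins, k=1)
    counts = matrix.values[iu, ju]
    keep = counts >= threshold
    loops = [
        (int(i), int(j), int(c))
        for i, j, c in zip(iu[keep], ju[keep], counts[keep])
    ]
    loops.sort(key=lambda t: (-t[2], t[0], t[1]))
    return loops


# -- I/O ---------------------------------------------------------------


def write_dense(matrix: ContactMatrix, path) -> None:
    """Dense TSV with bin start coordinates as row/column labels."""
    g = matrix.grid
    labels = [f"{g.chrom}:{g.bin_bounds(i)[0]}" for i in range(g.n_bins)]
    with open(path, "w") as fh:
        fh.write("bin\t" + "\t".join(labels) + "\n")
        for i, row in enumerate(matrix.values):
            fh.write(labels[i] + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_sparse(matrix: ContactMatrix, path) -> None:
    """Upper-triangle triplet TSV: bin_i, bin_j, value (nonzero only)."""
    iu, ju = np.triu_indices(matrix.grid.n_bins)
    with open(path, "w") as fh:
        fh.write("bin_i\tbin_j\tvalue\n")
        for i, j in zip(iu, ju):
            v = matrix.values[i, j]
            if v != 0:
                fh.write(f"{i}\t{j}\t{v:.6g}\n")


def read_dense(path, grid: BinGrid, kind: str = "raw") -> ContactMatrix:
    values = np.loadtxt(path, delimiter="\t", skiprows=1, usecols=range(1, grid.n_bins + 1))
    values = np.atleast_2d(values)
    if kind == "raw":
        values = values.astype(np.int64)
    return ContactMatrix(grid, values, kind)  # type: ignore[arg-type]


def plot_heatmap(matrix: ContactMatrix, path, vmax: float | None = None) -> None:
    """Optional PNG heatmap (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = matrix.grid
    fig, ax = plt.subplots(figsize=(6, 5))
    cmap = "RdBu_r" if matrix.kind == "difference" else "Reds"
    vmin = None
    if matrix.kind == "difference":
        lim = vmax if vmax is not None else float(np.abs(matrix.values).max() or 1)
        vmin, vmax = -lim, lim
    im = ax.imshow(
        matrix.values,
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
        extent=[g.window_start, g.window_end, g.window_end, g.window_start],
    )
    ax.set_xlabel(g.chrom)
    ax.set_ylabel(g.chrom)
    fig.colorbar(im, ax=ax, label=matrix.kind)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
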