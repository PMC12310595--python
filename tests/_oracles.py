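"""Independent brute-force oracles, kept free of m3c internals."""

from __future__ import annotations

from itertools import product

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
         "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
         "D": "H", "H": "D", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _matches_at(seq: str, pos: int, site: str) -> bool:
    if pos + len(site) > len(seq):
        return False
    return all(seq[pos + i] in IUPAC[c] for i, c in enumerate(site))


def brute_force_boundaries(seq: str, site: str, cut_offset: int) -> list[int]:
    """Sliding-window IUPAC scan on both strands; internal cut positions."""
    cuts = set()
    for pattern in {site, revcomp(site)}:
        for pos in range(len(seq) - len(pattern) + 1):
            if _matches_at(seq, pos, pattern):
                cuts.add(pos + cut_offset)
    return sorted(c for c in cuts if 0 < c < len(seq))


def brute_force_pair_matrix(
    chain_bins: list[list[int]], n_bins: int, mode: str
) -> dict[tuple[int, int], int]:
    """Enumerate unordered per-read bin pairs (None = outside window)."""
    counts: dict[tuple[int, int], int] = {}
    for bins in chain_bins:
        if len(bins) < 2:
            continue
        if mode == "first_two":
            pairs = [(bins[0], bins[1])]
        else:
            pairs = [
                (bins[i], bins[j])
                for i in range(len(bins))
                for j in range(i + 1, len(bins))
            ]
        for a, b in pairs:
            if a is None or b is None:
                continue
            key = (min(a, b), max(a, b))
            counts[key] = counts.get(key, 0) + 1
    return counts


def enumerate_negative_profile(
    negative_members: list[list[int]], n_bins: int
) -> tuple[list[float], list[float]]:
    """Exact removal-null when every negative read is drawn each iteration.

    Enumerates all equally likely combinations of removing one member per
    read and returns the per-bin mean and population sd of the presence
    frequency.  Only valid when the drawn sample is the whole negative set.
    """
    n = len(negative_members)
    freqs: list[list[float]] = []
    for removal in product(*(range(len(m)) for m in negative_members)):
        tally = [0] * n_bins
        for read, rm in zip(negative_members, removal):
            left = {b for i, b in enumerate(read) if i != rm}
            for b in left:
                if 0 <= b < n_bins:
                    tally[b] += 1
        freqs.append([t / n for t in tally])
    mean = [sum(f[b] for f in freqs) / len(freqs) for b in range(n_bins)]
    sd = [
        (sum((f[b] - mean[b]) ** 2 for f in freqs) / len(freqs)) ** 0.5
        for b in range(n_bins)
    ]
    return mean, sd
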