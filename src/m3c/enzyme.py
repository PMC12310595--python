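"""Restriction enzyme model and IUPAC recognition-site scanning.

A :class:`RestrictionEnzyme` is a recognition sequence (IUPAC nucleotide
codes) plus a cut offset: the number of bases from the 5' start of a
recognized occurrence to the fragment boundary it produces.  Scanning is
performed on the forward strand for both the recognition sequence and its
reverse complement, so non-palindromic sites are handled as the safe
superset of both strands' occurrences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Expansion of IUPAC nucleotide codes to the concrete bases they match.
#: Code N additionally matches a literal N in the genome; the other codes do
#: not, so runs of N in an assembly cannot create spurious cut sites.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGTN",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(site: str) -> str:
    parts = []
    for code in site:
        bases = IUPAC_CODES[code]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme defined by its recognition site and cut offset.

    Parameters
    ----------
    name:
        Display name, e.g. ``"NlaIII"``.
    recognition_sequence:
        Uppercase IUPAC nucleotide string, e.g. ``"CATG"``.
    cut_offset:
        Bases from the 5' start of an occurrence to the fragment boundary;
        must lie in ``[0, len(recognition_sequence)]``.  ``CATG`` with offset
        4 cuts after the site, leaving CATG at 3' fragment ends.
    """

    name: str
    recognition_sequence: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_sequence
        if not site:
            raise ValueError("recognition sequence must be non-empty")
        bad = set(site) - set(IUPAC_CODES)
        if bad:
            raise ValueError(
                f"invalid characters in recognition sequence: {sorted(bad)}"
            )
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError(
                f"cut_offset {self.cut_offset} outside [0, {len(site)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        return self.recognition_sequence == reverse_complement(
            self.recognition_sequence
        )

    def _patterns(self) -> tuple[re.Pattern, ...]:
        fwd = _iupac_regex(self.recognition_sequence)
        rev = _iupac_regex(reverse_complement(self.recognition_sequence))
        pats = [re.compile(f"(?=({fwd}))")]
        if rev != fwd:
            pats.append(re.compile(f"(?=({rev}))"))
        return tuple(pats)

    def scan(self, sequence: str) -> list[int]:
        """Sorted, deduplicated start positions of site occurrences.

        Both the recognition sequence and its reverse complement are matched
        on the forward strand; overlapping occurrences are all reported.
        """
        seq = sequence.upper()
        starts: set[int] = set()
        for pat in self._patterns():
            starts.update(m.start() for m in pat.finditer(seq))
        return sorted(starts)

    def cut_positions(self, sequence: str) -> list[int]:
        """Internal fragment boundaries produced by digesting ``sequence``.

        Each occurrence contributes ``start + cut_offset``; positions at 0 or
        at the sequence end are dropped (they coincide with the sequence
        limits and produce no internal boundary).
        """
        n = len(sequence)
        cuts = {s + self.cut_offset for s in self.scan(sequence)}
        return sorted(c for c in cuts if 0 < c < n)


#: Default enzyme: a 4-cutter leaving CATG at 3' fragment ends, the
#: conventional choice for multi-contact 3C libraries.
NLAIII = RestrictionEnzyme("NlaIII", "CATG", 4)
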