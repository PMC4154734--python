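"""Restriction enzyme definitions.

Only palindromic type IIP enzymes are supported: a palindromic recognition
sequence is its own reverse complement, so a single top-strand scan finds
every site on both strands. ``cut_offset_top`` records where the top strand
is cut (bases from the start of the recognition sequence); fragment
coordinates in this package are defined on recognition-site boundaries
because sequencing reconstructs the full site, so the offset is retained
for documentation and sticky-end bookkeeping only.
"""

from __future__ import annotations

from dataclasses import dataclass

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme with its recognition sequence and cut geometry."""

    name: str
    recognition: str
    cut_offset_top: int
    palindromic: bool = True

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError(f"{self.name}: recognition sequence shorter than 4 bp")
        if not set(self.recognition) <= set("ACGT"):
            raise ValueError(f"{self.name}: recognition must be over A,C,G,T")
        if not 0 <= self.cut_offset_top <= len(self.recognition):
            raise ValueError(f"{self.name}: cut offset outside recognition sequence")
        is_pal = reverse_complement(self.recognition) == self.recognition
        if self.palindromic != is_pal:
            raise ValueError(f"{self.name}: palindromic flag inconsistent with sequence")

    @property
    def site_length(self) -> int:
        return len(self.recognition)


class UnsupportedEnzymeError(ValueError):
    """Raised when a non-palindromic enzyme is passed to the digest engine."""


#: Built-in enzymes. Cut offsets follow the conventional cut points:
#: SbfI CCTGCA^GG, EcoRI G^AATTC, MspI C^CGG, MseI T^TAA, PstI CTGCA^G.
ENZYMES: dict[str, Enzyme] = {
    e.name: e
    for e in (
        Enzyme("SbfI", "CCTGCAGG", 6),
        Enzyme("EcoRI", "GAATTC", 1),
        Enzyme("MspI", "CCGG", 1),
        Enzyme("MseI", "TTAA", 1),
        Enzyme("PstI", "CTGCAG", 5),
    )
}


def get_enzyme(name: str) -> Enzyme:
    try:
        return ENZYMES[name]
    except KeyError:
        raise UnsupportedEnzymeError(
            f"unknown enzyme {name!r}; built-ins: {', '.join(ENZYMES)}"
        ) from None
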