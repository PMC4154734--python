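"""Reference genome container and FASTA I/O."""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

from .enzymes import reverse_complement

_VALID = set("ACGTN")


@dataclass
class ReferenceGenome:
    """Ordered map of contig name -> uppercase nucleotide string (A,C,G,T,N)."""

    sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for name, seq in self.sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty contig {name!r}")
            if not set(seq) <= _VALID:
                bad = sorted(set(seq) - _VALID)
                raise ValueError(f"contig {name!r}: invalid characters {bad}")
            clean[name] = seq
        self.sequences = clean

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self.sequences.items())

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def reverse_complemented(self) -> "ReferenceGenome":
        return ReferenceGenome(
            {name: reverse_complement(seq) for name, seq in self.sequences.items()}
        )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
        if not seqs:
            raise ValueError(f"no sequences in {path}")
        return cls(seqs)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
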