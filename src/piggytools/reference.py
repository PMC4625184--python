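"""Reference sequence containers and small DNA utilities.

A :class:`ReferenceSet` is an ordered collection of named contigs, the
in-memory analogue of a multi-FASTA file.  It stands in for both the host
genome and the hybrid genome+plasmid reference that junction reads are
mapped against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# 2-bit base codes; N (and anything unexpected) maps to 4 and poisons k-mers.
_CODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE_TABLE[ord(_b)] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE_TABLE[raw]


class ReferenceError(ValueError):
    """Invalid reference set (bad names, empty or non-DNA sequences)."""


@dataclass
class ReferenceSet:
    """Ordered map of contig name -> uppercase DNA sequence."""

    records: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, seq in self.records.items():
            if not name:
                raise ReferenceError("contig names must be non-empty")
            if not seq:
                raise ReferenceError(f"contig {name!r} has an empty sequence")
            if set(seq) - DNA_ALPHABET:
                bad = sorted(set(seq) - DNA_ALPHABET)
                raise ReferenceError(
                    f"contig {name!r} contains non-ACGTN characters: {bad}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __contains__(self, name: str) -> bool:
        return name in self.records

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReferenceSet):
            return NotImplemented
        return self.records == other.records

    def items(self):
        return self.records.items()

    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())

    def copy(self) -> "ReferenceSet":
        return ReferenceSet(dict(self.records))

    def with_contig(self, name: str, seq: str) -> "ReferenceSet":
        """Return a new set with one contig appended."""
        if name in self.records:
            raise ReferenceError(f"contig name {name!r} already present")
        rec = dict(self.records)
        rec[name] = seq
        return ReferenceSet(rec)
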