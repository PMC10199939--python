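"""Core genotype and mutation types shared across the design pipeline.

A *genotype* is an assignment of one amino-acid identity to each designed
position; positions outside the designed set implicitly carry the reference
identity and are never stored.  The reference itself is represented as a plain
mapping ``position -> amino acid`` over the designed positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.")


@dataclass(frozen=True, order=True)
class Mutation:
    """A single amino-acid substitution at a designed position."""

    position: int
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        if self.from_aa == self.to_aa:
            raise ValueError(f"mutation at {self.position} does not change identity")

    def __str__(self) -> str:  # e.g. "T65S"
        return f"{self.from_aa}{self.position}{self.to_aa}"


@dataclass(frozen=True)
class Genotype:
    """A full identity assignment over the designed positions.

    ``identities`` is a tuple of ``(position, amino_acid)`` pairs sorted by
    position.  Two genotypes compare equal iff they assign the same identity
    at every position.
    """

    identities: tuple[tuple[int, str], ...]

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, str]) -> "Genotype":
        return cls(tuple(sorted(mapping.items())))

    @classmethod
    def from_mutations(
        cls, reference: Mapping[int, str], mutations: Iterable[Mutation]
    ) -> "Genotype":
        """Embed a set of mutations into the full designed-position space."""
        ids = dict(reference)
        for m in mutations:
            if m.position not in ids:
                raise KeyError(f"position {m.position} is not a designed position")
            ids[m.position] = m.to_aa
        return cls.from_mapping(ids)

    @classmethod
    def from_string(cls, seq: str, positions: Iterable[int]) -> "Genotype":
        pos = list(positions)
        if len(seq) != len(pos):
            raise ValueError(
                f"genotype string length {len(seq)} != {len(pos)} designed positions"
            )
        return cls(tuple(zip(pos, seq)))

    def as_dict(self) -> dict[int, str]:
        return dict(self.identities)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.identities)

    def identity(self, position: int) -> str:
        for p, aa in self.identities:
            if p == position:
                return aa
        raise KeyError(f"position {position} not in genotype")

    def to_string(self) -> str:
        """Identity string in position order (the 'genotype string' of TSVs)."""
        return "".join(aa for _, aa in self.identities)

    def mutations(self, reference: Mapping[int, str]) -> tuple[Mutation, ...]:
        return tuple(
            Mutation(p, reference[p], aa)
            for p, aa in self.identities
            if aa != reference[p]
        )

    def n_mutations(self, reference: Mapping[int, str]) -> int:
        return sum(1 for p, aa in self.identities if aa != reference[p])

    def hamming(self, other: "Genotype") -> int:
        if self.positions != other.positions:
            raise ValueError("genotypes defined on different position sets")
        return sum(a != b for (_, a), (_, b) in zip(self.identities, other.identities))


def validate_amino_acid(aa: str) -> str:
    if aa not in AMINO_ACIDS:
        raise ValueError(f"unknown amino acid {aa!r}")
    return aa
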