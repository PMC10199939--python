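"""Phylogenetic conservation profiles.

Derives a position-specific scoring matrix (PSSM) from a pre-aligned set of
homologs and applies the conservation filter that keeps, per position, only
mutations scoring above a log-odds threshold (default -2 bits).  Alignment
columns are mapped to ungapped reference coordinates; columns aligned to
reference gaps are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genotypes import AMINO_ACIDS, GAP_CHARS, Genotype

logger = logging.getLogger(__name__)

#: uniform amino-acid background (per-letter frequency 1/20)
UNIFORM_BACKGROUND: dict[str, float] = {aa: 1.0 / 20.0 for aa in AMINO_ACIDS}


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple sequence alignment with a designated reference row."""

    sequences: tuple[str, ...]
    ids: tuple[str, ...]
    reference_index: int

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        alphabet = set(AMINO_ACIDS) | GAP_CHARS
        for sid, seq in zip(self.ids, self.sequences):
            bad = set(seq) - alphabet
            if bad:
                raise ValueError(f"sequence {sid!r} contains invalid characters {bad}")

    @property
    def reference_row(self) -> str:
        return self.sequences[self.reference_index]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def reference_column_map(self) -> dict[int, int]:
        """Map 1-based ungapped reference positions to 0-based alignment columns."""
        mapping: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(self.reference_row):
            if ch not in GAP_CHARS:
                pos += 1
                mapping[pos] = col
        return mapping

    def reference_sequence(self) -> str:
        return "".join(ch for ch in self.reference_row if ch not in GAP_CHARS)


@dataclass(frozen=True)
class PSSM:
    """Per-position, per-amino-acid log-odds conservation scores (bits).

    ``scores`` is indexed by 1-based ungapped reference position with one
    column per amino acid; ``reference`` records the reference identity at
    each position so filters can always retain it.
    """

    scores: pd.DataFrame
    background: dict[str, float]
    pseudocount_mass: float
    reference: dict[int, str] = field(default_factory=dict)

    def score(self, position: int, aa: str) -> float:
        if position not in self.scores.index:
            raise KeyError(f"position {position} not in PSSM")
        return float(self.scores.at[position, aa])

    @property
    def positions(self) -> list[int]:
        return list(self.scores.index)


def read_alignment(path, reference_id: str) -> Alignment:
    """Read a gapped FASTA alignment and locate the reference row."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper() for r in records)
    if reference_id not in ids:
        raise KeyError(f"reference id {reference_id!r} not found in {path}")
    return Alignment(seqs, ids, ids.index(reference_id))


def build_pssm(
    aln: Alignment,
    background: Mapping[str, float] | None = None,
    pseudocount_mass: float = 1.0,
) -> PSSM:
    """Column count statistics -> log2-odds scores against a background.

    score(p, a) = log2( (n_pa + m*q_a) / ((N_p + m) * q_a) ) with counts n_pa
    over non-gap characters in the alignment column of reference position p,
    N_p the non-gap total, q_a the background frequency and m the pseudocount
    mass.  A column with zero non-gap characters scores 0 everywhere.
    """
    bg = dict(background) if background is not None else dict(UNIFORM_BACKGROUND)
    total = sum(bg.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"background frequencies sum to {total}, expected 1")
    if pseudocount_mass < 0:
        raise ValueError("pseudocount_mass must be >= 0")

    colmap = aln.reference_column_map()
    refseq = aln.reference_sequence()
    q = np.array([bg[aa] for aa in AMINO_ACIDS])
    rows = []
    for pos in sorted(colmap):
        col = colmap[pos]
        chars = [s[col] for s in aln.sequences]
        counts = np.array(
            [sum(1 for ch in chars if ch == aa) for aa in AMINO_ACIDS], dtype=float
        )
        n_total = counts.sum()
        if n_total == 0:
            logger.warning("alignment column for position %d has no residues", pos)
            rows.append(np.zeros(len(AMINO_ACIDS)))
            continue
        with np.errstate(divide="ignore"):
            scores = np.log2(
                (counts + pseudocount_mass * q) / ((n_total + pseudocount_mass) * q)
            )
        rows.append(scores)

    frame = pd.DataFrame(
        rows, index=sorted(colmap), columns=list(AMINO_ACIDS), dtype=float
    )
    frame.index.name = "position"
    reference = {i + 1: aa for i, aa in enumerate(refseq)}
    return PSSM(frame, bg, float(pseudocount_mass), reference)


def pssm_allowed_mutations(
    pssm: PSSM, positions: Iterable[int], threshold: float = -2.0
) -> dict[int, set[str]]:
    """Per-position identity sets scoring above ``threshold`` bits.

    The reference identity is always retained regardless of its score.
    """
    allowed: dict[int, set[str]] = {}
    for pos in positions:
        if pos not in pssm.scores.index:
            raise KeyError(f"position {pos} not in PSSM")
        row = pssm.scores.loc[pos]
        keep = {aa for aa in AMINO_ACIDS if row[aa] > threshold}
        keep.add(pssm.reference[pos])
        allowed[pos] = keep
    return allowed


def delta_pssm(
    genotype: Genotype, reference: Mapping[int, str], pssm: PSSM
) -> dict[str, object]:
    """Conservation-score change of each mutation relative to the reference.

    Returns per-position differences (0 at unmutated positions) plus their
    sum and, over the mutated positions, mean and max (0 when unmutated).
    """
    per_position: dict[int, float] = {}
    deltas = []
    for pos, aa in genotype.identities:
        ref_aa = reference[pos]
        if aa == ref_aa:
            per_position[pos] = 0.0
        else:
            d = pssm.score(pos, aa) - pssm.score(pos, ref_aa)
            per_position[pos] = d
            deltas.append(d)
    return {
        "per_position": per_position,
        "sum": float(sum(deltas)),
        "mean": float(np.mean(deltas)) if deltas else 0.0,
        "max": float(max(deltas)) if deltas else 0.0,
    }


def write_pssm(pssm: PSSM, path) -> None:
    """TSV with 1-based position index, reference identity and one aa column each."""
    out = pssm.scores.copy()
    out.insert(0, "ref", [pssm.reference[p] for p in out.index])
    out.to_csv(path, sep="\t")


def read_pssm(path) -> PSSM:
    frame = pd.read_csv(path, sep="\t", index_col="position")
    reference = {int(p): aa for p, aa in frame["ref"].items()}
    scores = frame.drop(columns=["ref"]).astype(float)
    scores.columns = list(scores.columns)
    return PSSM(scores, dict(UNIFORM_BACKGROUND), float("nan"), reference)
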