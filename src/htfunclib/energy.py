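"""Energy-oracle contract, synthetic epistatic landscape and mutational scans.

The design pipeline only ever asks an *energy oracle* for a scalar energy per
genotype (the reference genotype is gauged to zero, so every energy is a
delta-delta-G).  In production that oracle wraps an external atomistic
program's per-mutation scan tables; for development and validation the
:class:`SyntheticLandscape` provides a pairwise (Potts-like) model with
additive field terms, couplings restricted to contacting position pairs, and
explicitly planted incompatible mutation pairs — the dominant source of
epistasis the library-design method is meant to avoid.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

from .genotypes import Genotype, Mutation

logger = logging.getLogger(__name__)

PairKey = tuple[int, int, str, str]  # (pos_p, pos_q, aa_p, aa_q) with pos_p < pos_q


class EnergyOracle(Protocol):
    """Anything that scores a genotype; reference scores 0 by convention."""

    reference: Mapping[int, str]

    def energy(self, genotype: Genotype) -> float: ...


@dataclass(frozen=True)
class EnergyRecord:
    genotype: Genotype
    energy: float
    ddg: float


@dataclass(frozen=True)
class SyntheticLandscape:
    """Additive-plus-pairwise energy function over the designed positions.

    E(g) = sum_p h_p(aa_p) + sum_{p<q} J_pq(aa_p, aa_q); both h and J vanish
    on reference identities, so E(reference) = 0 exactly.
    """

    reference: dict[int, str]
    allowed: dict[int, frozenset[str]]
    fields: dict[tuple[int, str], float]
    couplings: dict[PairKey, float]
    planted_pairs: tuple[tuple[tuple[int, str], tuple[int, str]], ...]
    seed: int

    @property
    def positions(self) -> list[int]:
        return sorted(self.reference)

    def energy(self, genotype: Genotype) -> float:
        muts = [(p, aa) for p, aa in genotype.identities if aa != self.reference[p]]
        for p, aa in muts:
            if aa not in self.allowed[p]:
                raise ValueError(f"identity {aa} at {p} outside landscape alphabet")
        e = sum(self.fields.get(m, 0.0) for m in muts)
        for (p, a), (q, b) in itertools.combinations(muts, 2):
            if p > q:
                (p, a), (q, b) = (q, b), (p, a)
            e += self.couplings.get((p, q, a, b), 0.0)
        return e

    def to_json(self, path) -> None:
        payload = {
            "reference": self.reference,
            "allowed": {p: sorted(s) for p, s in self.allowed.items()},
            "fields": [[p, aa, v] for (p, aa), v in self.fields.items()],
            "couplings": [[*k, v] for k, v in self.couplings.items()],
            "planted_pairs": [
                [list(a), list(b)] for a, b in self.planted_pairs
            ],
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticLandscape":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            reference={int(p): aa for p, aa in d["reference"].items()},
            allowed={int(p): frozenset(s) for p, s in d["allowed"].items()},
            fields={(int(p), aa): v for p, aa, v in d["fields"]},
            couplings={(int(p), int(q), a, b): v for p, q, a, b, v in d["couplings"]},
            planted_pairs=tuple(
                ((int(a[0]), a[1]), (int(b[0]), b[1])) for a, b in d["planted_pairs"]
            ),
            seed=int(d["seed"]),
        )


def generate_landscape(
    reference: Mapping[int, str],
    allowed: Mapping[int, Iterable[str]],
    contacts: Iterable[tuple[int, int]],
    field_scale: float = 1.0,
    coupling_scale: float = 0.3,
    n_incompatible_pairs: int = 0,
    incompatible_penalty: float = 10.0,
    seed: int = 0,
) -> SyntheticLandscape:
    """Draw a reproducible synthetic landscape with planted incompatibilities.

    Field terms (one per non-reference identity) and couplings (one per
    contacting position pair and non-reference identity pair) are Gaussian
    with the given scales.  ``n_incompatible_pairs`` distinct (position-pair,
    identity-pair) combinations additionally receive ``+incompatible_penalty``,
    modelling sterically/energetically incompatible mutation pairs; the
    planted pairs are recorded on the landscape for downstream ground truth.
    """
    rng = np.random.default_rng(seed)
    reference = dict(reference)
    allowed_sets = {p: frozenset(set(aas) | {reference[p]}) for p, aas in allowed.items()}
    contact_pairs = sorted({(min(p, q), max(p, q)) for p, q in contacts if p != q})

    fields: dict[tuple[int, str], float] = {}
    for p in sorted(allowed_sets):
        for aa in sorted(allowed_sets[p]):
            if aa != reference[p]:
                fields[(p, aa)] = float(rng.normal(0.0, field_scale))

    couplings: dict[PairKey, float] = {}
    candidate_keys: list[PairKey] = []
    for p, q in contact_pairs:
        for a in sorted(allowed_sets[p] - {reference[p]}):
            for b in sorted(allowed_sets[q] - {reference[q]}):
                key = (p, q, a, b)
                if coupling_scale > 0:
                    couplings[key] = float(rng.normal(0.0, coupling_scale))
                candidate_keys.append(key)

    if n_incompatible_pairs > len(candidate_keys):
        raise ValueError(
            f"requested {n_incompatible_pairs} incompatible pairs but only "
            f"{len(candidate_keys)} contacting identity pairs exist"
        )
    planted: list[tuple[tuple[int, str], tuple[int, str]]] = []
    if n_incompatible_pairs:
        idx = rng.choice(len(candidate_keys), size=n_incompatible_pairs, replace=False)
        for i in sorted(idx):
            p, q, a, b = candidate_keys[i]
            couplings[(p, q, a, b)] = couplings.get((p, q, a, b), 0.0) + float(
                incompatible_penalty
            )
            planted.append(((p, a), (q, b)))

    return SyntheticLandscape(
        reference=reference,
        allowed=allowed_sets,
        fields=fields,
        couplings=couplings,
        planted_pairs=tuple(planted),
        seed=int(seed),
    )


def ddg_scan(
    oracle: EnergyOracle,
    reference: Mapping[int, str],
    candidates: Mapping[int, Iterable[str]],
) -> pd.DataFrame:
    """Score every candidate single mutation on the reference background.

    Returns a table (position, from_aa, to_aa, ddg); candidate identities equal
    to the reference are logged and dropped.
    """
    ref_genotype = Genotype.from_mapping(reference)
    e_ref = oracle.energy(ref_genotype)
    rows = []
    for pos in sorted(candidates):
        for aa in sorted(set(candidates[pos])):
            if aa == reference[pos]:
                logger.debug("dropping reference identity %s%d from scan", aa, pos)
                continue
            g = Genotype.from_mutations(reference, [Mutation(pos, reference[pos], aa)])
            rows.append((pos, reference[pos], aa, oracle.energy(g) - e_ref))
    return pd.DataFrame(rows, columns=["position", "from_aa", "to_aa", "ddg"])


def write_scan_tsv(scan: pd.DataFrame, path, chain: str = "A") -> None:
    out = scan.copy()
    out.insert(1, "chain", chain)
    out.to_csv(path, sep="\t", index=False)


def read_scan_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    cols = ["position", "from_aa", "to_aa", "ddg"]
    missing = set(cols) - set(frame.columns)
    if missing:
        raise ValueError(f"scan table missing columns {sorted(missing)}")
    return frame[cols].astype({"position": int, "ddg": float})


def filter_by_ddg(scan: pd.DataFrame, threshold: float) -> dict[int, set[str]]:
    """Per-position mutation sets with ddg <= threshold.

    The reference identity is implicitly allowed at every position and is not
    listed among the returned mutations.
    """
    allowed: dict[int, set[str]] = {int(p): set() for p in scan["position"].unique()}
    kept = scan[scan["ddg"] <= threshold]
    for _, row in kept.iterrows():
        allowed[int(row["position"])].add(str(row["to_aa"]))
    return allowed


def scan_lookup(scan: pd.DataFrame) -> dict[tuple[int, str], float]:
    return {
        (int(r["position"]), str(r["to_aa"])): float(r["ddg"])
        for _, r in scan.iterrows()
    }


def epistasis_gap(
    oracle: EnergyOracle,
    combos: Sequence[Sequence[Mutation]],
    scan: pd.DataFrame,
) -> tuple[np.ndarray, dict[str, float]]:
    """Energy of each multipoint mutant minus the sum of its singles.

    A positive gap means the combination is worse than additivity predicts
    (incompatible mutations); the summary reports quartiles and 1.5*IQR
    whiskers of the gap distribution.
    """
    lut = scan_lookup(scan)
    reference = dict(oracle.reference)
    e_ref = oracle.energy(Genotype.from_mapping(reference))
    gaps = []
    for combo in combos:
        for m in combo:
            if (m.position, m.to_aa) not in lut:
                raise KeyError(f"mutation {m} absent from scan")
        g = Genotype.from_mutations(reference, combo)
        ddg_combo = oracle.energy(g) - e_ref
        gaps.append(ddg_combo - sum(lut[(m.position, m.to_aa)] for m in combo))
    gaps = np.asarray(gaps, dtype=float)
    if len(gaps):
        q1, q2, q3 = np.percentile(gaps, [25, 50, 75])
    else:
        q1 = q2 = q3 = float("nan")
    iqr = q3 - q1
    summary = {
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
    }
    return gaps, summary
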