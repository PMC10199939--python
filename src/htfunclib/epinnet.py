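"""EpiNNet: neural-network ranking of mutations for combinatorial libraries.

The stages mirror the library-design workflow: choose a ddG threshold that
keeps the union of neighborhood sequence spaces tractable; enumerate (or
subsample) each neighborhood's sequence space and score it with the energy
oracle; label designs better than the reference as successes and the worst
half as failures; pool the one-hot encoded, labelled designs across
neighborhoods; train a single-hidden-layer perceptron to predict the label;
probe the trained network with each single mutation and rank mutations by
the predicted probability of success; finally grow the library by adding
top-ranked mutations until the combinatorial space reaches the target size.

Mutations that are only deleterious in combination (epistatically
incompatible pairs) depress each other's single-mutation scores through the
shared hidden layer, which is what lets a ranking over *single* mutations
purge *pairwise* incompatibilities from the library.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .energy import EnergyOracle, filter_by_ddg, scan_lookup
from .genotypes import Genotype, Mutation

logger = logging.getLogger(__name__)

UNDETERMINED = -1


@dataclass(frozen=True)
class SiteNeighborhood:
    """A neighborhood expressed over designed-position indices (center first)."""

    center: int
    members: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.members or self.members[0] != self.center:
            raise ValueError("members must start with the center")


@dataclass
class NeighborhoodSample:
    neighborhood: SiteNeighborhood
    genotypes: list[Genotype]
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if len(self.genotypes) != len(self.energies):
            raise ValueError("genotypes and energies differ in length")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("non-finite energies in neighborhood sample")


class GenotypeEncoder:
    """One-hot encoding over per-position allowed identity sets (reference included)."""

    def __init__(self, allowed: Mapping[int, Iterable[str]], reference: Mapping[int, str]):
        self.reference = dict(reference)
        self.positions = sorted(self.reference)
        self.identities: dict[int, list[str]] = {
            p: sorted(set(allowed.get(p, ())) | {self.reference[p]})
            for p in self.positions
        }
        self.column_index: dict[tuple[int, str], int] = {}
        self.columns: list[tuple[int, str]] = []
        for p in self.positions:
            for aa in self.identities[p]:
                self.column_index[(p, aa)] = len(self.columns)
                self.columns.append((p, aa))

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def encode(self, genotypes: Sequence[Genotype]) -> np.ndarray:
        X = np.zeros((len(genotypes), self.n_columns), dtype=float)
        for i, g in enumerate(genotypes):
            for p, aa in g.identities:
                key = (p, aa)
                if key not in self.column_index:
                    raise ValueError(f"identity {aa} at {p} outside encoding alphabet")
                X[i, self.column_index[key]] = 1.0
        return X

    def decode(self, row: np.ndarray) -> Genotype:
        ids: dict[int, str] = {}
        for j, (p, aa) in enumerate(self.columns):
            if row[j] > 0.5:
                if p in ids:
                    raise ValueError(f"multiple active identities at position {p}")
                ids[p] = aa
        missing = set(self.positions) - set(ids)
        if missing:
            raise ValueError(f"no active identity at positions {sorted(missing)}")
        return Genotype.from_mapping(ids)


@dataclass
class TrainingDataset:
    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # neighborhood center per row
    encoder: GenotypeEncoder


@dataclass(frozen=True)
class LibraryDefinition:
    """Per-position allowed identity sets; the library is their product."""

    allowed: dict[int, frozenset[str]]
    reference: dict[int, str]
    target_size: int | None = None

    def __post_init__(self) -> None:
        for p, aas in self.allowed.items():
            if self.reference[p] not in aas:
                raise ValueError(f"reference identity missing at position {p}")


def space_size(allowed: Mapping[int, Iterable[str]] | LibraryDefinition) -> int:
    """Exact integer size of the combinatorial sequence space."""
    if isinstance(allowed, LibraryDefinition):
        allowed = allowed.allowed
    size = 1
    for aas in allowed.values():
        size *= len(set(aas))
    return size


def neighborhood_space_size(
    nbhd: SiteNeighborhood, mutations: Mapping[int, set[str]]
) -> int:
    size = 1
    for p in nbhd.members:
        size *= 1 + len(mutations.get(p, ()))
    return size


def select_ddg_threshold(
    neighborhoods: Sequence[SiteNeighborhood],
    scan: pd.DataFrame,
    grid: Sequence[float],
    max_total: int = 10**6,
    mode: str = "total",
) -> tuple[float, pd.DataFrame]:
    """Largest grid threshold keeping the implied design count under ``max_total``.

    ``mode='total'`` bounds the sum of neighborhood space sizes; the
    ``'per_neighborhood'`` alternative bounds each neighborhood separately.
    Returns the chosen threshold and the per-threshold size table.
    """
    grid = sorted(grid)
    if max_total <= 0:
        raise ValueError("max_total must be positive")
    rows = []
    chosen = None
    for t in grid:
        mutations = filter_by_ddg(scan, t)
        sizes = [neighborhood_space_size(n, mutations) for n in neighborhoods]
        total = sum(sizes)
        ok = total < max_total if mode == "total" else max(sizes) < max_total
        rows.append((t, total, max(sizes) if sizes else 1, ok))
        if ok:
            chosen = t
    table = pd.DataFrame(rows, columns=["threshold", "total", "max_neighborhood", "ok"])
    if chosen is None:
        logger.warning(
            "no threshold in grid keeps the space under %d; using smallest", max_total
        )
        chosen = grid[0]
    return float(chosen), table


def enumerate_neighborhood(
    nbhd: SiteNeighborhood,
    mutations: Mapping[int, set[str]],
    reference: Mapping[int, str],
    full_limit: int = 10_000,
    sample_fraction: float = 0.1,
    seed: int = 0,
) -> list[Genotype]:
    """Full enumeration below ``full_limit`` designs, else a seeded subsample.

    Genotypes are embedded in the full designed-position space with reference
    identities outside the neighborhood.  Subsampling draws
    ceil(fraction * size) distinct genotypes uniformly without replacement.
    """
    if not (0 < sample_fraction <= 1):
        raise ValueError("sample_fraction must lie in (0, 1]")
    members = list(nbhd.members)
    choices = [sorted({reference[p]} | set(mutations.get(p, ()))) for p in members]
    radices = [len(c) for c in choices]
    size = math.prod(radices)

    def genotype_at(index: int) -> Genotype:
        ids = dict(reference)
        for p, opts, r in zip(members, choices, radices):
            index, digit = divmod(index, r)
            ids[p] = opts[digit]
        return Genotype.from_mapping(ids)

    if size < full_limit:
        return [genotype_at(i) for i in range(size)]

    n = math.ceil(sample_fraction * size)
    rng = np.random.default_rng(seed)
    if size <= 10**7:
        idx = rng.choice(size, size=n, replace=False)
    else:  # rejection sampling with deduplication for huge spaces
        seen: set[int] = set()
        while len(seen) < n:
            seen.update(rng.integers(0, size, size=n - len(seen)).tolist())
        idx = np.fromiter(seen, dtype=np.int64)
    return [genotype_at(int(i)) for i in np.sort(idx)]


def label_designs(
    sample: NeighborhoodSample, reference_energy: float = 0.0
) -> np.ndarray:
    """Label 1 (better than reference), 0 (worst half) or undetermined (-1).

    The worst half is the ceil(n/2) highest-energy designs (stable ties);
    when a design satisfies both rules the success rule wins.
    """
    n = len(sample.energies)
    if n == 0:
        raise ValueError("empty neighborhood sample")
    labels = np.full(n, UNDETERMINED, dtype=int)
    order = np.argsort(-sample.energies, kind="stable")
    labels[order[: math.ceil(n / 2)]] = 0
    labels[sample.energies < reference_energy] = 1
    return labels


def assemble_dataset(
    samples: Sequence[NeighborhoodSample],
    allowed: Mapping[int, Iterable[str]],
    reference: Mapping[int, str],
    reference_energy: float = 0.0,
) -> TrainingDataset:
    """Pool labelled neighborhood designs into one one-hot training matrix."""
    encoder = GenotypeEncoder(allowed, reference)
    blocks, labels, prov = [], [], []
    for sample in samples:
        lab = label_designs(sample, reference_energy)
        keep = lab != UNDETERMINED
        genos = [g for g, k in zip(sample.genotypes, keep) if k]
        if not genos:
            continue
        blocks.append(encoder.encode(genos))
        labels.append(lab[keep])
        prov.extend([sample.neighborhood.center] * int(keep.sum()))
    if not blocks:
        raise ValueError("no labelled designs to assemble")
    return TrainingDataset(
        X=np.vstack(blocks),
        y=np.concatenate(labels),
        provenance=np.asarray(prov),
        encoder=encoder,
    )


@dataclass
class EpiNNetModel:
    classifier: MLPClassifier
    encoder: GenotypeEncoder
    holdout_accuracy: float

    def success_probability(self, genotypes: Sequence[Genotype]) -> np.ndarray:
        X = self.encoder.encode(genotypes)
        proba = self.classifier.predict_proba(X)
        success_col = list(self.classifier.classes_).index(1)
        return proba[:, success_col]


def train_epinnet(
    ds: TrainingDataset,
    hidden_size: int | None = None,
    max_iter: int = 2000,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> EpiNNetModel:
    """Fit the single-hidden-layer perceptron on the pooled dataset.

    The hidden layer width defaults to the number of designed positions.
    Returns the model plus its held-out accuracy on the (1 - train_fraction)
    split.
    """
    classes = set(np.unique(ds.y))
    if classes != {0, 1}:
        raise ValueError(f"need both success and failure labels, got {sorted(classes)}")
    if hidden_size is None:
        hidden_size = len(ds.encoder.positions)
    X_train, X_test, y_train, y_test = train_test_split(
        ds.X, ds.y, train_size=train_fraction, random_state=seed, shuffle=True
    )
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden_size,),
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_train, y_train)
    acc = float(clf.score(X_test, y_test))
    logger.info("EpiNNet held-out accuracy %.3f on %d rows", acc, len(y_test))
    return EpiNNetModel(clf, ds.encoder, acc)


def rank_mutations(
    model: EpiNNetModel,
    tolerated: Mapping[int, Iterable[str]],
    reference: Mapping[int, str],
    scan: pd.DataFrame | None = None,
) -> list[tuple[Mutation, float]]:
    """Score each tolerated single mutation on the reference background.

    Sorted by descending success probability; ties broken by lower ddG (when
    a scan is supplied), then position, then alphabetical identity.
    """
    muts: list[Mutation] = []
    for pos in sorted(tolerated):
        for aa in sorted(set(tolerated[pos])):
            if aa != reference[pos]:
                muts.append(Mutation(pos, reference[pos], aa))
    if not muts:
        return []
    genos = [Genotype.from_mutations(reference, [m]) for m in muts]
    scores = model.success_probability(genos)
    lut = scan_lookup(scan) if scan is not None else {}

    def sort_key(pair: tuple[Mutation, float]):
        m, s = pair
        return (-s, lut.get((m.position, m.to_aa), 0.0), m.position, m.to_aa)

    return sorted(zip(muts, scores), key=sort_key)


def select_library(
    ranked: Sequence[tuple[Mutation, float]],
    reference: Mapping[int, str],
    target_size: int,
) -> tuple[LibraryDefinition, list[tuple[Mutation, int]]]:
    """Grow the library by rank until the combinatorial space reaches target_size.

    The first mutation whose addition makes the space >= target_size is
    included.  Returns the library and the addition trace (mutation, space
    size after adding it).
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    allowed: dict[int, set[str]] = {p: {aa} for p, aa in reference.items()}
    trace: list[tuple[Mutation, int]] = []
    if space_size(allowed) >= target_size:
        return (
            LibraryDefinition(
                allowed={p: frozenset(s) for p, s in allowed.items()},
                reference=dict(reference),
                target_size=target_size,
            ),
            trace,
        )
    for m, _score in ranked:
        allowed[m.position].add(m.to_aa)
        size = space_size(allowed)
        trace.append((m, size))
        if size >= target_size:
            break
    else:
        if target_size > 1:
            logger.warning(
                "ranked list exhausted at space size %d < target %d",
                space_size(allowed),
                target_size,
            )
    lib = LibraryDefinition(
        allowed={p: frozenset(s) for p, s in allowed.items()},
        reference=dict(reference),
        target_size=target_size,
    )
    return lib, trace


def sample_space(
    lib: LibraryDefinition, n: int, seed: int = 0
) -> list[Genotype]:
    """Uniform independent draw per position among allowed identities."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    positions = sorted(lib.allowed)
    choices = {p: sorted(lib.allowed[p]) for p in positions}
    out = []
    for _ in range(n):
        ids = {p: choices[p][rng.integers(len(choices[p]))] for p in positions}
        out.append(Genotype.from_mapping(ids))
    return out


def enumerate_space(lib: LibraryDefinition) -> list[Genotype]:
    """Exhaustive enumeration of the library's combinatorial space."""
    positions = sorted(lib.allowed)
    choices = [sorted(lib.allowed[p]) for p in positions]
    radices = [len(c) for c in choices]
    size = math.prod(radices)
    out = []
    for index in range(size):
        ids = {}
        rem = index
        for p, opts, r in zip(positions, choices, radices):
            rem, digit = divmod(rem, r)
            ids[p] = opts[digit]
        out.append(Genotype.from_mapping(ids))
    return out


def _space_report(
    oracle: EnergyOracle,
    lib: LibraryDefinition,
    n: int,
    seed: int,
    exhaustive_limit: int,
) -> dict[str, float | int | bool]:
    size = space_size(lib)
    exhaustive = size <= exhaustive_limit
    genos = enumerate_space(lib) if exhaustive else sample_space(lib, n, seed)
    e_ref = oracle.energy(Genotype.from_mapping(dict(oracle.reference)))
    energies = np.array([oracle.energy(g) for g in genos])
    return {
        "space_size": size,
        "n_scored": len(genos),
        "exhaustive": exhaustive,
        "mean_energy": float(energies.mean()),
        "median_energy": float(np.median(energies)),
        "fraction_below_reference": float(np.mean(energies < e_ref)),
    }


def validate_spaces(
    oracle: EnergyOracle,
    enriched: LibraryDefinition,
    filtered: LibraryDefinition,
    n: int = 10_000,
    seed: int = 0,
    exhaustive_limit: int = 10_000,
) -> dict[str, dict]:
    """Compare energy distributions of the enriched and the filtered spaces.

    Spaces no larger than ``exhaustive_limit`` are enumerated exactly; larger
    ones are sampled (n genotypes, seeded).  Reports mean/median energy and
    the fraction of genotypes scoring strictly below the reference.
    """
    return {
        "enriched": _space_report(oracle, enriched, n, seed, exhaustive_limit),
        "filtered": _space_report(oracle, filtered, n, seed + 1, exhaustive_limit),
    }


def write_library_tsv(lib: LibraryDefinition, path) -> None:
    rows = [
        (p, lib.reference[p], "".join(sorted(lib.allowed[p])))
        for p in sorted(lib.allowed)
    ]
    pd.DataFrame(rows, columns=["position", "reference", "allowed"]).to_csv(
        path, sep="\t", index=False
    )


def read_library_tsv(path) -> LibraryDefinition:
    frame = pd.read_csv(path, sep="\t")
    allowed = {
        int(r["position"]): frozenset(str(r["allowed"])) for _, r in frame.iterrows()
    }
    reference = {int(r["position"]): str(r["reference"]) for _, r in frame.iterrows()}
    return LibraryDefinition(allowed=allowed, reference=reference)


def library_resfile_block(lib: LibraryDefinition, chain: str = "A") -> str:
    """Resfile-style text: one PIKAA line per designed position."""
    lines = ["NATRO", "start"]
    for p in sorted(lib.allowed):
        lines.append(f"{p} {chain} PIKAA {''.join(sorted(lib.allowed[p]))}")
    return "\n".join(lines) + "\n"
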