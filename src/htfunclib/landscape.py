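"""Origin-fixation evolutionary model and diffusion-map visualization.

A population evolves over a combinatorial genotype space by single
amino-acid substitutions.  The substitution rate from genotype i to an
adjacent genotype j is the classic origin-fixation form

    Q_ij = S_ij / (1 - exp(-S_ij)),

with S_ij the scaled selection coefficient; S_ij = 0 gives the neutral rate
1 (time measured so each possible amino-acid mutation occurs at rate 1).
With a binary functional phenotype f and selection strength c, S_ij =
c*(f_j - f_i), the chain is reversible with stationary distribution
pi_i proportional to exp(c*f_i), and c can be calibrated in closed form so the
population spends a target fraction of time (default 60%) at functional
genotypes.

Visualization uses the subdominant right eigenvectors of Q, pi-orthonormal
and scaled by 1/sqrt(-lambda_k), which gives coordinates in units of
sqrt(time): squared Euclidean distances approximate round-trip evolutionary
(commute) times.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .genotypes import Genotype

logger = logging.getLogger(__name__)

#: above this size the dense symmetric eigensolver is swapped for Lanczos
DENSE_SOLVER_LIMIT = 5_000


@dataclass(frozen=True)
class GenotypeSpace:
    """All genotypes over per-position allele sets; adjacency = 1 substitution."""

    positions: tuple[int, ...]
    alleles: tuple[tuple[str, ...], ...]

    @classmethod
    def from_allowed(cls, allowed: Mapping[int, Iterable[str]]) -> "GenotypeSpace":
        positions = tuple(sorted(allowed))
        return cls(positions, tuple(tuple(sorted(set(allowed[p]))) for p in positions))

    @property
    def size(self) -> int:
        return math.prod(len(a) for a in self.alleles)

    def genotype(self, index: int) -> Genotype:
        ids = {}
        rem = index
        for p, opts in zip(self.positions, self.alleles):
            rem, digit = divmod(rem, len(opts))
            ids[p] = opts[digit]
        return Genotype.from_mapping(ids)

    def index(self, genotype: Genotype) -> int:
        idx = 0
        stride = 1
        for p, opts in zip(self.positions, self.alleles):
            idx += opts.index(genotype.identity(p)) * stride
            stride *= len(opts)
        return idx

    def genotypes(self) -> list[Genotype]:
        return [self.genotype(i) for i in range(self.size)]

    def edges(self) -> list[tuple[int, int]]:
        """Adjacent index pairs (i < j): genotypes differing at one position."""
        out = []
        strides = []
        s = 1
        for opts in self.alleles:
            strides.append(s)
            s *= len(opts)
        for i in range(self.size):
            rem = i
            for opts, stride in zip(self.alleles, strides):
                digit = (rem // stride) % len(opts)
                for other in range(digit + 1, len(opts)):
                    out.append((i, i + (other - digit) * stride))
        return out


def fixation_rate(S: float) -> float:
    """Origin-fixation substitution rate S / (1 - exp(-S)); 1 at S = 0."""
    if not math.isfinite(S):
        raise ValueError("selection coefficient must be finite")
    if S == 0.0:
        return 1.0
    if S < -30.0:  # avoid overflow of exp(-S); rate ~ |S| * exp(S)
        return -S * math.exp(S) / (1.0 - math.exp(S))
    return S / (1.0 - math.exp(-S))


def build_rate_matrix(
    space: GenotypeSpace, f: Sequence[int], c: float
) -> sp.csr_matrix:
    """Sparse substitution-rate matrix with S_ij = c*(f_j - f_i) on edges."""
    if c < 0:
        raise ValueError("selection strength c must be >= 0")
    f = np.asarray(f, dtype=float)
    if len(f) != space.size:
        raise ValueError("functional indicator length != space size")
    up, down = fixation_rate(c), fixation_rate(-c)
    rows, cols, vals = [], [], []
    for i, j in space.edges():
        dS = f[j] - f[i]
        rate_ij = up if dS > 0 else down if dS < 0 else 1.0
        rate_ji = down if dS > 0 else up if dS < 0 else 1.0
        rows += [i, j]
        cols += [j, i]
        vals += [rate_ij, rate_ji]
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(space.size, space.size)).tocsr()
    Q = Q - sp.diags(np.asarray(Q.sum(axis=1)).ravel())
    return Q.tocsr()


def stationary(f: Sequence[int], c: float) -> np.ndarray:
    """Stationary distribution pi_i proportional to exp(c * f_i)."""
    f = np.asarray(f, dtype=float)
    w = np.exp(c * f)
    return w / w.sum()


def calibrate_c(f: Sequence[int], target_occupancy: float = 0.6) -> float:
    """Selection strength putting ``target_occupancy`` stationary mass on f=1.

    Closed form: c = ln( target/(1-target) * N_nonfunctional/N_functional ).
    """
    if not (0 < target_occupancy < 1):
        raise ValueError("target occupancy must lie in (0, 1)")
    f = np.asarray(f, dtype=int)
    n_func = int(f.sum())
    n_nonf = int(len(f) - n_func)
    if n_func == 0:
        raise ValueError("no functional genotypes to calibrate against")
    if n_nonf == 0:
        raise ValueError("no non-functional genotypes to calibrate against")
    return math.log(target_occupancy / (1 - target_occupancy) * n_nonf / n_func)


def stationary_from_rate_matrix(Q: sp.spmatrix) -> np.ndarray:
    """Left null vector of Q (pi @ Q = 0), via the dense null space."""
    A = Q.toarray().T
    _, _, vh = np.linalg.svd(A)
    pi = np.abs(vh[-1])
    return pi / pi.sum()


def diffusion_coordinates(
    Q: sp.spmatrix, pi: np.ndarray, k: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Subdominant-eigenvector coordinates in units of sqrt(time).

    Solves the pi-symmetrized eigenproblem; returns (coordinates, eigenvalues)
    where column m of the coordinates is u_m / sqrt(-lambda_m) with u_m the
    m-th subdominant right eigenvector of Q normalized under the pi-weighted
    inner product.  Deterministic sign: the largest-magnitude entry of each
    axis is positive.  Squared Euclidean distances between rows approximate
    round-trip (commute) evolutionary times.
    """
    n = Q.shape[0]
    if k >= n:
        raise ValueError(f"requested {k} axes for a space of {n} genotypes")
    sqrt_pi = np.sqrt(pi)
    D = sp.diags(sqrt_pi)
    Dinv = sp.diags(1.0 / sqrt_pi)
    A = D @ Q @ Dinv  # symmetric when Q is reversible w.r.t. pi
    if n <= DENSE_SOLVER_LIMIT:
        dense = A.toarray()
        dense = 0.5 * (dense + dense.T)  # clean numerical asymmetry
        eigvals, eigvecs = np.linalg.eigh(dense)
        order = np.argsort(-eigvals)  # 0 = lambda_0 > lambda_1 >= ...
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    else:
        eigvals, eigvecs = spla.eigsh(A, k=k + 1, which="LA")
        order = np.argsort(-eigvals)
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    coords = np.empty((n, k))
    lams = np.empty(k)
    for m in range(1, k + 1):
        lam = eigvals[m]
        if lam >= -1e-12:
            logger.warning("eigenvalue %d is ~0 (%.3g); disconnected space?", m, lam)
            lam = min(lam, -1e-12)
        u = eigvecs[:, m] / sqrt_pi  # right eigenvector of Q, pi-orthonormal
        if u[np.argmax(np.abs(u))] < 0:
            u = -u
        coords[:, m - 1] = u / math.sqrt(-lam)
        lams[m - 1] = lam
    return coords, lams


@dataclass
class LandscapeModel:
    space: GenotypeSpace
    f: np.ndarray
    c: float
    Q: sp.csr_matrix
    pi: np.ndarray
    eigenvalues: np.ndarray
    coordinates: np.ndarray


def build_landscape_model(
    space: GenotypeSpace,
    f: Sequence[int],
    target_occupancy: float = 0.6,
    k: int = 2,
    c: float | None = None,
) -> LandscapeModel:
    """Calibrate selection, build Q, and compute diffusion coordinates."""
    f = np.asarray(f, dtype=int)
    if c is None:
        c = calibrate_c(f, target_occupancy)
    Q = build_rate_matrix(space, f, c)
    pi = stationary(f, c)
    coords, lams = diffusion_coordinates(Q, pi, k=k)
    return LandscapeModel(space, f, float(c), Q, pi, lams, coords)


def region_logos(
    coordinates: np.ndarray,
    genotypes: Sequence[Genotype],
    axis: int,
    thresholds: Sequence[float],
    mask: Sequence[bool] | None = None,
) -> list[pd.DataFrame]:
    """Per-region position frequency matrices along one diffusion axis.

    ``thresholds`` (ascending) split the axis into len(thresholds)+1 regions:
    axis <= t_1, t_1 < axis <= t_2, ..., axis > t_last.  Rows (positions) of
    each returned frequency matrix sum to 1; an empty region yields zero
    counts and a warning.  ``mask`` optionally restricts the partition to
    (e.g.) functional genotypes.
    """
    thresholds = sorted(thresholds)
    vals = np.asarray(coordinates)[:, axis]
    keep = np.ones(len(genotypes), bool) if mask is None else np.asarray(mask, bool)
    positions = genotypes[0].positions if genotypes else ()
    alphabet = sorted({aa for g in genotypes for _, aa in g.identities})
    edges = [-np.inf, *thresholds, np.inf]
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        members = [
            g for g, v, k_ in zip(genotypes, vals, keep) if k_ and lo < v <= hi
        ]
        counts = pd.DataFrame(0.0, index=list(positions), columns=alphabet)
        for g in members:
            for p, aa in g.identities:
                counts.at[p, aa] += 1.0
        if members:
            counts = counts.div(counts.sum(axis=1), axis=0)
        else:
            logger.warning("empty region (%g, %g] on axis %d", lo, hi, axis)
        counts.index.name = "position"
        out.append(counts)
    return out


def write_coordinates_tsv(
    model: LandscapeModel, path, labels: Mapping[str, Sequence] | None = None
) -> None:
    genos = model.space.genotypes()
    data = {"genotype": [g.to_string() for g in genos]}
    for m in range(model.coordinates.shape[1]):
        data[f"axis{m + 1}"] = model.coordinates[:, m]
    data["functional"] = model.f
    if labels:
        data.update({k: list(v) for k, v in labels.items()})
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)
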