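"""Genotype-phenotype analysis of sorted deep-sequencing libraries.

Covers the downstream analyses of a FACS-sorted combinatorial library:
read-frequency enrichment and hit calling per fluorescence gate, filtering
external variant datasets to pocket-only mutants, sequence-derived feature
construction, a two-stage gradient-boosted classifier (functional vs. not,
then fluorescence channel), additive logistic-regression allele-preference
logos, and the exponential-decline-with-negative-epistasis fit of functional
fraction versus mutation count:

    F(n) = exp(-alpha*n - beta*n^2) = exp(-A*n - B*n*(n-1)/2),

with robustness A = alpha + beta >= 0 and epistasis B = 2*beta >= 0 (the
unique mapping under which the two forms coincide for all n).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

from .epinnet import GenotypeEncoder, SiteNeighborhood
from .genotypes import Genotype
from .pocket import max_sasa_delta
from .profiles import PSSM, delta_pssm

logger = logging.getLogger(__name__)

#: physicochemical amino-acid categories used for the category-change feature
AA_CATEGORIES: dict[str, str] = {
    **{aa: "aliphatic" for aa in "AVLIM"},
    **{aa: "aromatic" for aa in "FWYH"},
    **{aa: "polar" for aa in "STNQC"},
    **{aa: "positive" for aa in "KR"},
    **{aa: "negative" for aa in "DE"},
    **{aa: "special" for aa in "GP"},
}

NONFUNCTIONAL = "nonfunctional"
BOTH = "both"


@dataclass
class CountTable:
    """Per-sample read counts indexed by genotype string."""

    counts: pd.DataFrame  # index: genotype string; columns: sample ids

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative read counts")

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @classmethod
    def from_long_tsv(cls, path) -> "CountTable":
        frame = pd.read_csv(path, sep="\t", dtype={"genotype": str})
        wide = frame.pivot_table(
            index="genotype", columns="sample", values="count", fill_value=0
        )
        return cls(wide.astype(float))

    def to_long_tsv(self, path) -> None:
        long = self.counts.stack().rename("count").reset_index()
        long.columns = ["genotype", "sample", "count"]
        long.to_csv(path, sep="\t", index=False)


def enrichment(ct: CountTable, sorted_id: str, presorted_id: str) -> pd.Series:
    """Read-frequency ratio sorted/presorted per genotype.

    Genotypes observed only in the sorted sample get +inf (they are counted
    as enriched: the presorted pool is undersampled relative to the sorted
    one); genotypes absent from the sorted sample get 0.  Invariant to
    rescaling all counts of one sample.
    """
    for sid in (sorted_id, presorted_id):
        if sid not in ct.counts.columns:
            raise KeyError(f"sample {sid!r} not in count table")
        if ct.totals[sid] <= 0:
            raise ValueError(f"sample {sid!r} has zero total reads")
    fs = ct.counts[sorted_id] / ct.totals[sorted_id]
    fp = ct.counts[presorted_id] / ct.totals[presorted_id]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = fs / fp
    ratio[(fp == 0) & (fs > 0)] = np.inf
    ratio[fs == 0] = 0.0
    return ratio


def call_hits(
    enrichments: Mapping[str, pd.Series], threshold: float = 1.0
) -> pd.DataFrame:
    """Per-genotype functional call combining gates.

    A gate is hit when its enrichment exceeds ``threshold``.  The label is the
    single hit gate's name, 'both' for more than one, or 'nonfunctional'.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    gates = sorted(enrichments)
    frame = pd.DataFrame({g: enrichments[g] for g in gates}).fillna(0.0)
    labels = []
    for _, row in frame.iterrows():
        hits = [g for g in gates if row[g] > threshold]
        if not hits:
            labels.append(NONFUNCTIONAL)
        elif len(hits) == 1:
            labels.append(hits[0])
        else:
            labels.append(BOTH)
    frame["label"] = labels
    frame.index.name = "genotype"
    return frame


def pocket_filter(
    variants: Sequence[tuple[str, object]],
    reference_sequence: str,
    pocket: Iterable[int],
) -> list[tuple[str, object]]:
    """Keep variants whose every mutation lies at a pocket position (1-based)."""
    pocket = set(pocket)
    kept = []
    for seq, phenotype in variants:
        if len(seq) != len(reference_sequence):
            raise ValueError(
                f"variant length {len(seq)} != reference {len(reference_sequence)}"
            )
        mutated = {
            i + 1 for i, (a, b) in enumerate(zip(reference_sequence, seq)) if a != b
        }
        if mutated <= pocket:
            kept.append((seq, phenotype))
    return kept


def functional_fraction_by_n(
    n_mutations: Sequence[int], functional: Sequence[bool]
) -> pd.DataFrame:
    """Fraction of functional genotypes per mutation count; empty bins omitted."""
    frame = pd.DataFrame({"n": n_mutations, "functional": functional})
    grouped = frame.groupby("n")["functional"].agg(["mean", "size"]).reset_index()
    grouped.columns = ["n", "fraction", "count"]
    return grouped


@dataclass(frozen=True)
class DeclineFit:
    """Parameters of F(n) = exp(-A n - B n(n-1)/2) with A, B >= 0."""

    A: float  # robustness
    B: float  # epistasis
    residual: float

    @property
    def alpha(self) -> float:
        return self.A - self.B / 2.0

    @property
    def beta(self) -> float:
        return self.B / 2.0

    def predict(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return np.exp(-self.A * n - self.B * n * (n - 1) / 2.0)


def fit_decline(n: Sequence[float], F: Sequence[float]) -> DeclineFit:
    """Constrained least squares of the decline curve on linear F.

    Fitting on the linear scale tolerates near-zero fractions; A and B are
    bounded below by 0.
    """
    n = np.asarray(n, dtype=float)
    F = np.asarray(F, dtype=float)
    if len(n) < 2 or np.sum(n >= 1) < 2:
        raise ValueError("need at least two points with n >= 1")
    if np.all(F <= 0):
        raise ValueError("all fractions are zero; nothing to fit")
    if np.any(F < 0) or np.any(F > 1):
        raise ValueError("fractions must lie in [0, 1]")

    # log-linear initial guess for A, flat epistasis
    pos = F > 0
    slope = -np.polyfit(n[pos], np.log(F[pos]), 1)[0] if pos.sum() >= 2 else 0.1
    x0 = np.array([max(slope, 1e-6), 1e-6])

    def resid(params):
        A, B = params
        return np.exp(-A * n - B * n * (n - 1) / 2.0) - F

    sol = least_squares(resid, x0, bounds=([0.0, 0.0], [np.inf, np.inf]))
    return DeclineFit(float(sol.x[0]), float(sol.x[1]), float(np.sum(sol.fun**2)))


def build_features(
    genotypes: Sequence[Genotype],
    reference: Mapping[int, str],
    pssm: PSSM,
    neighborhoods: Sequence[SiteNeighborhood],
    areas: Mapping[str, Iterable[int]] | None = None,
) -> pd.DataFrame:
    """Sequence-only feature table for genotype-phenotype classification.

    Per genotype: categorical identity per position; total mutation count;
    mutation count per neighborhood (and per optional user-defined area);
    per-position conservation change (delta PSSM), accessible-area change
    (difference of tabulated per-amino-acid maxima) and a category-change
    flag; plus the mean and max of each per-position block over the mutated
    positions.
    """
    positions = sorted(reference)
    areas = {k: set(v) for k, v in (areas or {}).items()}
    rows = []
    for g in genotypes:
        row: dict[str, object] = {}
        muts = {p: aa for p, aa in g.identities if aa != reference[p]}
        for p in positions:
            row[f"aa_{p}"] = g.identity(p)
        row["n_mutations"] = len(muts)
        for nb in neighborhoods:
            row[f"nbhd_{nb.center}"] = sum(1 for p in nb.members if p in muts)
        for name, posset in areas.items():
            row[f"area_{name}"] = sum(1 for p in posset if p in muts)
        dp = delta_pssm(g, reference, pssm)
        dsasa = {}
        catchange = {}
        for p in positions:
            aa = g.identity(p)
            dsasa[p] = max_sasa_delta(reference[p], aa) if p in muts else 0.0
            catchange[p] = (
                float(AA_CATEGORIES[aa] != AA_CATEGORIES[reference[p]])
                if p in muts
                else 0.0
            )
            row[f"dpssm_{p}"] = dp["per_position"][p]
            row[f"dsasa_{p}"] = dsasa[p]
            row[f"catchange_{p}"] = catchange[p]
        mut_pos = list(muts)
        for name, block in (("dpssm", dp["per_position"]), ("dsasa", dsasa),
                            ("catchange", catchange)):
            vals = [block[p] for p in mut_pos]
            row[f"{name}_mean"] = float(np.mean(vals)) if vals else 0.0
            row[f"{name}_max"] = float(np.max(vals)) if vals else 0.0
        rows.append(row)
    frame = pd.DataFrame(rows)
    for p in positions:
        frame[f"aa_{p}"] = frame[f"aa_{p}"].astype("category")
    return frame


def prune_features(features: pd.DataFrame) -> pd.DataFrame:
    """Drop zero-variance (non-informative) columns, logging what went."""
    drop = [
        c for c in features.columns if features[c].nunique(dropna=False) <= 1
    ]
    if drop:
        logger.info("pruning non-informative features: %s", drop)
    return features.drop(columns=drop)


def _balanced_subsample(y: pd.Series, rng: np.random.Generator) -> np.ndarray:
    """Row indices with every class subsampled to the minority count."""
    counts = y.value_counts()
    n_min = counts.min()
    keep: list[int] = []
    for cls in counts.index:
        idx = np.flatnonzero(y.values == cls)
        keep.extend(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.array(keep))


@dataclass
class TwoStageClassifier:
    """Functional/non-functional gate followed by a channel classifier."""

    stage1: object
    stage2: object
    stage1_balanced_accuracy: float
    stage2_accuracy: float
    feature_importance: pd.DataFrame
    pruned: list[str]
    feature_columns: list[str]

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_columns]
        functional = self.stage1.predict(X).astype(bool)
        out = np.full(len(features), NONFUNCTIONAL, dtype=object)
        if functional.any():
            out[functional] = self.stage2.predict(X[functional])
        return out


def two_stage_classify(
    features: pd.DataFrame,
    labels: Sequence[str],
    stage1=None,
    stage2=None,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> TwoStageClassifier:
    """Train the two-stage genotype-phenotype classifier.

    Stage 1 is binary (functional = any label other than 'nonfunctional');
    stage 2 classifies the channel and is trained and evaluated only on
    functional rows.  Stage-1 accuracy is reported on a class-balanced
    held-out set (majority classes subsampled to the minority count).
    Default classifiers are gradient-boosted trees; any sklearn-style
    estimator pair can be plugged in.
    """
    import lightgbm as lgb

    y = pd.Series(list(labels))
    functional = (y != NONFUNCTIONAL).astype(int)
    if functional.nunique() < 2:
        raise ValueError("need both functional and non-functional examples")
    if y[functional == 1].nunique() < 2:
        raise ValueError("need at least two channel classes among functional rows")

    pruned_frame = prune_features(features)
    pruned = [c for c in features.columns if c not in pruned_frame.columns]
    X = pruned_frame

    if stage1 is None:
        stage1 = lgb.LGBMClassifier(random_state=seed, verbose=-1)
    if stage2 is None:
        stage2 = lgb.LGBMClassifier(random_state=seed, verbose=-1)

    rng = np.random.default_rng(seed)
    n = len(X)
    test_idx = rng.choice(n, size=max(1, int(round(test_fraction * n))), replace=False)
    test_mask = np.zeros(n, bool)
    test_mask[test_idx] = True
    # guarantee both stage-1 classes in both splits
    for cls in (0, 1):
        cls_idx = np.flatnonzero(functional.values == cls)
        if not test_mask[cls_idx].any():
            test_mask[cls_idx[0]] = True
        if test_mask[cls_idx].all():
            test_mask[cls_idx[0]] = False

    X_train, X_test = X[~test_mask], X[test_mask]
    y_train, y_test = y[~test_mask], y[test_mask]
    f_train, f_test = functional[~test_mask], functional[test_mask]

    stage1.fit(X_train, f_train)
    bal_idx = _balanced_subsample(f_test.reset_index(drop=True), rng)
    acc1 = float(
        np.mean(stage1.predict(X_test.iloc[bal_idx]) == f_test.values[bal_idx])
    )

    func_train = f_train.values == 1
    stage2.fit(X_train[func_train], y_train[func_train])
    func_test = f_test.values == 1
    if func_test.any():
        acc2 = float(
            np.mean(stage2.predict(X_test[func_test]) == y_test.values[func_test])
        )
    else:
        acc2 = float("nan")

    importance = pd.DataFrame(
        {
            "feature": list(X.columns),
            "stage1_importance": getattr(stage1, "feature_importances_", np.zeros(X.shape[1])),
        }
    ).sort_values("stage1_importance", ascending=False, ignore_index=True)

    return TwoStageClassifier(
        stage1, stage2, acc1, acc2, importance, pruned, list(X.columns)
    )


def hamming_ball(
    genotypes: Sequence[Genotype],
    centers: Sequence[Genotype],
    radius: int,
) -> list[int]:
    """Indices of genotypes within ``radius`` substitutions of any center."""
    return [
        i
        for i, g in enumerate(genotypes)
        if min(g.hamming(c) for c in centers) <= radius
    ]


def logistic_logo(
    genotypes: Sequence[Genotype],
    labels: Sequence[int],
    l2_C: float | None = 0.5,
    cv_folds: int = 10,
    center_genotypes: Sequence[Genotype] | None = None,
    radius: int = 2,
) -> pd.DataFrame:
    """Additive allele-preference logo from an L2 logistic regression.

    Fits a one-hot additive logistic model of the binary label, optionally
    restricted to genotypes within ``radius`` Hamming distance of any of
    ``center_genotypes``.  ``l2_C=None`` selects the regularization constant
    by cross-validation.  Returns per-(position, amino-acid) coefficients as
    delta-log2 odds ratios, mean-centered within each position over the
    identities observed there.
    """
    labels = np.asarray(labels, dtype=int)
    genotypes = list(genotypes)
    if center_genotypes is not None:
        keep = hamming_ball(genotypes, center_genotypes, radius)
        genotypes = [genotypes[i] for i in keep]
        labels = labels[keep]
    if len(genotypes) < 2:
        raise ValueError("fewer than two genotypes after filtering")
    if len(np.unique(labels)) < 2:
        raise ValueError("need both labels after filtering")

    positions = genotypes[0].positions
    observed: dict[int, set[str]] = {p: set() for p in positions}
    for g in genotypes:
        for p, aa in g.identities:
            observed[p].add(aa)
    reference = {p: sorted(observed[p])[0] for p in positions}
    encoder = GenotypeEncoder(observed, reference)
    X = encoder.encode(genotypes)

    if l2_C is None:  # L2 penalty is the estimator default
        model = LogisticRegressionCV(
            Cs=np.logspace(-3, 3, 13), cv=cv_folds, max_iter=5000
        )
    else:
        model = LogisticRegression(C=l2_C, max_iter=5000)
    model.fit(X, labels)
    coef_log2 = model.coef_.ravel() / math.log(2.0)

    frame = pd.DataFrame(
        0.0, index=list(positions), columns=sorted({aa for s in observed.values() for aa in s})
    )
    for (p, aa), j in encoder.column_index.items():
        frame.at[p, aa] = coef_log2[j]
    # mean-center per position over the identities actually observed there
    for p in positions:
        obs = sorted(observed[p])
        frame.loc[p, obs] -= frame.loc[p, obs].mean()
        unobs = [aa for aa in frame.columns if aa not in obs]
        frame.loc[p, unobs] = 0.0
    frame.index.name = "position"
    return frame
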