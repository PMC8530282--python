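"""Count-matrix preprocessing: filtering, normalization, adjustment, splitting.

The pipeline mirrors standard bulk RNA-seq practice for classifier inputs:

1. expression filters on counts-per-million (CPM) remove features that are
   too lowly or extremely highly expressed;
2. between-sample composition differences are normalized with TMM (trimmed
   mean of M-values) or, alternatively, upper-quartile factors;
3. counts are transformed to log2-CPM with a 0.5 prior count and effective
   library sizes;
4. quantile normalization forces every sample onto the across-sample mean
   of order statistics;
5. optional covariate adjustment removes nuisance effects (age, sex, BMI,
   batch) by OLS while retaining the class main effect;
6. samples are split into train/validation/test sets and 5 CV folds,
   stratified by the binary label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "SampleTable",
    "SplitAssignment",
    "PreprocessError",
    "compute_cpm",
    "filter_features",
    "tmm_factors",
    "uq_factors",
    "log2_cpm",
    "quantile_normalize",
    "adjust_covariates",
    "split_dataset",
    "restrict_to_panel",
    "read_counts_tsv",
    "write_matrix_tsv",
    "read_expression_tsv",
    "read_phenotype",
]


class PreprocessError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Raw integer read counts, features x samples."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    feature_kind: str = "gene"  # gene | isoform | exon

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise PreprocessError(
                f"count shape {self.counts.shape} inconsistent with ids "
                f"({len(self.feature_ids)} x {len(self.sample_ids)})"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise PreprocessError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise PreprocessError("duplicate sample ids")
        if self.counts.size and self.counts.min() < 0:
            raise PreprocessError("negative counts")
        if self.feature_kind not in ("gene", "isoform", "exon"):
            raise PreprocessError(f"unknown feature_kind {self.feature_kind!r}")

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def subset_features(self, keep_ids: Sequence[str]) -> "CountMatrix":
        index = {fid: i for i, fid in enumerate(self.feature_ids)}
        rows = [index[fid] for fid in keep_ids]
        return CountMatrix(
            list(keep_ids), list(self.sample_ids), self.counts[rows], self.feature_kind
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class ExpressionMatrix:
    """Normalized real-valued expression (log2-CPM scale), features x samples."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise PreprocessError("expression shape inconsistent with ids")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise PreprocessError("non-finite expression values")

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {sid: j for j, sid in enumerate(self.sample_ids)}
        cols = [index[sid] for sid in sample_ids]
        return ExpressionMatrix(
            list(self.feature_ids), list(sample_ids), self.values[:, cols]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class SampleTable:
    """Per-sample phenotype: binary label plus covariate columns."""

    frame: pd.DataFrame  # index: sample_id; column "label"; rest covariates

    def __post_init__(self) -> None:
        if "label" not in self.frame.columns:
            raise PreprocessError("phenotype table needs a 'label' column")
        if self.frame.index.has_duplicates:
            raise PreprocessError("duplicate sample ids in phenotype table")
        labels = set(pd.unique(self.frame["label"]))
        if not labels <= {0, 1}:
            raise PreprocessError(f"labels must be 0/1, got {sorted(labels)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        return self.frame.loc[list(sample_ids), "label"].to_numpy(dtype=int)


@dataclass
class SplitAssignment:
    """Sample partition into train/validation/test plus CV folds for train."""

    split: dict[str, str] = field(default_factory=dict)  # sample -> train|validation|test
    fold: dict[str, int] = field(default_factory=dict)  # train sample -> 1..n_folds

    def samples_in(self, which: str) -> list[str]:
        return [s for s, w in self.split.items() if w == which]

    def fold_samples(self, k: int) -> list[str]:
        return [s for s, f in self.fold.items() if f == k]

    @property
    def n_folds(self) -> int:
        return max(self.fold.values()) if self.fold else 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "split": w, "fold": self.fold.get(s, "")}
            for s, w in self.split.items()
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str) -> "SplitAssignment":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        split = dict(zip(df["sample_id"], df["split"]))
        fold = {
            s: int(f)
            for s, f in zip(df["sample_id"], df["fold"])
            if f == f and str(f) != ""  # skip NaN / empty
        }
        return cls(split, fold)


# ---------------------------------------------------------------------------
# CPM and filtering


def compute_cpm(counts: CountMatrix) -> np.ndarray:
    """Counts per million against raw (pre-filter) library sizes.

    Each column of the result sums to 1e6.  Raises when a sample has zero
    library size, naming the sample.
    """
    libsize = counts.library_sizes
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise PreprocessError(
            f"zero library size for sample(s) {[counts.sample_ids[j] for j in zero]}"
        )
    return counts.counts / libsize * 1e6


def filter_features(
    counts: CountMatrix,
    low_mean_cpm: float = 0.2,
    min_cpm: float = 0.5,
    min_samples: int = 50,
    high_cpm: float = 50_000.0,
    high_max_samples: int = 50,
) -> list[str]:
    """Expression filter on CPM; returns kept feature ids in input order.

    A feature is removed when its mean CPM is below ``low_mean_cpm`` or it
    fails to reach ``min_cpm`` in at least ``min_samples`` samples; it is
    additionally removed as an extreme outlier when it exceeds ``high_cpm``
    in at least one but fewer than ``high_max_samples`` samples.
    """
    n_samples = len(counts.sample_ids)
    if min_samples > n_samples:
        warnings.warn(
            f"min_samples={min_samples} exceeds sample count {n_samples}; "
            "the low-expression prevalence rule removes everything it judges",
            stacklevel=2,
        )
    cpm = compute_cpm(counts)
    mean_ok = cpm.mean(axis=1) >= low_mean_cpm
    prevalence_ok = (cpm > min_cpm).sum(axis=1) >= min_samples
    n_high = (cpm > high_cpm).sum(axis=1)
    extreme = (n_high >= 1) & (n_high < high_max_samples)
    keep = mean_ok & prevalence_ok & ~extreme
    return [fid for fid, k in zip(counts.feature_ids, keep) if k]


# ---------------------------------------------------------------------------
# Normalization factors


def _quantile_factor(counts: np.ndarray, libsize: np.ndarray, p: float = 0.75) -> np.ndarray:
    """Per-sample p-quantile of counts divided by library size (R type-7 quantile)."""
    return np.quantile(counts, p, axis=0, method="linear") / libsize


def tmm_factors(
    counts: CountMatrix,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean 75th percentile.  For each sample, M (log2 ratio) and A (mean
    log2 abundance) values are computed over features with nonzero counts in
    both the sample and the reference; the upper and lower ``logratio_trim``
    fraction by M and ``sum_trim`` fraction by A are discarded; the remaining
    M values are averaged with precision weights (inverse asymptotic variance
    of M) and exponentiated.  Factors are rescaled to geometric mean 1.

    A sample sharing no nonzero features with the reference gets factor 1
    with a warning.
    """
    y = counts.counts.astype(float)
    n_features, n_samples = y.shape
    if n_samples < 2:
        raise PreprocessError("TMM needs at least 2 samples")
    libsize = counts.library_sizes
    if np.any(libsize == 0):
        raise PreprocessError("zero library size")

    f75 = _quantile_factor(y, libsize)
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    ref = y[:, ref_idx]
    n_ref = libsize[ref_idx]

    log_factors = np.zeros(n_samples)
    for k in range(n_samples):
        obs = y[:, k]
        n_obs = libsize[k]
        mask = (obs > 0) & (ref > 0)
        if not mask.any():
            warnings.warn(
                f"sample {counts.sample_ids[k]} shares no expressed features "
                "with the reference; factor set to 1",
                stacklevel=2,
            )
            continue
        o, r = obs[mask], ref[mask]
        m = np.log2((o / n_obs) / (r / n_ref))
        a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
        v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
        if np.max(np.abs(m)) < 1e-6:
            continue
        n = m.size
        lo_l = np.floor(n * logratio_trim) + 1
        hi_l = n + 1 - lo_l
        lo_s = np.floor(n * sum_trim) + 1
        hi_s = n + 1 - lo_s
        rank_m = rankdata(m)
        rank_a = rankdata(a)
        keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
        if not keep.any():
            continue
        with np.errstate(divide="ignore"):
            w = 1.0 / v[keep]
        f = np.sum(w * m[keep]) / np.sum(w)
        log_factors[k] = 0.0 if np.isnan(f) else f

    factors = 2.0 ** log_factors
    return factors / np.exp(np.mean(np.log(factors)))


def uq_factors(counts: CountMatrix) -> np.ndarray:
    """Upper-quartile normalization factors (75th percentile of expressed counts)."""
    y = counts.counts.astype(float)
    libsize = counts.library_sizes
    expressed = y[y.sum(axis=1) > 0]
    if expressed.size == 0:
        raise PreprocessError("no expressed features for upper-quartile factors")
    f = _quantile_factor(expressed, libsize)
    if np.any(f == 0):
        raise PreprocessError("zero upper quartile; library too sparse for UQ")
    return f / np.exp(np.mean(np.log(f)))


def log2_cpm(counts: CountMatrix, factors: np.ndarray | None = None) -> ExpressionMatrix:
    """log2 CPM with prior count 0.5 against effective library sizes.

    ``value = log2((count + 0.5) / (libsize * factor + 1.0) * 1e6)``.
    """
    if factors is None:
        factors = np.ones(len(counts.sample_ids))
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise PreprocessError("normalization factors must be positive")
    eff_lib = counts.library_sizes * factors
    values = np.log2((counts.counts + 0.5) / (eff_lib + 1.0) * 1e6)
    return ExpressionMatrix(list(counts.feature_ids), list(counts.sample_ids), values)


# ---------------------------------------------------------------------------
# Quantile normalization


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean of order statistics.

    Ties within a column receive the average of the reference values at the
    tied ranks, so the transform is well defined and idempotent.
    """
    x = expr.values
    if x.shape[1] < 2:
        raise PreprocessError("quantile normalization needs >= 2 samples")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average reference values over runs of tied input values
        sorted_col = col[order]
        run_starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        run_ends = np.r_[run_starts[1:], sorted_col.size]
        for s, e in zip(run_starts, run_ends):
            if e - s > 1:
                assigned[order[s:e]] = reference[s:e].mean()
        out[:, j] = assigned
    return ExpressionMatrix(list(expr.feature_ids), list(expr.sample_ids), out)


# ---------------------------------------------------------------------------
# Covariate adjustment


def _design_matrix(
    samples: SampleTable, covariate_names: Sequence[str], sample_ids: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """[intercept | covariates (one-hot, first level dropped) | label]."""
    df = samples.frame.loc[list(sample_ids)]
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    for name in covariate_names:
        if name not in df.columns:
            raise PreprocessError(f"unknown covariate {name!r}")
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            levels = sorted(pd.unique(col.astype(str)))
            for level in levels[1:]:  # first level is the reference
                cols.append((col.astype(str) == level).to_numpy(dtype=float))
                names.append(f"{name}[{level}]")
    cols.append(df["label"].to_numpy(dtype=float))
    names.append("label")
    return np.column_stack(cols), names


def adjust_covariates(
    expr: ExpressionMatrix,
    samples: SampleTable,
    covariate_names: Sequence[str],
) -> ExpressionMatrix:
    """Remove covariate effects by OLS while retaining the class main effect.

    Per feature, ordinary least squares is fitted on the full design
    [intercept | covariates | label] and only the fitted covariate
    contribution is subtracted.  The operation is a projection: applying it
    twice equals applying it once.
    """
    design, names = _design_matrix(samples, covariate_names, expr.sample_ids)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify (approximately) collinear columns via QR diagonal
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise PreprocessError(f"design matrix is rank deficient; check columns {bad}")
    # beta: (p, n_features); covariate columns are 1..p-2 (excluding intercept, label)
    beta, *_ = np.linalg.lstsq(design, expr.values.T, rcond=None)
    cov_slice = slice(1, design.shape[1] - 1)
    fitted_cov = design[:, cov_slice] @ beta[cov_slice]
    return ExpressionMatrix(
        list(expr.feature_ids), list(expr.sample_ids), expr.values - fitted_cov.T
    )


# ---------------------------------------------------------------------------
# Splitting


def _apportion(total_per_split: Sequence[int], n_class: int, n_total: int) -> list[int]:
    """Largest-remainder apportionment of one class across splits."""
    ideal = [n_class * s / n_total for s in total_per_split]
    base = [int(np.floor(v)) for v in ideal]
    short = n_class - sum(base)
    remainders = sorted(
        range(len(ideal)), key=lambda i: (ideal[i] - base[i]), reverse=True
    )
    for i in remainders[:short]:
        base[i] += 1
    return base


def split_dataset(
    samples: SampleTable,
    sizes: tuple[int, int, int],
    n_folds: int = 5,
    seed: int = 0,
) -> SplitAssignment:
    """Label-stratified random partition into train/validation/test plus CV folds.

    ``sizes`` must sum to the number of samples.  The positive class is
    apportioned across the three splits by largest remainder, so each
    split's positive fraction is within one sample of the global fraction.
    Training samples are dealt round-robin into ``n_folds`` stratified folds
    of near-equal size.  Deterministic given ``seed``.
    """
    n = len(samples.sample_ids)
    if sum(sizes) != n:
        raise PreprocessError(f"split sizes {sizes} do not sum to {n} samples")
    rng = np.random.default_rng(seed)
    ids = np.array(samples.sample_ids)
    labels = samples.labels
    pos = ids[labels == 1]
    neg = ids[labels == 0]
    rng.shuffle(pos)
    rng.shuffle(neg)

    pos_per_split = _apportion(sizes, len(pos), n)
    neg_per_split = [s - p for s, p in zip(sizes, pos_per_split)]
    if any(v < 0 for v in neg_per_split):
        raise PreprocessError("requested sizes incompatible with class balance")

    names = ("train", "validation", "test")
    assignment = SplitAssignment()
    ip = in_ = 0
    split_members: dict[str, list[str]] = {}
    for name, np_, nn_ in zip(names, pos_per_split, neg_per_split):
        members = list(pos[ip : ip + np_]) + list(neg[in_ : in_ + nn_])
        ip += np_
        in_ += nn_
        for s in members:
            assignment.split[s] = name
        split_members[name] = members

    # folds: single round-robin over shuffled positives then negatives keeps
    # both per-class and total fold sizes within 1
    train_pos = [s for s in pos if assignment.split[s] == "train"]
    train_neg = [s for s in neg if assignment.split[s] == "train"]
    for i, s in enumerate(train_pos + train_neg):
        assignment.fold[s] = (i % n_folds) + 1
    return assignment


def restrict_to_panel(
    counts: CountMatrix,
    gene_panel: set[str],
    feature_to_gene: Mapping[str, str],
) -> CountMatrix:
    """Keep features whose gene belongs to the panel; order preserved."""
    missing = [f for f in counts.feature_ids if f not in feature_to_gene]
    if missing:
        raise PreprocessError(f"features without gene mapping: {missing[:5]}")
    keep = [f for f in counts.feature_ids if feature_to_gene[f] in gene_panel]
    if not keep:
        warnings.warn("gene panel leaves no features", stacklevel=2)
    index = {f: i for i, f in enumerate(counts.feature_ids)}
    rows = [index[f] for f in keep]
    return CountMatrix(
        keep, list(counts.sample_ids), counts.counts[rows], counts.feature_kind
    )


# ---------------------------------------------------------------------------
# I/O


def read_counts_tsv(path: str, feature_kind: str = "gene") -> CountMatrix:
    """Read a counts TSV with feature ids in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(),
        feature_kind,
    )


def write_matrix_tsv(matrix: CountMatrix | ExpressionMatrix, path: str) -> None:
    data = matrix.counts if isinstance(matrix, CountMatrix) else matrix.values
    pd.DataFrame(data, index=matrix.feature_ids, columns=matrix.sample_ids).to_csv(
        path, sep="\t", index_label="feature_id"
    )


def read_expression_tsv(path: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        [str(i) for i in df.index], [str(c) for c in df.columns], df.to_numpy(float)
    )


def read_phenotype(path: str) -> SampleTable:
    """Read a phenotype TSV/CSV with columns sample_id, label, covariates."""
    sep = "," if path.endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise PreprocessError("phenotype file needs a sample_id column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return SampleTable(df)
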