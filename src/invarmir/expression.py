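"""Expression matrices, environment assignments, and robust feature selection.

Expression data are feature x sample tables of log-scale values (miRNA or
mRNA).  Environments are labelled sample subgroups -- cancer subtypes in the
motivating application, or random splits -- across which residual invariance
is later tested.  Feature selection uses the median absolute deviation (MAD),
the robust variability measure standard in cancer-subtyping pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: minimum samples an environment must contain for the variance tests
#: downstream (two-sample t and F need a couple of degrees of freedom each).
DEFAULT_MIN_ENV_SIZE = 3


class ExpressionMatrixError(ValueError):
    """Malformed expression input (duplicates, non-numeric cells, NaN)."""


@dataclass
class ExpressionMatrix:
    """Feature x sample matrix of real-valued (log-scale) expression.

    Parameters
    ----------
    data
        DataFrame with feature identifiers as the index and sample
        identifiers as the columns.  Values must be finite reals.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        dup_f = idx[idx.duplicated()].unique()
        if len(dup_f):
            raise ExpressionMatrixError(
                f"duplicate feature id(s): {', '.join(map(str, dup_f[:5]))}"
            )
        dup_s = cols[cols.duplicated()].unique()
        if len(dup_s):
            raise ExpressionMatrixError(
                f"duplicate sample id(s): {', '.join(map(str, dup_s[:5]))}"
            )
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            bad = [c for c, dt in self.data.dtypes.items() if not np.issubdtype(dt, np.number)]
            raise ExpressionMatrixError(f"non-numeric column(s): {bad[:5]}")
        if self.data.isna().any().any():
            r, c = np.argwhere(self.data.isna().to_numpy())[0]
            raise ExpressionMatrixError(
                f"missing value at feature {idx[r]!r}, sample {cols[c]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        """Feature x sample array view of the data."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ExpressionMatrixError(f"unknown sample id(s): {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, sample_ids])


@dataclass
class EnvironmentAssignment:
    """Partition of samples into labelled environments (the set of settings
    across which invariance is tested).

    ``labels`` maps each sample id to its environment label.  At least two
    distinct environments are required and each must contain at least
    ``min_size`` samples.
    """

    labels: dict[str, str]
    min_size: int = DEFAULT_MIN_ENV_SIZE
    environments: list[str] = field(init=False)

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        for lab in self.labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        if len(counts) < 2:
            raise ValueError(
                f"need at least 2 distinct environments, got {sorted(counts)}"
            )
        for lab, n in counts.items():
            if n < self.min_size:
                raise ValueError(
                    f"environment {lab!r} has {n} samples, below minimum {self.min_size}"
                )
        # deterministic order: first appearance in the label map
        seen: list[str] = []
        for lab in self.labels.values():
            if lab not in seen:
                seen.append(lab)
        self.environments = seen

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels)

    def mask(self, environment: str, sample_ids: list[str]) -> np.ndarray:
        """Boolean mask over ``sample_ids`` of membership in ``environment``."""
        if environment not in self.environments:
            raise KeyError(f"unknown environment {environment!r}")
        unknown = [s for s in sample_ids if s not in self.labels]
        if unknown:
            raise ValueError(f"sample(s) without environment label: {unknown[:5]}")
        return np.array([self.labels[s] == environment for s in sample_ids])

    def check_samples(self, matrix: ExpressionMatrix) -> None:
        """Verify every labelled sample exists in ``matrix`` (cross-validation
        of the label table against the expression table)."""
        cols = set(matrix.sample_ids)
        unknown = [s for s in self.labels if s not in cols]
        if unknown:
            raise ValueError(
                f"labelled sample(s) absent from expression matrix: {unknown[:5]}"
            )


def read_expression_matrix(
    path,
    delimiter: str | None = None,
    drop_missing: bool = False,
) -> ExpressionMatrix:
    """Read a feature x sample expression table.

    First column holds feature ids, header row holds sample ids.  The
    delimiter is inferred from the file name (``.tsv``/``.txt`` -> tab,
    otherwise comma) when not given.  Gzip-compressed files are accepted.

    Parameters
    ----------
    drop_missing
        When True, features containing any missing value are dropped with a
        logged warning instead of raising.
    """
    if delimiter is None:
        name = str(path)
        if name.endswith(".gz"):
            name = name[:-3]
        delimiter = "\t" if name.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[np.argmax(bad.to_numpy())]
                raise ExpressionMatrixError(
                    f"non-numeric value at feature {row!r}, sample {col!r} in {path}"
                )
            df[col] = coerced
    if drop_missing and df.isna().any().any():
        bad_feats = df.index[df.isna().any(axis=1)]
        logger.warning(
            "dropping %d feature(s) with missing values: %s",
            len(bad_feats),
            list(bad_feats[:5]),
        )
        df = df.dropna(axis=0)
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path, delimiter: str | None = None) -> None:
    """Write a matrix in the format :func:`read_expression_matrix` reads."""
    if delimiter is None:
        name = str(path)
        if name.endswith(".gz"):
            name = name[:-3]
        delimiter = "\t" if name.endswith((".tsv", ".txt")) else ","
    matrix.data.to_csv(path, sep=delimiter)


def mad(values) -> float:
    """Median absolute deviation, median(|x - median(x)|), consistency
    constant 1 (unscaled -- only MAD ranks matter for selection)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    return float(np.median(np.abs(arr - np.median(arr))))


def select_by_mad(matrix: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the ``k`` features with largest MAD, ordered by decreasing MAD.

    Ties keep original input order (stable sort), so selection is
    deterministic and reproducible.
    """
    if not 1 <= k <= matrix.n_features:
        raise ValueError(f"k={k} out of range for {matrix.n_features} features")
    vals = matrix.values
    mads = np.median(np.abs(vals - np.median(vals, axis=1, keepdims=True)), axis=1)
    order = np.argsort(-mads, kind="stable")[:k]
    return ExpressionMatrix(matrix.data.iloc[order])


def random_environment_split(
    sample_ids: list[str],
    n_env: int,
    seed: int,
    min_size: int = DEFAULT_MIN_ENV_SIZE,
) -> EnvironmentAssignment:
    """Randomly partition samples into ``n_env`` environments of near-equal
    size (sizes differ by at most one).

    This is the label-free mode: when no subtype labels are available the
    samples are shuffled and dealt into ``n_env`` similar-sized groups.  The
    assignment is a deterministic function of the input order, ``n_env`` and
    ``seed``.
    """
    if n_env < 2:
        raise ValueError("need at least 2 environments")
    n = len(sample_ids)
    if n < n_env * min_size:
        raise ValueError(
            f"{n} samples cannot fill {n_env} environments of at least {min_size}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels: dict[str, str] = {}
    # deal round-robin so sizes differ by at most 1
    for pos, idx in enumerate(perm):
        labels[sample_ids[idx]] = f"env{pos % n_env + 1}"
    labels = {s: labels[s] for s in sample_ids}  # restore input order
    return EnvironmentAssignment(labels, min_size=min_size)


def read_environment_labels(path, min_size: int = DEFAULT_MIN_ENV_SIZE) -> EnvironmentAssignment:
    """Read a two-column ``sample_id,environment`` table (e.g. Pam50 subtype
    calls).  Gzip-compressed files are accepted."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns sample_id,environment")
    labels = {str(s): str(e) for s, e in zip(df.iloc[:, 0], df.iloc[:, 1])}
    if len(labels) != len(df):
        dup = df.iloc[:, 0][df.iloc[:, 0].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    return EnvironmentAssignment(labels, min_size=min_size)


def write_environment_labels(env: EnvironmentAssignment, path) -> None:
    pd.DataFrame(
        {"sample_id": list(env.labels), "environment": list(env.labels.values())}
    ).to_csv(path, index=False)


def match_samples(
    regulators: ExpressionMatrix, targets: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Intersect two matrices on shared sample ids (regulator order kept).

    Samples present in only one matrix are dropped with a logged warning.
    """
    shared = [s for s in regulators.sample_ids if s in set(targets.sample_ids)]
    if not shared:
        raise ValueError("no shared sample ids between the two matrices")
    dropped = (regulators.n_samples - len(shared)) + (targets.n_samples - len(shared))
    if dropped:
        logger.warning("dropped %d unmatched sample column(s) while pairing matrices", dropped)
    return regulators.subset_samples(shared), targets.subset_samples(shared)
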