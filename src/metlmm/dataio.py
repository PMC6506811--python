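"""Dataset container, validation and CSV input/output.

A clinical metabolomics run is represented as a samples x features matrix of
log2 intensities plus a per-sample metadata table carrying the subject
identifier (the random-effect grouping factor), the class label (e.g. tissue
type) and any number of numeric or categorical covariates used as fixed
effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CovariateInfo",
    "MetabolomicsDataset",
    "FixedEffectSpec",
    "load_dataset",
    "build_design",
    "write_processed",
    "read_processed",
]


@dataclass(frozen=True)
class CovariateInfo:
    """Declaration of one covariate column.

    kind is "numeric" or "categorical"; for categorical covariates ``levels``
    fixes the level order (first level is the default treatment-coding
    reference).
    """

    name: str
    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"covariate {self.name!r}: kind must be "
                             f"'numeric' or 'categorical', got {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValueError(f"categorical covariate {self.name!r} needs >=2 levels")


@dataclass
class MetabolomicsDataset:
    """Log2 abundance matrix together with aligned sample metadata.

    Attributes
    ----------
    abundances
        DataFrame [n_samples x n_features], index = sample ids, columns =
        feature ids, log2-scale intensities.
    subject
        Per-sample subject identifier (Series aligned to ``abundances``).
    class_label
        Per-sample categorical outcome (Series aligned to ``abundances``).
    class_levels
        Ordered class levels; the first is the reference level.
    covariates
        DataFrame of per-sample covariate values aligned to ``abundances``.
    covariate_info
        Declarations (numeric/categorical + level order) for each covariate
        column.
    feature_annotations
        Optional per-feature text annotations.
    """

    abundances: pd.DataFrame
    subject: pd.Series
    class_label: pd.Series
    class_levels: tuple[str, ...]
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    covariate_info: dict[str, CovariateInfo] = field(default_factory=dict)
    feature_annotations: pd.Series | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.abundances.columns)

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundances.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.subject.nunique()

    def validate(self) -> None:
        ab = self.abundances
        if ab.index.has_duplicates:
            dups = ab.index[ab.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if ab.columns.has_duplicates:
            dups = ab.columns[ab.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        for name, ser in (("subject", self.subject), ("class_label", self.class_label)):
            if not ser.index.equals(ab.index):
                raise ValueError(f"{name} is not aligned to the abundance rows")
        if not self.covariates.empty and not self.covariates.index.equals(ab.index):
            raise ValueError("covariates are not aligned to the abundance rows")
        if ab.isna().any().any():
            bad = ab.columns[ab.isna().any()].tolist()
            raise ValueError(f"missing values in abundances, features: {bad}")
        unknown = set(self.class_label.unique()) - set(self.class_levels)
        if unknown:
            raise ValueError(f"class labels outside declared levels: {sorted(unknown)}")
        for name, info in self.covariate_info.items():
            if name not in self.covariates.columns:
                raise ValueError(f"declared covariate {name!r} missing from table")
            col = self.covariates[name]
            if info.kind == "numeric" and not pd.api.types.is_numeric_dtype(col):
                raise ValueError(f"covariate {name!r} declared numeric but is not")
            if info.kind == "categorical":
                extra = set(col.astype(str).unique()) - set(info.levels)
                if extra:
                    raise ValueError(
                        f"covariate {name!r} has undeclared levels: {sorted(extra)}")
        # paired-design check: warn, not error (unbalanced cohorts are legal)
        counts = self.subject.value_counts()
        if not (counts == 2).all():
            off = counts[counts != 2]
            warnings.warn(
                f"{len(off)} subject(s) without exactly 2 samples "
                f"(e.g. {off.index[:3].tolist()}); not a strict paired design",
                stacklevel=2)
        else:
            per_subj = self.class_label.groupby(self.subject).nunique()
            if not (per_subj == 2).all():
                warnings.warn("some subjects do not carry two distinct class "
                              "labels; not a strict paired design", stacklevel=2)

    def subset_samples(self, sample_ids: list[str]) -> "MetabolomicsDataset":
        """Row-subset preserving all declarations (no re-validation warnings)."""
        import copy
        new = copy.copy(self)
        new.abundances = self.abundances.loc[sample_ids]
        new.subject = self.subject.loc[sample_ids]
        new.class_label = self.class_label.loc[sample_ids]
        new.covariates = (self.covariates.loc[sample_ids]
                          if not self.covariates.empty else self.covariates)
        return new


@dataclass(frozen=True)
class FixedEffectSpec:
    """Ordered fixed-effect terms for the per-feature model.

    ``terms`` name covariates and/or the class label (referred to by the
    pseudo-name used in the dataset schema, conventionally the metadata column
    name, e.g. "tissue"). Categorical terms expand to L-1 treatment-coded
    indicator columns against ``reference_levels`` (default: first declared
    level). An intercept column is always prepended.
    """

    terms: tuple[str, ...]
    reference_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.terms) == 0:
            raise ValueError("FixedEffectSpec needs at least one term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in FixedEffectSpec")

    def validate_for(self, dataset: MetabolomicsDataset,
                     class_term: str = "class") -> None:
        known = set(dataset.covariates.columns) | {class_term}
        missing = [t for t in self.terms if t not in known]
        if missing:
            raise ValueError(f"terms not present in dataset: {missing}")


def _categorical_columns(values: pd.Series, levels: tuple[str, ...],
                         reference: str, term: str) -> dict[str, np.ndarray]:
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not among levels of {term!r}")
    cols = {}
    vals = values.astype(str).to_numpy()
    for lev in levels:
        if lev == reference:
            continue
        cols[f"{term}[{lev}]"] = (vals == lev).astype(float)
    return cols


def build_design(dataset: MetabolomicsDataset, spec: FixedEffectSpec,
                 class_term: str = "class",
                 drop_aliased: bool = False) -> pd.DataFrame:
    """Expand a fixed-effect spec into a design matrix with intercept.

    Column order is deterministic: intercept first, then terms in spec order,
    categorical levels in declared order. Numeric covariates enter uncentered.
    Raises on a rank-deficient design, naming the aliased columns; with
    ``drop_aliased`` the aliased columns are silently removed instead (the
    behavior of R's mixed-model fitters on data subsets that lose a factor
    level).
    """
    spec.validate_for(dataset, class_term)
    columns: dict[str, np.ndarray] = {
        "(Intercept)": np.ones(dataset.n_samples)}
    for term in spec.terms:
        if term == class_term:
            levels = dataset.class_levels
            ref = spec.reference_levels.get(term, levels[0])
            columns.update(_categorical_columns(
                dataset.class_label, levels, ref, term))
        else:
            info = dataset.covariate_info.get(term)
            if info is None or info.kind == "numeric":
                columns[term] = dataset.covariates[term].to_numpy(dtype=float)
            else:
                ref = spec.reference_levels.get(term, info.levels[0])
                columns.update(_categorical_columns(
                    dataset.covariates[term], info.levels, ref, term))
    X = pd.DataFrame(columns, index=dataset.abundances.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _find_aliased(X.to_numpy(), list(X.columns))
        if not drop_aliased:
            raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
        X = X.drop(columns=aliased)
    return X


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan: columns not adding rank when appended in order."""
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, kept + [j]]
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


# -- CSV I/O ---------------------------------------------------------------

def load_dataset(abundance_path, metadata_path, *,
                 sample_col: str, subject_col: str, class_col: str,
                 numeric_covariates: list[str] | None = None,
                 categorical_covariates: dict[str, list[str]] | None = None,
                 class_levels: list[str] | None = None) -> MetabolomicsDataset:
    """Load and join an abundance CSV and a metadata CSV on the sample id.

    The abundance file has samples in rows and features in columns, first
    column the sample id. Metadata is keyed by the same id. Declared numeric
    covariates are parsed as numbers (a non-numeric value is an error naming
    the row and column); categorical covariates take their level order from
    ``categorical_covariates`` (observed sorted order if given as None).
    """
    numeric_covariates = numeric_covariates or []
    categorical_covariates = categorical_covariates or {}
    ab = pd.read_csv(abundance_path, comment="#", dtype={0: str})
    ab = ab.set_index(ab.columns[0])
    ab.index.name = sample_col
    meta = pd.read_csv(metadata_path, comment="#", dtype=str)
    if sample_col not in meta.columns:
        raise ValueError(f"metadata file lacks sample column {sample_col!r}")
    meta = meta.set_index(sample_col)

    for frame, label in ((ab, "abundance"), (meta, "metadata")):
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in {label} file: {dups}")
    only_ab = ab.index.difference(meta.index).tolist()
    only_meta = meta.index.difference(ab.index).tolist()
    if only_ab or only_meta:
        raise ValueError(
            "unmatched sample ids between files; "
            f"abundance-only: {only_ab}, metadata-only: {only_meta}")
    meta = meta.loc[ab.index]

    for col in (subject_col, class_col):
        if col not in meta.columns:
            raise ValueError(f"metadata file lacks required column {col!r}")

    try:
        ab = ab.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance value: {exc}") from exc

    cov_info: dict[str, CovariateInfo] = {}
    cov_cols: dict[str, pd.Series] = {}
    for name in numeric_covariates:
        parsed = pd.to_numeric(meta[name], errors="coerce")
        bad = parsed.isna() & meta[name].notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-numeric value {meta.loc[row, name]!r} in numeric "
                f"covariate {name!r}, sample {row!r}")
        cov_cols[name] = parsed.astype(float)
        cov_info[name] = CovariateInfo(name, "numeric")
    for name, levels in categorical_covariates.items():
        col = meta[name].astype(str)
        levs = tuple(levels) if levels else tuple(sorted(col.unique()))
        cov_cols[name] = col
        cov_info[name] = CovariateInfo(name, "categorical", levs)

    covs = pd.DataFrame(cov_cols, index=ab.index)
    if not covs.empty and covs.isna().any().any():
        bad_cols = covs.columns[covs.isna().any()].tolist()
        raise ValueError(f"missing values in covariates: {bad_cols}")

    cls = meta[class_col].astype(str)
    levels = tuple(class_levels) if class_levels else tuple(sorted(cls.unique()))
    return MetabolomicsDataset(
        abundances=ab,
        subject=meta[subject_col],
        class_label=cls,
        class_levels=levels,
        covariates=covs,
        covariate_info=cov_info,
    )


def write_processed(path, matrix: pd.DataFrame, *, header_meta: dict | None = None) -> None:
    """Write a samples x features matrix as CSV with a provenance header line."""
    meta = header_meta or {}
    parts = [f"{k}={v}" for k, v in meta.items()]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# metlmm " + " ".join(parts) + "\n")
        matrix.to_csv(fh, float_format="%.15g", lineterminator="\n")


def read_processed(path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_processed`."""
    df = pd.read_csv(path, comment="#", dtype={0: str})
    return df.set_index(df.columns[0]).astype(float)
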