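"""Loading, validation and writing of expression matrices and interaction lists.

All on-disk formats are plain tab-separated text:

* expression: first column = feature id, header row = sample ids, one
  feature per row;
* interactions: header ``regulator<TAB>target``, extra columns ignored.

Edge-shaped outputs keep ``regulator``/``target`` as the first two columns so
they import directly into generic network viewers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("darkmir")

MOLECULE_CLASSES = ("miRNA", "mRNA", "lncRNA")
TARGET_CLASSES = ("mRNA", "lncRNA")


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix for one molecule class.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows are features, columns are samples. Must be numeric, finite and
        free of missing values.
    molecule_class : str
        One of ``miRNA``, ``mRNA``, ``lncRNA``; uniform for the whole matrix.
    cohort_label : str
        Free-text cohort tag, e.g. ``"normal"`` or ``"tumor"``.
    is_log : bool
        Whether the stored values are on the log2(x+1) scale. Fold changes
        are always reported on the linear scale and are back-transformed
        when this flag is set.
    """

    values: pd.DataFrame
    molecule_class: str
    cohort_label: str = ""
    is_log: bool = False

    def __post_init__(self) -> None:
        if self.molecule_class not in MOLECULE_CLASSES:
            raise ValueError(
                f"molecule_class must be one of {MOLECULE_CLASSES}, "
                f"got {self.molecule_class!r}"
            )
        _check_unique(self.values.index, "feature id")
        _check_unique(self.values.columns, "sample id")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TypeError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite expression value at feature "
                f"{self.values.index[bad[0]]!r}, sample "
                f"{self.values.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """Expression vector of one sample (indexed by feature id)."""
        return self.values[sample_id]

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)],
            self.molecule_class,
            self.cohort_label,
            self.is_log,
        )

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature_id")


@dataclass
class InteractionSet:
    """A deduplicated universe of regulator -> target edges.

    ``edges`` is a two-column (``regulator``, ``target``) frame; the pair is
    unique and ``target_class`` (mRNA or lncRNA) is uniform, because
    miRNA-mRNA and miRNA-lncRNA networks are built separately.
    """

    edges: pd.DataFrame
    target_class: str
    source_tag: str = ""

    def __post_init__(self) -> None:
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(
                f"target_class must be one of {TARGET_CLASSES}, "
                f"got {self.target_class!r}"
            )
        self.edges = self.edges[["regulator", "target"]].reset_index(drop=True)
        if self.edges.duplicated().any():
            raise ValueError("InteractionSet contains duplicate edges")

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def edge_tuples(self) -> list[tuple[str, str]]:
        return list(map(tuple, self.edges.to_numpy()))

    @property
    def regulators(self) -> pd.Index:
        return pd.Index(self.edges["regulator"].unique())

    @property
    def targets(self) -> pd.Index:
        return pd.Index(self.edges["target"].unique())

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = sorted(index[index.duplicated()].unique().tolist())
        raise ValueError(f"duplicate {what}(s): {dups}")


def _read_header_ids(path: str | Path) -> list[str]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    return header.split("\t")[1:]


def load_expression(
    path: str | Path,
    molecule_class: str,
    preprocess: str = "log2p1",
    min_expressed_fraction: float = 0.1,
    cohort_label: str = "",
) -> ExpressionMatrix:
    """Load a tab-separated expression matrix.

    Features expressed (value > 0, pre-log) in fewer than
    ``min_expressed_fraction`` of samples are dropped, then ``log2(x+1)``
    is applied when ``preprocess="log2p1"``. Duplicate ids, non-numeric
    cells or missing values are hard errors.
    """
    if preprocess not in ("log2p1", "none"):
        raise ValueError(f"unknown preprocess {preprocess!r}")
    sample_ids = _read_header_ids(path)
    if len(set(sample_ids)) != len(sample_ids):
        seen: set[str] = set()
        dups = sorted({s for s in sample_ids if s in seen or seen.add(s)})
        raise ValueError(f"duplicate sample id(s): {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = sample_ids
    _check_unique(df.index, "feature id")
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ValueError(
                    f"non-numeric value at feature {row!r}, sample {col!r}: "
                    f"{df.loc[row, col]!r}"
                )
            df[col] = coerced
    if df.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    df = df.astype(float)

    expressed = (df > 0).mean(axis=1)
    keep = expressed >= min_expressed_fraction
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "load_expression(%s): dropped %d/%d features below "
            "min_expressed_fraction=%.3g",
            path, n_dropped, len(df), min_expressed_fraction,
        )
    df = df.loc[keep]
    if preprocess == "log2p1":
        if (df.to_numpy() < 0).any():
            raise ValueError("negative values are incompatible with log2(x+1)")
        df = np.log2(df + 1.0)
    return ExpressionMatrix(df, molecule_class, cohort_label,
                            is_log=(preprocess == "log2p1"))


def load_interactions(
    path: str | Path,
    target_class: str,
    case_sensitive: bool = True,
    source_tag: str = "",
) -> InteractionSet:
    """Load a regulator/target edge list, dropping duplicate pairs.

    Rows with a missing regulator or target are skipped (counted in the
    log); an empty file or a file with no usable rows is an error.
    Identifier matching is case-sensitive unless ``case_sensitive=False``,
    in which case ids are lower-cased before deduplication.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"interaction file {path} contains no rows")
    cols = list(df.columns)
    if "regulator" in cols and "target" in cols:
        df = df[["regulator", "target"]]
    else:  # fall back to positional first-two-columns
        df = df.iloc[:, :2]
        df.columns = ["regulator", "target"]
    n_in = len(df)
    df = df.dropna()
    n_skipped = n_in - len(df)
    if n_skipped:
        logger.warning(
            "load_interactions(%s): skipped %d row(s) with a missing "
            "regulator or target", path, n_skipped,
        )
    if df.empty:
        raise ValueError(f"interaction file {path} has no complete rows")
    if not case_sensitive:
        df = df.apply(lambda s: s.str.lower())
    n_before = len(df)
    df = df.drop_duplicates()
    n_removed = n_before - len(df)
    if n_removed:
        logger.info(
            "load_interactions(%s): removed %d redundant association(s)",
            path, n_removed,
        )
    return InteractionSet(df.reset_index(drop=True), target_class,
                          source_tag or str(path))


def align_universe(
    expr_regulators: ExpressionMatrix,
    expr_targets: ExpressionMatrix,
    interactions: InteractionSet,
) -> InteractionSet:
    """Restrict an interaction universe to edges measurable in both matrices.

    Keeps edges whose regulator is a feature of ``expr_regulators`` and
    whose target is a feature of ``expr_targets``; idempotent.
    """
    regs = set(expr_regulators.feature_ids)
    tgts = set(expr_targets.feature_ids)
    mask = interactions.edges["regulator"].isin(regs) & interactions.edges[
        "target"
    ].isin(tgts)
    kept = interactions.edges[mask].reset_index(drop=True)
    logger.info(
        "align_universe: kept %d/%d edges", len(kept), len(interactions)
    )
    if kept.empty:
        raise ValueError(
            "no overlap between interaction list and expression features"
        )
    return InteractionSet(kept, interactions.target_class,
                          interactions.source_tag)


def read_expression_tsv(
    path: str | Path, molecule_class: str, cohort_label: str = "",
    is_log: bool = True,
) -> ExpressionMatrix:
    """Read back a matrix written by :meth:`ExpressionMatrix.to_tsv` verbatim
    (no preprocessing, no filtering)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return ExpressionMatrix(df.astype(float), molecule_class, cohort_label,
                            is_log=is_log)
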