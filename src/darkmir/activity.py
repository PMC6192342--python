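"""miRNA activity scores, differential expression, and dark-matter flagging.

A miRNA's activity over a basic network is the sum of the frequency scores
of its retained edges, weighted by the fraction of its curated interactions
that survived thresholding:

    activity(miRNA) = (sum of its basic-network edge scores) * c1 / c2

where c1 is the miRNA's degree in the basic network and c2 its degree in the
full interaction universe (d1/d2 for the lncRNA-target network). A
"dark-matter" miRNA is one with top-ranked activity that is nevertheless not
differentially expressed between the cancer and normal cohorts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, InteractionSet
from .network import BasicNetwork, EdgeScoreTable

logger = logging.getLogger("darkmir")


def activity_scores(
    basic: BasicNetwork,
    scores: EdgeScoreTable,
    universe: InteractionSet,
) -> pd.DataFrame:
    """Rank miRNAs by activity over one basic network.

    Returns a frame (mirna, c1, c2, score_sum, activity) restricted to
    miRNAs with at least one basic-network edge (c1 >= 1), sorted by
    activity descending with a lexicographic tie-break. A basic-network
    edge absent from the universe indicates bookkeeping corruption and is
    an error.
    """
    uni = set(universe.edge_tuples)
    for e in basic.edge_tuples:
        if e not in uni:
            raise ValueError(
                f"basic-network edge {e} is not in the interaction universe"
            )
    c2 = universe.edges["regulator"].value_counts()
    grp = basic.edges.groupby("regulator")["score"]
    out = pd.DataFrame(
        {"c1": grp.size(), "score_sum": grp.sum()}
    ).reset_index(names="mirna")
    out["c2"] = out["mirna"].map(c2).astype(int)
    out["activity"] = out["score_sum"] * out["c1"] / out["c2"]
    out = out[["mirna", "c1", "c2", "score_sum", "activity"]]
    out = out.sort_values(["activity", "mirna"],
                          ascending=[False, True]).reset_index(drop=True)
    return out


def differential_expression(
    expr_cancer: ExpressionMatrix,
    expr_normal: ExpressionMatrix,
    fc_bounds: tuple[float, float] = (2.0, 0.5),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature fold change and Welch t-test between the two cohorts.

    The fold change is mean(cancer)/mean(normal) on the linear scale
    (back-transformed from log2(x+1) when the matrices are logged); the
    t-test runs on the stored (log-scale) values; p-values are
    Benjamini-Hochberg adjusted across features. A feature is differential
    when (FC >= upper or FC <= lower) and adjusted p < alpha. Features
    present in only one cohort are excluded with a warning count.
    """
    upper, lower = fc_bounds
    if not (lower < upper):
        raise ValueError("fc_bounds must be (upper, lower) with lower < upper")
    shared = expr_cancer.feature_ids.intersection(expr_normal.feature_ids)
    n_only = (
        len(expr_cancer.feature_ids) + len(expr_normal.feature_ids)
        - 2 * len(shared)
    )
    if n_only:
        logger.warning(
            "differential_expression: %d feature(s) present in only one "
            "cohort were excluded", n_only,
        )
    if len(shared) == 0:
        raise ValueError("cohorts share no features")
    shared = pd.Index(sorted(shared))
    c = expr_cancer.values.loc[shared].to_numpy()
    n = expr_normal.values.loc[shared].to_numpy()

    def _linear(a: np.ndarray, logged: bool) -> np.ndarray:
        return np.power(2.0, a) - 1.0 if logged else a

    mean_c = _linear(c, expr_cancer.is_log).mean(axis=1)
    mean_n = _linear(n, expr_normal.is_log).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_c / mean_n
    t, p = stats.ttest_ind(c, n, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    adj = multipletests(p, method="fdr_bh")[1]
    is_diff = ((fc >= upper) | (fc <= lower)) & (adj < alpha)
    return pd.DataFrame(
        {
            "feature": shared,
            "mean_cancer": mean_c,
            "mean_normal": mean_n,
            "fold_change": fc,
            "t_stat": t,
            "p_value": p,
            "adj_p": adj,
            "is_differential": is_diff,
        }
    ).reset_index(drop=True)


@dataclass
class DMReport:
    """Dark-matter call per miRNA plus the BMMN/BMLN coincidence degree.

    ``table`` columns: mirna, rank_mmn, rank_mln, activity_mmn,
    activity_mln, fold_change, is_differential, dm_flag. ``overlap`` is the
    Jaccard overlap proportion between the BMMN-active and BMLN-active
    miRNA sets.
    """

    table: pd.DataFrame
    overlap: float
    top_k: int

    @property
    def dm_mirnas(self) -> list[str]:
        return self.table.loc[self.table["dm_flag"], "mirna"].tolist()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def flag_dm(
    activity_mmn: pd.DataFrame,
    activity_mln: pd.DataFrame,
    de: pd.DataFrame,
    top_k: int = 20,
) -> DMReport:
    """Flag dark-matter miRNAs: top-k activity in either network, yet
    non-differential in expression.

    Activity frames come from :func:`activity_scores`; ``de`` from
    :func:`differential_expression` on the miRNA matrices. miRNAs missing
    from the differential table (e.g. filtered before testing) are treated
    as non-differential.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    rank_mmn = pd.Series(
        np.arange(1, len(activity_mmn) + 1), index=activity_mmn["mirna"]
    )
    rank_mln = pd.Series(
        np.arange(1, len(activity_mln) + 1), index=activity_mln["mirna"]
    )
    act_mmn = activity_mmn.set_index("mirna")["activity"]
    act_mln = activity_mln.set_index("mirna")["activity"]
    mirnas = sorted(set(rank_mmn.index) | set(rank_mln.index))
    de_idx = de.set_index("feature")
    rows = []
    for m in mirnas:
        r1 = rank_mmn.get(m, np.nan)
        r2 = rank_mln.get(m, np.nan)
        is_diff = bool(de_idx["is_differential"].get(m, False))
        fc = float(de_idx["fold_change"].get(m, np.nan))
        top = (r1 <= top_k if np.isfinite(r1) else False) or (
            r2 <= top_k if np.isfinite(r2) else False
        )
        rows.append(
            {
                "mirna": m,
                "rank_mmn": r1,
                "rank_mln": r2,
                "activity_mmn": float(act_mmn.get(m, 0.0)),
                "activity_mln": float(act_mln.get(m, 0.0)),
                "fold_change": fc,
                "is_differential": is_diff,
                "dm_flag": bool(top and not is_diff),
            }
        )
    table = pd.DataFrame(rows)
    set_mmn = set(rank_mmn.index)
    set_mln = set(rank_mln.index)
    union = set_mmn | set_mln
    overlap = len(set_mmn & set_mln) / len(union) if union else 0.0
    return DMReport(table, overlap, top_k)


def cross_condition_matrix(
    score_tables: Mapping[str, EdgeScoreTable],
    top_k: int = 200,
) -> pd.DataFrame:
    """Condition x edge matrix over the union of per-condition top edges.

    Rows are conditions (e.g. cancer types); columns are the union of each
    condition's ``top_k`` highest-scoring edges, labelled
    ``regulator|target`` in lexicographic order; cells hold that
    condition's score for the edge (0 where unscored). Used to contrast
    the edge signatures of different cancers.
    """
    if len(score_tables) < 2:
        raise ValueError("need at least 2 conditions")
    union: set[tuple[str, str]] = set()
    for tab in score_tables.values():
        top = tab.top(top_k)
        union |= set(map(tuple, top[["regulator", "target"]].to_numpy()))
    cols = sorted(union)
    data = {}
    for name, tab in score_tables.items():
        lookup = {
            (r, t): s
            for r, t, s in tab.table[
                ["regulator", "target", "score"]
            ].itertuples(index=False)
        }
        data[name] = [lookup.get(e, 0.0) for e in cols]
    mat = pd.DataFrame.from_dict(
        data, orient="index", columns=[f"{r}|{t}" for r, t in cols]
    )
    return mat.loc[sorted(score_tables)]
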