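"""Single-sample network perturbation statistics.

The procedure: compute a reference co-expression network over the normal
cohort (one Pearson correlation per curated regulator-target edge), then for
each query sample recompute every correlation with that sample appended and
test the per-edge change

    dPCC = PCC_{n+1} - PCC_n,      Z = dPCC * (n - 1) / (1 - PCC_n^2)

against a standard normal. An edge's frequency score over a cancer cohort is
the fraction of samples in which its dPCC is significant; the thresholded
set of high-frequency edges is the "basic" network (BMMN for mRNA targets,
BMLN for lncRNA targets).

The Z denominator is (1 - PCC^2)/(n - 1) with no square root; a
``z_variant="sqrt"`` alternative divides by the square root of that
quantity instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, InteractionSet

logger = logging.getLogger("darkmir")

_PCC_CLAMP = 1.0 - 1e-8


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two vectors.

    Returns NaN (the invalid marker) when either vector has zero variance.
    Vectors must have equal length >= 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("pearson expects two 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError("pearson needs at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float((xc @ yc) / (sx * sy))


def _rowwise_pearson(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Correlation of paired rows of two (edges x samples) arrays."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    sy = np.sqrt(np.einsum("ij,ij->i", Yc, Yc))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("ij,ij->i", Xc, Yc) / denom
    r[denom == 0.0] = np.nan
    return r


@dataclass
class ReferenceNetwork:
    """Per-edge reference correlations over the normal cohort (RMMN/RMLN).

    ``edges`` columns: regulator, target, pcc, valid. Edges whose regulator
    or target has zero variance across the reference samples are flagged
    invalid and excluded from all downstream perturbation statistics.
    """

    edges: pd.DataFrame
    n_ref: int
    target_class: str
    cohort_label: str = ""

    @property
    def valid_edges(self) -> pd.DataFrame:
        return self.edges[self.edges["valid"]].reset_index(drop=True)

    @property
    def n_valid(self) -> int:
        return int(self.edges["valid"].sum())

    def to_tsv(self, path: str | Path) -> None:
        out = self.edges.copy()
        out.insert(2, "n_ref", self.n_ref)
        out.to_csv(path, sep="\t", index=False)


def build_reference_network(
    expr_reg: ExpressionMatrix,
    expr_tgt: ExpressionMatrix,
    interactions: InteractionSet,
    cohort_label: str = "",
) -> ReferenceNetwork:
    """Pearson-correlate every interaction over the shared reference samples.

    Both matrices must carry the identical sample ids in identical order.
    """
    if list(expr_reg.sample_ids) != list(expr_tgt.sample_ids):
        raise ValueError(
            "regulator and target matrices must share the same sample ids "
            "in the same order"
        )
    n_ref = expr_reg.n_samples
    if n_ref < 3:
        raise ValueError("need at least 3 reference samples")
    regs = interactions.edges["regulator"].to_numpy()
    tgts = interactions.edges["target"].to_numpy()
    X = expr_reg.values.loc[regs].to_numpy()
    Y = expr_tgt.values.loc[tgts].to_numpy()
    r = _rowwise_pearson(X, Y)
    valid = np.isfinite(r)
    n_invalid = int((~valid).sum())
    if n_invalid:
        logger.info(
            "build_reference_network: %d/%d zero-variance edge(s) marked "
            "invalid", n_invalid, len(r),
        )
    edges = pd.DataFrame(
        {"regulator": regs, "target": tgts, "pcc": r, "valid": valid}
    )
    return ReferenceNetwork(edges, n_ref, interactions.target_class,
                            cohort_label or expr_reg.cohort_label)


def edge_z_statistic(
    pcc_n: float | np.ndarray,
    delta_pcc: float | np.ndarray,
    n_ref: int,
    variant: str = "plain",
):
    """Significance statistic for a single-sample correlation change.

    plain (default): Z = dPCC * (n_ref - 1) / (1 - PCC^2)
    sqrt:            Z = dPCC * sqrt((n_ref - 1) / (1 - PCC^2))

    |PCC| is clamped to 1 - 1e-8 so perfectly correlated reference edges do
    not divide by zero. The sign of Z equals the sign of dPCC.
    """
    if n_ref < 3:
        raise ValueError("n_ref must be at least 3")
    pcc = np.clip(np.asarray(pcc_n, dtype=float), -_PCC_CLAMP, _PCC_CLAMP)
    delta = np.asarray(delta_pcc, dtype=float)
    if np.any(np.abs(pcc_n) > 1 + 1e-12):
        raise ValueError("|pcc_n| must not exceed 1")
    if variant == "plain":
        z = delta * (n_ref - 1) / (1.0 - pcc**2)
    elif variant == "sqrt":
        z = delta * np.sqrt((n_ref - 1) / (1.0 - pcc**2))
    else:
        raise ValueError(f"unknown z variant {variant!r}")
    if np.isscalar(delta_pcc) or np.ndim(delta_pcc) == 0:
        return float(z)
    return z


@dataclass
class PerturbationProfile:
    """One sample's edge perturbation records (its ISMMN or ISMLN).

    ``records`` columns: regulator, target, pcc_ref, pcc_perturbed,
    delta_pcc, z, p_value, significant — one row per valid reference edge.
    """

    sample_id: str
    records: pd.DataFrame
    alpha: float
    mode: str
    n_ref: int

    @property
    def significant_edges(self) -> pd.DataFrame:
        return self.records[self.records["significant"]]

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def perturb_sample(
    ref: ReferenceNetwork,
    expr_reg: ExpressionMatrix,
    expr_tgt: ExpressionMatrix,
    sample_reg: pd.Series,
    sample_tgt: pd.Series,
    sample_id: str,
    alpha: float = 0.05,
    mode: str = "add",
    bh: bool = False,
    z_variant: str = "plain",
) -> PerturbationProfile:
    """Score every valid reference edge for one query sample.

    mode="add": the sample is appended to the n reference samples and each
    edge correlation is recomputed over n+1 points (the query sample must
    not already be a reference sample).

    mode="leave_one_out": the sample is a member of the reference cohort;
    the reference correlation is recomputed over the other n-1 samples and
    dPCC is (PCC over all n) - (PCC over the other n-1). Used for the
    normal cohort, where re-adding a member would be degenerate.

    Two-sided p-values come from the standard normal; ``bh=True``
    additionally applies a Benjamini-Hochberg adjustment within the profile
    before flagging significance.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    valid = ref.valid_edges
    regs = valid["regulator"].to_numpy()
    tgts = valid["target"].to_numpy()
    X = expr_reg.values.loc[regs].to_numpy()
    Y = expr_tgt.values.loc[tgts].to_numpy()
    n = X.shape[1]
    if n != ref.n_ref:
        raise ValueError("expression matrices do not match the reference")

    if mode == "add":
        if sample_id in expr_reg.sample_ids:
            raise ValueError(
                f"sample {sample_id!r} is already a reference sample; "
                "use mode='leave_one_out'"
            )
        xs = sample_reg.loc[regs].to_numpy(dtype=float)
        ys = sample_tgt.loc[tgts].to_numpy(dtype=float)
        if xs.shape[0] != X.shape[0] or ys.shape[0] != Y.shape[0]:
            raise ValueError("sample vectors inconsistent with matrices")
        Xp = np.column_stack([X, xs])
        Yp = np.column_stack([Y, ys])
        pcc_ref = valid["pcc"].to_numpy()
        pcc_pert = _rowwise_pearson(Xp, Yp)
        n_eff = n
    elif mode == "leave_one_out":
        if sample_id not in expr_reg.sample_ids:
            raise ValueError(
                f"sample {sample_id!r} is not a reference sample; "
                "use mode='add'"
            )
        pos = list(expr_reg.sample_ids).index(sample_id)
        keep = np.arange(n) != pos
        if keep.sum() < 3:
            raise ValueError("leave-one-out needs at least 4 reference samples")
        pcc_ref = _rowwise_pearson(X[:, keep], Y[:, keep])
        pcc_pert = valid["pcc"].to_numpy()  # correlation over all n
        n_eff = n - 1
    else:
        raise ValueError(f"unknown mode {mode!r}")

    delta = pcc_pert - pcc_ref
    with np.errstate(invalid="ignore"):
        z = edge_z_statistic(np.nan_to_num(pcc_ref), np.nan_to_num(delta),
                             n_eff, variant=z_variant)
        z = np.where(np.isfinite(pcc_ref) & np.isfinite(pcc_pert), z, np.nan)
        p = 2.0 * stats.norm.sf(np.abs(z))
    finite = np.isfinite(p)
    if bh and finite.any():
        p_adj = np.full_like(p, np.nan)
        p_adj[finite] = multipletests(p[finite], method="fdr_bh")[1]
        sig = np.where(finite, p_adj < alpha, False)
    else:
        sig = np.where(finite, p < alpha, False)
    records = pd.DataFrame(
        {
            "regulator": regs,
            "target": tgts,
            "pcc_ref": pcc_ref,
            "pcc_perturbed": pcc_pert,
            "delta_pcc": delta,
            "z": z,
            "p_value": p,
            "significant": sig.astype(bool),
        }
    )
    return PerturbationProfile(sample_id, records, alpha, mode, n_eff)


def perturb_cohort(
    ref: ReferenceNetwork,
    expr_reg: ExpressionMatrix,
    expr_tgt: ExpressionMatrix,
    cohort_reg: ExpressionMatrix,
    cohort_tgt: ExpressionMatrix,
    alpha: float = 0.05,
    mode: str = "add",
    bh: bool = False,
    z_variant: str = "plain",
) -> list[PerturbationProfile]:
    """Profile every sample of a cohort against the reference network."""
    if list(cohort_reg.sample_ids) != list(cohort_tgt.sample_ids):
        raise ValueError("cohort matrices must share sample ids and order")
    profiles = []
    for sid in cohort_reg.sample_ids:
        profiles.append(
            perturb_sample(
                ref, expr_reg, expr_tgt,
                cohort_reg.sample(sid), cohort_tgt.sample(sid),
                sid, alpha=alpha, mode=mode, bh=bh, z_variant=z_variant,
            )
        )
    return profiles


@dataclass
class EdgeScoreTable:
    """Per-edge significance frequency over a cancer cohort.

    ``table`` columns: regulator, target, sig_count, n_samples, score with
    score = sig_count / n_samples, sorted by score descending (ties broken
    lexicographically on regulator then target). Scores are stored at full
    precision; round to 3 decimals only for display.
    """

    table: pd.DataFrame
    alpha: float
    target_class: str

    def __len__(self) -> int:
        return len(self.table)

    def top(self, k: int) -> pd.DataFrame:
        return self.table.head(k)

    def score_of(self, regulator: str, target: str) -> float:
        m = (self.table["regulator"] == regulator) & (
            self.table["target"] == target
        )
        if not m.any():
            raise KeyError((regulator, target))
        return float(self.table.loc[m, "score"].iloc[0])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, alpha: float = 0.05,
                 target_class: str = "mRNA") -> "EdgeScoreTable":
        return cls(pd.read_csv(path, sep="\t"), alpha, target_class)


def compute_edge_scores(
    profiles: Sequence[PerturbationProfile],
    target_class: str | None = None,
) -> EdgeScoreTable:
    """Count, per edge, the cohort samples in which its change is significant.

    All profiles must share one edge universe and one alpha. The score is
    the significant-sample fraction (e.g. 630 of 755 samples -> 0.834), the
    per-edge "cancer score" that the basic network thresholds.
    """
    if len(profiles) == 0:
        raise ValueError("compute_edge_scores needs at least one profile")
    first = profiles[0]
    key = first.records[["regulator", "target"]]
    alphas = {p.alpha for p in profiles}
    if len(alphas) != 1:
        raise ValueError("profiles mix different alpha levels")
    counts = np.zeros(len(key), dtype=int)
    for p in profiles:
        if len(p.records) != len(key) or not (
            p.records["regulator"].to_numpy() == key["regulator"].to_numpy()
        ).all() or not (
            p.records["target"].to_numpy() == key["target"].to_numpy()
        ).all():
            raise ValueError("profiles do not share one edge universe")
        counts += p.records["significant"].to_numpy(dtype=int)
    n_samples = len(profiles)
    table = pd.DataFrame(
        {
            "regulator": key["regulator"],
            "target": key["target"],
            "sig_count": counts,
            "n_samples": n_samples,
            "score": counts / n_samples,
        }
    )
    table = table.sort_values(
        ["score", "regulator", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return EdgeScoreTable(table, first.alpha, target_class
                          or "mRNA")


@dataclass
class BasicNetwork:
    """Edges whose frequency score clears the threshold (BMMN or BMLN)."""

    edges: pd.DataFrame
    threshold: float
    target_class: str

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def node_counts(self) -> dict[str, int]:
        return {
            "miRNA": int(self.edges["regulator"].nunique()),
            self.target_class: int(self.edges["target"].nunique()),
        }

    @property
    def edge_tuples(self) -> list[tuple[str, str]]:
        return list(map(tuple, self.edges[["regulator", "target"]].to_numpy()))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for _, row in self.edges.iterrows():
            g.add_node(row["regulator"], kind="miRNA")
            g.add_node(row["target"], kind=self.target_class)
            g.add_edge(row["regulator"], row["target"], score=row["score"])
        return g

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def build_basic_network(
    scores: EdgeScoreTable,
    threshold: float = 0.4,
    target_class: str | None = None,
) -> BasicNetwork:
    """Threshold the score table: keep edges with score >= threshold."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    kept = scores.table[scores.table["score"] >= threshold].reset_index(
        drop=True
    )
    if kept.empty:
        warnings.warn(
            f"no edge reaches score threshold {threshold}; "
            "basic network is empty",
            UserWarning,
            stacklevel=2,
        )
    net = BasicNetwork(kept, threshold, target_class or scores.target_class)
    logger.info(
        "build_basic_network: %d edge(s) at threshold %.3g; nodes %s",
        len(net), threshold, net.node_counts,
    )
    return net
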