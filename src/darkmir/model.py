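"""Model/Results interface over the perturbation pipeline.

:class:`SampleNetworkModel` bundles the data of one target class — normal
and cancer expression for the miRNA regulators and their targets plus the
curated interaction universe — and ``fit()`` runs the whole chain (reference
network, per-sample perturbation profiles, edge frequency scores, basic
network), returning a :class:`SampleNetworkResults` that carries the
estimates and diagnostics and knows how to summarise and extend itself
(activity scores, dark-matter reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import activity as _activity
from .io import ExpressionMatrix, InteractionSet, align_universe
from .network import (
    BasicNetwork,
    EdgeScoreTable,
    PerturbationProfile,
    ReferenceNetwork,
    build_basic_network,
    build_reference_network,
    compute_edge_scores,
    perturb_cohort,
)


class SampleNetworkModel:
    """Single-sample network perturbation model for one target class.

    Parameters
    ----------
    expr_reg_normal, expr_tgt_normal : ExpressionMatrix
        The reference (normal) cohort: miRNA regulators and their targets,
        sharing the same sample ids in the same order.
    expr_reg_cancer, expr_tgt_cancer : ExpressionMatrix
        The query (cancer) cohort, same layout.
    interactions : InteractionSet
        The curated regulator-target universe; restricted on construction
        to edges measurable in both expression matrices.
    """

    def __init__(
        self,
        expr_reg_normal: ExpressionMatrix,
        expr_tgt_normal: ExpressionMatrix,
        expr_reg_cancer: ExpressionMatrix,
        expr_tgt_cancer: ExpressionMatrix,
        interactions: InteractionSet,
        align: bool = True,
    ) -> None:
        if align:
            interactions = align_universe(
                expr_reg_normal, expr_tgt_normal, interactions
            )
            interactions = align_universe(
                expr_reg_cancer, expr_tgt_cancer, interactions
            )
        self.expr_reg_normal = expr_reg_normal
        self.expr_tgt_normal = expr_tgt_normal
        self.expr_reg_cancer = expr_reg_cancer
        self.expr_tgt_cancer = expr_tgt_cancer
        self.interactions = interactions

    @classmethod
    def from_simulation(cls, sim, target_class: str = "mRNA",
                        align: bool = True) -> "SampleNetworkModel":
        """Build a model directly from :func:`darkmir.simulate.simulate`
        output for one target class."""
        return cls(
            sim.expr_mirna_normal,
            sim.expr_target_normal[target_class],
            sim.expr_mirna_cancer,
            sim.expr_target_cancer[target_class],
            sim.interactions[target_class],
            align=align,
        )

    def fit(
        self,
        alpha: float = 0.05,
        threshold: float = 0.4,
        normal_mode: str = "leave_one_out",
        profile_normals: bool = True,
        bh: bool = False,
        z_variant: str = "plain",
    ) -> "SampleNetworkResults":
        """Run the full perturbation chain.

        Cancer samples are profiled in ``add`` mode against the normal
        reference; normal samples (when ``profile_normals``) in
        ``normal_mode`` (leave-one-out by default, since re-adding a
        reference member is degenerate). ``threshold`` is the frequency
        score cut for the basic network.
        """
        ref = build_reference_network(
            self.expr_reg_normal, self.expr_tgt_normal, self.interactions
        )
        cancer_profiles = perturb_cohort(
            ref, self.expr_reg_normal, self.expr_tgt_normal,
            self.expr_reg_cancer, self.expr_tgt_cancer,
            alpha=alpha, mode="add", bh=bh, z_variant=z_variant,
        )
        normal_profiles: list[PerturbationProfile] = []
        if profile_normals:
            normal_profiles = perturb_cohort(
                ref, self.expr_reg_normal, self.expr_tgt_normal,
                self.expr_reg_normal, self.expr_tgt_normal,
                alpha=alpha, mode=normal_mode, bh=bh, z_variant=z_variant,
            )
        scores = compute_edge_scores(
            cancer_profiles, target_class=self.interactions.target_class
        )
        basic = build_basic_network(scores, threshold)
        return SampleNetworkResults(
            model=self,
            reference=ref,
            cancer_profiles=cancer_profiles,
            normal_profiles=normal_profiles,
            edge_scores=scores,
            basic_network=basic,
            alpha=alpha,
            threshold=threshold,
        )


@dataclass
class SampleNetworkResults:
    """Fitted perturbation pipeline for one target class."""

    model: SampleNetworkModel
    reference: ReferenceNetwork
    cancer_profiles: list[PerturbationProfile]
    normal_profiles: list[PerturbationProfile]
    edge_scores: EdgeScoreTable
    basic_network: BasicNetwork
    alpha: float
    threshold: float

    @property
    def target_class(self) -> str:
        return self.model.interactions.target_class

    def activity(self) -> pd.DataFrame:
        """miRNA activity ranking over this basic network."""
        return _activity.activity_scores(
            self.basic_network, self.edge_scores, self.model.interactions
        )

    def top_edges(self, k: int = 10) -> pd.DataFrame:
        return self.edge_scores.top(k)

    def summary(self) -> str:
        """statsmodels-style text summary of the fit."""
        ref = self.reference
        nc = self.basic_network.node_counts
        top = self.edge_scores.top(5)
        lines = [
            "Sample-specific network perturbation results",
            "=" * 52,
            f"target class:           {self.target_class}",
            f"reference samples:      {ref.n_ref}",
            f"cancer samples:         {len(self.cancer_profiles)}",
            f"interaction universe:   {len(self.model.interactions)} edges",
            f"valid reference edges:  {ref.n_valid}",
            f"alpha (per edge):       {self.alpha}",
            f"score threshold:        {self.threshold}",
            f"basic network edges:    {len(self.basic_network)}",
            "basic network nodes:    "
            + ", ".join(f"{v} {k}" for k, v in nc.items()),
            "-" * 52,
            "top edges by frequency score:",
        ]
        for _, r in top.iterrows():
            lines.append(
                f"  {r['regulator']} -> {r['target']}: "
                f"{r['score']:.3f} ({int(r['sig_count'])}/{int(r['n_samples'])})"
            )
        return "\n".join(lines)


def dark_matter_report(
    results_mmn: SampleNetworkResults,
    results_mln: SampleNetworkResults,
    expr_mirna_cancer: ExpressionMatrix,
    expr_mirna_normal: ExpressionMatrix,
    top_k: int = 20,
    fc_bounds: tuple[float, float] = (2.0, 0.5),
    de_alpha: float = 0.05,
) -> _activity.DMReport:
    """Combine the two fitted networks with miRNA differential expression
    into a dark-matter report: miRNAs with top-k activity in either basic
    network that are not differentially expressed."""
    de = _activity.differential_expression(
        expr_mirna_cancer, expr_mirna_normal, fc_bounds=fc_bounds,
        alpha=de_alpha,
    )
    return _activity.flag_dm(
        results_mmn.activity(), results_mln.activity(), de, top_k=top_k
    )
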