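"""Synthetic expression cohorts with planted network perturbations.

The generator emulates the structure of a tumor/normal study: a normal
cohort in which each curated miRNA-target edge has a fixed Pearson
correlation, and a cancer cohort in which a planted subset of "driver"
edges loses (or inverts) that correlation in a configurable fraction of
samples while every mean stays put. A disjoint set of miRNAs instead gets a
mean shift with no correlation change. The first group are the true
dark-matter miRNAs a perturbation analysis should find; the second are what
ordinary differential expression finds.

Generation is a Gaussian copula: each target is a linear mix of its
regulator's latent Gaussian and independent noise, so the configured
correlation is the exact population dependence parameter. Values are mapped
affinely onto a log2-expression-like scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, InteractionSet
from .network import edge_z_statistic


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic cohort generator.

    Defaults mirror a shrunken tumor study: 50 miRNAs each regulating 8
    mRNAs and 8 lncRNAs, 40 normal and 200 cancer samples, 20 driver edges
    per target class perturbed in 60% of cancer samples, 5 dark-matter
    regulators and 5 mean-shifted (log2 FC = 2) miRNAs. Background edges
    draw their correlation uniformly from ``base_pcc_range`` (repressive by
    default); driver edges use the strong ``driver_pcc`` so that a
    regulatory inversion is visible in a single sample.
    """

    n_mirna: int = 50
    n_targets: int = 400          # per target class (mRNA and lncRNA)
    n_edges_per_mirna: int = 8
    n_normal: int = 40
    n_cancer: int = 200
    base_pcc_range: tuple[float, float] = (-0.8, -0.3)
    driver_pcc: float = -0.95
    n_driver_edges: int = 20      # per target class
    perturb_fraction: float = 0.6
    perturb_mode: str = "flip_sign"
    n_dm_mirna: int = 5
    n_diff_mirna: int = 5
    diff_log2fc: float = 2.0
    mirna_mean: float = 6.0
    target_mean: float = 8.0
    expr_sd: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.base_pcc_range
        if not (-1 < lo <= hi < 1):
            raise ValueError("base_pcc_range must lie inside (-1, 1)")
        if not (-1 < self.driver_pcc < 1):
            raise ValueError("driver_pcc must lie inside (-1, 1)")
        if not (0 <= self.perturb_fraction <= 1):
            raise ValueError("perturb_fraction must be in [0, 1]")
        if self.perturb_mode not in ("decorrelate", "flip_sign"):
            raise ValueError(f"unknown perturb_mode {self.perturb_mode!r}")
        if min(self.n_mirna, self.n_targets, self.n_cancer) < 1:
            raise ValueError("counts must be positive")
        if self.n_normal < 3:
            raise ValueError("need at least 3 normal samples")
        if self.n_mirna * self.n_edges_per_mirna > self.n_targets:
            raise ValueError(
                "edges demand more targets than exist: "
                f"{self.n_mirna} x {self.n_edges_per_mirna} > {self.n_targets}"
            )
        if self.n_dm_mirna + self.n_diff_mirna > self.n_mirna:
            raise ValueError("dark-matter and differential sets exceed miRNAs")
        if self.n_dm_mirna > 0 and (
            self.n_driver_edges > self.n_dm_mirna * self.n_edges_per_mirna
        ):
            raise ValueError("more driver edges than dark-matter edges exist")
        if self.n_driver_edges > 0 and self.n_dm_mirna == 0:
            raise ValueError("driver edges require at least one dark-matter miRNA")


@dataclass
class GroundTruth:
    """What was planted: driver edges, their per-sample perturbation masks,
    dark-matter regulators and mean-shifted miRNAs."""

    driver_edges: Mapping[str, list[tuple[str, str]]]  # per target class
    dm_mirnas: set[str]
    diff_mirnas: set[str]
    perturbation_mask: Mapping[str, pd.DataFrame]  # edges x cancer samples

    def check_invariants(self) -> None:
        assert not (self.dm_mirnas & self.diff_mirnas)
        for tclass, edges in self.driver_edges.items():
            for reg, _ in edges:
                assert reg in self.dm_mirnas
            mask = self.perturbation_mask[tclass]
            assert list(mask.index) == [f"{r}|{t}" for r, t in edges]

    def background_edges(self, interactions: InteractionSet) -> list[tuple[str, str]]:
        """Edges whose regulator carries no planted signal of either kind.

        A mean-shifted miRNA perturbs the apparent correlation of all its
        edges once its sample is appended to an unshifted reference — that
        is genuine signal, not background — so background is defined as
        edges of regulators outside both planted sets.
        """
        planted = self.dm_mirnas | self.diff_mirnas
        return [e for e in interactions.edge_tuples if e[0] not in planted]


@dataclass
class SimulatedCohorts:
    """Everything :func:`simulate` emits, ready for the pipeline."""

    expr_mirna_normal: ExpressionMatrix
    expr_mirna_cancer: ExpressionMatrix
    expr_target_normal: Mapping[str, ExpressionMatrix]
    expr_target_cancer: Mapping[str, ExpressionMatrix]
    interactions: Mapping[str, InteractionSet]
    truth: GroundTruth
    config: SimulationConfig


def _feature_names(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}-{i + 1:0{width}d}" for i in range(n)]


def simulate(config: SimulationConfig) -> SimulatedCohorts:
    """Generate normal and cancer cohorts for both target classes.

    Each target is tied to exactly one regulator. For a driver edge, the
    masked fraction of cancer samples redraws the target either independent
    of the regulator (``decorrelate``) or with the correlation sign
    inverted (``flip_sign``); means never move. Mean-shifted miRNAs get
    ``diff_log2fc`` added in every cancer sample. Deterministic under
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    c = config

    mirnas = _feature_names("miR", c.n_mirna)
    dm = set(mirnas[: c.n_dm_mirna])
    diff = set(mirnas[c.n_dm_mirna: c.n_dm_mirna + c.n_diff_mirna])
    normal_ids = [f"N{i + 1:03d}" for i in range(c.n_normal)]
    cancer_ids = [f"T{i + 1:03d}" for i in range(c.n_cancer)]

    # latent regulator signals, shared by both target classes
    z_normal = rng.standard_normal((c.n_mirna, c.n_normal))
    z_cancer = rng.standard_normal((c.n_mirna, c.n_cancer))

    mir_normal = c.mirna_mean + c.expr_sd * z_normal
    mir_cancer = c.mirna_mean + c.expr_sd * z_cancer
    shift_rows = [i for i, m in enumerate(mirnas) if m in diff]
    mir_cancer[shift_rows, :] += c.diff_log2fc
    if c.noise_sd > 0:
        mir_normal = mir_normal + rng.normal(0, c.noise_sd, mir_normal.shape)
        mir_cancer = mir_cancer + rng.normal(0, c.noise_sd, mir_cancer.shape)

    expr_mirna_normal = ExpressionMatrix(
        pd.DataFrame(mir_normal, index=mirnas, columns=normal_ids),
        "miRNA", "normal", is_log=True,
    )
    expr_mirna_cancer = ExpressionMatrix(
        pd.DataFrame(mir_cancer, index=mirnas, columns=cancer_ids),
        "miRNA", "tumor", is_log=True,
    )

    target_prefix = {"mRNA": "gene", "lncRNA": "lnc"}
    expr_tn: dict[str, ExpressionMatrix] = {}
    expr_tc: dict[str, ExpressionMatrix] = {}
    interactions: dict[str, InteractionSet] = {}
    driver_edges: dict[str, list[tuple[str, str]]] = {}
    masks: dict[str, pd.DataFrame] = {}

    for tclass in ("mRNA", "lncRNA"):
        names = _feature_names(target_prefix[tclass], c.n_targets)
        # round-robin edge wiring: target j regulated by miRNA j // k
        reg_of = np.repeat(np.arange(c.n_mirna), c.n_edges_per_mirna)
        n_wired = len(reg_of)
        edges = pd.DataFrame(
            {
                "regulator": [mirnas[i] for i in reg_of],
                "target": names[:n_wired],
            }
        )
        interactions[tclass] = InteractionSet(edges, tclass, "synthetic")

        rho = rng.uniform(*c.base_pcc_range, size=n_wired)
        # drivers: spread evenly over the dark-matter regulators' edges
        drivers: list[int] = []
        if c.n_driver_edges:
            per = int(np.ceil(c.n_driver_edges / c.n_dm_mirna))
            for i in range(c.n_dm_mirna):
                base = i * c.n_edges_per_mirna
                drivers.extend(range(base, base + min(per, c.n_edges_per_mirna)))
            drivers = drivers[: c.n_driver_edges]
            rho[drivers] = c.driver_pcc
        driver_edges[tclass] = [
            (edges["regulator"].iat[j], edges["target"].iat[j])
            for j in drivers
        ]

        def _draw(z: np.ndarray, rho_eff: np.ndarray) -> np.ndarray:
            eps = rng.standard_normal(z.shape)
            lat = rho_eff[:, None] * z + np.sqrt(1 - rho_eff[:, None] ** 2) * eps
            return c.target_mean + c.expr_sd * lat

        tn = np.empty((c.n_targets, c.n_normal))
        tc = np.empty((c.n_targets, c.n_cancer))
        tn[:n_wired] = _draw(z_normal[reg_of], rho)
        tc[:n_wired] = _draw(z_cancer[reg_of], rho)
        # unwired targets: independent background
        tn[n_wired:] = c.target_mean + c.expr_sd * rng.standard_normal(
            (c.n_targets - n_wired, c.n_normal)
        )
        tc[n_wired:] = c.target_mean + c.expr_sd * rng.standard_normal(
            (c.n_targets - n_wired, c.n_cancer)
        )

        mask = rng.random((len(drivers), c.n_cancer)) < c.perturb_fraction
        rho_pert = (
            np.zeros(len(drivers))
            if c.perturb_mode == "decorrelate"
            else -rho[drivers]
        )
        if len(drivers):
            redraws = _draw(z_cancer[reg_of[drivers]], rho_pert)
            for i, row in enumerate(drivers):
                tc[row, mask[i]] = redraws[i, mask[i]]
        if c.noise_sd > 0:
            tn = tn + rng.normal(0, c.noise_sd, tn.shape)
            tc = tc + rng.normal(0, c.noise_sd, tc.shape)

        expr_tn[tclass] = ExpressionMatrix(
            pd.DataFrame(tn, index=names, columns=normal_ids),
            tclass, "normal", is_log=True,
        )
        expr_tc[tclass] = ExpressionMatrix(
            pd.DataFrame(tc, index=names, columns=cancer_ids),
            tclass, "tumor", is_log=True,
        )
        masks[tclass] = pd.DataFrame(
            mask,
            index=[f"{r}|{t}" for r, t in driver_edges[tclass]],
            columns=cancer_ids,
        )

    truth = GroundTruth(driver_edges, dm, diff, masks)
    truth.check_invariants()
    return SimulatedCohorts(
        expr_mirna_normal, expr_mirna_cancer, expr_tn, expr_tc,
        interactions, truth, dataclasses.replace(c),
    )


def expected_edge_score(
    config: SimulationConfig,
    reps: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo prediction of a driver edge's frequency score.

    Estimates, by simulating the raw statistic rather than running the
    pipeline, two per-sample probabilities under the config: the detection
    probability (power) when the appended cancer sample carries the planted
    perturbation, and the false-flag probability when it does not. The
    expected frequency score of a driver edge is then

        f * power + (1 - f) * false_flag_rate

    since only an f-fraction of cancer samples carry the perturbation while
    the rest are still tested. With ``f=0`` the prediction is 0 by
    convention (the edge is then not a driver at all).
    """
    config.validate()
    if config.perturb_fraction == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    n = config.n_normal
    rho = config.driver_pcc
    rho_p = 0.0 if config.perturb_mode == "decorrelate" else -rho

    def _corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        return np.einsum("ij,ij->i", ac, bc) / np.sqrt(
            np.einsum("ij,ij->i", ac, ac) * np.einsum("ij,ij->i", bc, bc)
        )

    def _flag_rate(rho_added: float) -> float:
        z_lat = rng.standard_normal((reps, n + 1))
        eps = rng.standard_normal((reps, n + 1))
        y = rho * z_lat + np.sqrt(1 - rho**2) * eps
        y[:, n] = rho_added * z_lat[:, n] + np.sqrt(1 - rho_added**2) * eps[:, n]
        r_ref = _corr(z_lat[:, :n], y[:, :n])
        r_all = _corr(z_lat, y)
        zstat = edge_z_statistic(r_ref, r_all - r_ref, n)
        p = 2 * stats.norm.sf(np.abs(zstat))
        return float((p < alpha).mean())

    power = _flag_rate(rho_p)
    false_flag = _flag_rate(rho)
    f = config.perturb_fraction
    return f * power + (1 - f) * false_flag
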