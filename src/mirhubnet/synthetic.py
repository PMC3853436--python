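"""Synthetic dual miRNA/mRNA profiling generator with planted ground truth.

The generator emulates a two-subtype tumour profiling study: two sample
classes of unequal size, a miRNA panel in which a few regulator ("hub")
miRNAs each drive a small correlated module, class-dependent mean shifts on
a fraction of miRNAs, target mRNAs linearly coupled (repression by default,
negative coupling) to their regulating miRNAs plus noise, and exponential
survival times with an optional class-dependent hazard.

Modules use a latent-factor construction: the hub itself carries the latent
factor (unit loading) and each of its ``module_size`` partner miRNAs loads
``rho`` on the hub's profile, with independent noise scaled so every
marginal variance is 1. Consequently corr(hub, member) = rho and
corr(member, member') = rho**2 — the members' association is *indirect*,
exactly the situation data-processing-inequality pruning is designed to
resolve into a hub-centred star.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np

from .exceptions import ParameterError
from .io import (
    ExpressionMatrix,
    SurvivalTable,
    TargetMap,
    write_expression,
    write_labels,
    write_survival,
    write_target_map,
)

__all__ = ["SyntheticConfig", "SyntheticTruth", "DualDataset", "generate_dual_dataset", "write_dataset"]


@dataclass
class SyntheticConfig:
    """Study-design knobs for the generator; defaults are the study regime.

    Class sizes default to the 15 basal-like / 41 luminal-A split of the
    motivating breast-cancer cohort. ``module_size`` counts correlated
    partners per hub, excluding the hub itself.
    """

    n_class_a: int = 15
    n_class_b: int = 41
    n_mirna: int = 200
    n_hubs: int = 10
    module_size: int = 5
    rho: float = 0.9
    de_fraction: float = 0.25
    effect_size: float = 1.0
    targets_per_mirna: int = 10
    n_genes: int = 2000
    coupling: float = -0.8
    noise_sd: float = 0.5
    baseline_hazard: float = 0.1
    hazard_ratio: float = 1.0
    de_on_hubs: bool = False
    hub_effect_boost: float = 1.0
    class_names: tuple[str, str] = ("basal_like", "luminal_A")
    seed: int = 0

    def validate(self) -> None:
        positive = [
            "n_class_a", "n_class_b", "n_mirna", "n_hubs", "module_size",
            "targets_per_mirna", "n_genes",
        ]
        for name in positive:
            if int(getattr(self, name)) <= 0:
                raise ParameterError(f"{name} must be a positive count")
        if not 0.0 <= self.rho < 1.0:
            raise ParameterError("rho must lie in [0, 1)")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ParameterError("de_fraction must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline_hazard must be > 0")
        if self.hazard_ratio <= 0:
            raise ParameterError("hazard_ratio must be > 0")
        if self.n_hubs * (self.module_size + 1) > self.n_mirna:
            raise ParameterError(
                "n_hubs * (module_size + 1) exceeds n_mirna: modules cannot be disjoint"
            )
        if self.targets_per_mirna > self.n_genes:
            raise ParameterError("targets_per_mirna exceeds n_genes")
        if len(set(self.class_names)) != 2:
            raise ParameterError("class_names must be two distinct names")


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    hub_ids: list[str]
    module_members: dict[str, list[str]]
    de_ids: dict[str, str]  # miRNA -> class name with the higher mean
    coupling_map: dict[str, dict[str, float]]  # miRNA -> {gene: coefficient}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


class DualDataset(NamedTuple):
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    targets: TargetMap
    survival: SurvivalTable
    truth: SyntheticTruth


def _mirna_id(i: int) -> str:
    return f"miR-{i + 1:04d}"


def _gene_id(i: int) -> str:
    return f"GENE{i + 1:05d}"


def generate_dual_dataset(config: SyntheticConfig) -> DualDataset:
    """Draw one dual-profiling dataset; bit-identical for equal config+seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_class_a + config.n_class_b
    m = config.n_mirna

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    class_a, class_b = config.class_names
    labels = {s: (class_a if i < config.n_class_a else class_b) for i, s in enumerate(sample_ids)}
    is_b = np.array([labels[s] == class_b for s in sample_ids])

    mirna_ids = [_mirna_id(i) for i in range(m)]

    # --- miRNA matrix: hub-carried latent factors, unit marginal variance
    X = rng.standard_normal((m, n))
    chosen = rng.choice(m, size=config.n_hubs * (config.module_size + 1), replace=False)
    hub_idx = chosen[: config.n_hubs]
    member_idx = chosen[config.n_hubs :].reshape(config.n_hubs, config.module_size)
    for h, members in zip(hub_idx, member_idx):
        X[members] = config.rho * X[h] + np.sqrt(1.0 - config.rho**2) * X[members]

    # --- class-dependent mean shifts; optionally concentrated on hub modules
    n_de = int(round(config.de_fraction * m))
    if n_de == 0:
        de_idx = np.array([], dtype=int)
    elif config.de_on_hubs:
        rest = np.setdiff1d(np.arange(m), chosen)
        order = np.concatenate([hub_idx, member_idx.ravel(), rng.permutation(rest)])
        de_idx = order[:n_de]
    else:
        de_idx = rng.choice(m, size=n_de, replace=False)
    up_in_b = rng.integers(0, 2, size=n_de).astype(bool)
    if config.de_on_hubs:
        # co-regulated modules trend together: a shifted member inherits its
        # hub's direction whenever the hub is shifted too
        hub_of = {m: h for h, members in zip(hub_idx, member_idx) for m in members}
        dir_of = {int(i): bool(b) for i, b in zip(de_idx, up_in_b)}
        up_in_b = np.array(
            [
                dir_of[int(hub_of[int(i)])]
                if int(i) in hub_of and int(hub_of[int(i)]) in dir_of
                else bool(b)
                for i, b in zip(de_idx, up_in_b)
            ]
        )
    hub_set = set(hub_idx.tolist())
    de_ids: dict[str, str] = {}
    for i, b_up in zip(de_idx, up_in_b):
        # regulator (hub) miRNAs may carry a larger subtype shift than the
        # run-of-the-mill differential features (hub_effect_boost >= 1)
        eff = config.effect_size * (config.hub_effect_boost if i in hub_set else 1.0)
        shift = np.where(is_b, eff, 0.0) if b_up else np.where(is_b, 0.0, eff)
        X[i] += shift
        de_ids[mirna_ids[i]] = class_b if b_up else class_a

    # --- targets and coupled mRNA matrix (coupling additive on shared genes)
    gene_ids = [_gene_id(i) for i in range(config.n_genes)]
    target_sets: dict[str, frozenset[str]] = {}
    coupling_map: dict[str, dict[str, float]] = {}
    C = np.zeros((config.n_genes, m))
    for i, mid in enumerate(mirna_ids):
        tgt = rng.choice(config.n_genes, size=config.targets_per_mirna, replace=False)
        target_sets[mid] = frozenset(gene_ids[g] for g in tgt)
        coupling_map[mid] = {gene_ids[g]: config.coupling for g in tgt}
        C[tgt, i] += config.coupling
    targeted = C.any(axis=1)
    G = rng.standard_normal((config.n_genes, n))  # untargeted genes: unit noise
    G[targeted] = C[targeted] @ X + config.noise_sd * rng.standard_normal((int(targeted.sum()), n))

    # --- exponential survival with administrative censoring at the 75th pct
    hazard = np.where(is_b, config.baseline_hazard * config.hazard_ratio, config.baseline_hazard)
    raw = rng.exponential(1.0 / hazard)
    horizon = float(np.percentile(raw, 75.0))
    time = np.minimum(raw, horizon)
    event = (raw <= horizon).astype(int)

    truth = SyntheticTruth(
        hub_ids=[mirna_ids[h] for h in hub_idx],
        module_members={
            mirna_ids[h]: [mirna_ids[j] for j in members]
            for h, members in zip(hub_idx, member_idx)
        },
        de_ids=de_ids,
        coupling_map=coupling_map,
    )
    return DualDataset(
        mirna=ExpressionMatrix(mirna_ids, sample_ids, X, labels),
        mrna=ExpressionMatrix(gene_ids, list(sample_ids), G, dict(labels)),
        targets=TargetMap(target_sets),
        survival=SurvivalTable(sample_ids, time, event),
        truth=truth,
    )


def write_dataset(data: DualDataset, outdir) -> None:
    """Write the four TSV files plus the truth record as JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(data.mirna, outdir / "mirna_expression.tsv")
    write_expression(data.mrna, outdir / "mrna_expression.tsv")
    write_labels(data.mirna.labels, data.mirna.sample_ids, outdir / "labels.tsv")
    write_target_map(data.targets, outdir / "targets.tsv")
    write_survival(data.survival, outdir / "survival.tsv")
    data.truth.to_json(outdir / "truth.json")
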