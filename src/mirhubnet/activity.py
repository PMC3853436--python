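"""miRNA activity scores: first principal component of each miRNA's targets.

For every miRNA, the rows of the mRNA matrix corresponding to its mapped
target genes are centred gene-wise and the first principal component of
that block is taken *across samples*, so the activity score is a length-
n_samples profile living in the same space as the expression data — the
prerequisite for building a second miRNA-miRNA network over samples.
The sign of each score is fixed so it correlates non-negatively with the
mean centred target profile (PCA signs are otherwise arbitrary). The
fraction of target-block variance explained by the first component is
recorded per miRNA; miRNAs whose first component explains little variance
can be flagged, but are never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError
from .io import ExpressionMatrix, TargetMap

logger = logging.getLogger(__name__)

__all__ = ["ActivityMatrix", "activity_scores", "flag_low_variance"]


@dataclass
class ActivityMatrix:
    """Per-miRNA first-PC activity profiles over samples."""

    mirna_ids: list[str]
    sample_ids: list[str]
    scores: np.ndarray
    var_explained: np.ndarray
    n_targets_used: np.ndarray

    def to_expression(self, labels=None) -> ExpressionMatrix:
        """View the activity scores as an expression matrix (for networks)."""
        return ExpressionMatrix(list(self.mirna_ids), list(self.sample_ids),
                                self.scores.copy(), labels)

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mirna": self.mirna_ids,
                "n_targets_used": self.n_targets_used,
                "var_explained": self.var_explained,
            }
        )


def _first_pc(block: np.ndarray) -> tuple[np.ndarray, float]:
    """First-PC sample scores and explained-variance fraction of a
    gene-centred (genes x samples) block."""
    centred = block - block.mean(axis=1, keepdims=True)
    if centred.shape[0] == 1:
        return centred[0].copy(), 1.0
    # SVD of the centred block: right singular vectors are sample-space PCs
    u, sing, vt = np.linalg.svd(centred, full_matrices=False)
    total = float((sing**2).sum())
    if total == 0.0:  # all-constant targets: no variance to summarise
        return np.zeros(centred.shape[1]), 1.0
    score = sing[0] * vt[0]
    return score, float(sing[0] ** 2 / total)


def activity_scores(
    mrna: ExpressionMatrix, targets: TargetMap, mirna_ids=None
) -> ActivityMatrix:
    """Activity profile for each miRNA with >= 1 mapped target present.

    ``mirna_ids`` restricts and orders the output (default: every miRNA in
    the map, sorted). Genes in the map but absent from the mRNA matrix are
    skipped; miRNAs left with no usable target are dropped with a warning.
    """
    if len(targets) == 0:
        raise InputError("empty target map")
    if mrna.n_samples < 2:
        raise InputError("mRNA matrix needs at least 2 samples")
    if mirna_ids is None:
        mirna_ids = sorted(targets.pairs)
    gene_pos = {g: i for i, g in enumerate(mrna.feature_ids)}

    kept, scores, var_exp, n_used = [], [], [], []
    for mid in mirna_ids:
        rows = sorted(gene_pos[g] for g in targets.targets_of(mid) if g in gene_pos)
        if not rows:
            logger.warning("miRNA %s has no mapped target in the mRNA matrix; dropped", mid)
            continue
        block = mrna.values[rows]
        score, ve = _first_pc(block)
        mean_profile = block - block.mean(axis=1, keepdims=True)
        ref = mean_profile.mean(axis=0)
        if score.std() > 0 and ref.std() > 0 and np.corrcoef(score, ref)[0, 1] < 0:
            score = -score
        kept.append(mid)
        scores.append(score)
        var_exp.append(ve)
        n_used.append(len(rows))

    if not kept:
        raise InputError("no miRNA has any mapped target present in the mRNA matrix")
    return ActivityMatrix(
        mirna_ids=kept,
        sample_ids=list(mrna.sample_ids),
        scores=np.vstack(scores),
        var_explained=np.asarray(var_exp),
        n_targets_used=np.asarray(n_used, dtype=int),
    )


def flag_low_variance(activity: ActivityMatrix, floor: float = 0.40) -> list[str]:
    """miRNAs whose first PC explains < ``floor`` of target variance.

    Advisory only — a low value signals that one component summarises the
    target block poorly; flagged miRNAs are reported, never removed.
    """
    return [m for m, v in zip(activity.mirna_ids, activity.var_explained) if v < floor]
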