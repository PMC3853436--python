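"""Model/Results front end for the dual-network subtype-miRNA procedure.

:class:`DualNetworkModel` bundles a dual profiling dataset (miRNA matrix
with two-class labels, mRNA matrix, miRNA->target map, optional survival
table); :meth:`~DualNetworkModel.fit` runs the full procedure —

1. SAM-style permutation differential expression on the miRNA matrix and
   selection of the differential panel (p < 0.05, FDR < 0.1);
2. a miRNA-miRNA network from miRNA expression (KSG MI + DPI pruning);
3. per-miRNA activity scores (first PC of target mRNAs) and a second
   network from the activity matrix;
4. topology summaries and centralities of both networks;
5. hub calling per network and intersection into the common-hub report —

and returns a :class:`DualNetworkResults` carrying every intermediate
product, a ``summary()`` table, an ``evaluate()`` validation battery and a
deterministic ``save()``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import activity as _activity
from . import diffexpr as _diffexpr
from . import evaluation as _evaluation
from . import hubs as _hubs
from . import io as _io
from . import mi as _mi
from . import topology as _topology
from .exceptions import InputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["DualNetworkModel", "DualNetworkResults"]


class DualNetworkModel:
    """The dual MI-network hub-intersection model for one dataset."""

    def __init__(self, mirna, mrna, targets, survival=None):
        if mirna.labels is None:
            raise InputError("miRNA matrix must carry two-class sample labels")
        if list(mirna.sample_ids) != list(mrna.sample_ids):
            raise InputError("miRNA and mRNA matrices must share the same samples, in order")
        self.mirna = mirna
        self.mrna = mrna
        self.targets = targets
        self.survival = survival

    @classmethod
    def from_files(cls, mirna_path, mrna_path, targets_path, labels_path, survival_path=None):
        mirna = _io.read_expression(mirna_path, labels_path)
        mrna = _io.read_expression(mrna_path)
        targets = _io.read_target_map(targets_path)
        survival = _io.read_survival(survival_path) if survival_path else None
        return cls(mirna, mrna, targets, survival)

    def fit(
        self,
        k_neighbors: int = 3,
        epsilon: float = 0.05,
        mi_floor="permutation",
        degree_threshold: int = 15,
        n_perm: int = 1000,
        p_max: float = 0.05,
        fdr_max: float = 0.1,
        feature_selection: str = "differential",
        seed: int = 0,
    ) -> "DualNetworkResults":
        """Run the full procedure; deterministic given the seed."""
        if feature_selection not in ("differential", "all"):
            raise ParameterError("feature_selection must be 'differential' or 'all'")
        de = _diffexpr.permutation_test(self.mirna, n_perm=n_perm, seed=seed)
        if feature_selection == "differential":
            selected = _diffexpr.select_differential(de, p_max=p_max, fdr_max=fdr_max)
            if len(selected) < 3:
                raise InputError(
                    f"only {len(selected)} differential miRNAs at p<{p_max}, FDR<{fdr_max}; "
                    "too few to build a network (try feature_selection='all')"
                )
        else:
            selected = list(self.mirna.feature_ids)

        expr_sub = self.mirna.subset(selected)
        net_expr = _mi.build_network(
            expr_sub, k_neighbors=k_neighbors, epsilon=epsilon, mi_floor=mi_floor, seed=seed
        )

        act = _activity.activity_scores(self.mrna, self.targets, mirna_ids=selected)
        net_act = _mi.build_network(
            act.to_expression(self.mirna.labels),
            k_neighbors=k_neighbors, epsilon=epsilon, mi_floor=mi_floor, seed=seed + 1,
        )

        cent_expr = _topology.node_centralities(net_expr)
        cent_act = _topology.node_centralities(net_act)
        summary_expr = _topology.network_summary(net_expr)
        summary_act = _topology.network_summary(net_act)

        trends = dict(zip(de.table["feature"], de.table["trend"]))
        report = _hubs.common_hub_report(
            cent_expr, cent_act, trends=trends, degree_threshold=degree_threshold
        )

        return DualNetworkResults(
            model=self,
            diffexpr=de,
            selected_features=selected,
            network_expression=net_expr,
            network_activity=net_act,
            activity=act,
            centralities_expression=cent_expr,
            centralities_activity=cent_act,
            summary_expression=summary_expr,
            summary_activity=summary_act,
            hub_report=report,
            seed=seed,
            params={
                "k_neighbors": k_neighbors, "epsilon": epsilon,
                "mi_floor": net_expr.mi_floor if mi_floor == "permutation" else mi_floor,
                "degree_threshold": degree_threshold, "n_perm": n_perm,
                "p_max": p_max, "fdr_max": fdr_max, "feature_selection": feature_selection,
            },
        )


@dataclass
class DualNetworkResults:
    """Everything the fitted procedure produced."""

    model: DualNetworkModel
    diffexpr: _diffexpr.DiffExprResult
    selected_features: list[str]
    network_expression: _mi.MiNetwork
    network_activity: _mi.MiNetwork
    activity: _activity.ActivityMatrix
    centralities_expression: pd.DataFrame
    centralities_activity: pd.DataFrame
    summary_expression: _topology.TopologySummary
    summary_activity: _topology.TopologySummary
    hub_report: _hubs.HubReport
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def common_hubs(self) -> list[str]:
        return self.hub_report.common_hub_ids

    def suggested_thresholds(self, alpha: float = 0.05) -> dict[str, int | None]:
        """Poisson-null advisory degree thresholds per network."""
        out = {}
        for name, summ in (("expression", self.summary_expression),
                           ("activity", self.summary_activity)):
            out[name] = (
                _hubs.suggest_threshold(summ.avg_degree, alpha) if summ.avg_degree > 0 else None
            )
        return out

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels-style."""
        s1, s2 = self.summary_expression, self.summary_activity
        lines = [
            "Dual miRNA interaction network summary",
            "=" * 54,
            f"{'':28s}{'expression':>12s}{'activity':>12s}",
            f"{'nodes':28s}{s1.n_nodes:>12d}{s2.n_nodes:>12d}",
            f"{'edges':28s}{s1.n_edges:>12d}{s2.n_edges:>12d}",
            f"{'density':28s}{s1.density:>12.3f}{s2.density:>12.3f}",
            f"{'avg degree':28s}{s1.avg_degree:>12.2f}{s2.avg_degree:>12.2f}",
            f"{'avg betweenness':28s}{s1.avg_betweenness:>12.2f}{s2.avg_betweenness:>12.2f}",
            f"{'avg closeness':28s}{s1.avg_closeness:>12.3f}{s2.avg_closeness:>12.3f}",
            f"{'centralization':28s}{s1.centralization:>12.3f}{s2.centralization:>12.3f}",
            f"{'heterogeneity':28s}{s1.heterogeneity:>12.3f}{s2.heterogeneity:>12.3f}",
            f"{'char path length':28s}{s1.char_path_length:>12.3f}{s2.char_path_length:>12.3f}",
            "-" * 54,
            f"differential miRNAs selected: {len(self.selected_features)} "
            f"of {self.model.mirna.n_features}",
            f"hub degree threshold: {self.hub_report.degree_threshold} "
            f"(hubs: {len(self.hub_report.hubs_a)} expression, "
            f"{len(self.hub_report.hubs_b)} activity)",
            f"common hubs: {len(self.common_hubs)}",
        ]
        if self.common_hubs:
            lines.append("top common hubs (avg degree):")
            for _, row in self.hub_report.table.head(10).iterrows():
                lines.append(
                    f"  {row['mirna']:<14s} deg={row['avg_degree']:<6.1f} "
                    f"btw={row['avg_betweenness']:<9.3f} clo={row['avg_closeness']:<7.4f} "
                    f"trend={row['trend']}"
                )
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def evaluate(
        self,
        pool_ids=None,
        n_iter: int = 1000,
        n_perm: int = 10000,
        classifiers=_evaluation.CLASSIFIERS,
        seed: int = 0,
    ) -> dict:
        """Run the validation battery on the common-hub set.

        Classifier comparison (hub set vs full differential panel, on both
        the expression and the activity matrix), the random-set correlation
        test against ``pool_ids`` (default: the differential panel), the
        global test, and — when a survival table is present — the K-means +
        log-rank survival comparison.
        """
        hubs = self.common_hubs
        if len(hubs) < 2:
            raise InputError("need at least 2 common hubs to evaluate")
        mirna = self.model.mirna
        act_expr = self.activity.to_expression(mirna.labels)
        out: dict = {"classification": [], "seed": seed}
        for kind, matrix in (("expression", mirna), ("activity", act_expr)):
            available = set(matrix.feature_ids)
            for feature_set, ids in (("common_hubs", hubs),
                                     ("differential", self.selected_features)):
                usable = [f for f in ids if f in available]
                for clf in classifiers:
                    rep = _evaluation.crossval_accuracy(matrix, usable, clf, seed=seed)
                    out["classification"].append(
                        {"matrix": kind, "feature_set": feature_set,
                         "classifier": clf, "accuracy": rep.accuracy}
                    )
        pool = list(pool_ids) if pool_ids is not None else list(self.selected_features)
        if len(pool) >= max(2, len(hubs)):
            rs = _evaluation.random_set_correlation_test(
                mirna, hubs, pool, n_iter=n_iter, seed=seed
            )
            out["random_set"] = {
                "candidate_mean_r": rs.candidate_mean_r,
                "max_null_mean_r": float(rs.null_means.max()),
                "empirical_p": rs.empirical_p,
            }
        gt = _evaluation.global_test(mirna, hubs, n_perm=n_perm, seed=seed)
        out["global_test"] = {"Q": gt.Q, "p_value": gt.p_value}
        if self.model.survival is not None:
            sc = _evaluation.survival_compare(mirna, hubs, self.model.survival, seed=seed)
            out["survival"] = {
                "log_rank_statistic": sc.statistic,
                "p_value": sc.p_value,
                "degenerate": sc.degenerate,
            }
        return out

    # ------------------------------------------------------------------
    def save(self, outdir) -> None:
        """Write every product as TSV/JSON; byte-identical across runs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _diffexpr.write_result(self.diffexpr, outdir / "diffexpr.tsv")
        (outdir / "selected_features.txt").write_text(
            "".join(f"{f}\n" for f in self.selected_features), encoding="utf-8"
        )
        _io.write_edge_list(self.network_expression, outdir / "network_expression_edges.tsv")
        _io.write_edge_list(self.network_activity, outdir / "network_activity_edges.tsv")
        _io.write_graphml(self.network_expression, outdir / "network_expression.graphml",
                          self.centralities_expression)
        _io.write_graphml(self.network_activity, outdir / "network_activity.graphml",
                          self.centralities_activity)
        _io.write_expression(self.activity.to_expression(), outdir / "activity_matrix.tsv")
        self.activity.report().to_csv(outdir / "activity_report.tsv", sep="\t",
                                      index=False, float_format="%.9g")
        for name, cent in (("expression", self.centralities_expression),
                           ("activity", self.centralities_activity)):
            cent.to_csv(outdir / f"centralities_{name}.tsv", sep="\t", float_format="%.9g")
        summary = {
            "expression": self.summary_expression.to_dict(),
            "activity": self.summary_activity.to_dict(),
            "params": self.params,
            "n_selected": len(self.selected_features),
            "n_common_hubs": len(self.common_hubs),
        }
        with open(outdir / "topology_summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, allow_nan=True)
        self.hub_report.table.to_csv(outdir / "hub_report.tsv", sep="\t",
                                     index=False, float_format="%.9g")
        with open(outdir / "hubs.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "common_hub_ids": self.common_hubs,
                    "hubs_expression": sorted(self.hub_report.hubs_a),
                    "hubs_activity": sorted(self.hub_report.hubs_b),
                    "degree_threshold": self.hub_report.degree_threshold,
                },
                fh, indent=1, sort_keys=True,
            )
        for name, net in (("expression", self.network_expression),
                          ("activity", self.network_activity)):
            top_n = min(10, max(net.n_nodes - 1, 0))
            if top_n:
                _topology.removal_curve(net, top_n=top_n).to_csv(
                    outdir / f"removal_curve_{name}.tsv", sep="\t",
                    index=False, float_format="%.9g",
                )
        (outdir / "summary.txt").write_text(self.summary() + "\n", encoding="utf-8")
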