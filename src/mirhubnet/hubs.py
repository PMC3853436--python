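"""Hub calling under a Poisson degree null and the common-hub report.

In an Erdős–Rényi random graph the degree distribution is approximately
Poisson with mean equal to the observed average degree, so
P(degree >= t | Poisson(lambda)) measures how surprising a node's degree
is under random wiring. The operational hub rule is a plain degree
threshold (default 15, a convention for disease-network hubs); the Poisson
tail and the smallest t with tail < alpha are exposed for transparency.

Hubs are called separately in the expression-based and activity-based
networks and intersected; the report averages each common hub's degree,
betweenness and closeness across the two networks and attaches its
differential-expression trend label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy.stats import poisson

from .exceptions import ParameterError

__all__ = [
    "HubReport",
    "poisson_degree_pvalue",
    "identify_hubs",
    "suggest_threshold",
    "common_hub_report",
]


@dataclass
class HubReport:
    """Common hubs of the two networks with averaged centralities."""

    common_hub_ids: list[str]
    table: pd.DataFrame  # mirna, avg_degree, avg_betweenness, avg_closeness, trend
    hubs_a: set[str]
    hubs_b: set[str]
    degree_threshold: int

    def __len__(self) -> int:
        return len(self.common_hub_ids)


def poisson_degree_pvalue(lam: float, t: int) -> float:
    """P(X >= t) for X ~ Poisson(lam), via the complemented CDF."""
    if lam <= 0:
        raise ParameterError("lam must be > 0")
    if t < 0:
        raise ParameterError("t must be a non-negative count")
    if t == 0:
        return 1.0
    return float(poisson.sf(t - 1, lam))


def identify_hubs(centralities: pd.DataFrame, degree_threshold: int = 15) -> set[str]:
    """Nodes with degree >= threshold."""
    return set(centralities.index[centralities["degree"] >= degree_threshold])


def suggest_threshold(avg_degree: float, alpha: float = 0.05) -> int:
    """Smallest t with P(degree >= t | Poisson(avg_degree)) < alpha.

    Advisory: quantifies where a degree becomes a rare event under random
    wiring; the operational hub rule remains an explicit threshold.
    """
    if avg_degree <= 0:
        raise ParameterError("avg_degree must be > 0")
    if alpha >= 1.0:
        return 0
    t = 1
    while poisson_degree_pvalue(avg_degree, t) >= alpha:
        t += 1
    return t


def common_hub_report(
    cent_a: pd.DataFrame,
    cent_b: pd.DataFrame,
    trends: Mapping[str, str] | None = None,
    degree_threshold: int = 15,
) -> HubReport:
    """Intersect the two networks' hub sets and average their centralities.

    Rows are sorted by averaged degree (descending), ties by averaged
    betweenness (descending) then ID. An empty intersection is a valid,
    empty report.
    """
    hubs_a = identify_hubs(cent_a, degree_threshold)
    hubs_b = identify_hubs(cent_b, degree_threshold)
    common = hubs_a & hubs_b
    rows = []
    for node in common:
        a, b = cent_a.loc[node], cent_b.loc[node]
        rows.append(
            {
                "mirna": node,
                "avg_degree": (a["degree"] + b["degree"]) / 2.0,
                "avg_betweenness": (a["betweenness"] + b["betweenness"]) / 2.0,
                "avg_closeness": (a["closeness"] + b["closeness"]) / 2.0,
                "trend": (trends or {}).get(node, "none"),
            }
        )
    table = pd.DataFrame(rows, columns=["mirna", "avg_degree", "avg_betweenness",
                                        "avg_closeness", "trend"])
    if len(table):
        table = table.sort_values(
            by=["avg_degree", "avg_betweenness", "mirna"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return HubReport(
        common_hub_ids=table["mirna"].tolist(),
        table=table,
        hubs_a=hubs_a,
        hubs_b=hubs_b,
        degree_threshold=degree_threshold,
    )
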