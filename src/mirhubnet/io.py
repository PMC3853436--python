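"""Readers and writers for the package's on-disk formats.

Everything is plain tab-separated UTF-8 text ('.' decimal): expression
matrices (features x samples with a header row of sample IDs), two-column
miRNA->gene target maps, three-column survival tables, and network edge
lists. Networks can additionally be exported as GraphML with centrality
node attributes. Sample class labels live in a sidecar two-column TSV
(sample, class) so expression files stay standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import networkx as nx

from .exceptions import FormatError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "TargetMap",
    "SurvivalTable",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_target_map",
    "write_target_map",
    "read_survival",
    "write_survival",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
]

# numbers are printed with 12 significant digits so that edge-list and
# matrix round-trips agree to well below 1e-9 relative error
_FLOAT_FMT = "%.12g"


@dataclass
class ExpressionMatrix:
    """A feature x sample real-valued matrix with optional 2-class labels."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise InputError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise InputError("duplicate feature IDs")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("duplicate sample IDs")
        if self.labels is not None:
            missing = [s for s in self.sample_ids if s not in self.labels]
            if missing:
                raise InputError(f"labels missing for samples: {missing[:5]}")
            classes = sorted(set(self.labels[s] for s in self.sample_ids))
            if len(classes) != 2:
                raise InputError(
                    f"expected exactly 2 sample classes, found {len(classes)}: {classes}"
                )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def classes(self) -> tuple[str, str]:
        """The two class names, sorted; class A is the first."""
        if self.labels is None:
            raise InputError("matrix carries no sample labels")
        names = sorted(set(self.labels[s] for s in self.sample_ids))
        return names[0], names[1]

    def class_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean column masks (class A, class B) in sample order."""
        a, b = self.classes
        lab = np.array([self.labels[s] for s in self.sample_ids])
        return lab == a, lab == b

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]

    def subset(self, feature_ids) -> "ExpressionMatrix":
        """Row-subset preserving the requested order."""
        wanted = list(feature_ids)
        missing = [f for f in wanted if f not in set(self.feature_ids)]
        if missing:
            raise InputError(f"features not in matrix: {missing}")
        idx = [self.feature_ids.index(f) for f in wanted]
        return ExpressionMatrix(wanted, list(self.sample_ids), self.values[idx], self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class TargetMap:
    """Mapping from miRNA ID to the set of gene IDs it targets."""

    pairs: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mirna, genes in self.pairs.items():
            if not mirna:
                raise InputError("empty miRNA ID in target map")
            if not genes:
                raise InputError(f"empty target set stored for {mirna!r}")
            self.pairs[mirna] = frozenset(genes)

    def targets_of(self, mirna: str) -> frozenset[str]:
        return self.pairs.get(mirna, frozenset())

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SurvivalTable:
    """Follow-up time and event indicator per sample."""

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise InputError("duplicate sample IDs in survival table")
        if not (len(self.sample_ids) == len(self.time) == len(self.event)):
            raise InputError("survival table columns have unequal lengths")
        if np.any(self.time < 0):
            raise InputError("negative survival times")
        if not np.all(np.isin(self.event, (0, 1))):
            raise InputError("event indicator must be 0 or 1")

    def lookup(self, sample_ids) -> tuple[np.ndarray, np.ndarray]:
        """(time, event) arrays aligned to ``sample_ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise InputError(f"samples missing from survival table: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return self.time[idx], self.event[idx]


# ---------------------------------------------------------------------------
# expression matrices


def read_expression(path, labels_path=None) -> ExpressionMatrix:
    """Load a features x samples TSV; rows with missing values are dropped.

    The first column holds feature IDs and the header row sample IDs.
    Duplicate feature IDs or fewer than two samples are format errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least 2 samples, found {df.shape[1]}")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{path}: duplicated feature ID(s): {dup}")
    n_bad = int(df.isna().any(axis=1).sum())
    if n_bad:
        logger.warning("%s: dropped %d feature row(s) with missing values", path, n_bad)
        df = df.dropna(axis=0)
    labels = read_labels(labels_path) if labels_path is not None else None
    return ExpressionMatrix(
        feature_ids=[str(f) for f in df.index],
        sample_ids=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        labels=labels,
    )


def write_expression(matrix: ExpressionMatrix, path, labels_path=None) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="feature")
    if labels_path is not None:
        if matrix.labels is None:
            raise InputError("matrix carries no labels to write")
        write_labels(matrix.labels, matrix.sample_ids, labels_path)


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: label sidecar must have exactly 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: Mapping[str, str], sample_ids, path) -> None:
    pd.DataFrame(
        {"sample": list(sample_ids), "class": [labels[s] for s in sample_ids]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# target maps and survival tables


def read_target_map(path) -> TargetMap:
    """Two-column TSV (mirna, gene), one pair per line, optional header."""
    pairs: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            mirna, gene = (f.strip() for f in fields)
            if lineno == 1 and (mirna.lower(), gene.lower()) == ("mirna", "gene"):
                continue
            if not mirna or not gene:
                raise FormatError(f"{path}:{lineno}: blank miRNA or gene field")
            pairs.setdefault(mirna, set()).add(gene)
    return TargetMap({m: frozenset(g) for m, g in pairs.items()})


def write_target_map(targets: TargetMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\tgene\n")
        for mirna in sorted(targets.pairs):
            for gene in sorted(targets.pairs[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def read_survival(path) -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    if not {"time", "event"} <= set(cols):
        raise FormatError(f"{path}: survival table needs 'time' and 'event' columns")
    df.columns = cols
    sample_col = [c for c in cols if c not in ("time", "event")][0]
    return SurvivalTable(
        sample_ids=[str(s) for s in df[sample_col]],
        time=df["time"].to_numpy(dtype=float),
        event=df["event"].to_numpy(dtype=int),
    )


def write_survival(table: SurvivalTable, path) -> None:
    pd.DataFrame(
        {"sample": table.sample_ids, "time": table.time, "event": table.event}
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# networks


def write_edge_list(network, path) -> None:
    """Edge list TSV (node_a, node_b, mi_nats); deterministic ordering.

    Within an edge node_a < node_b lexicographically; rows sorted by
    (node_a, node_b). MI is printed with 12 significant digits.
    """
    rows = []
    for u, v, w in network.graph.edges(data="weight"):
        a, b = sorted((u, v))
        rows.append((a, b, w))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tmi_nats\n")
        for a, b, w in rows:
            fh.write(f"{a}\t{b}\t{_FLOAT_FMT % w}\n")


def read_edge_list(path):
    """Inverse of :func:`write_edge_list` (weights to printed precision)."""
    from .mi import MiNetwork  # local import to avoid a cycle

    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["node_a", "node_b", "mi_nats"]:
            raise FormatError(f"{path}: unexpected edge-list header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            g.add_edge(fields[0], fields[1], weight=float(fields[2]))
    return MiNetwork(graph=g, k_neighbors=0, epsilon=float("nan"))


def write_graphml(network, path, centralities: pd.DataFrame | None = None) -> None:
    """GraphML export; node centrality columns become node attributes."""
    g = network.graph.copy()
    if centralities is not None:
        for node in g.nodes:
            if node in centralities.index:
                for col in centralities.columns:
                    g.nodes[node][col] = float(centralities.loc[node, col])
    nx.write_graphml(g, path)
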