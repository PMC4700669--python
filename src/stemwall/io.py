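"""Tab-delimited format adapters.

Everything round-trips: matrices (first column probe id, header = sample
ids) with a companion sample-design TSV, truth/annotation tables, DE
result tables, cluster assignments, qPCR long tables, edge lists, null
histograms. Networks additionally export GraphML, dendrograms Newick.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .containers import ExpressionMatrix, TruthLabels
from .coexpression import CoexpressionNetwork
from .qpcr import QPCRTable

PathLike = Union[str, Path]


def write_matrix(matrix: ExpressionMatrix, values_path: PathLike, design_path: PathLike) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="probe_id")
    design = matrix.design.copy()
    design.insert(len(design.columns), "n_chip", matrix.n_chip)
    design.to_csv(design_path, sep="\t", index_label="sample_id")


def read_matrix(values_path: PathLike, design_path: PathLike) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="probe_id")
    design = pd.read_csv(design_path, sep="\t", index_col="sample_id")
    n_chip = int(design["n_chip"].iloc[0]) if "n_chip" in design.columns else 61281
    design = design.drop(columns=["n_chip"], errors="ignore")
    design["is_stem"] = design["is_stem"].astype(bool)
    return ExpressionMatrix(values, design, n_chip)


def write_truth(truth: TruthLabels, path: PathLike) -> None:
    truth.table.to_csv(path, sep="\t", index_label="probe_id")


def read_truth(path: PathLike) -> TruthLabels:
    table = pd.read_csv(path, sep="\t", index_col="probe_id")
    table["archetype"] = table["archetype"].astype("Int64")
    table["tf_family"] = table["tf_family"].astype("string")
    table["pathway"] = table["pathway"].astype("string")
    table["is_tf"] = table["is_tf"].astype(bool)
    table["is_hub"] = table["is_hub"].astype(bool)
    return TruthLabels(table)


def write_de_table(de_table: pd.DataFrame, path: PathLike) -> None:
    de_table.reset_index().to_csv(path, sep="\t", index=False)


def read_de_table(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    return frame.set_index(["probe_id", "contrast"])


def write_assignment(labels: pd.Series, centroids: pd.DataFrame, archetype_corr: pd.Series,
                     labels_path: PathLike, centroids_path: PathLike) -> None:
    out = labels.rename("cluster").to_frame()
    out["centroid_corr"] = archetype_corr.reindex(labels).to_numpy()
    out.to_csv(labels_path, sep="\t", index_label="probe_id")
    centroids.to_csv(centroids_path, sep="\t", index_label="cluster")


def read_assignment(labels_path: PathLike) -> pd.Series:
    frame = pd.read_csv(labels_path, sep="\t", index_col="probe_id")
    return frame["cluster"].astype(int)


def write_qpcr_table(table: QPCRTable, path: PathLike) -> None:
    records = table.records.copy()
    records["efficiency"] = records["gene"].map(table.efficiencies)
    records["is_reference"] = records["gene"] == table.reference_gene
    records.to_csv(path, sep="\t", index=False)


def read_qpcr_table(path: PathLike) -> QPCRTable:
    records = pd.read_csv(path, sep="\t")
    eff = records.groupby("gene")["efficiency"].first()
    refs = sorted(set(records.loc[records["is_reference"], "gene"]))
    if len(refs) != 1:
        raise ValueError(f"expected exactly one reference gene, found {refs}")
    core = records.drop(columns=["efficiency", "is_reference"])
    return QPCRTable(core, eff, refs[0])


def write_network(net: CoexpressionNetwork, edges_path: PathLike,
                  graphml_path: Optional[PathLike] = None,
                  histogram_path: Optional[PathLike] = None) -> None:
    net.edge_table().to_csv(edges_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(net.graph, graphml_path)
    if histogram_path is not None and net.null_histogram is not None:
        net.null_histogram.to_csv(histogram_path, sep="\t", index=False)


def read_edge_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def dendrogram_to_newick(linkage_matrix: np.ndarray, leaf_names: list[str]) -> str:
    """Newick export of a SciPy linkage tree with branch lengths."""
    tree = hierarchy.to_tree(linkage_matrix)

    def walk(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = node.get_left(), node.get_right()
        ld = max(node.dist - left.dist, 0.0)
        rd = max(node.dist - right.dist, 0.0)
        return f"({walk(left)}:{ld:.6g},{walk(right)}:{rd:.6g})"

    return walk(tree) + ";"


def write_summary(summary: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (pd.Index, pd.Series, np.ndarray)):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
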