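"""Permutation-thresholded Pearson co-expression network.

Probe sets passing a variability filter (max/min >= 2 over the stem chips,
control prefixes removed) are correlated all-against-all across the 37
chips. The edge threshold is not assumed: each probe set's values are
independently permuted to build a random dataset, the full null PCC
distribution is histogrammed at 0.1 resolution, and the threshold is the
smallest 0.1-grid value no null pair exceeds in absolute value (0.8 at the
study's scale). Pairs with |PCC| above the threshold become edges; TF
sub-networks around the lignin / cellulose / hemicellulose gene sets rank
hub TFs by how many pathway genes they connect to.

All-pairs work is done blockwise on standardized rows so memory stays
bounded; only above-threshold pairs are ever materialized.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import networkx as nx

from . import config
from .containers import ExpressionMatrix

DEFAULT_BLOCK = 1024


def n_pairs(m: int) -> int:
    """Unordered pair count m(m-1)/2."""
    if m < 0:
        raise ValueError("m must be non-negative")
    return m * (m - 1) // 2


# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------

def filter_probesets(
    matrix: ExpressionMatrix,
    prefixes: Sequence[str] = config.CONTROL_PREFIXES,
    min_fold: float = 2.0,
) -> ExpressionMatrix:
    """Keep probes with max/min >= min_fold over the stem chips and ids not
    starting with a control prefix."""
    stem_cols = matrix.stem_samples()
    if not stem_cols:
        raise ValueError("matrix has no stem-experiment samples")
    stem = matrix.values[stem_cols]
    mins = stem.min(axis=1)
    if (mins <= 0).any():
        offenders = list(mins.index[mins <= 0][:5])
        raise ValueError(f"non-positive stem minimum for probes {offenders}")
    spread = stem.max(axis=1) / mins
    keep = spread >= min_fold
    for prefix in prefixes:
        keep &= ~matrix.values.index.str.startswith(prefix)
    return ExpressionMatrix(matrix.values[keep], matrix.design, matrix.n_chip)


# ---------------------------------------------------------------------------
# Pearson correlation, blockwise
# ---------------------------------------------------------------------------

def _standardize_rows(values: np.ndarray, log2: bool = True) -> np.ndarray:
    """Rows centered and scaled to unit norm so X @ X.T gives PCCs.

    Correlation is computed on log2 intensities by default: expression
    values are log-normally dispersed, and on the linear scale a handful of
    extreme values per probe set dominates the correlation (and fattens the
    permutation-null tail far beyond the 0.8 grid).
    """
    if log2:
        values = np.log2(values)
    x = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    if zero.any():
        raise ValueError(
            f"{int(zero.sum())} zero-variance rows; exclude them before correlation"
        )
    return x / norms


def drop_zero_variance(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove rows constant across samples (Pearson undefined), warning."""
    sd = matrix.values.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} zero-variance probe sets before correlation",
            stacklevel=2,
        )
        return ExpressionMatrix(matrix.values[~flat], matrix.design, matrix.n_chip)
    return matrix


def pairwise_pcc(
    matrix: ExpressionMatrix, block: int = DEFAULT_BLOCK, log2: bool = True
) -> np.ndarray:
    """All m(m-1)/2 unordered-pair PCCs as a condensed vector.

    Materializes the full condensed vector — meant for moderate m; network
    construction at scale goes through :func:`build_network`, which keeps
    only above-threshold pairs.
    """
    values = matrix.values.to_numpy(dtype=float)
    m, n = values.shape
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = _standardize_rows(values, log2=log2)
    out = np.empty(n_pairs(m))
    pos = 0
    for start in range(0, m, block):
        stop = min(start + block, m)
        r = x[start:stop] @ x.T
        for i in range(start, stop):
            row = r[i - start, i + 1 :]
            out[pos : pos + len(row)] = row
            pos += len(row)
    return np.clip(out, -1.0, 1.0)


def null_pcc_summary(
    matrix: ExpressionMatrix,
    bin_width: float = 0.1,
    block: int = DEFAULT_BLOCK,
    log2: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Histogram of all-pairs PCCs on [-1, 1] plus the maximum |PCC|.

    Blockwise: never materializes the full pair vector. Bins are
    left-closed, right-open, the final bin closed.
    """
    values = matrix.values.to_numpy(dtype=float)
    m, n = values.shape
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = _standardize_rows(values, log2=log2)
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 12)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    max_abs = 0.0
    for start in range(0, m, block):
        stop = min(start + block, m)
        r = np.clip(x[start:stop] @ x[start:].T, -1.0, 1.0)
        tri = np.concatenate(
            [r[i - start, i - start + 1 :] for i in range(start, stop)]
        )
        if len(tri):
            max_abs = max(max_abs, float(np.abs(tri).max()))
            idx = np.minimum(((tri - edges[0]) / bin_width).astype(np.int64), len(counts) - 1)
            counts += np.bincount(idx, minlength=len(counts))
    hist = pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})
    return hist, max_abs


# ---------------------------------------------------------------------------
# Permutation null and threshold
# ---------------------------------------------------------------------------

def permute_rows(matrix: ExpressionMatrix, seed: int = 0) -> ExpressionMatrix:
    """Independently permute each probe set's values across chips.

    Destroys every between-probe correlation while preserving each row's
    value multiset exactly — the random dataset for the null PCC
    distribution."""
    rng = np.random.default_rng(seed)
    values = matrix.values.to_numpy(dtype=float).copy()
    permuted = rng.permuted(values, axis=1)
    return ExpressionMatrix(
        pd.DataFrame(permuted, index=matrix.values.index, columns=matrix.values.columns),
        matrix.design,
        matrix.n_chip,
    )


def estimate_threshold(
    null_pccs: Optional[np.ndarray] = None,
    bin_width: float = 0.1,
    null_max_abs: Optional[float] = None,
) -> float:
    """Smallest 0.1-grid value t such that no null pair has |PCC| > t.

    Accepts either the raw null PCC vector or a precomputed maximum
    absolute null PCC from :func:`null_pcc_summary`. Errors when even the
    0.9 grid point is exceeded (no usable threshold below 1).
    """
    if null_max_abs is None:
        if null_pccs is None or len(null_pccs) == 0:
            raise ValueError("need null PCC values or their maximum")
        null_pccs = np.asarray(null_pccs, dtype=float)
        if (np.abs(null_pccs) > 1.0 + 1e-9).any():
            raise ValueError("null PCC values outside [-1, 1]")
        null_max_abs = float(np.abs(null_pccs).max())
    grid = np.round(np.arange(bin_width, 1.0, bin_width), 12)
    for t in grid:
        if null_max_abs <= t:
            return float(t)
    raise ValueError(
        f"max null |PCC| = {null_max_abs:.3f} exceeds every grid value below 1; "
        "no usable threshold"
    )


def null_histogram(null_pccs: np.ndarray, bin_width: float = 0.1) -> pd.DataFrame:
    """Frequency of null PCCs on [-1, 1] at ``bin_width`` resolution."""
    null_pccs = np.asarray(null_pccs, dtype=float)
    if len(null_pccs) and (np.abs(null_pccs) > 1.0 + 1e-9).any():
        raise ValueError("null PCC values outside [-1, 1]")
    edges = np.round(np.arange(-1.0, 1.0 + bin_width / 2, bin_width), 12)
    counts, _ = np.histogram(np.clip(null_pccs, -1.0, 1.0), bins=edges)
    return pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts})


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CoexpressionNetwork:
    """Thresholded |PCC| graph with its permutation-null provenance."""

    graph: nx.Graph
    threshold: float
    null_histogram: Optional[pd.DataFrame] = None

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"probe_a": a, "probe_b": b, "pcc": d["pcc"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["probe_a", "probe_b", "pcc"]).sort_values(
            ["probe_a", "probe_b"]
        ).reset_index(drop=True)


def build_network(
    matrix: ExpressionMatrix,
    threshold: float,
    null_hist: Optional[pd.DataFrame] = None,
    block: int = DEFAULT_BLOCK,
    log2: bool = True,
) -> CoexpressionNetwork:
    """Edges = probe pairs with |PCC| strictly above ``threshold``.

    Blockwise: only above-threshold pairs are materialized. A threshold of
    exactly 1 is permitted and yields an empty edge set (|PCC| > 1 being
    impossible)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    values = matrix.values.to_numpy(dtype=float)
    m, n = values.shape
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    x = _standardize_rows(values, log2=log2)
    ids = list(matrix.values.index)

    g = nx.Graph()
    g.add_nodes_from(ids)
    for start in range(0, m, block):
        stop = min(start + block, m)
        r = np.clip(x[start:stop] @ x[start:].T, -1.0, 1.0)
        for i in range(start, stop):
            row = r[i - start, i - start + 1 :]
            hits = np.flatnonzero(np.abs(row) > threshold)
            for j in hits:
                g.add_edge(ids[i], ids[i + 1 + j], pcc=float(row[j]))
    return CoexpressionNetwork(g, threshold, null_hist)


# ---------------------------------------------------------------------------
# Pathway sub-networks and hub TFs
# ---------------------------------------------------------------------------

def extract_pathway_subnetwork(
    net: CoexpressionNetwork,
    tf_set: Iterable[str],
    pathway_genes: Iterable[str],
) -> tuple[nx.Graph, pd.Series]:
    """TF-pathway bipartite sub-network plus each TF's pathway degree."""
    tf_set = set(tf_set)
    pathway_genes = set(pathway_genes)
    overlap = tf_set & pathway_genes
    if overlap:
        raise ValueError(
            f"genes cannot be both TF and pathway member: {sorted(overlap)[:5]}"
        )
    nodes = set(net.graph.nodes)
    missing = (tf_set | pathway_genes) - nodes
    if missing:
        raise ValueError(f"genes absent from network: {sorted(missing)[:5]}")

    sub = nx.Graph()
    degrees: dict[str, int] = {}
    for tf in sorted(tf_set):
        for gene in sorted(pathway_genes):
            if net.graph.has_edge(tf, gene):
                sub.add_edge(tf, gene, pcc=net.graph.edges[tf, gene]["pcc"])
                degrees[tf] = degrees.get(tf, 0) + 1
    return sub, pd.Series(degrees, dtype=int).sort_index()


def rank_hub_tfs(pathway_degree: pd.Series, min_degree: int = 4) -> list[str]:
    """TFs connected to at least ``min_degree`` pathway genes, by degree
    descending then id."""
    hubs = pathway_degree[pathway_degree >= min_degree]
    return sorted(hubs.index, key=lambda t: (-int(hubs[t]), t))
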