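"""Efficiency-corrected qPCR relative quantification.

Implements LinRegPCR-style amplification-efficiency estimation from raw
per-cycle fluorescence, Pfaffl-type relative quantification against a single
reference gene (a Ubiquitin analog) and the youngest internode as reference
sample, 5-fold regulation calls, and the concordance partition of qPCR hits
against the expression-array result.

The quantification model: for target gene g with amplification efficiency
E_g (per-cycle amplification factor, ideal 2.0) and reference gene R,

    ratio(g, i) = E_g ** (Ct_g(ref) - Ct_g(i)) / E_R ** (Ct_R(ref) - Ct_R(i))

evaluated per biological replicate (technical replicates averaged first)
and combined as the mean of per-replicate ratios. With E = 2 throughout
this reduces to the classic 2^(-ddCt).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import config

REQUIRED_COLUMNS = ("gene", "internode", "replicate", "tech_rep", "ct")


@dataclasses.dataclass
class QPCRTable:
    """Long-format Ct records with per-gene amplification efficiencies.

    ``records`` columns: gene, internode, replicate (biological),
    tech_rep, ct. ``efficiencies`` maps gene -> E in (1, 2.2].
    ``curves`` optionally maps gene -> per-cycle fluorescence array.
    """

    records: pd.DataFrame
    efficiencies: pd.Series
    reference_gene: str
    curves: Optional[dict[str, np.ndarray]] = None

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"qPCR records missing columns: {missing}")
        genes = set(self.records["gene"])
        if self.reference_gene not in genes:
            raise ValueError(f"reference gene {self.reference_gene!r} has no Ct records")
        refs = [g for g in genes if g == self.reference_gene]
        if len(refs) != 1:
            raise ValueError("exactly one reference gene must be designated")
        if (self.records["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        eff = self.efficiencies
        absent = genes - set(eff.index)
        if absent:
            raise ValueError(f"genes without efficiency estimates: {sorted(absent)[:5]}")
        bad = eff[(eff <= 1.0) | (eff > 2.2)]
        if len(bad):
            raise ValueError(f"efficiencies outside (1, 2.2]: {bad.to_dict()}")

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.records["gene"]))

    @property
    def internodes(self) -> list[str]:
        order = list(config.INTERNODES)
        present = set(self.records["internode"])
        return [i for i in order if i in present] + sorted(present - set(order))


# ---------------------------------------------------------------------------
# Amplification efficiency from raw fluorescence (LinRegPCR-style)
# ---------------------------------------------------------------------------

def estimate_efficiency(
    fluorescence: np.ndarray,
    window_len: int = 4,
    r2_min: float = 0.99,
) -> Optional[float]:
    """Per-reaction amplification efficiency from a raw fluorescence curve.

    Scans all ``window_len``-cycle windows with strictly positive
    fluorescence and rising signal, fits log10(F) against cycle number, and
    takes the window with maximal R-squared as the exponential phase.
    E = 10**slope. Returns None (with a diagnostic warning) when no window
    reaches ``r2_min`` or the fitted E is not an amplification (E <= 1).
    E is clipped to at most 2.2; values outside (1.6, 2.1] draw a warning.
    """
    f = np.asarray(fluorescence, dtype=float)
    if f.ndim != 1 or len(f) < window_len:
        raise ValueError(f"need a 1-D curve of at least {window_len} cycles")
    if window_len < 3:
        raise ValueError("window_len must be at least 3 for a regression fit")

    cycles = np.arange(len(f), dtype=float)
    best_r2, best_slope = -np.inf, np.nan
    for start in range(len(f) - window_len + 1):
        seg = f[start : start + window_len]
        if (seg <= 0).any() or not (np.diff(seg) > 0).all():
            continue
        fit = stats.linregress(cycles[start : start + window_len], np.log10(seg))
        r2 = fit.rvalue**2
        if r2 > best_r2:
            best_r2, best_slope = r2, fit.slope
    if not np.isfinite(best_slope) or best_r2 < r2_min:
        warnings.warn(
            f"no exponential-phase window of length {window_len} reached "
            f"R^2 >= {r2_min} (best {best_r2:.4f}); efficiency undefined",
            stacklevel=2,
        )
        return None
    e = 10.0**best_slope
    if e <= 1.0:
        warnings.warn(f"fitted efficiency {e:.3f} <= 1; not an amplification", stacklevel=2)
        return None
    if e > 2.2:
        warnings.warn(f"fitted efficiency {e:.3f} clipped to 2.2", stacklevel=2)
        e = 2.2
    elif not (1.6 < e <= 2.1):
        warnings.warn(f"fitted efficiency {e:.3f} outside the usual (1.6, 2.1]", stacklevel=2)
    return float(e)


# ---------------------------------------------------------------------------
# Relative quantification
# ---------------------------------------------------------------------------

def _replicate_cts(table: QPCRTable) -> pd.DataFrame:
    """Technical replicates averaged: one Ct per (gene, internode, replicate)."""
    return (
        table.records.groupby(["gene", "internode", "replicate"], sort=True)["ct"]
        .mean()
        .reset_index()
    )


def relative_expression(
    table: QPCRTable,
    reference_internode: str = config.REFERENCE_INTERNODE,
) -> pd.DataFrame:
    """Efficiency-corrected fold change of every gene in every internode
    relative to the reference internode (gene x internode table).

    Technical replicates are averaged first; the reference-internode Ct is
    the mean over its biological replicates; biological replicates of each
    target internode are combined as the mean of per-replicate ratios. The
    reference-internode column is 1 by construction.
    """
    cts = _replicate_cts(table)
    if reference_internode not in set(cts["internode"]):
        raise ValueError(f"reference internode {reference_internode!r} absent from table")

    ref_gene = table.reference_gene
    internodes = table.internodes
    genes = table.genes

    # Mean Ct in the reference internode, per gene.
    ref_in = cts[cts["internode"] == reference_internode]
    ct0 = ref_in.groupby("gene")["ct"].mean()

    # Reference-gene Ct per (internode, replicate).
    ref_rows = cts[cts["gene"] == ref_gene].set_index(["internode", "replicate"])["ct"]

    missing_ref = [
        (i, r)
        for i in internodes
        for r in sorted(set(cts[cts["internode"] == i]["replicate"]))
        if (i, r) not in ref_rows.index
    ]
    if missing_ref:
        raise ValueError(f"reference gene Ct missing for samples: {missing_ref[:5]}")

    e = table.efficiencies
    out = pd.DataFrame(index=pd.Index(genes, name="gene"), columns=internodes, dtype=float)
    for gene, sub in cts.groupby("gene"):
        eg = float(e[gene])
        for internode in internodes:
            if internode == reference_internode:
                out.loc[gene, internode] = 1.0
                continue
            rows = sub[sub["internode"] == internode]
            if rows.empty:
                out.loc[gene, internode] = np.nan
                continue
            ratios = []
            for _, row in rows.iterrows():
                d_target = ct0[gene] - row["ct"]
                d_ref = ct0[ref_gene] - ref_rows[(internode, row["replicate"])]
                ratios.append(eg**d_target / float(e[ref_gene]) ** d_ref)
            out.loc[gene, internode] = float(np.mean(ratios))
    return out


def call_regulated(fold_table: pd.DataFrame, fold_min: float = 5.0) -> pd.Series:
    """Genes whose expression changes ``fold_min``-fold or more in some
    internode relative to the reference: max ratio >= fold_min calls 'up',
    min ratio <= 1/fold_min calls 'down' ('up+down' when both). Returns a
    direction Series indexed by the called genes."""
    if fold_min <= 1:
        raise ValueError("fold_min must exceed 1")
    mx = fold_table.max(axis=1)
    mn = fold_table.min(axis=1)
    up = mx >= fold_min
    down = mn <= 1.0 / fold_min
    direction = pd.Series(index=fold_table.index, dtype=object)
    direction[up & ~down] = "up"
    direction[down & ~up] = "down"
    direction[up & down] = "up+down"
    return direction.dropna()


def expressed_genes(table: QPCRTable, ct_ceiling: float = 35.0) -> list[str]:
    """Genes detected at all: mean Ct at or below the ceiling."""
    mean_ct = table.records.groupby("gene")["ct"].mean()
    return sorted(mean_ct.index[mean_ct <= ct_ceiling])


# ---------------------------------------------------------------------------
# Concordance with the expression-array result
# ---------------------------------------------------------------------------

def concord_with_chip(
    qpcr_hits,
    chip_presence: Mapping[str, bool],
    chip_de,
) -> dict[str, list[str]]:
    """Partition qPCR-regulated genes against the array outcome.

    Returns the exhaustive, disjoint partition: ``validated`` (on the chip
    and array-significant), ``chip_lt2fold`` (on the chip but the array saw
    <2-fold change), ``absent_from_chip`` (no probe set for the gene).
    """
    hits = list(qpcr_hits)
    chip_de = set(chip_de)
    uncovered = [g for g in hits if g not in chip_presence]
    if uncovered:
        raise ValueError(f"chip presence unknown for genes: {uncovered[:5]}")
    contradictory = [g for g in chip_de if g in chip_presence and not chip_presence[g]]
    if contradictory:
        raise ValueError(
            f"genes flagged array-significant but absent from chip: {contradictory[:5]}"
        )
    part: dict[str, list[str]] = {"validated": [], "chip_lt2fold": [], "absent_from_chip": []}
    for g in hits:
        if not chip_presence[g]:
            part["absent_from_chip"].append(g)
        elif g in chip_de:
            part["validated"].append(g)
        else:
            part["chip_lt2fold"].append(g)
    return part


def concordance_sizes(partition: dict[str, list[str]]) -> dict[str, int]:
    sizes = {k: len(v) for k, v in partition.items()}
    sizes["total"] = sum(len(v) for v in partition.values())
    return sizes
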