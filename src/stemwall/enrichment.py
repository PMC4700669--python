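"""Hypergeometric over-representation of TF families.

For a selection of n_sel TFs drawn from a TF universe of size N carrying K
members of a family, the family's enrichment p-value is the upper tail
P(X >= k) of the hypergeometric distribution — the chance of seeing at
least the observed occurrence under random selection. Families whose
universe membership is unknown ('Others') carry no p-value.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

UNCLASSIFIED = "Others"


def hypergeometric_tail(k: int, K: int, n_sel: int, N_tf: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N_tf, K, n_sel).

    Evaluated through the survival function's log form for stability with
    large universes and extreme tails.
    """
    for name, v in (("k", k), ("K", K), ("n_sel", n_sel), ("N_tf", N_tf)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N_tf or n_sel > N_tf:
        raise ValueError("family size and selection size cannot exceed the universe")
    if k > min(K, n_sel):
        raise ValueError(f"occurrence k={k} exceeds min(K={K}, n_sel={n_sel})")
    if k == 0:
        return 1.0
    dist = stats.hypergeom(N_tf, K, n_sel)
    log_terms = dist.logpmf(np.arange(k, min(K, n_sel) + 1))
    return float(min(1.0, np.exp(log_terms.max()) * np.exp(log_terms - log_terms.max()).sum()))


def family_enrichment(
    selected_tfs: Iterable[str],
    family_map: Mapping[str, str],
    tf_universe: Iterable[str],
) -> pd.DataFrame:
    """Per-family occurrence and enrichment p-value for a TF selection.

    One row per family present in the selection, sorted by occurrence
    descending then family name; the unclassified bucket carries no
    p-value. TFs absent from ``family_map`` fall into that bucket.
    """
    selected = list(dict.fromkeys(selected_tfs))
    universe = list(dict.fromkeys(tf_universe))
    outside = set(selected) - set(universe)
    if outside:
        raise ValueError(f"selection not contained in universe: {sorted(outside)[:5]}")

    fam_of = {t: family_map.get(t, UNCLASSIFIED) for t in universe}
    n_sel, n_univ = len(selected), len(universe)

    sel_counts: dict[str, int] = {}
    for t in selected:
        sel_counts[fam_of[t]] = sel_counts.get(fam_of[t], 0) + 1
    univ_counts: dict[str, int] = {}
    for t in universe:
        univ_counts[fam_of[t]] = univ_counts.get(fam_of[t], 0) + 1

    rows = []
    for fam, k in sel_counts.items():
        if fam == UNCLASSIFIED:
            p = np.nan
        else:
            p = hypergeometric_tail(k, univ_counts[fam], n_sel, n_univ)
        rows.append({"family": fam, "occurrence": k, "family_size": univ_counts[fam], "p_value": p})
    frame = pd.DataFrame(rows, columns=["family", "occurrence", "family_size", "p_value"])
    frame = frame.sort_values(
        ["occurrence", "family"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    frame["selection_size"] = n_sel
    frame["universe_size"] = n_univ
    return frame


def benjamini_hochberg_column(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Optional BH-adjusted column over the defined p-values (diagnostics)."""
    out = enrichment.copy()
    defined = out["p_value"].notna()
    out["q_value"] = np.nan
    if defined.any():
        out.loc[defined, "q_value"] = stats.false_discovery_control(
            out.loc[defined, "p_value"].to_numpy(), method="bh"
        )
    return out
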