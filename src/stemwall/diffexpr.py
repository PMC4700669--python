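"""Differential expression of older internodes against the IN2 reference.

The selection criterion is a Bonferroni-corrected p-value threshold of
alpha / n, with n the number of probe sets on the physical array, combined
with a >= 2-fold change on the linear intensity scale. The test statistic
is an associative-analysis-style t: per probe and contrast, the difference
of log2 replicate means is scaled by a background noise standard deviation
pooled from the low-variability (equally expressed) probe sets, rather than
by the probe's own two-sample variance — with three replicates per group a
per-probe variance estimate is far too unstable, while thousands of
background probes pin down the chip noise level precisely.

    t = (mean log2 IN_i - mean log2 IN2) / (s_bg * sqrt(1/r_i + 1/r_ref))

with s_bg^2 the pooled within-internode log2 variance over the background
set (probes in the lowest ``background_quantile`` of coefficient of
variation across stem chips) and df = |background set| - 1. Two-sided
p-values come from the t distribution.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from . import config
from .containers import ExpressionMatrix


def bonferroni_threshold(alpha: float, n_chip: int) -> float:
    """Family-wise p-value cutoff alpha / n_chip."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_chip < 1:
        raise ValueError("n_chip must be a positive integer")
    return alpha / n_chip


def fold_change(mean_i: float, mean_ref: float) -> tuple[float, str]:
    """Linear-scale fold-change magnitude (>= 1) and direction.

    Returns ``(max(a/b, b/a), 'up'|'down'|'flat')``.
    """
    if mean_i <= 0 or mean_ref <= 0:
        raise ValueError("means must be strictly positive")
    if mean_i > mean_ref:
        return mean_i / mean_ref, "up"
    if mean_i < mean_ref:
        return mean_ref / mean_i, "down"
    return 1.0, "flat"


@dataclasses.dataclass
class DEResult:
    """Per-probe, per-contrast differential-expression statistics.

    ``table`` has a (probe_id, contrast) MultiIndex with columns mean_ref,
    mean_i (linear), fold_change (>= 1), direction, p_value, significant.
    ``alpha``/``fc_min``/``n_chip`` record the criteria the significance
    flag encodes.
    """

    table: pd.DataFrame
    alpha: float
    fc_min: float
    n_chip: int

    @property
    def contrasts(self) -> list[str]:
        return list(dict.fromkeys(self.table.index.get_level_values("contrast")))

    def significant_probes(self) -> pd.Index:
        sig = self.table[self.table["significant"]]
        return sig.index.get_level_values("probe_id").unique()


def background_set(
    matrix: ExpressionMatrix, background_quantile: float = 0.25
) -> pd.Index:
    """Low-variability probes: the lowest quantile of coefficient of
    variation (sd/mean of linear intensities) across the stem chips."""
    if not 0 < background_quantile <= 1:
        raise ValueError("background_quantile must lie in (0, 1]")
    stem = matrix.values[matrix.stem_samples()]
    cv = stem.std(axis=1, ddof=1) / stem.mean(axis=1)
    cutoff = cv.quantile(background_quantile)
    return matrix.probe_ids[cv <= cutoff]


def _pooled_background_variance(
    log2_stem: pd.DataFrame, matrix: ExpressionMatrix, bg: pd.Index
) -> tuple[float, int]:
    """Pooled within-internode log2 variance over the background set."""
    ss, dof = 0.0, 0
    for internode in matrix.internodes():
        cols = matrix.samples_for_internode(internode)
        sub = log2_stem.loc[bg, cols].to_numpy()
        ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum()
        dof += sub.shape[0] * (len(cols) - 1)
    if dof == 0 or ss == 0:
        raise ValueError(
            "background set has zero pooled variance; cannot form the noise "
            "reference (all background probes identical across replicates?)"
        )
    return ss / dof, dof


def associative_de_test(
    matrix: ExpressionMatrix,
    ref: str = config.REFERENCE_INTERNODE,
    background_quantile: float = 0.25,
    alpha: float = 0.05,
    fc_min: float = 2.0,
) -> DEResult:
    """Test every probe in every older-internode contrast against ``ref``.

    Requires at least two replicates per internode. The significance flag
    combines p < alpha / n_chip with linear fold change >= fc_min.
    """
    internodes = matrix.internodes()
    if ref not in internodes:
        raise ValueError(f"reference internode {ref!r} not present")
    for internode in internodes:
        if len(matrix.samples_for_internode(internode)) < 2:
            raise ValueError(f"internode {internode} has fewer than 2 replicates")

    stem_cols = matrix.stem_samples()
    log2_stem = np.log2(matrix.values[stem_cols])
    bg = background_set(matrix, background_quantile)
    s2_bg, df = _pooled_background_variance(log2_stem, matrix, bg)
    s_bg = np.sqrt(s2_bg)

    ref_cols = matrix.samples_for_internode(ref)
    r_ref = len(ref_cols)
    log2_ref_mean = log2_stem[ref_cols].mean(axis=1)
    lin_ref_mean = matrix.values[ref_cols].mean(axis=1)
    p_threshold = bonferroni_threshold(alpha, matrix.n_chip)

    blocks = []
    for internode in internodes:
        if internode == ref:
            continue
        cols = matrix.samples_for_internode(internode)
        r_i = len(cols)
        delta = log2_stem[cols].mean(axis=1) - log2_ref_mean
        se = s_bg * np.sqrt(1.0 / r_i + 1.0 / r_ref)
        t = delta / se
        p = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.nextafter(0, 1), 1.0)

        lin_mean = matrix.values[cols].mean(axis=1)
        ratio = lin_mean / lin_ref_mean
        magnitude = np.maximum(ratio, 1.0 / ratio)
        direction = np.where(ratio > 1, "up", np.where(ratio < 1, "down", "flat"))

        block = pd.DataFrame(
            {
                "mean_ref": lin_ref_mean,
                "mean_i": lin_mean,
                "fold_change": magnitude,
                "direction": direction,
                "p_value": p,
                "significant": (p < p_threshold) & (magnitude >= fc_min),
            }
        )
        block.index = pd.MultiIndex.from_product(
            [block.index, [f"{internode}_vs_{ref}"]], names=["probe_id", "contrast"]
        )
        blocks.append(block)

    return DEResult(pd.concat(blocks).sort_index(), alpha, fc_min, matrix.n_chip)


def select_de_genes(
    de: DEResult,
    alpha: float | None = None,
    fc_min: float | None = None,
) -> pd.Index:
    """Probes significant in at least one contrast.

    Passing ``alpha``/``fc_min`` re-evaluates the criteria on the stored
    p-values and fold changes instead of using the cached flag."""
    if alpha is None and fc_min is None:
        return de.significant_probes()
    alpha = de.alpha if alpha is None else alpha
    fc_min = de.fc_min if fc_min is None else fc_min
    threshold = bonferroni_threshold(alpha, de.n_chip)
    mask = (de.table["p_value"] < threshold) & (de.table["fold_change"] >= fc_min)
    return de.table.index.get_level_values("probe_id")[mask].unique()


def benjamini_hochberg(p_values: pd.Series) -> pd.Series:
    """BH-adjusted q-values, emitted for diagnostics only."""
    return pd.Series(
        stats.false_discovery_control(p_values.to_numpy(), method="bh"),
        index=p_values.index,
        name="q_value",
    )
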