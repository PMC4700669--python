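"""Seeded synthetic data emulating the stem-maturation study design.

Generates, with full planted-truth bookkeeping:

* a stem expression matrix (5 internodes x 3 replicates at defaults) in
  which a configurable fraction of probe sets follows one of ten temporal
  archetypes relative to the youngest internode, with multiplicative
  log-normal noise, and the remainder is flat background;
* an 18-tissue atlas matrix in which a designated TF subset is elevated in
  the four secondary-wall-forming tissues (petiole, stem, root, pod);
* a 37-chip network matrix (stem chips + atlas chips) with planted
  co-expression structure: wall-pathway gene groups (11 lignin, 3 cellulose,
  4 hemicellulose probe sets at defaults) sharing latent profiles, and hub
  TFs co-regulated with the core monolignol genes;
* a qPCR Ct table with planted fold profiles, per-gene amplification
  efficiencies, and optional raw fluorescence curves.

All randomness flows through one integer seed per call; identical arguments
give byte-identical outputs.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import config
from .containers import ExpressionMatrix, StudyDesign, TruthLabels
from .qpcr import QPCRTable

LOG2E_BASELINE_RANGE = (6.0, 12.0)  # per-probe baseline, log2 intensity units


def _probe_ids(n: int) -> list[str]:
    return [f"Mtr.{i + 1:05d}.1.S1_at" for i in range(n)]


def _tf_count(n_probesets: int, tf_fraction: Optional[float]) -> int:
    if tf_fraction is None:
        tf_fraction = config.N_TF_PANEL / config.N_CHIP_FULL
    return max(2, int(round(tf_fraction * n_probesets)))


# ---------------------------------------------------------------------------
# Stem matrix
# ---------------------------------------------------------------------------

def generate_stem_matrix(
    n_probesets: int,
    design: Optional[StudyDesign] = None,
    archetype_fractions: Optional[Mapping[int, float]] = None,
    noise_sd_log2: float = 0.2,
    seed: int = 0,
    tf_fraction: Optional[float] = None,
    pathway_sizes: Optional[Mapping[str, int]] = None,
) -> tuple[ExpressionMatrix, TruthLabels]:
    """Stem-experiment matrix with planted temporal archetypes.

    Each planted probe set's per-internode replicate mean equals its
    baseline times the archetype's relative level; every chip measurement
    carries independent multiplicative log-normal noise (additive Gaussian
    of sd ``noise_sd_log2`` on the log2 scale). Background probe sets are
    flat. TF flags, TF families and wall-pathway memberships (planted among
    archetype-10 genes, the maturation-peak shape) are recorded in the
    returned truth labels.
    """
    if n_probesets < 50:
        raise ValueError("n_probesets must be at least 50")
    if noise_sd_log2 < 0:
        raise ValueError("noise_sd_log2 must be non-negative")
    design = design or StudyDesign()
    fractions = dict(archetype_fractions or config.DEFAULT_ARCHETYPE_FRACTIONS)
    config.validate_fractions(fractions)
    sizes = dict(pathway_sizes or config.PATHWAY_SIZES)

    rng = np.random.default_rng(seed)
    probes = _probe_ids(n_probesets)
    stem_design = design.stem_design()

    truth = _plant_truth(rng, probes, fractions, tf_fraction, sizes)
    values = _stem_values(rng, truth, design, stem_design, noise_sd_log2)
    matrix = ExpressionMatrix(values, stem_design, n_chip=config.N_CHIP_FULL)
    return matrix, truth


def _plant_truth(
    rng: np.random.Generator,
    probes: list[str],
    fractions: Mapping[int, float],
    tf_fraction: Optional[float],
    pathway_sizes: Mapping[str, int],
) -> TruthLabels:
    n = len(probes)
    archetype = pd.array([pd.NA] * n, dtype="Int64")
    order = rng.permutation(n)
    pos = 0
    for label in sorted(fractions):
        count = int(round(fractions[label] * n))
        archetype[order[pos : pos + count]] = label
        pos += count

    n_tf = _tf_count(n, tf_fraction)
    is_tf = np.zeros(n, dtype=bool)
    # Bias TFs toward planted archetypes so wall clusters contain TFs.
    tf_order = rng.permutation(n)
    planted_first = np.concatenate(
        [tf_order[~pd.isna(archetype[tf_order])], tf_order[pd.isna(archetype[tf_order])]]
    )
    is_tf[planted_first[:n_tf]] = True

    families = np.array(list(config.TF_FAMILY_PROBS))
    probs = np.array(list(config.TF_FAMILY_PROBS.values()))
    probs = probs / probs.sum()
    tf_family = pd.array([pd.NA] * n, dtype="string")
    tf_family[is_tf] = rng.choice(families, size=int(is_tf.sum()), p=probs)

    # Wall-pathway genes: non-TF archetype-10 probe sets.
    pathway = pd.array([pd.NA] * n, dtype="string")
    candidates = np.flatnonzero((archetype == 10).to_numpy(dtype=bool, na_value=False) & ~is_tf)
    candidates = rng.permutation(candidates)
    pos = 0
    for name in ("lignin", "cellulose", "hemicellulose"):
        want = int(pathway_sizes.get(name, 0))
        take = min(want, len(candidates) - pos)
        pathway[candidates[pos : pos + take]] = name
        pos += take

    table = pd.DataFrame(
        {
            "archetype": archetype,
            "is_tf": is_tf,
            "tf_family": tf_family,
            "pathway": pathway,
            "is_hub": np.zeros(n, dtype=bool),
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return TruthLabels(table)


def _stem_values(
    rng: np.random.Generator,
    truth: TruthLabels,
    design: StudyDesign,
    stem_design: pd.DataFrame,
    noise_sd_log2: float,
) -> pd.DataFrame:
    n = len(truth.probes)
    baseline = rng.uniform(*LOG2E_BASELINE_RANGE, size=n)
    arch = truth.table["archetype"]
    rel = np.ones((n, len(design.internodes)))
    for label, vec in config.ARCHETYPES.items():
        mask = (arch == label).to_numpy(dtype=bool, na_value=False)
        rel[mask] = vec

    sample_ids = list(stem_design.index)
    internode_pos = {io: k for k, io in enumerate(design.internodes)}
    cols = np.array([internode_pos[stem_design.loc[s, "internode"]] for s in sample_ids])
    means = (2.0**baseline)[:, None] * rel[:, cols]
    noise = rng.normal(0.0, noise_sd_log2, size=means.shape) if noise_sd_log2 > 0 else 0.0
    values = means * 2.0**noise
    return pd.DataFrame(values, index=truth.probes, columns=sample_ids)


# ---------------------------------------------------------------------------
# Atlas matrix (18 tissues)
# ---------------------------------------------------------------------------

def generate_atlas_matrix(
    tf_probes: Sequence[str],
    design: Optional[StudyDesign] = None,
    wall_tissue_fold: float = 8.0,
    wall_specific: Optional[Sequence[str]] = None,
    noise_sd_log2: float = 0.2,
    seed: int = 0,
) -> ExpressionMatrix:
    """Per-tissue TF expression across the 18-tissue atlas.

    Probes named in ``wall_specific`` are elevated ``wall_tissue_fold``-fold
    in the wall-forming tissues (petiole, stem, root, pod); everything else
    is flat in expectation. ``wall_tissue_fold = 1`` is the null case."""
    if wall_tissue_fold < 1:
        raise ValueError("wall_tissue_fold must be at least 1")
    design = design or StudyDesign()
    missing = config.WALL_TISSUES - set(design.atlas_tissues)
    if missing:
        raise ValueError(f"atlas tissue panel missing wall tissues: {sorted(missing)}")
    probes = list(tf_probes)
    wall_specific = set(wall_specific or [])
    unknown = wall_specific - set(probes)
    if unknown:
        raise ValueError(f"wall_specific probes not in tf_probes: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(seed)
    tissues = list(design.atlas_tissues)
    baseline = rng.uniform(*LOG2E_BASELINE_RANGE, size=len(probes))
    wall_mask = np.array([p in wall_specific for p in probes])
    tissue_wall = np.array([t in config.WALL_TISSUES for t in tissues])

    log2_fold = np.log2(wall_tissue_fold)
    shift = np.where(wall_mask[:, None] & tissue_wall[None, :], log2_fold, 0.0)
    noise = rng.normal(0.0, noise_sd_log2, size=(len(probes), len(tissues))) if noise_sd_log2 > 0 else 0.0
    values = 2.0 ** (baseline[:, None] + shift + noise)

    frame = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=tissues)
    atlas_design = pd.DataFrame(
        {
            "internode": pd.NA,
            "replicate": 1,
            "tissue": tissues,
            "is_stem": False,
        },
        index=pd.Index(tissues, name="sample_id"),
    )
    return ExpressionMatrix(frame, atlas_design, n_chip=config.N_CHIP_FULL)


# ---------------------------------------------------------------------------
# 37-chip network matrix
# ---------------------------------------------------------------------------

def generate_network_matrix(
    stem: ExpressionMatrix,
    truth: TruthLabels,
    design: Optional[StudyDesign] = None,
    seed: int = 0,
    atlas_sd_log2: float = 1.0,
    noise_sd_log2: float = 0.2,
    n_hub_tfs: int = 3,
    n_core_lignin: int = 5,
    group_rho: float = 0.95,
) -> tuple[ExpressionMatrix, TruthLabels]:
    """Extend a stem matrix with atlas chips and plant co-expression truth.

    The atlas extension gives every probe set an independent per-tissue
    effect of sd ``atlas_sd_log2`` (log2) plus chip noise, emulating
    tissue-to-tissue variation. Co-regulated groups share their tissue
    effects: the ``n_core_lignin`` core monolignol genes and ``n_hub_tfs``
    hub TFs follow one latent profile with intra-group correlation
    ``group_rho`` (log2 scale), so hubs connect to the core lignin genes in
    the thresholded network; cellulose and hemicellulose genes form their
    own groups; the remaining lignin genes track the core latent only
    weakly. Returns the 37-chip matrix and truth labels with ``is_hub`` set.
    """
    if not 0 < group_rho < 1:
        raise ValueError("group_rho must lie in (0, 1)")
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    atlas_design = design.atlas_design()
    tissues = list(design.atlas_tissues)
    n = len(truth.probes)

    baseline = np.log2(stem.internode_means()[design.reference_internode].to_numpy())

    # Independent per-gene tissue effects.
    tissue_eff = rng.normal(0.0, atlas_sd_log2, size=(n, len(tissues)))

    table = truth.table.copy()
    lignin_idx = np.flatnonzero((table["pathway"] == "lignin").to_numpy(dtype=bool, na_value=False))
    cellulose_idx = np.flatnonzero((table["pathway"] == "cellulose").to_numpy(dtype=bool, na_value=False))
    hemi_idx = np.flatnonzero((table["pathway"] == "hemicellulose").to_numpy(dtype=bool, na_value=False))
    core_lignin = lignin_idx[: min(n_core_lignin, len(lignin_idx))]
    other_lignin = lignin_idx[len(core_lignin):]

    # Hub TFs: archetype-10 TFs (stem shape already matches the lignin genes).
    tf10 = np.flatnonzero(
        table["is_tf"].to_numpy() & (table["archetype"] == 10).to_numpy(dtype=bool, na_value=False)
    )
    hubs = rng.permutation(tf10)[: min(n_hub_tfs, len(tf10))]
    table.loc[table.index[hubs], "is_hub"] = True

    a = np.sqrt(group_rho)
    b = np.sqrt(1.0 - group_rho)
    latents = {
        "lignin": rng.normal(0.0, atlas_sd_log2, size=len(tissues)),
        "cellulose": rng.normal(0.0, atlas_sd_log2, size=len(tissues)),
        "hemicellulose": rng.normal(0.0, atlas_sd_log2, size=len(tissues)),
    }
    for idx, key in (
        (np.concatenate([core_lignin, hubs]), "lignin"),
        (cellulose_idx, "cellulose"),
        (hemi_idx, "hemicellulose"),
    ):
        for g in idx:
            tissue_eff[g] = a * latents[key] + b * rng.normal(
                0.0, atlas_sd_log2, size=len(tissues)
            )
    # Non-core lignin genes track the core latent weakly (shared pathway,
    # different regulation): correlation ~0.25 with the core group.
    for g in other_lignin:
        tissue_eff[g] = 0.5 * latents["lignin"] + np.sqrt(0.75) * rng.normal(
            0.0, atlas_sd_log2, size=len(tissues)
        )

    tissue_pos = {t: j for j, t in enumerate(tissues)}
    chip_cols = np.array([tissue_pos[atlas_design.loc[s, "tissue"]] for s in atlas_design.index])
    log2_atlas = baseline[:, None] + tissue_eff[:, chip_cols]
    if noise_sd_log2 > 0:
        log2_atlas = log2_atlas + rng.normal(0.0, noise_sd_log2, size=log2_atlas.shape)
    atlas_values = pd.DataFrame(
        2.0**log2_atlas, index=truth.probes, columns=list(atlas_design.index)
    )

    values = pd.concat([stem.values, atlas_values], axis=1)
    full_design = pd.concat([stem.design.loc[stem.values.columns], atlas_design])
    matrix = ExpressionMatrix(values, full_design, n_chip=stem.n_chip)
    return matrix, TruthLabels(table)


def correlated_block(
    rng: np.random.Generator,
    n_rows: int,
    n_cols: int,
    rho: float,
    sd_log2: float = 1.0,
    baseline_log2: float = 9.0,
) -> np.ndarray:
    """Linear-scale rows with planted pairwise log2-correlation ``rho``."""
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    z = rng.normal(0.0, 1.0, size=n_cols)
    e = rng.normal(0.0, 1.0, size=(n_rows, n_cols))
    log2 = baseline_log2 + sd_log2 * (np.sqrt(rho) * z + np.sqrt(1 - rho) * e)
    return 2.0**log2


# ---------------------------------------------------------------------------
# qPCR table
# ---------------------------------------------------------------------------

def generate_qpcr_table(
    n_tfs: int = 1045,
    design: Optional[StudyDesign] = None,
    fold_profile: Optional[pd.DataFrame] = None,
    efficiencies: Optional[pd.Series] = None,
    seed: int = 0,
    ct_noise_sd: float = 0.15,
    tech_reps: int = 2,
    reference_gene: str = "Ubiquitin",
    frac_regulated: float = 64 / 1045,
    frac_not_expressed: float = 129 / 1045,
    regulated_fold: float = 8.0,
    with_curves: bool = False,
    n_cycles: int = 40,
) -> tuple[QPCRTable, pd.DataFrame]:
    """Ct table for ``n_tfs`` TF genes plus one reference gene.

    Planted truth: ``frac_regulated`` of the TFs rise monotonically to
    ``regulated_fold`` at the oldest internode; ``frac_not_expressed``
    amplify only near the Ct ceiling; the rest are flat. Ct values follow
    Ct = base - log_E(fold) + noise, so relative quantification recovers
    the planted folds. Returns the table and the planted gene x internode
    fold profile (reference gene included, all ones).
    """
    if n_tfs < 1:
        raise ValueError("n_tfs must be positive")
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    genes = [f"TF{i + 1:04d}" for i in range(n_tfs)]
    internodes = list(design.internodes)
    n_in = len(internodes)

    if fold_profile is None:
        fold_profile = pd.DataFrame(
            1.0, index=pd.Index(genes, name="gene"), columns=internodes
        )
        n_reg = int(round(frac_regulated * n_tfs))
        ramp = np.geomspace(1.0, regulated_fold, n_in)
        order = rng.permutation(n_tfs)
        for g in order[:n_reg]:
            fold_profile.iloc[g] = ramp
    else:
        fold_profile = fold_profile.copy()
        genes = list(fold_profile.index)
        n_tfs = len(genes)

    if efficiencies is None:
        efficiencies = pd.Series(
            rng.uniform(1.8, 2.0, size=n_tfs), index=genes
        )
    else:
        efficiencies = efficiencies.copy()
    bad = efficiencies[(efficiencies <= 1.0) | (efficiencies > 2.0)]
    if len(bad):
        raise ValueError(f"planted efficiencies must lie in (1, 2]: {bad.to_dict()}")
    if reference_gene in genes:
        raise ValueError("reference gene name collides with a TF gene id")
    efficiencies = pd.concat([efficiencies, pd.Series({reference_gene: 1.9})])

    n_silent = int(round(frac_not_expressed * n_tfs))
    silent = list(np.array(genes)[np.sort(rng.permutation(n_tfs)[:n_silent])])
    base_ct = pd.Series(rng.uniform(18.0, 30.0, size=n_tfs), index=genes)
    base_ct[silent] = rng.uniform(36.0, 39.0, size=len(silent))
    base_ct[reference_gene] = 20.0

    full_profile = fold_profile.copy()
    full_profile.loc[reference_gene] = 1.0

    # Sample-level Ct shifts (RNA input / RT variation) are shared by every
    # gene measured in the same biological sample; the reference gene exists
    # to cancel exactly this component. Per-well noise is smaller.
    sample_shift = {
        (internode, rep): rng.normal(0.0, ct_noise_sd)
        for internode in internodes
        for rep in range(1, design.replicates_per_internode + 1)
    }
    records = []
    for gene in list(genes) + [reference_gene]:
        eg = float(efficiencies[gene])
        for internode in internodes:
            fold = float(full_profile.loc[gene, internode])
            mean_ct = base_ct[gene] - np.log(fold) / np.log(eg)
            for rep in range(1, design.replicates_per_internode + 1):
                shift = sample_shift[(internode, rep)]
                for tech in range(1, tech_reps + 1):
                    ct = mean_ct + shift + rng.normal(0.0, ct_noise_sd / 3)
                    records.append(
                        {
                            "gene": gene,
                            "internode": internode,
                            "replicate": rep,
                            "tech_rep": tech,
                            "ct": max(ct, 1.0),
                        }
                    )
    frame = pd.DataFrame.from_records(records)

    curves = None
    if with_curves:
        curves = {
            gene: amplification_curve(
                float(efficiencies[gene]), rng, n_cycles=n_cycles
            )
            for gene in list(genes) + [reference_gene]
        }

    table = QPCRTable(frame, efficiencies, reference_gene, curves)
    return table, full_profile


def amplification_curve(
    efficiency: float,
    rng: np.random.Generator,
    n_cycles: int = 40,
    f0: float = 1e-6,
    plateau: float = 1.0,
    noise_frac: float = 0.01,
) -> np.ndarray:
    """Logistic-saturating qPCR fluorescence curve with exponential phase at
    the stated efficiency and multiplicative read noise."""
    if not 1.0 < efficiency <= 2.2:
        raise ValueError("efficiency must lie in (1, 2.2]")
    c = np.arange(n_cycles, dtype=float)
    raw = f0 * efficiency**c
    f = plateau * raw / (plateau + raw)
    return f * (1.0 + rng.normal(0.0, noise_frac, size=n_cycles))
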