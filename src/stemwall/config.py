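"""Pipeline-wide constants and configuration.

Defaults follow the study design the pipeline targets: five stem internodes
(IN2 youngest .. IN9 oldest) sampled in three biological replicates on a
61,281-probe-set expression array, with an 18-tissue expression atlas
extending the stem chips to 37 chips for network inference.

The ten temporal archetypes are synthetic constants describing the canonical
relative-to-IN2 expression shapes the clustering stage labels: archetype 1
decays from a young-internode maximum, archetypes 5/8/10 peak mid-maturation
(internode 5) when secondary-wall deposition is most active, archetype 9
rises monotonically into senescence, and the remainder fluctuate without a
maturation trend. They parameterize the simulator and anchor cluster labels;
they are not measured values.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Study design constants
# ---------------------------------------------------------------------------

INTERNODES: tuple[str, ...] = ("IN2", "IN3", "IN5", "IN7", "IN9")
REFERENCE_INTERNODE: str = "IN2"
REPLICATES_PER_INTERNODE: int = 3

#: Number of probe sets on the full expression array (Bonferroni divisor).
N_CHIP_FULL: int = 61_281

#: Probe sets surviving the network-stage variability/prefix filter at full
#: scale; used as the default simulation size.
N_NETWORK_DEFAULT: int = 12_576

#: TF probe sets on the full array.
N_TF_PANEL: int = 1_394

#: Atlas tissue panel (18 tissues). Wall-forming tissues that accumulate
#: secondary cell walls are petiole, stem, root and pod.
ATLAS_TISSUES: tuple[str, ...] = (
    "leaf", "petiole", "stem", "shoot", "vegetative_bud", "flower",
    "pod", "seed_10dap", "seed_20dap", "seed_36dap", "root", "root_tip",
    "nodule", "cotyledon", "hypocotyl", "radicle", "stipule", "tendril",
)
WALL_TISSUES: frozenset[str] = frozenset({"petiole", "stem", "root", "pod"})

#: Tissues carrying a second atlas chip so that 15 stem chips + 22 atlas
#: chips = 37 chips total at the default scale.
ATLAS_EXTRA_CHIP_TISSUES: tuple[str, ...] = ("leaf", "stem", "root", "flower")

#: Total chip count for the co-expression stage at defaults.
N_NETWORK_CHIPS: int = 37

# ---------------------------------------------------------------------------
# Temporal archetypes (linear scale, relative to IN2 = 1)
# ---------------------------------------------------------------------------

ARCHETYPES: dict[int, np.ndarray] = {
    1: np.array([1.0, 0.6, 0.3, 0.3, 0.3]),    # early max, decays
    2: np.array([1.0, 1.5, 0.7, 2.5, 0.8]),    # fluctuating
    3: np.array([1.0, 0.4, 1.6, 0.6, 1.4]),    # fluctuating
    4: np.array([1.0, 2.5, 1.2, 0.5, 1.1]),    # fluctuating
    5: np.array([1.0, 2.0, 4.0, 1.5, 1.0]),    # early rise, IN5 peak, sharp drop
    6: np.array([1.0, 0.7, 1.3, 2.5, 0.6]),    # fluctuating
    7: np.array([1.0, 0.4, 1.0, 1.2, 1.0]),    # IN3 dip
    8: np.array([1.0, 2.5, 3.5, 2.5, 2.0]),    # early rise, IN5 peak, plateau
    9: np.array([1.0, 1.2, 1.6, 2.4, 4.0]),    # monotonic rise to IN9
    10: np.array([1.0, 1.3, 4.0, 2.0, 2.0]),   # IN5 peak, moderate decline
}

#: Clusters whose temporal shape tracks secondary-wall deposition.
WALL_CLUSTERS: frozenset[int] = frozenset({5, 8, 10})

#: Fraction of simulated probe sets planted in each archetype (remainder are
#: flat background). Mass concentrates in archetypes 1 and 10, the dominant
#: down- and up-regulated maturation responses.
DEFAULT_ARCHETYPE_FRACTIONS: dict[int, float] = {
    1: 0.10, 2: 0.02, 3: 0.02, 4: 0.02, 5: 0.03,
    6: 0.02, 7: 0.02, 8: 0.03, 9: 0.03, 10: 0.10,
}

#: TF family label frequencies used when planting annotation.
TF_FAMILY_PROBS: dict[str, float] = {
    "MYB": 0.14, "AP2/EREBP": 0.10, "bHLH": 0.09, "b-ZIP": 0.08,
    "NAC": 0.07, "WRKY": 0.07, "C2H2 (ZF)": 0.07, "HB": 0.06,
    "MADS": 0.04, "HSF": 0.03, "GRAS": 0.03, "C3H (ZF)": 0.03,
    "AUX/IAA": 0.03, "CCAAT-binding": 0.02, "ARF": 0.02,
    "Others": 0.12,
}

#: Pathway gene-set sizes (probe sets per wall-biosynthesis pathway).
PATHWAY_SIZES: dict[str, int] = {"lignin": 11, "cellulose": 3, "hemicellulose": 4}

#: Affymetrix control-probe prefixes removed before network construction.
CONTROL_PREFIXES: tuple[str, ...] = ("AFFX", "Sme", "RPTR")

# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters with their study defaults.

    ``profile`` selects the simulation scale: ``"default"`` runs the
    full post-filter size (12,576 probe sets, 37 chips), ``"tiny"`` a
    500-probe-set version for quick runs.
    """

    profile: str = "default"
    seed: int = 0

    # synthetic scale
    n_probesets: int = N_NETWORK_DEFAULT
    n_qpcr_tfs: int = 1_045
    noise_sd_log2: float = 0.2

    # differential expression
    alpha: float = 0.05
    fc_min: float = 2.0
    n_chip: int = N_CHIP_FULL
    background_quantile: float = 0.25

    # clustering
    k: int = 10
    linkage: str = "average"
    wall_clusters: tuple[int, ...] = (5, 8, 10)
    ratio_min: float = 2.0

    # network
    min_fold: float = 2.0
    prefixes: tuple[str, ...] = CONTROL_PREFIXES
    bin_width: float = 0.1
    permutation_replicates: int = 1

    # qPCR
    fold_min: float = 5.0
    reference_internode: str = REFERENCE_INTERNODE
    ct_ceiling: float = 35.0

    @classmethod
    def from_profile(cls, profile: str, seed: int = 0, **overrides) -> "PipelineConfig":
        if profile == "tiny":
            base = dict(profile="tiny", n_probesets=500, n_qpcr_tfs=60)
        elif profile == "default":
            base = dict(profile="default")
        else:
            raise ValueError(f"unknown profile {profile!r} (expected 'tiny' or 'default')")
        base.update(overrides)
        return cls(seed=seed, **base)


def fan_out_seeds(master_seed: int, n: int) -> list[int]:
    """Derive independent per-stage seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def archetype_matrix() -> np.ndarray:
    """The 10 archetype vectors stacked in label order, shape (10, 5)."""
    return np.vstack([ARCHETYPES[i] for i in range(1, 11)])


def validate_fractions(fractions: dict[int, float]) -> None:
    if any(f < 0 for f in fractions.values()):
        raise ValueError("archetype fractions must be non-negative")
    if sum(fractions.values()) > 1.0 + 1e-12:
        raise ValueError("archetype fractions must sum to at most 1")
    unknown = set(fractions) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetype indices: {sorted(unknown)}")
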