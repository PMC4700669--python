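"""Shared data containers: study design, expression matrices, truth labels."""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import config


@dataclasses.dataclass(frozen=True)
class StudyDesign:
    """The sampling layout: stem internode series plus the tissue atlas.

    At defaults this is 5 internodes x 3 replicates = 15 stem chips and
    22 atlas chips (18 tissues, four of them with a second chip), giving the
    37 chips the co-expression stage uses.
    """

    internodes: tuple[str, ...] = config.INTERNODES
    replicates_per_internode: int = config.REPLICATES_PER_INTERNODE
    atlas_tissues: tuple[str, ...] = config.ATLAS_TISSUES
    atlas_extra_chip_tissues: tuple[str, ...] = config.ATLAS_EXTRA_CHIP_TISSUES
    reference_internode: str = config.REFERENCE_INTERNODE

    def __post_init__(self) -> None:
        if self.reference_internode not in self.internodes:
            raise ValueError(
                f"reference internode {self.reference_internode!r} missing from internodes"
            )
        if self.replicates_per_internode < 1:
            raise ValueError("replicates_per_internode must be positive")
        missing = set(self.atlas_extra_chip_tissues) - set(self.atlas_tissues)
        if missing:
            raise ValueError(f"extra-chip tissues not in atlas panel: {sorted(missing)}")

    @property
    def n_stem_chips(self) -> int:
        return len(self.internodes) * self.replicates_per_internode

    @property
    def n_atlas_chips(self) -> int:
        return len(self.atlas_tissues) + len(self.atlas_extra_chip_tissues)

    @property
    def n_network_chips(self) -> int:
        return self.n_stem_chips + self.n_atlas_chips

    def stem_design(self) -> pd.DataFrame:
        """Per-chip design table for the stem experiment."""
        rows = [
            {
                "sample_id": f"{internode}_r{rep}",
                "internode": internode,
                "replicate": rep,
                "tissue": "stem",
                "is_stem": True,
            }
            for internode in self.internodes
            for rep in range(1, self.replicates_per_internode + 1)
        ]
        return pd.DataFrame(rows).set_index("sample_id")

    def atlas_design(self) -> pd.DataFrame:
        """Per-chip design table for the atlas extension chips."""
        tissues = list(self.atlas_tissues) + list(self.atlas_extra_chip_tissues)
        counts: dict[str, int] = {}
        rows = []
        for tissue in tissues:
            counts[tissue] = counts.get(tissue, 0) + 1
            rows.append(
                {
                    "sample_id": f"atlas_{tissue}_c{counts[tissue]}",
                    "internode": pd.NA,
                    "replicate": counts[tissue],
                    "tissue": tissue,
                    "is_stem": False,
                }
            )
        return pd.DataFrame(rows).set_index("sample_id")

    def network_design(self) -> pd.DataFrame:
        return pd.concat([self.stem_design(), self.atlas_design()])


@dataclasses.dataclass
class ExpressionMatrix:
    """Probe set x sample intensity matrix with per-sample design metadata.

    ``values`` holds strictly positive linear-scale intensities (probe sets
    as rows, chips as columns); ``design`` is indexed by sample id with
    columns internode / replicate / tissue / is_stem. ``n_chip`` is the
    probe-set count of the physical array, the Bonferroni divisor, which may
    exceed the number of rows actually carried (a filtered matrix remembers
    the chip it came from).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    n_chip: int = config.N_CHIP_FULL

    def __post_init__(self) -> None:
        if self.n_chip < 1:
            raise ValueError("n_chip must be a positive integer")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression matrix contains missing or non-finite values")
        if (vals <= 0).any():
            raise ValueError("expression values must be strictly positive (linear scale)")
        unmapped = [s for s in self.values.columns if s not in self.design.index]
        if unmapped:
            raise ValueError(f"samples missing from design table: {unmapped}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def stem_samples(self) -> list[str]:
        flags = self.design.loc[self.values.columns, "is_stem"]
        return [s for s, f in flags.items() if bool(f)]

    def samples_for_internode(self, internode: str) -> list[str]:
        sub = self.design.loc[self.values.columns]
        mask = sub["is_stem"].astype(bool) & (sub["internode"] == internode)
        return list(sub.index[mask])

    def internodes(self) -> list[str]:
        sub = self.design.loc[self.stem_samples()]
        seen: list[str] = []
        for internode in sub["internode"]:
            if internode not in seen:
                seen.append(internode)
        return seen

    def subset(self, probes: Iterable[str]) -> "ExpressionMatrix":
        probes = list(probes)
        missing = [p for p in probes if p not in self.values.index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[probes], self.design, self.n_chip)

    def internode_means(self) -> pd.DataFrame:
        """Replicate means per internode (linear scale), columns in design order."""
        cols = {}
        for internode in self.internodes():
            cols[internode] = self.values[self.samples_for_internode(internode)].mean(axis=1)
        return pd.DataFrame(cols)


@dataclasses.dataclass
class TruthLabels:
    """Planted ground truth for synthetic matrices.

    ``table`` is indexed by probe id with columns: ``archetype`` (nullable
    integer 1..10), ``is_tf`` (bool), ``tf_family`` (string or NA),
    ``pathway`` (lignin / cellulose / hemicellulose or NA), ``is_hub``
    (bool; TF planted co-regulated with the core monolignol genes).
    """

    table: pd.DataFrame

    REQUIRED = ("archetype", "is_tf", "tf_family", "pathway", "is_hub")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"truth table missing columns: {missing}")

    @property
    def probes(self) -> pd.Index:
        return self.table.index

    def de_probes(self) -> pd.Index:
        return self.table.index[self.table["archetype"].notna()]

    def archetype_of(self) -> pd.Series:
        return self.table["archetype"]

    def tf_probes(self) -> pd.Index:
        return self.table.index[self.table["is_tf"].astype(bool)]

    def pathway_probes(self, pathway: Optional[str] = None) -> pd.Index:
        col = self.table["pathway"]
        mask = col.notna() if pathway is None else (col == pathway)
        return self.table.index[mask]

    def hub_probes(self) -> pd.Index:
        return self.table.index[self.table["is_hub"].astype(bool)]
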