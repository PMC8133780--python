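"""Core in-memory containers for metabolite intensity data.

An :class:`IntensityTable` is a metabolite × sample matrix of peak
intensities together with per-sample metadata.  Missing values (peaks not
detected in a sample) are stored as NaN; the matrix carries an explicit
scale flag because every statistical operation downstream assumes
log-transformed intensities while instrument exports are linear.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SCALES = ("linear", "log10", "log2")

#: metadata columns recognised by the pipeline; only ``group`` is mandatory
SAMPLE_COLUMNS = ("group", "tissue", "age", "run_order", "batch")


@dataclass
class IntensityTable:
    """Metabolite × sample intensity matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by metabolite id, one column per sample id.
        NaN encodes a missing (undetected) entry.
    samples
        DataFrame indexed by sample id.  Must contain a non-empty
        ``group`` column (species or genotype); ``tissue``, ``age``,
        ``run_order`` and ``batch`` are optional.
    scale
        One of ``"linear"``, ``"log10"``, ``"log2"``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if "group" not in self.samples.columns:
            raise ValueError("sample metadata must contain a 'group' column")
        if list(self.values.columns) != list(self.samples.index):
            # allow same set in different order: realign metadata to matrix
            if set(self.values.columns) != set(self.samples.index):
                raise ValueError("sample ids in values and metadata disagree")
            self.samples = self.samples.loc[self.values.columns]
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate metabolite ids")
        if (self.samples["group"].astype(str).str.len() == 0).any():
            raise ValueError("empty group label")
        self.values = self.values.astype(float)
        # canonical axis names so tables compare equal across construction paths
        self.values.index.name = None
        self.values.columns.name = None

    # -- basic views -------------------------------------------------------

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean metabolite × sample mask, True where the value is missing."""
        return self.values.isna()

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_samples(self, group: str) -> list[str]:
        """Sample ids belonging to a metadata group label."""
        ids = self.samples.index[self.samples["group"] == group]
        if len(ids) == 0:
            raise KeyError(f"no samples in group {group!r}")
        return list(ids)

    # -- subsetting (always returns a new table) ---------------------------

    def subset_samples(self, sample_ids) -> "IntensityTable":
        sample_ids = list(sample_ids)
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)}")
        return replace(
            self,
            values=self.values[sample_ids].copy(),
            samples=self.samples.loc[sample_ids].copy(),
        )

    def drop_samples(self, sample_ids) -> "IntensityTable":
        keep = [s for s in self.values.columns if s not in set(sample_ids)]
        return self.subset_samples(keep)

    def subset_metabolites(self, metabolite_ids) -> "IntensityTable":
        metabolite_ids = list(metabolite_ids)
        missing = set(metabolite_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"unknown metabolite ids: {sorted(missing)}")
        return replace(self, values=self.values.loc[metabolite_ids].copy(),
                       samples=self.samples.copy())

    def drop_metabolites(self, metabolite_ids) -> "IntensityTable":
        keep = [m for m in self.values.index if m not in set(metabolite_ids)]
        return self.subset_metabolites(keep)

    def split_by(self, column: str) -> dict[str, "IntensityTable"]:
        """Partition samples by a metadata column (e.g. tissue)."""
        if column not in self.samples.columns:
            raise KeyError(f"no metadata column {column!r}")
        out = {}
        for label, meta in self.samples.groupby(column, sort=True):
            out[str(label)] = self.subset_samples(list(meta.index))
        return out


@dataclass
class PathwayMap:
    """Metabolite → pathway membership plus the purine-biosynthesis flag.

    ``purine_flag`` is the curated (restrictive) set of de novo purine
    biosynthesis metabolites used by the purine-versus-rest tests; it is
    data supplied with the map, not derived from pathway names.
    """

    membership: dict[str, set]
    pathway_names: dict[str, str] = field(default_factory=dict)
    purine_flag: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.membership = {m: set(p) for m, p in self.membership.items()}
        self.purine_flag = set(self.purine_flag)
        stray = self.purine_flag - set(self.membership)
        if stray:
            raise ValueError(
                f"purine-flagged metabolites absent from membership: {sorted(stray)}"
            )

    @property
    def pathway_ids(self) -> list[str]:
        out = set()
        for pws in self.membership.values():
            out |= pws
        return sorted(out)

    def metabolites_in(self, pathway_id: str) -> set:
        return {m for m, pws in self.membership.items() if pathway_id in pws}

    def annotated(self) -> set:
        """All metabolites carrying at least one pathway annotation."""
        return {m for m, pws in self.membership.items() if pws}
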