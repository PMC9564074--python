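"""In-memory containers for count tables and aligned multi-omics blocks.

A :class:`CountTable` is the basic object of the package: an integer
``samples x taxa`` matrix of genus-level amplicon read counts together with a
group label per sample (e.g. control / hypertensive / treated).  An
:class:`OmicsBlock` holds a continuous ``samples x features`` matrix for one
data modality (pathway abundances, bone phenotypes, blood pressure) and is
aligned to count tables by sample ID.

Both containers wrap :class:`pandas.DataFrame` objects and round-trip through
plain TSV files so that pipelines stay inspectable with standard shell tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["CountTable", "OmicsBlock", "GutnetError"]


class GutnetError(ValueError):
    """Base class for validation and configuration errors raised by gutnet."""


@dataclass
class CountTable:
    """Integer sample x taxon count matrix with per-sample group labels.

    Parameters
    ----------
    counts
        DataFrame indexed by sample ID with one column per taxon.  Values
        must be non-negative integers.
    groups
        Series indexed identically to ``counts`` mapping sample ID to its
        experimental group label.
    """

    counts: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(counts)
            self.counts = counts
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.number) or np.any(arr < 0)):
            raise GutnetError("counts must be non-negative numbers")
        if arr.size and np.any(arr != np.round(arr)):
            raise GutnetError("counts must be integers")
        groups = pd.Series(self.groups)
        if not groups.index.equals(counts.index):
            try:
                groups = groups.loc[counts.index]
            except KeyError as exc:
                raise GutnetError(
                    "groups must be provided for every sample in the count table"
                ) from exc
        self.groups = groups

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_names(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    @property
    def group_names(self) -> list[str]:
        # insertion order of first appearance, not lexicographic
        return list(dict.fromkeys(self.groups))

    def subset(self, group: str) -> "CountTable":
        """Return the sub-table of samples belonging to ``group``."""
        mask = self.groups == group
        if not mask.any():
            raise GutnetError(f"unknown group label: {group!r}")
        return CountTable(self.counts.loc[mask], self.groups.loc[mask])

    def take_samples(self, indices: Iterable[int], suffix: bool = True) -> "CountTable":
        """Positional sample selection; duplicated picks get unique IDs.

        Used by bootstrap resampling, where the same rat can be drawn twice.
        """
        idx = list(indices)
        counts = self.counts.iloc[idx].copy()
        groups = self.groups.iloc[idx].copy()
        if suffix:
            new_index = [f"{s}.r{i}" for i, s in enumerate(counts.index)]
            counts.index = new_index
            groups.index = new_index
        return CountTable(counts, groups)

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, counts_path: str | Path, metadata_path: str | Path) -> None:
        """Write counts (first column ``sample_id``) and sample->group metadata."""
        self.counts.rename_axis("sample_id").to_csv(counts_path, sep="\t")
        meta = self.groups.rename("group").rename_axis("sample_id")
        meta.to_csv(metadata_path, sep="\t")

    @classmethod
    def read_tsv(cls, counts_path: str | Path, metadata_path: str | Path) -> "CountTable":
        counts_path, metadata_path = Path(counts_path), Path(metadata_path)
        if not counts_path.exists():
            raise GutnetError(f"count table not found: {counts_path}")
        if not metadata_path.exists():
            raise GutnetError(f"sample metadata not found: {metadata_path}")
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
        if "group" not in meta.columns:
            raise GutnetError(f"metadata file {metadata_path} lacks a 'group' column")
        return cls(counts, meta["group"])


@dataclass
class OmicsBlock:
    """Continuous sample x feature matrix tagged with its data modality.

    The ``tag`` ("genus", "pathway", "phenotype", "blood_pressure", ...) is
    carried onto node attributes when blocks are merged into a multi-omics
    correlation network, and is prefixed to feature names on concatenation so
    names stay unique across blocks.
    """

    values: pd.DataFrame
    tag: str
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise GutnetError(f"block {self.tag!r} contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def prefixed(self) -> pd.DataFrame:
        """Feature matrix with ``tag:`` prefixed to every column name."""
        out = self.values.copy()
        out.columns = [f"{self.tag}:{c}" for c in out.columns]
        return out

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("sample_id").to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, tag: str) -> "OmicsBlock":
        path = Path(path)
        if not path.exists():
            raise GutnetError(f"omics block not found: {path}")
        return cls(pd.read_csv(path, sep="\t", index_col=0), tag)
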