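"""Core data model for the tissue expression atlas pipeline.

The central container is :class:`ExpressionMatrix`, a gene x column matrix
tagged with the normalization stage it has reached (raw counts, TPM, pTPM,
per-tissue means, TMM-corrected, or NX).  Sample metadata lives in
:class:`SampleSheet`, which enforces the tissue -> grouped tissue -> organ
system hierarchy, and :class:`PipelineConfig` holds every tunable threshold
of the annotation machinery.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml


class Stage(str, enum.Enum):
    """Normalization stage of an expression matrix."""

    counts = "counts"
    tpm = "tpm"
    ptpm = "ptpm"
    tissue_mean = "tissue_mean"
    tmm = "tmm"
    nx = "nx"


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Dense gene x column expression matrix with a unit-stage tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Genes in rows (index = gene ids), samples or tissues in columns.
        Values must be finite and non-negative.
    stage : Stage
        Which rung of the normalization ladder the values represent.
    gene_lengths : pandas.Series, optional
        Per-gene lengths in kilobases; required only for counts -> TPM.
    grouped : bool
        True when columns are grouped tissues (max over sub-tissues).
    """

    data: pd.DataFrame
    stage: Stage
    gene_lengths: pd.Series | None = None
    grouped: bool = False

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "column")
        values = self.data.to_numpy(dtype=float, copy=False)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"column {self.data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.data.index[bad[0]]!r}, "
                f"column {self.data.columns[bad[1]]!r}"
            )
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.data.index)
            if self.gene_lengths.isna().any():
                missing = self.gene_lengths.index[self.gene_lengths.isna()][0]
                raise ValueError(f"missing gene length for {missing!r}")
            if (self.gene_lengths <= 0).any():
                raise ValueError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def column_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, stage: Stage, grouped: bool | None = None) -> "ExpressionMatrix":
        """Derive a new matrix at a different stage, keeping gene lengths."""
        lengths = self.gene_lengths
        if lengths is not None:
            lengths = lengths.reindex(data.index).dropna()
            if len(lengths) != len(data.index):
                lengths = None
        return ExpressionMatrix(
            data=data,
            stage=stage,
            gene_lengths=lengths,
            grouped=self.grouped if grouped is None else grouped,
        )


class SampleSheet:
    """Sample annotation: sample -> tissue -> grouped tissue -> organ system.

    Each tissue must map to exactly one grouped tissue and each grouped
    tissue to exactly one organ system (the atlas hierarchy: individual
    tissue types are collapsed into grouped tissues, each belonging to a
    single organ system).
    """

    REQUIRED = ("sample_id", "tissue", "grouped_tissue", "organ_system")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing required column(s): {missing}")
        frame = frame.reset_index(drop=True)
        _check_unique(frame["sample_id"], "sample")
        for child, parent in (("tissue", "grouped_tissue"), ("grouped_tissue", "organ_system")):
            n_parents = frame.groupby(child)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                child_val = bad.index[0]
                parents = sorted(frame.loc[frame[child] == child_val, parent].unique())
                raise ValueError(
                    f"{child} {child_val!r} maps to multiple {parent}s: {parents}"
                )
        self.frame = frame

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.frame["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.frame["tissue"]))

    @property
    def grouped_tissues(self) -> list[str]:
        return list(dict.fromkeys(self.frame["grouped_tissue"]))

    @property
    def organ_systems(self) -> list[str]:
        return list(dict.fromkeys(self.frame["organ_system"]))

    def tissue_of(self) -> Mapping[str, str]:
        return dict(zip(self.frame["sample_id"], self.frame["tissue"]))

    def group_of(self) -> Mapping[str, str]:
        return dict(
            self.frame.drop_duplicates("tissue")[["tissue", "grouped_tissue"]].itertuples(index=False)
        )

    def organ_system_of(self) -> Mapping[str, str]:
        return dict(
            self.frame.drop_duplicates("grouped_tissue")[["grouped_tissue", "organ_system"]].itertuples(index=False)
        )

    def __len__(self) -> int:
        return len(self.frame)


class GeneAnnotation:
    """Per-gene annotation: protein-coding flag and optional gene name."""

    def __init__(self, frame: pd.DataFrame):
        if "gene_id" not in frame.columns or "is_protein_coding" not in frame.columns:
            raise ValueError("gene annotation requires columns gene_id, is_protein_coding")
        frame = frame.reset_index(drop=True)
        _check_unique(frame["gene_id"], "gene")
        frame = frame.copy()
        frame["is_protein_coding"] = frame["is_protein_coding"].astype(bool)
        self.frame = frame

    @property
    def gene_ids(self) -> pd.Index:
        return pd.Index(self.frame["gene_id"])

    @property
    def coding_genes(self) -> pd.Index:
        return pd.Index(self.frame.loc[self.frame["is_protein_coding"], "gene_id"])


@dataclass
class PipelineConfig:
    """All tunable thresholds of the annotation pipeline.

    Defaults follow the atlas protocol: a gene is detected at NX >= 1,
    elevation requires 4-fold expression, group enrichment spans 2-5
    tissues, "detected in many" means at least 31% of tissues, UMAP runs
    with n_neighbors=15 for 1000 epochs on unscaled input, k-means seeding
    uses DBSCAN at eps=0.1 (min_pts=5), k-means runs 50 iterations, cluster
    merging uses BH-adjusted p < 0.05 and final cluster-tissue association
    BH-adjusted p < 0.001, and exported FDR values are floored at 1e-100
    for display.
    """

    detection_threshold: float = 1.0
    fold_change: float = 4.0
    group_min: int = 2
    group_max: int = 5
    many_fraction: float = 0.31
    umap_n_neighbors: int = 15
    umap_n_epochs: int = 1000
    umap_min_dist: float = 0.01
    dbscan_eps: float = 0.1
    dbscan_min_pts: int = 5
    kmeans_iterations: int = 50
    merge_alpha: float = 0.05
    association_alpha: float = 0.001
    fdr_display_cap: float = 1e-100
    adjacency_eps: float | None = None  # default: dbscan_eps
    area_unit: float | None = None  # default: total hull area / 50
    cluster_test_mode: str = "standard"
    species_test_mode: str = "paper_literal"
    require_group_members_detected: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "detection_threshold",
            "fold_change",
            "dbscan_eps",
            "merge_alpha",
            "association_alpha",
            "fdr_display_cap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.group_min < 2:
            raise ValueError("group_min must be >= 2")
        if self.group_max < self.group_min:
            raise ValueError("group_max must be >= group_min")
        if not 0 < self.many_fraction < 1:
            raise ValueError("many_fraction must be in (0, 1)")
        for name in ("umap_n_neighbors", "umap_n_epochs", "dbscan_min_pts", "kmeans_iterations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def effective_adjacency_eps(self) -> float:
        return self.dbscan_eps if self.adjacency_eps is None else self.adjacency_eps

    def many_threshold(self, n_tissues: int) -> int:
        """Smallest tissue count qualifying as "detected in many".

        "At least 31%" of T tissues; the small epsilon guards against
        float round-up (0.31 * 100 is 31.000000000000004 in binary).
        At T = 44 this yields 14.
        """
        return int(math.ceil(self.many_fraction * n_tissues - 1e-9))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
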