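"""Rule-based tissue specificity and distribution categories.

Every gene is classified on its grouped-tissue NX profile into one of five
specificity categories and one of five distribution categories:

specificity (precedence order)
  tissue_enriched   one tissue has >= fold_change x the NX of any other
  group_enriched    2-5 tissues (NX above max/fold_change) whose mean NX is
                    >= fold_change x any tissue outside the group
  tissue_enhanced   one or more tissues with NX >= fold_change x the
                    all-tissue mean
  low_specificity   detected (NX >= detection_threshold) somewhere, no rule met
  not_detected      NX below the detection threshold everywhere

distribution
  detected_in_all / many (>= ceil(many_fraction x T), e.g. 14 of 44) /
  some / single / not_detected, by the count of tissues with
  NX >= detection_threshold.

Elevated categories additionally require the decisive statistic (max or
group mean) to reach the detection threshold, so all-near-zero genes can
never be called elevated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, PipelineConfig

SPECIFICITY_CATEGORIES = (
    "tissue_enriched",
    "group_enriched",
    "tissue_enhanced",
    "low_specificity",
    "not_detected",
)
ELEVATED_CATEGORIES = ("tissue_enriched", "group_enriched", "tissue_enhanced")
DISTRIBUTION_CATEGORIES = (
    "detected_in_all",
    "detected_in_many",
    "detected_in_some",
    "detected_in_single",
    "not_detected",
)


@dataclass
class SpecificityCall:
    gene_id: str
    category: str
    elevated_tissues: list[str] = field(default_factory=list)
    fold_change: float = float("nan")

    def __post_init__(self) -> None:
        if self.category not in SPECIFICITY_CATEGORIES:
            raise ValueError(f"unknown specificity category {self.category!r}")
        n = len(self.elevated_tissues)
        if self.category == "tissue_enriched" and n != 1:
            raise ValueError("tissue_enriched requires exactly one elevated tissue")
        if self.category in ("low_specificity", "not_detected") and n:
            raise ValueError(f"{self.category} must have no elevated tissues")


@dataclass
class DistributionCall:
    gene_id: str
    category: str
    n_detected: int

    def __post_init__(self) -> None:
        if self.category not in DISTRIBUTION_CATEGORIES:
            raise ValueError(f"unknown distribution category {self.category!r}")


def classify_specificity(nx_row: pd.Series, cfg: PipelineConfig) -> SpecificityCall:
    """Classify one gene's grouped NX profile; rules applied in precedence order."""
    if len(nx_row) < 2:
        raise ValueError("specificity classification needs at least 2 tissues")
    gene_id = str(nx_row.name) if nx_row.name is not None else ""
    v = nx_row.to_numpy(dtype=float)
    tissues = np.asarray(nx_row.index)
    det = cfg.detection_threshold
    fc = cfg.fold_change

    order = np.argsort(-v, kind="stable")
    mx = v[order[0]]
    second = v[order[1]]

    # (1) tissue enriched: the top tissue dominates every other by >= fc.
    # A tie for the maximum fails this for fc > 1 and falls through.
    if mx >= det and mx >= fc * second:
        with np.errstate(over="ignore", divide="ignore"):
            fold = float("inf") if second == 0 else float(mx / second)
        return SpecificityCall(gene_id, "tissue_enriched", [tissues[order[0]]], fold)

    # (2) group enriched: tissues above max/fc form the candidate group.
    if mx > 0:
        in_group = v > mx / fc
        size = int(in_group.sum())
        if cfg.group_min <= size <= cfg.group_max:
            group_mean = float(v[in_group].mean())
            outside = v[~in_group]
            out_max = float(outside.max()) if outside.size else 0.0
            members_ok = (not cfg.require_group_members_detected) or bool(
                (v[in_group] >= det).all()
            )
            if (
                group_mean >= det
                and members_ok
                and (out_max == 0 or group_mean >= fc * out_max)
            ):
                # members ordered by decreasing NX
                member_idx = order[np.isin(order, np.flatnonzero(in_group))]
                elevated = [tissues[i] for i in member_idx]
                fold = float("inf") if out_max == 0 else float(group_mean / out_max)
                return SpecificityCall(gene_id, "group_enriched", elevated, fold)

    # (3) tissue enhanced: any tissue >= fc x the all-tissue mean.
    mean_all = float(v.mean())
    if mean_all > 0:
        enhanced = (v >= fc * mean_all) & (v >= det)
        if enhanced.any():
            member_idx = order[np.isin(order, np.flatnonzero(enhanced))]
            elevated = [tissues[i] for i in member_idx]
            fold = float(mx / mean_all)
            return SpecificityCall(gene_id, "tissue_enhanced", elevated, fold)

    # (4) low specificity / (5) not detected
    if (v >= det).any():
        return SpecificityCall(gene_id, "low_specificity", [], float("nan"))
    return SpecificityCall(gene_id, "not_detected", [], float("nan"))


def classify_distribution(nx_row: pd.Series, cfg: PipelineConfig) -> DistributionCall:
    """Count detected tissues and bin into the five distribution categories.

    Precedence: not_detected (d=0), detected_in_all (d=T),
    detected_in_single (d=1), detected_in_many (d >= ceil(frac*T)),
    else detected_in_some.  Single is checked before many, which only
    matters for T <= 3 where the rules would otherwise overlap.
    """
    if len(nx_row) < 2:
        raise ValueError("distribution classification needs at least 2 tissues")
    gene_id = str(nx_row.name) if nx_row.name is not None else ""
    v = nx_row.to_numpy(dtype=float)
    t = len(v)
    d = int((v >= cfg.detection_threshold).sum())
    if d == 0:
        cat = "not_detected"
    elif d == t:
        cat = "detected_in_all"
    elif d == 1:
        cat = "detected_in_single"
    elif d >= cfg.many_threshold(t):
        cat = "detected_in_many"
    else:
        cat = "detected_in_some"
    return DistributionCall(gene_id, cat, d)


def classify_all(
    nx: ExpressionMatrix, cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every gene; returns (specificity table, distribution table).

    The specificity table has columns gene_id, category, elevated_tissues
    (list), fold_change; the distribution table gene_id, category,
    n_detected.  Both category sets partition the gene list (asserted).
    """
    spec_rows = []
    dist_rows = []
    for gene_id, row in nx.data.iterrows():
        s = classify_specificity(row, cfg)
        d = classify_distribution(row, cfg)
        spec_rows.append(
            {
                "gene_id": gene_id,
                "category": s.category,
                "elevated_tissues": s.elevated_tissues,
                "fold_change": s.fold_change,
            }
        )
        dist_rows.append({"gene_id": gene_id, "category": d.category, "n_detected": d.n_detected})
    spec = pd.DataFrame(spec_rows, columns=["gene_id", "category", "elevated_tissues", "fold_change"])
    dist = pd.DataFrame(dist_rows, columns=["gene_id", "category", "n_detected"])
    if len(spec):
        assert spec["category"].isin(SPECIFICITY_CATEGORIES).all()
        assert dist["category"].isin(DISTRIBUTION_CATEGORIES).all()
        assert len(spec) == len(dist) == nx.shape[0]
    return spec, dist


def specificity_summary(spec: pd.DataFrame) -> pd.Series:
    """Gene counts per specificity category (all five, zero-filled)."""
    counts = spec["category"].value_counts()
    return counts.reindex(SPECIFICITY_CATEGORIES, fill_value=0)


def distribution_summary(dist: pd.DataFrame) -> pd.Series:
    counts = dist["category"].value_counts()
    return counts.reindex(DISTRIBUTION_CATEGORIES, fill_value=0)


def elevated_counts_per_tissue(spec: pd.DataFrame) -> pd.Series:
    """Number of elevated (enriched/group/enhanced) genes per tissue."""
    counts: dict[str, int] = {}
    elevated = spec[spec["category"].isin(ELEVATED_CATEGORIES)]
    for tissues in elevated["elevated_tissues"]:
        for t in tissues:
            counts[t] = counts.get(t, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


def elevated_gene_sets(spec: pd.DataFrame) -> dict[str, set[str]]:
    """tissue -> set of genes elevated for that tissue."""
    sets: dict[str, set[str]] = {}
    elevated = spec[spec["category"].isin(ELEVATED_CATEGORIES)]
    for gene_id, tissues in zip(elevated["gene_id"], elevated["elevated_tissues"]):
        for t in tissues:
            sets.setdefault(t, set()).add(gene_id)
    return sets


def calls_to_tsv_frame(spec: pd.DataFrame, dist: pd.DataFrame) -> pd.DataFrame:
    """Flatten per-gene calls for TSV export (tissues semicolon-joined)."""
    out = spec.copy()
    out["elevated_tissues"] = out["elevated_tissues"].map(";".join)
    out = out.rename(columns={"category": "specificity"})
    out["distribution"] = dist["category"].to_numpy()
    out["n_detected"] = dist["n_detected"].to_numpy()
    return out


def calls_from_tsv_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`calls_to_tsv_frame` for the specificity columns."""
    spec = frame.rename(columns={"specificity": "category"})[
        ["gene_id", "category", "elevated_tissues", "fold_change"]
    ].copy()
    spec["elevated_tissues"] = (
        spec["elevated_tissues"].fillna("").map(lambda s: [t for t in str(s).split(";") if t])
    )
    spec["gene_id"] = spec["gene_id"].astype(str)
    return spec
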