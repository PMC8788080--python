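"""Ortholog filtering and two-species comparison of tissue expression.

Analyses rely on gene-to-gene comparisons, so only unambiguous ortholog
pairs are retained: all one2one pairs, plus one2many groups that
contribute exactly one high-confidence pair (that pair alone is kept).
many2many orthologs and one2many groups with only low-confidence pairs or
several high-confidence pairs are excluded.

On the retained pairs the module computes the 5x5 specificity-category
contingency between species, a per-pair agreement flag (same category and,
for elevated genes, overlapping elevated tissue sets under a user-supplied
tissue-vocabulary mapping), and per-tissue Spearman correlations of
ortholog expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .classify import ELEVATED_CATEGORIES, SPECIFICITY_CATEGORIES
from .datatypes import ExpressionMatrix

HOMOLOGY_TYPES = ("one2one", "one2many", "many2many")
CONFIDENCES = ("high", "low")


def validate_ortholog_map(orthologs: pd.DataFrame) -> pd.DataFrame:
    required = ["gene_id_a", "gene_id_b", "homology_type", "confidence"]
    missing = [c for c in required if c not in orthologs.columns]
    if missing:
        raise ValueError(f"ortholog table missing column(s): {missing}")
    orthologs = orthologs.copy()
    for c in ("gene_id_a", "gene_id_b"):
        orthologs[c] = orthologs[c].astype(str)
    if orthologs.duplicated(["gene_id_a", "gene_id_b"]).any():
        dup = orthologs[orthologs.duplicated(["gene_id_a", "gene_id_b"])].iloc[0]
        raise ValueError(f"duplicate ortholog pair ({dup['gene_id_a']}, {dup['gene_id_b']})")
    bad = ~orthologs["homology_type"].isin(HOMOLOGY_TYPES)
    if bad.any():
        raise ValueError(f"unknown homology type {orthologs.loc[bad, 'homology_type'].iloc[0]!r}")
    bad = ~orthologs["confidence"].isin(CONFIDENCES)
    if bad.any():
        raise ValueError(f"unknown confidence {orthologs.loc[bad, 'confidence'].iloc[0]!r}")
    return orthologs


def filter_orthologs(orthologs: pd.DataFrame) -> pd.DataFrame:
    """Keep one2one pairs and single-high-confidence one2many pairs."""
    orthologs = validate_ortholog_map(orthologs)
    keep = orthologs[orthologs["homology_type"] == "one2one"]
    o2m = orthologs[orthologs["homology_type"] == "one2many"]
    kept_o2m = []
    for _, group in o2m.groupby("gene_id_a"):
        high = group[group["confidence"] == "high"]
        if len(high) == 1:
            kept_o2m.append(high)
    parts = [keep] + kept_o2m
    out = pd.concat(parts, axis=0).reset_index(drop=True) if parts else keep
    return out


def classification_overlap(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    orthologs: pd.DataFrame,
    tissue_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ortholog-pair category comparison and 5x5 contingency matrix.

    Returns (overlap table, contingency).  A pair agrees when both species
    assign the same category and, for elevated categories, the elevated
    tissue sets overlap after mapping species-A tissue names through
    ``tissue_map`` (identity by default).  Pairs referencing genes missing
    from either call table are skipped with a warning.
    """
    tissue_map = tissue_map or {}
    a_idx = calls_a.set_index(calls_a["gene_id"].astype(str))
    b_idx = calls_b.set_index(calls_b["gene_id"].astype(str))
    rows = []
    skipped = 0
    for _, pair in orthologs.iterrows():
        ga, gb = str(pair["gene_id_a"]), str(pair["gene_id_b"])
        if ga not in a_idx.index or gb not in b_idx.index:
            skipped += 1
            continue
        ra, rb = a_idx.loc[ga], b_idx.loc[gb]
        cat_a, cat_b = ra["category"], rb["category"]
        tis_a = {tissue_map.get(t, t) for t in ra["elevated_tissues"]}
        tis_b = set(rb["elevated_tissues"])
        agree = cat_a == cat_b
        if agree and cat_a in ELEVATED_CATEGORIES:
            agree = bool(tis_a & tis_b)
        rows.append(
            {
                "gene_id_a": ga,
                "gene_id_b": gb,
                "category_a": cat_a,
                "category_b": cat_b,
                "elevated_tissues_a": sorted(tis_a),
                "elevated_tissues_b": sorted(tis_b),
                "agreement": agree,
            }
        )
    if skipped:
        warnings.warn(f"skipped {skipped} ortholog pair(s) with unknown genes")
    overlap = pd.DataFrame(
        rows,
        columns=[
            "gene_id_a", "gene_id_b", "category_a", "category_b",
            "elevated_tissues_a", "elevated_tissues_b", "agreement",
        ],
    )
    cats = list(SPECIFICITY_CATEGORIES)
    if len(overlap):
        contingency = pd.crosstab(overlap["category_a"], overlap["category_b"])
    else:
        contingency = pd.DataFrame()
    contingency = contingency.reindex(index=cats, columns=cats, fill_value=0).fillna(0).astype(int)
    return overlap, contingency


def agreement_rate(overlap: pd.DataFrame) -> float:
    """Fraction of retained ortholog pairs whose classifications agree."""
    if not len(overlap):
        return float("nan")
    return float(overlap["agreement"].mean())


def per_category_agreement(overlap: pd.DataFrame) -> pd.Series:
    """Agreement rate among pairs whose species-A category is elevated."""
    elevated = overlap[overlap["category_a"].isin(ELEVATED_CATEGORIES)]
    return elevated.groupby("category_a")["agreement"].mean()


def tissue_spearman(
    nx_a: ExpressionMatrix | pd.DataFrame,
    nx_b: ExpressionMatrix | pd.DataFrame,
    orthologs: pd.DataFrame,
    shared_tissues: list[tuple[str, str]] | list[str],
) -> pd.Series:
    """Per-tissue Spearman correlation of ortholog expression across species.

    ``shared_tissues`` is a list of (tissue_a, tissue_b) pairs, or plain
    names when both species use the same vocabulary.  Tissues with fewer
    than 3 shared ortholog pairs are skipped with a warning.
    """
    da = nx_a.data if isinstance(nx_a, ExpressionMatrix) else nx_a
    db = nx_b.data if isinstance(nx_b, ExpressionMatrix) else nx_b
    pairs = [
        (str(a), str(b))
        for a, b in zip(orthologs["gene_id_a"], orthologs["gene_id_b"])
        if str(a) in da.index and str(b) in db.index
    ]
    result = {}
    for entry in shared_tissues:
        ta, tb = (entry, entry) if isinstance(entry, str) else entry
        if ta not in da.columns or tb not in db.columns:
            warnings.warn(f"tissue pair ({ta}, {tb}) missing from a matrix; skipped")
            continue
        xa = np.array([da.at[a, ta] for a, _ in pairs])
        xb = np.array([db.at[b, tb] for _, b in pairs])
        if len(xa) < 3:
            warnings.warn(f"tissue {ta}: fewer than 3 shared genes; skipped")
            continue
        result[ta] = float(spearmanr(xa, xb).statistic)
    return pd.Series(result, name="spearman_rho", dtype=float)
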