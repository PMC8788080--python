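"""Hypergeometric overlap tests and Benjamini-Hochberg adjustment.

Two parameterizations are supported for each test family:

* ``standard`` — the conventional urn: m = successes in the population,
  n = failures, k = draws, and the upper-tail probability P(X >= q) of the
  observed overlap q.
* ``paper_literal`` — the argument lists exactly as the atlas protocol
  prints them (for the cross-species tissue-pair test: m = the smaller of
  the two per-tissue elevated counts, n = all orthologs, k = the union of
  elevated orthologs).  For the cluster-tissue test the printed arguments
  are internally inconsistent (cluster size appears as both m and k), so
  the standard urn is the default there; the literal form remains available.

The upper tail is inclusive of q, matching the ``phyper(q - 1, ...,
lower.tail = FALSE)`` convention.  BH-adjusted values below the display
cap (default 1e-100) are floored in the ``fdr_displayed`` column only; the
raw ``fdr`` is always retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .classify import elevated_gene_sets
from .datatypes import PipelineConfig

_P_FLOOR = 1e-320  # keep p in (0, 1] even past double underflow

MODES = ("standard", "paper_literal")


@dataclass
class HypergeomInputs:
    """Arguments of one hypergeometric test."""

    q: int
    m: int
    n: int
    k: int
    mode: str = "standard"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if min(self.q, self.m, self.n, self.k) < 0:
            raise ValueError("hypergeometric arguments must be non-negative")
        if self.q > min(self.m, self.k):
            raise ValueError(f"q={self.q} exceeds min(m={self.m}, k={self.k})")
        if self.k > self.m + self.n:
            raise ValueError(f"k={self.k} exceeds population m+n={self.m + self.n}")


def hypergeom_upper(q: int, m: int, n: int, k: int) -> float:
    """Inclusive upper tail P(X >= q), X ~ Hypergeometric(m successes, n failures, k draws).

    Uses the survival function; for tails beyond its resolution the mass
    is re-summed in log space, and the result is floored at 1e-320 so the
    returned probability is always positive.
    """
    HypergeomInputs(q, m, n, k)
    if q == 0:
        return 1.0
    p = float(hypergeom.sf(q - 1, m + n, m, k))
    if p < 1e-280:
        support = np.arange(q, min(m, k) + 1)
        logp = logsumexp(hypergeom.logpmf(support, m + n, m, k))
        p = float(np.exp(logp))
    return min(max(p, _P_FLOOR), 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finish_table(rows: list[dict], alpha: float, cap: float) -> pd.DataFrame:
    columns = ["test_id", "q", "m", "n", "k", "mode", "p_value", "fdr", "fdr_displayed", "significant"]
    if not rows:
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p_value"].to_numpy())
    table["fdr_displayed"] = np.maximum(table["fdr"], cap)
    table["significant"] = table["fdr"] < alpha
    return table[columns]


def cluster_tissue_enrichment(
    labels: pd.Series,
    spec_calls: pd.DataFrame,
    cfg: PipelineConfig,
    mode: str | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Test every cluster against every tissue with elevated genes.

    ``labels`` maps gene_id -> cluster id.  For each (cluster, tissue)
    pair, q is the number of genes both elevated for the tissue and in the
    cluster; in standard mode m = elevated genes for the tissue,
    n = all genes - m, k = cluster size.  BH adjustment is applied across
    all pairs tested in the batch.
    """
    mode = cfg.cluster_test_mode if mode is None else mode
    alpha = cfg.association_alpha if alpha is None else alpha
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    universe = set(labels.index.astype(str))
    total = len(universe)
    tissue_sets = {
        t: s & universe for t, s in elevated_gene_sets(spec_calls).items()
    }
    tissue_sets = {t: s for t, s in tissue_sets.items() if s}
    rows = []
    for cluster_id, members in labels.groupby(labels):
        cluster_genes = set(members.index.astype(str))
        k = len(cluster_genes)
        for tissue, elevated in sorted(tissue_sets.items()):
            q = len(cluster_genes & elevated)
            if mode == "standard":
                m, n_fail, draws = len(elevated), total - len(elevated), k
            else:  # the printed argument list, verbatim
                m, n_fail, draws = k, total, k
            rows.append(
                {
                    "test_id": f"cluster{cluster_id}|{tissue}",
                    "cluster_id": cluster_id,
                    "tissue": tissue,
                    "q": q,
                    "m": m,
                    "n": n_fail,
                    "k": draws,
                    "mode": mode,
                    "p_value": hypergeom_upper(q, m, n_fail, draws),
                }
            )
    table = _finish_table(rows, alpha, cfg.fdr_display_cap)
    if len(table):
        extra = pd.DataFrame(rows)[["cluster_id", "tissue"]]
        table = pd.concat([table, extra], axis=1)
    else:
        table["cluster_id"] = []
        table["tissue"] = []
    return table


def species_tissue_overlap(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    cfg: PipelineConfig,
    tissue_map: dict[str, str] | None = None,
    mode: str | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Tissue-pair overlap of elevated orthologs between two species.

    Both call tables must already be restricted to the shared ortholog
    universe, with gene ids translated to a common vocabulary.
    ``tissue_map`` translates species-A tissue names to species-B names
    (identity by default).  In paper_literal mode (default) q = orthologs
    elevated in both tissues, m = the smaller of the two elevated counts,
    n = all orthologs, k = elevated in either tissue.
    """
    mode = cfg.species_test_mode if mode is None else mode
    alpha = cfg.association_alpha if alpha is None else alpha
    universe = set(calls_a["gene_id"].astype(str)) & set(calls_b["gene_id"].astype(str))
    if not universe:
        raise ValueError("empty ortholog universe")
    total = len(universe)
    sets_a = {t: s & universe for t, s in elevated_gene_sets(calls_a).items()}
    sets_b = {t: s & universe for t, s in elevated_gene_sets(calls_b).items()}
    sets_a = {t: s for t, s in sets_a.items() if s}
    sets_b = {t: s for t, s in sets_b.items() if s}
    if tissue_map:
        sets_a = {tissue_map.get(t, t): s for t, s in sets_a.items()}
    rows = []
    for ta, sa in sorted(sets_a.items()):
        for tb, sb in sorted(sets_b.items()):
            q = len(sa & sb)
            union = len(sa | sb)
            if mode == "paper_literal":
                m, n_fail, draws = min(len(sa), len(sb)), total, union
            else:
                m, n_fail, draws = len(sa), total - len(sa), len(sb)
            rows.append(
                {
                    "test_id": f"{ta}|{tb}",
                    "tissue_a": ta,
                    "tissue_b": tb,
                    "q": q,
                    "m": m,
                    "n": n_fail,
                    "k": draws,
                    "mode": mode,
                    "p_value": hypergeom_upper(q, m, n_fail, draws),
                }
            )
    table = _finish_table(rows, alpha, cfg.fdr_display_cap)
    if len(table):
        extra = pd.DataFrame(rows)[["tissue_a", "tissue_b"]]
        table = pd.concat([table, extra], axis=1)
    return table


def gene_set_enrichment(
    labels: pd.Series,
    gene_sets: dict[str, list[str]],
    cfg: PipelineConfig,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Standard hypergeometric enrichment of GMT gene sets per cluster.

    Sets with no gene in the universe are skipped with a warning.  Stands
    in for external GO-term enrichment: any user-supplied collection works.
    """
    import warnings

    universe = set(labels.index.astype(str))
    total = len(universe)
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        if not in_universe:
            warnings.warn(f"gene set {name!r} has no genes in the universe; skipped")
            continue
        m = len(in_universe)
        for cluster_id, cluster in labels.groupby(labels):
            cluster_genes = set(cluster.index.astype(str))
            q = len(cluster_genes & in_universe)
            k = len(cluster_genes)
            rows.append(
                {
                    "test_id": f"cluster{cluster_id}|{name}",
                    "cluster_id": cluster_id,
                    "gene_set": name,
                    "q": q,
                    "m": m,
                    "n": total - m,
                    "k": k,
                    "mode": "standard",
                    "p_value": hypergeom_upper(q, m, total - m, k),
                }
            )
    table = _finish_table(rows, alpha, cfg.fdr_display_cap)
    if len(table):
        extra = pd.DataFrame(rows)[["cluster_id", "gene_set"]]
        table = pd.concat([table, extra], axis=1)
    return table
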