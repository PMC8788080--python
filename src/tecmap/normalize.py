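"""The normalization ladder: TPM -> pTPM -> tissue means -> TMM -> NX.

NX (normalized expression) is obtained by TMM-correcting tissue-averaged
pTPM values between columns and then pareto-scaling each gene row (dividing
by the square root of its standard deviation).  Grouped-tissue expression
is the maximum over member tissues.

The TMM step follows the trimmed-mean-of-M-values method of Robinson &
Oshlack as implemented in edgeR: M and A statistics on relative abundances,
rank-based trimming of 30% of M values and 5% of A values from each tail,
and a precision-weighted mean of the surviving M values.  TMM is
stage-agnostic: it is applied both to the tissue-mean matrix (for
classification) and to the full sample matrix (for gene clustering).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ExpressionMatrix, GeneAnnotation, SampleSheet, Stage


def compute_tpm(counts: ExpressionMatrix, lengths_kb: pd.Series | None = None) -> ExpressionMatrix:
    """Counts -> transcripts per million using per-gene lengths in kb.

    Per column: rate_g = count_g / length_g, tpm_g = 1e6 * rate_g / sum(rates).
    """
    if counts.stage != Stage.counts:
        raise ValueError(f"expected counts matrix, got stage {counts.stage.value}")
    if lengths_kb is None:
        lengths_kb = counts.gene_lengths
    if lengths_kb is None:
        raise ValueError("gene lengths (kb) required for counts -> TPM")
    lengths_kb = lengths_kb.reindex(counts.gene_ids)
    if lengths_kb.isna().any():
        missing = lengths_kb.index[lengths_kb.isna()][0]
        raise ValueError(f"missing length for gene {missing!r}")
    if (lengths_kb <= 0).any():
        raise ValueError("gene lengths must be positive")
    rates = counts.data.div(lengths_kb, axis=0)
    totals = rates.sum(axis=0)
    zero_cols = totals.index[totals == 0]
    if len(zero_cols):
        raise ValueError(f"all-zero column(s): {list(zero_cols)}")
    tpm = rates.div(totals, axis=1) * 1e6
    return counts.with_data(tpm, Stage.tpm)


def compute_ptpm(tpm: ExpressionMatrix, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Restrict to protein-coding genes and renormalize columns to 1e6 (pTPM)."""
    if tpm.stage != Stage.tpm:
        raise ValueError(f"expected tpm matrix, got stage {tpm.stage.value}")
    coding = [g for g in tpm.gene_ids if g in set(annotation.coding_genes)]
    if not coding:
        raise ValueError("no protein-coding genes present in the matrix")
    sub = tpm.data.loc[coding]
    totals = sub.sum(axis=0)
    zero_cols = totals.index[totals == 0]
    if len(zero_cols):
        raise ValueError(f"no protein-coding expression in column(s): {list(zero_cols)}")
    ptpm = sub.div(totals, axis=1) * 1e6
    return tpm.with_data(ptpm, Stage.ptpm)


def aggregate_tissue_mean(ptpm: ExpressionMatrix, sheet: SampleSheet) -> ExpressionMatrix:
    """Average replicate samples of each tissue (arithmetic mean per gene)."""
    tissue_of = sheet.tissue_of()
    missing = [c for c in ptpm.column_ids if c not in tissue_of]
    if missing:
        raise ValueError(f"sample(s) missing from sample sheet: {missing}")
    tissues = list(dict.fromkeys(tissue_of[c] for c in ptpm.column_ids))
    cols = {}
    for t in tissues:
        members = [c for c in ptpm.column_ids if tissue_of[c] == t]
        cols[t] = ptpm.data[members].mean(axis=1)
    out = pd.DataFrame(cols, index=ptpm.gene_ids)[tissues]
    return ptpm.with_data(out, Stage.tissue_mean)


@dataclass
class TmmFactors:
    """Per-column TMM scaling factors, renormalized to geometric mean 1."""

    factors: pd.Series
    reference_column_id: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_gm = np.log(self.factors.to_numpy()).mean()
        if abs(log_gm) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """TMM factor of one column against the reference (edgeR .calcFactorTMM)."""
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep]
    ref = ref[keep]
    if obs.size == 0:
        warnings.warn("no genes survive the zero filter; TMM factor set to 1")
        return 1.0
    log_r = np.log2((obs / lib_obs) / (ref / lib_ref))
    abs_e = (np.log2(obs / lib_obs) + np.log2(ref / lib_ref)) / 2.0
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0:
        warnings.warn("no finite M values; TMM factor set to 1")
        return 1.0
    if np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep.any():
        warnings.warn("trimming removed all genes; TMM factor set to 1")
        return 1.0
    w = 1.0 / v[keep]
    f = float(np.sum(log_r[keep] * w) / np.sum(w))
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_correct(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, TmmFactors]:
    """Between-column TMM correction.

    Corrected value = (value / column_sum) * mean_column_sum / factor —
    the factor rescales relative abundances, exactly as edgeR divides
    counts by (library size x normalization factor).  On matrices whose
    columns already share a common sum (TPM/pTPM and their tissue means)
    this reduces to value / factor.

    The reference column is the one whose 75th percentile of relative
    abundance is closest to the mean 75th percentile across columns.
    Factors are renormalized to geometric mean 1, so a matrix whose columns
    differ only by uniform scaling gets factors of exactly 1 and is left
    unchanged up to that common scale.
    """
    if matrix.shape[1] < 2:
        raise ValueError("TMM requires at least 2 columns")
    values = matrix.values
    lib = values.sum(axis=0)
    if (lib == 0).any():
        bad = matrix.column_ids[lib == 0][0]
        raise ValueError(f"all-zero column {bad!r}")
    rel = values / lib
    q75 = np.quantile(rel, 0.75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref_id = matrix.column_ids[ref_idx]
    factors = np.ones(matrix.shape[1])
    for j in range(matrix.shape[1]):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair_factor(values[:, j], values[:, ref_idx], lib[j], lib[ref_idx])
    factors = factors / np.exp(np.mean(np.log(factors)))
    effective = pd.Series(factors * lib / lib.mean(), index=matrix.column_ids)
    corrected = matrix.data.div(effective, axis=1)
    out = matrix.with_data(corrected, Stage.tmm)
    return out, TmmFactors(pd.Series(factors, index=matrix.column_ids), ref_id)


def pareto_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Gene-wise pareto scaling: divide each row by sqrt(its SD).

    SD uses the n-1 denominator.  Rows with zero SD pass through unchanged
    (the quoted procedure divides by sqrt(SD); only the Z-score transform
    has an explicit zero rule).  The scaled row's SD equals sqrt(original SD).
    """
    sd = matrix.data.std(axis=1, ddof=1)
    divisor = np.sqrt(sd)
    # constant rows can yield sd ~ 1e-16 from float round-off, not exactly 0
    zero = sd <= 1e-10 * (1.0 + matrix.data.abs().mean(axis=1))
    divisor[zero] = 1.0
    nx_data = matrix.data.div(divisor, axis=0)
    return matrix.with_data(nx_data, Stage.nx)


def grouped_tissue_max(nx: ExpressionMatrix, sheet: SampleSheet) -> ExpressionMatrix:
    """Collapse tissue columns to grouped tissues by the per-gene maximum."""
    group_of = sheet.group_of()
    missing = [c for c in nx.column_ids if c not in group_of]
    if missing:
        raise ValueError(f"tissue(s) not mapped to a grouped tissue: {missing}")
    groups = list(dict.fromkeys(group_of[c] for c in nx.column_ids))
    cols = {}
    for g in groups:
        members = [c for c in nx.column_ids if group_of[c] == g]
        cols[g] = nx.data[members].max(axis=1)
    out = pd.DataFrame(cols, index=nx.gene_ids)[groups]
    return nx.with_data(out, nx.stage, grouped=True)


def normalize_ladder(
    counts: ExpressionMatrix,
    sheet: SampleSheet,
    annotation: GeneAnnotation,
    lengths_kb: pd.Series | None = None,
    stage_in: Stage = Stage.counts,
) -> dict[str, ExpressionMatrix | TmmFactors]:
    """Run the full ladder and return every intermediate stage.

    Produces both the tissue-level NX matrices used for classification and
    the sample-level TMM matrix used for gene clustering.
    """
    if stage_in == Stage.counts:
        tpm = compute_tpm(counts, lengths_kb)
    elif stage_in == Stage.tpm:
        tpm = counts
    else:
        raise ValueError("stage_in must be counts or tpm")
    ptpm = compute_ptpm(tpm, annotation)
    tissue_mean = aggregate_tissue_mean(ptpm, sheet)
    tmm, factors = tmm_correct(tissue_mean)
    nx = pareto_scale(tmm)
    nx_grouped = grouped_tissue_max(nx, sheet)
    sample_tmm, sample_factors = tmm_correct(ptpm)
    return {
        "tpm": tpm,
        "ptpm": ptpm,
        "tissue_mean": tissue_mean,
        "tmm": tmm,
        "tmm_factors": factors,
        "nx": nx,
        "nx_grouped": nx_grouped,
        "sample_tmm": sample_tmm,
        "sample_tmm_factors": sample_factors,
    }
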