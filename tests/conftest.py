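"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tecmap import PipelineConfig, classify_all, normalize_ladder
from tecmap.synthetic import generate, low_noise_config


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def bench_ds():
    """The benchmark fixture: 2000 genes, 12 tissues, 8 planted modules."""
    return generate(low_noise_config(), seed=1)


@pytest.fixture(scope="session")
def bench_ladder(bench_ds):
    return normalize_ladder(bench_ds.counts, bench_ds.sheet, bench_ds.annotation)


@pytest.fixture(scope="session")
def bench_calls(bench_ladder):
    spec, dist = classify_all(bench_ladder["nx_grouped"], PipelineConfig())
    return spec, dist


@pytest.fixture(scope="session")
def tiny_ds():
    """A small, fast dataset for plumbing-level tests."""
    return generate(
        low_noise_config(n_genes=400, n_noncoding=20, n_replicates=2), seed=7
    )


def make_spec_calls(rows: list[tuple[str, str, list[str]]]) -> pd.DataFrame:
    """Build a specificity-call table from (gene, category, tissues) tuples."""
    return pd.DataFrame(
        [
            {
                "gene_id": g,
                "category": cat,
                "elevated_tissues": tissues,
                "fold_change": float("nan"),
            }
            for g, cat, tissues in rows
        ],
        columns=["gene_id", "category", "elevated_tissues", "fold_change"],
    )
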