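"""The normalization ladder: TPM, pTPM, tissue means, TMM, pareto, grouped max."""

import numpy as np
import pandas as pd
import pytest

from tecmap import (
    ExpressionMatrix,
    GeneAnnotation,
    SampleSheet,
    Stage,
    aggregate_tissue_mean,
    compute_ptpm,
    compute_tpm,
    grouped_tissue_max,
    normalize_ladder,
    pareto_scale,
    tmm_correct,
)


def em(values, genes=None, cols=None, stage=Stage.counts, lengths=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cols = cols or [f"s{i}" for i in range(values.shape[1])]
    ln = pd.Series(lengths, index=genes) if lengths is not None else None
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=cols), stage, ln)


class TestTpm:
    def test_equal_rates_split_the_million(self):
        m = em([[10], [20]], lengths=[1.0, 2.0])
        tpm = compute_tpm(m)
        np.testing.assert_allclose(tpm.values[:, 0], [500000, 500000])

    def test_single_gene_gets_everything(self):
        tpm = compute_tpm(em([[7.0]], lengths=[2.5]))
        assert tpm.values[0, 0] == pytest.approx(1e6)

    def test_columns_sum_to_a_million(self):
        rng = np.random.default_rng(1)
        m = em(rng.integers(0, 100, (50, 5)) + 1.0, lengths=rng.lognormal(0, 0.5, 50))
        tpm = compute_tpm(m)
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, atol=1e-6)

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            compute_tpm(em([[1, 0], [2, 0]], lengths=[1, 1]))


class TestPtpm:
    def test_renormalizes_over_coding_sum(self):
        tpm = em([[200000], [300000], [500000]], stage=Stage.tpm)
        ann = GeneAnnotation(
            pd.DataFrame({"gene_id": ["g0", "g1", "g2"], "is_protein_coding": [True, True, False]})
        )
        ptpm = compute_ptpm(tpm, ann)
        np.testing.assert_allclose(ptpm.values[:, 0], [400000, 600000])
        assert list(ptpm.gene_ids) == ["g0", "g1"]

    def test_all_coding_is_identity(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(1, 1, (20, 3))
        x = x / x.sum(axis=0) * 1e6
        tpm = em(x, stage=Stage.tpm)
        ann = GeneAnnotation(
            pd.DataFrame({"gene_id": [f"g{i}" for i in range(20)], "is_protein_coding": True})
        )
        np.testing.assert_allclose(compute_ptpm(tpm, ann).values, x, rtol=1e-12)

    def test_no_coding_genes_rejected(self):
        tpm = em([[1.0]], stage=Stage.tpm)
        ann = GeneAnnotation(pd.DataFrame({"gene_id": ["g0"], "is_protein_coding": [False]}))
        with pytest.raises(ValueError, match="protein-coding"):
            compute_ptpm(tpm, ann)


def make_sheet(mapping):
    rows = [
        {"sample_id": s, "tissue": t, "grouped_tissue": t, "organ_system": "os"}
        for s, t in mapping.items()
    ]
    return SampleSheet(pd.DataFrame(rows))


class TestTissueMean:
    def test_mean_of_replicates(self):
        m = em([[2.0, 4.0]], cols=["a", "b"], stage=Stage.ptpm)
        sheet = make_sheet({"a": "liver", "b": "liver"})
        out = aggregate_tissue_mean(m, sheet)
        assert out.values[0, 0] == pytest.approx(3.0)

    def test_single_replicate_identity(self):
        m = em([[5.0]], cols=["a"], stage=Stage.ptpm)
        out = aggregate_tissue_mean(m, make_sheet({"a": "liver"}))
        assert out.values[0, 0] == 5.0

    def test_matches_mean_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(2, 1, (10, 12))
        cols = [f"t{i}_r{j}" for i in range(4) for j in range(3)]
        m = em(x, cols=cols, stage=Stage.ptpm)
        sheet = make_sheet({c: c.split("_")[0] for c in cols})
        out = aggregate_tissue_mean(m, sheet)
        for ti in range(4):
            np.testing.assert_allclose(
                out.data[f"t{ti}"].to_numpy(), x[:, 3 * ti : 3 * ti + 3].mean(axis=1)
            )

    def test_unknown_sample_rejected(self):
        m = em([[1.0, 2.0]], cols=["a", "zz"], stage=Stage.ptpm)
        with pytest.raises(ValueError, match="zz"):
            aggregate_tissue_mean(m, make_sheet({"a": "liver"}))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(4)
        col = rng.lognormal(3, 1, 100)
        m = em(np.column_stack([col, col, col]), stage=Stage.tissue_mean)
        _, fac = tmm_correct(m)
        np.testing.assert_allclose(fac.factors.to_numpy(), 1.0, atol=1e-9)

    def test_pure_scaling_gives_unit_factors(self):
        rng = np.random.default_rng(5)
        col = rng.lognormal(3, 1, 100)
        m = em(np.column_stack([col, 3.0 * col]), stage=Stage.tissue_mean)
        _, fac = tmm_correct(m)
        np.testing.assert_allclose(fac.factors.to_numpy(), 1.0, atol=1e-9)

    def test_spike_in_compensated(self):
        rng = np.random.default_rng(6)
        col = rng.lognormal(3, 1, 200)
        spiked = col.copy()
        spiked[0] *= 100.0
        m = em(np.column_stack([col, spiked]), stage=Stage.tissue_mean)
        corrected, _ = tmm_correct(m)
        ratio = np.median(corrected.values[1:, 1] / corrected.values[1:, 0])
        assert 0.95 <= ratio <= 1.05

    def test_matches_edgeR_reference_factors(self):
        # factors frozen from edgeR::calcNormFactors(method="TMM") on this
        # exact matrix (lognormal(3,1), 10 differential genes in B, C = 3x)
        rng = np.random.default_rng(42)
        x = rng.lognormal(3, 1, size=(60, 4))
        x[:10, 1] *= 6
        x[:, 2] *= 3
        x = np.round(x, 6)
        m = em(x, cols=list("ABCD"), stage=Stage.tissue_mean)
        _, fac = tmm_correct(m)
        expected = [1.2337368754, 1.0304992366, 0.8274599526, 0.9505671374]
        np.testing.assert_allclose(fac.factors.to_numpy(), expected, rtol=1e-9)
        assert fac.reference_column_id == "D"

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(3, 1.5, (80, 6)) * rng.lognormal(0, 0.4, 6)
        _, fac = tmm_correct(em(x, stage=Stage.tissue_mean))
        assert abs(np.log(fac.factors.to_numpy()).mean()) < 1e-9

    def test_single_column_rejected(self):
        with pytest.raises(ValueError, match="2 columns"):
            tmm_correct(em([[1.0], [2.0]], stage=Stage.tissue_mean))


class TestPareto:
    def test_constant_row_unchanged(self):
        out = pareto_scale(em([[5.0, 5.0, 5.0]], stage=Stage.tmm))
        np.testing.assert_allclose(out.values, [[5, 5, 5]])

    def test_hand_formula_n_minus_1(self):
        out = pareto_scale(em([[1.0, 9.0, 2.0]], stage=Stage.tmm))
        expected = np.array([1, 9, 2]) / 19**0.25
        np.testing.assert_allclose(out.values[0], expected, rtol=1e-12)
        np.testing.assert_allclose(out.values[0], [0.479, 4.311, 0.958], atol=5e-4)

    def test_scaled_sd_is_sqrt_of_original(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(2, 1, (40, 7))
        out = pareto_scale(em(x, stage=Stage.tmm))
        sd_orig = x.std(axis=1, ddof=1)
        sd_scaled = out.values.std(axis=1, ddof=1)
        np.testing.assert_allclose(sd_scaled, np.sqrt(sd_orig), atol=1e-9)


class TestGroupedMax:
    def test_max_over_members(self):
        m = em([[2.0, 7.0]], cols=["t1", "t2"], stage=Stage.nx)
        rows = pd.DataFrame(
            {
                "sample_id": ["t1", "t2"],
                "tissue": ["t1", "t2"],
                "grouped_tissue": ["g", "g"],
                "organ_system": ["os", "os"],
            }
        )
        out = grouped_tissue_max(m, SampleSheet(rows))
        assert out.values[0, 0] == 7.0
        assert out.grouped

    def test_singleton_group_identity(self):
        m = em([[4.0]], cols=["t1"], stage=Stage.nx)
        rows = pd.DataFrame(
            {"sample_id": ["t1"], "tissue": ["t1"], "grouped_tissue": ["g1"], "organ_system": ["os"]}
        )
        assert grouped_tissue_max(m, SampleSheet(rows)).values[0, 0] == 4.0

    def test_98_to_44_mapping_matches_max_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.lognormal(0, 1, (15, 98))
        tissues = [f"t{i}" for i in range(98)]
        m = em(x, cols=tissues, stage=Stage.nx)
        rows = pd.DataFrame(
            {
                "sample_id": tissues,
                "tissue": tissues,
                "grouped_tissue": [f"g{i % 44}" for i in range(98)],
                "organ_system": [f"os{(i % 44) % 14}" for i in range(98)],
            }
        )
        out = grouped_tissue_max(m, SampleSheet(rows))
        assert out.shape == (15, 44)
        for gi in range(44):
            members = [i for i in range(98) if i % 44 == gi]
            np.testing.assert_allclose(out.data[f"g{gi}"].to_numpy(), x[:, members].max(axis=1))


def test_full_ladder_recovers_planted_fold_on_noiseless_fixture():
    from tecmap.synthetic import SyntheticConfig, generate

    cfg = SyntheticConfig(
        n_genes=300, noise_cv=0.0, dispersion=0.0, n_noncoding=10, low_amplitude=0.0
    )
    ds = generate(cfg, seed=11)
    ladder = normalize_ladder(ds.counts, ds.sheet, ds.annotation)
    nxg = ladder["nx_grouped"]
    truth = ds.coding_truth.set_index("gene_id")
    enriched = truth[truth["category"] == "tissue_enriched"]
    for gid, row in enriched.head(20).iterrows():
        profile = nxg.data.loc[gid]
        home = row["elevated_tissues"][0]
        others = profile.drop(home)
        assert profile[home] / others.max() == pytest.approx(8.0, rel=0.01)
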