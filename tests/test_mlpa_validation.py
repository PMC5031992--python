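"""MLPA normalisation, ploidy-adjusted calling and branch concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnaphylo.errors import UsageError
from cnaphylo.io_segments import filter_fragments, unify_breakpoints
from cnaphylo.mlpa_validation import (
    branch_concordance,
    call_copy_number,
    gene_ratios,
    make_calls,
    normalize_probe_length,
    validate_patient,
    validation_report,
    MLPAValidationRow,
)
from cnaphylo.phylogeny import build_tree, reconstruct_ancestors
from cnaphylo.synthetic_data import SimConfig, simulate_mlpa, simulate_patient


@pytest.fixture(scope="module")
def noiseless_mlpa():
    config = SimConfig(seed=5, noise_sd=0.0, triploid_fraction=0.25)
    _, profiles = simulate_patient(config, "lymph_from_epe", 0)
    table, probes, controls = simulate_mlpa(profiles, slope=0.002, noise_sd=0.0, seed=11)
    matrix = filter_fragments(unify_breakpoints(profiles))
    tree = reconstruct_ancestors(build_tree(matrix), matrix)
    return profiles, table, probes, controls, matrix, tree


class TestNormalizeProbeLength:
    def test_exactly_linear_data_normalises_to_one(self):
        lengths = np.array([100, 200, 300, 400])
        df = pd.DataFrame({
            "sample": "ctrl", "probe_id": [f"p{i}" for i in range(4)],
            "probe_length": lengths, "intensity": 0.5 + 0.002 * lengths,
        })
        out = normalize_probe_length(df, control_samples=["ctrl"])
        assert np.allclose(out["normalized"], 1.0)
        assert abs(out["normalized"].mean() - 1.0) < 1e-9

    def test_flat_data_divides_by_mean(self):
        df = pd.DataFrame({
            "sample": "s", "probe_id": list("abcd"),
            "probe_length": [100, 200, 300, 400], "intensity": [2.0, 2.0, 2.0, 2.0],
        })
        out = normalize_probe_length(df)
        assert np.allclose(out["normalized"], 1.0)

    def test_equal_lengths_skip_with_warning(self, caplog):
        df = pd.DataFrame({
            "sample": "s", "probe_id": list("abc"),
            "probe_length": [200, 200, 200], "intensity": [1.0, 2.0, 3.0],
        })
        with caplog.at_level("WARNING", logger="cnaphylo"):
            out = normalize_probe_length(df)
        assert (out["normalized"] == out["intensity"]).all()
        assert "skipped" in caplog.text

    def test_sloped_noiseless_ratios_recover_cn_over_two(self, noiseless_mlpa):
        profiles, table, probes, controls, matrix, _ = noiseless_mlpa
        norm = normalize_probe_length(table, probes, controls)
        ratios = gene_ratios(norm, controls)
        probe_by_gene = {p.gene: p for p in probes}
        checked = 0
        for p in profiles:
            for gene in ratios.columns:
                frag = probe_by_gene[gene].fragment
                pos = (frag.start + frag.end) // 2
                cn = next(
                    cn for seg, cn in p.segments
                    if seg.chromosome == frag.chromosome and seg.start <= pos < seg.end
                )
                assert ratios.loc[p.sample_id, gene] == pytest.approx(cn / 2, abs=1e-6)
                checked += 1
        assert checked > 50


class TestCallCopyNumber:
    @pytest.mark.parametrize(
        "ratio, ploidy, expected_adj, expected_call",
        [
            (1.5, 3.0, 1.0, "neutral"),  # the ploidy-adjustment formula
            (1.0, 2.0, 1.0, "neutral"),
            (0.5, 2.0, 0.5, "loss"),
            (1.5, 2.0, 1.5, "gain"),
        ],
    )
    def test_threshold_formula(self, ratio, ploidy, expected_adj, expected_call):
        call = call_copy_number(ratio, ploidy)
        assert call.adjusted_ratio == pytest.approx(expected_adj)
        assert call.call == expected_call

    def test_neutral_whenever_cn_equals_rounded_ploidy(self):
        for ploidy in (2, 3, 4):
            for cn in range(0, 9):
                call = call_copy_number(max(cn, 1e-9) / 2, float(ploidy))
                if cn == ploidy:
                    assert call.call == "neutral"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(UsageError):
            call_copy_number(1.0, 0.0)
        with pytest.raises(UsageError):
            call_copy_number(-1.0, 2.0)


class TestBranchConcordance:
    def test_two_sided_binomial_matches_pmf_summation(self):
        p = stats.binomtest(10, 10, 0.33).pvalue
        pmf = stats.binom.pmf(np.arange(11), 10, 0.33)
        direct = pmf[pmf <= pmf[10] * (1 + 1e-9)].sum()
        assert p == pytest.approx(direct, rel=1e-9)
        assert p == pytest.approx(1.53e-5, rel=0.01)

    def test_null_centre_is_not_significant(self):
        assert stats.binomtest(33, 100, 0.33).pvalue > 0.9

    def test_noiseless_pipeline_validates_everything(self, noiseless_mlpa):
        _, table, probes, controls, matrix, tree = noiseless_mlpa
        rows = validate_patient(tree, matrix, table, probes, controls)
        assert rows
        assert any(r.n_informative > 0 for r in rows)
        for r in rows:
            assert r.k_agree == r.n_informative
            if r.n_informative > 0:
                assert r.p < 1e-3
                assert r.percent == 100.0

    def test_zero_informative_row_flagged(self, noiseless_mlpa):
        _, table, probes, controls, matrix, tree = noiseless_mlpa
        norm = normalize_probe_length(table, probes, controls)
        calls = make_calls(gene_ratios(norm, controls), {})
        rows = [
            branch_concordance(tree, node, probes, matrix, calls)
            for node in tree.internal_nodes()
        ]
        empty = [r for r in rows if r.n_informative == 0]
        for r in empty:
            assert r.p == 1.0 and r.note

    def test_type_one_error_conservative_under_null(self):
        # MLPA agreement drawn at exactly the null rate: the two-sided exact
        # test should reject at <= alpha (discreteness makes it conservative)
        rng = np.random.default_rng(0)
        n_branches, n_probes, alpha = 1000, 20, 0.05
        ks = rng.binomial(n_probes, 0.33, size=n_branches)
        rejections = sum(stats.binomtest(int(k), n_probes, 0.33).pvalue < alpha for k in ks)
        lo, hi = stats.binom.interval(0.99, n_branches, alpha)
        assert rejections <= hi


def test_validation_report_fdr_column():
    rows = [
        MLPAValidationRow("P", "i", "a; b", 10, 10, 100.0, 1.53e-5),
        MLPAValidationRow("P", "ii", "c; d", 10, 5, 50.0, 0.3),
    ]
    out = validation_report(rows)
    assert out[0].p_adj == pytest.approx(2 * 1.53e-5)
    assert out[1].p_adj == pytest.approx(0.3)


def test_single_row_adjustment_is_identity():
    (row,) = validation_report([MLPAValidationRow("P", "i", "", 5, 5, 100.0, 0.01)])
    assert row.p_adj == pytest.approx(0.01)
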