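"""The synthetic-data generator: determinism, distributional contracts,
and cross-module consistency with the calling stage."""

import numpy as np
import pytest

from methtk.calling import CallingOptions, call_methylation, classify_context
from methtk.filtering import FilterSpec, filter_records
from methtk.grouping import build_sample_matrix, summarize_groups
from methtk.simulate import (
    SimulationTruth,
    build_cytosine_map,
    plant_truth,
    sample_baseline_rates,
    simulate_case_control,
    simulate_counts,
    simulate_expression,
    simulate_reads,
    simulate_reference,
)

LAX = CallingOptions(min_base_quality=0, min_mapping_quality=0)


class TestSimulateReference:
    def test_zero_density_means_no_cpg(self):
        seqs, cyt_map = simulate_reference(1, 2000, 0.0, seed=1)
        assert "CG" not in seqs["chr1"]
        assert (cyt_map.contexts == "CG").sum() == 0

    def test_same_seed_identical_output(self):
        a, _ = simulate_reference(2, 1500, 0.03, seed=42)
        b, _ = simulate_reference(2, 1500, 0.03, seed=42)
        assert a == b

    def test_different_seeds_differ(self):
        a, _ = simulate_reference(1, 1500, 0.03, seed=1)
        b, _ = simulate_reference(1, 1500, 0.03, seed=2)
        assert a != b

    def test_realized_cpg_count_near_expectation(self):
        # pooled over several seeds so a single 3-sigma draw cannot trip
        # the binomial check
        length, p, n_rep = 10_000, 0.05, 5
        total = 0.0
        for seed in range(n_rep):
            _, cyt_map = simulate_reference(1, length, p, seed=seed)
            total += (cyt_map.contexts == "CG").sum() / 2  # both strands listed
        n_steps = length / (1 + p)
        expected = p * n_steps * n_rep
        sd = np.sqrt(n_steps * p * (1 - p) * n_rep)
        assert abs(total - expected) <= 3 * sd

    def test_context_map_matches_classifier(self):
        seqs, cyt_map = simulate_reference(1, 3000, 0.04, seed=5)
        seq = seqs["chr1"]
        for i in range(len(cyt_map)):
            ctx = classify_context(seq, int(cyt_map.positions[i]) - 1, str(cyt_map.strands[i]))
            assert ctx == cyt_map.contexts[i]

    def test_map_covers_every_interior_cytosine(self):
        seqs, cyt_map = simulate_reference(1, 2000, 0.04, seed=6)
        seq = seqs["chr1"]
        mapped = set(zip(cyt_map.positions - 1, cyt_map.strands))
        for i, base in enumerate(seq):
            if base == "C" and i < len(seq) - 2:
                assert (i, "+") in mapped
            if base == "G" and i >= 2:
                assert (i, "-") in mapped


class TestPlantTruth:
    def _cg_map(self, seed=7):
        _, cyt_map = simulate_reference(1, 120_000, 0.02, seed=seed)
        return cyt_map.subset(cyt_map.contexts == "CG")

    def test_planted_dmrs_non_overlapping_and_sized(self):
        cg = self._cg_map()
        truth = plant_truth(cg, n_dmrs=10, dmr_n_cpg=8, delta=0.5, seed=1)
        assert len(truth.planted_dmrs) == 10
        by_pos = sorted(truth.planted_dmrs, key=lambda d: d.start)
        for a, b in zip(by_pos, by_pos[1:]):
            assert a.end <= b.start
        for d in truth.planted_dmrs:
            assert d.index_hi - d.index_lo + 1 == 8

    def test_group_rates_differ_by_exactly_delta_inside_dmrs(self):
        cg = self._cg_map()
        truth = plant_truth(cg, n_dmrs=5, dmr_n_cpg=10, delta=0.4, seed=2)
        diff = truth.rates_g1 - truth.rates_g2
        inside = np.zeros(len(cg), dtype=bool)
        for d in truth.planted_dmrs:
            np.testing.assert_allclose(
                np.abs(diff[d.index_lo : d.index_hi + 1]), 0.4, atol=1e-12
            )
            inside[d.index_lo : d.index_hi + 1] = True
        np.testing.assert_allclose(diff[~inside], 0.0)

    def test_rates_stay_in_unit_interval(self):
        cg = self._cg_map()
        truth = plant_truth(cg, n_dmrs=15, dmr_n_cpg=10, delta=0.8, seed=3)
        for arr in (truth.rates_g1, truth.rates_g2, truth.baseline_rates):
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_baseline_is_bimodal(self, rng):
        rates = sample_baseline_rates(20_000, rng)
        assert (rates > 0.8).mean() > 0.4  # high mode dominates
        assert (rates < 0.2).mean() > 0.1  # low mode present


class TestSimulateCounts:
    def _setup(self, seed=11, **kwargs):
        _, cyt_map = simulate_reference(1, 60_000, 0.02, seed=1)
        cg = cyt_map.subset(cyt_map.contexts == "CG")
        truth = plant_truth(cg, seed=2, n_dmrs=0, **kwargs)
        return cg, truth

    def test_high_coverage_low_dispersion_recovers_true_rates(self):
        cg, truth = self._setup(dispersion=1e-6)
        records, names, _ = simulate_counts(cg, truth, n_per_group=1,
                                            mean_coverage=10_000, seed=3)
        rates = np.array([r.rate for r in records[0]])
        true = truth.rates_g1[: len(rates)]
        assert np.abs(rates - true).max() < 0.01 * 3 + 0.02

    def test_zero_delta_group_means_close(self):
        cg, truth = self._setup()
        records, names, _ = simulate_counts(cg, truth, n_per_group=4,
                                            mean_coverage=30, seed=4)
        matrix = build_sample_matrix(records, names, min_coverage_per_sample=1)
        summary = summarize_groups(matrix, names[:4], names[4:], min_samples=3)
        assert np.abs(summary.diff).mean() < 0.1

    def test_moments_match_beta_binomial_closed_forms(self):
        """Across many positions at fixed coverage and rate, the mean and
        variance of n_meth/coverage match E=p and
        Var = p(1-p)(1+(c-1)rho)/c within 3 SE."""
        rng = np.random.default_rng(9)
        n, cov, p, rho = 5000, 30, 0.3, 0.1
        from methtk.simulate import _beta_binomial

        draws = _beta_binomial(rng, np.full(n, cov), np.full(n, p), rho) / cov
        var_expected = p * (1 - p) * (1 + (cov - 1) * rho) / cov
        se_mean = np.sqrt(var_expected / n)
        assert abs(draws.mean() - p) < 3 * se_mean
        # SE of the sample variance via the empirical fourth moment
        m4 = np.mean((draws - draws.mean()) ** 4)
        se_var = np.sqrt((m4 - var_expected**2) / n)
        assert abs(draws.var() - var_expected) < 3 * se_var

    def test_determinism(self):
        cg, truth = self._setup()
        a, _, _ = simulate_counts(cg, truth, 2, 20, seed=5)
        b, _, _ = simulate_counts(cg, truth, 2, 20, seed=5)
        assert a == b


class TestSimulateReads:
    def _ref(self):
        return simulate_reference(1, 6000, 0.05, seed=21)

    def test_rate_one_calls_back_fully_methylated(self, tmp_path):
        seqs, cyt_map = self._ref()
        bam = tmp_path / "r1.bam"
        simulate_reads(seqs, cyt_map, np.ones(len(cyt_map)), bam,
                       n_fragments=400, seed=1)
        records = call_methylation(bam, seqs, LAX)
        assert records and all(r.rate == 1.0 for r in records)

    def test_rate_zero_calls_back_unmethylated(self, tmp_path):
        seqs, cyt_map = self._ref()
        bam = tmp_path / "r0.bam"
        simulate_reads(seqs, cyt_map, np.zeros(len(cyt_map)), bam,
                       n_fragments=400, seed=2)
        records = call_methylation(bam, seqs, LAX)
        assert records and all(r.rate == 0.0 for r in records)

    def test_intermediate_rate_within_binomial_interval(self, tmp_path):
        seqs, cyt_map = self._ref()
        bam = tmp_path / "half.bam"
        simulate_reads(seqs, cyt_map, np.full(len(cyt_map), 0.5), bam,
                       n_fragments=4000, seed=3)
        records = call_methylation(bam, seqs, LAX)
        n_meth = sum(r.n_meth for r in records)
        total = sum(r.coverage for r in records)
        # pooled rate is a binomial proportion at p=0.5
        se = 0.5 / np.sqrt(total)
        assert abs(n_meth / total - 0.5) < 4 * se

    def test_overlapping_mates_counted_once(self, tmp_path):
        seqs, cyt_map = self._ref()
        bam = tmp_path / "ov.bam"
        # fragment shorter than two read lengths forces mate overlap
        simulate_reads(seqs, cyt_map, np.ones(len(cyt_map)), bam,
                       n_fragments=200, read_length=80, fragment_length=120, seed=4)
        records = call_methylation(bam, seqs, LAX)
        # 200 fragments: no position can exceed fragment coverage
        assert max(r.coverage for r in records) <= 200

    def test_error_rate_reflected_in_nm_tags(self, tmp_path):
        import pysam

        seqs, cyt_map = self._ref()
        bam = tmp_path / "err.bam"
        simulate_reads(seqs, cyt_map, np.zeros(len(cyt_map)), bam,
                       n_fragments=300, error_rate=0.01, seed=5)
        with pysam.AlignmentFile(str(bam)) as fh:
            nm = sum(read.get_tag("NM") for read in fh.fetch())
            bases = sum(read.query_length for read in fh.fetch())
        assert 0 < nm / bases < 0.02

    def test_conversion_rate_bounds_enforced(self, tmp_path):
        seqs, cyt_map = self._ref()
        with pytest.raises(ValueError):
            simulate_reads(seqs, cyt_map, np.ones(len(cyt_map)),
                           tmp_path / "x.bam", conversion_rate=0.5)


class TestSimulateExpression:
    def _dmr_meth(self, rng, n_dmrs=6, n_samples=8):
        import pandas as pd

        data = rng.random((n_dmrs, n_samples))
        return pd.DataFrame(
            data,
            index=[f"true_dmr_{i + 1}" for i in range(n_dmrs)],
            columns=[f"s{j}" for j in range(n_samples)],
        )

    def test_noise_free_links_have_unit_correlation(self, rng):
        meth = self._dmr_meth(rng)
        truth = SimulationTruth([], np.array([]), np.array([]), np.array([]), 0.1)
        table, links = simulate_expression(truth, meth, noise_sd=0.0, seed=1)
        for dmr_name, gene, sign in links:
            r = np.corrcoef(meth.loc[dmr_name], table.loc[gene])[0, 1]
            assert r == pytest.approx(float(sign))

    def test_unlinked_genes_uncorrelated_on_average(self, rng):
        meth = self._dmr_meth(rng, n_dmrs=2)
        truth = SimulationTruth([], np.array([]), np.array([]), np.array([]), 0.1)
        rs = []
        for seed in range(40):
            table, _ = simulate_expression(truth, meth, noise_sd=0.0,
                                           n_unlinked_genes=1, seed=seed)
            rs.append(np.corrcoef(meth.iloc[0], table.loc["bg_gene_1"])[0, 1])
        assert abs(np.mean(rs)) < 0.15

    def test_expression_non_negative(self, rng):
        meth = self._dmr_meth(rng)
        truth = SimulationTruth([], np.array([]), np.array([]), np.array([]), 0.1)
        table, _ = simulate_expression(truth, meth, noise_sd=2.0, seed=3)
        assert (table.to_numpy() >= 0).all()


class TestCrossModuleConsistency:
    def test_noise_free_pipeline_reproduces_truth_exactly(self, tmp_path):
        """simulate -> call -> filter -> summarize at error 0, conversion 1
        and binary rates returns the planted rates at every covered
        position."""
        seqs, cyt_map = simulate_reference(1, 8000, 0.04, seed=31)
        # binary truth: deterministic per-read outcomes
        rng = np.random.default_rng(32)
        true_rates = (rng.random(len(cyt_map)) < 0.5).astype(float)
        bam = tmp_path / "e2e.bam"
        simulate_reads(seqs, cyt_map, true_rates, bam, n_fragments=3000, seed=33)
        records = call_methylation(bam, seqs, CallingOptions(min_base_quality=0))
        kept, _ = filter_records(
            records,
            FilterSpec(min_coverage=1, max_coverage=None,
                       max_coverage_quantile=None, contexts={"CG", "CHG", "CHH"}),
        )
        rate_by_pos = {
            (str(c), int(p), str(s)): float(r)
            for c, p, s, r in zip(
                cyt_map.chroms, cyt_map.positions, cyt_map.strands, true_rates
            )
        }
        assert kept
        for rec in kept:
            assert rec.rate == rate_by_pos[(rec.chrom, rec.pos, rec.strand)]

    def test_case_control_preset_writes_complete_study(self, tmp_path):
        manifest = simulate_case_control(tmp_path / "study", seed=9,
                                         length=60_000, n_dmrs=5)
        assert len(manifest["samples"]) == 8
        assert (tmp_path / "study" / "truth.json").exists()
        assert (tmp_path / "study" / "expression.tsv").exists()
        truth = manifest["_truth_obj"]
        assert len(truth.planted_dmrs) == 5
        assert len(truth.expression_links) == 5

    def test_preset_deterministic_given_seed(self, tmp_path):
        m1 = simulate_case_control(tmp_path / "a", seed=5, length=40_000, n_dmrs=3)
        m2 = simulate_case_control(tmp_path / "b", seed=5, length=40_000, n_dmrs=3)
        for name in m1["samples"]:
            a = open(m1["samples"][name]).read()
            b = open(m2["samples"][name]).read()
            assert a == b
        assert open(m1["expression"]).read() == open(m2["expression"]).read()
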