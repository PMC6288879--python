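"""Simulation-layer behavior: drift, selection, pooled sampling, RNA counts."""

import numpy as np
import pandas as pd
import pytest

from evoreseq.config import ConfigError, EvolveConfig, PoolSeqConfig, RnaSimConfig
from evoreseq.sim import sample_pool_reads, simulate_er, simulate_rnaseq


def _alt_ref_counts(sync, truth, label):
    c = np.array([list(map(int, s.split(":"))) for s in sync[label]])
    alt_i = np.array(["ATCG".index(b) for b in truth.loci["alt"]])
    ref_i = np.array(["ATCG".index(b) for b in truth.loci["ref"]])
    idx = np.arange(len(c))
    return c[idx, alt_i], c[idx, ref_i], c[:, :4].sum(axis=1)


class TestEvolve:
    def test_no_evolution_returns_founder_freqs(self):
        cfg = EvolveConfig(n_loci=50, generations=0, s=0.5, n_selected_loci=10)
        truth, freqs = simulate_er(cfg, 42)
        expected = truth.loci["founder_freq"].to_numpy()
        assert np.allclose(freqs.to_numpy(), expected[:, None])

    def test_fixation_is_absorbing(self):
        cfg = EvolveConfig(n_loci=20, generations=15, founder_freq_dist=("uniform", 1.0, 1.0))
        _, freqs = simulate_er(cfg, 1)
        assert (freqs.to_numpy() == 1.0).all()

    def test_frequencies_stay_in_unit_interval(self):
        cfg = EvolveConfig(n_loci=200, generations=10, n_selected_loci=50, s=0.4, block_rho=0.5)
        _, freqs = simulate_er(cfg, 7)
        f = freqs.to_numpy()
        assert ((f >= 0) & (f <= 1)).all()

    def test_seed_reproducibility(self):
        cfg = EvolveConfig(n_loci=100, generations=5)
        _, f1 = simulate_er(cfg, 9)
        _, f2 = simulate_er(cfg, 9)
        assert f1.equals(f2)

    def test_selection_mean_matches_deterministic_recursion(self):
        """Replicate mean vs iterated p' = p(1+s)/(1+ps).

        At large N the agreement is within Monte-Carlo error; at N = 50 the
        concave selection map makes the mean lag slightly below the
        recursion (Jensen), so only a bounded deficit is required there.
        """
        p = 0.5
        for _ in range(10):
            p = p * 1.2 / (1 + 0.2 * p)
        big = EvolveConfig(
            n_pairs=1, generations=10, n_mothers=20000, n_loci=4000,
            n_selected_loci=4000, s=0.2, founder_freq_dist=("uniform", 0.5, 0.5), block_size=1,
        )
        _, freqs = simulate_er(big, 8)
        sel = freqs["selA"].to_numpy()
        se = sel.std(ddof=1) / np.sqrt(sel.size)
        assert abs(sel.mean() - p) < 3 * se
        small = EvolveConfig(
            n_pairs=1, generations=10, n_mothers=50, n_loci=10000,
            n_selected_loci=10000, s=0.2, founder_freq_dist=("uniform", 0.5, 0.5), block_size=1,
        )
        _, freqs = simulate_er(small, 77)
        m = freqs["selA"].mean()
        assert m < p and p - m < 0.015

    def test_drift_mean_preserved_and_variance_grows(self):
        cfg = EvolveConfig(
            n_pairs=2, n_mothers=25, n_loci=4000, generations=0,
            founder_freq_dist=("uniform", 0.5, 0.5), block_size=1,
        )
        variances = []
        for t in (2, 5, 10):
            c = EvolveConfig(
                n_pairs=2, n_mothers=25, n_loci=4000, generations=t,
                founder_freq_dist=("uniform", 0.5, 0.5), block_size=1,
            )
            _, f = simulate_er(c, 13)
            pooled = f.to_numpy().ravel()
            assert abs(pooled.mean() - 0.5) < 3 * pooled.std() / np.sqrt(pooled.size)
            variances.append(pooled.var())
        assert variances[0] < variances[1] < variances[2]
        # diploid scaling: var_t = p(1-p) (1 - (1 - 1/(2N))^t)
        n = 2 * 25
        expected = 0.25 * (1 - (1 - 1 / n) ** 10)
        assert variances[2] == pytest.approx(expected, rel=0.1)

    def test_haplodiploid_without_male_contribution_equals_diploid(self):
        kw = dict(n_loci=300, generations=6, n_pairs=2)
        _, f_dip = simulate_er(EvolveConfig(ploidy_model="diploid", **kw), 3)
        _, f_hap = simulate_er(
            EvolveConfig(ploidy_model="haplodiploid", male_contribution=False, **kw), 3
        )
        assert np.array_equal(f_dip.to_numpy(), f_hap.to_numpy())

    def test_invalid_config_raises(self):
        with pytest.raises(ConfigError):
            EvolveConfig(n_selected_loci=10, n_loci=5)
        with pytest.raises(ConfigError):
            EvolveConfig(block_rho=1.5)
        with pytest.raises(ConfigError):
            EvolveConfig(s=-0.1)


class TestPoolReads:
    def test_monomorphic_site_all_reference(self):
        cfg = EvolveConfig(n_pairs=1, n_loci=30, generations=0, founder_freq_dist=("uniform", 0.0, 0.0))
        truth, _ = simulate_er(cfg, 2)
        pool = PoolSeqConfig(mean_coverage_per_library=[50, 50], coverage_dispersion=0.0, error_rate=0.0)
        sync = sample_pool_reads(truth, pool, 3)
        alt, ref, cov = _alt_ref_counts(sync, truth, "selA")
        assert (ref == 50).all() and (alt == 0).all() and (cov == 50).all()

    def test_no_error_gives_at_most_two_alleles(self):
        cfg = EvolveConfig(n_pairs=2, n_loci=100, generations=3)
        truth, _ = simulate_er(cfg, 4)
        pool = PoolSeqConfig(mean_coverage_per_library=[40] * 4, error_rate=0.0)
        sync = sample_pool_reads(truth, pool, 5)
        for lab in truth.line_freqs.columns:
            c = np.array([list(map(int, s.split(":"))) for s in sync[lab]])
            assert ((c[:, :4] > 0).sum(axis=1) <= 2).all()

    def test_counts_sum_to_coverage_with_errors(self):
        cfg = EvolveConfig(n_pairs=1, n_loci=200, generations=2)
        truth, _ = simulate_er(cfg, 6)
        pool = PoolSeqConfig(mean_coverage_per_library=[80, 30], coverage_dispersion=0.0, error_rate=0.05)
        sync = sample_pool_reads(truth, pool, 7)
        for lab, cov in zip(truth.line_freqs.columns, (80, 30)):
            c = np.array([list(map(int, s.split(":"))) for s in sync[lab]])
            assert (c[:, :4].sum(axis=1) == cov).all()

    def test_two_stage_compound_binomial_variance(self):
        """Read-frequency variance = p(1-p) (1/(2n) + (1 - 1/(2n))/C)."""
        cfg = EvolveConfig(n_pairs=1, n_loci=10000, generations=0, founder_freq_dist=("uniform", 0.5, 0.5))
        truth, _ = simulate_er(cfg, 5)
        pool = PoolSeqConfig(
            pool_females=40, mean_coverage_per_library=[100, 100],
            coverage_dispersion=0.0, error_rate=0.0,
        )
        sync = sample_pool_reads(truth, pool, 6)
        alt, ref, _ = _alt_ref_counts(sync, truth, "selA")
        freq = alt / (alt + ref)
        theory = 0.25 * (1 / 80 + (1 - 1 / 80) / 100)
        assert freq.var() == pytest.approx(theory, rel=0.05)

    def test_coverage_count_mismatch_raises(self):
        cfg = EvolveConfig(n_pairs=2, n_loci=10, generations=0)
        truth, _ = simulate_er(cfg, 1)
        with pytest.raises(ConfigError):
            sample_pool_reads(truth, PoolSeqConfig(mean_coverage_per_library=[50]), 2)


class TestRnaSim:
    def test_poisson_limit_mean(self):
        """phi = 0, no line effects, no DE: counts are Poisson at L_j q_g."""
        cfg = RnaSimConfig(
            n_transcripts=3000, n_de=0, n_onoff=0, dispersion=0.0,
            line_effect_sd=0.0, within_pair_sd=0.0, lib_size_range=(1_000_000, 1_000_000),
        )
        counts, truth = simulate_rnaseq(cfg, 4, 11)
        lib = 1_000_000
        # pooled z-score across transcripts: observed vs expected mean
        y = counts.to_numpy(float)
        mu = y.mean(axis=1)
        # per-transcript expectation is unknown without q, but totals match lib size
        assert counts.sum(axis=0).to_numpy().mean() == pytest.approx(lib, rel=0.01)
        # Poisson: variance over the 8 iid libraries ~= mean
        big = mu > 50
        ratio = (y[big].var(axis=1, ddof=1) / mu[big]).mean()
        assert ratio == pytest.approx(1.0, abs=0.1)

    def test_onoff_zero_in_off_regime(self):
        cfg = RnaSimConfig(n_transcripts=100, n_de=20, n_onoff=20, within_pair_sd=0.0)
        counts, truth = simulate_rnaseq(cfg, 4, 12)
        t = truth.transcripts
        sel_cols = [c for c in counts.columns if c.startswith("sel")]
        ctl_cols = [c for c in counts.columns if c.startswith("ctl")]
        for tid, row in t[t["onoff"]].iterrows():
            off_cols = sel_cols if row["direction"] < 0 else ctl_cols
            assert (counts.loc[tid, off_cols] == 0).all()

    def test_planted_lfc_recovered_in_cpm_ratio(self):
        cfg = RnaSimConfig(
            n_transcripts=4000, n_de=400, n_onoff=0, dispersion=0.01,
            line_effect_sd=0.0, within_pair_sd=0.0, true_lfc_dist=("uniform_signed", 2.0, 2.0),
            lib_size_range=(5_000_000, 5_000_000),
        )
        counts, truth = simulate_rnaseq(cfg, 4, 13)
        t = truth.transcripts
        up = t.index[(t["de"]) & (t["direction"] > 0)]
        cpm = counts / counts.sum(axis=0) * 1e6
        sel = cpm.loc[up, [c for c in counts.columns if c.startswith("sel")]].mean(axis=1)
        ctl = cpm.loc[up, [c for c in counts.columns if c.startswith("ctl")]].mean(axis=1)
        big = ctl > 5
        ratios = (sel[big] / ctl[big]).to_numpy()
        assert np.median(ratios) == pytest.approx(4.0, rel=0.15)

    def test_opposite_splice_variants_share_locus(self):
        cfg = RnaSimConfig(n_transcripts=50, n_de=10, n_onoff=0)
        _, truth = simulate_rnaseq(cfg, 4, 14)
        t = truth.transcripts
        first_two = t.iloc[:2]
        assert first_two["locus"].nunique() == 1
        assert np.sign(first_two["true_lfc"].iloc[0]) == -np.sign(first_two["true_lfc"].iloc[1])
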