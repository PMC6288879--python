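"""Differential-expression screen: CPM filter, TMM, the three methods,
fold-change/concordance filters and the consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from evoreseq.config import RnaSimConfig
from evoreseq.de import (
    cpm,
    cpm_filter,
    fold_change,
    glm_lrt,
    pairwise_chisq,
    parse_labels,
    pca_screen,
    run_de,
    tmm_normalize,
)
from evoreseq.sim import simulate_rnaseq


def _labels():
    return ["selA", "ctlA", "selB", "ctlB", "selC", "ctlC", "selD", "ctlD"]


def _reference_tmm(counts, trim_m=0.3, trim_a=0.05):
    """Clean-room TMM oracle written directly from the published formulas."""
    y = counts.to_numpy(float)
    n = y.sum(axis=0)
    f75 = np.array([np.quantile(y[:, j] / n[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(abs(f75 - f75.mean())))
    fs = []
    for j in range(y.shape[1]):
        ok = (y[:, j] > 0) & (y[:, ref] > 0)
        xj, xr = y[ok, j], y[ok, ref]
        M = np.log2((xj / n[j]) / (xr / n[ref]))
        A = 0.5 * np.log2((xj / n[j]) * (xr / n[ref]))
        w = (n[j] - xj) / (n[j] * xj) + (n[ref] - xr) / (n[ref] * xr)
        G = M.size
        loM, hiM = np.floor(G * trim_m) + 1, G - np.floor(G * trim_m)
        loA, hiA = np.floor(G * trim_a) + 1, G - np.floor(G * trim_a)
        rM, rA = sps.rankdata(M), sps.rankdata(A)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if abs(M).max() < 1e-6 or not keep.any():
            fs.append(1.0)
        else:
            fs.append(2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])))
    fs = np.array(fs)
    return fs / np.exp(np.mean(np.log(fs)))


class TestCpmFilter:
    def test_retention_rules(self):
        # both library sizes exactly 2,000,000
        counts = pd.DataFrame(
            {
                "selA": [4, 0, 1, 1_999_995],
                "ctlA": [0, 0, 1, 1_999_999],
            },
            index=["keep", "dropzero", "droplow", "filler"],
        )
        out = cpm_filter(counts, min_cpm=1.0)
        assert "keep" in out.index  # CPM 2 in selA
        assert "dropzero" not in out.index
        assert "droplow" not in out.index  # CPM 0.5 in every library
        assert "filler" in out.index

    def test_zero_library_raises(self):
        with pytest.raises(ValueError):
            cpm_filter(pd.DataFrame({"a": [1], "b": [0]}))


class TestTmm:
    def test_elementwise_doubling_gives_unit_factors(self):
        rng = np.random.default_rng(1)
        x = rng.negative_binomial(5, 0.01, size=500)
        counts = pd.DataFrame({"a": x, "b": 2 * x})
        f = tmm_normalize(counts)
        assert np.allclose(f.to_numpy(), 1.0, atol=1e-9)

    def test_single_shared_transcript_gives_exact_m(self):
        counts = pd.DataFrame({"a": [100, 50, 0], "b": [100, 0, 80]})
        f = tmm_normalize(counts)
        # only the first transcript is positive in both; factor = 2^M rescaled
        na, nb = 150, 180
        m = np.log2((100 / nb) / (100 / na))  # library b vs reference
        expected_b = 2**m
        g = np.sqrt(expected_b)  # geometric-mean rescaling with f_a = 1
        assert f["b"] / f["a"] == pytest.approx(expected_b, rel=1e-9)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_cleanroom_reference_on_random_nb(self):
        rng = np.random.default_rng(9)
        q = rng.lognormal(0, 1.5, 1500)
        libs = rng.integers(5e5, 2e6, 8)
        mu = q[:, None] / q.sum() * libs[None, :]
        counts = pd.DataFrame(rng.negative_binomial(10, 10 / (10 + mu)), columns=_labels())
        mine = tmm_normalize(counts).to_numpy()
        ref = _reference_tmm(counts)
        assert np.allclose(mine, ref, rtol=0.02)
        assert np.exp(np.mean(np.log(mine))) == pytest.approx(1.0, abs=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.002, size=(800, 8)), columns=_labels()
        )
        f = tmm_normalize(counts)
        perm = list(reversed(_labels()))
        f2 = tmm_normalize(counts[perm])
        assert np.allclose(f[perm].to_numpy(), f2.to_numpy(), atol=1e-12)


class TestGlmLrt:
    def test_poisson_limit_matches_statsmodels(self, rna_planted):
        import statsmodels.api as sm

        from evoreseq.de import _design

        _, counts, _ = rna_planted
        counts = counts.head(120)
        pairs, regime, pair_idx = parse_labels(counts.columns)
        res = glm_lrt(counts, regime, pair_idx, dispersion=0.0)
        Xf = _design(regime, pair_idx, True)
        Xr = _design(regime, pair_idx, False)
        off = np.log(counts.sum(axis=0).to_numpy(float))
        for i in range(0, 120, 17):
            y = counts.iloc[i].to_numpy(float)
            if y.sum() == 0:
                continue
            mf = sm.GLM(y, Xf, family=sm.families.Poisson(), offset=off).fit()
            mr = sm.GLM(y, Xr, family=sm.families.Poisson(), offset=off).fit()
            assert res["lrt"].iloc[i] == pytest.approx(2 * (mf.llf - mr.llf), abs=1e-3)

    def test_null_p_values_approximately_uniform(self):
        cfg = RnaSimConfig(n_transcripts=2000, n_de=0, n_onoff=0, line_effect_sd=0.4)
        counts, _ = simulate_rnaseq(cfg, 4, 501)
        counts = cpm_filter(counts)
        pairs, regime, pair_idx = parse_labels(counts.columns)
        res = glm_lrt(counts, regime, pair_idx, factors=tmm_normalize(counts))
        ks = sps.kstest(res["p"], "uniform")
        assert ks.statistic < 0.05

    def test_power_at_fourfold_effect(self):
        cfg = RnaSimConfig(
            n_transcripts=2000, n_de=100, n_onoff=0, dispersion=0.05,
            true_lfc_dist=("uniform_signed", 2.0, 2.0), lib_size_range=(5_000_000, 5_000_000),
        )
        counts, truth = simulate_rnaseq(cfg, 4, 502)
        counts = cpm_filter(counts)
        pairs, regime, pair_idx = parse_labels(counts.columns)
        res = glm_lrt(counts, regime, pair_idx, factors=tmm_normalize(counts))
        de_ids = truth.transcripts.index[truth.transcripts["de"]]
        de_ids = [t for t in de_ids if t in res.index]
        frac = (res.loc[de_ids, "p_adj"] < 0.05).mean()
        assert frac >= 0.95


class TestPairwiseChisq:
    def test_matches_generic_contingency_oracle(self):
        rng = np.random.default_rng(5)
        xs = rng.integers(1, 500, size=200)
        xc = rng.integers(1, 500, size=200)
        counts = pd.DataFrame({"selA": xs, "ctlA": xc})
        res = pairwise_chisq(counts, "selA", "ctlA")
        ss, sc = xs.sum(), xc.sum()
        for i in range(0, 200, 13):
            table = np.array([[xs[i], ss - xs[i]], [xc[i], sc - xc[i]]])
            chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
            assert res["chi2"].iloc[i] == pytest.approx(chi2, abs=1e-6, rel=1e-9)
            assert res["p"].iloc[i] == pytest.approx(p, abs=1e-9)

    def test_identical_counts_and_subtotals_give_null(self):
        counts = pd.DataFrame({"selA": [30, 70], "ctlA": [30, 70]})
        res = pairwise_chisq(counts, "selA", "ctlA")
        assert np.allclose(res["chi2"], 0) and np.allclose(res["p"], 1)

    def test_chi2_scales_with_total_at_fixed_proportions(self):
        counts = pd.DataFrame({"selA": [30, 1000], "ctlA": [10, 1020]})
        doubled = counts * 2
        c1 = pairwise_chisq(counts, "selA", "ctlA")["chi2"]
        c2 = pairwise_chisq(doubled, "selA", "ctlA")["chi2"]
        assert np.allclose(c2, 2 * c1)


class TestPcaScreen:
    def test_regime_as_dominant_axis_chooses_pc1(self):
        rng = np.random.default_rng(6)
        G, labels = 300, _labels()
        pairs, regime, pair_idx = parse_labels(labels)
        base = rng.normal(8, 1, size=(G, 1))
        effect = np.zeros((G, 8))
        effect[:50] = 3.0 * regime[None, :]
        logcpm = pd.DataFrame(base + effect + rng.normal(0, 0.1, (G, 8)), columns=labels)
        pc, res = pca_screen(logcpm, regime, pair_idx)
        assert pc == 1
        top = res["p"].nsmallest(50).index
        assert len(set(top) & set(range(50))) >= 45

    def test_constant_transcript_excluded(self):
        labels = _labels()
        pairs, regime, pair_idx = parse_labels(labels)
        rng = np.random.default_rng(7)
        logcpm = pd.DataFrame(rng.normal(5, 1, (50, 8)) + regime[None, :], columns=labels)
        logcpm.iloc[0] = 3.0
        pc, res = pca_screen(logcpm, regime, pair_idx)
        assert np.isnan(res["r"].iloc[0]) and np.isnan(res["p"].iloc[0])

    def test_pair_structure_pushes_regime_to_higher_pc(self):
        """With a dominant line-pair axis (pairs A,B vs C,D), the regime axis
        is not PC 1 yet the screen recovers at least half of the transcripts
        planted at a two-unit log2 shift."""
        labels = _labels()
        pairs, regime, pair_idx = parse_labels(labels)
        ab_cd = np.array([1, 1, 1, 1, -1, -1, -1, -1], float)
        reg_sign = np.where(regime == 1, 1.0, -1.0)
        pcs, recalls = [], []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            G, nde = 600, 60
            pair_load = rng.normal(0, 0.8, G)
            lfc = np.zeros(G)
            lfc[:nde] = rng.choice([-1.0, 1.0], nde) * 2
            # keep the pair axis orthogonal to the planted regime loadings
            pair_load = pair_load - (pair_load @ lfc) / (lfc @ lfc) * lfc
            X = (
                pair_load[:, None] * ab_cd[None, :]
                + (lfc[:, None] / 2) * reg_sign[None, :]
                + rng.normal(0, 0.25, (G, 8))
            )
            pc, res = pca_screen(pd.DataFrame(X, columns=labels), regime, pair_idx)
            pcs.append(pc if pc is not None else 0)
            recalls.append((res["p"].iloc[:nde] < 0.05).mean())
        assert np.median(pcs) > 1
        assert np.mean(recalls) >= 0.5


class TestFoldChangeAndConsensus:
    def test_fold_change_arithmetic(self):
        labels = _labels()
        pairs, regime, pair_idx = parse_labels(labels)
        cpm_df = pd.DataFrame(
            [[0, 7.5] * 4, [4, 4] * 4], columns=labels, index=["down", "flat"], dtype=float
        )
        fc = fold_change(cpm_df, regime, pair_idx, pairs, prior=0.5)
        assert fc.loc["down", "lfc_A"] == pytest.approx(-4.0)
        assert fc.loc["down", "lfc_overall"] == pytest.approx(-4.0)
        assert fc.loc["flat", "lfc_overall"] == pytest.approx(0.0)
        assert not fc.loc["flat", "concordant"]

    def test_discordant_pair_fails_concordance(self):
        labels = _labels()
        pairs, regime, pair_idx = parse_labels(labels)
        row = [8, 4, 8, 4, 8, 4, 4, 8]  # pair D reversed
        cpm_df = pd.DataFrame([row], columns=labels, index=["t"], dtype=float)
        fc = fold_change(cpm_df, regime, pair_idx, pairs)
        assert not fc.loc["t", "concordant"]

    def test_consensus_is_union_with_provenance(self, rna_planted):
        _, counts, truth = rna_planted
        screen = run_de(counts)
        union = screen.glm_set | screen.chisq_set | screen.pca_set
        assert screen.consensus_set == union
        assert len(union) >= max(len(screen.glm_set), len(screen.chisq_set), len(screen.pca_set))
        for tid in screen.consensus_set:
            assert screen.table.loc[tid, "significant_by"] != ""
            assert screen.table.loc[tid, "concordant"] and screen.table.loc[tid, "passes_fc"]

    def test_planted_onoff_found_by_multiple_methods(self, rna_planted):
        _, counts, truth = rna_planted
        screen = run_de(counts)
        t = truth.transcripts
        n_methods = (
            screen.table[["sig_glm_lrt", "sig_pairwise_chisq", "sig_pca_screen"]]
            .sum(axis=1)
        )
        onoff = [x for x in t.index[t["onoff"]] if x in n_methods.index]
        assert (n_methods.loc[onoff] >= 2).mean() >= 0.9
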