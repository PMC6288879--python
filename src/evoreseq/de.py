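"""Three-method consensus screen for consistent differential expression.

The screen mirrors a replicated eight-library design (four selected /
control line pairs) in which line-by-regime interactions cannot be
estimated directly, so three complementary analyses are combined with
strict concordance and fold-change filters:

1. ``glm_lrt`` — negative-binomial log-linear models of the untransformed
   raw counts with regime and line-pair effects (no interaction), common
   dispersion across transcripts, likelihood-ratio tests of the regime
   effect against chi-square(1), BH-FDR at 0.05.
2. ``pairwise_chisq`` — per line pair, a Pearson chi-square test of the
   transcript's raw counts against the two libraries' genome-wide
   subtotals (2x2 table); a transcript passes when FDR < 0.05 in all four
   pairs.
3. ``pca_screen`` — PCA of mean-centered log2 CPM (TMM-normalized);
   the lowest-index principal component that separates selected from
   control lines in all four pairs is taken as the regime axis, each
   transcript is correlated with that component's sample scores, and
   transcripts with uncorrected two-sided P < 0.05 (t, 6 df) pass.

Each method additionally requires concordant per-pair log2 fold changes
(strictly the same sign in all four pairs) and an absolute overall fold
change > 2. The consensus set is the union of the three methods'
survivors, with per-method provenance retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .divergence import adjust_fdr

__all__ = [
    "parse_labels",
    "cpm_filter",
    "tmm_normalize",
    "cpm",
    "glm_lrt",
    "estimate_common_dispersion",
    "pairwise_chisq",
    "pca_screen",
    "fold_change",
    "run_de",
    "DEScreen",
]


def parse_labels(labels: Sequence[str]) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Split library labels of the form selA/ctlA into pairs and regimes."""
    pairs = sorted({lab[3:] for lab in labels})
    regime = np.array([1 if lab.startswith("sel") else 0 for lab in labels])
    pair_idx = np.array([pairs.index(lab[3:]) for lab in labels])
    return pairs, regime, pair_idx


def cpm_filter(
    counts: pd.DataFrame, min_cpm: float = 1.0, min_libs: int = 1
) -> pd.DataFrame:
    """Drop transcripts below ``min_cpm`` in fewer than ``min_libs`` libraries.

    CPM here uses the raw, pre-filter library sizes; downstream modeling
    recomputes library sizes on the retained matrix.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    cpm_ = counts.to_numpy(dtype=float) / lib[None, :] * 1e6
    keep = (cpm_ >= min_cpm).sum(axis=1) >= min_libs
    return counts.loc[keep]


def _tmm_pair(
    x: np.ndarray, nx: float, ref: np.ndarray, nr: float, trim_m: float, trim_a: float
) -> float:
    pos = (x > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    px = x[pos] / nx
    pr = ref[pos] / nr
    m = np.log2(px / pr)
    a = 0.5 * np.log2(px * pr)
    # asymptotic variance of M (delta method); weights are its inverse
    v = (nx - x[pos]) / (nx * x[pos]) + (nr - ref[pos]) / (nr * ref[pos])
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = np.sum(w * m[keep]) / np.sum(w)
    return float(2.0**f)


def tmm_normalize(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference library is the one whose 75th-percentile CPM is closest
    to the mean across libraries. Per library, log2 expression ratios M and
    average log intensities A against the reference are doubly trimmed
    (``trim_m`` of M, ``trim_a`` of A from each tail) and the factor is two
    to the precision-weighted mean of the surviving M values.
    """
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    f75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(y[:, j], lib[j], y[:, ref], lib[ref], trim_m, trim_a)
            for j in range(y.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def cpm(counts: pd.DataFrame, factors: Optional[pd.Series] = None) -> pd.DataFrame:
    """Counts per million on (optionally TMM-) effective library sizes."""
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if factors is not None:
        lib = lib * factors.to_numpy(dtype=float)
    return counts / lib * 1e6


# ---------------------------------------------------------------------------
# negative-binomial GLM, vectorized across transcripts


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Per-transcript NB log-likelihood (Poisson when phi == 0)."""
    mu = np.maximum(mu, 1e-12)
    if phi == 0:
        ll = y * np.log(mu) - mu - special.gammaln(y + 1)
    else:
        r = 1.0 / phi
        ll = (
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    return ll.sum(axis=-1)


def _nb_irls(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, phi: float, n_iter: int = 60
) -> np.ndarray:
    """Fit log-link NB GLMs with shared design across transcripts.

    Returns fitted means (G, J). Transcripts with empty groups converge to
    near-zero means for those groups; eta is clipped for stability.
    """
    G, J = y.shape
    p = X.shape[1]
    mu = y + 0.5
    eta = np.log(mu) - offset[None, :]
    for _ in range(n_iter):
        w = mu / (1.0 + phi * mu)
        z = eta + (y - mu) / mu
        XtWX = np.einsum("ji,gj,jk->gik", X, w, X)
        XtWz = np.einsum("ji,gj->gi", X, w * z)
        beta = np.linalg.solve(XtWX + 1e-10 * np.eye(p)[None], XtWz[..., None])[..., 0]
        eta_new = beta @ X.T
        eta_new = np.clip(eta_new, -40.0, 40.0)
        if np.max(np.abs(eta_new - eta)) < 1e-10:
            eta = eta_new
            mu = np.exp(np.clip(eta + offset[None, :], -40.0, 45.0))
            break
        eta = eta_new
        mu = np.exp(np.clip(eta + offset[None, :], -40.0, 45.0))
        mu = np.maximum(mu, 1e-12)
    return mu


def _design(regime: np.ndarray, pair_idx: np.ndarray, with_regime: bool) -> np.ndarray:
    J = regime.size
    n_pairs = pair_idx.max() + 1
    cols = [np.ones(J)]
    if with_regime:
        cols.append(regime.astype(float))
    for k in range(1, n_pairs):
        cols.append((pair_idx == k).astype(float))
    return np.column_stack(cols)


def estimate_common_dispersion(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> float:
    """Common NB dispersion by adjusted profile likelihood across transcripts.

    Alternates model fits at the current dispersion with 1-D maximization
    of the Cox-Reid-adjusted likelihood summed over transcripts.
    """
    phi = 0.1
    p = X.shape[1]
    for _ in range(3):
        mu = _nb_irls(y, X, offset, phi)

        def negll(log_phi: float) -> float:
            ph = float(np.exp(log_phi))
            w = mu / (1.0 + ph * mu)
            XtWX = np.einsum("ji,gj,jk->gik", X, w, X)
            sign, logdet = np.linalg.slogdet(XtWX + 1e-10 * np.eye(p)[None])
            return -(np.sum(_nb_loglik(y, mu, ph)) - 0.5 * np.sum(logdet))

        res = optimize.minimize_scalar(negll, bounds=(-10.0, 3.0), method="bounded")
        phi_new = float(np.exp(res.x))
        if abs(np.log(phi_new) - np.log(phi)) < 1e-4:
            phi = phi_new
            break
        phi = phi_new
    return phi


def glm_lrt(
    counts: pd.DataFrame,
    regime: np.ndarray,
    pair_idx: np.ndarray,
    factors: Optional[pd.Series] = None,
    dispersion: Optional[float] = None,
) -> pd.DataFrame:
    """NB GLM likelihood-ratio test of the regime effect per transcript.

    Full model: regime + line pair; reduced: line pair only. The deviance
    difference is referred to chi-square with 1 df; P values are BH
    adjusted. ``dispersion`` fixes the common NB dispersion (0 = Poisson);
    when None it is estimated from the data under the full model.
    """
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if factors is not None:
        lib = lib * factors.to_numpy(dtype=float)
    offset = np.log(lib)
    X_full = _design(regime, pair_idx, True)
    X_red = _design(regime, pair_idx, False)
    if dispersion is None:
        dispersion = estimate_common_dispersion(y, X_full, offset)
    mu_full = _nb_irls(y, X_full, offset, dispersion)
    mu_red = _nb_irls(y, X_red, offset, dispersion)
    ll_full = _nb_loglik(y, mu_full, dispersion)
    ll_red = _nb_loglik(y, mu_red, dispersion)
    lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
    p = stats.chi2.sf(lrt, df=1)
    return pd.DataFrame(
        {"lrt": lrt, "p": p, "p_adj": adjust_fdr(p), "dispersion": dispersion},
        index=counts.index,
    )


def pairwise_chisq(
    counts: pd.DataFrame, sel_label: str, ctl_label: str
) -> pd.DataFrame:
    """Pearson chi-square of each transcript's counts vs library subtotals.

    For transcript g with counts x_s, x_c and library totals S_s, S_c, the
    2x2 table is [[x_s, S_s - x_s], [x_c, S_c - x_c]] with expected counts
    from the margins. Zero-margin tables get chi2 = 0, P = 1, flagged.
    """
    xs = counts[sel_label].to_numpy(dtype=float)
    xc = counts[ctl_label].to_numpy(dtype=float)
    ss = xs.sum()
    sc = xc.sum()
    a, b = xs, ss - xs
    c, d = xc, sc - xc
    n = ss + sc
    r1 = a + c
    r2 = b + d
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / (ss * sc * r1 * r2)
    degenerate = (r1 == 0) | (r2 == 0) | (ss == 0) | (sc == 0)
    chi2 = np.where(degenerate, 0.0, chi2)
    p = np.where(degenerate, 1.0, stats.chi2.sf(chi2, df=1))
    return pd.DataFrame(
        {"chi2": chi2, "p": p, "p_adj": adjust_fdr(p), "degenerate": degenerate},
        index=counts.index,
    )


def pca_screen(
    logcpm: pd.DataFrame, regime: np.ndarray, pair_idx: np.ndarray
) -> Tuple[Optional[int], pd.DataFrame]:
    """PCA-based screen for a consistent regime axis.

    PCA is run on per-transcript mean-centered (not variance-scaled) log2
    CPM with the eight libraries as observations. The chosen component is
    the lowest-index one whose selected-minus-control score difference has
    the same strict sign in every pair; each transcript's centered profile
    is then correlated with that component's sample scores (two-sided P
    from t with J - 2 df, uncorrected). Returns ``(pc_index, frame)`` with
    ``pc_index`` None (and an empty significance column) when no component
    separates the regimes consistently. ``pc_index`` is 1-based.
    """
    M = logcpm.to_numpy(dtype=float)  # G x J
    G, J = M.shape
    Xc = (M - M.mean(axis=1, keepdims=True)).T  # J x G, centered per transcript
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S  # J x (J-1 nontrivial + null)
    n_pc = min(J - 1, scores.shape[1])
    n_pairs = pair_idx.max() + 1
    chosen = None
    for k in range(n_pc):
        diffs = []
        for pr in range(n_pairs):
            s_sel = scores[(pair_idx == pr) & (regime == 1), k].mean()
            s_ctl = scores[(pair_idx == pr) & (regime == 0), k].mean()
            diffs.append(s_sel - s_ctl)
        diffs = np.array(diffs)
        if (diffs > 0).all() or (diffs < 0).all():
            chosen = k
            break
    if chosen is None:
        out = pd.DataFrame(
            {"r": np.nan, "p": np.nan}, index=logcpm.index
        )
        return None, out
    v = scores[:, chosen]
    xg = Xc  # J x G, already centered per transcript
    vc = v - v.mean()
    sx = np.sqrt((xg**2).sum(axis=0))
    sv = np.sqrt((vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xg * vc[:, None]).sum(axis=0) / (sx * sv)
    r = np.where(sx > 0, r, np.nan)
    df = J - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    p = np.where(np.isfinite(r), p, np.nan)
    return chosen + 1, pd.DataFrame({"r": r, "p": p}, index=logcpm.index)


def fold_change(
    cpm_df: pd.DataFrame,
    regime: np.ndarray,
    pair_idx: np.ndarray,
    pairs: Sequence[str],
    prior: float = 0.5,
    fc_log2: float = 1.0,
) -> pd.DataFrame:
    """Per-pair and overall log2 fold changes with concordance flags.

    Per pair: ``log2((CPM_sel + prior) / (CPM_ctl + prior))``; overall is
    the mean of the per-pair values; ``concordant`` requires strictly the
    same sign in every pair (zeros fail); ``passes_fc`` is
    ``|overall| > 1`` (fold change > 2).
    """
    cols = cpm_df.columns.to_numpy()
    out = {}
    for k, pr in enumerate(pairs):
        sel_col = cols[(pair_idx == k) & (regime == 1)][0]
        ctl_col = cols[(pair_idx == k) & (regime == 0)][0]
        out[f"lfc_{pr}"] = np.log2(
            (cpm_df[sel_col].to_numpy(float) + prior)
            / (cpm_df[ctl_col].to_numpy(float) + prior)
        )
    res = pd.DataFrame(out, index=cpm_df.index)
    lfc = res.to_numpy()
    res["lfc_overall"] = lfc.mean(axis=1)
    res["concordant"] = (lfc > 0).all(axis=1) | (lfc < 0).all(axis=1)
    res["passes_fc"] = np.abs(res["lfc_overall"]) > fc_log2
    return res


@dataclass
class DEScreen:
    """Results of the three-method screen and the consensus set."""

    counts: pd.DataFrame
    tmm_factors: pd.Series
    cpm: pd.DataFrame
    fold_changes: pd.DataFrame
    glm: pd.DataFrame
    chisq: Dict[str, pd.DataFrame]
    pca_component: Optional[int]
    pca: pd.DataFrame
    table: pd.DataFrame  # per-transcript summary incl. consensus membership

    @property
    def glm_set(self) -> set:
        return set(self.table.index[self.table["sig_glm_lrt"]])

    @property
    def chisq_set(self) -> set:
        return set(self.table.index[self.table["sig_pairwise_chisq"]])

    @property
    def pca_set(self) -> set:
        return set(self.table.index[self.table["sig_pca_screen"]])

    @property
    def consensus_set(self) -> set:
        return set(self.table.index[self.table["consensus"]])


def run_de(
    counts: pd.DataFrame,
    min_cpm: float = 1.0,
    fdr: float = 0.05,
    pca_alpha: float = 0.05,
    prior: float = 0.5,
    fc_threshold: float = 1.0,
    dispersion: Optional[float] = None,
) -> DEScreen:
    """Run the full consensus screen on a raw count matrix.

    Columns must be labeled ``sel<pair>``/``ctl<pair>``. Transcripts are
    CPM-filtered, TMM factors computed, the three methods applied, and the
    consensus assembled as the union of the methods' survivors (each method
    already requires concordance and fold change > 2).
    """
    pairs, regime, pair_idx = parse_labels(counts.columns)
    filt = cpm_filter(counts, min_cpm=min_cpm)
    factors = tmm_normalize(filt)
    cpm_df = cpm(filt, factors)
    fc = fold_change(cpm_df, regime, pair_idx, pairs, prior=prior, fc_log2=fc_threshold)

    glm = glm_lrt(filt, regime, pair_idx, factors=factors, dispersion=dispersion)
    chisq = {}
    for k, pr in enumerate(pairs):
        cols = filt.columns.to_numpy()
        sel_col = cols[(pair_idx == k) & (regime == 1)][0]
        ctl_col = cols[(pair_idx == k) & (regime == 0)][0]
        chisq[pr] = pairwise_chisq(filt, sel_col, ctl_col)
    logcpm = np.log2(cpm_df + prior)
    pc_index, pca = pca_screen(logcpm, regime, pair_idx)

    base = fc["concordant"] & fc["passes_fc"]
    sig_glm = (glm["p_adj"] < fdr) & base
    chisq_all = np.ones(len(filt), dtype=bool)
    for pr in pairs:
        chisq_all &= (chisq[pr]["p_adj"] < fdr).to_numpy()
    sig_chisq = pd.Series(chisq_all, index=filt.index) & base
    if pc_index is None:
        sig_pca = pd.Series(False, index=filt.index)
    else:
        sig_pca = (pca["p"] < pca_alpha).fillna(False) & base
    consensus = sig_glm | sig_chisq | sig_pca

    table = pd.DataFrame(index=filt.index)
    for pr in pairs:
        table[f"lfc_{pr}"] = fc[f"lfc_{pr}"]
    table["lfc_overall"] = fc["lfc_overall"]
    table["concordant"] = fc["concordant"]
    table["passes_fc"] = fc["passes_fc"]
    table["p_glm"] = glm["p"]
    table["p_adj_glm"] = glm["p_adj"]
    for pr in pairs:
        table[f"p_adj_chisq_{pr}"] = chisq[pr]["p_adj"]
    table["pca_r"] = pca["r"]
    table["pca_p"] = pca["p"]
    table["sig_glm_lrt"] = sig_glm
    table["sig_pairwise_chisq"] = sig_chisq
    table["sig_pca_screen"] = sig_pca
    table["consensus"] = consensus
    table["significant_by"] = [
        ",".join(
            m
            for m, f in (
                ("glm_lrt", table["sig_glm_lrt"].iloc[i]),
                ("pairwise_chisq", table["sig_pairwise_chisq"].iloc[i]),
                ("pca_screen", table["sig_pca_screen"].iloc[i]),
            )
            if f
        )
        for i in range(len(table))
    ]
    return DEScreen(
        counts=filt,
        tmm_factors=factors,
        cpm=cpm_df,
        fold_changes=fc,
        glm=glm,
        chisq=chisq,
        pca_component=pc_index,
        pca=pca,
        table=table,
    )
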