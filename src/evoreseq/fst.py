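"""Pooled F_ST between a selected line and its paired control line.

The estimator is the classical proportion-of-diversity form
``F_ST = (pi_T - pi_S) / pi_T`` with a finite-sample correction for
two-stage pooled sampling: within each pool the heterozygosity
``1 - p**2 - q**2`` is rescaled by ``n/(n-1)`` with
``n = min(coverage, 2 * pool_size)`` (reads cannot carry more information
than the chromosomes in the pool), and the total diversity uses the mean
of the two pool frequencies with the analogous ``n_a + n_b`` correction.
Negative values are reported unclamped; sites monomorphic in both pools
have undefined F_ST and are skipped.

Window summaries average per-SNP F_ST over non-sliding, tiling 10-kb
windows after discarding sites in the top coverage percentile of any
involved library (default: top 2%).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["snp_fst", "pair_snp_fst", "window_fst"]


def _pi(p: np.ndarray, n_eff: np.ndarray) -> np.ndarray:
    het = 1.0 - p**2 - (1.0 - p) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        return het * n_eff / (n_eff - 1.0)


def snp_fst(c1a, c2a, c1b, c2b, pool_size: int):
    """Per-SNP pooled F_ST from allele counts of pools a and b.

    Accepts scalars or arrays. Returns NaN where total diversity is zero
    (monomorphic in both pools) or coverage <= 1 in either pool.
    """
    c1a, c2a, c1b, c2b = (np.asarray(c, dtype=float) for c in (c1a, c2a, c1b, c2b))
    ca = c1a + c2a
    cb = c1b + c2b
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = c1a / ca
        pb = c1b / cb
        na = np.minimum(ca, 2.0 * pool_size)
        nb = np.minimum(cb, 2.0 * pool_size)
        pi_a = _pi(pa, na)
        pi_b = _pi(pb, nb)
        p_t = 0.5 * (pa + pb)
        pi_t = _pi(p_t, na + nb)
        pi_s = 0.5 * (pi_a + pi_b)
        fst = np.where(
            (ca > 1) & (cb > 1) & (pi_t > 0), (pi_t - pi_s) / np.where(pi_t > 0, pi_t, 1.0), np.nan
        )
    if fst.ndim == 0:
        return float(fst)
    return fst


def pair_snp_fst(
    table: pd.DataFrame, sel_label: str, ctl_label: str, pool_size: int = 40
) -> pd.DataFrame:
    """Per-SNP F_ST for one selected/control pair from an AlleleCountTable."""
    c1a = table[f"{sel_label}_c1"].to_numpy(float)
    c2a = table[f"{sel_label}_c2"].to_numpy(float)
    c1b = table[f"{ctl_label}_c1"].to_numpy(float)
    c2b = table[f"{ctl_label}_c2"].to_numpy(float)
    out = table[["chrom", "pos"]].copy()
    out["cov_a"] = c1a + c2a
    out["cov_b"] = c1b + c2b
    out["fst"] = snp_fst(c1a, c2a, c1b, c2b, pool_size)
    return out


def window_fst(
    snps: pd.DataFrame,
    window: int = 10_000,
    max_cov_quantile: float = 0.98,
    pair: Optional[str] = None,
    coverage_cols: Sequence[str] = ("cov_a", "cov_b"),
) -> pd.DataFrame:
    """Average per-SNP F_ST over tiling windows.

    ``snps`` must carry ``chrom``, ``pos``, ``fst`` and per-library
    coverage columns. Sites in the top ``1 - max_cov_quantile`` of any
    listed library's empirical coverage distribution are excluded before
    averaging. Windows are 1-based ``[start, start + window - 1]`` tiling
    each scaffold from 1 to the last SNP; empty windows are emitted with
    ``n_snps = 0`` and missing value.
    """
    snps = snps.reset_index(drop=True)
    keep = np.ones(len(snps), dtype=bool)
    for col in coverage_cols:
        if col in snps:
            thr = np.quantile(snps[col].to_numpy(float), max_cov_quantile)
            keep &= snps[col].to_numpy(float) <= thr
    keep &= np.isfinite(snps["fst"].to_numpy(float))
    rows = []
    for chrom, sub_all in snps.groupby("chrom", sort=True):
        sub = sub_all[keep[sub_all.index.to_numpy()]] if len(snps) else sub_all
        last = int(sub_all["pos"].max())
        n_win = (last - 1) // window + 1
        idx = (sub["pos"].to_numpy(np.int64) - 1) // window
        for w in range(n_win):
            members = sub[idx == w] if len(sub) else sub
            start = w * window + 1
            rows.append(
                {
                    "chrom": chrom,
                    "win_start": start,
                    "win_end": start + window - 1,
                    "pair": pair,
                    "n_snps": int(len(members)),
                    "fst": float(members["fst"].mean()) if len(members) else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "win_start", "win_end", "pair", "n_snps", "fst"])
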