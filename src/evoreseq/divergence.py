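"""Per-variant binomial GLMM scan for consistent allele-frequency divergence.

At each variant the read counts of the two retained alleles are the
response of a logistic mixed model:

    logit P(allele1) = beta0 + beta1 * regime + u_line,   u_line ~ N(0, s2)

with selection regime (selected = 1 / control = 0) a fixed effect and line
(one of eight, one library per line) a random intercept. The random
intercept absorbs both genuine drift between replicate lines and the
extra-binomial noise of pooled sequencing, so the Wald test on ``beta1``
asks for divergence *consistent* across replicates, not merely large in
any one line.

Estimation maximizes the Laplace-approximated marginal likelihood over
(beta0, beta1, log s2); because each line contributes a single library the
conditional modes of the random intercepts decouple into independent
scalar problems. At the s2 = 0 boundary the fit reduces exactly to the
plain binomial GLM. Complete separation (one allele absent from every
library of one regime) is handled by adding 0.5 to each of the four
regime x allele marginal cells (spread evenly over the regime's libraries)
and refitting, flagged ``separated``.

Raw Wald P values are Benjamini-Hochberg adjusted and a variant is called
significant when the adjusted P is strictly below the threshold
(default 5e-6). Significant SNPs are then clustered into genomic regions:
a new region starts wherever the inter-SNP gap reaches the threshold
(default 60 kb), so that reported regions are separated by at least that
distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VariantTestResult",
    "GenomicRegion",
    "fit_variant_glmm",
    "fit_table",
    "adjust_fdr",
    "call_significant",
    "cluster_regions",
]

_LOG_S2_BOUNDS = (-12.0, 8.0)


@dataclass
class VariantTestResult:
    chrom: Optional[str]
    pos: Optional[int]
    beta1: float
    se: float
    z: float
    p: float
    sigma2: float
    fit_status: str  # ok | boundary_sigma0 | separated | failed
    p_adj: float = np.nan
    significant: bool = False


def _binom_loglik(eta: np.ndarray, y1: np.ndarray, n: np.ndarray) -> float:
    # binomial kernel; combinatorial constants dropped (cancel in comparisons)
    return float(np.sum(y1 * eta - n * np.logaddexp(0.0, eta)))


def _u_modes(xb: np.ndarray, y1, n, s2: float, u0: np.ndarray) -> np.ndarray:
    """Conditional modes of the per-line random intercepts (scalar Newton)."""
    u = u0.copy()
    for _ in range(50):
        eta = xb + u
        p = 1.0 / (1.0 + np.exp(-eta))
        g = y1 - n * p - u / s2
        h = n * p * (1 - p) + 1.0 / s2
        step = g / h
        step = np.clip(step, -4.0, 4.0)
        u = u + step
        if np.max(np.abs(step)) < 1e-10:
            break
    return u


def _laplace_negll(params, x, y1, n, u_cache) -> float:
    b0, b1, log_s2 = params
    s2 = np.exp(log_s2)
    xb = b0 + b1 * x
    u = _u_modes(xb, y1, n, s2, u_cache["u"])
    u_cache["u"] = u
    eta = xb + u
    p = 1.0 / (1.0 + np.exp(-eta))
    w = n * p * (1 - p)
    ll = (
        _binom_loglik(eta, y1, n)
        - np.sum(u * u) / (2 * s2)
        - 0.5 * np.sum(np.log1p(s2 * w))
    )
    return -ll


def _glm_fit(x: np.ndarray, y1: np.ndarray, n: np.ndarray):
    """Plain binomial-logit GLM by Newton-Raphson; returns (beta, cov, ll)."""
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    beta = np.zeros(2)
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1 - p)
        g = X.T @ (y1 - n * p)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(2), g)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -10, 10)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = n * p * (1 - p)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.pinv(H)
    return beta, cov, _binom_loglik(eta, y1, n)


def _is_separated(y1, y2, x) -> bool:
    for r in (0, 1):
        m = x == r
        if y1[m].sum() == 0 or y2[m].sum() == 0:
            return True
    return False


def fit_variant_glmm(
    y1: Sequence[float],
    y2: Sequence[float],
    regime: Sequence[int],
    chrom: Optional[str] = None,
    pos: Optional[int] = None,
) -> VariantTestResult:
    """Fit the binomial-logit mixed model at one variant.

    Parameters
    ----------
    y1, y2
        Per-library read counts of the two retained alleles.
    regime
        Per-library selection-regime indicator (1 = selected, 0 = control).
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    x = np.asarray(regime, dtype=float)
    if not (set(np.unique(x)) <= {0.0, 1.0}) or len({0.0, 1.0} & set(np.unique(x))) < 2:
        raise ValueError("regime must contain both 0 and 1")
    n = y1 + y2
    for r in (0, 1):
        if n[x == r].sum() <= 0:
            raise ValueError("each regime needs at least one nonzero total count")

    status = "ok"
    if _is_separated(y1, y2, x):
        status = "separated"
        for r in (0, 1):
            m = x == r
            add = 0.5 / m.sum()
            y1 = np.where(m, y1 + add, y1)
            y2 = np.where(m, y2 + add, y2)
        n = y1 + y2

    beta_glm, cov_glm, ll_glm = _glm_fit(x, y1, n)
    u_cache = {"u": np.zeros_like(y1)}
    start = np.array([beta_glm[0], beta_glm[1], np.log(0.05)])
    try:
        res = optimize.minimize(
            _laplace_negll,
            start,
            args=(x, y1, n, u_cache),
            method="L-BFGS-B",
            bounds=[(-25, 25), (-25, 25), _LOG_S2_BOUNDS],
        )
        ok = res.success or np.isfinite(res.fun)
    except (ValueError, FloatingPointError):
        ok = False

    if not ok:
        se = float(np.sqrt(max(cov_glm[1, 1], 0)))
        return VariantTestResult(chrom, pos, float(beta_glm[1]), se, np.nan, 1.0, np.nan, "failed")

    ll_mixed = -res.fun
    if ll_glm >= ll_mixed - 1e-7 or res.x[2] <= _LOG_S2_BOUNDS[0] + 1e-6:
        # variance component at the boundary: exact GLM
        b1 = float(beta_glm[1])
        se = float(np.sqrt(max(cov_glm[1, 1], 1e-300)))
        s2 = 0.0
    else:
        b0, b1, log_s2 = res.x
        s2 = float(np.exp(log_s2))
        xb = b0 + b1 * x
        u = _u_modes(xb, y1, n, s2, u_cache["u"])
        eta = xb + u
        p = 1.0 / (1.0 + np.exp(-eta))
        w = n * p * (1 - p)
        w_eff = w / (1.0 + s2 * w)
        X = np.column_stack([np.ones_like(x), x])
        M = (X * w_eff[:, None]).T @ X
        cov = np.linalg.pinv(M)
        se = float(np.sqrt(max(cov[1, 1], 1e-300)))
        b1 = float(b1)
    if s2 == 0.0 and status == "ok":
        status = "boundary_sigma0"
    z = b1 / se if se > 0 else np.nan
    pval = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0
    return VariantTestResult(chrom, pos, b1, se, float(z), pval, s2, status)


def fit_table(
    table: pd.DataFrame,
    labels: Sequence[str],
    regime: Sequence[int],
    alpha: float = 5e-6,
) -> pd.DataFrame:
    """Fit the GLMM at every row of an AlleleCountTable.

    ``labels`` are the library labels (matching ``{label}_c1/_c2`` columns)
    and ``regime`` their selected/control indicators. Returns a DataFrame
    of per-variant results with BH-adjusted P and significance calls. Fits
    are independent across variants; the output is a pure function of the
    input rows.
    """
    c1 = table[[f"{lab}_c1" for lab in labels]].to_numpy(dtype=float)
    c2 = table[[f"{lab}_c2" for lab in labels]].to_numpy(dtype=float)
    chroms = table["chrom"].to_numpy()
    poss = table["pos"].to_numpy()
    out = []
    for i in range(len(table)):
        try:
            r = fit_variant_glmm(c1[i], c2[i], regime, chrom=chroms[i], pos=int(poss[i]))
        except ValueError:
            r = VariantTestResult(chroms[i], int(poss[i]), np.nan, np.nan, np.nan, 1.0, np.nan, "failed")
        out.append(r)
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in out],
            "pos": [r.pos for r in out],
            "beta1": [r.beta1 for r in out],
            "se": [r.se for r in out],
            "z": [r.z for r in out],
            "p": [r.p for r in out],
            "sigma2": [r.sigma2 for r in out],
            "fit_status": [r.fit_status for r in out],
        }
    )
    df["p_adj"] = adjust_fdr(df["p"].to_numpy())
    df = call_significant(df, alpha=alpha)
    return df


def adjust_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_significant(results: pd.DataFrame, alpha: float = 5e-6) -> pd.DataFrame:
    """Flag variants with adjusted P strictly below ``alpha``."""
    results = results.copy()
    results["significant"] = results["p_adj"] < alpha
    return results


@dataclass
class GenomicRegion:
    chrom: str
    start: int
    end: int
    n_snps: int
    members: List[int]


def cluster_regions(
    variants: pd.DataFrame, gap: int = 60_000
) -> List[GenomicRegion]:
    """Cluster SNPs into regions separated by at least ``gap`` bp.

    Within each scaffold, positions are sorted and a new region starts
    whenever the distance to the previous SNP is >= ``gap``; regions never
    span scaffolds and the union of members equals the input.
    """
    regions: List[GenomicRegion] = []
    if len(variants) == 0:
        return regions
    for chrom, sub in variants.groupby("chrom", sort=True):
        pos = np.sort(sub["pos"].to_numpy(dtype=np.int64))
        members = [int(pos[0])]
        for pp in pos[1:]:
            if pp - members[-1] >= gap:
                regions.append(
                    GenomicRegion(str(chrom), members[0], members[-1], len(members), members)
                )
                members = [int(pp)]
            else:
                members.append(int(pp))
        regions.append(
            GenomicRegion(str(chrom), members[0], members[-1], len(members), members)
        )
    return regions


def regions_frame(regions: Iterable[GenomicRegion]) -> pd.DataFrame:
    rs = list(regions)
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in rs],
            "start": [r.start for r in rs],
            "end": [r.end for r in rs],
            "n_snps": [r.n_snps for r in rs],
        }
    )
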