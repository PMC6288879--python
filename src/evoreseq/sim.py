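"""Synthetic evolve-and-resequence data generator.

Three generators with the statistical structure the downstream analyses
assume:

``simulate_er``
    Wright-Fisher forward simulation of replicate selected/control line
    pairs from a shared founder population, with optional haplodiploid
    dynamics, per-generation deterministic selection shifts at planted
    loci, and block-correlated drift deviations as a hitchhiking stand-in.

``sample_pool_reads``
    Two-stage pooled sequencing: binomial sampling of pooled females,
    per-site coverage around each library's mean, binomial read sampling,
    and uniform base miscalls producing third-allele artifacts; emitted in
    Popoolation2 sync dialect.

``simulate_rnaseq``
    Negative-binomial transcript counts for the eight-library design with
    pair-shared line effects, planted regime log2 fold changes and
    on/off-switched transcripts.

All generators are deterministic given their seed; independent substreams
are spawned per purpose so that, e.g., disabling male transmission leaves
the female drift draws bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigError, EvolveConfig, PoolSeqConfig, RnaSimConfig

__all__ = [
    "SimTruth",
    "simulate_er",
    "sample_pool_reads",
    "simulate_rnaseq",
    "line_labels",
    "write_sync",
    "BASES",
]

BASES = np.array(["A", "T", "C", "G"])
#: sync column order
SYNC_BASES = ("A", "T", "C", "G", "N", "del")


def line_labels(n_pairs: int) -> List[str]:
    """Library/line labels in pipeline order: selA, ctlA, selB, ctlB, ..."""
    pairs = [chr(ord("A") + i) for i in range(n_pairs)]
    out = []
    for p in pairs:
        out += [f"sel{p}", f"ctl{p}"]
    return out


@dataclass
class SimTruth:
    """Planted ground truth of a simulation run.

    ``loci``: per-locus table (locus, chrom, pos, block, ref, alt,
    selected, s, founder_freq). ``line_freqs``: loci x lines final true
    alternate-allele frequencies. ``transcripts``: per-transcript table
    (transcript, locus, de, direction, true_lfc, onoff). Any component not
    produced by the generating call is ``None``.
    """

    loci: Optional[pd.DataFrame] = None
    line_freqs: Optional[pd.DataFrame] = None
    transcripts: Optional[pd.DataFrame] = None


def _founder_freqs(cfg: EvolveConfig, rng: np.random.Generator) -> np.ndarray:
    kind, *args = cfg.founder_freq_dist
    if kind == "uniform":
        lo, hi = args
        return rng.uniform(lo, hi, size=cfg.n_loci)
    a, b = args
    return rng.beta(a, b, size=cfg.n_loci)


def _locus_layout(cfg: EvolveConfig) -> pd.DataFrame:
    i = np.arange(cfg.n_loci)
    block = i // cfg.block_size
    within = i % cfg.block_size
    scaf = block // cfg.blocks_per_scaffold
    block_local = block % cfg.blocks_per_scaffold
    block_span = cfg.block_size * cfg.locus_spacing
    pos = 1 + block_local * (block_span + cfg.block_gap) + within * cfg.locus_spacing
    return pd.DataFrame(
        {
            "locus": i,
            "chrom": [f"sc{s + 1}" for s in scaf],
            "pos": pos.astype(np.int64),
            "block": block,
        }
    )


def _select_loci(cfg: EvolveConfig, rng: np.random.Generator) -> np.ndarray:
    """Pick selected loci block-aligned: whole blocks filled before the next."""
    if cfg.n_selected_loci == 0:
        return np.zeros(cfg.n_loci, dtype=bool)
    n_blocks = (cfg.n_loci + cfg.block_size - 1) // cfg.block_size
    order = rng.permutation(n_blocks)
    sel = np.zeros(cfg.n_loci, dtype=bool)
    need = cfg.n_selected_loci
    for b in order:
        if need == 0:
            break
        members = np.arange(b * cfg.block_size, min((b + 1) * cfg.block_size, cfg.n_loci))
        take = members[: min(need, len(members))]
        sel[take] = True
        need -= len(take)
    return sel


def _selection_shift(p: np.ndarray, s: float, mask: np.ndarray) -> np.ndarray:
    if s == 0 or not mask.any():
        return p
    out = p.copy()
    pm = p[mask]
    out[mask] = pm * (1 + s) / (1 + pm * s)
    return out


def _copula_binomial(
    p: np.ndarray,
    n_draws: int,
    block: np.ndarray,
    rho: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binomial(n_draws, p) counts with Gaussian-copula block correlation.

    Exact binomial marginals at every locus; rho > 0 couples the latent
    normals of loci sharing a block so their drift deviations co-move.
    """
    z_ind = rng.standard_normal(p.shape)
    if rho > 0:
        n_blocks = int(block.max()) + 1
        z_blk = rng.standard_normal(n_blocks)[block]
        z = np.sqrt(rho) * z_blk + np.sqrt(1.0 - rho) * z_ind
    else:
        z = z_ind
    u = stats.norm.cdf(z)
    return stats.binom.ppf(u, n_draws, p)


def simulate_er(cfg: EvolveConfig, seed: int):
    """Run the forward simulation.

    Returns ``(truth, line_freqs)`` where ``line_freqs`` is a DataFrame of
    final alternate-allele frequencies (loci x lines) also stored on the
    truth object. One founder frequency vector is shared by all lines; each
    line then drifts independently for ``cfg.generations`` generations, with
    the deterministic selection shift applied at planted loci in selected
    lines only, before gamete sampling.
    """
    if not isinstance(cfg, EvolveConfig):
        raise ConfigError("cfg must be an EvolveConfig")
    ss = np.random.SeedSequence(int(seed))
    rng_setup, rng_f, rng_m = (np.random.default_rng(s) for s in ss.spawn(3))

    layout = _locus_layout(cfg)
    p0 = _founder_freqs(cfg, rng_setup)
    selected = _select_loci(cfg, rng_setup)
    ref_idx = rng_setup.integers(0, 4, size=cfg.n_loci)
    alt_idx = (ref_idx + rng_setup.integers(1, 4, size=cfg.n_loci)) % 4
    block = layout["block"].to_numpy()

    labels = line_labels(cfg.n_pairs)
    n_gam_f = 2 * cfg.n_mothers
    haplo = cfg.ploidy_model == "haplodiploid"

    freqs = {}
    for lab in labels:
        is_sel = lab.startswith("sel")
        mask = selected if is_sel else np.zeros(cfg.n_loci, dtype=bool)
        pf = p0.copy()
        pm = p0.copy()
        for _ in range(cfg.generations):
            pf_star = _selection_shift(pf, cfg.s, mask)
            if haplo:
                pm_star = _selection_shift(pm, cfg.s, mask)
                pool = 0.5 * (pf_star + pm_star) if cfg.male_contribution else pf_star
                pf_next = (
                    _copula_binomial(pool, n_gam_f, block, cfg.block_rho, rng_f)
                    / n_gam_f
                )
                # haploid sons carry a single maternal gamete each
                pm = rng_m.binomial(cfg.n_mothers, pf_star) / cfg.n_mothers
                pf = pf_next
            else:
                pf = (
                    _copula_binomial(pf_star, n_gam_f, block, cfg.block_rho, rng_f)
                    / n_gam_f
                )
        freqs[lab] = pf

    line_freqs = pd.DataFrame(freqs, index=layout["locus"])
    loci = layout.copy()
    loci["ref"] = BASES[ref_idx]
    loci["alt"] = BASES[alt_idx]
    loci["selected"] = selected
    loci["s"] = np.where(selected, cfg.s, 0.0)
    loci["founder_freq"] = p0
    truth = SimTruth(loci=loci, line_freqs=line_freqs)
    return truth, line_freqs


def _coverage(
    mean: float, dispersion: float, size, rng: np.random.Generator
) -> np.ndarray:
    if dispersion == 0:
        return np.full(size, int(round(mean)), dtype=np.int64)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean), size=size).astype(np.int64)


def _split_three(n: np.ndarray, rng: np.random.Generator):
    """Split counts n uniformly into three parts (vectorized multinomial)."""
    a = rng.binomial(n, 1.0 / 3.0)
    b = rng.binomial(n - a, 0.5)
    return a, b, n - a - b


def sample_pool_reads(
    truth: SimTruth, poolcfg: PoolSeqConfig, seed: int
) -> pd.DataFrame:
    """Sample pooled sequencing reads from true line frequencies.

    Per site and library: pooled-female alternate-allele count is
    Binomial(2 * pool_females, p); coverage is drawn around the library
    mean; alternate reads are Binomial(coverage, pool frequency); each read
    is then miscalled to a uniformly chosen other base with probability
    ``error_rate``. Returns a sync-dialect DataFrame with columns
    ``chrom, pos, ref, <lib1>, ..., <libJ>`` where each library field is the
    colon-separated ``A:T:C:G:N:del`` count string.
    """
    loci, line_freqs = truth.loci, truth.line_freqs
    p = line_freqs.to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ConfigError("allele frequencies must lie in [0, 1]")
    n_loci, n_libs = p.shape
    means = list(poolcfg.mean_coverage_per_library)
    if len(means) != n_libs:
        raise ConfigError(
            f"need {n_libs} per-library mean coverages, got {len(means)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))

    two_n = 2 * poolcfg.pool_females
    pool_counts = rng.binomial(two_n, p)
    pool_freq = pool_counts / two_n

    cov = np.empty((n_loci, n_libs), dtype=np.int64)
    for j in range(n_libs):
        cov[:, j] = _coverage(means[j], poolcfg.coverage_dispersion, n_loci, rng)

    alt_reads = rng.binomial(cov, pool_freq)
    ref_reads = cov - alt_reads

    counts = np.zeros((n_loci, n_libs, 4), dtype=np.int64)
    ref_idx = np.array([np.flatnonzero(BASES == b)[0] for b in loci["ref"]])
    alt_idx = np.array([np.flatnonzero(BASES == b)[0] for b in loci["alt"]])
    eps = poolcfg.error_rate
    for source_reads, source_idx in ((ref_reads, ref_idx), (alt_reads, alt_idx)):
        if eps > 0:
            err = rng.binomial(source_reads, eps)
        else:
            err = np.zeros_like(source_reads)
        keep = source_reads - err
        np.add.at(counts, (np.arange(n_loci)[:, None], np.arange(n_libs)[None, :], source_idx[:, None]), keep)
        if eps > 0:
            others = np.array([[b for b in range(4) if b != i] for i in range(4)])
            e1, e2, e3 = _split_three(err, rng)
            for k, part in enumerate((e1, e2, e3)):
                dest = others[source_idx, k]
                np.add.at(
                    counts,
                    (np.arange(n_loci)[:, None], np.arange(n_libs)[None, :], dest[:, None]),
                    part,
                )

    labels = list(line_freqs.columns)
    out = {"chrom": loci["chrom"].to_numpy(), "pos": loci["pos"].to_numpy(), "ref": loci["ref"].to_numpy()}
    for j, lab in enumerate(labels):
        c = counts[:, j, :]
        out[lab] = [f"{a}:{t}:{cc}:{g}:0:0" for a, t, cc, g in c]
    return pd.DataFrame(out)


def write_sync(sync: pd.DataFrame, path) -> None:
    """Write a sync-dialect DataFrame to a tab-separated file (no header)."""
    sync.to_csv(path, sep="\t", header=False, index=False)


def _draw_lfc(cfg: RnaSimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    _, lo, hi = cfg.true_lfc_dist
    mag = rng.uniform(lo, hi, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    return mag * sign


def simulate_rnaseq(cfg: RnaSimConfig, n_pairs: int, seed: int):
    """Simulate the transcript count matrix.

    Counts are NB with mean ``L_j * q_g * 2**(offset_{g,line(j)} +
    regime_j * lfc_g)`` and dispersion phi; on/off transcripts have mean 0
    in their off regime. When ``n_de >= 2`` the first two regime-affected
    transcripts share a locus with opposite planted directions (the
    alternative-splice-variant pattern). Returns ``(counts, truth)`` where
    ``counts`` is a transcripts x libraries DataFrame.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    G, J = cfg.n_transcripts, 2 * n_pairs
    labels = line_labels(n_pairs)
    regime = np.array([1 if lab.startswith("sel") else 0 for lab in labels])
    pair = np.repeat(np.arange(n_pairs), 2)

    base = rng.lognormal(mean=0.0, sigma=1.5, size=G)
    q = base / base.sum()
    lib_sizes = rng.integers(cfg.lib_size_range[0], cfg.lib_size_range[1] + 1, size=J)

    de = np.zeros(G, dtype=bool)
    de[:cfg.n_de] = True
    lfc = np.zeros(G)
    lfc[:cfg.n_de] = _draw_lfc(cfg, cfg.n_de, rng)
    if cfg.n_de >= 2:
        # opposite splice variants of one locus
        lfc[1] = -abs(lfc[0]) if lfc[0] > 0 else abs(lfc[0])
    onoff = np.zeros(G, dtype=bool)
    if cfg.n_onoff:
        onoff[cfg.n_de - cfg.n_onoff : cfg.n_de] = True

    pair_off = rng.normal(0.0, cfg.line_effect_sd, size=(G, n_pairs))
    line_off = pair_off[:, pair] + rng.normal(0.0, cfg.within_pair_sd, size=(G, J))

    log2_mu = (
        np.log2(np.maximum(q[:, None] * lib_sizes[None, :], 1e-300))
        + line_off
        + regime[None, :] * lfc[:, None]
    )
    mu = np.exp2(log2_mu)
    if cfg.n_onoff:
        off_in_sel = lfc < 0  # reduced in selected lines -> off when selected
        off_mask = onoff[:, None] & (
            (off_in_sel[:, None] & (regime[None, :] == 1))
            | (~off_in_sel[:, None] & (regime[None, :] == 0))
        )
        mu = np.where(off_mask, 0.0, mu)

    if cfg.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / cfg.dispersion
        counts = np.where(mu > 0, rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-12))), 0)

    ids = [f"t{i:05d}" for i in range(G)]
    loci_ids = [f"g{i:05d}" for i in range(G)]
    if cfg.n_de >= 2:
        loci_ids[1] = loci_ids[0]
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="transcript"), columns=labels)
    direction = np.sign(lfc)
    truth = pd.DataFrame(
        {
            "transcript": ids,
            "locus": loci_ids,
            "de": de,
            "direction": direction,
            "true_lfc": np.where(onoff, np.inf * np.where(direction == 0, 1, direction), lfc),
            "onoff": onoff,
        }
    ).set_index("transcript")
    return counts_df, SimTruth(transcripts=truth)
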