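"""Configuration records for the simulation and pipeline layers.

All experiment-level defaults mirror the selection experiment this package
models: four replicate pairs of selected and control *Nasonia vitripennis*
lines, ten generations of selection, 50 reproducing mated females per line
per generation, a base population maintained at an effective size of 173,
pooled sequencing of 40 females per line, and an eight-library RNA-seq
design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence, Tuple

__all__ = [
    "EvolveConfig",
    "PoolSeqConfig",
    "RnaSimConfig",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration value is non-finite or out of range."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class EvolveConfig:
    """Parameters of the evolve-and-resequence forward simulation.

    Parameters
    ----------
    n_pairs
        Number of replicate selected/control line pairs.
    generations
        Generations of drift (and, in selected lines, selection).
    n_mothers
        Reproducing females per line per generation; drift samples
        ``2 * n_mothers`` gametes under the diploid model.
    founder_ne
        Effective size at which the shared base population is maintained.
        Documents the provenance of founder variation; the founder allele
        frequencies themselves are drawn from ``founder_freq_dist``.
    ploidy_model
        ``"diploid"`` (default) or ``"haplodiploid"``. Haplodiploidy tracks
        female and male allele frequencies separately (haploid males).
    n_loci, n_selected_loci
        Total simulated loci and how many are under selection in the
        selected lines.
    s
        Selection coefficient per selected locus; applied as the
        deterministic shift ``p* = p(1+s)/(1+p*s)`` before gamete sampling.
    founder_freq_dist
        ``("uniform", lo, hi)`` or ``("beta", a, b)`` on (0, 1).
    block_rho
        Correlation of stochastic trajectory deviations between loci within
        a linkage block (Gaussian-copula coupling of the binomial drift
        draws); a desk-scale stand-in for hitchhiking.
    block_size
        Loci per linkage block.
    locus_spacing, block_gap, blocks_per_scaffold
        Genomic layout of the simulated loci: base-pair spacing within a
        block, gap between blocks, and blocks placed per scaffold.
    """

    n_pairs: int = 4
    generations: int = 10
    n_mothers: int = 50
    founder_ne: int = 173
    ploidy_model: str = "diploid"
    male_contribution: bool = True  # haplodiploid only; False reduces to the diploid recursion
    n_loci: int = 1000
    n_selected_loci: int = 0
    s: float = 0.0
    founder_freq_dist: Tuple = ("uniform", 0.05, 0.95)
    block_rho: float = 0.0
    block_size: int = 10
    locus_spacing: int = 1000
    block_gap: int = 200_000
    blocks_per_scaffold: int = 25

    def __post_init__(self) -> None:
        _require(self.n_pairs >= 1, "n_pairs must be positive")
        _require(self.generations >= 0, "generations must be non-negative")
        _require(self.n_mothers >= 1, "n_mothers must be positive")
        _require(self.n_loci >= 1, "n_loci must be positive")
        _require(
            0 <= self.n_selected_loci <= self.n_loci,
            "n_selected_loci must lie in [0, n_loci]",
        )
        _require(self.s >= 0 and self.s == self.s, "s must be finite and >= 0")
        _require(0.0 <= self.block_rho <= 1.0, "block_rho must lie in [0, 1]")
        _require(self.block_size >= 1, "block_size must be positive")
        _require(
            self.ploidy_model in ("diploid", "haplodiploid"),
            "ploidy_model must be 'diploid' or 'haplodiploid'",
        )
        kind = self.founder_freq_dist[0]
        _require(kind in ("uniform", "beta"), "unknown founder_freq_dist kind")

    @property
    def n_lines(self) -> int:
        return 2 * self.n_pairs


@dataclass
class PoolSeqConfig:
    """Pooled-sequencing layer: pool size, per-library coverage, errors.

    ``mean_coverage_per_library`` defaults to eight values spanning the
    25-139x range of the emulated libraries. ``coverage_dispersion`` is the
    negative-binomial overdispersion of per-site coverage
    (``var = mu + d * mu**2``); 0 gives constant coverage at the mean.
    ``error_rate`` is the per-read probability of miscalling the base to a
    uniformly chosen other base, the source of third-allele artifacts.
    """

    pool_females: int = 40
    mean_coverage_per_library: Sequence[float] = (25, 139, 47, 88, 33, 110, 60, 75)
    coverage_dispersion: float = 0.05
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        _require(self.pool_females >= 1, "pool_females must be positive")
        _require(
            all(c > 0 for c in self.mean_coverage_per_library),
            "coverages must be positive",
        )
        _require(self.coverage_dispersion >= 0, "coverage_dispersion must be >= 0")
        _require(0 <= self.error_rate <= 0.1, "error_rate must lie in [0, 0.1]")


@dataclass
class RnaSimConfig:
    """RNA-seq count simulation: eight libraries, planted regime effects.

    ``line_effect_sd`` is the SD of per-pair log2-expression offsets shared
    by the two lines of a replicate pair (the dominant line-structure of the
    emulated data); ``within_pair_sd`` adds smaller line-specific noise.
    ``n_onoff`` of the ``n_de`` regime-affected transcripts are switched to
    zero expression in one regime. ``dispersion`` is the NB dispersion phi
    (``var = mu + phi * mu**2``); 0 gives Poisson counts.
    """

    n_transcripts: int = 5000
    n_de: int = 200
    n_onoff: int = 20
    true_lfc_dist: Tuple = ("uniform_signed", 1.0, 3.0)
    line_effect_sd: float = 0.5
    within_pair_sd: float = 0.1
    dispersion: float = 0.05
    lib_size_range: Tuple[int, int] = (4_000_000, 6_000_000)

    def __post_init__(self) -> None:
        _require(self.n_transcripts >= 1, "n_transcripts must be positive")
        _require(
            0 <= self.n_onoff <= self.n_de <= self.n_transcripts,
            "require n_onoff <= n_de <= n_transcripts",
        )
        _require(self.dispersion >= 0, "dispersion (phi) must be >= 0")
        _require(self.line_effect_sd >= 0, "line_effect_sd must be >= 0")
        _require(self.within_pair_sd >= 0, "within_pair_sd must be >= 0")
        lo, hi = self.lib_size_range
        _require(0 < lo <= hi, "lib_size_range must be positive and ordered")
        _require(
            self.true_lfc_dist[0] == "uniform_signed" and self.true_lfc_dist[1] >= 1.0,
            "true_lfc_dist must be ('uniform_signed', lo>=1, hi)",
        )


def config_dict(cfg) -> dict:
    """JSON-serializable view of any config dataclass (for run manifests)."""
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
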