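"""End-to-end pipeline: simulate -> filter -> GLMM -> F_ST -> DE -> RRHO.

Each stage writes TSV/JSON outputs into a run directory together with a
JSON manifest recording the configuration, the seed, and the SHA-256 of
every tabular output, so a rerun with the same configuration and seed is
bit-identical for deterministic outputs. A single user seed fans out to
per-stage child seeds through fixed stage indices, so toggling one stage
never shifts another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import divergence, fst, overlap, sim, sync_io
from .config import EvolveConfig, PoolSeqConfig, RnaSimConfig, config_dict

__all__ = ["RunConfig", "stage_seed", "run_pipeline", "report"]

_STAGE_IDS = {
    "simulate": 1,
    "filter_sync": 2,
    "glmm": 3,
    "fst": 4,
    "de": 5,
    "rrho": 6,
    "annotate": 7,
    "report": 8,
}


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters, defaulting to the analysis thresholds.

    Filtering: coverage > ``min_total`` everywhere, alternate reads >
    ``min_alt`` somewhere. GLMM: significance at BH-adjusted P <
    ``alpha``; regions split at gaps >= ``gap`` bp. F_ST: ``window`` bp
    tiles, top ``1 - max_cov_quantile`` coverage discarded. DE: CPM >=
    ``min_cpm`` in >= 1 library, FDR ``fdr``, fold change > ``fc``
    (absolute), PCA correlation P < ``pca_p``.
    """

    seed: int = 0
    min_total: int = 10
    min_alt: int = 5
    alpha: float = 5e-6
    gap: int = 60_000
    window: int = 10_000
    max_cov_quantile: float = 0.98
    min_cpm: float = 1.0
    fdr: float = 0.05
    fc: float = 2.0
    pca_p: float = 0.05
    fc_prior: float = 0.5
    evolve: EvolveConfig = dataclasses.field(default_factory=EvolveConfig)
    poolseq: PoolSeqConfig = dataclasses.field(default_factory=PoolSeqConfig)
    rnaseq: RnaSimConfig = dataclasses.field(default_factory=RnaSimConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["evolve"] = config_dict(self.evolve)
        d["poolseq"] = config_dict(self.poolseq)
        d["rnaseq"] = config_dict(self.rnaseq)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, klass in (("evolve", EvolveConfig), ("poolseq", PoolSeqConfig), ("rnaseq", RnaSimConfig)):
            if key in d and isinstance(d[key], dict):
                sub = {k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()}
                d[key] = klass(**sub)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    ss = np.random.SeedSequence([int(seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out: Path, cfg: RunConfig, outputs: Dict[str, Path]) -> None:
    manifest = {
        "config": cfg.to_dict(),
        "outputs": {k: {"path": str(p.name), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(cfg: RunConfig, out_dir, stages: Optional[list] = None) -> Dict[str, Path]:
    """Run the requested stages (default: all simulation-backed stages).

    Returns a mapping of output names to paths. Stage order is fixed;
    each stage reads only the files earlier stages wrote into ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or ["simulate", "filter_sync", "glmm", "fst", "de", "rrho"]
    outputs: Dict[str, Path] = {}

    labels = sim.line_labels(cfg.evolve.n_pairs)
    regime = [1 if lab.startswith("sel") else 0 for lab in labels]

    if "simulate" in stages:
        truth, _ = sim.simulate_er(cfg.evolve, stage_seed(cfg.seed, "simulate"))
        sync = sim.sample_pool_reads(truth, cfg.poolseq, stage_seed(cfg.seed, "simulate") + 1)
        sim.write_sync(sync, out / "pool.sync")
        truth.loci.to_csv(out / "truth_loci.tsv", sep="\t", index=False)
        truth.line_freqs.to_csv(out / "truth_freqs.tsv", sep="\t")
        counts, rtruth = sim.simulate_rnaseq(
            cfg.rnaseq, cfg.evolve.n_pairs, stage_seed(cfg.seed, "simulate") + 2
        )
        counts.to_csv(out / "counts.tsv", sep="\t")
        rtruth.transcripts.to_csv(out / "truth_transcripts.tsv", sep="\t")
        outputs.update(
            {
                "sync": out / "pool.sync",
                "truth_loci": out / "truth_loci.tsv",
                "truth_freqs": out / "truth_freqs.tsv",
                "counts": out / "counts.tsv",
                "truth_transcripts": out / "truth_transcripts.tsv",
            }
        )

    if "filter_sync" in stages:
        src = out / "pool.sync"
        if not src.exists():
            raise FileNotFoundError("filter_sync: missing pool.sync (run the simulate stage or provide it)")
        table, reasons = sync_io.filter_sync(
            sync_io.read_sync(src), cfg.min_total, cfg.min_alt, labels=labels
        )
        sync_io.write_allele_table(table, out / "allele_table.tsv")
        (out / "filter_reasons.json").write_text(json.dumps(reasons, indent=2, sort_keys=True))
        outputs["allele_table"] = out / "allele_table.tsv"
        outputs["filter_reasons"] = out / "filter_reasons.json"

    if "glmm" in stages:
        src = out / "allele_table.tsv"
        if not src.exists():
            raise FileNotFoundError("glmm: missing allele_table.tsv (run filter_sync first)")
        table = pd.read_csv(src, sep="\t")
        res = divergence.fit_table(table, labels, regime, alpha=cfg.alpha)
        res.to_csv(out / "variants.tsv", sep="\t", index=False)
        sig = res[res["significant"]]
        regions = divergence.cluster_regions(sig, gap=cfg.gap)
        with open(out / "regions.bed", "w") as fh:
            fh.write("# BED-like: chrom, 0-based half-open start/end, n_snps\n")
            for r in regions:
                fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.n_snps}\n")
        outputs["variants"] = out / "variants.tsv"
        outputs["regions"] = out / "regions.bed"

    if "fst" in stages:
        src = out / "allele_table.tsv"
        if not src.exists():
            raise FileNotFoundError("fst: missing allele_table.tsv (run filter_sync first)")
        table = pd.read_csv(src, sep="\t")
        frames = []
        for k in range(cfg.evolve.n_pairs):
            pair = chr(ord("A") + k)
            snps = fst.pair_snp_fst(table, f"sel{pair}", f"ctl{pair}", cfg.poolseq.pool_females)
            win = fst.window_fst(
                snps, window=cfg.window, max_cov_quantile=cfg.max_cov_quantile, pair=pair
            )
            frames.append(win)
        pd.concat(frames, ignore_index=True).to_csv(out / "fst_windows.tsv", sep="\t", index=False)
        outputs["fst_windows"] = out / "fst_windows.tsv"

    if "de" in stages:
        src = out / "counts.tsv"
        if not src.exists():
            raise FileNotFoundError("de: missing counts.tsv (run simulate or provide a count matrix)")
        counts = pd.read_csv(src, sep="\t", index_col=0)
        screen = de_mod.run_de(
            counts,
            min_cpm=cfg.min_cpm,
            fdr=cfg.fdr,
            pca_alpha=cfg.pca_p,
            prior=cfg.fc_prior,
            fc_threshold=float(np.log2(cfg.fc)),
        )
        screen.table.to_csv(out / "de_table.tsv", sep="\t")
        overlap_summary = {
            "glm_lrt": sorted(screen.glm_set),
            "pairwise_chisq": sorted(screen.chisq_set),
            "pca_screen": sorted(screen.pca_set),
            "consensus": sorted(screen.consensus_set),
            "pca_component": screen.pca_component,
        }
        (out / "de_overlap.json").write_text(json.dumps(overlap_summary, indent=2))
        outputs["de_table"] = out / "de_table.tsv"
        outputs["de_overlap"] = out / "de_overlap.json"

    if "rrho" in stages:
        de_path = out / "de_table.tsv"
        var_path = out / "variants.tsv"
        if not (de_path.exists() and var_path.exists()):
            raise FileNotFoundError("rrho: needs de_table.tsv and variants.tsv from earlier stages")
        de_table = pd.read_csv(de_path, sep="\t", index_col=0)
        variants = pd.read_csv(var_path, sep="\t")
        # synthetic transcript<->locus linkage by index for the integration layer
        n_loci = len(variants)
        if n_loci >= 2 and len(de_table) >= 2:
            de_key = np.sign(de_table["lfc_overall"]) * -np.log10(
                np.maximum(de_table["p_glm"].to_numpy(float), 1e-300)
            )
            de_ranked = list(de_table.index[np.argsort(-de_key, kind="mergesort")])
            locus_of = [i % n_loci for i in range(len(de_table))]
            div_p = np.maximum(variants["p"].to_numpy(float), 1e-300)
            div_key = -np.log10(div_p)[locus_of]
            div_ranked = list(de_table.index[np.argsort(-div_key, kind="mergesort")])
            m = overlap.rrho(de_ranked, div_ranked)
            pd.DataFrame(m.values, index=m.thresholds1, columns=m.thresholds2).to_csv(
                out / "rrho.tsv", sep="\t"
            )
            outputs["rrho"] = out / "rrho.tsv"
        fst_path = out / "fst_windows.tsv"
        if fst_path.exists() and n_loci >= 3 and len(de_table) >= 3:
            wins = pd.read_csv(fst_path, sep="\t")
            locus_pos = variants[["chrom", "pos"]].reset_index(drop=True)
            rows = []
            for k in range(cfg.evolve.n_pairs):
                pair = chr(ord("A") + k)
                expr = pd.DataFrame(
                    {
                        "chrom": locus_pos["chrom"].to_numpy()[
                            [i % n_loci for i in range(len(de_table))]
                        ],
                        "start": locus_pos["pos"].to_numpy()[
                            [i % n_loci for i in range(len(de_table))]
                        ],
                        "abs_lfc": de_table[f"lfc_{pair}"].abs().to_numpy(),
                    }
                )
                try:
                    r, p, n_obs = overlap.fst_expression_correlation(
                        wins[wins["pair"] == pair], expr, window=cfg.window
                    )
                except ValueError:
                    continue
                rows.append({"pair": pair, "rho": r, "p": p, "n": n_obs})
            if rows:
                pd.DataFrame(rows).to_csv(out / "fst_expression_corr.tsv", sep="\t", index=False)
                outputs["fst_expression_corr"] = out / "fst_expression_corr.tsv"

    _write_manifest(out, cfg, outputs)
    return outputs


def report(run_dir) -> Dict[str, Path]:
    """Render summary figures from a completed run directory (no RNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(run_dir)
    made: Dict[str, Path] = {}

    var_path = out / "variants.tsv"
    if var_path.exists():
        variants = pd.read_csv(var_path, sep="\t")
        manifest = json.loads((out / "manifest.json").read_text())
        alpha = manifest["config"]["alpha"]
        fig, ax = plt.subplots(figsize=(9, 3))
        offset = 0
        for chrom, sub in variants.groupby("chrom", sort=True):
            x = sub["pos"].to_numpy() + offset
            y = -np.log10(np.maximum(sub["p"].to_numpy(float), 1e-300))
            sig = sub["significant"].to_numpy(bool)
            ax.scatter(x[~sig], y[~sig], s=4, color="0.6")
            ax.scatter(x[sig], y[sig], s=6, color="red")
            offset = x.max() + 1
        ax.set_xlabel("genomic position (concatenated scaffolds)")
        ax.set_ylabel("-log10 P")
        ax.set_title(f"per-variant divergence (threshold: adjusted P < {alpha:g})")
        fig.tight_layout()
        fig.savefig(out / "manhattan.png", dpi=100)
        plt.close(fig)
        made["manhattan"] = out / "manhattan.png"

    de_path = out / "de_table.tsv"
    if de_path.exists():
        de_table = pd.read_csv(de_path, sep="\t", index_col=0)
        cons = de_table[de_table["consensus"]] if "consensus" in de_table else de_table.iloc[:0]
        fig, ax = plt.subplots(figsize=(5, max(2, 0.25 * max(len(cons), 1))))
        if len(cons):
            lfc_cols = [c for c in cons.columns if c.startswith("lfc_") and c != "lfc_overall"]
            data = cons.sort_values("lfc_overall")[lfc_cols] if lfc_cols else cons[["lfc_overall"]]
            im = ax.imshow(data.to_numpy(float), aspect="auto", cmap="RdYlGn")
            ax.set_yticks(range(len(data)))
            ax.set_yticklabels(data.index, fontsize=6)
            ax.set_xticks(range(data.shape[1]))
            ax.set_xticklabels(data.columns, fontsize=7)
            fig.colorbar(im, ax=ax, label="log2 FC")
        else:
            ax.text(0.5, 0.5, "no consensus transcripts", ha="center", va="center")
            ax.set_axis_off()
        ax.set_title("consensus transcripts")
        fig.tight_layout()
        fig.savefig(out / "de_heatmap.png", dpi=100)
        plt.close(fig)
        made["de_heatmap"] = out / "de_heatmap.png"

    rrho_path = out / "rrho.tsv"
    if rrho_path.exists():
        m = pd.read_csv(rrho_path, sep="\t", index_col=0)
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(m.to_numpy(float), origin="lower", cmap="coolwarm", aspect="auto")
        fig.colorbar(im, ax=ax, label="signed -log10 P")
        ax.set_xlabel("divergence rank threshold")
        ax.set_ylabel("expression rank threshold")
        ax.set_title("rank-rank hypergeometric overlap")
        fig.tight_layout()
        fig.savefig(out / "rrho.png", dpi=100)
        plt.close(fig)
        made["rrho"] = out / "rrho.png"

    return made
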