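"""SNP-to-gene assignment and a minimal coding-effect classifier.

Significant SNPs are assigned to every gene whose span, extended by a
10-kb flank on both sides (truncated at coordinate 1), contains the SNP.
Coding effects are called by rebuilding the affected codon from the CDS
coordinates of the gene's transcripts, honoring strand and phase, and
translating reference versus alternate codons with the standard genetic
code. UTR positions are folded into the intron bucket so the three-way
summary matches the partition introns / outside genes / coding regions;
the full category is kept internally.

Coordinates are 1-based inclusive throughout; GFF3 is read via gffutils
and genome sequence via pyfaidx (or any mapping of scaffold to sequence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import gffutils
import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "SnpEffect",
    "load_gene_models",
    "load_genome",
    "assign_genes",
    "classify_effect",
    "summarize_categories",
    "CATEGORIES",
]

CATEGORIES = (
    "coding_synonymous",
    "coding_missense",
    "intron",
    "outside_gene_within_10kb",
    "intergenic",
    "unknown",
)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int
    # mRNA id -> ordered CDS segments (start, end, phase)
    cds: Dict[str, List[Tuple[int, int, int]]] = field(default_factory=dict)


@dataclass
class SnpEffect:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_ids: List[str]
    category: str
    aa_change: Optional[str] = None


def load_genome(fasta_path) -> Dict[str, str]:
    """Read a FASTA into a plain chrom -> uppercase sequence mapping."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def load_gene_models(gff_path) -> List[GeneModel]:
    """Parse gene / mRNA / CDS features from a GFF3 file."""
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        gm = GeneModel(g.id, g.seqid, g.strand, g.start, g.end)
        for m in db.children(g, featuretype="mRNA", order_by="start"):
            segs = []
            for c in db.children(m, featuretype="CDS", order_by="start"):
                phase = int(c.frame) if c.frame not in (None, ".") else 0
                segs.append((c.start, c.end, phase))
            if segs:
                gm.cds[m.id] = segs
        genes.append(gm)
    return genes


def assign_genes(
    snps: pd.DataFrame, genes: Iterable[GeneModel], flank: int = 10_000
) -> pd.DataFrame:
    """Assign each SNP to every gene within ``flank`` bp of its span.

    ``snps`` needs ``chrom`` and ``pos`` columns. Returns one row per
    (SNP, gene) assignment; SNPs matching no gene get a row with
    ``gene_id`` None. Flanks are truncated at coordinate 1.
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for _, snp in snps.iterrows():
        hits = []
        for g in by_chrom.get(snp["chrom"], []):
            lo = max(1, g.start - flank)
            hi = g.end + flank
            if lo <= snp["pos"] <= hi:
                hits.append(g.gene_id)
        if hits:
            for gid in hits:
                rows.append({"chrom": snp["chrom"], "pos": int(snp["pos"]), "gene_id": gid})
        else:
            rows.append({"chrom": snp["chrom"], "pos": int(snp["pos"]), "gene_id": None})
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id"])


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def _codon_effect(
    gene: GeneModel,
    segs: List[Tuple[int, int, int]],
    pos: int,
    ref: str,
    alt: str,
    seq: str,
) -> Tuple[str, Optional[str]]:
    minus = gene.strand == "-"
    ordered = sorted(segs, key=lambda s: s[0], reverse=minus)
    pieces = []
    snp_idx = None
    for start, end, _ in ordered:
        part = seq[start - 1 : end]
        if minus:
            part = _revcomp(part)
        if start <= pos <= end:
            snp_idx = sum(len(p) for p in pieces) + (end - pos if minus else pos - start)
        pieces.append(part)
    cds_seq = "".join(pieces)
    first_phase = ordered[0][2]
    cds_seq = cds_seq[first_phase:]
    if snp_idx is None:
        raise ValueError("position not inside the given CDS segments")
    snp_idx -= first_phase
    if snp_idx < 0:
        return "unknown", None
    if len(cds_seq) % 3 != 0:
        warnings.warn(
            f"CDS length of {gene.gene_id} not divisible by 3; effect unknown",
            stacklevel=2,
        )
        return "unknown", None
    codon_i = snp_idx // 3
    within = snp_idx % 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return "unknown", None
    ref_cds = _COMPLEMENT[ref] if minus else ref
    alt_cds = _COMPLEMENT[alt] if minus else alt
    if codon[within] != ref_cds:
        raise ValueError(
            f"reference base mismatch at {gene.chrom}:{pos} (codon has {codon[within]}, expected {ref_cds})"
        )
    alt_codon = codon[:within] + alt_cds + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    change = f"{aa_ref}{codon_i + 1}{aa_alt}"
    if aa_ref == aa_alt:
        return "coding_synonymous", change
    return "coding_missense", change


def classify_effect(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    gene: Optional[GeneModel],
    genome: Dict[str, str],
    flank: int = 10_000,
) -> SnpEffect:
    """Classify one SNP against one gene model.

    Categories: coding (synonymous/missense) when the position falls in a
    CDS segment; intron when inside the gene span but not in CDS (UTRs
    included); outside_gene_within_10kb in the flank; intergenic otherwise
    or when ``gene`` is None. The reference base must match the genome.
    """
    if chrom in genome:
        g_base = genome[chrom][pos - 1].upper()
        if g_base != ref.upper():
            raise ValueError(
                f"reference mismatch at {chrom}:{pos}: genome has {g_base}, SNP says {ref}"
            )
    if gene is None:
        return SnpEffect(chrom, pos, ref, alt, [], "intergenic")
    if gene.start <= pos <= gene.end:
        for mrna_id, segs in gene.cds.items():
            if any(s <= pos <= e for s, e, _ in segs):
                if chrom not in genome:
                    return SnpEffect(chrom, pos, ref, alt, [gene.gene_id], "unknown")
                cat, change = _codon_effect(gene, segs, pos, ref, alt, genome[chrom])
                return SnpEffect(chrom, pos, ref, alt, [gene.gene_id], cat, change)
        return SnpEffect(chrom, pos, ref, alt, [gene.gene_id], "intron")
    lo = max(1, gene.start - flank)
    if lo <= pos <= gene.end + flank:
        return SnpEffect(chrom, pos, ref, alt, [gene.gene_id], "outside_gene_within_10kb")
    return SnpEffect(chrom, pos, ref, alt, [], "intergenic")


_SEVERITY = {
    "coding_synonymous": 0,
    "coding_missense": 0,
    "intron": 1,
    "outside_gene_within_10kb": 2,
    "intergenic": 3,
    "unknown": 4,
}


def summarize_categories(effects: Iterable[SnpEffect]) -> Dict[str, float]:
    """Proportions of SNPs by most-severe category.

    Each SNP (chrom, pos) is counted once under its most severe category
    (coding > intron > flank > intergenic); returns proportions over the
    four-way partition (coding, intron, outside, intergenic) summing to 1.
    Empty input returns an empty dict.
    """
    best: Dict[Tuple[str, int], SnpEffect] = {}
    for e in effects:
        key = (e.chrom, e.pos)
        if key not in best or _SEVERITY[e.category] < _SEVERITY[best[key].category]:
            best[key] = e
    if not best:
        return {}
    buckets = {"coding": 0, "intron": 0, "outside_gene_within_10kb": 0, "intergenic": 0}
    n = 0
    for e in best.values():
        if e.category in ("coding_synonymous", "coding_missense"):
            buckets["coding"] += 1
        elif e.category == "intron":
            buckets["intron"] += 1
        elif e.category == "outside_gene_within_10kb":
            buckets["outside_gene_within_10kb"] += 1
        elif e.category == "intergenic":
            buckets["intergenic"] += 1
        else:
            continue
        n += 1
    return {k: v / n for k, v in buckets.items()}
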