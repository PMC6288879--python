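"""Popoolation2 sync parsing and the variant coverage filters.

The sync dialect is tab-separated ``chrom pos ref lib1 ... libJ`` with each
library field an ``A:T:C:G:N:del`` colon-separated count vector. Variants
are reduced to exactly two retained alleles per site:

* biallelic sites pass when total coverage exceeds ``min_total`` in every
  library and the nonreference allele exceeds ``min_alt`` reads in at least
  one library;
* triallelic sites are rescued when coverage passes everywhere and, in at
  least one library, exactly two (not three) alleles exceed ``min_allele``
  reads — most such sites are genuinely biallelic with either both alleles
  differing from the reference or a low-coverage sequencing-error "allele".

The N and del columns are parsed but never counted as alleles; "coverage"
throughout is the sum of the four base counts. For rescued sites the
downstream coverage is the sum of the two retained alleles, keeping the
binomial denominator consistent with the two-allele response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SyncRecord",
    "SyncParseError",
    "read_sync",
    "filter_biallelic",
    "rescue_triallelic",
    "filter_sync",
    "allele_table_columns",
    "write_allele_table",
]

_BASES = ("A", "T", "C", "G")
_N_FIELDS = 6


class SyncParseError(ValueError):
    """Malformed sync input; message names the offending line number."""


@dataclass(frozen=True)
class SyncRecord:
    chrom: str
    pos: int
    ref: str
    counts: np.ndarray  # (n_libs, 6) non-negative ints, columns A,T,C,G,N,del

    @property
    def base_counts(self) -> np.ndarray:
        """Per-library counts of the four bases (N/del excluded)."""
        return self.counts[:, :4]


def read_sync(path) -> Iterator[SyncRecord]:
    """Stream SyncRecords from a sync file; empty file yields nothing."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SyncParseError(
                    f"line {lineno}: expected >= 4 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise SyncParseError(f"line {lineno}: non-integer position {pos_s!r}")
            libs = fields[3:]
            counts = np.empty((len(libs), _N_FIELDS), dtype=np.int64)
            for j, f in enumerate(libs):
                parts = f.split(":")
                if len(parts) != _N_FIELDS:
                    raise SyncParseError(
                        f"line {lineno}: library field {j + 1} has {len(parts)} values, expected {_N_FIELDS}"
                    )
                try:
                    counts[j] = [int(x) for x in parts]
                except ValueError:
                    raise SyncParseError(
                        f"line {lineno}: non-integer count in library field {j + 1}"
                    )
            if (counts < 0).any():
                raise SyncParseError(f"line {lineno}: negative count")
            yield SyncRecord(chrom, pos, ref, counts)


def allele_table_columns(labels: List[str]) -> List[str]:
    cols = ["chrom", "pos", "a1", "a2"]
    for lab in labels:
        cols += [f"{lab}_c1", f"{lab}_c2"]
    return cols + ["filter_class"]


def _row(rec: SyncRecord, a1: int, a2: int, labels, filter_class: str) -> dict:
    row = {"chrom": rec.chrom, "pos": rec.pos, "a1": _BASES[a1], "a2": _BASES[a2]}
    for j, lab in enumerate(labels):
        row[f"{lab}_c1"] = int(rec.counts[j, a1])
        row[f"{lab}_c2"] = int(rec.counts[j, a2])
    row["filter_class"] = filter_class
    return row


def _labels_for(rec: SyncRecord, labels) -> List[str]:
    if labels is not None:
        return list(labels)
    return [f"lib{j + 1}" for j in range(rec.counts.shape[0])]


def filter_biallelic(
    records: Iterable[SyncRecord],
    min_total: int = 10,
    min_alt: int = 5,
    labels: List[str] | None = None,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply the biallelic coverage filter.

    A site with exactly two segregating bases is retained iff total
    coverage is strictly greater than ``min_total`` in every library and a
    nonreference allele has strictly more than ``min_alt`` reads in at
    least one library. Returns the retained rows and drop-reason counts.
    """
    rows, reasons = [], {"not_biallelic": 0, "low_total": 0, "low_alt": 0}
    for rec in records:
        bc = rec.base_counts
        seg = np.flatnonzero(bc.sum(axis=0) > 0)
        if len(seg) != 2:
            reasons["not_biallelic"] += 1
            continue
        if not (bc.sum(axis=1) > min_total).all():
            reasons["low_total"] += 1
            continue
        try:
            ref_i = _BASES.index(rec.ref)
        except ValueError:
            ref_i = -1
        nonref = [b for b in seg if b != ref_i]
        if not ((bc[:, nonref] > min_alt).any()):
            reasons["low_alt"] += 1
            continue
        if ref_i in seg:
            a1, a2 = ref_i, [b for b in seg if b != ref_i][0]
        else:
            # both alleles differ from the reference: keep higher-count first
            tot = bc.sum(axis=0)
            a1, a2 = sorted(seg, key=lambda b: (-tot[b], _BASES[b]))
        if labels is None:
            labels = _labels_for(rec, None)
        rows.append(_row(rec, a1, a2, labels, "biallelic_pass"))
    table = pd.DataFrame(rows, columns=allele_table_columns(labels or []))
    return table, reasons


def rescue_triallelic(
    records: Iterable[SyncRecord],
    min_total: int = 10,
    min_allele: int = 5,
    labels: List[str] | None = None,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Rescue triallelic sites that are effectively biallelic.

    A site with exactly three segregating bases is rescued iff overall
    coverage is strictly greater than ``min_total`` in every library and at
    least one library has exactly two (not three) alleles with strictly
    more than ``min_allele`` reads. The two retained alleles are the pair
    with the greatest summed count across libraries (ties broken by higher
    summed count then alphabetical base order).
    """
    rows, reasons = [], {"not_triallelic": 0, "low_total": 0, "allele_rule": 0}
    for rec in records:
        bc = rec.base_counts
        seg = np.flatnonzero(bc.sum(axis=0) > 0)
        if len(seg) != 3:
            reasons["not_triallelic"] += 1
            continue
        if not (bc.sum(axis=1) > min_total).all():
            reasons["low_total"] += 1
            continue
        n_big = (bc[:, seg] > min_allele).sum(axis=1)
        if not (n_big == 2).any():
            reasons["allele_rule"] += 1
            continue
        tot = bc.sum(axis=0)
        pair = sorted(seg, key=lambda b: (-tot[b], _BASES[b]))[:2]
        a1, a2 = sorted(pair, key=lambda b: (-tot[b], _BASES[b]))
        if labels is None:
            labels = _labels_for(rec, None)
        rows.append(_row(rec, a1, a2, labels, "triallelic_rescued"))
    table = pd.DataFrame(rows, columns=allele_table_columns(labels or []))
    return table, reasons


def filter_sync(
    records: Iterable[SyncRecord],
    min_total: int = 10,
    min_alt: int = 5,
    labels: List[str] | None = None,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Run both filter paths over one pass of records."""
    recs = list(records)
    bi, r1 = filter_biallelic(recs, min_total, min_alt, labels=labels)
    tri, r2 = rescue_triallelic(recs, min_total, min_alt, labels=labels)
    parts = [t for t in (bi, tri) if len(t)]
    if parts:
        table = pd.concat(parts, ignore_index=True)
        table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    else:
        table = bi
    reasons = {f"biallelic_{k}": v for k, v in r1.items()}
    reasons.update({f"triallelic_{k}": v for k, v in r2.items()})
    return table, reasons


def write_allele_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
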