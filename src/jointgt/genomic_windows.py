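"""Cis-window covariate-set construction around gene transcription start sites.

A probe belongs to a gene's set iff it lies on the same chromosome and
within ``flank_bp`` base pairs of the transcription start site in either
direction (closed interval — a probe exactly at the boundary is included).
Strand never affects membership.  Default flanks follow common practice for
cis-regulatory reach: 1 Mb for copy number, 50 Kb for methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicFeature",
    "ProbeAnnotation",
    "WindowSpec",
    "CN_FLANK_BP",
    "ME_FLANK_BP",
    "build_sets",
    "read_gene_bed",
    "read_probe_bed",
    "normalize_chrom",
]

logger = logging.getLogger(__name__)

CN_FLANK_BP = 1_000_000
ME_FLANK_BP = 50_000


def normalize_chrom(chrom: str) -> str:
    """Case-fold and strip a leading ``chr`` prefix."""
    c = str(chrom).strip().lower()
    if c.startswith("chr"):
        c = c[3:]
    return c


@dataclass(frozen=True)
class GenomicFeature:
    """A response feature anchored at its transcription start site."""

    feature_id: str
    chrom: str
    tss: int
    strand: str = "."
    arm: str | None = None

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.feature_id}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r} for {self.feature_id}")


@dataclass(frozen=True)
class ProbeAnnotation:
    """A covariate probe reduced to a single genomic coordinate."""

    probe_id: str
    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position for probe {self.probe_id}")


@dataclass(frozen=True)
class WindowSpec:
    """Symmetric window half-width around the TSS, in base pairs."""

    flank_bp: int

    def __post_init__(self) -> None:
        if self.flank_bp <= 0:
            raise ValueError("flank_bp must be positive")


def build_sets(
    genes: Sequence[GenomicFeature],
    probes: Sequence[ProbeAnnotation],
    spec: WindowSpec,
) -> dict[str, list[int]]:
    """Map each gene to the indices of probes within its cis window.

    Returned lists index into ``probes`` and are ordered by ascending
    genomic position, ties broken by probe id.  Genes with no probe in the
    window map to an empty list (the caller flags them; they are never
    dropped).  Probes on chromosomes absent from the gene annotation are
    excluded with a logged warning.
    """
    gene_ids = [g.feature_id for g in genes]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("gene feature_ids are not unique")
    probe_ids = [p.probe_id for p in probes]
    if len(set(probe_ids)) != len(probe_ids):
        raise ValueError("probe_ids are not unique")

    gene_chroms = {normalize_chrom(g.chrom) for g in genes}
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    unknown = 0
    table: dict[str, list[tuple[int, str, int]]] = {}
    for i, p in enumerate(probes):
        c = normalize_chrom(p.chrom)
        if c not in gene_chroms:
            unknown += 1
            continue
        table.setdefault(c, []).append((p.pos, p.probe_id, i))
    if unknown:
        logger.warning(
            "excluded %d probes on chromosomes absent from the gene annotation",
            unknown,
        )
    for c, rows in table.items():
        rows.sort(key=lambda t: (t[0], t[1]))
        by_chrom[c] = (
            np.array([t[0] for t in rows], dtype=np.int64),
            np.array([t[2] for t in rows], dtype=np.intp),
        )

    out: dict[str, list[int]] = {}
    for g in genes:
        c = normalize_chrom(g.chrom)
        if c not in by_chrom:
            out[g.feature_id] = []
            continue
        pos, idx = by_chrom[c]
        lo = int(np.searchsorted(pos, g.tss - spec.flank_bp, side="left"))
        hi = int(np.searchsorted(pos, g.tss + spec.flank_bp, side="right"))
        out[g.feature_id] = [int(k) for k in idx[lo:hi]]
    return out


def _probe_point(start: int, end: int) -> int:
    """Single coordinate for a BED interval: start+1 for points, midpoint otherwise."""
    if end - start <= 1:
        return start + 1
    return (start + 1 + end) // 2


def read_gene_bed(path) -> list[GenomicFeature]:
    """Read a BED-like gene annotation.

    Columns: chrom, start, end, feature_id, score (ignored), strand,
    optional arm label in column 7.  The interval is taken as a point
    feature marking the TSS (0-based start converted to a 1-based
    coordinate).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"gene BED {path} needs at least 4 columns")
    genes = []
    for row in df.itertuples(index=False):
        start = int(row[1])
        strand = str(row[5]) if len(row) > 5 and pd.notna(row[5]) else "."
        arm = str(row[6]) if len(row) > 6 and pd.notna(row[6]) else None
        genes.append(
            GenomicFeature(
                feature_id=str(row[3]),
                chrom=str(row[0]),
                tss=start + 1,
                strand=strand,
                arm=arm,
            )
        )
    return genes


def read_probe_bed(path) -> list[ProbeAnnotation]:
    """Read a BED-like probe annotation (chrom, start, end, probe_id)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 4:
        raise ValueError(f"probe BED {path} needs at least 4 columns")
    return [
        ProbeAnnotation(
            probe_id=str(row[3]),
            chrom=str(row[0]),
            pos=_probe_point(int(row[1]), int(row[2])),
        )
        for row in df.itertuples(index=False)
    ]
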