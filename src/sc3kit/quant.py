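"""Strand-aware read-to-gene assignment, counting and RPM normalization.

Reads are assigned to a gene when they overlap its (extended) exonic span on
the same strand; overlaps with more than one candidate are ambiguous and
dropped; spike-in chromosomes (name prefix ``ERCC-`` by default) are tallied
separately and never enter gene counts. Counts are normalized to reads per
million using, by default, the per-cell total of gene-assigned reads, which
makes every non-empty RPM column sum to exactly 10^6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .errors import Sc3kitError, UnknownChromosomeError

logger = logging.getLogger(__name__)

AMBIGUOUS = "__ambiguous__"
UNASSIGNED = "__unassigned__"
SPIKE_IN = "__spike_in__"

DEFAULT_SPIKE_PREFIX = "ERCC-"

TALLY_COLUMNS = ("assigned", "ambiguous", "unassigned", "spike_in")


@dataclass(frozen=True)
class AlignedRead:
    """One aligned read: 1-based inclusive coordinates, explicit strand and cell."""

    chrom: str
    strand: str
    start: int
    end: int
    cell_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"read start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad read strand {self.strand!r}")


def read_bed6(path: str | Path) -> list[AlignedRead]:
    """Load reads from BED6 (0-based half-open -> 1-based closed; name = cell id)."""
    reads = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise Sc3kitError(f"{path}: line {i}: BED6 needs 6 columns")
        chrom, start0, end, name, _score, strand = fields[:6]
        reads.append(AlignedRead(chrom=chrom, strand=strand,
                                 start=int(start0) + 1, end=int(end), cell_id=name))
    return reads


def write_bed6(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.cell_id}\t0\t{r.strand}\n")


class _GeneIndex:
    """Per-(chrom, strand) exon intervals for overlap queries."""

    def __init__(self, ann: AnnotationSet):
        self.ann = ann
        self._exons: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list[str]]] = {}
        buckets: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
        for g in ann:
            for s, e in g.exons:
                buckets.setdefault((g.chrom, g.strand), []).append((s, e, g.gene_id))
        for key, ivs in buckets.items():
            ivs.sort()
            starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
            ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
            ids = [iv[2] for iv in ivs]
            self._exons[key] = (starts, ends, ids)

    def overlapping_genes(self, r: AlignedRead) -> set[str]:
        entry = self._exons.get((r.chrom, r.strand))
        if entry is None:
            return set()
        starts, ends, ids = entry
        hit = (starts <= r.end) & (ends >= r.start)
        return {ids[i] for i in np.flatnonzero(hit)}


def assign_read(
    r: AlignedRead,
    ann: AnnotationSet,
    *,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
    _index: "_GeneIndex | None" = None,
) -> str:
    """Assign one read: a gene_id, or AMBIGUOUS / UNASSIGNED / SPIKE_IN."""
    if r.chrom.startswith(spike_prefix):
        return SPIKE_IN
    if r.chrom not in ann.layout:
        raise UnknownChromosomeError(f"read on unknown chromosome {r.chrom!r}")
    index = _index or _GeneIndex(ann)
    hits = index.overlapping_genes(r)
    if not hits:
        return UNASSIGNED
    if len(hits) > 1:
        return AMBIGUOUS
    return hits.pop()


@dataclass
class CountMatrix:
    """Integer gene x cell counts plus per-cell read-category tallies."""

    counts: pd.DataFrame          # genes x cells, int
    tallies: pd.DataFrame         # cells x TALLY_COLUMNS, int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.columns)

    def validate(self) -> None:
        col_sums = self.counts.sum(axis=0)
        if not (col_sums.values == self.tallies["assigned"].values).all():
            raise Sc3kitError("tally 'assigned' does not equal column sums")
        if (self.counts.values < 0).any() or (self.tallies.values < 0).any():
            raise Sc3kitError("negative counts or tallies")


def count_cells(
    reads: Sequence[AlignedRead],
    ann: AnnotationSet,
    *,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
    cell_ids: Sequence[str] | None = None,
) -> CountMatrix:
    """Tally reads per (gene, cell); categories partition the input exactly."""
    index = _GeneIndex(ann)
    gene_ids = [g.gene_id for g in ann]
    cells = list(cell_ids) if cell_ids is not None else sorted({r.cell_id for r in reads})
    cell_pos = {c: i for i, c in enumerate(cells)}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}

    counts = np.zeros((len(gene_ids), len(cells)), dtype=np.int64)
    tallies = np.zeros((len(cells), len(TALLY_COLUMNS)), dtype=np.int64)
    cat_pos = {c: i for i, c in enumerate(TALLY_COLUMNS)}

    for r in reads:
        ci = cell_pos.get(r.cell_id)
        if ci is None:
            raise Sc3kitError(f"read cell {r.cell_id!r} not in provided cell_ids")
        result = assign_read(r, ann, spike_prefix=spike_prefix, _index=index)
        if result == SPIKE_IN:
            tallies[ci, cat_pos["spike_in"]] += 1
        elif result == AMBIGUOUS:
            tallies[ci, cat_pos["ambiguous"]] += 1
        elif result == UNASSIGNED:
            tallies[ci, cat_pos["unassigned"]] += 1
        else:
            counts[gene_pos[result], ci] += 1
            tallies[ci, cat_pos["assigned"]] += 1

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=cells),
        tallies=pd.DataFrame(tallies, index=cells, columns=list(TALLY_COLUMNS)),
    )
    cm.validate()
    return cm


@dataclass
class ExpressionMatrix:
    """Gene x cell matrix on an RPM or log2(RPM+1) scale."""

    values: pd.DataFrame
    scale: str  # "rpm" or "log2_rpm_plus1"

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)


def to_rpm(m: CountMatrix, *, denominator: str = "assigned") -> ExpressionMatrix:
    """Normalize counts to reads per million.

    ``denominator='assigned'`` (default) divides by gene-assigned reads so
    non-empty columns sum to exactly 10^6; ``'genome_mapped'`` divides by
    assigned + ambiguous + unassigned.
    """
    if denominator == "assigned":
        denom = m.tallies["assigned"].astype(float)
    elif denominator == "genome_mapped":
        denom = (
            m.tallies["assigned"] + m.tallies["ambiguous"] + m.tallies["unassigned"]
        ).astype(float)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")

    empty = denom[denom == 0].index.tolist()
    if empty:
        logger.warning("to_rpm: %d cell(s) with zero %s reads -> all-zero columns: %s",
                       len(empty), denominator, empty[:5])
    safe = denom.replace(0, 1.0)
    rpm = m.counts.astype(float).div(safe, axis=1) * 1e6
    return ExpressionMatrix(values=rpm, scale="rpm")


def to_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    if m.scale != "rpm":
        raise ValueError("to_log2 expects an RPM matrix")
    return ExpressionMatrix(values=np.log2(m.values + 1.0), scale="log2_rpm_plus1")


def expressed_genes(
    logm: ExpressionMatrix, threshold: float = 4.0, min_cells: int = 1
) -> list[str]:
    """Genes whose log2(RPM+1) exceeds ``threshold`` (strict) in >= ``min_cells`` cells."""
    if logm.scale != "log2_rpm_plus1":
        raise ValueError("expressed_genes expects a log2(RPM+1) matrix")
    n_above = (logm.values > threshold).sum(axis=1)
    return list(logm.values.index[n_above >= min_cells])
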