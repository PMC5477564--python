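"""Transcript-annotation rewriting for 3'-end tag counting.

Tag-counting protocols concentrate reads within a few hundred bases of each
transcription termination site (TTS), so genes whose annotated TTS falls short
of the true 3' end lose signal. This module rewrites a GFF3 annotation to
recover that signal: it removes unwanted biotypes, collapses genes that share
an identical TTS, and extends every remaining TTS downstream by up to a fixed
amount, stopping early at neighbouring gene landmarks.

Collision rules, applied against the ORIGINAL coordinates of all other
retained genes (never against already-extended neighbours, which keeps the
result independent of processing order):

* same-strand gene with its TSS inside the extension window -> stop 1 bp
  upstream (in the extending gene's 3' direction) of that TSS;
* opposite-strand gene with its TTS inside the window -> stop at the midpoint
  of the two TTSs (the lower-coordinate gene takes ``floor((t1+t2)/2)``, the
  other ``floor((t1+t2)/2)+1``, so the two extensions never overlap);
* any other gene body intruding into the window -> stop 1 bp before the first
  intruding base;
* the chromosome end clamps everything.

Coordinates are 1-based fully-closed throughout, as in GFF3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .errors import GffParseError, Sc3kitError, UnknownChromosomeError

logger = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "pseudogene", "tRNA", "ncRNA", "other")

DEFAULT_REMOVED_BIOTYPES = frozenset({"pseudogene", "tRNA", "ncRNA"})


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths (1-based coordinate space)."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise UnknownChromosomeError(f"unknown chromosome: {chrom!r}") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeLayout":
        """Read a two-column (name, length) chromosome-sizes table."""
        lengths: dict[str, int] = {}
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise Sc3kitError(f"{path}: line {i}: expected 2 tab-separated columns")
            name, length = fields[0], int(fields[1])
            if name in lengths:
                raise Sc3kitError(f"{path}: duplicate chromosome name {name!r}")
            lengths[name] = length
        return cls(lengths)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.lengths.items():
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class GeneModel:
    """A single gene with strand-dependent 5'/3' termini.

    ``tss``/``tts`` are derived: on '+' the TSS is ``start`` and the TTS is
    ``end``; on '-' they are reversed.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start {self.start} < 1")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) reversed")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) outside gene span")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping at ({s},{e})")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ExtensionConfig:
    """Parameters of the annotation-rewriting procedure."""

    max_extension: int = 10_000
    removed_biotypes: frozenset[str] = DEFAULT_REMOVED_BIOTYPES
    biotype_filter_order: str = "before_extension"
    feature_types_to_extend: frozenset[str] = frozenset({"gene", "transcript", "exon"})

    def __post_init__(self) -> None:
        if self.max_extension < 0:
            raise ValueError("max_extension must be >= 0")
        if self.biotype_filter_order not in ("before_extension", "after_extension"):
            raise ValueError(
                f"biotype_filter_order must be 'before_extension' or 'after_extension', "
                f"got {self.biotype_filter_order!r}"
            )


class AnnotationSet:
    """An indexed collection of :class:`GeneModel` over a :class:`GenomeLayout`."""

    def __init__(self, layout: GenomeLayout, genes: Iterable[GeneModel]):
        self.layout = layout
        self.genes: list[GeneModel] = list(genes)
        self._by_id: dict[str, GeneModel] = {}
        self._by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            if g.chrom not in layout:
                raise UnknownChromosomeError(
                    f"gene {g.gene_id} lies on unknown chromosome {g.chrom!r}"
                )
            if g.end > layout.length_of(g.chrom):
                raise ValueError(
                    f"gene {g.gene_id} ends at {g.end}, beyond chromosome "
                    f"{g.chrom} length {layout.length_of(g.chrom)}"
                )
            if g.gene_id in self._by_id:
                raise Sc3kitError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for lst in self._by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end, g.gene_id))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise Sc3kitError(f"no such gene: {gene_id!r}") from None

    def on_chrom(self, chrom: str) -> list[GeneModel]:
        return self._by_chrom.get(chrom, [])

    def with_genes(self, genes: Iterable[GeneModel]) -> "AnnotationSet":
        return AnnotationSet(self.layout, genes)


# ---------------------------------------------------------------------------
# GFF3 input / output
# ---------------------------------------------------------------------------

def _parse_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.rstrip(";").split(";"):
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"attribute {chunk!r} lacks '='")
        key, value = chunk.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


def _biotype_from_attrs(attrs: Mapping[str, str]) -> str:
    if attrs.get("pseudo", "").lower() == "true":
        return "pseudogene"
    raw = attrs.get("gene_biotype", attrs.get("biotype", "protein_coding"))
    return raw if raw in BIOTYPES else "other"


def read_gff3(path: str | Path, layout: GenomeLayout) -> AnnotationSet:
    """Parse a GFF3 annotation into an :class:`AnnotationSet`.

    Recognises ``gene`` rows (one :class:`GeneModel` each), ``mRNA`` /
    ``transcript`` rows linking to their gene, and ``exon`` rows linking to a
    transcript. A gene with no exon rows gets a single exon spanning its body.
    """
    genes: dict[str, dict] = {}
    transcript_to_gene: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GffParseError(f"expected 9 columns, got {len(fields)}", lineno)
            chrom, _source, ftype, start_s, end_s, _score, strand, _phase, raw_attrs = fields
            try:
                start, end = int(start_s), int(end_s)
                attrs = _parse_attributes(raw_attrs)
            except ValueError as exc:
                raise GffParseError(str(exc), lineno) from None
            if strand not in ("+", "-"):
                raise GffParseError(f"bad strand {strand!r}", lineno)

            if ftype == "gene":
                if chrom not in layout:
                    raise UnknownChromosomeError(
                        f"line {lineno}: gene on unknown chromosome {chrom!r}"
                    )
                gid = attrs.get("ID")
                if gid is None:
                    raise GffParseError("gene row lacks ID attribute", lineno)
                genes[gid] = {
                    "gene_id": gid,
                    "gene_name": attrs.get("Name", gid),
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "biotype": _biotype_from_attrs(attrs),
                    "exons": [],
                }
            elif ftype in ("mRNA", "transcript"):
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise GffParseError(f"{ftype} row lacks ID/Parent", lineno)
                transcript_to_gene[tid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise GffParseError("exon row lacks Parent", lineno)
                gid = transcript_to_gene.get(parent, parent)
                if gid in genes:
                    genes[gid]["exons"].append((start, end))
            # other feature types are ignored

    models = []
    for rec in genes.values():
        exons = tuple(sorted(set(rec.pop("exons")))) or None
        models.append(GeneModel(exons=exons or (), **rec))
    return AnnotationSet(layout, models)


def write_gff3(ann: AnnotationSet, path: str | Path) -> None:
    """Write gene + transcript + exon rows; round-trips coordinates exactly."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in ann.layout.lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in ann.genes:
            attrs = f"ID={g.gene_id};Name={g.gene_name};gene_biotype={g.biotype}"
            if g.biotype == "pseudogene":
                attrs += ";pseudo=True"
            tid = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsc3kit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tsc3kit\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={tid};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tsc3kit\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={tid}.exon{i};Parent={tid}\n"
                )


# ---------------------------------------------------------------------------
# Rewriting rules
# ---------------------------------------------------------------------------

def filter_biotypes(ann: AnnotationSet, cfg: ExtensionConfig) -> AnnotationSet:
    """Drop genes whose biotype is in ``cfg.removed_biotypes``."""
    return ann.with_genes(g for g in ann if g.biotype not in cfg.removed_biotypes)


def dedupe_identical_tts(ann: AnnotationSet) -> AnnotationSet:
    """Keep one gene per (chrom, strand, TTS): the longest span, ties by gene_id."""
    best: dict[tuple[str, str, int], GeneModel] = {}
    for g in ann:
        key = (g.chrom, g.strand, g.tts)
        cur = best.get(key)
        if cur is None or (g.span, _neg_id(g)) > (cur.span, _neg_id(cur)):
            best[key] = g
    kept_ids = {g.gene_id for g in best.values()}
    return ann.with_genes(g for g in ann if g.gene_id in kept_ids)


class _neg_id:
    """Orders gene_ids descending so max() picks the lexicographically smallest."""

    __slots__ = ("gid",)

    def __init__(self, g: GeneModel):
        self.gid = g.gene_id

    def __lt__(self, other: "_neg_id") -> bool:
        return self.gid > other.gid

    def __gt__(self, other: "_neg_id") -> bool:
        return self.gid < other.gid

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _neg_id) and self.gid == other.gid


def compute_extended_tts(g: GeneModel, ann: AnnotationSet, cfg: ExtensionConfig) -> int:
    """New TTS coordinate for ``g``: extend up to ``max_extension`` 3' of the
    current TTS, stopping at neighbour landmarks (see module docstring).

    All other genes are taken at their coordinates as stored in ``ann``.
    """
    if g.gene_id not in ann or ann.get(g.gene_id) != g:
        raise Sc3kitError(f"gene {g.gene_id!r} is not a member of the annotation set")
    t = g.tts
    chrom_len = ann.layout.length_of(g.chrom)
    if g.strand == "+":
        window_end = min(t + cfg.max_extension, chrom_len)
        cap = window_end
        if window_end <= t:
            return t
        for o in ann.on_chrom(g.chrom):
            if o.gene_id == g.gene_id:
                continue
            if o.start > window_end or o.end < t + 1:
                continue  # body does not intersect the window
            if o.strand == "+":
                cap = min(cap, max(o.start - 1, t))
            elif t + 1 <= o.tts <= window_end:
                cap = min(cap, (t + o.tts) // 2)
            else:
                cap = min(cap, max(o.start - 1, t))
        return max(cap, t)
    else:
        window_start = max(t - cfg.max_extension, 1)
        cap = window_start
        if window_start >= t:
            return t
        for o in ann.on_chrom(g.chrom):
            if o.gene_id == g.gene_id:
                continue
            if o.end < window_start or o.start > t - 1:
                continue
            if o.strand == "-":
                cap = max(cap, min(o.end + 1, t))
            elif window_start <= o.tts <= t - 1:
                cap = max(cap, (t + o.tts) // 2 + 1)
            else:
                cap = max(cap, min(o.end + 1, t))
        return min(cap, t)


def _apply_new_tts(g: GeneModel, new_tts: int) -> GeneModel:
    """Move the gene span and its 3'-most exon to the new TTS."""
    if g.strand == "+":
        if new_tts == g.end:
            return g
        exons = list(g.exons)
        last = max(range(len(exons)), key=lambda i: exons[i][1])
        exons[last] = (exons[last][0], new_tts)
        return replace(g, end=new_tts, exons=tuple(exons))
    else:
        if new_tts == g.start:
            return g
        exons = list(g.exons)
        first = min(range(len(exons)), key=lambda i: exons[i][0])
        exons[first] = (new_tts, exons[first][1])
        return replace(g, start=new_tts, exons=tuple(exons))


def extend_all(ann: AnnotationSet, cfg: ExtensionConfig | None = None) -> AnnotationSet:
    """Full rewrite: biotype filter, TTS dedup, then per-gene 3' extension.

    Every new TTS is computed against the original (pre-extension) coordinates
    of the retained set, so the result does not depend on gene order. With
    ``biotype_filter_order='after_extension'`` the removable biotypes stay in
    place during extension (and may block it) and are dropped afterwards.
    """
    cfg = cfg or ExtensionConfig()
    work = ann
    if cfg.biotype_filter_order == "before_extension":
        work = filter_biotypes(work, cfg)
    work = dedupe_identical_tts(work)
    extended = [
        _apply_new_tts(g, compute_extended_tts(g, work, cfg)) for g in work
    ]
    out = work.with_genes(extended)
    if cfg.biotype_filter_order == "after_extension":
        out = filter_biotypes(out, cfg)
    return out


# ---------------------------------------------------------------------------
# Gene-name mapping
# ---------------------------------------------------------------------------

def read_name_mapping(path: str | Path) -> dict[str, str]:
    """Two-column (old_name, new_name) TSV; duplicate keys are an error."""
    mapping: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise Sc3kitError(f"{path}: line {i}: expected 2 columns")
        if fields[0] in mapping:
            raise Sc3kitError(f"{path}: duplicate mapping key {fields[0]!r}")
        mapping[fields[0]] = fields[1]
    return mapping


def apply_name_mapping(ann: AnnotationSet, mapping: Mapping[str, str]) -> AnnotationSet:
    """Rename genes whose current name appears as a key; others untouched."""
    keys = list(mapping.keys())
    if len(set(keys)) != len(keys):
        raise Sc3kitError("name mapping contains duplicate keys")
    used = set()
    renamed = []
    for g in ann:
        if g.gene_name in mapping:
            used.add(g.gene_name)
            renamed.append(replace(g, gene_name=mapping[g.gene_name]))
        else:
            renamed.append(g)
    unused = set(keys) - used
    if unused:
        logger.warning("name mapping: %d unused key(s), e.g. %s",
                       len(unused), sorted(unused)[:3])
    return ann.with_genes(renamed)
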