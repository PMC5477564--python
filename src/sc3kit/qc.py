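"""Quality-control statistics for 3'-end tag-counting libraries.

Covers: read-category accounting (the five mapping-statistics columns must
partition the total), qPCR cycle-threshold prescreening of amplified cDNAs,
the read-density meta-profile around annotated TTSs, qPCR-vs-sequencing
concordance, and per-cell expression-percentile profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet
from .errors import Sc3kitError
from .quant import (
    AMBIGUOUS,
    DEFAULT_SPIKE_PREFIX,
    SPIKE_IN,
    UNASSIGNED,
    AlignedRead,
    ExpressionMatrix,
    _GeneIndex,
    assign_read,
)

CATEGORY_FIELDS = (
    "sc3seq_mapped",
    "mapped_others",
    "control_rna",
    "low_quality_adaptor_polyA",
    "unmapped",
)


@dataclass(frozen=True)
class ReadCategoryTally:
    """One sample's read accounting: five categories plus the claimed total."""

    sample_id: str
    total_reads: int
    sc3seq_mapped: int
    mapped_others: int
    control_rna: int
    low_quality_adaptor_polyA: int
    unmapped: int

    def __post_init__(self) -> None:
        for name in ("total_reads",) + CATEGORY_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{self.sample_id}: {name} negative")

    @property
    def category_sum(self) -> int:
        return sum(getattr(self, name) for name in CATEGORY_FIELDS)


def check_tally(t: ReadCategoryTally) -> bool:
    """True iff the five read categories sum exactly to the claimed total."""
    return t.category_sum == t.total_reads


def tallies_from_count_matrix(cm) -> list[ReadCategoryTally]:
    """Per-cell tallies of a quantified :class:`~sc3kit.quant.CountMatrix`
    mapped onto the five accounting categories (nothing is trimmed away
    in-silico, so the low-quality category is zero)."""
    out = []
    for cell, row in cm.tallies.iterrows():
        out.append(ReadCategoryTally(
            sample_id=str(cell),
            total_reads=int(row.sum()),
            sc3seq_mapped=int(row["assigned"]),
            mapped_others=int(row["ambiguous"]),
            control_rna=int(row["spike_in"]),
            low_quality_adaptor_polyA=0,
            unmapped=int(row["unassigned"]),
        ))
    return out


def read_tally_tsv(path) -> list[ReadCategoryTally]:
    df = pd.read_csv(path, sep="\t")
    id_col = "sample_id" if "sample_id" in df.columns else "gsm_id"
    return [
        ReadCategoryTally(
            sample_id=str(row[id_col]),
            total_reads=int(row["total_reads"]),
            sc3seq_mapped=int(row["sc3seq_mapped"]),
            mapped_others=int(row["mapped_others"]),
            control_rna=int(row["control_rna"]),
            low_quality_adaptor_polyA=int(row["low_quality_adaptor_polyA"]),
            unmapped=int(row["unmapped"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# qPCR prescreen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    gene_name: str
    ct: float

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError(f"{self.sample_id}/{self.gene_name}: ct must be > 0")


PASS, FAIL, INDETERMINATE = "pass", "fail", "indeterminate"


def prescreen_ct(
    records: Iterable[CtRecord],
    gapdh_max: float = 19.0,
    ppia_max: float = 20.0,
) -> dict[str, str]:
    """Per-sample good-quality call from housekeeping Ct values.

    A sample passes iff Ct(GAPDH) < gapdh_max AND Ct(PPIA) < ppia_max, both
    strict. Samples missing either marker are flagged indeterminate.
    """
    by_sample: dict[str, dict[str, float]] = {}
    for r in records:
        by_sample.setdefault(r.sample_id, {})[r.gene_name] = r.ct
    verdicts = {}
    for sample, cts in by_sample.items():
        if "GAPDH" not in cts or "PPIA" not in cts:
            verdicts[sample] = INDETERMINATE
        elif cts["GAPDH"] < gapdh_max and cts["PPIA"] < ppia_max:
            verdicts[sample] = PASS
        else:
            verdicts[sample] = FAIL
    return verdicts


def read_ct_tsv(path) -> list[CtRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CtRecord(sample_id=str(r["sample_id"]), gene_name=str(r["gene_name"]),
                 ct=float(r["ct"]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# TTS meta-profile
# ---------------------------------------------------------------------------

@dataclass
class MetaProfile:
    """Binned read density (kilo-RPM per bin) vs signed offset from the TTS."""

    offsets: np.ndarray                 # left edge of each bin, signed bp
    bin_size: int
    per_cell: pd.DataFrame              # bins x cells, kilo-RPM
    mean: pd.Series = field(init=False)  # cross-cell mean profile

    def __post_init__(self) -> None:
        if self.per_cell.shape[1]:
            self.mean = self.per_cell.mean(axis=1)
        else:
            self.mean = pd.Series(np.zeros(len(self.offsets)), index=self.per_cell.index)


def tts_metaprofile(
    reads: Sequence[AlignedRead],
    ann: AnnotationSet,
    window: tuple[int, int] = (-3000, 1000),
    bin_size: int = 50,
    tts_origin: Mapping[str, int] | None = None,
    spike_prefix: str = DEFAULT_SPIKE_PREFIX,
) -> MetaProfile:
    """Histogram of read 5'-end offsets from the assigned gene's TTS.

    Offsets are signed along the gene's 3' direction (negative = upstream of
    the TTS). ``ann`` is used for read assignment; ``tts_origin`` supplies the
    offset origin per gene (pass the original, pre-extension TTSs when ``ann``
    is the extended annotation; defaults to the TTSs stored in ``ann``).
    Each cell's histogram is scaled to kilo-RPM per bin: count / assigned
    reads x 10^3, so the profile integral over the window equals
    (assigned reads in window) / (assigned reads) x 10^3.
    """
    lo, hi = window
    if lo >= hi:
        raise ValueError("window must satisfy lo < hi")
    edges = np.arange(lo, hi + bin_size, bin_size)
    n_bins = len(edges) - 1
    index = _GeneIndex(ann)
    origins = tts_origin or {g.gene_id: g.tts for g in ann}

    cell_counts: dict[str, np.ndarray] = {}
    cell_assigned: dict[str, int] = {}
    for r in reads:
        result = assign_read(r, ann, spike_prefix=spike_prefix, _index=index)
        if result in (SPIKE_IN, AMBIGUOUS, UNASSIGNED):
            continue
        cell_assigned[r.cell_id] = cell_assigned.get(r.cell_id, 0) + 1
        gene = ann.get(result)
        tts = origins.get(result, gene.tts)
        pos5 = r.start if r.strand == "+" else r.end
        offset = pos5 - tts if gene.strand == "+" else tts - pos5
        if lo <= offset < hi:
            b = (offset - lo) // bin_size
            hist = cell_counts.setdefault(r.cell_id, np.zeros(n_bins))
            hist[b] += 1

    cells = sorted(cell_assigned)
    data = np.zeros((n_bins, len(cells)))
    for j, c in enumerate(cells):
        hist = cell_counts.get(c, np.zeros(n_bins))
        data[:, j] = hist / cell_assigned[c] * 1e3
    per_cell = pd.DataFrame(data, index=edges[:-1], columns=cells)
    return MetaProfile(offsets=edges[:-1], bin_size=bin_size, per_cell=per_cell)


# ---------------------------------------------------------------------------
# qPCR concordance
# ---------------------------------------------------------------------------

def qpcr_concordance(
    ct_records: Iterable[CtRecord],
    logm: ExpressionMatrix,
    housekeeping: frozenset[str] | set[str] = frozenset({"GAPDH", "PPIA"}),
) -> tuple[float, float, float]:
    """Least-squares fit of log2(RPM+1) against qPCR delta-Ct.

    delta-Ct for gene g in sample s = mean(housekeeping Cts of s) - Ct(g, s),
    so higher expression gives a larger delta-Ct. Returns (slope, intercept,
    Pearson r) over all (gene, sample) pairs present in both inputs.
    """
    ct = pd.DataFrame(
        [(r.sample_id, r.gene_name, r.ct) for r in ct_records],
        columns=["sample_id", "gene_name", "ct"],
    )
    if ct.empty:
        raise Sc3kitError("no Ct records supplied")
    hk = ct[ct["gene_name"].isin(housekeeping)]
    hk_mean = hk.groupby("sample_id")["ct"].mean()

    xs, ys = [], []
    for _, row in ct.iterrows():
        sample, gene = row["sample_id"], row["gene_name"]
        if gene in housekeeping:
            continue
        if sample not in hk_mean.index:
            continue
        if gene in logm.values.index and sample in logm.values.columns:
            xs.append(hk_mean[sample] - row["ct"])
            ys.append(logm.values.at[gene, sample])
    if len(xs) < 3:
        raise Sc3kitError(
            f"only {len(xs)} shared (gene, sample) pairs; need at least 3"
        )
    fit = stats.linregress(xs, ys)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


# ---------------------------------------------------------------------------
# Expression percentile profiles
# ---------------------------------------------------------------------------

def expression_percentiles(logm: ExpressionMatrix) -> pd.DataFrame:
    """Per-cell p25/p50/p75 (linear interpolation) and whisker = median + 2 sd.

    Restrict ``logm`` to the expressed-gene subset before calling.
    """
    vals = logm.values.to_numpy(dtype=float)
    p25, p50, p75 = np.percentile(vals, [25, 50, 75], axis=0)
    whisker = p50 + 2.0 * vals.std(axis=0, ddof=1)
    return pd.DataFrame(
        {"p25": p25, "p50": p50, "p75": p75, "whisker": whisker},
        index=logm.values.columns,
    )


def flag_percentile_outliers(
    percentiles: pd.DataFrame, column: str = "p75", k: float = 5.0
) -> list[str]:
    """Cells whose percentile deviates > k median-absolute-deviations from the
    cohort median of that percentile; a uniformity screen."""
    x = percentiles[column].to_numpy(dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        mad = np.finfo(float).eps
    return list(percentiles.index[np.abs(x - med) > k * mad])
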