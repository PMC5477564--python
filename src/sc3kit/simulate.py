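"""Synthetic genomes, annotations, reads and expression matrices.

Everything downstream of alignment is testable offline: this module plants
known gene-adjacency scenarios for the annotation rewriter, 3'-biased reads
for the quantifier and QC profiles, and lineage-structured log-expression
matrices for the classifier — each paired with a :class:`SimulationTruth`
recording exactly what was planted. All generators are deterministic per
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneModel, GenomeLayout
from .errors import Sc3kitError
from .quant import AlignedRead

SCENARIOS = (
    "isolated",
    "shared_tts",
    "tandem_same_strand",
    "convergent",
    "body_intrusion",
    "pseudogene_neighbor",
)

# Canonical per-lineage marker states used by the expression generator.
# Genes not listed are off. Designed so that, under the default rule order,
# each lineage's noiseless profile matches exactly its own rule.
LINEAGE_PROFILES: dict[str, dict[str, str]] = {
    "ePGC": {"PRDM1": "on", "TFAP2C": "on", "SOX17": "on", "POU5F1": "on",
             "NANOG": "on", "SOX2": "off"},
    "lPGC": {"POU5F1": "on", "NANOG": "on", "TFAP2C": "on", "PRDM1": "on",
             "SOX2": "off", "SOX17": "off"},
    "Post-EPI": {"POU5F1": "on", "NANOG": "on", "SOX2": "on", "PRDM14": "on",
                 "T": "off", "GATA4": "off"},
    "Pre-EPI": {"POU5F1": "on", "NANOG": "on", "SOX2": "on",
                "GATA6": "off", "TFAP2C": "off", "PRDM14": "off"},
    "Hypoblast": {"SOX17": "on", "GATA4": "on", "GATA6": "on", "NANOG": "off"},
    "TE": {"TFAP2C": "on", "GATA3": "on", "GATA6": "on", "NANOG": "off"},
    "Gastrulating": {"POU5F1": "on", "NANOG": "low", "PRDM14": "low",
                     "T": "on", "GATA4": "off", "GATA6": "off"},
    "VE/YE": {"POU5F1": "low", "FOXA1": "on"},
    "EXMC": {"POU5F1": "low", "COL6A1": "on"},
}

MARKER_GENES = sorted({g for prof in LINEAGE_PROFILES.values() for g in prof})


@dataclass
class SimulationTruth:
    """What was planted: gene scenarios, read provenance, cell labels, states."""

    gene_scenarios: dict[str, str] = field(default_factory=dict)
    read_provenance: list[tuple[str, str]] = field(default_factory=list)  # (cell, source)
    cell_labels: dict[str, str] = field(default_factory=dict)
    gene_states: pd.DataFrame | None = None  # marker genes x cells, on/low/off

    def planted_counts(self) -> pd.DataFrame:
        """Per-(source, cell) read totals from the provenance records."""
        df = pd.DataFrame(self.read_provenance, columns=["cell_id", "source"])
        return df.groupby(["source", "cell_id"]).size().unstack(fill_value=0)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_scenarios": self.gene_scenarios,
            "read_provenance": self.read_provenance,
            "cell_labels": self.cell_labels,
            "gene_states": (
                None if self.gene_states is None
                else self.gene_states.to_dict(orient="index")
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        states = payload.get("gene_states")
        return cls(
            gene_scenarios=payload.get("gene_scenarios", {}),
            read_provenance=[tuple(p) for p in payload.get("read_provenance", [])],
            cell_labels=payload.get("cell_labels", {}),
            gene_states=None if states is None else pd.DataFrame.from_dict(
                states, orient="index"),
        )


# ---------------------------------------------------------------------------
# Annotation scenarios
# ---------------------------------------------------------------------------

_SLOT = 60_000       # one scenario per slot; 10 kb windows never cross slots
_CONTENT_OFFSET = 12_000


def _scenario_genes(scenario: str, gid: str, chrom: str, base: int,
                    rng: np.random.Generator) -> list[GeneModel]:
    glen = int(rng.integers(2_000, 5_000))
    if scenario == "isolated":
        return [GeneModel(gid, gid, chrom, "+", base, base + glen - 1)]
    if scenario == "shared_tts":
        tts = base + glen - 1
        return [
            GeneModel(f"{gid}_a", f"{gid}_a", chrom, "+", base, tts),
            GeneModel(f"{gid}_b", f"{gid}_b", chrom, "+",
                      base + int(rng.integers(500, glen - 500)), tts),
        ]
    if scenario == "tandem_same_strand":
        tts = base + glen - 1
        gap = int(rng.integers(2_000, 8_000))
        down = tts + gap
        return [
            GeneModel(f"{gid}_up", f"{gid}_up", chrom, "+", base, tts),
            GeneModel(f"{gid}_down", f"{gid}_down", chrom, "+", down, down + 2_999),
        ]
    if scenario == "convergent":
        tts = base + glen - 1
        sep = int(rng.integers(2_000, 9_000))
        other = tts + sep  # TTS of the minus-strand partner
        return [
            GeneModel(f"{gid}_plus", f"{gid}_plus", chrom, "+", base, tts),
            GeneModel(f"{gid}_minus", f"{gid}_minus", chrom, "-", other, other + 2_999),
        ]
    if scenario == "body_intrusion":
        # opposite-strand body spans the whole extension window; both of its
        # termini sit outside the window, so only the body-edge rule applies
        g = GeneModel(f"{gid}_g", f"{gid}_g", chrom, "+", base, base + 1_999)
        intruder = GeneModel(f"{gid}_body", f"{gid}_body", chrom, "-",
                             base + 1_500, base + 1_999 + 10_500)
        return [g, intruder]
    if scenario == "pseudogene_neighbor":
        tts = base + glen - 1
        ps = tts + 3_000
        return [
            GeneModel(f"{gid}_g", f"{gid}_g", chrom, "+", base, tts),
            GeneModel(f"{gid}_ps", f"{gid}_ps", chrom, "+", ps, ps + 1_999,
                      biotype="pseudogene"),
        ]
    raise Sc3kitError(f"unknown scenario {scenario!r}")


def make_annotation(
    layout: GenomeLayout,
    scenario_counts: Mapping[str, int],
    seed: int,
) -> tuple[AnnotationSet, SimulationTruth]:
    """Plant the requested adjacency scenarios on the layout's chromosomes.

    Scenarios are laid out in non-interfering 60 kb slots so that every
    gene's 10 kb extension window stays inside its own slot.
    """
    for name in scenario_counts:
        if name not in SCENARIOS:
            raise Sc3kitError(f"unknown scenario {name!r}")
    rng = np.random.default_rng(seed)
    jobs = [s for s in SCENARIOS for _ in range(scenario_counts.get(s, 0))]

    slots: list[tuple[str, int]] = []
    for chrom, length in layout.lengths.items():
        for i in range(length // _SLOT):
            slots.append((chrom, i * _SLOT + 1))
    if len(jobs) > len(slots):
        raise Sc3kitError(
            f"genome too small: {len(jobs)} scenario(s) need {len(jobs)} slots "
            f"of {_SLOT} bp, layout provides {len(slots)}"
        )

    genes: list[GeneModel] = []
    truth = SimulationTruth()
    for i, scenario in enumerate(jobs):
        chrom, slot_start = slots[i]
        base = slot_start + _CONTENT_OFFSET
        gid = f"{scenario}_{i:03d}"
        for g in _scenario_genes(scenario, gid, chrom, base, rng):
            genes.append(g)
            truth.gene_scenarios[g.gene_id] = scenario
    return AnnotationSet(layout, genes), truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _truncated_exponential(rng: np.random.Generator, scale: float, upper: float) -> float:
    u = rng.random()
    return -scale * np.log1p(-u * (1.0 - np.exp(-upper / scale)))


def simulate_reads(
    ann: AnnotationSet,
    cells: int | Sequence[str],
    reads_per_cell: int,
    *,
    tts_bias_bp: int = 300,
    bias_scale: float = 100.0,
    spike_frac: float = 0.0,
    seed: int = 0,
    read_length: int = 36,
    n_spike_species: int = 8,
    expression_weights: Mapping[str, float] | None = None,
) -> tuple[list[AlignedRead], SimulationTruth]:
    """Draw 3'-biased reads from the genes of ``ann`` plus spike-in reads.

    Read 5' ends fall within ``tts_bias_bp`` upstream of each source gene's
    TTS, at truncated-exponential distances (scale ``bias_scale``); read
    strand equals gene strand. A ``spike_frac`` fraction of reads is placed
    on ``ERCC-`` chromosomes instead. Every read gets a provenance record.
    """
    if reads_per_cell < 0:
        raise Sc3kitError("reads_per_cell must be >= 0")
    rng = np.random.default_rng(seed)
    cell_ids = ([f"cell{j:03d}" for j in range(cells)]
                if isinstance(cells, int) else list(cells))
    gene_list = list(ann.genes)
    if not gene_list and spike_frac < 1.0 and reads_per_cell > 0:
        raise Sc3kitError("annotation has no genes to draw reads from")
    weights = None
    if expression_weights is not None:
        w = np.array([expression_weights.get(g.gene_id, 0.0) for g in gene_list])
        if w.sum() <= 0:
            raise Sc3kitError("expression_weights sum to zero over annotation genes")
        weights = w / w.sum()

    spikes = [f"ERCC-{k:05d}" for k in range(1, n_spike_species + 1)]
    reads: list[AlignedRead] = []
    truth = SimulationTruth()
    for cell in cell_ids:
        for _ in range(reads_per_cell):
            if spike_frac > 0 and rng.random() < spike_frac:
                chrom = spikes[int(rng.integers(len(spikes)))]
                start = int(rng.integers(1, 500))
                reads.append(AlignedRead(chrom, "+", start, start + read_length - 1, cell))
                truth.read_provenance.append((cell, chrom))
                continue
            gi = (int(rng.integers(len(gene_list))) if weights is None
                  else int(rng.choice(len(gene_list), p=weights)))
            g = gene_list[gi]
            offset = int(_truncated_exponential(rng, bias_scale, tts_bias_bp))
            chrom_len = ann.layout.length_of(g.chrom)
            if g.strand == "+":
                pos5 = max(g.tts - offset, 1)
                start, end = pos5, min(pos5 + read_length - 1, chrom_len)
            else:
                pos5 = min(g.tts + offset, chrom_len)
                start, end = max(pos5 - read_length + 1, 1), pos5
            reads.append(AlignedRead(g.chrom, g.strand, start, end, cell))
            truth.read_provenance.append((cell, g.gene_id))
    return reads, truth


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(
    n_cells_per_type: int | Mapping[str, int],
    *,
    profiles: Mapping[str, Mapping[str, str]] | None = None,
    on_mean: float = 6.0,
    on_sd: float = 1.0,
    on_floor: float = 5.5,
    low_mean: float = 3.0,
    low_sd: float = 0.1,
    low_band: tuple[float, float] = (2.9, 3.1),
    off_level: float = 0.0,
    n_background: int = 200,
    background_signature_sd: float = 1.0,
    dropout_p: float = 0.1,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Lineage-structured log2(RPM+1)-scale matrix (genes x cells) plus truth.

    Marker-gene values are drawn per planted state — on: max(N(on_mean,
    on_sd), on_floor); low: N(low_mean, low_sd) clipped into ``low_band``;
    off: ``off_level`` — then global Gaussian noise is added and values are
    clipped at zero. Background genes carry a per-lineage signature (so
    correlation-based clustering can recover the types) and are the only
    genes subject to dropout: marker states are the planted truth that the
    classifier is asked to recover.
    """
    rng = np.random.default_rng(seed)
    profiles = profiles or LINEAGE_PROFILES
    lineages = list(profiles)
    if isinstance(n_cells_per_type, int):
        n_per = {lab: n_cells_per_type for lab in lineages}
    else:
        n_per = dict(n_cells_per_type)
        for lab in n_per:
            if lab not in profiles:
                raise Sc3kitError(f"unknown lineage {lab!r}")

    marker_genes = sorted({g for prof in profiles.values() for g in prof})
    bg_genes = [f"BG{k:04d}" for k in range(n_background)]
    genes = marker_genes + bg_genes

    # per-lineage background signature, fixed for the seed
    signature = {
        lab: np.clip(rng.normal(2.0, background_signature_sd, n_background), 0, None)
        for lab in lineages
    }

    labels: dict[str, str] = {}
    data = np.zeros((len(genes), sum(n_per.values())))
    states = pd.DataFrame("off", index=marker_genes,
                          columns=range(sum(n_per.values())), dtype=object)
    j = 0
    cell_names = []
    for lab in lineages:
        for _ in range(n_per.get(lab, 0)):
            cell = f"{lab.replace('/', '_')}_{j:04d}"
            cell_names.append(cell)
            labels[cell] = lab
            prof = profiles[lab]
            col = np.zeros(len(genes))
            for i, g in enumerate(marker_genes):
                state = prof.get(g, "off")
                states.iat[i, j] = state
                if state == "on":
                    col[i] = max(rng.normal(on_mean, on_sd), on_floor)
                elif state == "low":
                    col[i] = float(np.clip(rng.normal(low_mean, low_sd), *low_band))
                else:
                    col[i] = off_level
            bg = signature[lab] + rng.normal(0, 0.3, n_background)
            if dropout_p > 0:
                bg = np.where(rng.random(n_background) < dropout_p, 0.0, bg)
            col[len(marker_genes):] = np.clip(bg, 0, None)
            data[:, j] = col
            j += 1
    if noise_sd > 0:
        data = data + rng.normal(0, noise_sd, data.shape)
    data = np.clip(data, 0, None)

    matrix = pd.DataFrame(data, index=genes, columns=cell_names)
    states.columns = cell_names
    truth = SimulationTruth(cell_labels=labels, gene_states=states)
    return matrix, truth
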