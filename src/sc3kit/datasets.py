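"""Bundled reference tables shipped with the package.

Two small plain-text tables travel with the code so that bookkeeping checks
run without any download: per-sample read-mapping statistics for the 474
sequenced transcriptomes, and the embryo/cell-line inventory of picked cells,
constructed cDNAs, good-quality cDNAs and sequenced libraries.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .qc import ReadCategoryTally


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("sc3kit") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_mapping_stats() -> pd.DataFrame:
    """Per-sample read-category statistics (one row per sequenced cell)."""
    return _load("mapping_stats.tsv")


def load_sample_inventory() -> pd.DataFrame:
    """Per-embryo/cell-line inventory: cells picked, cDNAs constructed,
    good-quality cDNAs and sequenced libraries."""
    return _load("sample_inventory.tsv")


def mapping_stats_tallies() -> list[ReadCategoryTally]:
    """The mapping-statistics table as ReadCategoryTally records."""
    df = load_mapping_stats()
    return [
        ReadCategoryTally(
            sample_id=row["gsm_id"],
            total_reads=int(row["total_reads"]),
            sc3seq_mapped=int(row["sc3seq_mapped"]),
            mapped_others=int(row["mapped_others"]),
            control_rna=int(row["control_rna"]),
            low_quality_adaptor_polyA=int(row["low_quality_adaptor_polyA"]),
            unmapped=int(row["unmapped"]),
        )
        for _, row in df.iterrows()
    ]
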