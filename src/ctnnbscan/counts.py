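"""Variant x sample count tables and replicate QC for the sort-seq assay.

The central container is :class:`BinCountMatrix`: raw read counts per
library variant over the six GFP sort bins (P1..P6, in increasing
fluorescence), the unsorted ``pool`` control and the ``plasmid`` donor
library, together with the per-bin mean GFP fluorescence from the FACS
summary.  Every library variant keeps an explicit row, zero where unseen,
so downstream enrichment is deterministic.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .reads import Category, ReadClassification
from .reference import VariantID

__all__ = [
    "BIN_SAMPLES",
    "BinCountMatrix",
    "count_reads",
    "normalize_sample",
    "replicate_concordance",
    "merge_replicates",
]

BIN_SAMPLES = ("P1", "P2", "P3", "P4", "P5", "P6")
CONTROL_SAMPLES = ("plasmid", "pool")


@dataclass
class BinCountMatrix:
    """Raw counts (variants x samples) plus per-bin mean GFP.

    ``counts`` rows are indexed by variant label (e.g. ``S45F``); columns
    are a subset of ``P1..P6, plasmid, pool``.  ``bin_mean_gfp`` maps each
    present bin to the arithmetic mean fluorescence of its sorted cells
    (arbitrary units) and must increase strictly from P1 to P6.
    """

    counts: pd.DataFrame
    bin_mean_gfp: dict[str, float] = field(default_factory=dict)
    sorted_cells: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        gfp = [self.bin_mean_gfp[b] for b in BIN_SAMPLES if b in self.bin_mean_gfp]
        if any(g <= 0 for g in gfp):
            raise ValueError("bin mean GFP values must be positive")
        if any(b - a <= 0 for a, b in zip(gfp, gfp[1:])):
            raise ValueError("bin mean GFP must increase strictly from P1 to P6")

    @property
    def bins(self) -> list[str]:
        return [b for b in BIN_SAMPLES if b in self.counts.columns]

    # -- IO -----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the wide counts TSV plus a ``<path>.json`` sidecar."""
        path = Path(path)
        self.counts.rename_axis("variant").to_csv(path, sep="\t")
        sidecar = {"bin_mean_gfp": self.bin_mean_gfp, "sorted_cells": self.sorted_cells}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path, sidecar_path: str | Path | None = None) -> "BinCountMatrix":
        path = Path(path)
        counts = pd.read_csv(path, sep="\t", index_col="variant")
        sidecar = Path(sidecar_path) if sidecar_path else Path(str(path) + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            counts,
            bin_mean_gfp={k: float(v) for k, v in meta.get("bin_mean_gfp", {}).items()},
            sorted_cells={k: int(v) for k, v in meta.get("sorted_cells", {}).items()},
        )


def count_reads(
    classifications: Iterable[ReadClassification],
    library: Iterable[VariantID],
) -> tuple[pd.Series, dict[str, int]]:
    """Tally one sample's classifications into a count column.

    Returns the per-variant VALID read counts (every library variant has an
    entry, zero where unseen) and the tally of every exclusion category for
    the QC log.  VALID reads plus excluded reads always add up to the total
    number of classifications (conservation).
    """
    labels = [v.label for v in library]
    counts = pd.Series(0, index=pd.Index(labels, name="variant"), dtype=int)
    tally: Counter[str] = Counter()
    for c in classifications:
        if c.category is Category.VALID:
            counts[c.variant.label] += 1
        else:
            tally[c.category.value] += 1
    return counts, dict(tally)


def normalize_sample(counts: pd.Series) -> pd.Series:
    """Counts -> within-sample frequencies summing to one.

    Each variant's reads are divided by the total number of filtered reads
    in the sample, so the normalized counts over all library variants sum
    to 1.
    """
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot normalize an empty sample (zero total reads)")
    return counts / total


def replicate_concordance(
    a: BinCountMatrix, b: BinCountMatrix
) -> pd.Series:
    """Per-sample Pearson r between two replicates' normalized frequencies.

    Samples present in both matrices are compared on their shared variant
    index.  A sample whose frequency vector is constant in either replicate
    (for example all-zero) has an undefined correlation and is reported as
    NaN.
    """
    shared = [c for c in a.counts.columns if c in b.counts.columns]
    idx = a.counts.index.intersection(b.counts.index)
    out = {}
    for s in shared:
        x, y = a.counts.loc[idx, s], b.counts.loc[idx, s]
        if x.sum() == 0 or y.sum() == 0:
            out[s] = np.nan
            continue
        fx, fy = normalize_sample(x), normalize_sample(y)
        if fx.std() == 0 or fy.std() == 0:
            out[s] = np.nan
            continue
        out[s] = float(np.corrcoef(fx, fy)[0, 1])
    return pd.Series(out, name="pearson_r")


def merge_replicates(replicates: list[BinCountMatrix]) -> BinCountMatrix:
    """Merge biological replicates by summing raw counts per sample.

    Raw counts are summed before normalization; the bin mean GFP values of
    the first replicate carrying them are retained (FACS gates are shared
    across replicates by design).
    """
    if not replicates:
        raise ValueError("no replicates to merge")
    counts = replicates[0].counts.copy()
    for rep in replicates[1:]:
        counts = counts.add(rep.counts, fill_value=0).astype(int)
    gfp: dict[str, float] = {}
    cells: dict[str, int] = {}
    for rep in replicates:
        for k, v in rep.bin_mean_gfp.items():
            gfp.setdefault(k, v)
        for k, v in rep.sorted_cells.items():
            cells[k] = cells.get(k, 0) + v
    return BinCountMatrix(counts, bin_mean_gfp=gfp, sorted_cells=cells)
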