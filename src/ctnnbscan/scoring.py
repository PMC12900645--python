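"""Mutational effect scores (MES) from binned sort-seq counts.

For variant v and sort bin b, let f_vb be the variant's normalized read
frequency in the bin and f_v,pool its frequency in the unsorted pool grown
through the same editing and selection.  The enrichment is

    e_vb = f_vb / f_v,pool

and the mutational effect score weights each bin's enrichment by that bin's
mean reporter fluorescence g_b and sums over the six bins:

    MES_v = sum_b e_vb * g_b .

MES is therefore expressed in the reporter's (arbitrary) fluorescence
units, on whatever scale the supplied g_b values are on; it is invariant to
per-sample sequencing depth because only frequencies enter.  The published
weak/strong threshold (18,000) refers to that same scale.

Variants unobserved in the pool have undefined enrichment and are excluded
from scoring (reported, not pseudocounted, by default; a +0.5 pseudocount
mode exists for sensitivity analysis).  Variants underrepresented in the
donor plasmid pool (frequency < 0.028%, i.e. a tenth of the 0.28% expected
under a uniform 342-member library) are flagged low-confidence; the flag
never alters any score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import BIN_SAMPLES, BinCountMatrix, normalize_sample

__all__ = [
    "LOW_CONFIDENCE_CUTOFF",
    "STRENGTH_THRESHOLD",
    "enrichment",
    "mes",
    "flag_low_confidence",
    "classify_strength",
    "score",
]

LOW_CONFIDENCE_CUTOFF = 0.00028  # plasmid frequency below this => low confidence
STRENGTH_THRESHOLD = 18000.0     # MES strictly above this => strong


def enrichment(
    matrix: BinCountMatrix, pseudocount: float = 0.0
) -> tuple[pd.DataFrame, list[str]]:
    """Per-variant, per-bin enrichment relative to the unsorted pool.

    Returns the enrichment frame (rows: variants scorable in the pool;
    columns: the six bins) and the list of variants excluded because their
    pool frequency is zero.  With ``pseudocount > 0`` the value is added to
    every raw count before normalization and nothing is excluded.
    """
    if "pool" not in matrix.counts.columns:
        raise ValueError("matrix lacks the unsorted 'pool' control sample")
    bins = matrix.bins
    if len(bins) != 6:
        raise ValueError(f"expected 6 sort bins, found {bins}")

    counts = matrix.counts
    if pseudocount:
        counts = counts + pseudocount
    f_pool = normalize_sample(counts["pool"])
    excluded = list(f_pool.index[f_pool == 0])
    keep = f_pool.index[f_pool > 0]

    e = pd.DataFrame(index=keep, columns=bins, dtype=float)
    for b in bins:
        f_b = normalize_sample(counts[b])
        e[b] = f_b.loc[keep] / f_pool.loc[keep]
    return e, excluded


def mes(enrich: pd.DataFrame | pd.Series, bin_mean_gfp: dict[str, float]) -> pd.Series | float:
    """Fluorescence-weighted sum of bin enrichments.

    Accepts a single enrichment row (Series over the six bins) or a frame
    of rows; linear in both the enrichments and the bin means.
    """
    g = pd.Series({b: float(bin_mean_gfp[b]) for b in BIN_SAMPLES if b in bin_mean_gfp})
    if len(g) != 6:
        raise ValueError("need mean GFP for all six bins")
    if isinstance(enrich, pd.Series):
        values = enrich.reindex(g.index)
        if values.isna().any():
            raise ValueError("enrichment row missing bins")
        if (values < 0).any():
            raise ValueError("enrichment values must be non-negative")
        return float((values * g).sum())
    e = enrich.reindex(columns=g.index)
    if e.isna().any().any():
        raise ValueError("enrichment frame missing bins")
    if (e.to_numpy() < 0).any():
        raise ValueError("enrichment values must be non-negative")
    return (e * g).sum(axis=1).rename("mes")


def flag_low_confidence(
    plasmid_freq: pd.Series | float, cutoff: float = LOW_CONFIDENCE_CUTOFF
):
    """Flag variants underrepresented in the donor plasmid pool."""
    return plasmid_freq < cutoff


def classify_strength(
    mes_values: pd.Series | float, threshold: float = STRENGTH_THRESHOLD
):
    """'strong' iff MES strictly exceeds the threshold, else 'weak'.

    The boundary value itself classifies as weak (the published rule is a
    strict inequality).
    """
    if isinstance(mes_values, pd.Series):
        return pd.Series(
            np.where(mes_values > threshold, "strong", "weak"),
            index=mes_values.index,
            name="strength_call",
        )
    return "strong" if mes_values > threshold else "weak"


def score(
    matrix: BinCountMatrix,
    threshold: float = STRENGTH_THRESHOLD,
    low_confidence_cutoff: float = LOW_CONFIDENCE_CUTOFF,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Full MES table for one merged count matrix.

    Columns: e_P1..e_P6, mes, plasmid_freq, low_confidence, strength_call.
    Variants excluded for zero pool frequency keep their row with NaN
    enrichments/MES and no strength call.
    """
    e, excluded = enrichment(matrix, pseudocount=pseudocount)
    mes_values = mes(e, matrix.bin_mean_gfp)

    out = pd.DataFrame(index=matrix.counts.index)
    for b in matrix.bins:
        out[f"e_{b}"] = e[b]
    out["mes"] = mes_values
    if "plasmid" in matrix.counts.columns:
        out["plasmid_freq"] = normalize_sample(matrix.counts["plasmid"])
        out["low_confidence"] = flag_low_confidence(
            out["plasmid_freq"], low_confidence_cutoff
        )
    out["strength_call"] = pd.NA
    scored = out.index.difference(pd.Index(excluded))
    out.loc[scored, "strength_call"] = classify_strength(
        out.loc[scored, "mes"], threshold
    )
    out.attrs["excluded_zero_pool"] = excluded
    return out
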