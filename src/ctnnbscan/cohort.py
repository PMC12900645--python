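"""Stratification of tumor cohorts by beta-catenin pathway mutation status.

Samples are assigned to exactly one of six groups based on their CTNNB1 /
AXIN1 mutation records and the mutational effect score (MES) of any exon 3
hotspot missense mutation:

1. ``strong``   — one hotspot missense mutation with MES > threshold, or
                  MES < threshold plus a copy-number gain over the mutant
                  allele (the gain reassigns weak to strong, never the
                  reverse);
2. ``weak``     — one hotspot missense mutation with MES < threshold and
                  no copy-number gain;
3. ``other``    — a CTNNB1 missense mutation outside the hotspot;
4. ``AXIN1``    — any coding mutation in AXIN1;
5. ``no_mutation`` — no coding mutation in either gene;
6. ``exclude``  — deletions or complex CTNNB1 events, membership in more
                  than one of groups 1-4, more than one hotspot missense
                  mutation, unparseable protein changes, or missing
                  required data.

Mutation catalogs are plain DataFrames with COSMIC-like columns:
``sample``, ``tissue``, ``gene``, ``protein_change``, ``mutation_class``
and optionally ``cnv_gain`` (boolean).  Protein changes accept the
``p.S45F`` and ``S45F`` dialects.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .degron import fisher_two_by_two
from .reference import AMINO_ACIDS
from .scoring import STRENGTH_THRESHOLD

__all__ = [
    "GROUPS",
    "parse_protein_change",
    "classify_sample",
    "classify_cohort",
    "tissue_summary",
    "mes_distribution_compare",
    "mls_adjusted_compare",
    "target_gene_percent",
    "geneset_score",
    "immune_score_test",
    "DOCKING_RESIDUES",
]

GROUPS = ("strong", "weak", "other", "AXIN1", "no_mutation", "exclude")

#: Direct beta-TRCP contact region (distinct from T41 / S45 phosphosites).
DOCKING_RESIDUES = range(32, 38)

_HOTSPOT = range(31, 49)

_PC_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")


def parse_protein_change(text: str) -> tuple[str, int, str] | None:
    """Parse a simple missense protein change; None for anything else.

    In-frame deletions, frameshifts, nonsense and multi-residue events do
    not parse and are treated as complex by the caller.
    """
    if not isinstance(text, str):
        return None
    m = _PC_RE.match(text.strip())
    if not m:
        return None
    ref_aa, residue, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    if ref_aa not in AMINO_ACIDS or alt_aa not in AMINO_ACIDS or ref_aa == alt_aa:
        return None
    return ref_aa, residue, alt_aa


@dataclass(frozen=True)
class SampleClassification:
    sample: str
    group: str
    reason: str = ""


def classify_sample(
    mutations: pd.DataFrame,
    mes_lookup: dict[str, float],
    threshold: float = STRENGTH_THRESHOLD,
    has_required_data: bool = True,
    sample: str = "",
) -> SampleClassification:
    """Assign one sample's mutation records to a single pathway group.

    ``mutations`` holds the sample's rows (possibly empty).  ``mes_lookup``
    maps hotspot variant labels (e.g. ``S45F``) to MES values.
    """
    if not has_required_data:
        return SampleClassification(sample, "exclude", "missing required data")

    ctnnb1 = mutations[mutations["gene"] == "CTNNB1"] if len(mutations) else mutations
    axin1 = mutations[mutations["gene"] == "AXIN1"] if len(mutations) else mutations

    hotspot: list[tuple[str, bool]] = []  # (label, cnv_gain)
    other_missense = 0
    for row in ctnnb1.itertuples():
        mclass = str(getattr(row, "mutation_class", "missense")).lower()
        if any(k in mclass for k in ("del", "complex", "frameshift", "nonsense")):
            return SampleClassification(sample, "exclude", f"CTNNB1 {mclass} event")
        parsed = parse_protein_change(row.protein_change)
        if parsed is None:
            return SampleClassification(
                sample, "exclude", f"unparseable protein change {row.protein_change!r}"
            )
        ref_aa, residue, alt_aa = parsed
        label = f"{ref_aa}{residue}{alt_aa}"
        if residue in _HOTSPOT and label in mes_lookup:
            gain_val = getattr(row, "cnv_gain", False)
            gain = (not pd.isna(gain_val)) and bool(gain_val)
            hotspot.append((label, gain))
        else:
            other_missense += 1

    memberships = []
    if hotspot:
        memberships.append("hotspot")
    if other_missense:
        memberships.append("other")
    if len(axin1):
        memberships.append("AXIN1")

    if len(memberships) > 1:
        return SampleClassification(
            sample, "exclude", "multiple pathway groups: " + "+".join(memberships)
        )
    if not memberships:
        return SampleClassification(sample, "no_mutation")
    if memberships == ["other"]:
        return SampleClassification(sample, "other")
    if memberships == ["AXIN1"]:
        return SampleClassification(sample, "AXIN1")

    if len(hotspot) > 1:
        return SampleClassification(sample, "exclude", "multiple hotspot mutations")
    label, gain = hotspot[0]
    mes_value = mes_lookup[label]
    if mes_value > threshold:
        return SampleClassification(sample, "strong", label)
    if gain:
        # copy-number gain over a low-MES mutant allele reassigns to strong
        return SampleClassification(sample, "strong", f"{label} + CNV gain")
    return SampleClassification(sample, "weak", label)


def classify_cohort(
    catalog: pd.DataFrame,
    mes_lookup: dict[str, float],
    threshold: float = STRENGTH_THRESHOLD,
    samples_missing_data: set[str] | None = None,
    all_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Classify every sample in a mutation catalog.

    ``all_samples`` may list samples without any mutation record (they
    classify as ``no_mutation``); ``samples_missing_data`` are excluded for
    lacking required data.  Returns a frame indexed by sample with
    ``group`` and ``reason`` columns; groups partition the cohort.
    """
    missing = samples_missing_data or set()
    samples = list(dict.fromkeys(catalog["sample"])) if len(catalog) else []
    if all_samples is not None:
        samples = list(dict.fromkeys(list(all_samples) + samples))
    grouped = catalog.groupby("sample") if len(catalog) else None
    rows = []
    for s in samples:
        muts = grouped.get_group(s) if grouped is not None and s in grouped.groups else catalog.iloc[0:0]
        c = classify_sample(
            muts, mes_lookup, threshold, has_required_data=s not in missing, sample=s
        )
        rows.append({"sample": s, "group": c.group, "reason": c.reason})
    return pd.DataFrame(rows).set_index("sample")


def tissue_summary(
    catalog: pd.DataFrame,
    mes_lookup: dict[str, float],
    threshold: float = STRENGTH_THRESHOLD,
    min_mutations: int = 100,
) -> pd.DataFrame:
    """Per-tissue MES distribution summaries ordered by weak:strong ratio.

    Considers hotspot missense records whose protein change has an MES.
    Tissues with fewer scored mutations than ``min_mutations`` are dropped.
    The weak:strong ratio is infinite for tissues without strong mutations;
    the output is sorted by decreasing ratio (most weak-shifted first).
    """
    records = []
    for row in catalog.itertuples():
        parsed = parse_protein_change(row.protein_change)
        if parsed is None:
            continue
        label = f"{parsed[0]}{parsed[1]}{parsed[2]}"
        if label in mes_lookup:
            records.append({"tissue": row.tissue, "mes": mes_lookup[label]})
    if not records:
        return pd.DataFrame(
            columns=["n", "median_mes", "n_weak", "n_strong", "weak_strong_ratio"]
        )
    df = pd.DataFrame(records)
    rows = []
    for tissue, sub in df.groupby("tissue"):
        if len(sub) < min_mutations:
            continue
        n_strong = int((sub["mes"] > threshold).sum())
        n_weak = len(sub) - n_strong
        ratio = n_weak / n_strong if n_strong else np.inf
        rows.append(
            {
                "tissue": tissue,
                "n": len(sub),
                "median_mes": float(sub["mes"].median()),
                "n_weak": n_weak,
                "n_strong": n_strong,
                "weak_strong_ratio": ratio,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["n", "median_mes", "n_weak", "n_strong", "weak_strong_ratio"]
        )
    out = pd.DataFrame(rows).set_index("tissue")
    return out.sort_values("weak_strong_ratio", ascending=False)


def mes_distribution_compare(mes_a, mes_b) -> float:
    """Two-sided Mann-Whitney p-value between two groups of MES values."""
    a, b = np.asarray(mes_a, dtype=float), np.asarray(mes_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need at least one value")
    return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)


def mls_adjusted_compare(
    catalog_a: pd.DataFrame,
    catalog_b: pd.DataFrame,
    mls_lookup: dict[str, float],
    mes_lookup: dict[str, float],
    n_resamples: int = 2000,
    seed: int = 0,
) -> dict:
    """Between-cohort MES difference adjusted for mutational likelihood.

    This is a resampling construction of this package (the comparison it
    emulates does not publish its adjustment method): the observed
    difference in mean MES between the cohorts' mutations is referred to a
    null in which each cohort's mutations are redrawn, with replacement,
    with probability proportional to that cohort's own MLS values over the
    scorable hotspot variants.  The p-value is two-sided with the +1
    finite-sample correction and is bit-reproducible given the seed.
    """
    if n_resamples < 100:
        warnings.warn("fewer than 100 resamples gives a coarse p-value")

    def _mes_of(catalog: pd.DataFrame) -> np.ndarray:
        vals = []
        for pc in catalog["protein_change"]:
            parsed = parse_protein_change(pc)
            if parsed is None:
                continue
            label = f"{parsed[0]}{parsed[1]}{parsed[2]}"
            if label in mes_lookup:
                vals.append(mes_lookup[label])
        return np.asarray(vals, dtype=float)

    obs_a, obs_b = _mes_of(catalog_a), _mes_of(catalog_b)
    if len(obs_a) == 0 or len(obs_b) == 0:
        raise ValueError("both catalogs need scorable hotspot mutations")
    observed = obs_a.mean() - obs_b.mean()

    labels = sorted(set(mls_lookup) & set(mes_lookup))
    weights = np.array([mls_lookup[l] for l in labels], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("MLS weights are all zero")
    weights = weights / weights.sum()
    mes_vec = np.array([mes_lookup[l] for l in labels], dtype=float)

    rng = np.random.default_rng(seed)
    null = np.empty(n_resamples)
    for i in range(n_resamples):
        a = mes_vec[rng.choice(len(labels), size=len(obs_a), p=weights)]
        b = mes_vec[rng.choice(len(labels), size=len(obs_b), p=weights)]
        null[i] = a.mean() - b.mean()
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_resamples + 1.0)
    return {"observed_diff": float(observed), "p_value": float(p), "null": null}


def target_gene_percent(
    expression: pd.DataFrame,
    classifications: pd.DataFrame | pd.Series,
    target_genes: list[str],
    baseline_group: str = "strong",
) -> dict:
    """Per-group target-gene expression as a percentage of the strong group.

    ``expression`` has genes as rows and samples as columns.  For each
    target gene the median expression is taken across the samples of each
    group, then expressed as a percentage of the same gene's median in the
    baseline (strong) group; the summary statistic is the median of those
    percentages across genes.  Genes with a zero baseline median are
    dropped with a warning.
    """
    groups = classifications["group"] if isinstance(classifications, pd.DataFrame) else classifications
    missing = [g for g in target_genes if g not in expression.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")

    medians = {}
    for group in groups.unique():
        cols = groups.index[groups == group].intersection(expression.columns)
        if len(cols) == 0:
            continue
        medians[group] = expression.loc[target_genes, cols].median(axis=1)
    if baseline_group not in medians:
        raise ValueError(f"no samples in baseline group {baseline_group!r}")
    base = medians[baseline_group]
    usable = base.index[base > 0]
    if len(usable) < len(base):
        warnings.warn(
            f"dropping genes with zero {baseline_group} median: "
            f"{sorted(set(base.index) - set(usable))}"
        )
    percent = pd.DataFrame(
        {g: 100.0 * m.loc[usable] / base.loc[usable] for g, m in medians.items()}
    )
    return {
        "per_gene_percent": percent,
        "median_percent": percent.median(axis=0),
    }


def geneset_score(expression: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """Mean per-gene z-score over a gene set, per sample.

    A documented stand-in for single-sample enrichment scoring: each set
    gene is z-scored across samples and the per-sample score is the mean z
    over the set.  Monotone in each member gene; 0 for a sample sitting at
    the cohort mean of every set gene.
    """
    if not gene_set:
        raise ValueError("empty gene set")
    missing = [g for g in gene_set if g not in expression.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing}")
    sub = expression.loc[gene_set].astype(float)
    sd = sub.std(axis=1, ddof=0)
    sd = sd.replace(0, np.nan)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0).rename("geneset_score")


def immune_score_test(
    scores: pd.Series,
    classifications: pd.DataFrame | pd.Series,
    group_a: str = "weak",
    group_b: str = "strong",
) -> dict:
    """Fisher test on immune scores dichotomized at zero vs one-or-greater.

    ``scores`` are per-sample ordinal infiltration scores in {0,1,2,3}.
    Samples with missing scores are dropped (the count is reported).
    """
    groups = classifications["group"] if isinstance(classifications, pd.DataFrame) else classifications
    merged = pd.DataFrame({"score": scores}).join(groups.rename("group"), how="inner")
    n_missing = int(merged["score"].isna().sum())
    merged = merged.dropna(subset=["score"])
    bad = set(merged["score"].unique()) - {0, 1, 2, 3}
    if bad:
        raise ValueError(f"scores outside 0-3: {sorted(bad)}")
    sub_a = merged[merged["group"] == group_a]
    sub_b = merged[merged["group"] == group_b]
    if len(sub_a) == 0 or len(sub_b) == 0:
        raise ValueError("both groups need scored samples")
    k_a = int((sub_a["score"] >= 1).sum())
    k_b = int((sub_b["score"] >= 1).sum())
    table, p = fisher_two_by_two(k_a, len(sub_a), k_b, len(sub_b))
    return {
        "table": table,
        "p_value": p,
        "n_missing": n_missing,
        "frac_nonzero_a": k_a / len(sub_a),
        "frac_nonzero_b": k_b / len(sub_b),
    }
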