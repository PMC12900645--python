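"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the assay and the
downstream cohort analyses, not the wet lab: per-variant reporter
fluorescence is lognormal around a true activity and cells are sorted into
six equally log-spaced gates with multinomial read sampling; tumor
catalogs draw mutations with probability proportional to mutational
likelihood times a tissue-specific selection weight over the true effect
score; exome SNV lists are multinomial draws from a 96-category spectrum;
expression matrices are negative binomial with group fold-changes on
target genes.  Every generator is deterministic given its seed and returns
the ground truth it sampled from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .counts import BIN_SAMPLES, BinCountMatrix
from .mls import CATEGORIES, TrinucSpectrum, _revcomp
from .reference import AmpliconReference, VariantID, default_library, default_reference

__all__ = [
    "SortSeqConfig",
    "SortSeqResult",
    "simulate_sortseq",
    "simulate_reads",
    "write_fastq",
    "CohortConfig",
    "simulate_tumor_catalog",
    "simulate_classified_cohort",
    "simulate_exome_snvs",
    "simulate_expression",
    "gaussian_selection",
    "flat_selection",
]


# ---------------------------------------------------------------------------
# Sort-seq
# ---------------------------------------------------------------------------

@dataclass
class SortSeqConfig:
    """Study conditions for the synthetic sort-seq experiment.

    Defaults mirror the assayed design: 342 library variants, biological
    noise sigma = 0.3 (natural-log scale) around each variant's true
    activity, six equally log-spaced gates spanning 100-31,623 arbitrary
    fluorescence units, 2,000 cells per variant and 2e6 reads per bin.
    ``plasmid_dropout_fraction`` of variants are underrepresented in the
    donor plasmid at ``dropout_weight`` of the uniform weight, emulating
    the minority of templates lost during library preparation.
    """

    sigma: float = 0.3
    gate_range: tuple[float, float] = (100.0, 31623.0)
    n_bins: int = 6
    cells_per_variant: int = 2000
    reads_per_bin: int = 2_000_000
    reads_control: int = 2_000_000
    plasmid_dropout_fraction: float = 0.09
    dropout_weight: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_bin <= 0 or self.reads_control <= 0:
            raise ValueError("read depth must be positive")
        if self.gate_range[0] <= 0 or self.gate_range[1] <= self.gate_range[0]:
            raise ValueError("gates must span a positive fluorescence range")

    def gate_edges(self) -> np.ndarray:
        lo, hi = self.gate_range
        return np.logspace(np.log10(lo), np.log10(hi), self.n_bins + 1)


@dataclass
class SortSeqResult:
    matrix: BinCountMatrix
    true_activity: pd.Series
    cell_composition: pd.DataFrame  # variants x bins, gated cell counts
    plasmid_weights: pd.Series


def default_activities(
    library: Sequence[VariantID], seed: int, gate_range: tuple[float, float] = (100.0, 31623.0)
) -> pd.Series:
    """Log-uniform true activities spanning the interior of the gate range."""
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(gate_range[0]) + 0.1, np.log10(gate_range[1]) - 0.1
    values = 10 ** rng.uniform(lo, hi, size=len(library))
    return pd.Series(values, index=[v.label for v in library], name="true_activity")


def simulate_sortseq(
    config: SortSeqConfig | None = None,
    activities: pd.Series | None = None,
    library: Sequence[VariantID] | None = None,
) -> SortSeqResult:
    """Generate one sort-seq experiment with known per-variant activities.

    Per variant, cell fluorescences are lognormal around the true activity;
    cells falling outside the gate range stay unsorted.  Reads per bin are
    multinomial over that bin's cell composition; the pool sample draws
    from the total (gated + ungated) cell composition, and the plasmid
    sample from the library representation itself.  Bin mean GFP is the
    arithmetic mean fluorescence of the bin's gated cells.
    """
    config = config or SortSeqConfig()
    library = list(library) if library is not None else default_library()
    labels = [v.label for v in library]
    if activities is None:
        activities = default_activities(library, config.seed, config.gate_range)
    activities = activities.reindex(labels)
    if activities.isna().any() or (activities <= 0).any():
        raise ValueError("every library variant needs a positive true activity")

    rng = np.random.default_rng(config.seed)
    n = len(labels)

    # donor plasmid representation with dropout
    weights = np.ones(n)
    n_drop = int(round(config.plasmid_dropout_fraction * n))
    drop_idx = rng.choice(n, size=n_drop, replace=False)
    weights[drop_idx] = config.dropout_weight
    weights = weights / weights.sum()

    # cells per variant follow the plasmid representation
    total_cells = config.cells_per_variant * n
    cells = rng.multinomial(total_cells, weights)

    edges = config.gate_edges()
    comp = np.zeros((n, config.n_bins), dtype=int)
    fluor_sum = np.zeros(config.n_bins)
    fluor_n = np.zeros(config.n_bins, dtype=int)
    for i in range(n):
        if cells[i] == 0:
            continue
        f = np.exp(rng.normal(np.log(activities.iloc[i]), config.sigma, size=cells[i]))
        which = np.searchsorted(edges, f, side="right") - 1
        gated = (which >= 0) & (which < config.n_bins)
        binned = which[gated]
        comp[i] = np.bincount(binned, minlength=config.n_bins)
        fluor_sum += np.bincount(binned, weights=f[gated], minlength=config.n_bins)
        fluor_n += comp[i]

    if (fluor_n == 0).any():
        raise ValueError("a gate received no cells; widen the activity range")
    bin_mean_gfp = {BIN_SAMPLES[b]: float(fluor_sum[b] / fluor_n[b]) for b in range(config.n_bins)}

    counts = pd.DataFrame(0, index=pd.Index(labels, name="variant"), columns=list(BIN_SAMPLES) + ["plasmid", "pool"])
    for b in range(config.n_bins):
        p = comp[:, b] / comp[:, b].sum()
        counts[BIN_SAMPLES[b]] = rng.multinomial(config.reads_per_bin, p)
    counts["plasmid"] = rng.multinomial(config.reads_control, weights)
    counts["pool"] = rng.multinomial(config.reads_control, cells / cells.sum())

    matrix = BinCountMatrix(
        counts,
        bin_mean_gfp=bin_mean_gfp,
        sorted_cells={BIN_SAMPLES[b]: int(fluor_n[b]) for b in range(config.n_bins)},
    )
    return SortSeqResult(
        matrix=matrix,
        true_activity=activities,
        cell_composition=pd.DataFrame(comp, index=labels, columns=list(BIN_SAMPLES)[: config.n_bins]),
        plasmid_weights=pd.Series(weights, index=labels, name="plasmid_weight"),
    )


# ---------------------------------------------------------------------------
# Read-level simulation (exercises the read classifier)
# ---------------------------------------------------------------------------

def simulate_reads(
    variant_counts: pd.Series,
    reference: AmpliconReference | None = None,
    library: Sequence[VariantID] | None = None,
    n_wildtype: int = 0,
    n_indel: int = 0,
    error_rate: float = 0.0,
    flip_strand: bool = True,
    seed: int = 0,
) -> tuple[list[str], dict[str, int]]:
    """Emit amplicon reads with known composition.

    ``variant_counts`` maps library variant labels to read counts; each
    read is the reference with the variant's template codon substituted.
    ``n_wildtype`` reference reads and ``n_indel`` reads carrying a 1-nt
    deletion are added, uniform substitution errors are applied at
    ``error_rate`` per base, and about half the reads are emitted on the
    reverse strand when ``flip_strand``.  Returns the reads (shuffled) and
    the generator's intended per-category composition (exact when
    ``error_rate`` is zero).
    """
    reference = reference or default_reference()
    library = list(library) if library is not None else default_library()
    by_label = {v.label: v for v in library}
    rng = np.random.default_rng(seed)
    ref_seq = reference.sequence

    reads: list[str] = []
    truth = {"VALID": 0, "NO_TARGET_MUTATION": 0, "HAS_INDEL": 0}
    for label, count in variant_counts.items():
        v = by_label[label]
        i = (reference.target_start - 1) + 3 * (v.residue - reference.first_codon_number)
        mutated = ref_seq[:i] + v.template_codon + ref_seq[i + 3 :]
        reads.extend([mutated] * int(count))
        truth["VALID"] += int(count)
    reads.extend([ref_seq] * n_wildtype)
    truth["NO_TARGET_MUTATION"] += n_wildtype
    for _ in range(n_indel):
        pos = int(rng.integers(1, len(ref_seq) - 1))
        reads.append(ref_seq[:pos] + ref_seq[pos + 1 :])
    truth["HAS_INDEL"] += n_indel

    out = []
    for read in reads:
        if error_rate > 0:
            bases = list(read)
            for j in range(len(bases)):
                if rng.random() < error_rate:
                    bases[j] = rng.choice([b for b in "ACGT" if b != bases[j]])
            read = "".join(bases)
        if flip_strand and rng.random() < 0.5:
            read = _revcomp(read)
        out.append(read)
    rng.shuffle(out)
    return out, {k: v for k, v in truth.items() if v}


def write_fastq(reads: list[str], path: str | Path) -> None:
    """Write reads as minimal FASTQ (uniform high quality)."""
    with open(path, "w") as fh:
        for i, read in enumerate(reads):
            fh.write(f"@read{i}\n{read}\n+\n{'I' * len(read)}\n")


# ---------------------------------------------------------------------------
# Tumor catalogs under MLS x selection
# ---------------------------------------------------------------------------

def gaussian_selection(optimum: float, width: float) -> Callable[[np.ndarray], np.ndarray]:
    """Selection weight peaked at an optimal effect score."""
    def weight(mes: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * ((mes - optimum) / width) ** 2)
    return weight


def flat_selection() -> Callable[[np.ndarray], np.ndarray]:
    """No selection: observed frequencies follow mutational likelihood alone."""
    return lambda mes: np.ones_like(np.asarray(mes, dtype=float))


@dataclass
class CohortConfig:
    """Tissues, sample counts and per-tissue selection over the effect score."""

    tissues: dict[str, tuple[Callable[[np.ndarray], np.ndarray], int]] = field(default_factory=dict)
    seed: int = 0


def simulate_tumor_catalog(
    config: CohortConfig,
    mes_table: pd.Series,
    mls_table: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw tumor mutation catalogs with probability ~ MLS x selection(MES).

    Returns the catalog (sample, tissue, gene, protein_change,
    mutation_class) and a truth frame with each tissue's sampling
    probabilities over the variant labels.
    """
    labels = mes_table.index.intersection(mls_table.index)
    mes = mes_table.loc[labels].to_numpy(dtype=float)
    mls = mls_table.loc[labels].to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)

    rows, truth_cols = [], {}
    counter = 0
    for tissue, (selection, n_samples) in config.tissues.items():
        w = mls * np.asarray(selection(mes), dtype=float)
        if (w < 0).any():
            raise ValueError("selection weights must be non-negative")
        if w.sum() <= 0:
            raise ValueError(f"all-zero sampling weights for tissue {tissue}")
        p = w / w.sum()
        truth_cols[tissue] = p
        picks = rng.choice(len(labels), size=n_samples, p=p)
        for k in picks:
            rows.append(
                {
                    "sample": f"T{counter:06d}",
                    "tissue": tissue,
                    "gene": "CTNNB1",
                    "protein_change": f"p.{labels[k]}",
                    "mutation_class": "missense",
                }
            )
            counter += 1
    catalog = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_cols, index=labels)
    return catalog, truth


def simulate_classified_cohort(
    mes_table: pd.Series,
    n_per_group: int = 10,
    threshold: float = 18000.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """A cohort with known pathway-group labels, covering all six groups.

    Samples are constructed per group: strong (high-MES hotspot mutation),
    strong via copy-number gain over a low-MES mutation, weak, other
    (non-hotspot CTNNB1 missense), AXIN1, no_mutation, and exclude
    (hotspot + AXIN1 co-mutation).  Returns the mutation catalog plus the
    per-sample truth labels; samples without records appear only in truth.
    """
    rng = np.random.default_rng(seed)
    strong_labels = mes_table.index[mes_table > threshold]
    weak_labels = mes_table.index[mes_table <= threshold]
    if len(strong_labels) == 0 or len(weak_labels) == 0:
        raise ValueError("MES table must contain both strong and weak variants")

    rows, truth = [], {}
    counter = 0

    def add(group: str, records: list[dict]) -> None:
        nonlocal counter
        sid = f"S{counter:05d}"
        counter += 1
        truth[sid] = group
        for r in records:
            rows.append({"sample": sid, "tissue": "liver", **r})

    for _ in range(n_per_group):
        hot_strong = rng.choice(strong_labels)
        hot_weak = rng.choice(weak_labels)
        add("strong", [{"gene": "CTNNB1", "protein_change": f"p.{hot_strong}",
                        "mutation_class": "missense", "cnv_gain": False}])
        add("strong", [{"gene": "CTNNB1", "protein_change": f"p.{hot_weak}",
                        "mutation_class": "missense", "cnv_gain": True}])
        add("weak", [{"gene": "CTNNB1", "protein_change": f"p.{hot_weak}",
                      "mutation_class": "missense", "cnv_gain": False}])
        add("other", [{"gene": "CTNNB1", "protein_change": "p.K335I",
                       "mutation_class": "missense", "cnv_gain": False}])
        add("AXIN1", [{"gene": "AXIN1", "protein_change": "p.R395C",
                       "mutation_class": "missense", "cnv_gain": False}])
        add("no_mutation", [])
        add("exclude", [
            {"gene": "CTNNB1", "protein_change": f"p.{hot_strong}",
             "mutation_class": "missense", "cnv_gain": False},
            {"gene": "AXIN1", "protein_change": "p.L396M",
             "mutation_class": "missense", "cnv_gain": False},
        ])

    catalog = pd.DataFrame(rows)
    return catalog, pd.Series(truth, name="group")


# ---------------------------------------------------------------------------
# Exome SNV lists and expression matrices
# ---------------------------------------------------------------------------

def simulate_exome_snvs(spectrum: TrinucSpectrum, n: int, seed: int = 0) -> pd.DataFrame:
    """Draw n SNVs (context, ref, alt) from a 96-category spectrum.

    Each record is presented on a random strand, so roughly half arrive
    purine-centered and exercise the reverse-complement collapse.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    p = np.array([spectrum.freq[c] for c in CATEGORIES])
    if p.sum() <= 0:
        raise ValueError("spectrum has zero mass")
    picks = rng.choice(len(CATEGORIES), size=n, p=p / p.sum())
    flip = rng.random(n) < 0.5
    rows = []
    for k, f in zip(picks, flip):
        context, alt = CATEGORIES[k]
        if f:
            context, alt = _revcomp(context), _revcomp(alt)
        rows.append({"context": context, "ref": context[1], "alt": alt})
    return pd.DataFrame(rows)


def simulate_expression(
    groups: pd.Series,
    fold_changes: dict[str, float],
    n_target_genes: int = 10,
    n_background_genes: int = 50,
    base_mean: float = 500.0,
    dispersion: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Negative binomial expression with group fold-changes on target genes.

    ``groups`` maps sample id to group label; ``fold_changes`` maps group
    labels to the multiplicative shift applied to target genes (groups not
    listed get fold 1).  Background genes are unshifted.  The dispersion is
    the NB alpha (variance = mu + alpha * mu^2).  Returns the genes x
    samples count matrix and the target gene names.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    samples = list(groups.index)
    target_genes = [f"TG{i:02d}" for i in range(n_target_genes)]
    background = [f"BG{i:03d}" for i in range(n_background_genes)]
    genes = target_genes + background

    base = base_mean * np.exp(rng.normal(0, 0.2, size=len(genes)))  # per-gene baseline
    shape = 1.0 / dispersion
    data = np.zeros((len(genes), len(samples)))
    for j, s in enumerate(samples):
        fold = float(fold_changes.get(groups[s], 1.0))
        mu = base.copy()
        mu[: n_target_genes] *= fold
        lam = rng.gamma(shape, mu * dispersion)
        data[:, j] = rng.poisson(lam)
    expr = pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=samples)
    return expr, target_genes
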