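"""Trinucleotide-context mutational likelihood scores (MLS).

Background mutational spectra are summarized in the standard 96 categories:
the mutated base with its immediate 5' and 3' neighbors, collapsed so that
the mutated base is always a pyrimidine (purine-centered changes are looked
up through the reverse complement), e.g. ``A[C>T]G``.  A spectrum is the
vector of relative frequencies of those categories in a set of somatic
single-nucleotide variants.

The MLS of a codon change is the probability-like weight of reaching the
target codon from the source codon through single-nucleotide steps.  Each
differing codon position mutates directly from its source base to its
target base; with k differing positions the path set is the k! orderings of
those changes.  A step's trinucleotide context reflects every previously
applied step within the codon plus the fixed reference flanks, its weight
is the spectrum frequency of its (context, alt) category, a path's score is
the product of its step weights, and the codon MLS is the sum over paths.
The MLS of an amino-acid change is the sum of the codon MLS over all sense
codons encoding the substituting amino acid.  Intermediate codons may be
stops — the path is a nucleotide-level process — but stop codons are never
amino-acid targets.

Whether observed mutation counts track MLS (i.e., whether mutational
opportunity alone explains a mutation pattern) is tested with a negative
binomial regression of counts on MLS against an intercept-only null, via a
likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .reference import (
    AmpliconReference,
    codons_for,
    enumerate_missense,
    translate_codon,
)

__all__ = [
    "CATEGORIES",
    "TrinucSpectrum",
    "count_spectrum",
    "codon_paths",
    "codon_mls",
    "aa_mls",
    "hotspot_mls_table",
    "selection_test",
    "SelectionTestResult",
    "consensus_filter",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def canonical_category(context: str, alt: str) -> tuple[str, str]:
    """Collapse (trinucleotide context, alt base) to its pyrimidine-centered form."""
    context, alt = context.upper(), alt.upper()
    if len(context) != 3 or any(b not in "ACGT" for b in context + alt):
        raise ValueError(f"bad substitution {context!r}>{alt!r}")
    if alt == context[1]:
        raise ValueError("alt base equals the reference base")
    if context[1] in "AG":
        return _revcomp(context), alt.translate(_COMPLEMENT)
    return context, alt


def _all_categories() -> list[tuple[str, str]]:
    cats = []
    for mid in "CT":
        for left in "ACGT":
            for right in "ACGT":
                for alt in "ACGT":
                    if alt != mid:
                        cats.append((left + mid + right, alt))
    return cats


#: The 96 pyrimidine-centered (trinucleotide, alt) categories in fixed order.
CATEGORIES: list[tuple[str, str]] = _all_categories()


@dataclass
class TrinucSpectrum:
    """Normalized frequencies over the 96 substitution categories."""

    freq: dict[tuple[str, str], float]
    n_snvs: int = 0

    def __post_init__(self) -> None:
        full = {c: 0.0 for c in CATEGORIES}
        for key, value in self.freq.items():
            if key not in full:
                raise ValueError(f"non-canonical category {key}")
            if value < 0:
                raise ValueError("frequencies must be non-negative")
            full[key] = float(value)
        total = sum(full.values())
        if total > 0:
            full = {k: v / total for k, v in full.items()}
        self.freq = full

    def frequency(self, context: str, alt: str) -> float:
        """Frequency of a substitution in context, on either strand."""
        return self.freq[canonical_category(context, alt)]

    def to_series(self) -> pd.Series:
        idx = pd.Index(
            [f"{c[0]}[{c[1]}>{alt}]{c[2]}" for c, alt in CATEGORIES],
            name="category",
        )
        return pd.Series([self.freq[k] for k in CATEGORIES], index=idx, name="freq")

    @classmethod
    def from_series(cls, s: pd.Series, n_snvs: int = 0) -> "TrinucSpectrum":
        freq = {}
        for label, value in s.items():
            context = label[0] + label[2] + label[6]
            alt = label[4]
            freq[(context, alt)] = float(value)
        return cls(freq, n_snvs=n_snvs)

    @classmethod
    def uniform(cls) -> "TrinucSpectrum":
        return cls({c: 1.0 for c in CATEGORIES})

    @classmethod
    def random(cls, rng: np.random.Generator, concentration: float = 1.0) -> "TrinucSpectrum":
        weights = rng.dirichlet(np.full(len(CATEGORIES), concentration))
        return cls(dict(zip(CATEGORIES, weights)))


def count_spectrum(
    snvs: list[tuple[str, str, str]] | pd.DataFrame,
) -> tuple[TrinucSpectrum, int]:
    """Estimate a 96-category spectrum from an SNV list.

    ``snvs`` is either a list of (context, ref, alt) tuples or a MAF-like
    frame with ``context``, ``ref`` and ``alt`` columns, where ``context``
    is the mutated base plus one neighbor on each side.  Records whose ref
    base disagrees with the context center are rejected; the function
    returns the spectrum and the number of rejected records.
    """
    if isinstance(snvs, pd.DataFrame):
        records = list(zip(snvs["context"], snvs["ref"], snvs["alt"]))
    else:
        records = list(snvs)
    counts: dict[tuple[str, str], float] = {c: 0.0 for c in CATEGORIES}
    rejected = 0
    n = 0
    for context, ref, alt in records:
        context, ref, alt = context.upper(), ref.upper(), alt.upper()
        if len(context) != 3 or context[1] != ref:
            rejected += 1
            continue
        try:
            key = canonical_category(context, alt)
        except ValueError:
            rejected += 1
            continue
        counts[key] += 1
        n += 1
    return TrinucSpectrum(counts, n_snvs=n), rejected


@dataclass(frozen=True)
class MutationStep:
    """One single-nucleotide change within a codon path."""

    position: int  # codon position, 1-based in {1,2,3}
    ref: str
    alt: str
    context: str  # trinucleotide around the changing base at the time of the step


def codon_paths(
    from_codon: str, to_codon: str, flank5: str = "N", flank3: str = "N"
) -> list[list[MutationStep]]:
    """All mutational paths between two codons, one base change at a time.

    Each differing position mutates directly from its source to its target
    base; the paths are the k! orderings of the k differing positions.  A
    step's context is computed from the current, partially mutated codon
    plus the fixed flanking bases, so later steps see earlier ones.
    Identical codons yield an empty list.
    """
    from_codon, to_codon = from_codon.upper(), to_codon.upper()
    for codon in (from_codon, to_codon):
        if len(codon) != 3 or any(b not in "ACGT" for b in codon):
            raise ValueError(f"not a valid codon: {codon!r}")
    diff = [i for i in range(3) if from_codon[i] != to_codon[i]]
    if not diff:
        return []
    paths = []
    for order in permutations(diff):
        state = list(from_codon)
        steps = []
        for i in order:
            padded = flank5 + "".join(state) + flank3
            context = padded[i : i + 3]
            steps.append(
                MutationStep(position=i + 1, ref=state[i], alt=to_codon[i], context=context)
            )
            state[i] = to_codon[i]
        paths.append(steps)
    return paths


def codon_mls(
    from_codon: str,
    to_codon: str,
    flank5: str,
    flank3: str,
    spectrum: TrinucSpectrum,
) -> float:
    """Sum over all paths of the product of per-step spectrum frequencies."""
    total = 0.0
    for path in codon_paths(from_codon, to_codon, flank5, flank3):
        weight = 1.0
        for step in path:
            weight *= spectrum.frequency(step.context, step.alt)
        total += weight
    return total


def aa_mls(
    residue: int,
    alt_aa: str,
    reference: AmpliconReference,
    spectrum: TrinucSpectrum,
) -> float:
    """MLS of an amino-acid change: sum of codon MLS over target codons.

    The source codon and its one-base flanks come from the gene sequence;
    target codons are every sense codon encoding ``alt_aa``.
    """
    ref_codon = reference.codon(residue)
    if alt_aa == translate_codon(ref_codon):
        raise ValueError(f"{alt_aa} is the reference amino acid at {residue}")
    if alt_aa == "*":
        raise ValueError("stop codons are not amino-acid MLS targets")
    flank5, flank3 = reference.codon_flanks(residue)
    return sum(
        codon_mls(ref_codon, codon, flank5, flank3, spectrum)
        for codon in codons_for(alt_aa)
        if codon != ref_codon
    )


def min_nt_changes(residue: int, alt_aa: str, reference: AmpliconReference) -> int:
    """Minimum nucleotide substitutions needed for the amino-acid change."""
    ref_codon = reference.codon(residue)
    return min(
        sum(a != b for a, b in zip(ref_codon, c))
        for c in codons_for(alt_aa)
        if c != ref_codon
    )


def hotspot_mls_table(
    reference: AmpliconReference, spectrum: TrinucSpectrum
) -> pd.DataFrame:
    """MLS records for all missense changes across the target region.

    One row per (residue, alt_aa): residue, ref_aa, alt_aa, min_nt_changes,
    mls; indexed by variant label.  342 rows for the default reference.
    """
    rows = []
    for v in enumerate_missense(reference):
        rows.append(
            {
                "variant": v.label,
                "residue": v.residue,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "min_nt_changes": min_nt_changes(v.residue, v.alt_aa, reference),
                "mls": aa_mls(v.residue, v.alt_aa, reference, spectrum),
            }
        )
    return pd.DataFrame(rows).set_index("variant")


@dataclass(frozen=True)
class SelectionTestResult:
    lrt_stat: float
    p_value: float
    slope: float
    ll_full: float
    ll_null: float


def selection_test(
    observed_counts: pd.Series | np.ndarray,
    mls_values: pd.Series | np.ndarray,
) -> SelectionTestResult:
    """Do observed mutation counts track mutational likelihood?

    Fits a negative binomial regression of counts on MLS and compares it to
    an intercept-only null by a likelihood-ratio test (chi-square, 1 df).
    A large p-value means mutational opportunity alone cannot be rejected
    as flat — i.e., no evidence the counts follow the MLS gradient.
    """
    import statsmodels.api as sm

    y = np.asarray(observed_counts, dtype=float)
    x = np.asarray(mls_values, dtype=float)
    if y.shape != x.shape:
        raise ValueError("counts and MLS must share an index")
    if not np.any(y > 0):
        raise ValueError("all-zero counts: degenerate fit")
    if np.ptp(x) == 0:
        # constant predictor carries no information; LRT statistic is zero
        return SelectionTestResult(0.0, 1.0, 0.0, np.nan, np.nan)

    # standardize the predictor for numerical stability; the LRT is
    # invariant to affine transformations of x
    xs = (x - x.mean()) / x.std()
    exog = sm.add_constant(xs)
    null_fit = sm.NegativeBinomial(y, np.ones((len(y), 1))).fit(
        disp=0, method="bfgs", maxiter=500
    )
    full_fit = sm.NegativeBinomial(y, exog).fit(
        disp=0, method="bfgs", maxiter=500, start_params=[null_fit.params[0], 0.0, null_fit.params[-1]]
    )
    lrt = max(0.0, 2.0 * (full_fit.llf - null_fit.llf))
    from scipy.stats import chi2

    return SelectionTestResult(
        lrt_stat=float(lrt),
        p_value=float(chi2.sf(lrt, df=1)),
        slope=float(full_fit.params[1]),
        ll_full=float(full_fit.llf),
        ll_null=float(null_fit.llf),
    )


def consensus_filter(
    df: pd.DataFrame, caller_columns: list[str], min_callers: int = 2
) -> pd.DataFrame:
    """Keep variants called by at least ``min_callers`` of the given workflows.

    ``caller_columns`` are boolean (or truthy) columns, one per variant
    caller, in a multi-caller MAF-like frame.
    """
    called = df[caller_columns].astype(bool).sum(axis=1)
    return df[called >= min_callers].copy()
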