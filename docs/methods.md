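# Methods

This note documents the models implemented in `ctnnbscan`, the choices made
where the underlying procedures were open, what the synthetic generators do
and do not emulate, and the numerical conventions.

## Amplicon model and read classification

The reference is a 162-nt amplicon: the human *CTNNB1* coding sequence for
codons 12–65, with the mutagenesis target (codons 31–48) at nucleotides
58–111, 1-based inclusive. Translating the target yields
`LDSGIHSGATTTAPSLSG`, i.e. the β-TRCP docking motif DSGIHS at residues
32–37 and the phosphosites T41 and S45. One flanking base on each side of
the target is always available for trinucleotide-context lookups.

Reads are merged single-end amplicon sequences and may arrive on either
strand; the orientation fitting the reference better is used. Bases beyond
the amplicon ends are soft-trimmed (alignment end gaps are free), so primer
or adaptor remnants do not affect classification. Indels are detected with
a global affine-gap alignment (match +1, mismatch −1, gap open −5, extend
−1); classification then proceeds on the gapless column comparison. A
same-length read with at most four mismatches skips the alignment: under
these gap costs an internal insertion–deletion pair always costs more than
the mismatches it could rescue, so such a read cannot hide an indel.

The exclusion cascade runs in fixed order — incomplete target coverage,
then indels anywhere, then codon-level rules. A read is VALID only with
exactly one mutated codon, inside the target, non-synonymous, matching the
template library codon for that substitution, and no other mismatches.
Reads with one valid target change plus additional substitutions elsewhere
are counted under `MULTI_TARGET` (more than one mutation event); the
category set has no dedicated slot for this case and such reads are
excluded either way. Per-base qualities are ignored; ambiguity codes count
as mismatches. The template library's codon per substitution is an input;
the default uses the most frequent human codon for each amino acid, which
is a documented convention, not a claim about the synthesized library.

## Counting and normalization

Every library variant keeps an explicit row (zero where unseen). Counts
are normalized within each sample to frequencies summing to one.
Replicate concordance is Pearson *r* on normalized frequencies per sample
(computed on frequencies rather than enrichment ratios — a documented
choice; either is defensible); replicates are then merged by summing raw
counts before normalization, with a per-replicate scoring path available.

## MES

MES_v = Σ_b (f_vb / f_v,pool) · g_b over the six bins. The formula is
applied literally: enrichment rows are not renormalized across bins before
fluorescence weighting. Bin mean GFP g_b is taken from the FACS sidecar
for real data; the synthetic generator records the arithmetic mean
fluorescence of each gate's cells (arithmetic rather than geometric mean
is a documented choice; the source procedure does not specify). Variants
with zero pool frequency are excluded and reported rather than
pseudocounted, because no pseudocount rule is part of the procedure; a
+0.5-pseudocount mode exists for sensitivity analysis. The weak/strong
threshold (default 18,000) is strict: a score exactly at the threshold is
weak. It is meaningful only relative to the supplied g_b scale. The
low-confidence plasmid-frequency cutoff is 0.028% (a tenth of the 0.28%
expected under a uniform 342-member library); flags never alter scores.

## MLS

Spectra are raw proportions of counted SNVs over the 96 pyrimidine-centered
categories, with reverse-complement lookup for purine-centered queries. No
opportunity (sequence-composition) normalization is applied by default.

Path model: each of the *k* differing codon positions mutates directly
from its source base to its target base; the path set is the *k*!
orderings. Detours through third bases are not allowed — admitting them
would make the path set infinite — and this direct-path reading is the
package's resolution of an ambiguity in the original description. A step's
context uses the current partially mutated codon plus fixed reference
flanks; edge codons take their flanks from the adjacent codons of the
supplied gene sequence. Stop codons are excluded as amino-acid targets but
permitted as path intermediates (the path is a nucleotide-level process).
Under a uniform spectrum the codon MLS has the closed form k!·f^k, which
the tests assert exactly, and the implementation is checked against an
independent brute-force path enumeration over all ordered sense-codon
pairs.

The selection test fits count ~ MLS with a negative binomial (NB2) MLE and
compares against an intercept-only fit by a likelihood-ratio test on one
degree of freedom. The predictor is standardized for numerical stability
(the LRT is invariant to this). A constant MLS vector returns statistic 0,
p = 1; all-zero counts are a degenerate-fit error.

## Degron property analysis

The property screen computes Spearman ρ (average ranks for ties) between a
position's 19 substitution scores and each amino-acid scale, sorted by
|ρ|. "Most disruptive quartile" is operationalized through the sign of the
scale's correlation with the effect scores: disruption means high effect
score, so a negative correlation marks the scale's five lowest-valued
amino acids as disruptive. Ties are broken by fixed alphabet order after
the value sort. The two bundled scales (Kyte–Doolittle hydropathy;
Chou–Fasman normalized β-sheet frequency) are standard published tables;
users can supply any scale as a TSV or AAindex flat-file entry.

Fisher's exact test is two-sided under the probability-mass convention
(sum of hypergeometric probabilities of all tables no more likely than the
observed one, at fixed margins); the tests verify it against an exhaustive
enumeration oracle. Degron peptide panels are user inputs aligned on the
DSGX core; both the 28-substrate and 29-sequence (including β-catenin
itself) panel definitions are supported — the analysis takes whatever set
is supplied and the count discrepancy between the two published panel
sizes is surfaced to the user rather than resolved.

## Cohort stratification and statistics

The six-group rules are applied with strict precedence: any *CTNNB1*
deletion/complex/frameshift/nonsense event, unparseable protein change,
multiple hotspot missense mutations, membership in more than one of
groups 1–4, or missing required data puts a sample in `exclude`. The
copy-number-gain reassignment applies only to low-MES hotspot mutations
and can only promote weak to strong. Protein changes accept `p.X##Y` and
`X##Y`. The docking-motif subgroup is residues 32–37.

`target_gene_percent` takes each gene's median per group as a percentage
of the strong group's median (unit-free per gene), then the median across
genes. `geneset_score` is a mean of per-gene z-scores across samples — a
simple single-sample enrichment stand-in, monotone in each member gene; no
numerical agreement with rank-weighted enrichment methods is claimed.
Distribution comparisons use the two-sided Mann–Whitney test (midranks for
ties). The MLS-adjusted comparison is this package's construction: the
observed between-cohort difference in mean MES is referred to a null in
which each cohort's mutations are resampled with probability proportional
to its own MLS values; the p-value is two-sided with the +1 correction and
seeded. Immune scores (ordinal 0–3) are dichotomized at 0 vs ≥1 and tested
with the same Fisher routine.

## Synthetic data

The sort-seq generator draws each cell's fluorescence lognormally around
its variant's true activity (shared σ on the natural-log scale — the
simplest model consistent with log-spaced gating, not a claim about
reporter biology), gates cells into six equally log-spaced bins, and
samples reads multinomially within bins. Defaults: 342 variants with
log-uniform activities, σ = 0.3, gates spanning 100–31,623 fluorescence
units (so that strong variants exceed the 18,000 threshold on the same
scale), 2,000 cells per variant, 2×10⁶ reads per bin, and 9% of variants
depleted to 1/20 weight in the plasmid (mirroring the minority of
underrepresented templates). The pool sample follows the cell composition;
the plasmid sample follows the library representation. The generator does
not emulate editing efficiency variation, FACS spillover, PCR jackpots or
realistic sequencing error profiles — read-level simulation applies
uniform substitution/indel rates only — so passing recovery tests show the
scoring mathematics is correct under the stated noise model, not that the
pipeline is robust to every artifact of real screens.

Tumor catalogs draw mutations with probability ∝ MLS × selection
weight(MES) per tissue; expression matrices are negative binomial
(gamma–Poisson, variance μ + αμ²) with group fold-changes on target genes.
Every generator is deterministic given its seed and returns its ground
truth.

## Problem sizes and tolerances

The default test suite runs in a few seconds: spectrum recovery uses 10⁴
SNVs (total-variation tolerance 0.05), NB-LRT calibration uses 200 null
seeds (KS uniformity at p > 0.01) and 50 power seeds at n = 105 variants,
and MES recovery uses the full default depth. Exact comparisons (path
enumeration, Fisher oracles, classification round trips) use relative
tolerance 1e−9 or exact equality. Frequencies must sum to 1 within 1e−12
after normalization.

## Known limitations

The per-substitution effect scores of the original screen are not bundled,
so analyses that need them (e.g. reproducing the published I35 property
correlations) require the user to supply a score table. The NB-LRT is
asymptotic; at much smaller variant counts its calibration degrades. The
MLS-adjusted cohort comparison is a stand-in for an unspecified published
adjustment and should not be expected to reproduce its numbers.
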