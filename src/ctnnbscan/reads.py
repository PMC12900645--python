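"""Classification of merged amplicon reads against the hotspot reference.

Each merged single-end read is assigned to exactly one category.  A read is
VALID — and contributes to a variant's count — only when it carries precisely
one non-synonymous codon change, inside the mutagenesis target, matching a
codon present in the HDR template library, with no other differences from
the reference anywhere in the amplicon.

The exclusion cascade runs in fixed priority order:

1. ``INCOMPLETE_COVERAGE`` — the read does not span the full target region;
2. ``HAS_INDEL`` — the optimal global alignment contains an internal
   insertion or deletion anywhere in the amplicon;
3. codon-level classification on the gapless column comparison:
   ``NO_TARGET_MUTATION``, ``OUTSIDE_ONLY``, ``MULTI_TARGET``,
   ``SYNONYMOUS_ONLY``, ``NOT_IN_LIBRARY`` or ``VALID``.

``MULTI_TARGET`` covers every read with more than one mutation event: two or
more mutated target codons, or one mutated target codon plus additional
substitutions outside the target (such reads violate the "no other
mutations" requirement but have no dedicated category of their own).

Reads may arrive on either strand; the orientation with the better fit to
the reference is used.  Bases beyond the amplicon ends are soft-trimmed
(alignment end gaps are free), so classification does not depend on primer
or adaptor remnants.  Per-base qualities are ignored.  IUPAC ambiguity
codes never match the reference and therefore count as mismatches.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import Align, SeqIO
from Bio.Seq import reverse_complement

from .reference import AmpliconReference, VariantID, translate_codon

__all__ = ["Category", "ReadClassification", "ReadClassifier", "classify_fastq"]


class Category(str, Enum):
    VALID = "VALID"
    NO_TARGET_MUTATION = "NO_TARGET_MUTATION"
    OUTSIDE_ONLY = "OUTSIDE_ONLY"
    MULTI_TARGET = "MULTI_TARGET"
    SYNONYMOUS_ONLY = "SYNONYMOUS_ONLY"
    NOT_IN_LIBRARY = "NOT_IN_LIBRARY"
    HAS_INDEL = "HAS_INDEL"
    INCOMPLETE_COVERAGE = "INCOMPLETE_COVERAGE"


@dataclass(frozen=True)
class ReadClassification:
    category: Category
    variant: VariantID | None = None

    def __post_init__(self) -> None:
        if (self.category is Category.VALID) != (self.variant is not None):
            raise ValueError("VALID classifications carry exactly one variant")


class ReadClassifier:
    """Classifies reads against a fixed reference and template library."""

    def __init__(self, reference: AmpliconReference, library: Iterable[VariantID]):
        self.reference = reference
        # (residue, observed codon) -> library variant
        self._codon_lookup: dict[tuple[int, str], VariantID] = {}
        for v in library:
            if v.template_codon is None:
                raise ValueError(f"library variant {v.label} lacks a template codon")
            self._codon_lookup[(v.residue, v.template_codon)] = v

        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "global"
        self._aligner.match_score = 1
        self._aligner.mismatch_score = -1
        self._aligner.open_gap_score = -5
        self._aligner.extend_gap_score = -1
        # soft-trim: bases beyond either amplicon end are free
        self._aligner.end_gap_score = 0

    # -- public API ---------------------------------------------------------

    def classify(self, read: str) -> ReadClassification:
        """Classify one merged read (either strand)."""
        read = read.strip().upper()
        if not read:
            raise ValueError("empty read")

        read = self._orient(read)
        aligned_read = self._project_onto_reference(read)
        if aligned_read is None:
            return ReadClassification(Category.HAS_INDEL)
        ref = self.reference
        start0, end0 = ref.target_start - 1, ref.target_end  # python slice bounds
        if any(b is None for b in aligned_read[start0:end0]):
            return ReadClassification(Category.INCOMPLETE_COVERAGE)

        mismatches = [
            i
            for i, b in enumerate(aligned_read)
            if b is not None and b != ref.sequence[i]
        ]
        in_target = [i for i in mismatches if start0 <= i < end0]
        outside = [i for i in mismatches if not (start0 <= i < end0)]

        if not mismatches:
            return ReadClassification(Category.NO_TARGET_MUTATION)
        if not in_target:
            return ReadClassification(Category.OUTSIDE_ONLY)

        mutated_codons = sorted({(i - start0) // 3 for i in in_target})
        if len(mutated_codons) > 1 or outside:
            return ReadClassification(Category.MULTI_TARGET)

        codon_idx = mutated_codons[0]
        residue = ref.first_codon_number + codon_idx
        obs = "".join(
            aligned_read[start0 + 3 * codon_idx + k] for k in range(3)
        )
        if any(b not in "ACGT" for b in obs):
            return ReadClassification(Category.NOT_IN_LIBRARY)
        if translate_codon(obs) == ref.ref_aa(residue):
            return ReadClassification(Category.SYNONYMOUS_ONLY)
        variant = self._codon_lookup.get((residue, obs))
        if variant is None:
            return ReadClassification(Category.NOT_IN_LIBRARY)
        return ReadClassification(Category.VALID, variant)

    # -- internals ----------------------------------------------------------

    def _orient(self, read: str) -> str:
        rc = reverse_complement(read)
        if len(read) == len(self.reference.sequence):
            fwd = sum(a != b for a, b in zip(read, self.reference.sequence))
            rev = sum(a != b for a, b in zip(rc, self.reference.sequence))
            return read if fwd <= rev else rc
        s_fwd = self._aligner.score(self.reference.sequence, read)
        s_rev = self._aligner.score(self.reference.sequence, rc)
        return read if s_fwd >= s_rev else rc

    def _project_onto_reference(self, read: str) -> list[str | None] | None:
        """Read base per reference position, or None where uncovered.

        Returns None (sentinel for the whole read) when the optimal
        alignment contains an internal insertion or deletion.
        """
        ref = self.reference.sequence
        if len(read) == len(ref):
            # fast path: identical length with few mismatches cannot hide an
            # indel under affine gap costs (an internal gap pair would cost
            # more than the mismatches it rescues)
            if sum(a != b for a, b in zip(read, ref)) <= 4:
                return list(read)
        alignment = self._aligner.align(ref, read)[0]
        blocks_ref, blocks_read = alignment.aligned
        if len(blocks_ref) != 1:
            # more than one aligned block => internal gap on one side
            return None
        (r0, r1), (q0, q1) = blocks_ref[0], blocks_read[0]
        projected: list[str | None] = [None] * len(ref)
        for off in range(r1 - r0):
            projected[r0 + off] = read[q0 + off]
        return projected


def classify_fastq(
    fastq_path: str | Path,
    reference: AmpliconReference,
    library: Iterable[VariantID],
) -> Iterator[ReadClassification]:
    """Stream classifications from a (optionally gzipped) FASTQ file."""
    classifier = ReadClassifier(reference, library)
    path = Path(fastq_path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for record in SeqIO.parse(fh, "fastq"):
            yield classifier.classify(str(record.seq))
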