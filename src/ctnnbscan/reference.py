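"""Amplicon reference model for the CTNNB1 exon 3 degron hotspot.

The saturation editing assay reads out a fixed 162-nt amplicon spanning the
mutation hotspot (beta-catenin codons 31-48, the 54-nt target at amplicon
positions 58-111, 1-based inclusive).  This module holds the reference
coordinate arithmetic, the missense variant library enumeration, and the
single-nucleotide reachability calculation over the genetic code.

Amino acids are one-letter codes; stop is ``*``.  All coordinates on the
amplicon are 1-based inclusive, matching the convention "region targeted for
mutagenesis (58-111 bp)".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "CODON_TABLE",
    "AmpliconReference",
    "VariantID",
    "default_reference",
    "default_library",
    "enumerate_missense",
    "single_nt_reachable",
    "translate_codon",
    "codons_for",
    "load_reference",
    "load_library",
    "write_library",
]

#: Fixed amino-acid alphabet used for deterministic ordering everywhere.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Sense-codon -> amino acid map from the standard genetic code.
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)

_STOP_CODONS = frozenset(standard_dna_table.stop_codons)

# Human CTNNB1 coding sequence, codons 12-65.  Codons 31-48 (amplicon
# positions 58-111) are the mutagenesis target; translating them yields
# LDSGIHSGATTTAPSLSG with the beta-TRCP docking motif DSGIHS at 32-37 and
# the phosphosites T41 and S45.
_REFERENCE_SEQ = (
    "ATGGCCATGGAACCAGACAGAAAAGCGGCTGTTAGTCACTGGCAGCAACAGTCTTAC"  # codons 12-30
    "CTGGACTCTGGAATCCATTCTGGTGCCACTACCACAGCTCCTTCTCTGAGTGGT"      # codons 31-48
    "AAAGGCAATCCTGAGGAAGAGGATGTGGATACCTCCCAAGTCCTGTATGAG"         # codons 49-65
)

#: Most frequent human codon per amino acid; default rule for the HDR
#: template library when the synthesized codons are not supplied.
PREFERRED_CODON: dict[str, str] = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}


def translate_codon(codon: str) -> str:
    """Translate a single codon; returns ``*`` for stop codons.

    Raises ValueError for anything that is not an ACGT triplet.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"not a valid codon: {codon!r}")
    if codon in _STOP_CODONS:
        return "*"
    return CODON_TABLE[codon]


def codons_for(aa: str) -> list[str]:
    """All sense codons encoding ``aa``, in alphabetical order."""
    return sorted(c for c, a in CODON_TABLE.items() if a == aa)


@dataclass(frozen=True)
class VariantID:
    """A single missense substitution in the hotspot library."""

    residue: int
    ref_aa: str
    alt_aa: str
    template_codon: str | None = None

    def __post_init__(self) -> None:
        if self.alt_aa == self.ref_aa:
            raise ValueError("alt_aa must differ from ref_aa")
        if self.alt_aa == "*":
            raise ValueError("stop substitutions are not part of the missense library")

    @property
    def label(self) -> str:
        """Protein-change label, e.g. ``S45F``."""
        return f"{self.ref_aa}{self.residue}{self.alt_aa}"


@dataclass(frozen=True)
class AmpliconReference:
    """The fixed amplicon against which every read is classified.

    ``target_start``/``target_end`` are 1-based inclusive nucleotide
    positions of the mutagenesis target; ``first_codon_number`` is the
    protein residue encoded by the first target codon.
    """

    sequence: str
    target_start: int = 58
    target_end: int = 111
    first_codon_number: int = 31

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if any(b not in "ACGT" for b in seq):
            raise ValueError("reference sequence must be ACGT only")
        span = self.target_end - self.target_start + 1
        if span <= 0 or span % 3:
            raise ValueError("target span must be a positive multiple of 3")
        if self.target_end > len(seq):
            raise ValueError("target extends beyond the reference")
        if self.target_start < 3 or self.target_end > len(seq) - 1:
            # one flanking base on each side is the minimum for
            # trinucleotide-context lookups at the target edges
            raise ValueError("target must leave flanking context on both sides")

    @property
    def n_codons(self) -> int:
        return (self.target_end - self.target_start + 1) // 3

    @property
    def residues(self) -> range:
        return range(self.first_codon_number, self.first_codon_number + self.n_codons)

    def codon(self, residue: int) -> str:
        """Reference codon for a target residue."""
        i = self._codon_offset(residue)
        return self.sequence[i : i + 3]

    def codon_flanks(self, residue: int) -> tuple[str, str]:
        """(5' base, 3' base) immediately adjacent to the residue's codon."""
        i = self._codon_offset(residue)
        return self.sequence[i - 1], self.sequence[i + 3]

    def ref_aa(self, residue: int) -> str:
        return translate_codon(self.codon(residue))

    @property
    def target_peptide(self) -> str:
        return "".join(self.ref_aa(r) for r in self.residues)

    def _codon_offset(self, residue: int) -> int:
        if residue not in self.residues:
            raise ValueError(
                f"residue {residue} outside target range "
                f"[{self.residues.start},{self.residues.stop - 1}]"
            )
        return (self.target_start - 1) + 3 * (residue - self.first_codon_number)


def default_reference() -> AmpliconReference:
    """The bundled 162-nt CTNNB1 amplicon (codons 31-48 targeted)."""
    return AmpliconReference(_REFERENCE_SEQ)


def enumerate_missense(
    reference: AmpliconReference | None = None,
    residues: Iterable[int] | None = None,
    exclude_stop: bool = True,
) -> list[VariantID]:
    """Enumerate every missense substitution over the target residues.

    Returns 19 variants per residue (20 amino acids minus the reference
    identity), in deterministic order: residue ascending, substituting amino
    acid in fixed alphabet order.  ``exclude_stop=False`` additionally keeps
    nonsense changes (these carry ``alt_aa='*'`` via plain tuples and are
    mainly useful for bookkeeping; the default library is missense-only).
    """
    ref = reference or default_reference()
    residues = list(residues) if residues is not None else list(ref.residues)
    if not residues:
        raise ValueError("empty residue range")
    out: list[VariantID] = []
    for res in residues:
        ref_aa = ref.ref_aa(res)  # raises for out-of-range residues
        alphabet = AMINO_ACIDS if exclude_stop else AMINO_ACIDS + "*"
        for alt in alphabet:
            if alt == ref_aa:
                continue
            if alt == "*":
                # represented outside VariantID's missense contract
                continue
            out.append(VariantID(res, ref_aa, alt, PREFERRED_CODON[alt]))
    return out


def default_library(reference: AmpliconReference | None = None) -> list[VariantID]:
    """The default 342-variant HDR template library (most-frequent-codon rule)."""
    return enumerate_missense(reference)


def single_nt_reachable(codon: str, exclude_stop: bool = True) -> set[str]:
    """Amino acids reachable from ``codon`` by exactly one base substitution.

    The encoded amino acid itself is never included (synonymous changes are
    not substitutions at the protein level); stop codons are excluded unless
    ``exclude_stop`` is False.
    """
    ref_aa = translate_codon(codon)
    out: set[str] = set()
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            aa = translate_codon(codon[:pos] + base + codon[pos + 1 :])
            if aa == ref_aa:
                continue
            if aa == "*" and exclude_stop:
                continue
            out.add(aa)
    return out


def hotspot_reachability(
    reference: AmpliconReference | None = None,
) -> dict[int, set[str]]:
    """Per-residue single-nucleotide-reachable missense sets for the target."""
    ref = reference or default_reference()
    return {res: single_nt_reachable(ref.codon(res)) for res in ref.residues}


# ---------------------------------------------------------------------------
# IO: FASTA + JSON sidecar for the reference, TSV for the library
# ---------------------------------------------------------------------------

def load_reference(fasta_path: str | Path, sidecar_path: str | Path | None = None) -> AmpliconReference:
    """Load an amplicon reference from a single-record FASTA + JSON sidecar.

    The sidecar carries ``target_start``, ``target_end`` and
    ``first_codon_number``; if omitted, ``<fasta>.json`` is tried, then the
    bundled defaults are used.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(records)}")
    seq = str(records[0].seq).upper()
    meta = {}
    candidate = Path(sidecar_path) if sidecar_path else Path(str(fasta_path) + ".json")
    if candidate.exists():
        meta = json.loads(candidate.read_text())
    return AmpliconReference(
        seq,
        target_start=int(meta.get("target_start", 58)),
        target_end=int(meta.get("target_end", 111)),
        first_codon_number=int(meta.get("first_codon_number", 31)),
    )


def write_reference(ref: AmpliconReference, fasta_path: str | Path) -> None:
    fasta_path = Path(fasta_path)
    fasta_path.write_text(f">amplicon\n{ref.sequence}\n")
    sidecar = {
        "target_start": ref.target_start,
        "target_end": ref.target_end,
        "first_codon_number": ref.first_codon_number,
    }
    Path(str(fasta_path) + ".json").write_text(json.dumps(sidecar, indent=1))


def load_library(path: str | Path) -> list[VariantID]:
    """Load a template library TSV (columns residue, ref_aa, alt_aa, template_codon)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"residue": int})
    return [
        VariantID(int(r.residue), r.ref_aa, r.alt_aa, getattr(r, "template_codon", None))
        for r in df.itertuples()
    ]


def write_library(library: list[VariantID], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "residue": [v.residue for v in library],
            "ref_aa": [v.ref_aa for v in library],
            "alt_aa": [v.alt_aa for v in library],
            "template_codon": [v.template_codon for v in library],
        }
    ).to_csv(path, sep="\t", index=False)
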