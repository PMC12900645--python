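"""Trinucleotide spectra, codon paths and mutational likelihood scores."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import ctnnbscan as cs
from ctnnbscan.mls import (
    CATEGORIES,
    TrinucSpectrum,
    _revcomp,
    canonical_category,
    codon_mls,
    codon_paths,
    min_nt_changes,
    selection_test,
)
from ctnnbscan.reference import codons_for, translate_codon


def oracle_codon_mls(from_codon, to_codon, flank5, flank3, spectrum):
    """Independent path-enumeration oracle (no shared code with codon_mls)."""
    diff = [i for i in range(3) if from_codon[i] != to_codon[i]]
    total = 0.0
    for order in permutations(diff):
        state = list(from_codon)
        product = 1.0
        for i in order:
            full = flank5 + "".join(state) + flank3
            context = full[i : i + 3]
            product *= spectrum.frequency(context, to_codon[i])
            state[i] = to_codon[i]
        total += product
    return total


class TestSpectrum:
    def test_single_snv(self):
        sp, rejected = cs.count_spectrum([("ACG", "C", "T")])
        assert rejected == 0
        assert sp.freq[("ACG", "T")] == 1.0
        assert sum(sp.freq.values()) == pytest.approx(1.0)

    def test_purine_centered_record_collapses_by_reverse_complement(self):
        a, _ = cs.count_spectrum([("ACG", "C", "T")])
        b, _ = cs.count_spectrum([("CGT", "G", "A")])  # revcomp of A[C>T]G
        assert a.freq == b.freq

    def test_mismatched_ref_rejected_with_count(self):
        sp, rejected = cs.count_spectrum([("ACG", "G", "T"), ("ACG", "C", "T")])
        assert rejected == 1
        assert sp.n_snvs == 1

    def test_normalization_invariant(self):
        rng = np.random.default_rng(0)
        sp = TrinucSpectrum.random(rng)
        assert sum(sp.freq.values()) == pytest.approx(1.0)
        assert len(sp.freq) == 96

    def test_estimation_is_order_invariant(self):
        records = [("ACG", "C", "T"), ("TCA", "C", "G"), ("ACG", "C", "T")]
        a, _ = cs.count_spectrum(records)
        b, _ = cs.count_spectrum(records[::-1])
        assert a.freq == b.freq

    def test_series_round_trip(self):
        sp = TrinucSpectrum.random(np.random.default_rng(1))
        again = TrinucSpectrum.from_series(sp.to_series())
        assert again.freq == pytest.approx(sp.freq)


class TestPaths:
    @pytest.mark.parametrize(
        "from_codon,to_codon,n_paths",
        [("ACC", "GCC", 1), ("ACC", "GTC", 2), ("ACC", "GTA", 6), ("ACC", "ACC", 0)],
    )
    def test_path_count_is_k_factorial(self, from_codon, to_codon, n_paths):
        assert len(codon_paths(from_codon, to_codon)) == n_paths

    def test_steps_apply_to_distinct_positions_and_reach_target(self):
        for path in codon_paths("ACC", "GTA", "T", "G"):
            state = list("ACC")
            positions = set()
            for step in path:
                assert step.position not in positions
                positions.add(step.position)
                assert state[step.position - 1] == step.ref
                state[step.position - 1] = step.alt
            assert "".join(state) == "GTA"

    def test_context_reflects_earlier_steps(self):
        # changing position 1 then 2: the second step's context contains the
        # already-mutated first base
        paths = codon_paths("ACC", "GTC", "T", "G")
        by_first = {p[0].position: p for p in paths}
        second_step = by_first[1][1]
        assert second_step.context == "GCC"[0:1] + "C" + "C"  # G (new base1), C, C
        second_step_other = by_first[2][1]
        assert second_step_other.context == "TAT"[0] + "A" + "T"  # flank5, A, T->mutated pos2


class TestCodonMLS:
    def test_uniform_spectrum_closed_form(self):
        sp = TrinucSpectrum.uniform()
        f = 1.0 / 96
        assert codon_mls("ACC", "GCC", "T", "A", sp) == pytest.approx(f)
        assert codon_mls("ACC", "GTC", "T", "A", sp) == pytest.approx(2 * f**2)
        assert codon_mls("ACC", "GTA", "T", "A", sp) == pytest.approx(6 * f**3)

    def test_single_difference_equals_category_frequency(self):
        sp = TrinucSpectrum.random(np.random.default_rng(2))
        value = codon_mls("ACC", "ATC", "G", "T", sp)
        assert value == pytest.approx(sp.frequency("ACT"[0] + "C" + "C", "T"))

    def test_strand_collapse_symmetry(self):
        """Reverse-complementing the whole locus leaves the score unchanged."""
        sp = TrinucSpectrum.random(np.random.default_rng(3))
        rng = np.random.default_rng(4)
        for _ in range(25):
            frm = "".join(rng.choice(list("ACGT"), 3))
            to = "".join(rng.choice(list("ACGT"), 3))
            f5, f3 = rng.choice(list("ACGT")), rng.choice(list("ACGT"))
            fwd = codon_mls(frm, to, f5, f3, sp)
            rev = codon_mls(_revcomp(frm), _revcomp(to), _revcomp(f3), _revcomp(f5), sp)
            assert rev == pytest.approx(fwd)

    def test_agrees_with_enumeration_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        sp = TrinucSpectrum.random(rng)
        for _ in range(100):
            frm = "".join(rng.choice(list("ACGT"), 3))
            to = "".join(rng.choice(list("ACGT"), 3))
            f5, f3 = rng.choice(list("ACGT")), rng.choice(list("ACGT"))
            assert codon_mls(frm, to, f5, f3, sp) == pytest.approx(
                oracle_codon_mls(frm, to, f5, f3, sp)
            )

    def test_point_mass_spectrum_hits_only_matching_steps(self):
        sp = TrinucSpectrum({("ACA", "T"): 1.0})
        # A[C>T]A: the middle base of ACA mutating to T matches the category
        assert codon_mls("ACA", "ATA", "G", "T", sp) == pytest.approx(1.0)
        # a change whose context never matches the category scores zero
        assert codon_mls("GGG", "GCG", "A", "A", sp) == 0.0


class TestAaMLS:
    def test_single_codon_amino_acids(self, reference):
        sp = TrinucSpectrum.random(np.random.default_rng(6))
        for alt in ("W", "M"):
            value = cs.aa_mls(41, alt, reference, sp)
            (codon,) = codons_for(alt)
            f5, f3 = reference.codon_flanks(41)
            assert value == pytest.approx(
                codon_mls(reference.codon(41), codon, f5, f3, sp)
            )

    def test_reference_amino_acid_rejected(self, reference):
        with pytest.raises(ValueError):
            cs.aa_mls(41, "T", reference, TrinucSpectrum.uniform())

    def test_uniform_spectrum_monotone_in_required_changes(self, reference):
        """k! f^k decreases with k for f < 1/2, so fewer changes score higher."""
        sp = TrinucSpectrum.uniform()
        table = cs.hotspot_mls_table(reference, sp)
        by_k = table.groupby("min_nt_changes")["mls"].max()
        assert by_k[1] > by_k[2] > by_k[3]

    def test_full_table_matches_oracle_record_for_record(self, reference):
        sp = TrinucSpectrum.random(np.random.default_rng(7))
        table = cs.hotspot_mls_table(reference, sp)
        assert len(table) == 342
        for row in table.sample(40, random_state=0).itertuples():
            ref_codon = reference.codon(row.residue)
            f5, f3 = reference.codon_flanks(row.residue)
            expected = sum(
                oracle_codon_mls(ref_codon, c, f5, f3, sp)
                for c in codons_for(row.alt_aa)
                if c != ref_codon
            )
            assert row.mls == pytest.approx(expected)

    def test_min_nt_changes(self, reference):
        # T41A: ACC->GCC is one change; T41M: ACC->ATG is two
        assert min_nt_changes(41, "A", reference) == 1
        assert min_nt_changes(41, "M", reference) == 2


class TestSelectionTest:
    def test_constant_mls_gives_null_result(self):
        result = selection_test(np.array([3, 1, 4, 1, 5]), np.ones(5))
        assert result.lrt_stat == 0.0 and result.p_value == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            selection_test(np.zeros(10), np.arange(10.0))

    def test_detects_mls_proportional_means(self):
        rng = np.random.default_rng(8)
        x = rng.lognormal(0, 1, 105)
        mu = 200 * x / x.mean()
        counts = rng.poisson(rng.gamma(1.0, mu))
        assert selection_test(counts, x).p_value < 0.01

    def test_null_counts_give_large_p(self):
        rng = np.random.default_rng(9)
        x = rng.lognormal(0, 1, 105)
        counts = rng.poisson(rng.gamma(1.0, 200.0, size=105))
        assert selection_test(counts, x).p_value > 0.05


def test_consensus_filter_keeps_multiply_called_variants():
    df = pd.DataFrame(
        {
            "variant": ["a", "b", "c"],
            "muse": [True, True, False],
            "mutect2": [True, False, False],
            "varscan2": [False, False, True],
        }
    )
    kept = cs.mls.consensus_filter(df, ["muse", "mutect2", "varscan2"], min_callers=2)
    assert list(kept["variant"]) == ["a"]
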