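"""Direct phasing routes: double peaks, deconvolution, peak heights."""

import numpy as np
import pytest

from haploweb.bruteforce import enumerate_deconvolutions
from haploweb.phasing import (
    AmbiguityError,
    PhasedGenotype,
    PhasingError,
    deconvolve_length_variant,
    estimate_offset,
    find_double_peaks,
    phase_by_peak_height,
    phase_dataset,
    resolve_single_double_peak,
)
from haploweb.reads import MixedRead, superpose
from haploweb.simdata import SimulationConfig, _mutate, _random_seq, simulate_dataset


class TestFindDoublePeaks:
    def test_clean_read_has_none(self):
        assert find_double_peaks(MixedRead.from_iupac("ACGTACGT")) == []

    def test_worked_example_positions(self, worked_example_reads):
        fwd, rev = worked_example_reads
        assert find_double_peaks(fwd) == [3, 4, 5, 6]
        assert find_double_peaks(rev) == [1, 2, 3]

    def test_count_equals_ambiguity_characters(self):
        read = MixedRead.from_iupac("ARGYTWSA")
        iupac = read.iupac
        n_ambig = sum(1 for c in iupac if c not in "ACGT")
        assert len(find_double_peaks(read)) == n_ambig


class TestSingleDoublePeak:
    def test_two_case_enumeration(self):
        read = MixedRead.from_iupac("AMGT")  # M = A/C at position 1
        assert resolve_single_double_peak(read) == ("AAGT", "ACGT")

    def test_clean_read_errors(self):
        with pytest.raises(PhasingError):
            resolve_single_double_peak(MixedRead.from_iupac("ACGT"))

    def test_multiple_doubles_error(self):
        with pytest.raises(PhasingError):
            resolve_single_double_peak(MixedRead.from_iupac("AMGR"))

    def test_resolution_round_trips_through_superpose(self):
        read = MixedRead.from_iupac("GTKCA")
        h1, h2 = resolve_single_double_peak(read)
        fwd, _ = superpose(h1, h2)
        assert fwd.sets == read.sets


class TestEstimateOffset:
    def test_single_deletion(self, worked_example_reads):
        assert estimate_offset(*worked_example_reads) == 1

    def test_homozygote_pattern_rejected(self, rng):
        seq = _random_seq(rng, 40)
        fwd, rev = superpose(seq, seq)
        with pytest.raises(PhasingError):
            estimate_offset(fwd, rev)

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_known_deletion_length_recovered(self, rng, k):
        s1 = _random_seq(rng, 80)
        s2 = _mutate(rng, s1[: 80 - k], 0.06)
        fwd, rev = superpose(s1, s2)
        assert estimate_offset(fwd, rev) == k


class TestDeconvolution:
    def test_worked_example_round_trip(self, worked_example_reads):
        fwd, rev = worked_example_reads
        assert deconvolve_length_variant(fwd, rev, 1) == ("ACGTACGT", "ACGACGT")

    def test_matches_exhaustive_oracle_on_small_instances(self):
        """On <=12 bp instances the constraint propagation must agree with
        full enumeration: unique solutions recovered exactly, multiple
        solutions reported as ambiguity, never guessed."""
        rng = np.random.default_rng(1)
        n_unique = n_ambiguous = 0
        for _ in range(250):
            L = int(rng.integers(6, 13))
            k = int(rng.integers(1, min(4, L - 2)))
            s1 = _random_seq(rng, L)
            s2 = _mutate(rng, s1[: L - k], 0.15)
            fwd, rev = superpose(s1, s2)
            solutions = enumerate_deconvolutions(fwd, rev, k)
            assert (s1, s2) in solutions
            try:
                got = deconvolve_length_variant(fwd, rev, k)
            except AmbiguityError:
                assert len(solutions) > 1
                n_ambiguous += 1
            else:
                assert solutions == [got]
                n_unique += 1
        assert n_unique > 100  # the sweep must mostly exercise real solves

    def test_periodic_repeats_stay_anchored(self):
        """Perfectly periodic alleles look maximally adversarial (every
        forward position is a double peak) yet remain uniquely solvable:
        the start-aligned/end-aligned coupling anchors each constraint
        chain at the read boundaries.  The exhaustive oracle confirms a
        single solution and propagation must find exactly it."""
        s1, s2 = "ATATATAT", "TATATAT"
        fwd, rev = superpose(s1, s2)
        assert enumerate_deconvolutions(fwd, rev, 1) == [(s1, s2)]
        assert deconvolve_length_variant(fwd, rev, 1) == (s1, s2)

    def test_wrong_offset_is_contradiction_not_guess(self, worked_example_reads):
        fwd, rev = worked_example_reads
        with pytest.raises(PhasingError):
            deconvolve_length_variant(fwd, rev, 2)

    def test_exact_recovery_of_simulated_long_pairs(self):
        """200 random 300-bp pairs with 1-5 bp deletions and >=5% divergence
        are recovered exactly, including the offset estimate."""
        rng = np.random.default_rng(2)
        for _ in range(200):
            s1 = _random_seq(rng, 300)
            k = int(rng.integers(1, 6))
            s2 = _mutate(rng, s1[: 300 - k], 0.05)
            fwd, rev = superpose(s1, s2)
            assert estimate_offset(fwd, rev) == k
            assert deconvolve_length_variant(fwd, rev, k) == (s1, s2)

    def test_bad_offset_rejected(self, worked_example_reads):
        fwd, rev = worked_example_reads
        with pytest.raises(PhasingError):
            deconvolve_length_variant(fwd, rev, 0)


class TestPeakHeight:
    def test_clear_cut_heights_accepted(self):
        fwd, _ = superpose("AAAA", "ACAA", bias=0.8)
        assert phase_by_peak_height(fwd) == ("AAAA", "ACAA")

    def test_below_threshold_declines(self):
        fwd, _ = superpose("AAAA", "ACAA", bias=0.55)
        assert phase_by_peak_height(fwd, 0.65) is None

    def test_missing_heights_error(self):
        fwd, _ = superpose("AAAA", "ACAA")
        with pytest.raises(PhasingError):
            phase_by_peak_height(fwd)

    def test_simulated_bias_recovers_alleles(self, rng):
        a = _random_seq(rng, 120)
        b = _mutate(rng, a, 0.05)
        fwd, _ = superpose(a, b, bias=0.8)
        assert phase_by_peak_height(fwd) == (a, b)


class TestPhasedGenotype:
    def test_route_homozygote_iff_identical(self):
        PhasedGenotype("i1", "m", ("AC", "AC"), "homozygote")
        with pytest.raises(ValueError):
            PhasedGenotype("i1", "m", ("AC", "AG"), "homozygote")
        with pytest.raises(ValueError):
            PhasedGenotype("i1", "m", ("AC", "AC"), "clark")

    def test_unresolved_carries_no_pair(self):
        PhasedGenotype("i1", "m", None, "unresolved")
        with pytest.raises(ValueError):
            PhasedGenotype("i1", "m", ("AC", "AG"), "unresolved")


class TestPhaseDataset:
    def test_homozygotes_only(self):
        reads = {
            f"i{n}": {"forward": MixedRead.from_iupac("ACGTT")} for n in range(3)
        }
        phased = phase_dataset(reads)
        assert all(g.route == "homozygote" for g in phased)

    def test_every_individual_appears_once_with_route(self, small_dataset):
        phased = phase_dataset(small_dataset.reads)
        assert sorted(g.individual_id for g in phased) == sorted(
            i.id for i in small_dataset.individuals
        )

    def test_simulation_truth_recovered(self, small_dataset):
        ds = small_dataset
        truth = {
            ind.id: tuple(sorted(ds.catalogue[a].seq for a in ind.allele_ids))
            for ind in ds.individuals
        }
        phased = phase_dataset(ds.reads)
        for g in phased:
            assert g.haplotypes is not None, g
            assert tuple(sorted(g.haplotypes)) == truth[g.individual_id]

    def test_full_heights_phase_everything(self):
        ds = simulate_dataset(SimulationConfig(seed=9, amplification_bias=0.8))
        phased = phase_dataset(ds.reads)
        truth = {
            ind.id: tuple(sorted(ds.catalogue[a].seq for a in ind.allele_ids))
            for ind in ds.individuals
        }
        assert all(g.haplotypes is not None for g in phased)
        assert all(tuple(sorted(g.haplotypes)) == truth[g.individual_id] for g in phased)

    def test_round_trip_reproduces_reads(self, small_dataset):
        """Re-superposing every phased pair reproduces the observed reads."""
        phased = phase_dataset(small_dataset.reads)
        for g in phased:
            a, b = g.haplotypes
            for h1, h2 in ((a, b), (b, a)):
                fwd, rev = superpose(h1, h2)
                obs = small_dataset.reads[g.individual_id]
                if fwd.sets == obs["forward"].sets and rev.sets == obs["reverse"].sets:
                    break
            else:
                raise AssertionError(f"{g.individual_id}: no orientation matches")

    def test_orphan_genotype_unresolved(self):
        # two heterozygotes share an allele; the third shares nothing and
        # cannot be reached by Clark's subtraction
        reads = {
            "i1": {"forward": MixedRead.from_iupac("AAAA")},
            "i2": {"forward": MixedRead.from_iupac("ARAA")},
            "i3": {"forward": MixedRead.from_iupac("TTYY")},
        }
        phased = {g.individual_id: g for g in phase_dataset(reads)}
        assert phased["i2"].haplotypes is not None
        assert phased["i3"].route == "unresolved"
        assert phased["i3"].haplotypes is None
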