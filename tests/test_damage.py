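"""Briggs-model damage simulator: unit, distributional, and contract tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from adnaplace.damage import (
    FIVE_PRIME,
    THREE_PRIME,
    DamageParameters,
    DamagedRead,
    ReadFilters,
    SimulationError,
    apply_deamination,
    damage_sequence,
    filter_reads,
    fragment_at_nicks,
    mark_nicks,
    reads_to_records,
    sample_overhang,
    simulate,
)
from adnaplace.fixtures import random_sequence
from adnaplace.io import Alignment, SequenceRecord, write_damage_log, write_fasta


def _read(residues, start=0, events=(), read_id="r", source_id="s"):
    return DamagedRead(
        read_id=read_id, source_id=source_id, start=start,
        end=start + len(residues), residues=residues,
        overhang_side=FIVE_PRIME, overhang_length=0, events=list(events),
    )


# --------------------------------------------------------------------- #
# nicking


class TestMarkNicks:
    def test_zero_rate_marks_nothing(self, rng):
        assert mark_nicks("ACGTACGT", 0.0, rng) == []

    def test_rate_one_marks_every_junction(self, rng):
        assert mark_nicks("ACGTA", 1.0, rng) == [0, 1, 2, 3]

    def test_gap_columns_carry_no_junctions(self, rng):
        # 3 non-gap residues -> only 2 junctions regardless of gaps
        nicks = mark_nicks("A--C-G", 1.0, rng)
        assert nicks == [0, 1]

    def test_empirical_rate_matches_nu(self, rng):
        nu = 0.01
        n_junctions = 100_000
        nicks = mark_nicks("A" * (n_junctions + 1), nu, rng)
        rate = len(nicks) / n_junctions
        se = np.sqrt(nu * (1 - nu) / n_junctions)
        assert abs(rate - nu) < 3 * se


class TestFragmentAtNicks:
    def test_no_nicks_whole_sequence(self):
        assert fragment_at_nicks("ACGTAC", []) == [(0, 6)]

    def test_example_cuts(self):
        spans = fragment_at_nicks("ACGTAC", [1, 3])
        assert ["ACGTAC"[a:b] for a, b in spans] == ["AC", "GT", "AC"]

    def test_gaps_stay_with_preceding_fragment(self):
        spans = fragment_at_nicks("AC--GT", [1])
        assert ["AC--GT"[a:b] for a, b in spans] == ["AC--", "GT"]

    @settings(deadline=None, max_examples=100)
    @given(data=st.data(),
           residues=st.text(alphabet="ACGT-", min_size=1, max_size=60))
    def test_fragments_tile_the_source(self, data, residues):
        n_nongap = len(residues) - residues.count("-")
        junctions = max(0, n_nongap - 1)
        nicks = sorted(
            data.draw(
                st.sets(st.integers(0, junctions - 1), max_size=junctions)
            )
        ) if junctions else []
        spans = fragment_at_nicks(residues, nicks)
        assert "".join(residues[a:b] for a, b in spans) == residues
        starts = [a for a, _ in spans]
        assert starts == sorted(starts)


# --------------------------------------------------------------------- #
# overhang sampling


class TestSampleOverhang:
    def test_lam_one_always_zero_length(self, rng):
        assert all(sample_overhang(1.0, rng)[1] == 0 for _ in range(200))

    def test_invalid_lam_rejected(self, rng):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                sample_overhang(bad, rng)

    def test_mean_length_matches_geometric(self, rng):
        lam = 0.5
        n = 100_000
        lengths = np.array([sample_overhang(lam, rng)[1] for _ in range(n)])
        expected_mean = (1 - lam) / lam
        se = np.sqrt((1 - lam) / lam**2 / n)
        assert abs(lengths.mean() - expected_mean) < 3 * se

    def test_side_balance(self, rng):
        n = 100_000
        sides = [sample_overhang(0.3, rng)[0] for _ in range(n)]
        frac = sides.count(FIVE_PRIME) / n
        se = np.sqrt(0.25 / n)
        assert abs(frac - 0.5) < 3 * se

    def test_length_distribution_chi_square(self, rng):
        lam = 0.3
        n = 100_000
        lengths = np.array([sample_overhang(lam, rng)[1] for _ in range(n)])
        kmax = 14  # pool the tail so expected counts stay large
        observed = np.bincount(np.minimum(lengths, kmax), minlength=kmax + 1)
        pmf = (1 - lam) ** np.arange(kmax + 1) * lam
        pmf[kmax] = (1 - lam) ** kmax  # tail mass P(L >= kmax)
        chi2, p = sps.chisquare(observed, n * pmf)
        assert p > 0.001


# --------------------------------------------------------------------- #
# deamination


class TestApplyDeamination:
    def test_zero_rates_change_nothing(self, rng):
        out, events = apply_deamination("CCGG", FIVE_PRIME, 2, 0.0, 0.0, rng)
        assert out == "CCGG" and events == []

    def test_five_prime_overhang_forced_flips(self, rng):
        out, events = apply_deamination("CCCC", FIVE_PRIME, 2, 1.0, 0.0, rng)
        assert out == "TTCC"
        assert [(e.position, e.region) for e in events] == [
            (0, "single_stranded"), (1, "single_stranded")]
        assert {e.kind for e in events} == {"C_to_T"}

    def test_g_untouched_on_five_prime_read(self, rng):
        out, _ = apply_deamination("ACGT", FIVE_PRIME, 4, 1.0, 1.0, rng)
        assert out == "ATGT"

    def test_three_prime_mirror(self, rng):
        out, events = apply_deamination("GGGG", THREE_PRIME, 1, 1.0, 0.0, rng)
        assert out == "GGGA"
        assert events[0].kind == "G_to_A"
        assert events[0].region == "single_stranded"

    def test_gaps_and_ambiguity_never_flip(self, rng):
        out, _ = apply_deamination("C-N-C", FIVE_PRIME, 5, 1.0, 1.0, rng)
        assert out == "T-N-T"

    def test_case_preserved(self, rng):
        out, _ = apply_deamination("cC", FIVE_PRIME, 2, 1.0, 0.0, rng)
        assert out == "tT"

    def test_overhang_counted_in_nongap_residues(self, rng):
        # L=1 covers the first non-gap residue, past any leading gaps
        out, _ = apply_deamination("--CC", FIVE_PRIME, 1, 1.0, 0.0, rng)
        assert out == "--TC"

    def test_negative_overhang_rejected(self, rng):
        with pytest.raises(ValueError):
            apply_deamination("CC", FIVE_PRIME, -1, 0.5, 0.5, rng)

    def test_region_rates_recovered(self, rng):
        delta_ss, delta_ds = 0.3, 0.05
        n = 100_000
        out, events = apply_deamination(
            "C" * n, FIVE_PRIME, n // 2, delta_ss, delta_ds, rng
        )
        ss = sum(1 for e in events if e.region == "single_stranded")
        ds = len(events) - ss
        half = n // 2
        for count, rate in ((ss, delta_ss), (ds, delta_ds)):
            se = np.sqrt(rate * (1 - rate) / half)
            assert abs(count / half - rate) < 3 * se


# --------------------------------------------------------------------- #
# full pass over one sequence


class TestDamageSequence:
    def test_no_damage_identity(self, rng):
        rec = SequenceRecord("s", "ACGTACGTAA")
        reads = damage_sequence(rec, DamageParameters.no_damage(), rng)
        assert len(reads) == 1
        assert reads[0].residues == rec.residues
        assert reads[0].events == []

    def test_empty_record_rejected(self, rng):
        with pytest.raises(SimulationError, match="empty"):
            damage_sequence(SequenceRecord("s", ""),
                            DamageParameters.no_damage(), rng)

    def test_reads_differ_from_source_only_at_events(self, rng):
        rec = random_sequence(5000, 0.5, rng, "s")
        params = DamageParameters(nu=0.02, lam=0.3, delta_ss=0.6, delta_ds=0.02)
        for read in damage_sequence(rec, params, rng):
            source = rec.residues[read.start:read.end]
            diffs = {i for i, (a, b) in enumerate(zip(source, read.residues))
                     if a != b}
            assert diffs == {e.position for e in read.events}

    def test_undamaging_reads_restores_source(self, rng):
        rec = random_sequence(3000, 0.5, rng, "s")
        params = DamageParameters(nu=0.03, lam=0.2, delta_ss=0.8, delta_ds=0.05)
        reads = damage_sequence(rec, params, rng)
        pieces = []
        for read in sorted(reads, key=lambda r: r.start):
            chars = list(read.residues)
            for ev in read.events:
                chars[ev.position] = {"C_to_T": "C", "G_to_A": "G"}[ev.kind]
            pieces.append("".join(chars))
        assert "".join(pieces) == rec.residues

    def test_single_damage_kind_per_read(self, rng):
        rec = random_sequence(20_000, 0.5, rng, "s")
        params = DamageParameters(nu=0.02, lam=0.2, delta_ss=0.9, delta_ds=0.1)
        for read in damage_sequence(rec, params, rng):
            kinds = {e.kind for e in read.events}
            assert len(kinds) <= 1
            if kinds:
                expected = "C_to_T" if read.overhang_side == FIVE_PRIME else "G_to_A"
                assert kinds == {expected}

    def test_reads_never_exceed_source_length(self, rng):
        rec = random_sequence(500, 0.5, rng, "s")
        params = DamageParameters(nu=0.05, lam=0.15, delta_ss=0.5, delta_ds=0.01)
        for read in damage_sequence(rec, params, rng):
            assert read.end - read.start == len(read.residues)
            assert len(read.residues) <= len(rec.residues)
            assert read.overhang_length <= read.nongap_length

    def test_interior_fragment_lengths_geometric(self, rng):
        nu = 0.02
        rec = random_sequence(300_000, 0.5, rng, "s")
        reads = damage_sequence(rec, DamageParameters(nu, 1.0, 0.0, 0.0), rng)
        interior = np.array([r.nongap_length for r in reads[1:-1]])
        assert interior.size > 100
        kmax = 300
        observed = np.bincount(np.minimum(interior, kmax), minlength=kmax + 1)[1:]
        k = np.arange(1, kmax + 1)
        pmf = (1 - nu) ** (k - 1) * nu
        pmf[-1] = (1 - nu) ** (kmax - 1)  # tail mass
        chi2, p = sps.chisquare(observed, interior.size * pmf)
        assert p > 0.001


# --------------------------------------------------------------------- #
# filters


class TestFilterReads:
    def test_all_gap_or_ambiguous_removed(self):
        kept = filter_reads([_read("---N--")], ReadFilters.none())
        assert kept == []

    def test_nongap_length_counted(self):
        filters = ReadFilters(min_length=3, min_reads=0)
        assert filter_reads([_read("A--C")], filters) == []
        assert len(filter_reads([_read("A-GC")], filters)) == 1

    def test_premask_rejects_disjoint_read(self):
        reference = Alignment([SequenceRecord("ref", "AAAA----")])
        overlapping = _read("CC", start=2)
        disjoint = _read("CC", start=5)
        kept = filter_reads([overlapping, disjoint], ReadFilters.none(),
                            reference=reference)
        assert [r.start for r in kept] == [2]

    def test_downsample_exact_count(self, rng):
        reads = [_read("ACGT", read_id=f"r{i}") for i in range(50)]
        filters = ReadFilters(min_length=0, min_reads=0, max_reads=10)
        kept = filter_reads(reads, filters, rng=rng)
        assert len(kept) == 10

    def test_downsample_uniform(self, rng):
        reads = [_read("ACGT", read_id=f"r{i}") for i in range(50)]
        filters = ReadFilters(min_length=0, min_reads=0, max_reads=10)
        counts = np.zeros(50)
        reps = 10_000
        for _ in range(reps):
            for r in filter_reads(reads, filters, rng=rng):
                counts[int(r.read_id[1:])] += 1
        expected = reps * 10 / 50
        chi2, p = sps.chisquare(counts, expected)
        assert p > 0.001


# --------------------------------------------------------------------- #
# the full loop


class TestSimulate:
    def test_min_reads_accumulation(self, rng):
        rec = random_sequence(2000, 0.4, rng, "s")
        params = DamageParameters(nu=0.001, lam=1.0, delta_ss=0.0, delta_ds=0.0)
        reads, _ = simulate([rec], params, ReadFilters(), seed=5)
        assert len(reads) >= 10

    def test_min_length_enforced(self, rng):
        rec = random_sequence(50_000, 0.4, rng, "s")
        params = DamageParameters(nu=0.03, lam=0.15, delta_ss=0.65, delta_ds=0.015)
        reads, _ = simulate([rec], params, ReadFilters(), seed=6)
        assert min(r.nongap_length for r in reads) >= 15

    def test_max_reads_downsamples(self, rng):
        rec = random_sequence(50_000, 0.4, rng, "s")
        params = DamageParameters(nu=0.02, lam=1.0, delta_ss=0.0, delta_ds=0.0)
        reads, _ = simulate([rec], params,
                            ReadFilters(min_length=15, min_reads=10, max_reads=20),
                            seed=6)
        assert len(reads) == 20

    def test_same_seed_byte_identical_outputs(self, rng):
        rec = random_sequence(5000, 0.5, rng, "s")
        params = DamageParameters(nu=0.01, lam=0.3, delta_ss=0.5, delta_ds=0.02)
        outputs = []
        for _ in range(2):
            reads, _ = simulate([rec], params, ReadFilters(), seed=42)
            fasta = write_fasta(reads_to_records(reads, aligned=True,
                                                 source_length=5000))
            outputs.append((fasta, write_damage_log(reads)))
        assert outputs[0] == outputs[1]

    def test_unsurvivable_source_raises_naming_it(self):
        rec = SequenceRecord("gappy", "-" * 30)
        params = DamageParameters.no_damage()
        filters = ReadFilters(min_length=1, min_reads=1, max_accumulation_passes=5)
        with pytest.raises(SimulationError, match="gappy"):
            simulate([rec], params, filters, seed=1)

    def test_accumulation_bound_with_survivors_warns(self, rng):
        # one read per pass (nu=0), min_reads unattainable within the bound
        rec = random_sequence(100, 0.5, rng, "s")
        params = DamageParameters.no_damage()
        filters = ReadFilters(min_length=0, min_reads=10,
                              max_accumulation_passes=3)
        with pytest.warns(UserWarning, match="accumulation"):
            reads, _ = simulate([rec], params, filters, seed=1)
        assert len(reads) == 3

    def test_aligned_records_preserve_columns(self, rng):
        rec = random_sequence(1000, 0.5, rng, "s")
        params = DamageParameters(nu=0.01, lam=1.0, delta_ss=0.0, delta_ds=0.0)
        reads, _ = simulate([rec], params, ReadFilters.none(), seed=9)
        for padded in reads_to_records(reads, aligned=True, source_length=1000):
            assert len(padded.residues) == 1000
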