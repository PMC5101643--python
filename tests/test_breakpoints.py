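"""Breakpoint analysis: repeat search, painting, switches, conversions."""

import itertools

import numpy as np
import pytest

from athcnv import breakpoints as bp
from athcnv.breakpoints import JunctionPainting, PaintingError
from athcnv.locus import psv_intervals
from athcnv.simulate import (
    EXTENSION_BP,
    MICROHOMOLOGY_BP,
    AccessionProfile,
    simulate_junction_amplicon,
    simulate_reference,
)

BASES = np.array(list("ACGT"))


def random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(BASES[rng.integers(0, 4, n)])


def reference_flanks(ref, locus, side, k=30):
    region, lcr = locus.region, locus.lcr

    def seg(a, b):
        return ref[a - region.start: b - region.start + 1]

    if side == "up":
        return (seg(lcr.left.start - k, lcr.left.start - 1),
                seg(lcr.right.start - k, lcr.right.start - 1))
    return (seg(lcr.left.end + 1, lcr.left.end + k),
            seg(lcr.right.end + 1, lcr.right.end + k))


def paint(ref, locus, prof, jtype, seq=None):
    seq = seq or simulate_junction_amplicon(prof, ref, locus)
    return bp.paint_junction(
        seq, locus.lcr, junction_type=jtype,
        flank_upstream_seqs=reference_flanks(ref, locus, "up"),
        flank_downstream_seqs=reference_flanks(ref, locus, "down"),
    )


class TestFindRepeats:
    def test_planted_lcr_pair_found_exactly(self, reference_and_locus):
        ref, locus = reference_and_locus
        hits = bp.find_repeats(
            ref, chrom=locus.region.chrom, origin=locus.region.start
        )
        assert len(hits) == 1
        h = hits[0]
        assert h.orientation == "direct"
        assert h.percent_identity >= 99.0
        for found, truth in (
            (h.interval_a, locus.lcr.left), (h.interval_b, locus.lcr.right)
        ):
            overlap = (
                min(found.end, truth.end) - max(found.start, truth.start) + 1
            )
            assert overlap / truth.length >= 0.9
            assert overlap / found.length >= 0.9

    def test_repeat_free_sequence_yields_nothing(self):
        assert bp.find_repeats(random_seq(25000, seed=7)) == []

    def test_two_exact_copies_give_full_identity_hit(self):
        block = random_seq(1000, seed=9)
        spacer = random_seq(3000, seed=10)
        seq = random_seq(500, 11) + block + spacer + block + random_seq(500, 12)
        hits = bp.find_repeats(seq)
        assert len(hits) == 1
        assert hits[0].percent_identity == 100.0
        assert hits[0].interval_a.length >= 1000

    def test_inverted_repeat_detected(self):
        block = random_seq(800, seed=13)
        rc = block.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq = random_seq(400, 14) + block + random_seq(2000, 15) + rc
        hits = bp.find_repeats(seq, min_length=500)
        assert any(h.orientation == "inverted" for h in hits)

    def test_short_sequence_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert bp.find_repeats(random_seq(500, seed=16)) == []

    def test_detection_robust_across_seeds(self):
        # planted 1238-bp/11-PSV repeats are always recovered
        for seed in range(10):
            ref, locus = simulate_reference(seed=seed)
            hits = bp.find_repeats(
                ref, chrom=locus.region.chrom, origin=locus.region.start
            )
            assert len(hits) == 1, f"seed {seed}"


class TestPaintJunction:
    def test_verbatim_left_lcr_paints_all_left(self, reference_and_locus):
        _, locus = reference_and_locus
        painting = bp.paint_junction(locus.lcr.left_seq(), locus.lcr)
        assert painting.calls == "L" * 11

    def test_verbatim_right_lcr_paints_all_right(self, reference_and_locus):
        _, locus = reference_and_locus
        painting = bp.paint_junction(locus.lcr.right_seq(), locus.lcr)
        assert painting.calls == "R" * 11

    def test_deletion_junction_first_interval_all_right(
        self, reference_and_locus
    ):
        ref, locus = reference_and_locus
        prof = AccessionProfile("d", "del-2", 2, 0, breakpoint_interval=1)
        painting = paint(ref, locus, prof, "deletion")
        assert painting.calls == "R" * 11
        assert painting.flank_upstream == "L"
        assert painting.flank_downstream == "R"

    def test_unpaintable_junction_raises(self, reference_and_locus):
        _, locus = reference_and_locus
        with pytest.raises(PaintingError):
            bp.paint_junction(random_seq(1500, seed=23), locus.lcr)

    def test_tolerates_scattered_substitutions(self, reference_and_locus):
        # single substitutions outside PSV contexts must not break calls
        ref, locus = reference_and_locus
        prof = AccessionProfile("d", "del-2", 2, 0, breakpoint_interval=1)
        seq = list(simulate_junction_amplicon(prof, ref, locus))
        rng = np.random.default_rng(31)
        protected = set()
        flank = 300  # amplicon flank used by the generator
        for p in locus.lcr.psv_positions:
            protected.update(range(flank + p - 9, flank + p + 8))
        n_sub = int(0.005 * len(seq))
        sites = [i for i in range(len(seq)) if i not in protected]
        for i in rng.choice(sites, size=n_sub, replace=False):
            seq[i] = "ACGT"[(("ACGT".index(seq[i])) + 1) % 4]
        painting = paint(ref, locus, prof, "deletion", seq="".join(seq))
        assert painting.calls.count("X") <= 1
        assert set(painting.calls) <= {"R", "X"}


class TestLocateBreakpoint:
    def test_recovery_over_all_intervals_both_types(
        self, reference_and_locus
    ):
        ref, locus = reference_and_locus
        n_int = len(psv_intervals(locus.lcr))
        for i in range(1, n_int + 1):
            for pattern, jtype, cn in (
                ("del-2", "deletion", 0), ("dupl-2", "duplication", 4)
            ):
                prof = AccessionProfile(
                    "s", pattern, 2, cn, breakpoint_interval=i
                )
                painting = paint(ref, locus, prof, jtype)
                iv = bp.locate_breakpoint(painting, locus.lcr)
                assert bp.switch_interval_index(iv, locus.lcr) == i

    def test_reciprocity_of_deletion_and_duplication(
        self, reference_and_locus
    ):
        # the double-Holliday-junction crossover predicts the same switch
        # interval from both reciprocal products
        ref, locus = reference_and_locus
        for i in (1, 2, 6, 12):
            d = AccessionProfile("d", "del-2", 2, 0, breakpoint_interval=i)
            u = AccessionProfile("u", "dupl-2", 2, 4, breakpoint_interval=i)
            iv_d = bp.locate_breakpoint(
                paint(ref, locus, d, "deletion"), locus.lcr
            )
            iv_u = bp.locate_breakpoint(
                paint(ref, locus, u, "duplication"), locus.lcr
            )
            assert iv_d == iv_u

    def test_published_interval_bounds(self, reference_and_locus):
        # deletion switches in the first interval, duplication in the second
        ref, locus = reference_and_locus
        d = AccessionProfile("d", "del-2", 2, 0, breakpoint_interval=1)
        u = AccessionProfile("u", "dupl-2", 2, 4, breakpoint_interval=2)
        iv_d = bp.locate_breakpoint(
            paint(ref, locus, d, "deletion"), locus.lcr
        )
        iv_u = bp.locate_breakpoint(
            paint(ref, locus, u, "duplication"), locus.lcr
        )
        assert iv_d == (1, 231)
        assert iv_u == (231, 769)

    def test_non_recombinant_repeat_rejected(self, reference_and_locus):
        ref, locus = reference_and_locus
        lcr = locus.lcr
        region = locus.region
        up = ref[lcr.left.start - 300 - region.start: lcr.left.start - region.start]
        down = ref[lcr.left.end + 1 - region.start: lcr.left.end + 301 - region.start]
        plain_left = up + lcr.left_seq() + down
        painting = bp.paint_junction(
            plain_left, lcr, junction_type="deletion",
            flank_upstream_seqs=reference_flanks(ref, locus, "up"),
            flank_downstream_seqs=reference_flanks(ref, locus, "down"),
        )
        assert painting.calls == "L" * 11
        with pytest.raises(ValueError, match="no recombinant"):
            bp.locate_breakpoint(painting, lcr)

    def test_breakpoint_recovery_with_substitution_noise(
        self, reference_and_locus
    ):
        ref, locus = reference_and_locus
        rng = np.random.default_rng(41)
        n_ok = 0
        n_total = 24
        flank = 300
        protected = set()
        for p in locus.lcr.psv_positions:
            protected.update(range(flank + p - 9, flank + p + 8))
        for trial in range(n_total):
            i = trial % 12 + 1
            prof = AccessionProfile("s", "del-2", 2, 0, breakpoint_interval=i)
            seq = list(simulate_junction_amplicon(prof, ref, locus))
            sites = [k for k in range(len(seq)) if k not in protected]
            for k in rng.choice(sites, size=int(0.005 * len(seq)),
                                replace=False):
                seq[k] = "ACGT"[("ACGT".index(seq[k]) + 1) % 4]
            try:
                painting = paint(ref, locus, prof, "deletion",
                                 seq="".join(seq))
                iv = bp.locate_breakpoint(painting, locus.lcr)
                if bp.switch_interval_index(iv, locus.lcr) == i:
                    n_ok += 1
            except (PaintingError, ValueError):
                pass
        assert n_ok / n_total >= 0.95


class TestConversions:
    def test_monotone_vector_has_no_conversions(self):
        p = JunctionPainting("j", "LLLRRRRRRRR", junction_type="deletion")
        assert bp.detect_conversions(p) == ()

    def test_single_isolated_site(self):
        p = JunctionPainting("j", "LLRLRRRRRRR", junction_type="deletion")
        sites = bp.detect_conversions(p)
        assert len(sites) == 1
        assert sites[0] in (3, 4)

    def test_alternating_vector_needs_five_flips(self):
        calls = "".join("LR"[i % 2] for i in range(11))
        p = JunctionPainting("j", calls)
        assert len(bp.detect_conversions(p)) == 5
        assert bp.minimal_flip_bruteforce(calls) == 5

    def test_masking_recovers_simulated_conversion(self, reference_and_locus):
        ref, locus = reference_and_locus
        prof = AccessionProfile(
            "c", "del-2", 2, 0, breakpoint_interval=1, conversion_sites=(5,)
        )
        painting = paint(ref, locus, prof, "deletion")
        iv = bp.locate_breakpoint(painting, locus.lcr)
        assert painting.conversion_sites == (5,)
        assert bp.switch_interval_index(iv, locus.lcr) == 1

    def test_agrees_with_bruteforce_on_all_eleven_site_vectors(self):
        # exhaustive: every L/R call vector over the 11 PSVs
        for vec in itertools.product("LR", repeat=11):
            calls = "".join(vec)
            p = JunctionPainting("j", calls, junction_type="deletion")
            got = len(bp.detect_conversions(p))
            expected = bp.minimal_flip_bruteforce(calls, "deletion")
            assert got == expected, calls


class TestDsbRegion:
    def test_published_union_span(self):
        assert bp.infer_dsb_region([(1, 231)], [(231, 769)]) == (1, 769)

    def test_identical_intervals(self):
        assert bp.infer_dsb_region([(231, 769)], [(231, 769)]) == (231, 769)

    def test_max_span_arithmetic(self):
        got = bp.infer_dsb_region(
            [(1, 231), (1, 231)], [(231, 769), (769, 900)]
        )
        assert got == (1, 900)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            bp.infer_dsb_region([], [(231, 769)])


class TestMicrohomology:
    def test_planted_extension_junction_has_nine_bases(
        self, reference_and_locus
    ):
        ref, locus = reference_and_locus
        region, lcr = locus.region, locus.lcr
        ext = ref[
            lcr.right.end + 1 - region.start:
            lcr.right.end + EXTENSION_BP + 1 - region.start
        ]
        resume = ref[lcr.left.end - MICROHOMOLOGY_BP + 1 - region.start:]
        assert bp.detect_microhomology(ext, resume[:60]) == MICROHOMOLOGY_BP

    def test_unrelated_sequences_share_almost_nothing(self):
        assert bp.detect_microhomology(
            random_seq(100, 51), random_seq(100, 52)
        ) <= 3

    def test_identical_twenty_mers(self):
        s = random_seq(20, 53)
        assert bp.detect_microhomology(s, s) == 20

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            bp.detect_microhomology("ACGT", "ACGT")
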