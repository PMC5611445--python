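import itertools

import numpy as np
import pytest

from regelscreen.homology_screen import (
    DotPlotParams,
    PresenceState,
    annotate_element_by_homology,
    call_element_presence,
    compute_dotplot,
    extract_diagonal_segments,
    global_align,
    identity_track,
    percent_identity,
)
from regelscreen.seq_model import ElementDefinition, ElementID, UpstreamRegion

from conftest import random_dna


def brute_force_hits(a, b, params):
    """Independent oracle: score every window pair with explicit loops."""
    w, half = params.window, params.window // 2
    hits = set()
    for i in range(len(a) - w + 1):
        for j in range(len(b) - w + 1):
            score = 0
            for k in range(w):
                x, y = a[i + k], b[j + k]
                if x == y and x != "N":
                    score += params.match_score
                else:
                    score += params.mismatch_score
            if score >= params.threshold:
                hits.add((i + half, j + half))
    return hits


class TestDotPlot:
    def test_min_matching_bases_at_default_scoring(self):
        # 5m - 4(25 - m) >= 45  =>  m >= 16.1, i.e. 17 identical bases
        assert DotPlotParams().min_matches_per_window() == 17

    def test_window_with_17_matches_hits_16_does_not(self):
        w = 25
        a = "A" * w
        hit16 = "A" * 16 + "C" * 9
        hit17 = "A" * 17 + "C" * 8
        params = DotPlotParams()
        assert not compute_dotplot(a, hit16, params).hits
        assert compute_dotplot(a, hit17, params).hits

    def test_self_comparison_hits_full_main_diagonal(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 200)
        plot = compute_dotplot(seq, seq)
        half = 25 // 2
        diag = {(i + half, i + half) for i in range(200 - 25 + 1)}
        assert diag <= plot.hits

    def test_short_sequence_gives_empty_plot(self):
        plot = compute_dotplot("ACGT", "ACGT")
        assert not plot.hits

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        # permissive threshold so random pairs also produce hits
        params = DotPlotParams(window=11, threshold=5, match_score=5,
                               mismatch_score=-4)
        a, b = random_dna(rng, 90), random_dna(rng, 70)
        plot = compute_dotplot(a, b, params)
        assert plot.hits == brute_force_hits(a, b, params)

    def test_n_counts_as_mismatch_even_against_n(self):
        params = DotPlotParams(window=5, threshold=25)
        assert compute_dotplot("ACGTA", "ACGTA", params).hits
        assert not compute_dotplot("ACGNA", "ACGNA", params).hits

    def test_raising_threshold_never_adds_hits(self):
        rng = np.random.default_rng(7)
        a, b = random_dna(rng, 150), random_dna(rng, 150)
        lo = compute_dotplot(a, b, DotPlotParams(window=15, threshold=20)).hits
        hi = compute_dotplot(a, b, DotPlotParams(window=15, threshold=40)).hits
        assert hi <= lo


class TestDiagonalSegments:
    def test_self_comparison_yields_full_length_segment(self):
        rng = np.random.default_rng(2)
        seq = random_dna(rng, 300)
        segs = extract_diagonal_segments(compute_dotplot(seq, seq))
        top = segs[0]
        assert top.length == 300 and top.start_a == 0 and top.diagonal == 0

    def test_gap_beyond_tolerance_splits_segment(self):
        params = DotPlotParams(window=25, threshold=45)
        plot_hits = frozenset({(50, 50), (200, 200)})
        from regelscreen.homology_screen import DotPlot

        plot = DotPlot(params, plot_hits, (300, 300))
        segs = extract_diagonal_segments(plot, max_gap=25)
        assert len(segs) == 2
        merged = extract_diagonal_segments(plot, max_gap=200)
        assert len(merged) == 1 and merged[0].length == 200 - 50 + 25

    def test_shared_block_recovered(self):
        rng = np.random.default_rng(3)
        block = random_dna(rng, 150)
        a = random_dna(rng, 100) + block + random_dna(rng, 100)
        b = random_dna(rng, 40) + block + random_dna(rng, 60)
        segs = extract_diagonal_segments(compute_dotplot(a, b))
        assert segs[0].length >= 150


def make_region(seq_5to3_ending_at_atg: str, species="sp") -> UpstreamRegion:
    return UpstreamRegion(species, seq_5to3_ending_at_atg,
                          len(seq_5to3_ending_at_atg))


class TestPresenceCalling:
    def element(self, rng, length=200, window=(-4000, -3800)):
        return ElementDefinition(
            ElementID.enhancer, "ref", random_dna(rng, length), window
        )

    def build_query(self, rng, ref, insert_at=-4000, upstream=6000,
                    insert=None):
        insert = ref.reference_sequence if insert is None else insert
        seq = list(random_dna(rng, upstream))
        lo = insert_at + upstream
        seq[lo : lo + len(insert)] = insert
        return make_region("".join(seq))

    def test_verbatim_element_called_present(self):
        rng = np.random.default_rng(4)
        ref = self.element(rng)
        call = call_element_presence(self.build_query(rng, ref), ref)
        assert call.state is PresenceState.present
        lo, hi = call.located_interval
        assert lo <= -4000 and hi >= -3800

    def test_block_at_threshold_length_called_absent(self):
        # a 90 bp conserved block fails the > 100 bp rule
        rng = np.random.default_rng(5)
        ref = self.element(rng)
        call = call_element_presence(
            self.build_query(rng, ref, insert=ref.reference_sequence[:90]),
            ref,
        )
        assert call.state is PresenceState.absent

    def test_short_contig_called_no_coverage(self):
        # contig extending only ~1 kb upstream cannot rule on a -4 kb element
        rng = np.random.default_rng(6)
        ref = self.element(rng)
        call = call_element_presence(make_region(random_dna(rng, 1000)), ref)
        assert call.state is PresenceState.no_coverage

    def test_region_built_from_element_is_present(self):
        rng = np.random.default_rng(7)
        ref = self.element(rng)
        assert (
            call_element_presence(self.build_query(rng, ref), ref).state
            is PresenceState.present
        )

    def test_raising_min_conserved_never_converts_absent_to_present(self):
        rng = np.random.default_rng(8)
        ref = self.element(rng)
        q = self.build_query(rng, ref, insert=ref.reference_sequence[:120])
        states = [
            call_element_presence(q, ref, min_conserved_length=m).state
            for m in (50, 100, 150, 250)
        ]
        seen_absent = False
        for st in states:
            if st is PresenceState.absent:
                seen_absent = True
            assert not (seen_absent and st is PresenceState.present)


class TestHomologyAnnotation:
    def setup_ref(self, rng):
        return ElementDefinition(
            ElementID.enhancer, "ref", random_dna(rng, 200), (-4000, -3800)
        )

    def mutate(self, rng, seq, n_mut):
        seq = list(seq)
        pos = rng.choice(len(seq), size=n_mut, replace=False)
        for i in pos:
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        return "".join(seq)

    def test_exact_copy_accepted_at_first_threshold(self):
        rng = np.random.default_rng(9)
        ref = self.setup_ref(rng)
        q = TestPresenceCalling().build_query(rng, ref)
        hit = annotate_element_by_homology(q, ref)
        assert hit is not None
        assert hit.accepted_at == 0.85 and hit.identity == 1.0

    def test_mutated_copy_accepted_only_at_matching_threshold(self):
        rng = np.random.default_rng(10)
        ref = self.setup_ref(rng)
        mutated = self.mutate(rng, ref.reference_sequence, 60)  # 70% identity
        q = TestPresenceCalling().build_query(rng, ref, insert=mutated)
        hit = annotate_element_by_homology(q, ref)
        assert hit is not None
        assert hit.accepted_at <= 0.70
        assert 0.60 <= hit.identity < 0.80

    def test_unrelated_sequence_rejected(self):
        rng = np.random.default_rng(11)
        ref = self.setup_ref(rng)
        q = make_region(random_dna(rng, 6000))
        assert annotate_element_by_homology(q, ref) is None

    def test_identity_nonincreasing_with_mutation_load(self):
        rng = np.random.default_rng(12)
        ref = self.setup_ref(rng)
        idents = []
        for n_mut in (0, 20, 40, 60):
            q = TestPresenceCalling().build_query(
                rng, ref, insert=self.mutate(rng, ref.reference_sequence, n_mut)
            )
            hit = annotate_element_by_homology(q, ref)
            idents.append(hit.identity if hit else 0.0)
        assert all(x >= y for x, y in zip(idents, idents[1:]))


def brute_force_global(a, b, match, mismatch, gap):
    """Exhaustive global alignment score over all monotone alignments
    (linear gap cost; tiny inputs only)."""
    best = -np.inf
    n, m = len(a), len(b)

    def rec(i, j, score):
        nonlocal best
        if i == n and j == m:
            best = max(best, score)
            return
        if i < n and j < m:
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s)
        if i < n:
            rec(i + 1, j, score + gap)
        if j < m:
            rec(i, j + 1, score + gap)

    rec(0, 0, 0)
    return best


class TestAlignmentUtilities:
    def test_identical_sequences_align_gapless(self):
        a, b = global_align("ACGTACGT", "ACGTACGT")
        assert a == b == "ACGTACGT"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "")

    @pytest.mark.parametrize(
        "x,y", [("ACGT", "ACT"), ("AAAC", "AAC"), ("GATTA", "GCTA")]
    )
    def test_score_matches_exhaustive_enumeration(self, x, y):
        # linear gaps: set open == extend so both scorers agree
        ra, rb = global_align(x, y, match=5, mismatch=-4, gap_open=-6,
                              gap_extend=-6)
        score = sum(
            5 if p == q else (-6 if "-" in (p, q) else -4)
            for p, q in zip(ra, rb)
        )
        assert score == brute_force_global(x, y, 5, -4, -6)

    def test_percent_identity_hand_count(self):
        assert percent_identity("AC-GT", "ACAGT") == pytest.approx(4 / 5)

    def test_percent_identity_bounds(self):
        assert percent_identity("AAAA", "AAAA") == 1.0
        assert percent_identity("AAAA", "CCCC") == 0.0

    def test_percent_identity_length_mismatch(self):
        with pytest.raises(ValueError):
            percent_identity("AC", "ACG")

    def test_identity_track_self_is_all_ones(self):
        rng = np.random.default_rng(13)
        seq = random_dna(rng, 400)
        track = identity_track(seq, seq, window=50, step=25)
        assert all(v == 1.0 for _, v in track)

    def test_identity_track_dips_over_mutated_block(self):
        rng = np.random.default_rng(14)
        seq = random_dna(rng, 600)
        mutated = seq[:250] + TestHomologyAnnotation().mutate(
            rng, seq[250:350], 60
        ) + seq[350:]
        track = identity_track(seq, mutated, window=100, step=50)
        values = dict(track)
        inside = min(v for p, v in track if 200 <= p <= 300)
        outside = min(v for p, v in track if p < 100 or p > 400)
        assert inside < 0.7 < outside

    def test_window_larger_than_alignment_collapses_to_overall_identity(self):
        a, b = "ACGTACGTA", "ACGTACCTA"
        track = identity_track(a, b, window=1000)
        ra, rb = global_align(a, b)
        assert track == [(0, percent_identity(ra, rb))]
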