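import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regelscreen.motif_catalog import (
    IUPAC,
    CoreRule,
    MotifState,
    Orientation,
    classify_motif_state,
    find_direct_repeat,
    iupac_match,
    load_default_catalog,
    reverse_complement_pattern,
    scan_species_motifs,
)
from regelscreen.reference_elements import ELEMENT_WINDOWS, build_templates
from regelscreen.seq_model import ElementID, UpstreamRegion, reverse_complement

from conftest import random_dna


def by_id(catalog, motif_id):
    return next(d for d in catalog if d.motif_id == motif_id)


class TestCatalogContent:
    def test_rare3_consensus(self, catalog):
        assert by_id(catalog, "RARE-3").consensus == "TGACCCTTTGGGGAT"

    def test_ppre_consensus(self, catalog):
        assert by_id(catalog, "PPRE-2").consensus == "GCAAACTTTC"

    def test_bre_critical_core_is_ttcc(self, catalog):
        for mid in ("BRE-1", "BRE-2"):
            d = by_id(catalog, mid)
            core = "".join(d.consensus[i] for i in sorted(d.critical_core))
            assert core == "TTCC"

    def test_cre_motifs_carry_the_cgtca_core(self, catalog):
        for mid in ("CRE-3", "CRE-2"):
            d = by_id(catalog, mid)
            core = "".join(d.consensus[i] for i in sorted(d.critical_core))
            assert core == "CGTCA"

    def test_motifs_without_mutagenesis_cannot_be_disrupted(self, catalog):
        for mid in ("GCCCCT-1", "GCCCCT-2", "GCCCCT-3", "CCAAT", "PPRE-2",
                    "NBRE"):
            assert by_id(catalog, mid).core_rule is CoreRule.none


class TestIupacMatch:
    def test_m_matches_a_and_c(self):
        for seq in ("AGGTCA", "AGGTAA"):
            hits = iupac_match("AGGTMA", seq)
            assert hits == [(0, "+", 0)]

    def test_cre_core_found_on_reverse_strand(self):
        # CGTCA reads TGACG on the forward strand
        seq = "TTTTGACGTTT"
        hits = iupac_match("CGTCA", seq, orientation=Orientation.both)
        assert ("-" in {h[1] for h in hits})

    def test_n_in_sequence_counts_as_mismatch(self):
        assert iupac_match("ACGT", "ACNT") == []
        assert iupac_match("ACGT", "ACNT", max_mismatch=1) == [(0, "+", 1)]

    def test_invalid_iupac_rejected(self):
        with pytest.raises(ValueError):
            iupac_match("ACGX", "ACGT")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_scan(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 500)
        pattern = "AGGTMA"

        def naive(pat):
            out = []
            for i in range(len(seq) - len(pat) + 1):
                mm = sum(
                    1
                    for p, s in zip(pat, seq[i : i + len(pat)])
                    if s == "N" or s not in IUPAC[p]
                )
                if mm <= 1:
                    out.append((i, mm))
            return out

        got = iupac_match(pattern, seq, max_mismatch=1,
                          orientation=Orientation.both)
        fwd = [(i, "+", mm) for i, mm in naive(pattern)]
        rev = [(i, "-", mm) for i, mm in
               naive(reverse_complement_pattern(pattern))]
        assert got == sorted(fwd + rev, key=lambda h: (h[0], h[1]))


class TestDirectRepeats:
    def test_perfect_dr1(self):
        for spacer_base in "ACGT":
            seq = "AGGTCA" + spacer_base + "AGGTCA"
            assert find_direct_repeat(seq, spacer=1) == [(0, 0, 0)]

    def test_ure1_is_degenerate_dr1_on_opposite_strand(self):
        # the murid URE1 reads as an imperfect AGGTCA direct repeat on its
        # reverse complement
        rc = reverse_complement("TCACCCTTGACCA")
        hits = find_direct_repeat(rc, spacer=1, max_mismatch_per_half=2)
        assert hits
        assert find_direct_repeat(rc, spacer=1, max_mismatch_per_half=0) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_dna(rng, 400)
        half, spacer, mm = "AGGTCA", 4, 2

        def naive():
            out = []
            L = len(half)
            for i in range(len(seq) - (2 * L + spacer) + 1):
                m1 = sum(1 for p, s in zip(half, seq[i : i + L])
                         if s not in IUPAC[p])
                m2 = sum(
                    1
                    for p, s in zip(half, seq[i + L + spacer : i + 2 * L + spacer])
                    if s not in IUPAC[p]
                )
                if m1 <= mm and m2 <= mm:
                    out.append((i, m1, m2))
            return out

        assert find_direct_repeat(seq, half, spacer, mm) == naive()


class TestClassification:
    def test_walrus_tata_variant_retains_at_richness(self, catalog):
        call = classify_motif_state("TAAATAA", by_id(catalog, "TATA"))
        assert call.state is MotifState.variant

    def test_gc_gain_in_tata_frame_disrupts(self, catalog):
        call = classify_motif_state("TACGTGA", by_id(catalog, "TATA"))
        assert call.state is MotifState.disrupted

    def test_ure1_nonbinding_mutant_disrupted(self, catalog):
        call = classify_motif_state("TCACAATTGACCA", by_id(catalog, "URE1_PPRE"))
        assert call.state is MotifState.disrupted
        call2 = classify_motif_state("TCACCCTAGACCA", by_id(catalog, "URE1_PPRE"))
        assert call2.state is MotifState.disrupted

    def test_bre_gtac_substitution_disrupted(self, catalog):
        call = classify_motif_state("GTAC", by_id(catalog, "BRE-1"))
        assert call.state is MotifState.disrupted

    def test_uptre_atttaa_mutant_disrupted(self, catalog):
        call = classify_motif_state("ATTTAA", by_id(catalog, "upTRE"))
        assert call.state is MotifState.disrupted

    def test_gap_majority_is_deleted(self, catalog):
        call = classify_motif_state("----AAA", by_id(catalog, "TATA"))
        assert call.state is MotifState.deleted

    def test_all_gaps_is_not_found(self, catalog):
        call = classify_motif_state("----", by_id(catalog, "BRE-1"))
        assert call.state is MotifState.not_found

    def test_non_core_mismatch_is_variant(self, catalog):
        d = by_id(catalog, "CRE-3")  # TKACGTCA, core CGTCA at 3..7
        call = classify_motif_state("AGACGTCA", d)
        assert call.state is MotifState.variant
        assert call.mismatch_positions and not call.core_mismatch_positions

    def test_gc_to_at_rule_ignores_gc_to_gc_changes(self, catalog):
        d = by_id(catalog, "RARE-3")  # TGACCCTTTGGGGAT
        swapped = "TGACGCTTTGGGGAT"  # C->G inside a half-site: not AT-ward
        assert classify_motif_state(swapped, d).state is MotifState.variant
        at_ward = "TGATCCTTTGGGGAT"  # C->T inside a half-site
        assert classify_motif_state(at_ward, d).state is MotifState.disrupted

    @given(st.text(alphabet="ACGTN-", min_size=7, max_size=7))
    @settings(max_examples=200, deadline=None)
    def test_total_function_over_observed_strings(self, observed):
        d = by_id(load_default_catalog(), "TATA")
        call = classify_motif_state(observed, d)
        assert call.state in MotifState
        # invariants of the call states
        if call.state is MotifState.intact:
            assert not call.mismatch_positions
        if call.state is MotifState.variant:
            assert call.mismatch_positions and not call.core_mismatch_positions
        if call.state is MotifState.disrupted:
            assert call.core_mismatch_positions


class TestSpeciesScan:
    def region_with(self, element, template, window):
        span = (-5000, 200)
        seq = list(random_dna(np.random.default_rng(0), span[1] - span[0],
                              gc=0.4))
        anchor = -span[0]
        seq[window[0] + anchor : window[1] + anchor] = template
        return UpstreamRegion("spX", "".join(seq), anchor)

    def test_consensus_built_element_scans_fully_intact(self, catalog,
                                                        templates):
        win = ELEMENT_WINDOWS[ElementID.enhancer]
        region = self.region_with("enhancer", templates[ElementID.enhancer],
                                  win)
        calls = scan_species_motifs(region, catalog, win, element="enhancer")
        assert calls and all(c.state is MotifState.intact for c in calls)

    def test_single_core_mutation_yields_one_disrupted_call(self, catalog,
                                                            templates):
        win = ELEMENT_WINDOWS[ElementID.enhancer]
        tpl = list(templates[ElementID.enhancer])
        d = by_id(catalog, "CRE-3")
        lo = d.expected_offset[0]
        # CGTCA -> CATCA at the CRE-3 core
        assert tpl[lo + 4] == "G"
        tpl[lo + 4] = "A"
        region = self.region_with("enhancer", "".join(tpl), win)
        calls = scan_species_motifs(region, catalog, win, element="enhancer")
        disrupted = [c for c in calls if c.state is MotifState.disrupted]
        assert [c.motif_id for c in disrupted] == ["CRE-3"]

    def test_region_without_coverage_gives_not_found(self, catalog):
        region = UpstreamRegion("spY", "ACGT" * 100, 400)
        calls = scan_species_motifs(region, catalog, (-4000, -3800),
                                    element="enhancer")
        assert calls and all(c.state is MotifState.not_found for c in calls)

    def test_overlapping_motifs_are_flagged(self, catalog, templates):
        win = ELEMENT_WINDOWS[ElementID.enhancer]
        region = self.region_with("enhancer", templates[ElementID.enhancer],
                                  win)
        calls = {c.motif_id: c for c in
                 scan_species_motifs(region, catalog, win, element="enhancer")}
        assert calls["URE1_PPRE"].overlapping and calls["RARE-1"].overlapping
        assert not calls["RARE-3"].overlapping

    def test_state_degrades_with_mutation_load(self, catalog, templates):
        rng = np.random.default_rng(21)
        win = ELEMENT_WINDOWS[ElementID.enhancer]
        fractions = []
        for p_mut in (0.0, 0.05, 0.15, 0.4):
            intact = total = 0
            for _ in range(5):
                tpl = list(templates[ElementID.enhancer])
                for i in range(len(tpl)):
                    if rng.random() < p_mut:
                        tpl[i] = "ACGT"[rng.integers(0, 4)]
                region = self.region_with("enhancer", "".join(tpl), win)
                for c in scan_species_motifs(region, catalog, win,
                                             element="enhancer"):
                    total += 1
                    intact += c.state is MotifState.intact
            fractions.append(intact / total)
        assert all(x >= y - 0.05 for x, y in zip(fractions, fractions[1:]))
        assert fractions[0] == 1.0 and fractions[-1] < 0.5
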