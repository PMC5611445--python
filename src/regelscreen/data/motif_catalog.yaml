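# Catalog of putative UCP1 transcription-factor binding motifs.
#
# consensus        IUPAC string, written on the strand of the element layout
# critical_core    0-based positions whose mutation is known (from site-
#                  directed mutagenesis) to abolish or drastically reduce
#                  factor binding; motifs without mutagenesis data carry no
#                  core and can never be called "disrupted"
# core_rule        positions | gc_to_at | tata | none
#                  gc_to_at: only G/C -> A/T changes inside the listed
#                  half-site positions count as core hits (AT-richness rule)
# element          which reference element layout the motif sits in
# offset           [start, end) in element-local coordinates
# spacer           for direct-repeat motifs: bases between the two half-sites
#
# Sources are the primary mutagenesis/characterisation studies for each
# motif (murid rodent UCP1 enhancer/promoter literature).

motifs:
  # --- enhancer box (~200 bp, ~2-5 kb upstream) -------------------------
  - motif_id: CRE-3
    consensus: TKACGTCA
    critical_core: [3, 4, 5, 6, 7]      # CGTCA
    core_rule: positions
    orientation: as_given
    element: enhancer
    offset: [6, 14]
    source: Kozak1994; Bokar1988 CRE-core mutagenesis
  - motif_id: URE1_PPRE
    consensus: TCACCCTTGACCA
    critical_core: [4, 5, 7]            # bases altered in non-binding mutants
    core_rule: positions
    orientation: as_given
    element: enhancer
    offset: [24, 37]
    source: Sears1996 PPARg-RXRa binding mutants
  - motif_id: RARE-1
    consensus: TCACCCTTGACCA            # overlaps URE1_PPRE
    critical_core: [0, 1, 2, 3, 4, 5, 7, 8, 9, 10, 11, 12]
    core_rule: gc_to_at
    orientation: as_given
    element: enhancer
    offset: [24, 37]
    source: Rabelo1995 AT-richness mutagenesis
  - motif_id: CRE-2
    consensus: AGTCGTCA
    critical_core: [3, 4, 5, 6, 7]      # CGTCA
    core_rule: positions
    orientation: as_given
    element: enhancer
    offset: [48, 56]
    source: Kozak1994; Bokar1988 CRE-core mutagenesis
  - motif_id: BRE-1
    consensus: TTCC
    critical_core: [0, 1, 2, 3]
    core_rule: positions
    orientation: as_given
    element: enhancer
    offset: [66, 70]
    source: Kozak1994 TTCC->GTAC mutagenesis
  - motif_id: RARE-2
    consensus: TTCCTTGACC                # overlaps BRE-1
    critical_core: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
    core_rule: gc_to_at
    orientation: as_given
    element: enhancer
    offset: [66, 76]
    source: Rabelo1995 AT-richness mutagenesis
  - motif_id: RARE-3
    consensus: TGACCCTTTGGGGAT
    critical_core: [0, 1, 2, 3, 4, 5, 9, 10, 11, 12, 13, 14]
    core_rule: gc_to_at
    orientation: as_given
    element: enhancer
    offset: [90, 105]
    source: Rabelo1995 AT-richness mutagenesis
  - motif_id: PPRE-2
    consensus: GCAAACTTTC
    critical_core: []
    core_rule: none
    orientation: as_given
    element: enhancer
    offset: [115, 125]
    source: Jastroch2008 predicted PPRE (no mutagenesis)
  - motif_id: upTRE
    consensus: AGGCAA
    critical_core: [1, 2, 3]            # AGGCAA -> ATTTAA abolishes T3 binding
    core_rule: positions
    orientation: as_given
    element: enhancer
    offset: [140, 146]
    source: Rabelo1996 TRE mutagenesis
  - motif_id: dnTRE
    consensus: AGAAGGGGTGAGGTCA
    critical_core: [10, 11, 12, 13, 14, 15]   # AGGTCA -> ATATTA abolishes
    core_rule: positions
    orientation: as_given
    element: enhancer
    offset: [152, 168]
    source: Rabelo1996 TRE mutagenesis
  - motif_id: NBRE
    consensus: TGAGGTCA                  # overlaps dnTRE 3' region
    critical_core: []
    core_rule: none
    orientation: as_given
    element: enhancer
    offset: [160, 168]
    source: Kumar2008 NR4A site (no mutagenesis)
  - motif_id: BRE-2
    consensus: TTCC
    critical_core: [0, 1, 2, 3]
    core_rule: positions
    orientation: as_given
    element: enhancer
    offset: [182, 186]
    source: Kozak1994 TTCC->GTAC mutagenesis

  # --- basal promoter (300 bp immediately upstream of the ATG) ----------
  - motif_id: GCCCCT-1
    consensus: GCCCCT
    critical_core: []
    core_rule: none
    orientation: as_given
    element: promoter
    offset: [2, 8]
    source: Yubero1994 footprinting (murid-only site)
  - motif_id: TATA
    consensus: TATAAAA
    critical_core: [0, 1, 2, 3, 4, 5, 6]
    core_rule: tata
    orientation: as_given
    element: promoter
    offset: [25, 32]
    source: Bouillaud1988; Xu TATA consensus
  - motif_id: GCCCCT-2
    consensus: GCCCCT
    critical_core: []
    core_rule: none
    orientation: as_given
    element: promoter
    offset: [120, 126]
    source: Yubero1994 footprinting
  - motif_id: CRE-4
    consensus: TGACGCGC
    critical_core: [0, 1, 2, 3, 4]      # TGACG = CRE core on this strand
    core_rule: positions
    orientation: both
    element: promoter
    offset: [170, 178]
    source: Kozak1994 reporter mutagenesis
  - motif_id: GCCCCT-3
    consensus: GCCCCT
    critical_core: []
    core_rule: none
    orientation: as_given
    element: promoter
    offset: [180, 186]
    source: Yubero1994 footprinting
  - motif_id: CCAAT
    consensus: CCAAT
    critical_core: []
    core_rule: none
    orientation: as_given
    element: promoter
    offset: [250, 255]
    source: Bouillaud1988 (no mutagenesis)

  # --- positionless nuclear-receptor repeat motifs ----------------------
  - motif_id: TRE_halfsite
    consensus: AGGTMA
    critical_core: []
    core_rule: none
    orientation: both
    source: Umesono1991 half-site consensus
  - motif_id: DR-1
    consensus: AGGTCA
    critical_core: []
    core_rule: none
    orientation: both
    spacer: 1
    source: direct repeat, 1 bp spacer
  - motif_id: DR-3
    consensus: AGGTCA
    critical_core: []
    core_rule: none
    orientation: both
    spacer: 3
    source: direct repeat, 3 bp spacer
  - motif_id: DR-4
    consensus: AGGTCA
    critical_core: []
    core_rule: none
    orientation: both
    spacer: 4
    source: direct repeat, 4 bp spacer
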