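"""Synthetic reference element library.

The real human/rat/mouse enhancer, PRR, CpG-island and promoter sequences
live in GenBank; this module builds synthetic equivalents with the same
documented structure: each element template carries the catalogued motif
consensus strings at their layout offsets, embedded in reproducible random
filler. The templates double as the simulator's ancestral elements and as
the homology-screen references, so motif truth is well defined.

Element windows are anchored to the ATG start codon (position 0):

* enhancer  — 200 bp at [-4000, -3800): the conserved distal enhancer box
  (~2-5 kb upstream in most eutherians)
* prr       — 678 bp at [-2773, -2095): the putative regulatory region
  described 2,095 bp upstream of the human gene
* cpg_island — 400 bp spanning [-250, +150): a CpG-island-qualifying block
  over the proximal promoter extending into exon 1
* promoter  — 300 bp at [-300, 0): basal promoter with TATA, GCCCCT, CRE-4
  and CCAAT sites
"""

from __future__ import annotations

import numpy as np

from .cpg_island import gc_fraction, obs_exp_ratio
from .motif_catalog import IUPAC, MotifDefinition, load_default_catalog
from .seq_model import ElementDefinition, ElementID

_TEMPLATE_SEED = 20170920  # fixed: templates are package constants

#: Anchored windows of the four elements (half-open).
ELEMENT_WINDOWS: dict[ElementID, tuple[int, int]] = {
    ElementID.enhancer: (-4000, -3800),
    ElementID.prr: (-2773, -2095),
    ElementID.cpg_island: (-250, 150),
    ElementID.promoter: (-300, 0),
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_filler(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(rng.choice(_BASES, size=n, p=p)).decode()


def concretize(pattern: str) -> str:
    """Deterministically replace IUPAC ambiguity letters with one base
    (alphabetically first member of the set)."""
    return "".join(sorted(IUPAC[c])[0] for c in pattern)


def _lay_out(
    length: int,
    motifs: list[MotifDefinition],
    rng: np.random.Generator,
    gc: float,
) -> str:
    seq = list(_random_filler(rng, length, gc))
    for d in motifs:
        lo, hi = d.expected_offset  # type: ignore[misc]
        inst = concretize(d.consensus)
        assert hi - lo == len(inst), d.motif_id
        seq[lo:hi] = inst
    return "".join(seq)


def build_cpg_block(rng: np.random.Generator, length: int = 400) -> str:
    """A CpG-island-qualifying block: GC-rich with frequent CpG
    dinucleotides, built to exceed O/E 0.6 and GC 0.5 by construction."""
    out: list[str] = []
    p = np.array([0.12, 0.33, 0.33, 0.12, 0.10])  # A, C, G, T, CpG-pair
    choices = ["A", "C", "G", "T", "CG"]
    while len(out) < length:
        out.append(choices[rng.choice(5, p=p / p.sum())])
    seq = "".join(out)[:length]
    assert obs_exp_ratio(seq) > 0.6 and gc_fraction(seq) > 0.5
    return seq


def build_templates(
    catalog: list[MotifDefinition] | None = None,
    background_gc: float = 0.40,
) -> dict[ElementID, str]:
    """Deterministic synthetic template sequences for the four elements."""
    catalog = catalog if catalog is not None else load_default_catalog()
    rng = np.random.default_rng(_TEMPLATE_SEED)
    enh_motifs = [d for d in catalog if d.element == "enhancer"]
    prom_motifs = [d for d in catalog if d.element == "promoter"]
    enhancer = _lay_out(200, enh_motifs, rng, background_gc)
    # the PRR embeds nuclear-receptor direct repeats and a CCAAT site, the
    # motif classes reported inside it, at fixed offsets
    prr = list(_random_filler(rng, 678, 0.45))
    prr[100:113] = "AGGTCAAAGGTCA"  # DR-1
    prr[400:416] = "AGGTCACTGAAGGTCA"  # DR-4
    prr[550:555] = "CCAAT"
    promoter = _lay_out(300, prom_motifs, rng, background_gc)
    cpg = build_cpg_block(rng)
    return {
        ElementID.enhancer: enhancer,
        ElementID.prr: "".join(prr),
        ElementID.cpg_island: cpg,
        ElementID.promoter: promoter,
    }


def default_elements(
    reference_species: str = "synthetic_eutherian_consensus",
) -> dict[ElementID, ElementDefinition]:
    """ElementDefinitions for the four synthetic reference elements."""
    templates = build_templates()
    return {
        eid: ElementDefinition(
            element_id=eid,
            reference_species=reference_species,
            reference_sequence=templates[eid],
            expected_window=ELEMENT_WINDOWS[eid],
        )
        for eid in templates
    }
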