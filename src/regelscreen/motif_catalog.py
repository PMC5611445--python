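"""Motif catalog, IUPAC scanning and per-species motif-state classification.

The packaged catalog holds the consensus strings of the transcription
factor binding motifs described for the murid UCP1 enhancer and basal
promoter, each with the "critical core" positions whose mutation was shown
by site-directed mutagenesis to abolish or drastically reduce factor
binding. Classification of an observed motif instance:

* ``intact``     — no mismatch to the IUPAC consensus
* ``variant``    — mismatches, but none triggering the critical core
* ``disrupted``  — a critical-core hit (per the motif's core rule)
* ``deleted``    — gap characters over at least half the motif span
* ``not_found``  — nothing observable (no residues, or outside coverage)

Motifs without mutagenesis data (PPRE-2, NBRE, GCCCCT, CCAAT, DR-*) carry
no core and can never be called disrupted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Optional, Sequence

import yaml

from .seq_model import UpstreamRegion, reverse_complement, slice_upstream, CoverageError

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class Orientation(str, Enum):
    as_given = "as_given"
    reverse_complement = "reverse_complement"
    both = "both"


class CoreRule(str, Enum):
    positions = "positions"   # any mismatch at a core position disrupts
    gc_to_at = "gc_to_at"     # only G/C -> A/T changes in half-sites disrupt
    tata = "tata"             # loss of the A/T-rich TATA frame
    none = "none"             # no mutagenesis data: never disrupted


class MotifState(str, Enum):
    intact = "intact"
    variant = "variant"
    disrupted = "disrupted"
    deleted = "deleted"
    not_found = "not_found"


@dataclass(frozen=True)
class MotifDefinition:
    motif_id: str
    consensus: str
    critical_core: frozenset[int] = frozenset()
    core_rule: CoreRule = CoreRule.positions
    orientation: Orientation = Orientation.as_given
    source: str = ""
    element: Optional[str] = None
    expected_offset: Optional[tuple[int, int]] = None  # element-local
    spacer: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"{self.motif_id}: empty consensus")
        bad = set(self.consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.motif_id}: invalid IUPAC {sorted(bad)}")
        if not self.critical_core <= set(range(len(self.consensus))):
            raise ValueError(f"{self.motif_id}: core outside consensus")


@dataclass(frozen=True)
class MotifCall:
    species_id: str
    motif_id: str
    state: MotifState
    observed: str = ""
    mismatch_positions: frozenset[int] = frozenset()
    core_mismatch_positions: frozenset[int] = frozenset()
    overlapping: bool = False


def load_default_catalog() -> list[MotifDefinition]:
    """The packaged motif catalog (editable YAML)."""
    text = (
        resources.files("regelscreen").joinpath("data/motif_catalog.yaml").read_text()
    )
    return load_catalog_from_text(text)


def load_catalog_from_text(text: str) -> list[MotifDefinition]:
    raw = yaml.safe_load(text)
    defs = []
    for entry in raw["motifs"]:
        defs.append(
            MotifDefinition(
                motif_id=entry["motif_id"],
                consensus=entry["consensus"].upper(),
                critical_core=frozenset(entry.get("critical_core", ())),
                core_rule=CoreRule(entry.get("core_rule", "positions")),
                orientation=Orientation(entry.get("orientation", "as_given")),
                source=entry.get("source", ""),
                element=entry.get("element"),
                expected_offset=(
                    tuple(entry["offset"]) if "offset" in entry else None
                ),
                spacer=entry.get("spacer"),
            )
        )
    return defs


def reverse_complement_pattern(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern."""
    return pattern.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def _mismatches(pattern: str, segment: str) -> int:
    n = 0
    for p, s in zip(pattern, segment):
        if s == "N" or s not in IUPAC[p]:
            n += 1
    return n


def iupac_match(
    pattern: str,
    seq: str,
    max_mismatch: int = 0,
    orientation: Orientation = Orientation.as_given,
) -> list[tuple[int, str, int]]:
    """All occurrences of ``pattern`` in ``seq`` with at most
    ``max_mismatch`` mismatches.

    Returns (position on the forward sequence, strand '+'/'-', mismatch
    count), sorted by position then strand. An N in the sequence counts as
    a mismatch regardless of the pattern letter.
    """
    pattern = pattern.upper()
    bad = set(pattern) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC letters {sorted(bad)}")
    seq = seq.upper()
    pats = []
    if orientation in (Orientation.as_given, Orientation.both):
        pats.append((pattern, "+"))
    if orientation in (Orientation.reverse_complement, Orientation.both):
        pats.append((reverse_complement_pattern(pattern), "-"))
    hits = []
    for pat, strand in pats:
        for i in range(len(seq) - len(pat) + 1):
            mm = _mismatches(pat, seq[i : i + len(pat)])
            if mm <= max_mismatch:
                hits.append((i, strand, mm))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def find_direct_repeat(
    seq: str,
    half_site: str = "AGGTCA",
    spacer: int = 1,
    max_mismatch_per_half: int = 0,
) -> list[tuple[int, int, int]]:
    """Direct repeats of ``half_site`` separated by exactly ``spacer`` bases.

    Returns (position of the first half-site, mismatches in half 1,
    mismatches in half 2) for the forward strand of ``seq``. Scan the
    reverse complement of ``seq`` separately for minus-strand repeats.
    """
    if spacer < 0:
        raise ValueError("spacer must be >= 0")
    half_site = half_site.upper()
    seq = seq.upper()
    L = len(half_site)
    out = []
    for i in range(len(seq) - (2 * L + spacer) + 1):
        mm1 = _mismatches(half_site, seq[i : i + L])
        if mm1 > max_mismatch_per_half:
            continue
        j = i + L + spacer
        mm2 = _mismatches(half_site, seq[j : j + L])
        if mm2 <= max_mismatch_per_half:
            out.append((i, mm1, mm2))
    return out


_GC = frozenset("GC")
_AT = frozenset("AT")


def classify_motif_state(
    observed: str,
    definition: MotifDefinition,
    species_id: str = "",
    deleted_gap_fraction: float = 0.5,
    overlapping: bool = False,
) -> MotifCall:
    """Classify one observed (possibly gapped) motif instance.

    ``observed`` must span exactly the motif's columns: its length equals
    the consensus length, with ``-`` marking deleted bases. The function is
    total over strings in {A,C,G,T,N,-}^L.
    """
    observed = observed.upper()
    cons = definition.consensus
    if len(observed) != len(cons):
        raise ValueError(
            f"{definition.motif_id}: observed length {len(observed)} != "
            f"consensus length {len(cons)}"
        )
    residues = sum(1 for c in observed if c != "-")
    if residues == 0:
        return MotifCall(species_id, definition.motif_id, MotifState.not_found,
                         observed, overlapping=overlapping)
    gaps = len(observed) - residues
    if gaps / len(observed) >= deleted_gap_fraction:
        return MotifCall(species_id, definition.motif_id, MotifState.deleted,
                         observed, overlapping=overlapping)

    mismatches = frozenset(
        i for i, (o, c) in enumerate(zip(observed, cons))
        if o in "N-" or o not in IUPAC[c]
    )
    core = _core_hits(observed, definition, mismatches)
    if core:
        state = MotifState.disrupted
    elif mismatches:
        state = MotifState.variant
    else:
        state = MotifState.intact
    return MotifCall(
        species_id,
        definition.motif_id,
        state,
        observed,
        mismatch_positions=mismatches,
        core_mismatch_positions=core,
        overlapping=overlapping,
    )


def _core_hits(
    observed: str, definition: MotifDefinition, mismatches: frozenset[int]
) -> frozenset[int]:
    rule = definition.core_rule
    core_mm = mismatches & definition.critical_core
    if rule is CoreRule.none:
        return frozenset()
    if rule is CoreRule.positions:
        return core_mm
    if rule is CoreRule.gc_to_at:
        # AT-richness rule: a core hit is a G/C consensus base observed as
        # A/T (or deleted) inside a half-site
        hits = set()
        for i in core_mm:
            cons_set = IUPAC[definition.consensus[i]]
            if cons_set <= _GC and (observed[i] in _AT or observed[i] == "-"):
                hits.add(i)
        return frozenset(hits)
    if rule is CoreRule.tata:
        # disrupted when the A/T-rich frame is lost: >= 3 core mismatches,
        # or any G/C (or gap) observed at positions 1-4 of the box
        gc_inner = frozenset(
            i for i in range(1, min(5, len(observed)))
            if observed[i] in _GC or observed[i] == "-"
        )
        if len(core_mm) >= 3:
            return core_mm
        return gc_inner & definition.critical_core
    raise AssertionError(f"unhandled core rule {rule}")


def scan_species_motifs(
    region: UpstreamRegion,
    catalog: Sequence[MotifDefinition],
    element_anchor: tuple[int, int],
    element: str = "enhancer",
    pad: int = 12,
) -> list[MotifCall]:
    """One MotifCall per catalog motif laid out in ``element``.

    ``element_anchor`` is the located anchored interval of the element in
    this species (from the homology screen). Each motif is searched inside
    its expected offset padded by ``pad`` bp; the best (fewest-mismatch,
    leftmost) hit is classified. Motifs whose window falls outside the
    record's coverage come back ``not_found``.
    """
    anchor_lo = element_anchor[0]
    positioned = [
        d for d in catalog if d.element == element and d.expected_offset
    ]
    overlap_ids = _overlapping_ids(positioned)
    calls = []
    for d in positioned:
        off_lo, off_hi = d.expected_offset  # type: ignore[misc]
        lo = anchor_lo + off_lo - pad
        hi = anchor_lo + off_hi + pad
        try:
            window, truncated = slice_upstream(region, lo, hi)
        except CoverageError:
            window, truncated = "", True
        if len(window) < len(d.consensus):
            calls.append(
                MotifCall(region.species_id, d.motif_id, MotifState.not_found,
                          overlapping=d.motif_id in overlap_ids)
            )
            continue
        hits = iupac_match(d.consensus, window,
                           max_mismatch=len(d.consensus),
                           orientation=d.orientation)
        pos, strand, _mm = min(hits, key=lambda h: (h[2], h[0], h[1]))
        observed = window[pos : pos + len(d.consensus)]
        if strand == "-":
            observed = reverse_complement(observed)
        call = classify_motif_state(
            observed, d, species_id=region.species_id,
            overlapping=d.motif_id in overlap_ids,
        )
        calls.append(call)
    return calls


def _overlapping_ids(defs: Iterable[MotifDefinition]) -> frozenset[str]:
    ids = set()
    ds = [d for d in defs if d.expected_offset]
    for i, a in enumerate(ds):
        for b in ds[i + 1 :]:
            alo, ahi = a.expected_offset  # type: ignore[misc]
            blo, bhi = b.expected_offset  # type: ignore[misc]
            if max(alo, blo) < min(ahi, bhi):
                ids.update((a.motif_id, b.motif_id))
    return frozenset(ids)
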