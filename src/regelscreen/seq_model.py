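"""Sequence data model and IO for start-codon-anchored upstream regions.

All coordinates in this package are 0-based and half-open, anchored so that
the A of the ATG start codon sits at position 0. Upstream positions are
negative: position -1 is the base immediately 5' of the A. An
:class:`UpstreamRegion` therefore covers ``[-anchor_offset,
len(sequence) - anchor_offset)`` in anchored coordinates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# IUPAC ambiguity codes other than N are collapsed to N on input: motif
# matching treats any N as a mismatch, so keeping finer ambiguity codes in
# genomic input would buy nothing.
_IUPAC_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHV"})


class SequenceError(ValueError):
    """Malformed or inconsistent sequence input."""


class CoverageError(ValueError):
    """Requested interval has no overlap with the covered extent."""


def normalize_sequence(seq: str) -> str:
    """Upper-case ``seq`` and map non-N IUPAC ambiguity letters to N.

    Raises :class:`SequenceError` on characters outside the IUPAC
    nucleotide alphabet (including gaps).
    """
    seq = seq.upper()
    bad = set(seq) - ALPHABET - set("RYSWKMBDHV")
    if bad:
        raise SequenceError(f"unexpected characters in sequence: {sorted(bad)}")
    mapped = seq.translate(_IUPAC_TO_N)
    n_mapped = sum(1 for a, b in zip(seq, mapped) if a != b)
    if n_mapped:
        logger.warning("mapped %d ambiguous IUPAC bases to N", n_mapped)
    return mapped


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N is self-complementary."""
    bad = set(seq) - ALPHABET
    if bad:
        raise SequenceError(f"cannot complement characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class UpstreamRegion:
    """One species' upstream sequence anchored to its ATG start codon.

    ``anchor_offset`` is the index of the A of the start codon within
    ``sequence``; it equals the upstream extent in bp. ``anchor_offset ==
    len(sequence)`` means the record is purely upstream sequence ending
    right at the start codon.
    """

    species_id: str
    sequence: str
    anchor_offset: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"{self.species_id}: empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise SequenceError(
                f"{self.species_id}: invalid characters {sorted(bad)}"
            )
        if not 0 <= self.anchor_offset <= len(self.sequence):
            raise SequenceError(
                f"{self.species_id}: anchor_offset {self.anchor_offset} "
                f"outside sequence of length {len(self.sequence)}"
            )

    @property
    def upstream_extent(self) -> int:
        """Covered bases 5' of the start codon."""
        return self.anchor_offset

    @property
    def downstream_extent(self) -> int:
        return len(self.sequence) - self.anchor_offset

    def covered_interval(self) -> tuple[int, int]:
        """Anchored-coordinate interval this record covers (half-open)."""
        return (-self.anchor_offset, len(self.sequence) - self.anchor_offset)


def slice_upstream(
    region: UpstreamRegion, from_pos: int, to_pos: int
) -> tuple[str, bool]:
    """Extract ``[from_pos, to_pos)`` in anchored coordinates.

    Returns ``(subsequence, truncated)`` where ``truncated`` flags that the
    requested interval extended beyond the record's coverage and only the
    covered part is returned. Raises :class:`CoverageError` when the overlap
    with coverage is empty (callers map this to a no_coverage state) and
    :class:`ValueError` on an empty or inverted request.
    """
    if from_pos >= to_pos:
        raise ValueError(f"empty interval [{from_pos}, {to_pos})")
    lo, hi = region.covered_interval()
    a, b = max(from_pos, lo), min(to_pos, hi)
    if a >= b:
        raise CoverageError(
            f"{region.species_id}: [{from_pos}, {to_pos}) outside coverage "
            f"[{lo}, {hi})"
        )
    truncated = (a, b) != (from_pos, to_pos)
    off = region.anchor_offset
    return region.sequence[a + off : b + off], truncated


class ElementID(str, Enum):
    """The four upstream regulatory elements screened by the pipeline."""

    enhancer = "enhancer"
    prr = "prr"
    cpg_island = "cpg_island"
    promoter = "promoter"


@dataclass(frozen=True)
class ElementDefinition:
    """A reference regulatory element with its expected anchored window."""

    element_id: ElementID
    reference_species: str
    reference_sequence: str
    expected_window: tuple[int, int]  # anchored, half-open, at or 5' of 0

    def __post_init__(self) -> None:
        if not self.reference_sequence:
            raise SequenceError(f"{self.element_id}: empty reference sequence")
        lo, hi = self.expected_window
        if lo >= hi:
            raise ValueError(f"{self.element_id}: empty expected_window")


class UCP1Status(str, Enum):
    intact = "intact"
    pseudogene = "pseudogene"
    unknown = "unknown"


TAXON_GROUPS = (
    "Monotremata",
    "Marsupialia",
    "Xenarthra",
    "Afrotheria",
    "Laurasiatheria",
    "Euarchontoglires",
)

EUTHERIAN_GROUPS = frozenset(TAXON_GROUPS[2:])


@dataclass(frozen=True)
class SpeciesMeta:
    species_id: str
    taxon_group: str
    ucp1_status: UCP1Status = UCP1Status.unknown

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise ValueError(f"unknown taxon group {self.taxon_group!r}")

    @property
    def is_eutherian(self) -> bool:
        return self.taxon_group in EUTHERIAN_GROUPS


_ANCHOR_RE = re.compile(r"\banchor=(\d+)\b")


def read_fasta(path: str | Path) -> list[UpstreamRegion]:
    """Read upstream regions from FASTA.

    The record id is the species id; an ``anchor=<int>`` key anywhere in the
    description gives the start-codon offset. Without it the record is taken
    to be pure upstream sequence (anchor at the sequence end).
    """
    regions: list[UpstreamRegion] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SequenceError(f"{path}: record without an id")
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate species_id {rec.id!r}")
        seen.add(rec.id)
        m = _ANCHOR_RE.search(rec.description)
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise SequenceError(f"{path}: record {rec.id!r} is empty")
        anchor = int(m.group(1)) if m else len(seq)
        regions.append(UpstreamRegion(rec.id, seq, anchor))
    return regions


def write_fasta(regions: Iterable[UpstreamRegion], path: str | Path) -> None:
    """Write regions as 60-column FASTA with ``anchor=`` metadata."""
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.species_id,
            description=f"anchor={r.anchor_offset}",
        )
        for r in regions
    ]
    SeqIO.write(records, str(path), "fasta")


def read_species_meta(path: str | Path) -> list[SpeciesMeta]:
    """Read the tab-separated species metadata table (header required)."""
    metas: list[SpeciesMeta] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for required in ("species_id", "taxon_group"):
            if required not in idx:
                raise ValueError(f"{path}: missing column {required!r}")
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            sid = parts[idx["species_id"]]
            if sid in seen:
                raise ValueError(f"{path}: duplicate species_id {sid!r}")
            seen.add(sid)
            status = (
                UCP1Status(parts[idx["ucp1_status"]])
                if "ucp1_status" in idx
                else UCP1Status.unknown
            )
            metas.append(SpeciesMeta(sid, parts[idx["taxon_group"]], status))
    return metas


def write_species_meta(metas: Iterable[SpeciesMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\ttaxon_group\tucp1_status\n")
        for m in metas:
            fh.write(f"{m.species_id}\t{m.taxon_group}\t{m.ucp1_status.value}\n")
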