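"""Majority-rule consensus over alignments and motif conservation summaries.

The consensus follows the simple-majority rule: per column, the most
frequent symbol among the included species if its frequency exceeds 50%,
else ``N``. Species with a pseudogenized gene are excluded from consensus
calculations by the callers. Gaps are first-class symbols in the vote by
default (indel-rich regions make gap-majority columns meaningful); a
skip-gaps mode votes only among residue-bearing rows.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .motif_catalog import MotifCall, MotifState
from .seq_model import SpeciesMeta, UCP1Status

logger = logging.getLogger(__name__)

ALN_ALPHABET = frozenset("ACGTN-")


@dataclass(frozen=True)
class Alignment:
    """A multiple alignment: ordered species -> gapped row."""

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        ids = [sid for sid, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species in alignment")
        for sid, seq in self.rows:
            bad = set(seq) - ALN_ALPHABET
            if bad:
                raise ValueError(f"{sid}: invalid alignment symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.rows)

    def row(self, species_id: str) -> str:
        for sid, seq in self.rows:
            if sid == species_id:
                return seq
        raise KeyError(species_id)

    @classmethod
    def from_mapping(cls, rows: Mapping[str, str]) -> "Alignment":
        return cls(tuple(rows.items()))


@dataclass(frozen=True)
class ConsensusTrack:
    consensus: str
    support: tuple[float, ...]


def majority_consensus(
    aln: Alignment,
    include: Iterable[str] | None = None,
    count_gaps: bool = True,
) -> ConsensusTrack:
    """Simple-majority (>50%) consensus over the included rows.

    Each species votes once per column. Columns without a strict majority
    symbol get ``N``. With ``count_gaps=False``, gapped rows abstain in a
    column; a column where everyone abstains is ``-``.
    """
    include = set(include) if include is not None else set(aln.species)
    if not include:
        raise ValueError("include set is empty")
    missing = include - set(aln.species)
    if missing:
        raise ValueError(f"species not in alignment: {sorted(missing)}")
    rows = [seq for sid, seq in aln.rows if sid in include]
    cons = []
    support = []
    for col in range(aln.length):
        symbols = [r[col] for r in rows]
        if not count_gaps:
            symbols = [s for s in symbols if s != "-"]
            if not symbols:
                cons.append("-")
                support.append(0.0)
                continue
        best, n = Counter(symbols).most_common(1)[0]
        frac = n / len(symbols)
        if frac > 0.5:
            cons.append(best)
            support.append(frac)
        else:
            cons.append("N")
            support.append(frac)
    return ConsensusTrack("".join(cons), tuple(support))


def motif_conservation_summary(
    calls: Sequence[MotifCall],
    meta: Sequence[SpeciesMeta],
) -> pd.DataFrame:
    """Per-motif state fractions split by gene status (intact vs pseudogene).

    Species whose call is ``not_found`` are dropped from denominators (no
    observable motif); motifs observable in no species are excluded with a
    logged note. Returns a motif x metric table with columns
    ``frac_<state>_<status>`` and ``n_<status>``.
    """
    status = {m.species_id: m.ucp1_status for m in meta}
    records: dict[str, dict[str, Counter]] = {}
    for call in calls:
        if call.state is MotifState.not_found:
            continue
        st = status.get(call.species_id, UCP1Status.unknown)
        records.setdefault(call.motif_id, {}).setdefault(
            st.value, Counter()
        )[call.state.value] += 1

    observable_states = [s.value for s in MotifState if s is not MotifState.not_found]
    all_motifs = {c.motif_id for c in calls}
    rows = []
    for motif_id in sorted(all_motifs):
        per_status = records.get(motif_id)
        if not per_status:
            logger.info("motif %s observable in no species; excluded", motif_id)
            continue
        row: dict[str, float | str] = {"motif_id": motif_id}
        for st in ("intact", "pseudogene", "unknown"):
            counts = per_status.get(st, Counter())
            n = sum(counts.values())
            row[f"n_{st}"] = n
            for state in observable_states:
                row[f"frac_{state}_{st}"] = counts[state] / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("motif_id") if rows else pd.DataFrame()
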