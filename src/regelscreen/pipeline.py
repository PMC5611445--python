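"""End-to-end orchestration: simulate-or-load, locate elements, CpG scan,
motif scan, consensus, presence matrix, gain/loss mapping, tallies.

Every stage is a library call; this module wires them together and writes
the tabular artifacts (all TSV/FASTA/newick with a provenance header
line). The drivers under ``analysis/`` and the CLI both route through
here.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

from . import __version__
from .cpg_island import CpGIslandCall, CpGParams, detect_cpg_islands
from .homology_screen import (
    DotPlotParams,
    HomologyHit,
    PresenceCall,
    PresenceState,
    annotate_element_by_homology,
    call_element_presence,
)
from .motif_catalog import MotifCall, load_default_catalog, scan_species_motifs
from .consensus_conservation import Alignment, majority_consensus
from .phylo_events import (
    GainLossMap,
    PresenceMatrix,
    SpeciesTree,
    build_presence_matrix,
    count_matrix_tallies,
    dollo_losses,
    write_gainloss_tsv,
)
from .reference_elements import default_elements
from .seq_model import (
    CoverageError,
    ElementDefinition,
    ElementID,
    SpeciesMeta,
    UpstreamRegion,
    slice_upstream,
)

logger = logging.getLogger(__name__)

#: Default CpG scan span around the start codon (extendable to 1 kb
#: upstream of exon 2 when exon-1 length is known).
CPG_SCAN_SPAN = (-600, 200)


def provenance_header(seed: Optional[int], config: object = None) -> str:
    blob = json.dumps(repr(config), sort_keys=True).encode()
    digest = hashlib.sha256(blob).hexdigest()[:12]
    return f"# regelscreen {__version__} seed={seed} config={digest}\n"


def call_cpg_presence(
    region: UpstreamRegion,
    params: CpGParams | None = None,
    span: tuple[int, int] = CPG_SCAN_SPAN,
    min_coverage_fraction: float = 0.5,
) -> tuple[PresenceCall, list[CpGIslandCall]]:
    """CpG-island presence for one species from the detector itself."""
    params = params or CpGParams()
    try:
        seq, _trunc = slice_upstream(region, *span)
    except CoverageError:
        return (
            PresenceCall(region.species_id, ElementID.cpg_island,
                         PresenceState.no_coverage),
            [],
        )
    covered = len(seq)
    islands = detect_cpg_islands(seq, params)
    if islands:
        best = max(islands, key=len)
        lo = max(span[0], region.covered_interval()[0])
        return (
            PresenceCall(
                region.species_id, ElementID.cpg_island, PresenceState.present,
                located_interval=(lo + best.start, lo + best.end),
                best_segment_length=len(best),
            ),
            islands,
        )
    if covered < min_coverage_fraction * (span[1] - span[0]):
        return (
            PresenceCall(region.species_id, ElementID.cpg_island,
                         PresenceState.no_coverage),
            [],
        )
    return (
        PresenceCall(region.species_id, ElementID.cpg_island,
                     PresenceState.absent),
        [],
    )


@dataclass
class ScreenResult:
    presence: list[PresenceCall]
    homology_hits: dict[tuple[str, str], HomologyHit]
    motif_calls: list[MotifCall]
    cpg_islands: dict[str, list[CpGIslandCall]]

    @property
    def matrix(self) -> PresenceMatrix:
        return build_presence_matrix(self.presence)


def screen_dataset(
    regions: Sequence[UpstreamRegion],
    elements: Optional[dict[ElementID, ElementDefinition]] = None,
    dotplot_params: Optional[DotPlotParams] = None,
    cpg_params: Optional[CpGParams] = None,
    min_conserved_length: int = 100,
) -> ScreenResult:
    """Run the full per-species screen.

    Enhancer, PRR and promoter presence come from the dot-plot homology
    screen against the reference elements; CpG-island presence from the
    sliding-window detector; enhancer/promoter motifs are scanned at their
    layout offsets inside elements located by iterative local alignment.
    """
    elements = elements or default_elements()
    dotplot_params = dotplot_params or DotPlotParams()
    catalog = load_default_catalog()

    presence: list[PresenceCall] = []
    hits: dict[tuple[str, str], HomologyHit] = {}
    motif_calls: list[MotifCall] = []
    cpg_islands: dict[str, list[CpGIslandCall]] = {}

    for region in regions:
        for eid, ref in elements.items():
            if eid is ElementID.cpg_island:
                call, islands = call_cpg_presence(region, cpg_params)
                presence.append(call)
                cpg_islands[region.species_id] = islands
                continue
            call = call_element_presence(
                region, ref, dotplot_params,
                min_conserved_length=min_conserved_length,
            )
            presence.append(call)
            if call.state is not PresenceState.present:
                continue
            hit = annotate_element_by_homology(region, ref)
            if hit is None:
                continue
            hits[(region.species_id, eid.value)] = hit
            if eid in (ElementID.enhancer, ElementID.promoter):
                motif_calls.extend(
                    scan_species_motifs(
                        region, catalog, hit.element_anchor,
                        element=eid.value,
                    )
                )
    return ScreenResult(presence, hits, motif_calls, cpg_islands)


def write_presence_matrix_tsv(
    matrix: PresenceMatrix,
    meta: Sequence[SpeciesMeta],
    path: str | Path,
    header: str = "",
) -> None:
    elements = matrix.elements
    by_id = {m.species_id: m for m in meta}
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write(
            "species_id\ttaxon_group\tucp1_status\t" + "\t".join(elements) + "\n"
        )
        for sid in matrix.species:
            m = by_id.get(sid)
            fh.write(
                "\t".join(
                    [
                        sid,
                        m.taxon_group if m else "",
                        m.ucp1_status.value if m else "unknown",
                    ]
                    + [matrix.state(sid, el).value for el in elements]
                )
                + "\n"
            )


def write_motif_calls_tsv(
    calls: Sequence[MotifCall], path: str | Path, header: str = ""
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write(
            "species_id\tmotif_id\tstate\tobserved\tn_mismatch\t"
            "n_core_mismatch\toverlapping\n"
        )
        for c in calls:
            fh.write(
                f"{c.species_id}\t{c.motif_id}\t{c.state.value}\t{c.observed}"
                f"\t{len(c.mismatch_positions)}\t{len(c.core_mismatch_positions)}"
                f"\t{int(c.overlapping)}\n"
            )


def write_tallies_tsv(
    matrix: PresenceMatrix,
    meta: Sequence[SpeciesMeta],
    path: str | Path,
    header: str = "",
) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("element_id\tscope\tn_present\tn_with_coverage\tn_total\n")
        for el in matrix.elements:
            for scope, kwargs in (
                ("all", {}),
                ("eutherian", {"eutherian_only": True}),
            ):
                n_p, n_c, n_t = count_matrix_tallies(matrix, meta, el, **kwargs)
                fh.write(f"{el}\t{scope}\t{n_p}\t{n_c}\t{n_t}\n")


def run_gain_loss(
    tree: SpeciesTree,
    matrix: PresenceMatrix,
    elements: Optional[Iterable[str]] = None,
) -> list[GainLossMap]:
    out = []
    for el in elements if elements is not None else matrix.elements:
        out.append(dollo_losses(tree, matrix, el))
    return out
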