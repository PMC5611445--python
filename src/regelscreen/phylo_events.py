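"""Presence matrix assembly and Dollo gain/loss mapping on a species tree.

Each regulatory element is a binary character scored present / absent /
no_coverage per species. Under Dollo parsimony the character is gained
exactly once — on the branch above the most recent common ancestor of all
present tips — and can only be lost thereafter. Losses are mapped as the
minimal set of branches such that a tip is absent iff it descends from a
loss branch; tips without coverage are missing data and never force a
loss.

Branches are identified by the label of the node below them: the tip label
for terminal branches, the internal node label from the newick when
present, else a deterministic ``node<k>`` preorder id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

from .homology_screen import PresenceCall, PresenceState
from .seq_model import ElementID, SpeciesMeta

logger = logging.getLogger(__name__)


class DolloError(ValueError):
    """Character states incompatible with a single-gain history."""


@dataclass
class PresenceMatrix:
    """Species x element call matrix with states present/absent/no_coverage."""

    entries: dict[tuple[str, str], PresenceState] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return sorted({s for s, _ in self.entries})

    @property
    def elements(self) -> list[str]:
        return sorted({e for _, e in self.entries})

    def state(self, species_id: str, element_id: str) -> PresenceState:
        return self.entries.get(
            (species_id, element_id), PresenceState.no_coverage
        )

    def column(self, element_id: str) -> dict[str, PresenceState]:
        return {
            s: st for (s, e), st in self.entries.items() if e == element_id
        }


def build_presence_matrix(calls: Iterable[PresenceCall]) -> PresenceMatrix:
    """Assemble calls into a matrix; conflicting duplicates are an error."""
    matrix = PresenceMatrix()
    for call in calls:
        eid = call.element_id.value if isinstance(call.element_id, ElementID) else str(call.element_id)
        key = (call.species_id, eid)
        if key in matrix.entries and matrix.entries[key] is not call.state:
            raise ValueError(
                f"conflicting duplicate call for {key}: "
                f"{matrix.entries[key].value} vs {call.state.value}"
            )
        matrix.entries[key] = call.state
    return matrix


def read_presence_matrix(path: str | Path) -> tuple[PresenceMatrix, list[SpeciesMeta]]:
    """Read a pre-filled species x element TSV (matrix-only mode).

    Expects columns species_id, taxon_group, optional ucp1_status, then one
    column per element with states present/absent/no_coverage.
    """
    from .seq_model import UCP1Status

    matrix = PresenceMatrix()
    metas = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {h: i for i, h in enumerate(header)}
        meta_cols = {"species_id", "taxon_group", "ucp1_status"}
        element_cols = [h for h in header if h not in meta_cols]
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            sid = parts[idx["species_id"]]
            metas.append(
                SpeciesMeta(
                    sid,
                    parts[idx["taxon_group"]],
                    UCP1Status(parts[idx["ucp1_status"]])
                    if "ucp1_status" in idx
                    else UCP1Status.unknown,
                )
            )
            for el in element_cols:
                matrix.entries[(sid, el)] = PresenceState(parts[idx[el]])
    return matrix, metas


def packaged_species_matrix() -> tuple[PresenceMatrix, list[SpeciesMeta]]:
    """The packaged 139-species element presence table."""
    path = resources.files("regelscreen").joinpath("data/species_elements.tsv")
    with resources.as_file(path) as p:
        return read_presence_matrix(p)


#: Curated coverage reclassifications for the gain/loss mapping. The
#: two-toed sloth's enhancer "absent" call is a coverage artifact: no
#: UCP1-containing contig or SRA read exists at all for this assembly, and
#: a close relative (the extinct giant ground sloth) retains partial
#: enhancer coverage, so the cell is treated as missing data rather than a
#: genuine loss.
CURATED_COVERAGE_OVERRIDES: dict[tuple[str, str], PresenceState] = {
    ("Choloepus_hoffmanni", "enhancer"): PresenceState.no_coverage,
}


def curated_species_matrix() -> tuple[PresenceMatrix, list[SpeciesMeta]]:
    """Packaged matrix with the curated coverage reclassifications applied
    (the view used for event mapping)."""
    matrix, meta = packaged_species_matrix()
    for key, state in CURATED_COVERAGE_OVERRIDES.items():
        if key in matrix.entries:
            matrix.entries[key] = state
    return matrix, meta


class SpeciesTree:
    """Rooted species tree with uniquely labelled tips and branch ids."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._label_nodes()

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
        tree.is_rooted = True
        return cls(tree)

    @classmethod
    def from_path(cls, path: str | Path) -> "SpeciesTree":
        return cls.from_newick(Path(path).read_text())

    @classmethod
    def packaged_mammal_tree(cls) -> "SpeciesTree":
        """The packaged 139-species mammal topology."""
        ref = resources.files("regelscreen").joinpath(
            "data/mammal_species_tree.nwk"
        )
        return cls.from_newick(ref.read_text())

    def _label_nodes(self) -> None:
        labels: set[str] = set()
        k = 0
        for node in self._tree.preorder_node_iter():
            if node.is_leaf():
                label = node.taxon.label.replace(" ", "_")
            elif node.label:
                label = node.label
            else:
                label = f"node{k}"
                k += 1
            if label in labels:
                raise ValueError(f"duplicate node label {label!r}")
            labels.add(label)
            node.branch_id = label  # type: ignore[attr-defined]
        tips = self.tip_labels
        if len(tips) != len(set(tips)):
            raise ValueError("duplicate tip labels")

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [
            l.taxon.label.replace(" ", "_") for l in self._tree.leaf_node_iter()
        ]

    def node(self, branch_id: str) -> dendropy.Node:
        for node in self._tree.preorder_node_iter():
            if node.branch_id == branch_id:
                return node
        raise KeyError(branch_id)

    def tips_below(self, branch_id: str) -> set[str]:
        return {
            l.taxon.label.replace(" ", "_")
            for l in self.node(branch_id).leaf_iter()
        }


@dataclass(frozen=True)
class GainLossMap:
    element_id: str
    gain_branch: str
    loss_branches: frozenset[str]
    n_independent_losses: int
    alternative_optima: int = 1  # number of co-minimal loss assignments


def _states_for_element(
    tree: SpeciesTree, matrix: PresenceMatrix, element_id: str
) -> dict[str, PresenceState]:
    tips = set(tree.tip_labels)
    states = {}
    for sp in tips:
        states[sp] = matrix.state(sp, element_id)
    extra = set(matrix.column(element_id)) - tips
    if extra:
        logger.warning(
            "%d matrix species not in tree (ignored): %s",
            len(extra), sorted(extra)[:5],
        )
    return states


def infer_gain_branch(
    tree: SpeciesTree, matrix: PresenceMatrix, element_id: str
) -> str:
    """Branch above the MRCA of all present tips (single-gain assumption)."""
    states = _states_for_element(tree, matrix, element_id)
    present = [sp for sp, st in states.items() if st is PresenceState.present]
    if not present:
        raise DolloError(f"{element_id}: no present tips")
    taxa = [
        t for t in tree.tree.taxon_namespace
        if t.label.replace(" ", "_") in set(present)
    ]
    if len(taxa) == 1:
        mrca = tree.tree.find_node_with_taxon_label(taxa[0].label)
    else:
        mrca = tree.tree.mrca(taxa=taxa)
    return mrca.branch_id  # type: ignore[attr-defined]


def dollo_losses(
    tree: SpeciesTree,
    matrix: PresenceMatrix,
    element_id: str,
    gain_branch: Optional[str] = None,
) -> GainLossMap:
    """Minimal irreversible-loss assignment explaining the absent tips.

    A loss branch is a maximal branch below the gain whose subtree contains
    at least one absent tip and no present tip; tips without coverage are
    compatible with either state and never force a loss. Ties (alternative
    co-minimal placements) arise when a loss subtree contains no_coverage
    tips whose deeper placement would also explain the data; the count of
    co-minimal assignments is reported.
    """
    if gain_branch is None:
        gain_branch = infer_gain_branch(tree, matrix, element_id)
    states = _states_for_element(tree, matrix, element_id)
    gain_node = tree.node(gain_branch)
    below = {l.taxon.label.replace(" ", "_") for l in gain_node.leaf_iter()}
    outside_present = [
        sp for sp, st in states.items()
        if st is PresenceState.present and sp not in below
    ]
    if outside_present:
        raise DolloError(
            f"{element_id}: present tips outside the gain clade: "
            f"{sorted(outside_present)}"
        )

    losses: list[dendropy.Node] = []
    alternatives = 1

    def visit(node: dendropy.Node) -> tuple[bool, bool]:
        """Post-order; returns (has_present, has_absent) below node and
        appends maximal all-absent branches to ``losses``."""
        nonlocal alternatives
        if node.is_leaf():
            st = states[node.taxon.label.replace(" ", "_")]
            return (st is PresenceState.present, st is PresenceState.absent)
        child_flags = [visit(c) for c in node.child_nodes()]
        has_present = any(p for p, _ in child_flags)
        has_absent = any(a for _, a in child_flags)
        if has_present:
            # children that carry absents but no presents are maximal losses
            for child, (p, a) in zip(node.child_nodes(), child_flags):
                if a and not p:
                    losses.append(child)
                    # deeper co-minimal placements exist when the loss
                    # subtree is padded with missing-data tips
                    if _has_missing(child, states):
                        alternatives *= _alt_placements(child, states)
        return has_present, has_absent

    has_present, has_absent = visit(gain_node)
    if not has_present and has_absent:
        # everything below the gain is absent/missing: one loss at the gain
        losses.append(gain_node)

    loss_ids = frozenset(n.branch_id for n in losses)  # type: ignore[attr-defined]
    return GainLossMap(
        element_id=element_id,
        gain_branch=gain_branch,
        loss_branches=loss_ids,
        n_independent_losses=len(loss_ids),
        alternative_optima=alternatives,
    )


def _has_missing(node: dendropy.Node, states: Mapping[str, PresenceState]) -> bool:
    return any(
        states[l.taxon.label.replace(" ", "_")] is PresenceState.no_coverage
        for l in node.leaf_iter()
    )


def _alt_placements(node: dendropy.Node, states: Mapping[str, PresenceState]) -> int:
    """Number of single-branch placements within ``node``'s subtree that
    cover all its absent tips (the maximal one plus deeper ones)."""
    absent = {
        l.taxon.label.replace(" ", "_")
        for l in node.leaf_iter()
        if states[l.taxon.label.replace(" ", "_")] is PresenceState.absent
    }
    count = 0
    for cand in node.preorder_iter():
        tips = {l.taxon.label.replace(" ", "_") for l in cand.leaf_iter()}
        if absent <= tips:
            count += 1
    return count


def count_matrix_tallies(
    matrix: PresenceMatrix,
    meta: Sequence[SpeciesMeta],
    element_id: str,
    groups: Optional[Iterable[str]] = None,
    eutherian_only: bool = False,
) -> tuple[int, int, int]:
    """(n_present, n_with_coverage, n_total) for one element after filters."""
    by_id = {m.species_id: m for m in meta}
    selected = []
    groups = set(groups) if groups is not None else None
    for sid in sorted(by_id):
        m = by_id[sid]
        if eutherian_only and not m.is_eutherian:
            continue
        if groups is not None and m.taxon_group not in groups:
            continue
        selected.append(sid)
    n_present = sum(
        1 for sid in selected
        if matrix.state(sid, element_id) is PresenceState.present
    )
    n_cov = sum(
        1 for sid in selected
        if matrix.state(sid, element_id) is not PresenceState.no_coverage
    )
    return n_present, n_cov, len(selected)


def write_gainloss_tsv(maps: Sequence[GainLossMap], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tbranch\tevent\n")
        for m in maps:
            fh.write(f"{m.element_id}\t{m.gain_branch}\tgain\n")
            for b in sorted(m.loss_branches):
                fh.write(f"{m.element_id}\t{b}\tloss\n")


def annotate_events_newick(tree: SpeciesTree, gl: GainLossMap) -> str:
    """Newick with comment tags on gain/loss branches for one element."""
    clone = dendropy.Tree(tree.tree)
    for node, orig in zip(clone.preorder_node_iter(), tree.tree.preorder_node_iter()):
        tags = []
        if orig.branch_id == gl.gain_branch:
            tags.append(f"gain:{gl.element_id}")
        if orig.branch_id in gl.loss_branches:
            tags.append(f"loss:{gl.element_id}")
        if tags:
            node.annotations.add_new("events", ",".join(tags))
    return clone.as_string(schema="newick", suppress_annotations=False)
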