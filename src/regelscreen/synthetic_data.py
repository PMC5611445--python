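"""Phylogenetic sequence-decay simulator with ground truth.

Generates upstream-region datasets with the structure the screening
pipeline assumes: an ancestral (root) sequence carrying the four synthetic
reference elements at their anchored offsets, evolved down a rooted tree
under a single-parameter symmetric (Jukes-Cantor-style) substitution
model with per-site indels, an elevated rate multiplier on designated
pseudogene branches, and whole-element deletion events on chosen branches.

Every residue carries a persistent homology key, so the simulator can emit
the induced true alignment (``truth_alignment``) and exact per-tip element
intervals and per-motif states — the ground truth each downstream stage is
scored against.

For a branch of length ``t`` expected substitutions/site the probability
that a site differs from its parent is ``(3/4)(1 - exp(-4t/3))``; indel
events arrive at ``indel_rate * t`` per site with geometric lengths
(mean 3 bp) and are suppressed inside motif critical cores so motif-state
truth stays well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

from .consensus_conservation import Alignment
from .motif_catalog import (
    MotifCall,
    MotifDefinition,
    classify_motif_state,
    load_default_catalog,
)
from .phylo_events import SpeciesTree
from .reference_elements import ELEMENT_WINDOWS, build_templates
from .seq_model import ElementID, SpeciesMeta, UCP1Status, UpstreamRegion

logger = logging.getLogger(__name__)

#: Eight-tip demo tree: two four-tip clades with labelled stems so deletion
#: and pseudogene events can target internal branches.
DEFAULT_TREE = (
    "(((t1:0.05,t2:0.05)pair12:0.08,(t3:0.05,t4:0.05)pair34:0.08)clade14:0.05,"
    "((t5:0.05,t6:0.05)pair56:0.08,(t7:0.05,t8:0.08)pair78:0.08)clade58:0.05)root;"
)


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the study conditions emulated."""

    tree_newick: str = DEFAULT_TREE
    span: tuple[int, int] = (-10_000, 200)  # anchored simulated extent
    background_gc: float = 0.40
    indel_rate: float = 0.01  # events per site per unit branch length
    indel_mean_length: float = 3.0
    pseudogene_branches: frozenset[str] = frozenset()
    pseudogene_rate_multiplier: float = 2.0
    deletion_events: dict[str, frozenset[str]] = field(default_factory=dict)
    protect_motif_cores: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.span
        if lo >= hi:
            raise ValueError("empty simulation span")
        for eid, (wlo, whi) in ELEMENT_WINDOWS.items():
            if wlo < lo or whi > hi:
                raise ValueError(f"{eid.value} template outside simulated span")
        if self.pseudogene_rate_multiplier < 1:
            raise ValueError("rate multiplier must be >= 1")
        if not 0 <= self.indel_rate:
            raise ValueError("indel_rate must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated tips."""

    root_length: int
    anchor_offset: int
    root_sequence: str
    element_root_intervals: dict[str, tuple[int, int]]  # root coords
    tip_keys: dict[str, list[int]]
    tip_bases: dict[str, dict[int, str]]
    master_order: list[int]
    element_intervals: dict[str, dict[str, Optional[tuple[int, int]]]]
    element_survival: dict[str, dict[str, float]]
    motif_states: dict[str, list[MotifCall]]
    branch_events: dict[str, list[str]]

    def element_present(self, tip: str, element_id: str,
                        min_fraction: float = 0.5) -> bool:
        return self.element_survival[tip][element_id] >= min_fraction


@dataclass
class SimResult:
    regions: list[UpstreamRegion]
    truth: SimTruth
    meta: list[SpeciesMeta]
    tree: SpeciesTree


_BASE_STR = "ACGT"


def _jc_substitute(
    bases: np.ndarray, t: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric-model substitution along one branch (vectorized)."""
    if t <= 0 or len(bases) == 0:
        return bases
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    hit = rng.random(len(bases)) < p_change
    if hit.any():
        bases = bases.copy()
        # uniform among the three other bases
        shift = rng.integers(1, 4, size=int(hit.sum()))
        bases[hit] = (bases[hit] + shift) % 4
    return bases


def simulate_dataset(config: SimConfig) -> SimResult:
    """Evolve the ancestral upstream region down the tree.

    Deterministic for a fixed config (including seed). Returns the tip
    sequences as UpstreamRegions, the ground truth, species metadata
    (pseudogene status from the configured branches) and the parsed tree.
    """
    rng = np.random.default_rng(config.seed)
    tree = SpeciesTree.from_newick(config.tree_newick)
    branch_ids = {n.branch_id for n in tree.tree.preorder_node_iter()}
    for b in set(config.deletion_events) | set(config.pseudogene_branches):
        if b not in branch_ids:
            raise ValueError(f"unknown branch id {b!r}")

    lo, hi = config.span
    length = hi - lo
    anchor = -lo  # index of anchored position 0 in root coordinates
    templates = build_templates(background_gc=config.background_gc)
    catalog = load_default_catalog()

    # root sequence: background + element templates
    p = np.array([
        (1 - config.background_gc) / 2, config.background_gc / 2,
        config.background_gc / 2, (1 - config.background_gc) / 2,
    ])
    root = rng.choice(4, size=length, p=p).astype(np.int8)
    element_root_intervals: dict[str, tuple[int, int]] = {}
    for eid, (wlo, whi) in ELEMENT_WINDOWS.items():
        enc = np.array([_BASE_STR.index(c) for c in templates[eid]], dtype=np.int8)
        root[wlo + anchor : whi + anchor] = enc
        element_root_intervals[eid.value] = (wlo + anchor, whi + anchor)

    protected = _protected_keys(catalog, element_root_intervals) \
        if config.protect_motif_cores else frozenset()

    master: list[int] = list(range(length))
    next_key = length
    geom_p = 1.0 / config.indel_mean_length

    tip_keys: dict[str, list[int]] = {}
    tip_bases: dict[str, dict[int, str]] = {}
    branch_events: dict[str, list[str]] = {}
    pseudo_tips: set[str] = set()

    def evolve(node: dendropy.Node, keys: list[int], bases: np.ndarray,
               pseudo: bool) -> None:
        nonlocal next_key
        bid = node.branch_id  # type: ignore[attr-defined]
        events: list[str] = []
        t = node.edge.length or 0.0
        pseudo = pseudo or bid in config.pseudogene_branches
        t_eff = t * (config.pseudogene_rate_multiplier if pseudo else 1.0)
        bases = _jc_substitute(bases, t_eff, rng)

        if t_eff > 0 and config.indel_rate > 0 and len(keys) > 0:
            n_events = rng.poisson(config.indel_rate * t_eff * len(keys))
            for _ in range(n_events):
                if not keys:
                    break
                L = int(rng.geometric(geom_p))
                pos = int(rng.integers(0, len(keys)))
                if rng.random() < 0.5:  # deletion
                    delc = slice(pos, min(pos + L, len(keys)))
                    if protected and any(
                        k in protected for k in keys[delc]
                    ):
                        continue
                    keys = keys[: delc.start] + keys[delc.stop :]
                    bases = np.concatenate(
                        [bases[: delc.start], bases[delc.stop :]]
                    )
                    events.append(f"del:{L}")
                else:  # insertion after pos
                    new = list(range(next_key, next_key + L))
                    next_key += L
                    ins_bases = rng.choice(4, size=L, p=p).astype(np.int8)
                    keys = keys[: pos + 1] + new + keys[pos + 1 :]
                    bases = np.concatenate(
                        [bases[: pos + 1], ins_bases, bases[pos + 1 :]]
                    )
                    midx = master.index(keys[pos]) if pos >= 0 else -1
                    master[midx + 1 : midx + 1] = new
                    events.append(f"ins:{L}")

        for eid_set_branch, elements in config.deletion_events.items():
            if eid_set_branch != bid:
                continue
            for el in elements:
                rlo, rhi = element_root_intervals[el]
                keep = [
                    (k, i) for i, k in enumerate(keys)
                    if not (rlo <= k < rhi)
                ]
                keys = [k for k, _ in keep]
                bases = bases[[i for _, i in keep]]
                events.append(f"element_deletion:{el}")

        if events:
            branch_events[bid] = events
        if node.is_leaf():
            tip = node.taxon.label.replace(" ", "_")
            tip_keys[tip] = keys
            tip_bases[tip] = {
                k: _BASE_STR[b] for k, b in zip(keys, bases.tolist())
            }
            if pseudo:
                pseudo_tips.add(tip)
        else:
            for child in node.child_nodes():
                evolve(child, list(keys), bases.copy(), pseudo)

    root_node = tree.tree.seed_node
    evolve(root_node, list(range(length)), root.copy(), False)

    regions, meta = [], []
    element_intervals: dict[str, dict[str, Optional[tuple[int, int]]]] = {}
    element_survival: dict[str, dict[str, float]] = {}
    motif_states: dict[str, list[MotifCall]] = {}
    for tip in sorted(tip_keys):
        keys = tip_keys[tip]
        bases = tip_bases[tip]
        seq = "".join(bases[k] for k in keys)
        # the anchor is the number of tip residues whose ancestry lies 5'
        # of the root anchor plus inserted residues among them
        key_pos = {k: i for i, k in enumerate(keys)}
        anchor_idx = _anchor_index(keys, anchor, length)
        regions.append(UpstreamRegion(tip, seq, anchor_idx))
        meta.append(
            SpeciesMeta(
                tip, "Laurasiatheria",
                UCP1Status.pseudogene if tip in pseudo_tips
                else UCP1Status.intact,
            )
        )
        intervals: dict[str, Optional[tuple[int, int]]] = {}
        survival: dict[str, float] = {}
        for el, (rlo, rhi) in element_root_intervals.items():
            surviving = [key_pos[k] for k in range(rlo, rhi) if k in key_pos]
            survival[el] = len(surviving) / (rhi - rlo)
            intervals[el] = (
                (min(surviving), max(surviving) + 1) if surviving else None
            )
        element_intervals[tip] = intervals
        element_survival[tip] = survival
        motif_states[tip] = _true_motif_states(
            tip, bases, catalog, element_root_intervals
        )

    truth = SimTruth(
        root_length=length,
        anchor_offset=anchor,
        root_sequence="".join(_BASE_STR[b] for b in root.tolist()),
        element_root_intervals=element_root_intervals,
        tip_keys=tip_keys,
        tip_bases=tip_bases,
        master_order=master,
        element_intervals=element_intervals,
        element_survival=element_survival,
        motif_states=motif_states,
        branch_events=branch_events,
    )
    return SimResult(regions=regions, truth=truth, meta=meta, tree=tree)


def _anchor_index(keys: list[int], anchor_key: int, root_length: int) -> int:
    """Tip-sequence index of the root anchor: the first residue whose root
    coordinate is at or 3' of the anchor (inserted residues inherit their
    left neighbour's side)."""
    for i, k in enumerate(keys):
        if k < root_length and k >= anchor_key:
            return i
    return len(keys)


def _protected_keys(
    catalog: list[MotifDefinition],
    element_root_intervals: dict[str, tuple[int, int]],
) -> frozenset[int]:
    protected = set()
    for d in catalog:
        if not d.element or not d.expected_offset or not d.critical_core:
            continue
        if d.element not in element_root_intervals:
            continue
        base = element_root_intervals[d.element][0] + d.expected_offset[0]
        protected.update(base + i for i in d.critical_core)
    return frozenset(protected)


def _true_motif_states(
    tip: str,
    bases: dict[int, str],
    catalog: list[MotifDefinition],
    element_root_intervals: dict[str, tuple[int, int]],
) -> list[MotifCall]:
    calls = []
    for d in catalog:
        if not d.element or not d.expected_offset:
            continue
        if d.element not in element_root_intervals:
            continue
        base = element_root_intervals[d.element][0] + d.expected_offset[0]
        observed = "".join(
            bases.get(base + i, "-") for i in range(len(d.consensus))
        )
        calls.append(classify_motif_state(observed, d, species_id=tip))
    return calls


def truth_alignment(truth: SimTruth) -> Alignment:
    """The alignment induced by the true homology map: one column per key
    surviving in at least one tip, ordered by the master key order."""
    live = set()
    for keys in truth.tip_keys.values():
        live.update(keys)
    columns = [k for k in truth.master_order if k in live]
    rows = []
    for tip in sorted(truth.tip_keys):
        bases = truth.tip_bases[tip]
        rows.append((tip, "".join(bases.get(k, "-") for k in columns)))
    return Alignment(tuple(rows))
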