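"""Windowed dot-plot homology screening and element presence calling.

The dot plot scores every aligned window of ``window`` bp between two
sequences with a +match/-mismatch scheme and records a hit at the window
midpoint when the summed score reaches ``threshold`` (defaults 25 bp,
threshold 45, +5/-4: at least 17 of 25 bases must match). Hits on a common
diagonal are merged into conserved segments; an element is called present
in a species when the longest segment against the reference exceeds a
minimum conserved length (default 100 bp), absent when the search window is
covered but no such segment exists, and no_coverage when the available
sequence spans too little of the expected window to judge.

Only the forward strand is scanned: upstream regions are compared in
genomic orientation throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from Bio import Align

from .seq_model import (
    CoverageError,
    ElementDefinition,
    ElementID,
    UpstreamRegion,
    slice_upstream,
)

logger = logging.getLogger(__name__)

#: Extra sequence searched on each side of an element's expected window.
#: The enhancer search is widened further (see element_search_window): in
#: some afroinsectiphilians it sits near -7.5 kb instead of -2 to -5 kb.
DEFAULT_SEARCH_PAD = 2000
ENHANCER_SEARCH_FLOOR = -10_000


@dataclass(frozen=True)
class DotPlotParams:
    window: int = 25
    threshold: int = 45
    match_score: int = 5
    mismatch_score: int = -4

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.threshold > self.window * self.match_score:
            raise ValueError("threshold unreachable for this window/score")

    def min_matches_per_window(self) -> int:
        """Smallest number of identical bases that makes a window a hit."""
        w, m, x = self.window, self.match_score, self.mismatch_score
        # solve m*k + x*(w-k) >= threshold for integer k
        import math

        return math.ceil((self.threshold - x * w) / (m - x))


@dataclass(frozen=True)
class DotPlot:
    params: DotPlotParams
    hits: frozenset[tuple[int, int]]  # window midpoints on (a, b)
    shape: tuple[int, int]  # len(a), len(b)


@dataclass(frozen=True)
class DiagonalSegment:
    start_a: int
    start_b: int
    length: int
    mean_window_score: float

    @property
    def diagonal(self) -> int:
        return self.start_a - self.start_b

    @property
    def end_a(self) -> int:
        return self.start_a + self.length


class PresenceState(str, Enum):
    present = "present"
    absent = "absent"
    no_coverage = "no_coverage"


@dataclass(frozen=True)
class PresenceCall:
    species_id: str
    element_id: ElementID
    state: PresenceState
    located_interval: Optional[tuple[int, int]] = None  # anchored coords
    best_segment_length: Optional[int] = None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def compute_dotplot(a: str, b: str, params: DotPlotParams | None = None) -> DotPlot:
    """All window midpoints (i, j) whose aligned window meets the threshold.

    N never matches anything (including another N). Sequences shorter than
    one window produce an empty plot with a warning.
    """
    params = params or DotPlotParams()
    w = params.window
    if len(a) < w or len(b) < w:
        logger.warning("sequence shorter than window %d: empty dot plot", w)
        return DotPlot(params, frozenset(), (len(a), len(b)))
    ea, eb = _encode(a), _encode(b)
    n_mask = (ea[:, None] == ord("N")) | (eb[None, :] == ord("N"))
    match = (ea[:, None] == eb[None, :]) & ~n_mask
    score = np.where(match, params.match_score, params.mismatch_score).astype(np.int32)
    rows, cols = len(a) - w + 1, len(b) - w + 1
    acc = np.zeros((rows, cols), dtype=np.int32)
    for k in range(w):
        acc += score[k : k + rows, k : k + cols]
    si, sj = np.nonzero(acc >= params.threshold)
    half = w // 2
    hits = frozenset(zip((si + half).tolist(), (sj + half).tolist()))
    return DotPlot(params, hits, (len(a), len(b)))


def extract_diagonal_segments(plot: DotPlot, max_gap: int = 10) -> list[DiagonalSegment]:
    """Merge hits on a common diagonal into segments.

    Hits whose midpoints on the same diagonal are separated by at most
    ``max_gap`` bp fuse into one segment; the segment length is the covered
    span in bp (window-start of the first hit to window-end of the last).
    Sorted by length descending, ties by (start_a, start_b).
    """
    w = plot.params.window
    half = w // 2
    by_diag: dict[int, list[int]] = {}
    for i, j in plot.hits:
        by_diag.setdefault(i - j, []).append(i)
    segments: list[DiagonalSegment] = []
    for diag, mids in by_diag.items():
        mids.sort()
        run_start = prev = mids[0]
        for m in mids[1:] + [None]:  # type: ignore[list-item]
            if m is not None and m - prev <= max_gap:
                prev = m
                continue
            start_a = run_start - half
            length = prev - run_start + w
            segments.append(
                DiagonalSegment(
                    start_a=start_a,
                    start_b=start_a - diag,
                    length=length,
                    mean_window_score=float("nan"),
                )
            )
            if m is not None:
                run_start = prev = m
    segments.sort(key=lambda s: (-s.length, s.start_a, s.start_b))
    return segments


def element_search_window(
    ref: ElementDefinition, pad: int = DEFAULT_SEARCH_PAD
) -> tuple[int, int]:
    """Anchored search window for an element: expected window padded by
    ``pad``; the enhancer search reaches down to -10 kb to catch displaced
    enhancer boxes."""
    lo, hi = ref.expected_window
    lo, hi = lo - pad, min(hi + pad, 0)
    if ref.element_id is ElementID.enhancer:
        lo = min(lo, ENHANCER_SEARCH_FLOOR)
    return lo, hi


def call_element_presence(
    query: UpstreamRegion,
    ref: ElementDefinition,
    params: DotPlotParams | None = None,
    min_conserved_length: int = 100,
    max_gap: int = 10,
    search_pad: int = DEFAULT_SEARCH_PAD,
    min_coverage_fraction: float = 0.5,
) -> PresenceCall:
    """Present / absent / no_coverage call for one element in one species.

    present: the longest gap-merged diagonal segment between the query's
    search window and the reference exceeds ``min_conserved_length``.
    no_coverage: the covered part of the expected window is shorter than
    ``min_coverage_fraction`` of it and no qualifying segment was found.
    absent: otherwise.
    """
    params = params or DotPlotParams()
    win_lo, win_hi = element_search_window(ref, search_pad)
    exp_lo, exp_hi = ref.expected_window
    cov_lo, cov_hi = query.covered_interval()
    covered_expected = max(
        0, min(exp_hi, cov_hi) - max(exp_lo, cov_lo)
    )
    try:
        window_seq, _trunc = slice_upstream(query, win_lo, win_hi)
    except CoverageError:
        return PresenceCall(query.species_id, ref.element_id, PresenceState.no_coverage)
    window_start = max(win_lo, cov_lo)  # anchored coord of window_seq[0]

    plot = compute_dotplot(window_seq, ref.reference_sequence, params)
    segments = extract_diagonal_segments(plot, max_gap=max_gap)
    best = segments[0] if segments else None
    if best is not None and best.length > min_conserved_length:
        lo = window_start + best.start_a
        return PresenceCall(
            query.species_id,
            ref.element_id,
            PresenceState.present,
            located_interval=(lo, lo + best.length),
            best_segment_length=best.length,
        )
    if covered_expected < min_coverage_fraction * (exp_hi - exp_lo):
        return PresenceCall(query.species_id, ref.element_id, PresenceState.no_coverage)
    return PresenceCall(
        query.species_id,
        ref.element_id,
        PresenceState.absent,
        best_segment_length=best.length if best else 0,
    )


def _make_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float, mode: str
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    match: float = 5,
    mismatch: float = -4,
    gap_open: float = -10,
    gap_extend: float = -1,
) -> tuple[str, str]:
    """Optimal global alignment under affine gap scoring.

    Returns the two gapped rows. The underlying dynamic program is
    deterministic; among co-optimal alignments the first enumerated one is
    returned.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, "global")
    aln = aligner.align(a.upper(), b.upper())[0]
    return aln[0], aln[1]


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Identical non-gap columns over columns with at least one residue."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned rows differ in length")
    ident = cols = 0
    for x, y in zip(aligned_a.upper(), aligned_b.upper()):
        if x == "-" and y == "-":
            continue
        cols += 1
        if x == y and x != "-":
            ident += 1
    return ident / cols if cols else 0.0


@dataclass(frozen=True)
class HomologyHit:
    """Accepted local-alignment hit of a reference element in a query."""

    query_interval: tuple[int, int]  # anchored coords in the query
    ref_interval: tuple[int, int]    # covered part of the reference
    identity: float
    accepted_at: float               # schedule threshold that accepted it

    @property
    def element_anchor(self) -> tuple[int, int]:
        """Estimated anchored interval of the full element (extrapolating
        the clipped reference ends)."""
        qlo, qhi = self.query_interval
        rlo, rhi = self.ref_interval
        return qlo - rlo, qhi  # 3' end left as aligned


def annotate_element_by_homology(
    query: UpstreamRegion,
    ref: ElementDefinition,
    identity_schedule: tuple[float, ...] = (0.85, 0.80, 0.75, 0.70, 0.65, 0.60),
    search_pad: int = DEFAULT_SEARCH_PAD,
    min_ref_fraction: float = 0.5,
    match: float = 5,
    mismatch: float = -4,
    gap_open: float = -10,
    gap_extend: float = -1,
) -> Optional[HomologyHit]:
    """Locate the reference element in the query by local alignment.

    Mirrors iterative assembly at decreasing stringency: the best local hit
    is accepted at the first threshold of the (strictly decreasing)
    schedule its percent identity meets; if even the last fails, or the
    aligned part of the reference spans less than ``min_ref_fraction`` of
    it, returns None. On success returns the located anchored interval in
    the query and the achieved identity.
    """
    if any(x <= y for x, y in zip(identity_schedule, identity_schedule[1:])):
        raise ValueError("identity_schedule must be strictly decreasing")
    if not all(0 < t <= 1 for t in identity_schedule):
        raise ValueError("identity thresholds must be in (0, 1]")
    win_lo, win_hi = element_search_window(ref, search_pad)
    try:
        window_seq, _ = slice_upstream(query, win_lo, win_hi)
    except CoverageError:
        return None
    window_start = max(win_lo, query.covered_interval()[0])
    if len(window_seq) == 0:
        return None
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend, "local")
    alns = aligner.align(window_seq, ref.reference_sequence)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    ref_span = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
    if ref_span < min_ref_fraction * len(ref.reference_sequence):
        return None
    identity = percent_identity(aln[0], aln[1])
    for thr in identity_schedule:
        if identity >= thr:
            q_lo = int(aln.aligned[0][0][0])
            q_hi = int(aln.aligned[0][-1][1])
            r_lo = int(aln.aligned[1][0][0])
            r_hi = int(aln.aligned[1][-1][1])
            return HomologyHit(
                query_interval=(window_start + q_lo, window_start + q_hi),
                ref_interval=(r_lo, r_hi),
                identity=identity,
                accepted_at=thr,
            )
    return None


def identity_track(
    a: UpstreamRegion | str,
    b: UpstreamRegion | str,
    window: int = 100,
    step: int = 25,
) -> list[tuple[int, float]]:
    """Per-window identity along the global alignment of two sequences.

    Returns (alignment column of window start, identity) pairs; a window
    larger than the alignment collapses to a single overall value.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    sa = a.sequence if isinstance(a, UpstreamRegion) else a
    sb = b.sequence if isinstance(b, UpstreamRegion) else b
    ra, rb = global_align(sa, sb)
    if window >= len(ra):
        return [(0, percent_identity(ra, rb))]
    out = []
    for s in range(0, len(ra) - window + 1, step):
        out.append((s, percent_identity(ra[s : s + window], rb[s : s + window])))
    return out
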