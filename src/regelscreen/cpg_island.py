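"""Sliding-window CpG-island detection.

Implements the Gardiner-Garden & Frommer criteria: a stretch longer than
``min_length`` bp whose 100 bp windows have an observed/expected CpG ratio
above 0.6 and a G+C fraction above 0.5. The observed/expected statistic for
a window of length L with n_C cytosines, n_G guanines and n_CpG CpG
dinucleotides is ``n_CpG * L / (n_C * n_G)`` (0 when either count is 0).

A qualifying window marks every position it covers; maximal marked runs at
least ``min_length`` long are reported (union semantics, no smoothing).
N bases count as neither C nor G and break CpG pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CpGParams:
    window: int = 100
    shift: int = 1
    min_length: int = 200
    min_obs_exp: float = 0.6
    min_gc: float = 0.5

    def __post_init__(self) -> None:
        if self.window < 10:
            raise ValueError("window must be >= 10")
        if self.min_length < self.window:
            raise ValueError("min_length must be >= window")
        if not 0 < self.min_obs_exp <= 2:
            raise ValueError("min_obs_exp must be in (0, 2]")
        if not 0 < self.min_gc <= 1:
            raise ValueError("min_gc must be in (0, 1]")
        if self.shift < 1:
            raise ValueError("shift must be >= 1")


@dataclass(frozen=True)
class CpGIslandCall:
    """A detected island, half-open in the scanned region's coordinates."""

    start: int
    end: int
    mean_obs_exp: float
    mean_gc: float

    def __len__(self) -> int:
        return self.end - self.start


def count_cpg(seq: str) -> int:
    """Number of CpG dinucleotides (C immediately followed by G)."""
    return seq.upper().count("CG")


def obs_exp_ratio(seq: str) -> float:
    """Observed/expected CpG ratio of ``seq``; 0 if it has no C or no G."""
    s = seq.upper()
    n_c, n_g = s.count("C"), s.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    return count_cpg(s) * len(s) / (n_c * n_g)


def gc_fraction(seq: str) -> float:
    s = seq.upper()
    if not s:
        return 0.0
    return (s.count("C") + s.count("G")) / len(s)


def _window_stats(seq: str, params: CpGParams) -> tuple[np.ndarray, ...]:
    """Per-window start positions with O/E ratio and GC fraction."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cpg = np.zeros(len(seq), dtype=bool)
    if len(seq) > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]
    w = params.window
    cum = lambda x: np.concatenate(([0], np.cumsum(x)))
    cc, cg, ccpg = cum(is_c), cum(is_g), cum(is_cpg)
    starts = np.arange(0, len(seq) - w + 1, params.shift)
    n_c = cc[starts + w] - cc[starts]
    n_g = cg[starts + w] - cg[starts]
    # a CpG pair must lie fully inside the window
    n_cpg = ccpg[starts + w - 1] - ccpg[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where((n_c > 0) & (n_g > 0), n_cpg * w / (n_c * n_g), 0.0)
    gc = (n_c + n_g) / w
    return starts, oe, gc


def detect_cpg_islands(region: str, params: CpGParams | None = None) -> list[CpGIslandCall]:
    """Scan ``region`` and return merged islands, sorted by start.

    Positions covered by any window passing both thresholds are marked;
    maximal marked runs shorter than ``min_length`` are dropped. Reported
    intervals are trimmed to the outermost qualifying window edges. A region
    shorter than one window yields an empty list with a warning.
    """
    params = params or CpGParams()
    seq = region.upper()
    if len(seq) < params.window:
        logger.warning(
            "region of length %d shorter than window %d; no scan",
            len(seq), params.window,
        )
        return []
    starts, oe, gc = _window_stats(seq, params)
    ok = (oe > params.min_obs_exp) & (gc > params.min_gc)
    marked = np.zeros(len(seq), dtype=bool)
    for s in starts[ok]:
        marked[s : s + params.window] = True

    calls: list[CpGIslandCall] = []
    padded = np.concatenate(([False], marked, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a < params.min_length:
            continue
        in_run = ok & (starts >= a) & (starts + params.window <= b)
        calls.append(
            CpGIslandCall(
                start=int(a),
                end=int(b),
                mean_obs_exp=float(oe[in_run].mean()),
                mean_gc=float(gc[in_run].mean()),
            )
        )
    return calls
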