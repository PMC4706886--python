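"""Redundancy removal: keep the L most mutually dissimilar topomaps.

Consecutive topomaps (4 ms apart at 250 Hz) are nearly identical, so most of
an answer window is redundant.  The city-block (Manhattan) distance between
each consecutive pair is ranked in descending order and, for the L
top-ranked pairs, the map that introduced the change is kept; the kept maps
are returned in temporal order.

"Pairs" means consecutive pairs (t, t+1) only — the step exists to remove
temporal redundancy, and an all-pairs variant would cost O(T^2) distances
per question for no extra coverage.  Which member of a selected pair to keep
is a convention; the later one is the default and the choice is exposed.
"""

from __future__ import annotations

import numpy as np

from .errors import ConsistencyError, DegenerateInputError, ParameterError
from .topomap import Topomap, TopomapSequence


def cityblock_distance(a: Topomap, b: Topomap) -> float:
    """Sum of |a - b| over in-mask pixels."""
    if a.shape != b.shape or not np.array_equal(a.mask, b.mask):
        raise ConsistencyError("topomaps must share grid shape and mask")
    return float(np.abs(a.pixels[a.mask] - b.pixels[b.mask]).sum())


def consecutive_distances(seq: TopomapSequence) -> np.ndarray:
    """City-block distances d_t between map_t and map_{t+1}, t = 0..L-2."""
    if len(seq) < 2:
        raise DegenerateInputError("need at least 2 topomaps")
    flat = seq.pixel_stack()[:, seq.mask]  # (n, P)
    return np.abs(np.diff(flat, axis=0)).sum(axis=1)


def select_discriminant_topomaps(
    seq: TopomapSequence, n_topomaps: int, keep: str = "later"
) -> TopomapSequence:
    """Keep the *n_topomaps* maps attached to the largest consecutive distances.

    Ties in distance are broken toward the earlier pair, so the selection is
    deterministic.  ``keep`` picks which member of each selected pair
    survives: ``"later"`` (default, the map that introduced the change) or
    ``"earlier"``.  The result preserves temporal order and has length
    exactly *n_topomaps*.
    """
    if keep not in ("later", "earlier"):
        raise ParameterError(f"keep must be 'later' or 'earlier', got {keep!r}")
    n = len(seq)
    if n < 2:
        raise DegenerateInputError("need at least 2 topomaps to rank pairs")
    if not 1 <= n_topomaps <= n - 1:
        raise ParameterError(
            f"n_topomaps must be in [1, {n - 1}] for a {n}-map sequence"
        )
    d = consecutive_distances(seq)
    # descending distance, ties by earlier pair index
    order = np.lexsort((np.arange(d.size), -d))
    top_pairs = order[:n_topomaps]
    offset = 1 if keep == "later" else 0
    kept = np.sort(top_pairs + offset)
    return TopomapSequence(seq.question_id, tuple(seq.maps[i] for i in kept))
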