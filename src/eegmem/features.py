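"""Block-wise first-order-statistic features and the question feature vector.

Each selected topomap is tiled into B x B blocks and, per block, up to five
first-order statistics of the in-mask pixel intensities are computed: mean,
standard deviation, entropy, skewness, kurtosis.  Concatenating the blocks
(row-major) gives one length-s vector per topomap, s = B*B*f.  The L
per-topomap vectors form the columns of the s x L feature matrix FM of a
question, and each row of FM is then summarised by four statistics
(mean mu_i, standard deviation delta_i, skewness sk_i, kurtosis k_i),
yielding a 4s-dimensional question vector whose length does not depend on L.

Conventions (fixed so every value is reproducible):

* population moments (n in the denominator); kurtosis is non-excess, so a
  Gaussian scores 3;
* zero-variance data has skewness 0 and kurtosis 0 by definition;
* entropy uses a 256-bin equal-width histogram in bits, with the bin range
  taken from the topomap's own min-max so blocks of one map share a scale;
  0*log(0) := 0;
* fully masked blocks emit all-zero statistics so s is identical for every
  topomap rendered on the same grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConsistencyError, ParameterError
from .topomap import Topomap, TopomapSequence

#: Canonical feature order; a FeatureSet is an in-order subset of this.
FEATURE_NAMES = ("mean", "standard_deviation", "entropy", "skewness", "kurtosis")

ENTROPY_BINS = 256


def feature_set(spec: int | Iterable[str]) -> tuple[str, ...]:
    """Normalize a feature-set spec to an ordered tuple of names.

    An integer n gives the first n features in canonical order (the
    convention used when reporting "# features" sweeps); an iterable of
    names is reordered canonically and validated.
    """
    if isinstance(spec, int):
        if not 1 <= spec <= len(FEATURE_NAMES):
            raise ParameterError(f"feature count must be 1..{len(FEATURE_NAMES)}")
        return FEATURE_NAMES[:spec]
    names = set(spec)
    unknown = names - set(FEATURE_NAMES)
    if unknown:
        raise ParameterError(f"unknown features {sorted(unknown)}")
    if not names:
        raise ParameterError("feature set must be non-empty")
    return tuple(f for f in FEATURE_NAMES if f in names)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockFeatureVector:
    """Length B*B*f feature vector of one topomap."""

    values: np.ndarray
    time_index: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ConsistencyError("non-finite feature value")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FeatureMatrix:
    """s x L matrix; column j is the j-th selected topomap's feature vector."""

    values: np.ndarray
    question_id: str = ""
    time_indices: tuple[int, ...] = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ConsistencyError("feature matrix must be 2-D and non-empty")
        object.__setattr__(self, "values", v)

    @property
    def s(self) -> int:
        return self.values.shape[0]

    @property
    def n_topomaps(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class QuestionFeatureVector:
    """4s-dimensional aggregated representation of one question."""

    values: np.ndarray
    question_id: str = ""
    label: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ConsistencyError("non-finite feature value")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------


def _moments(x: np.ndarray, axis=-1):
    """Population mean, SD, skewness, kurtosis; skew = kurt = 0 at zero SD.

    "Zero SD" is judged relative to the data's mean square so constant
    blocks are degenerate even when cancellation leaves m2 ~ eps^2.
    """
    mu = x.mean(axis=axis)
    d = x - np.expand_dims(mu, axis)
    m2 = (d**2).mean(axis=axis)
    floor = (x**2).mean(axis=axis) * 1e-26
    nonzero = m2 > floor
    sd = np.where(nonzero, np.sqrt(m2), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        sk = np.where(nonzero, (d**3).mean(axis=axis) / m2**1.5, 0.0)
        ku = np.where(nonzero, (d**4).mean(axis=axis) / m2**2, 0.0)
    return mu, sd, sk, ku


def _entropy(x: np.ndarray, value_range: tuple[float, float]) -> float:
    lo, hi = value_range
    if x.size == 0:
        return 0.0
    if hi <= lo:  # constant topomap: a single occupied bin
        return 0.0
    counts, _ = np.histogram(x, bins=ENTROPY_BINS, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def block_stats(
    pixels: np.ndarray,
    features: int | Iterable[str] = FEATURE_NAMES,
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """First-order statistics of one block's in-mask pixels, in feature order.

    *value_range* is the histogram range used by the entropy feature; the
    pipeline passes the enclosing topomap's min-max so all blocks of one map
    share a scale.  It defaults to the block's own range.  Empty blocks
    return all zeros.
    """
    fs = feature_set(features)
    x = np.asarray(pixels, dtype=float).ravel()
    if x.size == 0:
        return np.zeros(len(fs))
    mu, sd, sk, ku = _moments(x)
    out = []
    for name in fs:
        if name == "mean":
            out.append(float(mu))
        elif name == "standard_deviation":
            out.append(float(sd))
        elif name == "entropy":
            rng = value_range if value_range is not None else (x.min(), x.max())
            out.append(_entropy(x, rng))
        elif name == "skewness":
            out.append(float(sk))
        else:  # kurtosis
            out.append(float(ku))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Per-topomap vectors and the feature matrix
# ---------------------------------------------------------------------------


def _block_slices(n: int, b: int) -> list[slice]:
    edges = np.linspace(0, n, b + 1).round().astype(int)
    return [slice(edges[i], edges[i + 1]) for i in range(b)]


def topomap_feature_vector(
    tmap: Topomap, blocks_per_side: int, features: int | Iterable[str] = FEATURE_NAMES
) -> BlockFeatureVector:
    """Tile a topomap into B x B blocks and concatenate their statistics.

    Blocks tile the full pixel grid in row-major order (masked corner blocks
    included, emitting zeros) so the vector length B*B*f is the same for
    every map on a grid.
    """
    fm = sequence_feature_matrix(
        TopomapSequence(question_id="", maps=(tmap,)), blocks_per_side, features
    )
    return BlockFeatureVector(fm.values[:, 0], time_index=tmap.time_index)


def sequence_feature_matrix(
    seq: TopomapSequence,
    blocks_per_side: int,
    features: int | Iterable[str] = FEATURE_NAMES,
) -> FeatureMatrix:
    """Feature matrix FM (s x L) of a selected-topomap sequence.

    Equivalent to stacking :func:`topomap_feature_vector` per map, but the
    block loop is shared across maps so long sequences stay cheap.
    """
    fs = feature_set(features)
    b = int(blocks_per_side)
    h, w = seq.maps[0].shape
    if not 1 <= b <= min(h, w):
        raise ParameterError(f"blocks_per_side must be in [1, {min(h, w)}]")
    n_maps = len(seq)
    f = len(fs)
    want_entropy = "entropy" in fs
    stack = seq.pixel_stack()  # (L, H, W)
    mask = seq.mask
    if want_entropy:
        in_mask = stack[:, mask]
        vmin = in_mask.min(axis=1)
        vmax = in_mask.max(axis=1)
    out = np.zeros((b * b * f, n_maps))
    block = 0
    for rs in _block_slices(h, b):
        for cs in _block_slices(w, b):
            sel = mask[rs, cs]
            row0 = block * f
            block += 1
            if not sel.any():
                continue
            vals = stack[:, rs, cs][:, sel]  # (L, n_pix)
            mu, sd, sk, ku = _moments(vals, axis=1)
            for j, name in enumerate(fs):
                if name == "mean":
                    out[row0 + j] = mu
                elif name == "standard_deviation":
                    out[row0 + j] = sd
                elif name == "skewness":
                    out[row0 + j] = sk
                elif name == "kurtosis":
                    out[row0 + j] = ku
                else:
                    out[row0 + j] = [
                        _entropy(vals[l], (vmin[l], vmax[l])) for l in range(n_maps)
                    ]
    return FeatureMatrix(
        out,
        question_id=seq.question_id,
        time_indices=tuple(m.time_index for m in seq.maps),
    )


def build_feature_matrix(
    vectors: Sequence[BlockFeatureVector], question_id: str = ""
) -> FeatureMatrix:
    """Stack per-topomap vectors (temporal order) into the s x L matrix."""
    if not vectors:
        raise ParameterError("need at least one feature vector")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ConsistencyError(f"ragged feature-vector lengths {sorted(lengths)}")
    return FeatureMatrix(
        np.column_stack([v.values for v in vectors]),
        question_id=question_id,
        time_indices=tuple(v.time_index for v in vectors),
    )


# ---------------------------------------------------------------------------
# Row aggregation to the question vector
# ---------------------------------------------------------------------------


def aggregate_feature_matrix(
    fm: FeatureMatrix, label: int | None = None
) -> QuestionFeatureVector:
    """Summarise each FM row across the L topomaps by (mu, delta, sk, k).

    The four row statistics use the same population-moment conventions as
    :func:`block_stats`; row quadruples are concatenated in row order, so
    the result has length 4s regardless of L.
    """
    mu, sd, sk, ku = _moments(fm.values, axis=1)
    values = np.stack([mu, sd, sk, ku], axis=1).ravel()
    return QuestionFeatureVector(values, question_id=fm.question_id, label=label)


def concat_feature_matrix(fm: FeatureMatrix) -> np.ndarray:
    """Naive column-major flattening (length s*L); kept for dimensionality
    comparison against the aggregation path, not used by the pipeline."""
    return fm.values.ravel(order="F")
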