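"""Topomap rendering: instantaneous scalp potentials as 2-D images.

The potential vector at one time sample is interpolated from the electrode
positions onto a square pixel grid covering the head disc.  Interpolation is
piecewise-linear on the Delaunay triangulation of the electrodes; pixels
inside the head disc but outside the triangulation hull are filled from the
nearest electrode.  The interpolator is therefore linear in the potential
vector, which downstream tests rely on.  Pixels outside the head disc are
NaN and flagged by the mask; every downstream statistic excludes them.

No per-map intensity normalization is applied: pixel values are raw
interpolated microvolts, so amplitude information survives into the mean
features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import QhullError

from .errors import ConsistencyError, LayoutError, ParameterError
from .io_preprocess import EEGRecording, ElectrodeLayout

DEFAULT_GRID_SIZE = 64  # divisible by both 8x8 and 16x16 block tilings


@dataclass(frozen=True)
class Topomap:
    """One interpolated scalp image: H x W pixels plus a head-disc mask."""

    pixels: np.ndarray
    mask: np.ndarray
    time_index: int = 0

    def __post_init__(self):
        pix = np.asarray(self.pixels, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if pix.shape != mask.shape or pix.ndim != 2:
            raise ConsistencyError("pixels and mask must share a 2-D shape")
        if min(pix.shape) < 8:
            raise ParameterError("topomap grid must be at least 8x8")
        if not np.all(np.isfinite(pix[mask])):
            raise ConsistencyError("non-finite pixel inside the head mask")
        object.__setattr__(self, "pixels", pix)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def masked_values(self) -> np.ndarray:
        """In-mask pixel values as a flat vector."""
        return self.pixels[self.mask]


@dataclass(frozen=True)
class TopomapSequence:
    """Time-ordered topomaps of one question's answer window."""

    question_id: str
    maps: tuple[Topomap, ...]

    def __post_init__(self):
        maps = tuple(self.maps)
        if not maps:
            raise ParameterError("empty topomap sequence")
        shape, mask = maps[0].shape, maps[0].mask
        for m in maps[1:]:
            if m.shape != shape or not np.array_equal(m.mask, mask):
                raise ConsistencyError("all maps in a sequence must share grid and mask")
        idx = [m.time_index for m in maps]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ConsistencyError("time_index must be strictly increasing")
        object.__setattr__(self, "maps", maps)

    def __len__(self) -> int:
        return len(self.maps)

    def __getitem__(self, i) -> Topomap:
        return self.maps[i]

    @property
    def mask(self) -> np.ndarray:
        return self.maps[0].mask

    def pixel_stack(self) -> np.ndarray:
        """All maps as one (L, H, W) array."""
        return np.stack([m.pixels for m in self.maps])


def grid_coordinates(layout: ElectrodeLayout, grid_size: int):
    """Pixel-center coordinates and head-disc mask for a layout's grid.

    Returns ``(xx, yy, mask)`` where all three are (grid_size, grid_size);
    row 0 is the top of the head (largest y), matching image convention.
    """
    if grid_size < 8:
        raise ParameterError("grid_size must be >= 8")
    r = layout.head_radius
    coords = np.linspace(-r, r, grid_size)
    xx, yy = np.meshgrid(coords, coords[::-1])
    mask = xx**2 + yy**2 <= r**2 * (1 + 1e-12)
    return xx, yy, mask


def _interpolators(layout: ElectrodeLayout, values: np.ndarray):
    try:
        lin = LinearNDInterpolator(layout.positions, values)
    except QhullError as exc:
        raise LayoutError(f"degenerate electrode layout: {exc}") from exc
    near = NearestNDInterpolator(layout.positions, values)
    return lin, near


def _render_stack(
    values: np.ndarray, layout: ElectrodeLayout, grid_size: int
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate an (M, T) value matrix onto the grid -> ((T, H, W), mask)."""
    xx, yy, mask = grid_coordinates(layout, grid_size)
    pts = np.column_stack([xx[mask], yy[mask]])
    lin, near = _interpolators(layout, values)
    interp = lin(pts)  # (P, T); NaN outside the convex hull
    outside = np.isnan(interp[:, 0])
    if outside.any():
        interp[outside] = near(pts[outside])
    t = values.shape[1]
    stack = np.full((t, grid_size, grid_size), np.nan)
    stack[:, mask] = interp.T
    return stack, mask


def render_topomap(
    potentials: np.ndarray,
    layout: ElectrodeLayout,
    grid_size: int = DEFAULT_GRID_SIZE,
    time_index: int = 0,
) -> Topomap:
    """Render one potential vector (length M, layout order) as a topomap."""
    v = np.asarray(potentials, dtype=float).ravel()
    if v.size != len(layout):
        raise ConsistencyError(
            f"{v.size} potentials for a {len(layout)}-electrode layout"
        )
    stack, mask = _render_stack(v[:, None], layout, grid_size)
    return Topomap(stack[0], mask, time_index=time_index)


def epoch_to_topomaps(
    epoch: EEGRecording,
    layout: ElectrodeLayout,
    grid_size: int = DEFAULT_GRID_SIZE,
    question_id: str = "",
) -> TopomapSequence:
    """Render every sample of an epoch: exactly T topomaps in temporal order.

    The epoch's channels must match the layout's; rows are aligned to the
    layout order by channel id.
    """
    if set(epoch.channel_ids) != set(layout.channel_ids):
        raise ConsistencyError("epoch channels do not match layout channels")
    order = [epoch.channel_ids.index(c) for c in layout.channel_ids]
    values = epoch.potentials[order]  # (M, T) in layout order
    stack, mask = _render_stack(values, layout, grid_size)
    maps = tuple(
        Topomap(stack[t], mask, time_index=t) for t in range(stack.shape[0])
    )
    return TopomapSequence(question_id=question_id, maps=maps)


def save_topomap_png(tmap: Topomap, path, cmap: str = "RdBu_r") -> None:
    """Diagnostic PNG export (requires matplotlib; not used by the pipeline)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.where(tmap.mask, tmap.pixels, np.nan)
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(img, cmap=cmap)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
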