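"""Per-slice fibre components and the contact/enrichment selection algebra.

A *fibre component* is a maximal 8-connected set of collagen-candidate
pixels within one slice.  Starting from the thresholded candidate masks,
the selection proceeds:

1. subtract the cell-body mask, so no candidate pixel lies inside the cell;
2. label 8-connected components per slice;
3. keep components with strictly more than ``min_size`` pixels (the
   size-filtered universe *S*);
4. keep components with at least one pixel in the 8-neighbourhood of a cell
   pixel of the *same* slice (the contact seed *S'*);
5. enrich across planes: repeatedly add any component of *S* whose (y, x)
   pixel set intersects an already-selected component in an adjacent slice,
   until a fixed point is reached.

The enrichment chain is monotone and bounded by the finite universe, so the
fixed point always exists and is independent of visit order; it preserves
fibre continuity across slices even where the fibre itself no longer
touches the cell.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from typing import Iterable, Iterator

import numpy as np
from scipy import ndimage

from .stacks import MaskStack
from .threshold import ThresholdParams

# 8-connectivity structuring elements.
STRUCT_8 = np.ones((3, 3), dtype=bool)
# Same, with the origin removed: dilation by this marks exactly the pixels
# having a true 8-neighbour (the pixel itself does not count).
STRUCT_8_NO_CENTRE = np.array(
    [[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=bool
)


@dataclasses.dataclass(frozen=True)
class FibreComponent:
    """One per-slice 8-connected pixel set.

    ``pixels`` holds ``(y, x)`` coordinate tuples; ``label`` is unique
    within its slice and assigned in raster-scan order of each component's
    first-encountered pixel, starting at 1.  Labels carry no meaning beyond
    identity.
    """

    slice_index: int
    label: int
    pixels: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("a fibre component cannot be empty")

    @property
    def key(self) -> tuple[int, int]:
        return (self.slice_index, self.label)

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclasses.dataclass(frozen=True)
class FibreSelection:
    """An unordered set of fibre components (the sets S, S' and S'k)."""

    members: frozenset[FibreComponent]

    def __post_init__(self) -> None:
        keys = {c.key for c in self.members}
        if len(keys) != len(self.members):
            raise ValueError("duplicate (slice_index, label) in selection")

    @classmethod
    def of(cls, components: Iterable[FibreComponent]) -> "FibreSelection":
        return cls(frozenset(components))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[FibreComponent]:
        return iter(self.members)

    def __contains__(self, component: FibreComponent) -> bool:
        return component in self.members

    def keys(self) -> frozenset[tuple[int, int]]:
        return frozenset(c.key for c in self.members)

    def issubset(self, other: "FibreSelection") -> bool:
        return self.members <= other.members

    def by_slice(self) -> dict[int, list[FibreComponent]]:
        out: dict[int, list[FibreComponent]] = defaultdict(list)
        for c in self.members:
            out[c.slice_index].append(c)
        return dict(out)


@dataclasses.dataclass(frozen=True)
class ExtractionConfig:
    """Parameters of the whole extraction.

    ``min_size`` is strict: components must have *more* than this many
    pixels to enter the universe S (default 5, i.e. |T| > 5).  Connectivity
    is fixed at 8.  ``enrich`` toggles the cross-plane fixed-point step.
    """

    threshold: ThresholdParams = dataclasses.field(default_factory=ThresholdParams)
    min_size: int = 5
    enrich: bool = True

    def __post_init__(self) -> None:
        if self.min_size < 0:
            raise ValueError(f"min_size must be >= 0, got {self.min_size}")


def subtract_cell(collagen: MaskStack, cell: MaskStack) -> MaskStack:
    """Remove every cell pixel from the collagen candidate masks, per slice.

    Guarantees the output is disjoint from the cell mask everywhere.
    """
    if collagen.slices.shape != cell.slices.shape:
        raise ValueError(
            f"shape mismatch: collagen {collagen.slices.shape} "
            f"vs cell {cell.slices.shape}"
        )
    return MaskStack(collagen.slices & ~cell.slices)


def label_components(mask: np.ndarray, slice_index: int) -> list[FibreComponent]:
    """8-connected components of one binary slice.

    Components partition the foreground; labels follow raster-scan order of
    each component's first-encountered pixel, starting at 1.
    """
    mask = np.asarray(mask).astype(bool)
    labelled, n = ndimage.label(mask, structure=STRUCT_8)
    if n == 0:
        return []
    # Relabel so label order follows first occurrence in raster scan.
    flat = labelled.ravel()
    nonzero = np.flatnonzero(flat)
    raw_order = flat[nonzero]
    _, first_idx = np.unique(raw_order, return_index=True)
    raw_by_first = raw_order[np.sort(first_idx)]
    remap = np.zeros(n + 1, dtype=np.int64)
    remap[raw_by_first] = np.arange(1, n + 1)
    components: list[FibreComponent] = []
    ys, xs = np.nonzero(labelled)
    new_labels = remap[labelled[ys, xs]]
    for new in range(1, n + 1):
        sel = new_labels == new
        pixels = frozenset(
            (int(y), int(x)) for y, x in zip(ys[sel], xs[sel])
        )
        components.append(FibreComponent(slice_index, new, pixels))
    return components


def components_from_stack(masks: MaskStack) -> list[list[FibreComponent]]:
    """Label every slice of a mask stack; returns one component list per slice."""
    return [label_components(masks.slices[i], i) for i in range(masks.n_slices)]


def filter_size(
    components: Iterable[FibreComponent], min_size: int
) -> FibreSelection:
    """Keep exactly the components with strictly more than ``min_size`` pixels."""
    return FibreSelection.of(c for c in components if c.size > min_size)


def _neighbour_halo(cell_slice: np.ndarray) -> np.ndarray:
    """Pixels having at least one cell pixel among their 8 neighbours
    (the pixel itself excluded)."""
    return ndimage.binary_dilation(cell_slice, structure=STRUCT_8_NO_CENTRE)


def contact_with_cell(selection: FibreSelection, cell: MaskStack) -> FibreSelection:
    """Keep components with a pixel in the 8-neighbourhood of a cell pixel
    of the same slice.

    The neighbourhood excludes the pixel itself; after :func:`subtract_cell`
    fibre and cell masks are disjoint, so self-coincidence cannot occur
    anyway.  Cross-slice contact is deliberately not considered here — that
    is the enrichment's job.
    """
    halos: dict[int, np.ndarray] = {}
    kept = []
    for comp in selection:
        i = comp.slice_index
        if not (0 <= i < cell.n_slices):
            raise IndexError(
                f"component references slice {i} but the cell mask has "
                f"{cell.n_slices} slices"
            )
        if i not in halos:
            halos[i] = _neighbour_halo(cell.slices[i])
        halo = halos[i]
        if any(halo[y, x] for y, x in comp.pixels):
            kept.append(comp)
    return FibreSelection.of(kept)


def enrichment_chain(
    seed: FibreSelection, universe: FibreSelection
) -> list[FibreSelection]:
    """The monotone chain S'1 ⊆ S'2 ⊆ … up to its fixed point.

    ``chain[0]`` is the seed; each later element adds every universe
    component whose (y, x) pixel set intersects a component already
    selected in an adjacent slice (index ±1).  Iteration stops when a round
    adds nothing; the last element is the least fixed point.
    """
    if not seed.issubset(universe):
        raise ValueError("seed selection must be a subset of the universe")
    selected: dict[tuple[int, int], FibreComponent] = {c.key: c for c in seed}
    by_slice = universe.by_slice()
    remaining = {c.key: c for c in universe if c.key not in selected}
    chain = [FibreSelection.of(selected.values())]
    while remaining:
        # Selection snapshot at the start of the round: the literal S'(k-1).
        selected_per_slice: dict[int, list[FibreComponent]] = defaultdict(list)
        for c in selected.values():
            selected_per_slice[c.slice_index].append(c)
        added = []
        for comp in remaining.values():
            for neighbour_slice in (comp.slice_index - 1, comp.slice_index + 1):
                if any(
                    comp.pixels & other.pixels
                    for other in selected_per_slice.get(neighbour_slice, ())
                ):
                    added.append(comp)
                    break
        if not added:
            break
        for comp in added:
            selected[comp.key] = comp
            del remaining[comp.key]
        chain.append(FibreSelection.of(selected.values()))
    return chain


def enrich_across_planes(
    seed: FibreSelection, universe: FibreSelection
) -> FibreSelection:
    """Least fixed point of the cross-plane enrichment (see
    :func:`enrichment_chain`).  Independent of visit order."""
    return enrichment_chain(seed, universe)[-1]


def selection_to_masks(
    selection: FibreSelection, frame_shape: tuple[int, int], n_slices: int
) -> MaskStack:
    """Render a selection as a binary mask stack (per-slice pixel union)."""
    h, w = frame_shape
    out = np.zeros((n_slices, h, w), dtype=bool)
    for comp in selection:
        if not (0 <= comp.slice_index < n_slices):
            raise IndexError(
                f"component slice {comp.slice_index} outside stack of "
                f"{n_slices} slices"
            )
        for y, x in comp.pixels:
            if not (0 <= y < h and 0 <= x < w):
                raise IndexError(
                    f"pixel ({y}, {x}) outside frame {frame_shape} "
                    f"in slice {comp.slice_index}"
                )
            out[comp.slice_index, y, x] = True
    return MaskStack(out)
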