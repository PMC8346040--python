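"""Seeded synthetic FIB-SEM-like volumes with exact ground truth.

The generator emulates the imaging situation the extraction pipeline is
built for: an invasive cell — a compact ellipsoidal body carrying a few
protrusions, each a thicker base continued by a thin filopodium-like
filament — embedded in a meshwork of tube-like collagen fibres of few-pixel
radius that cross many slices.  A configurable fraction of the fibres is
routed to touch the cell surface; the rest are kept well apart, so the
ground truth of the contact rule is unambiguous.  Intensities follow
heavy-metal EM contrast: cell and collagen dark, resin background bright,
with additive Gaussian noise and a per-slice brightness drift.

All stochastic choices (placements, angles, noise) are drawn in a fixed
order from a single generator seeded once, so a volume is bit-reproducible
from its parameters.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
from scipy import ndimage

from .fibres import STRUCT_8, STRUCT_8_NO_CENTRE
from .stacks import MaskStack, VoxelStack


class GeometryError(ValueError):
    """Raised when the requested geometry cannot be placed in the volume."""


@dataclasses.dataclass(frozen=True)
class CellParams:
    """Ellipsoidal cell body plus protrusions (base + thin filament).

    ``centre`` and ``semi_axes`` are in (z, y, x) voxels; ``None`` means
    derived from the volume shape (centred body filling roughly a third of
    each axis).  Protrusion radii/lengths are in pixels; the slice spacing
    is treated as one pixel for 3D distances.
    """

    centre: tuple[float, float, float] | None = None
    semi_axes: tuple[float, float, float] | None = None
    n_protrusions: int = 4
    base_radius: float = 4.0
    base_length: float = 12.0
    filament_radius: float = 1.5
    filament_length: float = 45.0


@dataclasses.dataclass(frozen=True)
class FibreParams:
    """Tube-like collagen fibres.

    ``touch_fraction`` of ``count`` fibres are routed to pass within one
    pixel (Chebyshev) of the cell surface in at least one slice; the others
    keep Chebyshev distance >= 3 from the cell everywhere and never come
    near another fibre, so no overlap chain can recruit them.  ``length``
    is the approximate 3D centreline length in pixels; the in-plane drift
    of the centreline is at most ``slope_max`` pixels per slice.
    """

    count: int = 20
    touch_fraction: float = 0.5
    radius_range: tuple[float, float] = (2.0, 3.0)
    length_range: tuple[float, float] = (60.0, 400.0)
    slope_max: float = 1.5

    def __post_init__(self) -> None:
        if self.radius_range[0] < 1.0:
            raise ValueError("fibre radius must be >= 1 pixel")
        if not 0.0 <= self.touch_fraction <= 1.0:
            raise ValueError("touch_fraction must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class IntensityParams:
    """Grey-level model: per-region mean + per-slice drift + Gaussian noise.

    Defaults put cell and collagen equally dark (60) against a bright resin
    background (200); the noise standard deviation defaults to 10% of the
    140-grey-level fibre/background contrast.  Drift is a sinusoidal
    per-slice brightness offset, to which a local-mean threshold is
    insensitive by construction.
    """

    background: float = 200.0
    cell: float = 60.0
    fibre: float = 60.0
    noise_sd: float = 14.0
    drift_amplitude: float = 10.0


@dataclasses.dataclass(frozen=True)
class SyntheticParams:
    shape: tuple[int, int, int] = (16, 256, 256)
    cell: CellParams = dataclasses.field(default_factory=CellParams)
    fibres: FibreParams = dataclasses.field(default_factory=FibreParams)
    intensities: IntensityParams = dataclasses.field(default_factory=IntensityParams)
    seed: int = 0


@dataclasses.dataclass
class GroundTruth:
    """Exact truth paired with a synthetic volume.

    ``fibre_labels`` assigns one global integer identity per tube (0 =
    background); fibre voxels inside the cell are removed, mirroring the
    pipeline's subtraction semantics, so labels and cell mask are disjoint.
    ``touching_ids`` are the fibres with a voxel 8-adjacent (in-plane) to
    the cell mask in at least one slice.
    """

    cell_mask: MaskStack
    fibre_labels: np.ndarray
    touching_ids: frozenset[int]

    @property
    def fibre_ids(self) -> frozenset[int]:
        ids = np.unique(self.fibre_labels)
        return frozenset(int(i) for i in ids if i != 0)

    def pixels_of(self, fibre_id: int) -> np.ndarray:
        return self.fibre_labels == fibre_id

    def recompute_touching_ids(self) -> frozenset[int]:
        """Exhaustive per-slice 8-adjacency scan against the cell mask."""
        touching = set()
        for i in range(self.cell_mask.n_slices):
            halo = ndimage.binary_dilation(
                self.cell_mask.slices[i], structure=STRUCT_8_NO_CENTRE
            )
            touching.update(
                int(v) for v in np.unique(self.fibre_labels[i][halo]) if v != 0
            )
        return frozenset(touching)

    def reachable_ids(self) -> frozenset[int]:
        """Fibres the contact rule can select: touching fibres plus every
        fibre connected to one by a chain of same-(y, x) overlaps in
        adjacent slices or 8-adjacency within a slice."""
        ids = sorted(self.fibre_ids)
        masks = {fid: self.fibre_labels == fid for fid in ids}
        adjacency: dict[int, set[int]] = {fid: set() for fid in ids}
        for a_pos, a in enumerate(ids):
            ma = masks[a]
            dilated = np.stack(
                [ndimage.binary_dilation(s, structure=STRUCT_8) for s in ma]
            )
            for b in ids[a_pos + 1 :]:
                mb = masks[b]
                linked = bool(np.any(dilated & mb))  # same-slice adjacency
                if not linked:
                    linked = bool(np.any(ma[:-1] & mb[1:])) or bool(
                        np.any(ma[1:] & mb[:-1])
                    )
                if linked:
                    adjacency[a].add(b)
                    adjacency[b].add(a)
        reachable = set(self.touching_ids)
        frontier = list(reachable)
        while frontier:
            cur = frontier.pop()
            for nxt in adjacency[cur]:
                if nxt not in reachable:
                    reachable.add(nxt)
                    frontier.append(nxt)
        return frozenset(reachable)


# ---------------------------------------------------------------------------
# geometry rasterisation


def _rasterise_segment(
    volume: np.ndarray, a: np.ndarray, b: np.ndarray, radius: float
) -> None:
    """OR into ``volume`` all voxels within ``radius`` of segment a-b
    ((z, y, x) coordinates, slice spacing treated as 1 px)."""
    nz, ny, nx = volume.shape
    lo = np.maximum(np.floor(np.minimum(a, b) - radius - 1).astype(int), 0)
    hi = np.minimum(
        np.ceil(np.maximum(a, b) + radius + 1).astype(int) + 1, (nz, ny, nx)
    )
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    pts = np.stack([zz, yy, xx], axis=-1).astype(np.float64)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        t = np.zeros(pts.shape[:-1])
    else:
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    dist2 = np.sum((pts - closest) ** 2, axis=-1)
    volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= dist2 <= radius**2


def _render_cell(
    shape: tuple[int, int, int], params: CellParams, rng: np.random.Generator
) -> np.ndarray:
    nz, ny, nx = shape
    centre = np.array(
        params.centre
        if params.centre is not None
        else (nz / 2.0, ny / 2.0, nx / 2.0)
    )
    semi = np.array(
        params.semi_axes
        if params.semi_axes is not None
        else (0.30 * nz, 0.16 * ny, 0.16 * nx)
    )
    if np.any(semi <= 0):
        raise GeometryError("cell semi-axes must be positive")
    zz, yy, xx = np.ogrid[0:nz, 0:ny, 0:nx]
    body = (
        ((zz - centre[0]) / semi[0]) ** 2
        + ((yy - centre[1]) / semi[1]) ** 2
        + ((xx - centre[2]) / semi[2]) ** 2
    ) <= 1.0
    cell = np.ascontiguousarray(body)
    for _ in range(params.n_protrusions):
        # Mostly in-plane direction: protrusions reach sideways into the matrix.
        dz = rng.uniform(-0.2, 0.2)
        angle = rng.uniform(0, 2 * np.pi)
        direction = np.array([dz, np.sin(angle), np.cos(angle)])
        direction /= np.linalg.norm(direction)
        # Distance from centre to the ellipsoid surface along this direction.
        t_surface = 1.0 / np.sqrt(np.sum((direction / semi) ** 2))
        base_start = centre + direction * (t_surface - 1.0)
        base_end = base_start + direction * params.base_length
        filament_end = base_end + direction * params.filament_length
        _rasterise_segment(cell, base_start, base_end, params.base_radius)
        _rasterise_segment(cell, base_end, filament_end, params.filament_radius)
    return cell


def _disc_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dy**2 + dx**2 <= radius**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _rasterise_tube(
    shape: tuple[int, int, int],
    z_span: tuple[int, int],
    anchor_z: int,
    anchor_yx: np.ndarray,
    slope: np.ndarray,
    radius: float,
) -> np.ndarray:
    """Per-slice disc of ``radius`` around the centreline intersection with
    each slice plane; the centreline passes through ``anchor_yx`` at
    ``anchor_z`` and drifts by ``slope`` (dy, dx) pixels per slice."""
    nz, ny, nx = shape
    out = np.zeros(shape, dtype=bool)
    offsets = _disc_offsets(radius)
    for z in range(z_span[0], z_span[1]):
        centre = anchor_yx + slope * (z - anchor_z)
        pts = np.round(centre[None, :] + offsets).astype(int)
        keep = (
            (pts[:, 0] >= 0) & (pts[:, 0] < ny) & (pts[:, 1] >= 0) & (pts[:, 1] < nx)
        )
        pts = pts[keep]
        out[z, pts[:, 0], pts[:, 1]] = True
    return out


def _touch_candidate_band(cell_slice: np.ndarray, radius: float) -> np.ndarray:
    """In-plane ring of centreline positions that put a disc of ``radius``
    just outside the cell: between ceil(radius) and ceil(radius)+1 pixels
    (8-connected dilation steps) from the cell."""
    k = int(np.ceil(radius))
    inner = ndimage.binary_dilation(cell_slice, structure=STRUCT_8, iterations=k)
    outer = ndimage.binary_dilation(inner, structure=STRUCT_8)
    return outer & ~inner


def _cell_halos(cell: np.ndarray) -> np.ndarray:
    return np.stack(
        [ndimage.binary_dilation(s, structure=STRUCT_8_NO_CENTRE) for s in cell]
    )


def _sample_span(
    rng: np.random.Generator, nz: int, fibres: FibreParams
) -> tuple[tuple[int, int], np.ndarray, float]:
    radius = float(rng.uniform(*fibres.radius_range))
    length = float(rng.uniform(*fibres.length_range))
    slope = rng.uniform(-fibres.slope_max, fibres.slope_max, size=2)
    step = float(np.sqrt(1.0 + slope @ slope))
    n_span = int(np.clip(round(length / step), 3, nz))
    z0 = int(rng.integers(0, nz - n_span + 1))
    return (z0, z0 + n_span), slope, radius


def _is_single_chain(mask: np.ndarray, z_span: tuple[int, int]) -> bool:
    """True iff every slice of the span holds one 8-connected component of
    more than five pixels and consecutive slices share a (y, x) pixel."""
    for z in range(z_span[0], z_span[1]):
        frame = mask[z]
        if int(frame.sum()) <= 5:
            return False
        _, n = ndimage.label(frame, structure=STRUCT_8)
        if n != 1:
            return False
        if z + 1 < z_span[1] and not np.any(frame & mask[z + 1]):
            return False
    return True


def generate(params: SyntheticParams) -> tuple[VoxelStack, GroundTruth]:
    """Render a seeded volume and its exact ground truth.

    Touching fibres are placed first with first-writer-wins labelling, so
    the contact pixel verified at placement time always survives into the
    label raster and ``touching_ids`` is exactly the forced set.
    """
    nz, ny, nx = params.shape
    if min(params.shape) < 3:
        raise GeometryError(f"volume shape {params.shape} is too small")
    rng = np.random.default_rng(params.seed)
    cell = _render_cell(params.shape, params.cell, rng)
    halos = _cell_halos(cell)
    # Isolated fibres must keep Chebyshev distance >= 3 from the cell.
    cell_excl = np.stack(
        [
            ndimage.binary_dilation(s, structure=STRUCT_8, iterations=2)
            for s in cell
        ]
    )

    labels = np.zeros(params.shape, dtype=np.int32)
    occupied = np.zeros(params.shape, dtype=bool)
    n_touch = int(round(params.fibres.count * params.fibres.touch_fraction))

    for fid in range(1, params.fibres.count + 1):
        touching = fid <= n_touch
        placed = False
        for _ in range(500):
            (z_lo, z_hi), slope, radius = _sample_span(rng, nz, params.fibres)
            if touching:
                anchor_z = int(rng.integers(z_lo, z_hi))
                band = _touch_candidate_band(cell[anchor_z], radius)
                band_idx = np.argwhere(band)
                if len(band_idx) == 0:
                    continue
                anchor_yx = band_idx[rng.integers(len(band_idx))].astype(float)
            else:
                anchor_z = (z_lo + z_hi) // 2
                anchor_yx = rng.uniform([0, 0], [ny, nx])
            tube = _rasterise_tube(
                params.shape, (z_lo, z_hi), anchor_z, anchor_yx, slope, radius
            )
            writable = tube & ~cell & ~occupied
            if touching:
                # Contact must hold on pixels this fibre will actually own.
                if not np.any(writable & halos):
                    continue
                # The fibre must graze the cell, not pierce it: its owned
                # pixels must form one unbroken cross-slice chain of
                # per-slice discs that each survive the strict size filter,
                # so a single contact recovers the whole tube.
                if not _is_single_chain(writable, (z_lo, z_hi)):
                    continue
            else:
                if np.any(tube & cell_excl):
                    continue
                near_others = np.zeros(params.shape, dtype=bool)
                for z in range(nz):
                    blob = occupied[max(z - 1, 0) : min(z + 2, nz)].any(axis=0)
                    near_others[z] = ndimage.binary_dilation(
                        blob, structure=STRUCT_8
                    )
                if np.any(tube & near_others):
                    continue
                if not np.any(writable):
                    continue
            labels[writable] = fid
            occupied |= tube
            placed = True
            break
        if not placed:
            raise GeometryError(
                f"could not place fibre {fid} "
                f"({'touching' if touching else 'isolated'}) in {params.shape}"
            )

    truth = GroundTruth(
        cell_mask=MaskStack(cell),
        fibre_labels=labels,
        touching_ids=frozenset(range(1, n_touch + 1)),
    )
    recomputed = truth.recompute_touching_ids()
    if recomputed != truth.touching_ids:
        raise GeometryError(
            f"contact bookkeeping inconsistent: forced {set(truth.touching_ids)} "
            f"but adjacency scan found {set(recomputed)}"
        )

    inten = params.intensities
    field = np.full(params.shape, inten.background, dtype=np.float64)
    field[labels > 0] = inten.fibre
    field[cell] = inten.cell
    phase = rng.uniform(0, 2 * np.pi)
    drift = inten.drift_amplitude * np.sin(
        2 * np.pi * np.arange(nz) / max(nz, 1) + phase
    )
    field += drift[:, None, None]
    if inten.noise_sd > 0:
        field += rng.normal(0.0, inten.noise_sd, size=params.shape)
    stack = VoxelStack(
        np.clip(np.rint(field), 0, 255).astype(np.uint8),
        provenance=f"synthetic(seed={params.seed})",
    )
    return stack, truth


# ---------------------------------------------------------------------------
# scoring


@dataclasses.dataclass
class RecoveryReport:
    """How well a predicted fibre mask matches the ground truth.

    A fibre counts as recovered (or, for fibres outside the reference set,
    falsely included) when at least half of its ground-truth pixels outside
    the cell appear in the prediction.  ``jaccard`` is the pixel-wise
    Jaccard index between the prediction and the ground-truth pixels of the
    reference fibres.
    """

    reference_ids: frozenset[int]
    recall: dict[int, float]
    recovered_ids: frozenset[int]
    missed_ids: frozenset[int]
    false_inclusion_ids: frozenset[int]
    jaccard: float

    @property
    def n_recovered(self) -> int:
        return len(self.recovered_ids & self.reference_ids)

    @property
    def n_false_inclusions(self) -> int:
        return len(self.false_inclusion_ids)


def score_against_truth(
    predicted: MaskStack,
    truth: GroundTruth,
    reference_ids: Iterable[int] | None = None,
) -> RecoveryReport:
    """Score a predicted fibre mask stack against the ground truth.

    ``reference_ids`` names the fibres the prediction is expected to
    contain; by default it is the set the contact rule can reach (touching
    fibres plus overlap-chain neighbours), since fibres isolated from the
    cell are excluded by design.  Fibres outside the reference set that are
    nevertheless recovered count as false inclusions.
    """
    if predicted.slices.shape != truth.fibre_labels.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.slices.shape} "
            f"vs truth {truth.fibre_labels.shape}"
        )
    ref = (
        truth.reachable_ids()
        if reference_ids is None
        else frozenset(int(i) for i in reference_ids)
    )
    pred = predicted.slices
    recall: dict[int, float] = {}
    for fid in sorted(truth.fibre_ids):
        mask = truth.fibre_labels == fid
        total = int(mask.sum())
        recall[fid] = float((pred & mask).sum() / total) if total else 0.0
    recovered = frozenset(fid for fid, r in recall.items() if r >= 0.5)
    ref_mask = np.isin(truth.fibre_labels, sorted(ref)) if ref else np.zeros_like(pred)
    union = int((pred | ref_mask).sum())
    jaccard = float((pred & ref_mask).sum() / union) if union else 1.0
    return RecoveryReport(
        reference_ids=ref,
        recall=recall,
        recovered_ids=recovered,
        missed_ids=frozenset(ref - recovered),
        false_inclusion_ids=frozenset(recovered - ref),
        jaccard=jaccard,
    )
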