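# Methods

## The extraction model

`fibrecontact` quantifies which collagen fibres of an extracellular matrix
are in contact with a cell, from a volumetric FIB-SEM image stack.  The
input is an ordered stack of aligned, denoised intensity slices
*I<sub>i</sub>* (axis order (z, y, x), 0-based, y downward) together with a
per-slice binary cell-body mask *C<sub>i</sub>* produced upstream (in
practice by manual segmentation).  The pipeline is a composition of set
operations on binary rasters:

1. **Local-mean adaptive threshold.**  Each slice is binarised against
   *T = mean<sub>13×13</sub> − 6*: a pixel is a collagen candidate iff its
   intensity is at or below the mean of the 13×13 window centred on it,
   minus an offset of 6 grey levels.  Out-of-bounds window samples are
   edge-replicated.  This selects locally dark structures regardless of
   slow per-slice brightness drift, which cancels inside the window mean.
2. **Cell subtraction.**  Candidate masks are cleared of every cell pixel,
   so the collagen masks *M<sub>i</sub>* and cell masks *C<sub>i</sub>* are
   disjoint by construction.
3. **Per-slice components.**  Fibre components *T<sub>p,i</sub>* are the
   maximal 8-connected pixel sets of *M<sub>i</sub>* (diagonal neighbours
   connect).
4. **Strict size filter.**  The universe *S* keeps components with
   *strictly more than* 5 pixels; a 5-pixel component is always discarded,
   a 6-pixel one always kept.
5. **Same-slice contact.**  *S′* keeps components with a pixel in the
   8-neighbourhood of a cell pixel *of the same slice* (the neighbourhood
   excludes the pixel itself; disjointness makes self-coincidence
   impossible anyway).
6. **Cross-plane enrichment.**  Starting from *S′*, each round adds every
   component of *S* whose (y, x) pixel set shares at least one position
   with an already-selected component in an adjacent slice (index ±1),
   until a round adds nothing.  The chain is monotone and bounded by the
   finite universe, so this least fixed point always exists, is reached in
   at most |S| rounds, and is independent of visit order.  It keeps a
   fibre continuous across slices even where it no longer touches the
   cell.

The final selection is exported as 0/255 binary mask images, colour
overlays on the raw data, and a per-slice CSV report
(`slice,candidates,size_filtered,contact,enriched,fibre_pixels`), whose
counts obey |S′| ≤ |S′<sub>∞</sub>| ≤ |S| ≤ candidates on every slice.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `block_size` | 13 px | adaptive-threshold window edge (odd, ≥ 3) |
| `offset` | 6 grey levels | subtracted from the local mean to form *T* |
| `polarity` | `dark_foreground` | which side of *T* is foreground |
| `min_size` | 5 px | strict lower bound on component size |
| `enrich` | on | run the cross-plane fixed point |

The threshold polarity is configurable because either binary variant of
the mean-offset rule is defensible; with a positive offset only the
dark-foreground variant maps constant regions to background and picks out
discrete dark fibres, so it is the default.  Ties (intensity exactly equal
to *T*) fall to foreground under `dark_foreground`, which makes the two
polarities exact complements.

"Neighbouring plane" always means stack index ±1 as given.  Stacks with
slices lost to acquisition errors are treated as contiguous after whatever
gap handling happened upstream; no gap bridging beyond ±1 is attempted.
The enrichment recruits only from the size-filtered universe *S*, so
sub-6-pixel fragments can never re-enter through the fixed point.

## Numerical choices

The local mean is computed from an exact int64 integral image for integer
input and divided once by `block_size²`, so the fast path is bit-identical
to a naive per-pixel window loop — including at exact ties, where a
floating-point sliding filter could flip the comparison.  Component labels
follow raster-scan order of each component's first pixel; they carry no
meaning beyond identity.  Degenerate inputs (empty masks, empty
selections, zero fibres) propagate as empty results rather than errors;
contract violations (shape mismatches, even block sizes, out-of-bounds
components, a seed not inside its universe) raise immediately with the
offending index named.

## The synthetic volume generator

No microscope data ships with the package, so every stage is exercised on
seeded synthetic volumes with exact ground truth.  The generator renders:

- a **cell**: an ellipsoid (default semi-axes 0.30·n<sub>z</sub>,
  0.16·h, 0.16·w voxels) carrying a few protrusions, each a thicker
  cylindrical base (radius 4 px, length 12 px) continued by a thin
  filopodium-like filament (radius 1.5 px, length 45 px), emulating the
  protrusive structures of invasive cells in 3D collagen;
- **collagen fibres**: tubes rasterised per slice as a disc of the fibre
  radius (default 2–3 px, so every full disc exceeds the 5-pixel bound)
  around the centreline's intersection with the slice plane; centrelines
  drift at most 1.5 px in-plane per slice, so consecutive discs always
  overlap and each tube crosses many slices;
- **intensities**: background 200, cell 60, fibre 60 grey levels (cell and
  collagen equally dark against bright resin, as in heavy-metal-stained
  EM), plus a sinusoidal per-slice brightness drift (amplitude 10) and
  additive Gaussian noise whose default sd, 14 grey levels, is 10% of the
  140-grey-level fibre/background contrast.  Values are rounded and
  clipped to 8 bits.

A configurable fraction of fibres (default half of 20) is routed to touch
the cell: the centreline is anchored on a ring one dilation step outside
the cell at the disc radius, and a placement is accepted only if the
pixels the fibre will actually own (outside the cell, not claimed by an
earlier fibre) are 8-adjacent to the cell in some slice *and* form one
unbroken chain of per-slice single-component discs, each above the size
bound, with consecutive-slice overlap.  The chain condition makes the
fibre graze the cell rather than pierce it, so a single contact provably
recovers the whole tube — without it, a tube passing through the cell
body splits into two chains of which only one is reachable, which is
correct pipeline behaviour but an ambiguous ground truth.  Isolated
fibres keep Chebyshev distance ≥ 3 from the cell in every slice and stay
clear of a one-pixel dilation of every other fibre in the same and
adjacent slices, so no overlap chain can recruit them and the expected
answer is unambiguous.  Labels are written first-writer-wins, so the
contact pixel verified at placement always survives into the label raster
and the stored `touching_ids` equals the forced set (re-verified by an
exhaustive adjacency scan at generation time).  All stochastic choices
are drawn in fixed order from one seeded generator, making volumes
bit-reproducible.

What the generator does **not** emulate: detector noise spectra, charging
and curtaining artefacts, fibre branching, curved or bundled fibres,
anisotropic voxels, and imperfect manual cell masks.  Passing the
recovery checks therefore demonstrates the correctness of the selection
algebra and its robustness to additive noise and brightness drift — not
segmentation quality on real electron micrographs, which depends on the
upstream denoising and on how well the threshold parameters suit the
actual contrast.

## Scoring

`score_against_truth` counts a fibre as recovered when at least half of
its ground-truth pixels (which exclude in-cell voxels by construction)
appear in the predicted mask; the same rule decides whether a fibre
outside the expected set counts as a false inclusion, so a handful of
stray noise pixels does not.  The pixel-wise Jaccard index is computed
against the ground-truth pixels of a *reference* fibre set, by default the
fibres the contact rule can reach (touching fibres plus anything connected
to them by same-slice adjacency or adjacent-slice overlap): fibres
isolated from the cell are excluded by design, so scoring them against
the prediction would conflate the algorithm's selectivity with its
accuracy.  Callers can override the reference set to score against all
fibres.

## Problem sizes

The correctness checks run the full algebra against literal brute-force
evaluations of the set definitions (Python flood fill, exhaustive
neighbour scans, naive iteration to stabilisation) on 200 random 32×32×8
instances, and the threshold against a per-pixel window loop on 50 random
64×64 images.  Recovery is measured on 16-slice 256×256 volumes with 20
fibres — comfortably larger than any structure scale in the model while
keeping a full run to seconds.  Under the default-noise condition the
6-grey-level offset sits at 0.43 standard deviations of the noise, so
roughly a third of background pixels speckle into the candidate masks;
touching-fibre recovery survives this (the discs stay connected and in
contact), while pixel precision degrades on seeds where speckle
percolates into cell-contacting clusters — an honest property of the
method without upstream denoising, which is why the pixel-level Jaccard
claim is made only for the noise-free condition.

## Known limitations

- Fibre connectivity within a slice is 2D (8-connected); no true 26-
  connected 3D labelling, fibre skeletonisation, or radius/orientation
  estimation is attempted.
- Two fibres touching in-plane merge into one component; the pipeline
  cannot distinguish wrapped from merely touching fibres.
- The contact rule is exactly one pixel (8-neighbourhood); there is no
  distance tolerance, and the enrichment overlap test is strict nonempty
  intersection with no dilation.
- The cell mask is trusted as given; errors in it propagate directly into
  both the subtraction and the contact decision.
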