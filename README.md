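# fibrecontact

Extraction and quantification of the collagen fibres in contact with a
cell from volumetric FIB-SEM image stacks.

Invasive cells remodel the extracellular matrix through protrusions that
grip and degrade collagen; serial FIB-SEM imaging resolves this interface
at nanometre scale, but turning a grey-value volume into "the fibres
touching this cell" takes a reproducible segmentation-and-selection
procedure.  `fibrecontact` implements that procedure for anyone analysing
cell–ECM contact in aligned, denoised EM stacks with a per-slice
cell-body mask: matrix biologists, EM facilities, and image-analysis
engineers who need the selection to be testable rather than ad hoc.

## The method

For each slice *I<sub>i</sub>* a collagen candidate mask *M<sub>i</sub>*
is produced by a local-mean adaptive threshold (window 13 px, offset 6
grey levels; a pixel is foreground iff it lies at least 6 below the mean
of its window) and cleared of the cell mask *C<sub>i</sub>*.  A fibre
component *T<sub>p,i</sub>* is a maximal 8-connected pixel set of
*M<sub>i</sub>*.  The selection algebra is then

- *S* = { *T<sub>p,i</sub>* : |*T<sub>p,i</sub>*| > 5 } — strict size filter,
- *S′* = { *T<sub>p,i</sub>* ∈ *S* : ∃ q ∈ *T<sub>p,i</sub>*, r ∈ *C<sub>i</sub>*, q ∈ N<sub>r</sub> } — contact with the cell in the same slice, with N<sub>r</sub> the 8-neighbourhood,
- *S′<sub>k</sub>* = *S′<sub>k−1</sub>* ∪ { *T<sub>p,i</sub>* ∈ *S* : *T<sub>p,i</sub>* ∩ *T<sub>q,i±1</sub>* ≠ ∅, *T<sub>q,i±1</sub>* ∈ *S′<sub>k−1</sub>* } — iterated to its fixed point *S′<sub>∞</sub>*,

so a fibre stays selected across every slice it crosses as long as it
touches the cell in at least one plane.  The result is exported as binary
masks, colour overlays and a per-slice CSV report.  A seeded synthetic
volume generator (ellipsoidal cell with filopodium-like protrusions,
tube-like fibres, EM-like contrast with noise and per-slice drift)
provides exact ground truth for testing; see `docs/methods.md`.

## Worked example

```python
import dataclasses
from fibrecontact import SyntheticParams, extract_fibres, generate, score_against_truth
from fibrecontact.synthetic import FibreParams, IntensityParams

params = SyntheticParams(
    shape=(16, 256, 256),
    fibres=FibreParams(count=20, touch_fraction=0.5),
    intensities=IntensityParams(noise_sd=0.0, drift_amplitude=0.0),
    seed=2021,
)
stack, truth = generate(params)                      # EM-like volume + ground truth
masks, stages = extract_fibres(stack, truth.cell_mask)
report = score_against_truth(masks, truth)
print(f"candidate components : {sum(len(c) for c in stages.candidates)}")
print(f"size-filtered (S)    : {len(stages.universe)}")
print(f"cell contact (S')    : {len(stages.contact)}")
print(f"after enrichment     : {len(stages.final)} "
      f"({stages.iterations} iterations to the fixed point)")
print(f"touching recovered   : {report.n_recovered}/{len(report.reference_ids)}")
print(f"isolated included    : {report.n_false_inclusions}")
print(f"pixel Jaccard        : {report.jaccard:.3f}")
```

prints

```
candidate components : 317
size-filtered (S)    : 317
cell contact (S')    : 33
after enrichment     : 157 (14 iterations to the fixed point)
touching recovered   : 10/10
isolated included    : 0
pixel Jaccard        : 1.000
```

Of 317 per-slice fibre components, 33 touch the cell in their own slice;
the cross-plane enrichment then recruits the remaining cross-sections of
those same tubes (157 components over 16 slices), recovering all 10
fibres routed to touch the cell, none of the 10 isolated ones, and every
fibre pixel.

The same run from a shell, on files:

```sh
fibrecontact --input stack.tif --cell-mask cell.tif --out results/
fibrecontact --synthetic --seed 7 --out demo/        # no data needed
```

which writes `results/masks/` (0/255 binary fibre masks), `overlays/`
(grey EM base, cell in blue, fibres in yellow), `report.csv` (per-slice
component counts through each stage) and `config_echo.json`.

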