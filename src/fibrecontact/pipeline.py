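"""End-to-end extraction: threshold -> subtract -> label -> size filter ->
contact -> enrich -> export, with a per-slice tabular report.

The library surface is :func:`extract_fibres` (arrays in, selection out);
:func:`run_pipeline` adds file I/O, logging and report writing around it
for the command-line interface.  Input stacks are assumed to be aligned
and denoised already — registration and denoising are upstream concerns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import stacks
from .fibres import (
    ExtractionConfig,
    FibreComponent,
    FibreSelection,
    components_from_stack,
    contact_with_cell,
    enrichment_chain,
    filter_size,
    selection_to_masks,
    subtract_cell,
)
from .stacks import MaskStack, VoxelStack
from .synthetic import SyntheticParams, generate, score_against_truth
from .threshold import threshold_slice

logger = logging.getLogger("fibrecontact")

REPORT_COLUMNS = [
    "slice",
    "candidates",
    "size_filtered",
    "contact",
    "enriched",
    "fibre_pixels",
]


@dataclasses.dataclass
class ExtractionStages:
    """All intermediate selections of one extraction run."""

    candidates: list[list[FibreComponent]]
    universe: FibreSelection        # S: size-filtered components
    contact: FibreSelection         # S': same-slice cell contact
    chain: list[FibreSelection]     # S'1 ... S'inf (chain[0] is S')
    final: FibreSelection           # the fixed point (or S' if enrich off)

    @property
    def iterations(self) -> int:
        """Enrichment rounds that added at least one component."""
        return len(self.chain) - 1


@dataclasses.dataclass
class ContactReport:
    """Per-slice counts plus run-level metadata.

    Counts obey the monotone chain |S'| <= |S'inf| <= |S| <= candidates on
    every slice; :meth:`validate` asserts it.
    """

    per_slice: pd.DataFrame
    iterations: int
    config: dict

    def validate(self) -> None:
        df = self.per_slice
        if (df[REPORT_COLUMNS[1:]] < 0).any().any():
            raise ValueError("negative count in contact report")
        ok = (
            (df["contact"] <= df["enriched"])
            & (df["enriched"] <= df["size_filtered"])
            & (df["size_filtered"] <= df["candidates"])
        )
        if not ok.all():
            bad = df.loc[~ok, "slice"].tolist()
            raise ValueError(f"monotone chain violated on slices {bad}")


def threshold_stack(stack: VoxelStack, config: ExtractionConfig) -> MaskStack:
    """Adaptive-threshold every slice into a collagen candidate mask stack."""
    return MaskStack(
        np.stack([threshold_slice(s, config.threshold) for s in stack.slices])
    )


def select_fibres(
    collagen: MaskStack, cell: MaskStack, config: ExtractionConfig
) -> ExtractionStages:
    """Run the selection algebra on candidate masks that are already
    thresholded: subtraction, per-slice labelling, strict size filter,
    same-slice contact, and (optionally) cross-plane enrichment."""
    cleaned = subtract_cell(collagen, cell)
    candidates = components_from_stack(cleaned)
    universe = filter_size(
        (c for per_slice in candidates for c in per_slice), config.min_size
    )
    contact = contact_with_cell(universe, cell)
    chain = enrichment_chain(contact, universe) if config.enrich else [contact]
    return ExtractionStages(
        candidates=candidates,
        universe=universe,
        contact=contact,
        chain=chain,
        final=chain[-1],
    )


def extract_fibres(
    stack: VoxelStack, cell: MaskStack, config: ExtractionConfig | None = None
) -> tuple[MaskStack, ExtractionStages]:
    """Full extraction from an intensity stack: threshold, then select.

    Returns the final fibre mask stack and every intermediate stage.
    """
    config = config or ExtractionConfig()
    if stack.slices.shape != cell.slices.shape:
        raise ValueError(
            f"shape mismatch: stack {stack.slices.shape} "
            f"vs cell mask {cell.slices.shape}"
        )
    candidates = threshold_stack(stack, config)
    stages = select_fibres(candidates, cell, config)
    masks = selection_to_masks(stages.final, stack.frame_shape, stack.n_slices)
    return masks, stages


def build_report(
    stages: ExtractionStages,
    final_masks: MaskStack,
    config: ExtractionConfig,
) -> ContactReport:
    n_slices = final_masks.n_slices
    per_slice_counts = {
        name: np.zeros(n_slices, dtype=int)
        for name in ("candidates", "size_filtered", "contact", "enriched")
    }
    for i, comps in enumerate(stages.candidates):
        per_slice_counts["candidates"][i] = len(comps)
    for name, selection in (
        ("size_filtered", stages.universe),
        ("contact", stages.contact),
        ("enriched", stages.final),
    ):
        for comp in selection:
            per_slice_counts[name][comp.slice_index] += 1
    df = pd.DataFrame(
        {
            "slice": np.arange(n_slices),
            **per_slice_counts,
            "fibre_pixels": final_masks.slices.reshape(n_slices, -1).sum(axis=1),
        }
    )[REPORT_COLUMNS]
    report = ContactReport(
        per_slice=df,
        iterations=stages.iterations,
        config=_config_dict(config),
    )
    report.validate()
    return report


def _config_dict(config: ExtractionConfig) -> dict:
    return {
        "block_size": config.threshold.block_size,
        "offset_c": config.threshold.offset,
        "polarity": config.threshold.polarity,
        "min_size": config.min_size,
        "enrich": config.enrich,
    }


@dataclasses.dataclass
class PipelineConfig:
    """One run of the pipeline: either real input paths or synthetic mode."""

    input_path: str | None = None
    cell_mask_path: str | None = None
    out_dir: str = "fibrecontact_out"
    extraction: ExtractionConfig = dataclasses.field(default_factory=ExtractionConfig)
    synthetic: SyntheticParams | None = None
    verbose: bool = False

    def __post_init__(self) -> None:
        real = self.input_path is not None and self.cell_mask_path is not None
        if real == (self.synthetic is not None):
            raise ValueError(
                "exactly one of (input stack + cell mask paths) or synthetic "
                "mode must be active"
            )


def run_pipeline(config: PipelineConfig) -> ContactReport:
    """Execute the pipeline and write masks/, overlays/, report.csv and
    config_echo.json into the output directory; returns the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = None
    if config.synthetic is not None:
        logger.info("generating synthetic volume (seed=%d)", config.synthetic.seed)
        stack, truth = generate(config.synthetic)
        cell = truth.cell_mask
        stacks.write_stack(stack, out / "synthetic" / "stack.tif")
        stacks.write_mask_stack(cell, out / "synthetic" / "cell_mask.tif")
    else:
        logger.info("reading stack %s", config.input_path)
        stack = stacks.read_stack(config.input_path, kind="intensity")
        cell = stacks.read_stack(config.cell_mask_path, kind="mask")

    masks, stages = extract_fibres(stack, cell, config.extraction)
    logger.info(
        "selection: %d candidates -> %d size-filtered -> %d contact -> "
        "%d after %d enrichment iteration(s)",
        sum(len(c) for c in stages.candidates),
        len(stages.universe),
        len(stages.contact),
        len(stages.final),
        stages.iterations,
    )
    if config.verbose:
        for i, comps in enumerate(stages.candidates):
            logger.debug("slice %d: %d candidate components", i, len(comps))

    stacks.write_mask_stack(masks, out / "masks")
    stacks.write_overlay(stack, cell, masks, out / "overlays")
    report = build_report(stages, masks, config.extraction)
    report.per_slice.to_csv(out / "report.csv", index=False)
    echo = dict(report.config)
    echo["iterations_to_fixed_point"] = report.iterations
    if config.synthetic is not None:
        echo["synthetic_seed"] = config.synthetic.seed
        recovery = score_against_truth(masks, truth)
        echo["touching_fibres_recovered"] = recovery.n_recovered
        echo["touching_fibres_total"] = len(recovery.reference_ids)
        echo["jaccard"] = recovery.jaccard
    (out / "config_echo.json").write_text(json.dumps(echo, indent=2))
    return report
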