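"""End-to-end convenience wrappers: stack(s) -> cell scores -> sample score."""

from __future__ import annotations

from typing import Optional, Sequence

from .imaging import (GTUB, PCNT, CellAssembly, ImageStack,
                      SegmentationParams, SpotDetectionParams, assemble_cells,
                      detect_spots, max_project, pair_markers,
                      pcnt_structures, segment_nuclei)
from .scoring import CellScore, SampleScore, ScoringConfig, score_cells, score_sample


def analyze_stack(
    stack: ImageStack,
    config: ScoringConfig,
    seg_params: Optional[SegmentationParams] = None,
    spot_params: Optional[SpotDetectionParams] = None,
    pairing_radius_um: float = 0.5,
    max_assignment_um: float = 5.0,
) -> tuple[list[CellAssembly], int]:
    """Project, segment, detect, (pair,) and assemble one field."""
    proj = max_project(stack)
    px = stack.pixel_size_um
    nuclei = segment_nuclei(proj["DAPI"], px, seg_params)
    spots_pcnt = detect_spots(proj[PCNT], px, channel=PCNT, params=spot_params)
    if config.mode == "dual_marker_duplicated":
        spots_gtub = detect_spots(proj[GTUB], px, channel=GTUB,
                                  params=spot_params)
        structures = pair_markers(spots_pcnt, spots_gtub, pairing_radius_um)
    else:
        structures = pcnt_structures(spots_pcnt)
    return assemble_cells(nuclei, structures, px, max_assignment_um)


def score_stacks(
    stacks: Sequence[ImageStack],
    config: ScoringConfig,
    sample_id: str = "sample",
    condition: str = "vehicle",
    **kwargs,
) -> tuple[SampleScore, list[CellScore]]:
    """Run the full pipeline over a set of fields from one sample."""
    cell_scores: list[CellScore] = []
    offset = 0
    for stack in stacks:
        assemblies, _dropped = analyze_stack(stack, config, **kwargs)
        scores = score_cells(assemblies, config)
        for s in scores:  # make ids unique across fields
            s.cell_id += offset
        offset += len(scores) + 1000
        cell_scores.extend(scores)
    return score_sample(cell_scores, config, sample_id, condition), cell_scores
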