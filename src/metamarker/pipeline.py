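"""End-to-end orchestration: preprocess, screen, both marker searches, ORA."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import enrichment, io_prep, primary, screening, secondary


@dataclass
class PipelineResult:
    matrix: io_prep.MetabolomicMatrix
    screen: pd.DataFrame
    primary_result: primary.PrimarySearchResult
    secondary_result: secondary.EnsembleResult
    primary_markers: set[str]
    secondary_markers: set[str]
    combined: set[str]
    dual_status: set[str]
    ora_primary: list[enrichment.ORAResult] | None = None
    ora_combined: list[enrichment.ORAResult] | None = None


def run_pipeline(
    raw: io_prep.MetabolomicMatrix,
    pre_cfg: io_prep.PreprocessConfig | None = None,
    fit_cfg: primary.FitnessConfig | None = None,
    ga_cfg: primary.GAConfig | None = None,
    ens_cfg: secondary.EnsembleConfig | None = None,
    noise: secondary.NoiseModel | None = None,
    annotations: list[enrichment.PathwayAnnotation] | None = None,
) -> PipelineResult:
    """Run the full marker-discovery workflow on a raw abundance matrix.

    Primary markers are the union of metabolites over the GA-retained
    combinations; secondary markers are the ensemble-consensus selection.
    When pathway annotations are supplied, ORA is run for the primary set and
    for the primary+secondary union against the measured-metabolite universe.
    """
    m = io_prep.preprocess(raw, pre_cfg)
    screen = screening.screen_metabolites(m)
    prim = primary.ga_search(m, ga_cfg, fit_cfg)
    sec = secondary.run_ensemble(m, ens_cfg, nm=noise)
    primary_set = set().union(*(c.metabolite_ids for c in prim.combinations))
    secondary_set = sec.selected
    combined, dual = enrichment.combine_marker_sets(primary_set, secondary_set)
    result = PipelineResult(
        matrix=m,
        screen=screen,
        primary_result=prim,
        secondary_result=sec,
        primary_markers=primary_set,
        secondary_markers=secondary_set,
        combined=combined,
        dual_status=dual,
    )
    if annotations:
        universe = {
            mid
            for mid in m.metabolite_ids
            if any(mid in a.members for a in annotations)
        }
        if universe:
            result.ora_primary = enrichment.ora(
                primary_set & universe, annotations, universe
            )
            result.ora_combined = enrichment.ora(
                combined & universe, annotations, universe
            )
    return result
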