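"""End-to-end orchestration: classify, estimate bias, correct, evaluate.

This is the driver used by the analysis scripts and the acceptance tests:
starting from an AsvTable, a ReferenceSet and a MorphologyTable it runs the
full de-biasing workflow and returns every intermediate product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias import (
    BiasProfile,
    ReferenceComposition,
    build_reference_composition,
    close,
    estimate_bias_profile,
)
from .classify import ClassificationResult, classify_table, collapse_to_species
from .io import AsvTable, PipelineConfig, ReferenceSet
from .morphology import CorrectionFactors, MorphologyTable, apply_correction, train_from_sample
from .stats import BiasReductionReport, aitchison, bias_reduction_report, bray_curtis

logger = logging.getLogger(__name__)

CELL_MOCK_CLASSES = ("even_mock", "staggered_mock", "spike_in")


@dataclass
class PipelineResult:
    classifications: dict[str, ClassificationResult]
    species: pd.DataFrame
    category_fractions: pd.DataFrame
    flagged_samples: list[str]
    sample_info: pd.DataFrame
    references: dict[str, ReferenceComposition]
    bias_profile: BiasProfile
    factors: CorrectionFactors
    corrected: dict[str, pd.Series]
    distances: pd.DataFrame
    report: BiasReductionReport


def sample_info_frame(table: AsvTable) -> pd.DataFrame:
    rows = [
        {
            "sample_id": m.sample_id,
            "sample_class": m.sample_class,
            "protocol": m.protocol or "",
            "buffer": m.buffer or "",
            "input_cells": m.input_cells if m.input_cells is not None else np.nan,
        }
        for m in table.metadata
    ]
    return pd.DataFrame(rows).set_index("sample_id")


def build_references(
    species: pd.DataFrame,
    dna_design: dict[str, str],
    expected: dict[str, pd.Series],
) -> dict[str, ReferenceComposition]:
    """Reference composition per cell-mock class.

    Mock classes with DNA-mock replicates use their pooled (geometric-mean)
    DNA composition restricted to the design taxa; the spike-in class falls
    back to its nominal expected composition (it has no DNA mock).
    """
    references: dict[str, ReferenceComposition] = {}
    by_class: dict[str, list[pd.Series]] = {}
    for sample_id, sclass in dna_design.items():
        if sample_id not in species.index:
            logger.warning("DNA mock %s missing from species table", sample_id)
            continue
        taxa = expected[sclass].index
        row = species.loc[sample_id].reindex(taxa).fillna(0.0)
        if row.sum() <= 0:
            continue
        by_class.setdefault(sclass, []).append(close(row))
    for sclass, reps in by_class.items():
        references[sclass] = build_reference_composition(reps, source="dna_mock")
    for sclass, comp in expected.items():
        if sclass not in references and sclass in CELL_MOCK_CLASSES:
            references[sclass] = ReferenceComposition(source="expected", composition=close(comp.copy()))
    return references


def default_training_samples(
    sample_info: pd.DataFrame,
    training_class: str = "even_mock",
    training_cells: float = 1e6,
) -> dict[str, str]:
    """protocol -> sample_id of the designated training sample.

    By default the 10^6-cell even mock of each protocol.
    """
    out: dict[str, str] = {}
    mask = (sample_info["sample_class"] == training_class) & (
        np.isclose(sample_info["input_cells"], training_cells)
    )
    for sample_id, row in sample_info[mask].iterrows():
        if row["protocol"]:
            out[row["protocol"]] = sample_id
    return out


def _aligned_pair(observed: pd.Series, reference: pd.Series) -> tuple[pd.Series, pd.Series] | None:
    obs = observed.reindex(reference.index).fillna(0.0)
    if obs.sum() <= 0:
        return None
    return close(obs), reference


def run_pipeline(
    table: AsvTable,
    refs: ReferenceSet,
    morph: MorphologyTable,
    config: PipelineConfig,
    dna_design: dict[str, str],
    expected: dict[str, pd.Series],
    training_cells: float = 1e6,
    metric: str = "bray_curtis",
    seed: int = 0,
) -> PipelineResult:
    """Run the complete mock de-biasing workflow.

    ``dna_design`` maps DNA-mock sample ids to the cell-mock class they
    reference; ``expected`` maps each mock class to its designed
    composition (used for the staggered evaluability threshold and as the
    spike-in reference). Correction factors are trained on the
    ``training_cells`` even-mock sample of each protocol and applied to
    every cell-mock sample; distances to the reference composition are
    reported before and after correction.
    """
    results = classify_table(table, refs, config)
    species, fractions, flagged = collapse_to_species(table, results, config.accept_lv)
    info = sample_info_frame(table)
    references = build_references(species, dna_design, expected)
    profile = estimate_bias_profile(species, info, references, config, expected=expected)
    training = default_training_samples(info, training_cells=training_cells)
    factors = train_from_sample(training, profile, morph)
    group_of = {t: morph.group_of(t) for t in morph.table.index}
    dist = bray_curtis if metric == "bray_curtis" else aitchison

    corrected: dict[str, pd.Series] = {}
    rows = []
    for sample_id in species.index:
        row = info.loc[sample_id]
        sclass = row["sample_class"]
        if sclass not in references or sclass not in CELL_MOCK_CLASSES:
            continue
        if sample_id in flagged:
            continue
        ref = references[sclass].composition
        pair = _aligned_pair(species.loc[sample_id], ref)
        if pair is None:
            continue
        obs, ref_aligned = pair
        protocol = row["protocol"]
        try:
            corr = apply_correction(obs, factors, protocol, group_of, mode=config.correction_mode)
        except KeyError as exc:
            logger.warning("sample %s not corrected: %s", sample_id, exc)
            continue
        corrected[sample_id] = corr
        rows.append(
            {
                "sample_id": sample_id,
                "sample_class": sclass,
                "protocol": protocol,
                "input_cells": row["input_cells"],
                "metric": metric,
                "distance_before": dist(obs, ref_aligned),
                "distance_after": dist(corr, ref_aligned),
            }
        )
    distances = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "sample_class",
            "protocol",
            "input_cells",
            "metric",
            "distance_before",
            "distance_after",
        ],
    )
    if len(distances):
        report = bias_reduction_report(distances, strata=["sample_class", "protocol"])
    else:
        report = BiasReductionReport(per_sample=distances, summary=pd.DataFrame())
    return PipelineResult(
        classifications=results,
        species=species,
        category_fractions=fractions,
        flagged_samples=flagged,
        sample_info=info,
        references=references,
        bias_profile=profile,
        factors=factors,
        corrected=corrected,
        distances=distances,
        report=report,
    )
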