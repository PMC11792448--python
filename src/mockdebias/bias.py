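"""Compositional estimation of taxon-specific extraction bias.

The model treats observed mock relative abundances as a multiplicative
distortion of the input composition: ``observed_i ∝ reference_i * bias_i``.
Because compositions are scale-free, bias is identifiable only up to a
constant, so every bias vector is centered to geometric mean 1 over its
taxon subset. The reference composition is the DNA mock (the same taxa
supplied as purified DNA, bypassing extraction) or the nominal expected
composition for spike-in communities.

Per sample, bias is the centered element-wise ratio observed/reference;
per protocol, dilutions are treated as replicates and pooled by
element-wise geometric mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PipelineConfig

logger = logging.getLogger(__name__)


def geometric_mean(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(values))))


def close(composition: pd.Series) -> pd.Series:
    """Closure: rescale a positive vector to sum 1."""
    total = composition.sum()
    if total <= 0:
        raise ValueError("cannot close a non-positive composition")
    return composition / total


def center_to_gm1(values: pd.Series) -> pd.Series:
    """Rescale a positive vector to geometric mean 1 (the scale-free bias form)."""
    return values / geometric_mean(values.to_numpy())


@dataclass
class ReferenceComposition:
    source: str  # "dna_mock" | "expected"
    composition: pd.Series  # closed over its taxon subset


@dataclass
class BiasProfile:
    """Per-sample and per-protocol centered multiplicative bias estimates.

    ``pooled_bias`` pools dilutions of the primary (training) mock class per
    protocol; ``pooled_by_class`` keeps the per-protocol pool of every mock
    class separately, since different mock designs cover different taxa.
    """

    per_sample_bias: dict[str, pd.Series] = field(default_factory=dict)
    pooled_bias: dict[str, pd.Series] = field(default_factory=dict)
    pooled_by_class: dict[tuple[str, str], pd.Series] = field(default_factory=dict)

    def per_sample_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": sid, "taxon": t, "bias": b}
            for sid, vec in self.per_sample_bias.items()
            for t, b in vec.items()
        ]
        return pd.DataFrame(rows, columns=["sample_id", "taxon", "bias"])

    def pooled_frame(self) -> pd.DataFrame:
        rows = [
            {"protocol": p, "taxon": t, "bias": b}
            for p, vec in self.pooled_bias.items()
            for t, b in vec.items()
        ]
        return pd.DataFrame(rows, columns=["protocol", "taxon", "bias"])


def build_reference_composition(replicates: list[pd.Series], source: str = "dna_mock") -> ReferenceComposition:
    """Pool DNA-mock replicate compositions into one reference.

    Replicates are combined by element-wise geometric mean and re-closed,
    matching the multiplicative structure of the bias model. Taxa at zero in
    any replicate have no defined geometric mean and are excluded with a
    warning (they cannot serve as bias denominators anyway).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    taxa = replicates[0].index
    for r in replicates[1:]:
        if not r.index.equals(taxa):
            raise ValueError("replicates must share a taxon set")
    mat = np.vstack([r.to_numpy(dtype=float) for r in replicates])
    positive = (mat > 0).all(axis=0)
    if not positive.all():
        dropped = list(taxa[~positive])
        logger.warning("taxa undetected in a DNA-mock replicate, excluded from reference: %s", dropped)
    gm = np.exp(np.mean(np.log(mat[:, positive]), axis=0))
    comp = close(pd.Series(gm, index=taxa[positive]))
    return ReferenceComposition(source=source, composition=comp)


def select_evaluable_taxa(
    reference: ReferenceComposition,
    mock_type: str,
    config: PipelineConfig,
    expected: pd.Series | None = None,
) -> list[str]:
    """Taxa over which bias is estimated for a given mock type.

    Even and spike-in mocks use every reference taxon. In the staggered mock
    only taxa with expected relative abundance >= staggered_min_expected are
    evaluable — rarer members are not consistently detected and their
    near-zero counts would dominate log-scale statistics. ``expected`` is
    the designed composition (defaults to the reference itself).
    """
    taxa = list(reference.composition.index)
    if mock_type != "staggered_mock":
        return taxa
    exp = reference.composition if expected is None else expected
    return [t for t in taxa if t in exp.index and exp[t] >= config.staggered_min_expected]


def estimate_sample_bias(
    observed: pd.Series,
    reference: ReferenceComposition,
    taxon_subset: list[str],
) -> pd.Series | None:
    """Centered ratio estimate of one sample's multiplicative bias.

    Taxa undetected (zero) in the sample are dropped rather than imputed;
    if fewer than two evaluable taxa remain the sample is excluded (None).
    """
    ref = reference.composition
    subset = [t for t in taxon_subset if t in ref.index and t in observed.index]
    if any(ref[t] <= 0 for t in subset):
        raise ValueError("non-positive reference entry in taxon subset")
    detected = [t for t in subset if observed[t] > 0]
    if len(detected) < 2:
        return None
    ratio = observed[detected] / ref[detected]
    return center_to_gm1(ratio)


def pool_protocol_bias(per_sample: list[pd.Series]) -> pd.Series:
    """Element-wise geometric mean of per-sample bias vectors, re-centered.

    Samples estimated on different taxon subsets are reduced to the
    intersection (with a warning).
    """
    if not per_sample:
        raise ValueError("no samples to pool")
    common = per_sample[0].index
    for vec in per_sample[1:]:
        common = common.intersection(vec.index)
    if len(common) == 0:
        raise ValueError("no common taxa across samples")
    if any(len(vec) != len(common) for vec in per_sample):
        logger.warning("pooling bias over taxon intersection of %d taxa", len(common))
    mat = np.vstack([np.log(vec[common].to_numpy(dtype=float)) for vec in per_sample])
    pooled = pd.Series(np.exp(mat.mean(axis=0)), index=common)
    return center_to_gm1(pooled)


def estimate_bias_profile(
    species: pd.DataFrame,
    sample_info: pd.DataFrame,
    references: dict[str, ReferenceComposition],
    config: PipelineConfig,
    expected: dict[str, pd.Series] | None = None,
    primary_class: str = "even_mock",
) -> BiasProfile:
    """Estimate per-sample and pooled per-protocol bias for all mock samples.

    ``species`` holds closed species-level compositions (samples x taxa);
    ``sample_info`` carries sample_id-indexed columns sample_class and
    protocol; ``references`` maps each cell-mock sample class to its
    reference composition. Dilutions are treated as replicates and pooled
    per protocol within each mock class (designs cover different taxa);
    ``pooled_bias`` exposes the pool of ``primary_class``.
    """
    profile = BiasProfile()
    by_key: dict[tuple[str, str], list[pd.Series]] = {}
    for sample_id in species.index:
        info = sample_info.loc[sample_id]
        sclass = info["sample_class"]
        if sclass not in references:
            continue
        reference = references[sclass]
        exp = None if expected is None else expected.get(sclass)
        subset = select_evaluable_taxa(reference, sclass, config, expected=exp)
        vec = estimate_sample_bias(species.loc[sample_id], reference, subset)
        if vec is None:
            logger.warning("sample %s excluded: fewer than 2 evaluable taxa detected", sample_id)
            continue
        profile.per_sample_bias[sample_id] = vec
        protocol = info["protocol"]
        if isinstance(protocol, str) and protocol:
            by_key.setdefault((sclass, protocol), []).append(vec)
    for (sclass, protocol), vecs in sorted(by_key.items()):
        pooled = pool_protocol_bias(vecs)
        profile.pooled_by_class[(sclass, protocol)] = pooled
        if sclass == primary_class:
            profile.pooled_bias[protocol] = pooled
    return profile
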