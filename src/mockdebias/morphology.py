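"""Morphology-group summarization of extraction bias and its correction.

Extraction bias is driven largely by how hard a cell is to lyse, which
tracks coarse morphology: gram stain / cell-wall thickness and cell shape.
Summarizing per-taxon bias by the geometric mean within each morphology
group yields one multiplicative correction factor per (group, protocol)
pair — e.g. 3 groups x 8 protocols = 24 factors — which transfer to taxa
never seen in the training mock, as long as their group is known. Observed
relative abundances are corrected by dividing by the factor of the taxon's
group and re-closing.

Group membership is configuration data supplied as a TSV (taxon, gram,
shape, group); the package does not hard-code any organism's group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bias import BiasProfile, close, geometric_mean

logger = logging.getLogger(__name__)

GRAM_LEVELS = ("positive", "negative", "indeterminate_thick_wall")
SHAPE_LEVELS = ("ovoid", "rod")


@dataclass
class MorphologyTable:
    """taxon -> (gram, shape, group) annotation."""

    table: pd.DataFrame  # index taxon, columns gram, shape, group

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise ValueError("duplicate taxon in morphology table")
        bad_gram = set(self.table["gram"]) - set(GRAM_LEVELS)
        if bad_gram:
            raise ValueError(f"unknown gram levels: {sorted(bad_gram)}")
        bad_shape = set(self.table["shape"]) - set(SHAPE_LEVELS)
        if bad_shape:
            raise ValueError(f"unknown shape levels: {sorted(bad_shape)}")

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def group_of(self, taxon: str) -> str:
        if taxon not in self.table.index:
            raise KeyError(f"taxon {taxon!r} missing from morphology table")
        return self.table.loc[taxon, "group"]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MorphologyTable":
        df = pd.read_csv(path, sep="\t", index_col="taxon")
        return cls(df[["gram", "shape", "group"]])

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="taxon")


@dataclass
class CorrectionFactors:
    """group x protocol multiplicative factors, applied by division."""

    factors: pd.DataFrame  # index group, columns protocol, positive reals
    training_sample_id: str | None = None
    provenance: dict[str, list[str]] = field(default_factory=dict)  # group -> taxa used

    def __post_init__(self) -> None:
        vals = self.factors.to_numpy(dtype=float)
        if np.isfinite(vals).all() and (vals <= 0).any():
            raise ValueError("correction factors must be positive")

    @property
    def n_factors(self) -> int:
        return int(self.factors.notna().to_numpy().sum())

    def factor(self, group: str, protocol: str) -> float:
        try:
            f = self.factors.loc[group, protocol]
        except KeyError:
            raise KeyError(f"no correction factor for group {group!r} under protocol {protocol!r}")
        if pd.isna(f):
            raise KeyError(f"no correction factor for group {group!r} under protocol {protocol!r}")
        return float(f)

    def long_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "protocol": p, "factor": self.factors.loc[g, p]}
            for g in self.factors.index
            for p in self.factors.columns
            if not pd.isna(self.factors.loc[g, p])
        ]
        return pd.DataFrame(rows, columns=["group", "protocol", "factor"])

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CorrectionFactors":
        df = pd.read_csv(path, sep="\t")
        wide = df.pivot(index="group", columns="protocol", values="factor")
        return cls(factors=wide)

    def write_tsv(self, path: str | Path) -> None:
        self.long_frame().to_csv(path, sep="\t", index=False)


def summarize_bias_by_group(
    per_taxon_bias: dict[str, pd.Series],
    morph: MorphologyTable,
    training_sample_id: str | None = None,
) -> CorrectionFactors:
    """Geometric mean of per-taxon bias within each morphology group.

    ``per_taxon_bias`` maps protocol -> centered bias vector. Every biased
    taxon must carry a group annotation; groups with no biased taxon under a
    protocol are left missing and flagged.
    """
    protocols = sorted(per_taxon_bias)
    groups = morph.groups
    factors = pd.DataFrame(np.nan, index=groups, columns=protocols)
    provenance: dict[str, set[str]] = {g: set() for g in groups}
    for protocol in protocols:
        vec = per_taxon_bias[protocol]
        by_group: dict[str, list[float]] = {}
        for taxon, b in vec.items():
            g = morph.group_of(taxon)  # raises naming the taxon if missing
            by_group.setdefault(g, []).append(float(b))
            provenance[g].add(taxon)
        for g in groups:
            if g in by_group:
                factors.loc[g, protocol] = geometric_mean(np.array(by_group[g]))
            else:
                logger.warning("group %s absent from training data under protocol %s", g, protocol)
    return CorrectionFactors(
        factors=factors,
        training_sample_id=training_sample_id,
        provenance={g: sorted(t) for g, t in provenance.items()},
    )


def apply_correction(
    observed: pd.Series,
    factors: CorrectionFactors,
    protocol: str,
    group_of: dict[str, str],
    mode: str = "strict",
) -> pd.Series:
    """Divide observed relative abundances by their group's factor, re-close.

    In strict mode a taxon with no group (or no factor for its group under
    this protocol) is an error; lenient mode passes it through with factor 1
    and a warning, which is the sensible behavior for environmental samples
    where only annotatable taxa can be corrected.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    corrected = observed.astype(float).copy()
    for taxon in observed.index:
        try:
            g = group_of[taxon]
            f = factors.factor(g, protocol)
        except KeyError as exc:
            if mode == "strict":
                raise KeyError(f"cannot correct taxon {taxon!r}: {exc}") from exc
            logger.warning("taxon %s left uncorrected (factor 1): %s", taxon, exc)
            continue
        corrected[taxon] = observed[taxon] / f
    return close(corrected)


def train_from_sample(
    training_sample_ids: dict[str, str],
    bias_profile: BiasProfile,
    morph: MorphologyTable,
) -> CorrectionFactors:
    """Build correction factors from one designated training sample per protocol.

    ``training_sample_ids`` maps protocol -> sample_id of the training
    sample (e.g. the 10^6-cell even mock); protocols whose training sample
    has no bias estimate are omitted with a warning.
    """
    per_protocol: dict[str, pd.Series] = {}
    for protocol, sample_id in sorted(training_sample_ids.items()):
        vec = bias_profile.per_sample_bias.get(sample_id)
        if vec is None:
            logger.warning("no bias estimate for training sample %s (protocol %s); omitted", sample_id, protocol)
            continue
        per_protocol[protocol] = vec
    if not per_protocol:
        logger.warning("no training samples available; returning empty factors")
        return CorrectionFactors(factors=pd.DataFrame(), training_sample_id=None)
    label = ",".join(sorted(set(training_sample_ids.values())))
    return summarize_bias_by_group(per_protocol, morph, training_sample_id=label)
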