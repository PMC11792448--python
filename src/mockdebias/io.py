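"""Domain types, file I/O and configuration shared by all pipeline stages.

The pipeline starts from denoised amplicon data: a samples x ASVs count
matrix, one nucleotide sequence per ASV, and per-sample metadata describing
the mock design (sample class, extraction protocol, bacterial input cells).
Reference 16S sequences for the mock taxa are read from FASTA with one or
more copy variants per taxon, trimmed to a fixed window length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SAMPLE_CLASSES = (
    "even_mock",
    "staggered_mock",
    "spike_in",
    "skin",
    "negative_control",
    "dna_mock",
    "pcr_control",
)
KITS = ("Q", "Z")
LYSES = ("S", "T")
BUFFERS = ("q", "z")

_VALID_SEQ = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class SampleMetadata:
    """One row of the sample sheet.

    ``input_cells`` is the bacterial input cell number of the dilution
    series and is absent (None) for DNA mocks and controls. The extraction
    protocol renders as ``kit_lysis_buffer`` (e.g. ``Q_T_z``).
    """

    sample_id: str
    sample_class: str
    kit: str | None = None
    lysis: str | None = None
    buffer: str | None = None
    input_cells: float | None = None

    def __post_init__(self) -> None:
        if self.sample_class not in SAMPLE_CLASSES:
            raise ValueError(f"unknown sample_class {self.sample_class!r}")
        for value, levels, name in (
            (self.kit, KITS, "kit"),
            (self.lysis, LYSES, "lysis"),
            (self.buffer, BUFFERS, "buffer"),
        ):
            if value is not None and value not in levels:
                raise ValueError(f"unknown {name} level {value!r}")
        if self.input_cells is not None and self.input_cells < 0:
            raise ValueError("input_cells must be non-negative")

    @property
    def protocol(self) -> str | None:
        if None in (self.kit, self.lysis, self.buffer):
            return None
        return f"{self.kit}_{self.lysis}_{self.buffer}"


@dataclass
class ReferenceSet:
    """Per-taxon lists of trimmed 16S copy-variant sequences."""

    variants: dict[str, list[str]]
    trim_len: int

    def __post_init__(self) -> None:
        for taxon, seqs in self.variants.items():
            if not seqs:
                raise ValueError(f"taxon {taxon!r} has no variants")
            for s in seqs:
                if len(s) != self.trim_len:
                    raise ValueError(
                        f"variant of {taxon!r} has length {len(s)} != trim_len {self.trim_len}"
                    )

    @property
    def taxa(self) -> list[str]:
        return list(self.variants)

    def iter_variants(self) -> Iterable[tuple[str, str]]:
        for taxon, seqs in self.variants.items():
            for s in seqs:
                yield taxon, s


@dataclass
class AsvTable:
    """Samples x ASVs count matrix plus ASV sequences and sample metadata.

    ``counts`` is indexed by sample_id (rows) and ASV id (columns); row
    order matches ``metadata`` order.
    """

    counts: pd.DataFrame
    asv_sequences: dict[str, str]
    metadata: list[SampleMetadata]

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative count in ASV table")
        ids = [m.sample_id for m in self.metadata]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in metadata")
        if list(self.counts.index) != ids:
            raise ValueError("counts row order does not match metadata order")
        missing = [a for a in self.counts.columns if a not in self.asv_sequences]
        if missing:
            raise ValueError(f"ASVs without sequence: {missing[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def meta(self, sample_id: str) -> SampleMetadata:
        for m in self.metadata:
            if m.sample_id == sample_id:
                return m
        raise KeyError(sample_id)


@dataclass
class PipelineConfig:
    """All thresholds of the triage/bias pipeline, with their defaults.

    trim_len          reference window length in bp
    accept_lv         max Levenshtein distance for an ASV to count as its taxon
    error_lv_max      upper edge of the sequence-error band
    chimera_lv_min    smallest distance at which the chimera check starts
    chimera_cov_frac  fraction of the ASV that must be covered by exact
                      reference segments for a chimera call
    lcs_floor         shortest common substring still accepted as a segment
    kmeans_k          clusters for contaminant profiling
    staggered_min_expected  expected-abundance floor for evaluable taxa in
                      the staggered mock
    zero_count / zero_relabund  replacement values for zeros ahead of
                      log-scale computations
    """

    trim_len: int = 279
    accept_lv: int = 4
    error_lv_max: int = 8
    chimera_lv_min: int = 9
    chimera_cov_frac: float = 0.95
    lcs_floor: int = 20
    max_chimera_parts: int = 3
    kmeans_k: int = 4
    min_prevalence: int = 3
    origin_ratio_threshold: float = 5.0
    staggered_min_expected: float = 0.0007
    zero_count: float = 0.5
    zero_relabund: float = 1e-5
    correction_mode: str = "strict"  # or "lenient"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


def min_chimera_coverage(cov_frac: float, trim_len: int) -> int:
    """Smallest integer number of bases strictly exceeding cov_frac * trim_len.

    At the defaults (0.95, 279) this is 266: a chimera call requires more
    than 95% of the ASV to be exactly explained by reference segments.
    """
    return int(np.floor(cov_frac * trim_len + 1e-9)) + 1


# ---------------------------------------------------------------------------
# readers / writers


def read_reference_fasta(path: str | Path, trim_len: int, primer_pattern: str | None = None) -> ReferenceSet:
    """Read reference copy variants named ``<taxon>_<variant>`` and trim.

    The taxon is the record id up to the last underscore. Sequences are
    uppercased, optionally stripped of a leading primer matched by
    ``primer_pattern``, then truncated to their first ``trim_len`` bases.
    Records shorter than ``trim_len`` or containing non-ACGT characters
    (including IUPAC ambiguity codes) are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if trim_len < 1:
        raise ValueError("trim_len must be >= 1")
    variants: dict[str, list[str]] = {}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if primer_pattern is not None:
            m = re.match(primer_pattern, seq)
            if m:
                seq = seq[m.end():]
        if not _VALID_SEQ.match(seq):
            bad = sorted(set(seq) - set("ACGT"))
            raise ValueError(
                f"record {rec.id!r} contains non-ACGT characters {bad}; "
                "IUPAC ambiguity codes are not supported"
            )
        if len(seq) < trim_len:
            raise ValueError(f"record {rec.id!r} shorter than trim_len ({len(seq)} < {trim_len})")
        if "_" not in rec.id:
            raise ValueError(f"record id {rec.id!r} does not follow '<taxon>_<variant>'")
        taxon = rec.id.rsplit("_", 1)[0]
        variants.setdefault(taxon, []).append(seq[:trim_len])
    if not seen:
        raise ValueError(f"no records in {path}")
    return ReferenceSet(variants=variants, trim_len=trim_len)


def write_reference_fasta(refs: ReferenceSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=f"{taxon}_{i + 1}", description="")
        for taxon, seqs in refs.variants.items()
        for i, seq in enumerate(seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


_META_COLS = ["sample_id", "sample_class", "kit", "lysis", "buffer", "input_cells"]


def _metadata_from_frame(df: pd.DataFrame) -> list[SampleMetadata]:
    out = []
    for _, row in df.iterrows():
        def opt(col):
            v = row.get(col)
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                return None
            return v
        cells = opt("input_cells")
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                sample_class=str(row["sample_class"]),
                kit=opt("kit"),
                lysis=opt("lysis"),
                buffer=opt("buffer"),
                input_cells=float(cells) if cells is not None else None,
            )
        )
    return out


def read_asv_table(counts_path: str | Path, seqs_path: str | Path, metadata_path: str | Path) -> AsvTable:
    """Assemble an AsvTable from a TSV count matrix, ASV sequences and metadata.

    The count matrix has sample_id as its first column; sequences come as
    FASTA or a two-column TSV (asv_id, sequence); metadata is a TSV with the
    SampleMetadata columns. Samples present in only one of counts/metadata
    are an error, as are ASVs without a sequence or negative counts.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.index.name = None
    counts.columns.name = None
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative count in count table")

    seqs_path = Path(seqs_path)
    asv_sequences: dict[str, str] = {}
    first = seqs_path.read_text().lstrip()[:1]
    if first == ">":
        for rec in SeqIO.parse(str(seqs_path), "fasta"):
            asv_sequences[rec.id] = str(rec.seq).upper()
    else:
        df = pd.read_csv(seqs_path, sep="\t", header=None, names=["asv_id", "sequence"])
        asv_sequences = dict(zip(df["asv_id"].astype(str), df["sequence"].str.upper()))

    meta_df = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    metadata = _metadata_from_frame(meta_df)
    meta_ids = [m.sample_id for m in metadata]
    missing_meta = set(counts.index) - set(meta_ids)
    if missing_meta:
        raise ValueError(f"samples in counts but not metadata: {sorted(missing_meta)}")
    missing_counts = set(meta_ids) - set(counts.index)
    if missing_counts:
        raise ValueError(f"samples in metadata but not counts: {sorted(missing_counts)}")
    counts = counts.loc[meta_ids]
    no_seq = [a for a in counts.columns if a not in asv_sequences]
    if no_seq:
        raise ValueError(f"ASVs without sequence: {no_seq[:5]}")
    return AsvTable(counts=counts.astype(np.int64), asv_sequences=asv_sequences, metadata=metadata)


def write_asv_table(table: AsvTable, counts_path: str | Path, seqs_path: str | Path, metadata_path: str | Path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="sample_id")
    lines = [f"{a}\t{s}" for a, s in table.asv_sequences.items()]
    Path(seqs_path).write_text("\n".join(lines) + "\n")
    rows = []
    for m in table.metadata:
        rows.append({
            "sample_id": m.sample_id,
            "sample_class": m.sample_class,
            "kit": m.kit or "",
            "lysis": m.lysis or "",
            "buffer": m.buffer or "",
            "input_cells": "" if m.input_cells is None else repr(m.input_cells),
        })
    pd.DataFrame(rows, columns=_META_COLS).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# compositional primitives


def tss_normalize(values) -> pd.Series:
    """Total sum scaling: close a vector of counts to relative abundances.

    Raises on an all-zero (empty) sample.
    """
    s = pd.Series(values, dtype=float)
    if (s < 0).any():
        raise ValueError("negative value in counts")
    total = s.sum()
    if total <= 0:
        raise ValueError("empty sample: all counts are zero")
    return s / total


def replace_zeros(values, mode: str) -> pd.Series:
    """Replace zeros ahead of log-scale computations; no renormalization.

    mode='count' replaces zero counts by 0.5; mode='relabund' replaces zero
    relative abundances by 1e-5 (both configurable via PipelineConfig).
    Nonzero entries are untouched, so the operation is idempotent.
    """
    s = pd.Series(values, dtype=float)
    if (s < 0).any():
        raise ValueError("negative value")
    if mode == "count":
        fill = 0.5
    elif mode == "relabund":
        fill = 1e-5
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = s.copy()
    out[out == 0] = fill
    return out
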