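"""Reference-based triage of ASVs against the mock community.

Each ASV sequence is compared against every reference copy variant by
Levenshtein (edit) distance. The minimum distance drives a banded
classification:

* LV = 0                -> exact match
* 1 <= LV <= error_lv_max -> sequence error, assigned to the closest taxon
  (ties resolved by a nucleotide-substitution-model distance)
* LV > error_lv_max     -> candidate chimera: the sequence is greedily
  segmented into longest common substrings shared with reference variants;
  if more than chimera_cov_frac of the ASV is exactly explained by segments
  from two or three distinct taxa it is called a chimera, otherwise it is
  left unclassified (contaminants, foreign taxa, higher-order chimeras).

Accepted ASVs (LV <= accept_lv) are collapsed to species-level compositions;
the 5..error_lv_max band still counts as "sequence error" for triage
reporting but is excluded from the accepted composition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import edlib
import pandas as pd
from Bio import Align

from .io import AsvTable, PipelineConfig, ReferenceSet, min_chimera_coverage, tss_normalize

logger = logging.getLogger(__name__)

AMBIGUOUS = "ambiguous"


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions + indels) between two sequences."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def min_lv_to_references(seq: str, refs: ReferenceSet) -> tuple[int, set[str]]:
    """Minimum Levenshtein distance over all copy variants of all taxa.

    Returns the minimum and the full set of taxa achieving it.
    """
    best = math.inf
    argmin: set[str] = set()
    for taxon, variant in refs.iter_variants():
        d = levenshtein(seq, variant)
        if d < best:
            best = d
            argmin = {taxon}
        elif d == best:
            argmin.add(taxon)
    if not argmin:
        raise ValueError("empty reference set")
    return int(best), argmin


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-0.5,
    open_end_gap_score=0,
    extend_end_gap_score=0,
)


def _mismatch_proportion(a: str, b: str) -> float:
    """Mismatch proportion over paired columns of an end-gap-free alignment."""
    aln = _aligner.align(a, b)[0]
    blocks_a, blocks_b = aln.aligned
    paired = 0
    mismatches = 0
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        for off in range(ea - sa):
            paired += 1
            if a[sa + off] != b[sb + off]:
                mismatches += 1
    if paired == 0:
        return 1.0
    return mismatches / paired


def jukes_cantor_distance(a: str, b: str) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3) on an end-gap-free alignment.

    Undefined (p >= 0.75) distances are returned as +inf.
    """
    p = _mismatch_proportion(a, b)
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def resolve_ambiguous(seq: str, candidates: set[str], refs: ReferenceSet) -> str:
    """Break a Levenshtein tie between candidate taxa with a DNA evolution model.

    For each candidate, the closest copy variant (by LV) is aligned to the
    ASV and a Jukes-Cantor distance computed; the candidate with the smallest
    model distance wins. Ties within 1e-12 stay ``"ambiguous"``.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidates")
    dists: dict[str, float] = {}
    for taxon in candidates:
        closest = min(refs.variants[taxon], key=lambda v: levenshtein(seq, v))
        dists[taxon] = jukes_cantor_distance(seq, closest)
    best = min(dists.values())
    winners = [t for t, d in dists.items() if d - best <= 1e-12]
    if len(winners) > 1 or math.isinf(best):
        return AMBIGUOUS
    return winners[0]


@dataclass
class ChimeraCall:
    parent_pair: tuple[str, str]
    parts: list[tuple[str, int, int]]  # (taxon, start, end) half-open on the ASV
    covered_bases: int
    is_trimera: bool


@dataclass
class ClassificationResult:
    asv_id: str
    category: str  # exact | sequence_error | chimera | unclassified
    min_lv: int
    best_taxon: str | None = None
    chimera: ChimeraCall | None = None


class LcsIndex:
    """Seed-and-extend index for longest common substrings with the references.

    Every k-mer of every reference variant is indexed (k = lcs_floor). Any
    common substring of length >= k contains a shared k-mer, so extending
    each seed hit to its maximal exact run finds the true longest common
    substring whenever it is at least k long — and shorter runs are below
    the segmentation floor anyway.
    """

    def __init__(self, refs: ReferenceSet, k: int = 20):
        if k < 4:
            raise ValueError("k-mer size below 4 is not practical")
        self.k = k
        self.variants: list[tuple[str, str]] = list(refs.iter_variants())
        self.kmers: dict[str, list[tuple[int, int]]] = {}
        for vi, (_taxon, seq) in enumerate(self.variants):
            for pos in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[pos : pos + k], []).append((vi, pos))

    def best_match(self, masked_seq: str) -> tuple[int, int, str] | None:
        """(length, start_in_seq, taxon) of the longest unmasked shared run.

        Ties break by leftmost start on the ASV, then taxon name. Masked
        positions are sentinel characters and can neither seed nor extend.
        """
        k = self.k
        n = len(masked_seq)
        best_key = None
        best = None
        seen: set[tuple[int, int, int]] = set()
        for i in range(n - k + 1):
            window = masked_seq[i : i + k]
            if "#" in window:
                continue
            for vi, pos in self.kmers.get(window, ()):
                taxon, variant = self.variants[vi]
                li, lp = i, pos
                while li > 0 and lp > 0 and masked_seq[li - 1] == variant[lp - 1]:
                    li -= 1
                    lp -= 1
                run_id = (vi, lp - li, li)  # variant, diagonal, run start
                if run_id in seen:
                    continue
                seen.add(run_id)
                ri, rp = i + k, pos + k
                m = len(variant)
                while ri < n and rp < m and masked_seq[ri] == variant[rp]:
                    ri += 1
                    rp += 1
                key = (-(ri - li), li, taxon)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (ri - li, li, taxon)
        return best


def detect_chimera(
    seq: str,
    refs: ReferenceSet,
    min_cov: int,
    max_parts: int = 3,
    lcs_floor: int = 20,
    index: LcsIndex | None = None,
) -> ChimeraCall | None:
    """Greedy longest-common-substring segmentation of a candidate chimera.

    Repeatedly finds the longest exact substring shared between the
    still-unmasked part of the ASV and any reference variant, records it as a
    (taxon, interval) part and masks it, stopping after ``max_parts`` parts
    or when the best remaining run drops below ``lcs_floor``. The sequence is
    called a chimera iff the parts cover at least ``min_cov`` bases of the
    ASV and involve exactly two or three distinct taxa. Ties between equally
    long segments break by leftmost start on the ASV, then taxon name.
    """
    if min_cov > len(seq):
        logger.warning("min_cov %d exceeds sequence length %d; cannot call chimera", min_cov, len(seq))
        return None
    if index is None or index.k != lcs_floor:
        index = LcsIndex(refs, k=lcs_floor)
    masked = list(seq)
    parts: list[tuple[str, int, int]] = []
    covered = 0
    for round_no in range(max_parts):
        found = index.best_match("".join(masked))
        if found is None:
            break
        length, start, taxon = found
        if length < lcs_floor:
            break
        parts.append((taxon, start, start + length))
        covered += length
        for i in range(start, start + length):
            masked[i] = "#"
        # remaining rounds can each cover at most the current (longest-first) run
        if covered + (max_parts - round_no - 1) * length < min_cov:
            return None
    distinct = {t for t, _, _ in parts}
    if covered < min_cov or len(distinct) not in (2, 3):
        return None
    by_len = sorted(parts, key=lambda p: (-(p[2] - p[1]), p[1], p[0]))
    pair: list[str] = []
    for taxon, _, _ in by_len:
        if taxon not in pair:
            pair.append(taxon)
        if len(pair) == 2:
            break
    parts_sorted = sorted(parts, key=lambda p: p[1])
    return ChimeraCall(
        parent_pair=(pair[0], pair[1]),
        parts=parts_sorted,
        covered_bases=covered,
        is_trimera=len(parts) == 3,
    )


def classify_asv(
    seq: str,
    refs: ReferenceSet,
    config: PipelineConfig,
    asv_id: str = "",
    index: LcsIndex | None = None,
) -> ClassificationResult:
    """Classify one ASV into exact / sequence_error / chimera / unclassified."""
    min_lv, argmin = min_lv_to_references(seq, refs)
    if min_lv == 0:
        taxon = next(iter(argmin)) if len(argmin) == 1 else resolve_ambiguous(seq, argmin, refs)
        return ClassificationResult(asv_id, "exact", min_lv, best_taxon=taxon)
    if min_lv <= config.error_lv_max:
        taxon = next(iter(argmin)) if len(argmin) == 1 else resolve_ambiguous(seq, argmin, refs)
        return ClassificationResult(asv_id, "sequence_error", min_lv, best_taxon=taxon)
    call = detect_chimera(
        seq,
        refs,
        min_cov=min_chimera_coverage(config.chimera_cov_frac, config.trim_len),
        max_parts=config.max_chimera_parts,
        lcs_floor=config.lcs_floor,
        index=index,
    )
    if call is not None:
        return ClassificationResult(asv_id, "chimera", min_lv, chimera=call)
    return ClassificationResult(asv_id, "unclassified", min_lv)


def classify_table(table: AsvTable, refs: ReferenceSet, config: PipelineConfig) -> dict[str, ClassificationResult]:
    """Classify every ASV of a table (each unique sequence once)."""
    index = LcsIndex(refs, k=config.lcs_floor)
    return {
        asv_id: classify_asv(table.asv_sequences[asv_id], refs, config, asv_id=asv_id, index=index)
        for asv_id in table.counts.columns
    }


def classification_frame(results: dict[str, ClassificationResult]) -> pd.DataFrame:
    """Flatten classification results into a TSV-ready frame."""
    rows = []
    for asv_id, r in results.items():
        parts = ""
        covered = ""
        if r.chimera is not None:
            parts = ";".join(f"{t}:{s}-{e}" for t, s, e in r.chimera.parts)
            covered = r.chimera.covered_bases
        rows.append({
            "asv_id": asv_id,
            "category": r.category,
            "best_taxon": r.best_taxon or "",
            "min_lv": r.min_lv,
            "covered_bases": covered,
            "parts": parts,
        })
    return pd.DataFrame(rows)


def collapse_to_species(
    table: AsvTable,
    results: dict[str, ClassificationResult],
    accept_lv: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Collapse accepted ASVs to per-sample species-level compositions.

    ASVs at LV <= accept_lv with an unambiguous taxon are summed per taxon
    and TSS-normalized. The 5..error_lv_max band, chimeras and unclassified
    ASVs are excluded from the species table but accounted for in the
    per-sample category-fraction summary (exact / error / chimera /
    unclassified read fractions, which partition every sample's reads).

    Returns (species composition frame, fraction summary frame, list of
    flagged samples with zero accepted reads).
    """
    taxa = sorted({r.best_taxon for r in results.values() if r.best_taxon and r.best_taxon != AMBIGUOUS})
    frac_cols = ["exact", "sequence_error", "chimera", "unclassified"]
    species = pd.DataFrame(0.0, index=table.counts.index, columns=taxa)
    fractions = pd.DataFrame(0.0, index=table.counts.index, columns=frac_cols)
    flagged: list[str] = []
    counts = table.counts
    for asv_id in counts.columns:
        r = results[asv_id]
        fractions[r.category] += counts[asv_id]
        if r.min_lv <= accept_lv and r.best_taxon and r.best_taxon != AMBIGUOUS:
            species[r.best_taxon] += counts[asv_id]
    totals = counts.sum(axis=1).astype(float)
    nonzero = totals > 0
    fractions.loc[nonzero] = fractions.loc[nonzero].div(totals[nonzero], axis=0)
    for sample_id in species.index:
        row_sum = species.loc[sample_id].sum()
        if row_sum <= 0:
            flagged.append(sample_id)
        else:
            species.loc[sample_id] = tss_normalize(species.loc[sample_id]).to_numpy()
    return species, fractions, flagged
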