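"""Fully ground-truthed synthetic mock-community experiments.

The generator emulates the structure of a mock-community dilution study:

* a reference set of synthetic 16S windows, several copy variants per
  taxon, all taxon pairs well separated except one engineered close pair
  (emulating near-identical species such as E. coli / S. enterica);
* even, staggered and spike-in cell mocks over a dilution series of
  bacterial input cells, extracted under eight protocols (kit x lysis x
  buffer) whose taxon-specific multiplicative bias is structured by
  morphology group (log-bias = group mean + within-group spread);
* DNA mocks (bias-free references), negative controls and skin samples;
* sequencing artifacts with the dependencies the analysis assumes:
  recurrent and random sequence-error ASVs, chimeras whose fraction grows
  with input cells and whose parents favor abundant and similar taxa,
  reagent contaminants whose fraction decays as C/(C+N), and directional
  cross-contamination between mock and environmental samples.

Everything is labeled: per-read provenance, planted bias, designed
compositions and contaminant origins are returned as a GroundTruth object
so every pipeline stage can be scored against the truth.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import levenshtein
from .io import (
    AsvTable,
    ReferenceSet,
    SampleMetadata,
    write_asv_table,
    write_reference_fasta,
)
from .morphology import MorphologyTable

BASES = np.array(list("ACGT"))

DEFAULT_PROTOCOLS = tuple(
    f"{k}_{l}_{b}" for k, l, b in itertools.product("QZ", "ST", "qz")
)
DEFAULT_GROUPS = ("thick_wall_ovoid", "gram_pos_rod", "gram_neg_rod")
_GROUP_MORPHOLOGY = {
    "thick_wall_ovoid": ("indeterminate_thick_wall", "ovoid"),
    "gram_pos_rod": ("positive", "rod"),
    "gram_neg_rod": ("negative", "rod"),
}


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic experiment.

    Rates are read fractions; dilutions are bacterial input cell numbers.
    ``chimera_rate_max`` is the chimeric read fraction reached at the top
    of the dilution series (``n_max`` cells) and scales linearly with input
    cells; ``contaminant_cells`` is a fixed reagent load whose read share
    C/(C+N) decays with input. ``sampling='exact'`` replaces multinomial
    read sampling by expected (real-valued) counts for noiseless runs.
    """

    seed: int = 0
    n_taxa: int = 8
    n_spike_taxa: int = 3
    variants_per_taxon: int = 3
    trim_len: int = 279
    close_pair_lv: int = 6
    inter_taxon_min_lv: int = 20
    protocols: tuple[str, ...] = DEFAULT_PROTOCOLS
    groups: tuple[str, ...] = DEFAULT_GROUPS
    group_log_bias_means: dict | None = None  # (group, protocol) -> float
    within_group_log_sd: float = 0.2
    dilutions: tuple[float, ...] = (1e4, 1e5, 1e6, 1e7, 1e8)
    depth: int = 30_000
    sampling: str = "multinomial"  # or "exact"
    mock_types: tuple[str, ...] = ("even", "staggered")
    include_spike_in: bool = True
    n_dna_replicates: int = 2
    n_negative_controls: int = 1
    n_skin_samples: int = 4
    n_skin_taxa: int = 10
    random_error_rate: float = 0.002
    n_recurrent_error_asvs: int = 3
    recurrent_error_rate: float = 0.003
    chimera_rate_max: float = 0.13
    n_max: float = 1e8
    similarity_lambda: float = 30.0
    contaminant_cells: float = 200.0
    n_contaminant_asvs_per_origin: int = 4
    # reagent contamination is dominated by the buffer kitome, whose profile
    # is consistent across samples of a buffer; skin leakage is secondary
    contaminant_buffer_share: float = 0.85
    contaminant_weight_concentration: float = 10.0
    skin_input_cells: float = 1e6
    cross_contaminant_cells: float = 20.0
    control_cross_fraction: float = 0.02
    negative_depth_divisor: int = 20

    def mock_taxa(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_taxa)]

    def spike_taxa(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_spike_taxa)]

    def all_taxa(self) -> list[str]:
        return self.mock_taxa() + (self.spike_taxa() if self.include_spike_in else [])


def default_group_log_bias(config: GeneratorConfig) -> dict[tuple[str, str], float]:
    """Morphology-structured protocol bias on the log scale.

    Thick-walled / gram-positive cells lyse poorly and are underrepresented,
    gram-negative rods are overrepresented; "tough" lysis (T) shrinks the
    spread relative to "soft" lysis (S) without removing it (bead beating
    mitigates but does not eliminate lysis bias), and kit/buffer nudge it
    slightly.
    """
    groups = list(config.groups)
    base = dict(zip(groups, np.linspace(-1.2, 0.6, len(groups))))
    out: dict[tuple[str, str], float] = {}
    for protocol in config.protocols:
        kit, lysis, buffer = protocol.split("_")
        scale = 0.7 if lysis == "T" else 1.0
        for g in groups:
            v = base[g] * scale
            if kit == "Z":
                v *= 0.8
            if buffer == "z":
                v += 0.05 if base[g] < 0 else -0.05
            out[(g, protocol)] = v
    return out


def generate_morphology(config: GeneratorConfig) -> MorphologyTable:
    """Cyclic assignment of taxa (mock and spike-in) to morphology groups."""
    rows = {}
    for i, taxon in enumerate(config.all_taxa()):
        g = config.groups[i % len(config.groups)]
        gram, shape = _GROUP_MORPHOLOGY.get(g, ("positive", "rod"))
        rows[taxon] = {"gram": gram, "shape": shape, "group": g}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "taxon"
    return MorphologyTable(df)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_sub: int, forbidden: set[int] | None = None) -> str:
    """Substitute n_sub distinct positions (avoiding ``forbidden``) to new bases."""
    allowed = [i for i in range(len(seq)) if not forbidden or i not in forbidden]
    positions = rng.choice(len(allowed), size=n_sub, replace=False)
    out = list(seq)
    for idx in positions:
        pos = allowed[idx]
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_references(config: GeneratorConfig, rng: np.random.Generator | None = None) -> ReferenceSet:
    """Synthetic reference windows with controlled pairwise distances.

    All inter-taxon variant pairs are at Levenshtein distance at least
    ``inter_taxon_min_lv`` except the engineered close pair (the first two
    mock taxa) whose minimum distance is exactly ``close_pair_lv``.
    Within-taxon copy variants stay within distance 2 of the taxon base.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    taxa = config.all_taxa()
    for _attempt in range(20):
        bases: dict[str, str] = {}
        close_positions: set[int] = set()
        ok = True
        for i, taxon in enumerate(taxa):
            if i == 1:
                seq = _mutate(rng, bases[taxa[0]], config.close_pair_lv)
                close_positions = {
                    p for p in range(config.trim_len) if seq[p] != bases[taxa[0]][p]
                }
            else:
                seq = _random_seq(rng, config.trim_len)
                if any(
                    levenshtein(seq, other) < config.inter_taxon_min_lv + 4
                    for t, other in bases.items()
                    if t != taxa[0] or i != 1
                ):
                    ok = False
                    break
            bases[taxon] = seq
        if not ok:
            continue
        variants: dict[str, list[str]] = {}
        for i, taxon in enumerate(taxa):
            vs = [bases[taxon]]
            forbidden = close_positions if i in (0, 1) else None
            for _ in range(config.variants_per_taxon - 1):
                vs.append(_mutate(rng, bases[taxon], int(rng.integers(1, 3)), forbidden=forbidden))
            variants[taxon] = vs
        refs = ReferenceSet(variants=variants, trim_len=config.trim_len)
        if _verify_reference_distances(refs, taxa, config):
            return refs
    raise RuntimeError("could not satisfy reference distance constraints; relax config")


def _verify_reference_distances(refs: ReferenceSet, taxa: list[str], config: GeneratorConfig) -> bool:
    close = {taxa[0], taxa[1]}
    for ta, tb in itertools.combinations(taxa, 2):
        dmin = min(
            levenshtein(a, b)
            for a in refs.variants[ta]
            for b in refs.variants[tb]
        )
        if {ta, tb} == close:
            if dmin != config.close_pair_lv:
                return False
        elif dmin < config.inter_taxon_min_lv:
            return False
    return True


def pairwise_taxon_lv(refs: ReferenceSet) -> pd.DataFrame:
    """Minimum Levenshtein distance between copy variants of each taxon pair."""
    taxa = refs.taxa
    mat = pd.DataFrame(0, index=taxa, columns=taxa)
    for ta, tb in itertools.combinations(taxa, 2):
        d = min(levenshtein(a, b) for a in refs.variants[ta] for b in refs.variants[tb])
        mat.loc[ta, tb] = mat.loc[tb, ta] = d
    return mat


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    design_compositions: dict[str, pd.Series]  # sample_class -> designed composition
    true_composition: dict[str, pd.Series]  # sample_id -> designed composition
    biased_composition: dict[str, pd.Series]  # sample_id -> composition after bias
    true_bias: dict[str, pd.Series]  # protocol -> per-taxon efficiency (uncentered)
    read_labels: pd.DataFrame  # sample_id, asv_id, count, category, detail
    contaminant_origins: dict[str, str]  # asv_id -> buffer_q | buffer_z | skin_like
    dna_design: dict[str, str]  # dna-mock sample_id -> sample_class it references
    morphology: MorphologyTable
    refs: ReferenceSet
    config: GeneratorConfig

    def category_fractions(self) -> pd.DataFrame:
        """Planted per-sample read fractions by provenance category."""
        wide = (
            self.read_labels.pivot_table(
                index="sample_id", columns="category", values="count", aggfunc="sum", fill_value=0
            )
            .astype(float)
        )
        return wide.div(wide.sum(axis=1), axis=0)


class _AsvRegistry:
    """Stable sequence -> ASV id mapping (insertion-ordered, deterministic)."""

    def __init__(self) -> None:
        self.by_seq: dict[str, str] = {}

    def get(self, seq: str) -> str:
        if seq not in self.by_seq:
            self.by_seq[seq] = f"ASV{len(self.by_seq) + 1:05d}"
        return self.by_seq[seq]

    @property
    def sequences(self) -> dict[str, str]:
        return {asv_id: seq for seq, asv_id in self.by_seq.items()}


def _design_composition(kind: str, taxa: list[str]) -> pd.Series:
    if kind == "even" or kind == "spike":
        return pd.Series(1.0 / len(taxa), index=taxa)
    if kind == "staggered":
        w = np.power(10.0, -np.arange(len(taxa), dtype=float))
        return pd.Series(w / w.sum(), index=taxa)
    raise ValueError(kind)


class _ExperimentBuilder:
    def __init__(self, config: GeneratorConfig, refs: ReferenceSet, morph: MorphologyTable, rng: np.random.Generator):
        self.cfg = config
        self.refs = refs
        self.morph = morph
        self.rng = rng
        self.registry = _AsvRegistry()
        self.labels: list[dict] = []
        self.counts: dict[str, dict[str, float]] = {}
        self.metadata: list[SampleMetadata] = []
        self.taxon_lv = pairwise_taxon_lv(refs)
        self.contaminant_origins: dict[str, str] = {}
        self._setup_bias()
        self._setup_recurrent_errors()
        self._setup_contaminant_pools()
        self._setup_skin()

    # -- planted structure ---------------------------------------------------

    def _setup_bias(self) -> None:
        cfg = self.cfg
        means = cfg.group_log_bias_means or default_group_log_bias(cfg)
        self.true_bias: dict[str, pd.Series] = {}
        for protocol in cfg.protocols:
            logs = {}
            for taxon in cfg.all_taxa():
                g = self.morph.group_of(taxon)
                mu = means[(g, protocol)]
                logs[taxon] = mu + (
                    self.rng.normal(0.0, cfg.within_group_log_sd)
                    if cfg.within_group_log_sd > 0
                    else 0.0
                )
            self.true_bias[protocol] = pd.Series({t: math.exp(v) for t, v in logs.items()})

    def _setup_recurrent_errors(self) -> None:
        """Error ASVs that recur across samples (fixed sequence, LV 1..4)."""
        cfg = self.cfg
        self.recurrent: list[tuple[str, str, str]] = []  # (parent_variant, err_seq, taxon)
        taxa = cfg.mock_taxa()
        for i in range(cfg.n_recurrent_error_asvs):
            taxon = taxa[i % len(taxa)]
            parent = self.refs.variants[taxon][0]
            err = _mutate(self.rng, parent, int(self.rng.integers(1, 5)))
            self.recurrent.append((parent, err, taxon))

    def _setup_contaminant_pools(self) -> None:
        cfg = self.cfg
        self.buffer_pools: dict[str, tuple[list[str], np.ndarray]] = {}
        for buffer in ("q", "z"):
            seqs = [_random_seq(self.rng, cfg.trim_len) for _ in range(cfg.n_contaminant_asvs_per_origin)]
            ids = [self.registry.get(s) for s in seqs]
            weights = self.rng.dirichlet(np.full(len(ids), cfg.contaminant_weight_concentration))
            self.buffer_pools[buffer] = (ids, weights)
            for a in ids:
                self.contaminant_origins[a] = f"buffer_{buffer}"

    def _setup_skin(self) -> None:
        cfg = self.cfg
        seqs = [_random_seq(self.rng, cfg.trim_len) for _ in range(cfg.n_skin_taxa)]
        self.skin_ids = [self.registry.get(s) for s in seqs]
        self.skin_comps = [self.rng.dirichlet(np.ones(cfg.n_skin_taxa)) for _ in range(2)]
        mean_comp = np.mean(self.skin_comps, axis=0)
        top = np.argsort(mean_comp)[::-1][: cfg.n_contaminant_asvs_per_origin]
        self.skin_pool_ids = [self.skin_ids[i] for i in top]
        w = mean_comp[top]
        self.skin_pool_weights = w / w.sum()
        for a in self.skin_pool_ids:
            self.contaminant_origins[a] = "skin_like"

    # -- helpers -------------------------------------------------------------

    def _add(self, sample_id: str, asv_id: str, count: float, category: str, detail: str) -> None:
        if count <= 0:
            return
        self.counts.setdefault(sample_id, {})
        self.counts[sample_id][asv_id] = self.counts[sample_id].get(asv_id, 0.0) + count
        self.labels.append(
            {"sample_id": sample_id, "asv_id": asv_id, "count": count, "category": category, "detail": detail}
        )

    def _split(self, n: int, probs: np.ndarray) -> np.ndarray:
        if self.cfg.sampling == "exact":
            return n * probs
        return self.rng.multinomial(n, probs)

    def _binom(self, n: float, p: float) -> float:
        if self.cfg.sampling == "exact":
            return n * p
        return float(self.rng.binomial(int(n), p)) if n >= 1 else 0.0

    # -- read generation -----------------------------------------------------

    def _mock_reads(self, sample_id: str, n_reads: float, comp: pd.Series) -> None:
        cfg = self.cfg
        taxa = list(comp.index)
        taxon_counts = self._split(int(n_reads), comp.to_numpy() / comp.sum()) if cfg.sampling != "exact" else n_reads * (comp.to_numpy() / comp.sum())
        for taxon, tc in zip(taxa, taxon_counts):
            if tc <= 0:
                continue
            variants = self.refs.variants[taxon]
            vshare = np.full(len(variants), 1.0 / len(variants))
            vcounts = self._split(int(tc), vshare) if cfg.sampling != "exact" else tc * vshare
            for variant, vc in zip(variants, vcounts):
                if vc <= 0:
                    continue
                for parent, err_seq, err_taxon in self.recurrent:
                    if parent == variant and err_taxon == taxon:
                        k = self._binom(vc, cfg.recurrent_error_rate)
                        if k > 0:
                            self._add(sample_id, self.registry.get(err_seq), k, "error", taxon)
                            vc -= k
                k = self._binom(vc, cfg.random_error_rate)
                if k > 0 and cfg.sampling != "exact":
                    n_new = min(int(k), 2)
                    for part in self._split(int(k), np.full(n_new, 1.0 / n_new)):
                        if part <= 0:
                            continue
                        err = _mutate(self.rng, variant, int(self.rng.integers(1, 7)))
                        self._add(sample_id, self.registry.get(err), float(part), "error", taxon)
                    vc -= k
                self._add(sample_id, self.registry.get(variant), float(vc), "mock", taxon)

    def _chimera_reads(self, sample_id: str, n_reads: float, comp: pd.Series) -> None:
        cfg = self.cfg
        if n_reads < 1:
            return
        taxa = [t for t in comp.index if comp[t] > 0]
        if len(taxa) < 2:
            return
        pairs = list(itertools.combinations(taxa, 2))
        weights = np.array([
            comp[a] * comp[b] * math.exp(-self.taxon_lv.loc[a, b] / cfg.similarity_lambda)
            for a, b in pairs
        ])
        if weights.sum() <= 0:
            return
        weights /= weights.sum()
        n_distinct = min(int(n_reads), 4)
        alloc = self.rng.multinomial(int(n_reads), np.full(n_distinct, 1.0 / n_distinct))
        for c in alloc:
            if c <= 0:
                continue
            a, b = pairs[self.rng.choice(len(pairs), p=weights)]
            if self.rng.random() < 0.5:
                a, b = b, a
            va = self.refs.variants[a][self.rng.integers(len(self.refs.variants[a]))]
            vb = self.refs.variants[b][self.rng.integers(len(self.refs.variants[b]))]
            bp = int(self.rng.integers(40, cfg.trim_len - 40 + 1))
            seq = va[:bp] + vb[bp:]
            self._add(sample_id, self.registry.get(seq), float(c), "chimera", f"{a}+{b}")

    def _contaminant_reads(self, sample_id: str, n_reads: float, buffer: str) -> None:
        if n_reads < 1:
            return
        ids_b, w_b = self.buffer_pools[buffer]
        ids = list(ids_b) + list(self.skin_pool_ids)
        share = self.cfg.contaminant_buffer_share
        probs = np.concatenate([share * w_b, (1 - share) * self.skin_pool_weights])
        alloc = self.rng.multinomial(int(n_reads), probs / probs.sum())
        for asv_id, c in zip(ids, alloc):
            if c > 0:
                self._add(sample_id, asv_id, float(c), "contaminant", self.contaminant_origins[asv_id])

    def _cross_into_mock(self, sample_id: str, n_reads: float) -> None:
        """Skin material leaking into a mock sample."""
        if n_reads < 1:
            return
        comp = np.mean(self.skin_comps, axis=0)
        alloc = self.rng.multinomial(int(n_reads), comp / comp.sum())
        for asv_id, c in zip(self.skin_ids, alloc):
            if c > 0:
                self._add(sample_id, asv_id, float(c), "cross", "skin_like")

    def _cross_into_control(self, sample_id: str, n_reads: float) -> None:
        """Mock material leaking into a control or skin sample."""
        if n_reads < 1:
            return
        taxa = self.cfg.mock_taxa()
        comp = _design_composition("even", taxa)
        alloc = self.rng.multinomial(int(n_reads), comp.to_numpy())
        for taxon, c in zip(taxa, alloc):
            if c > 0:
                variant = self.refs.variants[taxon][0]
                self._add(sample_id, self.registry.get(variant), float(c), "cross", taxon)

    # -- samples -------------------------------------------------------------

    def add_cell_mock(self, sample_id: str, sample_class: str, protocol: str, comp: pd.Series, input_cells: float) -> tuple[pd.Series, pd.Series]:
        cfg = self.cfg
        kit, lysis, buffer = protocol.split("_")
        bias = self.true_bias[protocol][comp.index]
        biased = comp * bias
        biased = biased / biased.sum()
        q_chim = min(1.0, cfg.chimera_rate_max * input_cells / cfg.n_max)
        p_cont = cfg.contaminant_cells / (cfg.contaminant_cells + input_cells)
        p_cross = cfg.cross_contaminant_cells / (cfg.cross_contaminant_cells + input_cells)
        if cfg.sampling == "exact":
            q_chim = p_cont = p_cross = 0.0
        f_chim = q_chim
        f_cont = (1 - q_chim) * p_cont
        f_mock = 1.0 - f_chim - f_cont
        if cfg.sampling == "exact":
            n_mock, n_cont, n_chim = cfg.depth, 0.0, 0.0
        else:
            n_mock, n_cont, n_chim = self.rng.multinomial(cfg.depth, [f_mock, f_cont, f_chim])
        self._mock_reads(sample_id, n_mock, biased)
        self._contaminant_reads(sample_id, n_cont, buffer)
        self._chimera_reads(sample_id, n_chim, biased)
        if cfg.sampling != "exact" and cfg.n_skin_taxa > 0:
            self._cross_into_mock(sample_id, self._binom(cfg.depth, p_cross))
        self.metadata.append(
            SampleMetadata(sample_id, sample_class, kit=kit, lysis=lysis, buffer=buffer, input_cells=input_cells)
        )
        return comp, biased

    def add_dna_mock(self, sample_id: str, comp: pd.Series) -> None:
        self._mock_reads(sample_id, self.cfg.depth, comp)
        self.metadata.append(SampleMetadata(sample_id, "dna_mock"))

    def add_negative_control(self, sample_id: str, protocol: str) -> None:
        cfg = self.cfg
        kit, lysis, buffer = protocol.split("_")
        depth = max(50, cfg.depth // cfg.negative_depth_divisor)
        n_cross = self._binom(depth, cfg.control_cross_fraction)
        self._contaminant_reads(sample_id, depth - n_cross, buffer)
        self._cross_into_control(sample_id, n_cross)
        self.metadata.append(
            SampleMetadata(sample_id, "negative_control", kit=kit, lysis=lysis, buffer=buffer)
        )

    def add_skin(self, sample_id: str, protocol: str, subject: int) -> None:
        cfg = self.cfg
        kit, lysis, buffer = protocol.split("_")
        p_cont = cfg.contaminant_cells / (cfg.contaminant_cells + cfg.skin_input_cells)
        n_cont = self._binom(cfg.depth, p_cont)
        n_cross = self._binom(cfg.depth, cfg.control_cross_fraction)
        n_skin = cfg.depth - n_cont - n_cross
        comp = self.skin_comps[subject % len(self.skin_comps)]
        alloc = self.rng.multinomial(int(n_skin), comp / comp.sum())
        for asv_id, c in zip(self.skin_ids, alloc):
            if c > 0:
                self._add(sample_id, asv_id, float(c), "skin", "skin")
        self._contaminant_reads(sample_id, n_cont, buffer)
        self._cross_into_control(sample_id, n_cross)
        self.metadata.append(
            SampleMetadata(sample_id, "skin", kit=kit, lysis=lysis, buffer=buffer)
        )


def generate_experiment(
    config: GeneratorConfig,
    refs: ReferenceSet | None = None,
    morph: MorphologyTable | None = None,
) -> tuple[AsvTable, GroundTruth]:
    """Generate the full synthetic study: samples, counts and ground truth."""
    rng = np.random.default_rng(config.seed)
    if refs is None:
        refs = generate_references(config, rng)
    if morph is None:
        morph = generate_morphology(config)
    b = _ExperimentBuilder(config, refs, morph, rng)

    design: dict[str, pd.Series] = {}
    for kind in config.mock_types:
        design[f"{kind}_mock"] = _design_composition(kind, config.mock_taxa())
    if config.include_spike_in:
        design["spike_in"] = _design_composition("spike", config.spike_taxa())

    true_comp: dict[str, pd.Series] = {}
    biased_comp: dict[str, pd.Series] = {}
    dna_design: dict[str, str] = {}

    for protocol in config.protocols:
        for kind in config.mock_types:
            sclass = f"{kind}_mock"
            for n_cells in config.dilutions:
                sid = f"{kind}_{protocol}_e{int(round(math.log10(n_cells))):02d}"
                comp, biased = b.add_cell_mock(sid, sclass, protocol, design[sclass], n_cells)
                true_comp[sid] = comp
                biased_comp[sid] = biased
        if config.include_spike_in:
            for n_cells in config.dilutions:
                sid = f"spike_{protocol}_e{int(round(math.log10(n_cells))):02d}"
                comp, biased = b.add_cell_mock(sid, "spike_in", protocol, design["spike_in"], n_cells)
                true_comp[sid] = comp
                biased_comp[sid] = biased
        for i in range(config.n_negative_controls):
            b.add_negative_control(f"neg_{protocol}_{i + 1}", protocol)

    for kind in config.mock_types:
        sclass = f"{kind}_mock"
        for rep in "abcdefgh"[: config.n_dna_replicates]:
            sid = f"dna_{kind}_{rep}"
            b.add_dna_mock(sid, design[sclass])
            dna_design[sid] = sclass
            true_comp[sid] = design[sclass]

    if config.n_skin_taxa > 0:
        for i in range(config.n_skin_samples):
            protocol = config.protocols[i % len(config.protocols)]
            b.add_skin(f"skin_{i + 1}_{protocol}", protocol, subject=i % 2)

    sample_ids = [m.sample_id for m in b.metadata]
    asv_ids = list(b.registry.sequences)
    counts = pd.DataFrame(0.0, index=sample_ids, columns=asv_ids)
    for sid, row in b.counts.items():
        for asv_id, c in row.items():
            counts.loc[sid, asv_id] = c
    if config.sampling != "exact":
        counts = counts.round().astype(np.int64)
    table = AsvTable(counts=counts, asv_sequences=b.registry.sequences, metadata=b.metadata)
    truth = GroundTruth(
        design_compositions=design,
        true_composition=true_comp,
        biased_composition=biased_comp,
        true_bias=b.true_bias,
        read_labels=pd.DataFrame(b.labels, columns=["sample_id", "asv_id", "count", "category", "detail"]),
        contaminant_origins=b.contaminant_origins,
        dna_design=dna_design,
        morphology=morph,
        refs=refs,
        config=config,
    )
    return table, truth


def write_fixture(table: AsvTable, truth: GroundTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write the experiment in the pipeline's file dialects plus ground truth.

    Deterministic for a given generator seed: re-running with the same
    config yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "references": out / "references.fasta",
        "counts": out / "asv_counts.tsv",
        "sequences": out / "asv_sequences.tsv",
        "metadata": out / "sample_metadata.tsv",
        "morphology": out / "morphology.tsv",
        "true_bias": out / "truth_bias.tsv",
        "read_labels": out / "truth_read_labels.tsv",
        "design": out / "truth_design_compositions.tsv",
        "config": out / "generator_config.yaml",
    }
    write_reference_fasta(truth.refs, paths["references"])
    write_asv_table(table, paths["counts"], paths["sequences"], paths["metadata"])
    truth.morphology.write_tsv(paths["morphology"])
    rows = [
        {"protocol": p, "taxon": t, "bias": v}
        for p, vec in truth.true_bias.items()
        for t, v in vec.items()
    ]
    pd.DataFrame(rows).to_csv(paths["true_bias"], sep="\t", index=False)
    truth.read_labels.to_csv(paths["read_labels"], sep="\t", index=False)
    rows = [
        {"sample_class": c, "taxon": t, "expected": v}
        for c, vec in truth.design_compositions.items()
        for t, v in vec.items()
    ]
    pd.DataFrame(rows).to_csv(paths["design"], sep="\t", index=False)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(truth.config).items() if k != "group_log_bias_means"}
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=False))
    return paths
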