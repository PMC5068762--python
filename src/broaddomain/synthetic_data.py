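"""Synthetic peak universes with planted ground truth for every pipeline stage.

The generator emulates the study conditions of a sorted-nuclei H3K4me3
experiment downstream of peak calling:

* heavy-tailed peak lengths (log-normal body ~1.1-1.5 kb with a broad
  log-normal tail, so the all-peak mean is ~1.5 kb and the top-5% mean
  ~5 kb, a ~3.6-fold breadth ratio);
* two replicate NeuN+ cohorts sharing one master locus list with small
  boundary jitter and per-cohort dropout of broad specific peaks;
* cell-type specificity planted at a controlled enrichment ratio rho:
  peaks in the realized top-5% breadth class are specific with probability
  rho * f, the remainder with the probability that keeps the overall
  specific fraction at f.  Non-specific peaks get an overlapping
  counterpart peak in at least one other cell type (NeuN-/blood);
* a planted fraction (default 85%) of top-breadth peaks carry a TSS within
  +/- 4 kb of their midpoint; the remaining top peaks are kept gene-free
  within a guard zone so the fraction is recoverable;
* multi-species peak sets pre-mapped to the human frame with a planted
  conserved fraction (default 24%) of the cross-species shared loci drawn
  from the human broadest set;
* a preferential-attachment gene network whose earliest nodes are planted
  hubs;
* paired gray/white FPKM with a planted log2 effect for target genes.

Peaks are placed in non-overlapping slots along each chromosome (random
gaps by a Dirichlet split of the free space), so presence/absence logic is
exact by construction; a free-space allocator hands out inter-peak gaps to
"other cell type only" and species-only peaks without collisions.

Every generator records what it planted in a truth manifest (plain dict /
JSON) so tests can check recovery against known values.  Fixed seed, byte-
identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import GeneModel
from .breadth_rank import select_broadest
from .core_intervals import Peak, PeakSet
from .expression_qc import ExpressionMatrix
from .io_formats import (
    GenomeLayout,
    write_bed,
    write_chrom_sizes,
    write_edge_list,
    write_expression,
    write_gene_models,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticUniverse",
    "generate_universe",
    "generate_species_sets",
    "generate_network",
    "generate_expression",
]

# guard distances (bp): clearance around master peaks for gap allocations,
# and the no-TSS zone around deliberately gene-free broad peaks
_GAP_CLEARANCE = 800
_TSS_GUARD = 4500
_EDGE_MARGIN = 1000


@dataclass(frozen=True)
class SyntheticConfig:
    """All planted parameters of the synthetic universe.

    Defaults emulate the study conditions: ~1.5 kb mean peak length with a
    broad tail, 85% TSS proximity for the broadest class, specificity
    enrichment rho=2, 24% cross-species conservation, scale-free-ish network
    with planted hubs, and a 1.0 log2 gray/white effect over 6 subject pairs.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (
        ("chr1", 10_000_000),
        ("chr2", 10_000_000),
        ("chr3", 10_000_000),
        ("chr4", 10_000_000),
        ("chr5", 10_000_000),
    )
    n_peaks: int = 8000
    length_mu: float = math.log(1200.0)  # log-bp, typical-peak body
    length_sigma: float = 0.45
    broad_weight: float = 0.05
    broad_length_mu: float = math.log(5300.0)  # log-bp, broad tail
    broad_length_sigma: float = 0.28
    min_length: int = 200
    specific_fraction_all: float = 0.25
    enrichment_rho: float = 2.0
    broadest_fraction: float = 0.05
    tss_proximity_broad: float = 0.85
    n_background_genes: int = 300
    cohort_retention: float = 0.85  # broad specific peaks kept per cohort
    max_shift: int = 150  # re-detection positional jitter, bp
    n_other_extras: int = 400  # own peaks per other cell type
    # species / pseudo-liftover
    n_species: int = 3
    n_shared_species: int = 500
    conserved_fraction: float = 0.24
    species_jitter: int = 200
    n_species_only: int = 150
    # network
    network_nodes: int = 1000
    network_m: int = 2
    n_planted_hubs: int = 20
    # expression
    n_expr_pairs: int = 6
    expr_effect_log2: float = 1.0
    expr_noise_sd: float = 0.5
    expr_baseline_mean: float = 3.0
    expr_baseline_sd: float = 1.5
    expr_subject_sd: float = 0.3

    def validate(self) -> None:
        for name in ("broad_weight", "specific_fraction_all", "tss_proximity_broad",
                     "conserved_fraction", "cohort_retention", "broadest_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.enrichment_rho < 0:
            raise ValueError("enrichment_rho must be >= 0")
        if self.enrichment_rho * self.specific_fraction_all > 1.0:
            raise ValueError(
                "infeasible config: enrichment_rho * specific_fraction_all > 1 "
                "(broad peaks cannot be specific with probability > 1)"
            )
        if self.network_nodes < 10:
            raise ValueError("network_nodes must be >= 10")


class _GapAllocator:
    """Hands out non-overlapping sub-intervals of the free space between peaks."""

    def __init__(self, gaps: list[tuple[str, int, int]]):
        self.gaps = [g for g in gaps if g[2] - g[1] > 0]

    def allocate(self, length: int, rng: np.random.Generator) -> Optional[tuple[str, int, int]]:
        fitting = [i for i, (_, lo, hi) in enumerate(self.gaps) if hi - lo >= length]
        if not fitting:
            return None
        i = int(fitting[rng.integers(len(fitting))])
        chrom, lo, hi = self.gaps.pop(i)
        start = int(rng.integers(lo, hi - length + 1))
        end = start + length
        if start - lo > 0:
            self.gaps.append((chrom, lo, start))
        if hi - end > 0:
            self.gaps.append((chrom, end, hi))
        return chrom, start, end


@dataclass
class SyntheticUniverse:
    """Everything the pipeline consumes, plus the planted-truth manifest."""

    config: SyntheticConfig
    layout: GenomeLayout
    master: PeakSet  # the shared NeuN+ locus list
    cohorts: dict[str, PeakSet]  # cohort1 / cohort2 NeuN+ peak sets
    others: dict[str, PeakSet]  # NeuN- / blood pooled peak sets
    gene_models: list[GeneModel]
    broad_gene_ids: list[str]  # genes planted at TSS-proximal broad peaks
    truth: dict
    allocator: _GapAllocator = field(repr=False, default=None)

    def write(self, out_dir) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        write_chrom_sizes(self.layout, out / "genome.chrom.sizes")
        paths["chrom_sizes"] = str(out / "genome.chrom.sizes")
        for name, peaks in {**self.cohorts, **self.others}.items():
            p = out / f"{name}.bed"
            write_bed(peaks, p)
            paths[name] = str(p)
        write_gene_models(self.gene_models, out / "genes.tsv")
        paths["genes"] = str(out / "genes.tsv")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)
        paths["truth"] = str(out / "truth.json")
        return paths


def _draw_lengths(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    broad = rng.random(cfg.n_peaks) < cfg.broad_weight
    lengths = np.where(
        broad,
        rng.lognormal(cfg.broad_length_mu, cfg.broad_length_sigma, cfg.n_peaks),
        rng.lognormal(cfg.length_mu, cfg.length_sigma, cfg.n_peaks),
    )
    return np.maximum(lengths.astype(np.int64), cfg.min_length)


def _place_master(
    cfg: SyntheticConfig, lengths: np.ndarray, rng: np.random.Generator
) -> tuple[list[Peak], list[tuple[str, int, int]]]:
    """Sequential non-overlapping placement; returns peaks and free gaps."""
    chrom_names = [n for n, _ in cfg.genome]
    sizes = dict(cfg.genome)
    weights = np.array([sizes[c] for c in chrom_names], dtype=float)
    assignment = rng.choice(len(chrom_names), size=len(lengths), p=weights / weights.sum())
    peaks: list[Optional[Peak]] = [None] * len(lengths)
    gaps: list[tuple[str, int, int]] = []
    # adjacent loci must stay farther apart than two maximal re-detection
    # shifts, or shifted copies of neighbouring loci could touch
    min_gap = 2 * cfg.max_shift + 100
    for ci, chrom in enumerate(chrom_names):
        idx = np.flatnonzero(assignment == ci)
        total = int(lengths[idx].sum())
        free = sizes[chrom] - 2 * _EDGE_MARGIN - total - (len(idx) + 1) * min_gap
        if free < (len(idx) + 1) * 2 * _GAP_CLEARANCE:
            raise ValueError(
                f"infeasible config: {len(idx)} peaks totalling {total} bp do not "
                f"fit on {chrom} ({sizes[chrom]} bp) with clearance; enlarge the "
                "genome or reduce n_peaks"
            )
        split = rng.dirichlet(np.ones(len(idx) + 1)) * free
        cursor = _EDGE_MARGIN
        for k, i in enumerate(idx):
            gap = int(split[k]) + min_gap
            start = cursor + gap
            end = start + int(lengths[i])
            if gap > 2 * _GAP_CLEARANCE:
                gaps.append((chrom, cursor + _GAP_CLEARANCE, start - _GAP_CLEARANCE))
            peaks[i] = Peak(chrom, start, end, name=f"peak{int(i):05d}")
            cursor = end
        tail = sizes[chrom] - _EDGE_MARGIN - cursor
        if tail > 2 * _GAP_CLEARANCE:
            gaps.append((chrom, cursor + _GAP_CLEARANCE, sizes[chrom] - _EDGE_MARGIN - _GAP_CLEARANCE))
    return [p for p in peaks if p is not None], gaps


def _shift_peak(
    p: Peak, max_shift: int, chrom_len: int, rng: np.random.Generator,
    cell_type: Optional[str], cohort: Optional[str],
) -> Peak:
    """Length-preserving positional jitter (re-detection / liftOver noise).

    Capped at a quarter of the peak length so two independently shifted
    copies of the same locus always still overlap.
    """
    w = max(min(max_shift, p.length // 4), 1)
    shift = int(rng.integers(-w, w + 1))
    start = min(max(p.start + shift, 0), chrom_len - p.length)
    return Peak(p.chrom, start, start + p.length, name=p.name,
                cell_type=cell_type, cohort=cohort)


def _make_exons(lo: int, hi: int, rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    span = hi - lo
    n_ex = int(rng.integers(2, 6))
    if span < n_ex * 120:
        return ((lo, hi),)
    cuts = np.sort(rng.choice(np.arange(1, span // 60), size=2 * n_ex, replace=False)) * 60
    blocks = []
    for a, b in zip(cuts[0::2], cuts[1::2]):
        if b > a:
            blocks.append((lo + int(a), lo + int(b)))
    return tuple(blocks) if blocks else ((lo, hi),)


def generate_universe(config: SyntheticConfig) -> SyntheticUniverse:
    """Build the full synthetic peak universe with planted truth."""
    cfg = config
    cfg.validate()
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_len, rng_place, rng_spec, rng_gene, rng_cohort, rng_other, _, _ = (
        np.random.default_rng(s) for s in streams
    )
    layout = GenomeLayout(tuple(cfg.genome))
    sizes = layout.sizes

    lengths = _draw_lengths(cfg, rng_len)
    master_peaks, gaps = _place_master(cfg, lengths, rng_place)
    master = PeakSet(master_peaks, provenance="master")
    allocator = _GapAllocator(gaps)

    # --- breadth classes --------------------------------------------------
    # Master top-5% class, then each cohort's *realized* top class after its
    # dropout (removing broad peaks lowers the cohort's nearest-rank
    # threshold, pulling near-threshold peaks in).  Planting happens on the
    # union of all three classes so that whatever a cohort's selection
    # returns carries the broad-class specificity and TSS-proximity rates.
    _, summary = select_broadest(master, cfg.broadest_fraction)
    threshold = summary.percentile_threshold
    master_lengths = master.lengths
    top_mask = master_lengths > threshold
    n, b_master = len(master), int(top_mask.sum())

    f = cfg.specific_fraction_all
    p_broad = cfg.enrichment_rho * f
    p_typical = (n * f - b_master * p_broad) / (n - b_master) if n > b_master else f
    if not (0.0 <= p_typical <= 1.0) or p_broad > 1.0:
        raise ValueError(
            "infeasible config: breadth-conditional specificity probabilities "
            f"(broad {p_broad:.3f}, typical {p_typical:.3f}) outside [0, 1]; "
            "lower enrichment_rho or specific_fraction_all"
        )
    # exact-count planting: the configured rates hold exactly, not just in
    # expectation, so recovered enrichment is free of planting noise
    specific = np.zeros(n, dtype=bool)
    top_i = np.flatnonzero(top_mask)
    typ_i = np.flatnonzero(~top_mask)
    specific[rng_spec.choice(top_i, size=int(round(p_broad * len(top_i))),
                             replace=False)] = True
    specific[rng_spec.choice(typ_i, size=int(round(p_typical * len(typ_i))),
                             replace=False)] = True

    # per-cohort dropout among broad master peaks (specificity-blind, so the
    # kept top class retains the planted specificity rate unbiased)
    broad_idx = np.flatnonzero(top_mask)
    kept_idx: dict[str, np.ndarray] = {}
    top_in: dict[str, set[int]] = {}
    for cohort in ("cohort1", "cohort2"):
        drop = rng_cohort.random(len(broad_idx)) >= cfg.cohort_retention
        dropped = set(int(i) for i in broad_idx[drop])
        kept = np.array([i for i in range(n) if i not in dropped], dtype=np.int64)
        kept_idx[cohort] = kept
        k = math.ceil((1.0 - cfg.broadest_fraction) * len(kept))
        thr = np.sort(master_lengths[kept], kind="stable")[k - 1]
        top_in[cohort] = set(int(i) for i in kept[master_lengths[kept] > thr])
    union_top = set(top_i.tolist()) | top_in["cohort1"] | top_in["cohort2"]
    swap_ins = np.array(sorted(union_top - set(top_i.tolist())), dtype=np.int64)
    if len(swap_ins):  # upgrade swap-ins to the broad-class rate, exact count
        specific[swap_ins] = False
        specific[rng_spec.choice(swap_ins, size=int(round(p_broad * len(swap_ins))),
                                 replace=False)] = True
    n_shared_broad_specific = len(
        top_in["cohort1"] & top_in["cohort2"] & set(np.flatnonzero(specific).tolist())
    )

    # --- gene models ------------------------------------------------------
    union_idx = np.array(sorted(union_top), dtype=np.int64)
    b_union = len(union_idx)
    k_prox = int(round(cfg.tss_proximity_broad * b_union))
    prox_idx = rng_gene.choice(union_idx, size=k_prox, replace=False)
    prox_set = set(int(i) for i in prox_idx)
    # guard zones: midpoints of deliberately gene-free broad peaks
    guard: dict[str, np.ndarray] = {}
    for i in union_idx:
        if int(i) not in prox_set:
            p = master[int(i)]
            guard.setdefault(p.chrom, [])
            guard[p.chrom].append(p.midpoint)
    guard = {c: np.sort(np.array(v)) for c, v in guard.items()}

    def _clear_of_guard(chrom: str, pos: int) -> bool:
        g = guard.get(chrom)
        if g is None or len(g) == 0:
            return True
        j = int(np.searchsorted(g, pos))
        for k in (j - 1, j):
            if 0 <= k < len(g) and abs(int(g[k]) - pos) <= _TSS_GUARD:
                return False
        return True

    gene_models: list[GeneModel] = []
    broad_gene_ids: list[str] = []
    gene_counter = 0

    def _add_gene(chrom: str, tss: int) -> Optional[str]:
        nonlocal gene_counter
        strand = "+" if rng_gene.random() < 0.5 else "-"
        glen = int(rng_gene.integers(5_000, 50_000))
        if strand == "+":
            tes = min(tss + glen, sizes[chrom] - 1)
        else:
            tes = max(tss - glen, 0)
        if tes == tss:
            return None
        lo, hi = min(tss, tes), max(tss, tes)
        gene_id = f"g{gene_counter:05d}"
        gene_counter += 1
        gene_models.append(
            GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, tss=tss,
                      tes=tes, exons=_make_exons(lo, hi, rng_gene))
        )
        return gene_id

    for i in sorted(prox_set):
        p = master[i]
        for _attempt in range(20):
            tss = p.midpoint + int(rng_gene.integers(-3000, 3001))
            tss = min(max(tss, 0), sizes[p.chrom] - 1)
            if _clear_of_guard(p.chrom, tss):
                break
        gid = _add_gene(p.chrom, tss)
        if gid is not None:
            broad_gene_ids.append(gid)

    non_union = np.array([i for i in range(n) if i not in union_top], dtype=np.int64)
    n_bg = min(cfg.n_background_genes, len(non_union))
    for i in rng_gene.choice(non_union, size=n_bg, replace=False):
        p = master[int(i)]
        tss = p.midpoint + int(rng_gene.integers(-1000, 1001))
        tss = min(max(tss, 0), sizes[p.chrom] - 1)
        if _clear_of_guard(p.chrom, tss):
            _add_gene(p.chrom, tss)

    # --- cohorts: shifted re-detections of the kept master loci ----------
    cohorts: dict[str, PeakSet] = {}
    for cohort in ("cohort1", "cohort2"):
        peaks = [
            _shift_peak(master[int(i)], cfg.max_shift, sizes[master[int(i)].chrom],
                        rng_cohort, "NeuN+", cohort)
            for i in kept_idx[cohort]
        ]
        cohorts[cohort] = PeakSet(peaks, provenance=cohort)

    # --- other cell types: counterparts at non-specific loci + own extras -
    other_names = ("NeuN-", "blood")
    other_peaks: dict[str, list[Peak]] = {name: [] for name in other_names}
    for i in np.flatnonzero(~specific):
        p = master[int(i)]
        in_nn = rng_other.random() < 0.7
        in_bl = rng_other.random() < 0.5
        if not (in_nn or in_bl):
            in_nn = True
        if in_nn:
            other_peaks["NeuN-"].append(
                _shift_peak(p, cfg.max_shift, sizes[p.chrom], rng_other, "NeuN-", None))
        if in_bl:
            other_peaks["blood"].append(
                _shift_peak(p, cfg.max_shift, sizes[p.chrom], rng_other, "blood", None))
    for name in other_names:
        extra_lengths = np.maximum(
            rng_other.lognormal(cfg.length_mu, cfg.length_sigma, cfg.n_other_extras),
            cfg.min_length,
        ).astype(np.int64)
        for j, L in enumerate(extra_lengths):
            slot = allocator.allocate(int(L), rng_other)
            if slot is None:
                break
            chrom, s, e = slot
            other_peaks[name].append(
                Peak(chrom, s, e, name=f"{name}_extra{j:04d}", cell_type=name))
    others = {name: PeakSet(ps, provenance=name) for name, ps in other_peaks.items()}

    truth = {
        "seed": cfg.seed,
        "n_peaks": n,
        "n_broadest_master": b_master,
        "n_broad_class": b_union,
        "breadth_threshold_bp": int(threshold),
        "planted_rho": cfg.enrichment_rho,
        "p_specific_broad": p_broad,
        "p_specific_typical": p_typical,
        "n_specific_all": int(specific.sum()),
        "n_specific_broad_class": int(specific[union_idx].sum()),
        "specific_fraction_all": f,
        "tss_proximity_broad_planted": k_prox / b_union if b_union else float("nan"),
        "n_broad_genes": len(broad_gene_ids),
        "n_genes": len(gene_models),
        "n_shared_broad_specific_cohorts": n_shared_broad_specific,
        "cohort_sizes": {c: len(ps) for c, ps in cohorts.items()},
        "cohort_top_sizes": {c: len(t) for c, t in top_in.items()},
    }
    return SyntheticUniverse(
        config=cfg, layout=layout, master=master, cohorts=cohorts, others=others,
        gene_models=gene_models, broad_gene_ids=broad_gene_ids, truth=truth,
        allocator=allocator,
    )


def generate_species_sets(
    config: SyntheticConfig, universe: SyntheticUniverse
) -> tuple[dict[str, PeakSet], dict]:
    """Per-species broad-peak sets pre-mapped to the human coordinate frame.

    Plants ``n_shared_species`` loci present in every non-human species, of
    which a ``conserved_fraction`` are human broadest peaks (small jitter
    emulates liftOver noise); the rest sit in inter-peak gaps.  Each species
    additionally carries its own peaks in gaps no other species uses, so no
    locus is shared by accident.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[6])
    sizes = universe.layout.sizes
    human_top, _ = select_broadest(universe.cohorts["cohort1"], cfg.broadest_fraction)
    n_shared = min(cfg.n_shared_species, len(human_top))
    k_cons = int(round(cfg.conserved_fraction * n_shared))
    cons_pick = rng.choice(len(human_top), size=k_cons, replace=False)
    shared_loci: list[Peak] = [human_top[int(i)] for i in cons_pick]
    for j in range(n_shared - k_cons):
        L = int(max(rng.lognormal(cfg.broad_length_mu, cfg.broad_length_sigma),
                    cfg.min_length))
        slot = universe.allocator.allocate(L, rng)
        if slot is None:
            break
        chrom, s, e = slot
        shared_loci.append(Peak(chrom, s, e, name=f"shared{j:04d}"))
    species_names = [f"species{k + 1}" for k in range(cfg.n_species)]
    sets: dict[str, PeakSet] = {}
    for sp in species_names:
        peaks = [
            _shift_peak(p, cfg.species_jitter, sizes[p.chrom], rng, sp, None)
            for p in shared_loci
        ]
        for j in range(cfg.n_species_only):
            L = int(max(rng.lognormal(cfg.broad_length_mu, cfg.broad_length_sigma),
                        cfg.min_length))
            slot = universe.allocator.allocate(L, rng)
            if slot is None:
                break
            chrom, s, e = slot
            peaks.append(Peak(chrom, s, e, name=f"{sp}_only{j:04d}", cell_type=sp))
        sets[sp] = PeakSet(peaks, provenance=sp)
    truth = {
        "n_shared_planted": len(shared_loci),
        "n_conserved_planted": k_cons,
        "conserved_percent_planted": 100.0 * k_cons / len(shared_loci),
        "n_human_broadest": len(human_top),
    }
    return sets, truth


def generate_network(
    config: SyntheticConfig, gene_ids: Optional[Sequence[str]] = None
) -> tuple[nx.Graph, list, dict]:
    """Preferential-attachment gene network with planted early-node hubs.

    Growth: start from a (m+1)-clique; each new node attaches to ``m``
    distinct existing nodes drawn with probability proportional to
    degree + 1.  Connected by construction; the first ``n_planted_hubs``
    nodes are the planted high-centrality group.  Node labels come from
    ``gene_ids`` when given (hubs first), else synthetic ids.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(8)[7])
    n, m = cfg.network_nodes, cfg.network_m
    degree = np.zeros(n, dtype=np.int64)
    edges: list[tuple[int, int]] = []
    for i in range(m + 1):
        for j in range(i + 1, m + 1):
            edges.append((i, j))
            degree[i] += 1
            degree[j] += 1
    for t in range(m + 1, n):
        weights = degree[:t] + 1.0
        targets = rng.choice(t, size=m, replace=False, p=weights / weights.sum())
        for u in targets:
            edges.append((int(u), t))
            degree[u] += 1
            degree[t] += 1
    labels = list(gene_ids[:n]) if gene_ids is not None else []
    if len(set(labels)) != len(labels):
        raise ValueError("gene_ids must be unique")
    labels += [f"G{i:05d}" for i in range(n - len(labels))]  # filler ids
    graph = nx.Graph()
    graph.add_nodes_from(labels)
    graph.add_edges_from((labels[u], labels[v]) for u, v in edges)
    hubs = labels[: cfg.n_planted_hubs]
    truth = {"n_nodes": n, "m": m, "planted_hubs": list(hubs)}
    return graph, hubs, truth


def generate_expression(
    config: SyntheticConfig,
    gene_ids: Sequence[str],
    target_genes: Sequence[str],
) -> tuple[ExpressionMatrix, dict]:
    """Paired gray/white FPKM with a planted compartment effect.

    Per gene: log2 baseline ~ N(mean, sd); per subject: shared random
    effect; target genes shifted by ``expr_effect_log2`` in gray matter.
    FPKM = 2**log2-value, strictly positive.
    """
    cfg = config
    if not len(gene_ids):
        raise ValueError("gene_ids must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(9)[8])
    genes = list(gene_ids)
    targets = set(target_genes)
    n_g, n_p = len(genes), cfg.n_expr_pairs
    baseline = rng.normal(cfg.expr_baseline_mean, cfg.expr_baseline_sd, n_g)
    subject_eff = rng.normal(0.0, cfg.expr_subject_sd, n_p)
    is_target = np.array([g in targets for g in genes], dtype=float)
    cols, names, meta_rows = [], [], []
    for j in range(n_p):
        for comp in ("gray", "white"):
            noise = rng.normal(0.0, cfg.expr_noise_sd, n_g)
            shift = cfg.expr_effect_log2 * is_target if comp == "gray" else 0.0
            cols.append(2.0 ** (baseline + subject_eff[j] + shift + noise))
            names.append(f"s{j + 1:02d}_{comp}")
            meta_rows.append({"sample": f"s{j + 1:02d}_{comp}",
                              "subject": f"s{j + 1:02d}", "compartment": comp})
    values = pd.DataFrame(np.column_stack(cols), index=pd.Index(genes, name="gene_id"),
                          columns=names)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    truth = {
        "effect_log2": cfg.expr_effect_log2,
        "n_pairs": n_p,
        "n_target_genes": int(is_target.sum()),
    }
    return ExpressionMatrix(values=values, meta=meta), truth
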