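"""Miniature multi-omic fixture with planted ground truth.

Generates, on a single synthetic chromosome, a gene annotation, an
open-chromatin landscape, multi-resolution loop calls at three activation
stages, GWAS summary statistics with planted causal variants, a truth gene
list with designed precision/recall, and an expression matrix with five
planted trajectory archetypes — everything the pipeline reads, with the
planted variant-gene pairs recoverable by construction:

* every causal variant sits inside a dedicated OCR that is either looped
  to its effector gene's promoter (distal design) or lies inside the
  promoter window itself (proxy design);
* all anchor/OCR placements go through a reserved-interval registry, and
  background loops and OCRs avoid promoter windows and reserved zones, so
  at zero proxy noise no variant-gene pair other than the planted ones is
  derivable from the emitted files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import TruthSet
from .contact_map import Loop
from .genomic_core import (
    OCR,
    GeneModel,
    GenomicInterval,
    IntervalSet,
    PromoterWindow,
    SummaryStatRecord,
    TIMEPOINTS,
    promoter_windows,
    write_gene_table,
    write_ocr_bed,
    write_summary_stats,
)
from .contact_map import write_loops_bedpe

# Timepoint support patterns cycled over causal loci so that the
# stage-sharing tiers (all/two/one stages) are all exercised.
_TP_PATTERNS = (
    frozenset(TIMEPOINTS),
    frozenset(TIMEPOINTS),
    frozenset(TIMEPOINTS),
    frozenset({"unstim", "8h"}),
    frozenset({"8h", "24h"}),
    frozenset({"unstim", "24h"}),
    frozenset({"unstim"}),
    frozenset({"8h"}),
    frozenset({"24h"}),
)

_TRAITS = ("T1D", "RA", "IBD", "SLE", "CEL")


@dataclass(frozen=True)
class SimConfig:
    """Fixture parameters (defaults sized for second-scale test runs)."""

    seed: int = 7
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    edge_margin: int = 200_000
    n_genes: int = 200
    min_tss_spacing: int = 5_000
    tss_jitter: int = 2_000
    max_tss_per_gene: int = 3
    noncoding_fraction: float = 0.1
    n_ocrs: int = 1_000
    ocr_width_min: int = 200
    ocr_width_max: int = 1_000
    n_background_loops: int = 180
    n_sentinels: int = 50
    mean_proxies: float = 14.0
    # 0.64 (rather than a looser 0.6) keeps the number of planted effector
    # genes divisible by 4, so the designed precision 0.25 / recall 0.5
    # truth set is exactly constructible at the default sentinel count.
    causal_fraction: float = 0.64
    promoter_proxy_fraction: float = 0.25
    min_loop_distance: int = 20_000
    max_loop_distance: int = 150_000
    causal_z_center: float = 6.0
    null_z_center: float = 2.0
    ld_decay_bp: float = 20_000.0
    proxy_noise_sd: float = 0.0
    truth_precision: float = 0.25
    truth_recall: float = 0.5
    expr_genes_per_cluster: int = 40
    expr_noise_sd: float = 0.2
    expr_replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_ocrs", "n_sentinels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("causal_fraction", "promoter_proxy_fraction",
                     "noncoding_fraction", "truth_precision", "truth_recall"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class PlantedPair:
    variant_id: str
    gene_id: str
    evidence: str  # "distal_contact" or "promoter_proxy"
    timepoints: frozenset[str]


@dataclass
class GroundTruth:
    """Planted causal structure of a simulated fixture."""

    pairs: tuple[PlantedPair, ...]
    causal_by_sentinel: dict[str, str | None]
    effector_genes: frozenset[str]
    sentinel_pos: dict[str, tuple[str, int]]


@dataclass
class LocusPlan:
    sentinel_id: str
    kind: str  # "distal", "proxy", or "null"
    trait: str
    gene: GeneModel | None
    ocr: OCR | None
    causal_pos: int | None
    center: int
    timepoints: frozenset[str]
    loop_ids: tuple[str, ...] = ()


@dataclass
class Landscape:
    ocrs: list[OCR]
    loops: list[Loop]
    plans: list[LocusPlan]
    planted_contacts: list[tuple[str, str]]  # (ocr_id, gene_id) with a loop


@dataclass
class Fixture:
    config: SimConfig
    genes: list[GeneModel]
    landscape: Landscape
    records: list[SummaryStatRecord]
    ground_truth: GroundTruth
    truth_set: TruthSet
    truth_design: dict
    expression: pd.DataFrame
    expression_truth: dict[str, int]

    @property
    def ocrs(self) -> list[OCR]:
        return self.landscape.ocrs

    @property
    def loops(self) -> list[Loop]:
        return self.landscape.loops


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Place genes with guaranteed inter-gene TSS spacing.

    Primary TSS are at least ``min_tss_spacing + 2 * tss_jitter`` apart so
    that even jittered alternative TSS of different genes keep >= 5 kb
    spacing. Strands and 1-3 TSS per gene are drawn at random.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spacing = config.min_tss_spacing + 2 * config.tss_jitter
    usable = config.chrom_length - 2 * config.edge_margin - config.n_genes * spacing
    if usable <= 0:
        raise ValueError(
            f"infeasible density: {config.n_genes} genes x {spacing} bp spacing "
            f"exceed usable chromosome length"
        )
    offsets = np.sort(rng.uniform(0, usable, size=config.n_genes)).astype(int)
    genes = []
    for i, off in enumerate(offsets):
        primary = int(config.edge_margin + off + i * spacing)
        n_tss = int(rng.integers(1, config.max_tss_per_gene + 1))
        tss = {primary}
        while len(tss) < n_tss:
            jitter = int(rng.integers(-config.tss_jitter, config.tss_jitter + 1))
            if jitter != 0:
                tss.add(primary + jitter)
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lincRNA" if rng.random() < config.noncoding_fraction else "protein_coding"
        genes.append(
            GeneModel(
                gene_id=f"G{i:04d}",
                symbol=f"GENE{i}",
                chrom=config.chrom,
                strand=strand,
                tss_list=tuple(sorted(tss)),
                biotype=biotype,
            )
        )
    return genes


def _primary_tss(gene: GeneModel) -> int:
    # the jittered alternatives stay within tss_jitter of the primary, so
    # the median TSS is a stable stand-in for "the" promoter position
    return gene.tss_list[len(gene.tss_list) // 2]


# ---------------------------------------------------------------------------
# Regulatory landscape
# ---------------------------------------------------------------------------


def _aligned_bin(chrom: str, pos: int, resolution: int) -> GenomicInterval:
    start = (pos // resolution) * resolution
    return GenomicInterval(chrom, start, start + resolution)


def simulate_regulatory_landscape(
    config: SimConfig,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> Landscape:
    """OCRs and multi-resolution loops with planted promoter contacts.

    Raises if the configured number of causal loci cannot be placed
    without collisions (loudly, rather than silently shrinking the truth).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom, L = config.chrom, config.chrom_length
    windows = [w for g in genes for w in promoter_windows(g, L)]
    windows_sorted = sorted(windows, key=lambda w: w.interval.start)

    def window_hit(start: int, end: int, exclude_gene: str | None = None):
        for w in windows_sorted:
            if w.interval.start >= end:
                break
            if w.interval.end > start and w.gene_id != exclude_gene:
                return w
        return None

    reserved = IntervalSet()
    ocrs: list[OCR] = []
    loops: list[Loop] = []
    plans: list[LocusPlan] = []
    planted_contacts: list[tuple[str, str]] = []

    n_causal = round(config.n_sentinels * config.causal_fraction)
    n_proxy = round(n_causal * config.promoter_proxy_fraction)
    resolutions = (1000, 2000, 4000)

    coding = [g for g in genes if g.biotype == "protein_coding"]
    order = rng.permutation(len(coding))
    candidates = [coding[i] for i in order]

    def next_pattern(i: int) -> frozenset[str]:
        return _TP_PATTERNS[i % len(_TP_PATTERNS)]

    loop_serial = 0
    placed = 0
    ci = 0
    for gene in candidates:
        if placed >= n_causal:
            break
        sid = f"sent{placed:03d}"
        trait = _TRAITS[placed % len(_TRAITS)]
        tps = next_pattern(placed)
        tss = _primary_tss(gene)
        kind = "proxy" if placed < n_proxy else "distal"

        if kind == "proxy":
            width = int(rng.integers(config.ocr_width_min, min(config.ocr_width_max, 500) + 1))
            start = tss - width // 2
            end = start + width
            if (
                window_hit(start, end, exclude_gene=gene.gene_id) is not None
                or reserved.overlaps(start, end)
            ):
                continue
            peak = OCR(f"ocr_{sid}", GenomicInterval(chrom, start, end), tps)
            reserved.add(start, end)
            ocrs.append(peak)
            plans.append(
                LocusPlan(sid, "proxy", trait, gene, peak, tss, tss, tps)
            )
            placed += 1
            continue

        resolution = resolutions[placed % len(resolutions)]
        anchor_p = _aligned_bin(chrom, tss, resolution)
        if (
            window_hit(anchor_p.start, anchor_p.end, exclude_gene=gene.gene_id) is not None
            or reserved.overlaps(anchor_p.start, anchor_p.end)
        ):
            continue
        success = False
        for _ in range(40):
            direction = 1 if rng.random() < 0.5 else -1
            dist = int(rng.integers(config.min_loop_distance, config.max_loop_distance + 1))
            width = int(rng.integers(config.ocr_width_min, config.ocr_width_max + 1))
            ocr_start = tss + direction * dist
            ocr_end = ocr_start + width
            if ocr_start < config.edge_margin or ocr_end > L - config.edge_margin:
                continue
            anchor_o = _aligned_bin(chrom, (ocr_start + ocr_end) // 2, resolution)
            zone_start = min(ocr_start, anchor_o.start)
            zone_end = max(ocr_end, anchor_o.end)
            if window_hit(zone_start, zone_end) is not None:
                continue
            if reserved.overlaps(zone_start, zone_end):
                continue
            if anchor_p.overlaps(anchor_o):
                continue
            # commit
            reserved.add(anchor_p.start, anchor_p.end)
            reserved.add(zone_start, zone_end)
            causal_pos = (ocr_start + ocr_end) // 2
            peak = OCR(f"ocr_{sid}", GenomicInterval(chrom, ocr_start, ocr_end), tps)
            ocrs.append(peak)
            left, right = (
                (anchor_p, anchor_o)
                if anchor_p.start < anchor_o.start
                else (anchor_o, anchor_p)
            )
            lids = []
            for tp in sorted(tps):
                lid = f"loop_{sid}_{tp}"
                loops.append(
                    Loop(left, right, resolution, tp, qvalue=1e-8, loop_id=lid)
                )
                lids.append(lid)
            # with some probability also emit an equivalent coarser call,
            # exercising consensus merging inside the full pipeline
            if resolution < 4000 and rng.random() < 0.5:
                coarse = resolutions[resolutions.index(resolution) + 1]
                ap, ao = _aligned_bin(chrom, tss, coarse), _aligned_bin(chrom, causal_pos, coarse)
                if not ap.overlaps(ao):
                    cl, cr = (ap, ao) if ap.start < ao.start else (ao, ap)
                    for tp in sorted(tps):
                        loop_serial += 1
                        loops.append(
                            Loop(cl, cr, coarse, tp, qvalue=1e-7,
                                 loop_id=f"loop_coarse{loop_serial}")
                        )
            plans.append(
                LocusPlan(sid, "distal", trait, gene, peak, causal_pos,
                          causal_pos, tps, tuple(lids))
            )
            planted_contacts.append((peak.peak_id, gene.gene_id))
            placed += 1
            success = True
            break
        if not success:
            continue
    if placed < n_causal:
        raise RuntimeError(
            f"could only place {placed}/{n_causal} causal loci; "
            "lower density or enlarge the chromosome"
        )

    # null sentinels: association signals with no accessible causal variant
    n_null = config.n_sentinels - n_causal
    for i in range(n_null):
        sid = f"sent{n_causal + i:03d}"
        trait = _TRAITS[(n_causal + i) % len(_TRAITS)]
        for _ in range(200):
            center = int(rng.integers(config.edge_margin, L - config.edge_margin))
            if not reserved.overlaps(center - 70_000, center + 70_000):
                break
        else:
            raise RuntimeError("no free space for a null locus")
        reserved.add(center - 70_000, center + 70_000)
        plans.append(LocusPlan(sid, "null", trait, None, None, None, center,
                               frozenset()))

    # background OCRs, clear of promoter windows and all reserved zones
    n_background = max(0, config.n_ocrs - len(ocrs))
    bg_placed = 0
    attempts = 0
    while bg_placed < n_background and attempts < 50 * n_background:
        attempts += 1
        width = int(rng.integers(config.ocr_width_min, config.ocr_width_max + 1))
        start = int(rng.integers(config.edge_margin, L - config.edge_margin - width))
        end = start + width
        if reserved.overlaps(start, end) or window_hit(start, end) is not None:
            continue
        n_tp = int(rng.integers(1, 4))
        tps = frozenset(rng.choice(TIMEPOINTS, size=n_tp, replace=False).tolist())
        ocrs.append(OCR(f"bg_ocr{bg_placed:04d}", GenomicInterval(chrom, start, end), tps))
        reserved.add(start, end)
        bg_placed += 1

    # background loops: anchors clear of promoter windows and reserved
    # zones, so they can never support a promoter contact nor absorb a
    # planted loop during consensus merging
    bg_loops = 0
    attempts = 0
    while bg_loops < config.n_background_loops and attempts < 100 * config.n_background_loops:
        attempts += 1
        resolution = int(rng.choice(resolutions))
        p1 = int(rng.integers(config.edge_margin, L - config.edge_margin - 600_000))
        p2 = p1 + int(rng.integers(30_000, 500_000))
        a1 = _aligned_bin(chrom, p1, resolution)
        a2 = _aligned_bin(chrom, p2, resolution)
        if a1.overlaps(a2):
            continue
        bad = False
        for a in (a1, a2):
            if reserved.overlaps(a.start, a.end) or window_hit(a.start, a.end) is not None:
                bad = True
                break
        if bad:
            continue
        n_tp = int(rng.integers(1, 4))
        for tp in sorted(rng.choice(TIMEPOINTS, size=n_tp, replace=False).tolist()):
            loops.append(
                Loop(a1, a2, resolution, tp, qvalue=1e-7, loop_id=f"bg_loop{bg_loops:04d}_{tp}")
            )
        bg_loops += 1

    ocrs.sort(key=lambda o: (o.interval.chrom, o.interval.start))
    return Landscape(ocrs=ocrs, loops=loops, plans=plans, planted_contacts=planted_contacts)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------


def _z_to_p(z: np.ndarray | float) -> np.ndarray | float:
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)


def simulate_gwas(
    config: SimConfig,
    landscape: Landscape,
    rng: np.random.Generator | None = None,
) -> tuple[list[SummaryStatRecord], GroundTruth]:
    """Summary statistics with planted causal variants.

    The causal variant of each causal locus gets ``z ~ Normal(z_center, 1)``;
    proxy z-scores decay with distance, ``z_d = rho * z_causal`` with
    ``rho = exp(-d / ld_decay)``, plus Gaussian noise of sd
    ``proxy_noise_sd * sqrt(1 - rho^2)`` (zero by default, making the
    causal variant the posterior maximum of its locus). Proxies are
    rejection-sampled to stay outside every OCR, so only planted causal
    variants are accessible.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    occupied = IntervalSet()
    for o in landscape.ocrs:
        occupied.add(o.interval.start, o.interval.end)

    records: list[SummaryStatRecord] = []
    pairs: list[PlantedPair] = []
    causal_by_sentinel: dict[str, str | None] = {}
    sentinel_pos: dict[str, tuple[str, int]] = {}

    for plan in landscape.plans:
        sid = plan.sentinel_id
        sentinel_pos[sid] = (config.chrom, plan.center)
        n_var = max(2, int(rng.poisson(config.mean_proxies)))
        center = plan.center
        if plan.kind == "null":
            # keep even the lead variant outside open chromatin
            for _ in range(200):
                if not occupied.overlaps(center, center + 1):
                    break
                center = int(rng.integers(config.edge_margin,
                                          config.chrom_length - config.edge_margin))
            z_center = config.null_z_center
            causal_by_sentinel[sid] = None
        else:
            z_center = config.causal_z_center
            causal_by_sentinel[sid] = f"{sid}_v0"
        z0 = float(rng.normal(z_center, 1.0))
        positions = [center]
        while len(positions) < n_var:
            off = int(rng.integers(-60_000, 60_001))
            pos = center + off
            if off == 0 or pos < 0 or pos >= config.chrom_length:
                continue
            if occupied.overlaps(pos, pos + 1):
                continue
            if pos in positions:
                continue
            positions.append(pos)
        for j, pos in enumerate(positions):
            if j == 0:
                z = z0
            else:
                rho = math.exp(-abs(pos - center) / config.ld_decay_bp)
                z = rho * z0
                if config.proxy_noise_sd > 0:
                    z += config.proxy_noise_sd * math.sqrt(1 - rho * rho) * float(
                        rng.normal()
                    )
            records.append(
                SummaryStatRecord(
                    variant_id=f"{sid}_v{j}",
                    chrom=config.chrom,
                    pos=pos,
                    p_value=float(_z_to_p(z)),
                    sentinel_id=sid,
                    trait=plan.trait,
                )
            )
        if plan.kind != "null":
            pairs.append(
                PlantedPair(
                    variant_id=f"{sid}_v0",
                    gene_id=plan.gene.gene_id,
                    evidence="promoter_proxy" if plan.kind == "proxy" else "distal_contact",
                    timepoints=plan.timepoints,
                )
            )
    truth = GroundTruth(
        pairs=tuple(pairs),
        causal_by_sentinel=causal_by_sentinel,
        effector_genes=frozenset(p.gene_id for p in pairs),
        sentinel_pos=sentinel_pos,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Truth set with designed precision/recall
# ---------------------------------------------------------------------------


def simulate_truth_set(
    config: SimConfig,
    ground_truth: GroundTruth,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> tuple[TruthSet, dict]:
    """Truth gene list so that the perfect predictor (all planted effector
    genes) has exactly the configured precision and recall.

    With m planted effectors, the truth set holds ``m * precision``
    effectors plus decoys up to size ``m * precision / recall``; both
    counts must be integers, otherwise the targets are infeasible.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    effectors = sorted(ground_truth.effector_genes)
    m = len(effectors)
    overlap_f = m * config.truth_precision
    overlap = round(overlap_f)
    if abs(overlap_f - overlap) > 1e-9 or overlap < 1:
        raise ValueError(
            f"precision target {config.truth_precision} infeasible for {m} effectors"
        )
    size_f = overlap / config.truth_recall
    size = round(size_f)
    if abs(size_f - size) > 1e-9:
        raise ValueError(
            f"recall target {config.truth_recall} infeasible for overlap {overlap}"
        )
    decoy_pool = sorted(
        g.gene_id
        for g in genes
        if g.biotype == "protein_coding" and g.gene_id not in ground_truth.effector_genes
    )
    n_decoys = size - overlap
    if n_decoys > len(decoy_pool):
        raise ValueError("not enough non-effector genes for the requested decoys")
    chosen = rng.choice(len(effectors), size=overlap, replace=False)
    members = {effectors[i] for i in chosen}
    decoys = rng.choice(len(decoy_pool), size=n_decoys, replace=False)
    members |= {decoy_pool[i] for i in decoys}
    design = {
        "n_effectors": m,
        "overlap": overlap,
        "truth_size": size,
        "designed_precision": overlap / m,
        "designed_recall": overlap / size,
    }
    return TruthSet("planted", frozenset(members)), design


# ---------------------------------------------------------------------------
# Expression fixture (five trajectory archetypes)
# ---------------------------------------------------------------------------

# Five trajectory archetypes as evenly spaced phases of a cosine over the
# three stages. With three timepoints, row-standardized trajectories live
# on a circle, so even phase spacing is the best-separated 5-archetype
# layout that exists; it yields equal neighbour distances and a crisp
# elbow at k = 5.
ARCHETYPES = {
    c: tuple(
        math.cos(2 * math.pi * (c - 1) / 5 - 2 * math.pi * t / 3) for t in range(3)
    )
    for c in range(1, 6)
}


def simulate_expression(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Expression matrix with five planted archetypes plus Gaussian noise."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    columns = [
        f"{tp}_r{r + 1}" for tp in TIMEPOINTS for r in range(config.expr_replicates)
    ]
    rows, truth = [], {}
    index = []
    gi = 0
    for cluster, base in ARCHETYPES.items():
        for _ in range(config.expr_genes_per_cluster):
            gene = f"EXPR{gi:04d}"
            gi += 1
            values = [
                base[t] + float(rng.normal(0, config.expr_noise_sd))
                for t in range(len(TIMEPOINTS))
                for _ in range(config.expr_replicates)
            ]
            rows.append(values)
            index.append(gene)
            truth[gene] = cluster
    return pd.DataFrame(rows, index=index, columns=columns), truth


# ---------------------------------------------------------------------------
# Enrichment fixtures (permutation-test calibration and planted fold)
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentFixture:
    genes: list[GeneModel]
    sentinel_pos: dict[str, tuple[str, int]]
    v2g_pairs: set[tuple[str, str]]
    comparison_pairs: list[tuple[str, str]]
    true_fold: float


def simulate_enrichment_fixture(
    n_sentinels: int = 40,
    genes_per_locus: int = 50,
    v2g_per_locus: int = 5,
    mode: str = "enriched",
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> EnrichmentFixture:
    """Sentinels with a fixed-size 1 Mb gene universe and a V2G pair set.

    In ``enriched`` mode every comparison pair's gene is one of its
    sentinel's V2G genes, so the true enrichment fold is exactly
    ``genes_per_locus / v2g_per_locus``; in ``null`` mode comparison genes
    are drawn uniformly from the sentinel's universe (fold 1, calibrated
    p-values).
    """
    if mode not in ("enriched", "null"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    sentinel_pos: dict[str, tuple[str, int]] = {}
    v2g_pairs: set[tuple[str, str]] = set()
    comparison: list[tuple[str, str]] = []
    span = 1_800_000  # all TSS within +-900 kb of the sentinel
    for s in range(n_sentinels):
        chrom = f"chr{s + 1}"
        sid = f"sent{s:03d}"
        center = 2_000_000
        sentinel_pos[sid] = (chrom, center)
        tss = np.linspace(center - span // 2, center + span // 2, genes_per_locus).astype(int)
        ids = []
        for j in range(genes_per_locus):
            gid = f"{sid}_g{j:03d}"
            ids.append(gid)
            genes.append(
                GeneModel(gid, gid, chrom, "+", (int(tss[j]),), "protein_coding")
            )
        v2g_idx = rng.choice(genes_per_locus, size=v2g_per_locus, replace=False)
        v2g_here = [ids[i] for i in v2g_idx]
        v2g_pairs.update((sid, g) for g in v2g_here)
        if mode == "enriched":
            comparison.append((sid, v2g_here[int(rng.integers(0, v2g_per_locus))]))
        else:
            comparison.append((sid, ids[int(rng.integers(0, genes_per_locus))]))
    return EnrichmentFixture(
        genes=genes,
        sentinel_pos=sentinel_pos,
        v2g_pairs=v2g_pairs,
        comparison_pairs=comparison,
        true_fold=genes_per_locus / v2g_per_locus,
    )


# ---------------------------------------------------------------------------
# Orchestration and file output
# ---------------------------------------------------------------------------


def simulate_fixture(config: SimConfig = SimConfig()) -> Fixture:
    """Run every simulation stage with a single seeded generator."""
    rng = np.random.default_rng(config.seed)
    genes = simulate_genome(config, rng)
    landscape = simulate_regulatory_landscape(config, genes, rng)
    records, truth = simulate_gwas(config, landscape, rng)
    truth_set, design = simulate_truth_set(config, truth, genes, rng)
    expression, expr_truth = simulate_expression(config, rng)
    return Fixture(
        config=config,
        genes=genes,
        landscape=landscape,
        records=records,
        ground_truth=truth,
        truth_set=truth_set,
        truth_design=design,
        expression=expression,
        expression_truth=expr_truth,
    )


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture artifact in the dialects the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.tsv",
        "ocrs": outdir / "ocrs.bed",
        "loops": outdir / "loops.bedpe",
        "sumstats": outdir / "sumstats.tsv",
        "truth_genes": outdir / "truth_genes.txt",
        "expression": outdir / "expression.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_gene_table(fixture.genes, paths["genes"])
    write_ocr_bed(fixture.ocrs, paths["ocrs"])
    write_loops_bedpe(fixture.loops, paths["loops"])
    write_summary_stats(fixture.records, paths["sumstats"])
    paths["truth_genes"].write_text(
        "\n".join(sorted(fixture.truth_set.gene_ids)) + "\n"
    )
    fixture.expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    gt = fixture.ground_truth
    paths["ground_truth"].write_text(
        json.dumps(
            {
                "pairs": [
                    {
                        "variant_id": p.variant_id,
                        "gene_id": p.gene_id,
                        "evidence": p.evidence,
                        "timepoints": sorted(p.timepoints),
                    }
                    for p in gt.pairs
                ],
                "causal_by_sentinel": gt.causal_by_sentinel,
                "effector_genes": sorted(gt.effector_genes),
                "sentinel_pos": {k: list(v) for k, v in gt.sentinel_pos.items()},
                "truth_design": fixture.truth_design,
            },
            indent=2,
        )
    )
    return paths
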