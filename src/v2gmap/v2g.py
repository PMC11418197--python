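"""Effector-gene nomination from accessible credible-set variants.

A variant-gene pair is emitted with evidence ``promoter_proxy`` when the
variant lies in an open-chromatin region that overlaps the gene's promoter
window, and with evidence ``distal_contact`` when the variant lies in an
OCR at a loop anchor whose partner anchor overlaps the gene's promoter
window. Pairs supported by both kinds of evidence carry both tags.
"""

from __future__ import annotations

import json
import logging
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .contact_map import PromoterContact
from .credible_set import CredibleSet
from .genomic_core import (
    OCR,
    GeneModel,
    PromoterWindow,
    TIMEPOINTS,
    _open_text,
    distance_to_tss,
    intersect,
    nearest_gene,
    point_interval,
)

logger = logging.getLogger(__name__)

PROMOTER_PROXY = "promoter_proxy"
DISTAL_CONTACT = "distal_contact"

NEAREST_CLASSES = ("no_gene", "nearest_only", "nearest_plus_distal", "distal_only")
SHARING_TIERS = ("all_stages", "two_stages", "one_stage")


@dataclass(frozen=True)
class AccessibleVariant:
    """An accessible credible-set variant, ready for nomination."""

    variant_id: str
    sentinel_id: str
    trait: str
    chrom: str
    pos: int
    pp: float = float("nan")


@dataclass(frozen=True)
class V2GPair:
    """One nominated variant-gene pair with its evidence."""

    variant_id: str
    sentinel_id: str
    trait: str
    gene_id: str
    chrom: str
    pos: int
    evidence: frozenset[str]
    timepoints: frozenset[str]
    distance_bp: int
    ocr_ids: tuple[str, ...]
    loop_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "evidence", frozenset(self.evidence))
        object.__setattr__(self, "timepoints", frozenset(self.timepoints))
        if not self.evidence <= {PROMOTER_PROXY, DISTAL_CONTACT}:
            raise ValueError(f"unknown evidence tags {sorted(self.evidence)}")


@dataclass
class V2GSummary:
    """Descriptive statistics of a nominated pair set."""

    n_pairs: int
    n_variants: int
    n_genes: int
    genes_per_variant_median: float
    genes_per_variant_mean: float
    variants_per_gene_median: float
    ocrs_per_gene_median: float
    distance_median: float
    distance_mean: float
    genes_per_variant: dict[str, int] = field(default_factory=dict)
    variants_per_gene: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_variants": self.n_variants,
            "n_genes": self.n_genes,
            "genes_per_variant_median": self.genes_per_variant_median,
            "genes_per_variant_mean": self.genes_per_variant_mean,
            "variants_per_gene_median": self.variants_per_gene_median,
            "ocrs_per_gene_median": self.ocrs_per_gene_median,
            "distance_median": self.distance_median,
            "distance_mean": self.distance_mean,
        }


def accessible_variants(credible_sets: Iterable[CredibleSet]) -> list[AccessibleVariant]:
    """Flatten (constrained) credible sets into nomination inputs."""
    out = []
    for cs in credible_sets:
        for m in cs.members:
            out.append(
                AccessibleVariant(
                    variant_id=m.variant_id,
                    sentinel_id=cs.sentinel_id,
                    trait=cs.trait,
                    chrom=m.chrom,
                    pos=m.pos,
                    pp=m.pp,
                )
            )
    return out


def nominate(
    variants: Sequence[AccessibleVariant],
    contacts: Sequence[PromoterContact],
    windows: Sequence[PromoterWindow],
    ocrs: Sequence[OCR],
    genes: Mapping[str, GeneModel] | Sequence[GeneModel],
) -> list[V2GPair]:
    """Nominate effector genes for accessible credible-set variants.

    Emits the union of promoter-proxy pairs (variant in an OCR that
    overlaps a promoter window) and distal-contact pairs (variant in the
    OCR of a promoter contact), deduplicated on (variant, gene) with
    evidence tags and timepoint support merged.
    """
    genes_by_id = (
        dict(genes) if isinstance(genes, Mapping) else {g.gene_id: g for g in genes}
    )
    variant_ivs = [point_interval(v.chrom, v.pos) for v in variants]
    ocr_ivs = [o.interval for o in ocrs]
    window_ivs = [w.interval for w in windows]

    var_to_ocrs: dict[int, list[int]] = {}
    for vi, oi in intersect(variant_ivs, ocr_ivs):
        var_to_ocrs.setdefault(vi, []).append(oi)

    ocr_to_windows: dict[int, list[int]] = {}
    for oi, wi in intersect(ocr_ivs, window_ivs):
        ocr_to_windows.setdefault(oi, []).append(wi)

    contacts_by_ocr: dict[str, list[PromoterContact]] = {}
    for c in contacts:
        contacts_by_ocr.setdefault(c.ocr_id, []).append(c)

    merged: dict[tuple[str, str], dict] = {}

    def _add(variant: AccessibleVariant, gene_id: str, evidence: str,
             timepoints: frozenset[str], ocr_id: str, loop_ids=()):
        gene = genes_by_id.get(gene_id)
        if gene is None:
            logger.warning("nominated gene %s missing from annotation; skipped", gene_id)
            return
        key = (variant.variant_id, gene_id)
        entry = merged.setdefault(
            key,
            {
                "variant": variant,
                "gene": gene,
                "evidence": set(),
                "timepoints": set(),
                "ocr_ids": set(),
                "loop_ids": set(),
            },
        )
        entry["evidence"].add(evidence)
        entry["timepoints"] |= timepoints
        entry["ocr_ids"].add(ocr_id)
        entry["loop_ids"] |= set(loop_ids)

    for vi, variant in enumerate(variants):
        for oi in var_to_ocrs.get(vi, ()):
            ocr = ocrs[oi]
            for wi in ocr_to_windows.get(oi, ()):
                _add(variant, windows[wi].gene_id, PROMOTER_PROXY,
                     ocr.timepoints, ocr.peak_id)
            for contact in contacts_by_ocr.get(ocr.peak_id, ()):
                _add(variant, contact.gene_id, DISTAL_CONTACT,
                     contact.timepoints, ocr.peak_id, contact.loop_ids)

    pairs = []
    for (variant_id, gene_id), entry in sorted(merged.items()):
        v, g = entry["variant"], entry["gene"]
        pairs.append(
            V2GPair(
                variant_id=variant_id,
                sentinel_id=v.sentinel_id,
                trait=v.trait,
                gene_id=gene_id,
                chrom=v.chrom,
                pos=v.pos,
                evidence=frozenset(entry["evidence"]),
                timepoints=frozenset(entry["timepoints"]),
                distance_bp=distance_to_tss(v.pos, g),
                ocr_ids=tuple(sorted(entry["ocr_ids"])),
                loop_ids=tuple(sorted(entry["loop_ids"])),
            )
        )
    return pairs


def _median(xs) -> float:
    return float(statistics.median(xs))


def degree_and_distance(pairs: Sequence[V2GPair]) -> V2GSummary:
    """Genes-per-variant / variants-per-gene degrees and TSS distances."""
    if not pairs:
        raise ValueError("empty pair list")
    genes_per_variant: dict[str, set] = {}
    variants_per_gene: dict[str, set] = {}
    ocrs_per_gene: dict[str, set] = {}
    for p in pairs:
        genes_per_variant.setdefault(p.variant_id, set()).add(p.gene_id)
        variants_per_gene.setdefault(p.gene_id, set()).add(p.variant_id)
        ocrs_per_gene.setdefault(p.gene_id, set()).update(p.ocr_ids)
    gpv = {v: len(gs) for v, gs in genes_per_variant.items()}
    vpg = {g: len(vs) for g, vs in variants_per_gene.items()}
    distances = [p.distance_bp for p in pairs]
    return V2GSummary(
        n_pairs=len(pairs),
        n_variants=len(gpv),
        n_genes=len(vpg),
        genes_per_variant_median=_median(list(gpv.values())),
        genes_per_variant_mean=float(sum(gpv.values()) / len(gpv)),
        variants_per_gene_median=_median(list(vpg.values())),
        ocrs_per_gene_median=_median([len(s) for s in ocrs_per_gene.values()]),
        distance_median=_median(distances),
        distance_mean=float(sum(distances) / len(distances)),
        genes_per_variant=gpv,
        variants_per_gene=vpg,
    )


def classify_nearest(
    variants: Sequence[AccessibleVariant],
    pairs: Sequence[V2GPair],
    genes: Sequence[GeneModel],
    biotypes: set[str] | None = frozenset({"protein_coding"}),
) -> tuple[dict[str, str], dict[str, int]]:
    """Classify each accessible variant by its relation to the nearest gene.

    Four-way partition: ``no_gene`` (no nominated gene), ``nearest_only``,
    ``nearest_plus_distal``, ``distal_only``; "nearest" is the minimum-TSS-
    distance gene among the (biotype-filtered) annotation.
    """
    genes_by_variant: dict[str, set[str]] = {}
    for p in pairs:
        genes_by_variant.setdefault(p.variant_id, set()).add(p.gene_id)
    classes: dict[str, str] = {}
    for v in variants:
        nominated = genes_by_variant.get(v.variant_id, set())
        if not nominated:
            classes[v.variant_id] = "no_gene"
            continue
        near = nearest_gene(v.pos, v.chrom, genes, biotypes=set(biotypes) if biotypes else None)
        if near.gene_id in nominated:
            classes[v.variant_id] = (
                "nearest_only" if nominated == {near.gene_id} else "nearest_plus_distal"
            )
        else:
            classes[v.variant_id] = "distal_only"
    counts = {cls: 0 for cls in NEAREST_CLASSES}
    for cls in classes.values():
        counts[cls] += 1
    return classes, counts


def stage_sharing(pairs: Sequence[V2GPair]) -> tuple[dict[str, int], dict[str, int]]:
    """Per-gene count of supporting timepoints and tier totals.

    A gene is supported at a timepoint when at least one of its pairs
    carries that flag. Tiers: supported at all 3 stages, at 2, or at 1.
    """
    stages_by_gene: dict[str, set[str]] = {}
    for p in pairs:
        stages_by_gene.setdefault(p.gene_id, set()).update(p.timepoints)
    n_stages = {g: len(s) for g, s in stages_by_gene.items()}
    tiers = {t: 0 for t in SHARING_TIERS}
    for n in n_stages.values():
        if n >= 3:
            tiers["all_stages"] += 1
        elif n == 2:
            tiers["two_stages"] += 1
        elif n == 1:
            tiers["one_stage"] += 1
    return n_stages, tiers


def dynamic_subset(
    pairs: Sequence[V2GPair],
    cluster_assignments: Mapping[str, int],
    dynamic_clusters: set[int] = frozenset({1, 2, 3, 4, 5}),
) -> tuple[list[V2GPair], dict]:
    """Restrict pairs to genes in dynamically regulated expression clusters.

    Genes absent from the assignment table are treated as non-dynamic and
    logged.
    """
    kept, missing = [], set()
    for p in pairs:
        cluster = cluster_assignments.get(p.gene_id)
        if cluster is None:
            missing.add(p.gene_id)
            continue
        if cluster in dynamic_clusters:
            kept.append(p)
    if missing:
        logger.info(
            "dynamic_subset: %d genes absent from cluster table, treated as non-dynamic",
            len(missing),
        )
    report = {
        "n_pairs_in": len(pairs),
        "n_pairs_kept": len(kept),
        "n_genes_kept": len({p.gene_id for p in kept}),
        "n_genes_missing": len(missing),
    }
    return kept, report


def write_pairs_tsv(pairs: Iterable[V2GPair], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(
            "variant_id\tsentinel_id\ttrait\tgene_id\tchrom\tpos\tevidence\t"
            "timepoints\tdistance_bp\tocr_ids\tloop_ids\n"
        )
        for p in pairs:
            ev = ",".join(sorted(p.evidence))
            tps = ",".join(t for t in TIMEPOINTS if t in p.timepoints)
            fh.write(
                f"{p.variant_id}\t{p.sentinel_id}\t{p.trait}\t{p.gene_id}\t"
                f"{p.chrom}\t{p.pos + 1}\t{ev}\t{tps}\t{p.distance_bp}\t"
                f"{','.join(p.ocr_ids)}\t{','.join(p.loop_ids)}\n"
            )


def read_pairs_tsv(path: str | Path) -> list[V2GPair]:
    pairs = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            pairs.append(
                V2GPair(
                    variant_id=f[idx["variant_id"]],
                    sentinel_id=f[idx["sentinel_id"]],
                    trait=f[idx["trait"]],
                    gene_id=f[idx["gene_id"]],
                    chrom=f[idx["chrom"]],
                    pos=int(f[idx["pos"]]) - 1,
                    evidence=frozenset(x for x in f[idx["evidence"]].split(",") if x),
                    timepoints=frozenset(x for x in f[idx["timepoints"]].split(",") if x),
                    distance_bp=int(f[idx["distance_bp"]]),
                    ocr_ids=tuple(x for x in f[idx["ocr_ids"]].split(",") if x),
                    loop_ids=tuple(x for x in f[idx["loop_ids"]].split(",") if x),
                )
            )
    return pairs
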