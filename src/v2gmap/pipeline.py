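"""End-to-end orchestration: summary stats + OCRs + loops -> V2G pairs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .contact_map import ConsensusLoop, Loop, PromoterContact, build_consensus, promoter_interacting_ocrs
from .credible_set import (
    CredibleSet,
    FineMapConfig,
    build_credible_set,
    constrain_many,
    group_signals,
)
from .genomic_core import OCR, GeneModel, PromoterWindow, SummaryStatRecord, promoter_windows
from .v2g import V2GPair, accessible_variants, nominate


@dataclass
class PipelineResult:
    credible_sets: list[CredibleSet]
    accessible_sets: list[CredibleSet]
    constraint_report: dict
    consensus: list[ConsensusLoop]
    windows: list[PromoterWindow]
    contacts: list[PromoterContact]
    pairs: list[V2GPair]


def run_pipeline(
    records: Sequence[SummaryStatRecord],
    ocrs: Sequence[OCR],
    loops: Sequence[Loop],
    genes: Sequence[GeneModel],
    chrom_length: int | None = None,
    finemap: FineMapConfig = FineMapConfig(),
    timepoints: set[str] | None = None,
    merge_order: str = "resolutions_first",
    strand_aware_promoters: bool = True,
) -> PipelineResult:
    """Credible sets -> open-chromatin constraint -> loop consensus ->
    promoter contacts -> variant-gene nomination."""
    signals = group_signals(records)
    credible_sets = [build_credible_set(s, finemap) for s in signals]
    accessible_sets, report = constrain_many(credible_sets, ocrs, timepoints)
    consensus = build_consensus(loops, order=merge_order)
    windows = [
        w
        for g in genes
        for w in promoter_windows(g, chrom_length, strand_aware=strand_aware_promoters)
    ]
    windows.sort(key=lambda w: (w.interval.chrom, w.interval.start))
    contacts = promoter_interacting_ocrs(consensus, windows, ocrs)
    variants = accessible_variants(accessible_sets)
    pairs = nominate(variants, contacts, windows, ocrs, genes)
    return PipelineResult(
        credible_sets=credible_sets,
        accessible_sets=accessible_sets,
        constraint_report=report,
        consensus=consensus,
        windows=windows,
        contacts=contacts,
        pairs=pairs,
    )
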