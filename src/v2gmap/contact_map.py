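"""Hi-C loop canonicalization, consensus merging, and promoter-contact annotation.

Loops are called at multiple resolutions (1, 2 and 4 kb bins) and at three
activation stages. Consensus merging walks resolutions fine-to-coarse and
keeps a coarser call only when no already-kept loop overlaps it at BOTH
anchors, so the highest-resolution representative always wins; timepoint
union applies the same both-anchor rule across stages and records per-stage
support flags. Annotation then pairs each promoter-window-overlapping
anchor with the open-chromatin regions at the partner anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genomic_core import (
    OCR,
    GeneModel,
    GenomicInterval,
    ParseError,
    PromoterWindow,
    TIMEPOINTS,
    _open_text,
    intersect,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

RESOLUTIONS = (1000, 2000, 4000)


@dataclass(frozen=True)
class Loop:
    """One intra-chromosomal loop call at a single resolution/timepoint."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    resolution: int
    timepoint: str
    qvalue: float = 0.0
    loop_id: str = ""

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError(
                f"loop {self.loop_id or '<unnamed>'}: trans-chromosomal anchors "
                f"{self.anchor1.chrom} / {self.anchor2.chrom}"
            )
        if self.resolution not in RESOLUTIONS:
            raise ValueError(f"unknown resolution {self.resolution}")
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.anchor1.overlaps(self.anchor2):
            raise ValueError(f"loop {self.loop_id or '<unnamed>'}: overlapping anchors")


@dataclass(frozen=True)
class ConsensusLoop:
    """A merged loop with provenance of absorbed coarser/duplicate calls."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    resolution: int
    timepoints: frozenset[str]
    loop_ids: tuple[str, ...] = ()
    absorbed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", frozenset(self.timepoints))


@dataclass(frozen=True)
class PromoterContact:
    """An OCR <-> gene-promoter contact derived from a consensus loop."""

    ocr_id: str
    gene_id: str
    tss: int
    timepoints: frozenset[str]
    loop_ids: tuple[str, ...]
    contact_class: str  # "distal" or "promoter_proximal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "timepoints", frozenset(self.timepoints))


def canonicalize(loop: Loop) -> Loop:
    """Order anchors by start position; idempotent."""
    if loop.anchor1.start <= loop.anchor2.start:
        return loop
    return Loop(
        anchor1=loop.anchor2,
        anchor2=loop.anchor1,
        resolution=loop.resolution,
        timepoint=loop.timepoint,
        qvalue=loop.qvalue,
        loop_id=loop.loop_id,
    )


def _both_anchor_overlap(a1, a2, b1, b2) -> bool:
    return a1.overlaps(b1) and a2.overlaps(b2)


def _merge_key(c: ConsensusLoop):
    return (
        c.resolution,
        c.anchor1.chrom,
        c.anchor1.start,
        c.anchor1.end,
        c.anchor2.start,
        c.anchor2.end,
        tuple(sorted(c.loop_ids)),
    )


def _greedy_merge(candidates: Sequence[ConsensusLoop]) -> list[ConsensusLoop]:
    """Fine-to-coarse greedy both-anchor-overlap merge.

    Candidates are processed in a canonical order (resolution, then
    coordinates), so the result does not depend on input order. A
    candidate overlapping an already-kept loop at both anchors is absorbed
    into the first such loop (timepoints unioned, ids recorded).
    """
    kept: list[ConsensusLoop] = []
    by_chrom: dict[str, list[int]] = {}
    for cand in sorted(candidates, key=_merge_key):
        absorbed_into = None
        for k in by_chrom.get(cand.anchor1.chrom, ()):
            existing = kept[k]
            if _both_anchor_overlap(
                cand.anchor1, cand.anchor2, existing.anchor1, existing.anchor2
            ):
                absorbed_into = k
                break
        if absorbed_into is None:
            by_chrom.setdefault(cand.anchor1.chrom, []).append(len(kept))
            kept.append(cand)
        else:
            existing = kept[absorbed_into]
            kept[absorbed_into] = ConsensusLoop(
                anchor1=existing.anchor1,
                anchor2=existing.anchor2,
                resolution=existing.resolution,
                timepoints=existing.timepoints | cand.timepoints,
                loop_ids=existing.loop_ids,
                absorbed=existing.absorbed + cand.loop_ids + cand.absorbed,
            )
    return kept


def merge_resolutions(loops: Iterable[Loop]) -> list[ConsensusLoop]:
    """Merge loop calls across resolutions, keeping the finest representative.

    Every 1 kb loop is retained; a 2 kb (then 4 kb) call is added only if
    no already-kept loop overlaps it at both anchors, otherwise it is
    recorded as provenance on the absorbing loop.
    """
    candidates = [
        ConsensusLoop(
            anchor1=lp.anchor1,
            anchor2=lp.anchor2,
            resolution=lp.resolution,
            timepoints=frozenset({lp.timepoint}),
            loop_ids=(lp.loop_id,) if lp.loop_id else (),
        )
        for lp in (canonicalize(l) for l in loops)
    ]
    return _greedy_merge(candidates)


def union_timepoints(
    consensus_sets: Iterable[Sequence[ConsensusLoop]],
) -> list[ConsensusLoop]:
    """Union per-timepoint consensus sets with both-anchor deduplication.

    The finest representative is kept and every loop carries the union of
    the timepoint flags supporting it. Commutative in input order.
    """
    flat: list[ConsensusLoop] = []
    for cset in consensus_sets:
        flat.extend(cset)
    return _greedy_merge(flat)


def build_consensus(
    loops: Iterable[Loop], order: str = "resolutions_first"
) -> list[ConsensusLoop]:
    """Full consensus: merge within stage across resolutions, then across
    stages (``resolutions_first``), or the reverse (``stages_first``)."""
    loops = [canonicalize(l) for l in loops]
    if order == "resolutions_first":
        per_tp = {tp: [l for l in loops if l.timepoint == tp] for tp in TIMEPOINTS}
        return union_timepoints(
            merge_resolutions(ls) for ls in per_tp.values() if ls
        )
    if order == "stages_first":
        per_res: dict[int, list[Loop]] = {}
        for l in loops:
            per_res.setdefault(l.resolution, []).append(l)
        merged_within_res = [
            _greedy_merge(
                [
                    ConsensusLoop(
                        l.anchor1,
                        l.anchor2,
                        l.resolution,
                        frozenset({l.timepoint}),
                        (l.loop_id,) if l.loop_id else (),
                    )
                    for l in ls
                ]
            )
            for ls in per_res.values()
        ]
        return union_timepoints(merged_within_res)
    raise ValueError(f"unknown merge order {order!r}")


def promoter_interacting_ocrs(
    loops: Sequence[ConsensusLoop],
    windows: Sequence[PromoterWindow],
    ocrs: Sequence[OCR],
    require_timepoint_support: bool = True,
) -> list[PromoterContact]:
    """Derive OCR <-> gene-promoter contacts from consensus loops.

    For every loop anchor overlapping a promoter window, each OCR
    overlapping the partner anchor yields one contact to that window's
    gene; loops with promoters at both ends emit contacts in both
    directions. Duplicate (ocr, gene) contacts are collapsed with merged
    provenance. A contact is classed ``promoter_proximal`` when the OCR
    itself overlaps a promoter window of the target gene, else ``distal``.

    With ``require_timepoint_support`` (default) the supported timepoints
    are the intersection of loop and OCR flags and contacts with no
    common stage are dropped.
    """
    window_ivs = [w.interval for w in windows]
    ocr_ivs = [o.interval for o in ocrs]
    windows_by_gene: dict[str, list[PromoterWindow]] = {}
    for w in windows:
        windows_by_gene.setdefault(w.gene_id, []).append(w)

    anchor_ivs: list[GenomicInterval] = []
    anchor_owner: list[tuple[int, int]] = []  # (loop index, side 0/1)
    for li, lp in enumerate(loops):
        anchor_ivs.append(lp.anchor1)
        anchor_owner.append((li, 0))
        anchor_ivs.append(lp.anchor2)
        anchor_owner.append((li, 1))

    win_hits: dict[int, list[int]] = {}
    for ai, wi in intersect(anchor_ivs, window_ivs):
        win_hits.setdefault(ai, []).append(wi)
    ocr_hits: dict[int, list[int]] = {}
    for ai, oi in intersect(anchor_ivs, ocr_ivs):
        ocr_hits.setdefault(ai, []).append(oi)

    merged: dict[tuple[str, str], dict] = {}
    for ai, (li, side) in enumerate(anchor_owner):
        if ai not in win_hits:
            continue
        partner = ai + 1 if side == 0 else ai - 1
        if partner not in ocr_hits:
            continue
        lp = loops[li]
        for wi in win_hits[ai]:
            window = windows[wi]
            for oi in ocr_hits[partner]:
                ocr = ocrs[oi]
                tps = (
                    lp.timepoints & ocr.timepoints
                    if require_timepoint_support
                    else lp.timepoints
                )
                if require_timepoint_support and not tps:
                    continue
                key = (ocr.peak_id, window.gene_id)
                entry = merged.setdefault(
                    key,
                    {"tss": window.tss, "timepoints": set(), "loop_ids": set()},
                )
                entry["tss"] = min(entry["tss"], window.tss)
                entry["timepoints"] |= tps
                entry["loop_ids"] |= set(lp.loop_ids)

    ocr_by_id = {o.peak_id: o for o in ocrs}
    contacts = []
    for (ocr_id, gene_id), entry in sorted(merged.items()):
        ocr = ocr_by_id[ocr_id]
        proximal = any(
            ocr.interval.overlaps(w.interval) for w in windows_by_gene[gene_id]
        )
        contacts.append(
            PromoterContact(
                ocr_id=ocr_id,
                gene_id=gene_id,
                tss=entry["tss"],
                timepoints=frozenset(entry["timepoints"]),
                loop_ids=tuple(sorted(entry["loop_ids"])),
                contact_class="promoter_proximal" if proximal else "distal",
            )
        )
    return contacts


# ---------------------------------------------------------------------------
# BEDPE I/O
# ---------------------------------------------------------------------------

_BEDPE_EXTRA = ["resolution", "timepoint", "qvalue"]


def read_loops_bedpe(
    path: str | Path, chr_prefix: bool | None = None, min_significance: float | None = None
) -> list[Loop]:
    """Read loops from BEDPE + (resolution, timepoint, qvalue) columns.

    Files are assumed pre-filtered for significance upstream; when
    ``min_significance`` is given, records with qvalue above it are
    dropped on read.
    """
    loops: list[Loop] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 13:
                raise ParseError(f"{path}:{lineno}: expected >= 13 BEDPE columns")
            try:
                a1 = GenomicInterval(normalize_chrom(f[0], chr_prefix), int(f[1]), int(f[2]))
                a2 = GenomicInterval(normalize_chrom(f[3], chr_prefix), int(f[4]), int(f[5]))
                loop = canonicalize(
                    Loop(
                        anchor1=a1,
                        anchor2=a2,
                        resolution=int(f[10]),
                        timepoint=f[11],
                        qvalue=float(f[12]),
                        loop_id=f[6],
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if min_significance is not None and loop.qvalue > min_significance:
                continue
            loops.append(loop)
    return loops


def write_loops_bedpe(loops: Iterable[Loop], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for lp in loops:
            a1, a2 = lp.anchor1, lp.anchor2
            fh.write(
                f"{a1.chrom}\t{a1.start}\t{a1.end}\t{a2.chrom}\t{a2.start}\t{a2.end}\t"
                f"{lp.loop_id}\t0\t.\t.\t{lp.resolution}\t{lp.timepoint}\t{lp.qvalue!r}\n"
            )


def write_contacts_tsv(contacts: Iterable[PromoterContact], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("ocr_id\tgene_id\ttss\ttimepoints\tloop_ids\tclass\n")
        for c in contacts:
            tps = ",".join(t for t in TIMEPOINTS if t in c.timepoints)
            fh.write(
                f"{c.ocr_id}\t{c.gene_id}\t{c.tss + 1}\t{tps}\t"
                f"{','.join(c.loop_ids)}\t{c.contact_class}\n"
            )


def read_contacts_tsv(path: str | Path) -> list[PromoterContact]:
    contacts = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            contacts.append(
                PromoterContact(
                    ocr_id=f[idx["ocr_id"]],
                    gene_id=f[idx["gene_id"]],
                    tss=int(f[idx["tss"]]) - 1,
                    timepoints=frozenset(
                        t for t in f[idx["timepoints"]].split(",") if t
                    ),
                    loop_ids=tuple(x for x in f[idx["loop_ids"]].split(",") if x),
                    contact_class=f[idx["class"]],
                )
            )
    return contacts
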