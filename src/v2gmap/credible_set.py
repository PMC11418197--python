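"""95% credible sets from GWAS summary statistics, constrained to open chromatin.

Per association signal, two-sided p-values are converted to standard-normal
deviates, then to approximate Bayes factors, then normalized to posterior
probabilities; variants are taken in descending posterior order until the
cumulative sum reaches the coverage target. The resulting credible set can
then be filtered to variants falling in accessible open-chromatin regions
(without renormalization: the accessible set is a filter of the 95% set).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genomic_core import OCR, SummaryStatRecord, point_interval

logger = logging.getLogger(__name__)

#: Floor applied to p-values before the quantile transform, for numeric
#: stability of genome-wide-significant hits.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class FineMapConfig:
    """Fine-mapping parameters.

    ``bf_mode='wakefield'`` uses the approximate Bayes factor
    ``sqrt(V/(V+W)) * exp(z^2 W / (2 (V+W)))`` with prior variance ``W``
    and trait variance ``V`` (used when standard errors are absent);
    ``bf_mode='z2'`` uses ``exp(z^2/2)``.
    """

    prior_variance: float = 0.04
    trait_variance: float = 1.0
    bf_mode: str = "wakefield"
    coverage: float = 0.95
    renormalize_after_filter: bool = False

    def __post_init__(self) -> None:
        if self.prior_variance <= 0 or self.trait_variance <= 0:
            raise ValueError("prior_variance and trait_variance must be > 0")
        if not (0 < self.coverage < 1):
            raise ValueError("coverage must be in (0, 1)")
        if self.bf_mode not in ("wakefield", "z2"):
            raise ValueError(f"unknown bf_mode {self.bf_mode!r}")


@dataclass(frozen=True)
class AssociationSignal:
    """All summary-statistic records of one sentinel signal."""

    sentinel_id: str
    trait: str
    records: tuple[SummaryStatRecord, ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"signal {self.sentinel_id}: no records")
        for r in self.records:
            if r.sentinel_id != self.sentinel_id or r.trait != self.trait:
                raise ValueError(
                    f"signal {self.sentinel_id}/{self.trait}: record "
                    f"{r.variant_id} belongs to {r.sentinel_id}/{r.trait}"
                )
        object.__setattr__(self, "records", tuple(self.records))


@dataclass(frozen=True)
class CredibleVariant:
    """One credible-set member with its fine-mapping quantities."""

    variant_id: str
    chrom: str
    pos: int
    p_value: float
    z: float
    bf: float
    pp: float


@dataclass(frozen=True)
class CredibleSet:
    sentinel_id: str
    trait: str
    coverage_target: float
    members: tuple[CredibleVariant, ...]
    cumulative_pp: float


def group_signals(records: Iterable[SummaryStatRecord]) -> list[AssociationSignal]:
    """Group summary-stat records into per-(sentinel, trait) signals."""
    by_key: dict[tuple[str, str], list[SummaryStatRecord]] = {}
    for r in records:
        by_key.setdefault((r.sentinel_id, r.trait), []).append(r)
    return [
        AssociationSignal(sid, trait, tuple(recs))
        for (sid, trait), recs in sorted(by_key.items())
    ]


def p_to_z(p: float) -> float:
    """Two-sided p-value to non-negative standard-normal deviate.

    ``z = Phi^-1(1 - p/2)``, monotone decreasing in p. p-values below
    1e-300 are floored before the transform.
    """
    if not (0 < p <= 1):
        raise ValueError(f"p-value must be in (0, 1], got {p}")
    return float(stats.norm.isf(max(p, P_FLOOR) / 2))


def variant_bf(z: float, config: FineMapConfig = FineMapConfig()) -> float:
    """Approximate Bayes factor in favor of association, increasing in z."""
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    return math.exp(log_variant_bf(z, config))


def log_variant_bf(z: float, config: FineMapConfig = FineMapConfig()) -> float:
    if config.bf_mode == "z2":
        return z * z / 2.0
    v, w = config.trait_variance, config.prior_variance
    return 0.5 * math.log(v / (v + w)) + z * z * w / (2.0 * (v + w))


def posterior_probabilities(
    signal: AssociationSignal, config: FineMapConfig = FineMapConfig()
) -> np.ndarray:
    """Per-variant posterior probabilities, normalized to sum to 1.

    Computed in log space (softmax over log Bayes factors), so ties in
    p-value give exactly equal posteriors and extreme signals stay finite.
    """
    z = np.array([p_to_z(r.p_value) for r in signal.records])
    if config.bf_mode == "z2":
        log_bf = z * z / 2.0
    else:
        v, w = config.trait_variance, config.prior_variance
        log_bf = 0.5 * np.log(v / (v + w)) + z * z * w / (2.0 * (v + w))
    log_bf -= log_bf.max()
    bf = np.exp(log_bf)
    total = bf.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError(f"signal {signal.sentinel_id}: degenerate Bayes factors")
    return bf / total


def build_credible_set(
    signal: AssociationSignal, config: FineMapConfig = FineMapConfig()
) -> CredibleSet:
    """Minimal descending-posterior prefix with cumulative pp >= coverage.

    Ordering ties are broken by ascending p-value, then position, then
    variant id, so the set is deterministic.
    """
    pp = posterior_probabilities(signal, config)
    order = sorted(
        range(len(signal.records)),
        key=lambda i: (
            -pp[i],
            signal.records[i].p_value,
            signal.records[i].pos,
            signal.records[i].variant_id,
        ),
    )
    members: list[CredibleVariant] = []
    cum = 0.0
    for i in order:
        r = signal.records[i]
        members.append(
            CredibleVariant(
                variant_id=r.variant_id,
                chrom=r.chrom,
                pos=r.pos,
                p_value=r.p_value,
                z=p_to_z(r.p_value),
                bf=variant_bf(p_to_z(r.p_value), config),
                pp=float(pp[i]),
            )
        )
        cum += pp[i]
        if cum >= config.coverage - 1e-12:
            break
    return CredibleSet(
        sentinel_id=signal.sentinel_id,
        trait=signal.trait,
        coverage_target=config.coverage,
        members=tuple(members),
        cumulative_pp=float(cum),
    )


def constrain_to_ocr(
    cs: CredibleSet,
    ocrs: Sequence[OCR],
    timepoints: set[str] | None = None,
    renormalize: bool = False,
) -> tuple[CredibleSet, dict]:
    """Filter a credible set to variants inside accessible OCRs.

    A member is kept when its 1-bp interval overlaps at least one OCR
    accessible at any of the requested ``timepoints`` (all timepoints when
    ``None``). Posterior probabilities are retained as-is unless
    ``renormalize`` is set. Returns the filtered set and a size report.
    """
    eligible = [
        o
        for o in ocrs
        if timepoints is None or (o.timepoints & timepoints)
    ]
    kept = []
    for m in cs.members:
        iv = point_interval(m.chrom, m.pos)
        if any(o.interval.overlaps(iv) for o in eligible):
            kept.append(m)
    if not kept:
        logger.warning(
            "credible set %s/%s: no member in accessible open chromatin",
            cs.sentinel_id,
            cs.trait,
        )
    if renormalize and kept:
        total = sum(m.pp for m in kept)
        kept = [replace(m, pp=m.pp / total) for m in kept]
    filtered = CredibleSet(
        sentinel_id=cs.sentinel_id,
        trait=cs.trait,
        coverage_target=cs.coverage_target,
        members=tuple(kept),
        cumulative_pp=float(sum(m.pp for m in kept)),
    )
    report = {
        "sentinel_id": cs.sentinel_id,
        "trait": cs.trait,
        "n_before": len(cs.members),
        "n_after": len(kept),
    }
    return filtered, report


def constrain_many(
    credible_sets: Iterable[CredibleSet],
    ocrs: Sequence[OCR],
    timepoints: set[str] | None = None,
) -> tuple[list[CredibleSet], dict]:
    """Constrain several credible sets; report per-sentinel sizes and means."""
    filtered, reports = [], []
    for cs in credible_sets:
        f, rep = constrain_to_ocr(cs, ocrs, timepoints)
        filtered.append(f)
        reports.append(rep)
    summary = {
        "per_sentinel": reports,
        "mean_before": float(np.mean([r["n_before"] for r in reports])) if reports else 0.0,
        "mean_after": float(np.mean([r["n_after"] for r in reports])) if reports else 0.0,
    }
    return filtered, summary
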