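"""Truth-set benchmarking and enrichment testing for gene predictions.

Provides precision/recall against curated truth sets, pairwise set
concordance, a permutation null for sentinel-gene pair overlap (random
genes within a window of each sentinel), a one-sided two-proportion test
with continuity correction, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .genomic_core import GeneModel, _open_text

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TruthSet:
    """A named set of gold-standard gene identifiers."""

    name: str
    gene_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", frozenset(self.gene_ids))
        if not self.gene_ids:
            raise ValueError(f"truth set {self.name!r} is empty")


@dataclass(frozen=True)
class PRResult:
    overlap: int
    precision: float
    recall: float


@dataclass(frozen=True)
class PermutationConfig:
    """Permutation-null parameters: gene universe within ``window`` bp of
    each sentinel, ``iterations`` null draws (paper-scale default 10,000)."""

    window: int = 1_000_000
    iterations: int = 10_000
    seed: int = 0
    sample_without_replacement: bool = False

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class PermutationResult:
    observed: int
    null_draws: np.ndarray
    empirical_p: float
    fold: float

    @property
    def null_mean(self) -> float:
        return float(self.null_draws.mean())


def read_truth_set(path: str | Path, name: str | None = None) -> TruthSet:
    """Read a truth set: one gene symbol per line, optional ``#`` header."""
    genes = set()
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(harmonize_symbol(line))
    return TruthSet(name or Path(path).stem, frozenset(genes))


def harmonize_symbol(symbol: str) -> str:
    """Upper-case symbol harmonization for cross-study comparisons."""
    return symbol.strip().upper()


def harmonize_set(genes: Iterable[str], mapping: Mapping[str, str] | None = None) -> set[str]:
    """Upper-case (and optionally id-map) a gene set; unmapped kept as-is."""
    out = set()
    for g in genes:
        g = harmonize_symbol(g)
        if mapping is not None:
            g = harmonize_symbol(mapping.get(g, g))
        out.add(g)
    return out


def precision_recall(predicted: Iterable[str], truth: TruthSet) -> PRResult:
    """Precision = |P∩T| / |P|, recall = |P∩T| / |T|.

    Raises on an empty predicted set (precision undefined) and on an
    empty truth set.
    """
    pred = set(predicted)
    if not pred:
        raise ValueError("empty predicted set: precision undefined")
    overlap = len(pred & truth.gene_ids)
    return PRResult(
        overlap=overlap,
        precision=overlap / len(pred),
        recall=overlap / len(truth.gene_ids),
    )


def concordance(set_a: Iterable[str], set_b: Iterable[str]) -> dict:
    """Overlap with all three normalizations (of A, of B, Jaccard)."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("concordance requires two non-empty sets")
    overlap = len(a & b)
    return {
        "overlap": overlap,
        "frac_of_a": overlap / len(a),
        "frac_of_b": overlap / len(b),
        "jaccard": overlap / len(a | b),
    }


def gene_universe_by_sentinel(
    sentinel_pos: Mapping[str, tuple[str, int]],
    genes: Sequence[GeneModel],
    window: int,
) -> dict[str, list[str]]:
    """Genes with >= 1 TSS within ``window`` bp of each sentinel position."""
    universe: dict[str, list[str]] = {}
    for sid, (chrom, pos) in sentinel_pos.items():
        hits = sorted(
            g.gene_id
            for g in genes
            if g.chrom == chrom and any(abs(t - pos) <= window for t in g.tss_list)
        )
        universe[sid] = hits
    return universe


def permutation_enrichment(
    comparison_pairs: Sequence[tuple[str, str]],
    v2g_pairs: Iterable[tuple[str, str]],
    genes: Sequence[GeneModel],
    sentinel_pos: Mapping[str, tuple[str, int]],
    config: PermutationConfig = PermutationConfig(),
    rng: np.random.Generator | None = None,
) -> PermutationResult:
    """Permutation test for sentinel-gene pair overlap.

    ``observed`` counts comparison pairs also present in the V2G pair
    set. Each null iteration replaces every comparison pair's gene with
    one drawn uniformly from the genes within ``window`` of that pair's
    sentinel and recounts. ``empirical_p = (1 + #{null >= observed}) /
    (1 + iterations)``; ``fold = observed / mean(null)``.

    Sentinels with an empty window universe are excluded with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    v2g = set(v2g_pairs)
    universe = gene_universe_by_sentinel(sentinel_pos, genes, config.window)

    usable: list[tuple[str, str]] = []
    for sid, gene in comparison_pairs:
        if sid not in sentinel_pos:
            logger.warning("sentinel %s has no position; pair excluded", sid)
            continue
        if not universe.get(sid):
            logger.warning("sentinel %s: empty %d bp gene universe; pair excluded",
                           sid, config.window)
            continue
        usable.append((sid, gene))
    if not usable:
        raise ValueError("no usable comparison pairs")

    observed = sum((sid, gene) in v2g for sid, gene in usable)

    iters = config.iterations
    null = np.zeros(iters, dtype=np.int64)
    if config.sample_without_replacement:
        by_sentinel: dict[str, int] = {}
        for sid, _ in usable:
            by_sentinel[sid] = by_sentinel.get(sid, 0) + 1
        for sid, k in by_sentinel.items():
            genes_here = universe[sid]
            hits = np.array([(sid, g) in v2g for g in genes_here])
            k = min(k, len(genes_here))
            for it in range(iters):
                draw = rng.choice(len(genes_here), size=k, replace=False)
                null[it] += int(hits[draw].sum())
    else:
        # With-replacement per-pair uniform draws, vectorized per pair.
        for sid, _ in usable:
            genes_here = universe[sid]
            hits = np.array([(sid, g) in v2g for g in genes_here])
            draws = rng.integers(0, len(genes_here), size=iters)
            null += hits[draws]

    empirical_p = (1 + int((null >= observed).sum())) / (1 + iters)
    null_mean = null.mean()
    fold = float(observed / null_mean) if null_mean > 0 else math.inf
    return PermutationResult(
        observed=observed,
        null_draws=null,
        empirical_p=float(empirical_p),
        fold=fold,
    )


def proportion_enrichment(
    hits_in_set: int,
    set_size: int,
    hits_in_background: int,
    background_size: int,
    alternative: str = "greater",
    correction: bool = True,
) -> dict:
    """One-sided two-sample proportion test with continuity correction.

    Mirrors the classical chi-squared test of equal proportions with
    Yates correction (the default of the usual statistical software):
    the signed square root of the corrected chi-squared statistic is
    compared to the standard normal. ``ratio`` is the relative proportion
    (set over background); it is ``nan`` when the background proportion
    is zero, but the p-value is still computed.
    """
    if min(hits_in_set, hits_in_background) < 0 or set_size <= 0 or background_size <= 0:
        raise ValueError("counts must be non-negative with positive sizes")
    if hits_in_set > set_size or hits_in_background > background_size:
        raise ValueError("hits cannot exceed group size")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    x = np.array(
        [
            [hits_in_set, set_size - hits_in_set],
            [hits_in_background, background_size - hits_in_background],
        ],
        dtype=float,
    )
    n = x.sum()
    expected = np.outer(x.sum(axis=1), x.sum(axis=0)) / n
    yates = min(0.5, abs(x[0, 0] - expected[0, 0])) if correction else 0.0
    with np.errstate(invalid="ignore"):
        chi2 = float((((np.abs(x - expected) - yates) ** 2) / expected).sum())

    p1 = hits_in_set / set_size
    p2 = hits_in_background / background_size
    z = math.copysign(math.sqrt(chi2), p1 - p2)
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    else:
        p = float(stats.chi2.sf(chi2, df=1))
    ratio = p1 / p2 if p2 > 0 else float("nan")
    return {"ratio": ratio, "p": p, "statistic": chi2, "z": z}


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank downwards
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted
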