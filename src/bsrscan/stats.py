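"""Statistical kernel of the bulked-segregant association scan.

All functions here are pure.  The scan statistic is the Euclidean distance
(ED) between the two bulks' four-base frequency vectors at a SNP,

    ED = sqrt( (A1-A2)^2 + (C1-C2)^2 + (G1-G2)^2 + (T1-T2)^2 ),

computed on base *frequencies* rather than raw depths so that the two pools'
sequencing depths do not distort the comparison; ED is then raised to a power
k (default 5) to suppress background noise relative to true signal.  Loci
whose statistic reaches a fixed threshold (default 0.74 on raw ED) are
candidate association loci.  Per-unigene clustering of candidates is scored
with an upper-tail hypergeometric probability — the chance of drawing at
least y candidates among a unigene's N loci when K of the M genome-wide loci
are candidates — followed by Benjamini–Hochberg FDR adjustment across
unigenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom as _scipy_hypergeom

from .containers import BaseDepths, BsrScanError

__all__ = [
    "BaseFrequencies",
    "EdRecord",
    "EnrichmentParams",
    "UnigeneEnrichment",
    "base_frequencies",
    "euclidean_distance",
    "ed_power",
    "classify_candidate",
    "hypergeom_tail",
    "hypergeom_tail_many",
    "bh_fdr",
    "screen_significant",
]

ED_MAX = math.sqrt(2.0)

#: Above this population size the hypergeometric tail switches from exact
#: rational arithmetic to scipy's log-space survival function.
EXACT_HYPERGEOM_MAX_M = 1000

#: Smallest positive double; stands in for p-values that underflow to zero.
TINY_P = math.nextafter(0.0, 1.0)


class ZeroDepthError(BsrScanError):
    """Base frequencies are undefined at a locus/pool with zero total depth."""


@dataclass(frozen=True, slots=True)
class BaseFrequencies:
    """Fractions of A/C/G/T reads at one locus in one pool; sums to 1."""

    fa: float
    fc: float
    fg: float
    ft: float

    def as_array(self) -> np.ndarray:
        return np.array([self.fa, self.fc, self.fg, self.ft], dtype=float)


@dataclass(frozen=True, slots=True)
class EdRecord:
    """Per-locus scan statistic: ED, its k-th power, and the candidate flag."""

    unigene_id: str
    position: int
    ed: float
    ed_powered: float
    is_candidate: bool


@dataclass(frozen=True, slots=True)
class EnrichmentParams:
    """Genome-wide totals entering the hypergeometric test.

    ``m_total`` (M): loci surviving all filters, i.e. bulk-discrepant SNPs.
    ``k_assoc`` (K): of those, the candidate association loci.
    """

    m_total: int
    k_assoc: int

    def __post_init__(self) -> None:
        if not 0 <= self.k_assoc <= self.m_total:
            raise BsrScanError(
                f"require 0 <= K <= M, got K={self.k_assoc}, M={self.m_total}"
            )


@dataclass(frozen=True, slots=True)
class UnigeneEnrichment:
    """Per-unigene candidate enrichment: counts, tail P, FDR, call.

    ``p_underflow`` marks rows whose exact tail probability is below the
    smallest positive double and was clamped to it (never reported as 0).
    """

    unigene_id: str
    n_all: int
    y_assoc: int
    p_value: float
    fdr: float
    significant: bool
    p_underflow: bool = False


def base_frequencies(depths: BaseDepths) -> BaseFrequencies:
    """Convert base depths to base frequencies; errors on zero total depth."""
    total = depths.total()
    if total <= 0:
        raise ZeroDepthError("base frequencies undefined at zero total depth")
    return BaseFrequencies(
        depths.a / total, depths.c / total, depths.g / total, depths.t / total
    )


def _freq_array(f) -> np.ndarray:
    if isinstance(f, BaseFrequencies):
        return f.as_array()
    arr = np.asarray(f, dtype=float)
    if arr.shape != (4,):
        raise BsrScanError(f"frequency vector must have 4 entries, got {arr.shape}")
    return arr


def euclidean_distance(f_bulk1, f_bulk2) -> float:
    """ED between two four-base frequency vectors; symmetric, in [0, sqrt(2)]."""
    d = _freq_array(f_bulk1) - _freq_array(f_bulk2)
    return float(np.sqrt(np.dot(d, d)))


def ed_profile(freq_bulk1: np.ndarray, freq_bulk2: np.ndarray) -> np.ndarray:
    """Vectorized ED over (n, 4) frequency matrices for the two bulks."""
    d = np.asarray(freq_bulk1, float) - np.asarray(freq_bulk2, float)
    return np.sqrt((d * d).sum(axis=-1))


def ed_power(ed, k: int = 5):
    """Raise ED to the k-th power (default 5); monotone, so rankings hold."""
    if k < 1:
        raise BsrScanError(f"power k must be >= 1, got {k}")
    return np.power(ed, k) if isinstance(ed, np.ndarray) else float(ed) ** k


def classify_candidate(ed: float, threshold: float = 0.74) -> bool:
    """True iff the scan statistic reaches the association threshold (>=)."""
    if threshold <= 0:
        raise BsrScanError(f"threshold must be positive, got {threshold}")
    return bool(ed >= threshold)


def _hypergeom_sf(m_total: int, k_assoc: int, n_all: int, y_assoc: int) -> tuple[float, bool]:
    """P(X >= y) for X ~ Hypergeom(M, K, N); returns (p, underflowed).

    Exact rational arithmetic for M <= EXACT_HYPERGEOM_MAX_M (upper tail
    summed directly, avoiding 1 - (1 - tiny) cancellation); scipy's log-space
    survival function above.  Clamped to [TINY_P, 1].
    """
    if not (0 <= y_assoc <= n_all <= m_total and 0 <= k_assoc <= m_total):
        raise BsrScanError(
            "require 0 <= y <= N <= M and 0 <= K <= M, got "
            f"M={m_total}, K={k_assoc}, N={n_all}, y={y_assoc}"
        )
    if y_assoc == 0:
        return 1.0, False
    hi = min(k_assoc, n_all)
    if y_assoc > hi:
        # impossible to draw that many candidates: true tail mass is zero,
        # reported as the smallest positive double by policy
        return TINY_P, True
    if m_total <= EXACT_HYPERGEOM_MAX_M:
        numer = sum(
            math.comb(k_assoc, x) * math.comb(m_total - k_assoc, n_all - x)
            for x in range(y_assoc, hi + 1)
        )
        p = float(Fraction(numer, math.comb(m_total, n_all)))
    else:
        p = float(_scipy_hypergeom.sf(y_assoc - 1, m_total, k_assoc, n_all))
    underflow = p <= 0.0
    return min(max(p, TINY_P), 1.0), underflow


def hypergeom_tail(params: EnrichmentParams, n_all: int, y_assoc: int) -> float:
    """Upper-tail enrichment probability for one unigene.

    Probability of observing at least ``y_assoc`` candidate loci among the
    unigene's ``n_all`` loci when ``params.k_assoc`` of ``params.m_total``
    genome-wide loci are candidates.
    """
    p, _ = _hypergeom_sf(params.m_total, params.k_assoc, n_all, y_assoc)
    return p


def hypergeom_tail_many(
    params: EnrichmentParams, n_all: np.ndarray, y_assoc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`hypergeom_tail`; returns (p, underflow) arrays."""
    n_all = np.asarray(n_all, dtype=np.int64)
    y_assoc = np.asarray(y_assoc, dtype=np.int64)
    if params.m_total <= EXACT_HYPERGEOM_MAX_M:
        out = [
            _hypergeom_sf(params.m_total, params.k_assoc, int(n), int(y))
            for n, y in zip(n_all, y_assoc)
        ]
        p = np.array([x[0] for x in out])
        under = np.array([x[1] for x in out])
        return p, under
    if ((y_assoc < 0) | (y_assoc > n_all) | (n_all > params.m_total)).any():
        raise BsrScanError("require 0 <= y <= N <= M for every unigene")
    p = _scipy_hypergeom.sf(y_assoc - 1, params.m_total, params.k_assoc, n_all)
    under = p <= 0.0
    return np.clip(p, TINY_P, 1.0), under


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1; tied p-values
    share the adjusted value of their block.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise BsrScanError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise BsrScanError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def screen_significant(
    enrichments: Sequence[UnigeneEnrichment], fdr_cutoff: float = 0.01
) -> list[UnigeneEnrichment]:
    """Records with FDR strictly below the cutoff, sorted by (fdr, unigene)."""
    hits = [replace(e, significant=True) for e in enrichments if e.fdr < fdr_cutoff]
    return sorted(hits, key=lambda e: (e.fdr, e.unigene_id))
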