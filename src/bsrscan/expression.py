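"""Small expression-quantification helpers used around the scan.

FPKM normalization of fragment counts, the differential-expression threshold
screen (FDR < 0.01 and fold change >= 2 in either direction), and 2^-ddCt
relative expression for qRT-PCR validation against a single reference gene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from .containers import BsrScanError

CT_PLAUSIBLE_RANGE = (0.0, 45.0)


@dataclass(frozen=True, slots=True)
class ExpressionRecord:
    """Inputs of the FPKM formula for one gene in one library."""

    gene_id: str
    fragment_count: int
    effective_length_bp: int
    library_fragments: int


@dataclass(frozen=True, slots=True)
class DegRecord:
    """One gene's differential-expression summary between two groups."""

    gene_id: str
    fold_change: float  # expression ratio group1 / group2
    fdr: float

    @property
    def direction(self) -> str:
        return "up" if self.fold_change >= 1.0 else "down"


@dataclass(frozen=True, slots=True)
class CtQuadruple:
    """Averaged Ct values for the 2^-ddCt calculation.

    Target and reference gene Ct in the sample of interest and in the
    calibrator sample; technical replicates are averaged upstream.
    """

    ct_target_sample: float
    ct_ref_sample: float
    ct_target_calibrator: float
    ct_ref_calibrator: float

    def values(self) -> tuple[float, float, float, float]:
        return (
            self.ct_target_sample,
            self.ct_ref_sample,
            self.ct_target_calibrator,
            self.ct_ref_calibrator,
        )


def fpkm(record: ExpressionRecord) -> float:
    """Fragments per kilobase of transcript per million mapped fragments.

    fragment_count * 1e9 / (effective_length_bp * library_fragments).
    """
    if record.effective_length_bp <= 0:
        raise BsrScanError(f"{record.gene_id}: effective length must be > 0")
    if record.library_fragments <= 0:
        raise BsrScanError(f"{record.gene_id}: library size must be > 0")
    if record.fragment_count < 0:
        raise BsrScanError(f"{record.gene_id}: negative fragment count")
    if record.fragment_count == 0:
        return 0.0
    return record.fragment_count * 1e9 / (record.effective_length_bp * record.library_fragments)


def deg_screen(
    records: Sequence[DegRecord],
    fdr_cutoff: float = 0.01,
    fc_cutoff: float = 2.0,
) -> tuple[list[DegRecord], list[DegRecord]]:
    """Partition genes passing FDR < cutoff and |fold change| >= cutoff.

    A gene passes when its fold change in either direction reaches
    ``fc_cutoff``; returns (up-regulated, down-regulated) lists.
    """
    if fdr_cutoff <= 0 or fc_cutoff <= 0:
        raise BsrScanError("cutoffs must be positive")
    up, down = [], []
    for r in records:
        if r.fold_change <= 0:
            raise BsrScanError(f"{r.gene_id}: fold change must be positive")
        if not 0.0 <= r.fdr <= 1.0:
            raise BsrScanError(f"{r.gene_id}: FDR must be in [0, 1]")
        if r.fdr >= fdr_cutoff:
            continue
        if r.fold_change >= fc_cutoff:
            up.append(r)
        elif 1.0 / r.fold_change >= fc_cutoff:
            down.append(r)
    return up, down


def ddct_relative_expression(q: CtQuadruple) -> float:
    """Relative expression 2^-ddCt of a target gene.

    ddCt = (Ct_target - Ct_ref) in the sample minus the same difference in
    the calibrator; all four Ct values must be finite.
    """
    vals = q.values()
    if not all(math.isfinite(v) for v in vals):
        raise BsrScanError(f"non-finite Ct values: {vals}")
    lo, hi = CT_PLAUSIBLE_RANGE
    if any(not lo < v < hi for v in vals):
        warnings.warn(
            f"Ct values {vals} outside the plausible ({lo}, {hi}) cycle range",
            stacklevel=2,
        )
    d_sample = q.ct_target_sample - q.ct_ref_sample
    d_cal = q.ct_target_calibrator - q.ct_ref_calibrator
    return 2.0 ** -(d_sample - d_cal)
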