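"""The three-stage SNP filter preceding the ED scan.

Order matters and mirrors the analysis protocol:

1. read-support filter — drop loci where any pool has < ``min_support``
   reads, so frequencies are defined everywhere downstream;
2. parent-discrepant filter — drop loci where a bulk shows an allele that
   cannot be drawn from the parents of the cross (Mendelian impossibility);
3. bulk-consistent filter — drop loci where the two bulks are identical
   (same observed allele set and ED below epsilon): such loci carry no
   mapping information.  Survivors of all three stages define M, the
   genome-wide locus total of the enrichment test.

An allele is "observed" in a pool when its frequency reaches the
minor-allele floor (default 0.1), which absorbs sequencing error without
modelling base quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import POOL_INDEX, BsrScanError, LocusTable
from .stats import ed_profile

PAIRINGS = ("both_parents", "as_printed", "phenotype_matched")
SUPPORT_SCOPES = ("all_pools", "bulks_only")

_T01, _T02, _T03, _T04 = (POOL_INDEX[p] for p in ("T01", "T02", "T03", "T04"))


@dataclass
class FilterReport:
    """Per-stage locus counts and removed-locus logs of one scan."""

    n_input: int = 0
    n_after_support: int = 0
    n_after_discrepant: int = 0
    n_after_consistent: int = 0
    removed_support: list[tuple[str, int]] = field(default_factory=list)
    removed_discrepant: list[tuple[str, int]] = field(default_factory=list)
    removed_consistent: list[tuple[str, int]] = field(default_factory=list)

    def validate_monotone(self) -> None:
        counts = (
            self.n_input,
            self.n_after_support,
            self.n_after_discrepant,
            self.n_after_consistent,
        )
        if any(a < b for a, b in zip(counts, counts[1:])) or counts[-1] < 0:
            raise BsrScanError(f"filter counts not monotone: {counts}")


def _split(table: LocusTable, keep: np.ndarray) -> tuple[LocusTable, LocusTable]:
    keep = np.asarray(keep, dtype=bool)
    return table.subset(keep), table.subset(~keep)


def filter_read_support(
    table: LocusTable, min_support: int = 3, scope: str = "all_pools"
) -> tuple[LocusTable, LocusTable]:
    """Keep loci whose pools each have total depth >= ``min_support``.

    ``scope='bulks_only'`` applies the requirement to T03/T04 only.
    """
    if min_support < 1:
        raise BsrScanError(f"min_support must be >= 1, got {min_support}")
    if scope not in SUPPORT_SCOPES:
        raise BsrScanError(f"scope must be one of {SUPPORT_SCOPES}, got {scope!r}")
    totals = table.totals()
    if scope == "bulks_only":
        totals = totals[:, [_T03, _T04]]
    return _split(table, (totals >= min_support).all(axis=1))


def observed_alleles(table: LocusTable, minor_allele_floor: float = 0.1) -> np.ndarray:
    """(n, 4 pools, 4 bases) boolean: base frequency >= floor in that pool.

    A zero-depth pool observes no alleles.
    """
    freq = table.frequencies()
    obs = freq >= minor_allele_floor
    obs &= table.totals()[:, :, None] > 0
    return obs


def filter_parent_discrepant(
    table: LocusTable,
    pairing: str = "both_parents",
    minor_allele_floor: float = 0.1,
) -> tuple[LocusTable, LocusTable]:
    """Remove loci where a bulk shows an allele the parents cannot supply.

    ``pairing`` selects which parental allele set each bulk is checked
    against: ``both_parents`` (union of T01 and T02 — the weakest assumption,
    always valid for an F1), ``as_printed`` (T03 vs T01, T04 vs T02), or
    ``phenotype_matched`` (T03 vs T02, T04 vs T01).
    """
    if pairing not in PAIRINGS:
        raise BsrScanError(f"pairing must be one of {PAIRINGS}, got {pairing!r}")
    obs = observed_alleles(table, minor_allele_floor)
    if pairing == "both_parents":
        allowed_t03 = allowed_t04 = obs[:, _T01] | obs[:, _T02]
    elif pairing == "as_printed":
        allowed_t03, allowed_t04 = obs[:, _T01], obs[:, _T02]
    else:  # phenotype_matched
        allowed_t03, allowed_t04 = obs[:, _T02], obs[:, _T01]
    impossible = (obs[:, _T03] & ~allowed_t03).any(axis=1) | (
        obs[:, _T04] & ~allowed_t04
    ).any(axis=1)
    return _split(table, ~impossible)


def filter_bulk_consistent(
    table: LocusTable,
    consistency_eps: float = 1e-6,
    minor_allele_floor: float = 0.1,
) -> tuple[LocusTable, LocusTable]:
    """Remove loci where T03 and T04 are consistent (uninformative).

    Consistent means: identical observed allele sets AND ED below
    ``consistency_eps``.
    """
    obs = observed_alleles(table, minor_allele_floor)
    same_alleles = (obs[:, _T03] == obs[:, _T04]).all(axis=1)
    freq = table.frequencies()
    ed = ed_profile(freq[:, _T03], freq[:, _T04])
    return _split(table, ~(same_alleles & (ed < consistency_eps)))


def apply_filters(
    table: LocusTable,
    *,
    min_support: int = 3,
    support_scope: str = "all_pools",
    pairing: str = "both_parents",
    minor_allele_floor: float = 0.1,
    consistency_eps: float = 1e-6,
) -> tuple[LocusTable, FilterReport]:
    """Run the three stages in order and collect a :class:`FilterReport`."""
    report = FilterReport(n_input=len(table))
    kept, removed = filter_read_support(table, min_support, support_scope)
    report.n_after_support = len(kept)
    report.removed_support = removed.keys()
    kept, removed = filter_parent_discrepant(kept, pairing, minor_allele_floor)
    report.n_after_discrepant = len(kept)
    report.removed_discrepant = removed.keys()
    kept, removed = filter_bulk_consistent(kept, consistency_eps, minor_allele_floor)
    report.n_after_consistent = len(kept)
    report.removed_consistent = removed.keys()
    report.validate_monotone()
    return kept, report
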