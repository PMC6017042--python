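"""Model/results interface for the bulked-segregant association scan.

:class:`EdAssociationScan` holds the locus table and the scan configuration;
``fit()`` runs the full procedure — three-stage filtering, per-locus ED and
ED^k, candidate classification, per-unigene aggregation, hypergeometric
enrichment and BH-FDR — and returns a :class:`BsrScanResults` carrying the
per-locus and per-unigene tables, the genome-wide totals (M, K), the filter
report and a configuration snapshot.

Example
-------
>>> from bsrscan import EdAssociationScan
>>> model = EdAssociationScan.from_tsv("depths.tsv")   # doctest: +SKIP
>>> res = model.fit()                                   # doctest: +SKIP
>>> print(res.summary())                                # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import POOL_INDEX, BsrScanError, LocusTable, SnpLocus
from .filters import PAIRINGS, SUPPORT_SCOPES, FilterReport, apply_filters
from .io import write_results
from .stats import (
    EdRecord,
    EnrichmentParams,
    UnigeneEnrichment,
    bh_fdr,
    ed_power,
    ed_profile,
    hypergeom_tail_many,
    screen_significant,
)

THRESHOLD_DOMAINS = ("ed", "ed_powered")


class EmptyScanError(BsrScanError):
    """No loci survived filtering; the scan is undefined."""


@dataclass(frozen=True, slots=True)
class ScanConfig:
    """Tunable parameters of the association scan.

    min_support : minimum per-pool read depth for a locus to enter the scan.
    support_scope : 'all_pools' (every pool) or 'bulks_only' (T03/T04 only).
    threshold : association threshold (default 0.74).
    threshold_on : whether the threshold applies to raw 'ed' (default) or to
        'ed_powered'; 0.74 lies inside the raw-ED range [0, sqrt(2)].
    power : exponent k of the noise-suppressing ED^k transform (default 5).
    fdr_cutoff : per-unigene enrichment significance cutoff (strict <).
    pairing : parental allele-set check used by the discrepant filter.
    minor_allele_floor : frequency below which an allele is not "observed".
    consistency_eps : ED below which equal-allele-set bulks count as
        consistent.
    """

    min_support: int = 3
    support_scope: str = "all_pools"
    threshold: float = 0.74
    threshold_on: str = "ed"
    power: int = 5
    fdr_cutoff: float = 0.01
    pairing: str = "both_parents"
    minor_allele_floor: float = 0.1
    consistency_eps: float = 1e-6

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise BsrScanError("min_support must be >= 1")
        if self.support_scope not in SUPPORT_SCOPES:
            raise BsrScanError(f"support_scope must be one of {SUPPORT_SCOPES}")
        if self.threshold <= 0:
            raise BsrScanError("threshold must be positive")
        if self.threshold_on not in THRESHOLD_DOMAINS:
            raise BsrScanError(f"threshold_on must be one of {THRESHOLD_DOMAINS}")
        if self.power < 1:
            raise BsrScanError("power must be >= 1")
        if not 0 < self.fdr_cutoff <= 1:
            raise BsrScanError("fdr_cutoff must be in (0, 1]")
        if self.pairing not in PAIRINGS:
            raise BsrScanError(f"pairing must be one of {PAIRINGS}")
        if not 0 <= self.minor_allele_floor < 0.5:
            raise BsrScanError("minor_allele_floor must be in [0, 0.5)")
        if self.consistency_eps < 0:
            raise BsrScanError("consistency_eps must be >= 0")


class EdAssociationScan:
    """Bulked-segregant ED association scan over a table of SNP loci."""

    def __init__(self, loci, config: ScanConfig | None = None, **config_kwargs):
        if config is not None and config_kwargs:
            raise BsrScanError("pass either a ScanConfig or keyword overrides, not both")
        self.config = config or ScanConfig(**config_kwargs)
        if isinstance(loci, LocusTable):
            self.loci = loci
        else:
            self.loci = LocusTable.from_loci(loci)

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_tsv(cls, path, **config_kwargs) -> "EdAssociationScan":
        from .io import read_depth_tsv

        return cls(read_depth_tsv(path), **config_kwargs)

    @classmethod
    def from_vcf(cls, path, sample_map: Mapping[str, str], **config_kwargs):
        from .io import read_depth_vcf

        return cls(read_depth_vcf(path, sample_map), **config_kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **config_kwargs) -> "EdAssociationScan":
        return cls(LocusTable.from_dataframe(df), **config_kwargs)

    # -- fitting -----------------------------------------------------------
    def fit(self) -> "BsrScanResults":
        cfg = self.config
        kept, report = apply_filters(
            self.loci,
            min_support=cfg.min_support,
            support_scope=cfg.support_scope,
            pairing=cfg.pairing,
            minor_allele_floor=cfg.minor_allele_floor,
            consistency_eps=cfg.consistency_eps,
        )
        if len(kept) == 0:
            raise EmptyScanError("no loci survived filtering; nothing to scan")
        kept = kept.canonical_order()

        freq = kept.frequencies()
        ed = ed_profile(freq[:, POOL_INDEX["T03"]], freq[:, POOL_INDEX["T04"]])
        edk = ed_power(ed, cfg.power)
        stat = ed if cfg.threshold_on == "ed" else edk
        candidate = stat >= cfg.threshold

        params = EnrichmentParams(m_total=len(kept), k_assoc=int(candidate.sum()))

        locus_frame = kept.to_dataframe()
        locus_frame["ed"] = ed
        locus_frame["ed_powered"] = edk
        locus_frame["is_candidate"] = candidate

        agg = (
            locus_frame.groupby("unigene", sort=True)
            .agg(n_all=("ed", "size"), y_assoc=("is_candidate", "sum"))
            .reset_index()
        )
        p, underflow = hypergeom_tail_many(
            params, agg["n_all"].to_numpy(), agg["y_assoc"].to_numpy()
        )
        fdr = bh_fdr(p)
        unigene_frame = agg.assign(
            p_value=p,
            fdr=fdr,
            significant=fdr < cfg.fdr_cutoff,
            p_underflow=underflow,
        )
        return BsrScanResults(
            model=self,
            locus_frame=locus_frame,
            unigene_frame=unigene_frame,
            enrichment_params=params,
            filter_report=report,
        )


class BsrScanResults:
    """Fitted scan: per-locus and per-unigene tables plus run metadata."""

    def __init__(self, model, locus_frame, unigene_frame, enrichment_params, filter_report):
        self.model = model
        self.locus_frame: pd.DataFrame = locus_frame
        self.unigene_frame: pd.DataFrame = unigene_frame
        self.enrichment_params: EnrichmentParams = enrichment_params
        self.filter_report: FilterReport = filter_report
        self._check_conservation()

    def _check_conservation(self) -> None:
        uf = self.unigene_frame
        if int(uf["n_all"].sum()) != self.m_total:
            raise BsrScanError("unigene locus counts do not sum to M")
        if int(uf["y_assoc"].sum()) != self.k_assoc:
            raise BsrScanError("unigene candidate counts do not sum to K")
        if self.filter_report.n_after_consistent != self.m_total:
            raise BsrScanError("M does not match post-filter locus count")

    # -- scalar results ----------------------------------------------------
    @property
    def m_total(self) -> int:
        return self.enrichment_params.m_total

    @property
    def k_assoc(self) -> int:
        return self.enrichment_params.k_assoc

    @property
    def config(self) -> dict:
        return asdict(self.model.config)

    # -- record views ------------------------------------------------------
    @property
    def ed_records(self) -> list[EdRecord]:
        return [
            EdRecord(
                unigene_id=str(r.unigene),
                position=int(r.pos),
                ed=float(r.ed),
                ed_powered=float(r.ed_powered),
                is_candidate=bool(r.is_candidate),
            )
            for r in self.locus_frame.itertuples(index=False)
        ]

    @property
    def unigene_records(self) -> list[UnigeneEnrichment]:
        return [
            UnigeneEnrichment(
                unigene_id=str(r.unigene),
                n_all=int(r.n_all),
                y_assoc=int(r.y_assoc),
                p_value=float(r.p_value),
                fdr=float(r.fdr),
                significant=bool(r.significant),
                p_underflow=bool(r.p_underflow),
            )
            for r in self.unigene_frame.itertuples(index=False)
        ]

    def significant_unigenes(self) -> list[UnigeneEnrichment]:
        """Unigenes passing the strict FDR cutoff, sorted by (fdr, id)."""
        return screen_significant(
            self.unigene_records, self.model.config.fdr_cutoff
        )

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        rep = self.filter_report
        cfg = self.model.config
        sig = self.significant_unigenes()
        lines = [
            "Bulked-segregant ED association scan",
            "=" * 52,
            f"loci: input {rep.n_input} -> support {rep.n_after_support}"
            f" -> discrepant {rep.n_after_discrepant}"
            f" -> consistent {rep.n_after_consistent}",
            f"M (discrepant loci) = {self.m_total}   K (candidates) = {self.k_assoc}",
            f"threshold {cfg.threshold} on {cfg.threshold_on}; power k = {cfg.power}",
            f"unigenes tested = {len(self.unigene_frame)}; "
            f"significant (FDR < {cfg.fdr_cutoff}) = {len(sig)}",
        ]
        if sig:
            lines.append("-" * 52)
            lines.append(f"{'Unigene':<20}{'All':>5}{'Asso':>6}{'p-Value':>12}{'FDR':>12}")
            for e in sig[:20]:
                lines.append(
                    f"{e.unigene_id:<20}{e.n_all:>5}{e.y_assoc:>6}"
                    f"{e.p_value:>12.3e}{e.fdr:>12.3e}"
                )
        return "\n".join(lines)

    def save(self, out_dir) -> dict:
        """Write per-locus TSV, per-unigene TSV and run metadata."""
        return write_results(self, out_dir)

    def plot_ed(self, ax=None, powered: bool = False):
        """Scatter of the per-locus scan statistic in canonical locus order."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        col = "ed_powered" if powered else "ed"
        y = self.locus_frame[col].to_numpy()
        x = np.arange(len(y))
        cand = self.locus_frame["is_candidate"].to_numpy()
        ax.scatter(x[~cand], y[~cand], s=4, c="0.6", label="background")
        if cand.any():
            ax.scatter(x[cand], y[cand], s=8, c="crimson", label="candidate")
        cfg = self.model.config
        if (cfg.threshold_on == "ed") != powered:
            ax.axhline(cfg.threshold, ls="--", c="k", lw=0.8)
        ax.set_xlabel("locus (canonical order)")
        ax.set_ylabel("ED$^{%d}$" % cfg.power if powered else "ED")
        ax.legend(frameon=False, fontsize=8)
        return ax


def aggregate_unigenes(ed_records: Sequence[EdRecord]) -> list[tuple[str, int, int]]:
    """Per-unigene (id, locus count, candidate count), ordered by unigene id."""
    counts: dict[str, list[int]] = {}
    for r in ed_records:
        c = counts.setdefault(r.unigene_id, [0, 0])
        c[0] += 1
        c[1] += int(r.is_candidate)
    return [(uid, c[0], c[1]) for uid, c in sorted(counts.items())]


def run_bsr_scan(loci, config: ScanConfig | None = None, **config_kwargs) -> BsrScanResults:
    """Functional entry point: build the model and fit it in one call."""
    return EdAssociationScan(loci, config=config, **config_kwargs).fit()
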