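"""Reading and writing the pipeline's file formats.

Two input representations are supported:

* the depth-TSV dialect — tab-separated, UTF-8, ``#`` comment lines allowed,
  header ``unigene  pos  T01_A ... T04_T`` (18 columns); positions are
  1-based inclusive;
* VCF 4.x with per-sample allele-depth (``AD``) subfields, where CHROM holds
  the unigene id and a pool→sample mapping assigns samples to T01..T04.

Outputs are a per-locus TSV (depths, ED, ED^k, candidate flag), a
per-unigene TSV mirroring the enrichment table (All Count / Asso Count /
p-Value / FDR / Significant) and a plain-text run-metadata file.  Writing is
byte-stable for identical input and configuration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .containers import (
    BASE_INDEX,
    BASES,
    DEPTH_COLUMNS,
    POOLS,
    LocusTable,
    ValidationError,
)

TSV_HEADER = ("unigene", "pos", *DEPTH_COLUMNS)

LOCUS_RESULT_FILE = "locus_results.tsv"
UNIGENE_RESULT_FILE = "unigene_results.tsv"
METADATA_FILE = "run_metadata.txt"


@dataclass(slots=True)
class VcfIngestStats:
    """Counters of VCF records not converted into loci."""

    n_records: int = 0
    n_loci: int = 0
    skipped_non_snp: int = 0
    skipped_missing_ad: int = 0


def read_depth_tsv(path) -> LocusTable:
    """Parse the depth-TSV dialect into a :class:`LocusTable`.

    Malformed rows are reported with their 1-based line numbers; negative
    depths and duplicate (unigene, position) keys are hard errors.
    """
    path = Path(path)
    unigenes: list[str] = []
    positions: list[int] = []
    depths: list[list[int]] = []
    errors: list[str] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(fields) != TSV_HEADER:
                    raise ValidationError(
                        f"{path}:{lineno}: bad header; expected columns "
                        f"{' '.join(TSV_HEADER)}"
                    )
                header_seen = True
                continue
            if len(fields) != len(TSV_HEADER):
                errors.append(
                    f"line {lineno}: expected {len(TSV_HEADER)} columns, got {len(fields)}"
                )
                continue
            try:
                pos = int(fields[1])
                row = [int(x) for x in fields[2:]]
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            if pos < 1:
                errors.append(f"line {lineno}: position must be >= 1, got {pos}")
                continue
            neg = [c for c, v in zip(TSV_HEADER[2:], row) if v < 0]
            if neg:
                errors.append(f"line {lineno}: negative depth in column(s) {neg}")
                continue
            unigenes.append(fields[0])
            positions.append(pos)
            depths.append(row)
    if not header_seen:
        raise ValidationError(f"{path}: no header line found")
    if errors:
        raise ValidationError(f"{path}: malformed rows:\n  " + "\n  ".join(errors))
    if not unigenes:
        return LocusTable.empty()
    seen: dict[tuple[str, int], int] = {}
    dups = []
    for i, key in enumerate(zip(unigenes, positions)):
        if key in seen:
            dups.append(key)
        seen[key] = i
    if dups:
        raise ValidationError(f"{path}: duplicate (unigene, position) keys: {dups[:5]}")
    arr = np.asarray(depths, dtype=np.int64).reshape(len(unigenes), len(POOLS), len(BASES))
    return LocusTable(unigenes, positions, arr)


def write_depth_tsv(table: LocusTable, path) -> None:
    """Write a :class:`LocusTable` in the depth-TSV dialect (lossless)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("# bulked-pool SNP base depths; positions are 1-based inclusive\n")
        fh.write("\t".join(TSV_HEADER) + "\n")
        flat = table.depths.reshape(len(table), -1)
        for uid, pos, row in zip(table.unigene_ids, table.positions, flat):
            fh.write(f"{uid}\t{pos}\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_depth_vcf(path, sample_map: Mapping[str, str]) -> LocusTable:
    """Build a :class:`LocusTable` from a VCF with per-sample AD fields.

    ``sample_map`` maps pool ids (T01..T04) to VCF sample names.  Records
    whose REF or any ALT allele is not a single A/C/G/T base are skipped as
    non-SNPs; records with missing AD in any mapped sample are skipped.
    Skip counters land in ``table.meta['vcf_ingest']``.
    """
    import pysam

    missing_pools = [p for p in POOLS if p not in sample_map]
    if missing_pools:
        raise ValidationError(f"sample_map missing pools {missing_pools}")
    stats = VcfIngestStats()
    unigenes: list[str] = []
    positions: list[int] = []
    depths: list[np.ndarray] = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        header_samples = set(vf.header.samples)
        unmapped = [s for s in sample_map.values() if s not in header_samples]
        if unmapped:
            raise ValidationError(
                f"samples {unmapped} not present in VCF header "
                f"(has {sorted(header_samples)})"
            )
        for rec in vf:
            stats.n_records += 1
            alleles = (rec.ref,) + tuple(rec.alts or ())
            if any(a is None or len(a) != 1 or a.upper() not in BASE_INDEX for a in alleles):
                stats.skipped_non_snp += 1
                continue
            mat = np.zeros((len(POOLS), len(BASES)), dtype=np.int64)
            ok = True
            for pi, pool in enumerate(POOLS):
                ad = rec.samples[sample_map[pool]].get("AD")
                if ad is None or any(v is None for v in ad):
                    ok = False
                    break
                for allele, depth in zip(alleles, ad):
                    mat[pi, BASE_INDEX[allele.upper()]] += int(depth)
            if not ok:
                stats.skipped_missing_ad += 1
                continue
            unigenes.append(rec.chrom)
            positions.append(rec.pos)
            depths.append(mat)
    stats.n_loci = len(unigenes)
    if not unigenes:
        table = LocusTable.empty()
    else:
        table = LocusTable(unigenes, positions, np.stack(depths))
    table.meta["vcf_ingest"] = stats
    return table


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def write_results(result, out_dir) -> dict[str, Path]:
    """Write per-locus TSV, per-unigene TSV and run metadata for a scan.

    ``result`` is a :class:`bsrscan.model.BsrScanResults`.  Returns the paths
    written.  Output is byte-stable: fixed column order, canonical row order,
    ``%.10g`` float formatting, ``\\n`` line endings.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "locus": out_dir / LOCUS_RESULT_FILE,
        "unigene": out_dir / UNIGENE_RESULT_FILE,
        "metadata": out_dir / METADATA_FILE,
    }

    lf = result.locus_frame
    with paths["locus"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join((*TSV_HEADER, "ed", "ed_powered", "is_candidate")) + "\n")
        for row in lf.itertuples(index=False):
            d = dict(zip(lf.columns, row))
            fh.write(
                "\t".join(
                    [
                        str(d["unigene"]),
                        str(d["pos"]),
                        *(str(int(d[c])) for c in DEPTH_COLUMNS),
                        _fmt(d["ed"]),
                        _fmt(d["ed_powered"]),
                        str(bool(d["is_candidate"])),
                    ]
                )
                + "\n"
            )

    uf = result.unigene_frame
    with paths["unigene"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("Unigene\tAll Count\tAsso Count\tp-Value\tFDR\tSignificant\n")
        for row in uf.itertuples(index=False):
            d = dict(zip(uf.columns, row))
            fh.write(
                f"{d['unigene']}\t{int(d['n_all'])}\t{int(d['y_assoc'])}\t"
                f"{_fmt(d['p_value'])}\t{_fmt(d['fdr'])}\t{bool(d['significant'])}\n"
            )

    rep = result.filter_report
    with paths["metadata"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("bsrscan run metadata\n")
        fh.write("====================\n")
        for key in sorted(result.config):
            fh.write(f"config.{key}\t{result.config[key]}\n")
        fh.write(f"loci.input\t{rep.n_input}\n")
        fh.write(f"loci.after_read_support\t{rep.n_after_support}\n")
        fh.write(f"loci.after_parent_discrepant\t{rep.n_after_discrepant}\n")
        fh.write(f"loci.after_bulk_consistent\t{rep.n_after_consistent}\n")
        fh.write(f"M.total_discrepant_loci\t{result.m_total}\n")
        fh.write(f"K.candidate_loci\t{result.k_assoc}\n")
        fh.write(f"unigenes.tested\t{len(uf)}\n")
        fh.write(f"unigenes.significant\t{int(uf['significant'].sum())}\n")
    return paths
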