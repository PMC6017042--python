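"""Synthetic bulked-pool SNP depth datasets with known truth.

The generator emulates the statistical structure of an F1 pseudo-testcross
bulked-segregant design: two heterozygous outcrossing parents, and two
phenotypic bulks of ``bulk_size`` F1 individuals each.  At every simulated
SNP one parent is heterozygous (ref/alt) and the other homozygous ref, so
the Mendelian expectation of the alternate-allele frequency in a bulk is
0.25.  Realized bulk frequencies are binomial draws of ``2 * bulk_size``
chromosomes around that expectation — the finite-bulk sampling noise that
dominates the null variance of the ED statistic.  At loci of causal
unigenes the two bulks' expectations are pushed apart by
``causal_divergence`` (±d/2 around 0.25, clipped to [0, 1]), standing in
for linkage to the trait locus.  Read depths are Poisson per pool and base
calls are multinomial on the true frequencies perturbed by a uniform
base-miscall error.

Randomness is counter-based: each unigene owns a Philox substream keyed by
``(seed, unigene index)`` with a fixed draw layout, so datasets are
reproducible across runs and platforms and adding unigenes does not shift
the draws of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BASES, POOLS, BsrScanError, LocusTable
from .io import write_depth_tsv

LABEL_DISCREPANT = "discrepant"
LABEL_LOW_SUPPORT = "low-support-injected"
LABEL_MENDEL_IMPOSSIBLE = "mendelian-impossible-injected"
LABEL_CONSISTENT = "consistent-injected"

_MENDEL_EXPECTATION = 0.25  # alt-allele frequency in F1 of Aa x aa
_FODDER_STREAM = 2**33  # substream key offset for fodder injection
_CAUSAL_STREAM = 2**32  # substream key for causal-unigene choice


@dataclass(frozen=True, slots=True)
class SimConfig:
    """Study-design parameters of one synthetic dataset.

    ``loci_per_unigene`` may be an int or an inclusive ``(lo, hi)`` range;
    ``causal_divergence`` is the difference in alternate-allele frequency
    between the two bulks at causal loci; ``mean_depth`` is the Poisson mean
    read depth per pool per locus; ``error_rate`` is the per-read
    probability of miscalling to a uniformly chosen other base.
    """

    n_unigenes: int
    loci_per_unigene: int | tuple[int, int]
    n_causal: int
    causal_divergence: float
    bulk_size: int = 20
    mean_depth: float = 50.0
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_unigenes < 1:
            raise BsrScanError("n_unigenes must be >= 1")
        lo, hi = self.loci_range()
        if lo < 1 or hi < lo:
            raise BsrScanError(f"invalid loci_per_unigene {self.loci_per_unigene}")
        if not 0 <= self.n_causal <= self.n_unigenes:
            raise BsrScanError("n_causal must be in [0, n_unigenes]")
        if not 0.0 <= self.causal_divergence <= 1.0:
            raise BsrScanError("causal_divergence must be in [0, 1]")
        if self.bulk_size < 1:
            raise BsrScanError("bulk_size must be >= 1")
        if self.mean_depth <= 0:
            raise BsrScanError("mean_depth must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise BsrScanError("error_rate must be in [0, 1)")

    def loci_range(self) -> tuple[int, int]:
        if isinstance(self.loci_per_unigene, int):
            return self.loci_per_unigene, self.loci_per_unigene
        lo, hi = self.loci_per_unigene
        return int(lo), int(hi)


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``frame`` has one row per locus: unigene, pos, label, causal flag,
    ref/alt bases, heterozygous parent, and the true alternate-allele
    frequency in each pool.
    """

    config: SimConfig
    causal_unigene_ids: set[str] = field(default_factory=set)
    frame: pd.DataFrame = field(default_factory=pd.DataFrame)


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=[seed & (2**64 - 1), key]))


def _multinomial_rows(rng, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Row-wise multinomial via conditional binomials (vectorized over rows)."""
    n = np.asarray(n, dtype=np.int64)
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p, dtype=np.int64)
    remaining = n.copy()
    rem_p = np.ones(len(p))
    for b in range(p.shape[1] - 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            cond = np.where(rem_p > 0, p[:, b] / rem_p, 0.0)
        cond = np.clip(cond, 0.0, 1.0)
        out[:, b] = rng.binomial(remaining, cond)
        remaining -= out[:, b]
        rem_p -= p[:, b]
    out[:, -1] = remaining
    return out


def simulate_dataset(config: SimConfig) -> tuple[LocusTable, SimTruth]:
    """Draw one dataset; fully reproducible from ``config.seed``."""
    lo, hi = config.loci_range()
    width = max(5, len(str(config.n_unigenes)))
    uids = [f"UN{i:0{width}d}" for i in range(config.n_unigenes)]

    causal_rng = _substream(config.seed, _CAUSAL_STREAM)
    causal_idx = set(
        causal_rng.choice(config.n_unigenes, size=config.n_causal, replace=False).tolist()
    )

    all_uid, all_pos, all_depths, truth_rows = [], [], [], []
    half_d = config.causal_divergence / 2.0
    chrom = 2 * config.bulk_size
    e = config.error_rate

    for ui, uid in enumerate(uids):
        rng = _substream(config.seed, ui)
        n = lo if lo == hi else int(rng.integers(lo, hi + 1))
        pos_space = max(10 * n, 100)
        pos = np.sort(rng.choice(pos_space, size=n, replace=False) + 1)
        ref = rng.integers(0, 4, size=n)
        alt = (ref + rng.integers(1, 4, size=n)) % 4
        het_parent = rng.integers(0, 2, size=n)  # 0 -> T01 heterozygous

        causal = ui in causal_idx
        p3 = np.clip(_MENDEL_EXPECTATION + (half_d if causal else 0.0), 0.0, 1.0)
        p4 = np.clip(_MENDEL_EXPECTATION - (half_d if causal else 0.0), 0.0, 1.0)
        f3 = rng.binomial(chrom, np.full(n, p3)) / chrom
        f4 = rng.binomial(chrom, np.full(n, p4)) / chrom
        f1 = np.where(het_parent == 0, 0.5, 0.0)  # T01 alt-allele frequency
        f2 = np.where(het_parent == 1, 0.5, 0.0)

        depth = rng.poisson(config.mean_depth, size=(len(POOLS), n))
        alt_freqs = (f1, f2, f3, f4)
        mat = np.zeros((n, len(POOLS), len(BASES)), dtype=np.int64)
        rows = np.arange(n)
        for pi in range(len(POOLS)):
            true = np.zeros((n, len(BASES)))
            true[rows, ref] = 1.0 - alt_freqs[pi]
            true[rows, alt] = alt_freqs[pi]
            obs_p = true * (1.0 - e) + (1.0 - true) * (e / 3.0)
            mat[:, pi, :] = _multinomial_rows(rng, depth[pi], obs_p)

        all_uid.extend([uid] * n)
        all_pos.append(pos)
        all_depths.append(mat)
        for j in range(n):
            truth_rows.append(
                {
                    "unigene": uid,
                    "pos": int(pos[j]),
                    "label": LABEL_DISCREPANT,
                    "causal": causal,
                    "ref": BASES[ref[j]],
                    "alt": BASES[alt[j]],
                    "het_parent": POOLS[0] if het_parent[j] == 0 else POOLS[1],
                    "alt_freq_T01": float(f1[j]),
                    "alt_freq_T02": float(f2[j]),
                    "alt_freq_T03": float(f3[j]),
                    "alt_freq_T04": float(f4[j]),
                }
            )

    table = LocusTable(all_uid, np.concatenate(all_pos), np.concatenate(all_depths))
    truth = SimTruth(
        config=config,
        causal_unigene_ids={uids[i] for i in causal_idx},
        frame=pd.DataFrame(truth_rows),
    )
    return table, truth


def inject_filter_fodder(
    table: LocusTable,
    truth: SimTruth,
    fractions: tuple[float, float, float],
    seed: int | None = None,
) -> tuple[LocusTable, SimTruth]:
    """Replace stated fractions of loci with filter-removable classes.

    ``fractions`` = (low-support, Mendelian-impossible, bulk-identical);
    class sizes are ``round(f * n)`` and the classes are disjoint.  Truth
    labels are updated so filter recall is computable.
    """
    f_low, f_mendel, f_ident = (float(f) for f in fractions)
    if min(f_low, f_mendel, f_ident) < 0 or f_low + f_mendel + f_ident > 1:
        raise BsrScanError("fractions must be non-negative and sum to <= 1")
    n = len(table)
    counts = [int(round(f * n)) for f in (f_low, f_mendel, f_ident)]
    rng = _substream(seed if seed is not None else truth.config.seed, _FODDER_STREAM)
    perm = rng.permutation(n)
    idx_low = perm[: counts[0]]
    idx_mendel = perm[counts[0] : counts[0] + counts[1]]
    idx_ident = perm[counts[0] + counts[1] : sum(counts)]

    depths = table.depths.copy()
    frame = truth.frame.copy()
    base_index = {b: i for i, b in enumerate(BASES)}

    for i in idx_low:
        pool = int(rng.integers(0, len(POOLS)))
        major = int(depths[i, pool].argmax())
        depths[i, pool] = 0
        depths[i, pool, major] = 2  # below the default min_support of 3
        frame.iloc[i, frame.columns.get_loc("label")] = LABEL_LOW_SUPPORT

    for i in idx_mendel:
        ref_b = base_index[frame.iloc[i]["ref"]]
        alt_b = base_index[frame.iloc[i]["alt"]]
        forbidden = next(b for b in range(4) if b not in (ref_b, alt_b))
        total = max(int(depths[i, 2].sum()), 6)  # T03 carries the impossible allele
        depths[i, 2] = 0
        depths[i, 2, ref_b] = total - total // 2
        depths[i, 2, forbidden] = total // 2
        frame.iloc[i, frame.columns.get_loc("label")] = LABEL_MENDEL_IMPOSSIBLE

    for i in idx_ident:
        depths[i, 3] = depths[i, 2]  # T04 := T03, frequencies exactly equal
        frame.iloc[i, frame.columns.get_loc("label")] = LABEL_CONSISTENT

    new_table = LocusTable(table.unigene_ids, table.positions, depths, meta=table.meta)
    return new_table, SimTruth(
        config=truth.config,
        causal_unigene_ids=set(truth.causal_unigene_ids),
        frame=frame,
    )


TRUTH_FILE = "truth.tsv"
DEPTHS_FILE = "depths.tsv"


def write_sim_tsv(table: LocusTable, truth: SimTruth, out_dir) -> dict[str, Path]:
    """Write the depth TSV (pipeline dialect) and the truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    depth_path = out_dir / DEPTHS_FILE
    truth_path = out_dir / TRUTH_FILE
    write_depth_tsv(table, depth_path)
    truth.frame.to_csv(
        truth_path, sep="\t", index=False, float_format="%.10g", lineterminator="\n"
    )
    return {"depths": depth_path, "truth": truth_path}
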