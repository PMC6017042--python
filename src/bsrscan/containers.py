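"""In-memory containers for bulked-pool SNP depth data.

The atom of a BSR-seq scan is a SNP site on a unigene carrying four-base
read-depth vectors for each of four sequencing pools: the two parents of the
cross (``T01`` male, ``T02`` female) and the two phenotypic bulks (``T03``
early, ``T04`` late).  :class:`SnpLocus` is the per-site record;
:class:`LocusTable` is the columnar container the pipeline actually computes
on (a dense ``(n_loci, 4 pools, 4 bases)`` integer depth tensor plus unigene
ids and positions), behaving as a ``Sequence[SnpLocus]``.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POOLS: tuple[str, ...] = ("T01", "T02", "T03", "T04")
BASES: tuple[str, ...] = ("A", "C", "G", "T")
POOL_INDEX: dict[str, int] = {p: i for i, p in enumerate(POOLS)}
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

#: Column order of the depth-TSV dialect (after ``unigene`` and ``pos``).
DEPTH_COLUMNS: tuple[str, ...] = tuple(
    f"{pool}_{base}" for pool in POOLS for base in BASES
)


class BsrScanError(Exception):
    """Base class for all package errors."""


class ValidationError(BsrScanError):
    """Raised when input data violates a structural invariant."""


@dataclass(frozen=True, slots=True)
class BaseDepths:
    """Read counts of the four nucleotides at one locus in one pool."""

    a: int
    c: int
    g: int
    t: int

    def __post_init__(self) -> None:
        for name in ("a", "c", "g", "t"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"negative depth {name}={v}")

    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.c, self.g, self.t], dtype=np.int64)

    @classmethod
    def from_array(cls, arr: Iterable[int]) -> "BaseDepths":
        a, c, g, t = (int(x) for x in arr)
        return cls(a, c, g, t)


@dataclass(frozen=True, slots=True)
class SnpLocus:
    """One SNP site on a unigene with depths for all four pools."""

    unigene_id: str
    position: int
    depths: Mapping[str, BaseDepths]

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"position must be 1-based >= 1, got {self.position}"
            )
        missing = [p for p in POOLS if p not in self.depths]
        if missing:
            raise ValidationError(
                f"locus {self.unigene_id}:{self.position} missing pools {missing}"
            )

    def depth_matrix(self) -> np.ndarray:
        """(4 pools, 4 bases) depth matrix in canonical pool order."""
        return np.stack([self.depths[p].as_array() for p in POOLS])


class LocusTable(Sequence):
    """Columnar table of SNP loci; sequence protocol yields :class:`SnpLocus`.

    Parameters
    ----------
    unigene_ids : array-like of str
    positions : array-like of int, 1-based
    depths : int array, shape (n, 4, 4)
        Axis 1 is the pool (T01, T02, T03, T04); axis 2 the base (A, C, G, T).
    meta : dict, optional
        Free-form provenance (e.g. VCF ingest counters).
    """

    def __init__(self, unigene_ids, positions, depths, *, meta=None, validate=True):
        self.unigene_ids = np.asarray(unigene_ids, dtype=object)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.depths = np.asarray(depths, dtype=np.int64)
        self.meta: dict = dict(meta) if meta else {}
        if validate:
            self._validate()

    def _validate(self) -> None:
        n = len(self.unigene_ids)
        if self.positions.shape != (n,):
            raise ValidationError("positions length mismatch")
        if self.depths.shape != (n, len(POOLS), len(BASES)):
            raise ValidationError(
                f"depths must have shape ({n}, 4, 4), got {self.depths.shape}"
            )
        if n and self.positions.min(initial=1) < 1:
            bad = np.flatnonzero(self.positions < 1)
            raise ValidationError(f"non-positive positions at rows {bad[:5].tolist()}")
        if (self.depths < 0).any():
            bad = np.flatnonzero((self.depths < 0).any(axis=(1, 2)))
            raise ValidationError(f"negative depths at rows {bad[:5].tolist()}")
        keys = list(zip(self.unigene_ids, self.positions.tolist()))
        if len(set(keys)) != n:
            seen, dups = set(), []
            for k in keys:
                if k in seen:
                    dups.append(k)
                seen.add(k)
            raise ValidationError(f"duplicate (unigene, position) keys: {dups[:5]}")

    # -- sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.unigene_ids)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return LocusTable(
                self.unigene_ids[i], self.positions[i], self.depths[i],
                meta=self.meta, validate=False,
            )
        row = self.depths[i]
        return SnpLocus(
            unigene_id=str(self.unigene_ids[i]),
            position=int(self.positions[i]),
            depths={p: BaseDepths.from_array(row[j]) for j, p in enumerate(POOLS)},
        )

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_loci(cls, loci: Iterable[SnpLocus]) -> "LocusTable":
        loci = list(loci)
        if not loci:
            return cls.empty()
        return cls(
            [l.unigene_id for l in loci],
            [l.position for l in loci],
            np.stack([l.depth_matrix() for l in loci]),
        )

    @classmethod
    def empty(cls) -> "LocusTable":
        return cls(
            np.empty(0, dtype=object),
            np.empty(0, dtype=np.int64),
            np.empty((0, len(POOLS), len(BASES)), dtype=np.int64),
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LocusTable":
        required = ("unigene", "pos", *DEPTH_COLUMNS)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        depths = (
            df[list(DEPTH_COLUMNS)]
            .to_numpy(dtype=np.int64)
            .reshape(len(df), len(POOLS), len(BASES))
        )
        return cls(df["unigene"].to_numpy(dtype=object), df["pos"].to_numpy(), depths)

    def to_dataframe(self) -> pd.DataFrame:
        flat = self.depths.reshape(len(self), -1)
        df = pd.DataFrame(flat, columns=list(DEPTH_COLUMNS))
        df.insert(0, "pos", self.positions)
        df.insert(0, "unigene", self.unigene_ids)
        return df

    # -- derived quantities ------------------------------------------------
    def totals(self) -> np.ndarray:
        """(n, 4) per-pool total depth."""
        return self.depths.sum(axis=2)

    def frequencies(self) -> np.ndarray:
        """(n, 4, 4) per-pool base frequencies; pools with zero depth get 0s."""
        tot = self.totals().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.depths / tot[:, :, None]
        return np.nan_to_num(f, nan=0.0, posinf=0.0)

    def subset(self, mask_or_index) -> "LocusTable":
        idx = np.asarray(mask_or_index)
        return LocusTable(
            self.unigene_ids[idx], self.positions[idx], self.depths[idx],
            meta=self.meta, validate=False,
        )

    def canonical_order(self) -> "LocusTable":
        """Sorted copy: unigene id lexicographic, then position ascending."""
        order = np.lexsort((self.positions, self.unigene_ids.astype(str)))
        return self.subset(order)

    def keys(self) -> list[tuple[str, int]]:
        return list(zip(map(str, self.unigene_ids), self.positions.tolist()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LocusTable(n_loci={len(self)}, n_unigenes={len(set(self.unigene_ids))})"
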