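"""Core domain types shared across the screen pipeline.

All genomic coordinates are 0-based, half-open.  Conversions to/from the
1-based on-disk conventions (coverage files, VCF) happen only in
:mod:`corsivscreen.meth_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np

Genotype = Literal["hom_ref", "het", "hom_alt", "missing"]

GENOTYPES: tuple[Genotype, ...] = ("hom_ref", "het", "hom_alt", "missing")


class FormatError(ValueError):
    """Raised when an input file violates its format contract.

    Carries the offending path and line number when available.
    """

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ConfigurationError(ValueError):
    """Raised for invalid parameters or inconsistent configuration."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based, half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_size(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class MethCount:
    """Read counts for one CpG site (position of the C, forward strand)."""

    chrom: str
    pos: int
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError(
                f"negative counts at {self.chrom}:{self.pos} "
                f"({self.n_meth}/{self.n_unmeth})"
            )

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def frac_meth(self) -> float | None:
        """Methylated fraction, or None at zero depth (distinct from 0)."""
        d = self.depth
        return self.n_meth / d if d > 0 else None


class MethylomeLibrary:
    """Per-(subject, tissue) CpG methylation counts.

    Counts are stored per chromosome as parallel sorted arrays for fast
    position lookups; ``counts()`` yields them as :class:`MethCount`.
    """

    def __init__(
        self,
        subject: str,
        tissue: str,
        germ_layer: str | None = None,
    ) -> None:
        self.subject = subject
        self.tissue = tissue
        self.germ_layer = germ_layer
        # chrom -> (pos, n_meth, n_unmeth) int64 arrays, sorted by pos
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject, self.tissue)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def set_chrom(
        self, chrom: str, pos: np.ndarray, n_meth: np.ndarray, n_unmeth: np.ndarray
    ) -> None:
        pos = np.asarray(pos, dtype=np.int64)
        n_meth = np.asarray(n_meth, dtype=np.int64)
        n_unmeth = np.asarray(n_unmeth, dtype=np.int64)
        if not (len(pos) == len(n_meth) == len(n_unmeth)):
            raise ValueError("array length mismatch")
        if len(pos) and np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions on {chrom} not strictly increasing")
        if np.any(n_meth < 0) or np.any(n_unmeth < 0):
            raise ValueError(f"negative counts on {chrom}")
        self._data[chrom] = (pos, n_meth, n_unmeth)

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._data.get(chrom, (empty, empty, empty))

    @classmethod
    def from_records(
        cls,
        subject: str,
        tissue: str,
        records: Iterable[MethCount],
        germ_layer: str | None = None,
    ) -> "MethylomeLibrary":
        lib = cls(subject, tissue, germ_layer)
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(
                (rec.pos, rec.n_meth, rec.n_unmeth)
            )
        for chrom, rows in by_chrom.items():
            rows.sort()
            merged: list[tuple[int, int, int]] = []
            for pos, m, u in rows:
                if merged and merged[-1][0] == pos:
                    p0, m0, u0 = merged[-1]
                    merged[-1] = (p0, m0 + m, u0 + u)
                else:
                    merged.append((pos, m, u))
            arr = np.asarray(merged, dtype=np.int64).reshape(-1, 3)
            lib.set_chrom(chrom, arr[:, 0], arr[:, 1], arr[:, 2])
        return lib

    def counts(self) -> Iterable[MethCount]:
        for chrom in sorted(self._data):
            pos, m, u = self._data[chrom]
            for i in range(len(pos)):
                yield MethCount(chrom, int(pos[i]), int(m[i]), int(u[i]))

    def counts_at(
        self, chrom: str, positions: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(n_meth, n_unmeth) aligned to `positions`; zeros where absent."""
        positions = np.asarray(positions, dtype=np.int64)
        pos, m, u = self.chrom_arrays(chrom)
        meth = np.zeros(len(positions), dtype=np.int64)
        unmeth = np.zeros(len(positions), dtype=np.int64)
        if len(pos):
            idx = np.searchsorted(pos, positions)
            ok = (idx < len(pos)) & (pos[np.minimum(idx, len(pos) - 1)] == positions)
            meth[ok] = m[idx[ok]]
            unmeth[ok] = u[idx[ok]]
        return meth, unmeth

    def drop_positions(self, masked: Mapping[str, np.ndarray]) -> "MethylomeLibrary":
        """Return a copy without the given chrom->positions (CpG masking)."""
        out = MethylomeLibrary(self.subject, self.tissue, self.germ_layer)
        for chrom, (pos, m, u) in self._data.items():
            bad = np.asarray(masked.get(chrom, []), dtype=np.int64)
            if len(bad):
                keep = ~np.isin(pos, bad)
                out.set_chrom(chrom, pos[keep], m[keep], u[keep])
            else:
                out.set_chrom(chrom, pos.copy(), m.copy(), u.copy())
        return out

    def n_sites(self) -> int:
        return sum(len(pos) for pos, _, _ in self._data.values())

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MethylomeLibrary({self.subject!r}, {self.tissue!r}, "
            f"sites={self.n_sites()})"
        )


@dataclass(frozen=True)
class VariantRecord:
    """Minimal biallelic variant with per-subject genotypes."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    qual: float
    genotypes: Mapping[str, Genotype] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        for s, g in self.genotypes.items():
            if g not in GENOTYPES:
                raise ValueError(f"bad genotype {g!r} for subject {s!r}")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or len(self.alt) != 1

    @property
    def span(self) -> tuple[int, int]:
        """Reference span [start, end): indels overlap every covered base."""
        return (self.pos, self.pos + len(self.ref))

    def covers(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos < e


@dataclass(frozen=True)
class GeneModel:
    """Gene span with strand-aware TSS/TES."""

    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    name: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for {self.name}")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"txStart >= txEnd for {self.name}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end)


@dataclass(frozen=True)
class RepeatFeature:
    interval: GenomicInterval
    repeat_class: str
    repeat_family: str = ""

    def __post_init__(self) -> None:
        if not self.repeat_class:
            raise ValueError("empty repeat class")


@dataclass(frozen=True)
class DMR:
    """A differentially methylated region consumed from an external caller."""

    interval: GenomicInterval
    tissue: str
    direction: int  # +1 = higher methylation in group 1
    mean_diff: float = 0.0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 1):
            raise ValueError(f"direction must be +-1, got {self.direction}")
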