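"""100-bp binning, coverage adequacy, CpG-SNP masking and bin residuals.

Two implementations coexist on purpose: per-bin reference functions
(:func:`adequacy`, :func:`bin_methylation`, :func:`bin_residual`) that state
the rules plainly, and a vectorised :func:`screen_bins` used for
genome-scale runs.  The test suite holds them to the same answers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ConfigurationError, GenomicInterval, MethylomeLibrary, VariantRecord

ADEQUACY_POLICIES = ("screen", "all_libraries")


@dataclass(frozen=True)
class ScreenParams:
    """All screen thresholds in one place."""

    bin_size: int = 100
    min_depth: int = 5              # reads per CpG for "covered"
    delta_threshold: float = 10.0   # |residual| needed to enter a block, %-points
    sivi_threshold: float = 20.0
    min_cpg_corsiv: int = 5
    min_bins_per_block: int = 2
    snp_min_qual: float = 30.0
    sd_ddof: int = 1                # sample-sd convention in the SIVI B term
    adequacy_policy: str = "screen"

    def __post_init__(self) -> None:
        for name in ("bin_size", "min_depth", "min_cpg_corsiv", "min_bins_per_block"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.delta_threshold <= 0 or self.sivi_threshold <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.adequacy_policy not in ADEQUACY_POLICIES:
            raise ConfigurationError(
                f"adequacy_policy must be one of {ADEQUACY_POLICIES}"
            )


@dataclass(frozen=True)
class Bin:
    """A genome tile holding at least one CpG (start aligned to bin_size)."""

    chrom: str
    start: int
    end: int
    cpg_positions: np.ndarray

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def make_bins(genome, params: ScreenParams) -> list[Bin]:
    """Tile each chromosome into bin_size bins; keep bins with >= 1 CpG."""
    bins: list[Bin] = []
    for chrom in genome.chroms:
        pos = np.asarray(genome.cpg_positions[chrom], dtype=np.int64)
        if len(pos) == 0:
            continue
        bin_ids = pos // params.bin_size
        boundaries = np.flatnonzero(np.diff(bin_ids)) + 1
        for chunk, bid in zip(
            np.split(pos, boundaries), bin_ids[np.concatenate(([0], boundaries))]
        ):
            start = int(bid) * params.bin_size
            bins.append(Bin(chrom, start, start + params.bin_size, chunk))
    return bins


# ---------------------------------------------------------------------------
# CpG-SNP masking
# ---------------------------------------------------------------------------

def discordant_cpg_snp_positions(
    bins: Sequence[Bin],
    variants: Sequence[VariantRecord],
    subjects: tuple[str, str],
    params: ScreenParams,
) -> dict[str, set[int]]:
    """C positions of CpGs hit (at the C or the G) by a quality-passing
    variant whose genotypes are discordant between the two screen subjects."""
    a, b = subjects
    hit: dict[str, set[int]] = {}
    for v in variants:
        if not (v.qual >= params.snp_min_qual):
            continue
        if a not in v.genotypes or b not in v.genotypes:
            raise ConfigurationError(
                f"subject missing from genotypes at {v.chrom}:{v.pos} "
                f"(need {a!r} and {b!r})"
            )
        ga, gb = v.genotypes[a], v.genotypes[b]
        if ga == "missing" or gb == "missing" or ga == gb:
            continue
        s, e = v.span
        hit.setdefault(v.chrom, set()).update(range(s, e))
    masked: dict[str, set[int]] = {}
    for bin_ in bins:
        spans = hit.get(bin_.chrom)
        if not spans:
            continue
        for p in bin_.cpg_positions:
            p = int(p)
            if p in spans or (p + 1) in spans:  # the C or the G
                masked.setdefault(bin_.chrom, set()).add(p)
    return masked


def mask_cpg_snps(
    bins: Sequence[Bin],
    variants: Sequence[VariantRecord],
    subjects: tuple[str, str],
    params: ScreenParams,
) -> tuple[list[Bin], int]:
    """Drop masked CpGs from every bin; bins left empty disappear."""
    masked = discordant_cpg_snp_positions(bins, variants, subjects, params)
    out: list[Bin] = []
    n_masked = 0
    for bin_ in bins:
        bad = masked.get(bin_.chrom)
        if not bad:
            out.append(bin_)
            continue
        keep = np.asarray([int(p) not in bad for p in bin_.cpg_positions])
        n_masked += int((~keep).sum())
        if keep.all():
            out.append(bin_)
        elif keep.any():
            out.append(Bin(bin_.chrom, bin_.start, bin_.end,
                           bin_.cpg_positions[keep]))
    return out, n_masked


# ---------------------------------------------------------------------------
# Per-bin reference rules
# ---------------------------------------------------------------------------

def adequacy(bin_: Bin, library: MethylomeLibrary, params: ScreenParams) -> bool:
    """n <= 2: every CpG needs >= min_depth reads; n > 2: at least
    ceil(n/2) CpGs do."""
    meth, unmeth = library.counts_at(bin_.chrom, bin_.cpg_positions)
    depth = meth + unmeth
    n = bin_.n_cpg
    n_cov = int((depth >= params.min_depth).sum())
    if n <= 2:
        return n_cov == n
    return n_cov >= (n + 1) // 2


def bin_methylation(bin_: Bin, library: MethylomeLibrary) -> float | None:
    """Read-weighted percent methylation; None at zero total depth."""
    meth, unmeth = library.counts_at(bin_.chrom, bin_.cpg_positions)
    total = int(meth.sum() + unmeth.sum())
    if total == 0:
        return None
    return 100.0 * float(meth.sum()) / total


def bin_residual(
    bin_: Bin,
    libraries: Sequence[MethylomeLibrary],
    subject_a: str,
    subject_b: str,
    tissues: Sequence[str],
    params: ScreenParams,
) -> float | None:
    """Mean over tissues adequate in BOTH subjects of (%meth_B - %meth_A)."""
    by_key = {lib.key: lib for lib in libraries}
    diffs: list[float] = []
    for t in tissues:
        lib_a, lib_b = by_key.get((subject_a, t)), by_key.get((subject_b, t))
        if lib_a is None or lib_b is None:
            continue
        if not (adequacy(bin_, lib_a, params) and adequacy(bin_, lib_b, params)):
            continue
        ma, mb = bin_methylation(bin_, lib_a), bin_methylation(bin_, lib_b)
        if ma is None or mb is None:
            continue
        diffs.append(mb - ma)
    if not diffs:
        return None
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# Vectorised screen table
# ---------------------------------------------------------------------------

def library_column(subject: str, tissue: str, what: str) -> str:
    return f"{what}:{subject}:{tissue}"


def screen_bins(
    bins: Sequence[Bin],
    libraries: Sequence[MethylomeLibrary],
    subject_a: str,
    subject_b: str,
    tissues: Sequence[str],
    params: ScreenParams,
) -> pd.DataFrame:
    """Per-bin table with per-library read sums, adequacy, %meth, the
    individual-level residual (B - A averaged over tissues adequate in
    both), and the screen-entry flag (>= 2 adequate tissues per animal).

    ``all_adequate`` additionally marks bins adequate in every library
    (the stricter policy used for genome-wide clustering).
    """
    by_key = {lib.key: lib for lib in libraries}
    for s in (subject_a, subject_b):
        for t in tissues:
            if (s, t) not in by_key:
                raise ConfigurationError(f"no library for subject={s} tissue={t}")

    frames: list[pd.DataFrame] = []
    by_chrom: dict[str, list[Bin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)

    for chrom, chrom_bins in by_chrom.items():
        chrom_bins.sort(key=lambda b: b.start)
        sizes = np.asarray([b.n_cpg for b in chrom_bins])
        offsets = np.concatenate(([0], np.cumsum(sizes)))[:-1]
        positions = np.concatenate([b.cpg_positions for b in chrom_bins])
        cols: dict[str, np.ndarray] = {
            "chrom": np.repeat(chrom, len(chrom_bins)),
            "start": np.asarray([b.start for b in chrom_bins]),
            "end": np.asarray([b.end for b in chrom_bins]),
            "n_cpg": sizes,
        }
        adeq: dict[tuple[str, str], np.ndarray] = {}
        meth_pct: dict[tuple[str, str], np.ndarray] = {}
        for s in (subject_a, subject_b):
            for t in tissues:
                lib = by_key[(s, t)]
                m, u = lib.counts_at(chrom, positions)
                depth = m + u
                msum = np.add.reduceat(m, offsets)
                dsum = np.add.reduceat(depth, offsets)
                ncov = np.add.reduceat(
                    (depth >= params.min_depth).astype(np.int64), offsets
                )
                ok = np.where(sizes <= 2, ncov == sizes, ncov >= (sizes + 1) // 2)
                with np.errstate(invalid="ignore", divide="ignore"):
                    pct = np.where(dsum > 0, 100.0 * msum / np.maximum(dsum, 1),
                                   np.nan)
                adeq[(s, t)] = ok
                meth_pct[(s, t)] = pct
                cols[library_column(s, t, "msum")] = msum
                cols[library_column(s, t, "dsum")] = dsum
                cols[library_column(s, t, "adeq")] = ok
                cols[library_column(s, t, "meth")] = pct

        diffs = np.full((len(chrom_bins), len(tissues)), np.nan)
        for j, t in enumerate(tissues):
            both = adeq[(subject_a, t)] & adeq[(subject_b, t)]
            d = meth_pct[(subject_b, t)] - meth_pct[(subject_a, t)]
            diffs[both, j] = d[both]
        with np.errstate(invalid="ignore"):
            residual = np.nanmean(diffs, axis=1)
        n_a = np.sum([adeq[(subject_a, t)] for t in tissues], axis=0)
        n_b = np.sum([adeq[(subject_b, t)] for t in tissues], axis=0)
        cols["residual"] = residual
        cols["enters_screen"] = (n_a >= 2) & (n_b >= 2) & ~np.isnan(residual)
        cols["all_adequate"] = np.all(
            [adeq[(s, t)] for s in (subject_a, subject_b) for t in tissues], axis=0
        )
        frames.append(pd.DataFrame(cols))

    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "n_cpg", "residual",
                     "enters_screen", "all_adequate"]
        )
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(["chrom", "start"], ignore_index=True)


def write_bin_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_bin_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def bin_table_library_keys(table: pd.DataFrame) -> list[tuple[str, str]]:
    keys = []
    for col in table.columns:
        if col.startswith("msum:"):
            _, s, t = col.split(":", 2)
            keys.append((s, t))
    return keys
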