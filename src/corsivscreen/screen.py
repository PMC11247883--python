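"""Block building, the systemic interindividual variation index (SIVI),
CoRSIV classification, the permutation null, and truth-channel scoring.

SIVI for a block with inter-individual residuals (x, y, z), one per tissue:

    A = cbrt(|x * y * z|)        rewards large differences
    B = -sd(x, y, z)             rewards direction/magnitude consistency
    SIVI = A + B

The sd convention (sample, n-1) is configurable through ScreenParams.sd_ddof.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import ScreenParams, library_column
from .synthetic import KIND_DMR, KIND_NULL, KIND_SYSTEMIC, PlantedRegionTruth
from .types import GenomicInterval

logger = logging.getLogger(__name__)


def sivi(x: float, y: float, z: float, ddof: int = 1) -> float:
    """A + B for one residual triple (see module docstring)."""
    a = float(np.cbrt(abs(x * y * z)))
    b = -float(np.std([x, y, z], ddof=ddof))
    return a + b


def sivi_values(xyz: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Vectorised SIVI over rows of an (n, 3) residual array."""
    xyz = np.asarray(xyz, dtype=float)
    a = np.cbrt(np.abs(xyz[:, 0] * xyz[:, 1] * xyz[:, 2]))
    b = -np.std(xyz, axis=1, ddof=ddof)
    return a + b


@dataclass
class Block:
    """Run of >= min_bins_per_block consecutive qualifying bins."""

    chrom: str
    start: int
    end: int
    n_bins: int
    n_cpg: int
    direction: int                      # sign of the member-bin residuals
    mean_residual: float
    lib_meth: dict[tuple[str, str], float | None]
    lib_msum: dict[tuple[str, str], int]
    lib_dsum: dict[tuple[str, str], int]
    x: float | None = None
    y: float | None = None
    z: float | None = None
    a_term: float | None = None
    b_term: float | None = None
    sivi: float | None = None
    perm_p: float | None = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def build_blocks(
    table: pd.DataFrame,
    subject_a: str,
    subject_b: str,
    tissues: Sequence[str],
    params: ScreenParams,
) -> tuple[list[Block], int]:
    """Segment screen-entering bins into maximal same-direction runs.

    A run extends over bins whose starts differ by exactly bin_size, whose
    residuals are defined with |residual| >= delta_threshold, and share one
    sign.  Runs shorter than min_bins_per_block are discarded.  Returns
    (blocks, n_blocks_without_sivi) — a block loses its SIVI when any of
    the six libraries has zero reads over the block.
    """
    if len(tissues) != 3:
        raise ValueError("SIVI requires exactly three tissues")
    blocks: list[Block] = []
    n_undefined = 0
    eligible = table[
        table["enters_screen"]
        & table["residual"].notna()
        & (table["residual"].abs() >= params.delta_threshold)
    ]
    lib_keys = [(s, t) for s in (subject_a, subject_b) for t in tissues]
    for chrom, sub in eligible.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        res = sub["residual"].to_numpy()
        signs = np.sign(res).astype(int)
        breaks = np.flatnonzero(
            (np.diff(starts) != params.bin_size) | (np.diff(signs) != 0)
        ) + 1
        for run in np.split(np.arange(len(sub)), breaks):
            if len(run) < params.min_bins_per_block:
                continue
            rows = sub.iloc[run]
            msum = {
                k: int(rows[library_column(*k, "msum")].sum()) for k in lib_keys
            }
            dsum = {
                k: int(rows[library_column(*k, "dsum")].sum()) for k in lib_keys
            }
            meth = {
                k: (100.0 * msum[k] / dsum[k]) if dsum[k] > 0 else None
                for k in lib_keys
            }
            block = Block(
                chrom=str(chrom),
                start=int(rows["start"].iloc[0]),
                end=int(rows["end"].iloc[-1]),
                n_bins=len(run),
                n_cpg=int(rows["n_cpg"].sum()),
                direction=int(signs[run[0]]),
                mean_residual=float(rows["residual"].mean()),
                lib_meth=meth,
                lib_msum=msum,
                lib_dsum=dsum,
            )
            if all(meth[k] is not None for k in lib_keys):
                xyz = [
                    meth[(subject_b, t)] - meth[(subject_a, t)] for t in tissues
                ]
                block.x, block.y, block.z = (float(v) for v in xyz)
                block.a_term = float(np.cbrt(abs(np.prod(xyz))))
                block.b_term = -float(np.std(xyz, ddof=params.sd_ddof))
                block.sivi = block.a_term + block.b_term
            else:
                n_undefined += 1
                logger.info("block %s lacks reads in >=1 library; SIVI undefined",
                            block.id)
            blocks.append(block)
    if n_undefined:
        logger.warning("%d blocks had undefined SIVI (zero-read library)",
                       n_undefined)
    return blocks, n_undefined


def classify_corsivs(
    blocks: Sequence[Block], params: ScreenParams
) -> tuple[list[Block], list[Block]]:
    """(all candidates with SIVI >= threshold, the subset with enough CpGs)."""
    candidates = sorted(
        (b for b in blocks if b.sivi is not None and b.sivi >= params.sivi_threshold),
        key=lambda b: (b.chrom, b.start),
    )
    corsivs = [b for b in candidates if b.n_cpg >= params.min_cpg_corsiv]
    return candidates, corsivs


@dataclass(frozen=True)
class PermutationResult:
    n_blocks: int
    n_skipped: int
    n_iter: int
    genome_wide_rate: float    # fraction of (block, iteration) pairs >= threshold
    per_block_p: dict[str, float] = field(default_factory=dict)


def permutation_null(
    blocks: Sequence[Block],
    subject_a: str,
    subject_b: str,
    tissues: Sequence[str],
    params: ScreenParams,
    n_iter: int = 1000,
    seed: int = 0,
    batch: int = 50,
) -> PermutationResult:
    """Scramble the six (subject x tissue) labels of each block's six
    block-level methylation values, recompute SIVI each time.

    Per-block empirical p = fraction of iterations with permuted
    SIVI >= observed; the genome-wide rate counts permuted SIVIs clearing
    sivi_threshold over all (block, iteration) pairs.  Blocks with a
    missing library value are skipped and logged.
    """
    lib_keys = [(s, t) for s in (subject_a, subject_b) for t in tissues]
    usable = [b for b in blocks
              if b.sivi is not None
              and all(b.lib_meth[k] is not None for k in lib_keys)]
    n_skipped = len(blocks) - len(usable)
    if n_skipped:
        logger.warning("permutation skipped %d blocks with missing values",
                       n_skipped)
    if not usable:
        return PermutationResult(0, n_skipped, n_iter, 0.0, {})
    values = np.asarray(
        [[b.lib_meth[k] for k in lib_keys] for b in usable], dtype=float
    )
    observed = np.asarray([b.sivi for b in usable], dtype=float)
    rng = np.random.default_rng(seed)
    n = len(usable)
    ge_obs = np.zeros(n, dtype=np.int64)
    ge_thresh = 0
    done = 0
    while done < n_iter:
        m = min(batch, n_iter - done)
        # independent uniform permutation of the 6 labels per (block, iter)
        perm = np.argsort(rng.random((m, n, 6)), axis=2)
        vp = np.take_along_axis(values[None, :, :], perm, axis=2)
        xyz = vp[:, :, 3:6] - vp[:, :, 0:3]
        s = (np.cbrt(np.abs(xyz.prod(axis=2)))
             - np.std(xyz, axis=2, ddof=params.sd_ddof))
        ge_obs += (s >= observed[None, :]).sum(axis=0)
        ge_thresh += int((s >= params.sivi_threshold).sum())
        done += m
    per_block = {}
    for b, k in zip(usable, ge_obs):
        p = float(k) / n_iter
        b.perm_p = p
        per_block[b.id] = p
    rate = ge_thresh / (n * n_iter)
    return PermutationResult(n, n_skipped, n_iter, rate, per_block)


# ---------------------------------------------------------------------------
# Truth-channel scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryScore:
    sensitivity: float
    precision: float
    n_truth: int
    n_called: int
    n_true_positive_calls: int
    off_target_rate: float     # fraction of DMR/null truth regions hit


def score_recovery(
    called: Sequence[Block], truth: Sequence[PlantedRegionTruth]
) -> RecoveryScore:
    """Overlap-based recovery of planted systemic regions.

    A planted systemic region is recovered when any called region overlaps
    it; a call is a true positive when it overlaps any planted systemic
    region.  ``off_target_rate`` is the fraction of planted tissue-DMR and
    null regions overlapped by a call.
    """
    systemic = [t.interval for t in truth if t.kind == KIND_SYSTEMIC]
    decoys = [t.interval for t in truth if t.kind in (KIND_DMR, KIND_NULL)]
    call_ivs = [c.interval for c in called]

    def hit(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
        return any(iv.overlaps(o) for o in others)

    recovered = sum(hit(t, call_ivs) for t in systemic)
    tp_calls = sum(hit(c, systemic) for c in call_ivs)
    off = sum(hit(d, call_ivs) for d in decoys)
    return RecoveryScore(
        sensitivity=recovered / len(systemic) if systemic else float("nan"),
        precision=tp_calls / len(call_ivs) if call_ivs else float("nan"),
        n_truth=len(systemic),
        n_called=len(call_ivs),
        n_true_positive_calls=tp_calls,
        off_target_rate=off / len(decoys) if decoys else float("nan"),
    )


# ---------------------------------------------------------------------------
# Block table I/O (BED6+ style)
# ---------------------------------------------------------------------------

def blocks_to_frame(blocks: Sequence[Block]) -> pd.DataFrame:
    rows = []
    for b in blocks:
        rows.append({
            "chrom": b.chrom, "start": b.start, "end": b.end,
            "name": b.id, "sivi": b.sivi, "n_cpg": b.n_cpg,
            "x": b.x, "y": b.y, "z": b.z,
            "direction": "+" if b.direction > 0 else "-",
            "perm_p": b.perm_p, "n_bins": b.n_bins,
            "mean_residual": b.mean_residual,
        })
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "sivi", "n_cpg",
                       "x", "y", "z", "direction", "perm_p", "n_bins",
                       "mean_residual"],
    )


def write_blocks(blocks: Sequence[Block], path) -> None:
    blocks_to_frame(blocks).to_csv(path, sep="\t", index=False)


def read_regions_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
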