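"""Matched control regions and genomic-context annotation.

Controls are drawn per CoRSIV from the screen-adequate bin pool on the same
chromosome, requiring an exact CpG-count match at the current target size;
after max_attempts failures the target size grows by one bin and the draw
restarts.  Each CoRSIV has its own seeded stream so matching is invariant
to input order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneModel, GenomicInterval, RepeatFeature, VariantRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ControlRegion:
    interval: GenomicInterval
    matched_corsiv_id: str
    n_cpg: int
    relaxation_count: int

    @property
    def size(self) -> int:
        return self.interval.size


def _region_rng(seed: int, region_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0xFFFFFFFF, zlib.crc32(region_id.encode())])
    )


def match_controls(
    corsivs: Sequence,
    bin_table: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    seed: int,
    max_attempts: int = 1000,
    bin_size: int = 100,
) -> tuple[list[ControlRegion], list[str]]:
    """One control per CoRSIV: same chromosome, identical CpG count, same
    size up to +bin_size per relaxation.  Controls never overlap a CoRSIV
    or another control.  Returns (controls, unmatched CoRSIV ids).

    ``corsivs`` must expose chrom/start/end/n_cpg (Block does); the bin
    table provides the sampling pool (enters_screen bins) and the CpG
    census for counting CpGs in candidate windows.
    """
    by_chrom_bins: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pool: dict[str, np.ndarray] = {}
    corsiv_ivs: dict[str, list[tuple[int, int]]] = {}
    for c in corsivs:
        corsiv_ivs.setdefault(c.chrom, []).append((c.start, c.end))

    for chrom, sub in bin_table.groupby("chrom"):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(dtype=np.int64)
        ncpg = sub["n_cpg"].to_numpy(dtype=np.int64)
        by_chrom_bins[chrom] = (starts, np.concatenate(([0], np.cumsum(ncpg))))
        adequate = sub.loc[sub["enters_screen"], "start"].to_numpy(dtype=np.int64)
        ivs = corsiv_ivs.get(chrom, [])
        if ivs:
            keep = np.ones(len(adequate), dtype=bool)
            for s, e in ivs:
                keep &= ~((adequate < e) & (adequate + bin_size > s))
            adequate = adequate[keep]
        pool[chrom] = adequate

    def cpgs_in(chrom: str, start: int, end: int) -> int:
        starts, cum = by_chrom_bins[chrom]
        lo = np.searchsorted(starts, start)
        hi = np.searchsorted(starts, end)
        return int(cum[hi] - cum[lo])

    controls: list[ControlRegion] = []
    accepted: dict[str, list[tuple[int, int]]] = {}
    unmatched: list[str] = []
    for c in corsivs:
        cid = f"{c.chrom}:{c.start}-{c.end}"
        rng = _region_rng(seed, cid)
        chrom_len = chrom_sizes[c.chrom]
        candidates = pool.get(c.chrom, np.empty(0, dtype=np.int64))
        size = c.end - c.start
        relax = 0
        found = None
        while found is None and size <= chrom_len and len(candidates):
            for _ in range(max_attempts):
                s = int(candidates[rng.integers(len(candidates))])
                e = s + size
                if e > chrom_len:
                    continue
                if cpgs_in(c.chrom, s, e) != c.n_cpg:
                    continue
                if any(s < oe and os_ < e for os_, oe in corsiv_ivs.get(c.chrom, [])):
                    continue
                if any(s < oe and os_ < e for os_, oe in accepted.get(c.chrom, [])):
                    continue
                found = (s, e)
                break
            else:
                size += bin_size
                relax += 1
                continue
        if found is None:
            logger.warning("no control found for CoRSIV %s", cid)
            unmatched.append(cid)
            continue
        s, e = found
        accepted.setdefault(c.chrom, []).append((s, e))
        controls.append(
            ControlRegion(GenomicInterval(c.chrom, s, e), cid, c.n_cpg, relax)
        )
    return controls, unmatched


# ---------------------------------------------------------------------------
# Genic annotation
# ---------------------------------------------------------------------------

def _distance_to_point(iv: GenomicInterval, point: int) -> int:
    """Minimal |distance| between any base of the region and a coordinate."""
    if point < iv.start:
        return iv.start - point
    if point >= iv.end:
        return point - (iv.end - 1)
    return 0


def genic_annotation(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int = 2500,
) -> pd.DataFrame:
    """TSS/TES/gene_body/intergenic flags; multiple flags allowed."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for iv in regions:
        tss = tes = body = False
        for g in by_chrom.get(iv.chrom, []):
            if _distance_to_point(iv, g.tss) <= window:
                tss = True
            if _distance_to_point(iv, g.tes) <= window:
                tes = True
            if iv.overlaps(g.interval):
                body = True
        rows.append({
            "region": str(iv), "tss": tss, "tes": tes, "gene_body": body,
            "intergenic": not (tss or tes or body),
        })
    return pd.DataFrame(rows)


def yates_2x2(table: np.ndarray) -> tuple[float, float | None]:
    """Yates-corrected chi-square on a 2x2 table; p is None on a zero margin."""
    table = np.asarray(table, dtype=float)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 0.0, None
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def tss_enrichment_test(
    corsiv_flags: Sequence[bool], control_flags: Sequence[bool]
) -> tuple[float, float, float | None]:
    """(odds ratio, chi2, p) for TSS-flag frequency, CoRSIVs vs controls."""
    a = int(np.sum(corsiv_flags))
    b = len(corsiv_flags) - a
    c = int(np.sum(control_flags))
    d = len(control_flags) - c
    chi2, p = yates_2x2([[a, b], [c, d]])
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    return odds, chi2, p


# ---------------------------------------------------------------------------
# Genetic-variant concordance
# ---------------------------------------------------------------------------

def classify_variant(v: VariantRecord, subjects: tuple[str, str]) -> str | None:
    """'discordant' (GTs differ, both called), 'concordant' (equal, shared
    non-reference), else None."""
    ga = v.genotypes.get(subjects[0], "missing")
    gb = v.genotypes.get(subjects[1], "missing")
    if ga == "missing" or gb == "missing":
        return None
    if ga != gb:
        return "discordant"
    if ga == "hom_ref":
        return None
    return "concordant"


def count_variant_concordance(
    regions: Sequence[GenomicInterval],
    variants: Sequence[VariantRecord],
    subjects: tuple[str, str],
    window: int = 1000,
) -> tuple[int, int]:
    """(concordant, discordant) variant counts in windows centred on the
    regions' midpoints (start inclusive, end exclusive)."""
    half = window // 2
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    conc = disc = 0
    for iv in regions:
        mid = (iv.start + iv.end) // 2
        ws, we = mid - half, mid + half
        for v in by_chrom.get(iv.chrom, []):
            s, e = v.span
            if s < we and ws < e:
                kind = classify_variant(v, subjects)
                if kind == "concordant":
                    conc += 1
                elif kind == "discordant":
                    disc += 1
    return conc, disc


def variant_concordance_test(
    corsiv_counts: tuple[int, int], control_counts: tuple[int, int]
) -> tuple[float, float | None]:
    """2x2 chi-square of (concordant, discordant) x (CoRSIV, control)."""
    return yates_2x2([list(corsiv_counts), list(control_counts)])


# ---------------------------------------------------------------------------
# Repeat flank profile
# ---------------------------------------------------------------------------

def flank_strata(flank: int = 50_000, step: int = 5_000) -> list[str]:
    labels = ["overlap"]
    for lo in range(0, flank, step):
        labels.append(f"{lo // 1000}-{(lo + step) // 1000}kb")
    return labels


def repeat_flank_profile(
    regions: Sequence[GenomicInterval],
    repeats: Sequence[RepeatFeature],
    flank: int = 50_000,
    step: int = 5_000,
) -> pd.DataFrame:
    """Number of regions with >= 1 overlapping repeat, per repeat class and
    distance stratum.  'overlap' counts repeats intersecting the region
    itself; flank strata pool the two sides and exclude directly
    overlapping repeats (those belong to 'overlap' only)."""
    classes = sorted({r.repeat_class for r in repeats})
    labels = flank_strata(flank, step)
    counts = pd.DataFrame(0, index=classes, columns=labels)
    by_chrom: dict[str, list[RepeatFeature]] = {}
    for r in repeats:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    for iv in regions:
        seen: set[tuple[str, str]] = set()
        for r in by_chrom.get(iv.chrom, []):
            riv = r.interval
            if riv.overlaps(iv):
                seen.add((r.repeat_class, "overlap"))
                continue
            for k, lo in enumerate(range(0, flank, step)):
                hi = lo + step
                left = (riv.start < iv.start - lo) and (riv.end > iv.start - hi)
                right = (riv.start < iv.end + hi) and (riv.end > iv.end + lo)
                if left or right:
                    seen.add((r.repeat_class, labels[k + 1]))
        for cls, label in seen:
            counts.loc[cls, label] += 1
    return counts
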