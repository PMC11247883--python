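"""Readers and writers for the external text formats the pipeline touches.

On-disk conventions differ from the internal one (0-based half-open):
coverage files and VCF are 1-based on disk; BED and the annotation TSVs are
0-based half-open.  All conversions live here and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .types import (
    DMR,
    FormatError,
    GeneModel,
    Genotype,
    GenomicInterval,
    MethCount,
    MethylomeLibrary,
    RepeatFeature,
    VariantRecord,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Bismark-style coverage files
# ---------------------------------------------------------------------------

def read_coverage(
    path: str | Path,
    subject: str,
    tissue: str,
    germ_layer: str | None = None,
    cpg_positions: dict[str, np.ndarray] | None = None,
) -> MethylomeLibrary:
    """Read a Bismark-style coverage file into a :class:`MethylomeLibrary`.

    Expected columns (tab-delimited): chrom, start (1-based), end, %meth,
    count_methylated, count_unmethylated.  The %meth column is ignored and
    recomputed from counts on demand.

    If ``cpg_positions`` (0-based C positions per chromosome) is given,
    records landing one base downstream of a known CpG — i.e. reverse-strand
    G calls — are folded into the C site; duplicate positions are summed.
    """
    path = Path(path)
    records: list[MethCount] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"expected 6 tab-delimited columns, got {len(fields)}",
                    str(path), lineno,
                )
            chrom, start_s = fields[0], fields[1]
            try:
                start = int(start_s)
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise FormatError(f"non-numeric field: {exc}", str(path), lineno)
            if start < 1:
                raise FormatError(f"position {start} < 1", str(path), lineno)
            if n_meth < 0 or n_unmeth < 0:
                raise FormatError(
                    f"negative count ({n_meth}/{n_unmeth})", str(path), lineno
                )
            pos = start - 1  # to 0-based
            if cpg_positions is not None and chrom in cpg_positions:
                known = cpg_positions[chrom]
                i = np.searchsorted(known, pos)
                on_c = i < len(known) and known[i] == pos
                if not on_c and i > 0 and known[i - 1] == pos - 1:
                    pos = pos - 1  # G of the CpG: merge into the C site
            records.append(MethCount(chrom, pos, n_meth, n_unmeth))
    if not records:
        logger.warning("coverage file %s is empty", path)
    return MethylomeLibrary.from_records(subject, tissue, records, germ_layer)


def write_coverage(library: MethylomeLibrary, path: str | Path) -> None:
    """Write 1-based, tab-delimited coverage (round-trips with read_coverage)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in library.counts():
            depth = rec.depth
            pct = 100.0 * rec.n_meth / depth if depth > 0 else 0.0
            fh.write(
                f"{rec.chrom}\t{rec.pos + 1}\t{rec.pos + 1}\t{pct:.6g}"
                f"\t{rec.n_meth}\t{rec.n_unmeth}\n"
            )


# ---------------------------------------------------------------------------
# VCF (minimal subset)
# ---------------------------------------------------------------------------

_GT_CODE: dict[Genotype, str] = {
    "hom_ref": "0/0",
    "het": "0/1",
    "hom_alt": "1/1",
    "missing": "./.",
}


def _decode_gt(gt_field: str, alt_index: int) -> Genotype:
    gt = gt_field.split(":")[0].replace("|", "/")
    if gt in (".", "./."):
        return "missing"
    try:
        alleles = [int(a) if a != "." else -1 for a in gt.split("/")]
    except ValueError:
        return "missing"
    if len(alleles) == 1:
        alleles = alleles * 2
    if any(a < 0 for a in alleles):
        return "missing"
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt == 2:
        return "hom_alt"
    if n_alt == 1:
        return "het"
    return "hom_ref"


def read_variants(
    path: str | Path, min_quality: float = 0.0
) -> list[VariantRecord]:
    """Read a minimal VCF; drops records below ``min_quality`` (inclusive
    keep at the boundary), splits multi-allelic records into biallelics."""
    path = Path(path)
    subjects: list[str] = []
    out: list[VariantRecord] = []
    saw_header = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) > 9:
                    subjects = cols[9:]
                saw_header = True
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(
                    f"expected >= 8 VCF columns, got {len(fields)}",
                    str(path), lineno,
                )
            chrom, pos_s, _id, ref, alt_s, qual_s = fields[:6]
            try:
                pos = int(pos_s) - 1
                qual = float(qual_s) if qual_s != "." else float("nan")
            except ValueError as exc:
                raise FormatError(f"non-numeric field: {exc}", str(path), lineno)
            if subjects and len(fields) < 10 + len(subjects) - 1 + 0:
                if len(fields) - 9 < len(subjects):
                    raise FormatError(
                        f"{len(subjects)} subjects declared but only "
                        f"{max(0, len(fields) - 9)} genotype columns",
                        str(path), lineno,
                    )
            if not (qual >= min_quality):  # NaN qual also dropped
                continue
            alts = alt_s.split(",")
            for ai, alt in enumerate(alts, start=1):
                if alt in (".", "*"):
                    continue
                gts: dict[str, Genotype] = {}
                for si, subj in enumerate(subjects):
                    gts[subj] = _decode_gt(fields[9 + si], ai)
                out.append(
                    VariantRecord(chrom, pos, ref, alt, qual, gts)
                )
    if not saw_header:
        logger.warning("VCF %s has no #CHROM header line", path)
    return out


def write_variants(
    variants: Sequence[VariantRecord], subjects: Sequence[str], path: str | Path
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                  "FORMAT"] + list(subjects)
        fh.write("\t".join(header) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            row = [v.chrom, str(v.pos + 1), ".", v.ref, v.alt, f"{v.qual:.6g}",
                   "PASS", ".", "GT"]
            for s in subjects:
                row.append(_GT_CODE[v.genotypes.get(s, "missing")])
            fh.write("\t".join(row) + "\n")


def filter_population_variants(
    records: Iterable[VariantRecord], min_valid_gt: int, min_maf: float
) -> list[VariantRecord]:
    """Keep records with >= min_valid_gt non-missing genotypes and minor
    allele frequency >= min_maf (both thresholds inclusive)."""
    kept = []
    for rec in records:
        gts = [g for g in rec.genotypes.values() if g != "missing"]
        if len(gts) < min_valid_gt:
            continue
        alt_alleles = sum({"hom_ref": 0, "het": 1, "hom_alt": 2}[g] for g in gts)
        f = alt_alleles / (2 * len(gts))
        if min(f, 1.0 - f) >= min_maf:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# BED and annotation TSVs
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    path = Path(path)
    out: list[GenomicInterval] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("expected >= 3 BED columns", str(path), lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"non-numeric coordinate: {exc}", str(path), lineno)
            try:
                out.append(GenomicInterval(fields[0], start, end))
            except ValueError as exc:
                raise FormatError(str(exc), str(path), lineno)
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
) -> None:
    path = Path(path)
    ivs = list(intervals)
    with path.open("w") as fh:
        for i, iv in enumerate(ivs):
            row = f"{iv.chrom}\t{iv.start}\t{iv.end}"
            if names is not None:
                row += f"\t{names[i]}"
            fh.write(row + "\n")


def read_genes(path: str | Path) -> list[GeneModel]:
    """refGene-style TSV: chrom, strand, txStart, txEnd, name (0-based)."""
    path = Path(path)
    out: list[GeneModel] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FormatError("expected 5 gene columns", str(path), lineno)
            try:
                out.append(
                    GeneModel(fields[0], fields[1], int(fields[2]),
                              int(fields[3]), fields[4])
                )
            except ValueError as exc:
                raise FormatError(str(exc), str(path), lineno)
    return out


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\t{g.name}\n")


def read_repeats(path: str | Path) -> list[RepeatFeature]:
    """RepeatMasker-derived TSV: chrom, start, end, class, family."""
    path = Path(path)
    out: list[RepeatFeature] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError("expected >= 4 repeat columns", str(path), lineno)
            family = fields[4] if len(fields) > 4 else ""
            try:
                out.append(
                    RepeatFeature(
                        GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                        fields[3], family,
                    )
                )
            except ValueError as exc:
                raise FormatError(str(exc), str(path), lineno)
    return out


def write_repeats(repeats: Iterable[RepeatFeature], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in repeats:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.repeat_class}"
                     f"\t{r.repeat_family}\n")


def read_dmrs(path: str | Path, tissue: str | None = None) -> list[DMR]:
    """DMR TSV: chrom, start, end[, tissue, direction(+/-), mean_diff]."""
    path = Path(path)
    out: list[DMR] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError("expected >= 3 DMR columns", str(path), lineno)
            t = fields[3] if len(fields) > 3 and fields[3] else (tissue or "")
            direction = 1
            if len(fields) > 4 and fields[4] in ("+", "-"):
                direction = 1 if fields[4] == "+" else -1
            mean_diff = float(fields[5]) if len(fields) > 5 else 0.0
            try:
                out.append(
                    DMR(GenomicInterval(fields[0], int(fields[1]), int(fields[2])),
                        t, direction, mean_diff)
                )
            except ValueError as exc:
                raise FormatError(str(exc), str(path), lineno)
    return out


def write_dmrs(dmrs: Iterable[DMR], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for d in dmrs:
            iv = d.interval
            sign = "+" if d.direction > 0 else "-"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{d.tissue}\t{sign}"
                     f"\t{d.mean_diff:.6g}\n")
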