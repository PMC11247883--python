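"""Synthetic multi-tissue methylome cohorts with a known planted truth.

Generates a toy genome (chromosome sizes + CpG coordinates), per-(subject,
tissue) beta-binomial read counts around a shared baseline profile, planted
regions of three kinds (systemic inter-individual variants, tissue-specific
DMR-like regions, inert nulls), CpG-destroying SNPs with genotypes, and
simple gene/repeat/CpG-island annotation tracks.

Determinism: every random draw comes from a stream keyed by
``(seed, purpose, chrom, ...)``, so per-chromosome generation is
order-independent and a fixed seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import meth_io
from .types import (
    ConfigurationError,
    GeneModel,
    Genotype,
    GenomicInterval,
    MethylomeLibrary,
    RepeatFeature,
    VariantRecord,
)

DEFAULT_TISSUES = ("cortex", "lung", "wbc")
GERM_LAYERS = {"cortex": "ectoderm", "lung": "endoderm", "wbc": "mesoderm"}

KIND_SYSTEMIC = "systemic_variant"
KIND_DMR = "tissue_dmr"
KIND_NULL = "null"


def _rng(seed: int, *keys) -> np.random.Generator:
    """Independent stream keyed by (seed, *keys); strings hashed via crc32."""
    entropy = [int(seed) & 0xFFFFFFFF]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class SyntheticGenome:
    """Chromosome sizes plus sorted forward-strand CpG (C) coordinates."""

    chrom_sizes: Mapping[str, int]
    cpg_positions: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, size in self.chrom_sizes.items():
            pos = np.asarray(self.cpg_positions.get(chrom, []))
            if len(pos) == 0:
                raise ValueError(f"no CpGs on {chrom}")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"CpG positions not strictly increasing on {chrom}")
            if pos[0] < 0 or pos[-1] >= size:
                raise ValueError(f"CpG position out of bounds on {chrom}")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def n_cpgs(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return len(self.cpg_positions[chrom])
        return sum(len(p) for p in self.cpg_positions.values())

    def cpgs_in(self, interval: GenomicInterval) -> np.ndarray:
        pos = self.cpg_positions[interval.chrom]
        lo, hi = np.searchsorted(pos, [interval.start, interval.end])
        return pos[lo:hi]


@dataclass(frozen=True)
class PlantedRegionTruth:
    """Ground truth for one planted region.

    ``subject_offsets`` maps subject id to a methylation-fraction offset
    applied in every affected tissue.  Systemic regions affect all tissues;
    tissue-DMR regions affect a strict subset (same offset in all subjects);
    null regions carry no offsets.
    """

    interval: GenomicInterval
    kind: str
    affected_tissues: tuple[str, ...]
    subject_offsets: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in (KIND_SYSTEMIC, KIND_DMR, KIND_NULL):
            raise ValueError(f"unknown planted-region kind {self.kind!r}")
        if self.kind == KIND_NULL and self.subject_offsets:
            raise ValueError("null regions must not carry offsets")


@dataclass(frozen=True)
class SimulationParams:
    chrom_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000}
    )
    n_subjects: int = 2
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    cpg_rate: float = 0.03           # expected CpGs per bp
    depth_mean: float = 18.0         # mirrors the ~18x screen coverage
    beta_binomial_rho: float = 0.02  # within-site overdispersion, 0 => binomial
    baseline_meth: float | None = None  # constant baseline; None => bimodal draw
    tissue_effect_sd: float = 0.02   # genome-wide tissue signature
    n_planted_systemic: int = 0
    n_planted_dmr: int = 0
    n_planted_null: int = 0
    systemic_effect: float = 0.25
    systemic_effect_max: float | None = None  # draw U(effect, max) when set
    dmr_effect: float = 0.25
    region_span: int = 300
    min_region_cpgs: int = 6
    cpg_snp_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not self.tissues:
            raise ConfigurationError("at least one tissue required")
        if not 0 < self.cpg_rate < 0.5:
            raise ConfigurationError("cpg_rate must be in (0, 0.5)")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        for name in ("beta_binomial_rho", "cpg_snp_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.baseline_meth is not None and not 0 <= self.baseline_meth <= 1:
            raise ConfigurationError("baseline_meth must be in [0, 1]")
        if self.region_span <= 0 or self.min_region_cpgs < 1:
            raise ConfigurationError("invalid planted-region geometry")

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(f"s{i + 1}" for i in range(self.n_subjects))


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def generate_genome(params: SimulationParams) -> SyntheticGenome:
    """Draw CpG coordinates with geometric spacing (mean 1/cpg_rate, min 2)."""
    cpgs: dict[str, np.ndarray] = {}
    for chrom, size in params.chrom_sizes.items():
        rng = _rng(params.seed, "genome", chrom)
        # gap = 1 + Geometric(p) >= 2; E[gap] = 1 + 1/p = 1/cpg_rate
        p = params.cpg_rate / (1.0 - params.cpg_rate)
        positions: list[np.ndarray] = []
        last = 0
        while last < size - 1:
            n_draw = max(64, int((size - last) * params.cpg_rate * 1.2))
            gaps = 1 + rng.geometric(p, size=n_draw)
            pos = last + np.cumsum(gaps)
            positions.append(pos)
            last = int(pos[-1])
        pos = np.concatenate(positions)
        pos = pos[pos < size - 1]  # the G at pos+1 must also fit
        if len(pos) == 0:
            raise ConfigurationError(
                f"chromosome {chrom} too short for cpg_rate={params.cpg_rate}"
            )
        cpgs[chrom] = pos.astype(np.int64)
    return SyntheticGenome(dict(params.chrom_sizes), cpgs)


# ---------------------------------------------------------------------------
# Planted truth
# ---------------------------------------------------------------------------

def _candidate_region_starts(
    genome: SyntheticGenome, params: SimulationParams
) -> list[tuple[str, int]]:
    span = params.region_span
    out: list[tuple[str, int]] = []
    for chrom, size in genome.chrom_sizes.items():
        pos = genome.cpg_positions[chrom]
        starts = np.arange(100, max(100, size - span), 100)
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, starts + span)
        ok = (hi - lo) >= params.min_region_cpgs
        out.extend((chrom, int(s)) for s in starts[ok])
    return out


def plant_regions(
    genome: SyntheticGenome, params: SimulationParams
) -> list[PlantedRegionTruth]:
    """Choose disjoint intervals and assign systemic/DMR/null effects."""
    n_total = params.n_planted_systemic + params.n_planted_dmr + params.n_planted_null
    if n_total == 0:
        return []
    rng = _rng(params.seed, "plant")
    candidates = _candidate_region_starts(genome, params)
    order = rng.permutation(len(candidates))
    chosen: list[tuple[str, int]] = []
    # 200 bp buffer keeps planted blocks from fusing with a neighbour
    occupied: dict[str, list[tuple[int, int]]] = {}
    for idx in order:
        chrom, s = candidates[idx]
        e = s + params.region_span
        clash = any(s < oe + 200 and os_ - 200 < e for os_, oe in occupied.get(chrom, []))
        if clash:
            continue
        occupied.setdefault(chrom, []).append((s, e))
        chosen.append((chrom, s))
        if len(chosen) == n_total:
            break
    if len(chosen) < n_total:
        raise ConfigurationError(
            f"genome too small: placed {len(chosen)} of {n_total} planted regions"
        )
    kinds = (
        [KIND_SYSTEMIC] * params.n_planted_systemic
        + [KIND_DMR] * params.n_planted_dmr
        + [KIND_NULL] * params.n_planted_null
    )
    rng.shuffle(kinds)
    subjects = params.subjects
    truth: list[PlantedRegionTruth] = []
    for (chrom, s), kind in zip(chosen, kinds):
        iv = GenomicInterval(chrom, s, s + params.region_span)
        if kind == KIND_SYSTEMIC:
            if params.n_subjects == 2:
                sign = rng.choice([-1.0, 1.0])
                hi = params.systemic_effect_max or params.systemic_effect
                mag = rng.uniform(params.systemic_effect, hi)
                offsets = {subjects[1]: float(sign * mag)}
            else:
                # per-animal systemic level, identical across tissues
                offsets = {
                    s_: float(rng.uniform(-params.systemic_effect,
                                          params.systemic_effect))
                    for s_ in subjects
                }
            truth.append(PlantedRegionTruth(iv, kind, params.tissues, offsets))
        elif kind == KIND_DMR:
            tissue = params.tissues[rng.integers(len(params.tissues))]
            sign = rng.choice([-1.0, 1.0])
            offsets = {s_: float(sign * params.dmr_effect) for s_ in subjects}
            truth.append(PlantedRegionTruth(iv, kind, (tissue,), offsets))
        else:
            truth.append(PlantedRegionTruth(iv, kind, (), {}))
    return truth


# ---------------------------------------------------------------------------
# Read counts
# ---------------------------------------------------------------------------

def _baseline(
    genome: SyntheticGenome,
    params: SimulationParams,
    chrom: str,
    truth: Sequence[PlantedRegionTruth] = (),
) -> np.ndarray:
    n = genome.n_cpgs(chrom)
    if params.baseline_meth is not None:
        base = np.full(n, params.baseline_meth)
    else:
        rng = _rng(params.seed, "baseline", chrom)
        low = rng.random(n) < 0.25
        base = np.where(low, rng.beta(2.0, 18.0, n), rng.beta(18.0, 3.0, n))
    # planted regions sit at a mid-range level so +-effect offsets cannot
    # clip against 0/1 (identical across subjects and tissues)
    pos = genome.cpg_positions[chrom]
    for t in truth:
        if t.interval.chrom != chrom:
            continue
        r = _rng(params.seed, "plantbase", chrom, t.interval.start)
        lo, hi = np.searchsorted(pos, [t.interval.start, t.interval.end])
        base[lo:hi] = r.uniform(0.35, 0.55)
    return base


def _tissue_effect(genome: SyntheticGenome, params: SimulationParams,
                   tissue: str, chrom: str) -> np.ndarray:
    if params.tissue_effect_sd <= 0:
        return np.zeros(genome.n_cpgs(chrom))
    rng = _rng(params.seed, "tissue", tissue, chrom)
    return rng.normal(0.0, params.tissue_effect_sd, genome.n_cpgs(chrom))


def _planted_offsets(
    genome: SyntheticGenome,
    truth: Sequence[PlantedRegionTruth],
    subject: str,
    tissue: str,
    chrom: str,
) -> np.ndarray:
    off = np.zeros(genome.n_cpgs(chrom))
    pos = genome.cpg_positions[chrom]
    for t in truth:
        if t.interval.chrom != chrom or tissue not in t.affected_tissues:
            continue
        delta = t.subject_offsets.get(subject, 0.0)
        if delta == 0.0:
            continue
        lo, hi = np.searchsorted(pos, [t.interval.start, t.interval.end])
        off[lo:hi] += delta
    return off


def _draw_counts(
    rng: np.random.Generator, p: np.ndarray, depth: np.ndarray, rho: float
) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    if rho <= 0:
        return rng.binomial(depth, p)
    safe = np.clip(p, 1e-9, 1 - 1e-9)
    a = safe * (1.0 - rho) / rho
    b = (1.0 - safe) * (1.0 - rho) / rho
    pp = rng.beta(a, b)
    pp = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, pp))
    return rng.binomial(depth, pp)


def _plant_cpg_snps(
    genome: SyntheticGenome,
    params: SimulationParams,
    truth: Sequence[PlantedRegionTruth],
    subjects: Sequence[str],
) -> tuple[list[VariantRecord], dict[str, dict[str, np.ndarray]]]:
    """Plant homozygous-alternate CpG-destroying SNPs in single subjects.

    Returns (variant records, zero_sites[subject][chrom] -> CpG positions
    forced to 0% methylation in that subject).  Planted regions are avoided
    so CpG-SNP masking cannot eat the truth channel.
    """
    variants: list[VariantRecord] = []
    zero_sites: dict[str, dict[str, list[int]]] = {s: {} for s in subjects}
    if params.cpg_snp_rate <= 0:
        return variants, {s: {} for s in subjects}
    planted_by_chrom: dict[str, list[PlantedRegionTruth]] = {}
    for t in truth:
        planted_by_chrom.setdefault(t.interval.chrom, []).append(t)
    for chrom in genome.chroms:
        rng = _rng(params.seed, "snp", chrom)
        pos = genome.cpg_positions[chrom]
        pick = rng.random(len(pos)) < params.cpg_snp_rate
        for t in planted_by_chrom.get(chrom, []):
            lo, hi = np.searchsorted(pos, [t.interval.start, t.interval.end])
            pick[lo:hi] = False
        for cpg in pos[pick]:
            subj = subjects[int(rng.integers(len(subjects)))]
            on_g = bool(rng.random() < 0.5)
            vpos = int(cpg) + (1 if on_g else 0)
            ref, alt = ("G", "A") if on_g else ("C", "T")
            qual = float(30.0 + 30.0 * rng.random())
            gts: dict[str, Genotype] = {
                s: ("hom_alt" if s == subj else "hom_ref") for s in subjects
            }
            variants.append(VariantRecord(chrom, vpos, ref, alt, qual, gts))
            zero_sites[subj].setdefault(chrom, []).append(int(cpg))
    out = {
        s: {c: np.asarray(sorted(v), dtype=np.int64) for c, v in per.items()}
        for s, per in zero_sites.items()
    }
    return variants, out


def _make_library(
    genome: SyntheticGenome,
    params: SimulationParams,
    subject: str,
    tissue: str,
    truth: Sequence[PlantedRegionTruth],
    zero_sites: Mapping[str, np.ndarray],
) -> MethylomeLibrary:
    lib = MethylomeLibrary(subject, tissue, GERM_LAYERS.get(tissue))
    for chrom in genome.chroms:
        rng = _rng(params.seed, "lib", subject, tissue, chrom)
        pos = genome.cpg_positions[chrom]
        depth = rng.poisson(params.depth_mean, len(pos))
        p = (
            _baseline(genome, params, chrom, truth)
            + _tissue_effect(genome, params, tissue, chrom)
            + _planted_offsets(genome, truth, subject, tissue, chrom)
        )
        meth = _draw_counts(rng, p, depth, params.beta_binomial_rho)
        zeros = zero_sites.get(chrom)
        if zeros is not None and len(zeros):
            idx = np.searchsorted(pos, zeros)
            idx = idx[(idx < len(pos)) & (pos[np.minimum(idx, len(pos) - 1)] == zeros)]
            meth[idx] = 0  # destroyed CpG reads as fully unmethylated
        lib.set_chrom(chrom, pos, meth, depth - meth)
    return lib


def generate_cohort(
    genome: SyntheticGenome, params: SimulationParams
) -> tuple[list[MethylomeLibrary], list[PlantedRegionTruth], list[VariantRecord]]:
    """Full cohort: one library per (subject, tissue), truth and variants."""
    truth = plant_regions(genome, params)
    subjects = params.subjects
    variants, zero_sites = _plant_cpg_snps(genome, params, truth, subjects)
    libraries = [
        _make_library(genome, params, s, t, truth, zero_sites.get(s, {}))
        for s in subjects
        for t in params.tissues
    ]
    return libraries, truth, variants


def generate_two_group_cohort(
    genome: SyntheticGenome,
    params: SimulationParams,
    group_effect_at: Sequence[GenomicInterval],
    group_effect: float = 0.2,
    affected_tissues: Sequence[str] | None = None,
    group_labels: tuple[str, str] = ("ivp", "moet"),
) -> tuple[dict[str, list[MethylomeLibrary]], list[PlantedRegionTruth]]:
    """Two groups of ``params.n_subjects`` animals each; group 1 receives a
    methylation offset at the given intervals (all tissues unless a subset
    is named).  An empty interval list yields a valid null cohort."""
    if params.n_subjects < 2:
        raise ConfigurationError("two-group cohorts need >= 2 subjects per group")
    tissues = tuple(affected_tissues) if affected_tissues else params.tissues
    unknown = set(tissues) - set(params.tissues)
    if unknown:
        raise ConfigurationError(f"unknown tissues {sorted(unknown)}")
    g1 = tuple(f"{group_labels[0]}{i + 1}" for i in range(params.n_subjects))
    g2 = tuple(f"{group_labels[1]}{i + 1}" for i in range(params.n_subjects))
    kind = KIND_SYSTEMIC if set(tissues) == set(params.tissues) else KIND_DMR
    truth = [
        PlantedRegionTruth(iv, kind, tissues, {s: group_effect for s in g1})
        for iv in group_effect_at
    ]
    cohort: dict[str, list[MethylomeLibrary]] = {group_labels[0]: [],
                                                 group_labels[1]: []}
    for label, members in ((group_labels[0], g1), (group_labels[1], g2)):
        for s in members:
            for t in params.tissues:
                cohort[label].append(_make_library(genome, params, s, t, truth, {}))
    return cohort, truth


def truth_to_dmrs(
    truth: Sequence[PlantedRegionTruth], tissues: Sequence[str]
) -> list["meth_io.DMR"]:
    """Emit the planted group-effect regions as per-tissue DMR records."""
    from .types import DMR

    out = []
    for t in truth:
        if not t.subject_offsets:
            continue
        delta = float(np.mean(list(t.subject_offsets.values())))
        for tissue in t.affected_tissues:
            if tissue in tissues:
                out.append(DMR(t.interval, tissue, 1 if delta >= 0 else -1,
                               abs(delta)))
    return out


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

def generate_annotations(
    genome: SyntheticGenome, params: SimulationParams
) -> tuple[list[GeneModel], list[RepeatFeature], list[GenomicInterval]]:
    """Seeded toy gene models, repeat intervals and CpG islands."""
    genes: list[GeneModel] = []
    repeats: list[RepeatFeature] = []
    islands: list[GenomicInterval] = []
    classes = [("LINE", "L1"), ("LINE", "BovB"), ("SINE", "BOV-A2"),
               ("LTR", "ERV1"), ("DNA", "hAT")]
    gi = 0
    for chrom, size in genome.chrom_sizes.items():
        rng = _rng(params.seed, "annot", chrom)
        cursor = int(rng.integers(1_000, 10_000))
        while cursor < size - 12_000:
            length = int(rng.integers(2_000, 10_000))
            strand = "+" if rng.random() < 0.5 else "-"
            gi += 1
            g = GeneModel(chrom, strand, cursor, cursor + length, f"gene{gi}")
            genes.append(g)
            if rng.random() < 0.5:
                s = max(0, g.tss - int(rng.integers(0, 800)))
                islands.append(GenomicInterval(chrom, s, s + int(rng.integers(500, 2_000))))
            cursor += length + int(rng.integers(5_000, 20_000))
        n_rep = max(1, size // 5_000)
        starts = rng.integers(0, size - 2_100, n_rep)
        for s in np.sort(starts):
            length = int(rng.integers(200, 2_000))
            cls, fam = classes[int(rng.integers(len(classes)))]
            repeats.append(
                RepeatFeature(GenomicInterval(chrom, int(s), int(s) + length),
                              cls, fam)
            )
    return genes, repeats, islands


# ---------------------------------------------------------------------------
# On-disk cohort
# ---------------------------------------------------------------------------

def write_genome(genome: SyntheticGenome, outdir: str | Path) -> None:
    outdir = Path(outdir)
    with (outdir / "chrom_sizes.tsv").open("w") as fh:
        for chrom, size in genome.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")
    with (outdir / "cpg_positions.tsv").open("w") as fh:
        for chrom in genome.chroms:
            for p in genome.cpg_positions[chrom]:
                fh.write(f"{chrom}\t{p}\n")


def read_genome(indir: str | Path) -> SyntheticGenome:
    indir = Path(indir)
    sizes: dict[str, int] = {}
    with (indir / "chrom_sizes.tsv").open() as fh:
        for line in fh:
            chrom, size = line.split("\t")
            sizes[chrom] = int(size)
    cpgs: dict[str, list[int]] = {}
    with (indir / "cpg_positions.tsv").open() as fh:
        for line in fh:
            chrom, p = line.split("\t")
            cpgs.setdefault(chrom, []).append(int(p))
    return SyntheticGenome(
        sizes, {c: np.asarray(v, dtype=np.int64) for c, v in cpgs.items()}
    )


def write_cohort(
    outdir: str | Path,
    genome: SyntheticGenome,
    libraries: Sequence[MethylomeLibrary],
    truth: Sequence[PlantedRegionTruth],
    variants: Sequence[VariantRecord],
    subjects: Sequence[str],
) -> dict[str, str]:
    """Write coverage files, VCF, truth BEDs and genome tables; returns a
    name->path manifest fragment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    write_genome(genome, outdir)
    manifest["chrom_sizes"] = str(outdir / "chrom_sizes.tsv")
    manifest["cpg_positions"] = str(outdir / "cpg_positions.tsv")
    for lib in libraries:
        path = outdir / f"{lib.subject}_{lib.tissue}.cov"
        meth_io.write_coverage(lib, path)
        manifest[f"coverage:{lib.subject}:{lib.tissue}"] = str(path)
    vcf = outdir / "genotypes.vcf"
    meth_io.write_variants(variants, subjects, vcf)
    manifest["vcf"] = str(vcf)
    for kind in (KIND_SYSTEMIC, KIND_DMR, KIND_NULL):
        ivs = [t.interval for t in truth if t.kind == kind]
        path = outdir / f"truth_{kind}.bed"
        meth_io.write_bed(ivs, path)
        manifest[f"truth:{kind}"] = str(path)
    return manifest


def null_params(params: SimulationParams) -> SimulationParams:
    """Same cohort geometry with every planted effect removed."""
    return replace(
        params, n_planted_systemic=0, n_planted_dmr=0, n_planted_null=0,
        cpg_snp_rate=0.0,
    )
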