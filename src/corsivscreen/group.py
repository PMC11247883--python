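"""Two-group (e.g. embryo-culture vs in-vivo control) comparisons at
regions, direction-bias tests, clustering sanity checks and the
inter-tissue correlation validation rule."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .context import yates_2x2
from .types import DMR, GenomicInterval, MethylomeLibrary

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# DMR overlap
# ---------------------------------------------------------------------------

def overlap_is_valid(region: GenomicInterval, dmr: DMR | GenomicInterval) -> bool:
    """Overlap counts when it spans at least half of the smaller feature."""
    div = dmr.interval if isinstance(dmr, DMR) else dmr
    inter = region.intersection_size(div)
    if inter == 0:
        return False
    return inter >= 0.5 * min(region.size, div.size)


def dmr_enrichment(
    corsivs: Sequence[GenomicInterval],
    controls: Sequence[GenomicInterval],
    dmrs_by_tissue: Mapping[str, Sequence[DMR]],
) -> pd.DataFrame:
    """Per tissue: how many CoRSIVs / controls have >= 1 valid DMR overlap,
    plus a Yates chi-square on region-set x overlap."""
    rows = []
    for tissue, dmrs in dmrs_by_tissue.items():
        n_cor = sum(any(overlap_is_valid(r, d) for d in dmrs) for r in corsivs)
        n_ctl = sum(any(overlap_is_valid(r, d) for d in dmrs) for r in controls)
        chi2, p = yates_2x2(
            [[n_cor, len(corsivs) - n_cor], [n_ctl, len(controls) - n_ctl]]
        )
        rows.append({
            "tissue": tissue, "n_corsiv_overlap": n_cor,
            "n_control_overlap": n_ctl, "n_corsiv": len(corsivs),
            "n_control": len(controls), "chi2": chi2, "p": p,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Read-level per-region test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionGroupTest:
    region_id: str
    table: tuple[tuple[int, int], tuple[int, int]]  # rows meth/unmeth, cols g1/g2
    chi2: float
    p: float
    direction: int          # sign of (group1 meth fraction - group2's)
    degenerate: bool
    p_adj: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_adj is not None and self.p_adj < 0.05


def region_read_counts(
    region: GenomicInterval, libraries: Sequence[MethylomeLibrary]
) -> tuple[int, int]:
    """(methylated, unmethylated) reads summed over all region CpGs and
    libraries."""
    meth = unmeth = 0
    for lib in libraries:
        pos, m, u = lib.chrom_arrays(region.chrom)
        lo, hi = np.searchsorted(pos, [region.start, region.end])
        meth += int(m[lo:hi].sum())
        unmeth += int(u[lo:hi].sum())
    return meth, unmeth


def region_read_test(
    region: GenomicInterval,
    group1_libs: Sequence[MethylomeLibrary],
    group2_libs: Sequence[MethylomeLibrary],
    region_id: str | None = None,
) -> RegionGroupTest:
    """Yates-corrected chi-square on pooled methylated/unmethylated reads.

    Degenerate margins (a group without reads, or all reads one way) give
    chi2 = 0, p = 1, flagged, so genome-scale sweeps never abort."""
    m1, u1 = region_read_counts(region, group1_libs)
    m2, u2 = region_read_counts(region, group2_libs)
    table = ((m1, m2), (u1, u2))
    chi2, p = yates_2x2(np.asarray(table))
    degenerate = p is None
    if degenerate:
        chi2, p = 0.0, 1.0
    f1 = m1 / (m1 + u1) if m1 + u1 > 0 else 0.0
    f2 = m2 / (m2 + u2) if m2 + u2 > 0 else 0.0
    return RegionGroupTest(
        region_id or str(region), table, chi2, p,
        int(np.sign(f1 - f2)), degenerate,
    )


def adjust_pvalues(pvals: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment; 'fdr_bh' (default) or 'bonferroni'."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method=method)[1]


def attach_adjusted(
    tests: Sequence[RegionGroupTest], method: str = "fdr_bh"
) -> list[RegionGroupTest]:
    """Return copies carrying p_adj (adjusted jointly across the input)."""
    adj = adjust_pvalues([t.p for t in tests], method=method)
    return [
        RegionGroupTest(t.region_id, t.table, t.chi2, t.p, t.direction,
                        t.degenerate, float(a))
        for t, a in zip(tests, adj)
    ]


def significant_region_enrichment(
    corsiv_tests: Sequence[RegionGroupTest],
    control_tests: Sequence[RegionGroupTest],
    alpha: float = 0.05,
) -> dict:
    """2x2 Yates chi-square: (significant at adjusted alpha / not) x
    (CoRSIV / control)."""
    n_sig_c = sum(t.p_adj is not None and t.p_adj < alpha for t in corsiv_tests)
    n_sig_k = sum(t.p_adj is not None and t.p_adj < alpha for t in control_tests)
    table = [[n_sig_c, len(corsiv_tests) - n_sig_c],
             [n_sig_k, len(control_tests) - n_sig_k]]
    chi2, p = yates_2x2(table)
    return {
        "table": table, "chi2": chi2, "p": p,
        "n_sig_corsiv": n_sig_c, "n_sig_control": n_sig_k,
        "n_corsiv": len(corsiv_tests), "n_control": len(control_tests),
    }


def per_tissue_and_combined_enrichment(
    tests_by_tissue: Mapping[str, tuple[Sequence[RegionGroupTest],
                                        Sequence[RegionGroupTest]]],
    alpha: float = 0.05,
) -> dict:
    """Per-tissue enrichment plus one pooled table (sum of the per-tissue
    tables)."""
    out: dict = {"per_tissue": {}}
    pooled = np.zeros((2, 2), dtype=int)
    for tissue, (ct, kt) in tests_by_tissue.items():
        res = significant_region_enrichment(ct, kt, alpha)
        out["per_tissue"][tissue] = res
        pooled += np.asarray(res["table"])
    chi2, p = yates_2x2(pooled)
    out["combined"] = {"table": pooled.tolist(), "chi2": chi2, "p": p}
    return out


# ---------------------------------------------------------------------------
# Direction bias
# ---------------------------------------------------------------------------

def direction_bias_test(signed_values: Sequence[float]) -> float:
    """Exact two-sided sign test (binomial, p0 = 0.5) on nonzero signs."""
    arr = np.asarray(signed_values, dtype=float)
    n_pos = int((arr > 0).sum())
    n_neg = int((arr < 0).sum())
    n = n_pos + n_neg
    if n == 0:
        raise ValueError("direction bias test needs at least one nonzero value")
    return float(stats.binomtest(n_pos, n, 0.5).pvalue)


# ---------------------------------------------------------------------------
# Clustering sanity check
# ---------------------------------------------------------------------------

def region_methylation_matrix(
    regions: Sequence[GenomicInterval], libraries: Sequence[MethylomeLibrary]
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Regions x libraries matrix of read-weighted %meth; complete-case
    rows only (a region with any zero-depth library is dropped)."""
    keys = [lib.key for lib in libraries]
    rows = []
    for iv in regions:
        vals = []
        for lib in libraries:
            m, u = region_read_counts(iv, [lib])
            vals.append(100.0 * m / (m + u) if m + u > 0 else np.nan)
        rows.append(vals)
    mat = np.asarray(rows, dtype=float)
    mat = mat[~np.isnan(mat).any(axis=1)]
    return mat, keys


def _is_clean_cut(assignment: np.ndarray, groups: Sequence[str]) -> bool:
    """True when cluster labels and group labels induce the same partition."""
    by_group: dict[str, set[int]] = {}
    for a, g in zip(assignment, groups):
        by_group.setdefault(g, set()).add(int(a))
    labels_used = [v for v in by_group.values()]
    if any(len(v) != 1 for v in labels_used):
        return False
    flat = [next(iter(v)) for v in labels_used]
    return len(set(flat)) == len(flat)


def cluster_libraries(
    matrix: np.ndarray,
    subjects: Sequence[str],
    tissues: Sequence[str],
    linkage_method: str = "average",
) -> tuple[np.ndarray, str]:
    """Hierarchical clustering of library columns (Euclidean distance).

    Returns (linkage matrix, label): 'by_tissue' if cutting at k=#tissues
    recovers the tissue partition, 'by_individual' for the subject
    partition, 'mixed' otherwise (including degenerate inputs).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[1] < 2:
        raise ValueError("need at least two libraries to cluster")
    dists = pdist(matrix.T, metric="euclidean")
    z = hierarchy.linkage(dists, method=linkage_method)
    if np.allclose(dists, 0):
        return z, "mixed"
    label = "mixed"
    n_tissues = len(set(tissues))
    n_subjects = len(set(subjects))
    tissue_cut = hierarchy.fcluster(z, t=n_tissues, criterion="maxclust")
    subject_cut = hierarchy.fcluster(z, t=n_subjects, criterion="maxclust")
    by_tissue = _is_clean_cut(tissue_cut, list(tissues))
    by_subject = _is_clean_cut(subject_cut, list(subjects))
    if by_tissue and not by_subject:
        label = "by_tissue"
    elif by_subject and not by_tissue:
        label = "by_individual"
    elif by_tissue and by_subject:
        label = "mixed"
    return z, label


# ---------------------------------------------------------------------------
# Validation criterion (inter-tissue correlation)
# ---------------------------------------------------------------------------

DEFAULT_TISSUE_PAIRS = (("liver", "kidney"), ("kidney", "cortex"),
                        ("liver", "cortex"))


def validate_regions(
    region_meth: Mapping[str, pd.DataFrame],
    tissue_pairs: Sequence[tuple[str, str]] = DEFAULT_TISSUE_PAIRS,
    r_threshold: float = 0.71,
    blood_column: str = "blood",
) -> pd.DataFrame:
    """Validate regions by inter-tissue Pearson correlation across animals.

    ``region_meth`` maps region id -> DataFrame (animals x tissues) of
    methylation levels.  A region is validated when the maximum of the
    pairwise correlations reaches ``r_threshold`` (inclusive); zero-variance
    tissues make that pair undefined and excluded.  For validated regions
    with a blood column, blood-vs-tissue correlations are reported too.
    """
    rows = []
    for rid, df in region_meth.items():
        if len(df) < 3:
            raise ValueError(f"region {rid}: need >= 3 animals")
        rs: dict[str, float] = {}
        for t1, t2 in tissue_pairs:
            a, b = df[t1].to_numpy(float), df[t2].to_numpy(float)
            if np.std(a) == 0 or np.std(b) == 0:
                rs[f"r_{t1}_{t2}"] = np.nan
                continue
            rs[f"r_{t1}_{t2}"] = float(stats.pearsonr(a, b)[0])
        defined = [v for v in rs.values() if not np.isnan(v)]
        max_r = max(defined) if defined else np.nan
        validated = bool(defined) and max_r >= r_threshold
        row = {"region": rid, **rs, "max_r": max_r, "validated": validated}
        if validated and blood_column in df.columns:
            blood = df[blood_column].to_numpy(float)
            tissues = {t for pair in tissue_pairs for t in pair}
            for t in sorted(tissues):
                a = df[t].to_numpy(float)
                if np.std(a) == 0 or np.std(blood) == 0:
                    row[f"r_blood_{t}"] = np.nan
                else:
                    row[f"r_blood_{t}"] = float(stats.pearsonr(blood, a)[0])
        rows.append(row)
    return pd.DataFrame(rows)
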