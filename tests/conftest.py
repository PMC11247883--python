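import numpy as np
import pandas as pd
import pytest

from corsivscreen import (
    ScreenParams,
    SimulationParams,
    generate_cohort,
    generate_genome,
)
from corsivscreen.binning import library_column


@pytest.fixture(scope="session")
def screen_params():
    return ScreenParams()


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(
        chrom_sizes={"chr1": 400_000, "chr2": 200_000},
        n_planted_systemic=8,
        n_planted_dmr=8,
        n_planted_null=8,
        depth_mean=20.0,
        systemic_effect=0.25,
        systemic_effect_max=0.30,
        beta_binomial_rho=0.01,
        region_span=600,
        min_region_cpgs=10,
        cpg_snp_rate=0.002,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_genome(small_params):
    return generate_genome(small_params)


@pytest.fixture(scope="session")
def small_cohort(small_genome, small_params):
    libraries, truth, variants = generate_cohort(small_genome, small_params)
    return {
        "genome": small_genome,
        "params": small_params,
        "libraries": libraries,
        "truth": truth,
        "variants": variants,
        "subjects": small_params.subjects,
        "tissues": small_params.tissues,
    }


def make_bin_table(
    entries,
    subjects=("s1", "s2"),
    tissues=("cortex", "lung", "wbc"),
    chrom="chr1",
    bin_size=100,
):
    """Build a minimal screen-bin table for block-builder tests.

    ``entries``: list of (start, residual-or-None[, lib_meth dict]).  Library
    read sums default to depth 100 at the stated %meth for every library so
    block-level values are well defined.
    """
    rows = []
    for entry in entries:
        start, residual = entry[0], entry[1]
        meths = entry[2] if len(entry) > 2 else {}
        row = {
            "chrom": chrom,
            "start": start,
            "end": start + bin_size,
            "n_cpg": 3,
            "residual": np.nan if residual is None else residual,
            "enters_screen": residual is not None,
            "all_adequate": residual is not None,
        }
        for s in subjects:
            for t in tissues:
                pct = meths.get((s, t), 50.0)
                row[library_column(s, t, "msum")] = int(round(pct))
                row[library_column(s, t, "dsum")] = 100
                row[library_column(s, t, "adeq")] = True
                row[library_column(s, t, "meth")] = pct
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def bin_table_factory():
    return make_bin_table
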