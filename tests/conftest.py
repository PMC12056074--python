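import json

import numpy as np
import pandas as pd
import pytest

from spermeth.simulate import SimConfig
from spermeth.study import simulate_study

SMALL_OVERRIDES = dict(
    n_cpg=4000,
    chrom_length_bp=200_000,
    n_genes_per_chrom=40,
    n_islands_per_chrom=8,
    n_chg=500,
    n_chh=500,
    n_control_sites=100,
    n_snp=100,
)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """One small synthetic study shared by the whole session (read-only)."""
    outdir = tmp_path_factory.mktemp("fixture")
    cfg = SimConfig(seed=11, **SMALL_OVERRIDES)
    manifest = simulate_study(cfg, outdir)
    return manifest, outdir


@pytest.fixture(scope="session")
def small_matrix(small_study):
    """MethMatrix over the small study's good samples (CpG context)."""
    from spermeth import io as io_mod
    from spermeth.core import MethMatrix

    manifest, outdir = small_study
    tables = {
        sid: io_mod.read_bismark_cov(outdir / manifest["files"][f"cov:{sid}"])
        for sid in manifest["good_samples"]
    }
    return MethMatrix.from_site_tables(tables)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def textbook_pedigree():
    """Founders s, d; full sibs a, b; c = offspring of the full sibs."""
    return pd.DataFrame(
        {
            "id": ["s", "d", "a", "b", "c"],
            "sire": ["0", "0", "s", "s", "a"],
            "dam": ["0", "0", "d", "d", "b"],
        }
    )
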