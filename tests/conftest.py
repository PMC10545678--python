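import numpy as np
import pandas as pd
import pytest

from prskit.io import DosageMatrix
from prskit.simulate import SimTruth, simulate_panel


@pytest.fixture(scope="session")
def panel_small():
    """Two-ancestry panel with moderate divergence, reused across modules."""
    return simulate_panel(n_per_ancestry=300, m_variants=120, n_blocks=12,
                          divergence=0.1, seed=11)


@pytest.fixture(scope="session")
def truth_null():
    return SimTruth(variant_effects={}, beta_prs=0.0, famhx_log_or=0.0)


@pytest.fixture()
def toy_dosages():
    """Three samples x three variants, fully observed, alleles as in meta."""
    keys = ["1:1000:A:G", "1:2000:C:T", "1:3000:A:C"]
    dos = pd.DataFrame([[0.0, 1.0, 2.0], [1.0, 1.0, 1.0], [2.0, 0.0, 0.0]],
                       index=["s1", "s2", "s3"], columns=keys)
    dos.index.name = "sample_id"
    meta = pd.DataFrame(
        {"chrom": ["1", "1", "1"], "pos": [1000, 2000, 3000],
         "effect_allele": ["A", "C", "A"], "other_allele": ["G", "T", "C"]},
        index=pd.Index(keys, name="key"))
    return DosageMatrix(dos, meta)


def make_sumstats(rows):
    """Helper: build a summary-stats frame from (id, chrom, pos, ea, oa, eaf, beta, se) rows."""
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "effect_allele",
                                     "other_allele", "eaf", "beta", "se"])
    df["n_cases"] = 1000
    df["n_controls"] = 2000
    df["ancestry_label"] = "TEST"
    from prskit.io import variant_key
    df["key"] = [variant_key(c, p, a, b) for c, p, a, b in
                 zip(df["chrom"], df["pos"], df["effect_allele"], df["other_allele"])]
    return df
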