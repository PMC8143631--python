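import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import apcscreen as apc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> apc.TmtSimConfig:
    return apc.TmtSimConfig(n_proteins=200, frac_regulated=0.1, cv=0.1, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return apc.simulate_tmt(small_config)


@pytest.fixture(scope="session")
def contrast(small_dataset) -> apc.Contrast:
    _, truth = small_dataset
    return apc.Contrast(
        treated=truth.design["treated"], control=truth.design["control"]
    )


@pytest.fixture(scope="session")
def irs2_like_sequence() -> str:
    """Synthetic IRS2-like protein: a 1350-residue random backbone with an
    extended destruction box planted at residues 972-980 (the span the
    degron occupies in the human protein).  The real sequence is not
    bundled; only the coordinate arithmetic is exercised."""
    rng = np.random.default_rng(1972)
    backbone = "".join(rng.choice(list("ACDEFGHISTVWY"), size=1350))  # no R/K/L/N
    dbox = "RTALSELSN"  # RxxLxxxxN instance
    return backbone[:971] + dbox + backbone[980:]


def make_psm_table(values, peptides=None, proteins=None, posteriors=None,
                   decoys=None) -> pd.DataFrame:
    """Small hand-built PSM tables for worked examples."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n, n_ch = values.shape
    df = pd.DataFrame(values, columns=[f"ch{k + 1}" for k in range(n_ch)])
    df.insert(0, "psm_id", [f"psm{i + 1}" for i in range(n)])
    df.insert(1, "peptide", peptides if peptides is not None else [f"PEPTIDE{i}" for i in range(n)])
    df.insert(2, "proteins", proteins if proteins is not None else ["P1"] * n)
    df.insert(3, "is_decoy", decoys if decoys is not None else [False] * n)
    df.insert(4, "posterior", posteriors if posteriors is not None else [0.99] * n)
    return df
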