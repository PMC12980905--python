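import numpy as np
import pandas as pd
import pytest

from crcrelapse import signatures, synthetic
from crcrelapse.variants import MutationTable

SAMPLES = ("P_A", "L_A", "L_B", "L_C", "LR_A", "LR_B", "LR_C", "N")
TISSUE = {"P_A": "primary", "N": "normal",
          "L_A": "metastasis", "L_B": "metastasis", "L_C": "metastasis",
          "LR_A": "relapse", "LR_B": "relapse", "LR_C": "relapse"}


def make_meta(samples=SAMPLES, patient="pt1", purity=0.6) -> pd.DataFrame:
    return pd.DataFrame({
        "patient": patient,
        "tissue": [TISSUE[s] for s in samples],
        "purity": [1.0 if TISSUE[s] == "normal" else purity for s in samples],
    }, index=pd.Index(samples, name="sample"))


def make_table(alt, depth, samples=SAMPLES, **meta_kwargs) -> MutationTable:
    """Build a one-patient table from (n_mut x n_sample) count arrays."""
    alt = np.atleast_2d(np.asarray(alt))
    depth = np.atleast_2d(np.asarray(depth))
    n = alt.shape[0]
    ids = [f"m{i}" for i in range(n)]
    muts = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, n + 1) * 1000,
        "ref": "C", "alt": "T", "alt_base": "T", "context": "ACA",
        "gene": [f"GENE{i}" for i in range(n)],
        "effect": "non-silent", "driver": False,
    }, index=pd.Index(ids, name="mutation"))
    return MutationTable(
        muts=muts,
        depth=pd.DataFrame(depth, index=ids, columns=list(samples)),
        alt=pd.DataFrame(alt, index=ids, columns=list(samples)),
        meta=make_meta(samples, **meta_kwargs),
    )


def full_cover_segments(samples=SAMPLES, major=1, minor=1) -> pd.DataFrame:
    """One segment covering all of chr1 for every tumor sample."""
    rows = [{"sample": s, "chrom": "chr1", "start": 1, "end": 10**9,
             "major": major, "minor": minor}
            for s in samples if TISSUE.get(s, "metastasis") != "normal"]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def catalog() -> pd.DataFrame:
    return signatures.synthetic_catalog()


@pytest.fixture(scope="session")
def shared_sim() -> synthetic.PatientSim:
    return synthetic.simulate_patient("P01", "shared", seed=3)
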