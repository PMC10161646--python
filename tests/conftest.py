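import numpy as np
import pandas as pd
import pytest

import splicecross as sc


@pytest.fixture(scope="session")
def f2_cohort():
    """One shared F2 cohort at study scale (n=143) with a modest marker panel."""
    spec = sc.PedigreeSpec()
    genome = sc.GenomeSpec(n_markers=400)
    founders = sc.simulate_founders(spec, genome, fst=0.3, seed=11)
    f2, pedigree = sc.simulate_f2(founders, spec, genome, seed=12)
    return {"spec": spec, "genome": genome, "founders": founders,
            "f2": f2, "pedigree": pedigree}


@pytest.fixture(scope="session")
def f2(f2_cohort):
    return f2_cohort["f2"]


@pytest.fixture(scope="session")
def grm(f2):
    return sc.compute_grm(f2)


@pytest.fixture(scope="session")
def sex_cov(f2):
    return sc.sex_covariate(f2.sex)


@pytest.fixture(scope="session")
def f2_large():
    """A larger F2 cohort (n=500) for recovery-style checks."""
    spec = sc.PedigreeSpec(n_f2=500)
    genome = sc.GenomeSpec(n_markers=400)
    founders = sc.simulate_founders(spec, genome, fst=0.3, seed=21)
    f2, _ = sc.simulate_f2(founders, spec, genome, seed=22)
    return f2


@pytest.fixture(scope="session")
def grm_large(f2_large):
    return sc.compute_grm(f2_large)


def make_counts(events_meta: pd.DataFrame, samples, inclusion, exclusion):
    return sc.JunctionCountTable(
        events=events_meta,
        samples=list(samples),
        inclusion=np.asarray(inclusion),
        exclusion=np.asarray(exclusion),
    )


def event_meta(n, li=100, le=100):
    """Minimal event metadata block for n hand-built events."""
    return pd.DataFrame(
        {
            "gene_id": [f"G{i}" for i in range(n)],
            "event_class": "SE",
            "chrom": "1",
            "start": 1000,
            "end": 2000,
            "inclusion_length": li,
            "exclusion_length": le,
        },
        index=pd.Index([f"E{i}" for i in range(n)], name="event_id"),
    )
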