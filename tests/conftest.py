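"""Shared fixtures: synthetic cohorts generated once per session."""

import numpy as np
import pandas as pd
import pytest

from cladecall import (
    CohortConfig,
    HierarchicalClades,
    build_matrix,
    generate_cohort,
)

COHORT_SEED = 20170901 % 2**16  # fixed study seed for the shared fixtures


@pytest.fixture(scope="session")
def cohort():
    """Default 92-clone cohort: (ct, truth) at the shared seed."""
    ct, truth = generate_cohort(seed=COHORT_SEED)
    return ct, truth


@pytest.fixture(scope="session")
def cohort_matrix(cohort):
    ct, _ = cohort
    return build_matrix(ct, "ancestor")


@pytest.fixture(scope="session")
def cohort_clades(cohort_matrix):
    return HierarchicalClades(cohort_matrix).fit()


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """Noise-free cohort (all SDs zero): quantification must be exact."""
    from cladecall import default_signatures
    from cladecall.signatures import DEFAULT_PANEL, ClassSignature, SignatureSet

    base = default_signatures()
    sigs = tuple(
        ClassSignature(s.class_name, s.mean_log2, (0.0,) * len(s.sd_log2))
        for s in base.signatures
    )
    sigset = SignatureSet(DEFAULT_PANEL, sigs)
    config = CohortConfig(tech_sd=0.0, loading_sd=0.0, seed=11)
    ct, truth = generate_cohort(config, sigset)
    return ct, truth, sigset


def tiny_ct_table(records):
    """Build a Ct DataFrame from (clone, gene, bio, tech, ct) tuples."""
    return pd.DataFrame(
        records, columns=["clone", "gene", "bio_rep", "tech_rep", "ct"]
    )
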