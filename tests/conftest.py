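import numpy as np
import pandas as pd
import pytest

import microstab as ms


@pytest.fixture
def two_taxon_model():
    """Hand-solvable system: d eta1/dt = 1 - 2 pi1, denominator = taxon 2.

    Equilibrium pi* = (0.5, 0.5); Jacobian [[-0.5, 0], [0.5, 0]];
    eigenvalues {0, -0.5}.
    """
    return ms.CLVModel(
        taxon_names=["a", "d"],
        denominator=1,
        g=[1.0, 0.0],
        A=[[-2.0, 0.0], [0.0, 0.0]],
        B=np.zeros((2, 0)),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 6-taxon cohort with mild process noise, 16 subjects."""
    cfg = ms.SyntheticConfig(
        n_taxa=6,
        n_subjects=16,
        timepoints_range=(3, 5),
        gap_range=(2, 7),
        sigma_eta=0.02,
        seed=7,
    )
    model, truth = ms.generate_clv_system(cfg)
    table, meta, _ = ms.simulate_cohort(model, cfg, attractor=truth.attractor)
    return model, truth, table, meta, cfg


@pytest.fixture
def counts_table():
    data = pd.DataFrame(
        [[3000, 2000, 100], [1500, 3000, 500], [4000, 900, 100]],
        index=["s1", "s2", "s3"],
        columns=["gA", "gB", "gC"],
        dtype=float,
    )
    return ms.AbundanceTable(data, kind="counts")


def make_meta(rows):
    """rows: (sample_id, subject_id, day[, study, intervention, enterotype])"""
    recs = []
    for r in rows:
        rec = {
            "sample_id": r[0],
            "subject_id": r[1],
            "day": r[2],
            "study_id": r[3] if len(r) > 3 else "st1",
            "intervention": r[4] if len(r) > 4 else "none",
            "enterotype": r[5] if len(r) > 5 else "Rum",
        }
        recs.append(rec)
    from microstab.io import validate_metadata

    return validate_metadata(pd.DataFrame(recs))
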