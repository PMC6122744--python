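import numpy as np
import pandas as pd
import pytest

import twinmeth as tm


def make_paired_sheet(n_pairs: int) -> pd.DataFrame:
    """Minimal discordant-pair sample sheet."""
    ids = [f"P{i:03d}" for i in range(n_pairs)]
    cols = [f"{p}_{s}" for p in ids for s in ("case", "control")]
    return pd.DataFrame(
        {
            "pair_id": np.repeat(ids, 2),
            "status": ["case", "control"] * n_pairs,
        },
        index=pd.Index(cols, name="sample_id"),
    )


def make_group_sheet(n_case: int, n_control: int) -> pd.DataFrame:
    """Unpaired two-group sample sheet (for variability testing)."""
    ids = [f"C{i:03d}" for i in range(n_case)] + [f"H{i:03d}" for i in range(n_control)]
    return pd.DataFrame(
        {"status": ["case"] * n_case + ["control"] * n_control},
        index=pd.Index(ids, name="sample_id"),
    )


@pytest.fixture(scope="session")
def annotation_small():
    return tm.generate_probe_annotation(2000, seed=11)


@pytest.fixture(scope="session")
def annotation_mid():
    return tm.generate_probe_annotation(20_000, seed=7)


@pytest.fixture(scope="session")
def default_cohort(annotation_mid):
    """Default-condition twin cohort: no DMPs, 0.5% DVPs at v=4."""
    config = tm.SyntheticConfig(seed=42)
    intensities, beta, sheet, truth = tm.generate_twin_cohort(config, annotation_mid)
    return config, intensities, beta, sheet, truth


@pytest.fixture(scope="session")
def small_cohort(annotation_small):
    config = tm.SyntheticConfig(
        seed=5, n_probes=2000, n_pairs=25, n_chips=5, frac_dvp=0.01
    )
    intensities, beta, sheet, truth = tm.generate_twin_cohort(config, annotation_small)
    return config, intensities, beta, sheet, truth
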