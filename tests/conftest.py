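import numpy as np
import pandas as pd
import pytest

import mirmycn as mm


@pytest.fixture(scope="session")
def noiseless_screen():
    """Zero-noise screen: 10 miRNAs, 3 planted targets at -3 log2."""
    config = mm.ScreenSimConfig(
        n_mirnas=10, n_targeting=3, effect_log2=-3.0, noise_sd=0.0,
        n_analog_screens=5, seed=7,
    )
    plates, truth = mm.generate_screen(config)
    return plates, truth


@pytest.fixture(scope="session")
def noisy_cohort():
    """80-sample cohort with 12 planted inverse-coupled miRNAs (|r|=0.6)."""
    planted = tuple(f"mir-{i:04d}" for i in range(1, 13))
    config = mm.CohortSimConfig(
        n_samples=80, n_mirnas=60, n_genes=500, activity_gene_fraction=0.1,
        planted_inverse=planted, coupling_r=0.6, seed=11,
    )
    mirna_m, mrna_m, truth = mm.generate_cohort(config)
    return mirna_m, mrna_m, truth, planted


@pytest.fixture(scope="session")
def noiseless_timecourse():
    """Zero-noise time course with one planted TG slope of -1/week."""
    slopes = {"mir-0001": (-1.0, 0.0)}
    config = mm.TimecourseSimConfig(
        n_mirnas=20, planted_slopes=slopes, cq_noise_sd=0.0, seed=3
    )
    return mm.generate_timecourse(config)
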