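"""Shared fixtures: canonical species and simulated runs.

Expensive simulated runs are session-scoped; everything is generated
programmatically, nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from murosearch import chem, pipeline, synthetic_runs as sr
from murosearch.identification import SpectrumRecord

GM = "GlcN-MurNAc"


@pytest.fixture(scope="session")
def fig4_pair():
    """The exactly isobaric dimer pair: 4-3 of two AEmA vs 3-3 AEm x AEmAA."""
    return (
        chem.chain_species(["AEmA", "AEmA"], [GM, GM]),
        chem.chain_species(["AEm", "AEmAA"], [GM, GM]),
    )


@pytest.fixture(scope="session")
def fig5_pair():
    """3-3 AEm x AEmA and its isobaric 4-3 reading AEmA x AEm."""
    return (
        chem.chain_species(["AEm", "AEmA"], [GM, GM]),
        chem.chain_species(["AEmA", "AEm"], [GM, GM]),
    )


def simulated_ms2(species, activation="ETD", charge=2, seed=0, **noise):
    """One MS2 spectrum drawn from the fragment predictions of a species."""
    params = sr.SimulationParams(**noise)
    rng = np.random.default_rng(seed)
    prec = chem.mz_from_neutral(species.neutral_mass, charge)
    mz, inten = sr._ms2_peaks(species, activation, charge, params, rng, prec)
    return SpectrumRecord(
        scan_id=f"sim-{species.label()[:12]}-{activation}-{seed}",
        retention_time=10.0,
        ms_level=2,
        mz=mz,
        intensity=inten,
        precursor_mz=prec,
        precursor_charge=charge,
        activation=activation,
    )


@pytest.fixture(scope="session")
def headline_truth():
    return sr.headline_truth(seed=11)


@pytest.fixture(scope="session")
def headline_run(headline_truth):
    return sr.simulate_run(headline_truth)


@pytest.fixture(scope="session")
def headline_report(headline_run):
    return pipeline.run_pipeline({}, run=headline_run)


@pytest.fixture(scope="session")
def noisy_run(headline_truth):
    params = sr.SimulationParams(
        fragment_dropout=0.10, spurious_peak_fraction=0.20, intensity_cv=0.3
    )
    return sr.simulate_run(headline_truth, params)


@pytest.fixture(scope="session")
def noisy_report(noisy_run):
    return pipeline.run_pipeline({}, run=noisy_run)
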