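"""Ground-truth LC-MS/MS run simulation.

No public raw data exists for the *C. difficile* muropeptide run this
package targets, so every pipeline stage is exercised against synthetic runs
with the same statistical structure: Gaussian elution peaks over a ~50-min
gradient, monomer/dimer/trimer species at realistic ion-count splits, charge
states 1-4 with data-dependent MS2 (top-5 multiply charged precursors,
paired HCD/ETD events, dynamic exclusion), 3-point isotope envelopes, MS2
peaks drawn from the fragment predictions with configurable intensity noise,
peak dropout and spurious peaks, and optional in-source-decay satellites
that share their parent's elution profile exactly.

Abundances are stated as monoisotopic ion counts (the quantity an XIC of the
monoisotopic precursor integrates), so noise-free quantification recovers
the injected numbers exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem, fragmentation
from .chem import CrosslinkedSpecies, chain_species, monomer
from .identification import SpectrumRecord, fragment_charges
from .search_space import DEFAULT_GLYCOFORMS, DEFAULT_STEMS, SearchConfig

__all__ = [
    "SpeciesTruth",
    "GroundTruth",
    "SimulationParams",
    "simulate_run",
    "make_fixture_suite",
    "ground_truth_frame",
    "HEADLINE_CLASS_SPLIT",
]

#: monomer/dimer/trimer share of total identified ion counts used for the
#: headline parameter-recovery fixture (percent)
HEADLINE_CLASS_SPLIT = {"monomer": 29.2, "dimer": 57.4, "trimer": 13.4}

_DEFAULT_CHARGES = {1: {1: 0.3, 2: 0.7}, 2: {2: 0.6, 3: 0.4}, 3: {2: 0.3, 3: 0.5, 4: 0.2}}


@dataclass(frozen=True)
class SpeciesTruth:
    """One injected species with its elution and charge-state model."""

    species: CrosslinkedSpecies
    abundance: float  # monoisotopic ion count, summed over the run
    rt_center: float  # minutes
    rt_sigma: float = 0.15
    charge_fractions: dict[int, float] = field(default_factory=lambda: {2: 1.0})
    isd_parent: int | None = None  # index of the parent whose elution is shared

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if abs(sum(self.charge_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("charge fractions must sum to 1")


@dataclass(frozen=True)
class GroundTruth:
    entries: tuple[SpeciesTruth, ...]
    seed: int = 0
    rt_start: float = 0.0
    rt_end: float = 50.0
    ms1_cycle: float = 0.02  # minutes


@dataclass(frozen=True)
class SimulationParams:
    top_n: int = 5
    ms2_min_charge: int = 2
    dynamic_exclusion_min: float = 0.5
    fragment_dropout: float = 0.0  # probability a predicted MS2 peak is missing
    spurious_peak_fraction: float = 0.0  # spurious peaks per predicted peak
    intensity_cv: float = 0.0  # lognormal CV on every simulated intensity
    ms2_base_intensity: float = 1000.0
    isotope_peaks: int = 3


def _elution_profiles(truth: GroundTruth, times: np.ndarray) -> np.ndarray:
    """Per-entry per-MS1-scan monoisotopic weights summing to 1 over the run."""
    profiles = np.zeros((len(truth.entries), times.size))
    for i, entry in enumerate(truth.entries):
        src = entry
        if entry.isd_parent is not None:
            src = truth.entries[entry.isd_parent]  # exact co-elution
        w = np.exp(-0.5 * ((times - src.rt_center) / src.rt_sigma) ** 2)
        total = w.sum()
        if total <= 0:
            raise ValueError(
                f"species {i} elutes outside the simulated gradient window"
            )
        profiles[i] = w / total
    return profiles


def _isotope_factors(neutral_mass: float, n: int) -> np.ndarray:
    # crude binomial-style envelope adequate below ~3 kDa: the heavy-isotope
    # rate grows linearly with mass
    r = neutral_mass / 1800.0
    factors = [1.0]
    for k in range(1, n):
        factors.append(r**k / math.factorial(k))
    return np.array(factors)


def _noise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    if cv <= 0:
        return values
    sigma = np.sqrt(np.log(1 + cv**2))
    return values * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=values.shape)


def _ms2_peaks(
    species: CrosslinkedSpecies,
    activation: str,
    charge: int,
    params: SimulationParams,
    rng: np.random.Generator,
    precursor_mz: float,
):
    charges = fragment_charges(charge)
    if species.n_units == 1:
        frags = fragmentation.predict_linear_fragments(
            species.units[0], activation, charges
        )
    else:
        frags = fragmentation.predict_crosslinked_fragments(
            species, activation, charges
        )
    mzs = np.array([f.mz for f in frags])
    ints = np.full(mzs.shape, params.ms2_base_intensity)
    ints = _noise(rng, ints, params.intensity_cv)
    if params.fragment_dropout > 0:
        keep = rng.random(mzs.size) >= params.fragment_dropout
        mzs, ints = mzs[keep], ints[keep]
    if params.spurious_peak_fraction > 0:
        n_spur = int(round(params.spurious_peak_fraction * len(frags)))
        if n_spur:
            spur_mz = rng.uniform(100.0, precursor_mz + 50.0, size=n_spur)
            spur_int = np.full(n_spur, 0.4 * params.ms2_base_intensity)
            spur_int = _noise(rng, spur_int, max(params.intensity_cv, 0.2))
            mzs = np.concatenate([mzs, spur_mz])
            ints = np.concatenate([ints, spur_int])
    order = np.argsort(mzs, kind="stable")
    return mzs[order], ints[order]


def simulate_run(
    truth: GroundTruth, params: SimulationParams = SimulationParams()
) -> list[SpectrumRecord]:
    """Simulate a centroided data-dependent LC-MS/MS run.

    MS1 scans run on a fixed cycle; after each MS1 scan the top-N most
    abundant multiply charged precursors (outside the dynamic-exclusion
    window) each trigger an HCD and an ETD MS2 event.  Seeded and
    bit-reproducible.
    """
    rng = np.random.default_rng(truth.seed)
    times = np.arange(truth.rt_start, truth.rt_end, truth.ms1_cycle)
    profiles = _elution_profiles(truth, times)
    masses = [e.species.neutral_mass for e in truth.entries]
    envelope = [_isotope_factors(m, params.isotope_peaks) for m in masses]

    spectra: list[SpectrumRecord] = []
    excluded_until: dict[tuple[int, int], float] = {}
    scan_counter = 0

    for ti, t in enumerate(times):
        mz_list, int_list = [], []
        current: list[tuple[float, int, int]] = []  # (intensity, entry, charge)
        for ei, entry in enumerate(truth.entries):
            mono_total = entry.abundance * profiles[ei, ti]
            if mono_total <= 0:
                continue
            for z, frac in entry.charge_fractions.items():
                mono = mono_total * frac
                if mono <= 0:
                    continue
                mz0 = chem.mz_from_neutral(masses[ei], z)
                for k, factor in enumerate(envelope[ei]):
                    mz_list.append(mz0 + k * chem.CONSTANTS.neutron_spacing / z)
                    int_list.append(mono * factor)
                current.append((mono, ei, z))
        mzs = np.array(mz_list)
        ints = _noise(rng, np.array(int_list), params.intensity_cv)
        order = np.argsort(mzs, kind="stable") if mzs.size else slice(None)
        scan_counter += 1
        spectra.append(
            SpectrumRecord(
                scan_id=str(scan_counter),
                retention_time=float(t),
                ms_level=1,
                mz=mzs[order] if mzs.size else mzs,
                intensity=ints[order] if mzs.size else ints,
            )
        )
        # data-dependent selection
        eligible = [
            (inten, ei, z)
            for inten, ei, z in current
            if z >= params.ms2_min_charge and excluded_until.get((ei, z), -1.0) < t
        ]
        eligible.sort(reverse=True)
        for rank, (inten, ei, z) in enumerate(eligible[: params.top_n]):
            excluded_until[(ei, z)] = t + params.dynamic_exclusion_min
            species = truth.entries[ei].species
            prec_mz = chem.mz_from_neutral(masses[ei], z)
            for j, activation in enumerate(("HCD", "ETD")):
                frag_mz, frag_int = _ms2_peaks(
                    species, activation, z, params, rng, prec_mz
                )
                scan_counter += 1
                offset = truth.ms1_cycle * (
                    (2 * rank + j + 1) / (2 * params.top_n + 2)
                )
                spectra.append(
                    SpectrumRecord(
                        scan_id=str(scan_counter),
                        retention_time=float(t + offset),
                        ms_level=2,
                        mz=frag_mz,
                        intensity=frag_int,
                        precursor_mz=prec_mz,
                        precursor_charge=z,
                        activation=activation,
                    )
                )
    return spectra


def ground_truth_frame(truth: GroundTruth) -> pd.DataFrame:
    """Sidecar table of the injected ground truth."""
    return pd.DataFrame(
        {
            "species": [e.species.label() for e in truth.entries],
            "size_class": [e.species.size_class for e in truth.entries],
            "neutral_mass": [e.species.neutral_mass for e in truth.entries],
            "abundance": [e.abundance for e in truth.entries],
            "rt_center": [e.rt_center for e in truth.entries],
            "rt_sigma": [e.rt_sigma for e in truth.entries],
            "charges": [
                ",".join(str(z) for z in sorted(e.charge_fractions)) for e in truth.entries
            ],
            "topologies": [",".join(e.species.topologies) for e in truth.entries],
            "isd_parent": [
                "" if e.isd_parent is None else truth.entries[e.isd_parent].species.label()
                for e in truth.entries
            ],
        }
    )


# ---------------------------------------------------------------------------
# Canonical fixtures


def _default_truth_entry(
    species: CrosslinkedSpecies, abundance: float, rt_center: float
) -> SpeciesTruth:
    return SpeciesTruth(
        species=species,
        abundance=abundance,
        rt_center=rt_center,
        charge_fractions=dict(_DEFAULT_CHARGES[min(species.n_units, 3)]),
    )


def table3_trimers() -> list[CrosslinkedSpecies]:
    """The nine independently verified trimer/partial-glycan compositions."""
    gm = "GlcN-MurNAc"
    return [
        chain_species(["AEm", "AEm", "AEmA"], [gm, gm, gm]),
        chain_species(["AEm", "AEmA", "AEmA"], [gm, gm, gm]),
        chain_species(["AEm", "AEm", "AEm"], [gm, gm, gm]),
        chain_species(["AEmA", "AEmA", "AEmA"], [gm, gm, gm]),
        chain_species(["AEm", "AEm", "AEmG"], [gm, gm, gm]),
        chain_species(["AEm", "AEm", "AEmA"], [gm, "MurNAc", gm]),
        chain_species(["AEm", "AEm", "AEmA"], [gm, gm, "none"]),
        chain_species(["AEm", "AEm", "AEmA"], [gm, "none", "none"]),
        chain_species(["AEm", "AEmA", "AEmG"], [gm, gm, gm]),
    ]


def make_fixture_suite(seed: int = 0) -> dict:
    """Standing test fixtures: the isobaric dimer pairs, the trimer set, a
    wildcard sequence variant, and the monomer DB scenario."""
    gm = "GlcN-MurNAc"
    fig4_43 = chain_species(["AEmA", "AEmA"], [gm, gm])  # 4-3
    fig4_33 = chain_species(["AEm", "AEmAA"], [gm, gm])  # isobaric 3-3 reading
    fig5_33 = chain_species(["AEm", "AEmA"], [gm, gm])  # 3-3
    fig5_43 = chain_species(["AEmA", "AEm"], [gm, gm])  # isobaric 4-3 reading
    trimers = table3_trimers()
    suite = {
        "fig4_pair": (fig4_43, fig4_33),
        "fig5_pair": (fig5_33, fig5_43),
        "table3_trimers": trimers,
        "wildcard_monomer": monomer("AEmF", gm),
        "monomer_config": SearchConfig(
            stems=DEFAULT_STEMS, glycoforms=DEFAULT_GLYCOFORMS
        ),
        "headline_truth": headline_truth(seed=seed),
    }
    return suite


def headline_truth(
    seed: int = 0,
    rt_start: float = 0.0,
    rt_end: float = 12.0,
    total_ions: float = 3e6,
) -> GroundTruth:
    """A compact run with monomer/dimer/trimer ion counts injected at the
    29.2 : 57.4 : 13.4 split, plus distinct elution peaks per species."""
    gm = "GlcN-MurNAc"
    split = HEADLINE_CLASS_SPLIT
    entries = (
        _default_truth_entry(
            monomer("AEmA", gm), total_ions * split["monomer"] / 100.0, rt_start + 3.0
        ),
        _default_truth_entry(
            chain_species(["AEm", "AEmA"], [gm, gm]),
            total_ions * split["dimer"] / 100.0,
            rt_start + 6.0,
        ),
        _default_truth_entry(
            chain_species(["AEm", "AEm", "AEmA"], [gm, gm, gm]),
            total_ions * split["trimer"] / 100.0,
            rt_start + 9.0,
        ),
    )
    return GroundTruth(entries=entries, seed=seed, rt_start=rt_start, rt_end=rt_end)


def with_isd_satellite(
    truth: GroundTruth,
    parent_index: int,
    satellite_species: CrosslinkedSpecies,
    fraction: float = 0.2,
    rt_shift: float = 0.0,
) -> GroundTruth:
    """Add a glycan-loss satellite of one parent species.

    With ``rt_shift == 0`` the satellite shares the parent's elution profile
    exactly (electrospray in-source decay); a non-zero shift turns it into a
    genuine chromatographically distinct species.
    """
    parent = truth.entries[parent_index]
    if rt_shift == 0.0:
        sat = SpeciesTruth(
            species=satellite_species,
            abundance=parent.abundance * fraction,
            rt_center=parent.rt_center,
            rt_sigma=parent.rt_sigma,
            charge_fractions=dict(parent.charge_fractions),
            isd_parent=parent_index,
        )
    else:
        sat = SpeciesTruth(
            species=satellite_species,
            abundance=parent.abundance * fraction,
            rt_center=parent.rt_center + rt_shift,
            rt_sigma=parent.rt_sigma,
            charge_fractions=dict(parent.charge_fractions),
        )
    return replace(truth, entries=truth.entries + (sat,))
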