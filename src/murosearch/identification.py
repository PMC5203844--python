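"""Spectrum-to-candidate matching, scoring, ranking and isobaric grouping.

Precursors are matched at a ppm tolerance against the candidate database
(5 ppm by default); fragments at 20 ppm for HCD and 0.5 Da for ETD (ion-trap
ETD read-out).  The score is deliberately transparent rather than a
re-implementation of any proprietary scheme:

    score = (fraction of predicted primary-series fragments matched)
          + (fraction of total observed intensity explained)       in [0, 2]

with the primary series being b/y for HCD and c/z (both hydrogen-transfer
variants) for ETD.  All candidates with score >= 0 are retained and ranked —
the "score cut of zero" policy — because reversed-sequence decoys are
uninformative for a search space this small; isobaric groups plus per-ID ppm
errors are reported instead so every call is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import chem, fragmentation
from .chem import CrosslinkedSpecies
from .search_space import CandidateDB

__all__ = [
    "SpectrumRecord",
    "FragmentMatch",
    "Identification",
    "match_precursor",
    "match_fragments",
    "score_and_rank",
    "isobaric_groups",
    "fragment_charges",
]

_PRIMARY = {"HCD": ("b", "y"), "ETD": ("c", "z", "z+H")}


@dataclass
class SpectrumRecord:
    """One MS1 scan or MS2 spectrum (centroided)."""

    scan_id: str
    retention_time: float  # minutes
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    activation: str | None = None  # HCD | ETD for MS2

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must align")
        if np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.ms_level >= 2:
            if self.precursor_mz is None or self.precursor_charge is None:
                raise ValueError("MS2 spectra need precursor m/z and charge")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass(frozen=True)
class FragmentMatch:
    fragment: fragmentation.TheoreticalFragment
    peak_index: int
    observed_mz: float
    intensity: float
    error_da: float

    @property
    def error_ppm(self) -> float:
        return 1e6 * self.error_da / self.observed_mz


@dataclass
class Identification:
    """A candidate assignment for one MS2 spectrum."""

    spectrum: SpectrumRecord
    candidate: CrosslinkedSpecies
    candidate_index: int
    precursor_ppm_error: float
    matched_fragments: list[FragmentMatch] = field(default_factory=list)
    score: float = 0.0
    isobaric_group: int | None = None
    topology_call: str = "n/a"  # 3-3 | 4-3 | ambiguous | n/a


def match_precursor(
    observed_mz: float,
    charge: int,
    db: CandidateDB,
    tol_ppm: float = 5.0,
) -> list[tuple[int, float]]:
    """DB entries whose theoretical m/z at this charge is within ``tol_ppm``.

    Returns ``(entry index, signed ppm error)`` sorted by absolute error.
    """
    if charge < 1:
        raise ValueError("charge must be >= 1")
    hits = []
    for idx in db.query_mz(observed_mz, charge, tol_ppm):
        theo = chem.mz_from_neutral(db.entries[idx].neutral_mass, charge)
        hits.append((idx, 1e6 * (observed_mz - theo) / theo))
    hits.sort(key=lambda h: abs(h[1]))
    return hits


def _tolerance_da(mz: float, activation: str, hcd_tol_ppm: float, etd_tol_da: float):
    if activation == "HCD":
        return mz * hcd_tol_ppm * 1e-6
    return etd_tol_da


def match_fragments(
    spectrum: SpectrumRecord,
    fragments: Sequence[fragmentation.TheoreticalFragment],
    hcd_tol_ppm: float = 20.0,
    etd_tol_da: float = 0.5,
) -> list[FragmentMatch]:
    """Greedy nearest-peak assignment; each observed peak and each predicted
    fragment is used at most once.  ETD matching sees both z variants because
    the prediction emits them explicitly."""
    if spectrum.n_peaks == 0 or not fragments:
        return []
    activation = (spectrum.activation or "HCD").upper()
    pairs = []
    for fi, frag in enumerate(fragments):
        tol = _tolerance_da(frag.mz, activation, hcd_tol_ppm, etd_tol_da)
        lo = np.searchsorted(spectrum.mz, frag.mz - tol, side="left")
        hi = np.searchsorted(spectrum.mz, frag.mz + tol, side="right")
        for pi in range(lo, hi):
            pairs.append((abs(spectrum.mz[pi] - frag.mz), fi, pi))
    pairs.sort()
    used_peaks: set[int] = set()
    used_frags: set[int] = set()
    matches = []
    for err, fi, pi in pairs:
        if fi in used_frags or pi in used_peaks:
            continue
        used_frags.add(fi)
        used_peaks.add(pi)
        frag = fragments[fi]
        matches.append(
            FragmentMatch(
                fragment=frag,
                peak_index=pi,
                observed_mz=float(spectrum.mz[pi]),
                intensity=float(spectrum.intensity[pi]),
                error_da=float(spectrum.mz[pi] - frag.mz),
            )
        )
    return matches


def fragment_charges(precursor_charge: int) -> tuple[int, ...]:
    """Fragment charge states considered: 1 .. min(precursor charge, 2)."""
    return tuple(range(1, min(precursor_charge, 2) + 1))


def predict_for_spectrum(
    candidate: CrosslinkedSpecies, spectrum: SpectrumRecord
) -> list[fragmentation.TheoreticalFragment]:
    charges = fragment_charges(spectrum.precursor_charge or 2)
    activation = (spectrum.activation or "HCD").upper()
    if candidate.n_units == 1:
        return fragmentation.predict_linear_fragments(
            candidate.units[0], activation, charges
        )
    return fragmentation.predict_crosslinked_fragments(candidate, activation, charges)


def score_identification(
    spectrum: SpectrumRecord,
    candidate: CrosslinkedSpecies,
    hcd_tol_ppm: float = 20.0,
    etd_tol_da: float = 0.5,
) -> tuple[float, list[FragmentMatch]]:
    """Two-term score: primary-series coverage plus explained intensity."""
    fragments = predict_for_spectrum(candidate, spectrum)
    matches = match_fragments(spectrum, fragments, hcd_tol_ppm, etd_tol_da)
    activation = (spectrum.activation or "HCD").upper()
    primary = _PRIMARY[activation]
    n_primary = sum(1 for f in fragments if f.series in primary)
    n_primary_matched = sum(1 for m in matches if m.fragment.series in primary)
    coverage = n_primary_matched / n_primary if n_primary else 0.0
    total = spectrum.total_intensity
    explained = sum(m.intensity for m in matches) / total if total > 0 else 0.0
    return coverage + explained, matches


def score_and_rank(
    spectrum: SpectrumRecord,
    candidates: Sequence[tuple[int, float]],
    db: CandidateDB,
    hcd_tol_ppm: float = 20.0,
    etd_tol_da: float = 0.5,
) -> list[Identification]:
    """Score precursor-matched candidates and rank them.

    Ties break by fewer modifications, then fewer units, then lexicographic
    stem order.  Everything with score >= 0 is retained.
    """
    idents = []
    for idx, ppm_err in candidates:
        entry = db.entries[idx]
        score, matches = score_identification(
            spectrum, entry, hcd_tol_ppm, etd_tol_da
        )
        idents.append(
            Identification(
                spectrum=spectrum,
                candidate=entry,
                candidate_index=idx,
                precursor_ppm_error=ppm_err,
                matched_fragments=matches,
                score=score,
            )
        )
    idents.sort(
        key=lambda ident: (
            -ident.score,
            ident.candidate.n_modifications(),
            ident.candidate.n_units,
            tuple(u.stem for u in ident.candidate.units),
        )
    )
    return idents


def isobaric_groups(db: CandidateDB, tol_ppm: float = 5.0) -> list[list[int]]:
    """Partition DB entries into groups indistinguishable by precursor mass.

    Single-linkage over the sorted mass list: consecutive entries closer than
    ``tol_ppm`` join the same group, so every within-group neighbour pair is
    within tolerance.
    """
    if not len(db):
        return []
    order = np.argsort([e.neutral_mass for e in db.entries], kind="stable")
    masses = np.array([db.entries[i].neutral_mass for i in order])
    groups: list[list[int]] = [[int(order[0])]]
    for i in range(1, len(masses)):
        if chem.ppm_diff(masses[i - 1], masses[i]) <= tol_ppm:
            groups[-1].append(int(order[i]))
        else:
            groups.append([int(order[i])])
    return groups


def group_annotation(db: CandidateDB, group: Sequence[int]) -> str:
    """Bracketed ambiguity annotation for an isobaric group of size > 1."""
    labels = sorted(db.entries[i].label() for i in group)
    if len(labels) == 1:
        return labels[0]
    return "[" + " | ".join(labels) + "]"
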