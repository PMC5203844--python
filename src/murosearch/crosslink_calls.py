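"""Automated 3-3 vs 4-3 cross-link topology calls for isobaric candidates.

A dimer composition read off the precursor mass alone is often compatible
with two cross-link topologies — e.g. two disaccharide-AEmA units joined 4-3
are exactly isobaric with disaccharide-AEm joined 3-3 to disaccharide-AEmAA.
ETD resolves this: cleaving the cross-link amide yields a c/z pair that
splits donor from acceptor content, and those splitting masses differ between
the two interpretations.

One subtlety makes naive "exclusive fragment" logic fail: a 4-3 donor's
mDAP-Ala backbone N-Calpha cleavage is exactly isobaric with the 3-3
interpretation's splitting pair.  The caller therefore works in two stages:

1. Fragments exclusive to one topology's *full* predicted set (matched among
   the strong peaks) decide directly.
2. Otherwise the cross-link-splitting ions are compared, with a
   mutual-explanation tie-break: a topology is preferred when its full set
   explains every matched splitting peak while the rival leaves some peak
   unexplained.

HCD spectra carry no c/z splitting ions; there only the unambiguous internal
fragment rule applies (an internal fragment with the mass of two mDAP
residues proves a 3-3 link; Ala + 2 mDAP can arise from either form and is
never used).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import fragmentation
from .chem import CrosslinkedSpecies
from .identification import Identification, SpectrumRecord, fragment_charges

__all__ = ["TopologyCall", "ConsensusCall", "classify_crosslink", "batch_call"]

#: a diagnostic peak must sit in the top half of the spectrum's intensities
STRONG_PEAK_QUANTILE = 0.5


@dataclass
class TopologyCall:
    """Per-spectrum topology decision with the matched diagnostic evidence."""

    composition: str
    call: str  # 3-3 | 4-3 | ambiguous
    activation: str
    evidence: list[tuple[float, float]] = field(default_factory=list)  # (mz, error)

    def __post_init__(self) -> None:
        if self.call != "ambiguous" and not self.evidence:
            raise ValueError("a decided call requires matched diagnostic evidence")


@dataclass
class ConsensusCall:
    composition: str
    call: str
    n_spectra: int
    n_conflicts: int
    per_spectrum: list[TopologyCall]
    note: str = (
        "a co-eluting minor amount of the other cross-link form cannot be excluded"
    )


def _strong_peaks(spectrum: SpectrumRecord) -> tuple[np.ndarray, np.ndarray]:
    if spectrum.n_peaks == 0:
        return spectrum.mz, spectrum.intensity
    threshold = float(np.quantile(spectrum.intensity, STRONG_PEAK_QUANTILE))
    keep = spectrum.intensity >= threshold
    return spectrum.mz[keep], spectrum.intensity[keep]


def _matched(mzs: np.ndarray, targets: Sequence[float], tol_da: float):
    """(target, error) pairs for targets with a peak within tolerance."""
    hits = []
    for t in targets:
        if mzs.size == 0:
            continue
        i = int(np.argmin(np.abs(mzs - t)))
        err = float(mzs[i] - t)
        if abs(err) <= tol_da:
            hits.append((t, err))
    return hits


def _exclusive(frags, other, tol_da):
    other_mz = np.array(sorted(f.mz for f in other)) if other else np.array([])
    out = []
    for f in frags:
        if other_mz.size == 0 or np.min(np.abs(other_mz - f.mz)) > tol_da:
            out.append(f)
    return out


def _group_by_topology(candidates: Sequence[CrosslinkedSpecies]):
    groups: dict[str, CrosslinkedSpecies] = {}
    for cand in candidates:
        topos = set(cand.topologies)
        if len(topos) != 1:
            continue  # mixed-link trimers are not pairwise-callable
        groups.setdefault(topos.pop(), cand)
    return groups


def classify_crosslink(
    ms2: SpectrumRecord,
    candidates: Sequence[CrosslinkedSpecies],
    hcd_tol_ppm: float = 20.0,
    etd_tol_da: float = 0.5,
) -> TopologyCall:
    """Call the cross-link topology of one isobaric candidate group.

    ``candidates`` must share their precursor mass and contain both a pure
    3-3 and a pure 4-3 interpretation.
    """
    masses = [c.neutral_mass for c in candidates]
    if max(masses) - min(masses) > 1e-3:
        raise ValueError("candidates are not isobaric")
    groups = _group_by_topology(candidates)
    if not {"3-3", "4-3"} <= set(groups):
        raise ValueError("candidate group must contain both 3-3 and 4-3 topologies")
    sp33, sp43 = groups["3-3"], groups["4-3"]
    composition = f"{sp33.label()} vs {sp43.label()}"
    activation = (ms2.activation or "HCD").upper()
    strong_mz, _ = _strong_peaks(ms2)

    if activation == "HCD":
        tol_da = 0.0  # per-fragment ppm handled below
        diag = fragmentation.diagnostic_internal_fragments(sp33, sp43)
        votes: dict[str, list[tuple[float, float]]] = {"3-3": [], "4-3": []}
        for f in diag:
            if f.diagnostic_for not in votes:
                continue
            tol = f.mz * hcd_tol_ppm * 1e-6
            votes[f.diagnostic_for].extend(_matched(strong_mz, [f.mz], tol))
        return _decide(composition, activation, votes["3-3"], votes["4-3"])

    charges = fragment_charges(ms2.precursor_charge or 2)
    full33 = fragmentation.predict_crosslinked_fragments(sp33, "ETD", charges)
    full43 = fragmentation.predict_crosslinked_fragments(sp43, "ETD", charges)
    tol_da = etd_tol_da

    # stage 1: fragments exclusive to one full prediction
    ex33 = _matched(strong_mz, [f.mz for f in _exclusive(full33, full43, tol_da)], tol_da)
    ex43 = _matched(strong_mz, [f.mz for f in _exclusive(full43, full33, tol_da)], tol_da)
    if len(ex33) != len(ex43):
        return _decide(composition, activation, ex33, ex43)
    if ex33 and ex43:
        return TopologyCall(composition, "ambiguous", activation)

    # stage 2: the cross-link-splitting c/z ions
    split33 = fragmentation.crosslink_splitting_ions(sp33, "ETD", charges)
    split43 = fragmentation.crosslink_splitting_ions(sp43, "ETD", charges)
    s33 = _matched(strong_mz, [f.mz for f in _exclusive(split33, split43, tol_da)], tol_da)
    s43 = _matched(strong_mz, [f.mz for f in _exclusive(split43, split33, tol_da)], tol_da)
    if not s33 and not s43:
        return TopologyCall(composition, "ambiguous", activation)
    if s33 and s43:
        # mutual explanation: prefer the topology whose full set explains
        # every matched splitting peak
        peaks = [mz + err for mz, err in s33 + s43]
        expl33 = _explains_all(full33, peaks, tol_da)
        expl43 = _explains_all(full43, peaks, tol_da)
        if expl33 and not expl43:
            return _decide(composition, activation, s33, [])
        if expl43 and not expl33:
            return _decide(composition, activation, [], s43)
        return TopologyCall(composition, "ambiguous", activation)
    return _decide(composition, activation, s33, s43)


def _explains_all(frags, peaks, tol_da) -> bool:
    mzs = np.array(sorted(f.mz for f in frags))
    return all(np.min(np.abs(mzs - p)) <= tol_da for p in peaks)


def _decide(composition, activation, ev33, ev43) -> TopologyCall:
    if len(ev33) > len(ev43):
        return TopologyCall(composition, "3-3", activation, list(ev33))
    if len(ev43) > len(ev33):
        return TopologyCall(composition, "4-3", activation, list(ev43))
    return TopologyCall(composition, "ambiguous", activation)


def _rival_candidates(
    ident: Identification,
    db,
    tol_ppm: float,
) -> list[CrosslinkedSpecies]:
    """Isobaric opposite-topology interpretations of one identification.

    Candidates come from the database entries within the precursor tolerance
    that are pure single-topology species of the same size and elemental
    composition; when several exist the best-matching one (fragment score
    against the identification's spectrum) represents the rival topology.
    """
    from .identification import score_identification

    cand = ident.candidate
    own_topos = set(cand.topologies)
    if len(own_topos) != 1:
        return []
    own = own_topos.pop()
    other = "4-3" if own == "3-3" else "3-3"
    try:
        own_comp = cand.composition
    except ValueError:  # wildcard-modified species have no formula
        return []
    rivals = []
    for idx in db.query_mass(cand.neutral_mass, tol_ppm):
        entry = db.entries[idx]
        if entry.n_units != cand.n_units:
            continue
        if set(entry.topologies) != {other}:
            continue
        try:
            if entry.composition != own_comp:
                continue
        except ValueError:
            continue
        rivals.append(entry)
    if len(rivals) > 1:
        rivals.sort(key=lambda sp: -score_identification(ident.spectrum, sp)[0])
    return rivals[:1]


def batch_call(
    identifications: Sequence[Identification],
    db=None,
    hcd_tol_ppm: float = 20.0,
    etd_tol_da: float = 0.5,
    tol_ppm: float = 5.0,
) -> list[ConsensusCall]:
    """Majority topology call per composition across its MS2 spectra.

    Identifications are grouped by order-insensitive unit content.  The rival
    topology interpretation of each group is taken from the candidate
    database when one is given (exactly isobaric, same elemental
    composition), otherwise from the identifications themselves.  Groups with
    both pure topologies available are classified spectrum by spectrum; the
    majority among decided calls wins, and conflicting decided calls are
    counted.
    """
    def _comp_key(cand: CrosslinkedSpecies):
        try:
            return (cand.n_units, tuple(sorted(cand.composition.items())))
        except ValueError:  # wildcard species: fall back to unit content
            return (cand.n_units, cand.composition_key())

    by_comp: dict[tuple, dict] = {}
    for ident in identifications:
        cand = ident.candidate
        if cand.n_units < 2:
            continue
        rec = by_comp.setdefault(_comp_key(cand), {"candidates": {}, "idents": []})
        rec["candidates"][cand.label()] = cand
        rec["idents"].append(ident)
    out = []
    for key, rec in by_comp.items():
        candidates = dict(rec["candidates"])
        if db is not None:
            for ident in rec["idents"]:
                for rival in _rival_candidates(ident, db, tol_ppm):
                    candidates.setdefault(rival.label(), rival)
        candidate_list = list(candidates.values())
        groups = _group_by_topology(candidate_list)
        if not {"3-3", "4-3"} <= set(groups):
            continue
        seen_scans: set[str] = set()
        calls = []
        for ident in rec["idents"]:
            if ident.spectrum.scan_id in seen_scans:
                continue
            seen_scans.add(ident.spectrum.scan_id)
            # classify against the identified candidate and one rival of the
            # opposite topology (isobaric, same elemental composition)
            own = ident.candidate
            own_topos = set(own.topologies)
            if len(own_topos) != 1:
                continue
            rival_topo = "4-3" if own_topos == {"3-3"} else "3-3"
            rival = groups.get(rival_topo)
            if rival is None or rival.label() == own.label():
                continue
            calls.append(
                classify_crosslink(
                    ident.spectrum, [own, rival], hcd_tol_ppm, etd_tol_da
                )
            )
        decided = [c.call for c in calls if c.call != "ambiguous"]
        if decided:
            winner, n_win = Counter(decided).most_common(1)[0]
            conflicts = len(decided) - n_win
        else:
            winner, conflicts = "ambiguous", 0
        out.append(
            ConsensusCall(
                composition=calls[0].composition if calls else str(key),
                call=winner,
                n_spectra=len(calls),
                n_conflicts=conflicts,
                per_spectrum=calls,
            )
        )
    return out
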