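"""Theoretical fragment ions for linear and cross-linked muropeptides.

HCD spectra of muropeptides are dominated by b/y ions, internal fragments and
glycan losses; ETD spectra by c/z ions plus unusually strong glycosidic
cleavages at three bonds: GlcN|MurNAc, MurNAc|lactyl and lactyl|Ala1.  For
cross-linked species the prediction is topology-aware: a fragment carries
every unit still covalently attached through the cross-link graph, so the
c/z pair produced by cleaving the cross-link amide itself "splits" donor from
acceptor content and differs in mass between the 3-3 and 4-3 interpretations
of the same overall composition.

Ion-type arithmetic (singly protonated, neutral piece masses P):

====== =====================================
b      P                      (no water)
y      P (includes C-terminal water)
c      b + NH3
z      y - NH3 + H            (z-radical)
z+H    z + H                  (hydrogen transfer from the c ion)
====== =====================================

so that b_i + y_(n-i) = M + 2*proton and c + z = M + H + 2*proton for 1+
pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from pyteomics import mass as _pmass

from . import chem
from .chem import (
    CrosslinkedSpecies,
    Muropeptide,
    H_ATOM,
    NH3,
    PROTON,
    WATER,
)

__all__ = [
    "TheoreticalFragment",
    "predict_linear_fragments",
    "predict_crosslinked_fragments",
    "crosslink_splitting_ions",
    "internal_fragment_masses",
    "diagnostic_internal_fragments",
    "flag_topology_diagnostics",
    "fragments_to_frame",
]

#: lactyl group left on the peptide after the MurNAc|lactyl ether cleavage
LACTYL_MASS = _pmass.calculate_mass(formula="C3H4O2")

#: internal fragments longer than this are not enumerated (combinatorics cap)
MAX_INTERNAL_LENGTH = 4

_GLYCAN_BOND_DISTAL = "GlcN|MurNAc"
_GLYCAN_BOND_LACTYL = "MurNAc|lactyl"
_GLYCAN_BOND_STEM = "lactyl|Ala1"


@dataclass(frozen=True)
class TheoreticalFragment:
    """One predicted fragment ion."""

    series: str  # b | y | c | z | z+H | Y | B | internal
    cleavage_site: str
    charge: int
    mz: float
    neutral_mass: float
    units_covered: frozenset[int]
    diagnostic_for: str = "none"  # 3-3 | 4-3 | none

    def with_diagnostic(self, topology: str) -> "TheoreticalFragment":
        return replace(self, diagnostic_for=topology)


def _ion(series, site, neutral, charge, units) -> TheoreticalFragment:
    return TheoreticalFragment(
        series=series,
        cleavage_site=site,
        charge=charge,
        mz=(neutral + charge * PROTON) / charge,
        neutral_mass=neutral,
        units_covered=frozenset(units),
    )


# ---------------------------------------------------------------------------
# Species graph helpers


def _attachment_position(species: CrosslinkedSpecies, link, unit: int) -> int:
    if link.donor_unit == unit:
        return link.donor_position
    return link.acceptor_position


def _component_masses(species: CrosslinkedSpecies):
    """For every link, the mass and unit set of each side when that link is cut.

    Returns ``{link_index: (mass_units_side_of_donor, units, mass_other, units)}``
    where masses are standalone neutral masses of the sub-species (internal
    cross-link waters already subtracted).
    """
    n = len(species.units)
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for li, link in enumerate(species.links):
        adj[link.donor_unit].append((link.acceptor_unit, li))
        adj[link.acceptor_unit].append((link.donor_unit, li))

    out = {}
    for li, link in enumerate(species.links):
        # component containing the donor when link li is removed
        seen = {link.donor_unit}
        stack = [link.donor_unit]
        while stack:
            for nxt, l2 in adj[stack.pop()]:
                if l2 != li and nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        donor_side = seen
        other_side = set(range(n)) - seen

        def side_mass(units: set[int]) -> float:
            internal_links = sum(
                1
                for l2i, l2 in enumerate(species.links)
                if l2i != li and l2.donor_unit in units and l2.acceptor_unit in units
            )
            return (
                sum(species.units[u].neutral_mass for u in units)
                - internal_links * WATER
            )

        out[li] = (side_mass(donor_side), donor_side, side_mass(other_side), other_side)
    return out


# ---------------------------------------------------------------------------
# Linear (single-unit) prediction


def _glycosidic_fragments(
    species: CrosslinkedSpecies, charges: Sequence[int]
) -> list[TheoreticalFragment]:
    """Y/B pairs for the three glycan bonds, for every glycosylated unit."""
    total = species.neutral_mass
    all_units = frozenset(range(len(species.units)))
    frags: list[TheoreticalFragment] = []
    for ui, unit in enumerate(species.units):
        gf = unit.glycoform
        if not gf.monosaccharides:
            continue
        gmass = gf.modification_mass
        removable: list[tuple[str, float]] = []
        if len(gf.monosaccharides) >= 2:
            distal = chem.Glycoform(
                (gf.monosaccharides[0],), reduced=False
            ).modification_mass
            removable.append((_GLYCAN_BOND_DISTAL, distal))
        if any("MurNAc" in s for s in gf.monosaccharides):
            removable.append((_GLYCAN_BOND_LACTYL, gmass - LACTYL_MASS))
        removable.append((_GLYCAN_BOND_STEM, gmass))
        for bond, removed in removable:
            site = f"u{ui + 1}:glycan:{bond}"
            y_neutral = total - removed
            for z in charges:
                frags.append(_ion("Y", site, y_neutral, z, all_units))
            # oxocarbenium-like glycan counterpart, singly charged
            frags.append(_ion("B", site, removed, 1, {ui}))
    return frags


def predict_linear_fragments(
    unit: Muropeptide | CrosslinkedSpecies,
    activation: str,
    charges: Iterable[int] = (1,),
) -> list[TheoreticalFragment]:
    """b/y (HCD) or c/z (ETD) at every stem amide bond, the glycan retained on
    N-terminal fragments, plus glycosidic Y/B ions; HCD adds internal
    fragments up to :data:`MAX_INTERNAL_LENGTH` residues."""
    if isinstance(unit, CrosslinkedSpecies):
        if unit.n_units != 1:
            raise ValueError("use predict_crosslinked_fragments for multimers")
        unit = unit.units[0]
    activation = activation.upper()
    if activation not in ("HCD", "ETD"):
        raise ValueError(f"activation must be HCD or ETD, got {activation!r}")
    charges = tuple(charges)
    species = CrosslinkedSpecies((unit,))
    total = species.neutral_mass
    stem = unit.stem
    n = len(stem)
    frags: list[TheoreticalFragment] = []
    mods_at = {m.residue_position: m.delta_mass for m in unit.mods}
    prefix = unit.glycoform.modification_mass
    for i in range(1, n):
        prefix += chem.residue_mass(stem[i - 1]) + mods_at.get(i, 0.0)
        b_neutral = prefix
        y_neutral = total - b_neutral
        site = f"u1:{i}"
        for z in charges:
            if activation == "HCD":
                frags.append(_ion("b", site, b_neutral, z, {0}))
                frags.append(_ion("y", site, y_neutral, z, {0}))
            else:
                frags.append(_ion("c", site, b_neutral + NH3, z, {0}))
                z_neutral = y_neutral - NH3 + H_ATOM
                frags.append(_ion("z", site, z_neutral, z, {0}))
                frags.append(_ion("z+H", site, z_neutral + H_ATOM, z, {0}))
    frags.extend(_glycosidic_fragments(species, charges))
    if activation == "HCD":
        for start, end, mass_ in _linear_internal_pieces(unit):
            frags.append(_ion("internal", f"u1:{start}-{end}", mass_, 1, {0}))
    return frags


def _linear_internal_pieces(unit: Muropeptide):
    stem = unit.stem
    mods_at = {m.residue_position: m.delta_mass for m in unit.mods}
    n = len(stem)
    for start in range(2, n):  # internal: both termini cleaved
        for end in range(start, min(start + MAX_INTERNAL_LENGTH - 1, n - 1) + 1):
            if end >= n:
                continue
            mass_ = sum(
                chem.residue_mass(stem[p - 1]) + mods_at.get(p, 0.0)
                for p in range(start, end + 1)
            )
            yield start, end, mass_


# ---------------------------------------------------------------------------
# Cross-linked prediction


def predict_crosslinked_fragments(
    species: CrosslinkedSpecies,
    activation: str,
    charges: Iterable[int] = (1,),
) -> list[TheoreticalFragment]:
    """Topology-aware prediction for 2-3 unit species.

    For each backbone bond of each unit, the two pieces carry everything still
    attached through the cross-link graph (a link at stem position p stays
    with the piece containing residue p).  The cross-link amide itself is also
    cleavable, producing the donor/acceptor "splitting" pair.
    """
    activation = activation.upper()
    if activation not in ("HCD", "ETD"):
        raise ValueError(f"activation must be HCD or ETD, got {activation!r}")
    if species.n_units == 1:
        return predict_linear_fragments(species.units[0], activation, charges)
    charges = tuple(charges)
    total = species.neutral_mass
    n_units = len(species.units)
    all_units = frozenset(range(n_units))
    comp = _component_masses(species)
    frags: list[TheoreticalFragment] = []

    def emit_pair(site, b_neutral, n_side_units):
        y_neutral = total - b_neutral
        c_side_units = all_units - n_side_units
        for z in charges:
            if activation == "HCD":
                frags.append(_ion("b", site, b_neutral, z, n_side_units))
                frags.append(_ion("y", site, y_neutral, z, c_side_units))
            else:
                frags.append(_ion("c", site, b_neutral + NH3, z, n_side_units))
                z_neutral = y_neutral - NH3 + H_ATOM
                frags.append(_ion("z", site, z_neutral, z, c_side_units))
                frags.append(_ion("z+H", site, z_neutral + H_ATOM, z, c_side_units))

    # backbone bonds within each unit
    for ui, unit in enumerate(species.units):
        stem = unit.stem
        mods_at = {m.residue_position: m.delta_mass for m in unit.mods}
        attachments = []  # (position on this unit, mass carried, units carried)
        for li, link in enumerate(species.links):
            if link.donor_unit == ui or link.acceptor_unit == ui:
                pos = _attachment_position(species, link, ui)
                d_mass, d_units, o_mass, o_units = comp[li]
                if ui in d_units:
                    attachments.append((pos, o_mass - WATER, o_units))
                else:
                    attachments.append((pos, d_mass - WATER, d_units))
        prefix = unit.glycoform.modification_mass
        for i in range(1, len(stem)):
            prefix += chem.residue_mass(stem[i - 1]) + mods_at.get(i, 0.0)
            b_neutral = prefix + sum(m for p, m, _ in attachments if p <= i)
            n_side = frozenset({ui}) | frozenset(
                itertools.chain.from_iterable(u for p, _, u in attachments if p <= i)
            )
            emit_pair(f"u{ui + 1}:{i}", b_neutral, n_side)

    # the cross-link amide itself: donor component is the acylating side
    for li, link in enumerate(species.links):
        d_mass, d_units, _, _ = comp[li]
        emit_pair(f"link:{li + 1}", d_mass - WATER, frozenset(d_units))

    frags.extend(_glycosidic_fragments(species, charges))

    if activation == "HCD":
        for nodes, mass_ in internal_fragment_masses(species):
            units_cov = frozenset(u for u, _ in nodes)
            site = "internal:" + "+".join(f"u{u + 1}:{p}" for u, p in sorted(nodes))
            frags.append(_ion("internal", site, mass_, 1, units_cov))
    return frags


def crosslink_splitting_ions(
    species: CrosslinkedSpecies,
    activation: str,
    charges: Iterable[int] = (1,),
) -> list[TheoreticalFragment]:
    """Only the fragments from cleaving a cross-link amide (the c/z or b/y
    pair that separates donor content from acceptor content)."""
    frags = predict_crosslinked_fragments(species, activation, charges)
    return [f for f in frags if f.cleavage_site.startswith("link:")]


# ---------------------------------------------------------------------------
# Internal fragments across the link graph


def _residue_graph(species: CrosslinkedSpecies):
    nodes = [
        (ui, pos)
        for ui, unit in enumerate(species.units)
        for pos in range(1, len(unit.stem) + 1)
    ]
    adj: dict[tuple[int, int], set[tuple[int, int]]] = {nd: set() for nd in nodes}
    for ui, unit in enumerate(species.units):
        for pos in range(1, len(unit.stem)):
            adj[(ui, pos)].add((ui, pos + 1))
            adj[(ui, pos + 1)].add((ui, pos))
    for link in species.links:
        a = (link.donor_unit, link.donor_position)
        b = (link.acceptor_unit, link.acceptor_position)
        adj[a].add(b)
        adj[b].add(a)
    return adj


def internal_fragment_masses(
    species: CrosslinkedSpecies,
    max_length: int = MAX_INTERNAL_LENGTH,
    spanning_only: bool = False,
):
    """Masses of internal residue runs (simple paths in the residue graph).

    Internal fragments exclude any unit's position-1 residue (those pieces are
    ordinary b-type ions).  With ``spanning_only`` only paths covering at least
    two units — i.e. running through a cross-link — are kept.  Yields
    ``(frozenset of (unit, position), residue-sum mass)``.
    """
    adj = _residue_graph(species)
    mods_at = {
        (ui, m.residue_position): m.delta_mass
        for ui, unit in enumerate(species.units)
        for m in unit.mods
    }

    def node_mass(nd):
        ui, pos = nd
        return chem.residue_mass(species.units[ui].stem[pos - 1]) + mods_at.get(
            nd, 0.0
        )

    seen_paths: set[frozenset] = set()
    results = []
    eligible = [nd for nd in adj if nd[1] != 1]
    for start in eligible:
        stack = [(start, (start,))]
        while stack:
            current, path = stack.pop()
            if len(path) >= 2:
                key = frozenset(path)
                if key not in seen_paths:
                    seen_paths.add(key)
                    if not spanning_only or len({u for u, _ in key}) >= 2:
                        results.append((key, sum(node_mass(nd) for nd in key)))
            if len(path) < max_length:
                for nxt in adj[current]:
                    if nxt not in path and nxt[1] != 1:
                        stack.append((nxt, path + (nxt,)))
    return results


def diagnostic_internal_fragments(
    species_a: CrosslinkedSpecies,
    species_b: CrosslinkedSpecies,
    tol_da: float = 0.01,
) -> list[TheoreticalFragment]:
    """Internal fragments achievable under exactly one of two isobaric
    topology candidates (b-type offset, singly protonated).

    The classic case: for an isobaric 3-3 vs 4-3 dimer pair, an internal
    fragment with the mass of two mDAP residues is exclusive evidence for the
    3-3 form (the mDAPs are directly bonded), while Ala + 2 mDAP can arise
    from either form and is therefore never emitted.
    """
    if abs(species_a.neutral_mass - species_b.neutral_mass) > 1e-6:
        raise ValueError("diagnostic internal comparison requires isobaric candidates")
    frags = []
    # candidate diagnostics must run through the cross-link, but exclusivity is
    # checked against *every* internal fragment of the rival interpretation
    # (e.g. Ala+mDAP spans the link in a 4-3 dimer yet also occurs within one
    # unit of the 3-3 form, so it is never diagnostic)
    spanning = {
        "a": internal_fragment_masses(species_a, spanning_only=True),
        "b": internal_fragment_masses(species_b, spanning_only=True),
    }
    all_internal = {
        "a": internal_fragment_masses(species_a, spanning_only=False),
        "b": internal_fragment_masses(species_b, spanning_only=False),
    }
    for (this, other), sp_this in zip(
        (("a", "b"), ("b", "a")), (species_a, species_b)
    ):
        other_masses = [m for _, m in all_internal[other]]
        topo = _dominant_topology(sp_this)
        for nodes, mass_ in spanning[this]:
            if all(abs(mass_ - om) > tol_da for om in other_masses):
                site = "internal:" + "+".join(
                    f"u{u + 1}:{p}" for u, p in sorted(nodes)
                )
                frags.append(
                    _ion(
                        "internal", site, mass_, 1, frozenset(u for u, _ in nodes)
                    ).with_diagnostic(topo)
                )
    return frags


def _dominant_topology(species: CrosslinkedSpecies) -> str:
    topos = set(species.topologies)
    if len(topos) == 1:
        return topos.pop()
    return "mixed"


def flag_topology_diagnostics(
    frags_a: Sequence[TheoreticalFragment],
    topo_a: str,
    frags_b: Sequence[TheoreticalFragment],
    topo_b: str,
    tol_da: float,
) -> tuple[list[TheoreticalFragment], list[TheoreticalFragment]]:
    """Flag fragments whose m/z separates two topology interpretations.

    A fragment is diagnostic for its own topology iff no fragment of the other
    interpretation lies within ``tol_da`` — guaranteeing every flagged
    fragment differs by more than the matching tolerance between topologies.
    """
    mz_a = sorted(f.mz for f in frags_a)
    mz_b = sorted(f.mz for f in frags_b)

    def exclusive(frags, other_mz, topo):
        out = []
        for f in frags:
            if all(abs(f.mz - om) > tol_da for om in other_mz):
                out.append(f.with_diagnostic(topo))
            else:
                out.append(f)
        return out

    return exclusive(frags_a, mz_b, topo_a), exclusive(frags_b, mz_a, topo_b)


def fragments_to_frame(frags: Sequence[TheoreticalFragment]):
    """Fragment table as a DataFrame (for TSV export / spectrum annotation)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "series": [f.series for f in frags],
            "cleavage_site": [f.cleavage_site for f in frags],
            "charge": [f.charge for f in frags],
            "mz": [f.mz for f in frags],
            "neutral_mass": [f.neutral_mass for f in frags],
            "units_covered": [
                "+".join(str(u + 1) for u in sorted(f.units_covered)) for f in frags
            ],
            "diagnostic_for": [f.diagnostic_for for f in frags],
        }
    )
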