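"""Monoisotopic mass model for muropeptide building blocks and assembled species.

Muropeptides are the disaccharide-peptide fragments released from bacterial
peptidoglycan by muramidase digestion: a short glycan (zero to two
monosaccharides, optionally borohydride-reduced, 1,6-anhydro or
de-N-acetylated) attached through its lactyl group to a peptide stem built
from standard amino acids plus meso-diaminopimelic acid (mDAP).  Stems can be
cross-linked into dimers and trimers either 4-3 (donor d-Ala4 carboxyl to
acceptor mDAP3 amine, d,d-transpeptidation) or 3-3 (donor mDAP3 to acceptor
mDAP3, l,d-transpeptidation); each cross-link is a condensation that loses one
water.

All arithmetic is done on elemental compositions with full-precision
monoisotopic element masses (via :mod:`pyteomics.mass`).  The rounded values
commonly typed into commercial search software (e.g. 438.185 for reduced
GlcN-MurNAc, 172.0848 for mDAP) are reproduced by this model to within a
milli-Dalton; :data:`AS_CONFIGURED_GLYCOFORM_MASSES` carries those rounded
values for callers that need to mirror a search exactly as it was configured.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "CONSTANTS",
    "PhysicalConstants",
    "ResidueSpec",
    "RESIDUES",
    "MDAP_CODE",
    "MET_MDAP_OFFSET",
    "Glycoform",
    "GLYCOFORMS",
    "AS_CONFIGURED_GLYCOFORM_MASSES",
    "StemModification",
    "amidation",
    "anhydro_stem",
    "wildcard",
    "Muropeptide",
    "CrossLink",
    "CrosslinkedSpecies",
    "monomer",
    "chain_species",
    "residue_mass",
    "glycan_mass",
    "species_neutral_mass",
    "mz_from_neutral",
    "neutral_from_mz",
    "ppm_diff",
]

Composition = _pmass.Composition


def _fmass(formula: str) -> float:
    return _pmass.calculate_mass(formula=formula)


@dataclass(frozen=True)
class PhysicalConstants:
    """Shared mass constants (all monoisotopic, Da)."""

    proton_mass: float = _pmass.nist_mass["H+"][0][0]
    water_mass: float = _fmass("H2O")
    hydrogen_mass: float = _fmass("H")
    ammonia_mass: float = _fmass("NH3")
    #: monoisotopic element masses, keyed by element symbol
    elements: Mapping[str, float] = field(
        default_factory=lambda: {
            el: _pmass.nist_mass[el][0][0] for el in ("H", "C", "N", "O", "S")
        }
    )
    #: average spacing of an isotope cluster (13C - 12C)
    neutron_spacing: float = _pmass.nist_mass["C"][13][0] - _pmass.nist_mass["C"][12][0]


CONSTANTS = PhysicalConstants()

WATER = CONSTANTS.water_mass
PROTON = CONSTANTS.proton_mass
NH3 = CONSTANTS.ammonia_mass
H_ATOM = CONSTANTS.hydrogen_mass

#: single-letter code reserved for meso-diaminopimelic acid
MDAP_CODE = "m"
#: the fixed-modification mass used to encode mDAP as modified methionine
#: in software without custom residues (131.0405 + 41.0443 = 172.0848)
MET_MDAP_OFFSET = 41.0443


@dataclass(frozen=True)
class ResidueSpec:
    """One peptide-stem residue: dehydrated (in-chain) composition and mass."""

    code: str
    name: str
    composition: Composition

    @property
    def monoisotopic_mass(self) -> float:
        return _pmass.calculate_mass(composition=self.composition)


def _std_residues() -> dict[str, ResidueSpec]:
    names = {
        "A": "alanine", "C": "cysteine", "D": "aspartate", "E": "glutamate",
        "F": "phenylalanine", "G": "glycine", "H": "histidine", "I": "isoleucine",
        "K": "lysine", "L": "leucine", "M": "methionine", "N": "asparagine",
        "P": "proline", "Q": "glutamine", "R": "arginine", "S": "serine",
        "T": "threonine", "V": "valine", "W": "tryptophan", "Y": "tyrosine",
    }
    table = {
        code: ResidueSpec(code, name, Composition(_pmass.std_aa_comp[code]))
        for code, name in names.items()
    }
    table[MDAP_CODE] = ResidueSpec(
        MDAP_CODE, "meso-diaminopimelic acid", Composition(formula="C7H12N2O3")
    )
    return table


#: residue table: the 20 standard amino acids plus mDAP (code ``m``)
RESIDUES: dict[str, ResidueSpec] = _std_residues()


def residue_mass(code: str) -> float:
    """Monoisotopic residue (dehydrated) mass for a stem letter."""
    try:
        return RESIDUES[code].monoisotopic_mass
    except KeyError:
        raise KeyError(f"unknown residue code {code!r}") from None


# ---------------------------------------------------------------------------
# Glycans

#: glycosidic-addition compositions (already dehydrated).  MurNAc is stated as
#: the N-terminal modification left after the lactyl-Ala1 amide is formed;
#: anhydro-MurNAc follows the reduced-form mass convention (reduced - H2O).
_MONOSACCHARIDES: dict[str, Composition] = {
    "GlcN": Composition(formula="C6H11NO4"),            # 161.0688
    "GlcNAc": Composition(formula="C8H13NO5"),          # 203.0794
    "MurNAc": Composition(formula="C11H17NO7"),         # 275.1005 unreduced
    "deacetyl-MurNAc": Composition(formula="C9H15NO6"), # MurNAc - C2H2O
    "anhydro-MurNAc": Composition(formula="C11H17NO6"), # reduced - H2O
}

_REDUCIBLE = {"MurNAc", "deacetyl-MurNAc"}


@dataclass(frozen=True)
class Glycoform:
    """Ordered glycan on the stem N-terminus, e.g. ``(GlcN, MurNAc)``.

    ``reduced`` adds H2 (muramitol after borohydride treatment; the default,
    because every muramidase-released reducing end is reduced before LC).
    ``modification_mass_override`` mirrors a rounded value as typed into a
    search engine; when set it replaces the formula-derived mass.
    """

    monosaccharides: tuple[str, ...] = ()
    reduced: bool = True
    modification_mass_override: float | None = None

    def __post_init__(self) -> None:
        for sugar in self.monosaccharides:
            if sugar not in _MONOSACCHARIDES:
                raise ValueError(f"unsupported monosaccharide {sugar!r}")
        if "anhydro-MurNAc" in self.monosaccharides and self.reduced:
            raise ValueError("anhydro and reduced are mutually exclusive on MurNAc")
        if not self.monosaccharides and self.reduced:
            # an empty glycoform has nothing to reduce; normalise
            object.__setattr__(self, "reduced", False)

    @property
    def composition(self) -> Composition:
        comp = Composition()
        for sugar in self.monosaccharides:
            comp += _MONOSACCHARIDES[sugar]
        if self.reduced and any(s in _REDUCIBLE for s in self.monosaccharides):
            comp += Composition(formula="H2")
        return comp

    @property
    def modification_mass(self) -> float:
        """Mass added to a bare peptide stem (0 for the empty glycoform)."""
        if self.modification_mass_override is not None:
            return self.modification_mass_override
        if not self.monosaccharides:
            return 0.0
        return _pmass.calculate_mass(composition=self.composition)

    @property
    def name(self) -> str:
        if not self.monosaccharides:
            return "none"
        for nm, gf in GLYCOFORMS.items():
            if (
                gf.monosaccharides == self.monosaccharides
                and gf.reduced == self.reduced
            ):
                return nm
        return "-".join(self.monosaccharides) + ("(red)" if self.reduced else "")


#: the five glycoforms searched for C. difficile muropeptides, by the names
#: used in composition tables, plus the empty glycoform under "none"
GLYCOFORMS: dict[str, Glycoform] = {
    "MurNAc": Glycoform(("MurNAc",)),
    "GlcN-MurN": Glycoform(("GlcN", "deacetyl-MurNAc")),
    "GlcN-anhMurNAc": Glycoform(("GlcN", "anhydro-MurNAc"), reduced=False),
    "GlcN-MurNAc": Glycoform(("GlcN", "MurNAc")),
    "GlcNAc-MurNAc": Glycoform(("GlcNAc", "MurNAc")),
    "none": Glycoform(()),
}

#: N-terminal modification masses exactly as they are typed into a search
#: engine (three-decimal values); used to mirror a configured search
AS_CONFIGURED_GLYCOFORM_MASSES: dict[str, float] = {
    "MurNAc": 277.116,
    "GlcN-MurN": 396.174,
    "GlcN-anhMurNAc": 420.174,
    "GlcN-MurNAc": 438.185,
    "GlcNAc-MurNAc": 480.196,
    "none": 0.0,
}


def glycoform(name: str | None, as_configured: bool = False) -> Glycoform:
    """Look up a named glycoform; ``None``/"none" gives the empty glycan.

    With ``as_configured=True`` the rounded search-engine modification mass
    overrides the formula-derived one.
    """
    if name is None:
        name = "none"
    try:
        gf = GLYCOFORMS[name]
    except KeyError:
        raise KeyError(f"unknown glycoform {name!r}") from None
    if as_configured:
        gf = replace(
            gf, modification_mass_override=AS_CONFIGURED_GLYCOFORM_MASSES[name]
        )
    return gf


def glycan_mass(gf: Glycoform) -> float:
    """N-terminal modification mass of a glycoform (Da)."""
    return gf.modification_mass


# ---------------------------------------------------------------------------
# Stem modifications

#: amidation of a side-chain carboxyl: -OH + NH2, i.e. -O +NH = -0.98402 Da
AMIDATION_DELTA = _fmass("NH") - _fmass("O")
AMIDATION_COMP = Composition(formula="NH") - Composition(formula="O")

WILDCARD_RANGE = (-130.0, 210.0)


@dataclass(frozen=True)
class StemModification:
    """A per-residue mass modification on the peptide stem (1-based position)."""

    kind: str  # amidation | anhydro | wildcard
    delta_mass: float
    residue_position: int

    def __post_init__(self) -> None:
        if self.kind not in ("amidation", "anhydro", "wildcard"):
            raise ValueError(f"unknown stem modification kind {self.kind!r}")
        if self.residue_position < 1:
            raise ValueError("residue_position is 1-based")
        if self.kind == "wildcard" and not (
            WILDCARD_RANGE[0] <= self.delta_mass <= WILDCARD_RANGE[1]
        ):
            raise ValueError(
                f"wildcard delta {self.delta_mass:+.3f} outside {WILDCARD_RANGE}"
            )

    @property
    def composition(self) -> Composition | None:
        """Elemental composition of the delta, if it has one (wildcards do not)."""
        if self.kind == "amidation":
            return AMIDATION_COMP
        if self.kind == "anhydro":
            return Composition(formula="H-2O-1")
        return None


def amidation(position: int) -> StemModification:
    return StemModification("amidation", AMIDATION_DELTA, position)


def anhydro_stem(position: int) -> StemModification:
    """Water loss on a stem residue (e.g. anhydro-mDAP at the C-terminus)."""
    return StemModification("anhydro", -WATER, position)


def wildcard(delta: float, position: int) -> StemModification:
    return StemModification("wildcard", delta, position)


# ---------------------------------------------------------------------------
# Assembled species

_AMIDATABLE = {"E", MDAP_CODE}


@dataclass(frozen=True)
class Muropeptide:
    """One glycan chain plus one peptide stem with per-residue modifications."""

    glycoform: Glycoform = GLYCOFORMS["none"]
    stem: str = ""
    mods: tuple[StemModification, ...] = ()

    def __post_init__(self) -> None:
        for code in self.stem:
            if code not in RESIDUES:
                raise KeyError(f"unknown residue code {code!r} in stem {self.stem!r}")
        for mod in self.mods:
            if mod.residue_position > len(self.stem):
                raise ValueError(
                    f"modification position {mod.residue_position} beyond stem "
                    f"{self.stem!r}"
                )
            if (
                mod.kind == "amidation"
                and self.stem[mod.residue_position - 1] not in _AMIDATABLE
            ):
                raise ValueError(
                    "amidation allowed only on E or mDAP, not "
                    f"{self.stem[mod.residue_position - 1]!r}"
                )

    @property
    def neutral_mass(self) -> float:
        mass = self.glycoform.modification_mass + WATER
        mass += sum(residue_mass(c) for c in self.stem)
        mass += sum(mod.delta_mass for mod in self.mods)
        return mass

    @property
    def composition(self) -> Composition:
        """Elemental composition (independent of any rounded mass overrides).

        Raises for wildcard modifications, which carry no formula.
        """
        comp = Composition(formula="H2O") + self.glycoform.composition
        for code in self.stem:
            comp += RESIDUES[code].composition
        for mod in self.mods:
            mcomp = mod.composition
            if mcomp is None:
                raise ValueError("wildcard modifications have no elemental formula")
            comp += mcomp
        return comp

    def label(self) -> str:
        mods = "".join(
            f"[{m.kind[:4]}{m.delta_mass:+.3f}@{m.residue_position}]"
            for m in self.mods
        )
        return f"{self.glycoform.name}-{self.stem}{mods}"


@dataclass(frozen=True)
class CrossLink:
    """One cross-link: donor unit/position to acceptor unit/position (0-based units)."""

    donor_unit: int
    donor_position: int  # 3 => 3-3 link, 4 => 4-3 link
    acceptor_unit: int
    acceptor_position: int = 3

    def __post_init__(self) -> None:
        if self.donor_position not in (3, 4):
            raise ValueError("donor_position must be 3 (3-3) or 4 (4-3)")
        if self.acceptor_position != 3:
            raise ValueError("acceptor position is the mDAP in position 3")

    @property
    def topology(self) -> str:
        return "3-3" if self.donor_position == 3 else "4-3"


@dataclass(frozen=True)
class CrosslinkedSpecies:
    """An ordered list of muropeptide units joined by cross-links.

    By convention the first k-1 units are donors and the last is the terminal
    acceptor.  Each cross-link is a condensation losing one water.
    """

    units: tuple[Muropeptide, ...]
    links: tuple[CrossLink, ...] = ()

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("species needs at least one unit")
        if len(self.links) != len(self.units) - 1:
            raise ValueError(
                f"{len(self.units)} units need {len(self.units) - 1} links, "
                f"got {len(self.links)}"
            )
        for link in self.links:
            for idx in (link.donor_unit, link.acceptor_unit):
                if not 0 <= idx < len(self.units):
                    raise ValueError(f"link references unit {idx} of {len(self.units)}")
            donor = self.units[link.donor_unit]
            if link.donor_position == 3 and len(donor.stem) != 3:
                raise ValueError(
                    "a 3-3 donor is a tripeptide ending in mDAP, got stem "
                    f"{donor.stem!r}"
                )
            if link.donor_position == 4 and len(donor.stem) < 4:
                raise ValueError(
                    f"a 4-3 donor needs a residue in position 4, got {donor.stem!r}"
                )
            acceptor = self.units[link.acceptor_unit]
            if len(acceptor.stem) < 3 or acceptor.stem[2] != MDAP_CODE:
                raise ValueError(
                    f"acceptor stem {acceptor.stem!r} has no mDAP in position 3"
                )
        if len(self.units) > 1 and not self._connected():
            raise ValueError("cross-link graph does not connect all units")

    def _connected(self) -> bool:
        adj: dict[int, set[int]] = {i: set() for i in range(len(self.units))}
        for link in self.links:
            adj[link.donor_unit].add(link.acceptor_unit)
            adj[link.acceptor_unit].add(link.donor_unit)
        seen = {0}
        stack = [0]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == len(self.units)

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def neutral_mass(self) -> float:
        return sum(u.neutral_mass for u in self.units) - len(self.links) * WATER

    @property
    def composition(self) -> Composition:
        comp = Composition()
        for unit in self.units:
            comp += unit.composition
        comp -= Composition(formula="H2O") * len(self.links)
        return comp

    @property
    def size_class(self) -> str:
        return {1: "monomer", 2: "dimer", 3: "trimer"}.get(
            self.n_units, f"{self.n_units}-mer"
        )

    @property
    def topologies(self) -> tuple[str, ...]:
        return tuple(link.topology for link in self.links)

    def n_modifications(self) -> int:
        return sum(len(u.mods) for u in self.units)

    def label(self) -> str:
        parts = [u.label() for u in self.units]
        links = ",".join(
            f"{l.donor_unit + 1}:{l.donor_position}>{l.acceptor_unit + 1}:3"
            for l in self.links
        )
        return " + ".join(parts) + (f" [{links}]" if links else "")

    def composition_key(self) -> tuple:
        """Order-insensitive content key: unit multiset, ignoring topology.

        Two species with the same key are built from the same monomer content
        and the same number of cross-links (hence equal mass when the residue
        multisets agree).
        """
        return (
            tuple(sorted((u.glycoform.name, u.stem, u.mods) for u in self.units)),
            len(self.links),
        )


def monomer(
    stem: str,
    glyco: str | Glycoform | None = "GlcN-MurNAc",
    mods: Iterable[StemModification] = (),
    as_configured: bool = False,
) -> CrosslinkedSpecies:
    """Convenience constructor for a single muropeptide species."""
    gf = glyco if isinstance(glyco, Glycoform) else glycoform(glyco, as_configured)
    return CrosslinkedSpecies((Muropeptide(gf, stem, tuple(mods)),))


def chain_species(
    stems: Sequence[str],
    glycos: Sequence[str | Glycoform | None],
    as_configured: bool = False,
) -> CrosslinkedSpecies:
    """Build a linear donor chain: unit i donates to unit i+1, last is acceptor.

    The link topology follows the donor stem: a tripeptide (AEm) donates 3-3
    from its mDAP, a longer stem (AEmA) donates 4-3 from its position-4 Ala.
    """
    if len(stems) != len(glycos):
        raise ValueError("stems and glycoforms must align")
    units = []
    for stem, glyco in zip(stems, glycos):
        gf = glyco if isinstance(glyco, Glycoform) else glycoform(glyco, as_configured)
        units.append(Muropeptide(gf, stem))
    links = []
    for i in range(len(units) - 1):
        pos = 3 if len(units[i].stem) == 3 else 4
        links.append(CrossLink(i, pos, i + 1))
    return CrosslinkedSpecies(tuple(units), tuple(links))


def species_neutral_mass(species: CrosslinkedSpecies) -> float:
    """Neutral monoisotopic mass: unit masses minus one water per cross-link."""
    return species.neutral_mass


# ---------------------------------------------------------------------------
# m/z arithmetic


def mz_from_neutral(neutral_mass: float, charge: int) -> float:
    """(M + z * proton) / z for a positive ion."""
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return (neutral_mass + charge * PROTON) / charge


def neutral_from_mz(mz: float, charge: int) -> float:
    if charge < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    return mz * charge - charge * PROTON


def ppm_diff(m1: float, m2: float) -> float:
    """Relative difference in parts per million, |m1 - m2| / min(m1, m2)."""
    if m1 <= 0 or m2 <= 0:
        raise ValueError("masses must be positive")
    return 1e6 * abs(m1 - m2) / min(m1, m2)


def amidation_states(stem: str) -> list[tuple[StemModification, ...]]:
    """All amidation on/off combinations over the E and mDAP sites of a stem."""
    sites = [i + 1 for i, c in enumerate(stem) if c in _AMIDATABLE]
    states: list[tuple[StemModification, ...]] = []
    for r in range(len(sites) + 1):
        for combo in itertools.combinations(sites, r):
            states.append(tuple(amidation(p) for p in combo))
    return states
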