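"""Candidate enumeration for monomer, dimer and trimer searches.

The search space mirrors how a muropeptide search is actually configured:
a handful of peptide stems (read from a FASTA-like list), the five glycoforms
seen in *C. difficile* digests, optional amidation, and — for multimers — the
biological constraint that every donor stem is either the tripeptide AEm
(3-3 links, l,d-transpeptidation) or the tetrapeptide AEmA (4-3 links,
d,d-transpeptidation), while the terminal acceptor may be any monomer stem
discovered in the monomer pass.

A separate wildcard pass finds unanticipated single-residue mass deltas in a
stated window, annotating deltas that coincide with a standard residue
substitution or a water loss.
"""

from __future__ import annotations

import io
import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import chem
from .chem import (
    CrossLink,
    CrosslinkedSpecies,
    Muropeptide,
    StemModification,
    glycoform,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "CandidateDB",
    "WildcardHit",
    "build_monomer_db",
    "build_multimer_db",
    "resolve_wildcard",
    "read_stems_fasta",
    "DEFAULT_STEMS",
    "DEFAULT_GLYCOFORMS",
    "MULTIMER_GLYCOFORMS",
]

#: monomer-search stems
DEFAULT_STEMS = ("AEm", "AEmA", "AEmG")
#: glycoform names enabled as variable N-terminal modifications in the
#: monomer search (plus "none")
DEFAULT_GLYCOFORMS = (
    "MurNAc",
    "GlcN-MurN",
    "GlcN-anhMurNAc",
    "GlcN-MurNAc",
    "GlcNAc-MurNAc",
)
#: the five per-unit glycosylation options of the multimer searches
#: (no glycan, MurNAc, GlcN-MurN, GlcN-MurNAc, GlcNAc-MurNAc)
MULTIMER_GLYCOFORMS = ("none", "MurNAc", "GlcN-MurN", "GlcN-MurNAc", "GlcNAc-MurNAc")


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of one search pass."""

    stems: tuple[str, ...] = DEFAULT_STEMS
    glycoforms: tuple[str, ...] = DEFAULT_GLYCOFORMS
    amidation: bool = False
    anhydro: bool = True
    wildcard_range: tuple[float, float] | None = None
    donor_stems: tuple[str, ...] = ("AEm", "AEmA")
    max_units: int = 1
    charge_range: tuple[int, int] = (1, 4)
    precursor_tol_ppm: float = 5.0
    hcd_tol_ppm: float = 20.0
    etd_tol_da: float = 0.5
    as_configured_masses: bool = False

    def __post_init__(self) -> None:
        if self.max_units not in (1, 2, 3):
            raise ValueError("max_units must be 1, 2 or 3")
        if self.max_units > 1:
            bad = set(self.donor_stems) - {"AEm", "AEmA"}
            if bad:
                raise ValueError(f"multimer donor stems restricted to AEm/AEmA: {bad}")
        if self.wildcard_range is not None and self.amidation:
            # the two-pass strategy: wildcard runs with variable mods off
            raise ValueError("wildcard and amidation are separate search passes")

    @property
    def effective_glycoforms(self) -> tuple[str, ...]:
        if self.anhydro:
            return self.glycoforms
        return tuple(g for g in self.glycoforms if "anh" not in g)


class CandidateDB:
    """A list of candidate species with a sorted mass index for ppm lookup."""

    def __init__(self, entries: Sequence[CrosslinkedSpecies]):
        self.entries: list[CrosslinkedSpecies] = list(entries)
        masses = np.array([e.neutral_mass for e in self.entries], dtype=float)
        self._order = np.argsort(masses, kind="stable")
        self._sorted_masses = masses[self._order]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def masses(self) -> np.ndarray:
        return self._sorted_masses

    def distinct_mass_count(self, tol_ppm: float = 5.0) -> int:
        """Number of masses separated by more than ``tol_ppm`` from the next."""
        if not len(self):
            return 0
        m = self._sorted_masses
        gaps = np.diff(m) / m[:-1] * 1e6
        return int(np.sum(gaps > tol_ppm)) + 1

    def query_mass(self, neutral_mass: float, tol_ppm: float) -> list[int]:
        """Indices of entries within ``tol_ppm`` of a neutral mass."""
        tol = neutral_mass * tol_ppm * 1e-6
        lo = np.searchsorted(self._sorted_masses, neutral_mass - tol, side="left")
        hi = np.searchsorted(self._sorted_masses, neutral_mass + tol, side="right")
        return [int(self._order[i]) for i in range(lo, hi)]

    def query_mz(self, mz: float, charge: int, tol_ppm: float) -> list[int]:
        return self.query_mass(chem.neutral_from_mz(mz, charge), tol_ppm)

    # -- TSV round trip -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "units": e.n_units,
                    "stems": ";".join(u.stem for u in e.units),
                    "glycoforms": ";".join(u.glycoform.name for u in e.units),
                    "links": ";".join(
                        f"{l.donor_unit + 1}:{l.donor_position}>{l.acceptor_unit + 1}:3"
                        for l in e.links
                    ),
                    "mods": ";".join(
                        f"{u_i + 1}:{m.kind}:{m.residue_position}:{m.delta_mass:.5f}"
                        for u_i, u in enumerate(e.units)
                        for m in u.mods
                    ),
                    "neutral_mass": e.neutral_mass,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["units", "stems", "glycoforms", "links", "mods", "neutral_mass"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CandidateDB":
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        entries = []
        for _, row in df.iterrows():
            stems = str(row["stems"]).split(";")
            glycos = str(row["glycoforms"]).split(";")
            per_unit_mods: dict[int, list[StemModification]] = {}
            if row["mods"]:
                for tok in str(row["mods"]).split(";"):
                    u_i, kind, pos, delta = tok.split(":")
                    per_unit_mods.setdefault(int(u_i) - 1, []).append(
                        StemModification(kind, float(delta), int(pos))
                    )
            units = tuple(
                Muropeptide(
                    glycoform(g), s, tuple(per_unit_mods.get(i, ()))
                )
                for i, (s, g) in enumerate(zip(stems, glycos))
            )
            links = []
            if row["links"]:
                for tok in str(row["links"]).split(";"):
                    donor, acceptor = tok.split(">")
                    d_u, d_p = donor.split(":")
                    a_u, _ = acceptor.split(":")
                    links.append(CrossLink(int(d_u) - 1, int(d_p), int(a_u) - 1))
            entries.append(CrosslinkedSpecies(units, tuple(links)))
        return cls(entries)


# ---------------------------------------------------------------------------
# Builders


def build_monomer_db(config: SearchConfig) -> CandidateDB:
    """One entry per stem x glycoform-or-none x allowed modification state."""
    if config.max_units != 1:
        raise ValueError("build_monomer_db requires max_units = 1")
    if not config.stems:
        warnings.warn("empty stem list: monomer database is empty", stacklevel=2)
        return CandidateDB([])
    entries = []
    glyco_options = config.effective_glycoforms + ("none",)
    for stem in config.stems:
        states = chem.amidation_states(stem) if config.amidation else [()]
        for glyco_name in glyco_options:
            gf = glycoform(glyco_name, config.as_configured_masses)
            for mods in states:
                entries.append(CrosslinkedSpecies((Muropeptide(gf, stem, mods),)))
    db = CandidateDB(entries)
    logger.info(
        "monomer DB: %d entries, %d distinct masses", len(db), db.distinct_mass_count()
    )
    return db


def _dedup_key(species: CrosslinkedSpecies) -> tuple:
    """Unordered-donor deduplication key.

    Donor units (all but the terminal acceptor) are interchangeable as a
    multiset; the key also carries the terminal acceptor and the multiset of
    link topologies.
    """
    donors = tuple(
        sorted((u.stem, u.glycoform.name, u.mods) for u in species.units[:-1])
    )
    terminal = species.units[-1]
    return (
        donors,
        (terminal.stem, terminal.glycoform.name, terminal.mods),
        tuple(sorted(species.topologies)),
    )


def build_multimer_db(
    config: SearchConfig,
    acceptor_stems: Sequence[str],
    deduplicate: bool = True,
) -> CandidateDB:
    """Enumerate dimer/trimer candidates.

    Non-terminal units draw their stems from ``config.donor_stems`` (AEm
    donates 3-3, AEmA donates 4-3) and the terminal acceptor from
    ``acceptor_stems`` (the monomer stems discovered in the monomer pass).
    Each unit independently takes one of the configured glycosylation options.
    Entries differing only in donor order are deduplicated.
    """
    if config.max_units not in (2, 3):
        raise ValueError("build_multimer_db requires max_units of 2 or 3")
    if not acceptor_stems:
        raise ValueError("acceptor stem list is empty")
    k = config.max_units
    glyco_options = config.glycoforms
    entries: list[CrosslinkedSpecies] = []
    seen: set[tuple] = set()
    n_ordered = 0
    for donor_combo in itertools.product(config.donor_stems, repeat=k - 1):
        for acceptor in acceptor_stems:
            stems = donor_combo + (acceptor,)
            for glyco_combo in itertools.product(glyco_options, repeat=k):
                n_ordered += 1
                units = tuple(
                    Muropeptide(
                        glycoform(g, config.as_configured_masses), s
                    )
                    for s, g in zip(stems, glyco_combo)
                )
                links = tuple(
                    CrossLink(i, 3 if len(stems[i]) == 3 else 4, i + 1)
                    for i in range(k - 1)
                )
                species = CrosslinkedSpecies(units, links)
                if deduplicate:
                    key = _dedup_key(species)
                    if key in seen:
                        continue
                    seen.add(key)
                entries.append(species)
    db = CandidateDB(entries)
    logger.info(
        "%d-mer DB: %d ordered combinations, %d entries after dedup, "
        "%d distinct masses",
        k,
        n_ordered,
        len(db),
        db.distinct_mass_count(),
    )
    return db


# ---------------------------------------------------------------------------
# Wildcard pass


@dataclass(frozen=True)
class WildcardHit:
    """A base candidate explaining an observed mass via one residue delta."""

    entry_index: int
    entry: CrosslinkedSpecies
    delta: float
    admissible_positions: tuple[int, ...]
    annotations: tuple[str, ...] = ()


def _annotate_delta(stem: str, delta: float, tol_da: float) -> list[str]:
    notes = []
    if abs(delta + chem.WATER) <= tol_da:
        notes.append("water loss (anhydro residue, e.g. C-terminal anhydro-mDAP)")
    for pos, code in enumerate(stem, start=1):
        base = chem.residue_mass(code)
        for other, spec in chem.RESIDUES.items():
            if other == code:
                continue
            if abs(delta - (spec.monoisotopic_mass - base)) <= tol_da:
                label = "I/L" if other in ("I", "L") else other
                note = f"position-{pos} {code}→{label} substitution"
                if note not in notes:
                    notes.append(note)
    return notes


def resolve_wildcard(
    observed_neutral: float,
    base_db: CandidateDB,
    tol_ppm: float = 5.0,
    wildcard_range: tuple[float, float] = chem.WILDCARD_RANGE,
) -> list[WildcardHit]:
    """Explain an observed neutral mass as base candidate + one residue delta.

    The delta must lie inside the wildcard window and outside the plain
    precursor tolerance (otherwise the base candidate already matches).
    Deltas coinciding with a standard residue substitution or a water loss are
    annotated.
    """
    hits = []
    lo, hi = wildcard_range
    for idx, entry in enumerate(base_db.entries):
        if entry.n_units != 1:
            raise ValueError("wildcard resolution runs on a monomer database")
        delta = observed_neutral - entry.neutral_mass
        tol_da = observed_neutral * tol_ppm * 1e-6
        if not (lo <= delta <= hi) or abs(delta) <= tol_da:
            continue
        stem = entry.units[0].stem
        hits.append(
            WildcardHit(
                entry_index=idx,
                entry=entry,
                delta=delta,
                admissible_positions=tuple(range(1, len(stem) + 1)),
                annotations=tuple(_annotate_delta(stem, delta, tol_da)),
            )
        )
    # interpretable deltas (substitutions, water loss) rank ahead of bare ones
    hits.sort(key=lambda h: (0 if h.annotations else 1, abs(h.delta)))
    return hits


# ---------------------------------------------------------------------------
# FASTA stems


def read_stems_fasta(source, met_as_mdap: bool = True) -> tuple[str, ...]:
    """Read peptide stems from a FASTA-like list.

    With ``met_as_mdap`` (the import convention for software that encodes mDAP
    as methionine + 41.0443), every ``M`` is converted to the reserved mDAP
    code ``m``; sequences may also use ``m`` directly.
    """
    if isinstance(source, (str,)) and "\n" in source:
        handle: io.TextIOBase | str = io.StringIO(source)
    else:
        handle = source
    stems = []
    # pearson variant: ';' comment lines carry the residue-code convention
    for record in SeqIO.parse(handle, "fasta-pearson"):
        seq = str(record.seq)
        if met_as_mdap:
            seq = seq.replace("M", chem.MDAP_CODE)
        for code in seq:
            if code not in chem.RESIDUES:
                raise KeyError(f"unknown residue code {code!r} in stem {seq!r}")
        stems.append(seq)
    return tuple(stems)


def stems_to_fasta(stems: Iterable[str], met_convention: bool = False) -> str:
    """Serialise stems to FASTA; optionally re-encode mDAP as M (met + 41.0443)."""
    lines = [
        "; peptide stems; 'm' denotes meso-diaminopimelic acid (mDAP)"
        if not met_convention
        else "; peptide stems; M denotes mDAP via fixed +41.0443 on methionine"
    ]
    for i, stem in enumerate(stems, start=1):
        seq = stem.replace(chem.MDAP_CODE, "M") if met_convention else stem
        lines.append(f">stem_{i} {stem}")
        lines.append(seq)
    return "\n".join(lines) + "\n"
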