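"""XIC extraction, charge-state summation, in-source-decay flagging and
class-level composition summaries.

The quantity reported per species is the extracted-ion-chromatogram (XIC)
integral of the monoisotopic precursor, summed over the charge states in
which the species was observed.  The integral is the plain sum of per-scan
ion counts (not a trapezoid over retention time), so it is proportional to
scan rate — a caveat, not a bug, since all comparisons are within one run.

A species that lacks one or more monosaccharides relative to a fuller
glycoform of the same peptide content, and whose elution profile tracks the
fuller form essentially exactly (apex within 0.1 min and Pearson r >= 0.95),
is flagged as in-source decay: glycan loss in the electrospray source rather
than a genuine digestion product.  Flagged integrals can be reported merged
into the parent or kept separate; the two views conserve the total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import chem
from .chem import CrosslinkedSpecies
from .identification import Identification, SpectrumRecord

__all__ = [
    "XicTrace",
    "QuantRow",
    "extract_xic",
    "quantify",
    "flag_in_source_decay",
    "class_percentages",
    "quant_frame",
]


@dataclass
class XicTrace:
    """Per-MS1-scan intensity at a target m/z window."""

    target_mz: float
    tol_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    @property
    def integral(self) -> float:
        return float(self.intensity.sum())

    @property
    def apex_rt(self) -> float:
        if self.rt.size == 0 or self.intensity.max(initial=0.0) <= 0:
            return float("nan")
        return float(self.rt[int(np.argmax(self.intensity))])


@dataclass
class QuantRow:
    species: CrosslinkedSpecies
    species_label: str
    charges_observed: tuple[int, ...]
    total_integral: float
    size_class: str
    apex_rt: float
    percent_of_total: float = float("nan")
    in_source_decay_parent: str | None = None


def extract_xic(
    run: Sequence[SpectrumRecord],
    target_mz: float,
    tol_ppm: float = 10.0,
    rt_window: tuple[float, float] | None = None,
) -> XicTrace:
    """Sum, per MS1 scan, the intensities of peaks within +/- tol_ppm of the
    target m/z; the trace is restricted to ``rt_window`` when given."""
    ms1 = [s for s in run if s.ms_level == 1]
    if not ms1:
        raise ValueError("run contains no MS1 scans")
    tol = target_mz * tol_ppm * 1e-6
    rts, ints = [], []
    for scan in ms1:
        if rt_window is not None and not (
            rt_window[0] <= scan.retention_time <= rt_window[1]
        ):
            continue
        lo = np.searchsorted(scan.mz, target_mz - tol, side="left")
        hi = np.searchsorted(scan.mz, target_mz + tol, side="right")
        rts.append(scan.retention_time)
        ints.append(float(scan.intensity[lo:hi].sum()))
    return XicTrace(
        target_mz=target_mz,
        tol_ppm=tol_ppm,
        rt=np.asarray(rts, dtype=float),
        intensity=np.asarray(ints, dtype=float),
    )


def quantify(
    identifications: Sequence[Identification],
    run: Sequence[SpectrumRecord],
    tol_ppm: float = 10.0,
    rt_window: tuple[float, float] | None = None,
    charge_range: tuple[int, int] = (1, 4),
) -> tuple[list[QuantRow], dict[tuple[str, int], XicTrace]]:
    """One row per distinct identified species.

    The integral is the sum over charge states of the monoisotopic XIC
    integral.  Beyond the charges seen in MS2, every charge in
    ``charge_range`` with signal contributes (MS2 selection skips singly
    charged precursors, yet 1+ monomers still carry XIC signal).
    Percentages are of the total identified XIC quantity, so the per-class
    sums reproduce the class-level split.  Returns the rows and the
    per-(species, charge) traces.
    """
    if not identifications:
        raise ValueError("no identifications to quantify")
    by_species: dict[str, dict] = {}
    for ident in identifications:
        label = ident.candidate.label()
        rec = by_species.setdefault(
            label, {"species": ident.candidate, "charges": set()}
        )
        if ident.spectrum.precursor_charge:
            rec["charges"].add(int(ident.spectrum.precursor_charge))
    rows: list[QuantRow] = []
    traces: dict[tuple[str, int], XicTrace] = {}
    for label, rec in by_species.items():
        species = rec["species"]
        total = 0.0
        apex = float("nan")
        best = -np.inf
        observed: list[int] = []
        for z in range(charge_range[0], charge_range[1] + 1):
            trace = extract_xic(
                run, chem.mz_from_neutral(species.neutral_mass, z), tol_ppm, rt_window
            )
            if trace.integral <= 0 and z not in rec["charges"]:
                continue
            observed.append(z)
            traces[(label, z)] = trace
            total += trace.integral
            if trace.integral > best:
                best = trace.integral
                apex = trace.apex_rt
        charges = tuple(observed) or tuple(sorted(rec["charges"]))
        rows.append(
            QuantRow(
                species=species,
                species_label=label,
                charges_observed=charges,
                total_integral=total,
                size_class=species.size_class,
                apex_rt=apex,
            )
        )
    grand_total = sum(r.total_integral for r in rows)
    for r in rows:
        r.percent_of_total = (
            100.0 * r.total_integral / grand_total if grand_total > 0 else float("nan")
        )
    rows.sort(key=lambda r: -r.total_integral)
    return rows, traces


# ---------------------------------------------------------------------------
# In-source decay


def _glycan_subform(sub: CrosslinkedSpecies, parent: CrosslinkedSpecies) -> bool:
    """True if ``sub`` equals ``parent`` in peptide content and links, with each
    unit's glycan either identical or missing distal monosaccharides."""
    if sub.n_units != parent.n_units or sub.links != parent.links:
        return False
    strictly_smaller = False
    for u_sub, u_par in zip(sub.units, parent.units):
        if u_sub.stem != u_par.stem or u_sub.mods != u_par.mods:
            return False
        s_sugars = u_sub.glycoform.monosaccharides
        p_sugars = u_par.glycoform.monosaccharides
        if s_sugars == p_sugars:
            continue
        # must be a suffix (distal sugars lost) or the empty glycan
        if len(s_sugars) >= len(p_sugars):
            return False
        if s_sugars and p_sugars[-len(s_sugars):] != s_sugars:
            return False
        strictly_smaller = True
    return strictly_smaller


def _best_trace(label: str, traces: dict[tuple[str, int], XicTrace]) -> XicTrace | None:
    cands = [t for (lbl, _), t in traces.items() if lbl == label]
    if not cands:
        return None
    return max(cands, key=lambda t: t.integral)


def flag_in_source_decay(
    rows: Sequence[QuantRow],
    traces: dict[tuple[str, int], XicTrace],
    apex_tol_min: float = 0.1,
    min_correlation: float = 0.95,
) -> list[QuantRow]:
    """Flag glycan-loss satellites that co-elute exactly with a fuller parent.

    A row is flagged iff (1) its species is a glycan sub-form of another
    row's species, (2) the XIC apexes differ by at most ``apex_tol_min``
    minutes and (3) the Pearson correlation of the overlapping trace points is
    at least ``min_correlation``.  Rows without a glycoform relationship are
    never flagged regardless of co-elution.
    """
    rows = list(rows)
    for row in rows:
        best_parent = None
        for parent in rows:
            if parent is row:
                continue
            if not _glycan_subform(row.species, parent.species):
                continue
            t_row = _best_trace(row.species_label, traces)
            t_par = _best_trace(parent.species_label, traces)
            if t_row is None or t_par is None:
                continue
            if not (
                np.isfinite(t_row.apex_rt)
                and np.isfinite(t_par.apex_rt)
                and abs(t_row.apex_rt - t_par.apex_rt) <= apex_tol_min
            ):
                continue
            common = np.intersect1d(t_row.rt, t_par.rt)
            if common.size < 3:
                continue
            a = t_row.intensity[np.isin(t_row.rt, common)]
            b = t_par.intensity[np.isin(t_par.rt, common)]
            if a.std() == 0 or b.std() == 0:
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            if r >= min_correlation:
                best_parent = parent.species_label
                break
        row.in_source_decay_parent = best_parent
    return rows


def merge_in_source_decay(rows: Sequence[QuantRow]) -> list[QuantRow]:
    """Merge flagged satellite integrals into their parents.

    Total integral is conserved exactly; percentages are recomputed.
    """
    merged: dict[str, QuantRow] = {}
    extra: dict[str, float] = {}
    for row in rows:
        if row.in_source_decay_parent is None:
            merged[row.species_label] = QuantRow(
                species=row.species,
                species_label=row.species_label,
                charges_observed=row.charges_observed,
                total_integral=row.total_integral,
                size_class=row.size_class,
                apex_rt=row.apex_rt,
            )
        else:
            extra[row.in_source_decay_parent] = (
                extra.get(row.in_source_decay_parent, 0.0) + row.total_integral
            )
    for parent_label, add in extra.items():
        if parent_label in merged:
            merged[parent_label].total_integral += add
    out = list(merged.values())
    grand = sum(r.total_integral for r in out)
    for r in out:
        r.percent_of_total = 100.0 * r.total_integral / grand if grand > 0 else 0.0
    out.sort(key=lambda r: -r.total_integral)
    return out


# ---------------------------------------------------------------------------
# Reports


def class_percentages(rows: Sequence[QuantRow]) -> dict[str, float]:
    """Per-class share of the total identified XIC quantity, in percent."""
    total = sum(r.total_integral for r in rows)
    out: dict[str, float] = {}
    for row in rows:
        out[row.size_class] = out.get(row.size_class, 0.0) + row.total_integral
    return {k: (100.0 * v / total if total > 0 else 0.0) for k, v in out.items()}


def quant_frame(rows: Sequence[QuantRow]) -> pd.DataFrame:
    """Quant table mirroring the standard composition-table columns."""
    return pd.DataFrame(
        {
            "Peptides": [
                ", ".join(u.stem for u in r.species.units) for r in rows
            ],
            "Charges": [
                ", ".join(str(z) for z in r.charges_observed) for r in rows
            ],
            "Glycans": [
                ", ".join(u.glycoform.name for u in r.species.units) for r in rows
            ],
            "Links": [", ".join(r.species.topologies) for r in rows],
            "Neutral mass": [round(r.species.neutral_mass, 3) for r in rows],
            "Elution time": [round(r.apex_rt, 2) for r in rows],
            "XIC integral": [r.total_integral for r in rows],
            "% of XICs sum": [round(r.percent_of_total, 2) for r in rows],
            "In-source decay of": [r.in_source_decay_parent or "" for r in rows],
        }
    )


def tic_frame(run: Sequence[SpectrumRecord]) -> pd.DataFrame:
    """Total-ion-chromatogram export (MS1 scans) for plotting."""
    ms1 = [s for s in run if s.ms_level == 1]
    return pd.DataFrame(
        {
            "rt_min": [s.retention_time for s in ms1],
            "tic": [s.total_intensity for s in ms1],
        }
    )
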