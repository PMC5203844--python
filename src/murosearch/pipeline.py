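"""End-to-end orchestration: build-db -> search -> quantify -> call-links -> report.

The default recipe is the two-pass strategy: a standard search (stems x
glycoforms x amidation, plus dimer/trimer databases whose terminal acceptors
are the monomer stems actually identified), then an optional wildcard pass
with variable modifications off that explains leftover precursors as a base
monomer plus one residue mass delta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import (
    chem,
    crosslink_calls,
    identification as ident_mod,
    mzml_io,
    quantitation,
    search_space,
)
from .config import DEFAULT_CONFIG
from .identification import Identification, SpectrumRecord

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and input context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"{stage} stage: {message}")


@dataclass
class RunReport:
    class_percentages: dict[str, float]
    quant_rows: list[quantitation.QuantRow]
    quant_table: pd.DataFrame
    topology_calls: list[crosslink_calls.ConsensusCall]
    isobaric_annotations: list[str]
    unidentified_masses: list[float]
    identifications: list[Identification]
    sequence_variants: list[search_space.WildcardHit] = field(default_factory=list)
    log: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.quant_table.to_csv(outdir / "quant.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "composition": [c.composition for c in self.topology_calls],
                "call": [c.call for c in self.topology_calls],
                "n_spectra": [c.n_spectra for c in self.topology_calls],
                "n_conflicts": [c.n_conflicts for c in self.topology_calls],
                "note": [c.note for c in self.topology_calls],
            }
        ).to_csv(outdir / "topology_calls.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "scan": [i.spectrum.scan_id for i in self.identifications],
                "rt_min": [i.spectrum.retention_time for i in self.identifications],
                "candidate": [i.candidate.label() for i in self.identifications],
                "charge": [
                    i.spectrum.precursor_charge for i in self.identifications
                ],
                "ppm_error": [i.precursor_ppm_error for i in self.identifications],
                "score": [i.score for i in self.identifications],
                "isobaric_group": [i.isobaric_group for i in self.identifications],
            }
        ).to_csv(outdir / "identifications.tsv", sep="\t", index=False)


def _load_run(config: dict, run: Sequence[SpectrumRecord] | None):
    if run is not None:
        return list(run)
    if not config.get("mzml"):
        raise PipelineError("input", "config references neither an mzML nor spectra")
    return mzml_io.read_mzml(config["mzml"])


def _build_databases(config: dict, acceptor_stems: Sequence[str]):
    base = search_space.SearchConfig(
        stems=tuple(config["stems"]),
        glycoforms=tuple(config["glycoforms"]),
        amidation=bool(config["amidation"]),
        anhydro=bool(config["anhydro"]),
        precursor_tol_ppm=float(config["precursor_tol_ppm"]),
        as_configured_masses=bool(config["as_configured_masses"]),
    )
    monomer_db = search_space.build_monomer_db(base)
    dbs = [monomer_db]
    for k in (2, 3):
        if config["max_units"] >= k:
            multi_cfg = search_space.SearchConfig(
                stems=tuple(config["stems"]),
                glycoforms=tuple(config["multimer_glycoforms"]),
                max_units=k,
                as_configured_masses=bool(config["as_configured_masses"]),
            )
            dbs.append(search_space.build_multimer_db(multi_cfg, list(acceptor_stems)))
    combined = search_space.CandidateDB(
        [e for db in dbs for e in db.entries]
    )
    return monomer_db, combined


def run_pipeline(
    config: dict | None = None,
    run: Sequence[SpectrumRecord] | None = None,
) -> RunReport:
    """Execute all stages on one run with the configured tolerances."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})

    spectra = _load_run(cfg, run)
    ms2 = [s for s in spectra if s.ms_level == 2]
    if not ms2:
        raise PipelineError("search", "run contains no MS2 spectra")
    if not any(s.ms_level == 1 for s in spectra):
        raise PipelineError("quantify", "run contains no MS1 scans")

    # pass 0: monomer-only search to discover acceptor stems
    mono_cfg = search_space.SearchConfig(
        stems=tuple(cfg["stems"]),
        glycoforms=tuple(cfg["glycoforms"]),
        amidation=bool(cfg["amidation"]),
        anhydro=bool(cfg["anhydro"]),
        as_configured_masses=bool(cfg["as_configured_masses"]),
    )
    mono_db = search_space.build_monomer_db(mono_cfg)
    found_stems: list[str] = []
    for spec in ms2:
        for idx, _ in ident_mod.match_precursor(
            spec.precursor_mz, spec.precursor_charge, mono_db, cfg["precursor_tol_ppm"]
        ):
            stem = mono_db.entries[idx].units[0].stem
            if stem not in found_stems:
                found_stems.append(stem)
    # donor stems are valid terminal acceptors too: a donor peptide present in
    # cross-linked form is available as the last unit of a longer oligomer
    for stem in ("AEm", "AEmA"):
        if stem not in found_stems:
            found_stems.append(stem)
    acceptors = found_stems

    monomer_db, db = _build_databases(cfg, acceptors)
    groups = ident_mod.isobaric_groups(db, cfg["precursor_tol_ppm"])
    group_of = {
        idx: gi for gi, group in enumerate(groups) for idx in group
    }

    identifications: list[Identification] = []
    unmatched: list[SpectrumRecord] = []
    for spec in ms2:
        try:
            cands = ident_mod.match_precursor(
                spec.precursor_mz, spec.precursor_charge, db, cfg["precursor_tol_ppm"]
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise PipelineError("search", f"scan {spec.scan_id}: {exc}") from exc
        if not cands:
            unmatched.append(spec)
            continue
        ranked = ident_mod.score_and_rank(
            spec, cands, db, cfg["hcd_tol_ppm"], cfg["etd_tol_da"]
        )
        top = ranked[0]
        top.isobaric_group = group_of.get(top.candidate_index)
        identifications.append(top)

    # wildcard pass on leftover precursors (variable mods off)
    variants: list[search_space.WildcardHit] = []
    if cfg["wildcard"]:
        wc_cfg = search_space.SearchConfig(
            stems=tuple(cfg["stems"]),
            glycoforms=tuple(cfg["glycoforms"]),
            amidation=False,
            wildcard_range=tuple(cfg["wildcard_range"]),
            as_configured_masses=bool(cfg["as_configured_masses"]),
        )
        wc_db = search_space.build_monomer_db(wc_cfg)
        still_unmatched = []
        for spec in unmatched:
            neutral = chem.neutral_from_mz(spec.precursor_mz, spec.precursor_charge)
            hits = search_space.resolve_wildcard(
                neutral, wc_db, cfg["precursor_tol_ppm"], tuple(cfg["wildcard_range"])
            )
            if hits:
                variants.append(hits[0])
            else:
                still_unmatched.append(spec)
        unmatched = still_unmatched

    if not identifications:
        raise PipelineError("search", "no precursor matched any candidate")

    try:
        rows, traces = quantitation.quantify(
            identifications, spectra, cfg["xic_tol_ppm"]
        )
        rows = quantitation.flag_in_source_decay(
            rows, traces, cfg["isd_apex_tol_min"], cfg["isd_min_correlation"]
        )
    except Exception as exc:
        raise PipelineError("quantify", str(exc)) from exc

    calls = crosslink_calls.batch_call(
        identifications,
        db,
        cfg["hcd_tol_ppm"],
        cfg["etd_tol_da"],
        cfg["precursor_tol_ppm"],
    )

    annotations = [
        ident_mod.group_annotation(db, g) for g in groups if len(g) > 1
    ]
    unidentified = sorted(
        {
            round(chem.neutral_from_mz(s.precursor_mz, s.precursor_charge), 3)
            for s in unmatched
        }
    )

    report = RunReport(
        class_percentages=quantitation.class_percentages(rows),
        quant_rows=rows,
        quant_table=quantitation.quant_frame(rows),
        topology_calls=calls,
        isobaric_annotations=annotations,
        unidentified_masses=unidentified,
        identifications=identifications,
        sequence_variants=variants,
        log={
            "n_ms2": len(ms2),
            "db_size": len(db),
            "distinct_masses": db.distinct_mass_count(),
            "n_identified": len(identifications),
            "match_rate": len(identifications) / len(ms2),
            "acceptor_stems": acceptors,
        },
    )
    logger.info("pipeline report: %s", report.log)
    if cfg.get("output_dir"):
        report.write(cfg["output_dir"])
    return report
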