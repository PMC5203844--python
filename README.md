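# murosearch

An open engine for automated structural analysis of bacterial peptidoglycan
by LC-MS/MS: muropeptide identification, 3–3 vs 4–3 cross-link
disambiguation, and extracted-ion-chromatogram (XIC) quantification — plus a
synthetic-run simulator so the whole pipeline is testable end to end.

## The problem

Peptidoglycan (PG) is the cell-wall polymer of β-1,4-linked
GlcNAc–MurNAc glycan chains carrying short peptide stems
(l-Ala–iso-d-Glu–mDAP–d-Ala–d-Ala in many bacteria, with mDAP =
*meso*-diaminopimelic acid). Stems are cross-linked either **4–3**
(donor d-Ala⁴ → acceptor mDAP³, d,d-transpeptidases, the penicillin target)
or **3–3** (donor mDAP³ → acceptor mDAP³, l,d-transpeptidases, not
β-lactam-inhibited). Muramidase digestion releases disaccharide-peptide
monomers, dimers and trimers ("muropeptides") that nano-LC-MS/MS can
identify and quantify — but conventional workflows annotate the spectra by
hand. `murosearch` automates the search: it enumerates the candidate space,
matches precursors at ppm accuracy, predicts topology-aware fragment ions
for cross-linked species, calls the cross-link form from diagnostic ETD
c/z ions, and integrates XICs into composition tables. Defaults model
*Clostridioides difficile* PG, which is heavily de-N-acetylated (GlcN
instead of GlcNAc) and mostly 3–3 cross-linked.

## The model in brief

* **Masses.** Everything is monoisotopic and built from elemental
  compositions: residue masses (20 amino acids + mDAP, 172.0848 Da),
  N-terminal glycoform masses (reduced MurNAc 277.116; GlcN-MurN 396.174;
  GlcN-anhydro-MurNAc 420.174; GlcN-MurNAc 438.185; GlcNAc-MurNAc 480.196),
  amidation (−0.984 on E/mDAP), and one −18.0106 condensation per
  cross-link:

  `M(species) = Σ_units (glycan + Σ residues + H₂O + Σ mods) − n_links × H₂O`

* **Search space.** Monomers = stems × glycoforms × modification states.
  Dimers/trimers restrict non-terminal donors to AEm (→3–3) or AEmA (→4–3)
  with any discovered monomer as terminal acceptor, deduplicated over donor
  order. A separate wildcard pass explains leftover precursors as a base
  monomer ± one residue mass delta in [−130, +210] Da.

* **Fragments.** b/y (HCD) and c/z, z+H (ETD) at every stem bond with the
  glycan kept N-terminal; glycosidic Y/B ions at the GlcN|MurNAc,
  MurNAc|lactyl and lactyl|Ala₁ bonds; internal fragments (HCD). For
  cross-linked species the prediction follows the link graph, so cleaving
  the cross-link amide yields the c/z pair that splits donor from acceptor
  content — the masses that distinguish isobaric 3–3/4–3 readings (e.g.
  c = 828.38 identifies an intact GlcN-MurNAc-AEm donor, 3–3; c = 899.42 an
  intact GlcN-MurNAc-AEmA donor, 4–3).

* **Quantification.** XIC integral = per-scan ion count of the monoisotopic
  precursor summed over charge states 1–4; class percentages over the total
  identified signal; glycan-loss satellites that co-elute exactly with a
  fuller parent (apex Δ ≤ 0.1 min, Pearson r ≥ 0.95) are flagged as
  in-source decay and can be merged or reported separately.

Tolerances default to 5 ppm (precursor), 20 ppm (HCD fragments) and 0.5 Da
(ETD fragments); all candidates are retained and ranked (score cut of zero)
because reversed-sequence decoys are uninformative for a search space this
small — isobaric-group annotations and per-ID ppm errors are reported
instead.

## Worked example

Simulate a ground-truth run (monomer/dimer/trimer ion counts injected at a
29.2 : 57.4 : 13.4 split over a 12-min window) and analyse it:

```sh
murosearch simulate --seed 7 --out demo.mzML --truth-out truth.tsv
murosearch report --mzml demo.mzML --out demo_report
```

prints

```
wrote 828 spectra to demo.mzML
{
  "class_percentages": {
    "dimer": 57.4,
    "monomer": 29.199999999999996,
    "trimer": 13.4
  },
  "n_ms2": 228,
  "db_size": 722,
  "distinct_masses": 216,
  "n_identified": 228,
  "match_rate": 1.0,
  "acceptor_stems": ["AEmA", "AEm"]
}
```

— every MS2 spectrum is identified and the injected class split is recovered
exactly. `demo_report/quant.tsv` mirrors a published-style composition
table:

```
Peptides        Charges  Glycans                                 Links     Neutral mass  Elution time  XIC integral  % of XICs sum
AEm, AEmA       2, 3     GlcN-MurNAc, GlcN-MurNAc                3-3       1709.747      6.0           1722000.0     57.4
AEmA            1, 2     GlcN-MurNAc                                       899.397       3.0           876000.0      29.2
AEm, AEm, AEmA  2, 3, 4  GlcN-MurNAc, GlcN-MurNAc, GlcN-MurNAc   3-3, 3-3  2520.096      9.0           402000.0      13.4
```

and `topology_calls.tsv` records the consensus 3–3 call for the dimer with
zero conflicting spectra. The same stages are available from Python
(`murosearch.run_pipeline`) and piecewise (`build-db`, `search`, `quantify`,
`call-links`).

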