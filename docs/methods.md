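# Methods

## Mass model

All masses are monoisotopic and derived from elemental compositions using
the standard element masses shipped with pyteomics. The residue table holds
the 20 proteinogenic amino acids plus *meso*-diaminopimelic acid (code `m`,
composition C₇H₁₂N₂O₃, 172.08479 Da). For interoperability with software
that lacks custom residues, FASTA import/export supports the convention of
writing mDAP as methionine with a fixed +41.0443 offset (131.0405 + 41.0443
= 172.0848).

Glycoforms are N-terminal stem modifications. The five shipped defaults are
stated as the mass added to a bare peptide stem, after borohydride
reduction of the MurNAc reducing end (+H₂, the default state because every
muramidase-released reducing end is reduced before LC to collapse anomers):

| glycoform        | composition route (Da) | as-configured (Da) |
|------------------|------------------------|--------------------|
| MurNAc           | 277.1162               | 277.116            |
| GlcN-MurN        | 396.1744               | 396.174            |
| GlcN-anhMurNAc   | 420.1744               | 420.174            |
| GlcN-MurNAc      | 438.1850               | 438.185            |
| GlcNAc-MurNAc    | 480.1955               | 480.196            |

The 1,6-anhydro form follows the *reduced-form* mass convention (reduced
minus one water, i.e. C₁₁H₁₇NO₆ for the MurNAc part); anhydro and reduced
are mutually exclusive on the same ring. "As-configured" masses are the
three-decimal values a user types into a search engine; they are carried as
optional overrides so a historical search can be mirrored exactly, while
internal arithmetic stays at full precision to avoid compounding rounding
across trimers (three glycoforms plus two cross-links would otherwise
accumulate ~5 mDa of rounding).

A cross-linked species is an ordered unit list plus link records
`(donor unit, donor position ∈ {3,4}, acceptor unit, acceptor position 3)`.
Donor position 3 (a tripeptide ending in mDAP) encodes a 3–3 link; donor
position 4 a 4–3 link. Each link is a condensation: the species mass is the
sum of unit masses minus one water per link. Validation enforces stem
length vs donor position, an mDAP in acceptor position 3, and a connected
link graph.

A note on the near-isobaric monomer pair GlcNAc-MurNAc-AEmA vs
GlcN-MurNAc-AEm(I/L): with full-precision compositions they differ by
38.65 ppm; with the as-configured three-decimal glycoform masses (how the
separation is seen inside a configured search) by 38.19 ppm, i.e. 38 ppm at
integer precision — either way ~8× the 5 ppm precursor tolerance, which is
why precursor mass alone resolves almost the entire search space.

## Search space

The monomer database is the product stems × (glycoforms + none) ×
modification states. Amidation (−0.98402, −OH→−NH₂) is enumerated
independently on each E and mDAP site (at most two sites per supported
stem). Dimers and trimers restrict the k−1 non-terminal units to the donor
stems AEm and AEmA — the substrates of l,d- and d,d-transpeptidases — and
take the terminal acceptor from the monomer stems actually identified in a
first monomer-only pass; the pipeline always adds AEm and AEmA to the
acceptor list because a peptide serving as a donor is necessarily present
in linked form and can equally terminate a longer oligomer. Each unit
independently takes one of five glycosylation options (none, MurNAc,
GlcN-MurN, GlcN-MurNAc, GlcNAc-MurNAc). Topology is modelled natively per
unit rather than through concatenated-sequence tricks, so fragment
predictions are correct on both sides of every cross-link.

Deduplication treats donor units as an unordered multiset (key: sorted
donor (stem, glycoform) pairs + terminal acceptor + link-topology
multiset). Both the ordered and deduplicated counts are logged, along with
the number of distinct masses at 5 ppm resolution; for the full-scale
configuration (2×2 donors, 20 acceptors, 5 glycoforms per unit) the ordered
count is 10,000 and the deduplicated one 5,225.

The wildcard pass runs as a separate search with variable modifications
off. An observed neutral mass is explained as base monomer + Δ with
Δ ∈ [−130, +210] Da and |Δ| beyond the precursor window; Δ values matching
a single-residue substitution or a water loss are annotated. Substitution
annotations are ranked first, but precursor mass alone genuinely cannot
arbitrate between, say, A→F on a GlcN-MurNAc base and E→Y on a
GlcNAc-MurNAc base (0.4 mDa apart); all consistent readings are reported.

## Fragment prediction

Ion arithmetic, for a neutral N-terminal piece P (glycan included) and
C-terminal piece Q (water included): b = P, y = Q, c = P + NH₃,
z• = Q − NH₃ + H, z+H = z• + H, each protonated per charge. These satisfy
b+y = M + 2 protons and c+z• = M + H + 2 protons for 1+ pairs, which the
suite asserts at every bond. ETD predictions emit both z variants because
hydrogen transfer from the c to the z fragment is common at precursor
charge 2+. Glycosidic cleavages are predicted at the three bonds observed
to fragment strongly under ETD (GlcN|MurNAc, MurNAc|lactyl with the lactyl
group C₃H₄O₂ retained on the peptide, lactyl|Ala₁) as Y (peptide-side) and
B (glycan-side) ions. HCD predictions add internal fragments with a b-type
offset (residue sum + proton); the ion-type offset is configurable in
principle, b-type being the conventional reading, and enumeration is
capped at 4 residues to bound combinatorics. Fragment charges run from 1
to min(precursor charge, 2), appropriate for the sub-1-kDa fragments these
species produce.

For cross-linked species, every backbone bond of every unit is cleaved
with the piece masses computed over the link graph: a side-chain link at
stem position p travels with the piece containing residue p. The
cross-link amide itself is also cleavable, producing the
"splitting" c/z (or b/y) pair that separates donor content from acceptor
content.

## Topology calling

For an isobaric 3–3/4–3 candidate pair, diagnostic evidence is sought only
among strong peaks (top half of the spectrum's intensities; the threshold
is intensity-scale-invariant and configurable). ETD calling is two-stage:

1. *Exclusive full-set ions.* Fragments predicted under exactly one
   topology (no counterpart within the 0.5 Da ETD tolerance in the other
   topology's full prediction) decide directly when matched.
2. *Splitting-ion comparison.* Otherwise the cross-link-splitting c/z pairs
   are compared. A subtlety motivates the tie-break: the mDAP–Ala backbone
   N–Cα cleavage of a 4–3 donor is *exactly* isobaric with the 3–3
   reading's splitting pair (e.g. 828.38/884.39 for the
   disaccharide-AEm/AEmA content), so observing that pair alone supports
   3–3 only because the rival 4–3 reading would additionally predict its
   own splitting ions (899.42/813.35) — when those are absent the call is
   3–3; when present, only the 4–3 full set explains all matched splitting
   peaks and the call is 4–3.

HCD spectra contain no c/z splitting ions and are called only through the
unambiguous internal-fragment rule: an internal fragment with the mass of
two mDAP residues (344.170 + ion offset) requires directly bonded mDAPs
and proves 3–3; Ala + 2×mDAP arises under either topology and is excluded.
Internal-fragment diagnostics are computed generically: candidate
diagnostics are link-spanning residue paths, and exclusivity is tested
against *all* internal paths of the rival reading.

Per-composition consensus (`batch_call`) groups identifications by
elemental composition, classifies each spectrum against the identified
candidate plus one rival-topology interpretation drawn from the database
(exactly isobaric, same elemental composition; ties resolved by fragment
score), takes the majority among decided calls and reports the number of
conflicting decided calls, with the standing caveat that a co-eluting
minor amount of the other form cannot be excluded by MS2 alone.

## Identification and scoring

Precursors are matched at 5 ppm against a sorted mass index; fragments at
20 ppm (HCD) or 0.5 Da (ETD) by greedy nearest-peak assignment with each
observed peak and each predicted fragment used at most once. The score is
deliberately transparent:

    score = matched fraction of primary-series predictions (b/y or c/z/z+H)
          + fraction of total observed intensity explained          ∈ [0, 2]

All candidates with score ≥ 0 are retained and ranked (ties: fewer
modifications, then fewer units, then lexicographic stems). No decoy FDR
is computed — reversed-sequence decoys are uninformative when the search
space is a few hundred masses and the precursor carries most of the
information — instead every report carries isobaric-group annotations
(single-linkage at 5 ppm, bracket notation for groups > 1) and per-ID ppm
errors so calls can be audited. A ±1 isotope-error rescue is not enabled:
the instrument-reported monoisotopic precursor is trusted.

## Quantification

An XIC sums, per MS1 scan, the intensities within ±10 ppm of the target
m/z. The per-species quantity is the monoisotopic XIC integral summed over
charge states 1–4 (charges beyond those MS2-sampled are included when they
carry signal, since data-dependent selection skips 1+ ions that still
contribute XIC). The integral is a plain sum of per-scan ion counts, not a
trapezoid — proportional to scan rate, which is immaterial within one run
but means cross-run comparisons require matched cycle times. Percentages
are of the total identified XIC signal, so per-class sums equal the
class-level split. Full-window integrals are used rather than apex-local
ones.

In-source decay: a species is flagged as an electrospray glycan-loss
satellite of a fuller parent iff (1) peptide content and links are
identical and each unit's glycan is a distal-truncation (or absence) of
the parent's — the recognised losses (GlcN 161.069, GlcNAc 203.079, whole
glycoform) follow from the glycoform compositions, nothing is hard-coded;
(2) XIC apexes agree within 0.1 min; and (3) the Pearson correlation of
overlapping trace points is ≥ 0.95. The 0.1 min / 0.95 thresholds are this
package's operationalisation of "exact co-elution"; both are parameters.
Merged and separate reporting conserve the total integral exactly.

## Synthetic runs

The simulator emulates the acquisition the pipeline expects: MS1 scans on
a fixed 0.02-min cycle over a ~50-min gradient, Gaussian elution profiles,
charge states 1–4 with per-species fractions, 3-point isotope envelopes
(heavy-isotope factor growing linearly with mass, adequate below ~3 kDa —
no averagine model), and data-dependent MS2: after each MS1 scan the top-5
multiply charged (≥2+) precursors outside a 0.5-min dynamic-exclusion
window each trigger an HCD and an ETD event. MS2 peaks are drawn from the
package's own fragment predictions with optional lognormal intensity
noise, per-peak dropout and spurious peaks. Species abundance is defined
as the *monoisotopic* ion count so that noise-free XIC integrals recover
injected values exactly. In-source-decay satellites share their parent's
elution profile bit-for-bit. Runs are seeded and reproducible, and are
written as standard mzML 1.1 (centroided, 64-bit uncompressed arrays);
the writer's output round-trips through Bioconductor's mzR in the test
suite.

What the simulator does *not* model — profile-mode peaks, chimeric MS2,
chromatographic tailing, charge-dependent fragmentation efficiency,
realistic intensity structure across ion series — bounds what passing
round trips show: they validate the bookkeeping (mass model, matching,
integration, calling logic) on data with the assumed statistical
structure, not robustness to every artefact of real runs.

The standing recovery fixture injects one monomer, one 3–3 dimer and one
trimer with ion counts split 29.2 : 57.4 : 13.4 (the class proportions the
method reports on real *C. difficile* digests) over a compressed 12-min
window — a problem size (600 MS1 scans, ~230 MS2 spectra) chosen to keep
the full suite fast while exercising every stage; stochastic-noise
properties use 20% spurious peaks, 10% fragment dropout and 30% intensity
CV.

## Numerical and design notes

* Positions are 1-based along the stem; mDAP is position 3 in all
  supported stems.
* The one composition-table entry whose printed mass (2646.138, the
  all-GlcNAc-MurNAc trimer) disagrees with additive recomputation by
  ~0.010 Da — an order of magnitude beyond every other row — is treated as
  a typo and excluded from the verified mass set rather than "corrected".
* The published theoretical value 899.32 for the 4–3 splitting c-ion is
  not reproducible by standard c-ion arithmetic; this package's value
  (899.420) matches the reported observed peak (899.45) within ion-trap
  tolerance and is used for matching.
* Isobaric-group partitioning is single-linkage over the sorted mass list,
  so chains of pairwise-close masses group together; annotations use
  bracket notation.
* Degenerate inputs: empty stem lists build an empty database with a
  warning; an empty spectrum matches nothing; species eluting outside the
  simulated window are rejected at simulation time; MS1-free runs are
  rejected at XIC extraction.

## Limitations

* O-acetylation and other remodelling chemistries are out of scope, as are
  tetramers and higher oligomers, average-mass mode, a/x ions and
  intensity prediction.
* Trimer topology calls are per-link only insofar as pairwise diagnostics
  support them; stereochemical isomers (duplicate elution peaks with
  identical MS2) are reported as isobaric groups, not resolved.
* The score is a transparent coverage+intensity heuristic, not a
  calibrated probability; with a score cut of zero, downstream review of
  the ranked table replaces FDR control.
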