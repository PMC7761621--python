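# Methods

## Scope and model of the data

`ptmquant` operates strictly downstream of a database search. Its unit of
evidence is the PSM row of a MaxQuant-style `evidence.txt`: a plain peptide
sequence, a modified sequence with inline tokens, a charge state, a
precursor intensity, and a raw-file label. Nothing in the package rescores
identifications, reads spectra, or models fragment ions; intensities are
taken at face value as the search engine reported them.

Two kinds of quantities are computed from these rows:

* **Deterministic transformations** — occupancy ratios, LFQ shares,
  coverage maps, peptide masses. These have no free parameters beyond
  display conventions and are implemented as plain functions.
* **One estimated quantity with uncertainty** — the intensity-weighted
  deamidation rate. This is the only place where a statistical procedure
  (the bootstrap) runs, and it is exposed as a Model/Results pair
  (`DeamidationModel.fit()` → `DeamidationResults`) so estimates,
  uncertainties and diagnostics travel together.

## The deamidation-rate estimator

Definition (per residue class, N or Q, within one raw file):

1. Per PSM: fraction = deamidated residues of the class / residues of the
   class, attributed by the *position* of the deamidation token in the
   modified sequence — the summary column alone (e.g. "Deamidation (NQ)")
   cannot distinguish an N event from a Q event. PSMs whose peptide has no
   residue of the class are excluded for that class.
2. Per (plain sequence, charge): `Σ fraction·intensity / Σ intensity` over
   all PSMs of the group, deamidated or not. Pooling the denominator over
   both forms is what bounds the rate to [0, 1]. PSMs without intensity are
   excluded from both sums (a weight of "absent" is undefined) but still
   counted in the scan tallies that the output files report.
3. Per peptide: unweighted mean over its charge states. Per raw file:
   unweighted mean over peptides.
4. Uncertainty: the per-peptide rates are resampled with replacement
   `n_boot` times; the mean, SD and the 2.5/97.5 percentile interval of the
   bootstrap means are reported, on the percent scale.

Choices worth knowing:

* **Bootstrap unit.** Resampling acts on the per-peptide rates within a raw
  file. Resampling the per-raw-file averages instead would be degenerate
  (one value per file); resampling PSMs would ignore the two-level
  averaging. The per-peptide level matches the variance that matters for
  the reported per-file mean.
* **CI method.** Percentile intervals, the standard choice for a plain
  bootstrap; the `ci_method` argument exists so a different interval could
  be added without touching callers. With n_boot = 1000 the Monte-Carlo
  error on the 95% bounds is a few percent of the SD — adequate for a
  comparative measure.
* **Seeding.** Every (raw file, residue class) cell draws from a generator
  keyed on `(seed, crc32(raw file), class)`, so results are invariant to
  row order and to which other files are present. Default seed 1218.
* **Empty classes.** A raw file with no eligible peptide for a class
  reports mean/SD/CI of 0 together with its scan count, and its bootstrap
  draws are written as zeros, so the output files keep their rectangular
  shape (n_boot rows per file per class).
* **Degenerate input.** A single peptide rate yields SD 0 and a point CI;
  all-zero rates yield an all-zero row — exactly what an unmodified control
  sample should produce.

## Occupancy ratios

`modified intensity / reference intensity` per replicate, with the
carbamidomethylated form serving as the reduced reference for cysteine
oxidation states. Forms observed at different charges are compared directly
— the pair is flagged `cross_charge` rather than normalised, because any
charge correction would presume ionisation behaviour the data do not
constrain. When a form appears at several charges the most intense
candidate is used. Missed-cleavage variants covering the same site are
separate evidence and are never pooled.

Display conventions (full precision is always kept internally): ratios ≥ 1
print with one decimal; ratios < 1 with one significant figure; replicate
means print as integers from 10 up. Replicate means are taken over the
display-rounded per-replicate ratios, which is how such summary tables are
conventionally assembled from their printed cells.

## LFQ shares

`share = mean intensity / Σ mean intensities × 100`, over a declared
protein set. Dispersion is percent CV across replicates. Missing LFQ values
are ignored in means, not imputed as zero — LFQ missingness reflects
detection, not absence. The MaxLFQ algorithm itself is out of scope; this
module consumes its output.

## Coverage

Intervals are 1-based inclusive in precursor numbering (initiator Met
counted), merged with adjacency, and the fraction is computed over the
mature range only: a 283-residue precursor whose Met1 is removed has a
282-residue denominator. Peptides matching several positions or proteins
contribute coverage to each match, and non-matching peptides are reported,
never dropped.

## Masses and m/z

Monoisotopic residue masses are frozen to five decimals in
`ptmquant.constants` so printed m/z values never drift with an external
library upgrade; a test cross-checks the table against pyteomics. The
charge carrier is the bare proton (1.0072765 Da), not the hydrogen atom;
the two conventions differ by under 0.001 Th at 3+, so comparisons against
published values use a ±0.002 Th window rather than guessing which
convention a third party used. The modification registry ships the deltas
of the study's search space; the two ubiquitin-remnant adducts use their
conventionally reported deltas (+114.0429, +383.2281) directly.

## The synthetic evidence generator

The generator emulates the *statistical* structure of an evidence table:
digestion (trypsin/chymotrypsin, no cleavage before proline, up to 3 missed
cleavages by default, peptide lengths 6–30), per-site Bernoulli
modification states, log-normal intensities (location ~N(16, 1) per peptide
on the natural-log scale, sigma 1 per PSM — spanning roughly 10⁵–10⁹,
matching the magnitudes such tables contain), charge states 1+/2+/3+ with
weights 0.1/0.6/0.3, optional missing intensities, and theoretical m/z from
the package's own mass table.

It does **not** emulate: retention time, co-elution and interference,
intensity censoring at the detection limit, charge-dependent ionisation
efficiency, in-source deamidation artifacts, or search-engine
misassignment. Passing recovery tests therefore show that the *estimator*
is correct under clean sampling assumptions — not that real evidence is
free of those artifacts. One deliberate lever exists:
`modified_intensity_factor` scales modified-form intensities to study the
bias that differential ionisation induces in the intensity-weighted
estimator (default 1.0 = state-independent, under which the estimator is
unbiased for occupancy).

The bundled `vdac_synthetic.fasta` is a *constructed* scaffold, not the
SwissProt VDAC1 sequence: it embeds every published peptide at its
published coordinates (283 residues, Ala2 after the cleaved initiator Met,
the seven deamidation sites N37/N106/Q166/N207/N214/Q226/N239, single
internal Met155, Cys127/Cys232, and the uncovered runs T19–K20, L29, R63,
G220–K224 flanked by tryptic sites), with filler residues elsewhere. All
coverage and simulation results depend only on these pinned features. The
VDAC2/VDAC3 entries are minor variants for multi-protein fixtures.

## Parameter-recovery study

`recovery_study()` checks the estimator end to end: a synthetic protein
with 16 single-Asn tryptic peptides, 2000 PSMs per site, one replicate,
state-independent log-normal intensities; 100 runs per true occupancy
(0.05, 0.3, 0.8). Reported: mean bias of the per-file estimate and the
fraction of runs whose bootstrap 95% CI covers the truth. Sixteen peptides
keep the percentile bootstrap's small-sample undercoverage mild while the
whole 300-run study stays under two minutes on one core; these problem
sizes are the package's stated study conditions, not tuned values.

## Known limitations

* Occupancy ratios are rough stoichiometry estimates; no correction for
  ionisation-efficiency differences between modified and unmodified forms.
* The deamidation rate is comparative, not an absolute site stoichiometry,
  and inherits whatever in-source deamidation the sample preparation
  introduced.
* The evidence parser accepts the parenthesised-token and bracketed-delta
  dialects; exotic search-engine dialects need a column/dialect mapping and
  possibly new registry aliases.
* Protein-level aggregation keys on the leading razor protein as given;
  razor assignment itself is not re-derived.
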