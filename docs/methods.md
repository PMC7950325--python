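# Methods

## Mass model

All arithmetic uses neutral monoisotopic masses. Residue masses are the
standard monoisotopic amino acid table (via pyteomics, ≥5 decimals);
water 18.010565 Da, proton 1.007276 Da. A peptide's neutral mass is
Σ residues + water + Σ modification deltas + label · 2.004246 Da, where
the label is the number of ¹⁸O atoms at the C-terminus (0–2).

Modification deltas are fixed at: nitration +44.985078 Da (Tyr, Trp),
Met sulfoxide +15.994915 Da, carbamidomethyl +57.021464 Da (Cys, fixed),
and chlorination +33.961028 Da (Tyr, optional, for hypochlorite-type
comparisons). The direct Tyr/Trp side-chain cross-link loses two hydrogen
atoms; the link delta is fixed at −2.015650 Da. Masses are reported to
3 decimals and m/z to 4; internal computation keeps full precision.
Published theoretical masses for the reference cross-linked pairs are
printed to 2–3 decimals by the original search tools, whose exact mass
table is unknown; agreement within 0.002 Da is treated as exact (our
di-Tyr reference pair computes to 2944.312 vs a printed 2944.311).

## Digestion

Trypsin cleaves C-terminal to K/R, suppressed before Pro (the reference
peptides GEWTCKPIAEK and WDRQGENGQMMSCTCLGNGK require the suppression).
Fully specific peptides are unions of 1..(m+1) consecutive
zero-missed-cleavage fragments; semispecific mode additionally keeps
peptides with exactly one tryptic terminus. Chain ends count as tryptic.
Defaults: ≤2 missed cleavages, lengths 6–45, ≤3 variable modifications
per peptide — common search-engine settings where the source experiment
prints none. Correctness is checked against a brute-force oracle that
tests every substring of random chains against the cleavage-site list.

## Cross-link search

Candidates are all unordered pairs of distinct peptide forms in which
each chain carries an unmodified residue of the required type (YY, WW or
YW), one candidate per eligible residue combination, the longer chain
designated α. Explosion control: chain mass ≤6000 Da, pair mass
≤8000 Da, ≤3 variable modifications per chain. Precursors given as
(m/z, z) are converted to neutral mass and matched at 10 ppm (4.5 ppm
for linear-peptide work, per the printed acquisition settings). Fragment
ladders are standard b/y (optionally c/z·); a fragment containing the
linked residue additionally carries the partner peptide's full mass plus
the link delta; C-terminal fragments inherit the ¹⁸O label.

The match score is deliberately transparent (the original study relied
on an undocumented vendor score with a manual-validation cutoff of 50):
score = 100 × (matched weight / total weight) over the theoretical
ladder at 0.02 m/z tolerance, link-retaining fragments weighted 2,
plain fragments 1. It is deterministic and invariant to uniform
intensity scaling. Filtering keeps matches with score strictly above the
threshold (default 50), precursor intensity ≥2000, and — when replicate
tags are present — identification in ≥2 replicates; ties break by higher
score then smaller |ppm|. Decoys are reversed sequences with the
C-terminal K/R fixed; FDR is the decoy/target ratio above the cutoff
(default target 5%).

## ¹⁶O/¹⁸O doublets

Classification works in neutral-mass space: shift = z · Δm/z. Admissible
shifts are k · 2.004246 Da for k = 1..4; k = 2 ⇒ linear, k = 4 ⇒
cross-linked, k ∈ {1, 3} ⇒ partial incorporation, anything else (or a
negative shift) unclassified. The source experiment states only the
integer +4/+6/+8 Da selection windows; the ±0.015 Da neutral-mass
tolerance and the co-elution criterion (overlapping retention windows,
same charge, greedy pairing by combined intensity with each feature used
once) are this package's choices.

## Relative site occupancy

RSO(site) = 100 × Σ area(forms modified at the site) / Σ area(all forms
covering the site), pooling charge states and overlapping peptide
species; Met-oxidized forms stay in the denominator. A site with no
covering record is *not identified*, distinct from 0%. A site covered
only by modified forms reports 100% with a low-confidence flag (no
unmodified evidence), a case the source convention leaves open.
Replicates are averaged at the RSO level (mean ± SD), matching how such
experiments report three independent experiments, not pooled at the area
level. Condition differences are Δ = RSO_A − RSO_B per site; a site seen
in only one condition contributes with the other set to 0% and an
assumed-zero flag; |Δ| > 10% is the default reporting threshold.
Coverage statistics report % residues covered (optionally excluding a
configured glycosylation-site list) and per-class (Y/W/M) censuses with
both of-total and of-identified percentages.

## Domain report

Modules are non-overlapping 1-based inclusive intervals on the mature
chain; residues outside every module are "linker/interdomain". Module
boundary coordinates are not part of the package's claims — the fixture
table is synthetic and users supply their own (e.g. from UniProt feature
annotations). Occupancy bins are half-open, lower-exclusive: (1,10],
(10,20], (20,30], (30,100]; ≤1% is unbinned. Topology: observed in the
SEC dimer fraction ⇒ intermolecular; monomer (never dimer) ⇒
intramolecular; unfractionated only ⇒ ambiguous.

## Synthetic data

The simulator emulates processed data, not raw spectra: identified MS1
features/areas and centroided MGF peak lists. The standard chain is a
265-residue synthetic mini-fibronectin that embeds the eight parent
peptides of the four characterized cross-links with native flanking K/R
context (the two fibrin-binding-2 Trp link sites sit 14 residues apart,
as in the real chain), plus extra Y/W/M-bearing peptides for
quantification. The four pairs are planted with the modification states
their observed masses imply (one nitration on the Trp–Trp and Tyr–Trp
pairs involving the heavy chain).

Default noise conditions: peptide-level log-normal abundance
(σ = 0.5 ln-units, median 10⁶), per-form measurement jitter σ = 0.1,
Gaussian 2 ppm mass error, charges 2–6, missed-cleavage retention
1.0/0.5/0.25, 95% double / 5% single ¹⁸O incorporation, 10% random noise
features, 30% fragment dropout with 20 noise peaks per spectrum.
Abundance noise is shared between the modification forms of one peptide
(ionization and loading vary per peptide, not per form), so the RSO
estimator's target is unbiased; fully independent per-form noise of the
same magnitude would bias the ratio upward by ~1–2 points at low
occupancy. Default planted occupancies cycle 35/25/18/12/5/2% over
non-link Y/W sites (the reported dynamic range for this chemistry, mean
≈12–14%) and 40/10% for Met.

What passing tests show — and don't: closed-loop identity (zero noise ⇒
exact recovery), ±2-point occupancy recovery at σ = 0.5 noise, ≥95%
cross-link recall/precision over seeds, and correct doublet calls are
properties under this generative model. Real data add retention-time
drift, co-elution interference, isotope-envelope integration error and
chimeric MS2 spectra, none of which are modeled; areas and peak lists
are taken as given (no raw-file processing, no match-between-runs, no
protein-level FDR).

## Problem sizes and determinism

The packaged studies run on the 265-residue fixture: ~56k cross-link
candidates (targets + decoys, with modification forms), tens of spectra,
three replicates; recall/precision studies use ten seeds. All randomness
flows from a single integer seed through `numpy.random.default_rng`;
identical seed and config give byte-identical outputs.

## Known limitations

- The score is a fragment-coverage statistic, not a probabilistic model;
  thresholds transfer across datasets only qualitatively.
- Doublet pairing is greedy; dense feature maps could mispair co-eluting
  unrelated features.
- Self-pairs (a peptide cross-linked to another copy of itself) are not
  enumerated; homodimeric links at the same residue are invisible.
- ¹⁸O back-exchange kinetics and mixed-incorporation deconvolution are
  reduced to the three-state linear/cross-linked/partial call.
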