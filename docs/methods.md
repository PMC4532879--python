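# Methods

## The measurement being modelled

A cleavable protein interaction reporter (PIR) crosslinker joins two
surface lysines in living cells. In MS2 the reagent fragments into a
reporter ion and the two released peptides, each retaining a residual
"stump" of 197.0324 Da on its crosslinked lysine, so a genuine
crosslinked precursor obeys

    M_precursor = M_reporter + M_peptide1 + M_peptide2.

Combining this with metabolic labelling (SILAC: heavy Lys +8.014199 Da,
heavy Arg +6.020129 Da) lets the same crosslinked species be compared
between two cell states in MS1, giving per-crosslink ("edge-level")
relative abundances rather than the protein-level averages of ordinary
quantitative proteomics.

## Pipeline model and assumptions

**Identification.** PSMs are assumed to come from an external search
engine over a concatenated target + reversed-decoy database (the package
only re-scores synthetic spectra, with a deterministic b/y-ion fraction
matcher used purely as test plumbing). PSMs are thresholded by score to a
peptide-level FDR: the accepted set is the largest score-ordered prefix
with decoy/target ≤ the threshold (the conventional estimator; 5%
default). Surviving stump-bearing peptides map onto PIR relationships by
released-peptide mass within 10 ppm; a pair is reported only when each
mass slot resolves to exactly one peptide, and spectra with shared-mass
candidates go to a secondary ambiguous list rather than being silently
dropped. Crosslink-level FDR is #(pairs with ≥ 1 decoy peptide) / #pairs.

A crosslinkable peptide must contain an *internal* lysine — any Lys that
is not the peptide's C-terminal residue, since a C-terminal Lys is a
tryptic terminus rather than a blocked (missed) cleavage site. Digestion
follows the Keil rule (cleave after K/R, not before P), fully tryptic
only, up to 3 missed cleavages at the crosslink stage and 2 at the
global stage.

**Quantification.** Each species is integrated as a trapezoidal XIC area
at ±10 ppm; scans inside the window with no matching peak count as zero
intensity so sparse peak lists do not bridge elution gaps. Ratios are
expressed on the resistant/sensitive (R/S) scale before pooling:
log2(heavy/light) in a forward replicate (resistant heavy),
log2(light/heavy) after a label swap. A channel with non-positive area
makes the replicate unquantified; pairs with no quantified replicate are
reported identified-only. Replicates with affine retention-time drift
can be brought onto a reference run by a single global linear fit over
shared high-intensity landmarks (`linear_rt_alignment`); full
warping-based alignment is out of scope. "CI" is the **full width** of the two-sided
95% Student-t interval, 2·t(0.975, n−1)·s/√n — the half-width/full-width
choice was open and full width is the declared convention, so the
significance rule is |mean log2(R/S)| > 1 AND full CI width < 1. A
single replicate has an undefined (infinite) interval and is never
significant. Replicates are pooled as one sample regardless of
biological/technical provenance. Replicate retention-time alignment
beyond a shared clock is not performed; the quantifier integrates over a
common window, which suffices for the synthetic chromatograms and for
well-aligned runs (full warping-based alignment is out of scope).

**Network.** Node identity is (peptide sequence, modification string,
crosslink site), collapsing light/heavy label states. Edge classes:
different proteins → inter; same protein with disjoint peptide ranges →
intra (the conservative single-molecule reading, even though a dimer
could also produce such a link); overlapping ranges force two subunits —
unambiguous homodimer when both peptide sequences occur exactly once in
the protein, else ambiguous homooligomer. Intermolecular edges
deduplicate to unordered protein pairs; nodal distance against a
known-PPI edge list is 0 for a known edge, otherwise shortest-path
length − 1. GraphML export carries node colour classes (up/down/
unchanged at |log2| > 1 by default, configurable; unquantified
separate) and edge-level quantification.

**Structure mapping.** A peptide (≥ 6 residues) is located in a chain by
exact substring match of the chain's one-letter sequence, requiring a
unique occurrence; an optional offset table substitutes for alignment.
Model 1 is used for multi-model structures and altloc 'A' is preferred.
The distance reported is the Euclidean Cα–Cα distance.

**Orientation.** For two elongated partners, sites are converted to
fractional positions p within their rod domains; a link is
parallel-consistent iff |pA − pB| ≤ δ and antiparallel-consistent iff
|pA − (1 − pB)| ≤ δ, with δ = 0.15 by default. Satisfying both (near the
midpoint) or neither is ambiguous; a site outside its rod is reported
separately. The rule, δ and rod boundaries are configurable because no
formal geometric criterion exists for the published manual assignment;
the package deliberately does not treat any particular parallel/
antiparallel split as a target.

## Key parameters (defaults)

| parameter | default | unit | why |
|---|---|---|---|
| PIR relationship tolerance | 20 | ppm | acquisition-time criterion |
| precursor tolerance / 13C offsets | 25 / ≤3 | ppm / peaks | search setting |
| fragment tolerance (crosslink / global) | 0.36 / 1.0005 | Da | search setting |
| XIC tolerance | ±10 | ppm | quantification setting |
| missed cleavages (crosslink / global) | 3 / 2 | sites | crosslinker blocks cleavage |
| PSM FDR | 5 | % | peptide-stage filter |
| significance | \|log2\|>1 ∧ CI<1 | — | edge-change call |
| stump mass | 197.0324 | Da | reagent residual on Lys |
| heavy Lys / Arg | 8.014199 / 6.020129 | Da | SILAC labels |
| proton / water / 13C spacing | 1.00727646688 / 18.0105646863 / 1.00335 | Da | standard monoisotopic constants |

The reporter ion mass is a required configuration value; the simulator
uses its own fixed 752.41312 Da, and the PIR check accepts a
configurable additive constant (default 0) to absorb alternative stump
bookkeeping conventions. Released-peptide masses are taken to already
include the stump on the crosslinked lysine. Whether 13C offsets apply
inside the PIR check is exposed as `max_c13` (default 0). A fragment may
pair with itself only under the homodimer flag (default off; the
synthetic end-to-end flows enable it because planted homodimers produce
coinciding released-peptide masses).

Histone residues are reported in canonical histone-mark nomenclature
(UniProt index − 1); all internal coordinates are 1-based UniProt-style,
and the conversion happens only at report boundaries, driven by a
configurable histone-name pattern list.

## Synthetic data: what it emulates and what it does not

The generator plants crosslinks at 75% intra / 6% unambiguous homodimer
(remainder inter) on a random proteome with boosted K/R frequencies
(9%/5%), five replicates with replicates 1–3 forward and 4–5 reversed,
and renders triangular elution profiles whose light/heavy areas encode
each replicate's observed ratio, plus MS2 events with reporter +
released-peptide masses and random noise fragments. Null pairs draw
their true log2(R/S) from Normal(0, 1.25) — the observed across-pair
spread in the motivating data — and each replicate measurement adds
Normal(0, 1.25/√5) noise on the log2 scale; area magnitudes are
lognormal around a base intensity. Everything is deterministic under the
seed.

Not emulated: realistic chromatographic peak shapes or tailing, isotope
envelopes and charge-state distributions, retention-time drift between
replicates, interference/co-isolation, intensity-dependent
(heteroscedastic) ratio noise, and real search-engine score
distributions. Simulated replicates share one retention-time clock, so
the linear alignment step is exercised on constructed drift rather than
on the end-to-end flows. Passing tests therefore demonstrate correctness of the
computational contracts (mass arithmetic, pairing, FDR accounting,
integration, classification) and calibrated behaviour under an idealized
noise model — not performance on raw instrument data.

Reference values for the significance rule's sensitivity and false-call
rate on planted |log2| = 2 effects (five replicates, per-replicate noise
1.25/√5) were computed once by the deterministic simulation at a fixed
seed and frozen into a regression test; they document behaviour under
those conditions rather than a performance claim.

## Numerical choices

Monoisotopic masses throughout (averaged masses are out of scope);
residue masses from pyteomics. ppm errors are computed relative to the
precursor neutral mass and signed; PIR matches sort by |ppm|. XIC areas
use the trapezoidal rule on the per-scan grid with zero fill. Sample
statistics use ddof = 1; the label-swap comparison is an ordinary
least-squares fit of forward versus reverse means over shared pairs
(≥ 3 required). Degenerate inputs reject loudly: empty pair lists for
FDR, zero-length rods, charge < 1, non-finite modification deltas,
residue 1 of a histone.

## Problem sizes

Module tests run on proteins ≤ 200 residues against brute-force oracles;
end-to-end flows use 20–120 planted crosslinks on 20–40 synthetic
proteins, where the whole suite and the acceptance script each finish in
seconds. These sizes exercise every code path (all four link classes,
label swap, decoy leakage, ambiguity) while keeping the oracles
enumerable.

## Known limitations

Real-data identification quality is bounded by the external search
engine; the package consumes PSM tables and does not rescore. Structure
mapping requires exact sequence agreement (no isoform/variant
tolerance). The homodimer-uniqueness test is substring-based and so
treats I/L as distinct. Protein-level roll-up is a simple mean of
peptide ratios. The orientation rule is a declared operationalization,
not a reconstruction of any published manual assignment.
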