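# Methods

This note documents the models and procedures implemented in `antquant`,
the assumptions behind them, the parameters that matter, and what the
simulation-based validation does and does not demonstrate.

## Quantification model

Protein abundance is estimated per gel slice by the exponentially modified
protein abundance index, `emPAI = 10^(N_obsd/N_obsbl) − 1`. `N_obsd`
counts distinct accepted peptide sequences, collapsing charge states —
the usual convention, since a peptide seen at 2+ and 3+ is one piece of
sequence evidence. `N_obsd` is not restricted to the observability
window (a detected peptide is evidence regardless of where it falls), but
is clamped at `N_obsbl` with a logged warning so the index stays within
its defined range. `N_obsbl` counts fully cleaved tryptic peptides of the
*mature* sequence — for secreted proteins the annotated signal peptide is
removed first, because the instrument samples the processed protein —
with length ≥ `min_peptide_length` (default 6) and monoisotopic mass in
`[m_min_da, m_max_da]` (default 800–3000 Da). The window and length
defaults follow common emPAI practice and are config-exposed; no single
standard exists, so no analysis here depends on absolute `N_obsbl` —
only on counts and ratios.

Digestion uses the trypsin rule "cleave C-terminal to K or R except
before P", with 0-based half-open residue coordinates and optional
missed-cleavage joins of up to m+1 adjacent fragments. Monoisotopic
residue masses come from the standard table (water 18.010565 Da);
average residue masses, used for gel-scale molecular weights, come from
the standard Expasy/IUPAC table (water 18.0153 Da).

Top3 — the mean of a protein's three most intense precursor ions, or of
all when fewer than three — is computed per slice alongside emPAI. It is
used here only for the trypsin volume correction; whole-appendage values
are emPAI-based.

A protein whose sequence yields no observable peptides (`N_obsbl = 0`,
e.g. an incompletely known gene model) is reported as
*detected-unquantified*, a distinct cell state that counts as presence in
all comparative analyses but is excluded from arithmetic. This mirrors
the dash cells of the published tables and is required to reproduce their
narrative counts (e.g. 29 worker-antennal P450s includes three dash rows).

## Identification and FDR

PSMs pass two conjunctive filters: score strictly above the per-spectrum
identity threshold (the search engine's P < 0.05 bound), and score at or
above the global cutoff chosen as the smallest value for which
`#decoys ≥ c / #targets ≥ c ≤ fdr_target` (default 1%). The D/T
estimator was chosen over 2D/(T+D) for simplicity and monotonicity; ties
at the cutoff are accepted. If no finite cutoff reaches the target the
maximum observed score + 1e-6 is returned (empty acceptance) with a
warning. Protein inference is by accession only — no grouping or
parsimony — matching the hit-counting semantics of the original analysis.
Proteins with exactly one distinct accepted peptide are flagged, mirroring
the tables' single-peptide footnotes; the flag does not affect presence.

## Normalization and volume correction

Per sample, every emPAI is divided by the reference protein's (GAPDH)
emPAI in its home slice; if the reference is quantified in more than one
slice (possible through spurious matches) its maximum-emPAI slice is used
with a warning, and a missing reference is an error naming the sample.

The volume correction assumes trypsin autolysis signal is inversely
proportional to the relative sample volume injected from a slice. The
factor `f(s)` is the mean of exactly two component ratios — trypsin emPAI
and trypsin Top3, each taken against the slice containing the reference —
so `f(ref) = 1` by construction, and corrected values are
`value × f(s)`. This is the literal reading of the stated assumption; the
opposite convention (trypsin signal proportional to injected volume, i.e.
divide by `f(s)`) is genuinely plausible for other acquisition setups and
is available as `trypsin_proportional = true`. The mean ± SD of `f`
across slices is reported as the sample volume error factor.

Whole-appendage values are the *sum* of corrected normalized emPAI across
slices: a protein's peptides may split across gel segments, and summing
collects them; the alternative (maximum over slices) is not used. Mixed
dash/value slices keep the numeric sum with a completeness warning.

## Comparative analyses

Detection is strict `value > 0` or dash — no abundance floor, since the
published tables count cells as small as 0.0068. The three-appendage
presence partition is computed by set algebra over the 7 exclusive
regions and cross-checked against brute-force membership enumeration.
Family summaries split antenna-only detections into worker-only /
male-only / both, with shared-with-tibia and tibia-only classes; class
counts always sum to the family total. Ratios are reported raw and
rounded half-away-from-zero at the configured precision, with "fold"
values rounded to the nearest integer; a ratio whose denominator is
absent or unquantified returns a detected-only-in-numerator sentinel
rather than a number.

The positional-bias analysis for tandem gene models splits the mature
sequence at floor(L/2), assigns each detected peptide to a half by its
midpoint residue, and tests the counts against the observable-peptide
split between halves with a two-sided exact binomial test. The test
itself is an extension beyond the original qualitative argument and is
labelled as such in the pipeline output.

## Native-gel reasoning

Average-mass molecular weights feed a mean-subunit estimate (sequences
below a cutoff, default 35 kDa, are excluded as likely incomplete gene
models) and linear oligomer masses: with a 44 kDa mean receptor subunit,
2+2 heteromers sit near 176 kDa and 4+4 heteromers near 352 kDa, matching
the 200–350 and 400–600 kDa gel sections. Section ranges are closed
intervals in kDa. The dilution-shift classifier compares a subunit's
high-MW/low-MW abundance ratio between dilute and concentrated loadings:
a fold difference below 1.5 (invented default, config-exposed) is called
a stable complex; larger shifts are concentration-dependent association,
directed toward the form whose share grew.

## The simulator: what it emulates and what it does not

The generator reproduces the study design — three pooled appendage
samples in four gel slices, a GAPDH-like reference, trypsin autolysis in
every slice, reversed-sequence decoys — with known ground truth.
Proteins are random sequences of length 80–600 with ~11% K/R (typical
tryptic site density); a fraction are secreted with 15–30-residue signal
peptides; four mandatory roles (reference, trypsin, co-receptor, SNMP)
are always present along with OBP/CSP/P450/TULIP family members.
Proteins are binned into slices by molecular weight; slice volume factors
default to {0.6, 1.0, 1.1, 0.8} relative to the reference slice, chosen
to yield a recovered volume error factor near 1.2 ± 0.4 as observed in
practice.

Detection is a saturating stand-in (no detectability model exists for
this dataset): each observable peptide of protein p in slice s is seen
with probability `q = 1 − (1 + C_p·V_s/κ)^(−β)`, κ = 5, β = 1. Under
this curve emPAI grows roughly linearly with log concentration before
saturating, akin to the empirical relation the index is based on.
Abundances default to log-uniform over a 100-fold range with 20%
per-tissue absences; the co-receptor is simulated at 20 (worker) vs 4
(male) — the measured 5:1 caste ratio at levels where both castes are
robustly detectable, as they were in practice — and SNMP at 1:1.
Trypsin signal is generated inversely proportional to slice volume,
which is exactly the assumption the correction stage makes; the
simulation therefore exercises the correction as specified but cannot
test that assumption itself. Scores are Gaussian (true N(60,10), null
N(15,8), identity threshold 30); decoys and an equal number of false
target matches draw from the null distribution, implementing the
working assumption of target-decoy estimation. All randomness flows from
a single seeded generator; chromatography, isotope envelopes and spectra
are not modelled.

Consequently, passing the simulation-based checks shows that the
pipeline recovers what this generative model encodes — rank order of
abundances, a known caste ratio, FDR control against the configured null,
volume-factor correction — not that emPAI is unbiased on real spectra,
nor that real trypsin autolysis tracks volume inversely.

## Validation choices and measured behaviour

* **Rank recovery** is measured as the Spearman correlation between the
  full ground-truth concentration vector (every protein × tissue cell,
  absences included, the trypsin reagent excluded) and the estimated
  table, over 25 replicate simulations of 200 proteins — a scale that
  keeps the whole validation under a minute on one CPU. Restricted to
  present-only cells the intrinsic counting noise of emPAI at these
  conditions caps even an ideal estimator near 0.89, so the full-vector
  definition (which also credits correct absence calls) is used.
* **Ratio recovery** is summarised by the geometric mean across the 25
  replicates. emPAI's saturation compresses large ratios: the 5:1
  simulation is recovered near 3.5, comfortably within a factor of two,
  and single replicates scatter around that by roughly ×/÷1.6 — the
  same kind of compression is visible in the real data, where the
  printed co-receptor ratio is 4.8 against "approximately 5:1".
* **Volume-correction efficacy** uses probe proteins present uniformly
  across slices at a moderate abundance (C = κ), where detection responds
  to injected volume; for saturated proteins no volume correction is
  recoverable from counts, and the corrected-vs-uncorrected CV comparison
  is only meaningful in the responsive regime.
* **Factor recovery** (`f(s)` vs `1/V_s`) is assessed on
  within-replicate-centred log factors averaged over replicates, because
  a single replicate's factor is dominated by the saturated trypsin
  emPAI counting noise.
* **Determinism** is byte-level identity of every pipeline output under a
  fixed seed. The manifest's stage timings are wall-clock and are the one
  field exempt from the comparison; the manifest's content-hash block is
  compared instead.

## Known limitations

* The search engine's exact identity-threshold computation and internal
  emPAI variant are not reproduced; both paths here use the same formula,
  differing only via the mature sequence.
* Protein inference has no grouping: shared peptides credit every
  matching accession independently.
* The dash (detected-unquantified) state propagates through aggregation
  but not through arithmetic; ratios against a dash cell return a
  sentinel, not a number.
* Whole-antenna and native-gel abundances are normalized to different
  references (GAPDH vs trypsin) and are deliberately never cross-compared.
* The published whole-dataset presence partition (2,949 proteins) and the
  44 kDa mean receptor mass require the deposited raw spectra and
  external sequence sets; they are reference examples in the
  documentation, not recomputed quantities.
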