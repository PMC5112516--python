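# Methods

## Binding model

The core model is the McGhee–von Hippel isotherm for non-cooperative
binding of a protein to an effectively infinite, homogeneous DNA lattice,
in which each bound protein occludes `n` contiguous nucleotides:

    ν / P_f = K (1 − nν) [ (1 − nν) / (1 − (n−1)ν) ]^(n−1)

* ν — binding density, bound proteins per nucleotide (ν = P_b / D_t);
* P_f = P_t − P_b — free protein, M;
* K — intrinsic association constant, M⁻¹, on the per-nucleotide lattice
  scale (K_D = 1/K);
* the bracketed factor counts the conditional probability that a stretch
  of `n` free nucleotides is available, which is what distinguishes lattice
  binding from simple site binding and lets `n` be estimated from a
  titration.

Assumptions: one protein species, one binding mode, no cooperativity
(unit cooperativity parameter), no sequence specificity, DNA long enough
that end effects vanish. All DNA concentrations are **molarity of
nucleotides** (ct-DNA quantified at 260 nm with ε = 6600 M⁻¹cm⁻¹ per
nucleotide), so `n` comes out in nucleotides ("bases"). `n` is treated as a
continuous parameter: it is a fitted effective occlusion length, not an
integer contact count.

The observed signal is tryptophan-fluorescence quenching,
Q_obs = (F_i − F_obs)/F_i, linked to occupancy by Q = Q_max · P_b/P_t. No
inner-filter or dilution correction is applied; small negative Q_obs
(noise at the start of a titration) is clamped to zero with a warning,
negative fluorescence is an error.

## Inner solve

At given (K, n, Q_max, P_t, D_t) the bound concentration P_b is the unique
root of the residual g(P_b) = ν/P_f − K(1−nν)[(1−nν)/(1−(n−1)ν)]^(n−1)
on the open bracket (0, min(P_t, D_t/n)): g → −K at the lower end and
→ +∞ at the upper end, and the residual is monotone on the bracket
(verified against a dense-grid scan in the tests rather than assumed).
The solver is plain bisection with bracket endpoints offset by a relative
ε = 10⁻¹⁵, default relative tolerance 10⁻¹² on P_b, at most 200
iterations, vectorised across titration points. D_t = 0 short-circuits to
P_b = 0. The n = 1 special case reduces to simple independent-site
binding with a closed-form quadratic root, kept in the package as an
analytic cross-check oracle.

## Outer fit

(K, n, Q_max) are estimated by weighted nonlinear least squares on Q_obs,
with the bisection solve nested in each model evaluation. Choices:

* **Weights** — uniform by default (the minimal assumption and standard
  practice for quenching titrations); user-supplied arrays or a crude
  1/Q variance model are options.
* **Parameterisation** — (ln K, ln n, ln Q_max), which enforces
  positivity; bounds ln n ≥ 0 (n ≥ 1) and ln Q_max ≤ 0 (Q_max ≤ 1).
  Because of the bounds the optimiser is SciPy's trust-region-reflective
  least squares, the bounded analogue of Levenberg–Marquardt damping.
* **Multistart** — K and n are strongly correlated, so the fit starts from
  the grid n ∈ {2,4,6,8,10,12} × K_D ∈ {1,10,100} µM with Q_max
  initialised at max(Q_obs); lowest final RSS wins, ties broken towards
  the smaller n.
* **Convergence** — ftol/xtol 10⁻¹², gtol 10⁻¹⁰, max 2000 function
  evaluations per start; fewer than 5 points raises an error, as does a
  signal-free titration (max Q_obs < 10⁻³), rather than returning a
  meaningless optimum.
* **Uncertainties** — linearised covariance at the optimum, (JᵀJ)⁻¹ scaled
  by RSS/(N−3), propagated to the (K_D, n, Q_max) scale by the delta
  method. These are first-order SEs, not replicate SDs or bootstrap CIs;
  the tests check they agree with the empirical replicate SD within a
  factor of two at the default design. Reports print K_D at integer µM
  and n at one decimal (the study table's precision); JSON keeps full
  precision.

## Synthetic titrations

The generator emulates the study's measurement design: P_t = 5.5 µM,
F_i = 1000 a.u., 25 log-spaced DNA additions spanning three decades up to
50·n·P_t nucleotides (a ≈ 50-fold lattice-site excess, carrying the curve
well into the Q_max plateau), additive Gaussian noise on **fluorescence**
(what the instrument records), default σ = 1% of F_i. Replicate r of a
recovery study uses seed `base_seed + r`. The generator does not model
photobleaching, inner-filter effects, dilution volumes or temperature
drift, so passing recovery tests demonstrate the estimator's statistical
behaviour under the assumed noise model, not robustness to those
instrument artefacts.

At this design, 100-replicate recovery of a Sac7d-like truth
(K_D = 13 µM, n = 6.4, Q_max = 0.9) gives median |relative error| ≈ 7%
for K_D, ≈ 3% for n, < 1% for Q_max, with mean signed K_D bias well under
5% — comfortably inside the 15%/15%/10% bands the tests enforce.

## Sequence analytics

* **Expression construct** — "RGSHHHHHHGS" inserted after the initiator
  methionine and "LN" after the last lysine (residues downstream of that
  lysine preserved); +13 residues. Tagging an already-tagged record
  raises instead of double-tagging.
* **Alignment** — pairwise Needleman–Wunsch global alignment (Biopython's
  `PairwiseAligner`), default scoring match 1 / mismatch 0 / affine gaps
  −10/−0.5 on the identity scale: for 60–66-residue family members at
  ≥ 70% identity this recovers the columns a multiple aligner would.
  Pre-aligned FASTA is accepted and bypasses alignment.
* **Identity/similarity** — similarity uses the eight standard side-chain
  classes GAVLI / FYW / CM / ST / KRH / DE / NQ / P (a partition, so
  identity ≤ similarity always). Published percent-identity tools differ
  on the denominator, so it is an option: `shorter_sequence` (default) or
  `alignment_length`.
* **Net charge / pI** — Henderson–Hasselbalch summation over K, R, H, the
  N-terminus (basic) and D, E, C, Y, the C-terminus (acidic), with an
  EMBOSS-style pKa set (N-term 8.6, C-term 3.6, K 10.8, R 12.5, H 6.5,
  D 3.9, E 4.1, C 8.5, Y 10.1); overridable. pI by root bisection of the
  charge, which is strictly decreasing in pH. The family convention of
  suffixing paralogs in order of increasing basicity is implemented as a
  sort on pI. Computed on the tagged constructs (the form actually
  studied), Sac7d comes out at +7.6 at pH 7.4; different published pKa
  sets move such values by a few tenths of a charge.
* **Mass** — average residue masses (IUPAC average atomic weights) plus
  one water. Tagged Sac7d: 9103 Da.

## Packaged data and its limits

`data/study_table.csv` transcribes the study's printed per-protein table
(masses, yields, K_D, n, Tm, aggregation flags, stability groups), with
decimal commas normalised to points. Stability group membership is data,
not inferred — though a convenience largest-gap splitter exists and, on
this table, reproduces the same split.

Only Sac7d (UniProt P13123) is packaged as a real sequence; its identity
is internally verified (computed tagged mass 9103 Da equals the table
value; residues V2/E14/T17/I20/R25/V30 match every documented position).
The other twelve sequences are **synthetic** Sac7d-backbone variants
carrying exactly the documented residue differences: the stability
determinants at positions 17/30, the position-2/14 relationships among
the Sulfolobus paralogs, the Metallosphaera QDL 11–13 motif with
V4I/I20V/R25K, and Aho7c's missing penultimate lysine. They make the
determinant check and pipeline demonstrations runnable offline, but their
masses, charges and pairwise divergences are illustrative, not the real
proteins' values — in particular the real family's 71–98% identity span
requires the actual UniProt sequences.

## Stability analytics

Group statistics use the sample (n−1) SD, which reproduces the printed
±1.7 (n = 7) and ±1.5 (n = 6) figures at one decimal. The determinant
rule evaluated at Sac7d positions 17 and 30 (mapped by pairwise alignment
to the reference) is: non-aggregating low-Tm proteins carry at least one
destabilising residue (T17 or V30); high-Tm proteins carry neither.
Mse7 and Mcu7 unfold irreversibly (aggregation), so their Tm values are
not comparable two-state midpoints and they are excluded from the rule.

## Problem sizes

Default analysis sizes — 25-point titrations, 100-replicate recovery
studies, 1000-draw solver cross-validations against a 10⁶-point grid
oracle — were chosen so each stage completes in about a minute on one
core while leaving the acceptance bands statistically meaningful.
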