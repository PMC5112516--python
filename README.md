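# sul7d

Quantitative analytics for the archaeal **Sul7d** ("7 kDa DNA-binding")
chromatin protein family — Sac7d, Sso7d and their homologs from the
*Sulfolobales*. These small, highly basic, hyperthermostable proteins bind
double-stranded DNA non-specifically, and their affinities are classically
measured by **reverse titration**: protein is held at a fixed concentration
(5–6 µM), sonicated calf-thymus DNA is added stepwise, and binding is read
out as quenching of the protein's single-tryptophan fluorescence.

The package is aimed at biophysicists analysing such titrations and at
protein engineers comparing family members as scaffold candidates.

## The model

Binding of a protein that covers `n` contiguous nucleotides of an
effectively infinite DNA lattice, without cooperativity, follows the
McGhee–von Hippel isotherm

```
ν / P_f = K (1 − nν) [ (1 − nν) / (1 − (n−1)ν) ]^(n−1)
```

with ν = P_b/D_t the binding density (bound proteins per nucleotide),
P_f = P_t − P_b the free protein, K the association constant (M⁻¹) and D_t
the total DNA in nucleotide molarity. The observed signal is

```
Q_obs = (F_i − F_obs) / F_i ,   Q = Q_max · P_b / P_t
```

Given (K, n, Q_max), P_b is defined implicitly; `sul7d` solves it by
**bisection** inside every model evaluation and estimates the three
parameters by multistart **damped nonlinear least squares**, reporting
K_D = 1/K, the site size n (nucleotides), Q_max, standard errors and
diagnostics. Alongside the fitting core, the package implements the
family's sequence analytics (RGS-His6 expression-construct assembly,
percent identity/similarity under eight residue classes, Henderson–
Hasselbalch net charge and pI, average mass) and the thermostability group
statistics with the position-17/30 determinant check (Sac7d numbering).

## Worked example

Simulate a Sac7d-like titration (true K_D = 13 µM, n = 6.4, Q_max = 0.9,
protein at 5.5 µM, 1% fluorescence noise) and refit it:

```python
from sul7d import BindingParameters, fit_titration
from sul7d.synthetic_data import NoiseModel, simulate_titration

truth = BindingParameters.from_kd(13e-6, n=6.4, q_max=0.9)
exp = simulate_titration(truth, noise=NoiseModel(sigma_rel=0.01, seed=7))
fit = fit_titration(exp)
print(f"K_D = {fit.kd_uM:.1f} ± {fit.se['kd_uM']:.1f} uM, "
      f"n = {fit.params.n:.1f} ± {fit.se['n']:.1f} bases, "
      f"Q_max = {fit.params.q_max:.2f}")
```

```
K_D = 13.1 ± 1.0 uM, n = 6.5 ± 0.3 bases, Q_max = 0.91
```

The fitted K_D and site size recover the truth within their standard
errors — the typical behaviour at this design, where the median error of
K_D over 100 replicates is ≈ 7%. The same machinery is available from the
shell (`sul7d simulate | fit | recover | seqstats | stability`).

The numbered drivers under `analysis/` run the full study pipeline:
simulate titrations for all 13 family members at their reported
(K_D, n) (`01`), fit them into a study-table-style report (`02`), run the
parameter-recovery study (`03`), compute sequence statistics and pairwise
identity/similarity matrices (`04`), and the thermostability group
statistics and determinant check (`05`). Outputs land under `results/`.

Packaged data: the study's printed per-protein table (masses, K_D, n, Tm,
stability groups) and the real Sac7d sequence (UniProt P13123). The other
twelve study sequences are not redistributable and are represented by
clearly-labelled synthetic backbone variants carrying only the documented
determinant residues (see `docs/methods.md`).

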