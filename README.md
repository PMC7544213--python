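# tandemrrm

Solution-NMR and ITC analysis for multidomain protein–RNA binding studies,
built around the tandem RNA-recognition-motif (RRM) case: two ~90-residue
folded domains joined by a flexible linker that may — or may not — tumble
as one rigid body, binding a short single-stranded RNA element weakly.

The package implements the four quantitative chains such a study rests on,
each with a synthetic-data generator so every stage is testable without
downloading spectra:

1. **Chemical-shift perturbation (CSP) mapping and titration fitting.**
   Per-residue amide perturbations
   `Δδ = sqrt(½(ΔδH² + (0.14·ΔδN)²))`, classification of large shifts
   (> 0.025 ppm), structure mapping via the PDB B-factor column, and a
   global fast-exchange fit of the titration course
   `δobs(L) = δfree + (δbound − δfree)·fb(P, L, Kd)` with the single-site
   ligand-depletion quadratic for the bound fraction.
2. **¹⁵N relaxation and rotational correlation times.** Exponential decay
   fitting, mean-T1/T2 estimation
   `τc = (1/4πνN)·sqrt(6·T1/T2 − 7)`, an empirical linear-in-MW predicted
   τc with η(T)/T temperature scaling, and a rigid-vs-flexible verdict
   from the calculated/predicted ratio: domains that reorient independently
   tumble measurably faster than one rigid particle of the same mass.
3. **Residual dipolar coupling (RDC) alignment-tensor fitting.** Saupe
   tensor by SVD against structure N–H vectors (fit directly in Hz),
   parameters (Da, rhombicity R, ZYZ Euler angles), the RDC R-factor
   `100·sqrt(⟨(Dobs−Dcalc)²⟩/(2⟨Dobs²⟩))`, and the per-domain vs joint fit
   comparison: if the inter-domain orientation in solution matches the
   coordinates, one tensor fits everything; if not, the joint R-factor
   degrades by >50%.
4. **ITC isotherm models.** Wiseman one-site (n, Kd, ΔH) and sequential
   two-site (K1, K2, ΔH1, ΔH2) forward models with perfusion-cell
   concentration bookkeeping, nonlinear least-squares fitting,
   equivalence-point location (a transition at molar ratio 2.0 is the
   signature of two proteins per RNA), and dilution controls.

## Worked example

```python
from tandemrrm import (InjectionSchedule, IsothermModel, OneSiteParams,
                       gen_isotherm, estimate_tumbling)
from tandemrrm.synth import gen_relaxation_set, NoiseSpec

# ITC: simulate a weak one-site isotherm (0.3 ucal heat noise) and refit it
schedule = InjectionSchedule.standard(n_injections=30, syringe_conc_uM=7000,
                                      cell_conc_uM=800)
iso = gen_isotherm(OneSiteParams(n=0.9, Kd_uM=139.0, dH_kcal_mol=-5.0),
                   schedule, noise=NoiseSpec(sd=0.3, seed=11))
print(IsothermModel(iso, "one_site").fit().summary())

# tumbling: rates for a 10.57 ns rotor at 500 MHz, against the rigid-body
# prediction for a 21,854 Da particle
rates = gen_relaxation_set(10.57, 500.0, n_residues=40)
print(estimate_tumbling(rates, MW_Da=21854).summary())
```

prints

```
ITC isotherm fit (one_site)
  n             : 0.9002 +/- 0.000686
  Kd_uM         : 139.7 +/- 0.511
  dH_kcal_mol   : -5.004 +/- 0.00561
  q_offset_ucal : 0 +/- 0
  Wiseman c     : 5.15
  injections    : 29
  residual norm : 1.383 ucal

Tumbling estimate (nu_N = 50.66 MHz, T = 298.15 K, MW = 21854 Da, n = 40 residues)
  <T1> = 597.2 ms   <T2> = 70.0 ms
  tau_c calculated = 10.44 ns
  tau_c predicted  = 13.44 ns
  ratio calc/pred  = 0.777  ->  independent/flexible
```

The isotherm fit recovers the generating parameters (n ≈ 0.9, Kd ≈ 140 μM,
ΔH ≈ −5 kcal/mol) despite the low Wiseman c; the tumbling estimate shows a
measured τc well under the rigid-body prediction — the relaxation signature
of two domains reorienting partly independently.

## Command line

Every stage is also exposed as a `tandemrrm` subcommand:

```sh
tandemrrm simulate structure --n-residues 25 --geometry two_domain --out toy.pdb
tandemrrm simulate rdc --pdb toy.pdb --da 10.6 --rhombicity 0.23 --out rdcs.tsv
tandemrrm rdc-fit --rdcs rdcs.tsv --pdb toy.pdb --domains "1-25:D1,26-50:D2"
tandemrrm tauc --rates rates.tsv --mw 21854 --field 500
tandemrrm itc-fit --isotherm isotherm.csv --model one_site
tandemrrm report            # bundled end-to-end demo pipeline
```

File formats are plain TSV/CSV with mandatory headers (documented in the
reader docstrings in `tandemrrm.io`): peak lists
(`residue_number, residue_name, dH_ppm, dN_ppm, intensity`), RDC tables
(`residue_number, D_obs_Hz[, D_err_Hz, domain]`), relaxation tables
(`residue_number, R1_s, R2_s, hetNOE`), and isotherm CSVs with
`# key=value` header lines for the cell geometry and concentrations.
Structures are the PDB ATOM subset.

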