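# lmp2f12

An integral-direct, iteration-free, **local explicitly correlated MP2**
(LMP2-F12) implementation at desk scale, for quantum chemists who want a
transparent, fully tested reference implementation of the machinery behind
linear-scaling explicitly correlated perturbation theory:

* density-fitted canonical MP2 and **MP2-F12 (ansatz 2B, fixed amplitudes,
  CABS)** with robust fitting of the geminal integrals,
* **Boys localization**, projected atomic orbitals (PAOs) and modified
  **Boughton–Pulay (BP) domains** (primary domains, extended domains,
  PAO-center domains, CABS domains, local fitting domains),
* **Cholesky/Laplace factorization of orbital-energy denominators**, which
  makes the domain equations uncoupled and iteration-free,
* the **local coupling-intermediate algorithm** that evaluates the
  conventional/geminal coupling term C without fifth-power steps,
* a second-order **CABS singles** correction to the HF energy.

Everything — the Gaussian integral engine (McMurchie–Davidson, with native
kernels for 1/r12, Gaussian geminals and Gaussian/r12), a DF-RHF reference
provider and run-time-generated basis-set families — is self-contained
(numpy/scipy only).

## The model in brief

The correlation energy is assembled per localized occupied orbital (LMO):

    E_c(LMP2-F12) = Σ_i δE_i^MP2(E_i) + Σ'_{ij} δE_ij^MP2(P_ij) + Σ_i δE_i^F12(E_i)

δE_i^MP2(E_i) is the MP2 contribution of LMO *i* evaluated in its extended
domain E_i (the CMO plus all strong-pair partners, with pseudocanonical
occupied/virtual spaces built from BP-truncated LMOs and PAOs). The primed
sum covers LMO pairs in no ED — classified *distant* when the approximate
pair energy |δE_ij(P_ij)| < ε_w = 1e-5 Eh — via dipole–dipole multipole
estimates (pair-domain evaluation when the primary domains overlap). Energy
denominators 1/(ε_a − ε_i + ε_b − ε_j) are replaced by a pivoted Cholesky
factorization of the Cauchy matrix 1/(x_ai + x_bj) (6–8 vectors at the 1e-4
residual threshold), so amplitudes are products of ω-scaled fitted integrals
J^ω and no amplitude equations are solved.

The explicitly correlated part uses the Slater geminal f12 = −(1/γ)e^(−γ r12)
(γ = 0.9/1.0/1.1 for DZ/TZ/QZ-type sets), represented by a 6-term Gaussian
expansion, and the ansatz-2B projector Q12 = (1−O1)(1−O2) − V1V2 with the
cusp-fixed amplitudes (3/8 direct, 1/8 exchange). Per pair, four
intermediates enter: E_F12 = Σ_{i≤j} (B − X + C + V)/(1 + δij). V and X
combine exact f12/r12 and f12² integrals with RI projection corrections, B
uses the commutator identity f T f = {T, f²}/2 + (∇1 f12)² for the kinetic
content plus an RI-consistent treatment of the remaining Fock content (F+K
commutator approximation), and C couples to the conventional amplitudes
through CABS/virtual Fock blocks, evaluated locally with the same ω vectors
as the MP2 part.

## Worked example

`examples/01_canonical_mp2_f12.py` (helium, DZ-quality basis):

    HF energy (svp-d):               -2.81738784 Eh
    MP2 correlation (svp-d):         -0.02718600 Eh
    F12 correction:                  -0.00816697 Eh
    CABS singles (HF error):         -0.01462675 Eh
    MP2 correlation (large):         -0.03546369 Eh

    error vs large-basis MP2:   plain 0.008278  with F12 0.000111 Eh

The F12 correction removes ~99% of the basis-set incompleteness of the
small-basis MP2 correlation energy, and the CABS singles term shrinks the HF
basis error — the whole point of explicitly correlated MP2. The other
examples walk through domain construction on a water dimer
(`02_local_domains.py`), the full local pipeline with its energy breakdown
(`03_lmp2_f12_water.py`) and the denominator factorization
(`04_denominators.py`).

A thin CLI wraps the same pipelines:

    lmp2f12 fixture --kind water_chain --n 2 -o dimer.xyz
    lmp2f12 run --geometry dimer.xyz --mode lmp2-f12 --report report.json

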