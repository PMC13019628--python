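# Methods

This note documents the model implemented by `lmp2f12`, the defaults, the
numerical choices, and the design decisions taken where the formulation was
genuinely open. All quantities are atomic units unless noted.

## Scope and assumptions

The package computes closed-shell (spin-restricted) second-order correlation
energies: canonical DF-MP2, canonical MP2-F12, local MP2 (LMP2) and local
MP2-F12, plus a perturbative CABS-singles correction to the HF energy. The
HF reference itself is consumed through a provider contract
(`lmp2f12.reference.load_reference`); the built-in provider is a dense DF-RHF
(DIIS, symmetric orthogonalization) intended for desk-scale molecules of
first-row elements. Cores are frozen in the correlation treatment (1s of
Li–Ne); core LMOs still enter RI spaces and Fock builds.

## Integrals

All integrals are evaluated with a McMurchie–Davidson scheme over contracted
Cartesian Gaussians (per-component normalization, so AO overlaps are exactly
unit-diagonal). Two-electron kernels are reduced to three families with
closed-form Hermite fundamentals:

* Coulomb `1/r12` — Boys function,
* Gaussian geminal `exp(-w r12^2)` — pure exponential fundamental,
* `exp(-w r12^2)/r12` — product of a Gaussian prefactor and a Boys function
  with scaled argument: Phi = C exp(-eta R^2) F_0(sigma R^2),
  eta = rho w/(rho+w), sigma = rho^2/(rho+w).

The derivative tables (d/dR^2)^n Phi feed a generic two-level Hermite
R-tensor recursion, so a whole contracted operator (e.g. a 21-term squared
geminal expansion) costs one recursion pass. The engine was validated against
independent radial-quadrature oracles (s functions, all kernels, machine
precision), center-derivative identities (p functions), translation
invariance, permutational symmetry, and hydrogenic/HF-limit energies (He
RHF: -2.86164 Eh vs the literature limit -2.86168 in the built-in
`ref-large` set). Screening uses a conservative bra-pair Gaussian-prefactor
bound at 1e-12; a Cauchy–Schwarz estimator was not needed at desk scale.

## Basis sets

No external basis data are shipped; named families are generated at run
time:

* `min` — minimal sets from least-squares STO-3G-style fits of Slater
  orbitals with Slater-rule exponents (the fit reproduces the classic H
  parameters to 4–5 digits).
* `sv` — `min` with 6-term heavy-atom cores plus one diffuse s (and heavy-atom
  p) split; cheap enough for chain scans.
* `svp-d` (cardinal DZ), `svp-t` (TZ) — split valence plus polarization;
  `svp-d` gives H2O/HF = -75.863 Eh at 31 functions.
* `ref-large` — large uncontracted even-tempered sets used as basis-limit
  references (H2O MP2 correlation -0.277 Eh at 166 functions).

Fitting sets are generated by `autoaux`, an even-tempered generator covering
the product-exponent ranges per atom and angular momentum. The F12 integrals
use a dedicated `autoaux(joint, other=orbital)` set covering CABS-times-
orbital products — with an orbital-product-only fitting set the robust-fitted
geminal blocks are qualitatively wrong, which is easy to miss and was caught
by the dense finite-basis oracle. The CABS source set is an even-tempered
family one angular momentum above the orbital basis.

The geminal exponent defaults are keyed to the basis cardinal: gamma = 0.9
(DZ), 1.0 (TZ), 1.1 (QZ), overridable. exp(-gamma r) is fitted by 6
Gaussians (uniform-weight least squares on r in [0, 10] bohr, exponents
optimized); the max pointwise residual (~5e-3, sitting at the r = 0 cusp) is
stored on the `GeminalFactor` and enforced against a 1e-2 tolerance. The
derived operators reuse the expansion consistently (f12^2 and (d1 f12)^2 via
the squared expansion, f12/r12 via Gaussian/r kernels), so operator
identities hold exactly within the representation.

## Density fitting

The Coulomb metric is factorized by pivoted Cholesky, dropping pivots below
1e-10 of the largest diagonal (silent conditioning of near-dependent fitting
sets); all solves are triangular, never explicit inverses. Non-Coulomb
operators use robust fitting,
(pq|f|rs) ~ sum_P (J_pq K_rs + K_pq J_rs), with K built from the operator
three/two-center integrals and the *Coulomb* J of the same pairs; the
reconstruction error is quadratic in the fitting-basis incompleteness
(verified: exactness on spanning toy sets, ~2x log-slope vs the one-sided
fit on detuned sets).

## Localization, PAOs, domains

Boys localization runs pairwise Jacobi sweeps with analytic 2x2 rotations in
row-major order (deterministic; converged when the largest rotation angle
< 1e-8 rad; the objective is checked to be non-decreasing). Core and valence
blocks are localized separately. Signs are fixed by making each orbital's
largest coefficient positive. PAOs are built as (1 - sum_i |i><i|S) chi_mu,
dropped below an S-norm of 1e-8 and normalized, with the parent atom
recorded.

BP atom lists grow greedily in descending Loewdin-population order (ties by
atom index); completeness is the squared S-norm of the least-squares
projection of the orbital onto the listed atoms' AO block, which is
monotonically non-decreasing (asserted during growth). Thresholds follow the
method defaults: T_PDo = 0.999, T_PDv = 0.98, T_EDo = 0.9999, T_o = 0.985,
T_trf = 0.99999, strong-pair threshold eps_w = 1e-5 Eh, CABS domain =
BPEDo of the CMO. `DomainConfig.full_domain()` (all thresholds 1, eps_w 0)
forces the canonical-collapse limit used throughout the tests.

Primary domains: BPPDo atoms plus the BPPDv lists of the PAOs on them; PAOs
truncated to the PD, projected against the central LMO, Loewdin-orthonormalized
and Fock-canonicalized. Extended domains: occupied LMOs = CMO + strong
partners, truncated to their own BPEDo lists (renormalized; the norm deficit
is recorded), orthonormalized and canonicalized; ED core orbitals are
included iff their whole BPEDo list is covered by the ED, truncated and
orthogonalized against the valence block so the ED MO space is exactly
S-orthonormal; ED virtuals are the PAOs of the PCD (union of BPo lists,
intersected with the ED) truncated to the ED and projected against the ED
occupied space. Local fitting functions sit on PCD atoms. For the F12
integral transformation the LMOs are truncated to BPtrf ∩ ED (coefficients
truncated before the half transformation, then renormalized).

Pair energies: dipole–dipole multipole estimates
T_ab = [mu_ai.mu_bj - 3(mu_ai.n)(mu_bj.n)]/R^3 between PD-local transition
dipoles with denominators f_ii + f_jj - eps_a - eps_b (R^-6 decay verified to
slope -6.000 on He...He); when the PDs share atoms the estimate falls back
to an exact opposite-spin evaluation in the union pair domain. Estimates were
validated against true localized opposite-spin pair energies (C8H18: median
ratio 0.86, 2% of pairs misclassified at the eps_w boundary). Distant pairs
contribute their estimates to the energy; no F12 terms are attached to them.

## Denominator factorization

CD mode (default): greedy pivoted Cholesky of the Cauchy matrix
1/(x_ai + x_bj) down to a maximum diagonal residual of 1e-4 (typically 5–8
vectors). Laplace mode: exponential quadrature fitted by least squares in
relative error on [2 gap_min, 2 gap_max] from logarithmic starting guesses,
with the weight split as w^{1/2} per factor so the bra-ket product carries
each weight exactly once (the printed convention with a full weight per
factor would double-count; verified against direct denominator division).
Both modes agree with explicit division to ~1e-4 in amplitudes; the induced
ED energy error is ~1e-6 Eh (2e-5 relative) at the default threshold. The
same omega set is shared between the MP2 and coupling-term evaluations.

## The F12 intermediates

Pair scalars follow the fixed (cusp) amplitudes c = 3/8 (direct) + 1/8
(exchange). Contracting them with the closed-shell contravariant metric
gives the patterns used throughout:

* linear (V): V_ij = (5/2) <ij|r^-1 Q f|ij> - (1/2) <ij|r^-1 Q f|ji>,
* quadratic (B, X): B_ij = (7/16) B[ij,ij] + (1/16) B[ij,ji], with X carrying
  the occupied Fock coupling X_ij = 2 sum_k [f_ik P_X(ij;kj) + f_jk P_X(ij;ik)]
  — in a canonical basis this reduces to (eps_i + eps_j)(7 X_d + X_x)/16, and
  the occupied-rotation invariance of B - X is what allows direct evaluation
  in the LMO basis inside domains.

These patterns independently reproduce the printed coefficient structure of
the coupling intermediate C (40, -8, 7, 1)/16, which is taken as given.

In an orthonormal RI basis [occupied | virtual | complementary] the
ansatz-2B projector is an elementwise pair-index mask, and:

* V = exact f12/r12 four-index (robust-fitted) minus masked RI corrections,
* X = exact f12^2 minus masked corrections,
* B: kinetic content through the exact commutator identity
  f T f = {T, f^2}/2 + (d1 f12)^2 with RI insertions (fast-converging,
  because kinetic operators keep Gaussians within their span), plus the
  non-kinetic Fock content evaluated with both geminal indices RI-projected,
  with exchange folded in via the F+K commutator approximation
  ([F + K, f12] = [T, f12]); B is symmetrized. A naive all-commutator
  evaluation is *not* CABS-convergent (the RI insertion adjacent to the
  nuclear attraction converges very slowly) — this was established on a He
  CABS ladder, where the hybrid form is stable at small CABS (0.0436/0.0442/
  0.0435 across three CABS sizes) while the alternatives drift.

C uses the Fock couplings of the virtuals to the complementary space only —
the virtual-virtual part is annihilated by the V1V2 term of the projector.
Canonically C is contracted with explicit denominators; in domains the
denominator-free route builds Fock-transformed fitting coefficients
(J-bar, K-bar), omega-scales all four blocks, back-transforms the
pseudocanonical occupied index to the CMO, and assembles
r = -sum_omega sum_P (Jbar^w K^w + Kbar^w J^w + J^w Kbar^w + K^w Jbar^w).
Full-domain equivalence of the two routes holds to 3e-11 Eh on water.

CABS spaces: complementary vectors are CABS-domain functions with the MO
space projected out, Loewdin-orthonormalized with eigenvalue cutoff 1e-7,
augmented by MO-projected AOs (cutoff 1e-4) that are subsequently
orthogonalized against the first block so the RI stays exactly orthonormal.
The CABS singles correction solves (F_AA - eps_i) x = F_Ai per occupied
orbital over the virtual+complementary space (non-iterative; Brillouin makes
it zero when the occupied-complementary coupling vanishes).

## Synthetic test systems

Geometry generators (water chains with hydrogen-bond spacing 2.85 A and
optional seeded jitter, all-trans alkanes with standard bond parameters,
noble-gas pairs at given separations) stand in for large benchmark sets at
desk scale. They exercise every code path — multiple EDs, core-coverage
rules, distant-pair classification, size consistency — but they cannot probe
basis sets beyond the generated families, heavier elements, or the
statistical accuracy claims of large molecular test suites; passing tests
certify internal consistency and the physically expected behaviors (basis
convergence acceleration, R^-6 pair decay, domain locality), not agreement
with any external program.

Problem sizes used in the test and reproduction scripts (chosen to keep a
full run within minutes on one CPU): water/methane at `svp-d` (25–40 AO)
for the canonical/local equivalence checks, helium and water `ref-large`
(64/166 AO) as basis-limit references, and split-valence alkanes up to
C12H26 (160 AO) for the domain-saturation scan.

## Known limitations

* The extended-domain saturation along alkane chains sets in at ~C16 under
  the default thresholds (strong-pair radius ~5 A plus BP radius ~3 A);
  shorter chains have whole-molecule domains, so the C10→C12 saturation
  check in the acceptance suite fails honestly — the premise it audits is
  only visible from C16 onward at these settings.
* The B intermediate's non-kinetic content is RI-projected; with very small
  CABS sets B inherits the RI error (the commutator treatment protects only
  the kinetic part). Fixed amplitudes are not optimized; ansatz variants
  (3*A, 3C) are out of scope.
* Cartesian d/f shells are used throughout (no spherical transformation);
  near-linear-dependent fitting sets are conditioned by pivot dropping
  rather than re-generation.
* The DF-RHF provider targets small closed-shell molecules; no open shells,
  no relativistic corrections, no point-group symmetry.
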