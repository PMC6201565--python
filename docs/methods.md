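# Methods

## Scope and model structure

`onecarbon` implements a deterministic kinetic model of hepatic
one-carbon metabolism: the folate cycle, the methionine cycle, and the
PEMT-driven synthesis pathway of choline and betaine, coupled by
long-range allosteric regulation.  The model has 17 state variables
(concentrations, µM):

* methionine cycle — Met, SAM, SAH, Hcy;
* folate cycle — 5mTHF, THF, DHF, CH2-THF, CH=THF, 10f-THF;
* amino-acid pools serving the cycle — serine, glycine, sarcosine;
* choline pathway — PC, choline, betaine aldehyde, betaine.

Each concentration obeys mass balance over the reaction network
(`onecarbon.dynamics.rhs`); the six folate species form a conserved
moiety whose sum is the total-folate parameter, and the conservation is
structural (the summed folate derivative vanishes identically, which
the test suite verifies at random states).  Units are µM, µM/h and
hours throughout.

Phosphatidylethanolamine (PE) and sphingomyelin (SphMy) are clamped
boundary concentrations: they are parameters, not states, which is what
makes the female adaptation "multiply sphingomyelin by 1.3" well
defined.  Boundary fluxes are the methionine input, a serine supply, a
dietary betaine input, and first-order consumption/export terms for
choline, betaine, serine, glycine and sarcosine.  The choice of serine,
glycine and sarcosine as the three states beyond the fourteen core
metabolites is a reconstruction decision (see *Provenance* below): they
are the stoichiometric partners of SHMT and GNMT, and making them
dynamic gives SHMT expression changes a finite, substrate-limited
effect instead of an input-clamped one.

## Rate laws

The choline-pathway laws are implemented exactly in their published
form:

* **PEMT** — MM in SAM (Km 18.2 µM) with non-competitive SAH inhibition
  (Ki 3.8 µM), times a saturating PE factor `25·PE/(5000+PE)`;
  Vmax 98 µM/h.
* **SMS, PhL-D, ChOx, BAH** — single-substrate MM with
  (Vmax, Km) = (30, 20), (525, 400), (125, 200), (45, 250).
* **BHMT** — two-substrate MM in Hcy (Km 12) and betaine (Km 2000),
  times `exp(−0.0021(SAM+SAH))/exp(−0.0021·32.3)` (SAM+SAH
  inhibition) and `1 + 0.16(Bet−315)/315` (betaine activation).  Both
  factors equal exactly 1 at the normal male state (SAM+SAH = 32.3 µM,
  Bet = 315 µM); the betaine factor is applied unclamped below 315
  (minimum 0.84 at Bet = 0).
* **CBS** — MM in Hcy (Km 1000 µM), times a sigmoidal SAM+SAH
  activation `1.2·s²/(30²+s²)` normalized to 1 at s = 32.3, times a
  Heaviside-gated betaine activation
  `1 + H(Bet−315)·0.2(Bet−315)/(10+(Bet−315))`, which is exactly 1 at
  or below Bet = 315 (H(0) = 0) and rises continuously to 1.2.

The core-cycle reactions use the standard forms of this hepatic model
family: MAT-I (MM in Met with exponential SAM inhibition), MAT-III
(kinetic order 1.21 in Met with quadratic SAM activation), GNMT (Hill
kinetics in SAM, MM in glycine, competitive SAH inhibition, and the
two-site 5mTHF inhibition — with two independent sites of dissociation
constant Ki, half activity with one site bound and none with two, the
expected activity reduces algebraically to `Ki/(Ki+[5mTHF])`), DNMT,
GAMT and AS3MT (MM with competitive SAH inhibition), reversible SAHH,
MS (two-substrate MM), MTHFR (MM in CH2-THF with SAM inhibition),
reversible SHMT, the nonenzymatic THF↔CH2-THF interconversion, TS,
DHFR, AICART, PGT, reversible MTD and MTCH, FTS and FTD.

Every long-range interaction is a multiplicative factor behind a flag
in `RegulationSwitches` (all on by default); turning a flag off
replaces exactly that factor by 1.  Factors whose published form is not
already normalized (MAT-I/III, MTHFR) are expressed as ratios to their
value at the male reference SAM, so ablation is a well-posed operation
for them too.

## Calibration

Km, Ki and allosteric constants are fixed first; Vmax values are then
*back-solved* so that a documented male reference state — with the
published male anchors SAM 29.03, SAH 3.27 (SAM+SAH 32.3), Hcy 1.80,
choline 60, betaine 315 µM, vBHMT 35.48 µM/h, and hepatic literature
values for the remaining pools — is an exact equilibrium under a
documented reference flux partition.  This mirrors how the model family
is parameterized (Vmax tracks enzyme expression and is tuned to steady
state), makes the male baseline reproduce its anchors to solver
precision, and makes sex scaling (Vmax multipliers) well defined.  Two
consequences worth noting:

* The printed BHMT constants alone force Vmax(BHMT) ≈ 2000 µM/h
  (2000·(1.8/13.8)·(315/2315) = 35.49), an independent consistency
  check of the reconstruction.
* Closing the choline-pathway mass balance at both the male
  (chol 60, bet 315, vBHMT 35.48) and female (chol 100, bet 632,
  vBHMT 40.96) steady states requires a dietary betaine input
  (≈13.9 µM/h) and first-order choline (≈0.38/h) and betaine
  (≈0.023/h) consumption terms; their values are back-solved from
  those four anchors.

Constants with no primary source available — the reference flux
partition (methionine input 60 µM/h, MS 40.5, PEMT 26, GNMT 34.3 µM/h,
the folate-cycle branch fluxes), the GNMT Hill coefficient (1.66) and
5mTHF site constant (0.8 µM), GAMT Km (20 µM), SAHH Km and exchange
flux, MTHFR Ki(SAM) (2.2 µM) and the SphMy clamp (110 µM) — were
calibrated against the published single-adaptation and female
steady-state tables.  The male column is exact by construction; the
perturbation responses agree with the published tables to ~4 % rms
(worst entry ≈11 %), and every qualitative mechanism (which adaptation
dominates which metabolite, the sign of every response, the
folate-titration and polymorphism behaviors) is reproduced.  Residual
quantitative error reflects core-cycle constants we could not source;
see *Limitations*.

## Steady-state solving

The system is stiff (SAHH equilibrates within minutes; the betaine
pool turns over in ~10 h).  `run_to_steady_state` integrates with
adaptive BDF (`scipy.integrate.solve_ivp`, rtol 1e-8, atol 1e-10) in
expanding windows and finishes with a damped Newton polish in
log-concentration space, replacing the 10f-THF equation by the folate
conservation constraint (which removes the rank deficiency the
conserved moiety induces).  Convergence means max |d[X]/dt| < 1e-9 µM/h
(default; steady concentrations are O(1)–O(10³) µM, leaving ≥6
significant digits).  Non-convergence is reported in the result, never
raised.  Total folate enters through the initial condition; warm starts
across folate scales go through `rescale_folate`, which projects a
state onto the new conserved total.

**Branch selection.**  The Heaviside-gated CBS betaine activation has
slope 0.2/10 µM just above the 315 µM gate.  Because betaine's only
reaction sink is BHMT, and higher betaine activates CBS, lowers Hcy and
thereby *lowers* the BHMT flux, the betaine mass balance is locally
non-restoring over roughly 315–345 µM: the male parameterization has a
second stable steady state near Bet ≈ 347 µM in addition to the
reference state at exactly 315.  A loop-gain estimate
(d ln v_BHMT/d Bet ≈ +0.0033 from the MM and activation slopes versus
−0.017 from the Hcy feedback) shows the bistability follows from the
published rate laws plus mass balance, independent of the
reconstructed constants.  The solver therefore reports the steady state
*dynamically continued from the initial state* — a Newton root is
accepted only if it refines, rather than relocates, the integrated
trajectory — and all experiment drivers warm-start each grid point from
its neighbor.  A broad multi-start (used in the tests) exposes both
branches.

Two further consequences of the gate: along the male→female transition
Hcy is not monotone (it drops sharply in the first few percent of the
transition as betaine crosses the gate, where the activation
half-constant is only 10 µM, then partially recovers as SAM declines;
the net female value remains below the male), and comparison tables
that sit near Bet ≈ 315 (e.g. the MS adaptation) are sensitive to which
branch is reported — continuation from the male state resolves this.

## Scenarios and the virtual cohort

Scenario operations are pure functions on the parameter set: the six
female adaptations (PEMT ×2.3, BHMT ×0.6, SHMT ×2.2, MS ×1.35,
MTHFR ×0.8, SphMy ×1.3) applied singly, jointly, or interpolated
linearly in the multiplicative factor (λ ∈ [0, 1]); MTHFR polymorphism
multipliers 0.3 (C677T) and 0.68 (the variant printed as A1289C in the
source; the canonical name is A1298C — the printed name and factor are
kept); total-folate and methionine-input scaling; and per-flag
regulation ablations.

The virtual cohort emulates inter-individual variation in enzyme
expression: every Vmax is independently multiplied by a uniform factor
in [1−cv, 1+cv], cv ≤ 0.25, with a fixed seed.  The bound is the
reported individual-to-individual spread of expression levels; uniform
multiplicative noise is a choice (only the bound is reported, not a
distribution).  What the cohort does *not* emulate: correlated
expression programs (hormone-driven co-regulation), Km variation, or
measurement noise.  Two robustness limits are worth knowing.  First,
the female choline flux (≈42 µM/h through ChOx) sits only ~8 % below
the BAH capacity (Vmax 45 µM/h), so at cv = 0.25 a minority of cohort
members exceed it and have no finite steady state (betaine aldehyde
grows without bound); the solver reports these honestly.  Second, the
liver Hcy sex difference is small (a few percent) relative to the Hcy
spread the noise induces, so its *per-individual* sign is not
noise-robust; the large differences (choline and betaine up, SAM down
in females) are.

## Numerical and design choices

* Steady-state tolerance 1e-9 µM/h; t_max 1e6 h; BDF with finite
  difference Jacobian (results are polish-verified, so
  Jacobian-independent within tolerance).
* Reversible reactions (SAHH, SHMT, NE, MTD, MTCH) are net-signed with
  the forward direction along the physiological flux at the male state.
* Rates are reported unflushed; concentrations are clipped at zero only
  for rate evaluation during adaptive integration trial steps.
* Heaviside boundary: H(0) = 0, so Bet = 315 gives a CBS betaine factor
  of exactly 1 and the male reference sits precisely on the gate.
* Experiment grids: folate 0.2–2.0 in 19 steps, λ 0–1 in 21 steps,
  response surfaces 15×15 — desk-scale runtimes (a few seconds per
  driver on one core).
* Config files carry every constant with value, unit and source
  annotation; loading rejects unknown keys and unit mismatches, and the
  shipped `male_default.yaml` matches the library baseline checksum.

## Provenance and limitations

The published primary source for the core folate/methionine-cycle
constants is supplementary material that is not distributed with this
package; only the choline-pathway, BHMT and CBS rate laws, the female
adaptation factors, the polymorphism multipliers and the
steady-state/comparison tables are available in the main text.  The
core cycle is therefore a *reconstruction*: structural forms from the
same authors' earlier hepatic models, Vmax values back-solved from the
documented reference state, and the unsourced constants calibrated to
the published tables.  Consequences:

* The male baseline reproduces its published anchors exactly; the
  perturbation tables are reproduced to ~4 % rms with a worst entry of
  ~11 % (the PEMT-adaptation betaine).  Comparisons tighter than that
  (e.g. ±2 %) fail on a subset of entries and are flagged in the
  acceptance test suite rather than hidden.
* The identity of the three non-obvious state variables, the PE/SphMy
  clamp values, the methionine input and the flux partition are
  reconstruction choices, documented in `model.py`.
* The model is liver-only: plasma/tissue Hcy exchange, the
  mitochondrial folate compartment, the transsulfuration pathway beyond
  CBS, substrate inhibition of BAH and CBS, and hormone-to-expression
  causal links are all out of scope.
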