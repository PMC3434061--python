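# Methods

## The model

The package models the *E. coli* hipBA operon: a toxin (HipA, `A`) and its
antitoxin (HipB, `B`) cotranscribed from one promoter. HipB dimerizes
irreversibly (`B2`), the dimer captures two HipA copies into the inert
complex `AB2A`, and both `B2` and `AB2A` repress the promoter by binding it
(promoter states `P`, `P'`, `P''`). The wild-type network has 8 species and
17 mass-action reactions; all amounts are molecule counts per cell, all
rates per hour. Each of the 17 rate constants carries a nominal value and a
tested range spanning a factor of ten on either side (see
`hipba.parameters.PARAMETER_TABLE`).

Both backends — the stiff ODE integrator and the exact Gillespie
simulator — are generated from the same `ReactionNetwork` reaction list, so
they cannot drift apart. Degradation acts only on free species (`M`, `A`,
`B`, `B2`, `AB2A`), never on promoter-bound complexes.

### Event-rate convention

The dimer and complex balance equations of the deterministic model carry
half factors, which we keep by construing reactions as *events*:

* one dimerization event consumes 2 `B` and makes 1 `B2` at deterministic
  rate ½·β_B2·B²;
* one association event consumes 2 `A` + 1 `B2` at ½·μ·A²·B2;
* one dissociation event releases 2 `A` + 1 `B2` at ½·μ_R·AB2A (the ½ on
  the dissociation event is forced by internal consistency: the toxin line
  gains +μ_R·AB2A, i.e. two toxins per event).

The SSA uses the combinatorial counterparts `β_B2·B(B−1)/2` and
`μ·(A(A−1)/2)·B2`, which coincide with the event rates in the large-count
limit but differ at counts ≤ 2 — the correct behaviour for exact stochastic
simulation (two molecules are needed for a dimerization, not "B²").

One typographical point: the reaction listing prints the HipA translation
channel with the HipB symbol; the rate table's "HipA translation" row gives
β_A = 12, which is what the implementation uses.

### Promoter copy number

One copy per gene (single chromosomal operon), configurable via
`build_network(..., promoter_copies=n)`. Amounts are treated as counts
rather than concentrations because the stochastic model requires counts and
the deterministic model shares its parameters for a controlled comparison.

## Architecture variants

* **uncoupled** — hipA and hipB each get their own promoter (three states
  each) and their own mRNA: 12 species. All rate constants equal the
  wild-type values; both repressors can bind both promoters (the symmetric
  reading — nothing in the construction makes repression promoter-specific).
  The comparison carries an intrinsic asymmetry: two promoter copies total
  versus one in the wild type, which is inherent to splitting the operon.
* **no_feedback** — only the free promoter state exists and transcription is
  constitutive at α; dimerization, complex formation and all degradations
  are untouched. Expression rises because repression is gone.

## Quasi-steady-state reduction

Promoter states, mRNA, `B` and `B2` relax fast relative to `A` and `AB2A`.
Setting their derivatives to zero at fixed (A, AB2A) gives promoter
occupancies in closed form, mRNA by transcription/decay balance, `B` from a
quadratic, and a scalar fixed-point equation for `B2` solved by Brent's
method on a bracket whose upper end is the dimer level implied by fully
active transcription (the one-dimensional bracketed solve was chosen over a
general Newton method for robustness; the promoter binding fluxes cancel
identically at promoter equilibrium, which collapses the six balances to
that single scalar equation). The reduced planar field (dA/dt, dAB2A/dt) is
evaluated on a 60×60 logarithmic grid spanning 1e−2…1e3 molecules in each
coordinate — more than an order of magnitude beyond the nominal equilibrium
(A\* ≈ 1.16, AB2A\* ≈ 4.64) in both directions. Nullclines are traced by
sign-change detection along grid lines refined by bisection; equilibria are
found by Newton solves seeded in every grid cell where both components
change sign, then merged below 0.5% relative distance. Stability is
classified by the eigenvalues of a finite-difference Jacobian (a
convenience check, not a primary output). The intersection count is
verified to be invariant under grid doubling, and every intersection lifts
(via the fast-state map) to a full-model equilibrium with residual < 1e−4.

## Monostability scans

Parameter draws are log-normal with median equal to the nominal value and
log-scale σ chosen so the central 95% interval equals the tested range
(σ = ln 10 / 1.96 for the ten-fold ranges); draws are untruncated. Initial
conditions draw mRNA uniformly on [0, 100] and every non-promoter protein
species (including `B2` and `AB2A`) uniformly on [0, 1000], with promoters
held at the free state. Each initial condition is integrated for 1000 h
(LSODA), Newton-polished, and accepted as a steady state when the residual
infinity norm is < 1e−4 molecules/hour; non-converged runs are excluded and
counted, never silently dropped. Final states are clustered by
single-linkage with distance `max_species |x−y| / max(x, y, 1e−6)` and a 1%
threshold — the ε guard makes the relative metric well-defined at zero
amounts. The full study sizes (100 repeats × 17 parameters × 500 initial
conditions; 1000 simultaneous combinations) are the config defaults; the
test suite and the acceptance script run a scaled-down replicate
(50 draws × 50 initial conditions) chosen to exercise the same design at
interactive runtimes. A planted one-species autocatalytic switch with
analytically placed stable states (100 and 400 molecules) serves as the
positive control that the 1% clustering actually detects bistability.

## Stochastic simulation

Direct-method Gillespie, seeded and bit-reproducible. The default initial
condition is the deterministic equilibrium rounded to integers (promoter
copies assigned to the highest-occupancy state), which minimizes the
transient; zeros are available by passing `init` explicitly. Runs default to
1000 h with the first 100 h discarded as burn-in — the relaxation times in
the system are minutes to hours (slowest: 1/δ_A ≈ 50 min), so 100 h is a
conservative margin for stationarity. Trajectories are stored at full event
resolution (an int64 matrix reconstructed from the event log by cumulative
stoichiometry; tens of MB at the propensities reached here, so no thinning
is applied) and every statistic is dwell-time weighted over the
piecewise-constant path, not per-event weighted.

The engine is calibrated against closed forms: a constitutive birth–death
fixture (stationary mean α/δ_M = 10, Fano 1 — Poisson), a two-state
promoter fixture (bound occupancy θ/(θ+γ)), and a 10× volume-scaled system
whose time averages approach the deterministic equilibrium.

## The persistence statistic R

`R = free HipA / (free HipA + free HipB)`, with R > 0.5 classifying a
persister. Free HipA is the unbound monomer `A`: toxin sequestered in
`AB2A` is neutralized and excluded. Free HipB is every antitoxin **not**
sequestered in the toxin complex: `B + 2·B2`, counting two antitoxins per
dimer, because the dimer is the active form that captures HipA. The
monomer-only alternative (`R = A/(A+B)`) is available as
`compute_R(..., count_dimers=False)` as a sensitivity check; at nominal
parameters it classifies the majority of dwell time as persistent (free
monomeric HipB is scarce since dimerization is fast relative to
degradation), which is inconsistent with persistence being a rare
phenotype, and it erases the noise contrast between the wild-type and
uncoupled architectures. The dimer-inclusive reading is therefore the
default. Intervals with no free protein at all (A + B(+2B2) = 0) leave R
undefined; they are treated as data gaps (excluded from means, Fano factors
and histograms), not errors, and occupy a negligible dwell fraction at
nominal parameters.

Noise is reported as the Fano factor σ²/μ **of R**, computed dwell-weighted
per replicate cell; per-species Fano factors are available through
`time_weighted_stats` for diagnostics. Replicate cells are independent
seeds; the architecture comparison runs ≥ 10 cells per architecture
(500 h each after a 100 h burn-in in the shipped analyses) and scores the
expected orderings with one-sided Mann–Whitney rank tests across replicate
cells at α = 0.05.

## Numerical choices

* Stiff integration: LSODA, rtol 1e−7/atol 1e−9 for scan steady states,
  tighter (1e−9/1e−11) for reference equilibria; equilibria polished with
  `scipy.optimize.root` (Powell hybrid) and accepted below a residual of
  1e−6 molecules/hour (1e−4 inside the scans, where extreme draws make the
  Jacobian badly scaled).
* Round-off negatives after polishing (> −1e−8) are clipped to zero;
  anything more negative is rejected as non-converged.
* Nullcline intersections merged below 0.5% relative distance; the
  clustering ε guard is 1e−6 molecules.
* SSA random numbers come from a seeded Mersenne-Twister stream; exponential
  waiting times use `−log(1−u)` so u = 0 is safe.

## What the generator emulates — and what it does not

The stochastic simulator *is* the data source for every distributional
claim: there is no external dataset. It reproduces intrinsic reaction noise
(shared-transcript correlation of toxin and antitoxin, rare threshold
crossings of R) under constant conditions. It does not model cell growth,
division or dilution, extrinsic noise, the duration of the growth-arrest
state once a cell crosses the threshold (the kinetics are only valid for
normally growing cells), population dynamics, or interactions with other
toxin–antitoxin loci. Passing tests therefore certify the circuit-level
stochastic mechanism, not organism-level persister frequencies.

## Known limitations

* The reduced model assumes a unique nonnegative fast-state solution at
  every (A, AB2A); this holds on the scanned ranges (the implied-dimer map
  is monotone) but is not proven globally.
* Monostability is Monte-Carlo evidence, not a bifurcation-theoretic proof.
* Grid-cell sign-change seeding can in principle miss tangential nullcline
  intersections; the grid-doubling invariance check mitigates this.
* The uncoupled comparison doubles the total promoter count by
  construction; mean shifts partly reflect that intrinsic asymmetry.
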