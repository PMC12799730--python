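# Methods

## Model

The system contains two tRNA species with totals `T1_tot` (preferred) and
`T2_tot` (non-preferred), a ribosome pool `R_tot`, and `N` identical
transcripts of `L` codons of which a fraction `f_op` are optimal (read by
the preferred tRNA). Seven counts evolve — charged and uncharged tRNAs of
each species, free ribosomes, and ribosomes on optimal / non-optimal
codons — under mass action:

- charging converts uncharged to charged tRNA at `k_charge·T_ui`;
- elongation from codon class *i* proceeds at `k_speed·R_bi·T_ci` and
  converts one charged tRNA to uncharged;
- initiation occupies a binding site at `k_bind_eff·N·R_f`;
- every elongation event moves the ribosome: with probability `1/L` it
  terminates (one protein, ribosome freed), otherwise it re-lands on an
  optimal codon with probability `f_op`. Newly initiated ribosomes land
  optimally with the same probability.

This is the *mean-field* picture: only how many ribosomes sit on each
codon class is tracked, not where. Three conservation laws hold exactly:
`T_ci + T_ui = Ti_tot` and `R_f + R_b1 + R_b2 = R_tot`. The protein
expression rate is the termination flux
`P_r = k_speed·(R_b1·T_c1 + R_b2·T_c2)/L`.

A note on the bound-ribosome balance: writing the codon-class exchange as
a bare conversion flux (`R_b2·T_c2·f_op` against `R_b1·T_c1·(1−f_op)`)
without the initiation/termination and `k_speed` factors is not a
consistent mass-action network — those class derivatives would sum to
zero while the free-ribosome equation does not. The network above is the
consistent completion; its fixed point satisfies exactly the familiar
stationarity balances (binding = termination, charging = consumption per
species, and the class-exchange balance
`R_b1·T_c1·(1−f_op) = R_b2·T_c2·f_op`), so every steady-state result is
independent of this modeling choice; only transients and fluctuations see
the full network.

## Steady-state solver

At stationarity the class elongation fluxes split as `f_op·E` and
`(1−f_op)·E` where `E` is the total elongation flux, which forces

    T_ui = (class flux)/k_charge,   R_f = E/(L·k_bind_eff·N),
    R_bi = (class flux)/(k_speed·T_ci),

leaving the single equation `R_f(E) + R_b1(E) + R_b2(E) = R_tot`. The
left side is strictly increasing on `(0, E_max)` — `E_max` being the flux
that would fully drain the busier charged pool — and runs from 0 to +∞,
so the unique physical root is bracketed a priori and found by Brent's
method at machine precision. No starting point, damping, or fallback
ladder is needed; residuals of all four balances are verified `< 1e-10`
relative (configurable) and a violation raises with the residual vector.
At `f_op` exactly 0 or 1 the unused class idles fully charged and the
remaining two balances reduce to a quadratic with one positive root,
solved in closed form; the flux equation remains valid there and serves
as an independent numerical cross-check in the tests.

Two limits are exposed analytically: the one-codon closed form above, and
the infinite-charging limit (`T_ci = Ti_tot`), where the per-ribosome
speed is the `f_op`-weighted harmonic mean of `k_speed·T1_tot` and
`k_speed·T2_tot` and `E` follows linearly from the binding/termination
balance.

## Units and calibration

`k_speed` multiplies `R_b·T_c`, so despite its conventional "codons/s"
label it is a second-order constant (per charged tRNA per bound ribosome
per second); the biologically meaningful translation speed is
`k_speed·T_c` codons/s. Likewise the model consumes an effective binding
constant `k_bind_eff` (per free ribosome per site per second);
`molar_to_effective_bind` converts a laboratory `M⁻¹s⁻¹` constant for a
chosen cell volume (2.5×10⁶ M⁻¹s⁻¹ at ~8×10⁻¹⁶ L gives ≈5.2×10⁻³, close
to the calibrated value below).

`calibrate()` inverts target steady-state fractions exactly: a total
charged fraction `c` fixes both charged pools (total uncharged
`(1−c)(T1_tot+T2_tot)` splits across classes as `f_op : 1−f_op`), the
active-ribosome target `a` is then linear in `E`, and the two rate
constants follow from the charging and binding balances. Infeasible
targets (a pool driven negative, or `a = 1`, which would require infinite
binding against a positive termination flux) raise with the achievable
range. Calibrating the symmetric reference set (1250/1250 tRNAs, 500
ribosomes, 100×300 codons, `k_speed = 0.02`) to 88 % charged / 88 %
active gives

    k_charge  = 484/15    ≈ 32.2667 s⁻¹
    k_bind_eff = 121/22500 ≈ 5.3778e-3 s⁻¹,

which the packaged parameter sets store at full precision. These imply a
per-ribosome speed of exactly 22.0 codons/s (`0.02·1100`) and a ribosome
density of 0.489 per 100 nt. Published tabulations of comparable models
quote 21 codons/s; the difference traces to an unstated measurement
definition (e.g. averaging over stochastic runs or over all ribosomes
including free ones), and we report the well-defined 22.0 rather than
forcing agreement.

The reference charging range explored in sweeps is 3–300 s⁻¹ (the
calibrated value is its geometric midpoint); the charging-*limited*
regime, where the expression optimum pins to the preferred-tRNA fraction,
lies below that range (`f_op_max` for a 70:30 pool is 0.757 at
`k_charge = 3` and reaches 0.70 only near `k_charge ≈ 0.03`).

## Stochastic simulators

Both SSA cores use the direct method with one uniform pair per event
(waiting time + elementary channel; secondary choices reuse the channel
draw's fractional remainder), so trajectories are bit-identical given
`(params, config, seed)`; replicate *i* uses `seed + i`. Counts are
64-bit integers and the three conservation laws hold exactly at every
event. If the total propensity reaches zero the run halts cleanly and
remaining records repeat the frozen state.

The **mean-field SSA** expands the network into ten elementary channels
(2 charging, 2 initiation landings, and per class
termination / re-land-optimal / re-land-non-optimal). Termination with
probability `1/L` per elongation event is the geometric transcript-length
approximation implied by the mean-field off-rate.

The **codon-resolved SSA** assigns every transcript an explicit codon
sequence (from `generate_transcript`, Bernoulli or exact-count placement)
and tracks each ribosome's position; elongation propensity is
`k_speed·T_c(class at the ribosome's codon)` and termination is
positional (stepping past codon `L−1`). This relaxes the mean-field
assumption that only composition matters. Optional exclusion enforces a
minimum anchor spacing (`footprint` codons, default 0 = off) *exactly*:
propensities count only unblocked ribosomes and transcripts with clear
initiation regions, maintained incrementally (swap-remove membership
arrays, per-transcript occupancy grid), not by rejection thinning.
Without exclusion, arrangement of codons along a transcript provably does
not affect stationary means (each ribosome's transit time is a sum of the
same per-codon exponentials in any order), which the tests exploit.

Stationary estimates average records after a burn-in (default half the
run; records are uniform in time so the plain mean is the time-weighted
mean) and report standard errors across replicates; protein production
rate is the protein increment over the window divided by its duration.

## Sweeps and the expression maximum

`sweep_fop` solves one steady state per grid point (default step 0.01
across [0, 1]); per-point failures are recorded, not fatal.
`find_fop_max` scans the coarse grid (step ≤ 0.05, ties toward smaller
`f_op`) and refines the bracketing interval by golden section to
`refine_tol` (default 1e-3). When the relative P_r range over the grid is
below 1e-9 — symmetric pools with effectively instantaneous charging —
the argmax is numerically meaningless and the result is flagged `flat`
with `f_op_max = NaN` instead of an arbitrary point. Note that at
symmetric pools the curve is only *asymptotically* flat: the relative
range is ≈1.2 % at `k_charge = 300` and ≈4×10⁻⁶ at 10⁶; the flag
therefore triggers only at extreme charging rates, while at moderate ones
the genuine (tiny-amplitude) maximum at 0.5 is reported.

`sweep_kcharge_fopmax` tabulates `f_op_max` over a log-spaced charging
grid (default 20 points in [3, 300]) per tRNA fraction and raises if a
curve is non-monotone beyond tolerance (a solver-defect canary).
`scaling_check` verifies the tRNA scaling law (`Ti_tot → α·Ti_tot`,
`k_charge, k_speed → /α` leaves P_r invariant — α cancels identically in
the stationarity balances) and reports the maximum relative deviation,
which sits at solver precision (<1e-8 asserted, ~1e-15 observed).
`effective_fop` reduces a mixed transcript population to its codon-mass
weighted fraction Σ(copies·L·f)/Σ(copies·L); the codon-resolved SSA test
quantifies, rather than assumes, that a mixed system matches a single
solve at this effective fraction (equal lengths; widely differing lengths
are untested territory).

## Phage fitness conversion

`growth_rate(p)` solves `r = kC·(b·e^(−τ·r) − 1)` with burst size
`b = p/virion_size` (defaults: lysis time τ = 12 min, 400 capsid proteins
per virion, `kC` = 1/min). The residual is strictly decreasing in `r`
with guaranteed sign change on `[−kC, max(0, kC·(b−1)) + ε]` (expanded
geometrically if rounding ever defeats the argument), so Brent's method
returns the unique root; the residual at the root is below 1e-12 across
the tested range. `doublings_per_hour` is the linear map `60·r/ln 2`;
`relative_fitness` normalizes to a named reference condition. The lysis
time shares a conventional symbol with the transcript length; the two
live in separate parameter types. Only `kC = 1` is anchored to published
usage; other values are supported but unvalidated.

## What the tests do and do not show

The stochastic cross-validation (10 replicates × 5000 s at the reference
parameterization; smaller 4 × 400–600 s runs for the codon-resolved and
scaling corroborations) checks 3-standard-error agreement between SSA
time averages and the numeric steady state — it validates the solver and
simulators against *each other* and the model's internal limits, not
against any organism. The two-codon abstraction ignores the 61-codon
code, wobble pairing, amino-acid identity, ribosome drop-off, mRNA
turnover and transcription; transcripts are homogeneous within a class;
exclusion is off by default to match the mean-field equations. Passing
tests therefore demonstrate correctness of the mathematics and its
implementation under these assumptions, not predictive accuracy for real
cells.

Problem sizes in the test-suite and acceptance runs (grid steps, replica
counts, run lengths) are the package's defaults chosen to put Monte-Carlo
error well below the effect sizes being checked.

## Numerical choices

- Steady-state residual tolerance 1e-10 relative (configurable); Brent
  tolerances at float precision.
- Time courses: LSODA with rtol 1e-10 / atol 1e-9; conservation to 1e-8
  relative asserted along trajectories; integration failure raises with
  the last good time.
- Degenerate inputs: `f_op` exactly 0/1 dispatch to the closed form;
  a zero tRNA pool on one side requires the matching boundary `f_op`
  (validation error otherwise); empty transcript-class sets, non-integer
  SSA initial counts, and inconsistent initial states are rejected.
- Tie-breaks: grid argmax ties resolve toward smaller `f_op`; golden
  section returns the bracket midpoint at convergence.
- Seeds: replicate seeds are `base + index` and must fit in [0, 2³¹).
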