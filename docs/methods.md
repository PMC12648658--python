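# Methods

This note records the models implemented in `solvkit`, their
assumptions, the defaults that matter, and the design choices made where
the conventions in the literature genuinely diverge.

## Units

Energies kcal/mol, lengths Å, times fs, temperatures K, masses amu.
`solvkit.units.KB_KCAL_MOL_K = 0.0019872041` is the single source of
truth for the Boltzmann constant; thermal constants in other unit
systems (kJ/mol for the metadynamics module, SI for the hydrodynamic
finite-size correction, amu Å² fs⁻² for kinetic energies) are derived
from it or from CODATA values via `scipy.constants` at import time.
Energy tables and datasets declare their unit (`hartree`, `eV`,
`kJ/mol`, `kcal/mol`) and are converted on load
(1 Hartree = 627.5094740631 kcal/mol).

## Dispersion energy

Two-body D3(0)-style correction with zero damping.  Per atom pair:

* coordination numbers from the standard counting function
  CN_A = Σ_B 1/(1 + exp(−k₁(k₂(R_cov,A + R_cov,B)/r − 1))), k₁ = 16,
  k₂ = 4/3, summed over lattice images within `cn_cutoff` (default
  20 Å) when periodic;
* C₆(CN_A, CN_B) by Gaussian-weighted interpolation over tabulated
  reference points, L = exp(−k₃[(ΔCN_A)² + (ΔCN_B)²]), k₃ = 4, with the
  largest exponent subtracted before exponentiation for stability;
* C₈ = 3 C₆ √Q_A √Q_B, with √Q in Å² after table-load conversion;
* damping f_n(r) = 1/(1 + 6(r/(sr_n R₀))^(−α_n)), α₆ = 14, α₈ = 16,
  sr₈ = 1; the pair sum runs over all lattice images within `cutoff`
  (default 50 Å) with a ½ factor for double counting.

Per-element-pair s₈ overrides take precedence over the global s₈; this
is how a single ion–water channel is tuned while the solvent–solvent
parametrization stays fixed.  Three-body (Axilrod–Teller) dispersion,
Becke–Johnson damping, charge-dependent C₆ scaling and analytic forces
are out of scope; the two-body zero-damping form is the common
operating default this package targets.

**Convergence of the lattice sum.**  The tail beyond a cutoff R is
≈ (2π/3) ρ C₆,eff / R³ per molecule.  At liquid-water density and C₆ of
physical magnitude this is ~10⁻³ kcal/mol per molecule between 30 and
50 Å cutoffs, decaying cubically; the default 50 Å keeps the truncation
well below fitting noise but not below 10⁻⁴ kcal/mol.  The test suite
asserts the cubic decay rather than an absolute figure, since the
absolute tail scales with the table's C₆.

**Element tables.**  `data/d3_minimal.yaml` ships rounded, D3-style
magnitudes for H/O/Mg/Cl for CLI convenience; it is illustrative data,
and every quantitative test instead uses the deterministic synthetic
table from `synth.toy_element_table()`, whose C₆/C₈ magnitudes are
chosen so the C₈ channel is clearly identifiable in a cluster's
interaction energy.

## Fitting with one-body exclusion

The model interaction energy of a record is
(E_base,total + E_disp,total) − Σ_f (E_base,f + E_disp,f) at frozen
geometry.  The deviation subtracts the reference interaction energy
after removing the record's one-body correction — the externally
computed monomer-deformation energy (e.g. from a spectroscopic monomer
potential).  The correction is an input, never computed here; it
defaults to zero, and planting one in the synthetic generator leaves
deviations exactly unchanged (verified by test).

The objective is MAE per molecule: each record's |deviation| divided by
its own molecule count, then averaged.  (An alternative reading —
dividing the dataset MAE by a common molecule count — coincides when
all records share one size; the per-record reading is what the report
normalization flag records.)  RMSE/mol is reported alongside for
diagnostics only.

Optimization is a coarse grid scan (41 points per axis by default, ties
broken toward smaller parameter values for determinism) followed by
Nelder–Mead refinement from the grid optimum; MAE is piecewise-linear
so gradient methods are avoided.  The full evaluation trace is kept in
the report, and the solution is asserted to be no worse than any grid
point.  If the objective varies by ≤ 10⁻¹² along a free parameter's
grid axis through the optimum, the fit is degenerate and aborts naming
the parameter.

Two modes: `engine` evaluates dispersion from geometry; `components`
uses precomputed (E₆, E₈) unit sums per record (total and fragments)
and needs no geometry.  When all free parameters are linear (s₆, s₈,
per-pair s₈) the engine precomputes its pair-class unit sums once per
record, making the modes numerically identical (asserted to 10⁻⁸
kcal/mol).  sr₆ enters the damping nonlinearly: it is fit only in
engine mode, and requesting it in components mode warns and holds it
fixed.

## Trajectory observables

**RDF.**  Minimum-image pair histogram normalized per frame by the
ideal-gas expectation n_b·V_shell/V with exact spherical-shell volumes
(not 4πr²Δr, which carries an O(Δr²) bias); self-pairs excluded for
identical species; r_max capped at half the smallest box width.  The
implementation reproduces MDAnalysis `InterRDF` to 10⁻¹⁰ on a shared
fixture (independent-oracle test).

**Diffusion.**  Coordinates are unwrapped by accumulating minimum-image
frame-to-frame displacements (valid while per-step motion stays below
half the box).  MSD(t) is averaged over all time origins and atoms with
the FFT decomposition (O(T log T)), verified against the brute-force
origin average.  D_L = slope/6 by least squares over a window that
excludes 10% head and 10% tail by default (configurable in fs) to stay
in the diffusive regime; a log-log MSD slope farther than 0.3 from 1
flags the estimate as non-diffusive (a ballistic fixture shows slope 2
and is flagged).  The Yeh–Hummer correction
D_∞ = D_L + k_B T ξ/(6π η L) uses ξ = 2.837297, valid for cubic boxes
only; non-cubic boxes must be corrected by other means and are
rejected.  Viscosity is an input, never computed.

**VACF and vDOS.**  C_vv(t) = (1/N) Σ_i ⟨v_i(0)·v_i(t)⟩ over all time
origins (FFT).  The vDOS is the trapezoid-rule cosine transform of
C_vv(t)·sin²(πt/T_max) — the Hann window spanning the full record —
multiplied, when requested, by the harmonic quantum factor
Q(ω) = x/(1 − e^(−x)), x = ħω/k_BT, which tends to 1 at low frequency
and equals 1/(1 − e⁻¹) ≈ 1.5820 at ħω = k_BT.  The frequency grid runs
from 0 to Nyquist in 1 cm⁻¹ steps by default.  Because the prose
normalization conventions vary, the spectrum is returned both raw and
normalized to unit integral over the grid.

**H-bond angles.**  For each covalent O–H bond (O–H < 1.2 Å) and each
acceptor oxygen with O···O below the 3.5 Å cutoff, the angle between
O_d→H and O_d→O_a is histogrammed in degrees; the reported peak is the
vertex of a parabola through the maximal bin and its neighbors.  This
donor-side definition with a 3.5 Å O–O cutoff is the common convention
of the experimental H-bond-angle literature; other definitions (H···O
distance criteria, acceptor-side angles) would shift the distribution
and are intentionally not mixed in.

**Tetrahedral order.**  The Errington–Debenedetti form
q = 1 − (3/8) Σ_{j<k} (cos ψ_jk + 1/3)² over the four nearest oxygen
neighbors (minimum image): q = 1 for a perfect tetrahedron, −3 for four
parallel bonds, and ⟨q⟩ = 0 for uncorrelated positions — all three
asserted.

**Coordination CV.**  s = Σ_i f(r_i) with f(r) = 1/(1+e^{a(r−r₀)}),
defaults r₀ = 3.0 Å (a typical first minimum of an ion–oxygen RDF for
Mg²⁺) and a = 4.0 Å⁻¹.  Two orientations of this Fermi switch circulate
in the literature: counting waters *inside* the shell (s ≈ 6 at the
six-fold minimum) and the complementary outside-counting bracket
Σ[1 − f].  The inside-counting form is the default because coordination
free-energy surfaces are conventionally plotted against the inside
count; the literal outside-counting form is available via
`literal=True` / `--outside-counting` for reproduction purposes.  The CV is
monotone non-increasing in every distance and bounded in [0, N]
(property-tested).

**Thermodynamics.**  ΔH_fus = (⟨U_l⟩−⟨U_s⟩) + PV and
ΔH_vap = (⟨U_g⟩−⟨U_l⟩) + RT with RT = k_B T per mole computed from T
when not supplied.  c_p = dH/dT and α_P = −(1/ρ) dρ/dT by central
differences (second-order one-sided at the ends) on a uniform T grid,
with optional quadratic Savitzky–Golay pre-smoothing; both reproduce
polynomial closed forms to 10⁻¹⁰ and locate the α_P sign change at a
planted density maximum within one grid step.

**Bootstrap.**  Percentile bootstrap over replicas/blocks with
replacement, 2.5/97.5 percentiles, seed-deterministic; a coverage
simulation (400 Gaussian repeats) confirms ≈95% interval coverage.

## Well-tempered metadynamics (toy driver)

Overdamped Langevin dynamics (Euler–Maruyama, default dt = 10⁻⁴ CV
units²-compatible, mobility 1) on analytic 1-D potentials, with
Gaussian hills of width σ deposited every `stride` steps at height
w₀·exp(−V_bias/k_BΔT), ΔT = (γ−1)T, γ > 1 enforced.  The accumulated
bias and its gradient live on a fine grid (linear interpolation) so the
cost per step is independent of hill count; the exact hill list is the
returned BiasHistory.  Reflecting walls at the grid edge keep the
walker in range.  The FES estimate is F(s) = −γ/(γ−1)·V_bias(s),
shifted to min 0; minima are interior grid minima, the barrier is
F(saddle) − F(global minimum) between the two deepest minima, and the
mechanism side (lower/higher s intermediate) is readable from the
minima list.  Driving a real ion–water potential is out of scope; the
FES/barrier/rate machinery equally accepts externally produced bias or
FES tables (delimited-text import/export).

Recovery conditions used by the tests and the acceptance script,
chosen once: quartic double well V = 30·((s)²−1)² kJ/mol, T = 300 K,
γ = 15, w₀ = 1.2 kJ/mol, σ = 0.15, stride 250, 6×10⁵ steps.  The mean
recovered barrier over 5 seeds sits within a few percent of 30 kJ/mol
with a spread of roughly ±1.5 kJ/mol; the small positive bias is the
usual finite-hill-width broadening of the WT estimator.

Rate scaling: k_X = k_ref·exp[(ΔA‡_ref − ΔA‡_X)/(k_B T)], temperature
defaulting to 300 K (ambient).  This transfers a reference model's
absolute rate through barrier differences only — prefactors are assumed
equal — which is exactly what it is: an exponential scaling, not
transition-state theory.

## Synthetic data: what it does and does not emulate

All generators are bit-deterministic under (parameters, seed) and emit
a truth/metadata sidecar.

* **Fit datasets** place a Mg-like ion at the origin with rigid
  gas-phase-geometry waters (0.9572 Å, 104.52°) at shell radii
  1.95–2.45 Å (minimum inter-fragment distance 1.5 Å, 10⁴ packing
  attempts before erroring).  The "base" (dispersion-free) energies come
  from a smooth Born–Mayer repulsion A·e^(−r/ρ) (A = 2000 kcal/mol,
  ρ = 0.35 Å) so the dispersion part of the reference is exactly
  identifiable; the reference interaction energy is base + planted
  dispersion + optional Gaussian noise.  These clusters are chemically
  shaped, not chemically accurate: passing recovery tests shows the
  fitting machinery is correct, not that any real reference set is
  reproduced.
* **Langevin fixture**: free particles propagated with the exact
  Gaussian (Ornstein–Uhlenbeck) propagator, so D = k_B T/(m γ) holds
  with no discretization error; defaults 400 particles, γ = 0.02 fs⁻¹,
  m = 18 amu, 4000 × 1 fs steps, MSD fit window 200–1200 fs (beyond
  three velocity-correlation times, before origin statistics degrade).
  Real liquids add caging and hydrodynamic memory the fixture lacks.
* **Harmonic fixture**: analytically integrated oscillators with
  thermal initial conditions; the velocity spectrum is a line at the
  set wavenumber, resolvable only if the run covers ≥ 20 periods.
* **LJ fluid**: a small velocity-Verlet Lennard-Jones liquid with
  velocity-rescaling thermostatting — a structured-fluid smoke fixture
  (first-shell peak, flat tail) with no planted truth.
* **Ideal gas / water box**: uniform uncorrelated positions (flat RDF,
  ⟨q⟩ = 0) and randomly packed rigid waters (O–O ≥ 2.5 Å) for geometry
  and normalization tests.

## Numerical choices and degenerate inputs

Grid-scan ties break toward smaller parameter values; the MSD window
must retain ≥ 10 samples; RDF requires a periodic cell and caps r_max
at half the box; vacf/vdos reject missing velocities and non-uniform
time grids; zero interatomic distance, singular periodic cells, unknown
element symbols, non-partition fragment maps and missing reference
energies all raise typed errors naming the offender.  Bootstrap
requires ≥ 100 resamples.  All RNG flows through
`numpy.random.default_rng(seed)`.

## Known limitations

No analytic forces or stress; no three-body dispersion; no
charge-dependent (EEQ) C₆; binary trajectory formats are not read; the
metadynamics driver is 1-D, single-walker, toy-scale; viscosity for the
finite-size correction is an input; IR intensities are not computed
(the vDOS is a mass-weighted velocity spectrum, not a dipole spectrum).
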