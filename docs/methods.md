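# Methods

## Model

One bead per amino-acid residue, placed at the residue center of mass
and carrying the average residue mass.  The potential is the sum of
harmonic stretch, bend and torsion terms along the backbone plus a
truncated 12-6 Lennard-Jones term between non-bonded beads and a
constant offset `U_o`:

    E_total = E_b + E_a + E_d + E_vdW + U_o
    E_b = K_b (r - r_o)^2,  E_a = K_a (theta - theta_o)^2,
    E_d = K_d (phi - phi_o)^2,  E_vdW = 4 eps [(sigma/r)^12 - (sigma/r)^6]

Assumptions worth making explicit:

- **Position-specific bonded types.**  Each bond/angle/dihedral of the
  template chain is its own type (keys `"9-10"`, `"2-3-4"`, ...),
  shared across replicated chains.  This mirrors a calibration whose
  reference energies include sequence context, so chemically identical
  pairs (G-Y vs Y-G) may carry different parameters.
- **Species-wise non-bonded terms.**  LJ parameters are per amino-acid
  species; cross terms use the geometric mean of *both* `eps` and
  `sigma`.  Whether `sigma` should mix geometrically or arithmetically
  is genuinely open; geometric is the default and the
  Lorentz-Berthelot alternative is available via
  `mix_pair(..., rule="lorentz")`.
- **No electrostatics.**  Charge effects enter only through the
  reference energies used in calibration.
- **Exclusions.**  1-2 pairs are always excluded from the LJ sum.
  1-3 is excluded and 1-4 included by default: the bending calibration
  drops non-bonded contributions entirely, while the torsion
  calibration excludes only non-adjacent pairs.  Both flags are
  configurable (`ExclusionPolicy`), and setting `eps = 0` is verified
  to be equivalent to excluding a pair.
- **Harmonic convention.**  The bonded forms carry no 1/2 prefactor,
  so the curvature of each term at its minimum is `2K`.  Fitted
  stiffnesses follow the same convention (a harmonic fit of a Morse
  scan with `D = 100`, `a = 1` converges to `K = D a^2 = 100`,
  i.e. curvature `2K = 2 D a^2`).
- **Dihedral continuity.**  The deviation `phi - phi_o` is wrapped
  onto (-180, 180] before squaring; without wrapping the quadratic
  form is discontinuous at the branch cut.

### Units

kcal/mol, A, u, fs (LAMMPS "real"-style).  Angles are degrees in files
and APIs, radians inside stiffnesses (`K_a`, `K_d` are kcal/mol/rad^2).
Stress converts to GPa (1 kcal mol^-1 A^-3 = 6.9477 GPa), pressure
targets are atm, densities g/cm^3.

### Periodic evaluation

All systems are orthorhombic and periodic.  The pair list is a Verlet
list over a KD-tree with a 2 A skin, rebuilt when any displacement
exceeds half the skin.  Box edges shorter than twice the listing
radius are common here — the 4x4 bundle is ~19 x 22 A across with a
12 A cutoff — so each pair entry carries an integer image shift and
short axes have their periodic images enumerated explicitly (beads
interact with several images of a neighbour, and with their own
images, exactly as an engine with ghost atoms would).  The
implementation is validated against a brute-force all-images sum.

The virial stress is accumulated per interaction as W = sum r (x) F
with positions taken relative to one site of the interaction, which is
exact for the multi-body angle and torsion terms; the tensile-positive
stress is -(W + kinetic)/V.  It is verified against (1/V) dE/d(strain)
by central differences to better than 1e-4 relative, and against the
closed form for a single stretched bond exactly.

### LJ truncation

Plain cut at 12 A, no shift, no tail correction, by default.  The
energy-shifted variant (`shift_lj = True`) subtracts the cutoff energy
per pair; forces are identical, but the continuous energy surface lets
gradient-based minimizers converge to much tighter force tolerances.
Protocols that need tightly converged minima (e.g. 0.005%-increment
verification stretches) should enable it.

## Calibration

Each bonded term is calibrated from an energy scan of a minimal
cluster: separations for bonds (residue j displaced along the i-j
line), in-plane rotations for bends (the j-k distance is preserved
exactly and asserted to 1e-10), rotations about the j-k axis for
torsions (the center of rotation is l's projection onto the axis, so
every other internal coordinate of the quadruple is preserved and the
energy variation is purely torsional).  The energy comes from an
oracle callback — the boundary behind which an all-atom engine or scan
files live; synthetic oracles stand in for them offline.

Fitting choices:

- **Window.**  Samples within k_B * 300 K (~0.6 kcal/mol) of the scan
  minimum, at least 5 points, expandable; "the vicinity of the
  minimum" has no canonical width, and a thermal window is the natural
  scale at ambient conditions.
- **Free equilibrium.**  The harmonic fit `c + K (x - x_0)^2` treats
  `x_0` as a free parameter rather than pinning it to the minimum
  sample, so coarse grids do not quantize equilibria.  A fit whose
  `x_0` escapes the window, or whose curvature is non-positive, is an
  error; a scan whose minimum sits on the boundary asks for a wider
  range instead of extrapolating.
- **LJ fits** use `U_0 + 4 eps [(sigma/r)^12 - (sigma/r)^6]` with
  initial guesses `sigma = r_min / 2^(1/6)`, `eps = well depth`, over
  the lower half of the well (widened when too few samples); the far
  tail is deliberately excluded so that slowly-varying background
  contributions do not bias the well parameters.
- **Scenario averaging.**  Non-bonded calibration runs three
  scenarios — rotate residue J to its minimum-energy orientation about
  X, Y or Z, then scan the separation — and averages the fitted
  (eps, sigma) arithmetically.  Whether the average should be
  arithmetic is not canonical; arithmetic is assumed.  Orientation
  argmin ties break toward the smallest angle.
- **Scan steps** default to 0.02 A (separations) and 1 degree
  (angles); orientation grids use 5-degree steps.

The core consistency property is the round trip: scans generated from
a known force field (the `CGOracle`, whose reference geometry is the
exact internal-coordinate minimum built by NeRF) refit every one of
the 59 + 58 + 57 bonded terms and 7 pair species of the MaSp1
construct to ~1e-11 relative error.

## Simulation

- **Minimization** at fixed box: L-BFGS (scipy) with analytic
  gradients, or FIRE, selected by flag; the contract is max per-bead
  force component <= `force_tol` (default 1e-4 kcal/mol/A) or a
  flagged iteration cap.  Note the unshifted LJ cutoff bounds the
  reachable tolerance on dense systems (see above).
- **Dynamics**: velocity Verlet with two-level force splitting —
  bonded forces on an inner 0.2 fs substep (5 per 1 fs outer step),
  LJ forces on the outer step — because the calibrated bending and
  torsion terms are stiff.  A stochastic velocity-rescaling thermostat
  and a Berendsen-style anisotropic barostat (lateral axes only in
  `NPT-lateral`) control temperature and pressure.  These differ from
  a Nose-Hoover chain in their fluctuation spectra but not in the
  time-averaged temperature/pressure on which every contract here is
  stated; static-stretch results do not depend on the thermostat.
- **Annealing** runs a staged schedule (heat soak, linear cool,
  ambient pressure-coupled equilibration), with every span scalable;
  stationarity is diagnosed from the trailing-window mean and standard
  deviation of density and box lengths.
- **Stretching** is quasi-static: per increment the loading-axis box
  length is multiplied by (1 + delta), coordinates are scaled
  affinely, and the system relaxes either by minimization at fixed
  lateral box (`static_minimize`) or by thermostatted NPT-lateral
  dynamics followed by minimization (`equilibrate_then_minimize`).
  Two presets ship: 0.005% increments static, and 0.05% increments
  with 200 ps equilibration.  Strain is reported both as true strain
  n ln(1 + delta) (increments are multiplicative on the current
  length) and engineering strain; stress is the static virial of the
  post-relaxation configuration — per-increment stress could equally
  be time-averaged, and the choice matters only at noise level.

## Mechanics extraction

- **Elastic window**: longest initial window with linear-fit
  R^2 >= 0.995 (falling back, flagged, to the full range when no
  window qualifies — a flat noisy curve then reports a near-zero
  modulus rather than an error).
- **Yield**: 0.2%-offset construction against the fitted elastic line
  by default (offset 0 gives the departure point); absence of a
  crossing reports "no yield" rather than a guess.
- **Failure**: global stress maximum, accepted only when a later
  sample drops by >= 20% of the peak or the curve was truncated by a
  non-finite energy.
- **Toughness**: trapezoidal integral of stress over true strain up to
  failure, converted to MJ/m^3 (x1000 from GPa).  Integrals of
  noise-level curves can come out marginally negative; the summary
  clamps those to zero and records the raw value.
- **Orientation fraction**: per rigid copy, the principal axis is the
  leading singular vector of the centered coordinates; the angle to
  the loading axis is folded onto [0, 90] degrees and compared to a
  10-degree tolerance by default.

## Synthetic data

The synthetic layer exists so that every stage is testable offline:

- `OraclePotential` families (harmonic, Morse, LJ, angularly-modulated
  LJ, cosine orientation profiles) with seeded Gaussian noise generate
  scans with known ground truth.
- `default_forcefield` is a complete, deterministic parameter set with
  plausible magnitudes for a residue-bead silk model: bond stiffnesses
  100-300 kcal/mol/A^2 around 3.7-3.9 A, bending terms ~18-30
  kcal/mol/rad^2 at 145-160 degrees with the poly-alanine block pinned
  at 162 degrees and the G-Y-G / G-L-G triples at >= 3x the median
  stiffness, torsions 4-8 kcal/mol/rad^2, and species-wise LJ wells
  growing with residue bulk.  These are placeholders, NOT calibrated
  reference values; real parameter tables are transcribed into the
  same YAML schema.
- `make_test_assembly` builds the study systems: single chain, 4x4
  anti-parallel bundle (16 chains, 960 beads), its 3x2x3 ordered
  tiling (17,280 beads), and 20-copy random/semi-ordered packs in the
  126.5^3 A^3 and 98.5 x 98.5 x 197 A^3 boxes.  The semi-ordered pack
  places 13 of 20 copies aligned with Z by construction.

What the synthetic systems do *not* emulate: chains start extended
(with a small golden-angle helical offset, amplitude 0.4 A, so that no
bending/torsion triple is collinear — torsion gradients genuinely
diverge at collinearity); real pre-equilibration geometry is unknown
and is the job of annealing.  The packing fixtures use a geometrically
compacted bundle surrogate (1.7 A bond spacing, 3.2/2.8 A lateral
spacings) so a rigid copy fits the packing boxes; rejection sampling
cannot reach the near-space-filling densities an optimizing packer
achieves, so copy counts, box dimensions and orientation statistics
are faithful while the packing density is not.  Passing tests
therefore demonstrate the correctness of the machinery — calibration,
evaluation, protocols, extraction — not the mechanical realism of the
placeholder parameters.

A lattice variant with `spanning_bonds=True` bonds each chain to its
own periodic image along Z (type key `"60-1"` for the 60-mer),
modelling an infinitely continued fiber.  It provides a coherent
elastic backbone for verification stretches: a bundle of *finite*
extended chains has almost no longitudinal stiffness before annealing
(free ends simply relax), so elastic-segment checks use the continuous
variant.

## Problem sizes and tolerances used in the shipped checks

The test-suite and acceptance-script runs use desk-scale spans chosen
as the smallest sizes that still exercise each property: full 60-residue
calibration round-trips (181 terms); 20 random 50-bead systems for
gradient checks (<= 1e-6 relative); anneal schedules of 0.6-1.2 ps per
stage on the 960-bead bundle with trailing density stationarity at
< 2% relative standard deviation; 50-increment 0.05% stretches; and
10-increment 0.005% verification stretches on a 4-chain continuous
fiber.  Production-scale spans (tens of ns, 17k beads) use the same
code paths with larger numbers.

## Known limitations

- Berendsen-style pressure coupling does not sample a true isobaric
  ensemble; it is adequate for relaxation and time-averaged targets.
- No bond breaking: failure is read off the stress curve, not from
  topology changes.
- The minimizer cannot certify global minima; stretch protocols track
  the local basin, which is the intended quasi-static behaviour.
- Mixed-periodicity boxes fall back to an O(N^2) pair search.
- Random packing is rejection sampling; dense packings need an
  external packer, whose output can be imported via the LAMMPS data
  reader.
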