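# Methods

## Hydrogen-bond geometry densitometry

**Definitions.** For a donor–acceptor pair, d is the heavy-atom
(oxygen–oxygen or oxygen–protein-heavy-atom) distance and θ is the angle at
the donor hydrogen formed by donor heavy atom, hydrogen, and acceptor heavy
atom; cos θ = −1 is a perfectly linear bond.  The hydrogen used is the donor
hydrogen closer to the acceptor (in all physically relevant geometries this
is the bonding hydrogen).  No angular filter is applied anywhere: every
ordered (donor, acceptor) pair within the 3.5 Å cutoff contributes exactly
one sample, so the "hydrogen bond" populations are really neighbor
configurations, including bent and non-bonded ones.

**Populations.** The first solvation shell is defined by water oxygens
within 3.5 Å (inclusive) of at least one protein carbon or oxygen atom;
nitrogen atoms do not define the shell but do accept bonds.  Bulk waters
are farther than 10 Å (exclusive) from all protein C/O.  The populations
are: WW1 (water donors to shell water-oxygen acceptors), WP1 (water donors
to protein O/N acceptors within the cutoff), WC1 (the WP1 subset whose
acceptor is an Asp/Glu carboxylate oxygen), SHELL_ALL = WW1 ∪ WP1,
WW1_WC1 = WW1 ∪ WC1 (the composite some density figures use), and BULK
(water donors to bulk water-oxygen acceptors).  Ions are neither donors
nor acceptors.

**Histogram grid.** d ∈ [2.3, 3.5] Å and cos θ ∈ [−1, 0], both with
0.025-wide bins (48 × 40).  The grid is configurable; samples outside it
(e.g. cos θ > 0 neighbors) are counted in an overflow tally and excluded
from the normalization, never silently dropped.  Densities are normalized
so that ∑ p·Δd·Δcos θ = 1 (enforced to 1 × 10⁻⁹ at construction), and
differences integrate to 0 at the same tolerance.  Δp requires equal
molality tags on both operands; ΔΔp requires order-1 operands of the same
population with the minuend at the higher molality.  Region integrals
(defaults: VERY_STRONG d < 2.8 Å; MODERATE d > 2.8 Å ∧ −1 < cos θ < −0.75)
assign straddling bins by bin-center membership.

**Periodic boundaries.** Orthorhombic boxes only, minimum-image convention,
enforced box edge > 7 Å (twice the pair cutoff); triclinic input is
rejected.  Neighbor searches use a periodic KD-tree; the test suite checks
sample-for-sample identity against a brute-force O(N²) scan with explicit
minimum-image arithmetic on frames up to 500 atoms, with and without a box.

**Bulk reference.** The bulk density may be computed per run or loaded from
a density CSV produced elsewhere; a frame stride (default 100 in the
trajectory-analysis setting, 1 in the synthetic demos) thins the frames
used for the bulk reference, which is far more populous per frame than the
shell.

## Distance → OH-stretch frequency map

ν(d) = ν_free − A·exp(−(d − d0)/λ), with defaults ν_free = 3700 cm⁻¹
(the free/dangling-OH resonance), A = 900 cm⁻¹, d0 = 2.3 Å, λ = 0.3 Å on
the domain [2.3, 3.5] Å.  These defaults map the shortest (strongest) bonds
to ≈2800 cm⁻¹ and approach — without exceeding — the free-OH region at the
domain edge (ν(3.5) ≈ 3684 cm⁻¹), consistent with the red-shift of
stronger hydrogen bonds.  The calibration is an explicit input everywhere;
it is never hard-coded into an analysis.  cos θ does not shift the
frequency; it enters only through the density mass (the map is a function
of O–O distance alone).  Each d-bin contributes a unit-area Gaussian of
width σ_ν = 80 cm⁻¹ (configurable; the true lineshape is unknown at this
level of modeling) at ν(bin-center d), weighted by bin mass.  The output
integrates to the input mass (checked to 1 × 10⁻⁶); a wavenumber grid that
would clip more than the 4σ tails is rejected with an estimate of the
clipped mass.  Transition-dipole weighting, electric-field maps and Fermi
resonance are out of scope: the projection is population-weighted only.

## IR solvation-shell spectroscopy

**Pipeline order** (default): baseline-correct sample and reference →
find the subtraction coefficient → subtract → normalize the SC product to
the amide II integral over [1500.1, 1550] cm⁻¹ (trapezoidal rule on the
native grid).  A flag allows normalizing the baseline-corrected inputs
instead.  Spectra on different grids are rejected, never silently
interpolated; an explicit linear `resample` utility is provided.

**Baseline.** The anchor windows default to [2625, 2654] and
[3895.5, 3954.8] cm⁻¹ (protein L preset; a lysozyme preset uses
[2615, 2624.6] and [3755.2, 4000] cm⁻¹).  Each anchor is (mean wavenumber
of the window's grid points, mean absorbance there); the line through the
two anchors is subtracted over the whole spectrum.  Using the grid-point
mean as the abscissa (rather than the nominal window midpoint) makes the
correction annihilate straight lines exactly on any discrete grid, which
in turn makes baseline correction idempotent and the noise-free pipeline
an exact inversion.

**Coefficient.** The optimal c is the largest c ≥ 0 with
min(sample − c·reference) ≥ −tolerance over the negativity region
(default: full measured range minus 20 cm⁻¹ edge guards).  Because the
constraint set is an intersection of half-lines in c, the optimum has the
closed form c = min_i (s_i + tol)/r_i over the constraining points, which
this package evaluates exactly; tests cross-check it against a dense grid
scan (step 10⁻⁴).

Two conventions make the criterion robust on noisy data, where "no
negative spectral features" is otherwise ill-posed:

1. the residual is boxcar-smoothed over 7 grid points before its minimum is
   taken, so a "feature" must be wider than single-point noise;
2. constraints are evaluated only where the smoothed reference exceeds 15%
   of its maximum in the region — where the solvent does not absorb, the
   residual sign carries no information about over-subtraction, and small
   denominators would amplify noise into large coefficient errors.

The automatic tolerance is the expected deepest dip of the smoothed
subtraction noise: σ_pair/√w · √(2 ln(N/w)), where σ_pair combines the
noise levels of both spectra (each estimated as the residual standard
deviation in the flattest 50 cm⁻¹ window), w = 7 is the smoothing width
and N the number of region points.  Centering the tolerance on the
extreme-value scale of the noise removes the systematic under-subtraction
that a fixed small multiple of σ produces.  These conventions (w, floor,
tolerance rule) were fixed using development seeds disjoint from the test
seeds.  The deliberate residual risk: if a real SC spectrum touches zero
*only* where the solvent barely absorbs, the floor hides that constraint
and c is overestimated; for aqueous systems the zero-touching region lies
inside strong water absorption, where the constraint is kept.

**Recovery performance** (measured by the test suite on synthetic pairs,
signal-to-noise 100 relative to the SC amide I peak, 20 seeds): coefficient
error < 2%, normalized SC RMS error < 5% of the SC peak; noise-free pairs
invert exactly (RMS < 10⁻⁹ after normalization, zero tolerance).

## Synthetic generators

**Frames.** No dynamics and no physical water packing: the generator
places a protein-like cluster (surface carbons on a sphere of radius 16 Å
by default, other atoms ≥7.5 Å beneath the surface so they can never
accept bonds from shell waters) centered in a 100 Å box (the box scale of
the source simulations), then builds water *pairs* with exact draws of
(d, cos θ): shell pairs anchored at surface carbons with both members
within 3.5 Å of their anchor, bulk pairs in an annulus beyond 10 Å from
all protein C/O.  O–H length 0.97 Å, H–O–H angle 104.5° (TIP3P-like rigid
geometry); the bonding hydrogen realizes the drawn cos θ through the
closed-form solution of the hydrogen-centered-angle relation and the
second hydrogen points away from the partner.  Inter-pair separations are
guaranteed larger than the pair cutoff, so classification yields exactly
the requested shell/bulk counts with an empty intermediate zone, and every
enumerated sample carries a prescribed draw.  Water counts must be even;
each pair contributes both ordered samples, sharing one distance draw with
independent cos θ draws, so the effective sample size for d statistics is
the pair count (the recovery tests widen their binomial envelopes by the
factor 1 + cos-bin probability accordingly).  Default generating
distributions: shell d ~ truncated normal (2.70 Å, 0.12 Å) — short,
nearly linear bonds (cos θ ~ (−0.95, 0.08)); bulk d ~ (2.90 Å, 0.15 Å),
cos θ ~ (−0.85, 0.15) — the shell-vs-bulk contrast that the difference
maps are built to resolve.  In the report demo the shell distance location
decreases mildly with molality (2.72 − 0.025·b Å), emulating the
salt-induced strengthening of shell bonds.  What the generator does *not*
emulate: excluded volume, water–water packing beyond each pair,
hydrogen-bond cooperativity, ions, or carboxylate acceptors at the surface
(synthetic WC1 is empty by construction) — passing tests demonstrate the
correctness of the measurement chain, not the realism of a water model.

**Spectra.** reference = Σ Gaussian bands (libration tail, HOH bend,
association band, split OH stretch, all ≈0 in the baseline anchor
windows); sample = c_true·(noise-free reference) + SC bands (amide II,
amide I, perturbed-shell OH) + linear drift + i.i.d. Gaussian noise of
amplitude σ (default 2.2 × 10⁻³ a.u. ≈ SNR 100 against the SC amide I
peak).  Both components of the two-component assumption are therefore
exact at zero noise, and the SC component touches zero inside strongly
absorbing solvent regions, which is what pins the coefficient.  c_true
defaults to 0.97, a few-percent solute volume fraction; it is a free
parameter because the solute-concentration → excluded-volume relation is
system-specific.

## Numerical conventions

* Integrals over wavenumber bands: trapezoidal rule on the native grid.
* Density/difference CSV: two leading rows of bin edges, then the value
  matrix, with a JSON sidecar (molality, population, sample and overflow
  counts, difference tags); `%.17g` formatting makes round-trips exact.
* Frame seeds: all generation flows from `numpy.random.default_rng(seed)`;
  identical model → byte-identical frames.  The report derives child seeds
  from the config seed via `SeedSequence`, so re-running a config
  reproduces every numeric artifact bit for bit.
* Boundary conventions: "within 3.5 Å" is ≤, "more than 10 Å" is >; both
  are measure-zero choices.
* The transfer-cost utility converts Å²·mN/m per molecule to kJ/mol via
  Avogadro's number (1 Å²·mN/m = 10⁻²³ J); with the default microscopic
  factor 0.5 and tensions 72 → 76 mN/m, 10,000 Å² costs ≈120 kJ/mol.

## Test-problem sizes

Statistical recovery tests use 500 frames × 200 shell + 200 bulk waters
(10⁵ ordered samples per population) around a 35 Å cluster in a 120 Å box;
oracle-parity tests use 50 disordered frames of ≤500 atoms; Monte-Carlo
coefficient recovery uses 20 seeds at SNR 100 on the 1 cm⁻¹ grid over
[1000, 4000] cm⁻¹.  These sizes give 4σ-level statistical power per
histogram bin while keeping the default suite fast.

## Known limitations

* Only orthorhombic periodic boxes; no triclinic support.
* The bond enumeration treats each ordered pair once and never splits a
  donor's two hydrogens across one acceptor.
* The distance→frequency defaults are a plausible parametric stand-in, not
  a fitted spectroscopic map; analyses that depend on absolute band
  positions should supply their own calibration.
* The IR-SSS tolerance rule is a declared convention; the historical
  practice of manually nudging the coefficient for noise and drift has no
  published rule and cannot be reproduced exactly.
* DCD/XTC trajectory input is not implemented; convert to multi-model PDB
  or extended XYZ first (the `Frame` API is format-agnostic, so a binary
  adapter only needs to produce positions, roles and water topology).
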