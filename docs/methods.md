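# Methods

## Scope and model

`cdshape` analyses ensembles of n-unit cyclodextrin conformers (n ≥ 3;
the default and the tested case is the β-cyclodextrin heptamer).  A
conformer is a frame of Cartesian coordinates in Å; a topology maps
atoms to per-unit roles (O2, O3, O4, C2, C6), to unit membership, and
to hydroxypropyl (HP) substituent groups.  Unit indexing is 1-based and
cyclic, so each adjacent-pair descriptor has exactly n values per frame
and the cross-cavity partner of unit i is unit i+3 (mod n).

Per-frame descriptors: d1(i) = |O2(i)−O3(i+1)|, d2(i) = |O4(i)−O4(i+1)|,
d3(i) = |COM(unit i) − O4(i+3)|, the flip angle θ(i) at vertex C2(i+1)
subtended by C6(i) and C6(i+1), d4(j) = |COM(ring) − COM(HP j)|, the
mass-weighted radius of gyration Rg, and the circularity
C = min d3 / max d3 ∈ (0, 1].

Classification criteria are strict inequalities exactly as defined:
a counted flip angle is θ > 90°, an inserted HP is d4 < 3 Å.  A frame
shows cavity self-closure when at least one HP is inserted.

### Flip counting semantics

θ(i) compares the primary-rim orientation of two *adjacent* units, so
flipping one glucose unit (reflecting its C6 through the glycosidic
plane) sends **both** flanking angles above 90°: an isolated flipped
unit contributes an angle count of 2, two isolated flipped units a
count of 4, and two *adjacent* flipped units a count of 2 (their shared
pair has both C6 on the same side and is not counted).  The package
consistently reports the counted-angle number (`n_flips`); the
generator's ground truth additionally records the number of flipped
units (`n_flipped_units`).  Mixture-recovery tests identify generator
states through their angle-count signatures.

### Centre-of-mass conventions

All centres of mass are mass-weighted with standard atomic masses
inferred from element symbols (overridable in the topology file), and
include every atom present in the input — hydrogens when the input has
them.  The unit COM in d3 uses only the native glucose atoms of that
unit (HP atoms are excluded even when anchored there, keeping d3
comparable across substitution patterns); the ring COM in d4 uses all
non-HP atoms.  Whether hydrogens or substituent atoms belong in these
COMs is a genuine modelling choice; the defaults above are exposed
through the topology's unit-membership and HP-group sets, which the
topology file can redefine.

## Free-energy surfaces

The (d1(i), d2(i)) pairs of all units and all frames are pooled into
one sample set (one surface per ensemble).  A 2-D histogram with
0.1 Å bins over [2, 8] Å on both axes (configurable) is normalised to
P(x, y) over retained samples — samples outside the window are dropped
— and Boltzmann-inverted: F = −k_B T log P with
k_B = 0.0019872041 kcal mol⁻¹ K⁻¹, optionally shifted so min F = 0.
Empty bins have undefined F (NaN internally, absent from exports),
never an infinite sentinel.  The 0.1 Å default resolves basin
separations of ~0.5–1 Å typical of CD rim-distance distributions.

Percentage statistics (flip populations, closure) are computed at full
precision; rounding (integer percent for flip classes, two decimals for
closure) happens only in the report writer.  The standard deviation of
circularity is the population form (divide by n, `ddof=0`,
configurable), the usual convention when the frames *are* the ensemble.

## Synthetic conformer generator

The generator builds idealised pseudo-atom conformers whose labels are
exact by construction.  Each unit carries its five role atoms plus two
filler ring carbons (so unit COMs have non-trivial mass weighting);
each HP group is four pseudo-atoms (3 C, 1 O) whose mass-weighted COM
is placed exactly at the requested d4.  Default geometry (all lengths
Å): O4 atoms on a regular heptagon of circumradius 5.0; secondary-rim
O2/O3 at radius 5.6, height +1.2, with the angular stagger solved so
every d1 equals the 3.5 target; C2 at radius 4.8 in the glycosidic
plane; C6 directly below C2 at height −2.4.  These offsets put
unflipped flip-angles at 60.0° and flipped ones at 119.95° — about 30°
of margin on either side of the 90° threshold — and exterior/inserted
HP placements target d4 = 8 / 1.5 Å versus the 3 Å cutoff, so
coordinate noise up to σ ≈ 0.1 Å essentially never moves a frame
across a classification boundary (label recovery ≥ 99% is asserted in
the tests).

Transformations: a flip reflects the unit's primary-rim atoms (C6 and
the C5 filler) through the best-fit plane of the O4 atoms — the O4
atoms are untouched, so the operation is an exact involution; an
elliptical squeeze scales one in-plane axis about the O4 centroid by a
ratio ≤ 1 (circularity decreases strictly with the ratio); HP
placement measures the ring COM of the current (possibly distorted)
frame so the d4 target is exact.  Ensembles draw frames i.i.d. from a
state mixture (fractions validated to sum to 1) and add isotropic
Gaussian coordinate noise, 0.05 Å by default, from an explicit seeded
generator — the same seed reproduces an ensemble bit for bit.

The named default mixtures emulate the qualitative conformational
states of CD ensembles at ambient temperature: a 58/35/7% no/one/two-
flip mixture for the unsubstituted heptamer and an exterior/inserted
two-state mixture for self-closure studies.  What the generator does
*not* emulate: chemically realistic glucose internal geometry,
force-field energetics, correlated (non-isotropic) thermal motion, or
continuous flip pathways.  Tests passing on these ensembles therefore
validate the *analysis* (descriptor algebra, classification logic,
statistics) — they are not evidence about real HPβCD conformational
populations.

## Toy replica-exchange sampler

A minimal replica-exchange Monte Carlo over the discrete synthetic
state space (flip set, per-HP exterior/inserted mode, optional
continuous ellipse ratio), giving the statistics layer
temperature-structured input.  The energy model is additive and
deliberately chemically naive, in kcal/mol: `flip_penalty` (default
1.5) per flipped unit; −`insertion_well` (default 1.0) per inserted HP,
making self-closure energetically favourable and hence *less* probable
at higher temperature; `ellipse_stiffness`·n·(1−ratio)² (default
stiffness 20) for elliptical distortion.  `insertion_barrier` (default
2.0) damps HP toggle acceptance symmetrically by exp(−barrier/k_BT) in
both directions — a Metropolis–Hastings thinning that slows
insertion/ejection kinetics without changing the stationary
distribution.

The temperature ladder is geometric, T_k = T_min·r^k with
r = (T_max/T_min)^(1/(n−1)) — the standard equal-acceptance heuristic;
the conventional 8-replica ladder spans 269.5–570.9 K with adjacent
gaps inside 30–60 K.  Sweeps propose every flip toggle, every HP
toggle and one reflected Gaussian ellipse move; neighbour exchanges are
attempted every `exchange_interval` sweeps (default 10) with
alternating even/odd pairing and acceptance
min(1, exp[(β_i−β_j)(E_i−E_j)]).  Temperature slots keep their
temperature and swap configurations, so collected samples are already
demultiplexed.  Sampled states are rendered into conformers through the
synthetic builder (cached per discrete state).

## Numerical choices

* Angles are reported in degrees (internal trigonometry in radians);
  flip-angle arms shorter than 10⁻⁶ Å raise an error rather than
  silently returning 0.
* Coordinates are Å everywhere; XYZ files are assumed Å (the format
  does not mandate units).  PDB alternate locations: the first altloc
  is kept, others dropped with a logged warning.
* File reads stream frame by frame (constant memory in frame count);
  10⁴–10⁵-frame files never need whole-file residency.
* Metric TSVs carry units in the single header row (`d1_1(Angstrom)`)
  and 6 significant digits; read-back reproduces values at that
  precision.  PDB output carries 3 decimals (10⁻³ Å round trip).
* Exchange probabilities are computed in log space and clipped at 0
  before exponentiation, so extreme β or E never overflow.

## Validation strategy and problem sizes

Every descriptor is checked against an independent pure-Python
brute-force implementation (1e-12 relative) on 200 random conformers,
and for rigid-motion invariance / uniform-scaling covariance over 100
random rotations and translations.  Boltzmann-inversion identities are
asserted to 1e-9.  Statistical checks run at sizes chosen to make
3σ binomial bounds meaningful on a desktop: 1,000–2,000-frame
ensembles for mixture recovery (20 seeds for the excursion-rate
property), 10⁵ Monte Carlo sweeps for two-level Boltzmann occupancy,
and 20,000-sweep, 4-replica runs (5 seeds) for the
closure-versus-temperature monotonicity trend.

## Known limitations

* The pseudo-atom builder is a geometric idealisation; its Rg and
  circularity values are not comparable in absolute terms to atomistic
  CD ensembles (e.g. the builder's mean Rg ≈ 5.2 Å reflects its
  reduced atom set, not a prediction).
* The toy energy model has no molecular meaning; only the *shape* of
  its temperature trends (e.g. closure decreasing with T for a
  favourable insertion well) carries over conceptually.
* The flip transformation moves only primary-rim atoms; real glucose
  flips reorient the whole pyranose ring and partially change d1/d3 in
  ways the builder does not mimic.
* Binary trajectory formats (DCD/XTC) are out of scope; multi-model
  PDB and XYZ are the supported inputs.
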