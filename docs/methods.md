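# Methods

This note records the definitions, conventions and design decisions behind
`hydroshell`, and what its synthetic generators do and do not emulate.

## Geometry and units

All configurations live in orthorhombic periodic boxes; triclinic cells are
rejected at the parser. Lengths are Å, temperatures K, molar densities
mol/l; the conversion to number density is n = ρ·N_A·10⁻²⁷ Å⁻³ (exact
CODATA N_A). Pair distances use the minimum-image convention, valid for
separations up to half the smallest box edge; the RDF enforces
r_max ≤ L/2 so no image pair is counted twice.

Molecular topology (which hydrogens belong to which oxygen) is inferred by
nearest-oxygen assignment under minimum image with a 1.2 Å O–H cutoff, and
fails loudly if any oxygen does not end up with exactly two hydrogens. This
is deliberate: a "structureless gas" at liquid density contains overlapping
molecules for which the assignment is genuinely ambiguous, and silently
guessing would corrupt every hydrogen-bond count downstream.

## Neighbour shells, RDF, coordination

Neighbours are oxygen–oxygen throughout: the shells of water, g_OO(r) and
the d5 convention all refer to oxygen positions. Neighbour tables are
sorted ascending with ties broken by ascending molecule index (stable
sort), so tables are bit-for-bit reproducible.

g(r) uses the standard estimator: unordered pair counts per bin, doubled,
divided by N·ρ times the exact shell volume (4π/3)(r₊³−r₋³), averaged over
frames. Default bin width 0.05 Å. The running coordination number
n(r) = 4πρ∫₀^r g r′² dr′ is a trapezoidal integral over bin centres
anchored at n(0)=0; a direct cutoff count is exposed alongside and serves
as the reference in tests. Against an ideal gas both reproduce
(4/3)πρr³ within counting error.

## Order parameters

**Tetrahedrality.** Q = 1 − (3/8)Σ_{j<k≤4}(cos ψ_jk + ⅓)², with ψ_jk the
angles at the central oxygen subtended by its four nearest oxygens — no
distance cutoff, displacement vectors always minimum-image. Q = 1 for
ideal tetrahedral directions; the degenerate all-collinear case gives
Q = −3; the mean over a structureless shell is 0 (nearest-neighbour
directions of a Poisson process are i.i.d. uniform, making each
E[(cos ψ + ⅓)²] = 4/9).

**LSI.** With a molecule's neighbour distances ordered
r₁ < … < r_n < cutoff < r_{n+1}, the gaps Δ_j = r_{j+1} − r_j (j = 1…n,
the last gap crossing the cutoff) have LSI = population variance of the
Δ's, in Å². Cutoff default 3.7 Å, the conventional first-shell/gap
boundary, exposed as a parameter. A molecule with no neighbour inside the
cutoff has no defined LSI and is flagged NaN (counted and logged, excluded
from summaries) — never reported as zero. If any molecule's table ends
before its first beyond-cutoff neighbour the computation refuses and asks
for a larger table rather than returning a silently truncated variance.

**d5** is simply the rank-5 table entry.

**Summaries** treat frames as independent blocks: the reported mean is the
mean of per-frame means and the standard error is the block-mean standard
deviation over √(number of frames). With a single frame the SE is
undefined (NaN), not zero. Frame-block averaging was chosen over pooled
per-molecule averaging because frames, not molecules, are the approximately
independent unit in a trajectory.

**Two-mode splitting.** `midpoint_split` assigns values to low/high modes:
deterministic 1-d two-means (centroids initialised at the sample extremes)
locates the mode centres, and the decision threshold is the point
equidistant from the centres in units of each mode's spread. For equal
spreads this is the plain midpoint; for unequal spreads (the LSI of
expanded environments is ~3× broader than that of collapsed ones) the
plain midpoint of means is biased into the broad mode, while the
equal-z-score boundary sits in the density valley.

## Hydrogen bonds and motifs

The bond criterion is geometric and donor-centred: an edge donor→acceptor
exists iff the O_d–O_a minimum-image distance is < 3.5 Å and the angle
between O_d→H and O_d→O_a is < 30°. Both thresholds, and an alternative
hydrogen-centred angle convention (deviation from O_d–H···O_a linearity),
are parameters, since geometric H-bond definitions vary across the
literature and exact population counts depend on the choice. Inequalities
are strict, with a 1e-12 cosine guard so a geometry at exactly the
threshold never bonds regardless of rounding order. Each hydrogen donates
at most one bond: among acceptors satisfying the criterion the smallest
angle wins, ties broken by molecule index. This keeps n_D ≤ 2, consistent
with the motif alphabet (no triple-donor labels).

Motif labels concatenate donor and acceptor counts ("D"·n_D + "A"·n_A);
zero-bond molecules are "free"; acceptor counts above 3 are folded into
the 3-acceptor tail (logged), since five-bonded DDAAA is the largest motif
of interest. The asymmetry statistic is P(DDA) − P(DAA); the DDAAA
population is its companion indicator.

## Synthetic generators: what they emulate

All generators are deterministic given a seed, and monomers are rigid:
r_OH = 0.96 Å, H–O–H = 104.5° (gas-phase values) — except lattice
hydrogens, which sit on tetrahedral bond directions (109.47°, the ice
geometry).

- **ideal_gas** — uniform oxygen positions, uniformly random orientations.
  Emulates only the structureless limit: no excluded volume, so at liquid
  density molecules interpenetrate (topology inference on such frames can
  legitimately fail). Default density 55.3173 mol/l (ambient water).
- **tetrahedral_lattice** — diamond-cubic oxygen sublattice at the
  requested density (N = 8m³ enforced), hydrogens along two of the four
  bond directions chosen per site at random, Gaussian thermal noise σ.
  Noise displaces molecules rigidly (one displacement per molecule):
  independent per-atom noise at realistic σ routinely stretches O–H
  beyond the 1.2 Å topology cutoff, i.e. it models dissociation rather
  than libration-free thermal disorder, so rigid displacement is the
  physically sensible reading. Proton placement is random two-of-four,
  not globally ice-rule consistent: the analyses consume local motif
  statistics, not proton order, and under random placement every molecule
  donates twice while acceptor counts are Binomial(4, ½) — DDAA modal at
  6/16, flanked by DDA and DDAAA. The σ = 0 lattice is an analytic fixed
  point: Q = 1, first shell uniformly at a√3/4, LSI = (3/16)(J − Ḡ)²-type
  closed form with J the shell gap.
- **two_state_mixture** — labelled central sites on a 12 Å cubic grid,
  each wrapped in a template environment: 4 first-shell neighbours at
  2.75 Å (from the diamond lattice at the low-density-amorphous anchor,
  51.86 mol/l), then either an expanded second shell (a_LDA/√2 ≈ 4.49 Å,
  no interstitial) or a collapsed one (a_HDA/√2 ≈ 4.17 Å at the
  64.76 mol/l anchor, plus one interstitial at 3.30 Å inside the H-bond
  cutoff). The interstitial radius is a stylised stand-in — no
  quantitative experimental template exists for interstitial occupancy —
  and is exposed as a module constant. The 12 Å pitch keeps cluster
  environments non-interacting (closest inter-cluster approach ≈ 2.4 Å
  between outer-shell partners, never inside a labelled site's analysis
  ranks), which is why the frame's molar density is reported as a derived
  quantity rather than honoured as an input: clean per-site ground truth
  and liquid packing density are mutually exclusive in a template
  construction. Default thermal noise σ = 0.1 Å (a conservative
  crystalline-range RMS displacement).
- **motif_fixture** — a central molecule plus the minimal partner set in
  ideal bonding geometry (O–O 2.8 Å, donor angles 0°): donated bonds along
  the central O–H directions, accepted bonds from lone-pair-like
  directions plus the anti-bisector for the fifth. Partner orientations
  are chosen so no spurious bonds arise even where partners fall within
  3.5 Å of each other.

What a green test on these generators does **not** establish: agreement
with any real or simulated water ensemble. The generators provide known
statistical structure (shell radii, mixture fractions, motif ground
truth), not physics — no sampling, no energetics, no proton order, no
temperature dependence. Observables whose headline values come from
large-scale path-integral simulation (motif populations vs temperature,
dipole trends, TMD location from computed pressures) are outside what
desk-scale synthetic data can reproduce; the pipeline computes them from
user-supplied trajectories or input tables instead.

## TMD extraction

`tmd_from_isochore` consumes an input (T, p) series — pressures are never
computed here — requires the sampled minimum to be interior ("minimum not
bracketed" otherwise), fits a quadratic through a window (default 3
points, configurable since the appropriate window depends on how densely
the isochore was sampled) and returns the vertex. Uncertainty: with
per-point error bars, the delta-method propagation of the weighted
least-squares covariance; without them, half the local temperature
spacing. A seeded Monte-Carlo self-test verifies ~3σ calibration of the
propagated uncertainty.

## Numerical conventions

- Ties in neighbour distance: ascending molecule index (stable sorts).
- Strict threshold inequalities in H-bond detection, with a 1e-12 guard.
- Flagged-missing values are NaN and excluded+counted, never zeroed.
- The LSI uses the population (not sample) variance of the gaps.
- RDF shell volumes are exact cubic differences, not 4πr²Δr.
- All randomness flows through `numpy.random.default_rng(seed)`.

## Known limitations

- Orthorhombic boxes only; no binary trajectory formats.
- O(N²) distance computation — appropriate at the N ≈ 300–3000 scale the
  package targets, no cell lists.
- The H-bond criterion is one geometric convention among several; motif
  populations shift by a few percent across published variants.
- Ideal-gas frames at liquid density cannot be used for H-bond/topology
  analyses (overlapping molecules), by construction of that generator.
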