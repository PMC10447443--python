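# Methods

This note records the model implemented by `shiftsel`, the conventions and
numerical choices made where several were defensible, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Local molecular environments

A *local molecular environment* is a central molecule together with every
molecule having at least one atom within a cutoff (default 7 Å) of any atom
of the central molecule, distances taken under the minimum-image convention.
Exactly one environment is extracted per molecule per snapshot, in
deterministic (trajectory, frame, molecule id) order.

Conventions:

* **Boundary inclusion is closed** (`d ≤ cutoff`). The boundary is a
  measure-zero set, but determinism requires picking a side.
* **Unwrapping.** Each molecule is first made whole by walking its bond
  tree outward from its first site, replacing each bond vector by its
  minimum image. Every member molecule of an environment is then rigidly
  translated by the lattice vector that realizes its closest contact with
  the central molecule, so environments are finite clusters with intact
  geometry. Any unwrapping that preserves minimum-image contacts would do;
  this one is chosen for being anchor-free at the molecule level.
* **Neighbor search.** An exact, vectorized all-pairs minimum-image
  distance matrix per snapshot, reduced to molecule-pair minima. At the
  system sizes this package targets (≲ a few hundred atoms per frame) this
  is faster in numpy than a Python cell list and is trivially exact, which
  is the contract; the brute-force periodic-image oracle in the test suite
  checks it on random cells, including triclinic ones. For orthorhombic
  cells the nearest image follows from fractional rounding; for triclinic
  cells a 27-candidate search around the rounded image is used (exact for
  the moderately tilted cells produced by MD packages; pathologically
  skewed cells are out of scope). The single-pair
  `minimum_image_vector` searches 5³ candidates.

## Shift matching (the selection statistic)

Experimental distributions and predictions are both modeled as Gaussians.
Per site, the Z score between the two Gaussians is converted to a
two-tailed p-value, `p_val = erfc(Z/√2)`, which is the closed form of
`sqrt(2/π) ∫_Z^∞ exp(−x²/2) dx`; the equivalence is asserted to 1e-10 by
quadrature in the tests. The p-value is divided by
`max(1, σ_pred/σ⁰)`, where σ⁰ is the site's **first quartile** of all
prediction uncertainties (25th percentile, linear interpolation — the rule
is configurable). This caps the reward for predictions whose own
uncertainty is so large that any experimental distribution would overlap
them. The per-environment probability is the geometric mean of site
probabilities, computed in log space; a zero site probability
short-circuits to exactly 0 (no `log(0)`).

Selection is by strict threshold (`p_j > 0.33` by default; ties at the
threshold are excluded) or by top fraction (`k = round(f·n)`, at least 1;
ties broken by stable index order). Raising the threshold can only shrink
the selection; this monotonicity is property-tested.

Sites with several symmetry-equivalent protons can be matched per proton or
per resonance; in per-resonance mode the predicted shifts and uncertainties
of the group are arithmetically averaged before Eq.-level matching, since
assignment tables are per resonance. Per-proton is the default; the
averaging mode is exercised in the tests.

Missing predictions for an included site fail loudly by default;
`on_missing="skip"` drops those environments with a logged warning, because
silently dropping sites (rather than environments) would bias p_j upward.

Threshold diagnostics compare the histogram of selected predicted shifts
per site with the experimental Gaussian discretized on the same bins:
overlap coefficient `Σ min(p, q)` and Jensen–Shannon divergence with
base-2 logarithm (so JS ∈ [0, 1]). Binning is Freedman–Diaconis on the
pooled support with a floor of 20 bins; all-identical predictions fall back
to a single bin, logged.

## Hydrogen bonds

An O–H⋯X motif (X = O or N) with H⋯X distance **< 2.5 Å** and O–H–X angle
**> 130°**. Only the central molecule's hydroxyl donor is scanned (a
general donor scan would be a separate feature); candidate acceptors are
all O/N atoms of all members — including the central molecule itself, so
intramolecular bonds count — except the donor oxygen. Ties are broken by
shortest H⋯X distance. Census fractions are counts over
{acceptor site labels} ∪ {"none"} and sum to 1.

## Dihedrals

Signed torsions in (−180°, 180°], IUPAC right-handed sign convention; the
opposite handedness is available via `convention="reverse"` since published
histograms do not always state theirs. Histograms use fixed periodic
binning on (−180, 180] with the wrap point folded into the topmost bin.

## Alignment and density maps

Environments are superposed on a user-chosen set of ≥ 3 non-collinear
central-molecule sites by least-RMSD rigid fit (Kabsch via
`scipy.spatial.transform.Rotation.align_vectors`, proper rotations only),
onto the first environment as reference frame (the choice of reference is a
free gauge; difference maps always share one reference). The returned RMSD
over alignment atoms is the global minimum over rigid motions, checked in
tests against 1000 random rotations with optimal translation.

Per-element density maps follow
`G(r) = (1/N_env) Σ_env Σ_atoms exp(−|r − r_a|²/(2σ²))` with σ = 0.5 Å and
**unnormalized** Gaussians, so the map value is exactly 1 where an atom of
the element sits in every environment. The grid is 31×31×31 nodes spanning
center ± 6 Å inclusive per axis (spacing 0.4 Å), centered on the
aligned-atom centroid; node placement (inclusive endpoints) is our
registration choice. Maps are linear in the environment set and
permutation-invariant. Difference maps are pointwise selected − reference
on identical grids.

## Radial distribution functions

Partial pair distributions g_ab(r) are computed by minimum-image
histogramming with ideal-gas normalization (self-pairs excluded), requiring
`r_max ≤` half the smallest cell face spacing. The total is
`G(r) = Σ_ab w_ab g_ab(r)` with X-ray-like weights
`w_ab ∝ c_a c_b Z_a Z_b` (normalized; plain concentration products
available), and the differential correlation function is Keen-style
`D(r) = 4πρ r (G(r) − 1)` with ρ the total atom number density. These
conventions are stated explicitly because experimental reduction software
applies its own; comparisons against a measured curve should treat overall
convention differences through the residual, not expect bit-level match.
An optional per-snapshot list of central molecules restricts one side of
every pair, giving the distribution seen from a selected ensemble.
`curve_residual` interpolates the simulated curve linearly onto the
reference grid over the overlapping support and reports the residual RMSE
over the full range and over 3–10 Å.

## Formation energies

`ΔE_form = E(all members) − E(members without the central molecule)`, which
contains both the central molecule's interaction with its surroundings and
its conformational self-energy. Energies come from a pluggable backend
(kJ/mol at the interface). The built-in test backend is a bounded Gaussian
pair attraction `E = −ε Σ_{i<j} exp(−r_ij²/(2 r₀²))` (ε = 1 kJ/mol,
r₀ = 3 Å): strictly pairwise-additive, so formation energies decompose in
closed form, and bounded at the short intramolecular distances where
Lennard-Jones-type potentials diverge. An external-process adapter (write
XYZ, parse the last stdout token, unit scale factor) hooks up production
backends. Relative energies are re-zeroed to the mean of a reference set
(whose re-zeroed mean is then exactly 0); group summaries report the
standard error of the mean `s/√n` (undefined for n = 1).

## Synthetic data

The generator emulates what the method assumes about its inputs, not any
particular chemistry:

* **Toy molecule** (11 atoms): hydroxyl O1–H1 on a CH₂ (C2) linked by one
  rotatable bond to a CH (C3) bearing an N acceptor (N1) and a carbonyl
  (C4=O2) — the smallest realization of every analysis target: one
  conformer-defining torsion ("backbone", ±60° classes A/B), one free
  hydroxyl torsion, one O–H donor, and both N and O acceptors.
* **Packings**: random insertion with overlap rejection (minimum
  intermolecular atom distance 2.0 Å) into a cubic cell; defaults of 32
  molecules in a 28 Å cell give a comfortably insertable density. H-bond
  class molecules are posed with their donor aimed at a neighbor's acceptor
  (H⋯X ∈ 2.05–2.35 Å, angle 150–178°); non-bonded molecules are kept free
  of acceptors within a buffer band (3.0 Å / 120°) so the planted labels
  are unambiguous — geometries inside the band between the strict criteria
  and the buffer are excluded *from generation*, not from detection. Labels
  are verified against the detector before a packing is accepted. When
  every molecule is H-bond class, the first-placed molecule (which has no
  pre-existing partner) is closed afterwards by swinging its hydroxyl
  torsion — an internal degree of freedom — until its donor reaches a
  neighbor's acceptor with margin inside the criteria.
* **Shifts**: per-site class means plus Gaussian noise (scale 0.4 × the
  site linewidth), log-normal uncertainties with median half the linewidth
  (heteroscedastic, so the quartile cap is exercised). "Experimental"
  distributions are centered on the target-class means (conformer A,
  H-bonded) with linewidths emulating amorphous solids: 2–6 ppm for
  carbons, 0.6–1 ppm for CH protons, 1.8 ppm for the hydroxyl proton.
* **Statistical benchmark**: `generate_scoring_benchmark` plants a
  subpopulation directly in prediction tables (default: 20 % of 10⁴
  environments, the rest displaced by 3 joint standard deviations on 5 of
  8 sites). Scoring consumes only tables, so this tests the selection
  machinery at scale without paying for geometry.

What the generator does **not** emulate: force-field dynamics and realistic
packing correlations, anisotropic or non-Gaussian lineshapes, correlated
prediction errors across sites, and conformation-dependent prediction
uncertainty. Passing tests therefore demonstrate that the statistic and its
implementation behave as specified under the assumed noise model — not that
any particular real material's ensemble would be recovered.

All generators are deterministic functions of a single seed
(`numpy.random.SeedSequence` fan-out per frame/stage).

## Problem sizes

Default study sizes are chosen so every analysis is informative yet the
whole pipeline runs in minutes on one CPU: 50 snapshots × 32 molecules for
the synthetic study, 10⁴ environments for the statistical benchmark, and
8010 snapshots × 128 three-atom molecules for the environment-count
bookkeeping run (which only exercises extraction arithmetic, so trivial
molecules suffice).

## Known limitations

* Extraction exactness for triclinic cells assumes moderate tilt (MD-like
  reduced cells); extreme skew would need a wider image search.
* The pipeline's default energy backend is the toy pair potential;
  production energetics require an external code through the adapter.
* Ensemble-restricted G(r) uses the selected molecules as histogram
  centers within full periodic snapshots; it is not defined for isolated
  clusters.
* Site labels must be consistent across all molecules and frames; there is
  no automatic re-mapping between labeling schemes beyond the optional
  equivalent-proton groups.
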