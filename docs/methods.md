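# Methods

## Kinematic model

The molecule is a rooted, directed spanning tree of rigid bodies. Rigid
bodies are found by union–find: every non-rotatable bond (aromatic/partial
double bonds, ribose and base ring bonds, bonds to the 2′-OH oxygen) merges
its two atoms, and atoms with a single covalent neighbor merge into that
neighbor. Rotatable bonds are the backbone bonds P–O5′ (α), O5′–C5′ (β),
C5′–C4′ (γ), C3′–O3′ (ε), O3′–P (ζ) and the glycosidic bond (χ). Covalent
topology comes from name templates for the four ribonucleotides (hydrogens
included) plus the inter-residue O3′–P link; geometry is never used to
infer bonding, so strained conformations keep their topology. A rotatable
bond whose distal side collapses into the same body (for example a bare
terminal O3′ with no hydroxyl hydrogen) carries no degree of freedom.

A conformation is coordinate-primary: Cartesian coordinates are the state,
and torsions are measured from them (IUPAC quadruples and sign convention).
Moves are applied incrementally — each changed torsion rotates its subtree
about the current bond axis, parents before children. This makes the model
well defined even when a resealed backbone carries small junction strain,
at the cost that absolute torsion vectors are reproduced only to ~1e-4 rad
after pucker moves (the ribose embedding slightly perturbs adjacent
dihedrals). Applying a zero increment is the exact identity.

## The pucker coordinate τ

Each complete ribose contributes one internal degree of freedom. τ (in
degrees) maps affinely onto the pseudorotation phase P, calibrated on two
anchors: τ = −154° ↔ P ≈ 18° (C3′-endo) and τ = +44.7° ↔ P ≈ 162°
(C2′-endo). Ring geometry for a given phase is generated by an
exact-closure embedding — five atoms on a phase-adjusted circle with
out-of-plane displacements z_j ∝ cos(P + 4πj/5), amplitude chosen so the
torsional pucker amplitude is ≈ 39°. Exocyclic substituents and the three
attachment anchors (glycosidic N, C5′, O3′) ride local ring-atom frames.

Because the affine slope (≈ 0.725) differs from one, τ cannot be
360-periodic: it is treated as a real-valued coordinate with a branch cut
at ±180°, increments are applied unwrapped, and measurement reports a
continuous overshoot near the cut. Pucker deformations are *relative*: the
ideal embeddings at the current and the target τ are both placed on the
parent anchor and atoms follow the map between them, so the deformation
tends to the identity as the step vanishes. This matters numerically — a
naive re-embedding "snaps" a slightly non-ideal ring (PDB coordinates are
quantized to 1 mÅ) onto ideal geometry, which injects first-order
hydrogen-bond drift and spuriously lifts the rank deficiency of the cycle
Jacobian.

## Constraints and null-space moves

Each WC pair defines one cycle with six constraint rows: the instantaneous
positions of the donor hydrogen and of the acceptor atom, differenced
between the two tree branches of the cycle. Torsion columns are analytic
(axis × lever arm, signed by branch membership); τ columns are central
finite differences (step 1e-5 rad) of the local re-embedding transforms,
validated in the tests against a full finite-difference oracle. Because
both constrained endpoints lie on the donor–acceptor axis, the combination
u·(rows_h) + u·(rows_a) with u along that axis vanishes identically, so a
generic cycle has rank 5 and the null space has dimension n − 5m.

The null-space basis is taken from the SVD with a relative singular-value
cutoff of 1e-6. The spectrum is strongly bimodal — structural zeros sit
below 1e-8 of the largest singular value while the smallest physical value
is orders of magnitude higher — so the cutoff separates structure from
numerical noise with a wide margin; a much tighter cutoff misclassifies
the finite-difference noise floor of the τ columns as rank.

A null-space move projects a standard-normal trial vector, rescales it so
no component exceeds `max_step` (0.1 rad), applies it, and then measures
the relative displacement of every constrained endpoint in the partner
body's frame. Displacements beyond `eps_closure` (0.05 Å) reject the move.
The drift is quadratic in the step (halving the step shrinks it ~4×), so
the gate is a genuine second-order guarantee, not an assumption: at the
full 0.1 rad cap a large fraction of moves is rejected and the sampler
simply retries.

## Rebuild moves

A rebuild selects a contiguous run of unpaired nucleotides, redraws each
ribose's τ from the mixture 0.6·N(−154°, 11.5°) + 0.5·N(44.7°, 17.2°)
(weights normalized to 6/11 and 5/11; the optional `shift` raises the
second mean, e.g. by 60°, to oversample non-helical puckers), resamples χ
uniformly, and reseals the segment's 3′ O3′–P bond by damped pseudoinverse
iterations over the segment's non-ribose backbone torsions. The closure
target is the position of the downstream phosphorus, whose original
coordinates — like those of every atom outside the segment — are kept
bitwise unchanged; convergence to 0.01 Å leaves at most that much bond
strain at the junction, absorbed by the coordinate-primary representation.
When the residual stalls in a local minimum of the nonlinear map the
segment torsions are re-seeded at random within the same 100-iteration
budget.

The sampler dispatches two-nucleotide segments. With only one nucleotide
the four available torsions often cannot reach the closure target at all
after a large pucker change (brute-force minimum residuals near 0.8 Å on
the loop fixture), which would bias the accepted pucker distribution; with
two nucleotides (nine torsions) closure succeeds essentially always and
the accepted τ values reproduce the mixture.

## Sampler

The pool starts from the input conformation. Seeds are drawn by the shell
rule: a fully random torsion vector is generated, a shell radius is drawn
uniformly on [0, r_init], and the pool member whose C4′ RMSD to the start
falls inside the shell (width r_init/100) and is closest to the random
vector in torsion space becomes the seed; empty shells are redrawn up to 50
times, then the member nearest the last radius is used. RMSDs use optimal
superposition, so rigid drift of the whole molecule cannot exhaust the
exploration budget. Rebuilds are dispatched with probability 0.1.
Candidates are accepted if clash-free (hard spheres at `vdw_scale` = 0.5;
pairs separated by one or two bonds, or within one rigid body, excluded) and
if every hydrogen bond remains within `eps_closure` of its geometry in the
*initial* structure — a cumulative gate, deliberately stricter than
verifying each move against its seed only, so pool membership certifies
closure rather than trusting a chain of per-move checks. Clash detection
uses a cubic spatial hash with cells at least twice the largest scaled
radius (27-cell neighborhoods), and is tested for exact agreement with an
all-pairs oracle. Everything is driven by one numpy Generator; identical
inputs give bit-identical pools.

The optional Metropolis pairing bias accepts a candidate with probability
min(1, e^−Δd), where d sums over target residue pairs the smallest
deviation of any charged-hydrogen→acceptor candidate vector from a 2 Å
target length; charged hydrogens are base hydrogens bonded to N or O, and
acceptors are base N/O atoms without a bonded hydrogen.

## RDC ensemble fitting

The fit minimizes ‖D_obs − Σ w_i D_i‖² subject to w ≥ 0 and Σw ≤ 1 (a flag
switches to Σw = 1). The solver is an active-set method: plain non-negative
least squares when the sum constraint is slack, otherwise an active-set
iteration on the equality-constrained KKT system with standard
step-to-boundary handling. First-order optimality is re-verified after
every solve. Tests cross-check the objective against an independent
general-purpose convex solver.

Support recovery is a property of the *data*, not only the solver: with s
candidates whose vectors positively span coupling space, an exact
noise-free mixture has infinitely many non-negative representations, and no
method can promise that the optimum it returns uses exactly the true
components. With ~12 couplings this identifiability limit is reached around
three mixture components; with ~30 couplings mixtures of five are recovered
exactly. The synthetic RDC fixture models candidates as a shared alignment
signature (sd 10 Hz) plus per-conformer deviations (sd 3 Hz), mirroring how
back-calculated sets from one molecule behave.

## Analysis metrics

C4′ RMSD superposes before measuring. Flexibility profiles report the
circular variance (1 − |mean resultant|) of every degree of freedom across
a pool. Chemical-shift agreement uses 30-bin histograms over the predicted
mean ± four predicted standard deviations, with 1e-6 pseudocounts in empty
bins and renormalization, compared by the symmetrized Kullback–Leibler
divergence (natural log); RMSD_CS is the plain RMS over (residue, proton)
records present in both tables, with unmatched records reported. Residues
in a WC pair are tagged helical.

## Synthetic fixtures

The hairpin generator builds WC-paired stems by stacking base-pair frames
along a helix. Bases are idealized planar polygons (regular rings,
bisector-placed substituents); the central hydrogen bond of each pair is
placed colinear at 2.1 Å, and both C1′ atoms sit at a common height off
the pair axis so purine and pyrimidine strand assignments share one
helical lattice. The stacking parameters (twist, rise, displacement,
inclination, χ, γ, β and the stem pucker) are calibrated numerically so
consecutive stem residues connect through an ideal-length O3′–P bond with
the ζ and α crossing torsions at their A-form values (−71° and −68°); ε is
the compliant torsion that absorbs the idealization error. Because the
covalent geometry is idealized rather than fiber-averaged, the calibrated
twist and rise differ from fiber A-RNA values — the fixture is an
internally consistent WC-paired helix, not a crystallographic one. Loops
grow by natural-extension chaining and are re-closed onto the 3′ stem with
the same damped pseudoinverse iteration the rebuild move uses; loop base
orientations are then swept about their glycosidic bonds to relieve steric
overlap, and the free phosphate oxygens are rebuilt from the final
backbone. Generation retries deterministically-jittered loop torsions
until the structure closes and passes the half-radii clash check.

What the fixture does not emulate: sequence-dependent helical parameters,
stacking energetics, non-canonical pairs, solvent. Tests passing on it
show that the kinematic machinery is correct, not that sampled ensembles
reproduce solution behavior of real RNA.

The RDC fixture is described above. Default problem sizes in the tests and
the acceptance script (a 12-nt hairpin, pools of a few hundred samples,
10^4 dispatch attempts, 10^5 pucker draws) were chosen as the smallest
sizes at which the measured rates and distributions are statistically
stable.

## Known limitations

* Only canonical A·U and G·C pairs become constraints; wobble pairs are
  skipped with a warning, and stacking is not detected.
* The cumulative closure gate bounds how far stems can flex; exploration
  beyond that is carried by loop rebuilds.
* τ has a branch cut at ±180° (far-west puckers are reported as an
  overshoot), and sugar re-embedding idealizes ring geometry to the
  embedding family.
* One chain, standard nucleotides, PDB format only.
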