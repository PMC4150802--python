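# rnakin

Torsion-space kinematic conformational sampling for RNA, with hydrogen-bond
closure constraints, ribose-pucker rebuilds, and a constrained quadratic
program that selects parsimonious conformational ensembles from residual
dipolar couplings (RDCs).

`rnakin` is aimed at structural-biology users who want broad, physically
constrained conformational ensembles of non-coding RNA orders of magnitude
faster than molecular dynamics: NMR ensemble analysis, flexibility profiling
of hairpins and pseudoknots, and ensemble selection against RDC data.

## The model

An RNA molecule is represented by its rotatable single bonds. Atoms joined
by non-rotatable bonds (ring and partial-double bonds, plus atoms with a
single covalent neighbor) merge into rigid bodies; a rooted, directed
spanning tree over the bodies carries one torsional degree of freedom per
edge — the backbone angles α, β, γ, ε, ζ and the glycosidic angle χ. The
sugar angle δ is not an independent torsion: each ribose ring is driven by a
single differentiable pucker coordinate τ, an affine recoding of the
pseudorotation phase calibrated so τ = −154° is C3′-endo and τ = +44.7° is
C2′-endo.

Every canonical Watson–Crick pair contributes a hydrogen-bond distance
constraint — U(N3)–H3···A(N1) or G(N1)–H1···C(N3) — that closes a kinematic
cycle. Differentiating the positions of the donor hydrogen and the acceptor
along both branches of each of the *m* cycles yields the 6m × n Jacobian
**J** of the instantaneous relation dx = **J** dθ. Because both constrained
endpoints lie on the hydrogen-bond axis, each generic cycle removes five
degrees of freedom, and the right singular vectors of **J** with vanishing
singular value span the (n − 5m)-dimensional null space **N**.

Two complementary moves grow a conformational pool:

* **null-space move** — a random trial vector Δθ is projected,
  θ_new = θ_seed + **N N**ᵀ Δθ, rescaled so no torsion changes by more than
  0.1 rad, applied, and *verified*: if any constrained endpoint moved more
  than ε (0.05 Å) the move is rejected;
* **rebuild move** — a free (unpaired) segment of two nucleotides has its
  ribose puckers redrawn from the bimodal mixture
  P(τ) ∝ 0.6 N(−154°, 11.5°) + 0.5 N(44.7°, 17.2°), its glycosidic angles
  randomized, and its 3′ O3′–P bond resealed by damped Moore–Penrose
  pseudoinverse iterations over the segment backbone torsions.

Moves are dispatched at a 10/90 rebuild/null-space rate; seeds are drawn by
a shell rule that favors sparsely populated regions within the exploration
radius (C4′ RMSD to the start), and candidates enter the pool only if free
of hard-sphere clashes at half van der Waals radii.

Given observed couplings ¹D_obs and per-conformer back-calculated vectors
¹D_i, the ensemble fit solves

    min_w || ¹D_obs − Σ_i w_i ¹D_i ||²   s.t.  w_i ≥ 0,  Σ_i w_i ≤ 1

with a deterministic active-set method; the support of w is the ensemble
and the weights are its populations.

## Worked example

Generate an idealized 4-bp/4-nt hairpin fixture and sample 50 conformations
inside a 3 Å exploration radius:

```sh
rnakin fixtures hairpin --stem 4 --loop 4 --seed 1 --out fix/
rnakin sample --pdb fix/hairpin.pdb --pairs fix/pairs.tsv \
       --radius 3.0 --n 50 --seed 11 --out run/
```

which prints

```
wrote fix/hairpin.pdb (12 nt, 4 WC pairs) and fix/pairs.tsv
accepted 50 samples in 633 attempts (rebuild fraction 0.109); wrote run/samples.pdb
```

The 633 attempts reflect the explicit closure/clash gates (null-space moves
at the full 0.1 rad cap are often rejected by the 0.05 Å hydrogen-bond
verification); the rebuild fraction sits at the configured 10% dispatch
rate. `run/samples.pdb` holds the pool as a multi-model PDB, with
provenance and per-attempt logs in the accompanying TSV files.

Fitting a synthetic two-member ensemble from RDC tables:

```sh
rnakin rdcfit --observed obs.tsv --candidates 'cand_*.tsv' --out weights.json
# -> ensemble of 2 members, R^2 1.000, RMSD 0.000 Hz -> weights.json
```

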