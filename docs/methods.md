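# Methods

## Model

`allofep` implements a statistical-mechanical model of allostery on a Cα
elastic network. The central assumptions:

- **One reference structure.** Both the ligand-free and the ligand-bound
  systems are harmonic expansions about the *same* reference coordinates
  (a "ground-state model"). The computed free-energy differences are
  therefore purely configurational-entropic: they measure changed dynamics,
  not conformational change.
- **Indirect binding.** A bound ligand is represented only by stiffening all
  pairwise springs inside its binding site by a factor α. No ligand atoms,
  chemistry, or binding poses enter the model; the site definition is the
  only ligand-specific input.
- **Harmonic, unit-mass, Cα-only.** Modes are plain eigenvectors of the
  energy Hessian with every Cα given unit mass. The energy conventions are
  kept literal: the base network energy carries no ½ prefactor while the
  site term does, so a site pair's effective constant is k(1 + α/2)
  (configurable via `site_term_half`; at α = 100 the distinction from
  k(1 + α) is ~1 %).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `enm_cutoff` | 25 | Å | pair inclusion cutoff of the base network |
| exponent | 6 | – | force-constant decay k = k0·(d⁰)⁻⁶ |
| `k0` | 1 | kcal/mol/Å² ·Å⁶ | global spring scale; cancels exactly in Δg and ΔG (eigenvector shapes and eigenvalue ratios are scale-invariant), kept for unit bookkeeping |
| `alpha` | 100 | – | site stiffening; chosen large enough that the ligated site is effectively rigidified — site-mean Δg grows monotonically in α (see the α-sweep in the acceptance script) |
| `n_modes` | 10 | – | internal modes summed per system, counted after removing rigid modes; each system uses its own lowest modes (no mode matching) |
| `d_c` | 11 | Å | neighborhood radius of the allosteric potential, evaluated on the shared reference |
| `c` | 1 | kcal/mol/Å² | intensity scale; enters both systems identically and cancels in Δg |
| temperature | 300 | K | kT ≈ 0.5961 kcal/mol; sets the output scale only |
| `rigid_tol` | 1e-8 | – | eigenvalues below rigid_tol·λ_max are classified rigid |

## Numerical choices

- **Eigensolver.** Dense `scipy.linalg.eigh` up to 800 residues, shift-invert
  `eigsh` beyond; both paths are cross-checked against each other in the
  suite. Mode vectors get a deterministic sign (largest-magnitude component
  positive) so reruns are byte-identical.
- **Rigid modes.** A connected structure must show 5 (exactly collinear
  toys) or 6 near-zero modes; more triggers a diagnostic error reporting the
  connected components of the spring network, fewer an ill-conditioning
  error.
- **Degeneracy.** Symmetric oligomers produce degenerate eigenvalue
  multiplets whose individual eigenvectors are basis-arbitrary. Per-mode
  quantities inside a multiplet are therefore basis-dependent; their
  multiplet sums are not (verified by randomly remixing multiplets). Summed
  profiles over a mode window that splits a multiplet should be read with
  care; the run log records the eigenvalue heads so such splits are
  auditable.
- **Near-zero intensities.** A residue whose d_c-neighborhood moves rigidly
  in some mode has ε ≈ 0 and an unstable log-ratio. Intensities are floored
  at 1e-12 × median(ε) and the residue flagged (`eps-floored`); residues
  with *no* neighbor inside d_c get undefined Δg (`no-neighbors`) and are
  excluded from averages rather than poisoning them.
- **Modulation formula.** ΔΔg defaults to the difference of two Δg profiles,
  Δg(0→n) − Δg(0→m) — the form every worked cooperativity number takes; the
  literal log-ratio ln[ε⁽ⁿ⁾ε⁽⁰⁾/(ε⁽ᵐ⁾)²] (which differs by the m-vs-free
  term) is available as `formula="eq17"` / `--modulation-formula eq17`, and
  analogously for the global ΔΔG.
- **Site detection.** With full heavy-atom records a residue joins a
  ligand's site if any heavy atom lies within the contact cutoff (4.5 Å
  default); with Cα-only input the criterion is Cα within cutoff + 3.0 Å,
  the 3 Å standing in for typical side-chain reach. The mode used is
  recorded on the site. This contact rule is a documented convention of the
  package — published site definitions, where available, can be supplied
  explicitly instead.
- **Chain grouping.** Chains with ≥ 95 % global sequence identity are
  grouped as homologous monomers; per-aligned-position means and standard
  errors across a group give the monomer-averaged profile. Positions absent
  from any chain of a group (deletions) are dropped.

## Synthetic data

The fixture generators produce seeded, manifest-backed toys: an ideal
α-helix (rise 1.5 Å, 100° twist, 2.3 Å radius), a random globule
(rejection-sampled, ≥ 3.5 Å separation, radius ≈ 3.1·N^⅓ Å giving
protein-like packing density), an exact C2 dimer, a two-domain hinge, and a
disconnected pair. The hinge — two globules joined by a three-residue
zigzag linker about 10 Å of gap apart — is the minimal allosteric
caricature: restraining a four-residue surface patch on domain A measurably
perturbs domain B. The linker is zigzag and the gap short deliberately: an
exactly collinear linker produces bending modes so soft they collide with
the rigid-mode threshold. The globule ligand is draped over an outermost
residue and its two nearest neighbors so its contact set is a genuine
multi-residue patch for every seed.

What the toys do **not** emulate: secondary-structure topology, a native
fold's spectral gap between collective and local modes, realistic binding
pockets, or crystallographic artifacts. Passing tests therefore validate
the mathematics and the pipeline mechanics, not biological accuracy on real
assemblies. One visible consequence: on toys, profiles computed with 10 vs
50 modes correlate only moderately (Pearson r ≈ 0.3–0.9 across seeds),
because 40 extra modes are a quarter of a 60-residue toy's internal
spectrum — in a real protein they are under one percent, and each mode
enters Δg with equal weight.

## Problem sizes

The test suite and acceptance script run on 10–60-residue toys (hinge 60,
globule 30, dimer 40, oracle fixtures 10–20), sizes at which dense
diagonalization and the deliberately naive O(N²)–O(N⁴) oracles are
instantaneous; the pipeline itself handles thousands of residues via the
iterative solver.

## Known limitations

- No mass weighting, no anharmonicity, no solvent; α is a phenomenological
  dial, not a fitted interaction strength.
- Absolute Δg magnitudes depend on the mode count and on site definitions;
  comparisons are most meaningful within one run (site vs protein mean,
  residue vs residue, m vs n ligands).
- Agonist/antagonist identity of a ligand is outside the model's scope: the
  same restraint represents any occupant of the site.
- Assemblies are taken as given; no symmetry expansion or structure repair
  is attempted.
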