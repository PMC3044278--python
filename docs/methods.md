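# Methods

## Model and assumptions

The package treats a single static protein structure as an undirected,
weighted network: one node per amino acid, plus one node per bound non-water
hetero-group unless the user merges it into a residue or excludes it. A
signal initiated at one node performs a discrete-time random walk whose
one-step probabilities are proportional to inter-residue contact affinities.
The walk is made absorbing at a node *k*; the fundamental matrix
`F^k = (I − T^k)⁻¹` then gives expected visit counts before absorption, and
the expected visiting time (EVT) averages these counts over every possible
absorbing node. The underlying assumptions are:

- signal transmission strength between residues scales with the number of
  heavy-atom contacts, normalised for residue size
  (`a_ij = N_ij / √(N_i N_j)`);
- all routes matter: allosteric communication is treated as diffusion over
  the whole network, not as one or a few optimal paths (the shortest-path
  SVT baseline exists precisely to test this assumption);
- a single conformation suffices; no ensemble averaging and no prediction of
  the direction or magnitude of conformational change, only of which sites
  carry signal.

Because the affinities are symmetric, the non-absorbing walk is reversible
with stationary distribution `π_i ∝ d_i`; the test suite asserts
`‖πT − π‖∞ < 1e-10` as a conservation check.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 8.0 Å | heavy-atom contact distance; sensible range 3–12 Å. 8 Å is used throughout because profiles are robust in the 6–12 Å band (the `scan-cutoffs` operation measures this robustness directly) while short cutoffs rewire the network qualitatively. |
| `ligands` | `include` | each non-water hetero-group is its own node, so chromophores and cofactors can serve as initiation sites. |
| `merge` | none | folds a hetero-group's atoms into a covalently linked residue (one node, summed heavy count) — e.g. retinal into Lys296 of rhodopsin, giving the conjugated "LYR296" initiation node. |
| `component_policy` | `error` | a disconnected contact graph makes `I − T^k` singular; the default refuses and names the offending nodes, `largest` reduces to the largest component explicitly. |
| `MIN_MUTATIONS` | 3 | complexes with fewer alanine mutations are dropped before regression; with two points the correlation is identically one and carries no information. |

## Numerical choices

- **Contact test**: closed boundary (`d ≤ cutoff`). Counting uses a k-d tree
  (`scipy.spatial.cKDTree`) and is tested against an explicit
  O(n²·atoms²) double loop.
- **Fundamental matrices** are obtained by LU factorisation and linear
  solves against the identity, never by forming an explicit inverse first; a
  reciprocal-condition estimate (LAPACK `gecon`) triggers a warning above a
  condition number of 1e12 and an error when the system is singular.
- **Diagonal conventions**: when building `M`, the absorbing row of each
  extended `F^k` is 0 and the absorbing column is 1; at the (k, k) entry the
  column convention wins, so the initiation-equals-absorbing chain
  contributes exactly one visit at k. Every entry of `M` is therefore
  ≥ 1/n.
- **z-scores** use the population standard deviation (divisor n) over one
  profile (one row of `M`); normalising per profile rather than over the
  whole matrix is a deliberate choice — the profile is the object that mimics
  one perturbation — and the initiation node's own value is included in
  μ and σ. A constant profile is an error, not a silent zero.
- **Hop distances** (for scaled profiles and the SVT baseline) are unweighted
  shortest-path lengths on the binary contact graph. SVT counts **all** tied
  shortest paths; each path credits every node it contains except the start,
  and the endpoint once, mirroring the EVT entering-once convention; the
  same 1/n averaging keeps SVT and EVT directly comparable.
- **Altlocs**: for each atom name the highest-occupancy conformer is kept,
  ties broken by alternate-location code order; only the first MODEL of
  multi-model files is read. Hydrogen means element H or D, inferred from
  the element column with an atom-name fallback. These rules are
  deterministic but not uniquely mandated by the science, so profile values
  on real structures can shift slightly under different conventions.
- **Hot-spot regression** is ordinary least squares of ΔΔG on the z-scored
  average-EVT traffic of the mutated wild-type residues, one model per
  complex (pooling across complexes would answer a different question).
  Reported: slope, intercept, correlation between fitted and observed ΔΔG
  (equal to |r(x, y)| for a single predictor — asserted in tests), residual
  standard error with n−2 degrees of freedom, and the overall-F p-value.
  Residue-to-node matching is exact on chain + residue number + insertion
  code; a miss is an error naming the residue.

## Synthetic data

`evtnet.toys` generates PDB-format structures whose contact graph at 8 Å is
*exactly* a requested topology (path, ring, star, grid, or a custom embedded
edge list): node centres 7 Å apart for bonded pairs, each "residue" a cluster
of heavy atoms within 0.45 Å of its centre, offsets drawn from a seeded
scrambled Sobol sequence so output is deterministic and byte-reproducible.
The generator brute-force-verifies the realised contact graph and refuses
geometrically unrealisable specs. `random_connected_network` additionally
draws abstract connected affinity networks (integer contact counts 1–6,
heavy counts 3–9) for oracle cross-checks without any geometry.

These fixtures emulate the *network* properties the method consumes — exact
topology, size-heterogeneous nodes, weighted edges — and deliberately not
protein geometry: no secondary structure, no realistic packing density, no
ligand chemistry, no missing atoms or disorder. Passing tests therefore
demonstrate that the Markov machinery, profile transforms and regressions
are computed correctly, and that profiles are robust across cutoffs on these
networks; they do not by themselves validate biological conclusions on real
structures. For that purpose the suite contains two further checks that run
when deposited rhodopsin (2J4Y) and LOV2 (2V0U) coordinate files are placed
under `data/`: published per-residue z-EVT values within ±0.15 and cutoff
correlations above 0.8. The ±0.15 slack acknowledges the reconstruction
choices above (affinity formula wording, altloc handling).

The Monte-Carlo oracle simulates absorbing walks directly from `T`
(vectorised over walks, counting every arrival, absorbing node counted once
on entry, per-walk step cap 1e7) and shares no code with the linear-algebra
path; the acceptance-level test requires every entry of `M` on ten random
networks (n ≤ 8) to lie within three standard errors of the oracle at
200,000 walks.

## Problem sizes

The default validation suite uses networks of 2–9 nodes for exact checks,
n ≤ 8 for the 200,000-walk oracle comparison, a 36-node grid for the cutoff
scan, and 500 synthetic complexes for regression recovery; the acceptance
script mirrors these sizes with a 50,000-walk oracle pass. On real
structures the dense per-absorbing-node solves cost O(n⁴) overall, which for
a typical single-chain protein (n ≈ 350 including a ligand node) takes a few
seconds.

## Known limitations

- Edge weights are purely contact-count based: no hydrogen-bond, energetic
  or covalent-bond awareness beyond what the merge map expresses.
- Single-structure, single-conformer: dynamics enter only implicitly through
  the long cutoff.
- The affinity formula is the size-normalised contact count; other
  normalisations would change absolute EVT values (though profile shapes are
  empirically robust across cutoffs).
- SVT path-counting conventions (start excluded, endpoint counted once) are
  stated choices; other conventions shift the baseline but not the EVT
  model.
- mmCIF input is not supported; structures must be PDB-format text.
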