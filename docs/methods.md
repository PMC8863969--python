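# Methods

## Elastic networks and the two-state potential

Each end state is reduced to its Cα trace and equipped with an anisotropic
network model: nodes i and j are connected iff their reference distance
satisfies R⁰_ij ≤ r_c (boundary inclusive), and the energy is
U_S(R) = (γ/2) Σ (R_ij − R⁰_ij)² over the contacts of state S.  Contact sets
are fixed from each state's reference once and never recomputed for
intermediate conformers, so the two surfaces differ both in topology and in
reference distances; this is what makes the mixed potential bistable.
Units: distances in Å, γ in kcal/(mol·Å²), energies in kcal/mol; no thermal
scaling is applied.  γ rescales all energies uniformly and does not change
the pathway.

The two surfaces combine as U = ½(U_A + U_B − |U_A − U_B|), i.e. exactly
min(U_A, U_B); the absolute value is used instead of √((U_A−U_B)²) to avoid
cancellation noise.  U is continuous but non-smooth on the cusp hypersurface
{U_A = U_B}.  Membership of the cusp is decided by an absolute gap
tolerance ε† in kcal/mol (the natural reading of a bare-number tolerance
compared against energies in kcal/mol).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| r_c | 13 | Å | contact cutoff of both networks |
| γ | 0.1 | kcal/(mol·Å²) | uniform spring constant |
| M (`n_images`) | 50 | – | interpolation images seeding the cusp search |
| ε† (`eps_cusp`) | 5·10⁻⁵ | kcal/mol | gap tolerance defining the cusp |
| ε_conv | 10⁻⁴ | kcal/mol | transition-state energy convergence |
| s_A, s_B | 1.0 | – | initial steepest-descent step sizes |
| `step_shrink` | 0.5 | – | step reduction on a failed step |
| `collect_rmsd` | 0.1 | Å | conformer collection spacing |
| `descent_force_tol` | 10⁻⁶ | kcal/(mol·Å) | descent termination (force max-norm) |

Only the cusp-crossing seed depends on M; on the canonical hinge system the
refined transition-state energy changes by ~10⁻⁷ kcal/mol between M = 30 and
M = 50 (tested for two M values on a smaller system as well).

## Transition-state search

From the current cusp point R†(n), one steepest-descent step is taken on
each surface (R^A = R† + s_A f_A, R^B = R† + s_B f_B).  Because each
endpoint moved downhill on its own surface, the segment [R^A, R^B] normally
brackets a sign change of the gap; bisection along it (at most 200 halvings)
yields R†(n+1) with |U_A − U_B| ≤ ε†.  Convergence is declared when the cusp
energy changes by less than ε_conv between iterations — this check runs
before the energy-increase check, so a converged point that fluctuates by
less than ε_conv is accepted rather than triggering endless step shrinking.
If the segment fails to bracket the cusp, or the energy rises by ε_conv or
more ("spanning the saddle"), both step sizes are halved and the step is
retried from the current point; step sizes below 10⁻¹² abort the search.

## Steepest descents and conformer collection

Each descent acts on a single surface with backtracking: a trial step
R + s·f is accepted only if the surface energy does not increase, otherwise
s is halved and the step retried; after an accepted step s recovers (doubles,
capped at its initial value) so an early shrink does not slow the remainder.
Conformers are collected whenever the plain shared-frame RMSD from the last
collected conformer reaches `collect_rmsd`; the start (transition state) and
the final minimum are always included, so only the terminal pair of each
branch may sit closer than the spacing.  Collected single-surface energies
are non-increasing by construction.

Termination is on the force max-norm, not on the per-step energy decrement.
The decrement of a fixed-step descent scales as s·|f|², which becomes tiny
on the soft collective modes that dominate hinge motions long before the
minimum is reached (measured on the hinge fixture: an ε_conv decrement test
would stop ~10 Å short of the end state).  The force max-norm measures
distance to stationarity directly.

A subtlety worth knowing: finite steepest-descent steps are individually
free of net force and torque (the ANM energy is rigid-motion invariant), yet
their composition along a curved path accumulates a small net rigid rotation
— a geometric phase, like a falling cat reorienting with zero angular
momentum.  The descent therefore reaches the end minimum in a very slightly
rotated frame (≈0.2 Å apparent shared-frame RMSD on the hinge fixture at an
on-surface energy of 3·10⁻⁸ kcal/mol).  Endpoint recovery is accordingly
assessed with best-fit (Kabsch) RMSD, the frame-free measure; collection
spacing along a descent remains shared-frame, where consecutive iterates are
genuinely co-oriented.

## Superposition

Rigid superposition uses the least-squares rotation from
`scipy.spatial.transform.Rotation.align_vectors` (proper rotation
guaranteed); the reported RMSD is recomputed from the transformed residuals
rather than from the solver's residual shortcut, which loses ~10⁻⁷ Å to
cancellation on near-exact matches.  Point sets with fewer than three
residues, or with rank < 2 after centering (collinear), are rejected.  Tests
cross-check against Horn's closed-form quaternion solution, an independent
algorithm family.

## Analyses

The reaction coordinate of conformer R(n) is
x(n) = d⁽⁰⁾·v(n)/|d⁽⁰⁾|² with v(n) = R(n) − R_A and d⁽⁰⁾ = R_B − R_A, so the
end states map to exactly 0 and 1 and rigid interpolation image k maps to
k/(M−1).  Energy tables re-evaluate every conformer from its coordinates and
fail loudly (integrity error) if cached values disagree beyond 10⁻⁹.
Residue-pair distances and the acute inter-segment angle
(arccos|û₁·û₂| ∈ [0°, 90°]; lines are undirected, so parallel and
antiparallel both read 0°) are frame-invariant.  Cosine cross-correlation
maps C_ij = cos(h_i, h_j) are offered from two displacement sources — the
deformation between consecutive path conformers, or a low-frequency ANM
eigenvector of one end state — selected explicitly by the caller because
they answer different questions (what moved at that moment vs. what the
state's topology prefers to move).  Residues with displacement norm below
10⁻¹² have no defined direction and are reported as NaN (empty CSV cells),
never as 0.  Conformer indices are 1-based in all written tables, 0-based in
the API.

## Synthetic two-state systems

The canonical generator builds two internally rigid arms sharing a vertex
residue, opened at 60° (state A) vs 140° (state B), 30 residues per arm,
consecutive Cα spacing 3.8 Å, no jitter, seed 42.  The arms are ideal
α-helix Cα traces (2.3 Å radius, 1.5 Å rise, 99.1° twist per residue,
rescaled to the requested spacing) rather than straight lines: a collinear
bead chain has zero quadratic bending stiffness in a distance-based network,
which would leave each end state's minimum degenerate along the hinge
coordinate — a few locally bent vertex residues could satisfy every
cross-arm contact without moving the arms.  Helices triangulate their own
contacts, so each end state is an isolated minimum, as for a real fold.  The
resulting inter-state RMSD is 13.6 Å, a realistic large closure motion.

The generators are pure functions of their spec including the seed (state A
jitter drawn before state B; the draw order is part of the contract).  A
second generator produces a self-avoiding random chain (3.8 Å steps, 3.0 Å
excluded-volume floor) plus a smooth three-mode cosine displacement field
rescaled to an exact RMS amplitude, for stress tests.

What the synthetic systems do **not** emulate: side chains, sequence
heterogeneity, membrane anisotropy, multiple metastable intermediates, and
the dense irregular contact networks of real folds.  Passing tests on them
demonstrates the correctness of the machinery (superposition, cusp search,
descents, analyses), not the biological fidelity of any particular pathway.

## Problem sizes and costs

The test suite and the acceptance script run the full pipeline on the
61-residue hinge (≈500/450 contacts per state; ~10 s), a 21-residue hinge
for repeated builds, and 2–20-node toys for closed-form and grid-search
oracles.  These sizes keep every oracle exhaustive (10⁶-point line scans,
~4·10⁵-point cusp grids, full finite-difference gradients) while the whole
suite stays around half a minute.

## Known limitations

- The cusp potential has no off-diagonal coupling; barrier heights are
  meaningful relative to one another (e.g. vs. rigid interpolation), not as
  absolute free energies, and γ sets only the overall scale.
- Steepest descent converges linearly; very soft systems may need the
  iteration budget (`max_descent_iterations`, default 2·10⁵) raised.
- If the two networks order the surfaces identically along the whole
  interpolation (no gap sign change) the cusp seed does not exist and the
  run aborts with both endpoint gaps reported; this happens when the end
  states are too similar or the mapping is wrong.
- Mappings must be supplied explicitly when author numbering differs between
  the end-state models; no sequence alignment is attempted.
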