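# Methods

## Model and pipeline

The pipeline predicts a steady-state flux distribution for a
metabolic network under a measured proteome, in five stages.

1. **Proteome processing.** Replicate intensities (strictly positive)
   are normalized per condition so that a chosen replicate statistic
   (total intensity by default; median or none selectable) equals the
   condition mean of that statistic. Per-protein log2 fold changes
   are ratios of condition means; significance uses Welch's
   unequal-variance two-sample t-test. A protein is differentially
   expressed (DE) when |log2FC| > 1.2 *on the log2 scale* and
   p < 0.05 (raw p-values by default; Benjamini–Hochberg optional,
   off by default). The 1.2 threshold is applied to the log2 value as
   literally defined, not to the raw ratio; both the threshold and
   alpha are parameters.

2. **GPR evaluation.** Gene–protein–reaction rules are Boolean trees
   (AND/OR over gene leaves, AND binding tighter than OR). Against an
   expression map they evaluate AND → min, OR → max. Missing genes
   follow a policy: under the default `unbounded` policy an
   unmeasured OR-branch is ignored when a measured sibling exists
   (the measured isoenzyme is evidence), while an unmeasured
   AND-child makes the complex unmeasured and the constraint is
   dropped; `zero` treats missing as level 0; `ignore` drops missing
   leaves everywhere. The choice matters only for partially measured
   complexes, which the data model cannot resolve in principle.

3. **Expression bounds.** A reaction whose GPR evaluates to level *p*
   gets bounds (−s·p, +s·p) if reversible and (0, +s·p) if
   irreversible, with scale *s* = 1 by default (expression units are
   used as flux units directly; the proportionality constant is a
   free parameter of the method). Bounds are *not* intersected with
   the model defaults unless `cap_at_default` is set — the mapping
   replaces the default bounds outright; the cap option exists
   because an abundant protein can otherwise widen the flux space
   beyond the model's physical limits. Reactions without GPR
   (exchanges, spontaneous reactions) keep their model bounds;
   default bounds for otherwise unconstrained reactions are ±1000
   arbitrary flux units (community convention; units are nominally
   mmol·gDW⁻¹·h⁻¹ but never enforced).

4. **Two-stage LP.** Biomass is maximized subject to S v = 0 and the
   bounds; the optimum Z\* is then fixed as the constraint
   c'v ≥ γ·Z\* (γ = 1 by default, relaxed by 1e-9 relative to absorb
   solver round-off) and Σ|vᵢ| is minimized after splitting
   v = v⁺ − v⁻ with component-wise box bounds
   v⁺ ∈ [max(L,0), max(U,0)], v⁻ ∈ [max(−U,0), max(−L,0)], which
   reproduce L ≤ v ≤ U exactly, including strictly positive lower
   bounds. Both LPs are solved with HiGHS through scipy on a single
   thread with a fixed variable order, so repeated runs are
   bit-reproducible. L1 minimization does not strictly guarantee a
   unique argmin (the set of L1-minimal optima can still be a face);
   determinism of the solver, not uniqueness of the polytope vertex,
   is what makes results reproducible. The sum runs over all
   reactions by default; an exclusion set (e.g. exchanges) is
   accepted.

5. **Mutants.** Knockout sets a reaction's bounds to (0, 0);
   overexpression multiplies both bounds by a factor ≥ 1 (default 2).
   These are reaction-level operations; a gene-level knockout wrapper
   re-evaluates GPRs with the deleted genes forced to zero and knocks
   out reactions whose rule evaluates to 0.

## Comparative analysis

Fluxes v > 0 are transformed to log2(v) and divided by the sample SD
(ddof = 1) of the log2 values of the strictly positive fluxes of
*that* dataset; each condition is normalized by its own SD before
pairing. Fluxes ≤ 0 (zero or reverse flux), for which the transform
is undefined, are carried at their original value and classified
`nonpositive`; they count toward totals but not toward the numeric
comparison. The fold change is the difference of normalized values
(condition minus control).

The significance cut-off is data-driven: the smallest candidate c on
a 0.001-step grid such that #{|fc| > c} / n_total < 30%. The grid
starts at 0.001 rather than 0 because a zero cut-off would call any
nonzero change significant. By construction the classification never
exceeds the 30% proportion, and the exceedance count is
non-increasing in c, so the returned candidate is minimal. When all
finite fold changes are zero the smallest candidate is returned and
nothing is flagged.

Pathway summaries count classes per subsystem and per category tag
(carbon / nitrogen / anabolic / catabolic / exchange). The C/N ratio
is the affected-reaction proportion among carbon-tagged reactions
divided by that among nitrogen-tagged ones (reported as undefined
when either side is empty or the denominator is zero), with the
inverse reported alongside. The KEGG Mapper export writes one
"KEGG-id color" line per annotated reaction: blue = up, red = down,
lightgreen = unchanged, gray = nonpositive.

## Synthetic data

`make_toy_model` composes motifs with known LP behavior: a capped
uptake (cap 10 by default) feeding an n-step linear chain (n = 3)
into a biomass sink — optimum = cap, minimal total flux =
cap·(n + 2) — plus optional two-reaction detours parallel to the
first chain step (degenerate at the FBA stage, idle after L1
minimization) and three-reaction futile cycles (driven to zero by L1
minimization). Chain step 1 carries an AND complex, step 2 an OR
isoenzyme pair, later steps single genes, so all GPR semantics are
exercised on the biomass path.

`make_proteome` draws replicate intensities log-normally: per-protein
baselines spread log-uniformly within ±1 log2 around a mean of 50,
replicate noise N(0, σ) in log2 units with σ = 0.2, three replicates,
two conditions (control T35, stress T22). A fraction (10% by
default) of proteins is shifted by +2 log2 units in non-control
conditions; injected identities are recorded as ground truth. These
defaults give a t-test sensitivity ≥ 0.9 at a ~0 false-positive rate,
which is the regime the DE-recovery checks target. The
`stress_bundle` variant instead pins the DE set to the biomass-path
genes and downshifts them by −4 log2 units — more than the ±1 log2
baseline spread, so every shifted level lands below the uptake cap
and the stress optimum falls below control for every seed.

What the generator does *not* emulate: peptide-level artifacts,
missing values, intensity-dependent variance, batch effects, or
genome-scale network size (thousands of reactions). Passing tests
therefore demonstrate correctness of the algorithms and their
contracts, not robustness to real proteomics pathologies or
genome-scale numerical conditioning.

A second generator, `make_random_model`, emits random sparse
stoichiometries (≤ 12 reactions, bounds containing zero so v = 0 is
always feasible) for cross-checking the LP layer against an
independent solver route.

## Numerical choices and degenerate inputs

- LP feasibility/optimality: HiGHS defaults (~1e-9 primal);
  assertions compare at 1e-6 relative.
- pFBA biomass retention: γ·Z\* relaxed by 1e-9·max(1, |Z\*|).
- SD normalization with fewer than two positive fluxes is undefined;
  the constant 1.0 is substituted with a warning.
- A correlation of constant flux vectors is reported as NaN with a
  warning rather than raised.
- Proteins with fewer than two replicates in either group are
  excluded from the t-test with a warning.
- Validation reports (never raises) structural errors: inverted
  bounds, dangling metabolite references, duplicate ids, missing
  biomass/objective, negative lower bounds on irreversible reactions.

## Known limitations

- On the toy chain, all active fluxes scale together, so
  condition-vs-condition fold changes are nearly uniform and the
  <30% cut-off rule then classifies nothing as changed — a
  degeneracy of the symmetric fixture, not of the method. Networks
  with branch points (or mutants that reroute flux) produce
  non-trivial classifications.
- The L1-minimal solution is unique only up to the solver's
  deterministic tie-breaking.
- SBML support covers Level 3 + fbc gene associations and stores
  subsystem/category annotations in notes; exotic SBML constructs
  are out of scope. The JSON dialect is the canonical lossless
  format; the TSV dialect writes float reprs to stay lossless.
- Compartments are carried as metabolite tags only; no transport or
  compartment-consistency logic depends on them.
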