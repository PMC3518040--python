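# Methods

## Model representation

The yeast apoptosis model is a *timed signed logical hypergraph*. A
hyperarc is an AND-conjunction of signed literals producing one target; the
update rule of a species is the OR over its producing hyperarcs (the
standard logical-hypergraph convention — the interaction tables alone do
not define a combination rule, and OR is the only choice under which a
table of independent literature-derived interactions composes). Species
with no producing interaction at the current timescale cutoff default to 0,
which reproduces the all-zero non-input column of the model at t = 0.
Inputs and the housekeeping constant are boundary conditions: the nine
stimulus rows and the single declared-output row of the interaction table
are kept as bookkeeping pseudo-arcs (so the census of 115 interactions and
its timescale distribution 16/9/60/18/12 over t = 0/2/4/5/6 are preserved)
but take no part in value updates — stimulus values are set by the
scenario at every cutoff, matching the published steady-state table in
which inputs are 1 already at t = 0.

Two interactions carry a leading stoichiometric coefficient
("2 CDC48 = ROS-CYT", "2 NDI1 = ROS-CYT"). Boolean logic has no
stoichiometry; reading them as plain activations would switch cytosolic ROS
(and through it the Apoptosis output) on in *every* scenario, because
Cdc48 is housekeeping-fed — contradicting the model's own no-stimulus
survival behaviour and the Bir1-overexpression control. The cited biology
for both arcs concerns *overexpression* phenotypes, so the coefficient is
interpreted as an overexpression dose requirement: the arcs are retained in
the network (they count in the census and in structural analyses) but
never fire at ordinary Boolean levels (`dose_gated`).

Timescales 1 and 3 are accepted by the types but unused (reserved).

## Logical steady states

`compute_lss` computes the least fixed point of the three-valued (Kleene)
update: start from the clamped boundary with all other species
undetermined; set a species to 1 as soon as one active arc evaluates to 1,
to 0 once every active arc evaluates to 0 (or none exists); iterate to
convergence. The iteration is monotone in the information order, so it
terminates after at most |species| sweeps and is order-independent.
Species left undetermined take cycle-dependent values. Soundness: if the
fixed point determines a value, one can show by induction on sweeps that
every synchronous trajectory satisfies it after finitely many steps, hence
every state of every attractor carries it — the property the brute-force
oracle checks on random networks.

A three-valued fixed point was chosen over seeded binary iteration so that
feedback-dependent species are reported honestly. The concrete case: under
heat stress alone, the Hog1 → Hog1-dependent-genes → Ptp3 ⊣ Hog1 negative
loop has no classical point value; the LSS reports `?` and the synchronous
trajectory oscillates with period 6.

Snapshot tables recompute an independent LSS per cutoff (each column is
"all interactions with t ≤ x"), rather than chaining columns. Synchronous
trajectories update all species simultaneously with inputs/clamps held;
asynchronous schemes are out of scope. All tie-breaks are deterministic:
species are processed in species-table order, attractors are sorted by
their lexicographically smallest state.

`enumerate_attractors` compiles the free species into bitmask transition
functions and exhaustively traverses the 2^f transition graph (default
bound f ≤ 22), returning points, cycles and exact basin sizes. It is
tested against an independent dict-based orbit tracer.

## Perturbation semantics

Two perturbation mechanisms are distinguished:

* **Clamp** — the species' value is fixed (overexpression = clamp 1);
  literals referencing it evaluate against the clamped value. This is what
  makes "constant Bir1" block the `YCA1 + !BIR1` caspase gate.
* **Deletion** — gene knockout: the species is fixed at 0 *and* every
  hyperarc it participates in (either side, either sign) is removed. A
  deleted protein cannot mediate its reactions. This is the semantics under
  which deleting both Stm1 compartment nodes switches the Stm1-mediated
  DNA-fragmentation interaction off, reproducing the knockout phenotype
  (the printed sign of that interaction, `!STM1-NUC = DNA-FRAG`, is kept
  verbatim even though the cited biology — Stm1 as a death *promoter* — and
  the knockout experiment both go the other way; deletion semantics
  reconciles the knockout result without rewriting the table).

The robustness sweep (single deletion of every non-input species in the
additive-mode scenario) never leaves the Apoptosis output undetermined.

## Structural analysis

The interaction matrix records product/activating/inhibiting participation
of every species in every interaction; row sums give the per-species
connectivity census. The census matches the published counts for H2B (5),
CAMP (2), RedActinDyn (3), Ros-MT (1) and MCD1-NUC (1). Two discrepancies
in the published summary are reported as encoded, not patched: the
housekeeping node has 16 interactions in the table (summary says 18), and
CPR3 is a source (never a target) although the summary omits it.

Dependencies classify ordered pairs by *walk parity* on the signed species
digraph (one edge per tail literal): positive-parity walks only →
activator, negative only → inhibitor, both → ambivalent, none → none.
Parity reachability is computed by BFS on the parity-doubled graph; an
independent sign-semiring transitive closure serves as the test oracle.
Walks (not simple paths) are the right notion here: traversing an
odd-signed feedback loop legitimately flips the sign of an influence, which
is exactly how mixed feedback produces ambivalence. "Complete" influences
are those carried by a walk of the deciding sign through single-literal
interactions only (no co-factor requirements); the `YCA1 + !BIR1` gate
makes Bir1 an *incomplete* inhibitor of apoptosis, while
`!NMA111-NUC = BIR1` makes nuclear Nma111 a *complete* inhibitor of Bir1.
Structure is cutoff-independent by default with an optional cutoff filter.

## Continuous conversion

Per non-input species, dx/dt = (B(x̃) − x)/τ with B the exact multilinear
interpolation of the species' Boolean rule over its regulator cube
(corner tables are precompiled; evaluation contracts one axis at a time,
O(2^m) per species with m ≤ 11 regulators in this model). Modes: raw
coordinates (`boolecube`), per-edge Hill sigmoids (`hillcube`), or Hill
sigmoids normalized to f(1) = 1 (`normalized-hillcube`, the case-study
default, since un-normalized cascades saturate below 1 at every stage).

Defaults n = 3, k = 0.5, τ = 1 for every edge and species — conventional
sigmoidal-logic defaults; nothing in the underlying qualitative data pins
them. All are overridable per edge/species. Properties verified: Boolean
fixed points are boolecube equilibria; trajectories remain in [0, 1]
(within solver tolerance 1e-3); with n = 20 the normalized equilibria land
within 0.05 of the logical steady state in the additive-mode scenario.
Integration uses LSODA with rtol 1e-6 / atol 1e-8; equilibrium is declared
when ‖dx/dt‖∞ < 1e-6 over the final time-constant of the run. Stimuli
enter as exponential pulses u(t) = A·e^(−λt) (the simplest monotone
one-parameter decay); translocation pairs stay as the two compartment
nodes of the Boolean model, with no depletion term added to the source
compartment.

## Case-study design

Continuous case studies start from the *resting state*: the no-stimulus
LSS with cycle-dependent species resolved to 0. Starting from the zero
vector instead would transiently fire every `!housekeeping` literal (the
cell would "die of not yet having its constitutive proteins").

* **Hog1/heat.** In the encoded rules Hog1 is produced by !Ptp2, !Ptp3 and
  the osmotic-stress input only (the heat route through Sho1 described in
  the source literature has no arc of its own), so the simulated transient
  is the disinhibition dynamics of the phosphatase subsystem under the
  heat scenario: Hog1 rises while Ptp2/Ptp3 are still absent, peaks
  strictly below 1 (finite rise time against its time constant), and is
  pulled to an interior plateau by the Ptp3 feedback (peak ≈ 0.81,
  plateau ≈ 0.44 at default parameters). Only the qualitative shape is
  meaningful; absolute percentages depend on the unpublished Hill
  parameters. Because the disinhibition is basal, a zero-amplitude pulse
  does not leave Hog1 flat — a known property of the encoded rule set.
* **Bir1/acetic acid.** The rule set gives Bir1 degradation no
  acid-responsive route (cytosolic Nma111 is heat-activated only), so the
  stress phase imposes a decaying time course on Bir1 directly,
  representing its Nma111-mediated degradation during acid stress; the
  acid pulse and rising cytochrome c then drive apoptosis to its maximum
  through the caspase gate. The reversal variant releases Bir1 after the
  pulse: it re-accumulates (rule `!NMA111-NUC`) and pushes apoptosis back
  to zero — the deliberately implausible "revived cell" consistency
  control. The overexpression variant clamps Bir1 at 1; apoptosis then
  never leaves zero.
* **Stm1/H₂O₂.** Discrete study; knockout uses deletion semantics (above).
  With Stm1 present, H₂O₂ drives apoptosis through the separase/ROS route;
  DNA fragmentation through the Stm1 arc does not fire in this scenario
  because nuclear Stm1 is accumulated (see the sign caveat above) — the
  knockout claim is about the route being off, which holds in both cases,
  and the Mg²⁺-dependent Tat-D route stays available independently.

## Synthetic networks

The generator produces random signed logical hypergraphs with the encoded
model's shape statistics (mean tail ≈ 1.16, ≈ 17% negated literals) at
configurable size. Tail-size and sign fractions are allocated by
deterministic quota rather than per-literal coin flips, so requested
fractions are met exactly (up to rounding) for every seed; all sampling
goes through one explicitly threaded integer-only `random.Random`, giving
platform-stable reproducibility. Generated networks satisfy every network
invariant (no arcs onto inputs, no self-loops, distinct interactions) and
round-trip through the rule-file grammar. They emulate the *structural*
statistics only — no biological modularity, no translocation pairs, no
timescale semantics beyond uniform sampling — so oracle-equivalence results
on them validate the engine's logic, not biological conclusions.

## Known discrepancies and limitations

* The published additive-mode table shows Apoptosis = 0 at t = 4/5,
  although the printed interaction table contains t = 4 arcs
  (DNA-fragmentation → apoptosis, ROS → apoptosis) with active sources;
  the engine yields 1 there. Likewise the Stm1 compartment rows at t = 6
  (printed 0/1) are not derivable from the printed rules (housekeeping
  keeps cytosolic Stm1 on; adozelesin activates the proteasome, blocking
  nuclear accumulation). These cells are documented exclusions.
* The prose reaction-per-timescale counts (27/53/17/18) disagree with the
  row-by-row assignments (16/9/60/18/12); the encoding follows the rows.
* Problem sizes used in tests: oracle sweeps run 200 random networks of up
  to 12 species (exhaustive 2^n enumeration), dependency oracles up to 10
  species, continuous case studies integrate the full 73-species model for
  25–80 time units.
* Humanized-extension wiring is reconstructed from the described behaviour
  and end-state tables (no extension rule table is published); timescales
  are the minimal assignments reproducing the final-stage columns, and
  only those columns are asserted. Whether VCP inherits the
  overexpression-gated ROS arc is unstated; it is inherited here.
* Multi-level logic, asynchronous/probabilistic updates, parameter fitting
  to experimental time courses, and SBML/graphical model building are out
  of scope.
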