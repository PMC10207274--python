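# Methods

## State space and energies

An *n*-site molecule is represented by all 2ⁿ protonation microstates,
each a binary occupancy vector with bit 1 = protonated, bit order = site
index order, written left-to-right from site 0 (so `"110"` has sites 0
and 1 protonated). Sites carry exactly one dissociable proton; a group
with several must be split into single-proton sites (the package assigns
no meaning to a site protonation above 1). Enumeration is capped at
n = 20 (2²⁰ states, explicit); there is no implicit-representation
shortcut for larger n. Microstates are always ordered by removed-proton
count, then lexicographically, so every output is byte-stable.

Each microstate stores one relative free energy *g* in log10 units. The
gauge is fixed by g = 0 for the fully protonated state; any supplied
energies are shifted to this reference (populations depend only on
differences, so the shift is unobservable — this gauge invariance is
itself a tested property). Edge microconstants are derived quantities:
pKa(edge) = g(to) − g(from).

Accepting an edge list instead of energies requires checking
thermodynamic cycle closure: energies are accumulated breadth-first from
the reference, then every supplied edge is re-verified against the
assigned energies. The default closure tolerance is 1e−6 log10 units
(configurable); strict mode raises, lenient mode returns a
`ConsistencyReport` with the maximum residual, missing edges, and a
three-way status (consistent / inconsistent / incomplete). A spanning
subset of edges is sufficient input; a graph that does not connect the
reference to every microstate is reported incomplete.

## Equilibrium quantities

The weight law is `w(m) = d(m)·pH − g(m)` in log10 (d = protons
removed); populations are the base-10 softmax of these weights. All sums
go through a shifted log-sum-exp, so populations remain finite and
normalized for |pH| up to 100 and energies up to several hundred log
units, and no molar concentration is ever materialized — only ratios.

Macrostates are keyed by bound-proton count, not formal charge; charge
labels are derivable from each site's protonated-form charge but play no
computational role. Apparent pKa values come from the macrostate
partition sums `S_j = log10 Σ_{d=j} 10^(−g)` as `S_{j−1} − S_j`,
reported in dissociation order without sorting (a warning is emitted if
they are non-monotonic, possible under cooperative coupling). Their sum
telescopes to g(fully deprotonated) — an exact identity used as a test.

Within-macrostate dominance is the pH-independent Boltzmann split
`10^(−g) / Σ 10^(−g)` over a proton-count class; branching
probabilities out of a microstate are the analogous split over the edge
microconstants of its protonated sites, equal to the equilibrium
population ratio of the product microstates (they are equilibrium
ratios, not kinetic rates).

## Site metrics

ASP of group G is the summed population of G-protonated microstates.
pASPA is computed entirely in the log domain as
`pH + L_prot − L_deprot`, where the L's are log10 partition sums
restricted to G-protonated / G-deprotonated states; this form never
under- or overflows at finite pH and makes the monoprotic reduction
(pASPA ≡ pKa) exact to machine precision. The identity
`ASP = [H⁺]/([H⁺] + ASPA)` then holds by construction and is asserted to
1e−10 in tests. Both asymptotes of pASPA are computed analytically, never
from a grid: the low-pH limit is the group's microconstant in the fully
protonated molecule, the high-pH limit its microconstant when it holds
the last proton. Numerically the profile reaches these limits to ~1e−4
about 10 pH units beyond the system's extreme microconstants.

pK50 is found by a coarse scan of ASP − ½ (default window pH −5..20,
step 0.05, both configurable) followed by bisection on each bracket to
|ΔpH| ≤ 1e−12. Bisection was chosen over derivative methods because ASP
is cheap to evaluate and the bracket is guaranteed. If no crossing lies
in the window a `WindowError` tells the caller to widen it. When several
crossings exist, all are reported and `pk50` is left unset rather than
picking one silently (strict mode raises).

**Multiple crossings are real, not a numerical artifact.** Individual
site titration curves of strongly coupled systems need not be monotone:
e.g. a 4–6-site system with repulsive couplings of ~3 log units can have
a site whose ASP crosses ½ three times (the random generator at
n = 5 produces such cases). The qualitative rule — acidity decreases,
pASPA rises with pH — is therefore asserted only for moderately coupled
fixtures and measured as a majority trend on random systems. What *is*
exact at every crossing is the identity-line property: ASP = ½ forces
pASPA = pH there, so each crossing is a point where the pASPA profile
meets the identity line; tests check this at every crossing, unique or
not.

The whole-molecule Bjerrum curve n̄(pH) equals the sum of the per-site
ASP curves; `bjerrum()` recomputes both routes and raises if they differ
beyond 1e−10, making every call a cross-check of the two code paths.

## Synthetic systems

The generator uses a pairwise (Ising-like) model: site i has an
intrinsic micro-pKa (its value in the fully protonated molecule) and
deprotonated pairs add a symmetric coupling c_ij, so
`g(D) = Σ_{i∈D} pka_i + Σ_{{i,j}⊆D} c_ij` for deprotonated set D. This
is the minimal model that reproduces the context dependence of
microconstants (a site's pKa rises by Σ_{j∈D} c_ij as neighbours
deprotonate) while being cycle-consistent by construction; any
consistent energy assignment remains admissible input, the generator
exists for testing and simulation. c ≥ 0 is anticooperative (repulsive),
the ordinary electrostatic situation in polyprotic acids; negative
couplings are accepted but produce cooperative behaviour (possible
non-monotonic apparent pKa order).

Defaults for random systems: intrinsic pKa uniform on 1..12 (the span of
common ionizable groups in water), couplings uniform on 0..3 log units
(from near-independent to strongly interacting, the range over which the
contrast between apparent pKa and pK50 is visible). Seeds are mandatory
arguments; no global RNG state. What the generator does **not** emulate:
tautomerism/conformers, temperature and ionic-strength effects, activity
corrections, beyond-pairwise (three-body) couplings, and measurement
noise — so passing tests demonstrate the statistical-thermodynamic
machinery on exact inputs, not robustness to experimental error in
microconstants.

Parameter recovery closes the loop: the engine's pASPA asymptotes return
exactly the generator's (pka_i, pka_i + Σ_j c_ij), and zero-coupling
systems factorize into products of monoprotic titration terms.

## Serialization and CLI

System JSON carries exactly one of `energies` (bitstring → g), `edges`
(microconstant list), or `model` (pairwise parameters); edge lists are
also read from CSV. Numbers are written with 12 significant digits
('.' decimal, LF endings): pKa data are rarely meaningful past two
decimals, while 12 digits keep round-trips at ~5e−12 relative. Every CLI
subcommand is a pure function of its input file and flags; exit codes
distinguish schema (2), consistency (3), window (4), and size (5)
errors.

## Problem sizes in the checks

The test suite and acceptance script use systems of up to 6 sites
(64 microstates) for identity checks — 200 seeded random systems for the
cross-route identities, 1000 random diprotic systems for the
pK50-contraction trend, 1000 shuffled spanning-tree orders for path
independence — and enumerate up to n = 10 (1024 states, 5120 edges) for
the combinatorial counts. These sizes exercise every code path at
machine precision while keeping a full run under a minute on one CPU.

## Known limitations

- Site metrics assume one dissociable proton per site; multivalent
  groups must be modeled as split sites, and the package refuses to
  interpret anything else.
- Apparent pKa values of strongly cooperative systems (large negative
  couplings) can come out in non-monotonic order; they are reported
  as-is with a warning rather than re-sorted.
- No structure input (SMILES/SDF) and no microconstant prediction:
  microconstants or energies are inputs, obtained from experiment or an
  external predictor.
- No temperature or ionic-strength dependence; all quantities refer to
  the conditions under which the input microconstants were determined.
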