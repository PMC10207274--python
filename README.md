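# micropka

Microstate thermodynamics of multiprotic ionization: pH-dependent
microspecies populations, macroscopic (apparent) pKa, per-group site
titration curves, and the single-proton midpoint **pK50**.

## The problem

A molecule with *n* ionizable sites exists in solution as 2ⁿ protonation
**microstates** — every assignment of a bound proton to each site — joined
by *n*·2ⁿ⁻¹ one-proton equilibria, each with its own **microconstant**
(micro-pKa). Ordinary titration resolves only the *macrostates* (states
sharing a bound-proton count / formal charge), yielding at most *n*
apparent pKa values. Those macroconstants are log-ratios of summed
microstate weights and, in general, **belong to no individual functional
group**: for coupled groups, "assigning" an apparent pKa to the amine or
the carboxyl is ill-defined and can invert across a congeneric series.
This matters anywhere group-level acidity drives decisions — lead
optimization in drug discovery being the canonical case.

## The model

Each microstate *m* carries a relative free energy *g(m)* in log10 units
(the sum of micro-pKa values along any deprotonation path from the fully
protonated reference; cycle closure makes this path-independent). At a
given pH its statistical weight is

```
w(m) = 10^( d(m)·pH − g(m) )        d(m) = protons removed
```

and populations are the normalized weights (a base-10 softmax — the
binding-polynomial partition function). From this single object the
package computes:

* **populations / macrostate populations** — microspecies distribution
  versus pH; **n̄(pH)**, the Bjerrum average-bound-protons curve;
* **macroscopic pKa** — `pKa_j = S_{j−1} − S_j` with
  `S_j = log10 Σ_{d(m)=j} 10^{−g(m)}`;
* **microstate dominance** and per-proton **dissociation branching**
  within/out of each macrostate;
* **ASP** (averaged site protonation) — the probability that group G is
  protonated: its site titration curve;
* **ASPA / pASPA** (averaged single-proton acidity) — the pH-dependent
  constant-like ratio `[H⁺]·Σ[G-deprotonated states] / Σ[G-protonated
  states]`, tied to ASP by the exact identity
  `ASP = [H⁺]/([H⁺] + ASPA)`;
* **pK50** — the pH at which ASP = ½: a pH-independent, per-group
  intrinsic acidity that reduces to the ordinary pKa for monoprotic
  compounds, and equals the pH where the pASPA profile crosses the
  identity line.

Systems are supplied as per-microstate energies, as an edge list of
microconstants (validated for thermodynamic cycle closure), or generated
from an Ising-like pairwise model (intrinsic pKa per site + symmetric
coupling matrix).

## Worked example

A triprotic, drug-like molecule — carboxyl (intrinsic pKa 2.2), proximal
amine (2.9), distal amine (7.5) — with repulsive couplings of 0.3–0.9
log units:

```python
import numpy as np
from micropka import PairwiseModel, from_pairwise, macro_pkas, pk50

coupling = np.array([[0.0, 0.9, 0.3],
                     [0.9, 0.0, 0.5],
                     [0.3, 0.5, 0.0]])
mol = from_pairwise(PairwiseModel([2.2, 2.9, 7.5], coupling,
                                  labels=["COOH", "N-prox", "N-dist"]))
print([round(x, 2) for x in macro_pkas(mol).pka_macro])
for site in mol.sites:
    rep = pk50(mol, site.index)
    print(site.label, round(rep.pk50, 2), f"ASP(7.4) = {rep.asp_at[7.4]:.1%}")
```

prints

```
[2.12, 3.88, 8.3]
COOH 2.28 ASP(7.4) = 0.0%
N-prox 3.72 ASP(7.4) = 0.0%
N-dist 8.3 ASP(7.4) = 88.8%
```

Read: the titration experiment would report apparent pKa 2.12 / 3.88 /
8.30, but the *group* acidities are pK50 2.28 (carboxyl) and 3.72
(proximal amine) — closer together than the two apparent values they are
usually "assigned" to, because both groups share the first two
deprotonations. The distal amine's pK50 coincides with the third
apparent pKa only because one microstate dominates that macrostate; at
physiological pH 7.4 it is still 88.8% protonated.

The same is available from the shell:

```bash
micropka simulate --pk 5 --pk 5 --coupling 2 -o dip.json
micropka macro dip.json        # apparent pKa 4.69897 / 7.30103
micropka pk50 dip.json         # pK50 = 6 for both equivalent sites
micropka profiles dip.json -o profiles.csv
```

Subcommands: `validate`, `simulate`, `populations`, `macro`, `profiles`,
`pk50`.

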