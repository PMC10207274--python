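"""Partition-function computations over protonation microstates.

Relative to the fully protonated reference, the statistical weight of
microstate ``m`` at a given pH is ``10**(d_m * pH - g_m)``, where ``d_m``
is the number of protons removed and ``g_m`` the relative free energy in
log10 units.  This is the standard proton-binding-polynomial weight: each
dissociation trades one factor of proton activity ``10**-pH`` for one
factor ``10**-pka`` along the path.  All sums are taken with a shifted
log-sum-exp so that populations stay finite and normalized for |pH| up to
100 and |g| up to several hundred; no molar concentration is ever
materialized, only ratios and fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .microstates import MicrostateSystem, Occupancy, StateLike, as_occupancy

LN10 = np.log(10.0)


def lse10(a: np.ndarray, axis: int | None = None) -> np.ndarray:
    """log10 of a sum of powers of 10, computed stably: log10(sum(10**a))."""
    return logsumexp(np.asarray(a, dtype=float) * LN10, axis=axis) / LN10


@dataclass
class PopulationVector:
    """Microstate probabilities at one pH, aligned with ``system.states``."""

    pH: float
    fractions: np.ndarray


@dataclass
class MacroReport:
    """Apparent (macroscopic) pKa values in dissociation order.

    ``S[j]`` is the log10 partition sum of the *j*-protons-removed
    macrostate, ``log10(sum over {m: d_m = j} of 10**(-g_m))``; the
    *j*-th apparent pKa is the log-ratio ``S[j-1] - S[j]``.  Step ``j``
    is the loss of the j-th proton from the fully protonated form.
    """

    pka_macro: list[float]
    S: list[float]


@dataclass
class DominanceTable:
    """Within-macrostate microstate fractions (Boltzmann split, pH-independent)."""

    fractions: dict[int, dict[Occupancy, float]]

    def of(self, d: int) -> dict[Occupancy, float]:
        return self.fractions[d]


def log_weights(system: MicrostateSystem, pH) -> np.ndarray:
    """Unnormalized log10 statistical weights ``d_m * pH - g_m``.

    ``pH`` may be a scalar or an array; the microstate axis is last.
    """
    pH = np.asarray(pH, dtype=float)
    return np.multiply.outer(pH, system.d.astype(float)) - system.g


def population_matrix(system: MicrostateSystem, pH) -> np.ndarray:
    """Normalized microstate probabilities (softmax in base 10 of the weights)."""
    w = log_weights(system, pH)
    w = w - lse10(w, axis=-1)[..., None]
    return np.power(10.0, w)


def populations(system: MicrostateSystem, pH: float) -> PopulationVector:
    """Microstate probability distribution at one pH.

    Fractions are nonnegative, sum to 1, and are gauge-invariant (a common
    shift of all ``g`` cancels in the normalization).
    """
    return PopulationVector(pH=float(pH), fractions=population_matrix(system, float(pH)))


def macrostate_populations(system: MicrostateSystem, pH) -> np.ndarray:
    """Probability of each protonation macrostate, grouped by proton count.

    Entry ``j`` (along the last axis) is the total population of microstates
    with ``j`` protons removed from the fully protonated form, i.e. the
    j-th coefficient class of the binding polynomial.
    """
    p = population_matrix(system, pH)
    n = system.n_sites
    out = np.zeros(p.shape[:-1] + (n + 1,))
    for j in range(n + 1):
        out[..., j] = p[..., system.d == j].sum(axis=-1)
    return out


def macro_pkas(system: MicrostateSystem) -> MacroReport:
    """Apparent pKa values from the macrostate partition sums.

    The observed macroconstants of a multiprotic compound are not single
    microconstants but log-ratios of summed microstate weights:
    ``pKa_macro_j = S_{j-1} - S_j`` with ``S_j = log10 sum_{d_m=j} 10**-g_m``.
    Values are reported in dissociation order (first proton lost first) and
    deliberately not sorted; a warning is emitted if they are non-monotonic,
    which can happen under strong cooperative coupling.
    """
    n = system.n_sites
    S = [float(lse10(-system.g[system.d == j])) for j in range(n + 1)]
    pka = [S[j - 1] - S[j] for j in range(1, n + 1)]
    if any(b < a for a, b in zip(pka, pka[1:])):
        warnings.warn(
            "macroscopic pKa values are non-monotonic in dissociation order "
            "(cooperative coupling?)",
            stacklevel=2,
        )
    return MacroReport(pka_macro=pka, S=S)


def nbar(system: MicrostateSystem, pH) -> np.ndarray:
    """Average number of bound ionizable protons (the Bjerrum function).

    ``nbar(pH) = sum_m (n - d_m) * p_m(pH)``; identically equal to the sum
    of the per-site protonation probabilities (ASP) over all sites.
    """
    p = population_matrix(system, pH)
    bound = (system.n_sites - system.d).astype(float)
    return p @ bound


def microstate_dominance(system: MicrostateSystem) -> DominanceTable:
    """Relative contribution of each microstate to its parent macrostate.

    Within a fixed proton count the pH-dependent factor ``10**(d*pH)`` is
    shared, so the split is the pH-independent Boltzmann ratio
    ``10**(-g_m) / sum_{d_m'=d} 10**(-g_m')``.
    """
    table: dict[int, dict[Occupancy, float]] = {}
    for j in range(system.n_sites + 1):
        mask = system.d == j
        logw = -system.g[mask]
        frac = np.power(10.0, logw - lse10(logw))
        table[j] = {
            s: float(f)
            for s, f in zip([st for st, m in zip(system.states, mask) if m], frac)
        }
    return DominanceTable(fractions=table)


def branching_probabilities(
    system: MicrostateSystem, microstate: StateLike
) -> dict[int, float]:
    """Per-site dissociation probability out of a given microstate.

    For each protonated site ``i`` with edge microconstant ``k_i``, the
    probability that the next proton lost is the one at ``i`` equals the
    equilibrium population ratio of the product microstates,
    ``10**(-k_i) / sum_j 10**(-k_j)`` -- an equilibrium branching ratio,
    not a kinetic rate.
    """
    occ = as_occupancy(microstate)
    g0 = system.energy(occ)
    prot = [i for i, b in enumerate(occ) if b]
    if not prot:
        raise ValueError("branching is undefined for the fully deprotonated microstate")
    ks = np.array(
        [system.energy(occ[:i] + (0,) + occ[i + 1 :]) - g0 for i in prot]
    )
    frac = np.power(10.0, -ks - lse10(-ks))
    return {i: float(f) for i, f in zip(prot, frac)}
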