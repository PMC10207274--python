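"""Synthetic microstate systems with known ground truth.

The factory here builds cycle-consistent systems from an Ising-like
pairwise model: site ``i`` has an intrinsic micro-pKa (its microconstant
in the fully protonated molecule) and deprotonated sites interact through
a symmetric coupling matrix ``c``.  For the deprotonated set ``D``,

    g(D) = sum_{i in D} pka_i  +  sum_{{i,j} subset D} c_ij

so the microconstant of site ``i`` given already-deprotonated set ``D`` is
``pka_i + sum_{j in D} c_ij`` -- a group's acidity depends on the
protonation state of its neighbours, exactly the context dependence that
makes macroscopic pKa unassignable to single groups.  Nonnegative
couplings are anticooperative (each removal makes the next one harder),
the usual electrostatic situation in polyprotic acids.

These generators are fixtures and oracle substrates: their parameters are
recoverable from the engine's outputs (the pASPA asymptotes of site ``i``
are exactly ``pka_i`` and ``pka_i + sum_j c_ij``), which turns every
property test into a parameter-recovery check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SchemaError
from .microstates import MicrostateSystem, Site, _check_n, enumerate_microstates


@dataclass
class PairwiseModel:
    """Intrinsic per-site micro-pKa values plus a symmetric coupling matrix.

    ``coupling[i, j]`` (log10 units) is added to the deprotonation cost
    whenever sites i and j are both deprotonated; the diagonal must be
    zero and ``c >= 0`` means anticooperative (repulsive) interaction.
    """

    intrinsic_pka: np.ndarray
    coupling: np.ndarray
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.intrinsic_pka = np.asarray(self.intrinsic_pka, dtype=float)
        self.coupling = np.asarray(self.coupling, dtype=float)
        n = self.intrinsic_pka.size
        if self.intrinsic_pka.ndim != 1 or n == 0:
            raise SchemaError("intrinsic_pka must be a nonempty 1-D array")
        if self.coupling.shape != (n, n):
            raise SchemaError(f"coupling must be {n}x{n}")
        if not np.allclose(self.coupling, self.coupling.T, atol=0.0):
            raise SchemaError("coupling matrix must be symmetric")
        if np.any(np.diag(self.coupling) != 0.0):
            raise SchemaError("coupling matrix must have a zero diagonal")
        if not (np.all(np.isfinite(self.intrinsic_pka)) and np.all(np.isfinite(self.coupling))):
            raise SchemaError("model parameters must be finite")

    @property
    def n_sites(self) -> int:
        return self.intrinsic_pka.size


def from_pairwise(model: PairwiseModel, name: str = "pairwise") -> MicrostateSystem:
    """Build the full microstate system of a pairwise model.

    Cycle-consistent by construction: ``g`` is a single-valued function of
    the deprotonated set, so every closed path on the hypercube sums to 0.
    """
    n = model.n_sites
    _check_n(n)
    pk = model.intrinsic_pka
    c = model.coupling
    energies = {}
    for occ in enumerate_microstates(n):
        u = 1.0 - np.asarray(occ, dtype=float)  # deprotonation indicator
        energies[occ] = float(u @ pk + 0.5 * u @ c @ u)
    if model.labels is not None:
        if len(model.labels) != n:
            raise SchemaError("labels length must match the number of sites")
        sites = tuple(Site(i, str(lab)) for i, lab in enumerate(model.labels))
    else:
        sites = n
    return MicrostateSystem(sites, energies, name=name)


def symmetric_system(
    n_sites: int, pk: float, c: float = 0.0, name: str = "symmetric"
) -> MicrostateSystem:
    """All sites equivalent: equal intrinsic pKa, equal pairwise coupling.

    Models molecules like a fully symmetric polycarboxylic acid, where the
    macroscopic pKa values spread out over several log units purely through
    statistics and coupling while every group is chemically identical --
    the case where per-group assignment of apparent pKa is meaningless but
    all sites share one pK50.  With ``c = 0`` the macroconstants carry the
    exact statistical factors ``pk + log10(j / (n - j + 1))``.
    """
    n = _check_n(n_sites)
    coupling = np.full((n, n), float(c))
    np.fill_diagonal(coupling, 0.0)
    return from_pairwise(
        PairwiseModel(np.full(n, float(pk)), coupling), name=name
    )


def monoprotic(pk: float, label: str = "G1", kind: str = "acid") -> MicrostateSystem:
    """The two-state monoprotic reference system HA <-> A: g = {1: 0, 0: pk}."""
    if not np.isfinite(pk):
        raise SchemaError("pk must be finite")
    return MicrostateSystem(
        (Site(0, label, kind=kind),),
        {(1,): 0.0, (0,): float(pk)},
        name=f"monoprotic(pK={pk:g})",
    )


def random_system(
    n_sites: int,
    seed: int,
    pka_range: tuple[float, float] = (1.0, 12.0),
    coupling_range: tuple[float, float] = (0.0, 3.0),
    name: str | None = None,
) -> MicrostateSystem:
    """Reproducible random pairwise system (property-test fuel).

    Intrinsic pKa values are uniform over ``pka_range`` and couplings
    uniform over ``coupling_range`` (nonnegative by default, i.e.
    anticooperative).  The seed is a mandatory argument; no global RNG
    state is touched.
    """
    n = _check_n(n_sites)
    rng = np.random.default_rng(seed)
    pk = rng.uniform(*pka_range, size=n)
    coupling = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    vals = rng.uniform(*coupling_range, size=len(iu[0]))
    coupling[iu] = vals
    coupling.T[iu] = vals
    return from_pairwise(
        PairwiseModel(pk, coupling),
        name=name if name is not None else f"random(n={n}, seed={seed})",
    )
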