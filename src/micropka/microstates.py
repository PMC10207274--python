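"""The protonation hypercube: microstates, one-proton edges, free energies.

A molecule with ``n`` ionizable sites exists in solution as a collection of
``2**n`` protonation *microstates*, one for every assignment of a bound
proton to each site.  A microstate is written as a binary occupancy vector
(bit ``1`` = protonated, bit order = site index order).  Microstates are the
vertices of an *n*-dimensional hypercube whose ``n * 2**(n-1)`` edges are
single-proton dissociations; each edge carries an ionization microconstant
(micro-pKa, log10 units).

Rather than storing one number per edge, a system stores one relative free
energy ``g`` per microstate, in log10 units, defined as the sum of
micro-pKa values along any deprotonation path from the fully protonated
reference (``g = 0`` for the all-ones state).  Thermodynamic cycle closure
makes this path-independent, and every edge microconstant is recovered as
``pka = g(to) - g(from)``.  The functions :func:`edges_to_energies` and
:func:`energies_to_edges` convert between the two representations and
verify cycle closure on the way in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

from .errors import ConsistencyError, SchemaError, SizeError

#: Hard cap on explicit enumeration: 2**20 microstates.
MAX_SITES = 20

#: Default cycle-closure tolerance, log10 units.
DEFAULT_TOLERANCE = 1e-6

Occupancy = tuple[int, ...]
StateLike = Union[str, Sequence[int]]


def as_occupancy(state: StateLike) -> Occupancy:
    """Coerce a bitstring like ``"110"`` or an int sequence to an occupancy tuple."""
    if isinstance(state, str):
        if not state or any(c not in "01" for c in state):
            raise SchemaError(f"occupancy bitstring must be nonempty 0/1, got {state!r}")
        return tuple(int(c) for c in state)
    occ = tuple(int(b) for b in state)
    if not occ or any(b not in (0, 1) for b in occ):
        raise SchemaError(f"occupancy vector must be nonempty 0/1, got {state!r}")
    return occ


def bitstring(state: StateLike) -> str:
    """Render an occupancy as a bitstring, site 0 leftmost."""
    return "".join(str(b) for b in as_occupancy(state))


@dataclass(frozen=True)
class Site:
    """One ionizable group carrying at most one dissociable proton.

    Groups with several dissociable protons (e.g. a primary ammonium modeled
    to full depth) must be split into multiple single-proton sites.

    Parameters
    ----------
    index : int
        0-based position in the occupancy vector; unique and contiguous
        within a system.
    label : str
        Free-text display label, e.g. ``"N18"``.
    kind : {"acid", "base"}
        Display-only classification.
    charge_protonated : int, optional
        Formal charge of the group when protonated.  Defaults to 0 for an
        acid (COOH) and +1 for a base (NH+).
    """

    index: int
    label: str
    kind: str = "acid"
    charge_protonated: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("acid", "base"):
            raise SchemaError(f"site kind must be 'acid' or 'base', got {self.kind!r}")
        if self.charge_protonated is None:
            object.__setattr__(
                self, "charge_protonated", 1 if self.kind == "base" else 0
            )


def default_sites(n_sites: int) -> tuple[Site, ...]:
    """Placeholder sites ``G1 .. Gn`` for systems given without site metadata."""
    return tuple(Site(i, f"G{i + 1}") for i in range(n_sites))


@dataclass(frozen=True)
class Microstate:
    """One protonation microstate: occupancy vector plus relative free energy.

    ``g`` is in log10 units relative to the fully protonated reference;
    ``d`` is the number of protons removed from that reference.
    """

    occupancy: Occupancy
    g: float

    @property
    def d(self) -> int:
        return len(self.occupancy) - sum(self.occupancy)

    @property
    def bitstring(self) -> str:
        return bitstring(self.occupancy)


@dataclass(frozen=True)
class MicroEquilibrium:
    """A hypercube edge: a reversible one-proton dissociation.

    ``from_state`` is the protonated side, ``to_state`` the deprotonated
    side; they differ in exactly one position, which goes 1 -> 0 at
    ``site``.  ``pka_micro`` is the ionization microconstant in log10 units.
    """

    from_state: Occupancy
    to_state: Occupancy
    site: int
    pka_micro: float

    def __post_init__(self) -> None:
        f = as_occupancy(self.from_state)
        t = as_occupancy(self.to_state)
        object.__setattr__(self, "from_state", f)
        object.__setattr__(self, "to_state", t)
        if len(f) != len(t):
            raise SchemaError("edge endpoints have different lengths")
        diff = [i for i, (a, b) in enumerate(zip(f, t)) if a != b]
        if diff != [self.site] or f[self.site] != 1 or t[self.site] != 0:
            raise SchemaError(
                f"edge {bitstring(f)}->{bitstring(t)} is not a single 1->0 "
                f"flip at site {self.site}"
            )
        if not np.isfinite(self.pka_micro):
            raise SchemaError("micro-pKa must be finite")


@dataclass
class ConsistencyReport:
    """Outcome of structural and cycle-closure validation.

    ``status`` is ``"consistent"`` when every check passed within
    tolerance, ``"inconsistent"`` when cycle closure (or finiteness)
    failed, and ``"incomplete"`` when microstates or spanning edges are
    missing.
    """

    max_cycle_residual: float
    n_edges_given: int
    n_edges_expected: int
    missing_edges: list = field(default_factory=list)
    status: str = "consistent"
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.status == "consistent"


class MicrostateSystem:
    """All ``2**n`` microstates of an *n*-site molecule with their energies.

    This is the substrate of the binding-polynomial partition function:
    everything downstream (populations, macroscopic pKa, site titration
    curves) is computed from the ``g`` vector held here.

    Parameters
    ----------
    sites : int or sequence of Site
        Site metadata, or just the site count (labels default to G1..Gn).
    energies : mapping
        Occupancy (tuple or bitstring) -> relative free energy ``g``
        in log10 units.  Gauge: energies are shifted so the fully
        protonated microstate has ``g = 0`` (populations only depend on
        differences, so this is unobservable).
    name : str
        Free-text system name.
    check : bool
        When True (default), require exactly ``2**n`` distinct finite
        entries and normalize the gauge at construction.  ``check=False``
        defers all of that to :func:`validate_system`.
    """

    def __init__(
        self,
        sites: int | Sequence[Site],
        energies: Mapping[StateLike, float],
        name: str = "",
        check: bool = True,
    ) -> None:
        if isinstance(sites, (int, np.integer)):
            if not 1 <= int(sites) <= MAX_SITES:
                raise SizeError(f"n_sites must be in 1..{MAX_SITES}, got {sites}")
            sites = default_sites(int(sites))
        self.sites: tuple[Site, ...] = tuple(sites)
        if [s.index for s in self.sites] != list(range(len(self.sites))):
            raise SchemaError("site indices must be 0-based, unique and contiguous")
        self.name = name

        n = len(self.sites)
        table = {as_occupancy(k): float(v) for k, v in energies.items()}
        if any(len(occ) != n for occ in table):
            raise SchemaError("occupancy length does not match the number of sites")
        # canonical order: d ascending, then lexicographic
        self.states: list[Occupancy] = sorted(
            table, key=lambda s: (n - sum(s), s)
        )
        self.g: np.ndarray = np.array([table[s] for s in self.states], dtype=float)
        self.d: np.ndarray = np.array([n - sum(s) for s in self.states], dtype=np.int64)
        self._index: dict[Occupancy, int] = {s: i for i, s in enumerate(self.states)}
        self.consistency_report: ConsistencyReport | None = None

        if check:
            if len(self.states) != 2**n:
                raise SchemaError(
                    f"expected {2**n} microstates for {n} sites, got {len(self.states)}"
                )
            if not np.all(np.isfinite(self.g)):
                raise SchemaError("all microstate energies must be finite")
            ref = self._index[(1,) * n]
            if self.g[ref] != 0.0:
                self.g -= self.g[ref]

    # -- basic introspection -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def all_ones(self) -> Occupancy:
        return (1,) * self.n_sites

    @property
    def all_zeros(self) -> Occupancy:
        return (0,) * self.n_sites

    def index(self, state: StateLike) -> int:
        return self._index[as_occupancy(state)]

    def energy(self, state: StateLike) -> float:
        return float(self.g[self.index(state)])

    def bitstrings(self) -> list[str]:
        return [bitstring(s) for s in self.states]

    def microstates(self) -> list[Microstate]:
        return [Microstate(s, float(g)) for s, g in zip(self.states, self.g)]

    def site_index(self, site: int | str | Site) -> int:
        """Resolve a site given by index, label, or Site object."""
        if isinstance(site, Site):
            site = site.index
        if isinstance(site, (int, np.integer)):
            i = int(site)
            if not 0 <= i < self.n_sites:
                raise KeyError(f"site index {i} out of range 0..{self.n_sites - 1}")
            return i
        for s in self.sites:
            if s.label == site:
                return s.index
        raise KeyError(f"unknown site label {site!r}")

    def occupancy_matrix(self) -> np.ndarray:
        """(n_states, n_sites) 0/1 matrix, rows in canonical state order."""
        return np.array(self.states, dtype=np.int8)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MicrostateSystem(name={self.name!r}, n_sites={self.n_sites}, "
            f"n_states={self.n_states})"
        )


# -- enumeration -------------------------------------------------------------


def _check_n(n_sites: int) -> int:
    if not isinstance(n_sites, (int, np.integer)) or not 1 <= int(n_sites) <= MAX_SITES:
        raise SizeError(f"n_sites must be an integer in 1..{MAX_SITES}, got {n_sites!r}")
    return int(n_sites)


def enumerate_microstates(n_sites: int) -> list[Occupancy]:
    """All ``2**n`` occupancy vectors, ordered by (d ascending, lexicographic).

    The fully protonated state comes first, the fully deprotonated last;
    within each proton-count class the order is lexicographic, so the
    output is byte-stable across runs.
    """
    n = _check_n(n_sites)
    states = [tuple(bits) for bits in product((0, 1), repeat=n)]
    states.sort(key=lambda s: (n - sum(s), s))
    return states


def hypercube_edges(n_sites: int) -> list[tuple[Occupancy, Occupancy, int]]:
    """All ``n * 2**(n-1)`` one-proton transitions of the hypercube.

    Each entry is ``(from_state, to_state, site)`` with the bit at ``site``
    flipping 1 -> 0.  Order: canonical state order, then site index.
    """
    n = _check_n(n_sites)
    edges = []
    for s in enumerate_microstates(n):
        for i, b in enumerate(s):
            if b:
                edges.append((s, s[:i] + (0,) + s[i + 1 :], i))
    return edges


# -- representation conversion ----------------------------------------------


def edges_to_energies(
    edges: Iterable[MicroEquilibrium],
    tolerance: float = DEFAULT_TOLERANCE,
    sites: Sequence[Site] | None = None,
    name: str = "",
    strict: bool = False,
) -> tuple[MicrostateSystem, ConsistencyReport]:
    """Assign microstate free energies from a set of edge microconstants.

    Energies are accumulated breadth-first from the fully protonated
    reference (``g = 0``).  Every supplied edge is then re-checked:
    ``|pka - (g(to) - g(from))| <= tolerance`` must hold, otherwise the
    microconstant set violates thermodynamic cycle closure and the report
    status is ``"inconsistent"``.  Missing edges are allowed as long as the
    edge graph still connects the reference to every microstate; if not,
    the status is ``"incomplete"``.

    In strict mode a non-consistent outcome raises
    :class:`~micropka.errors.ConsistencyError`; in lenient mode the report
    carries the verdict.
    """
    edge_list = list(edges)
    if not edge_list:
        raise SchemaError("empty edge list")
    n = len(edge_list[0].from_state)
    if any(len(e.from_state) != n for e in edge_list):
        raise SchemaError("edges reference inconsistent site counts")
    _check_n(n)

    adjacency: dict[Occupancy, list[tuple[Occupancy, float]]] = {}
    for e in edge_list:
        adjacency.setdefault(e.from_state, []).append((e.to_state, e.pka_micro))
        adjacency.setdefault(e.to_state, []).append((e.from_state, -e.pka_micro))

    ref = (1,) * n
    g: dict[Occupancy, float] = {ref: 0.0}
    frontier = [ref]
    while frontier:
        nxt = []
        for u in frontier:
            for v, dg in adjacency.get(u, ()):
                if v not in g:
                    g[v] = g[u] + dg
                    nxt.append(v)
        frontier = nxt

    expected = hypercube_edges(n)
    given = {(e.from_state, e.to_state) for e in edge_list}
    missing = [e for e in expected if (e[0], e[1]) not in given]

    residual = 0.0
    for e in edge_list:
        if e.from_state in g and e.to_state in g:
            residual = max(residual, abs(e.pka_micro - (g[e.to_state] - g[e.from_state])))

    messages: list[str] = []
    if len(g) < 2**n:
        status = "incomplete"
        messages.append(
            f"edge graph reaches only {len(g)} of {2**n} microstates from the "
            "fully protonated reference"
        )
    elif residual > tolerance:
        status = "inconsistent"
        messages.append(
            f"max cycle-closure residual {residual:.3g} exceeds tolerance {tolerance:.3g}"
        )
    else:
        status = "consistent"

    report = ConsistencyReport(
        max_cycle_residual=residual,
        n_edges_given=len(edge_list),
        n_edges_expected=n * 2 ** (n - 1),
        missing_edges=missing,
        status=status,
        messages=messages,
    )
    if strict and not report.ok:
        raise ConsistencyError("; ".join(messages) or report.status)

    system = MicrostateSystem(
        sites if sites is not None else n, g, name=name, check=(status != "incomplete")
    )
    system.consistency_report = report
    return system, report


def energies_to_edges(system: MicrostateSystem) -> list[MicroEquilibrium]:
    """Recover all ``n * 2**(n-1)`` edge microconstants from the energies.

    Each edge carries ``pka_micro = g(to) - g(from)``; the result
    round-trips through :func:`edges_to_energies` to machine precision.
    """
    edges = []
    for s in system.states:
        gs = system.energy(s)
        for i, b in enumerate(s):
            if b:
                t = s[:i] + (0,) + s[i + 1 :]
                edges.append(MicroEquilibrium(s, t, i, system.energy(t) - gs))
    return edges


def validate_system(
    system: MicrostateSystem,
    tolerance: float = DEFAULT_TOLERANCE,
    strict: bool = False,
) -> ConsistencyReport:
    """Structural validation of a system; idempotent.

    Checks microstate completeness (exactly ``2**n`` distinct states),
    energy finiteness, and the gauge convention (``g = 0`` for the fully
    protonated state; if violated, all energies are shifted in place and a
    warning is emitted -- populations are gauge-invariant so this is safe).
    Cycle closure is automatic in the energy representation, so the
    residual reported here is always 0 for structurally valid systems.
    """
    n = system.n_sites
    messages: list[str] = []
    status = "consistent"

    if system.n_states != 2**n:
        status = "incomplete"
        messages.append(f"{system.n_states} microstates present, expected {2**n}")
    if not np.all(np.isfinite(system.g)):
        status = "inconsistent"
        messages.append("non-finite microstate energies")

    ref = (1,) * n
    if status != "inconsistent" and ref in system._index:
        shift = float(system.g[system.index(ref)])
        if shift != 0.0:
            warnings.warn(
                f"fully protonated reference has g = {shift:g}; shifting all "
                "energies so g(reference) = 0 (gauge fix)",
                stacklevel=2,
            )
            system.g -= shift
    elif ref not in system._index:
        if status == "consistent":
            status = "incomplete"
        messages.append("fully protonated reference microstate missing")

    report = ConsistencyReport(
        max_cycle_residual=0.0,
        n_edges_given=n * 2 ** (n - 1) if status == "consistent" else 0,
        n_edges_expected=n * 2 ** (n - 1),
        missing_edges=[],
        status=status,
        messages=messages,
    )
    if strict and not report.ok:
        raise ConsistencyError("; ".join(messages) or status)
    system.consistency_report = report
    return report
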