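"""Per-group acidity measures: ASP, ASPA/pASPA, and the pK50 midpoint.

Macroscopic pKa values from ordinary titration belong to whole-molecule
charge-state transitions, not to individual functional groups.  The
quantities here are the group-resolved alternatives:

* **ASP** (averaged site protonation) -- the probability that a specific
  group G carries its proton at a given pH; the group's site titration
  curve, between 0 and 1.
* **ASPA** (averaged single-proton acidity) -- the equilibrium-constant-like
  ratio ``[H+] * (sum of G-deprotonated microstates) / (sum of
  G-protonated microstates)``.  Because numerator and denominator mix
  charge states, ASPA depends on pH; ``pASPA = -log10(ASPA)``.  The two
  are tied by the exact identity ``ASP = [H+] / ([H+] + ASPA)``.
* **pK50** (single-proton midpoint) -- the pH at which ASP = 1/2; a
  pH-independent intrinsic acidity constant for the group, equal to the
  ordinary pKa in the monoprotic case, and equal to the pH at which the
  pASPA profile crosses the identity line.

pASPA interpolates between two analytically known asymptotes: at low pH
it equals the group's microconstant in the fully protonated molecule, at
high pH its microconstant in the state where only this group is still
protonated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import bisect
from scipy.special import expit

from .equilibrium import LN10, log_weights, lse10, nbar
from .errors import ConsistencyError, SizeError, WindowError
from .microstates import MicrostateSystem, Site

#: Default pK50 scan window and step (pH units).
DEFAULT_WINDOW = (-5.0, 20.0)
DEFAULT_STEP = 0.05


@dataclass
class TitrationProfile:
    """ASP and pASPA for one site over a pH grid."""

    site: Site
    pH_grid: np.ndarray
    asp: np.ndarray
    paspa: np.ndarray


@dataclass
class SiteReport:
    """pK50 summary for one site.

    ``pk50`` is set iff the ASP curve crosses 1/2 exactly once inside the
    scan window; with several crossings all are listed and ``pk50`` is left
    unset rather than picked silently.
    """

    site: Site
    pk50: float | None
    crossings: list[float]
    paspa_low: float
    paspa_high: float
    asp_at: dict[float, float] = field(default_factory=dict)

    @property
    def ambiguous(self) -> bool:
        return len(self.crossings) != 1


def _site_log_sums(system: MicrostateSystem, site: int, pH):
    """log10 partition sums restricted to G-protonated / G-deprotonated states."""
    w = log_weights(system, pH)
    mask = system.occupancy_matrix()[:, site] == 1
    return lse10(w[..., mask], axis=-1), lse10(w[..., ~mask], axis=-1)


def asp(system: MicrostateSystem, site, pH):
    """Averaged site protonation: P(site is protonated) at the given pH.

    Accepts a scalar or array pH; the site may be given by index or label.
    """
    i = system.site_index(site)
    Lp, Ld = _site_log_sums(system, i, pH)
    # ASP = 1 / (1 + 10**(Ld - Lp)), evaluated through the logistic for stability
    return expit((Lp - Ld) * LN10)


def paspa(system: MicrostateSystem, site, pH):
    """Negative log10 of the averaged single-proton acidity.

    Computed entirely in the log domain, ``pASPA = pH + log10(ASP/(1-ASP))``
    never under- or overflows for finite pH; it is infinite only in the
    literal pH limits.  For a monoprotic compound it reduces to the pKa,
    constant in pH.
    """
    i = system.site_index(site)
    Lp, Ld = _site_log_sums(system, i, pH)
    return np.asarray(pH, dtype=float) + Lp - Ld


def aspa(system: MicrostateSystem, site, pH):
    """Averaged single-proton acidity ``[H+] * (1 - ASP) / ASP`` (may over/underflow)."""
    with np.errstate(over="ignore", under="ignore"):
        return np.power(10.0, -paspa(system, site, pH))


def _check_grid(pH_grid) -> np.ndarray:
    grid = np.asarray(pH_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise SizeError("pH grid must be a nonempty 1-D array")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise SizeError("pH grid must be strictly ascending")
    return grid


def default_grid(pH_min: float = 0.0, pH_max: float = 14.0, step: float = 0.1) -> np.ndarray:
    """Inclusive pH grid, endpoint-safe against float accumulation."""
    n = int(round((pH_max - pH_min) / step))
    return pH_min + step * np.arange(n + 1)


def profile(system: MicrostateSystem, site, pH_grid) -> TitrationProfile:
    """Vectorized ASP and pASPA over an ascending pH grid."""
    grid = _check_grid(pH_grid)
    i = system.site_index(site)
    Lp, Ld = _site_log_sums(system, i, grid)
    return TitrationProfile(
        site=system.sites[i],
        pH_grid=grid,
        asp=expit((Lp - Ld) * LN10),
        paspa=grid + Lp - Ld,
    )


def asymptotes(system: MicrostateSystem, site) -> tuple[float, float]:
    """Analytic low- and high-pH limits of the site's pASPA profile.

    The low-pH asymptote is the group's microconstant in the fully
    protonated molecule, ``g(all-ones with this site cleared)``; the
    high-pH asymptote is its microconstant when it holds the last proton,
    ``g(all-zeros) - g(only this site protonated)``.
    """
    i = system.site_index(site)
    ones = system.all_ones
    zeros = system.all_zeros
    only_i = zeros[:i] + (1,) + zeros[i + 1 :]
    low = system.energy(ones[:i] + (0,) + ones[i + 1 :]) - system.energy(ones)
    high = system.energy(zeros) - system.energy(only_i)
    return low, high


def pk50(
    system: MicrostateSystem,
    site,
    window: tuple[float, float] = DEFAULT_WINDOW,
    step: float = DEFAULT_STEP,
    xtol: float = 1e-12,
    report_pH: Sequence[float] = (7.4,),
    strict: bool = False,
) -> SiteReport:
    """Locate the single-proton midpoint(s) of a site's ASP curve.

    A coarse scan over ``window`` brackets every sign change of
    ``ASP - 1/2``; each bracket is refined by bisection (ASP is cheap and
    the bracket guaranteed, so no derivative method is needed).  If the
    crossing is unique it is reported as ``pk50``; multiple crossings are
    all returned with ``pk50`` unset (strict mode raises instead).

    Raises
    ------
    WindowError
        If no crossing lies inside the scan window; widen ``window``.
    """
    i = system.site_index(site)
    lo, hi = window
    n_steps = int(np.ceil((hi - lo) / step))
    grid = lo + (hi - lo) * np.arange(n_steps + 1) / n_steps
    f = asp(system, i, grid) - 0.5

    crossings: list[float] = []
    for k in range(len(grid) - 1):
        a, b = f[k], f[k + 1]
        if a == 0.0:
            crossings.append(float(grid[k]))
        elif a * b < 0.0:
            root = bisect(
                lambda x: float(asp(system, i, float(x)) - 0.5),
                float(grid[k]),
                float(grid[k + 1]),
                xtol=xtol,
            )
            crossings.append(float(root))
    if f[-1] == 0.0:
        crossings.append(float(grid[-1]))

    if not crossings:
        raise WindowError(
            f"ASP of site {system.sites[i].label!r} never crosses 1/2 inside "
            f"pH window {window}; widen the window"
        )
    if len(crossings) > 1 and strict:
        raise ConsistencyError(
            f"site {system.sites[i].label!r} has {len(crossings)} ASP midpoints: "
            f"{crossings}"
        )

    low, high = asymptotes(system, i)
    return SiteReport(
        site=system.sites[i],
        pk50=crossings[0] if len(crossings) == 1 else None,
        crossings=crossings,
        paspa_low=low,
        paspa_high=high,
        asp_at={float(p): float(asp(system, i, float(p))) for p in report_pH},
    )


def bjerrum(system: MicrostateSystem, pH_grid) -> np.ndarray:
    """Average bound protons over a pH grid (the fraction-ionized profile).

    The whole-molecule binding curve is the simple sum of the individual
    per-site ASP curves; this is verified on every call as an internal
    cross-check of the two computation paths.
    """
    grid = _check_grid(pH_grid)
    nb = nbar(system, grid)
    total = np.zeros_like(nb)
    for s in system.sites:
        total = total + asp(system, s.index, grid)
    if np.max(np.abs(nb - total)) > 1e-10:
        raise ConsistencyError(
            "nbar and the sum of per-site ASP curves disagree beyond 1e-10"
        )
    return nb
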