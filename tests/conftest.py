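"""Shared fixtures and independent oracles.

The oracle functions here deliberately avoid the package's log-sum-exp
machinery: they evaluate statistical weights as plain powers of ten and
normalize naively, which is accurate for the small, well-scaled systems
used in tests and provides an independent computation path.
"""

from __future__ import annotations

import numpy as np
import pytest

from micropka import (
    MicrostateSystem,
    PairwiseModel,
    from_pairwise,
    monoprotic,
    symmetric_system,
)


@pytest.fixture
def mono4() -> MicrostateSystem:
    """Monoprotic acid with pKa 4."""
    return monoprotic(4.0)


@pytest.fixture
def coupled_diprotic() -> MicrostateSystem:
    """Two equivalent sites, intrinsic pKa 5, anticooperative coupling 2."""
    return symmetric_system(2, 5.0, 2.0)


@pytest.fixture
def indep_pair() -> MicrostateSystem:
    """Two identical independent sites, intrinsic pKa 5 (statistical factors)."""
    return symmetric_system(2, 5.0, 0.0)


@pytest.fixture
def triprotic_drug_like() -> MicrostateSystem:
    """Three coupled sites (carboxyl-like, amine-like, amine-like):
    intrinsic pKa 2, 3, 8 with pairwise couplings 1-2 log units."""
    coupling = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.5], [2.0, 1.5, 0.0]])
    return from_pairwise(
        PairwiseModel(np.array([2.0, 3.0, 8.0]), coupling), name="triprotic"
    )


@pytest.fixture
def hexaprotic_symmetric() -> MicrostateSystem:
    """Six equivalent acid sites, like a symmetric hexacarboxylic acid."""
    return symmetric_system(6, 2.0, 0.7)


# -- independent oracles -----------------------------------------------------


def naive_populations(system: MicrostateSystem, pH: float) -> np.ndarray:
    """Microstate probabilities by direct power-of-ten arithmetic."""
    w = np.array(
        [10.0 ** (float(d) * pH - g) for d, g in zip(system.d, system.g)]
    )
    return w / w.sum()


def naive_asp(system: MicrostateSystem, site: int, pH: float) -> float:
    """Per-site protonation probability summed over the naive populations."""
    p = naive_populations(system, pH)
    mask = np.array([s[site] == 1 for s in system.states])
    return float(p[mask].sum())
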