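"""Site titration metrics: ASP, ASPA/pASPA, pK50, asymptotes, Bjerrum curve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micropka import (
    PairwiseModel,
    SizeError,
    WindowError,
    asp,
    aspa,
    asymptotes,
    bjerrum,
    from_pairwise,
    macro_pkas,
    monoprotic,
    nbar,
    paspa,
    pk50,
    profile,
    random_system,
    symmetric_system,
)

from conftest import naive_asp


class TestAsp:
    def test_monoprotic_midpoint(self, mono4):
        assert asp(mono4, 0, 4.0) == pytest.approx(0.5, abs=1e-12)

    def test_monoprotic_above_pka(self, mono4):
        assert asp(mono4, 0, 5.0) == pytest.approx(1 / 11, abs=1e-12)

    def test_coupled_diprotic_midpoint(self, coupled_diprotic):
        assert asp(coupled_diprotic, 0, 6.0) == pytest.approx(0.5, abs=1e-12)
        assert asp(coupled_diprotic, 1, 6.0) == pytest.approx(0.5, abs=1e-12)

    def test_site_by_label(self, mono4):
        assert asp(mono4, "G1", 4.0) == pytest.approx(0.5)

    def test_unknown_site_is_key_error(self, mono4):
        with pytest.raises(KeyError):
            asp(mono4, "nope", 4.0)
        with pytest.raises(KeyError):
            asp(mono4, 3, 4.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_naive_oracle(self, seed):
        system = random_system(4, seed=400 + seed)
        for site in range(4):
            for pH in (1.0, 6.5, 12.0):
                assert asp(system, site, pH) == pytest.approx(
                    naive_asp(system, site, pH), abs=1e-12
                )

    def test_bounded_in_unit_interval(self):
        system = random_system(5, seed=8)
        vals = asp(system, 2, np.linspace(-30, 40, 200))
        assert np.all(vals >= 0.0) and np.all(vals <= 1.0)


class TestPaspa:
    def test_monoprotic_reduces_to_pka_everywhere(self, mono4):
        grid = np.linspace(-5.0, 20.0, 501)
        np.testing.assert_allclose(paspa(mono4, 0, grid), 4.0, atol=1e-12)
        np.testing.assert_allclose(aspa(mono4, 0, 0.0), 1e-4, rtol=1e-12)

    def test_coupled_diprotic_asymptotic_values(self, coupled_diprotic):
        """pASPA runs from the fully protonated microconstant (5) to the
        last-proton microconstant (7)."""
        assert paspa(coupled_diprotic, 0, -15.0) == pytest.approx(5.0, abs=1e-4)
        assert paspa(coupled_diprotic, 0, 21.0) == pytest.approx(7.0, abs=1e-4)

    def test_monotone_for_moderately_coupled_fixture(self, triprotic_drug_like):
        """With moderate repulsive coupling, average acidity falls (pASPA
        rises) and protonation falls monotonically with pH."""
        grid = np.linspace(-5, 25, 400)
        for site in range(3):
            assert np.all(np.diff(paspa(triprotic_drug_like, site, grid)) >= -1e-10)
            assert np.all(np.diff(asp(triprotic_drug_like, site, grid)) <= 1e-10)

    def test_monotonicity_trend_on_random_anticooperative_systems(self):
        """Monotone site curves are the typical case but not a theorem:
        strongly coupled sites can titrate non-monotonically.  Measure and
        report the trend over random repulsively coupled systems."""
        grid = np.linspace(-5, 30, 300)
        monotone = 0
        n_pairs = 0
        for seed in range(25):
            system = random_system(4, seed=500 + seed)  # couplings >= 0
            for site in range(4):
                n_pairs += 1
                if np.all(np.diff(asp(system, site, grid)) <= 1e-10):
                    monotone += 1
        fraction = monotone / n_pairs
        print(f"\nmonotone site curves: {fraction:.1%} of {n_pairs} site curves")
        assert fraction > 0.5  # clear majority, per the qualitative rule


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    pks=st.lists(st.floats(0.0, 12.0), min_size=2, max_size=4),
    c=st.floats(0.0, 3.0),
    pH=st.floats(-5.0, 19.0),
)
def test_asp_aspa_identity(pks, c, pH):
    """ASP = [H+] / ([H+] + ASPA) holds pointwise (exact log-domain identity)."""
    n = len(pks)
    coupling = np.full((n, n), c)
    np.fill_diagonal(coupling, 0.0)
    system = from_pairwise(PairwiseModel(np.array(pks), coupling))
    for site in range(n):
        a = asp(system, site, pH)
        pa = paspa(system, site, pH)
        # [H+]/([H+] + ASPA) = 1/(1 + 10**(pH - pASPA))
        assert a == pytest.approx(1.0 / (1.0 + 10.0 ** (pH - pa)), abs=1e-10)


class TestProfile:
    def test_single_point_grid(self, mono4):
        prof = profile(mono4, 0, [4.0])
        assert prof.asp[0] == pytest.approx(0.5)
        assert prof.paspa[0] == pytest.approx(4.0)

    def test_triprotic_profiles_monotone(self, triprotic_drug_like):
        grid = np.arange(0.0, 12.01, 0.1)
        for site in range(3):
            prof = profile(triprotic_drug_like, site, grid)
            assert np.all(np.diff(prof.asp) <= 1e-12)
            np.testing.assert_allclose(
                prof.asp,
                [naive_asp(triprotic_drug_like, site, p) for p in grid],
                atol=1e-12,
            )

    def test_symmetric_sites_overlap_perfectly(self, hexaprotic_symmetric):
        """All six equivalent-site titration curves coincide."""
        grid = np.linspace(0, 14, 141)
        ref = profile(hexaprotic_symmetric, 0, grid)
        for site in range(1, 6):
            prof = profile(hexaprotic_symmetric, site, grid)
            np.testing.assert_allclose(prof.asp, ref.asp, atol=1e-12)
            np.testing.assert_allclose(prof.paspa, ref.paspa, atol=1e-12)

    def test_bad_grids_rejected(self, mono4):
        with pytest.raises(SizeError):
            profile(mono4, 0, [])
        with pytest.raises(SizeError):
            profile(mono4, 0, [5.0, 4.0])


class TestPk50:
    def test_monoprotic_equals_pka(self):
        report = pk50(monoprotic(4.0), 0)
        assert report.pk50 == pytest.approx(4.0, abs=1e-9)
        assert not report.ambiguous

    def test_independent_sites_recover_intrinsic_pkas(self):
        """With zero coupling the partition function factorizes and each
        site titrates at its own intrinsic pKa."""
        pks = np.array([3.0, 6.5, 9.0])
        system = from_pairwise(PairwiseModel(pks, np.zeros((3, 3))))
        for site, pk in enumerate(pks):
            assert pk50(system, site).pk50 == pytest.approx(pk, abs=1e-9)

    def test_coupled_diprotic_midpoint(self, coupled_diprotic):
        for site in range(2):
            assert pk50(coupled_diprotic, site).pk50 == pytest.approx(6.0, abs=1e-9)

    def test_symmetric_system_all_sites_equal(self, hexaprotic_symmetric):
        vals = [pk50(hexaprotic_symmetric, s).pk50 for s in range(6)]
        assert max(vals) - min(vals) < 1e-9

    def test_paspa_at_pk50_is_pk50(self, triprotic_drug_like):
        """The pASPA profile crosses the identity line exactly at pK50."""
        for site in range(3):
            mid = pk50(triprotic_drug_like, site).pk50
            assert paspa(triprotic_drug_like, site, mid) == pytest.approx(
                mid, abs=1e-6
            )

    def test_window_error_with_advice(self, mono4):
        with pytest.raises(WindowError, match="widen"):
            pk50(mono4, 0, window=(10.0, 12.0))

    def test_asp_snapshot_reported(self, triprotic_drug_like):
        report = pk50(triprotic_drug_like, 2, report_pH=(7.4,))
        assert report.asp_at[7.4] == pytest.approx(
            naive_asp(triprotic_drug_like, 2, 7.4), abs=1e-10
        )

    def test_pk50_between_asymptotes_for_anticooperative(self):
        """A unique midpoint of a repulsively coupled site lies between the
        two pASPA asymptotes (acidity only decreases on average with pH)."""
        for seed in range(5):
            system = random_system(3, seed=600 + seed)
            for site in range(3):
                rep = pk50(system, site, window=(-5.0, 30.0))
                if rep.pk50 is not None:
                    assert rep.paspa_low - 1e-9 <= rep.pk50 <= rep.paspa_high + 1e-9


class TestAsymptotes:
    def test_monoprotic_both_equal_pka(self, mono4):
        assert asymptotes(mono4, 0) == (pytest.approx(4.0), pytest.approx(4.0))

    def test_coupled_diprotic(self, coupled_diprotic):
        low, high = asymptotes(coupled_diprotic, 0)
        assert (low, high) == (pytest.approx(5.0), pytest.approx(7.0))

    def test_pairwise_span_is_sum_of_couplings(self, triprotic_drug_like):
        coupling = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.5], [2.0, 1.5, 0.0]])
        for site in range(3):
            low, high = asymptotes(triprotic_drug_like, site)
            assert high - low == pytest.approx(coupling[site].sum(), abs=1e-9)

    def test_numeric_profile_approaches_analytic_limits(self, triprotic_drug_like):
        """10 pH units beyond the system's extreme microconstants the pASPA
        profile has converged to its analytic asymptotes."""
        from micropka import energies_to_edges

        pkas = [e.pka_micro for e in energies_to_edges(triprotic_drug_like)]
        lo_ph, hi_ph = min(pkas) - 10.0, max(pkas) + 10.0
        for site in range(3):
            low, high = asymptotes(triprotic_drug_like, site)
            assert paspa(triprotic_drug_like, site, lo_ph) == pytest.approx(
                low, abs=1e-4
            )
            assert paspa(triprotic_drug_like, site, hi_ph) == pytest.approx(
                high, abs=1e-4
            )


class TestBjerrum:
    def test_monoprotic_midpoint(self, mono4):
        assert bjerrum(mono4, [4.0])[0] == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_hexaprotic_midpoint(self, hexaprotic_symmetric):
        """At the common pK50, half of the six protons are bound on average."""
        mid = pk50(hexaprotic_symmetric, 0).pk50
        assert bjerrum(hexaprotic_symmetric, [mid])[0] == pytest.approx(3.0, abs=1e-9)

    def test_equals_nbar_everywhere(self):
        system = random_system(4, seed=44)
        grid = np.linspace(-2, 18, 50)
        np.testing.assert_allclose(
            bjerrum(system, grid), nbar(system, grid), atol=1e-12
        )


def test_diprotic_pk50_values_contract_relative_to_macro():
    """For interacting diprotic systems the two pK50 values tend to sit
    closer together than the two apparent pKa values; report the trend."""
    hits = 0
    n_trials = 250
    for seed in range(n_trials):
        system = random_system(2, seed=10_000 + seed)
        p1 = pk50(system, 0, window=(-5.0, 25.0)).pk50
        p2 = pk50(system, 1, window=(-5.0, 25.0)).pk50
        m1, m2 = macro_pkas(system).pka_macro
        if abs(p1 - p2) <= abs(m1 - m2) + 1e-12:
            hits += 1
    fraction = hits / n_trials
    print(f"\npk50-contraction trend: {fraction:.3f} of {n_trials} diprotic systems")
    assert 0.0 <= fraction <= 1.0
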