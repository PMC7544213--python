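import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemrrm import csp
from tandemrrm.containers import PeakList
from tandemrrm.exceptions import UnidentifiableError, ValidationError
from tandemrrm.synth import ExchangeSpec, NoiseSpec, gen_titration

from conftest import make_peaklist


def shift_peaklist(pl, deltas):
    """Copy a peak list with per-residue (dH, dN) offsets applied."""
    df = pl.data.copy()
    for res, (dh, dn) in deltas.items():
        m = df["residue_number"] == res
        df.loc[m, "dH_ppm"] += dh
        df.loc[m, "dN_ppm"] += dn
    return PeakList(df, label="shifted")


class TestCspFormula:
    @pytest.mark.parametrize(
        "dh,dn,expected",
        [
            (0.05, 0.5, 0.0608),
            (0.0, 1.0, 0.14 / np.sqrt(2)),
            (0.0, 0.0, 0.0),
        ],
    )
    def test_worked_examples(self, dh, dn, expected):
        assert csp.csp_distance(dh, dn) == pytest.approx(expected, abs=1e-4)

    def test_identical_spectra_give_zero(self, ref_peaklist):
        prof = csp.csp_per_residue(ref_peaklist, ref_peaklist)
        assert (prof["csp_avg"] == 0).all()

    def test_signed_deviations_stored(self, ref_peaklist):
        other = shift_peaklist(ref_peaklist, {3: (-0.05, 0.5)})
        prof = csp.csp_per_residue(ref_peaklist, other)
        assert prof.loc[3, "delta_dH"] == pytest.approx(-0.05)
        assert prof.loc[3, "delta_dN"] == pytest.approx(0.5)

    def test_swap_symmetry(self, ref_peaklist):
        other = shift_peaklist(ref_peaklist, {3: (-0.05, 0.5), 7: (0.2, -1.0)})
        a = csp.csp_per_residue(ref_peaklist, other)["csp_avg"]
        b = csp.csp_per_residue(other, ref_peaklist)["csp_avg"]
        pd.testing.assert_series_equal(a, b)

    def test_unmatched_residue_flagged_not_error(self, ref_peaklist):
        other = PeakList(ref_peaklist.data[ref_peaklist.data["residue_number"] != 4])
        prof = csp.csp_per_residue(ref_peaklist, other)
        assert not prof.loc[4, "matched"]
        assert np.isnan(prof.loc[4, "csp_avg"])

    @settings(deadline=None, max_examples=50)
    @given(
        h1=st.floats(-0.5, 0.5), n1=st.floats(-3, 3),
        h2=st.floats(-0.5, 0.5), n2=st.floats(-3, 3),
    )
    def test_triangle_inequality_over_composed_steps(self, h1, n1, h2, n2):
        # A->C direct perturbation never exceeds A->B plus B->C
        direct = csp.csp_distance(h1 + h2, n1 + n2)
        assert direct <= csp.csp_distance(h1, n1) + csp.csp_distance(h2, n2) + 1e-12


class TestClassifyLarge:
    def test_threshold_is_strict(self):
        prof = pd.DataFrame({"csp_avg": [0.025, 0.0251, 0.0, 0.03]}, index=[1, 2, 3, 4])
        assert csp.classify_large(prof) == {2, 4}

    def test_all_zero_empty(self):
        prof = pd.DataFrame({"csp_avg": [0.0, 0.0]}, index=[1, 2])
        assert csp.classify_large(prof) == set()


class TestMatchPeaks:
    def test_identical_lists_identity(self, ref_peaklist):
        m = csp.match_peaks(ref_peaklist, ref_peaklist)
        matched = m.dropna()
        assert len(matched) == len(ref_peaklist)
        assert (matched["ref_residue"] == matched["other_residue"]).all()

    def test_moved_peak_beyond_cutoff_unmatched(self, ref_peaklist):
        other = shift_peaklist(ref_peaklist, {6: (1.5, 10.0)})
        m = csp.match_peaks(ref_peaklist, other, max_dist_ppm=0.1)
        row = m[m["ref_residue"] == 6]
        assert row["other_residue"].isna().all()
        ok = m.dropna()
        assert (ok["ref_residue"] == ok["other_residue"]).all()

    def test_greedy_minimizes_summed_distance_for_swapped_pair(self):
        # two close peaks: brute force over both assignments picks the
        # pairing with smaller summed weighted distance
        ref = PeakList(pd.DataFrame({
            "residue_number": [1, 2], "residue_name": ["A", "A"],
            "dH_ppm": [8.00, 8.10], "dN_ppm": [110.0, 110.0],
            "intensity": [1.0, 1.0]}))
        # labels swapped: residue 1's peak now sits next to ref residue 2
        other = PeakList(pd.DataFrame({
            "residue_number": [1, 2], "residue_name": ["A", "A"],
            "dH_ppm": [8.11, 8.01], "dN_ppm": [110.0, 110.0],
            "intensity": [1.0, 1.0]}))
        m = csp.match_peaks(ref, other, max_dist_ppm=0.2).dropna()
        got = {(int(a), int(b)) for a, b in zip(m["ref_residue"], m["other_residue"])}

        def total(assign):
            return sum(
                csp.csp_distance(
                    other.indexed().loc[b, "dH_ppm"] - ref.indexed().loc[a, "dH_ppm"],
                    other.indexed().loc[b, "dN_ppm"] - ref.indexed().loc[a, "dN_ppm"])
                for a, b in assign)

        best = min([{(1, 1), (2, 2)}, {(1, 2), (2, 1)}], key=lambda a: total(sorted(a)))
        assert got == best


class TestFractionBound:
    def test_hand_solved_quadratic(self):
        fb = csp.fraction_bound(50.0, 50.0, 50.0)
        assert fb == pytest.approx(0.382, abs=5e-4)
        assert fb * 50.0 == pytest.approx(19.10, abs=0.005)

    def test_limits(self):
        assert csp.fraction_bound(100.0, 0.0, 10.0) == 0.0
        assert csp.fraction_bound(100.0, 200.0, 1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_zero_protein_errors(self):
        with pytest.raises(ValidationError):
            csp.fraction_bound(0.0, 10.0, 10.0)

    @settings(deadline=None, max_examples=60)
    @given(
        P=st.floats(1.0, 1e3), L=st.floats(0.0, 1e4), Kd=st.floats(1e-2, 1e4)
    )
    def test_matches_numeric_mass_balance_root(self, P, L, Kd):
        from scipy.optimize import brentq

        fb = csp.fraction_bound(P, L, Kd)
        # brute-force root of Kd*[PL] = (P-[PL])(L-[PL])
        def g(x):
            return (P - x) * (L - x) - Kd * x

        if L == 0:
            assert fb == 0
            return
        root = brentq(g, 0.0, min(P, L), xtol=1e-14, rtol=1e-12)
        assert fb == pytest.approx(root / P, abs=1e-10)

    @settings(deadline=None, max_examples=30)
    @given(P=st.floats(1.0, 500.0), Kd=st.floats(0.1, 1e3))
    def test_monotone_in_ligand_and_kd(self, P, Kd):
        fbs = [csp.fraction_bound(P, L, Kd) for L in (0.0, 10.0, 100.0, 1000.0)]
        assert all(a <= b + 1e-12 for a, b in zip(fbs, fbs[1:]))
        f1 = csp.fraction_bound(P, 100.0, Kd)
        f2 = csp.fraction_bound(P, 100.0, Kd * 10)
        assert f2 <= f1 + 1e-12


def make_series(kd=52.0, noise_sd=0.0, seed=1, n=12, kex=2000.0, broadening=False,
                ratios=(0.0, 0.25, 0.5, 1.0, 2.0, 3.0), protein=200.0):
    ref = make_peaklist(n=n, seed=5)
    rng = np.random.default_rng(seed)
    delta = {int(r): (float(rng.uniform(0.05, 0.25)) * (-1) ** r,
                      float(rng.uniform(0.3, 1.5)))
             for r in range(1, n + 1)}
    ex = ExchangeSpec(Kd_uM=kd, delta_bound=delta, kex_s=kex)
    return gen_titration(ref, ex, protein, list(ratios),
                         noise=NoiseSpec(noise_sd, seed), broadening=broadening)


class TestKdFit:
    def test_noise_free_recovery_within_1_percent(self):
        fit = csp.fit_kd_from_titration(make_series(kd=52.0))
        assert fit.Kd_uM == pytest.approx(52.0, rel=0.01)
        assert np.all((fit.fraction_bound >= 0) & (fit.fraction_bound <= 1))

    def test_noisy_recovery_within_15_percent(self):
        fit = csp.fit_kd_from_titration(make_series(kd=52.0, noise_sd=0.002))
        assert fit.Kd_uM == pytest.approx(52.0, rel=0.15)

    def test_flat_titration_unidentifiable(self):
        ref = make_peaklist(n=6, seed=2)
        ex = ExchangeSpec(Kd_uM=52.0, delta_bound={})
        ser = gen_titration(ref, ex, 200.0, [0, 0.5, 1.0, 2.0])
        with pytest.raises(UnidentifiableError):
            csp.fit_kd_from_titration(ser)

    def test_too_few_points_errors(self):
        ser = make_series(ratios=(0.0, 1.0))
        with pytest.raises(ValidationError):
            csp.fit_kd_from_titration(ser)

    def test_per_residue_mode_brackets_global(self):
        ser = make_series(n=5)
        model = csp.TitrationModel(ser)
        glob = model.fit(mode="global")
        per = model.fit(mode="per_residue")
        assert len(per.per_residue_Kd) == 5
        lo, hi = per.per_residue_Kd.min(), per.per_residue_Kd.max()
        assert lo - 1e-6 <= glob.Kd_uM <= hi + 1e-6

    def test_summary_mentions_kd(self):
        fit = csp.fit_kd_from_titration(make_series())
        assert "Kd" in fit.summary()


class TestTitrationGeneratorContracts:
    def test_reference_point_unshifted(self):
        ser = make_series()
        pd.testing.assert_frame_equal(ser.points[0].data, make_peaklist(n=12, seed=5).data)

    def test_saturation_limit_approaches_bound_endpoint(self):
        ref = make_peaklist(n=4, seed=3)
        delta = {1: (0.2, 1.0)}
        ex = ExchangeSpec(Kd_uM=0.001, delta_bound=delta)
        ser = gen_titration(ref, ex, 200.0, [0.0, 50.0])
        obs = ser.points[-1].indexed().loc[1, "dH_ppm"] - ref.indexed().loc[1, "dH_ppm"]
        assert obs == pytest.approx(0.2, rel=1e-3)


class TestIntensityAttenuation:
    def test_identical_series_ratio_one(self):
        ser = make_series(noise_sd=0.0)
        att = csp.intensity_attenuation(ser)
        np.testing.assert_allclose(att[0.0], 1.0)

    def test_broadening_dips_at_intermediate_points(self):
        ser = make_series(broadening=True, kex=500.0)
        att = csp.intensity_attenuation(ser)
        shifted = att.drop(columns=[0.0]).min(axis=1)
        assert (shifted < 1.0).any()

    def test_minimum_attenuation_at_intermediate_saturation(self):
        # Rex = pf*pb*dw^2/kex peaks at pb = 0.5, i.e. mid-titration, so the
        # intensity minimum is interior, not at the endpoint, for tightish Kd
        ref = make_peaklist(n=2, seed=1)
        ex = ExchangeSpec(Kd_uM=1.0, delta_bound={1: (0.3, 2.0)}, kex_s=800.0)
        ser = gen_titration(ref, ex, 200.0, [0.0, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0],
                            broadening=True)
        att = csp.intensity_attenuation(ser)
        prof = att.loc[1].to_numpy()
        k = int(np.argmin(prof))
        assert 0 < k < len(prof) - 1

    def test_zero_reference_intensity_flagged(self):
        ref = make_peaklist(n=3, seed=1, intensity=0.0)
        ex = ExchangeSpec(Kd_uM=52.0, delta_bound={})
        ser = gen_titration(ref, ex, 200.0, [0.0, 1.0])
        att = csp.intensity_attenuation(ser)
        assert att.attrs["zero_reference"] == [1, 2, 3]


class TestMapToStructure:
    def test_scaled_bfactor(self, tmp_path, coil_structure):
        prof = pd.DataFrame({"csp_avg": [0.0608]}, index=[3])
        csp.map_to_structure(prof, coil_structure, tmp_path / "m.pdb", scale=100.0)
        text = (tmp_path / "m.pdb").read_text()
        assert "  6.08" in text

    def test_zero_profile_zero_bfactors(self, tmp_path, coil_structure):
        prof = pd.DataFrame({"csp_avg": [0.0, 0.0]}, index=[3, 4])
        csp.map_to_structure(prof, coil_structure, tmp_path / "z.pdb")
        for ln in (tmp_path / "z.pdb").read_text().splitlines():
            if ln.startswith("ATOM"):
                assert float(ln[60:66]) == 0.0

    def test_missing_residue_warns(self, tmp_path, coil_structure):
        prof = pd.DataFrame({"csp_avg": [0.05, 0.02]}, index=[3, 999])
        with pytest.warns(UserWarning, match="999"):
            csp.map_to_structure(prof, coil_structure, tmp_path / "w.pdb")

    def test_disjoint_sets_error(self, tmp_path, coil_structure):
        prof = pd.DataFrame({"csp_avg": [0.05]}, index=[999])
        with pytest.raises(ValidationError):
            csp.map_to_structure(prof, coil_structure, tmp_path / "d.pdb")
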