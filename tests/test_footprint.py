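"""Unzipping prediction, curve alignment, open-bp assignment, footprinting."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from dnaclamp.footprint import (
    BindingEvent,
    Fdc,
    HairpinConstruct,
    STEP_CLASSES,
    UnzipTheory,
    align_fdc,
    assign_fdc,
    assign_open_bp,
    canonical_step,
    detect_binding_events,
    nn_energy_profile,
    predict_equilibrium_fdc,
    score_binding_sites,
    step_degeneracies,
    theoretical_extension,
)
from dnaclamp.polymer import fjc_extension, wlc_extension
from dnaclamp.synth import gen_hairpin, gen_unzip_pair


class TestNnEnergies:
    def test_gc_more_stable_than_at(self):
        gc = nn_energy_profile("GCGCGCGCGC").mean()
        at = nn_energy_profile("ATATATATAT").mean()
        assert gc > at

    def test_reverse_complement_invariance(self):
        seq = "ACGGTTACGCATG"
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert nn_energy_profile(seq).sum() == pytest.approx(nn_energy_profile(rc).sum(), rel=1e-12)

    def test_salt_destabilizes_at_low_ionic_strength(self):
        assert nn_energy_profile("ACGTACGT", salt=0.01).mean() < nn_energy_profile(
            "ACGTACGT", salt=1.0
        ).mean()

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            nn_energy_profile("ACGTN")


class TestTheoreticalExtension:
    def test_closed_hairpin_is_handles_plus_bead(self, theory480):
        F = 12.0
        x = theoretical_extension(0, F, theory480)
        xb = F / (theory480.construct.k_trap / 1000.0)
        xh = wlc_extension(F, theory480.handle, "extensible")
        assert x == pytest.approx(xb + xh, rel=1e-12)

    def test_monotone_in_open_bp(self, theory480, rng):
        for _ in range(5):
            F = rng.uniform(5, 25)
            xs = [theoretical_extension(n, F, theory480) for n in range(0, 481, 40)]
            assert np.all(np.diff(xs) > 0)

    def test_composes_polymer_models(self, theory480):
        """Full unzip: ssDNA term equals the FJC of 2N bases."""
        F = 15.0
        x = theoretical_extension(480, F, theory480)
        x0 = theoretical_extension(0, F, theory480)
        assert x - x0 == pytest.approx(fjc_extension(F, theory480.fjc, 960), rel=1e-10)

    def test_out_of_range_rejected(self, theory480):
        with pytest.raises(ValueError):
            theoretical_extension(481, 10.0, theory480)


class TestPredictFdc:
    def test_at_insert_dips_below_gc_baseline(self):
        seq = "GC" * 60 + "AT" * 30 + "GC" * 60
        theory = UnzipTheory.from_construct(HairpinConstruct(stem_sequence=seq))
        fdc = predict_equilibrium_fdc(theory, spacing=1.0)
        at_zone = (fdc.n > 125) & (fdc.n < 170)
        gc_zone = (fdc.n > 20) & (fdc.n < 110)
        assert fdc.force[at_zone].mean() < fdc.force[gc_zone].mean()

    def test_thermal_mean_tracks_zero_temperature_argmin(self, theory480):
        """Boltzmann mean open-bp number stays within thermal rounding of an
        independently computed minimum-energy state away from rips."""
        fdc = predict_equilibrium_fdc(theory480, spacing=2.0)
        kBT = theory480.kBT
        cum = np.concatenate([[0.0], np.cumsum(theory480.dg_open)])
        k_trap = theory480.construct.k_trap / 1000.0

        def x_tot(n, F):
            return (
                F / k_trap
                + wlc_extension(F, theory480.handle, "extensible")
                + fjc_extension(F, theory480.fjc, 2 * n)
            )

        def helmholtz(n, X):
            try:
                F = brentq(lambda f: x_tot(n, f) - X, 1e-3, 40.0, xtol=1e-10)
            except ValueError:
                return np.inf  # state cannot balance this position
            w_h = quad(lambda f: wlc_extension(f, theory480.handle, "extensible"), 0, F, limit=200)[0]
            w_ss = quad(lambda f: fjc_extension(f, theory480.fjc, 2 * n), 0, F, limit=200)[0]
            a_el = F**2 / (2 * k_trap) + (F * x_tot(n, F) - F**2 / k_trap) - w_h - w_ss
            return cum[n] + a_el / kBT

        idx = np.linspace(40, fdc.distance.size - 40, 6).astype(int)
        for i in idx:
            X = fdc.distance[i]
            ns = np.arange(max(0, int(fdc.n[i]) - 60), min(480, int(fdc.n[i]) + 60))
            A = [helmholtz(int(n), X) for n in ns]
            n_star = ns[int(np.argmin(A))]
            assert abs(fdc.n[i] - n_star) <= 12  # thermal rounding across a rip

    def test_sample_mode_is_seeded(self, theory480):
        a = predict_equilibrium_fdc(theory480, spacing=4.0, mode="sample", rng=np.random.default_rng(5))
        b = predict_equilibrium_fdc(theory480, spacing=4.0, mode="sample", rng=np.random.default_rng(5))
        assert np.array_equal(a.force, b.force) and np.array_equal(a.n, b.n)


class TestAlign:
    def test_identity_alignment(self, theory480):
        th = predict_equilibrium_fdc(theory480)
        cal = align_fdc(th, th)
        assert cal.distance_scale == pytest.approx(1.0, abs=1e-6)
        assert cal.force_scale == pytest.approx(1.0, abs=1e-6)
        assert not cal.at_boundary

    def test_distortion_roundtrip(self, theory480):
        th = predict_equilibrium_fdc(theory480)
        distorted = Fdc(distance=th.distance / 1.03, force=th.force / 0.98)
        cal = align_fdc(distorted, th)
        assert cal.distance_scale == pytest.approx(1.03, abs=0.002)
        assert cal.force_scale == pytest.approx(0.98, abs=0.002)

    def test_excessive_distortion_flagged(self, theory480):
        th = predict_equilibrium_fdc(theory480)
        bad = Fdc(distance=th.distance / 1.08, force=th.force)
        assert align_fdc(bad, th).at_boundary


class TestAssignOpenBp:
    def test_exact_on_noise_free_points(self, theory480, rng):
        """Every synthetic (x_th(n, F), F) point maps back to exactly n."""
        for n in range(0, 481, 16):
            F = rng.uniform(8.0, 20.0)
            x = theoretical_extension(n, F, theory480)
            assert assign_open_bp(x, F, theory480) == n

    def test_clamped_below_zero(self, theory480):
        x_low = theoretical_extension(0, 10.0, theory480) - 50.0
        assert assign_open_bp(x_low, 10.0, theory480) == 0

    def test_tie_breaks_toward_smaller_n(self, theory480):
        F = 15.0
        x_mid = 0.5 * (
            theoretical_extension(100, F, theory480) + theoretical_extension(101, F, theory480)
        )
        assert assign_open_bp(x_mid, F, theory480) == 100


class TestDetectEvents:
    def test_ligand_free_pair_gives_no_events(self, hairpin480, theory480):
        unz, rez, _ = gen_unzip_pair(hairpin480, seed=11, theory=theory480)
        assert detect_binding_events(unz, rez, theory480) == []

    def test_planted_event_recovered(self, hairpin480, theory480):
        unz, rez, _ = gen_unzip_pair(hairpin480, planted_events=[(201, 10.0)], seed=21, theory=theory480)
        events = detect_binding_events(unz, rez, theory480)
        assert len(events) >= 1
        best = min(events, key=lambda e: abs(e.n_hat - 200))
        assert abs(best.n_hat - 200) <= 2  # fork stalls at n = j - 1
        assert best.rupture_force > best.baseline_force + 2.0

    def test_rezip_blocking_artifacts_not_called(self, hairpin480, theory480):
        """Kinetic states that delay refolding enrich the rezip histogram only
        and must not appear as binding."""
        unz, rez, _ = gen_unzip_pair(
            hairpin480, rezip_artifacts=[(240, 6.0)], seed=31, theory=theory480
        )
        assert detect_binding_events(unz, rez, theory480) == []

    def test_ligand_free_histograms_match(self, hairpin480, theory480):
        """Unzip and rezip n-histograms agree bin-wise within Poisson noise."""
        unz, rez, _ = gen_unzip_pair(hairpin480, seed=41, theory=theory480)
        assign_fdc(unz, theory480)
        assign_fdc(rez, theory480)
        hu = np.bincount(unz.n, minlength=481).astype(float)
        hr = np.bincount(rez.n, minlength=481).astype(float)
        resid = np.abs(hu - hr) / np.sqrt(np.maximum(hu + hr, 1.0))
        assert np.mean(resid <= 4.0) > 0.99


class TestScoring:
    def test_uniform_events_give_uniform_pnorm(self, hairpin480):
        """Events distributed proportionally to degeneracy score 1/10 each."""
        deg = step_degeneracies(hairpin480.stem_sequence)
        seq = hairpin480.stem_sequence
        events = []
        counts = dict.fromkeys(STEP_CLASSES, 0)
        for j in range(1, len(seq)):
            cls = canonical_step(seq[j - 1 : j + 1])
            if counts[cls] < deg[cls]:  # every step occurrence once
                counts[cls] += 1
                events.append(
                    BindingEvent(n_hat=j - 1.5, width=1.0, rupture_force=20.0, baseline_force=15.0)
                )
        table = score_binding_sites(events, hairpin480, offset=2)
        assert np.allclose(table.table["p_norm"], 0.1, atol=1e-12)

    def test_all_cg_events(self, hairpin480):
        seq = hairpin480.stem_sequence
        cg_steps = [j for j in range(1, len(seq)) if seq[j - 1 : j + 1] == "CG"]
        events = [
            BindingEvent(n_hat=j - 1.5, width=1.0, rupture_force=25.0, baseline_force=15.0)
            for j in cg_steps
        ]
        table = score_binding_sites(events, hairpin480, offset=2)
        assert table.p_norm("CG") == pytest.approx(1.0)
        assert sum(table.table["p_norm"]) == pytest.approx(1.0)

    def test_force_threshold_filters_weak_events(self, hairpin480):
        strong = BindingEvent(n_hat=200.0, width=1.0, rupture_force=22.0, baseline_force=15.0)
        weak = BindingEvent(n_hat=100.0, width=1.0, rupture_force=16.0, baseline_force=15.0)
        table = score_binding_sites([strong, weak], hairpin480, force_threshold=5.0)
        assert len(table.events) == 1
        assert table.events[0].n_hat == 200.0

    def test_pnorm_normalized_whenever_events_exist(self, hairpin480, rng):
        events = [
            BindingEvent(
                n_hat=float(rng.integers(5, 470)), width=1.0, rupture_force=20.0, baseline_force=15.0
            )
            for _ in range(25)
        ]
        table = score_binding_sites(events, hairpin480)
        assert table.table["p_norm"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_planted_cg_motifs_dominate_with_at_flanks(self, hairpin480, theory480):
        """Events planted at ACGT motifs score CG highest with A-T flanks."""
        unz, rez, _ = gen_unzip_pair(
            hairpin480, planted_events=[(201, 10.0)], seed=61, theory=theory480
        )
        events = detect_binding_events(unz, rez, theory480)
        table = score_binding_sites(events, hairpin480)
        assert table.p_norm("CG") == max(table.table["p_norm"])
        assert table.flank_freq["AT"] > 0.5


def test_step_degeneracies_match_brute_force(hairpin480):
    seq = hairpin480.stem_sequence
    deg = step_degeneracies(seq)
    for cls in STEP_CLASSES:
        brute = sum(
            1 for i in range(len(seq) - 1) if canonical_step(seq[i : i + 2]) == cls
        )
        assert deg[cls] == brute
    assert sum(deg.values()) == len(seq) - 1
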