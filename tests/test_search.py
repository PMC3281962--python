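"""MGF I/O, Poisson-tail scoring, search, and target-decoy q-values."""

import io
import math

import numpy as np
import pytest

import uniblue as ub
from uniblue.search import PSM, _psm_order

MGF_TEXT = """BEGIN IONS
TITLE=scan1
PEPMASS=500.25
CHARGE=2+
200.1 10.0
300.2 20.0
END IONS

BEGIN IONS
TITLE=scan2
PEPMASS=600.5
CHARGE=3+
210.0 1.0
END IONS

BEGIN IONS
TITLE=scan3
PEPMASS=400.0
111.0 5.0
END IONS
"""


class TestMgf:
    def test_three_blocks(self):
        spectra = ub.read_mgf(io.StringIO(MGF_TEXT))
        assert [s.title for s in spectra] == ["scan1", "scan2", "scan3"]

    def test_charge_dialect(self):
        spectra = ub.read_mgf(io.StringIO(MGF_TEXT))
        assert spectra[0].charge == 2
        assert spectra[1].charge == 3
        assert spectra[2].charge is None

    def test_missing_pepmass_skipped(self, caplog):
        text = "BEGIN IONS\nTITLE=bad\n100.0 1.0\nEND IONS\n" + MGF_TEXT
        with caplog.at_level("WARNING"):
            spectra = ub.read_mgf(io.StringIO(text))
        assert len(spectra) == 3
        assert any("no PEPMASS" in r.message for r in caplog.records)

    def test_roundtrip(self):
        spectra = ub.read_mgf(io.StringIO(MGF_TEXT))
        buf = io.StringIO()
        ub.write_mgf(spectra, buf)
        buf.seek(0)
        back = ub.read_mgf(buf)
        for a, b in zip(spectra, back):
            assert a.title == b.title
            assert a.charge == b.charge
            assert a.precursor_mz == pytest.approx(b.precursor_mz)
            assert np.allclose(a.mz, b.mz)
            assert np.allclose(a.intensity, b.intensity)


class TestScorePsm:
    def test_zero_matches_p_is_one(self):
        spec = ub.Spectrum("t", 500.0, 2,
                           np.array([5000.0, 6000.0]), np.array([1.0, 1.0]))
        k, N, p = ub.score_psm(spec, "PEPTIDER")
        assert k == 0 and p == 1.0

    def test_closed_form_poisson_tail_at_lambda_one(self):
        """Spectrum engineered so the random-match rate is exactly 1 and two
        ions match: p must equal the closed-form tail 1 - 2/e."""
        seq = "PEPTIDEK"
        ions = sorted(i.mz for i in ub.fragment_ladder(seq))
        params = ub.SearchParams()
        n_peaks, N = 10, 2 * (len(seq) - 1)
        span = n_peaks * 2 * params.fragment_tolerance * N  # lambda = 1
        lo = 300.0
        hi = lo + span
        inside = [m for m in ions if lo + 5 < m < hi - 5]
        peaks = [lo, hi, inside[0], inside[1]]
        # fillers far (> 2 Da) from every theoretical ion
        x = lo + 1.3
        while len(peaks) < n_peaks:
            if min(abs(x - m) for m in ions) > 2.0:
                peaks.append(x)
            x += 7.13
        spec = ub.Spectrum("t", 500.0, 2, np.array(peaks), np.ones(len(peaks)))
        k, N_out, p = ub.score_psm(spec, seq, params, max_fragment_charge=1)
        assert (k, N_out) == (2, N)
        assert p == pytest.approx(1 - math.exp(-1) * (1 + 1), rel=1e-6)

    def test_extra_match_never_raises_p(self, rng):
        seq = "LDKELKDTAR"
        ions = sorted(i.mz for i in ub.fragment_ladder(seq))
        base = [100.0, 1500.0] + [x for x in np.linspace(110, 1400, 20)
                                  if min(abs(x - m) for m in ions) > 2.0]
        spec0 = ub.Spectrum("t", 500.0, 2, np.array(base), np.ones(len(base)))
        _, _, p0 = ub.score_psm(spec0, seq, max_fragment_charge=1)
        with_match = base + [ions[3]]
        spec1 = ub.Spectrum("t", 500.0, 2, np.array(with_match),
                            np.ones(len(with_match)))
        _, _, p1 = ub.score_psm(spec1, seq, max_fragment_charge=1)
        assert p1 < p0

    def test_degenerate_scan_range_rejected(self):
        spec = ub.Spectrum("t", 500.0, 2, np.array([400.0, 400.0]),
                           np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="degenerate"):
            ub.score_psm(spec, "PEPTIDER")

    def test_empty_spectrum_rejected(self):
        spec = ub.Spectrum("t", 500.0, 2, np.array([]), np.array([]))
        with pytest.raises(ValueError):
            ub.score_psm(spec, "PEPTIDER")


def _mini_dataset(seed=3, **kw):
    config = ub.SimConfig(seed=seed, n_proteins=10, n_spectra=30,
                          mz_jitter_sd=0.0, n_noise_peaks=0, **kw)
    ds = ub.simulate_dataset(config)
    index = ub.build_index(ub.make_decoy_db(ds.records), min_length=5,
                           max_variable=6)
    return ds, index


class TestSearchDataset:
    def test_noise_free_self_identification(self):
        ds, index = _mini_dataset()
        params = ub.SearchParams(max_variable=6)
        psms = ub.search_dataset(ds.spectra, index, params)
        truth = {t.spectrum_id: t.modform for t in ds.truths}
        assert psms
        for psm in psms:
            assert psm.modform.key() == truth[psm.spectrum_id].key()

    def test_absent_peptide_yields_no_confident_hit(self):
        ds, index = _mini_dataset()
        # peptide not present in the simulated proteome
        foreign = ub.Modform("WWWWHHHHWWWWR")
        cfg = ub.SimConfig(seed=9, mz_jitter_sd=0.0, n_noise_peaks=0)
        spec, _ = ub.simulate_spectrum(foreign, cfg, np.random.default_rng(0))
        psms = ub.search_dataset([spec], index, ub.SearchParams())
        assert not psms or psms[0].p_value > 0.01

    def test_no_candidates_yields_no_psm(self):
        _, index = _mini_dataset()
        spec = ub.Spectrum("t", 9.0, 1, np.array([300.0, 400.0]),
                           np.array([1.0, 1.0]))
        assert ub.search_dataset([spec], index, ub.SearchParams()) == []

    def test_min_length_excluded_before_scoring(self):
        rec = ub.ProteinRecord("p", "", "GGKAAR")
        index = ub.build_index([rec], fixed=(), variable=())
        # precursor matching the tripeptide GGK
        mass = ub.peptide_mass("GGK")
        spec = ub.Spectrum("t", ub.mz_from_mass(mass, 1), 1,
                           np.array([150.0, 250.0]), np.array([1.0, 1.0]))
        assert ub.search_dataset([spec], index, ub.SearchParams()) == []

    def test_uncharged_spectrum_tries_fallback_charges(self):
        ds, index = _mini_dataset()
        pick = next(
            i for i, t in enumerate(ds.truths) if t.charge in (2, 3)
        )
        truth = ds.truths[pick]
        spec = ds.spectra[pick]
        unlabeled = ub.Spectrum(spec.title, spec.precursor_mz, None,
                                spec.mz, spec.intensity)
        psms = ub.search_dataset([unlabeled], index,
                                 ub.SearchParams(max_variable=6))
        assert psms and psms[0].modform.key() == truth.modform.key()

    def test_permissive_evalue_keeps_garbage_hits(self):
        """With the huge E-value cap nothing is discarded before validation:
        even a spectrum matching no ions yields its best candidate."""
        rec = ub.ProteinRecord("p", "", "AAADEFGHIKAAADEFGHIR")
        index = ub.build_index([rec], fixed=(), variable=())
        mass = ub.peptide_mass("AAADEFGHIK")
        spec = ub.Spectrum("t", ub.mz_from_mass(mass, 2), 2,
                           np.array([3000.0, 4000.0]), np.array([1.0, 1.0]))
        psms = ub.search_dataset([spec], index, ub.SearchParams())
        assert len(psms) == 1
        assert psms[0].k == 0 and psms[0].p_value == 1.0


def _psm(e_value, is_decoy, seq="PEPTIDER", k=5):
    return PSM(spectrum_id=f"s{e_value}", modform=ub.Modform(seq),
               protein_id="p", is_decoy=is_decoy, k=k, N=14,
               p_value=min(1.0, e_value), e_value=e_value, n_candidates=1)


class TestComputeFdr:
    def test_hand_computed_small_case(self):
        """10 targets, then 1 decoy, then 5 targets by ascending E-value."""
        psms = (
            [_psm(0.001 * i, False) for i in range(1, 11)]
            + [_psm(0.02, True)]
            + [_psm(0.03 + 0.001 * i, False) for i in range(5)]
        )
        out = ub.compute_fdr(psms)
        qs = [p.q_value for p in out]
        # FDR after the decoy: 1/10; at the very end: 1/15; q is the running
        # minimum from the bottom, so everything from the decoy on gets 1/15
        assert qs[:10] == [0.0] * 10
        assert all(q == pytest.approx(1 / 15) for q in qs[10:])

    def test_zero_decoys(self):
        out = ub.compute_fdr([_psm(0.01 * i, False) for i in range(1, 6)])
        assert all(p.q_value == 0.0 for p in out)

    def test_all_decoys_q_is_one(self):
        out = ub.compute_fdr([_psm(0.01 * i, True) for i in range(1, 6)])
        assert all(p.q_value == 1.0 for p in out)

    def test_q_monotone_any_input(self, rng):
        psms = [
            _psm(float(rng.uniform(0, 1)), bool(rng.random() < 0.4))
            for _ in range(200)
        ]
        out = ub.compute_fdr(psms)
        qs = [p.q_value for p in out]
        assert qs == sorted(qs)
        assert [p.rank for p in out] == list(range(1, 201))

    def test_order_matches_ranking(self, rng):
        psms = [_psm(float(rng.uniform(0, 1)), False) for _ in range(20)]
        out = ub.compute_fdr(psms)
        keys = [_psm_order(p) for p in out]
        assert keys == sorted(keys)


class TestNullCalibration:
    def test_decoy_only_pvalues_super_uniform(self, rng):
        """Random spectra searched against a decoy-only database give
        conservative (super-uniform) p-values: P(p <= a) <= a + slack.

        Exact uniformity is unattainable: the match count is discrete and
        ladder ions outside the peak range can never match, both of which
        push p-values upward (the safe direction for FDR control)."""
        cfg = ub.SimConfig(seed=5, n_proteins=20)
        records, _ = ub.simulate_proteome(cfg, np.random.default_rng(5))
        decoys = [r for r in ub.make_decoy_db(records) if r.is_decoy]
        index = ub.build_index(decoys, min_length=5)
        masses = np.array([e.mass for e in index.entries])
        ps = []
        for i in range(1000):
            m = float(rng.choice(masses))
            mz = rng.uniform(200, 1400, size=50)
            spec = ub.Spectrum(f"r{i}", ub.mz_from_mass(m, 2), 2, mz,
                               np.ones(50))
            hits = ub.search_dataset([spec], index, ub.SearchParams())
            if hits:
                ps.append(hits[0].p_value)
        ps = np.array(ps)
        assert len(ps) >= 900
        for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
            se = math.sqrt(alpha * (1 - alpha) / len(ps))
            assert (ps <= alpha).mean() <= alpha + 3 * se


class TestFdrControl:
    def test_realized_fdp_within_bound(self):
        """Pooled over 20 seeded replicates of the synthetic benchmark, the
        realized false-assignment proportion at nominal q <= 0.05 stays
        below 0.10."""
        accepted = wrong = 0
        for rep in range(20):
            cfg = ub.SimConfig(seed=100 + rep, n_proteins=20, n_spectra=100)
            ds = ub.simulate_dataset(cfg)
            index = ub.build_index(ub.make_decoy_db(ds.records), min_length=5)
            psms = ub.compute_fdr(
                ub.search_dataset(ds.spectra, index, ub.SearchParams())
            )
            truth = {t.spectrum_id: t.modform for t in ds.truths}
            conf = [p for p in psms if p.q_value <= 0.05 and not p.is_decoy]
            accepted += len(conf)
            wrong += sum(
                1 for p in conf if p.modform.key() != truth[p.spectrum_id].key()
            )
        assert accepted > 500
        assert wrong / accepted <= 0.10
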