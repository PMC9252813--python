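"""Candidate retrieval, ranking, evaluation and the library simulator."""

import numpy as np
import pytest

from ms2ident.chem import Formula, Molecule, adduct_mz
from ms2ident.identify import (CandidateRecord, EvaluationReport,
                               SpectralLibrary, evaluate, identify,
                               load_library, retrieve_candidates, save_library,
                               true_compound_rank)
from ms2ident.simulate import NoiseModel, simulate_library
from ms2ident.spectra import SpectrumSet, make_spectrum


def _record(identifier, formula_text, mz_peaks=((100.0, 50.0), (150.0, 100.0))):
    formula = Formula.from_string(formula_text)
    molecule = Molecule(structure="", formula=formula)
    precursor = adduct_mz(formula.mass, "[M+H]+")
    spectra = SpectrumSet.from_spectra([
        make_spectrum(mz_peaks, precursor_mz=precursor, ion_mode="positive",
                      adduct="[M+H]+", collision_energy=20)
    ])
    return CandidateRecord(identifier=identifier, molecule=molecule, spectra=spectra)


class TestRetrieve:
    def test_window_returns_matching_masses(self):
        lib = SpectralLibrary([
            _record("a", "C6H12O6"), _record("b", "C6H12O6"), _record("c", "C12H22O11"),
        ])
        hits = retrieve_candidates(lib, adduct_mz(180.063388, "[M+H]+"), "[M+H]+", 10)
        idents = sorted(h.identifier for h in hits)
        assert idents == ["a", "b"]  # both 180.0634 records, not the 342.1162 one

    def test_far_query_empty(self):
        lib = SpectralLibrary([_record("a", "C6H12O6")])
        assert retrieve_candidates(lib, 500.0, "[M+H]+", 10) == []

    def test_tight_window_still_finds_exact_mass(self):
        lib = SpectralLibrary([_record("a", "C6H12O6")])
        hits = retrieve_candidates(lib, adduct_mz(180.063388, "[M+H]+"), "[M+H]+", 0.1)
        assert len(hits) >= 1

    def test_index_equals_linear_scan(self):
        rng = np.random.default_rng(15)
        library, _ = simulate_library(40, seed=15, noise_model=NoiseModel.none())
        for _ in range(50):
            mz = float(rng.uniform(50, 550))
            ppm = float(rng.uniform(1, 5000))
            got = {r.identifier for r in retrieve_candidates(library, mz, "[M+H]+", ppm)}
            tol = mz * ppm * 1e-6
            want = {
                r.identifier for r in library.records
                if abs(adduct_mz(r.neutral_mass, "[M+H]+") - mz) <= tol
            }
            assert got == want


class TestIdentify:
    def test_self_query_rank1_score1(self, clean_library):
        library, testset = clean_library
        query, true_id = testset[0]
        res = identify(query, library)
        assert res.status == "ok"
        assert res.hits[0].identifier == true_id
        assert res.hits[0].score == pytest.approx(1.0)

    def test_no_candidates_status(self, clean_library):
        library, _ = clean_library
        q = SpectrumSet.from_spectra([
            make_spectrum([(100.0, 50.0)], precursor_mz=9999.0,
                          ion_mode="positive", adduct="[M+H]+", collision_energy=20)
        ])
        res = identify(q, library)
        assert res.status == "no-candidates"
        assert res.hits == ()

    def test_top_n_truncation(self):
        lib = SpectralLibrary([_record(f"c{i}", "C6H12O6") for i in range(5)])
        q = lib["c0"].spectra
        res = identify(q, lib, top_n=1)
        assert len(res.hits) == 1
        assert res.n_candidates == 5

    def test_scores_non_increasing_vs_full_scan(self, clean_library):
        from ms2ident.scoring import multi_energy_score

        library, testset = clean_library
        for query, _ in testset[:5]:
            res = identify(query, library, top_n=None, mass_tol_ppm=3e5)
            scores = [h.score for h in res.hits]
            assert scores == sorted(scores, reverse=True)
            # brute force: score every candidate in the window directly
            brute = sorted(
                (multi_energy_score(query, r.spectra).value
                 for r in retrieve_candidates(library, query.precursor_mz,
                                              "[M+H]+", 3e5)),
                reverse=True,
            )
            assert scores == pytest.approx(brute)


class TestEvaluate:
    def test_counting_identities_on_hand_built_ranks(self):
        # three isobaric candidates; craft queries hitting known ranks
        report = EvaluationReport(
            n_queries=3, frac_rank1=1 / 3, frac_rank_le5=2 / 3,
            frac_rank_le10=2 / 3, frac_correct_formula_top1=2 / 3,
            median_candidates=11,
        )
        assert report.frac_rank1 <= report.frac_rank_le5 <= report.frac_rank_le10

    def test_rank_counting_from_identification(self, clean_library):
        library, testset = clean_library
        query, true_id = testset[1]
        res = identify(query, library, top_n=None)
        assert true_compound_rank(res, true_id) == 1

    def test_all_self_queries_give_perfect_report(self, clean_library):
        library, testset = clean_library
        report = evaluate(testset, library)
        assert report.frac_rank1 == 1.0
        assert report.frac_rank_le5 == 1.0
        assert report.frac_rank_le10 == 1.0
        assert report.frac_correct_formula_top1 == 1.0

    def test_report_matches_recount_oracle(self):
        library, testset = simulate_library(
            20, seed=99, noise_model=NoiseModel(jitter_ppm=5.0, n_spurious=6)
        )
        report = evaluate(testset, library, method="dice")
        ranks = []
        for query, true_id in testset:
            res = identify(query, library, method="dice", top_n=None)
            ranks.append(true_compound_rank(res, true_id) or 10**9)
        n = len(testset)
        assert report.frac_rank1 == sum(r == 1 for r in ranks) / n
        assert report.frac_rank_le5 == sum(r <= 5 for r in ranks) / n
        assert report.frac_rank_le10 == sum(r <= 10 for r in ranks) / n

    def test_formula_accuracy_bounds_rank1(self):
        library, testset = simulate_library(
            25, seed=5, noise_model=NoiseModel(jitter_ppm=8.0, n_spurious=10)
        )
        report = evaluate(testset, library)
        assert report.frac_correct_formula_top1 >= report.frac_rank1

    def test_unknown_truth_rejected(self, clean_library):
        library, testset = clean_library
        with pytest.raises(ValueError, match="not in library"):
            evaluate([(testset[0][0], "no-such-id")], library)


class TestSimulator:
    def test_same_seed_identical(self):
        a = simulate_library(10, seed=3)
        b = simulate_library(10, seed=3)
        for ra, rb in zip(a[0].records, b[0].records):
            assert ra.identifier == rb.identifier
            assert ra.spectra.spectra == rb.spectra.spectra
        for (qa, ia), (qb, ib) in zip(a[1], b[1]):
            assert ia == ib and qa.spectra == qb.spectra

    def test_zero_noise_queries_equal_library(self):
        library, testset = simulate_library(8, seed=4, noise_model=NoiseModel.none())
        for query, true_id in testset:
            rec = library[true_id]
            for e in query.energies:
                q, r = query.spectra[e], rec.spectra.spectra[e]
                assert q.mzs == r.mzs
                assert q.intensities == r.intensities

    def test_generated_spectra_satisfy_invariants(self):
        library, testset = simulate_library(10, seed=6)
        for rec in library.records:
            for spec in rec.spectra:
                assert spec.mzs == sorted(spec.mzs)
                assert max(spec.intensities) == 100.0
                assert spec.precursor_mz >= max(spec.mzs) - 1e-9
                assert spec.collision_energy in (10, 20, 40)

    def test_energy_dependent_fragmentation(self):
        """Higher collision energy shifts intensity toward lower m/z."""
        library, _ = simulate_library(30, seed=8, noise_model=NoiseModel.none())

        def weighted_mean_mz(spec):
            tot = sum(spec.intensities)
            return sum(m * i for m, i in zip(spec.mzs, spec.intensities)) / tot

        lo = np.mean([weighted_mean_mz(r.spectra.spectra[10]) for r in library.records])
        hi = np.mean([weighted_mean_mz(r.spectra.spectra[40]) for r in library.records])
        assert hi < lo

    def test_degradation_with_spurious_peaks(self):
        """Mean rank-1 accuracy does not improve as spurious peaks increase."""
        means = []
        for n_spur in (0, 20):
            vals = []
            for rep in range(4):
                library, testset = simulate_library(
                    15, seed=100 + rep,
                    noise_model=NoiseModel(jitter_ppm=5.0, n_spurious=n_spur),
                )
                vals.append(evaluate(testset, library).frac_rank1)
            means.append(np.mean(vals))
        assert means[1] <= means[0]


class TestLibraryIO:
    def test_msp_library_roundtrip(self, tmp_path, clean_library):
        library, _ = clean_library
        path = tmp_path / "lib.msp"
        save_library(library, path)
        back = load_library(path)
        assert len(back) == len(library)
        for rec in library.records:
            rec2 = back[rec.identifier]
            assert rec2.molecule.formula == rec.molecule.formula
            assert rec2.neutral_mass == pytest.approx(rec.neutral_mass, abs=1e-5)
            for e in rec.spectra.energies:
                s0, s1 = rec.spectra.spectra[e], rec2.spectra.spectra[e]
                assert s1.mzs == pytest.approx(s0.mzs, abs=1e-6)
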