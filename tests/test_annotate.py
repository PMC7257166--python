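"""Spectrum annotation: precursor calls, candidate scoring, digest reports."""

import numpy as np
import pytest

from xgox.annotate import (
    EmptySpectrumError,
    Spectrum,
    annotate_digest,
    annotate_spectrum,
    classify_precursor,
    default_mass_list,
)
from xgox.core import OxForm, parse_code
from xgox.simulate import SpectrumNoiseModel, simulate_spectrum

ML = default_mass_list()


class TestPrecursorClassification:
    def test_minus2_call_for_oxidized_h4p3(self):
        call = classify_precursor(1059.33, ML, 0.3)
        assert call.category == "minus2"
        assert "H4P3" in call.compositions

    def test_plus16_ambiguity_c1_vs_formate(self):
        call = classify_precursor(1107.35, ML, 0.3)
        assert call.category == "plus16"
        assert set(call.compositions) >= {"H5P2", "H4P3"}
        forms = {(c, f) for c, f, _ in call.matches}
        assert ("H5P2", "C1_aldonic") in forms
        assert ("H4P3", "none") in forms  # the formate adduct row

    def test_non_oxidized_call(self):
        call = classify_precursor(899.29, ML, 0.3)
        assert call.category == "non-oxidized"
        assert call.compositions == ("H3P3",)

    def test_unassigned_when_nothing_matches(self):
        assert classify_precursor(500.0, ML.iloc[:0], 0.3).category == "unassigned"


class TestSpectrumAnnotation:
    def test_empty_peak_list_is_an_error(self):
        with pytest.raises(EmptySpectrumError):
            annotate_spectrum(Spectrum(927.3, peaks=[]), ML)

    def test_no_candidate_match_is_not_an_error(self):
        ann = annotate_spectrum(Spectrum(500.0, peaks=[(200.0, 1.0)]), ML)
        assert ann.call.category == "unassigned"
        assert ann.annotations == []

    def test_published_927_peak_list_resolves_oxidized_lgx(self):
        """The published informative ions (B at 453/615, 2,4X at 413, ...)
        single out the L-terminal isomer among all seven -2 H4P2
        candidates."""
        peaks = [
            (293, 20.0),
            (311, 1.0),
            (413, 2.0),
            (453, 100.0),
            (473, 42.0),
            (615, 3.0),
            (747, 2.0),
            (849, 1.0),
            (867, 3.0),
            (909, 13.0),
        ]
        ann = annotate_spectrum(Spectrum(927.3, peaks=peaks), ML)
        assert ann.call.category == "minus2"
        top = ann.annotations[0]
        assert top.candidate.code == "O4k:LGX"
        assert top.co_optimal
        matched_ints = {round(f.mz) for f, _, _ in top.matched}
        assert {453, 413} <= matched_ints

    def test_published_1059_union_list_reports_coeluting_isomers(self):
        """The -2 H4P3 peak was published as two co-eluting isomers; on the
        combined fragment list the G-terminal isomer is top-ranked and the
        X-terminal one is reported with its distinct supporting ions."""
        peaks = [(x, 10.0) for x in
                 [293, 453, 455, 473, 527, 605, 765, 767, 821, 839, 899, 999, 1041]]
        ann = annotate_spectrum(Spectrum(1059.33, peaks=peaks), ML)
        codes = [a.candidate.code for a in ann.annotations]
        assert codes[0] == "O4k:GXXX"
        assert ann.annotations[0].co_optimal
        xxxg = next(a for a in ann.annotations if a.candidate.code == "O4k:XXXG")
        assert {767, 473, 455} <= {round(f.mz) for f, _, _ in xxxg.matched}

    def test_formate_adduct_suppresses_oxidized_annotation(self):
        """A plus16 precursor showing the -46 formic acid loss is annotated
        as the formate adduct of the non-oxidized composition."""
        base = 1107.35
        peaks = [(base - 46.005, 50.0), (base - 18.011, 10.0), (767.25, 20.0)]
        ann = annotate_spectrum(Spectrum(base, peaks=peaks), ML)
        assert ann.formate_adduct
        assert ann.annotations  # non-oxidized H4P3 candidates
        assert all(a.candidate.oxidation is OxForm.NONE for a in ann.annotations)
        assert all("formate" in a.note for a in ann.annotations)

    def test_plus16_without_loss_stays_composition_level(self):
        ann = annotate_spectrum(Spectrum(1107.35, peaks=[(300.0, 5.0)]), ML)
        assert ann.call.category == "plus16"
        assert not ann.formate_adduct
        assert ann.annotations == []  # C1 products are not localizable

    def test_noise_free_spectrum_uniquely_top_ranks_truth(self, noiseless):
        for code in ("O4k:GXXX", "O4k:XGXL", "O4k:LLG", "O4k:XXG"):
            s = parse_code(code)
            sp = simulate_spectrum(s, noiseless, 0)
            ann = annotate_spectrum(sp, ML)
            assert [a.candidate for a in ann.annotations if a.co_optimal] == [s]

    def test_determinism_and_lexicographic_ties(self):
        peaks = [(x, 10.0) for x in [293, 453, 867, 909]]
        first = annotate_spectrum(Spectrum(927.3, peaks=peaks), ML)
        second = annotate_spectrum(Spectrum(927.3, peaks=peaks), ML)
        codes = [a.candidate.code for a in first.annotations]
        assert codes == [a.candidate.code for a in second.annotations]
        scores = [a.score for a in first.annotations]
        for (c1, s1), (c2, s2) in zip(
            zip(codes, scores), zip(codes[1:], scores[1:])
        ):
            assert s1 > s2 or (s1 == s2 and c1 < c2)

    def test_score_monotone_in_matched_peaks(self):
        """Adding one more true peak never lowers a candidate's score."""
        s = parse_code("O4k:LGX")
        sp_full = simulate_spectrum(s, SpectrumNoiseModel.noiseless(), 0)
        for k in range(2, len(sp_full.peaks)):
            partial = Spectrum(sp_full.precursor_mz, peaks=sp_full.peaks[:k])
            bigger = Spectrum(sp_full.precursor_mz, peaks=sp_full.peaks[: k + 1])
            def score_of(ann):
                return next(
                    a.score for a in ann.annotations if a.candidate == s
                )
            assert score_of(annotate_spectrum(bigger, ML)) >= score_of(
                annotate_spectrum(partial, ML)
            )


class TestDigestReport:
    def test_empty_digest_gives_empty_report(self):
        report = annotate_digest([], ML)
        assert report.entries == [] and report.product_tally() == {}

    def test_two_spectrum_digest(self):
        spectra = [
            Spectrum(927.3, peaks=[(x, 10.0) for x in [293, 311, 413, 453, 473, 615]]),
            Spectrum(1059.33, peaks=[(x, 10.0) for x in [293, 453, 605, 765, 899, 999, 1041]]),
        ]
        report = annotate_digest(spectra, ML)
        assert len(report.entries) == 2
        assert all(e.call.category == "minus2" for e in report.entries)
        tally = report.product_tally()
        assert tally.get("O4k:LGX") == 1 and tally.get("O4k:GXXX") == 1

    def test_simulated_digest_top1_accuracy(self, noiseless):
        """>= 95% of simulated product spectra rank the generating structure
        co-optimal at default noise."""
        rng = np.random.default_rng(42)
        codes = ["O4k:GXXX", "O4k:XXXG", "O4k:XGX", "O4k:LGX", "O4k:XXG",
                 "O4k:GLXX", "O4k:XGXL", "O4k:LLG", "O4k:GX", "O4k:XGLL"]
        noise = SpectrumNoiseModel()
        n, hits = 0, 0
        for rep in range(5):
            for code in codes:
                s = parse_code(code)
                sp = simulate_spectrum(s, noise, rng)
                ann = annotate_spectrum(sp, ML)
                n += 1
                hits += s in [a.candidate for a in ann.annotations if a.co_optimal]
        assert hits / n >= 0.95

    def test_report_dataframe_round(self):
        sp = Spectrum(927.3, peaks=[(453.1, 10.0)], spectrum_id="p4")
        df = annotate_digest([sp], ML).to_dataframe()
        assert {"spectrum_id", "candidate", "score", "co_optimal"} <= set(df.columns)
        assert (df["spectrum_id"] == "p4").all()
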