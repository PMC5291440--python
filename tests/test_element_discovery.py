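import numpy as np
import pytest

import promcnn as pc
from promcnn.errors import ConfigurationError, DataError
from promcnn.sequence_io import PROMOTER
from promcnn.synthetic_data import consensus_pwm, minus10_box


def make_promoters(rng, n, length=251, tss_index=201, motif="TATAAA", start=156):
    """Background records with `motif` planted at 1-based `start`."""
    bases = np.array(list("ATGC"))
    out = []
    for i in range(n):
        seq = list("".join(bases[rng.integers(0, 4, length)]))
        seq[start - 1 : start - 1 + len(motif)] = motif
        out.append(pc.SequenceRecord(f"p{i}", "".join(seq), label=PROMOTER, tss_index=tss_index))
    return out


def oracle_classifier(motif="TATAAA", start=156):
    """Rule-based classifier: promoter iff `motif` occupies 1-based `start`."""
    from promcnn.sequence_io import decode_one_hot

    def classify(batch):
        out = []
        for mat in batch:
            seq = decode_one_hot(np.round(mat))
            out.append(1 if seq[start - 1 : start - 1 + len(motif)] == motif else 0)
        return np.array(out)

    return classify


class TestSubstitutionProfile:
    def test_profile_has_one_point_per_window_start(self, rng):
        promoters = make_promoters(rng, 5)
        profile = pc.substitution_profile(
            oracle_classifier(), promoters, window_length=6, replicates=1, seed=0
        )
        # 251-nt windows, 6-nt window, stride 1 -> 246 points
        assert len(profile.window_starts) == 251 - 6 + 1 == 246
        assert profile.window_starts[0] == 1
        assert profile.tss_relative_starts[0] == 1 - 201

    def test_constant_classifier_gives_flat_profile(self, rng):
        promoters = make_promoters(rng, 4, length=60, tss_index=41)
        constant = lambda batch: np.ones(len(batch), dtype=int)
        profile = pc.substitution_profile(constant, promoters, window_length=6, replicates=2, seed=0)
        assert profile.baseline_sensitivity == 1.0
        assert (profile.sensitivities == 1.0).all()

    def test_oracle_dip_localizes_motif(self, rng):
        # motif TATAAA at 1-based 156..161; overlapping window starts are
        # 151..161; a random window restores an overlap of k bases with
        # probability 4^-k, so Sn <= ~0.25 there and 1.0 elsewhere
        promoters = make_promoters(rng, 40, motif="TATAAA", start=156)
        profile = pc.substitution_profile(
            oracle_classifier("TATAAA", 156), promoters, window_length=6, replicates=10, seed=1
        )
        assert profile.baseline_sensitivity == 1.0
        for i, s in enumerate(profile.window_starts):
            if 151 <= s <= 161:
                overlap = min(s + 5, 161) - max(s, 156) + 1
                assert profile.sensitivities[i] <= 0.25 ** overlap + 0.25, (s, overlap)
            else:
                assert profile.sensitivities[i] == 1.0, s
        # fully covered window starts (all 6 bases inside the motif span)
        assert profile.sensitivities[155].max() <= 0.01

    def test_deterministic_given_seed(self, rng):
        promoters = make_promoters(rng, 6, length=60, tss_index=41, start=20)
        kwargs = dict(window_length=4, replicates=3, seed=9)
        a = pc.substitution_profile(oracle_classifier("TATAAA", 20), promoters, **kwargs)
        b = pc.substitution_profile(oracle_classifier("TATAAA", 20), promoters, **kwargs)
        assert np.array_equal(a.sensitivities, b.sensitivities)

    def test_window_longer_than_sequence_rejected(self, rng):
        promoters = make_promoters(rng, 2, length=30, tss_index=21, start=5)
        with pytest.raises(DataError):
            pc.substitution_profile(oracle_classifier(), promoters, window_length=31)

    def test_empty_promoter_set_rejected(self):
        with pytest.raises(DataError):
            pc.substitution_profile(oracle_classifier(), [], window_length=6)

    def test_monotone_restoration_bound(self, small_trained, small_corpus):
        # random damage cannot systematically help: Sn <= baseline + 3 SE
        params, _ = small_trained
        _, records = small_corpus
        promoters = [r for r in records if r.label == PROMOTER][:80]
        profile = pc.substitution_profile(params, promoters, window_length=6, replicates=5, seed=2)
        limit = profile.baseline_sensitivity + 3 * np.maximum(profile.standard_errors, 1.0 / (5 * len(promoters)))
        assert (profile.sensitivities <= limit + 1e-12).all()

    def test_replicate_averaging_reduces_variance(self, rng):
        # profile-point variance across independent runs shrinks ~ 1/replicates
        promoters = make_promoters(rng, 12, length=40, tss_index=21, motif="TAT", start=15)
        clf = oracle_classifier("TAT", 15)
        variances = []
        for reps in (2, 8, 32):
            point = [
                pc.substitution_profile(
                    promoters=promoters, model=clf, window_length=3, replicates=reps, seed=run
                ).sensitivities[16]  # start 17: single-base overlap, Sn ~ 0.25 per record
                for run in range(15)
            ]
            variances.append(np.var(point))
        assert variances[0] > variances[1] > variances[2]


class TestProfileMinima:
    def test_flat_profile_gives_no_intervals(self, rng):
        promoters = make_promoters(rng, 4, length=60, tss_index=41)
        constant = lambda batch: np.ones(len(batch), dtype=int)
        profile = pc.substitution_profile(constant, promoters, window_length=6, replicates=2, seed=0)
        assert pc.profile_minima(profile, 0.5) == []

    def test_single_motif_single_interval_covering_span(self, rng):
        promoters = make_promoters(rng, 40, motif="TATAAA", start=156)
        profile = pc.substitution_profile(
            oracle_classifier("TATAAA", 156), promoters, window_length=6, replicates=10, seed=1
        )
        intervals = pc.profile_minima(profile, drop_fraction=0.5)
        assert len(intervals) == 1
        lo, hi = intervals[0]
        # implicated window starts cover sequence positions 151..166
        # (TSS-relative -50..-35); the motif span lies inside
        assert lo <= 156 - 201 and hi >= 161 - 201
        assert (lo, hi) == (151 - 201, 166 - 201)

    def test_two_motifs_two_disjoint_intervals(self, rng):
        bases = np.array(list("ATGC"))
        promoters = []
        for i in range(40):
            seq = list("".join(bases[rng.integers(0, 4, 251)]))
            seq[170:178] = "TATAAAAG"
            seq[199:203] = "TCAG"
            promoters.append(
                pc.SequenceRecord(f"p{i}", "".join(seq), label=PROMOTER, tss_index=201)
            )
        model = pc.build_positional_motif_model(251, [("TATAAAAG", 171), ("TCAG", 200)])
        profile = pc.substitution_profile(model, promoters, window_length=6, replicates=10, seed=3)
        intervals = pc.profile_minima(profile, drop_fraction=0.5)
        assert len(intervals) == 2
        (a_lo, a_hi), (b_lo, b_hi) = intervals
        assert a_hi < b_lo  # disjoint
        assert a_lo <= -30 <= a_hi  # covers first motif start
        assert b_lo <= -1 <= b_hi  # covers second motif start

    def test_zero_baseline_rejected(self, rng):
        promoters = make_promoters(rng, 4, length=60, tss_index=41)
        never = lambda batch: np.zeros(len(batch), dtype=int)
        profile = pc.substitution_profile(never, promoters, window_length=6, replicates=1, seed=0)
        with pytest.raises(DataError, match="baseline"):
            pc.profile_minima(profile, 0.5)


class TestInformationProfile:
    def test_invariant_uniform_and_half_columns(self):
        records = [
            pc.SequenceRecord("a", "TAAC"),
            pc.SequenceRecord("b", "TCAC"),
            pc.SequenceRecord("c", "TGTC"),
            pc.SequenceRecord("d", "TTTC"),
        ]
        profile = pc.information_profile(records)
        ic = profile.information_bits
        assert ic[0] == pytest.approx(2.0)  # all T
        assert ic[1] == pytest.approx(0.0)  # A,C,G,T equal
        assert ic[2] == pytest.approx(1.0)  # A/T at 0.5 each
        assert ic[3] == pytest.approx(2.0)  # all C

    def test_ic_bounds_and_frequencies(self, rng):
        records = make_promoters(rng, 50, length=40, tss_index=21, motif="TATAAT", start=10)
        profile = pc.information_profile(records)
        assert ((profile.information_bits >= 0) & (profile.information_bits <= 2 + 1e-12)).all()
        assert np.allclose(profile.base_frequencies.sum(axis=1), 1.0)

    def test_n_bases_excluded_from_counts(self):
        records = [pc.SequenceRecord("a", "AN"), pc.SequenceRecord("b", "AA")]
        profile = pc.information_profile(records)
        assert profile.information_bits[1] == pytest.approx(2.0)  # only one A observed

    def test_small_sample_correction_reduces_ic(self):
        records = [pc.SequenceRecord("a", "AAAA"), pc.SequenceRecord("b", "AAAA")]
        raw = pc.information_profile(records).information_bits
        corrected = pc.information_profile(records, small_sample_correction=True).information_bits
        assert (corrected < raw).all()

    def test_mixed_lengths_rejected(self):
        with pytest.raises(DataError):
            pc.information_profile([pc.SequenceRecord("a", "AA"), pc.SequenceRecord("b", "A")])

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            pc.information_profile([])


class TestProfileLogoConcordance:
    def test_high_ic_positions_lie_in_minima_intervals(self, rng):
        # jitter-0 planted motif: IC >= 1 positions must fall inside the
        # union of substitution-profile minima intervals
        spec = pc.CorpusSpec(
            n_promoters=200, n_nonpromoters=0, window_length=81, tss_index=61,
            motifs=(minus10_box(weight=1.0, offset=-12),), seed=17,
        )
        records = pc.generate_corpus(spec)
        start, _ = spec.motif_positions(spec.motifs[0])
        model = pc.build_positional_motif_model(81, [("TATAAT", start)])
        profile = pc.substitution_profile(model, records[:60], window_length=6, replicates=10, seed=4)
        intervals = pc.profile_minima(profile, 0.5)
        info = pc.information_profile(records)
        covered = set()
        for lo, hi in intervals:
            covered.update(range(lo, hi + 1))
        for pos0, ic in enumerate(info.information_bits):
            if ic >= 1.0:
                assert (pos0 + 1 - 61) in covered


class TestOutputTables:
    def test_profile_table_columns_and_convention_header(self, tmp_path, rng):
        promoters = make_promoters(rng, 4, length=40, tss_index=21, motif="TAT", start=15)
        profile = pc.substitution_profile(
            oracle_classifier("TAT", 15), promoters, window_length=3, replicates=2, seed=0
        )
        path = tmp_path / "profile.tsv"
        from promcnn.element_discovery import write_profile

        write_profile(profile, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("#")
        assert "indexed by start" in lines[0]
        assert len(lines) == 2 + len(profile.window_starts)
        first = lines[2].split("\t")
        assert first[0] == "1"
        assert first[1] == str(1 - 21)

    def test_logo_table_written(self, tmp_path, rng):
        records = make_promoters(rng, 4, length=20, tss_index=11, motif="TAT", start=5)
        from promcnn.element_discovery import write_information_profile

        path = tmp_path / "logo.tsv"
        write_information_profile(pc.information_profile(records), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 2 + 20
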