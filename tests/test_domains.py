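import numpy as np
import pytest

from ompfam.domains import (consensus_potra_set, detect_lipobox, extract_region,
                            PotraSegment, scan_potras, split_domains)
from ompfam.io import SequenceRecord
from ompfam.profiles import Hit, build_profile, calibrate
from ompfam.synth import (TEMPLATES, architecture_parts, make_domain_library,
                          sample_sequence)


def _hit(env_start, env_end, profile="omp85"):
    return Hit(query_profile=profile, target_id="t", score=100.0,
               evalue=1e-30, env_start=env_start, env_end=env_end)


class TestSplitDomains:
    def test_partition_arithmetic(self):
        rec = SequenceRecord("t", "A" * 500)
        part = split_domains(rec, _hit(150, 480))
        assert part.barrel == (150, 500)
        assert part.nterm == (1, 149)

    def test_short_nterm_absent(self):
        rec = SequenceRecord("t", "A" * 400)
        part = split_domains(rec, _hit(15, 390))
        assert part.barrel == (15, 400)
        assert part.nterm is None  # 14 residues < 20

    def test_exactly_twenty_residues_kept(self):
        rec = SequenceRecord("t", "A" * 400)
        part = split_domains(rec, _hit(21, 390))
        assert part.nterm == (1, 20)

    def test_corrupt_hit_rejected(self):
        rec = SequenceRecord("t", "A" * 100)
        with pytest.raises(ValueError, match="beyond"):
            split_domains(rec, _hit(150, 200))

    def test_partition_reconstructs_sequence(self):
        rng = np.random.default_rng(0)
        residues = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                           for i in rng.integers(0, 20, 300))
        rec = SequenceRecord("t", residues)
        part = split_domains(rec, _hit(101, 290))
        nterm = extract_region(rec, part.nterm)
        barrel = extract_region(rec, part.barrel)
        assert nterm.residues + residues[part.nterm[1]:part.barrel[0] - 1] \
            + barrel.residues == residues
        assert part.barrel[1] == len(rec)


@pytest.fixture(scope="module")
def zero_noise_potra_setup():
    """Profile and a 3-POTRA N-terminal region at zero divergence."""
    lib = make_domain_library(6)
    rng = np.random.default_rng(7)
    parts = architecture_parts(TEMPLATES["TamA"], lib, rng,
                               family_divergence=0.0)
    rec, truth = sample_sequence(TEMPLATES["TamA"], parts, 0.0, 0.0,
                                 np.random.default_rng(8))
    rows = [(f"r{i}", lib["potra"]) for i in range(4)]
    profile = build_profile(rows, name="potra")
    calibrate(profile, seed=9)
    return profile, rec, truth


class TestScanPotras:
    def test_zero_noise_recovers_planted_coordinates(self, zero_noise_potra_setup):
        profile, rec, truth = zero_noise_potra_setup
        barrel_start = [s for k, s, _ in truth.domain_coords if k == "barrel"][0]
        nterm = SequenceRecord(rec.id, rec.residues[:barrel_start - 1])
        segments = scan_potras(nterm, profile)
        expected = [(s, e) for k, s, e in truth.domain_coords if k == "potra"]
        assert [(s.start, s.end) for s in segments] == expected
        assert [s.index for s in segments] == [1, 2, 3]

    def test_region_without_potras_yields_nothing(self, zero_noise_potra_setup):
        profile, _, _ = zero_noise_potra_setup
        rng = np.random.default_rng(10)
        junk = SequenceRecord("j", "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 200)))
        assert scan_potras(junk, profile) == []

    def test_segments_ordered_and_in_band(self, zero_noise_potra_setup,
                                          potra_profile, small_dataset):
        by_id = {r.id: r for r in small_dataset.records}
        for sid in [r.id for r in small_dataset.records
                    if r.id.startswith("BamA")][:5]:
            truth = small_dataset.truth[sid]
            barrel_start = [s for k, s, _ in truth.domain_coords
                            if k == "barrel"][0]
            nterm = SequenceRecord(sid, by_id[sid].residues[:barrel_start - 1])
            segments = scan_potras(nterm, potra_profile)
            assert all(25 <= s.length <= 125 for s in segments)
            starts = [s.start for s in segments]
            assert starts == sorted(starts)
            for a, b in zip(segments, segments[1:]):
                assert a.end < b.start

    def test_uncalibrated_profile_rejected(self):
        profile = build_profile([("a", "ACDEFGHIKL")])
        with pytest.raises(ValueError, match="calibrated"):
            scan_potras(SequenceRecord("x", "ACDEFGHIKL"), profile)


class TestConsensusPotraSet:
    def _segments(self, sid, count, scores=None):
        scores = scores or [50.0] * count
        return [PotraSegment(id=sid, index=i + 1, start=1 + 80 * i,
                             end=75 + 80 * i, score=scores[i])
                for i in range(count)]

    def test_excess_segments_trimmed_to_modal_count(self):
        cluster = {f"s{i}": self._segments(f"s{i}", 5) for i in range(3)}
        cluster["s3"] = self._segments("s3", 6, [50, 10, 50, 50, 50, 50])
        out = consensus_potra_set(cluster)
        assert len(out["s3"]) == 5
        # the lowest-scoring segment was dropped; survivors renumbered N->C
        assert [s.index for s in out["s3"]] == [1, 2, 3, 4, 5]
        assert all(s.score >= 50 for s in out["s3"])

    def test_uniform_counts_unchanged(self):
        cluster = {f"s{i}": self._segments(f"s{i}", 3) for i in range(3)}
        out = consensus_potra_set(cluster)
        assert all(len(v) == 3 for v in out.values())

    def test_modal_tie_broken_toward_larger_count(self):
        cluster = {"a": self._segments("a", 2), "b": self._segments("b", 2),
                   "c": self._segments("c", 3), "d": self._segments("d", 3)}
        out = consensus_potra_set(cluster)
        assert len(out["c"]) == 3 and len(out["a"]) == 2  # nothing trimmed

    def test_never_increases_counts(self):
        cluster = {"a": self._segments("a", 1), "b": self._segments("b", 4)}
        out = consensus_potra_set(cluster)
        for sid in cluster:
            assert len(out[sid]) <= max(1, 4)
        assert len(out["a"]) == 1

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            consensus_potra_set({})


class TestDetectLipobox:
    def test_planted_signal_positive(self):
        lib = make_domain_library(11)
        rng = np.random.default_rng(12)
        parts = architecture_parts(TEMPLATES["Lipo"], lib, rng, 0.0)
        rec, _ = sample_sequence(TEMPLATES["Lipo"], parts, 0.0, 0.0,
                                 np.random.default_rng(13))
        call = detect_lipobox(rec)
        assert call.positive and 15 <= call.cys_position <= 40

    def test_no_cysteine_negative(self):
        rec = SequenceRecord("t", "MLLLLLLLLLLLAGSAGSAGS" + "A" * 40)
        assert not detect_lipobox(rec).positive

    def test_cysteine_outside_window_negative(self):
        seq = "M" + "A" * 44 + "LLLLLLLLLAGC" + "A" * 30  # C at position 57
        assert not detect_lipobox(SequenceRecord("t", seq)).positive

    def test_hydrophilic_core_negative(self):
        # correct motif, but preceded by charged residues
        seq = "M" + "A" * 7 + "DEDEDKRK" + "LAGC" + "A" * 40
        assert not detect_lipobox(SequenceRecord("t", seq)).positive

    def test_hydrophobic_core_positive(self):
        seq = "M" + "A" * 7 + "LLVVIIFF" + "LAGC" + "A" * 40
        call = detect_lipobox(SequenceRecord("t", seq))
        assert call.positive and call.cys_position == 20
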