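import numpy as np
import pytest
from scipy import stats

from mockbarcode.community import (
    AMPLICON_STARTS,
    BARCODE_LENGTH,
    PLATFORM_PRESETS,
    TREATMENT_PRESETS,
    CommunitySpec,
    SpeciesRecord,
    TreatmentModel,
    community_manifest,
    generate_community,
    read_manifest,
    read_reference_library,
    simulate_amplicon_pool,
    simulate_reads,
    simulate_template_pool,
    write_manifest,
    write_reference_library,
)
from mockbarcode.primers import DEFAULT_PRIMERS_407, best_cocktail_mismatch


def hamming_fraction(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


class TestGenerateCommunity:
    def test_contract_small(self):
        records = generate_community(
            CommunitySpec(n_species=5, min_pairwise_divergence=0.02, seed=1))
        assert len(records) == 5
        for i in range(5):
            for j in range(i + 1, 5):
                assert hamming_fraction(records[i].barcode_seq,
                                        records[j].barcode_seq) > 0.02

    def test_determinism(self, tmp_path):
        spec = CommunitySpec(n_species=8, seed=42)
        a, b = generate_community(spec), generate_community(spec)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_manifest(a, pa)
        write_manifest(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    @pytest.mark.slow
    def test_full_scale_mass_ratio(self):
        records = generate_community(CommunitySpec(n_species=374, seed=7))
        masses = [sp.abdominal_mass_mg for sp in records]
        ratio = max(masses) / min(masses)
        assert 7500 * 0.99 <= ratio <= 7500 * 1.01

    def test_barcode_invariants(self, small_community):
        for sp in small_community:
            assert len(sp.barcode_seq) == BARCODE_LENGTH
            assert set(sp.barcode_seq) <= set("ACGT")
            assert sp.abdominal_mass_mg > 0
            gc = (sp.barcode_seq.count("G") + sp.barcode_seq.count("C"))
            assert sp.gc_fraction == gc / BARCODE_LENGTH

    def test_mismatch_counts_match_sites(self, small_community):
        for sp in small_community:
            assert best_cocktail_mismatch(
                DEFAULT_PRIMERS_407.forward, sp.fwd_site_seq) == sp.fwd_mismatches
            assert best_cocktail_mismatch(
                DEFAULT_PRIMERS_407.reverse, sp.rev_site_seq) == sp.rev_mismatches

    def test_mismatch_counts_follow_profile(self):
        spec = CommunitySpec(n_species=374, seed=3)
        records = generate_community(spec)
        observed = np.bincount([sp.fwd_mismatches for sp in records],
                               minlength=5)
        profile = spec.mismatch_profile["fwd"]
        expected = np.array([profile[i] for i in range(5)]) * len(records)
        _, p = stats.chisquare(observed[:5], expected)
        assert p > 0.001

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            CommunitySpec(mismatch_profile={"fwd": {0: 0.5}, "rev": {0: 1.0}})

    def test_species_record_validation(self):
        with pytest.raises(ValueError, match="mass"):
            SpeciesRecord("x", "o", "ACGT" * 10, -1.0, "A", "A", True)


class TestTemplatePool:
    def test_uniform_when_unbiased(self, small_community):
        model = TreatmentModel("single_leg", mass_exponent=0.0, pool_noise_cv=0.0)
        shares = simulate_template_pool(small_community, model)
        assert np.allclose(shares, 1 / len(small_community))

    def test_two_species_two_thirds_exponent(self):
        seq = "ACGT" * 164 + "AC"
        a = SpeciesRecord("a", "o", seq, 1.0, "A", "A", True)
        b = SpeciesRecord("b", "o", seq, 8.0, "A", "A", True)
        model = TreatmentModel("bulk_abdomen", mass_exponent=2 / 3,
                               pool_noise_cv=0.0)
        shares = simulate_template_pool([a, b], model)
        assert np.allclose(shares, [1 / 5, 4 / 5])  # 8^(2/3) = 4

    @pytest.mark.slow
    def test_share_ratio_tracks_mass_ratio(self):
        records = generate_community(CommunitySpec(n_species=374, seed=7))
        model = TreatmentModel("bulk_abdomen", mass_exponent=0.66,
                               pool_noise_cv=0.0)
        shares = simulate_template_pool(records, model)
        ratio = shares.max() / shares.min()
        assert abs(ratio - 360) / 360 < 0.01

    def test_exact_ratio_identity_no_noise(self, small_community):
        model = TreatmentModel("bulk_abdomen", mass_exponent=0.5,
                               pool_noise_cv=0.0)
        shares = simulate_template_pool(small_community, model)
        masses = np.array([sp.abdominal_mass_mg for sp in small_community])
        assert np.isclose(shares.max() / shares.min(),
                          (masses.max() / masses.min()) ** 0.5)

    def test_seeded_noise_deterministic(self, small_community):
        model = TreatmentModel("bulk_leg", mass_exponent=0.5, pool_noise_cv=0.3)
        s1 = simulate_template_pool(small_community, model, seed=9)
        s2 = simulate_template_pool(small_community, model, seed=9)
        assert np.array_equal(s1, s2)

    def test_empty_community_raises(self):
        with pytest.raises(ValueError):
            simulate_template_pool([], TreatmentModel())


class TestAmpliconPool:
    def test_no_penalty_is_identity(self):
        model = TreatmentModel(mismatch_penalty=1.0)
        templates = np.array([0.2, 0.3, 0.5])
        out = simulate_amplicon_pool(templates, np.array([0, 2, 5]), model)
        assert np.allclose(out, templates)

    def test_two_species_derived_ratio(self):
        # equal templates, m = (0, 2), penalty 0.5, efficiency 1, 10 cycles:
        # per-cycle factors 2 and 1.25 -> ratio 1.6^10 (computed independently)
        model = TreatmentModel(pcr_cycles=10, max_efficiency=1.0,
                               mismatch_penalty=0.5)
        out = simulate_amplicon_pool(np.array([0.5, 0.5]), np.array([0, 2]), model)
        expected_ratio = (2 / 1.25) ** 10
        assert np.isclose(out[0] / out[1], expected_ratio, rtol=1e-12)

    def test_normalized(self, biased_shares):
        assert np.isclose(biased_shares.sum(), 1.0)
        assert (biased_shares >= 0).all()

    def test_strictly_decreasing_in_mismatches(self):
        model = TreatmentModel(mismatch_penalty=0.8)
        out = simulate_amplicon_pool(np.full(5, 0.2), np.arange(5), model)
        assert (np.diff(out) < 0).all()

    def test_no_overflow_at_40_cycles(self):
        model = TreatmentModel(pcr_cycles=40, max_efficiency=1.0,
                               mismatch_penalty=0.5)
        out = simulate_amplicon_pool(np.full(4, 0.25), np.array([0, 1, 2, 8]),
                                     model)
        assert np.isfinite(out).all() and np.isclose(out.sum(), 1.0)


class TestSimulateReads:
    def test_exact_substrings_when_error_free(self, small_community,
                                              biased_shares,
                                              clean_single_profile):
        reads = simulate_reads(biased_shares, small_community, 200,
                               clean_single_profile, 407, seed=5)
        amplicons = {sp.bin_id: sp.amplicon_seq(407) for sp in small_community}
        for read in reads:
            assert read.seq in amplicons[read.source_bin]

    def test_depth_and_truth_labels(self, small_community, biased_shares,
                                    clean_single_profile):
        reads = simulate_reads(biased_shares, small_community, 150,
                               clean_single_profile, 463, seed=5)
        assert len(reads) == 150
        bin_ids = {sp.bin_id for sp in small_community}
        assert all(r.source_bin in bin_ids for r in reads)

    def test_multinomial_gof(self, small_community, clean_single_profile):
        shares = np.full(len(small_community), 1 / len(small_community))
        depth = 100_000
        reads = simulate_reads(shares, small_community, depth,
                               clean_single_profile, 407, seed=6)
        counts = np.zeros(len(small_community))
        index = {sp.bin_id: i for i, sp in enumerate(small_community)}
        for read in reads:
            counts[index[read.source_bin]] += 1
        _, p = stats.chisquare(counts, shares * depth)
        assert p > 0.001

    def test_seeded_fastq_identical(self, tmp_path, small_community,
                                    biased_shares):
        profile = PLATFORM_PRESETS["pgm_like"]
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        simulate_reads(biased_shares, small_community, 100, profile, 407,
                       seed=8).write_fastq(p1)
        simulate_reads(biased_shares, small_community, 100, profile, 407,
                       seed=8).write_fastq(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_paired_profile_returns_mates(self, small_community, biased_shares,
                                          clean_paired_profile):
        r1, r2 = simulate_reads(biased_shares, small_community, 50,
                                clean_paired_profile, 407, seed=9)
        assert len(r1) == len(r2) == 50
        assert [a.id for a in r1] == [b.id for b in r2]

    def test_bad_inputs(self, small_community, biased_shares,
                        clean_single_profile):
        with pytest.raises(ValueError):
            simulate_reads(biased_shares, small_community, 0,
                           clean_single_profile, 407)
        with pytest.raises(ValueError):
            simulate_reads(biased_shares, small_community, 10,
                           clean_single_profile, 999)


class TestPresets:
    def test_platform_invariants(self):
        miseq = PLATFORM_PRESETS["miseq_like"]
        assert miseq.paired and abs(miseq.qv_slope) < 1e-9
        for name in ("pgm_like", "s5_like"):
            profile = PLATFORM_PRESETS[name]
            assert not profile.paired
            assert profile.qv_slope < 0
            assert profile.indel_rate > miseq.indel_rate

    def test_treatment_presets(self):
        assert TREATMENT_PRESETS["single_leg"].mass_exponent == 0.0
        assert TREATMENT_PRESETS["bulk_abdomen"].mass_exponent == 0.66

    def test_amplicon_classes_collapse_to_two(self):
        assert sorted(AMPLICON_STARTS) == [407, 463]


class TestSerialization:
    def test_library_round_trip(self, tmp_path, small_community):
        path = tmp_path / "library.fasta"
        write_reference_library(small_community, path)
        back = read_reference_library(path)
        assert [(sp.bin_id, sp.barcode_seq) for sp in small_community] == back

    def test_manifest_round_trip_and_gc(self, tmp_path, small_community):
        path = tmp_path / "manifest.tsv"
        write_manifest(small_community, path)
        df = read_manifest(path)
        assert len(df) == len(small_community)
        for sp, gc in zip(small_community, df["gc"]):
            assert abs(gc - sp.gc_fraction) < 1e-5

    def test_manifest_rev_na_iff_unknown(self, small_community):
        df = community_manifest(small_community)
        assert (df["rev_mismatches"].isna() == ~df["rev_site_known"]).all()

    def test_empty_community_warns(self, tmp_path):
        with pytest.warns(UserWarning):
            write_reference_library([], tmp_path / "empty.fasta")
        with pytest.warns(UserWarning):
            write_manifest([], tmp_path / "empty.tsv")
        assert read_reference_library(tmp_path / "empty.fasta") == []
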