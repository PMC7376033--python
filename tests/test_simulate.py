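"""In-silico digestion, haplotype construction, molecule and trio simulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lcrkit.simulate import (
    Haplotype,
    ModuleSpec,
    SimParams,
    build_haplotype,
    default_catalog,
    digest_sequence,
    shared_identical_segments,
    simulate_molecules,
    simulate_trio,
)

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq):
    return seq.translate(_COMP)[::-1]


class TestDigest:
    def test_motif_hit_at_one_based_start(self):
        assert list(digest_sequence("AACTTAAGTT").positions) == [3]

    def test_single_base_change_destroys_motif(self):
        # CTTCAG at the homologous position yields no label
        assert digest_sequence("AACTTCAGTT").n_labels == 0

    def test_gttaag_has_no_label_on_either_strand(self):
        seq = "AAGTTAAGTT"
        assert digest_sequence(seq).n_labels == 0
        assert digest_sequence(revcomp(seq)).n_labels == 0

    def test_n_never_matches(self):
        assert digest_sequence("CTTNAGCTTAAG").positions.tolist() == [7]

    def test_close_occurrences_merge_to_midpoint(self):
        seq = "CTTAAG" + "A" * 94 + "CTTAAG"  # starts 1 and 101, 100 bp apart
        lm = digest_sequence(seq, res_bp=200)
        assert lm.positions.tolist() == [51]

    @given(st.text(alphabet="ACGT", min_size=0, max_size=300))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_digest_is_strand_symmetric_for_palindromic_motif(self, seq):
        fwd = digest_sequence(seq, res_bp=0)
        rev = digest_sequence(revcomp(seq), res_bp=0)
        # label at 1-based start p maps to start (len - p - 4) on the
        # reverse strand for a 6-mer palindrome
        expect = sorted(len(seq) - p - 4 for p in fwd.positions)
        assert rev.positions.tolist() == expect


class TestBuildHaplotype:
    def test_concatenation_realizes_offsets_in_order(self):
        mods = [ModuleSpec("ANCHOR_5A"), ModuleSpec("SD160", "+", "a"), ModuleSpec("ANCHOR_3A")]
        hap = build_haplotype("LCR22A", mods, "h")
        assert hap.length_bp == sum(m.length_bp for m in mods)
        first = mods[0].label_offsets
        assert hap.labelmap.positions[: len(first)].tolist() == list(first)

    def test_reflection_is_involutive(self):
        fwd = ModuleSpec("SD160", "+", "a")
        rev = ModuleSpec("SD160", "-", "a")
        L = fwd.length_bp
        back = tuple(L - o + 1 for o in reversed(rev.oriented_offsets))
        assert back == fwd.oriented_offsets
        assert rev.oriented_offsets != fwd.oriented_offsets

    def test_partial_module_must_be_first_duplicon(self):
        bad = [ModuleSpec("SD160", "+", "a"), ModuleSpec("SD160_PARTIAL")]
        with pytest.raises(ValueError, match="5'-most"):
            build_haplotype("LCR22A", bad)
        with pytest.raises(ValueError, match="reference orientation"):
            ModuleSpec("SD160_PARTIAL", "-")
            build_haplotype("LCR22A", [ModuleSpec("SD160_PARTIAL", "-")])

    def test_paralog_variants_share_features_but_not_labels(self):
        from lcrkit.assembly import feature_signature

        h1 = build_haplotype("LCR22A", [ModuleSpec("SD160", "+", "a")], "v-a")
        h2 = build_haplotype("LCR22A", [ModuleSpec("SD160", "+", "b")], "v-b")
        assert feature_signature(h1) == feature_signature(h2)
        assert h1.labelmap.positions.tolist() != h2.labelmap.positions.tolist()

    def test_default_catalog_density_in_study_band(self, catalog):
        for hap in catalog.haplotypes.values():
            assert 15.0 <= hap.labelmap.density_per_100kbp() <= 17.0


class TestSimulateMolecules:
    def test_noise_free_molecules_are_exact_slices(self, catalog):
        hap = catalog.haplotypes["A-1x160"]
        clean = SimParams(coverage=2.0, fp_rate=0.0, fn_rate=0.0, sf=0.0, sd=0.0)
        for mol in simulate_molecules([hap], clean, seed=1):
            start = mol.source_meta["window_start_bp"]
            truth = hap.labelmap.window(start, start + mol.length_bp - 1) - start + 1
            got = mol.labelmap.positions
            if mol.source_meta["flipped"]:
                got = (mol.length_bp - got + 1)[::-1]
            assert got.tolist() == truth.tolist()

    def test_fn_one_drops_every_label(self, catalog):
        hap = catalog.haplotypes["D-ref"]
        params = SimParams(coverage=1.0, fn_rate=1.0, fp_rate=0.0)
        assert all(m.n_labels == 0 for m in simulate_molecules([hap], params, seed=2))

    def test_length_filter_and_throughput(self, catalog):
        hap = catalog.haplotypes["D-ref"]
        params = SimParams(coverage=5.0)
        mols = simulate_molecules([hap], params, seed=3)
        assert all(m.length_bp >= params.min_len_bp for m in mols)
        assert sum(m.length_bp for m in mols) >= 5.0 * hap.length_bp

    def test_zero_target_gives_empty_set(self, catalog):
        hap = catalog.haplotypes["D-ref"]
        assert simulate_molecules([hap], SimParams(target_total_bp=0), seed=4) == []

    def test_fn_rate_recovered_from_truth_bookkeeping(self, catalog):
        hap = catalog.haplotypes["A-ref"]
        params = SimParams(coverage=10.0, fn_rate=0.13)
        mols = simulate_molecules([hap], params, seed=5)
        assert sum(m.length_bp for m in mols) >= 10e6
        n_true = sum(m.source_meta["n_true_in_window"] for m in mols)
        n_kept = sum(sum(m.source_meta["is_true_label"]) for m in mols)
        assert 1 - n_kept / n_true == pytest.approx(0.13, abs=0.01)


class TestSimulateTrio:
    def test_fixed_seed_is_deterministic(self, catalog, sim_params):
        t1 = simulate_trio(catalog, sim_params, seed=42, family_id="f")
        t2 = simulate_trio(catalog, sim_params, seed=42, family_id="f")
        assert t1.truth == t2.truth
        assert np.array_equal(t1.proband_deletion.positions, t2.proband_deletion.positions)

    def test_breakpoint_lies_in_a_shared_sd160_segment(self, catalog, sim_params):
        for seed in range(12):
            trio = simulate_trio(catalog, sim_params, seed=100 + seed)
            truth = trio.truth
            lo, hi = truth.shared_segment
            assert lo <= truth.breakpoint_bp <= hi
            origin = trio.mother if truth.parent_of_origin == "mother" else trio.father
            hap_a = next(
                h for h in origin["LCR22A"] if h.haplotype_id == truth.parent_A_haplotype_id
            )
            mod = hap_a.module_at(truth.breakpoint_bp)
            assert mod is not None and mod.module_name == "SD160"

    def test_intact_homolog_is_a_parental_haplotype(self, catalog, sim_params):
        trio = simulate_trio(catalog, sim_params, seed=7)
        other = trio.father if trio.truth.parent_of_origin == "mother" else trio.mother
        for locus, hap in trio.proband_intact.items():
            assert hap.haplotype_id in {h.haplotype_id for h in other[locus]}

    def test_deletion_contig_is_template_switch_mosaic(self, catalog, sim_params):
        trio = simulate_trio(catalog, sim_params, seed=8)
        truth = trio.truth
        origin = trio.mother if truth.parent_of_origin == "mother" else trio.father
        hap_a = next(
            h for h in origin["LCR22A"] if h.haplotype_id == truth.parent_A_haplotype_id
        )
        hap_d = next(
            h for h in origin["LCR22D"] if h.haplotype_id == truth.parent_D_haplotype_id
        )
        pos = trio.proband_deletion.positions
        bp = truth.breakpoint_bp
        prefix = pos[pos < bp]
        assert prefix.tolist() == hap_a.labelmap.positions[
            hap_a.labelmap.positions < bp
        ].tolist()
        d_pos = hap_d.labelmap.positions
        expect_suffix = d_pos[d_pos >= truth.breakpoint_bp_D] - truth.breakpoint_bp_D + bp
        assert pos[pos >= bp].tolist() == expect_suffix.tolist()

    def test_origin_weighting_approaches_19_to_11(self, catalog, sim_params):
        n = 200
        p = 19 / 30
        mothers = sum(
            simulate_trio(catalog, sim_params, seed=500 + i).truth.parent_of_origin == "mother"
            for i in range(n)
        )
        se = (p * (1 - p) / n) ** 0.5
        assert abs(mothers / n - p) <= 3 * se

    def test_shared_segments_require_matching_orientation(self, catalog):
        inv = catalog.haplotypes["A-inv160"]
        d = catalog.haplotypes["D-ref"]
        assert shared_identical_segments(inv, d) == []
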