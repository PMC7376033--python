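"""Anchoring, molecule assignment, signatures, grouping, inversion calls."""

import numpy as np
import pytest

from lcrkit.align import AlignParams, align
from lcrkit.assembly import (
    AnchorRegion,
    anchors_for,
    chain_haplotypes,
    detect_inversion,
    feature_signature,
    find_anchor_molecules,
    group_haplotypes,
    label_signature,
    HaplotypeCall,
)
from lcrkit.pipeline import noisy_contig
from lcrkit.simulate import Haplotype, SimParams, simulate_molecules
from lcrkit.types import LabelMap


class TestAnchors:
    def test_anchor_regions_satisfy_span_and_label_rules(self, catalog):
        for hap in catalog.haplotypes.values():
            regions = anchors_for(hap)
            assert {a.side for a in regions} == {"5prime", "3prime"}
            for a in regions:
                a.validate(hap.labelmap)

    def test_undersized_anchor_is_rejected(self, catalog):
        hap = catalog.haplotypes["A-ref"]
        with pytest.raises(ValueError, match="span"):
            AnchorRegion("LCR22A", "5prime", 1, 50_000).validate(hap.labelmap)

    def test_anchor_spanning_molecules_are_anchored(self, catalog, aln_params):
        hap = catalog.haplotypes["A-1x160"]
        clean = SimParams(coverage=4.0, fp_rate=0.0, fn_rate=0.0, sf=0.0, sd=0.0)
        mols = simulate_molecules([hap], clean, seed=1)
        alns = {
            m.molecule_id: (align(m.labelmap, hap.labelmap, aln_params) or [None])[0]
            for m in mols
        }
        anchored = find_anchor_molecules(alns, hap, params=aln_params)
        a5 = next(a for a in anchors_for(hap) if a.side == "5prime")
        for m in mols:
            start = m.source_meta["window_start_bp"]
            covers = start <= a5.start_bp and start + m.length_bp - 1 >= a5.end_bp
            if covers:
                assert m.molecule_id in anchored["LCR22A:5prime"]

    def test_duplicon_interior_molecule_is_not_anchored(self, catalog, aln_params):
        hap = catalog.haplotypes["A-ref"]
        # a synthetic read wholly inside the first SD160 copy
        mod, start, end = next(x for x in hap.layout if x[0].module_name == "SD160")
        window = hap.labelmap.window(start, end - 1) - start + 1
        mol_map = LabelMap("inside", end - start + 1, window)
        aln = (align(mol_map, hap.labelmap, aln_params) or [None])[0]
        anchored = find_anchor_molecules({"inside": aln}, hap, params=aln_params)
        assert all("inside" not in ids for ids in anchored.values())

    def test_noisy_anchor_overlap_sensitivity(self, catalog, aln_params):
        """At study noise rates, molecules fully covering an anchor are
        essentially always anchored there."""
        hap = catalog.haplotypes["A-1x160"]
        mols = simulate_molecules([hap], SimParams(coverage=25.0), seed=2)
        alns = {
            m.molecule_id: (align(m.labelmap, hap.labelmap, aln_params) or [None])[0]
            for m in mols
        }
        anchored = find_anchor_molecules(alns, hap, params=aln_params)
        a5 = next(a for a in anchors_for(hap) if a.side == "5prime")
        eligible = hit = 0
        for m in mols:
            start = m.source_meta["window_start_bp"]
            if start <= a5.start_bp and start + m.length_bp - 1 >= a5.end_bp:
                eligible += 1
                hit += m.molecule_id in anchored["LCR22A:5prime"]
        assert eligible >= 10
        assert hit / eligible >= 0.99


class TestChaining:
    def test_structurally_distinct_heterozygote_recovers_complete(self, catalog, aln_params):
        h1, h2 = catalog.haplotypes["A-1x160"], catalog.haplotypes["A-ref"]
        mols = simulate_molecules([h1, h2], SimParams(coverage=50.0), seed=3)
        calls, rep = chain_haplotypes(mols, [h1, h2], aln_params)
        assert {c.haplotype.haplotype_id for c in calls} == {"A-1x160", "A-ref"}
        assert all(c.is_complete for c in calls)
        assert rep["assigned"] + rep["ambiguous"] + rep["filtered"] == rep["total"]

    def test_homozygote_merges_into_one_call_at_double_coverage(self, catalog, aln_params):
        hap = catalog.haplotypes["D-inv"]
        mols = simulate_molecules([hap, hap], SimParams(coverage=30.0), seed=4)
        calls, _ = chain_haplotypes(mols, [hap, hap], aln_params)
        assert len(calls) == 1
        assert calls[0].n_copies == 2
        assert calls[0].is_complete

    def test_degenerate_candidate_pair_is_diagnosed(self, catalog, aln_params):
        hap = catalog.haplotypes["D-inv"]
        twin = Haplotype("D-twin", hap.locus, hap.modules, hap.labelmap, hap.layout)
        mols = simulate_molecules([hap], SimParams(coverage=12.0), seed=5)
        calls, _ = chain_haplotypes(mols, [hap, twin], aln_params)
        assert all("degenerate pair" in c.diagnostics for c in calls)
        assert not any(c.is_complete for c in calls)

    def test_completion_is_monotone_in_coverage(self, catalog, aln_params):
        h1, h2 = catalog.haplotypes["D-ref"], catalog.haplotypes["D-inv"]
        mols = simulate_molecules([h1, h2], SimParams(coverage=40.0), seed=6)
        half, _ = chain_haplotypes(mols[: len(mols) // 2], [h1, h2], aln_params)
        full, _ = chain_haplotypes(mols, [h1, h2], aln_params)
        for c_half, c_full in zip(half, full):
            if c_half.is_complete:
                assert c_full.is_complete


class TestSignatures:
    def test_feature_signature_ignores_paralog_variants(self, catalog):
        h = catalog.haplotypes
        assert feature_signature(h["D-inv"]) == feature_signature(h["D-inv-2"])
        assert feature_signature(h["D-ref"]) != feature_signature(h["D-inv"])

    def test_copy_number_and_orientation_are_distinguished(self, catalog):
        h = catalog.haplotypes
        sigs = {feature_signature(h[k]) for k in ("A-ref", "A-1x160", "A-3x160", "A-partial",
                                                  "A-inv160")}
        assert len(sigs) == 5

    def test_whole_haplotype_reversal_changes_signature(self, catalog):
        hap = catalog.haplotypes["A-inv160"]
        flipped = Haplotype(
            "rev", hap.locus,
            tuple(
                type(m)(m.module_name, "-" if m.orientation == "+" else "+",
                        m.paralog_variant)
                for m in reversed(hap.modules)
            ),
            hap.labelmap, hap.layout,
        )
        assert feature_signature(flipped) != feature_signature(hap)

    def test_label_signature_tolerates_sub_jitter_perturbation(self, catalog, rng):
        hap = catalog.haplotypes["A-1x160"]
        pos = hap.labelmap.positions + rng.integers(-1_500, 1_500, hap.labelmap.n_labels)
        pos = np.sort(pos)
        wobbled = Haplotype(
            "wob", hap.locus, hap.modules,
            LabelMap("wob", hap.length_bp, pos, dict(hap.labelmap.meta)), hap.layout,
        )
        exemplars = []
        k1 = label_signature(hap, 2_000, exemplars)
        k2 = label_signature(wobbled, 2_000, exemplars)
        assert k1 == k2

    def test_single_polymorphic_label_separates_keys(self, catalog):
        h = catalog.haplotypes
        exemplars = []
        assert label_signature(h["D-inv"], 2_000, exemplars) != label_signature(
            h["D-inv-2"], 2_000, exemplars
        )


class TestGrouping:
    def _calls(self, catalog, ids, roles=None):
        out = []
        for i, hid in enumerate(ids):
            c = HaplotypeCall(catalog.haplotypes[hid], status="complete")
            c.role = (roles or {}).get(i, "parent-of-origin")
            out.append(c)
        return out

    def test_feature_group_counts(self, catalog):
        calls = self._calls(catalog, ["A-ref", "A-ref", "A-1x160"])
        table = group_haplotypes(calls, "features")
        assert table["count"].sum() == 3
        assert len(table) == 2

    def test_label_groups_refine_feature_groups(self, catalog):
        calls = self._calls(catalog, ["D-ref", "D-inv", "D-inv-2", "D-inv"])
        feat = group_haplotypes(calls, "features")
        lab = group_haplotypes(calls, "labels")
        assert len(lab) >= len(feat)
        # every label group sits inside one feature group
        keymap = {}
        exemplars = []
        for c in calls:
            keymap.setdefault(label_signature(c.haplotype, 2_000, exemplars), set()).add(
                feature_signature(c.haplotype)
            )
        assert all(len(v) == 1 for v in keymap.values())

    def test_homozygote_counts_twice(self, catalog):
        c = HaplotypeCall(catalog.haplotypes["D-inv"], status="complete", n_copies=2)
        c.role = "NAHR-negative"
        table = group_haplotypes([c], "features")
        assert table["count"].sum() == 2


class TestInversion:
    def test_truth_haplotypes(self, catalog):
        assert detect_inversion(catalog.haplotypes["D-ref"]) is False
        assert detect_inversion(catalog.haplotypes["D-inv"]) is True

    def test_window_not_covered_is_indeterminate(self, catalog):
        hap = catalog.haplotypes["D-ref"]
        pos = hap.labelmap.positions
        rel0 = 21_400_000 - hap.base_bp
        kept = pos[pos < rel0]
        truncated = Haplotype(
            "trunc", hap.locus, hap.modules,
            LabelMap("trunc", hap.length_bp, kept, dict(hap.labelmap.meta)), hap.layout,
        )
        assert detect_inversion(truncated) is None

    def test_noisy_consensus_detection_accuracy(self, catalog, rng):
        ok = 0
        n = 60
        for i in range(n):
            hid = "D-inv" if rng.random() < 0.74 else "D-ref"
            hap = catalog.haplotypes[hid]
            lm = noisy_contig(hap.labelmap, rng, 300.0, 0.02, 0.01)
            noisy = Haplotype(hid, hap.locus, hap.modules, lm, hap.layout)
            ok += detect_inversion(noisy) is (hid != "D-ref")
        assert ok / n >= 0.95
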