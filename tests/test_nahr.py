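"""Label partition, interval localization, annotation, and classification."""

import numpy as np
import pytest

from lcrkit.nahr import (
    NAHRLocalizationError,
    annotate_interval,
    classify_event,
    localize_trio,
    nahr_interval,
    partition_labels,
)
from lcrkit.pipeline import default_annotations, noisy_contig
from lcrkit.simulate import (
    ModuleSpec,
    SimParams,
    build_haplotype,
    simulate_trio,
)
from lcrkit.types import AnnotationInterval, LabelMap


def _hap(locus, positions, length, hap_id="p"):
    mods = [ModuleSpec("ANCHOR_5A" if locus == "LCR22A" else "ANCHOR_5D")]
    hap = build_haplotype(locus, mods, hap_id)
    lm = LabelMap(hap_id, length, positions, dict(hap.labelmap.meta))
    return type(hap)(hap_id, locus, hap.modules, lm, hap.layout)


class TestPartition:
    def _grid(self, start, n, step=6_000):
        return np.arange(start, start + n * step, step)

    def test_everywhere_discriminating_parents_collapse_to_one_gap(self):
        # parents share no label positions at all (independent irregular grids)
        rng = np.random.default_rng(2)
        a_pos = np.cumsum(rng.integers(4_500, 8_000, 30)) + 2_000
        d_pos = np.cumsum(rng.integers(4_500, 8_000, 30)) + 4_600
        bp = 95_000
        contig = np.concatenate([a_pos[a_pos < bp], d_pos[d_pos >= bp]])
        L = 200_000
        pa, pd = _hap("LCR22A", a_pos, L, "pa"), _hap("LCR22D", d_pos, L, "pd")
        cmap = LabelMap("c", L, contig)
        part = partition_labels(cmap, pa, pd)
        f0, f1 = part.ambiguous
        assert f1 - f0 == 0  # no shared labels: ambiguity is the bare gap
        ev = nahr_interval(part, cmap, pa, pd)
        assert ev.ambiguous_interval[0] < bp <= ev.ambiguous_interval[1]
        # the single inter-label gap containing the switch (grids step < 8 kbp
        # each, so the combined A-to-D gap is below ~16 kbp)
        assert ev.width_bp <= 16_000

    def test_identical_parents_are_fully_ambiguous(self):
        pos = self._grid(5_000, 30)
        L = 200_000
        pa, pd = _hap("LCR22A", pos, L, "pa"), _hap("LCR22D", pos, L, "pd")
        cmap = LabelMap("c", L, pos)
        part = partition_labels(cmap, pa, pd)
        assert part.prefix == (0, 0)
        assert part.suffix == (30, 30)
        ev = nahr_interval(part, cmap, pa, pd)
        assert {"fully-ambiguous-5prime", "fully-ambiguous-3prime"} <= set(ev.flags)

    def test_partition_is_exhaustive_and_disjoint(self, catalog, sim_params):
        for seed in range(8):
            trio = simulate_trio(catalog, sim_params, seed=40 + seed)
            origin = trio.mother if trio.truth.parent_of_origin == "mother" else trio.father
            pa = next(h for h in origin["LCR22A"]
                      if h.haplotype_id == trio.truth.parent_A_haplotype_id)
            pd = next(h for h in origin["LCR22D"]
                      if h.haplotype_id == trio.truth.parent_D_haplotype_id)
            part = partition_labels(trio.proband_deletion, pa, pd)
            (p0, p1), (m0, m1), (s0, s1) = part.prefix, part.ambiguous, part.suffix
            assert (p0, p1, m0, m1, s0, s1) == (0, m0, p1, s0, m1,
                                                trio.proband_deletion.n_labels)

    def test_single_parent_match_is_an_error(self, catalog):
        pa = catalog.haplotypes["A-1x160"]
        pd = catalog.haplotypes["D-ref"]
        contig = LabelMap("c", pa.length_bp, pa.labelmap.positions)
        with pytest.raises(NAHRLocalizationError, match="no recombinant structure"):
            partition_labels(contig, pa, pd)


class TestInterval:
    def test_width_is_positional_subtraction(self):
        # prefix ends at abs 18,650,000, suffix starts at 18,678,000 -> 28 kbp
        L = 900_000
        base_off = 18_000_000  # _hap has no flank module, so base == locus start
        a_last = 18_650_000 - base_off
        d_first = 18_678_000 - base_off
        a_pos = np.array([a_last - 12_000, a_last, a_last + 50_000], dtype=np.int64)
        d_pos = np.array([a_last - 30_000 + 9, d_first, d_first + 11_000], dtype=np.int64)
        pa, pd = _hap("LCR22A", a_pos, L, "pa"), _hap("LCR22D", d_pos, L, "pd")
        contig = np.array([a_last - 12_000, a_last, d_first, d_first + 11_000])
        from lcrkit.align import AlignParams

        part = partition_labels(
            LabelMap("c", L, contig), pa, pd,
            AlignParams(min_matched_sites=2, T_confirm=1.0),
        )
        ev = nahr_interval(part, LabelMap("c", L, contig), pa, pd)
        assert ev.width_bp == 28_000
        assert ev.ambiguous_interval_abs == (18_650_000, 18_678_000)

    def test_interval_shrinks_as_discriminating_labels_are_added(self):
        L = 400_000
        base = np.arange(6_000, 390_000, 6_000)
        bp = 200_000
        rng = np.random.default_rng(0)
        widths = []
        extra_sets = [
            [],
            [150_000 + 3_000, 250_000 + 3_000],
            [150_000 + 3_000, 180_000 + 3_000, 220_000 + 3_000, 250_000 + 3_000],
        ]
        for extras in extra_sets:
            a_extra = [e for e in extras if e < bp]
            d_extra = [e for e in extras if e >= bp]
            a_pos = np.sort(np.concatenate([base, a_extra])).astype(np.int64)
            d_pos = np.sort(np.concatenate([base, d_extra])).astype(np.int64)
            pa, pd = _hap("LCR22A", a_pos, L, "pa"), _hap("LCR22D", d_pos, L, "pd")
            contig = np.concatenate([a_pos[a_pos < bp], d_pos[d_pos >= bp]])
            part = partition_labels(LabelMap("c", L, contig), pa, pd)
            ev = nahr_interval(part, LabelMap("c", L, contig), pa, pd)
            assert ev.ambiguous_interval[0] < bp <= ev.ambiguous_interval[1]
            widths.append(ev.width_bp)
        assert widths[0] > widths[1] > widths[2]


class TestAnnotate:
    def test_contains_fam230a(self):
        anns = default_annotations()
        names = annotate_interval((18_450_000, 18_470_000), anns)
        assert "FAM230A" in names

    def test_does_not_contain_bcrp7_outside_its_span(self):
        anns = default_annotations()
        names = annotate_interval((18_860_000, 18_870_000), anns)
        assert "BCRP7" not in names

    def test_one_bp_overlap_counts_and_empty_set(self):
        iv = AnnotationInterval("X", 100, 200, "chr22")
        assert annotate_interval((200, 300), [iv]) == {"X"}
        assert annotate_interval((201, 300), [iv]) == frozenset()
        assert annotate_interval((10, 20), []) == frozenset()


class TestClassifyAndLocalize:
    def test_default_cohort_events_are_in_reference_sd160(self, catalog, sim_params):
        anns = default_annotations()
        for seed in range(10):
            trio = simulate_trio(catalog, sim_params, seed=70 + seed)
            ev = localize_trio(trio, anns)
            assert ev.category == "in_SD160_ref"
            assert ev.annotations  # every event overlaps >= 1 annotation

    def test_noisy_localization_keeps_breakpoint(self, catalog, sim_params, rng):
        anns = default_annotations()
        hits = n = 0
        for seed in range(25):
            trio = simulate_trio(catalog, sim_params, seed=700 + seed)
            contig = noisy_contig(trio.proband_deletion, rng, 300.0, 0.02, 0.01)
            try:
                ev = localize_trio(trio, anns, contig=contig)
            except NAHRLocalizationError:
                continue
            n += 1
            lo, hi = ev.ambiguous_interval
            hits += lo <= trio.truth.breakpoint_bp <= hi
        assert n >= 23
        assert hits / n >= 0.9

    def test_dense_polymorphisms_give_narrow_intervals(self, dense_cat, sim_params):
        anns = default_annotations()
        widths = []
        for seed in range(20):
            trio = simulate_trio(dense_cat, sim_params, seed=900 + seed)
            ev = localize_trio(trio, anns)
            widths.append(ev.width_bp)
        assert min(widths) <= 30_000

    def test_inverted_a_module_event_classifies_as_inv(self, catalog):
        # synthetic event: ambiguous interval inside the inverted SD160 of
        # A-inv160, D span in the 5' LCR22D region
        hap_a = catalog.haplotypes["A-inv160"]
        hap_d = catalog.haplotypes["D-ref"]
        mod, a_start, a_end = next(
            x for x in hap_a.layout if x[0].module_name == "SD160"
        )
        from lcrkit.nahr import NAHREvent

        d_lo = 21_090_000 - hap_d.base_bp
        ev = NAHREvent(
            "synthetic", "mother", (0, a_start + 10_000), (1, a_start + 40_000),
            (a_start + 10_000, a_start + 40_000),
            (a_start + 10_000 + hap_a.base_bp, a_start + 40_000 + hap_a.base_bp),
            (d_lo, d_lo + 30_000), 30_000,
        )
        out = classify_event(ev, hap_a, hap_d, default_annotations())
        assert out.category == "in_SD160_inv"

    def test_sd22_3_vs_sd160_category(self, catalog):
        hap_a = catalog.haplotypes["A-ref"]
        hap_d = catalog.haplotypes["D-ref"]
        mod, a_start, a_end = next(
            x for x in hap_a.layout if x[0].module_name == "SD22_3"
        )
        d_mod, d_start, d_end = next(
            x for x in hap_d.layout if x[0].module_name == "SD160"
        )
        from lcrkit.nahr import NAHREvent

        ev = NAHREvent(
            "synthetic", "father", (0, a_start + 5_000), (1, a_start + 25_000),
            (a_start + 5_000, a_start + 25_000),
            (a_start + 5_000 + hap_a.base_bp, a_start + 25_000 + hap_a.base_bp),
            (d_start + 60_000, d_start + 80_000), 20_000,
        )
        out = classify_event(ev, hap_a, hap_d, default_annotations())
        assert out.category == "SD22_3_vs_SD160"
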