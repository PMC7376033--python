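"""Localizing the NAHR recombination interval on a deletion contig.

A proband's deletion contig is an LCR22A prefix fused to an LCR22D suffix
somewhere inside a shared, near-identical segment. Against the two
parent-of-origin haplotypes, its labels partition into a leading run that
matches only the LCR22A parent, a trailing run that matches only the
LCR22D parent, and an ambiguous middle where the parents are locally
identical: the recombination happened somewhere in that middle. Label
polymorphisms and spacing discrepancies between the parental maps shrink
the ambiguous interval; with densely polymorphic 160 kbp module ends it
can close to a few tens of kbp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import AlignParams, align
from .simulate import Haplotype
from .types import AnnotationInterval, LabelMap

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "NAHREvent",
    "NAHRLocalizationError",
    "partition_labels",
    "nahr_interval",
    "annotate_interval",
    "classify_event",
    "localize_trio",
]

CATEGORY_PRIORITY = (
    "in_SD160_ref",
    "in_SD160_inv",
    "A_SD160_vs_BCRP2",
    "SD22_3_vs_SD160",
    "flanking_SD160",
)

# the LCR22D region 5' of its 160 kbp module implicated in inverted-module
# events (absolute coordinates, ~21.08-21.15 Mbp)
_D_5PRIME_REGION = (21_080_000, 21_150_000)


class NAHRLocalizationError(ValueError):
    """The contig/parent trio does not present a recombinant structure."""


@dataclass(frozen=True)
class Partition:
    """Index partition of contig labels: prefix / ambiguous / suffix.

    ``prefix`` runs through the last A-unique label, ``suffix`` starts at
    the first D-unique label, and everything between (labels the locally
    identical parents share) is ambiguous. The three ranges are disjoint
    and exhaustive by construction.
    """

    prefix: tuple  # (start_idx, end_idx) exclusive end; may be empty (i, i)
    ambiguous: tuple
    suffix: tuple
    matched_A: tuple  # contig label indices matched to the A parent
    matched_D: tuple
    pos_A: dict  # contig idx -> matched A-parent position (bp)
    pos_D: dict

    @property
    def n_labels(self) -> int:
        return self.suffix[1]


def partition_labels(
    proband_contig: LabelMap,
    parent_A: Haplotype,
    parent_D: Haplotype,
    params: AlignParams | None = None,
) -> Partition:
    """Partition contig labels by parental consistency.

    The contig is aligned to each parental haplotype; a label "matches" a
    parent when it is paired in that parent's best alignment (presence
    within the sizing tolerance and spacing agreement are what the DP
    scores). The prefix runs through the last label matching the LCR22A
    parent only, the suffix starts at the first label matching the LCR22D
    parent only, and the shared labels between those bounds are ambiguous.
    Raises :class:`NAHRLocalizationError` when the contig matches only one
    parent, or when A-unique evidence appears past D-unique evidence.
    """
    params = params or AlignParams()
    n = proband_contig.n_labels
    matched = {}
    pos_of = {}
    for tag, parent in (("A", parent_A), ("D", parent_D)):
        alns = align(proband_contig, parent.labelmap, params)
        best = alns[0] if alns else None
        if best is None or best.significance > params.T_confirm:
            raise NAHRLocalizationError(
                f"no recombinant structure: contig does not align to parent {tag}"
            )
        matched[tag] = frozenset(i for i, _ in best.pairs)
        tpos = parent.labelmap.positions
        pos_of[tag] = {i: int(tpos[j]) for i, j in best.pairs}
    mA, mD = matched["A"], matched["D"]
    if not mA or not mD:
        raise NAHRLocalizationError("no recombinant structure: one parent never matches")

    # unique-evidence bounds: every label up to the last A-unique label must
    # be A-derived, every label from the first D-unique label on must be
    # D-derived; labels matching both parents in between are the ambiguous
    # (shared) recombination region
    a_unique = mA - mD
    d_unique = mD - mA
    if bool(a_unique) != bool(d_unique):
        # unique evidence for exactly one parent: the contig is not a
        # recombinant of the two (near-identical duplicons make the *other*
        # parent align too, but never uniquely)
        raise NAHRLocalizationError(
            "no recombinant structure: unique label evidence for only one parent"
        )
    iA = max(a_unique) if a_unique else None
    iD = min(d_unique) if d_unique else None
    if iA is not None and iD is not None and iA > iD:
        raise NAHRLocalizationError(
            "inconsistent parental assignment: A-unique evidence past D-unique evidence"
        )
    f = iA + 1 if iA is not None else 0
    l = iD - 1 if iD is not None else n - 1
    return Partition(
        prefix=(0, f),
        ambiguous=(f, l + 1),
        suffix=(l + 1, n),
        matched_A=tuple(sorted(mA)),
        matched_D=tuple(sorted(mD)),
        pos_A=pos_of["A"],
        pos_D=pos_of["D"],
    )


@dataclass(frozen=True)
class NAHREvent:
    """A localized NAHR deletion event."""

    family_id: str
    parent_of_origin: str
    prefix_last_label: tuple  # (contig index, contig/parent-A bp) or None
    suffix_first_label: tuple
    ambiguous_interval: tuple  # (start_bp, end_bp) on the parent-A coordinate
    ambiguous_interval_abs: tuple  # hg38-like absolute coordinates
    d_span: tuple  # homologous LCR22D span (haplotype coordinates)
    width_bp: int
    annotations: frozenset = frozenset()
    category: str = ""
    flags: tuple = ()


def nahr_interval(
    partition: Partition,
    proband_contig: LabelMap,
    parent_A: Haplotype,
    parent_D: Haplotype,
    family_id: str = "",
    parent_of_origin: str = "",
) -> NAHREvent:
    """The ambiguous genomic interval of a partitioned contig.

    Runs from the parent-A position of the last prefix label to the
    (parent-A-projected) position of the first suffix label; the
    homologous LCR22D span is reported alongside. A fully ambiguous
    contig yields the whole aligned span, flagged.
    """
    pos = proband_contig.positions
    flags = []
    p0, p1 = partition.prefix
    s0, s1 = partition.suffix
    if p1 > p0:
        last_idx = p1 - 1
        a_start = partition.pos_A.get(last_idx, int(pos[last_idx]))
        prefix_last = (last_idx, a_start)
    else:
        mA = [i for i in partition.matched_A]
        a_start = partition.pos_A[min(mA)]
        prefix_last = None
        flags.append("fully-ambiguous-5prime")
    if s1 > s0:
        first_idx = s0
        d_first = partition.pos_D[first_idx]
        # the contig frame coincides with the parent-A frame up to the
        # breakpoint and is offset by a constant beyond it; the contig
        # position of the first suffix label is its A-projected position
        a_end = int(pos[first_idx])
        suffix_first = (first_idx, a_end)
    else:
        mD = [i for i in partition.matched_D]
        a_end = int(pos[max(mD)])
        d_first = partition.pos_D[max(mD)]
        suffix_first = None
        flags.append("fully-ambiguous-3prime")
    width = int(a_end - a_start)
    d_end = int(d_first)
    d_start = max(1, d_end - width)
    return NAHREvent(
        family_id=family_id,
        parent_of_origin=parent_of_origin,
        prefix_last_label=prefix_last,
        suffix_first_label=suffix_first,
        ambiguous_interval=(int(a_start), int(a_end)),
        ambiguous_interval_abs=(
            int(a_start) + parent_A.base_bp,
            int(a_end) + parent_A.base_bp,
        ),
        d_span=(d_start, d_end),
        width_bp=width,
        flags=tuple(flags),
    )


def annotate_interval(
    interval: tuple[int, int], annotations: list[AnnotationInterval]
) -> frozenset:
    """Names of annotations overlapping ``interval`` by >= 1 bp (absolute)."""
    lo, hi = interval
    return frozenset(a.name for a in annotations if a.overlaps(lo, hi))


def classify_event(
    event: NAHREvent,
    parent_A: Haplotype,
    parent_D: Haplotype,
    annotations: list[AnnotationInterval] = (),
) -> NAHREvent:
    """Assign the event to one of the recombination-locus categories.

    ``in_SD160_ref``/``in_SD160_inv`` when the ambiguous interval lies
    within 160 kbp modules on both parents (reference or inverted LCR22A
    copy); otherwise one of the outside categories. Multi-module
    intervals are resolved by the category priority and flagged.
    """
    a_lo, a_hi = event.ambiguous_interval
    d_lo, d_hi = event.d_span

    def mods_over(hap, lo, hi):
        return [
            m for m, s, e in hap.layout if s <= hi and lo <= e and not _is_plumbing(m)
        ]

    a_mods = mods_over(parent_A, a_lo, a_hi)
    d_mods = mods_over(parent_D, d_lo, d_hi)
    a_names = {m.module_name for m in a_mods}
    d_names = {m.module_name for m in d_mods}
    d_abs = (d_lo + parent_D.base_bp, d_hi + parent_D.base_bp)

    candidates = []
    a_sd160 = [m for m in a_mods if m.module_name == "SD160"]
    if a_sd160 and "SD160" in d_names:
        if all(m.orientation == "+" for m in a_sd160):
            candidates.append("in_SD160_ref")
        else:
            candidates.append("in_SD160_inv")
    if a_sd160 and _overlaps(d_abs, _D_5PRIME_REGION):
        candidates.append("in_SD160_inv" if any(
            m.orientation == "-" for m in a_sd160) else "A_SD160_vs_BCRP2")
    if "SD22_3" in a_names and "SD160" in d_names:
        candidates.append("SD22_3_vs_SD160")
    if not candidates:
        candidates.append("flanking_SD160")
    category = min(set(candidates), key=CATEGORY_PRIORITY.index)

    flags = list(event.flags)
    if len(a_names | {"D:" + x for x in d_names}) > 2 and len(set(candidates)) > 1:
        flags.append("multi-overlap")
    names = annotate_interval(event.ambiguous_interval_abs, list(annotations)) | (
        annotate_interval(d_abs, list(annotations))
    )
    return NAHREvent(
        **{
            **event.__dict__,
            "category": category,
            "annotations": frozenset(names),
            "flags": tuple(flags),
        }
    )


def _is_plumbing(mod) -> bool:
    return mod.module_name.startswith(("FLANK", "ANCHOR"))


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def localize_trio(
    trio,
    annotations: list[AnnotationInterval] = (),
    params: AlignParams | None = None,
    contig: LabelMap | None = None,
) -> NAHREvent:
    """Partition, localize, annotate and classify one trio's deletion.

    ``contig`` overrides the trio's truth contig (e.g. a noisy consensus).
    """
    origin_parent = trio.mother if trio.truth.parent_of_origin == "mother" else trio.father
    hap_a = next(
        h for h in origin_parent["LCR22A"] if h.haplotype_id == trio.truth.parent_A_haplotype_id
    )
    hap_d = next(
        h for h in origin_parent["LCR22D"] if h.haplotype_id == trio.truth.parent_D_haplotype_id
    )
    cmap = contig if contig is not None else trio.proband_deletion
    part = partition_labels(cmap, hap_a, hap_d, params)
    event = nahr_interval(
        part, cmap, hap_a, hap_d,
        family_id=trio.family_id,
        parent_of_origin=trio.truth.parent_of_origin,
    )
    return classify_event(event, hap_a, hap_d, annotations)
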