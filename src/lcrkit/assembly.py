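"""Localized haplotype validation from anchored single molecules.

A haplotype call is *complete* when single molecules (i) anchor in the
duplication-free flanks, (ii) chain contiguously from the 5' anchor to
the 3' anchor, (iii) uniquely support every segmental-duplicon module
through paralogous label polymorphisms, and (iv) give >= 5x label
coverage over anchor and duplicon-overlapping labels. Molecules that
align equally well to several candidate haplotypes (because the
candidates are locally identical) are retained as *ambiguous*: they
confirm the shared backbone and count toward coverage by default, but
can never provide unique duplicon support.

Haplotypes are grouped at two granularities: by segmental-duplication
*features* (module string with orientations, partial modules distinct)
and by full DLE-1 *label* patterns, the latter refining the former.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import Alignment, AlignParams, align
from .simulate import (
    DUPLICON_MODULES,
    INVERSION_WINDOW,
    Haplotype,
    default_catalog,
)
from .types import LabelMap, Molecule

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorRegion",
    "HaplotypeCall",
    "anchors_for",
    "find_anchor_molecules",
    "chain_haplotypes",
    "feature_signature",
    "label_signature",
    "detect_inversion",
    "group_haplotypes",
]


@dataclass(frozen=True)
class AnchorRegion:
    """A duplication-free flank with a unique label pattern.

    Coordinates are haplotype/reference-map relative (1-based inclusive).
    A valid anchor spans >= 100 kbp and holds >= 12 labels on its map.
    """

    locus: str
    side: str  # "5prime" | "3prime"
    start_bp: int
    end_bp: int

    def validate(self, labelmap: LabelMap) -> None:
        if self.end_bp - self.start_bp + 1 < 100_000:
            raise ValueError(f"anchor {self.locus}/{self.side}: span < 100 kbp")
        if labelmap.window(self.start_bp, self.end_bp).size < 12:
            raise ValueError(f"anchor {self.locus}/{self.side}: fewer than 12 labels")


def anchors_for(hap: Haplotype) -> list[AnchorRegion]:
    """Anchor regions of a haplotype, from its ANCHOR_* modules."""
    out = []
    for mod, start, end in hap.layout:
        if mod.module_name.startswith("ANCHOR_5"):
            out.append(AnchorRegion(hap.locus, "5prime", start, end))
        elif mod.module_name.startswith("ANCHOR_3"):
            out.append(AnchorRegion(hap.locus, "3prime", start, end))
    return out


def find_anchor_molecules(
    alignments: dict[str, Alignment],
    target: Haplotype,
    anchors: list[AnchorRegion] | None = None,
    params: AlignParams | None = None,
    min_anchor_labels: int = 9,
) -> dict[str, set]:
    """Molecules anchored in each anchor region of ``target``.

    ``alignments`` maps molecule id to its alignment against the target. A
    molecule is anchored at a region when its alignment passes
    ``T_confirm`` and >= ``min_anchor_labels`` of its matched labels fall
    inside the region (three quarters of the minimum 12 anchor labels).
    """
    params = params or AlignParams()
    anchors = anchors if anchors is not None else anchors_for(target)
    pos = target.labelmap.positions
    out: dict[str, set] = {f"{a.locus}:{a.side}": set() for a in anchors}
    for mol_id, aln in alignments.items():
        if aln is None or aln.significance > params.T_confirm:
            continue
        tpos = pos[[j for _, j in aln.pairs]]
        for a in anchors:
            inside = np.count_nonzero((tpos >= a.start_bp) & (tpos <= a.end_bp))
            if inside >= min_anchor_labels:
                out[f"{a.locus}:{a.side}"].add(mol_id)
    return out


@dataclass
class HaplotypeCall:
    """Validation outcome for one candidate haplotype."""

    haplotype: Haplotype
    supporting_molecules: list = field(default_factory=list)
    ambiguous_molecules: list = field(default_factory=list)
    per_label_coverage: np.ndarray | None = None  # uniquely-assigned molecules
    consistent_coverage: np.ndarray | None = None  # assigned + ambiguous-consistent
    status: str = "incomplete"
    diagnostics: tuple = ()
    n_copies: int = 1
    role: str = ""

    @property
    def is_complete(self) -> bool:
        return self.status == "complete"


def _core_label_mask(hap: Haplotype) -> np.ndarray:
    """Labels in anchor or duplicon modules (the >=5x coverage domain)."""
    pos = hap.labelmap.positions
    mask = np.zeros(pos.size, dtype=bool)
    for mod, start, end in hap.layout:
        if mod.is_duplicon or mod.module_name.startswith("ANCHOR"):
            mask |= (pos >= start) & (pos <= end)
    return mask


def chain_haplotypes(
    molecules,
    candidates: list[Haplotype],
    params: AlignParams | None = None,
    assign_margin: float = 0.75,
    min_coverage: int = 5,
    coverage_counts_ambiguous: bool = True,
) -> tuple[list[HaplotypeCall], dict]:
    """Assign molecules to candidate haplotypes and validate completeness.

    Every molecule is aligned to every candidate; it is *assigned* to the
    candidate whose best alignment beats all others by ``assign_margin``
    score units (unique polymorphic-label support), *ambiguous* when
    several candidates tie within the margin, and *filtered* when no
    candidate alignment passes ``T_confirm``. Identical candidate ids are
    merged up front (homozygote: one call, coverage doubled).

    Returns the calls plus a conservation report
    ``{"assigned": n, "ambiguous": n, "filtered": n, "total": n}``.
    """
    params = params or AlignParams()
    merged: dict[str, HaplotypeCall] = {}
    copies: dict[str, int] = defaultdict(int)
    for hap in candidates:
        copies[hap.haplotype_id] += 1
        merged.setdefault(hap.haplotype_id, HaplotypeCall(hap))
    calls = list(merged.values())
    for call in calls:
        call.n_copies = copies[call.haplotype.haplotype_id]
        n = call.haplotype.labelmap.n_labels
        call.per_label_coverage = np.zeros(n, dtype=np.int64)
        call.consistent_coverage = np.zeros(n, dtype=np.int64)

    degenerate = set()
    for i, a in enumerate(calls):
        for b in calls[i + 1 :]:
            pa, pb = a.haplotype.labelmap.positions, b.haplotype.labelmap.positions
            if pa.size == pb.size and np.array_equal(pa, pb):
                degenerate.add(a.haplotype.haplotype_id)
                degenerate.add(b.haplotype.haplotype_id)

    report = {"assigned": 0, "ambiguous": 0, "filtered": 0, "total": 0}
    spans: dict[str, list] = defaultdict(list)  # hap id -> (start,end,unique) target spans
    for mol in molecules:
        report["total"] += 1
        best_by_hap: dict[str, Alignment] = {}
        for call in calls:
            alns = align(mol.labelmap, call.haplotype.labelmap, params)
            if alns and alns[0].significance <= params.T_confirm:
                best_by_hap[call.haplotype.haplotype_id] = alns[0]
        if not best_by_hap:
            report["filtered"] += 1
            continue
        ranked = sorted(best_by_hap.items(), key=lambda kv: -kv[1].score)
        top_id, top = ranked[0]
        contenders = [
            (hid, a) for hid, a in ranked if a.score >= top.score - assign_margin
        ]
        unique = len(contenders) == 1
        if unique:
            report["assigned"] += 1
        else:
            report["ambiguous"] += 1
        for call in calls:
            hid = call.haplotype.haplotype_id
            if hid not in dict(contenders):
                continue
            aln = best_by_hap[hid]
            jidx = [j for _, j in aln.pairs]
            call.consistent_coverage[jidx] += 1
            tpos = call.haplotype.labelmap.positions
            spans[hid].append((int(tpos[min(jidx)]), int(tpos[max(jidx)]), unique))
            if unique:
                call.per_label_coverage[jidx] += 1
                call.supporting_molecules.append(mol.molecule_id)
            else:
                call.ambiguous_molecules.append(mol.molecule_id)

    for call in calls:
        hap = call.haplotype
        hid = hap.haplotype_id
        diagnostics = []
        if hid in degenerate and len(calls) > 1:
            diagnostics.append("degenerate pair")
        cov = call.consistent_coverage if coverage_counts_ambiguous else call.per_label_coverage
        core = _core_label_mask(hap)
        cov_ok = bool(core.any()) and int(cov[core].min()) >= min_coverage
        if not cov_ok:
            diagnostics.append("coverage-below-minimum")

        anchors = anchors_for(hap)
        chain_ok = False
        if len(anchors) == 2:
            lo = anchors[0].start_bp if anchors[0].side == "5prime" else anchors[1].start_bp
            hi = anchors[1].end_bp if anchors[1].side == "3prime" else anchors[0].end_bp
            first = hap.labelmap.window(lo, hi)
            if first.size:
                chain_ok = _covers_contiguously(spans[hid], int(first[0]), int(first[-1]))
        if not chain_ok:
            diagnostics.append("no-anchor-to-anchor-chain")

        unique_ok = True
        if len(calls) > 1:
            for mod, start, end in hap.layout:
                if not mod.is_duplicon:
                    continue
                if not any(u and s <= end and start <= e for s, e, u in spans[hid]):
                    unique_ok = False
                    break
        if not unique_ok:
            diagnostics.append("duplicon-without-unique-support")

        call.diagnostics = tuple(diagnostics)
        call.status = (
            "complete"
            if cov_ok and chain_ok and unique_ok and "degenerate pair" not in diagnostics
            else "incomplete"
        )
    return calls, report


def _covers_contiguously(spans, lo: int, hi: int) -> bool:
    ordered = sorted((s, e) for s, e, _u in spans)
    reach = lo
    for s, e in ordered:
        if s > reach:
            return False
        reach = max(reach, e)
        if reach >= hi:
            return True
    return reach >= hi


# ---------------------------------------------------------------------------
# Signatures and grouping


def feature_signature(hap: Haplotype) -> str:
    """Module-level signature: duplicons and the inversion, in order.

    Invariant to label-level (paralog-variant) differences; partial 160 kbp
    modules render distinctly; orientation-sensitive, so a reversed
    haplotype is not identified with the original.
    """
    parts = []
    for mod in hap.modules:
        if mod.is_duplicon or mod.module_name == "INV64":
            parts.append(f"{mod.module_name}{mod.orientation}")
    return "|".join(parts)


def label_signature(
    hap: Haplotype, jitter_bp: int = 2_000, exemplars: list | None = None
) -> str:
    """Canonical label-pattern key, by matching against exemplar patterns.

    Two haplotypes share a key iff they share a feature signature and
    their label sets correspond one-to-one within ``jitter_bp`` (compared
    elementwise in order). ``exemplars`` is the mutable registry of
    (key, feature_sig, positions) already seen; pass the same list across
    calls to group a cohort.
    """
    if exemplars is None:
        exemplars = []
    fsig = feature_signature(hap)
    pos = hap.labelmap.positions
    for key, sig, ref in exemplars:
        if sig != fsig or ref.size != pos.size:
            continue
        if pos.size == 0 or int(np.max(np.abs(ref - pos))) <= jitter_bp:
            return key
    key = f"L{len(exemplars) + 1}"
    exemplars.append((key, fsig, pos))
    return key


def detect_inversion(
    hap: Haplotype,
    reference: Haplotype | None = None,
    params: AlignParams | None = None,
    window: tuple[int, int] = INVERSION_WINDOW,
    pad_bp: int = 6_000,
) -> bool | None:
    """Orientation call for the ~64 kbp LCR22D inversion, from labels alone.

    Extracts the haplotype's labels across the inversion window (absolute
    coordinates 21,424,743-21,510,142) and aligns them against the
    reference-orientation pattern in both orientations; the winning
    orientation decides. Returns ``None`` (indeterminate) when the window
    is not covered by at least 4 labels -- distinct from ``False``.
    """
    if hap.locus != "LCR22D":
        raise ValueError("inversion detection applies to LCR22D haplotypes")
    if reference is None:
        reference = default_catalog().haplotypes["D-ref"]
    w0, w1 = window
    rel0, rel1 = w0 - hap.base_bp, w1 - hap.base_bp
    obs = hap.labelmap.window(rel0 - pad_bp, rel1 + pad_bp)
    ref0, ref1 = w0 - reference.base_bp, w1 - reference.base_bp
    ref = reference.labelmap.window(ref0 - pad_bp, ref1 + pad_bp)
    if obs.size < 4 or ref.size < 4:
        return None
    span = int(ref1 - ref0 + 2 * pad_bp + 1)
    qmap = LabelMap("inv-obs", span, np.clip(obs - (rel0 - pad_bp) + 1, 1, span))
    tmap = LabelMap("inv-ref", span, np.clip(ref - (ref0 - pad_bp) + 1, 1, span))
    p = params or AlignParams()
    p = AlignParams(
        fp_rate=p.fp_rate, fn_rate=p.fn_rate, sf=p.sf, sd=p.sd,
        T_screen=p.T_screen, T_confirm=1.0, min_matched_sites=2,
        allow_reverse=True, lookback=4,
    )
    alns = align(qmap, tmap, p)
    if not alns:
        return None
    return alns[0].orientation == "-"


def detect_inversion_from_molecules(
    molecules,
    reference: Haplotype,
    inverted_reference: Haplotype,
    params: AlignParams | None = None,
    margin: float = 1.0,
) -> bool | None:
    """Molecule-vote inversion call for one LCR22D homolog.

    Each molecule is aligned to a reference-orientation and an
    inverted-orientation version of the haplotype (identical outside the
    inversion); molecules whose scores differ by more than ``margin`` vote
    for the better one. Majority decides; ``None`` when no molecule is
    informative.
    """
    params = params or AlignParams()
    votes = 0
    informative = 0
    for mol in molecules:
        a_ref = align(mol.labelmap, reference.labelmap, params)
        a_inv = align(mol.labelmap, inverted_reference.labelmap, params)
        s_ref = a_ref[0].score if a_ref else 0.0
        s_inv = a_inv[0].score if a_inv else 0.0
        if abs(s_ref - s_inv) <= margin:
            continue
        informative += 1
        votes += 1 if s_inv > s_ref else -1
    if informative == 0 or votes == 0:
        return None
    return votes > 0


def group_haplotypes(
    calls: list[HaplotypeCall],
    granularity: str = "features",
    jitter_bp: int = 2_000,
) -> pd.DataFrame:
    """Frequency table of haplotype groups, stratified by cohort role.

    ``granularity`` is ``"features"`` (segmental-duplication module string)
    or ``"labels"`` (full label-pattern refinement). Each call contributes
    ``n_copies`` (homozygotes count twice). Only complete calls are
    grouped; incomplete calls are tallied in an ``"(incomplete)"`` row.
    """
    if granularity not in ("features", "labels"):
        raise ValueError("granularity must be 'features' or 'labels'")
    exemplars: list = []
    rows = []
    for call in calls:
        if call.is_complete:
            if granularity == "features":
                key = feature_signature(call.haplotype)
            else:
                key = label_signature(call.haplotype, jitter_bp, exemplars)
        else:
            key = "(incomplete)"
        rows.append({"group": key, "role": call.role or "unspecified", "n": call.n_copies})
    if not rows:
        return pd.DataFrame(columns=["group", "count"]).set_index("group")
    df = pd.DataFrame(rows)
    table = df.pivot_table(index="group", columns="role", values="n", aggfunc="sum", fill_value=0)
    table["count"] = table.sum(axis=1)
    return table.sort_values("count", ascending=False)
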