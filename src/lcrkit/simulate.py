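"""Synthetic LCR22 references, diploid trios with known NAHR, and molecules.

The 22q11.2 deletion region is flanked by two large low-copy repeats,
LCR22A and LCR22D, built from a small set of segmental-duplication
modules: a ~160 kbp duplicon (SD22-4) shared between the two loci at >99%
identity, an LCR22A-specific SD22-3 duplicon, a frequent ~64 kbp LCR22D
inversion, unique spacer sequence, and duplication-free anchor flanks.
This module realizes such structures as label maps on an hg38-like
coordinate frame (LCR22A at 18.0-19.15 Mbp, LCR22D at 21.0-21.7 Mbp), so
that the annotation coordinates the field uses (FAM230A/B, BCRP2/6/7, the
inversion label window) apply directly.

Paralogous label polymorphisms -- single labels present or absent between
near-identical duplicon copies -- concentrate in the first ~40 kbp and
last ~30 kbp of the 160 kbp module; the middle ~95 kbp is identical
between copies and is the dominant NAHR substrate. Two polymorphic sites
are placed to reproduce documented paralog differences: a D-only label at
21,300,467 and an A-only label at 18,746,350.

Everything downstream (alignment, assembly, NAHR localization) is tested
against the truth bookkeeping these simulators record.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .types import LabelMap, Molecule, merge_by_resolution

logger = logging.getLogger(__name__)

__all__ = [
    "ModuleSpec",
    "Haplotype",
    "SimParams",
    "NAHRTruth",
    "Trio",
    "Catalog",
    "digest_sequence",
    "build_haplotype",
    "simulate_molecules",
    "simulate_trio",
    "default_catalog",
    "dense_catalog",
    "decoy_map",
    "LCR22A_BASE",
    "LCR22D_BASE",
    "INVERSION_WINDOW",
    "DEFAULT_ANNOTATIONS",
]

LCR22A_BASE = 18_000_000  # hg38-like coordinate where the 5' LCR22A anchor starts
LCR22D_BASE = 21_000_000
FLANK_BP = 80_000  # unique flanking sequence outside the anchors; haplotype
# position p maps to absolute coordinate (locus base - FLANK_BP) + p
INVERSION_WINDOW = (21_424_743, 21_510_142)  # first/last label of the ~64 kbp inversion

# name -> (start, end, reference_id); BCRP2 is printed with two right ends
# in the source annotation sets; both are carried, the larger is default.
DEFAULT_ANNOTATIONS = {
    "FAM230A": (18_422_244, 18_500_594, "chr22"),
    "FAM230B": (21_169_946, 21_182_974, "chr22"),
    "BCRP7": (18_855_621, 18_858_640, "chr22"),
    "BCRP2": (21_103_016, 21_122_286, "chr22"),
    "BCRP2_alt": (21_103_016, 21_121_784, "chr22"),
    "BCRP6": (21_290_760, 21_294_586, "chr22"),
}

DUPLICON_MODULES = frozenset({"SD160", "SD160_PARTIAL", "SD22_3"})

# --- SD160 paralogous label polymorphisms (offsets within the module) -----
POLY_5PRIME = (8_500, 17_200, 26_350)  # first ~40 kbp
POLY_3PRIME = (140_467, 146_900, 153_300)  # last ~30 kbp
POLY_MID_DENSE = (48_000, 63_500, 79_000, 94_500, 110_000, 125_500)
_END_POLY = POLY_5PRIME + POLY_3PRIME

# variant id -> polymorphic offsets present in that paralog copy;
# offset 26,350 realizes the A-only label (18,746,350 in the second A-ref
# copy) and offset 140,467 the D-only label (21,300,467)
SD160_VARIANTS: dict[str, tuple[int, ...]] = {
    "a": (8_500, 146_900, 153_300),
    "b": (17_200, 26_350, 153_300),
    "c": (8_500, 17_200, 146_900),
    "d": (8_500, 140_467, 146_900),
    "e": (17_200, 140_467, 153_300),
    "a_dense": (8_500, 48_000, 79_000, 110_000, 146_900, 153_300),
    "d_dense": (63_500, 94_500, 125_500, 140_467, 146_900),
}

_MODULE_LENGTHS = {
    "FLANK_5A": 80_000,
    "FLANK_3A": 80_000,
    "FLANK_5D": 80_000,
    "FLANK_3D": 80_000,
    "ANCHOR_5A": 150_000,
    "SPACER_A1": 150_000,
    "SD22_3": 120_000,
    "SD160": 160_000,
    "SD160_PARTIAL": 50_000,
    "SPACER_A2": 140_000,
    "SPACER_A3": 155_000,
    "ANCHOR_3A": 115_000,
    "ANCHOR_5D": 110_000,
    "SPACER_D1": 50_000,
    "SPACER_D2": 100_000,
    "INV64": 95_000,
    "SPACER_D3": 50_000,
    "ANCHOR_3D": 135_000,
}

# fixed per-module seeds: the catalog is a deterministic constant of the package
_MODULE_SEEDS = {
    "FLANK_5A": 108,
    "FLANK_3A": 109,
    "FLANK_5D": 207,
    "FLANK_3D": 208,
    "ANCHOR_5A": 101,
    "SPACER_A1": 102,
    "SD22_3": 103,
    "SD160": 104,
    "SPACER_A2": 105,
    "SPACER_A3": 106,
    "ANCHOR_3A": 107,
    "ANCHOR_5D": 201,
    "SPACER_D1": 202,
    "SPACER_D2": 203,
    "INV64": 204,
    "SPACER_D3": 205,
    "ANCHOR_3D": 206,
}


@dataclass(frozen=True)
class ModuleSpec:
    """One oriented module instance in a haplotype's module string."""

    module_name: str
    orientation: str = "+"
    paralog_variant: str = ""
    label_offsets: tuple = ()
    length_bp: int = 0

    def __post_init__(self):
        if self.orientation not in ("+", "-"):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")
        if not self.label_offsets:
            offs, length = _module_offsets(self.module_name, self.paralog_variant)
            object.__setattr__(self, "label_offsets", offs)
            object.__setattr__(self, "length_bp", length)
        if any(not 1 <= o <= self.length_bp for o in self.label_offsets):
            raise ValueError(f"{self.module_name}: offsets outside [1, {self.length_bp}]")
        if list(self.label_offsets) != sorted(set(self.label_offsets)):
            raise ValueError(f"{self.module_name}: offsets must be strictly increasing")

    @property
    def oriented_offsets(self) -> tuple:
        """Offsets as realized: '-' reverses and reflects (o -> L - o + 1)."""
        if self.orientation == "+":
            return self.label_offsets
        return tuple(self.length_bp - o + 1 for o in reversed(self.label_offsets))

    @property
    def is_duplicon(self) -> bool:
        return self.module_name in DUPLICON_MODULES


def _grid_offsets(
    length_bp: int,
    seed: int,
    lo: int = 4_400,
    hi: int = 7_900,
    forbidden: tuple = (),
    margin: int = 3_600,
) -> tuple[int, ...]:
    """Deterministic irregular label grid with all gaps >= lo (> imaging res)."""
    rng = np.random.default_rng(seed)
    out: list[int] = []
    pos = 2_500 + int(rng.integers(0, 2_000))
    while pos <= length_bp - 2_500:
        if all(abs(pos - f) >= margin for f in forbidden):
            out.append(pos)
            pos += int(rng.integers(lo, hi + 1))
        else:
            pos += margin
    return tuple(out)


def _base_offsets(name: str) -> tuple[int, ...]:
    if name == "SD160":
        return _grid_offsets(
            _MODULE_LENGTHS["SD160"], _MODULE_SEEDS["SD160"], lo=4_400, hi=5_900,
            forbidden=_END_POLY,
        )
    if name == "SD160_PARTIAL":
        # the last 50 kbp of the full module, invariant across haplotypes
        full = _base_offsets("SD160")
        cut = _MODULE_LENGTHS["SD160"] - _MODULE_LENGTHS["SD160_PARTIAL"]
        return tuple(o - cut for o in full if o > cut + 2_000)
    if name == "INV64":
        offs = _grid_offsets(
            _MODULE_LENGTHS["INV64"], _MODULE_SEEDS["INV64"],
            forbidden=(4_743, 90_142), margin=4_200,
        )
        # pin the documented first/last labels of the inversion window
        return tuple(sorted(set(offs) | {4_743, 90_142}))
    return _grid_offsets(_MODULE_LENGTHS[name], _MODULE_SEEDS[name])


def _module_offsets(name: str, variant: str) -> tuple[tuple[int, ...], int]:
    if name not in _MODULE_LENGTHS:
        raise ValueError(f"unknown module {name!r}")
    offs = set(_base_offsets(name))
    if variant:
        if name != "SD160":
            raise ValueError(f"paralog variants only apply to SD160, not {name}")
        if variant.endswith("_dense"):
            # dense copies carry mid-module polymorphic slots; their shared
            # base clears those slots so presence/absence stays clean
            offs = {
                o for o in offs
                if all(abs(o - m) >= 3_600 for m in POLY_MID_DENSE)
            }
        offs |= set(SD160_VARIANTS[variant])
    return tuple(sorted(offs)), _MODULE_LENGTHS[name]


@dataclass(frozen=True)
class Haplotype:
    """An ordered module string plus its realized label map.

    ``labelmap`` positions are 1-based within the haplotype; the hg38-like
    absolute coordinate is ``base_bp + position``, with ``base_bp`` chosen
    so the 5' anchor begins at 18,000,001 (LCR22A) / 21,000,001 (LCR22D)
    after the flanking module. ``layout`` gives each module's (start, end)
    in haplotype coordinates.
    """

    haplotype_id: str
    locus: str  # "LCR22A" | "LCR22D"
    modules: tuple
    labelmap: LabelMap
    layout: tuple  # ((module, start_bp, end_bp), ...)
    frequency: float = 0.0

    @property
    def base_bp(self) -> int:
        base = LCR22A_BASE if self.locus == "LCR22A" else LCR22D_BASE
        flank = sum(
            m.length_bp for m, _, _ in self.layout if m.module_name.startswith("FLANK_5")
        )
        return base - flank

    @property
    def length_bp(self) -> int:
        return self.labelmap.length_bp

    def module_at(self, pos_bp: int) -> ModuleSpec | None:
        for mod, start, end in self.layout:
            if start <= pos_bp <= end:
                return mod
        return None


def build_haplotype(
    locus: str,
    modules: Sequence[ModuleSpec],
    haplotype_id: str = "hap",
    frequency: float = 0.0,
) -> Haplotype:
    """Concatenate oriented modules into a realized haplotype map.

    A partial 160 kbp module may only appear as the 5'-most duplicon of a
    haplotype, in reference orientation; violations raise ``ValueError``.
    """
    if locus not in ("LCR22A", "LCR22D"):
        raise ValueError(f"locus must be LCR22A or LCR22D, got {locus!r}")
    seen_duplicon = False
    for mod in modules:
        if mod.module_name == "SD160_PARTIAL":
            if seen_duplicon:
                raise ValueError("SD160_PARTIAL must be the 5'-most duplicon")
            if mod.orientation != "+":
                raise ValueError("SD160_PARTIAL only occurs in reference orientation")
        if mod.is_duplicon:
            seen_duplicon = True
    positions: list[int] = []
    layout = []
    cursor = 0
    for mod in modules:
        positions.extend(cursor + o for o in mod.oriented_offsets)
        layout.append((mod, cursor + 1, cursor + mod.length_bp))
        cursor += mod.length_bp
    base = LCR22A_BASE if locus == "LCR22A" else LCR22D_BASE
    base -= sum(m.length_bp for m in modules if m.module_name.startswith("FLANK_5"))
    lm = LabelMap(
        haplotype_id,
        cursor,
        np.asarray(positions, dtype=np.int64),
        {"locus": locus, "base_bp": base},
    )
    return Haplotype(haplotype_id, locus, tuple(modules), lm, tuple(layout), frequency)


# ---------------------------------------------------------------------------
# In-silico digestion


def digest_sequence(sequence: str, motif: str = "CTTAAG", res_bp: int = 3_500) -> LabelMap:
    """Label positions of a labeling-motif digest of ``sequence``.

    One label at the 1-based start of every motif occurrence on the given
    strand; occurrences closer than ``res_bp`` merge to their midpoint.
    The DLE-1 motif CTTAAG is its own reverse complement, so this single
    scan is strand-complete for the default motif. ``N`` never matches.
    """
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bp")
    seq = sequence.upper()
    motif = motif.upper()
    hits = []
    start = seq.find(motif)
    while start != -1:
        hits.append(start + 1)
        start = seq.find(motif, start + 1)
    pos = merge_by_resolution(np.asarray(hits, dtype=np.int64), res_bp)
    length = max(len(seq), 1)
    return LabelMap("digest", length, pos)


# ---------------------------------------------------------------------------
# Molecule simulation


@dataclass(frozen=True)
class SimParams:
    """Molecule-simulation parameters in vendor quality-report units.

    ``fp_rate`` is expected false labels per true label (recommended band
    3-5%), ``fn_rate`` the per-label miss probability (band 9-17%).
    ``sf``/``sd`` parameterize sizing noise with std
    ``sqrt(sf^2 + sd^2 * d)`` at distance ``d`` from the molecule start.
    Lengths follow ``min_len_bp`` plus an exponential with overall mean
    ``mean_len_bp`` (the >150 kbp length filter is built in). Throughput
    defaults to ``coverage`` times the genome length when
    ``target_total_bp`` is not set.
    """

    fp_rate: float = 0.04
    fn_rate: float = 0.13
    sf: float = 250.0
    sd: float = 2.9
    res_bp: int = 3_500
    min_len_bp: int = 150_000
    mean_len_bp: int = 250_000
    target_total_bp: int | None = None
    coverage: float = 50.0
    density_target: float = 16.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.fn_rate <= 1:
            raise ValueError("fn_rate must lie in [0,1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")
        if self.res_bp < 0 or self.min_len_bp < 0:
            raise ValueError("res_bp and min_len_bp must be >= 0")


def simulate_molecules(
    genome: Sequence[Haplotype | LabelMap],
    params: SimParams | None = None,
    seed: int | None = None,
) -> list[Molecule]:
    """Draw error-bearing molecules from the haplotypes of a genome.

    Start positions are uniform along each source map (chosen with
    probability proportional to its length); molecule length is
    ``min_len_bp`` plus an exponential. True labels inside the window are
    dropped independently at ``fn_rate``; false labels are added as a
    Poisson count of ``fp_rate`` per true label, placed uniformly but away
    from existing labels by at least ``res_bp`` (observed-artifact
    semantics); every label is perturbed by Gaussian sizing noise with std
    ``sqrt(sf^2 + sd^2 * d)``; labels closer than ``res_bp`` merge. Each
    molecule is flipped end-for-end with probability 1/2.

    Truth bookkeeping lands in ``source_meta``: source map id, window
    start, orientation, per-label truth flags and source positions, and
    the pre-noise true label count.
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    sources = [h.labelmap if isinstance(h, Haplotype) else h for h in genome]
    if not sources:
        return []
    lengths = np.asarray([s.length_bp for s in sources], dtype=float)
    total_source = float(lengths.sum())
    target = (
        params.target_total_bp
        if params.target_total_bp is not None
        else int(params.coverage * total_source)
    )
    molecules: list[Molecule] = []
    emitted = 0
    serial = 0
    mean_extra = max(params.mean_len_bp - params.min_len_bp, 1)
    while emitted < target:
        src = sources[int(rng.choice(len(sources), p=lengths / total_source))]
        length = int(params.min_len_bp + rng.exponential(mean_extra))
        start = int(rng.integers(1, max(src.length_bp - params.min_len_bp, 1) + 1))
        length = min(length, src.length_bp - start + 1)
        if length < params.min_len_bp:
            continue
        serial += 1
        mol = _one_molecule(src, start, length, params, rng, f"{src.map_id}.m{serial}")
        molecules.append(mol)
        emitted += length
    return molecules


def _one_molecule(src: LabelMap, start: int, length: int, params: SimParams, rng, mol_id):
    end = start + length - 1
    true_pos = src.window(start, end).astype(np.int64)
    n_true = true_pos.size
    keep = rng.random(n_true) >= params.fn_rate
    pos = (true_pos[keep] - start + 1).astype(float)
    truth_src = true_pos[keep].astype(np.int64)

    if pos.size:
        # cumulative (stretch-like) sizing error: a Brownian component whose
        # marginal std at distance d from the molecule start is sd*sqrt(d),
        # plus an independent per-label placement jitter sf -- so a label's
        # total position-error std is sqrt(sf^2 + sd^2 * d) while the error
        # of an interval of length D keeps the interval-scaling variance
        # ~ 2*sf^2 + sd^2 * D.
        gaps = np.diff(np.concatenate([[0.0], pos]))
        brownian = np.cumsum(rng.normal(0.0, 1.0, pos.size) * params.sd * np.sqrt(gaps))
        pos = pos + brownian + rng.normal(0.0, params.sf, pos.size)
        pos = np.clip(pos, 1, length)

    # false labels are spurious detections on the *measured* molecule: they
    # appear after sizing noise, away from existing labels by >= res_bp
    n_fp = rng.poisson(params.fp_rate * n_true)
    fp_positions: list[float] = []
    for _ in range(n_fp):
        for _attempt in range(40):
            cand = float(rng.integers(1, length + 1))
            near_true = pos.size and np.min(np.abs(pos - cand)) < params.res_bp
            near_fp = any(abs(cand - f) < params.res_bp for f in fp_positions)
            if not near_true and not near_fp:
                fp_positions.append(cand)
                break
    pos = np.concatenate([pos, np.asarray(fp_positions)])
    truth_src = np.concatenate([truth_src, np.full(len(fp_positions), -1, dtype=np.int64)])
    is_true = truth_src >= 0
    order = np.argsort(pos, kind="stable")
    pos, truth_src, is_true = pos[order], truth_src[order], is_true[order]

    # resolution merge with truth carried through (any true member -> true)
    merged_pos: list[float] = []
    merged_true: list[bool] = []
    merged_src: list[int] = []
    i = 0
    n = pos.size
    while i < n:
        j = i
        while j + 1 < n and pos[j + 1] - pos[j] < params.res_bp:
            j += 1
        merged_pos.append(float(np.floor((pos[i] + pos[j]) / 2 + 0.5)))
        merged_true.append(bool(is_true[i : j + 1].any()))
        srcs = truth_src[i : j + 1]
        real = srcs[srcs >= 0]
        merged_src.append(int(real[0]) if real.size else -1)
        i = j + 1
    pos = np.asarray(merged_pos)
    is_true = np.asarray(merged_true)
    truth_src = np.asarray(merged_src, dtype=np.int64)

    flipped = bool(rng.random() < 0.5)
    if flipped and pos.size:
        pos = (length - pos + 1)[::-1]
        is_true = is_true[::-1]
        truth_src = truth_src[::-1]
    # de-duplicate after rounding (extremely rare)
    if pos.size > 1:
        keep2 = np.concatenate([[True], np.diff(pos) > 0])
        pos, is_true, truth_src = pos[keep2], is_true[keep2], truth_src[keep2]

    lm = LabelMap(mol_id, length, pos.astype(np.int64) if pos.size else pos)
    quality = 0.6 + 0.4 * rng.random(pos.size)
    return Molecule(
        mol_id,
        lm,
        quality,
        source_meta={
            "source_map": src.map_id,
            "window_start_bp": start,
            "flipped": flipped,
            "is_true_label": tuple(bool(b) for b in is_true),
            "true_source_positions": tuple(int(p) for p in truth_src),
            "n_true_in_window": int(n_true),
        },
    )


# ---------------------------------------------------------------------------
# Catalogs


@dataclass(frozen=True)
class Catalog:
    """Named haplotypes per locus with population frequencies."""

    haplotypes: Mapping[str, Haplotype]

    def by_locus(self, locus: str) -> list[Haplotype]:
        return [h for h in self.haplotypes.values() if h.locus == locus]

    def sample(self, locus: str, rng) -> Haplotype:
        haps = self.by_locus(locus)
        freqs = np.asarray([h.frequency for h in haps], dtype=float)
        freqs = freqs / freqs.sum()
        return haps[int(rng.choice(len(haps), p=freqs))]


def _m(name, orientation="+", variant=""):
    return ModuleSpec(name, orientation, variant)


def default_catalog() -> Catalog:
    """The package's standing haplotype catalog.

    LCR22A is structurally diverse (copy number/orientation of the 160 kbp
    module, presence of SD22-3, a 5'-terminal partial module); LCR22D is
    structurally stable apart from paralog-label variants and the ~64 kbp
    inversion, which is the major allele at 73.7%.
    """
    haps = {}

    def add(hap):
        haps[hap.haplotype_id] = hap

    f5, f3 = _m("FLANK_5A"), _m("FLANK_3A")
    a5, a3 = _m("ANCHOR_5A"), _m("ANCHOR_3A")
    s1, s2, s3 = _m("SPACER_A1"), _m("SPACER_A2"), _m("SPACER_A3")
    add(build_haplotype(
        "LCR22A",
        [f5, a5, s1, _m("SD22_3"), _m("SD160", "+", "a"), s2, _m("SD160", "+", "b"), s3, a3, f3],
        "A-ref", 0.24,
    ))
    add(build_haplotype(
        "LCR22A", [f5, a5, s1, _m("SD160", "+", "a"), s2, s3, a3, f3], "A-1x160", 0.29,
    ))
    add(build_haplotype(
        "LCR22A",
        [f5, a5, s1, _m("SD160", "+", "b"), s2, _m("SD160", "+", "c"), _m("SD160", "+", "a"),
         s3, a3, f3],
        "A-3x160", 0.18,
    ))
    add(build_haplotype(
        "LCR22A",
        [f5, a5, s1, _m("SD160_PARTIAL"), s2, _m("SD160", "+", "c"), s3, a3, f3],
        "A-partial", 0.16,
    ))
    add(build_haplotype(
        "LCR22A",
        [f5, a5, s1, _m("SD22_3"), _m("SD160", "-", "a"), s2, s3, a3, f3],
        "A-inv160", 0.13,
    ))

    g5, g3 = _m("FLANK_5D"), _m("FLANK_3D")
    d5, d3 = _m("ANCHOR_5D"), _m("ANCHOR_3D")
    t1, t2, t3 = _m("SPACER_D1"), _m("SPACER_D2"), _m("SPACER_D3")
    add(build_haplotype(
        "LCR22D",
        [g5, d5, t1, _m("SD160", "+", "d"), t2, _m("INV64", "+"), t3, d3, g3],
        "D-ref", 0.263,
    ))
    add(build_haplotype(
        "LCR22D",
        [g5, d5, t1, _m("SD160", "+", "d"), t2, _m("INV64", "-"), t3, d3, g3],
        "D-inv", 0.47,
    ))
    add(build_haplotype(
        "LCR22D",
        [g5, d5, t1, _m("SD160", "+", "e"), t2, _m("INV64", "-"), t3, d3, g3],
        "D-inv-2", 0.267,
    ))
    return Catalog(haps)


def dense_catalog() -> Catalog:
    """A catalog whose 160 kbp modules carry dense mid-module polymorphisms.

    Used to demonstrate that the ambiguous NAHR interval shrinks to the
    spacing between discriminating labels (down to ~20-30 kbp).
    """
    haps = {}
    a5, a3 = _m("ANCHOR_5A"), _m("ANCHOR_3A")
    d5, d3 = _m("ANCHOR_5D"), _m("ANCHOR_3D")
    haps["A-dense"] = build_haplotype(
        "LCR22A",
        [_m("FLANK_5A"), a5, _m("SPACER_A1"), _m("SD160", "+", "a_dense"), _m("SPACER_A2"),
         _m("SPACER_A3"), a3, _m("FLANK_3A")],
        "A-dense", 1.0,
    )
    haps["D-dense"] = build_haplotype(
        "LCR22D",
        [_m("FLANK_5D"), d5, _m("SPACER_D1"), _m("SD160", "+", "d_dense"), _m("SPACER_D2"),
         _m("INV64", "-"), _m("SPACER_D3"), d3, _m("FLANK_3D")],
        "D-dense", 1.0,
    )
    return Catalog(haps)


def decoy_map(length_bp: int = 1_000_000, seed: int = 7_777, map_id: str = "decoy") -> LabelMap:
    """A random off-locus reference map at typical label density."""
    rng = np.random.default_rng(seed)
    gaps = rng.integers(4_200, 8_400, size=length_bp // 4_200)
    pos = 3_000 + np.cumsum(gaps)
    pos = pos[pos <= length_bp - 2_000]
    return LabelMap(map_id, length_bp, pos.astype(np.int64), {"decoy": True})


# ---------------------------------------------------------------------------
# Trio simulation with known NAHR truth


@dataclass(frozen=True)
class NAHRTruth:
    """Ground truth of one simulated NAHR deletion."""

    family_id: str
    parent_of_origin: str  # "mother" | "father"
    parent_A_haplotype_id: str
    parent_D_haplotype_id: str
    breakpoint_bp: int  # on the parental LCR22A haplotype coordinate
    breakpoint_bp_D: int  # homologous position on the LCR22D haplotype
    shared_segment: tuple  # (start_bp, end_bp) on the LCR22A coordinate

    def __post_init__(self):
        lo, hi = self.shared_segment
        if not lo <= self.breakpoint_bp <= hi:
            raise ValueError("breakpoint must lie inside the shared segment")


@dataclass(frozen=True)
class Trio:
    """Mother, father, and a proband carrying one NAHR deletion contig."""

    family_id: str
    mother: Mapping[str, tuple]  # locus -> (Haplotype, Haplotype)
    father: Mapping[str, tuple]
    proband_intact: Mapping[str, Haplotype]  # locus -> inherited haplotype
    proband_deletion: LabelMap  # A-prefix fused to D-suffix
    truth: NAHRTruth


def shared_identical_segments(
    hap_a: Haplotype, hap_d: Haplotype, min_len_bp: int = 10_000
) -> list[tuple]:
    """Identical-label runs between homologous SD160 copies of two haplotypes.

    Returns ``(a_start, a_end, d_start, d_end)`` tuples in the respective
    haplotype coordinates. For each pair of same-orientation full 160 kbp
    modules, the module span is split at every discriminating offset (a
    label present in exactly one copy); maximal runs with identical label
    content, at least ``min_len_bp`` long, qualify as NAHR substrate.
    """
    out = []
    for mod_a, a_start, _ in hap_a.layout:
        if mod_a.module_name != "SD160":
            continue
        for mod_d, d_start, _ in hap_d.layout:
            if mod_d.module_name != "SD160" or mod_d.orientation != mod_a.orientation:
                continue
            set_a = set(mod_a.label_offsets)
            set_d = set(mod_d.label_offsets)
            discriminating = sorted(set_a ^ set_d)
            bounds = [0] + [d for d in discriminating] + [mod_a.length_bp]
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                # keep clear of the discriminating labels themselves
                lo2, hi2 = lo + 2_000, hi - 2_000
                if hi2 - lo2 >= min_len_bp:
                    out.append((a_start + lo2, a_start + hi2, d_start + lo2, d_start + hi2))
    return out


def simulate_trio(
    catalog: Catalog,
    params: SimParams | None = None,
    seed: int | None = None,
    family_id: str = "fam",
    origin_female_prob: float = 19 / 30,
    max_retries: int = 64,
) -> Trio:
    """Draw a deletion trio with a known template-switch breakpoint.

    Four parental haplotypes per locus are drawn from catalog frequencies;
    the parent-of-deletion-origin is female with probability 19/30 (the
    observed 19:11 excess). Within that parent, an LCR22A and an LCR22D
    haplotype sharing an identical SD160 segment recombine at a breakpoint
    uniform over the union of shared segments; the proband receives the
    resulting A-prefix/D-suffix fusion contig plus one intact haplotype
    per locus from the other parent. Parent draws without any shared
    segment are resampled (bounded, logged).
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    for attempt in range(max_retries):
        mother = {
            loc: (catalog.sample(loc, rng), catalog.sample(loc, rng))
            for loc in ("LCR22A", "LCR22D")
        }
        father = {
            loc: (catalog.sample(loc, rng), catalog.sample(loc, rng))
            for loc in ("LCR22A", "LCR22D")
        }
        origin = "mother" if rng.random() < origin_female_prob else "father"
        origin_parent = mother if origin == "mother" else father
        other_parent = father if origin == "mother" else mother

        pairs = []
        for hap_a in origin_parent["LCR22A"]:
            for hap_d in origin_parent["LCR22D"]:
                segs = shared_identical_segments(hap_a, hap_d)
                if segs:
                    pairs.append((hap_a, hap_d, segs))
        if not pairs:
            logger.info("%s: no shared segment on attempt %d; resampling", family_id, attempt)
            continue
        hap_a, hap_d, segs = pairs[int(rng.integers(len(pairs)))]
        seg_lens = np.asarray([s[1] - s[0] for s in segs], dtype=float)
        seg = segs[int(rng.choice(len(segs), p=seg_lens / seg_lens.sum()))]
        a_lo, a_hi, d_lo, _ = seg
        bp_a = int(rng.integers(a_lo, a_hi + 1))
        bp_d = d_lo + (bp_a - a_lo)

        pos_a = hap_a.labelmap.positions
        pos_d = hap_d.labelmap.positions
        prefix = pos_a[pos_a < bp_a]
        suffix = pos_d[pos_d >= bp_d] - bp_d + bp_a
        contig_len = bp_a + (hap_d.length_bp - bp_d)
        contig = LabelMap(
            f"{family_id}-del",
            contig_len,
            np.concatenate([prefix, suffix]),
            {
                "family_id": family_id,
                "kind": "deletion_contig",
                "parent_A": hap_a.haplotype_id,
                "parent_D": hap_d.haplotype_id,
                "breakpoint_bp": bp_a,
            },
        )
        truth = NAHRTruth(
            family_id=family_id,
            parent_of_origin=origin,
            parent_A_haplotype_id=hap_a.haplotype_id,
            parent_D_haplotype_id=hap_d.haplotype_id,
            breakpoint_bp=bp_a,
            breakpoint_bp_D=bp_d,
            shared_segment=(a_lo, a_hi),
        )
        intact = {
            loc: other_parent[loc][int(rng.integers(2))] for loc in ("LCR22A", "LCR22D")
        }
        return Trio(family_id, mother, father, intact, contig, truth)
    raise RuntimeError(
        f"{family_id}: no parental haplotype pair with a shared segment after "
        f"{max_retries} draws"
    )
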