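"""Dynamic-programming alignment of label maps with a sizing-error model.

A molecule (or consensus contig) is aligned to a reference/haplotype label
map by chaining matched label pairs. Extending a chain from matched pair
(i', j') to (i, j) scores

    match_reward - (dq - dr)^2 / (2 * (sf^2 + sd^2 * dr))
                 - fp_cost * (skipped query labels)
                 - fn_cost * (skipped target labels)

where ``dq``/``dr`` are the query/target interval lengths: the classic
restriction-map scoring with Gaussian interval error whose variance grows
linearly with interval length. Costs default to negative log-probabilities
of the corresponding error events at the configured FP/FN rates, and the
match reward to the log-likelihood ratio of a true versus a random label
match at the map's label density.

Alignments are *local*: the optimum over all chain start/end points is
reported (one best chain per orientation). Significance is an analytic
tail bound under a Poisson-label null, see :func:`significance`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .types import LabelMap, Molecule

logger = logging.getLogger(__name__)

__all__ = [
    "AlignParams",
    "Alignment",
    "QCReport",
    "align",
    "significance",
    "screen_decoys",
    "compute_qc",
]

# noise-free interval comparisons must not divide by zero
_MIN_VAR = 1.0

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass(frozen=True)
class AlignParams:
    """Scoring and thresholding parameters for label-map alignment.

    ``sf`` (bp) and ``sd`` (sqrt-bp) parameterize the interval-error
    variance ``sf^2 + sd^2 * dr``. ``fp_rate`` is the expected number of
    false labels per true label, ``fn_rate`` the per-label miss
    probability; both feed the default skip costs. ``T_screen`` and
    ``T_confirm`` are significance thresholds for decoy screening and
    haplotype confirmation. ``lookback`` bounds the number of consecutive
    skipped labels the DP considers on either map.
    """

    fp_rate: float = 0.04
    fn_rate: float = 0.13
    sf: float = 350.0
    sd: float = 2.9
    T_screen: float = 1e-13
    T_confirm: float = 1e-11
    min_matched_sites: int = 15
    min_len_bp: int = 150_000
    allow_reverse: bool = True
    lookback: int = 6
    match_reward: float | None = None
    fp_cost: float | None = None
    fn_cost: float | None = None

    def __post_init__(self):
        for name in ("T_screen", "T_confirm"):
            t = getattr(self, name)
            if not (0 < t <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {t}")
        if self.min_matched_sites < 2:
            raise ValueError("min_matched_sites must be >= 2")

    def costs_for_density(self, density_per_bp: float) -> tuple[float, float, float]:
        """(match_reward, fp_cost, fn_cost), deriving unset ones from rates."""
        sigma = math.sqrt(self.sf**2 + self.sd**2 / max(density_per_bp, 1e-9))
        reward = self.match_reward
        if reward is None:
            # log LR of a true match vs a Poisson background label
            reward = math.log(
                max((1.0 - self.fn_rate), 1e-6)
                / max(density_per_bp * sigma * math.sqrt(2 * math.pi), 1e-12)
            )
            reward = max(reward, 0.5)
        fp_cost = self.fp_cost if self.fp_cost is not None else -math.log(max(self.fp_rate, 1e-6))
        fn_cost = self.fn_cost if self.fn_cost is not None else -math.log(max(self.fn_rate, 1e-6))
        return reward, fp_cost, fn_cost


@dataclass(frozen=True)
class Alignment:
    """A monotone pairing of query labels onto target labels."""

    query_id: str
    target_id: str
    orientation: str  # "+" or "-"
    pairs: tuple  # ((query_idx, target_idx), ...) in original query indexing
    score: float
    significance: float
    step_penalties: tuple  # per-step (dq-dr)^2 / (2 var) along the chain
    unaligned_query_labels: int
    unaligned_target_labels: int

    @property
    def penalty_sum(self) -> float:
        return float(sum(self.step_penalties))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def target_span(self, target: LabelMap) -> tuple[int, int]:
        idx = [j for _, j in self.pairs]
        return int(target.positions[min(idx)]), int(target.positions[max(idx)])


def _dp_kernel_py(q, r, sf2, sd2, reward, fp_cost, fn_cost, lookback):
    nq, nr = len(q), len(r)
    S = np.full((nq, nr), -np.inf)
    BI = np.full((nq, nr), -1, dtype=np.int64)
    BJ = np.full((nq, nr), -1, dtype=np.int64)
    for i in range(nq):
        for j in range(nr):
            best = reward
            bi = bj = -1
            i0 = i - lookback if i >= lookback else 0
            j0 = j - lookback if j >= lookback else 0
            for ip in range(i0, i):
                dq = q[i] - q[ip]
                for jp in range(j0, j):
                    if S[ip, jp] == -np.inf:
                        continue
                    dr = r[j] - r[jp]
                    var = sf2 + sd2 * dr
                    if var < _MIN_VAR:
                        var = _MIN_VAR
                    pen = (dq - dr) * (dq - dr) / (2.0 * var)
                    cand = (
                        S[ip, jp]
                        + reward
                        - pen
                        - fp_cost * (i - ip - 1)
                        - fn_cost * (j - jp - 1)
                    )
                    if cand > best:
                        best = cand
                        bi, bj = ip, jp
            S[i, j] = best
            BI[i, j] = bi
            BJ[i, j] = bj
    return S, BI, BJ


if _HAVE_NUMBA:
    _dp_kernel = njit(cache=True, fastmath=False)(_dp_kernel_py)
else:  # pragma: no cover
    _dp_kernel = _dp_kernel_py


def _traceback(S, BI, BJ):
    i, j = np.unravel_index(int(np.argmax(S)), S.shape)
    best = float(S[i, j])
    chain = []
    while i >= 0:
        chain.append((int(i), int(j)))
        i, j = int(BI[i, j]), int(BJ[i, j])
        if i < 0:
            break
    chain.reverse()
    return best, chain


def _chain_penalties(q, r, chain, sf2, sd2) -> tuple:
    pens = []
    for (i0, j0), (i1, j1) in zip(chain[:-1], chain[1:]):
        dq = float(q[i1] - q[i0])
        dr = float(r[j1] - r[j0])
        var = max(sf2 + sd2 * dr, _MIN_VAR)
        pens.append((dq - dr) ** 2 / (2.0 * var))
    return tuple(pens)


def align(
    query: LabelMap,
    target: LabelMap,
    params: AlignParams | None = None,
) -> list[Alignment]:
    """Align ``query`` to ``target``; best local chain per orientation.

    Returns alignments with positive score, best first (at most one per
    orientation; lower-scoring overlapping sub-chains are not enumerated).
    Queries with fewer than ``params.min_matched_sites`` labels yield an
    empty list (logged, not raised).
    """
    params = params or AlignParams()
    if query.n_labels < params.min_matched_sites:
        logger.info(
            "query %s has %d labels < min %d; skipping",
            query.map_id,
            query.n_labels,
            params.min_matched_sites,
        )
        return []
    if target.n_labels == 0:
        return []
    density = target.n_labels / target.length_bp
    reward, fp_cost, fn_cost = params.costs_for_density(density)
    sf2, sd2 = params.sf**2, params.sd**2

    out = []
    orientations = ["+", "-"] if params.allow_reverse else ["+"]
    for orient in orientations:
        qmap = query if orient == "+" else query.reflected()
        q = qmap.positions.astype(np.float64)
        r = target.positions.astype(np.float64)
        S, BI, BJ = _dp_kernel(
            q, r, sf2, sd2, reward, fp_cost, fn_cost, int(params.lookback)
        )
        score, chain = _traceback(S, BI, BJ)
        if score <= 0 or not chain:
            continue
        pens = _chain_penalties(q, r, chain, sf2, sd2)
        if orient == "-":
            nq = query.n_labels
            pairs = tuple((nq - 1 - i, j) for i, j in chain)
        else:
            pairs = tuple(chain)
        aln = Alignment(
            query_id=query.map_id,
            target_id=target.map_id,
            orientation=orient,
            pairs=pairs,
            score=score,
            significance=1.0,
            step_penalties=pens,
            unaligned_query_labels=query.n_labels - len(chain),
            unaligned_target_labels=target.n_labels - len(chain),
        )
        aln = replace(aln, significance=significance(aln, target, params))
        out.append(aln)
    out.sort(key=lambda a: (-a.score, a.orientation))
    return out


def significance(alignment: Alignment, target: LabelMap, params: AlignParams | None = None) -> float:
    """Analytic chance probability of an alignment under a Poisson null.

    Models the target as a Poisson label process at its observed density
    and asks how likely a monotone chain as long and as tight as the
    observed one is by chance: each chain step requires a random label
    within the 3-sigma sizing window (probability ``1 - exp(-2*lambda*tol)``)
    and at least as close to prediction as observed (``|z_i|/3`` for ``z``
    uniform on the window, floored at 1e-3). The product over steps, times
    the number of possible chain starts, is clipped to (0, 1]. Monotone
    non-increasing in the number of matched pairs at fixed penalty.
    """
    params = params or AlignParams()
    k = alignment.n_pairs
    if k == 0:
        return 1.0
    lam = target.n_labels / target.length_bp
    nq = k + alignment.unaligned_query_labels
    starts = max(nq * target.n_labels, 1)
    if k == 1:
        return 1.0
    # typical target interval for the tolerance width
    mean_gap = 1.0 / lam
    tol = 3.0 * math.sqrt(params.sf**2 + params.sd**2 * mean_gap)
    p_hit = 1.0 - math.exp(-2.0 * lam * tol)
    log_sig = math.log(starts)
    for pen in alignment.step_penalties:
        z = math.sqrt(max(2.0 * pen, 0.0))
        closeness = min(max(z / 3.0, 1e-3), 1.0)
        log_sig += math.log(p_hit) + math.log(closeness)
    return min(1.0, math.exp(max(log_sig, -745.0)))


def screen_decoys(
    molecules: Sequence[Molecule],
    decoy_targets: Sequence[LabelMap],
    params: AlignParams | None = None,
) -> tuple[list[Molecule], dict]:
    """Remove molecules that align to any decoy map at ``T_screen``.

    Mirrors off-target filtering against non-locus reference maps before
    localized assembly: a molecule whose best decoy alignment reaches
    significance <= ``T_screen`` is discarded. Returns the retained
    molecules and a ``{"removed": n, "retained": n}`` report.
    """
    params = params or AlignParams()
    if not decoy_targets:
        return list(molecules), {"removed": 0, "retained": len(molecules)}
    kept = []
    removed = 0
    for mol in molecules:
        hit = False
        for decoy in decoy_targets:
            alns = align(mol.labelmap, decoy, params)
            if alns and alns[0].significance <= params.T_screen:
                hit = True
                break
        if hit:
            removed += 1
        else:
            kept.append(mol)
    return kept, {"removed": removed, "retained": len(kept)}


def _rescue_ends(chain, qpos, tpos, params, z_max: float = 3.5, look: int = 4) -> int:
    """Greedily pair query labels past the local chain's ends.

    Local alignment censors its ends exactly where error events cluster;
    for unbiased rate estimation the molecule's outermost labels are
    paired to the nearest spacing-consistent target (|z| <= ``z_max``)
    regardless of score profit. Mutates ``chain``; returns pairs added.
    """
    added = 0
    order = np.argsort(qpos)
    for direction in (+1, -1):
        qp_last, j_last = chain[-1] if direction == 1 else chain[0]
        if direction == 1:
            pending = [float(qpos[i]) for i in order if qpos[i] > qp_last]
        else:
            pending = [float(qpos[i]) for i in order[::-1] if qpos[i] < qp_last]
        for qp in pending:
            dq = abs(qp - qp_last)
            best_j, best_z = -1, z_max
            for step in range(1, look + 1):
                j = j_last + direction * step
                if not 0 <= j < len(tpos):
                    break
                dr = abs(float(tpos[j]) - float(tpos[j_last]))
                z = abs(dq - dr) / math.sqrt(max(params.sf**2 + params.sd**2 * dr, _MIN_VAR))
                if z <= best_z:
                    best_j, best_z = j, z
            if best_j < 0:
                continue
            if direction == 1:
                chain.append((qp, best_j))
            else:
                chain.insert(0, (qp, best_j))
            qp_last, j_last = qp, best_j
            added += 1
    return added


@dataclass(frozen=True)
class QCReport:
    """Molecule-quality summary in the units of vendor quality reports."""

    fp_rate: float | None
    fn_rate: float | None
    labels_per_100kbp: float
    total_bp: int
    n_molecules: int
    n_aligned: int
    length_quantiles: dict = field(default_factory=dict)
    flags: tuple = ()

    FP_BAND = (0.03, 0.05)
    FN_BAND = (0.09, 0.17)


def compute_qc(
    molecules: Sequence[Molecule],
    targets: Sequence[LabelMap],
    params: AlignParams | None = None,
    alignments: Sequence[Alignment] | None = None,
) -> QCReport:
    """Estimate FP/FN label rates by aligning molecules to truth maps.

    Each molecule's best alignment projects the full molecule window onto
    the target; target labels in the projected window without a partner
    count as misses (FN per true label) and unmatched molecule labels as
    false labels (FP per true label). QC alignments use deliberately
    *cheap* skip costs (unless the caller pins ``fp_cost``/``fn_cost``) so
    the chain does not paper over error events by pairing outlier labels.
    Values outside the recommended FP 3-5% / FN 9-17% bands are flagged;
    with no aligned molecules the rates are undefined (None) and flagged.
    """
    params = params or AlignParams()
    import dataclasses as _dc

    qc_params = params
    if params.fp_cost is None and params.fn_cost is None:
        qc_params = _dc.replace(params, fp_cost=1.7, fn_cost=1.3)
    total_bp = int(sum(m.length_bp for m in molecules))
    n_labels = int(sum(m.n_labels for m in molecules))
    lengths = np.asarray([m.length_bp for m in molecules], dtype=float)
    quantiles = (
        {
            q: float(np.quantile(lengths, q))
            for q in (0.05, 0.25, 0.5, 0.75, 0.95)
        }
        if len(lengths)
        else {}
    )
    density = 1e5 * n_labels / total_bp if total_bp else 0.0

    by_id = {t.map_id: t for t in targets}
    matched = missed = extra = 0
    n_aligned = 0
    for mol in molecules:
        best = None
        if alignments is not None:
            cands = [a for a in alignments if a.query_id == mol.molecule_id]
            best = max(cands, key=lambda a: a.score, default=None)
        else:
            for t in targets:
                for a in align(mol.labelmap, t, qc_params):
                    if best is None or a.score > best.score:
                        best = a
        if best is None or best.significance > params.T_confirm:
            continue
        n_aligned += 1
        target = by_id[best.target_id]
        tpos = target.positions.astype(float)
        # oriented query positions, and the chain in oriented order
        qpos = mol.labelmap.positions.astype(float)
        if best.orientation == "-":
            qpos = mol.length_bp - qpos + 1
        chain = sorted(((float(qpos[i]), j) for i, j in best.pairs), key=lambda x: x[0])
        n_pairs = len(chain) + _rescue_ends(chain, qpos, tpos, params)
        jlo, jhi = chain[0][1], chain[-1][1]
        # project the molecule ends past the chain onto the target frame so
        # end-censored misses are counted
        t_lo = float(tpos[jlo]) - (chain[0][0] - 1)
        t_hi = float(tpos[jhi]) + (mol.length_bp - chain[-1][0])
        n_target_window = int(
            np.searchsorted(tpos, t_hi, side="right") - np.searchsorted(tpos, t_lo, side="left")
        )
        matched += n_pairs
        missed += max(n_target_window - n_pairs, 0)
        extra += mol.n_labels - n_pairs

    if n_aligned == 0 or matched == 0:
        fp = fn = None
        flags = ("no-aligned-molecules",)
    else:
        true_in_span = matched + missed
        fn = missed / true_in_span
        fp = extra / true_in_span
        flags = tuple(
            f
            for f, bad in (
                ("fp-outside-band", not QCReport.FP_BAND[0] <= fp <= QCReport.FP_BAND[1]),
                ("fn-outside-band", not QCReport.FN_BAND[0] <= fn <= QCReport.FN_BAND[1]),
            )
            if bad
        )
    return QCReport(
        fp_rate=fp,
        fn_rate=fn,
        labels_per_100kbp=density,
        total_bp=total_bp,
        n_molecules=len(molecules),
        n_aligned=n_aligned,
        length_quantiles=quantiles,
        flags=flags,
    )
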