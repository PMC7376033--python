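"""Exact and Monte-Carlo contingency statistics, plus trio marker logic.

The 2x2 Fisher exact test is implemented by direct enumeration of all
tables compatible with the observed margins, summing the hypergeometric
point probabilities of every table at most as probable as the observed one
(the two-sided "point probability" convention, with a 1e-7 relative
tolerance on the comparison). R-by-C tables are tested by Monte-Carlo
sampling of fixed-margin tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "TrioMarkers",
    "fisher_2x2",
    "fisher_rxc_mc",
    "proportion_summary",
    "parent_of_origin",
    "origin_ratio",
]

_REL_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable:
    """An R x C table of non-negative integer counts with axis labels."""

    counts: np.ndarray
    rows: Sequence[str] = ()
    cols: Sequence[str] = ()

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if np.any(c < 0):
            raise ValueError("contingency table counts must be non-negative")
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)


def _as_2x2(table) -> np.ndarray:
    t = table.counts if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    return t


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Enumerates every table with the observed margins; the p-value is the sum
    of hypergeometric point probabilities of tables whose probability is at
    most (1 + 1e-7) times that of the observed table. A zero margin yields
    p = 1 by convention.
    """
    t = _as_2x2(table)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0

    # log point probability of the table with x in cell (0,0)
    base = (
        gammaln(r1 + 1)
        + gammaln(r2 + 1)
        + gammaln(c1 + 1)
        + gammaln(n - c1 + 1)
        - gammaln(n + 1)
    )

    def logp(x: int) -> float:
        return float(
            base
            - gammaln(x + 1)
            - gammaln(r1 - x + 1)
            - gammaln(c1 - x + 1)
            - gammaln(r2 - c1 + x + 1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    lp_obs = logp(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = logp(x)
        if lp <= lp_obs + math.log1p(_REL_TOL):
            total += math.exp(lp)
    return min(total, 1.0)


def _log_table_prob(t: np.ndarray, lgr: float, lgc: float, lgn: float) -> float:
    return float(lgr + lgc - lgn - gammaln(t + 1.0).sum())


def fisher_rxc_mc(table, n_sim: int = 100_000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo Fisher test for an R x C table with fixed margins.

    Samples ``n_sim`` tables uniformly from the fixed-margin null (random
    pairing of row and column category multisets, equivalent to the
    multivariate hypergeometric null) and estimates
    ``p = (1 + #{P(sampled) <= P(observed)}) / (n_sim + 1)``.

    Returns ``(p_hat, standard_error)``.
    """
    t = (
        table.counts
        if isinstance(table, ContingencyTable)
        else np.asarray(table, dtype=np.int64)
    )
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000")
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = int(t.sum())
    if n == 0 or (r > 0).sum() < 2 or (c > 0).sum() < 2:
        return 1.0, 0.0

    lgr = float(gammaln(r + 1.0).sum())
    lgc = float(gammaln(c + 1.0).sum())
    lgn = float(gammaln(n + 1.0))
    lp_obs = _log_table_prob(t, lgr, lgc, lgn)
    thresh = lp_obs + math.log1p(_REL_TOL)

    rng = np.random.default_rng(seed)
    row_of = np.repeat(np.arange(t.shape[0]), r)
    col_of = np.repeat(np.arange(t.shape[1]), c)
    nrow, ncol = t.shape
    hits = 0
    for _ in range(n_sim):
        perm = rng.permutation(n)
        flat = row_of[perm] * ncol + col_of
        sim = np.bincount(flat, minlength=nrow * ncol).reshape(nrow, ncol)
        if _log_table_prob(sim, lgr, lgc, lgn) <= thresh:
            hits += 1
    p_hat = (1 + hits) / (n_sim + 1)
    se = math.sqrt(p_hat * (1 - p_hat) / (n_sim + 1))
    return p_hat, se


def proportion_summary(numerator: int, denominator: int) -> tuple[float, str]:
    """Percentage rounded half-up to 1 decimal, plus the exact fraction."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    pct = math.floor(1000.0 * numerator / denominator + 0.5) / 10.0
    return pct, f"{numerator}/{denominator}"


# ---------------------------------------------------------------------------
# Parent-of-deletion-origin from STRP markers


@dataclass(frozen=True)
class TrioMarkers:
    """Alleles of one microsatellite marker in a deletion trio.

    The proband is hemizygous across the deleted interval, so it carries a
    single allele per marker: the one on the intact homolog, transmitted by
    the parent that did *not* contribute the deleted chromosome. A marker
    is informative when the retained allele is carried by exactly one
    parent; the parent whose allele is missing is the
    parent-of-deletion-origin.
    """

    marker_id: str
    mother_alleles: tuple
    father_alleles: tuple
    proband_allele: object


@dataclass
class OriginCall:
    origin: str  # "mother", "father", or "indeterminate"
    informative: list = field(default_factory=list)
    excluded: list = field(default_factory=list)
    reason: str = ""


def parent_of_origin(markers: Sequence[TrioMarkers]) -> OriginCall:
    """Assign parent-of-deletion-origin from informative markers.

    The retained proband allele matching exactly one parent votes for the
    *other* parent as origin (the origin parent's allele was deleted).
    Assignment requires >= 3 informative markers, all concordant; anything
    less, or any discordance, is indeterminate. Markers whose proband
    allele is carried by neither parent are flagged Mendelian-inconsistent
    and excluded.
    """
    votes: list[tuple[str, str]] = []
    excluded = []
    for m in markers:
        in_mother = m.proband_allele in m.mother_alleles
        in_father = m.proband_allele in m.father_alleles
        if not in_mother and not in_father:
            excluded.append((m.marker_id, "mendelian-inconsistent"))
            continue
        if in_mother and in_father:
            continue  # uninformative
        votes.append((m.marker_id, "father" if in_mother else "mother"))
    call = OriginCall("indeterminate", informative=votes, excluded=excluded)
    if len(votes) < 3:
        call.reason = f"only {len(votes)} informative markers (minimum 3)"
        return call
    origins = {v for _, v in votes}
    if len(origins) > 1:
        call.reason = "discordant informative markers"
        return call
    call.origin = origins.pop()
    return call


def origin_ratio(assignments) -> float:
    """female:male parent-of-origin ratio, rounded half-up to 1 decimal.

    ``assignments`` is either a mapping with 'mother'/'father' counts, a
    pair ``(n_female, n_male)``, or an iterable of 'mother'/'father' calls.
    """
    if isinstance(assignments, Mapping):
        nf, nm = int(assignments.get("mother", 0)), int(assignments.get("father", 0))
    elif (
        isinstance(assignments, Sequence)
        and len(assignments) == 2
        and all(isinstance(x, (int, np.integer)) for x in assignments)
    ):
        nf, nm = int(assignments[0]), int(assignments[1])
    else:
        vals = list(assignments)
        nf = sum(1 for v in vals if v == "mother")
        nm = sum(1 for v in vals if v == "father")
    if nm == 0:
        raise ValueError("female:male ratio undefined with zero male assignments")
    return math.floor(10.0 * nf / nm + 0.5) / 10.0
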