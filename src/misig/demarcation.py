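"""Genus demarcation boundary, classification and type/non-type separation.

Every genome in a cohort is scored against one primary reference (the type
strain of the type species of the genus under analysis).  The genus
demarcation boundary is the (AF, ANI) corner set by the *highest* AF and the
highest ANI attained by any other type species in the family/order: genomes
at or below that corner are as distant from the reference as other genera,
genomes above it in both axes sit inside the reference genus.  A two-sided
Wilcoxon rank-sum (Mann-Whitney U) test checks that the type and non-type
clouds differ in AF and in ANI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import MisigError
from .io import ManifestEntry, PairwiseScore, Role

__all__ = [
    "Boundary",
    "Classification",
    "Zone",
    "WilcoxonResult",
    "AgreementSummary",
    "compute_boundary",
    "classify",
    "wilcoxon_rank_sum",
    "agreement_summary",
]


class Zone(str, Enum):
    within_genus = "within_genus"
    at_or_below_boundary = "at_or_below_boundary"
    borderline = "borderline"


@dataclass(frozen=True, slots=True)
class Boundary:
    """Per-genus demarcation corner and the type species that set it."""

    af_boundary: float
    ani_boundary: float
    setting_species_af: str
    setting_species_ani: str

    @property
    def joint(self) -> bool:
        """True when a single species attains both maxima."""
        return self.setting_species_af == self.setting_species_ani


@dataclass(frozen=True, slots=True)
class Classification:
    genome_id: str
    zone: Zone
    af: float
    ani: float


@dataclass(frozen=True, slots=True)
class WilcoxonResult:
    statistic_U: float
    p_two_sided: float
    method: str  # "exact" | "normal_approx"
    n1: int
    n2: int


@dataclass(frozen=True, slots=True)
class AgreementSummary:
    n_total: int
    n_agree: int
    n_disagree: int
    disagreeing_ids: tuple[str, ...]

    @property
    def fraction_agree(self) -> float:
        return self.n_agree / self.n_total


# ---------------------------------------------------------------------------
# Boundary and classification
# ---------------------------------------------------------------------------

def compute_boundary(type_scores: Sequence[PairwiseScore]) -> Boundary:
    """Boundary = per-axis maxima over type-species scores vs the reference.

    The AF and ANI maxima are taken independently, so different species may
    set the two axes.  Scores with undefined ANI still contribute their AF;
    at least one score with defined ANI is required.
    """
    scores = list(type_scores)
    if not scores:
        raise MisigError("no type species: cannot derive a boundary")
    af_best = max(scores, key=lambda s: s.af_mean)
    with_ani = [s for s in scores if s.ani_mean is not None]
    if not with_ani:
        raise MisigError("no type species with defined ANI: cannot derive a boundary")
    ani_best = max(with_ani, key=lambda s: s.ani_mean)
    return Boundary(
        af_boundary=af_best.af_mean,
        ani_boundary=ani_best.ani_mean,
        setting_species_af=af_best.genome_a,
        setting_species_ani=ani_best.genome_a,
    )


def classify(score: PairwiseScore, boundary: Boundary) -> Classification:
    """Place a genome relative to the boundary corner.

    Equality counts as ``at_or_below``; a genome above the corner in one axis
    but not the other is ``borderline`` (the quadrant plots never assign that
    mixed region to either side).
    """
    if score.ani_mean is None:
        raise MisigError(f"score undefined: {score.genome_a} vs {score.genome_b}")
    af, ani = score.af_mean, score.ani_mean
    below_af = af <= boundary.af_boundary
    below_ani = ani <= boundary.ani_boundary
    if below_af and below_ani:
        zone = Zone.at_or_below_boundary
    elif not below_af and not below_ani:
        zone = Zone.within_genus
    else:
        zone = Zone.borderline
    return Classification(genome_id=score.genome_a, zone=zone, af=af, ani=ani)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney U)
# ---------------------------------------------------------------------------

_EXACT_N_MAX = 20


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of sample x vs y (ties count 1/2)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_p(ranks_x: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    """Two-sided exact p by counting the tie-free U null distribution.

    Classic recursion on the number of rank subsets attaining each U value;
    the two-sided p sums both tails at least as extreme as ``u_obs`` under the
    symmetric null.
    """
    # count[u] = number of n1-subsets of ranks 1..N with U statistic u
    n_u = n1 * n2
    # DP over items; f[k][u] = #ways to choose k of the first i ranks with u
    f = np.zeros((n1 + 1, n_u + 1), dtype=np.float64)
    f[0, 0] = 1.0
    for i in range(1, n1 + n2 + 1):
        # adding rank i as a member of group 1 contributes (i - k) ... use the
        # standard recurrence f_new[k][u] = f[k][u] + f[k-1][u - (i - k)]
        for k in range(min(i, n1), 0, -1):
            shift = i - k  # number of group-2 elements below this rank so far
            if shift > n_u:
                continue
            f[k, shift:] += f[k - 1, : n_u + 1 - shift]
    counts = f[n1]
    total = counts.sum()
    lo = min(u_obs, n_u - u_obs)
    hi = max(u_obs, n_u - u_obs)
    us = np.arange(n_u + 1)
    p = counts[(us <= lo + 1e-9) | (us >= hi - 1e-9)].sum() / total
    return float(min(p, 1.0))


def _approx_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Tie-corrected normal approximation with continuity correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    mu = n1 * n2 / 2.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float]
) -> WilcoxonResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    Exact enumeration of the U null distribution when n1+n2 <= 20 and no value
    is shared across the groups; tie-corrected normal approximation (with
    continuity correction) otherwise.
    """
    x = np.asarray(group_a, dtype=np.float64)
    y = np.asarray(group_b, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise MisigError("empty group: both samples must be non-empty")
    u = _u_statistic(x, y)
    cross_ties = bool(set(x.tolist()) & set(y.tolist()))
    if x.size + y.size <= _EXACT_N_MAX and not cross_ties:
        p = _exact_p(x, len(x), len(y), u)
        method = "exact"
    else:
        p = _approx_p(x, y, u)
        method = "normal_approx"
    return WilcoxonResult(
        statistic_U=u, p_two_sided=p, method=method, n1=len(x), n2=len(y)
    )


# ---------------------------------------------------------------------------
# Agreement with current taxonomy
# ---------------------------------------------------------------------------

def agreement_summary(
    classifications: Sequence[Classification],
    roles: Mapping[str, Role] | Iterable[ManifestEntry],
) -> AgreementSummary:
    """Fraction of genomes whose zone matches their annotated role.

    A non-type genome agrees when it falls within the genus; a type species
    agrees when it sits at or below the boundary it helped set.  Borderline
    genomes count as disagreement and are listed.  The primary reference, if
    classified, behaves like a non-type genome (its self-score is (1, 100)).
    """
    if not isinstance(roles, Mapping):
        roles = {e.genome_id: e.role for e in roles}
    if not classifications:
        raise MisigError("nothing to summarize: no classifications")
    n_agree = 0
    disagreeing: list[str] = []
    for c in classifications:
        try:
            role = roles[c.genome_id]
        except KeyError:
            raise MisigError(f"invalid role: genome {c.genome_id!r} missing from manifest") from None
        if role is Role.type_species:
            ok = c.zone is Zone.at_or_below_boundary
        else:  # non_type and primary_reference cluster with the genus
            ok = c.zone is Zone.within_genus
        if ok:
            n_agree += 1
        else:
            disagreeing.append(c.genome_id)
    return AgreementSummary(
        n_total=len(classifications),
        n_agree=n_agree,
        n_disagree=len(disagreeing),
        disagreeing_ids=tuple(disagreeing),
    )
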