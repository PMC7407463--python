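"""Selection and mate allocation.

Candidates are truncation-selected on an estimated breeding value; the
crossbred litters are then produced either by random mating or by an
optimized allocation of the selected P1 sires to the P2 dams.  Two mating
criteria are supported, both computed from Mendelian transmission
probabilities of each candidate pair:

* EFI  - expected future inbreeding: mean expected offspring homozygosity
  over the marker loci (1 - expected heterozygosity).
* ETGV - expected total genetic value of the offspring under estimated
  (or true) additive and dominance effects in the +-a, d parameterization.

The allocation itself is a transportation linear program: each sire
receives exactly ``quota`` dams, each dam at most one sire.  Extreme
points of that polytope are integral, so the LP relaxation (solved with
HiGHS via :func:`scipy.optimize.linprog`) yields a 0/1 assignment; a
deterministic greedy repair guards against fractional vertices returned
on ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import csr_matrix

__all__ = [
    "MatingPlan",
    "select_candidates",
    "offspring_genotype_probs",
    "efi",
    "etgv",
    "efi_matrix",
    "etgv_matrix",
    "optimize_matings",
    "random_mating_plan",
]


@dataclass
class MatingPlan:
    """Sire-dam pairs with quota bookkeeping.

    ``pairs`` holds (sire, dam) as indices into the caller's selected
    sets; each dam appears at most once and each sire exactly ``quota``
    times.
    """

    pairs: np.ndarray  # (n_pairs, 2) int
    objective: str  # "random" | "min_EFI" | "max_ETGV"
    objective_value: float
    quota: int

    @property
    def sires(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def dams(self) -> np.ndarray:
        return self.pairs[:, 1]

    def validate(self, n_sires: int, n_dams: int) -> None:
        s, d = self.sires, self.dams
        if np.unique(d).size != d.size:
            raise ValueError("a dam appears in more than one pair")
        counts = np.bincount(s, minlength=n_sires)
        if not np.all(counts[np.unique(s)] == self.quota):
            raise ValueError("sire quota violated")


def select_candidates(
    scores: np.ndarray,
    sexes: np.ndarray,
    n_males: int,
    n_females: int,
    second_tranche: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Truncation selection of the top males and females by score.

    Ties at the boundary break by ascending index, so selection is
    deterministic.  Returns (selected males, selected females, second
    tranche of females), the second tranche being female ranks
    n_females+1 .. 2*n_females (used to produce crossbreds in the dam
    breed).
    """
    from .genome import FEMALE, MALE

    scores = np.asarray(scores, dtype=float)
    males = np.flatnonzero(np.asarray(sexes) == MALE)
    females = np.flatnonzero(np.asarray(sexes) == FEMALE)
    need_f = 2 * n_females if second_tranche else n_females
    if males.size < n_males or females.size < need_f:
        raise ValueError("insufficient candidates for requested selection")
    # sort by (-score, index): stable sort on index-ordered arrays
    m_rank = males[np.argsort(-scores[males], kind="stable")]
    f_rank = females[np.argsort(-scores[females], kind="stable")]
    sel_m = np.sort(m_rank[:n_males])
    sel_f = np.sort(f_rank[:n_females])
    tranche2 = np.sort(f_rank[n_females : 2 * n_females]) if second_tranche else np.array([], dtype=int)
    return sel_m, sel_f, tranche2


def offspring_genotype_probs(
    sire_dosage: np.ndarray, dam_dosage: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Mendelian offspring genotype probabilities (P(AA), P(Aa), P(aa))."""
    zs = np.asarray(sire_dosage)
    zd = np.asarray(dam_dosage)
    if np.any((zs > 2) | (zd > 2)):
        raise ValueError("dosages must be in {0, 1, 2}")
    ts = zs / 2.0  # transmission probability of the reference allele
    td = zd / 2.0
    p_aa = ts * td
    p_bb = (1 - ts) * (1 - td)
    return p_aa, 1.0 - p_aa - p_bb, p_bb


def efi(sire_dosage: np.ndarray, dam_dosage: np.ndarray) -> float:
    """Expected future inbreeding of one mating: mean expected offspring
    homozygosity over loci."""
    p_aa, _, p_bb = offspring_genotype_probs(sire_dosage, dam_dosage)
    return float(np.mean(p_aa + p_bb))


def etgv(
    sire_dosage: np.ndarray,
    dam_dosage: np.ndarray,
    a_hat: np.ndarray,
    d_hat: np.ndarray,
) -> float:
    """Expected total genetic value of one mating's offspring:
    sum_k P(AA) a_k + P(Aa) d_k + P(aa) (-a_k)."""
    a_hat = np.asarray(a_hat, dtype=float)
    d_hat = np.asarray(d_hat, dtype=float)
    if a_hat.size != np.asarray(sire_dosage).size or d_hat.size != a_hat.size:
        raise ValueError("effect vectors misaligned with loci")
    p_aa, p_ab, p_bb = offspring_genotype_probs(sire_dosage, dam_dosage)
    return float(np.sum(p_aa * a_hat + p_ab * d_hat - p_bb * a_hat))


def efi_matrix(sire_dosages: np.ndarray, dam_dosages: np.ndarray) -> np.ndarray:
    """EFI for every sire x dam pair (vectorized over the whole grid)."""
    ts = sire_dosages / 2.0  # (ns, L)
    td = dam_dosages / 2.0  # (nd, L)
    # mean over loci of ts*td + (1-ts)*(1-td)
    L = ts.shape[1]
    cross = ts @ td.T + (1 - ts) @ (1 - td).T
    return cross / L


def etgv_matrix(
    sire_dosages: np.ndarray,
    dam_dosages: np.ndarray,
    a_hat: np.ndarray,
    d_hat: np.ndarray,
) -> np.ndarray:
    """ETGV for every sire x dam pair.

    Uses E[TGV] = sum_k (ts+td-1) a_k + (ts+td-2 ts td) d_k, the expansion
    of the genotype-probability form, which factorizes over the grid.
    """
    ts = sire_dosages / 2.0
    td = dam_dosages / 2.0
    add = (ts * a_hat).sum(axis=1)[:, None] + (td * a_hat).sum(axis=1)[None, :] \
        - np.sum(a_hat)
    dom = (ts * d_hat).sum(axis=1)[:, None] + (td * d_hat).sum(axis=1)[None, :] \
        - 2.0 * (ts * d_hat) @ td.T
    return add + dom


def optimize_matings(
    score_matrix: np.ndarray,
    sense: str,
    quota: int,
    dam_cap: int = 1,
) -> MatingPlan:
    """Optimal assignment of ``quota`` dams per sire, each dam used at
    most ``dam_cap`` times, minimizing or maximizing the summed score.

    Transportation structure makes the LP relaxation integral; the
    returned assignment is verified and, if the solver lands on a
    fractional vertex (ties), repaired deterministically.
    """
    S = np.asarray(score_matrix, dtype=float)
    n_s, n_d = S.shape
    if sense not in ("min", "max"):
        raise ValueError("sense must be 'min' or 'max'")
    if n_d * dam_cap < n_s * quota:
        raise ValueError(
            f"infeasible quotas: {n_s} sires x {quota} dams exceed {n_d} available dams"
        )
    c = S.ravel() if sense == "min" else -S.ravel()

    rows, cols, data = [], [], []
    for i in range(n_s):  # sire quota equality
        rows += [i] * n_d
        cols += list(range(i * n_d, (i + 1) * n_d))
        data += [1.0] * n_d
    a_eq = csr_matrix((data, (rows, cols)), shape=(n_s, n_s * n_d))
    rows, cols, data = [], [], []
    for j in range(n_d):  # dam capacity inequality
        rows += [j] * n_s
        cols += [i * n_d + j for i in range(n_s)]
        data += [1.0] * n_s
    a_ub = csr_matrix((data, (rows, cols)), shape=(n_d, n_s * n_d))

    res = linprog(
        c,
        A_eq=a_eq, b_eq=np.full(n_s, float(quota)),
        A_ub=a_ub, b_ub=np.full(n_d, float(dam_cap)),
        bounds=(0.0, 1.0),
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"mate-allocation LP failed: {res.message}")
    theta = res.x.reshape(n_s, n_d)

    if np.all(np.abs(theta - np.round(theta)) < 1e-6):
        theta = np.round(theta)
    else:  # fractional vertex: deterministic greedy repair
        theta = _repair_fractional(theta, S, sense, quota, dam_cap)

    pairs = np.argwhere(theta > 0.5)
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    obj = float(S[pairs[:, 0], pairs[:, 1]].sum())
    plan = MatingPlan(
        pairs=pairs,
        objective="min_EFI" if sense == "min" else "max_ETGV",
        objective_value=obj,
        quota=quota,
    )
    plan.validate(n_s, n_d)
    return plan


def _repair_fractional(
    theta: np.ndarray, S: np.ndarray, sense: str, quota: int, dam_cap: int
) -> np.ndarray:
    """Round a fractional LP vertex: greedy by score (then lexicographic
    by ids) subject to the quota constraints."""
    n_s, n_d = S.shape
    order = np.argsort(S.ravel() if sense == "min" else -S.ravel(), kind="stable")
    out = np.zeros_like(S)
    sire_used = np.zeros(n_s, dtype=int)
    dam_used = np.zeros(n_d, dtype=int)
    for flat in order:
        i, j = divmod(int(flat), n_d)
        if sire_used[i] < quota and dam_used[j] < dam_cap:
            out[i, j] = 1.0
            sire_used[i] += 1
            dam_used[j] += 1
    if np.any(sire_used != quota):
        raise RuntimeError("fractional repair failed to satisfy quotas")
    return out


def random_mating_plan(
    n_sires: int,
    n_dams: int,
    quota: int,
    rng: np.random.Generator,
) -> MatingPlan:
    """Random balanced plan: dams are shuffled and dealt to sires in
    blocks of ``quota``."""
    if n_dams != n_sires * quota:
        raise ValueError("random plan needs n_dams = n_sires * quota")
    dams = rng.permutation(n_dams)
    sires = np.repeat(np.arange(n_sires), quota)
    pairs = np.column_stack([sires, dams])
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    plan = MatingPlan(pairs=pairs, objective="random", objective_value=np.nan, quota=quota)
    plan.validate(n_sires, n_dams)
    return plan
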