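"""Trait architecture: correlated QTL effects with directional dominance.

A single maternal trait (think litter size) is controlled by ``m`` QTL.
Additive and dominance effects are breed-specific but correlated across
the three populations (P1, P2, CB) with correlation ``r_qtl``, modelling
genotype-by-genotype / genotype-by-environment interaction.  Heterosis is
generated by *directional dominance*: the dominance effect at each locus
is split as d = mu_d + d*, where the constant mu_d = -b/m is set by the
inbreeding-depression parameter b (b = -10 means one unit of performance
lost per 10% increase in genomic homozygosity) and d* is a zero-mean
normal deviate.

True values
-----------
* ``tbv_purebred``  - breeding value on the purebred scale, the centered
  gene-content regression on within-breed substitution effects
  alpha = a + d (q - p).
* ``tbv_crossbred`` - breeding value on the crossbred scale: substitution
  effects use CB-population effects and the *opposite* breed's allele
  frequencies, alpha_C = a_c + (q_opp - p_opp) d_c.
* ``ttgv``          - total (additive + dominance) genotypic value of a
  crossbred individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import Cohort

__all__ = [
    "POPULATIONS",
    "VarianceCase",
    "TraitArchitecture",
    "build_effect_covariances",
    "sample_qtl_effects",
    "calibrate_variances",
    "tbv_purebred",
    "tbv_crossbred",
    "ttgv",
    "genotypic_value",
    "phenotype",
    "genomic_inbreeding",
    "heterosis_expected",
    "write_architecture",
    "read_architecture",
]

POPULATIONS = ("P1", "P2", "CB")

# Additive and dominance genetic variances for total number born
# (Landrace, Yorkshire, F1) used as the base scale of QTL effects.
_SIGMA_U_BASE = (0.86, 0.54, 0.28)
_SIGMA_V_BASE = (0.04, 0.06, 0.02)

_CASE_PRESETS = {1: (0.1, 0.01), 2: (0.1, 0.1), 3: (0.3, 0.1)}


@dataclass
class VarianceCase:
    """Genetic-parameter case: heritabilities, effect correlation, and the
    per-population variance components (realized values filled in by
    :func:`calibrate_variances`)."""

    h2: float
    hd2: float
    r_qtl: float = 0.5
    b: tuple[float, float, float] = (-10.0, -10.0, -10.0)
    sigma_u_base: tuple[float, float, float] = _SIGMA_U_BASE
    sigma_v_base: tuple[float, float, float] = _SIGMA_V_BASE
    # realized (post-calibration) components, per population
    sigma_u: np.ndarray | None = None
    sigma_v: np.ndarray | None = None
    sigma_e: np.ndarray | None = None

    def __post_init__(self):
        if not -1.0 <= self.r_qtl <= 1.0:
            raise ValueError("invalid correlation: r_qtl must be in [-1, 1]")
        if self.h2 + self.hd2 >= 1.0:
            raise ValueError("infeasible case: h2 + hd2 must be < 1")

    @classmethod
    def preset(cls, case: int, r_qtl: float = 0.5) -> "VarianceCase":
        h2, hd2 = _CASE_PRESETS[case]
        return cls(h2=h2, hd2=hd2, r_qtl=r_qtl)


@dataclass
class TraitArchitecture:
    """Sampled per-locus effects for the trait QTL.

    ``a`` and ``d_star`` are (3, m) arrays ordered as ``POPULATIONS``;
    ``qtl_loci`` holds the global locus indices of the m trait QTL.
    ``founder_freqs`` (3, m) are fixed at calibration time and provide the
    centering frequencies of the purebred-scale breeding values.
    """

    qtl_loci: np.ndarray  # (m,) global locus indices
    a: np.ndarray  # (3, m)
    d_star: np.ndarray  # (3, m)
    mu_d: np.ndarray  # (3,)
    sigma_a: np.ndarray  # (3, 3) per-locus additive covariance
    sigma_d: np.ndarray  # (3, 3) per-locus dominance covariance
    founder_freqs: np.ndarray | None = None  # (3, m) set by calibration

    @property
    def m(self) -> int:
        return self.qtl_loci.size

    @property
    def d(self) -> np.ndarray:
        """Total dominance effects d = mu_d + d*."""
        return self.mu_d[:, None] + self.d_star

    def pop(self, population: str) -> int:
        return POPULATIONS.index(population)


def build_effect_covariances(case: VarianceCase, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus 3x3 covariance matrices of additive and dominance effects.

    Diagonals are sigma/m so that the m loci jointly carry the base
    variances; off-diagonals apply the across-population correlation.
    """
    if m < 1:
        raise ValueError("need at least one QTL")

    def cov(sig):
        s = np.asarray(sig, dtype=float) / m
        root = np.sqrt(np.outer(s, s))
        c = case.r_qtl * root
        np.fill_diagonal(c, s)
        return c

    return cov(case.sigma_u_base), cov(case.sigma_v_base)


def sample_qtl_effects(
    case: VarianceCase,
    m: int,
    candidate_loci: np.ndarray,
    rng: np.random.Generator,
) -> TraitArchitecture:
    """Sample m trait QTL and their correlated effects.

    ``candidate_loci`` are the global indices of QTL eligible to carry the
    trait (segregating in at least one breed); m of them are drawn
    uniformly without replacement.  Effect triples are i.i.d. across loci
    from MVN(0, sigma_a) and MVN(0, sigma_d); mu_d = -b/m per population.
    """
    candidate_loci = np.asarray(candidate_loci)
    if candidate_loci.size < m:
        raise ValueError(
            f"only {candidate_loci.size} segregating QTL available, need {m}"
        )
    sigma_a, sigma_d = build_effect_covariances(case, m)
    loci = np.sort(rng.choice(candidate_loci, size=m, replace=False))
    a = rng.multivariate_normal(np.zeros(3), sigma_a, size=m, method="cholesky").T
    d_star = rng.multivariate_normal(np.zeros(3), sigma_d, size=m, method="cholesky").T
    mu_d = -np.asarray(case.b, dtype=float) / m
    return TraitArchitecture(
        qtl_loci=loci, a=a, d_star=d_star, mu_d=mu_d,
        sigma_a=sigma_a, sigma_d=sigma_d,
    )


def _dominance_scale(a, d_star, mu_d, p, ratio) -> float:
    """Scalar s >= 0 such that scaling d* by s makes the realized
    dominance-to-additive variance ratio equal ``ratio``.

    Both variances are quadratics in s (mu_d is not scaled), so the
    condition sigma_v^2(s) = ratio * sigma_u^2(s) is a quadratic with a
    single positive root in the regular case.  When the target is
    unattainable (the directional mean alone carries more dominance
    variance than the target; only possible for very small QTL numbers)
    the closest attainable ratio is used and a warning is emitted.
    """
    import warnings

    q = 1.0 - p
    w = 2.0 * p * q
    qp = q - p
    alpha0 = a + mu_d * qp
    # sigma_v^2(s) = A s^2 + B s + C ; sigma_u^2(s) = D s^2 + E s + F
    A = np.sum((w * d_star) ** 2)
    B = 2.0 * mu_d * np.sum(w**2 * d_star)
    C = mu_d**2 * np.sum(w**2)
    D = np.sum(w * (d_star * qp) ** 2)
    E = 2.0 * np.sum(w * alpha0 * d_star * qp)
    F = np.sum(w * alpha0**2)
    if A <= 0:  # no dominance deviations to scale
        return 1.0
    ca, cb, cc = A - ratio * D, B - ratio * E, C - ratio * F
    disc = cb**2 - 4 * ca * cc
    if disc >= 0 and ca != 0:
        roots = [(-cb + np.sqrt(disc)) / (2 * ca), (-cb - np.sqrt(disc)) / (2 * ca)]
        pos = [r for r in roots if r > 0]
        if pos:
            return float(min(pos))
    # unattainable: the ratio as a function of s has analytic critical
    # points; take the s (>= 0, finite) with the ratio closest to target
    def f_ratio(s):
        return (A * s**2 + B * s + C) / (D * s**2 + E * s + F)

    cands = [0.0]
    crit = np.roots([A * E - B * D, 2 * (A * F - C * D), B * F - C * E])
    cands += [float(r) for r in crit if np.isreal(r) and r.real > 0]
    best = min(cands, key=lambda s: abs(f_ratio(s) - ratio))
    warnings.warn(
        "dominance-variance target unattainable by rescaling d*; "
        f"using closest attainable ratio {f_ratio(best):.3g} (target {ratio:.3g}, "
        f"s = {best:.3g})"
    )
    return float(best)


def calibrate_variances(
    arch: TraitArchitecture,
    case: VarianceCase,
    freqs_p1: np.ndarray,
    freqs_p2: np.ndarray,
    n_passes: int = 2,
) -> tuple[TraitArchitecture, VarianceCase]:
    """Rescale dominance deviations and derive residual variances.

    Per population t (CB frequencies taken as the parental mean), the
    realized additive variance sigma_u^2 = sum 2pq alpha^2 and dominance
    variance sigma_v^2 = sum (2pq d)^2 are computed at founder
    frequencies; d* is rescaled by a per-population scalar (exact solve
    of the scaling quadratic, since alpha depends on d) so that
    sigma_v^2 / sigma_u^2 = hd2 / h2, and the residual follows as
    sigma_e^2 = sigma_u^2 (1 - h2 - hd2) / h2.  mu_d is left untouched so
    the depression parameter b is preserved exactly.
    """
    freqs = np.vstack([freqs_p1, freqs_p2, 0.5 * (freqs_p1 + freqs_p2)])
    if freqs.shape[1] != arch.m:
        raise ValueError("frequency vectors misaligned with trait QTL")
    ratio = case.hd2 / case.h2
    d_star = arch.d_star.copy()

    def components(t, ds):
        p = freqs[t]
        q = 1.0 - p
        w = 2.0 * p * q
        d = arch.mu_d[t] + ds
        alpha = arch.a[t] + d * (q - p)
        return float(np.sum(w * alpha**2)), float(np.sum((w * d) ** 2))

    for t in range(3):
        d_star[t] *= _dominance_scale(
            arch.a[t], d_star[t], arch.mu_d[t], freqs[t], ratio
        )

    sigma_u = np.empty(3)
    sigma_v = np.empty(3)
    for t in range(3):
        sigma_u[t], sigma_v[t] = components(t, d_star[t])
    sigma_e = sigma_u * (1.0 - case.h2 - case.hd2) / case.h2
    if np.any(sigma_e <= 0):
        raise ValueError("infeasible residual variance")

    arch2 = replace(arch, d_star=d_star, founder_freqs=freqs)
    case2 = replace(case, sigma_u=sigma_u, sigma_v=sigma_v, sigma_e=sigma_e)
    return arch2, case2


# ---------------------------------------------------------------------------
# true genetic values
# ---------------------------------------------------------------------------


def _qtl_dosages(cohort: Cohort, arch: TraitArchitecture) -> np.ndarray:
    return cohort.dosages(arch.qtl_loci).astype(np.float64)


def tbv_purebred(
    cohort: Cohort,
    arch: TraitArchitecture,
    current_freqs: np.ndarray | None = None,
    founder_freqs: np.ndarray | None = None,
) -> np.ndarray:
    """True breeding value on the purebred scale.

    TBVP_i = sum_j (z_ij - 2 p_fj) alpha_j with alpha_j = a_j + d_j (q_j - p_j):
    substitution effects at the breed's *current* frequencies, centering at
    the breed's *founder* frequencies.
    """
    if cohort.breed not in ("P1", "P2"):
        raise ValueError("purebred-scale TBV is defined for P1/P2 cohorts")
    t = arch.pop(cohort.breed)
    if current_freqs is None:
        current_freqs = cohort.allele_freqs(arch.qtl_loci)
    if founder_freqs is None:
        if arch.founder_freqs is None:
            raise ValueError("architecture not calibrated: founder frequencies missing")
        founder_freqs = arch.founder_freqs[t]
    p = np.asarray(current_freqs, dtype=float)
    pf = np.asarray(founder_freqs, dtype=float)
    if p.size != arch.m or pf.size != arch.m:
        raise ValueError("frequency vectors misaligned with trait QTL")
    alpha = arch.a[t] + arch.d[t] * (1.0 - 2.0 * p)
    z = _qtl_dosages(cohort, arch)
    return (z - 2.0 * pf) @ alpha


def tbv_crossbred(
    cohort: Cohort,
    arch: TraitArchitecture,
    opposite_freqs: np.ndarray,
    own_freqs: np.ndarray | None = None,
) -> np.ndarray:
    """True breeding value on the crossbred scale.

    Uses CB-population effects with the opposite breed's current allele
    frequencies: TBVC_i = sum_j (z_ij - 2 p_own,j) (a_cj + (q_opp - p_opp) d_cj).
    """
    if cohort.breed not in ("P1", "P2"):
        raise ValueError("crossbred-scale TBV is defined for purebred cohorts")
    c = arch.pop("CB")
    if own_freqs is None:
        own_freqs = cohort.allele_freqs(arch.qtl_loci)
    p_own = np.asarray(own_freqs, dtype=float)
    p_opp = np.asarray(opposite_freqs, dtype=float)
    if p_own.size != arch.m or p_opp.size != arch.m:
        raise ValueError("frequency vectors misaligned with trait QTL")
    alpha_c = arch.a[c] + (1.0 - 2.0 * p_opp) * arch.d[c]
    z = _qtl_dosages(cohort, arch)
    return (z - 2.0 * p_own) @ alpha_c


def genotypic_value(dosages: np.ndarray, a: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Total genotypic value sum z a + sum z(2-z) d for given effects;
    z(2-z) is the heterozygote indicator."""
    z = np.asarray(dosages, dtype=np.float64)
    return z @ a + (z * (2.0 - z)) @ d


def ttgv(cohort: Cohort, arch: TraitArchitecture) -> np.ndarray:
    """True total genetic value of crossbred individuals (CB effects)."""
    if cohort.breed != "CB":
        raise ValueError("TTGV is defined for CB cohorts")
    c = arch.pop("CB")
    return genotypic_value(_qtl_dosages(cohort, arch), arch.a[c], arch.d[c])


def phenotype(
    genetic_values: np.ndarray,
    sex: np.ndarray,
    sigma_e2: float,
    rng: np.random.Generator,
    mean: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Phenotypes y = mean + g + e, recorded for females only.

    Returns (female_indices, records); males yield no record, mirroring a
    maternal trait such as litter size.
    """
    if sigma_e2 < 0:
        raise ValueError("negative residual variance")
    from .genome import FEMALE

    females = np.flatnonzero(np.asarray(sex) == FEMALE)
    g = np.asarray(genetic_values, dtype=float)[females]
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=females.size)
    return females, mean + g + e


def genomic_inbreeding(dosages: np.ndarray) -> np.ndarray:
    """Per-individual genomic inbreeding: fraction of homozygous loci."""
    z = np.asarray(dosages)
    if z.shape[-1] == 0:
        raise ValueError("empty locus set")
    return (z != 1).mean(axis=-1)


def write_architecture(arch: TraitArchitecture, gmap, case: VarianceCase, path) -> None:
    """Serialize a trait architecture as TSV: a commented header block
    with the case parameters, then one row per QTL with positions and
    the six per-population effects."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "chrom": gmap.chrom[arch.qtl_loci],
            "pos_cM": gmap.pos_cM[arch.qtl_loci],
            "a_P1": arch.a[0], "a_P2": arch.a[1], "a_C": arch.a[2],
            "d_P1": arch.d[0], "d_P2": arch.d[1], "d_C": arch.d[2],
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# h2={case.h2} hd2={case.hd2} r_qtl={case.r_qtl} "
                 f"b={','.join(str(x) for x in case.b)} m={arch.m} "
                 f"mu_d={','.join(format(x, '.10g') for x in arch.mu_d)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_architecture(path) -> "pd.DataFrame":
    """Read back the TSV written by :func:`write_architecture` (effects
    table only; the header line carries the case parameters)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#")


def heterosis_expected(d_c: np.ndarray, freqs_p1: np.ndarray, freqs_p2: np.ndarray) -> float:
    """Expected heterosis H = sum_j d_cj (p_P1j - p_P2j)^2."""
    d_c = np.asarray(d_c, dtype=float)
    dp = np.asarray(freqs_p1, dtype=float) - np.asarray(freqs_p2, dtype=float)
    if d_c.size != dp.size:
        raise ValueError("effect and frequency vectors misaligned")
    return float(np.sum(d_c * dp**2))
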