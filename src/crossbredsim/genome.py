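"""Forward-in-time genome simulation.

This module simulates a neutral historical population (drift, recurrent
mutation, recombination), forms two divergently selected breeds from it,
and provides genome summary statistics: marker quality control, linkage
disequilibrium (LD) decay and the between-breed relationship computed
from allele frequencies.

Biology and conventions
-----------------------
* Loci are biallelic; the genotype dosage is the number of copies of the
  reference allele (0/1/2).
* Recombination follows the Haldane model: the number of crossovers per
  chromosome per meiosis is Poisson with mean ``length_cM / 100`` and
  crossover positions are uniform, without interference.
* Mutation is a recurrent symmetric allele flip applied per transmitted
  gamete per locus.
* Map distance is in cM; where a physical distance is wanted the
  1 cM = 1 Mbp convention applies.

Implementation note: haplotypes are stored bit-packed (``np.packbits``
layout, one bit per locus) because whole-genome meiosis over thousands of
generations is memory-bandwidth bound.  Use :meth:`Cohort.dosages` /
:meth:`Cohort.haplotype_bits` for unpacked views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "MALE",
    "FEMALE",
    "GenomeMap",
    "HaplotypePool",
    "Cohort",
    "demography_trajectory",
    "simulate_historical",
    "make_gametes",
    "reproduce",
    "form_breeds",
    "qc_markers",
    "ld_r2_decay",
    "breed_relationship",
    "pack_haplotypes",
    "unpack_haplotypes",
]

MALE = np.int8(0)
FEMALE = np.int8(1)


# ---------------------------------------------------------------------------
# genome map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeMap:
    """Positions and roles of all simulated loci.

    Loci are stored sorted by (chromosome, position); ``is_qtl`` marks
    QTL, all other loci are markers.
    """

    chrom_length_cM: np.ndarray  # (n_chrom,)
    pos_cM: np.ndarray  # (n_loci,) sorted within chromosome
    chrom: np.ndarray  # (n_loci,) chromosome index per locus
    is_qtl: np.ndarray  # (n_loci,) bool

    def __post_init__(self):
        if self.pos_cM.size == 0:
            raise ValueError("invalid genome: map contains no loci")
        for c in range(self.n_chromosomes):
            sl = slice(self.chrom_start[c], self.chrom_start[c + 1])
            p = self.pos_cM[sl]
            if p.size and (p.min() < 0 or p.max() > self.chrom_length_cM[c]):
                raise ValueError("locus position outside its chromosome")
            if np.any(np.diff(p) < 0):
                raise ValueError("locus positions not sorted within chromosome")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_length_cM)

    @property
    def n_loci(self) -> int:
        return self.pos_cM.size

    @property
    def n_bytes(self) -> int:
        return (self.n_loci + 7) // 8

    @property
    def chrom_start(self) -> np.ndarray:
        return np.searchsorted(self.chrom, np.arange(self.n_chromosomes + 1))

    @property
    def marker_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @classmethod
    def random(
        cls,
        n_chromosomes: int,
        chrom_cM: float,
        n_markers: int,
        n_qtl: int,
        rng: np.random.Generator,
    ) -> "GenomeMap":
        """Scatter markers and QTL uniformly at random along the genome."""
        n = n_markers + n_qtl
        chrom = rng.integers(0, n_chromosomes, size=n)
        pos = rng.uniform(0.0, chrom_cM, size=n)
        order = np.lexsort((pos, chrom))
        chrom, pos = chrom[order], pos[order]
        is_qtl = np.zeros(n, dtype=bool)
        is_qtl[rng.choice(n, size=n_qtl, replace=False)] = True
        return cls(
            chrom_length_cM=np.full(n_chromosomes, float(chrom_cM)),
            pos_cM=pos,
            chrom=chrom,
            is_qtl=is_qtl,
        )


# ---------------------------------------------------------------------------
# packed haplotype helpers
# ---------------------------------------------------------------------------


def pack_haplotypes(bits: np.ndarray) -> np.ndarray:
    """Pack a (..., n_loci) 0/1 array into packbits layout."""
    return np.packbits(bits.astype(np.uint8), axis=-1)


def unpack_haplotypes(packed: np.ndarray, n_loci: int) -> np.ndarray:
    """Inverse of :func:`pack_haplotypes`."""
    return np.unpackbits(packed, axis=-1, count=n_loci)


def _dosages_from_packed(packed: np.ndarray, n_loci: int,
                         loci: np.ndarray | slice | None = None) -> np.ndarray:
    bits = np.unpackbits(packed, axis=-1, count=n_loci)
    z = bits.sum(axis=-2, dtype=np.uint8)
    return z if loci is None else z[..., loci]


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePool:
    """A generation of haplotypes with no pedigree structure."""

    generation: int
    packed: np.ndarray  # (n, 2, n_bytes) uint8, bit-packed haplotypes
    sex: np.ndarray  # (n,) int8 MALE/FEMALE
    n_loci: int
    size_trajectory: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n(self) -> int:
        return self.packed.shape[0]

    def haplotype_bits(self) -> np.ndarray:
        return unpack_haplotypes(self.packed, self.n_loci)

    def dosages(self, loci: np.ndarray | slice | None = None) -> np.ndarray:
        return _dosages_from_packed(self.packed, self.n_loci, loci)

    def allele_freqs(self) -> np.ndarray:
        return self.haplotype_bits().mean(axis=(0, 1))


@dataclass
class Cohort:
    """A generation of pedigreed individuals of one population.

    ``sire``/``dam`` hold ids (-1 for unknown/founder parents) referencing
    strictly earlier generations.  Crossbred (CB) animals have a P1 sire
    and a P2 dam.
    """

    ids: np.ndarray  # (n,) int64
    sex: np.ndarray  # (n,) int8
    breed: str  # "P1" | "P2" | "CB"
    sire: np.ndarray  # (n,) int64
    dam: np.ndarray  # (n,) int64
    generation: int
    packed: np.ndarray  # (n, 2, n_bytes) uint8
    n_loci: int

    @property
    def n(self) -> int:
        return self.ids.size

    def haplotype_bits(self) -> np.ndarray:
        return unpack_haplotypes(self.packed, self.n_loci)

    def dosages(self, loci: np.ndarray | slice | None = None) -> np.ndarray:
        return _dosages_from_packed(self.packed, self.n_loci, loci)

    def allele_freqs(self, loci: np.ndarray | slice | None = None) -> np.ndarray:
        bits = self.haplotype_bits()
        if loci is not None:
            bits = bits[:, :, loci]
        return bits.mean(axis=(0, 1))

    @property
    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    @property
    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def subset(self, rows: np.ndarray) -> "Cohort":
        return Cohort(
            ids=self.ids[rows], sex=self.sex[rows], breed=self.breed,
            sire=self.sire[rows], dam=self.dam[rows],
            generation=self.generation, packed=self.packed[rows],
            n_loci=self.n_loci,
        )


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _copy_bits(src, dst, lo, hi):
    """Copy bit positions [lo, hi) between 1-D packed rows (MSB-first)."""
    if hi <= lo:
        return
    b0 = lo >> 3
    b1 = (hi - 1) >> 3
    m0 = 0xFF >> (lo & 7)
    m1 = (0xFF << (7 - ((hi - 1) & 7))) & 0xFF
    if b0 == b1:
        m = m0 & m1
        dst[b0] = (dst[b0] & (0xFF ^ m)) | (src[b0] & m)
    else:
        dst[b0] = (dst[b0] & (0xFF ^ m0)) | (src[b0] & m0)
        for b in range(b0 + 1, b1):
            dst[b] = src[b]
        dst[b1] = (dst[b1] & (0xFF ^ m1)) | (src[b1] & m1)


@njit(cache=True)
def _assemble_gametes(parent_packed, parent_idx, starts, xo_cuts, xo_offsets, chrom_start, out):
    """Build each gamete by copying parental haplotype segments between
    sorted crossover cut points (bit indices)."""
    n_g = parent_idx.shape[0]
    n_chrom = chrom_start.shape[0] - 1
    for g in range(n_g):
        p = parent_idx[g]
        for c in range(n_chrom):
            lo = chrom_start[c]
            hi = chrom_start[c + 1]
            h = starts[g, c]
            k0 = xo_offsets[g * n_chrom + c]
            k1 = xo_offsets[g * n_chrom + c + 1]
            prev = lo
            for k in range(k0, k1):
                cut = xo_cuts[k]
                if cut > prev:
                    _copy_bits(parent_packed[p, h], out[g], prev, cut)
                    prev = cut
                h = 1 - h
            _copy_bits(parent_packed[p, h], out[g], prev, hi)


def _gametes_from_cuts(
    parent_packed: np.ndarray,
    parent_idx: np.ndarray,
    starts: np.ndarray,
    cuts: np.ndarray,
    offsets: np.ndarray,
    chrom_start: np.ndarray,
    n_bytes: int,
) -> np.ndarray:
    """Deterministic gamete assembly given crossover cut points (testable
    separately from the random draws)."""
    out = np.zeros((parent_idx.size, n_bytes), dtype=np.uint8)
    _assemble_gametes(
        np.ascontiguousarray(parent_packed),
        parent_idx.astype(np.int64),
        starts.astype(np.int8),
        cuts.astype(np.int64),
        offsets.astype(np.int64),
        chrom_start.astype(np.int64),
        out,
    )
    return out


def make_gametes(
    packed: np.ndarray,
    parent_idx: np.ndarray,
    gmap: GenomeMap,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
    recombination: bool = True,
) -> np.ndarray:
    """One recombinant, mutated gamete (packed) per entry of ``parent_idx``."""
    n_g = parent_idx.size
    n_chrom = gmap.n_chromosomes
    chrom_start = gmap.chrom_start.astype(np.int64)

    starts = rng.integers(0, 2, size=(n_g, n_chrom), dtype=np.int8)
    if recombination:
        counts = rng.poisson(gmap.chrom_length_cM / 100.0, size=(n_g, n_chrom))
    else:
        counts = np.zeros((n_g, n_chrom), dtype=np.int64)
    offsets = np.zeros(n_g * n_chrom + 1, dtype=np.int64)
    np.cumsum(counts.ravel(), out=offsets[1:])
    total = int(offsets[-1])

    cuts = np.empty(total, dtype=np.int64)
    if total:
        group_chrom = np.repeat(np.tile(np.arange(n_chrom), n_g), counts.ravel())
        xpos = rng.uniform(0.0, 1.0, size=total) * gmap.chrom_length_cM[group_chrom]
        for c in range(n_chrom):
            m = group_chrom == c
            sl = slice(chrom_start[c], chrom_start[c + 1])
            cuts[m] = chrom_start[c] + np.searchsorted(gmap.pos_cM[sl], xpos[m])
        group_id = np.repeat(np.arange(n_g * n_chrom), counts.ravel())
        order = np.lexsort((cuts, group_id))
        cuts = cuts[order]

    out = _gametes_from_cuts(packed, parent_idx, starts, cuts, offsets,
                             chrom_start, gmap.n_bytes)

    if mutation_rate > 0.0:
        n_mut = rng.binomial(n_g * gmap.n_loci, mutation_rate)
        if n_mut:
            g_i = rng.integers(0, n_g, size=n_mut)
            l_i = rng.integers(0, gmap.n_loci, size=n_mut)
            flat = g_i * gmap.n_bytes + (l_i >> 3)
            masks = (np.uint8(0x80) >> (l_i & 7).astype(np.uint8)).astype(np.uint8)
            np.bitwise_xor.at(out.reshape(-1), flat, masks)
    return out


def reproduce(
    packed: np.ndarray,
    sire_idx: np.ndarray,
    dam_idx: np.ndarray,
    gmap: GenomeMap,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
) -> np.ndarray:
    """Offspring packed haplotypes (n, 2, n_bytes); paternal gamete first."""
    pat = make_gametes(packed, sire_idx, gmap, rng, mutation_rate)
    mat = make_gametes(packed, dam_idx, gmap, rng, mutation_rate)
    return np.stack([pat, mat], axis=1)


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    sex = np.empty(n, dtype=np.int8)
    half = n // 2
    sex[:half] = MALE
    sex[half:] = FEMALE
    return rng.permutation(sex)


# ---------------------------------------------------------------------------
# historical population
# ---------------------------------------------------------------------------


def demography_trajectory(
    n_constant: int = 1000,
    n_decline: int = 1000,
    n_expand: int = 10,
    size_start: int = 2500,
    size_bottleneck: int = 300,
    size_end: int | None = None,
) -> np.ndarray:
    """Population-size trajectory: constant phase, linear bottleneck,
    linear re-expansion.  Entry 0 is the initial generation."""
    size_end = size_start if size_end is None else size_end
    const = np.full(n_constant + 1, size_start)
    decline = np.linspace(size_start, size_bottleneck, n_decline + 1)[1:]
    expand = np.linspace(size_bottleneck, size_end, n_expand + 1)[1:]
    return np.concatenate([const, decline, expand]).round().astype(int)


def simulate_historical(
    gmap: GenomeMap,
    trajectory: np.ndarray,
    mutation_rate: float = 2.5e-4,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> HaplotypePool:
    """Random-mating historical population under drift and mutation.

    Starts from allele frequency 0.5 at every locus (haplotype bits drawn
    i.i.d. Bernoulli(0.5)) and advances one generation per trajectory
    entry beyond the first.  Each offspring draws a random sire and dam
    with replacement; sexes are assigned to keep counts balanced.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    trajectory = np.asarray(trajectory, dtype=int)
    if trajectory.size == 0 or np.any(trajectory < 2):
        raise ValueError("invalid demography: every generation needs at least 2 individuals")

    n0 = int(trajectory[0])
    packed = rng.integers(0, 256, size=(n0, 2, gmap.n_bytes), dtype=np.uint8)
    _zero_pad_bits(packed, gmap.n_loci)
    sex = _balanced_sexes(n0, rng)

    for t in range(1, trajectory.size):
        n_t = int(trajectory[t])
        males = np.flatnonzero(sex == MALE)
        females = np.flatnonzero(sex == FEMALE)
        sires = males[rng.integers(0, males.size, size=n_t)]
        dams = females[rng.integers(0, females.size, size=n_t)]
        packed = reproduce(packed, sires, dams, gmap, rng, mutation_rate)
        sex = _balanced_sexes(n_t, rng)

    return HaplotypePool(
        generation=trajectory.size - 1,
        packed=packed,
        sex=sex,
        n_loci=gmap.n_loci,
        size_trajectory=trajectory,
    )


def _zero_pad_bits(packed: np.ndarray, n_loci: int) -> None:
    """Clear the unused trailing bits of the last byte in place."""
    rem = n_loci % 8
    if rem:
        packed[..., -1] &= np.uint8((0xFF << (8 - rem)) & 0xFF)


# ---------------------------------------------------------------------------
# breed formation
# ---------------------------------------------------------------------------


def _deal_mates(
    top_m: np.ndarray,
    top_f: np.ndarray,
    ids: np.ndarray,
    sire: np.ndarray,
    dam: np.ndarray,
    rng: np.random.Generator,
    max_fix_rounds: int = 200,
) -> np.ndarray:
    """Assign each selected female a selected male (quotas balanced to
    within one female), avoiding full-sib and parent-offspring pairs.
    Arguments are candidate row indices plus the cohort's id/sire/dam
    arrays; returns the male row index mated to each entry of ``top_f``."""
    reps = -(-top_f.size // top_m.size)
    assigned = np.tile(top_m, reps)[: top_f.size]
    assigned = assigned[rng.permutation(assigned.size)]

    def forbidden(mi: int, fi: int) -> bool:
        full_sib = sire[mi] >= 0 and sire[mi] == sire[fi] and dam[mi] == dam[fi]
        parent_off = ids[mi] == sire[fi] or ids[fi] == dam[mi]
        return bool(full_sib or parent_off)

    for _ in range(max_fix_rounds):
        bad = [j for j in range(top_f.size) if forbidden(assigned[j], top_f[j])]
        if not bad:
            return assigned
        for j in bad:
            k = int(rng.integers(0, top_f.size))
            assigned[j], assigned[k] = assigned[k], assigned[j]
    raise RuntimeError("mating restriction could not be satisfied: too few unrelated candidates")


def form_breeds(
    pool: HaplotypePool,
    gmap: GenomeMap,
    rng: np.random.Generator,
    n_generations: int = 20,
    base_males: int = 80,
    base_females: int = 400,
    sel_males: int = 40,
    sel_females: int = 400,
    litter_size: int = 10,
    dummy_h2: float = 0.5,
    mutation_rate: float = 2.5e-4,
) -> tuple[Cohort, Cohort]:
    """Form two breeds by divergent phenotypic selection.

    Two disjoint base samples (``base_males`` M + ``base_females`` F) are
    drawn from the historical pool, then truncation-selected for
    ``n_generations`` on a transient additive dummy trait (h2 = 0.5,
    discarded afterwards): P1 upward, P2 downward.  Each generation
    ``sel_males`` males and ``sel_females`` females are kept; each male is
    mated to ``sel_females / sel_males`` females, litters of
    ``litter_size`` with equal sexes, avoiding full-sib and
    parent-offspring pairs.
    """
    males = np.flatnonzero(pool.sex == MALE)
    females = np.flatnonzero(pool.sex == FEMALE)
    if males.size < 2 * base_males or females.size < 2 * base_females:
        raise ValueError("historical pool too small to sample two breed bases")

    m_pick = rng.choice(males, size=2 * base_males, replace=False)
    f_pick = rng.choice(females, size=2 * base_females, replace=False)

    # transient dummy trait: additive effects at the QTL, rescaled to h2
    qtl = gmap.qtl_index
    effects = rng.standard_normal(qtl.size)
    base_rows = np.concatenate([m_pick, f_pick])
    z = _dosages_from_packed(pool.packed[base_rows], gmap.n_loci, qtl).astype(np.float64)
    sd_g = (z @ effects).std()
    if sd_g == 0:
        sd_g = 1.0
    sigma_e = sd_g * np.sqrt((1.0 - dummy_h2) / dummy_h2)

    out: list[Cohort] = []
    for b, (direction, tag) in enumerate([(1.0, "P1"), (-1.0, "P2")]):
        rows = np.concatenate(
            [m_pick[b * base_males : (b + 1) * base_males],
             f_pick[b * base_females : (b + 1) * base_females]]
        )
        packed = pool.packed[rows].copy()
        sex = np.concatenate(
            [np.full(base_males, MALE), np.full(base_females, FEMALE)]
        ).astype(np.int8)
        ids = np.arange(rows.size, dtype=np.int64)
        sire = np.full(rows.size, -1, dtype=np.int64)
        dam = np.full(rows.size, -1, dtype=np.int64)
        next_id = rows.size

        for _gen in range(1, n_generations + 1):
            zq = _dosages_from_packed(packed, gmap.n_loci, qtl).astype(np.float64)
            pheno = zq @ effects + rng.normal(0.0, sigma_e, size=packed.shape[0])
            score = direction * pheno
            cand_m = np.flatnonzero(sex == MALE)
            cand_f = np.flatnonzero(sex == FEMALE)
            n_m = min(sel_males, cand_m.size)  # base generation may offer fewer males
            if n_m < 1 or cand_f.size < sel_females:
                raise RuntimeError("insufficient candidates during breed formation")
            top_m = cand_m[np.argsort(-score[cand_m], kind="stable")[:n_m]]
            top_f = cand_f[np.argsort(-score[cand_f], kind="stable")[:sel_females]]

            mate_male = _deal_mates(top_m, top_f, ids, sire, dam, rng)

            sires_rep = np.repeat(mate_male, litter_size)
            dams_rep = np.repeat(top_f, litter_size)
            new_sire = ids[sires_rep]
            new_dam = ids[dams_rep]
            packed = reproduce(packed, sires_rep, dams_rep, gmap, rng, mutation_rate)
            n_off = sires_rep.size
            half = litter_size // 2
            sex = np.tile(
                np.concatenate([np.full(half, MALE), np.full(litter_size - half, FEMALE)]),
                top_f.size,
            ).astype(np.int8)
            ids = np.arange(next_id, next_id + n_off, dtype=np.int64)
            next_id += n_off
            sire, dam = new_sire, new_dam

        out.append(
            Cohort(ids=ids, sex=sex, breed=tag, sire=sire, dam=dam,
                   generation=n_generations, packed=packed, n_loci=gmap.n_loci)
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# genome statistics
# ---------------------------------------------------------------------------


def qc_markers(
    p1: Cohort,
    p2: Cohort,
    gmap: GenomeMap,
    maf_min: float = 0.05,
    hwe_t: float = 0.15,
) -> np.ndarray:
    """Marker quality control applied independently in both breeds.

    A marker is kept iff, in *each* breed, its minor allele frequency is
    at least ``maf_min`` and the absolute deviation of the observed
    heterozygote frequency from the Hardy-Weinberg expectation 2pq is at
    most ``hwe_t``.  QTL are never filtered.  Returns a boolean keep-mask
    over ``gmap.marker_index``.
    """
    markers = gmap.marker_index
    keep = np.ones(markers.size, dtype=bool)
    for cohort in (p1, p2):
        z = cohort.dosages(markers)
        p = z.mean(axis=0, dtype=np.float64) / 2.0
        maf = np.minimum(p, 1.0 - p)
        het_obs = (z == 1).mean(axis=0)
        het_exp = 2.0 * p * (1.0 - p)
        keep &= (maf >= maf_min) & (np.abs(het_obs - het_exp) <= hwe_t)
    if not keep.any():
        raise RuntimeError("marker QC removed every marker")
    return keep


def ld_r2_decay(
    dosages: np.ndarray,
    pos_cM: np.ndarray,
    chrom: np.ndarray,
    bin_edges: np.ndarray,
) -> "pd.DataFrame":
    """Mean squared dosage correlation (r2) of marker pairs by distance bin.

    Only intra-chromosome pairs up to ``bin_edges[-1]`` cM apart enter the
    averages; pairs involving a monomorphic marker are excluded.  Under
    the 1 cM = 1 Mbp convention bins can be read as physical distances.
    """
    import pandas as pd

    bin_edges = np.asarray(bin_edges, dtype=float)
    max_dist = bin_edges[-1]
    n = dosages.shape[0]
    X = dosages.astype(np.float64)
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Xn = np.zeros_like(X)
    Xn[:, ok] = X[:, ok] / sd[ok] / np.sqrt(n)

    sums = np.zeros(bin_edges.size - 1)
    counts = np.zeros(bin_edges.size - 1, dtype=np.int64)
    for c in np.unique(chrom):
        ci = np.flatnonzero(chrom == c)
        if ci.size < 2:
            continue
        p = pos_cM[ci]
        M = Xn[:, ci]
        good = ok[ci]
        lag = 1
        while lag < ci.size:
            d = p[lag:] - p[:-lag]
            within = d <= max_dist
            if not within.any():
                break
            r = (M[:, lag:] * M[:, :-lag]).sum(axis=0)
            valid = within & good[lag:] & good[:-lag]
            if valid.any():
                b = np.digitize(d[valid], bin_edges) - 1
                inside = (b >= 0) & (b < bin_edges.size - 1)
                np.add.at(sums, b[inside], (r[valid] ** 2)[inside])
                np.add.at(counts, b[inside], 1)
            lag += 1
    mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"dist_lo_cM": bin_edges[:-1], "dist_hi_cM": bin_edges[1:],
         "n_pairs": counts, "mean_r2": mean_r2}
    )


def breed_relationship(freqs_p1: np.ndarray, freqs_p2: np.ndarray) -> float:
    """Between-breed relationship: 8 x sample covariance (n-1 denominator)
    of the two breeds' allele-frequency vectors."""
    freqs_p1 = np.asarray(freqs_p1, dtype=np.float64)
    freqs_p2 = np.asarray(freqs_p2, dtype=np.float64)
    if freqs_p1.size != freqs_p2.size:
        raise ValueError("frequency vectors differ in length")
    if freqs_p1.size < 2:
        raise ValueError("covariance undefined for fewer than 2 loci")
    return float(8.0 * np.cov(freqs_p1, freqs_p2, ddof=1)[0, 1])
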