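"""Multi-generation two-way crossbreeding scheme.

The scheme mirrors a terminal pig cross: a sire breed (P1) and a dam
breed (P2) are each selected within-breed every generation (12 males and
204 females out of 2,448 candidates at study scale), the selected
parents are mated at random within breed (each sire to 17 dams, litters
of 12 with 10 females), and the commercial crossbreds (CB) are produced
by mating the selected P1 males to the *second-best* 204 P2 females —
the best 204 are reserved for the P2 nucleus.

Scenarios (selection criterion / CB mating rule):

========  ==================  =========================================
scenario  selection           creation of crossbreds
========  ==================  =========================================
S1        EBVP (GBLUP)        random mating
S2        EBVP (GBLUP)        minimize expected future inbreeding (EFI)
S3        EBVC (trivariate)   random mating
S4        EBVC (trivariate)   maximize expected total genetic value
S4star    EBVC (trivariate)   as S4 but scoring matings with the *true*
                              QTL effects and genotypes (upper bound)
========  ==================  =========================================

Information flow: candidates are selected at birth, before any own
record.  A female born in wave g delivers her record one cycle later, so
the evaluation of wave-g candidates uses purebred female records of
waves <= g-1 and crossbred records of waves <= g-2 (the commercial tier
reports with an extra lag).  CB cohort g is born together with purebred
wave g+1 and shares its P1 sires.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import genome as gn
from . import mating as mt
from . import trait as tr
from ._rng import spawn_rng
from .config import ScalePreset, ScenarioConfig

__all__ = [
    "Foundation",
    "SchemeResult",
    "prepare_foundation",
    "run_scenario",
    "run_replicates",
    "compute_rpc",
    "mean_abs_freq_difference",
]


@dataclass
class Foundation:
    """Everything upstream of the breeding scheme: genome, the two breed
    cohorts at the end of breed formation, and the QC-passed markers."""

    gmap: gn.GenomeMap
    p1: gn.Cohort
    p2: gn.Cohort
    qc_keep: np.ndarray  # bool over gmap.marker_index
    replicate: int = 0

    @property
    def marker_loci(self) -> np.ndarray:
        return self.gmap.marker_index[self.qc_keep]


def prepare_foundation(scale: ScalePreset, master_seed: int, replicate: int = 0) -> Foundation:
    """Historical population, breed formation and marker QC for one
    replicate.  Reusable across scenarios sharing the master seed."""
    gmap = gn.GenomeMap.random(
        scale.n_chrom, scale.chrom_cM, scale.n_markers, scale.n_qtl,
        spawn_rng(master_seed, "genome", replicate),
    )
    traj = gn.demography_trajectory(
        n_constant=scale.hist_constant, n_decline=scale.hist_decline,
        n_expand=scale.hist_expand, size_start=scale.hist_size,
        size_bottleneck=scale.hist_bottleneck,
    )
    pool = gn.simulate_historical(
        gmap, traj, scale.mutation_rate,
        rng=spawn_rng(master_seed, "historical", replicate),
    )
    p1, p2 = gn.form_breeds(
        pool, gmap, spawn_rng(master_seed, "breed-formation", replicate),
        n_generations=scale.bf_generations,
        base_males=scale.bf_base_males, base_females=scale.bf_base_females,
        sel_males=scale.bf_sel_males, sel_females=scale.bf_sel_females,
        litter_size=scale.bf_litter, dummy_h2=scale.bf_dummy_h2,
        mutation_rate=scale.mutation_rate,
    )
    keep = gn.qc_markers(p1, p2, gmap, scale.maf_min, scale.hwe_t)
    return Foundation(gmap=gmap, p1=p1, p2=p2, qc_keep=keep, replicate=replicate)


@dataclass
class SchemeResult:
    """Per-generation metrics plus run bookkeeping."""

    config: ScenarioConfig
    metrics: pd.DataFrame
    founder_rpc: float
    heterosis_first: float
    heterosis_last: float
    plan_log: pd.DataFrame
    case: tr.VarianceCase
    arch: tr.TraitArchitecture | None = None


def compute_rpc(
    cohort: gn.Cohort,
    arch: tr.TraitArchitecture,
    own_freqs: np.ndarray,
    opposite_freqs: np.ndarray,
) -> float:
    """Purebred-crossbred genetic correlation cor(TBVP, TBVC) of one
    purebred cohort; NaN when either value vector is constant."""
    tbvp = tr.tbv_purebred(cohort, arch, current_freqs=own_freqs)
    tbvc = tr.tbv_crossbred(cohort, arch, opposite_freqs=opposite_freqs, own_freqs=own_freqs)
    if np.std(tbvp) == 0 or np.std(tbvc) == 0:
        return float("nan")
    return float(np.corrcoef(tbvp, tbvc)[0, 1])


def mean_abs_freq_difference(freqs_p1: np.ndarray, freqs_p2: np.ndarray) -> float:
    """Mean absolute between-breed allele-frequency difference."""
    return float(np.mean(np.abs(np.asarray(freqs_p1) - np.asarray(freqs_p2))))


# ---------------------------------------------------------------------------
# internal machinery
# ---------------------------------------------------------------------------


class _Records:
    """Cumulative phenotype records of one population."""

    def __init__(self):
        self.wave: list[int] = []
        self.y: list[np.ndarray] = []
        self.fg: list[np.ndarray] = []
        self.dosages: list[np.ndarray] = []

    def add(self, wave: int, y: np.ndarray, fg: np.ndarray, dosages: np.ndarray):
        self.wave.append(wave)
        self.y.append(y)
        self.fg.append(fg)
        self.dosages.append(dosages)

    def upto(self, wave_max: int) -> ev.PopRecords | None:
        sel = [i for i, w in enumerate(self.wave) if w <= wave_max]
        if not sel:
            return None
        return ev.PopRecords(
            y=np.concatenate([self.y[i] for i in sel]),
            fg=np.concatenate([self.fg[i] for i in sel]),
            dosages=np.vstack([self.dosages[i] for i in sel]),
        )


class _Scheme:
    def __init__(self, config: ScenarioConfig, foundation: Foundation):
        self.cfg = config
        self.scale = config.scale
        self.fnd = foundation
        self.gmap = foundation.gmap
        self.markers = foundation.marker_loci
        self._ids = itertools.count(1_000_000)
        self.plan_rows: list[dict] = []
        self.b_hat_rows: dict[int, dict] = {}

    # -- helpers ----------------------------------------------------------

    def _rng(self, label: str, index: int = 0) -> np.random.Generator:
        return spawn_rng(self.cfg.seed, label, index * 1000 + self.fnd.replicate)

    def _new_ids(self, n: int) -> np.ndarray:
        return np.fromiter(itertools.islice(self._ids, n), dtype=np.int64, count=n)

    def _offspring(
        self, sire_cohort, dam_cohort, sire_rows, dam_rows, breed, generation,
        litter_size, females_per_litter, rng,
    ) -> gn.Cohort:
        """Expand mating pairs into litters with a fixed sex split."""
        if breed == "CB":
            packed = np.stack(
                [
                    gn.make_gametes(sire_cohort.packed, np.repeat(sire_rows, litter_size),
                                    self.gmap, rng, self.scale.mutation_rate),
                    gn.make_gametes(dam_cohort.packed, np.repeat(dam_rows, litter_size),
                                    self.gmap, rng, self.scale.mutation_rate),
                ],
                axis=1,
            )
        else:
            packed = gn.reproduce(
                sire_cohort.packed, np.repeat(sire_rows, litter_size),
                np.repeat(dam_rows, litter_size), self.gmap, rng,
                self.scale.mutation_rate,
            )
        n_litters = sire_rows.size
        n_off = n_litters * litter_size
        n_m = litter_size - females_per_litter
        sex = np.tile(
            np.concatenate([np.full(n_m, gn.MALE), np.full(females_per_litter, gn.FEMALE)]),
            n_litters,
        ).astype(np.int8)
        return gn.Cohort(
            ids=self._new_ids(n_off),
            sex=sex,
            breed=breed,
            sire=sire_cohort.ids[np.repeat(sire_rows, litter_size)],
            dam=dam_cohort.ids[np.repeat(dam_rows, litter_size)],
            generation=generation,
            packed=packed,
            n_loci=self.gmap.n_loci,
        )

    def _phenotype(self, cohort: gn.Cohort, wave: int):
        t = {"P1": 0, "P2": 1, "CB": 2}[cohort.breed]
        zq = cohort.dosages(self.arch.qtl_loci).astype(np.float64)
        g = tr.genotypic_value(zq, self.arch.a[t], self.arch.d[t])
        females, y = tr.phenotype(
            g, cohort.sex, float(self.case.sigma_e[t]), self._rng_ph
        )
        zm = cohort.dosages(self.markers)
        self.records[cohort.breed].add(
            wave, y, tr.genomic_inbreeding(zm[females]), zm[females]
        )

    # -- main loop --------------------------------------------------------

    def run(self) -> SchemeResult:
        cfg, scale = self.cfg, self.scale

        # founders: 12 M + 204 F sampled uniformly from each breed cohort
        rngf = self._rng("founders")
        founders = {}
        for cohort in (self.fnd.p1, self.fnd.p2):
            males = rngf.choice(cohort.males, size=scale.n_males, replace=False)
            females = rngf.choice(cohort.females, size=scale.n_females, replace=False)
            rows = np.concatenate([np.sort(males), np.sort(females)])
            founders[cohort.breed] = cohort.subset(rows)
            founders[cohort.breed].generation = 0

        # trait architecture, calibrated at founder frequencies
        qtl = self.gmap.qtl_index
        fr = {b: founders[b].allele_freqs(qtl) for b in ("P1", "P2")}
        seg = ((fr["P1"] > 0) & (fr["P1"] < 1)) | ((fr["P2"] > 0) & (fr["P2"] < 1))
        case = tr.VarianceCase.preset(cfg.case, r_qtl=cfg.r_qtl)
        arch = tr.sample_qtl_effects(
            case, scale.n_trait_qtl, qtl[seg], self._rng("effects")
        )
        qsub = np.searchsorted(qtl, arch.qtl_loci)
        self.arch, self.case = tr.calibrate_variances(
            arch, case, fr["P1"][qsub], fr["P2"][qsub]
        )

        self.records = {"P1": _Records(), "P2": _Records(), "CB": _Records()}
        self._rng_ph = self._rng("phenotypes")
        pb = {"P1": [founders["P1"]], "P2": [founders["P2"]]}
        cb: list[gn.Cohort] = []
        for b in ("P1", "P2"):
            self._phenotype(founders[b], 0)

        for g in range(cfg.n_generations):
            fit = None
            if g == 0:
                sel = {
                    b: (founders[b].males, founders[b].females, founders[b].females)
                    for b in ("P1", "P2")
                }
            elif self.cfg.random_selection:
                rng_sel = self._rng("random-selection", g)
                sel = {}
                for b in ("P1", "P2"):
                    cand = pb[b][g]
                    sel[b] = mt.select_candidates(
                        rng_sel.random(cand.n), cand.sex,
                        scale.n_males, scale.n_females,
                        second_tranche=(b == "P2"),
                    )
            else:
                fit, scores = self._evaluate(pb, g)
                sel = {}
                for b in ("P1", "P2"):
                    cand = pb[b][g]
                    sel[b] = mt.select_candidates(
                        scores[b], cand.sex, scale.n_males, scale.n_females,
                        second_tranche=(b == "P2"),
                    )

            # purebred next generation: balanced random within-breed mating
            for b in ("P1", "P2"):
                cand = pb[b][g]
                males, females, _ = sel[b]
                plan = mt.random_mating_plan(
                    males.size, females.size, scale.quota, self._rng(f"pb-plan-{b}", g)
                )
                pb[b].append(
                    self._offspring(
                        cand, cand, males[plan.sires], females[plan.dams],
                        b, g + 1, scale.litter_size, scale.females_per_litter,
                        self._rng(f"pb-reproduce-{b}", g),
                    )
                )
                self._phenotype(pb[b][g + 1], g + 1)

            # crossbred cohort g: selected P1 males x P2 second tranche
            sire_cohort = pb["P1"][g]
            dam_cohort = pb["P2"][g]
            sires = sel["P1"][0]
            dams = sel["P2"][2]
            plan = self._cb_plan(g, fit, sire_cohort, dam_cohort, sires, dams)
            cb.append(
                self._offspring(
                    sire_cohort, dam_cohort, sires[plan.sires], dams[plan.dams],
                    "CB", g, scale.litter_size, scale.females_per_litter,
                    self._rng("cb-reproduce", g),
                )
            )
            self._phenotype(cb[g], g)

        self.pb, self.cb = pb, cb  # retained for inspection
        return self._collect(pb, cb)

    # -- evaluation per scenario ------------------------------------------

    def _evaluate(self, pb, g):
        """Fit the scenario's evaluation model and score the wave-g
        candidates of both breeds.

        Training: purebred female records of waves <= g-1 and crossbred
        records of waves <= g-2 (commercial records lag one extra cycle).
        """
        cfg, case = self.cfg, self.case
        rec = {b: self.records[b].upto(g - 1) for b in ("P1", "P2")}
        rec["CB"] = self.records["CB"].upto(g - 2)
        cand_z = {b: pb[b][g].dosages(self.markers) for b in ("P1", "P2")}
        cand_freq = {b: cand_z[b].mean(axis=0, dtype=np.float64) / 2.0 for b in ("P1", "P2")}

        scores: dict[str, np.ndarray] = {}
        b_hat: dict[str, float] = {}
        if cfg.uses_crossbred_data:
            freqs = {}
            for pop in ("P1", "P2", "CB"):
                r = rec[pop]
                if r is not None and r.n > 0:
                    freqs[pop] = r.dosages.mean(axis=0, dtype=np.float64) / 2.0
                elif pop == "CB":
                    freqs[pop] = 0.5 * (cand_freq["P1"] + cand_freq["P2"])
                else:
                    freqs[pop] = cand_freq[pop]
            fit = ev.trivariate_snpblup_fit(
                rec, case.sigma_u, case.sigma_v, case.sigma_e, cfg.r_qtl, freqs,
                dense_limit=self.scale.dense_limit,
            )
            for b, opp in (("P1", "P2"), ("P2", "P1")):
                scores[b] = ev.ebv_crossbred(cand_z[b], fit, cand_freq[b], cand_freq[opp])
            b_hat = dict(fit.b_hat)
        else:
            fit = None
            for t, b in enumerate(("P1", "P2")):
                gf = ev.gblup_fit(
                    rec[b], cand_z[b], float(case.sigma_u[t]), float(case.sigma_e[t])
                )
                scores[b] = ev.ebv_purebred(gf)
                b_hat[b] = gf.b_hat["pop"]
        self.b_hat_rows[g] = b_hat
        return fit, scores

    def _cb_plan(self, g, fit, sire_cohort, dam_cohort, sires, dams) -> mt.MatingPlan:
        scale, cfg = self.scale, self.cfg
        rule = cfg.cb_mating
        if g == 0 or (rule == "max_ETGV" and fit is None):
            rule = "random"
        if rule == "random":
            plan = mt.random_mating_plan(
                sires.size, dams.size, scale.quota, self._rng("cb-plan", g)
            )
            score_mean = float("nan")
        elif rule == "min_EFI":
            zs = sire_cohort.dosages(self.markers)[sires].astype(np.float64)
            zd = dam_cohort.dosages(self.markers)[dams].astype(np.float64)
            S = mt.efi_matrix(zs, zd)
            plan = mt.optimize_matings(S, "min", scale.quota)
            score_mean = plan.objective_value / plan.pairs.shape[0]
        else:
            if rule == "max_ETGV_true":
                loci = self.arch.qtl_loci
                a_hat, d_hat = self.arch.a[2], self.arch.d[2]
            else:
                loci = self.markers
                a_hat, d_hat = fit.a_hat[2], fit.d_hat[2]
            zs = sire_cohort.dosages(loci)[sires].astype(np.float64)
            zd = dam_cohort.dosages(loci)[dams].astype(np.float64)
            S = mt.etgv_matrix(zs, zd, a_hat, d_hat)
            plan = mt.optimize_matings(S, "max", scale.quota)
            score_mean = plan.objective_value / plan.pairs.shape[0]
        self.plan_rows.append(
            {"generation": g, "rule": rule, "mean_pair_score": score_mean}
        )
        return plan

    # -- metrics -----------------------------------------------------------

    def _collect(self, pb, cb) -> SchemeResult:
        cfg = self.cfg
        arch, case = self.arch, self.case
        qtl_loci = arch.qtl_loci
        rows = []
        base = {}
        for w in range(cfg.n_generations + 1):
            row = {"generation": w}
            f = {b: pb[b][w].allele_freqs(qtl_loci) for b in ("P1", "P2")}
            rpcs = []
            for b, opp in (("P1", "P2"), ("P2", "P1")):
                cohort = pb[b][w]
                tbvp = tr.tbv_purebred(cohort, arch, current_freqs=f[b])
                row[f"tbvp_{b}"] = float(tbvp.mean())
                rpc = compute_rpc(cohort, arch, f[b], f[opp])
                row[f"rpc_{b}"] = rpc
                rpcs.append(rpc)
                row[f"fg_{b}"] = float(
                    tr.genomic_inbreeding(cohort.dosages(self.markers)).mean()
                )
            row["rpc_mean"] = float(np.nanmean(rpcs))
            row["heterosis"] = tr.heterosis_expected(arch.d[2], f["P1"], f["P2"])
            row["dp_abs_mean"] = mean_abs_freq_difference(f["P1"], f["P2"])
            if w < len(cb):
                row["cb_ttgv"] = float(tr.ttgv(cb[w], arch).mean())
                row["fg_CB"] = float(
                    tr.genomic_inbreeding(cb[w].dosages(self.markers)).mean()
                )
            else:
                row["cb_ttgv"] = np.nan
                row["fg_CB"] = np.nan
            rows.append(row)
        df = pd.DataFrame(rows)
        for col in ("tbvp_P1", "tbvp_P2", "cb_ttgv"):
            df[col + "_rel"] = df[col] - df[col].iloc[0]
        for w, bh in self.b_hat_rows.items():
            for pop, val in bh.items():
                df.loc[df["generation"] == w, f"bhat_{pop}"] = val
        het = df["heterosis"].to_numpy()
        return SchemeResult(
            config=cfg,
            metrics=df,
            founder_rpc=float(df["rpc_mean"].iloc[0]),
            heterosis_first=float(het[0]),
            heterosis_last=float(het[len(cb) - 1]) if len(cb) else float("nan"),
            plan_log=pd.DataFrame(self.plan_rows),
            case=case,
            arch=arch,
        )


def run_scenario(config: ScenarioConfig, foundation: Foundation | None = None) -> SchemeResult:
    """Run one replicate of one scenario.

    A prepared :class:`Foundation` may be passed to share the historical
    population and breed formation across scenarios (they are
    deterministic given the master seed and replicate, so passing one is
    purely a time saver).
    """
    if foundation is None:
        foundation = prepare_foundation(config.scale, config.seed, replicate=0)
    return _Scheme(config, foundation).run()


def run_replicates(
    config: ScenarioConfig,
    n_replicates: int | None = None,
    foundations: list[Foundation] | None = None,
) -> tuple[pd.DataFrame, list[SchemeResult]]:
    """Independent replicates; returns (per-generation means with _sd
    columns, the individual results)."""
    n = config.replicates if n_replicates is None else n_replicates
    if n < 1:
        raise ValueError("need at least one replicate")
    results = []
    for rep in range(n):
        fnd = foundations[rep] if foundations else prepare_foundation(
            config.scale, config.seed, replicate=rep
        )
        results.append(_Scheme(config, fnd).run())
    num = [r.metrics.select_dtypes("number") for r in results]
    stacked = pd.concat(num, keys=range(n))
    mean = stacked.groupby(level=1).mean()
    sd = stacked.groupby(level=1).std(ddof=1 if n > 1 else 0)
    out = mean.copy()
    if n > 1:
        for col in sd.columns:
            if col != "generation":
                out[col + "_sd"] = sd[col]
    return out, results
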