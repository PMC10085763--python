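"""Rapid-cycle recurrent genomic selection engine.

Reproduces the study design end-to-end on simulated populations:

C0   train on replicated F4-line phenotypes; pick the best families by a
     rank-sum over mean yield, heritability and (optionally) prediction
     ability; pick the top lines per family as parents.
C1   intermate the parents via a structured crossing plan (within-family
     and between-family crosses, every family intercrossed >= 3 times);
     genotype the F1s from bulked sibling tissue; predict their GEBVs
     jointly with the (never-updated) training set; truncation-select.
C2+  repeat recombination from the selected F1s; an F1's "family" is its
     cross of origin.
End  advance a rank-band sample of F1s per cycle to inbred lines by
     selfing and measure realized gain in a simulated multi-year trial,
     alongside gain on simulation-truth breeding values.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from . import models as _models
from . import simpop as _simpop
from .evaluation import CVScheme, GainReport, cross_validate, cycle_means, realized_gain
from .genotypes import MarkerMatrix, filter_markers
from .kinship import (
    Pedigree,
    distance_summary_from_dosages,
    gaussian_kernels,
    genomic_matrix_from_dosages,
    pedigree_matrix,
)
from .models import ChainSettings, GEBVTable, rank_and_select
from .simpop import SimIndividual, TrainingPopConfig, meiosis

__all__ = [
    "SchemeConfig",
    "CrossPlan",
    "CyclePopulation",
    "SchemeResult",
    "PlanError",
    "select_families",
    "select_c0_parents",
    "make_cross_plan",
    "make_cycle_cross_plan",
    "bulk_f1_genotype",
    "run_cycle",
    "run_scheme",
]


class PlanError(ValueError):
    pass


@dataclasses.dataclass
class SchemeConfig:
    """All knobs of the recurrent scheme; defaults follow the study
    design (6 families x 10 parents, 36+110 C1 crosses, top 26/29
    selections, 32-35 lines advanced per cycle)."""

    training: TrainingPopConfig = dataclasses.field(default_factory=TrainingPopConfig)
    n_families_select: int = 6
    n_top_lines_per_family: int = 10
    crosses_within_per_family: int = 6
    crosses_between_per_pair: int = 10
    n_between_pairs: int = 11
    min_intercross_uses: int = 3
    n_cycles: int = 3
    n_f1_per_cycle: tuple = (136, 80, 110)
    n_select_per_cycle: tuple = (26, 29)
    cycle_crosses: tuple = ((19, 69), (19, 69))  # (within, between) for C2+, per plan
    bulk_plants: tuple = (3, 6)
    model_preset: str = "P+RKHS-KA"
    chain: ChainSettings = dataclasses.field(default_factory=ChainSettings)
    maf_threshold: float = 0.05
    family_criteria: tuple = ("mean_gy", "h2", "within_ability", "between_ability")
    cv_k_folds: int = 5
    cv_repeats: int = 2
    do_final_trial: bool = True
    n_advance_per_cycle: tuple = (32, 34, 35)
    advance_rank_band: int = 58
    selfing_to_line: int = 5  # F1 -> F6
    n_c0_checks: int = 17
    trial_years: tuple = (1, 2)
    trial_reps: int = 2
    trial_h2: float = 0.5


@dataclasses.dataclass
class CrossPlan:
    """List of ordered crosses (parent_a, parent_b, kind) with kind in
    {'within', 'between'}; no selfing pairs."""

    crosses: list[tuple[str, str, str]]

    @property
    def n_within(self) -> int:
        return sum(1 for *_, k in self.crosses if k == "within")

    @property
    def n_between(self) -> int:
        return sum(1 for *_, k in self.crosses if k == "between")

    def __len__(self) -> int:
        return len(self.crosses)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.crosses, columns=["parent_a", "parent_b", "kind"])


@dataclasses.dataclass
class CyclePopulation:
    label: str
    individuals: list[SimIndividual]
    gebvs: GEBVTable | None
    selected_ids: list[str]
    plan: CrossPlan | None
    training_gebv_mean: float | None = None

    def mean_tbv(self) -> float:
        return float(np.mean([i.true_breeding_value for i in self.individuals]))


@dataclasses.dataclass
class SchemeResult:
    cycles: list[CyclePopulation]
    gain_true: GainReport
    gain_phenotype: GainReport | None
    gebv_cycle_means: pd.DataFrame
    family_summary: pd.DataFrame
    trial_table: pd.DataFrame | None


# ---------------------------------------------------------------------------
# C0 selection


def select_families(summary: pd.DataFrame, n_select: int,
                    criteria=("mean_gy", "h2", "within_ability", "between_ability")
                    ) -> list[str]:
    """Composite rank-sum family selection: each criterion ranked
    higher-is-better, ranks summed, top ``n_select`` families chosen;
    ties broken by family id."""
    df = summary.copy()
    missing = [c for c in criteria if c not in df.columns]
    if missing:
        raise ValueError(f"summary lacks criteria columns {missing}")
    rank_sum = sum(df[c].rank(ascending=False, method="average") for c in criteria)
    df = df.assign(_rank_sum=rank_sum).sort_values(["_rank_sum", "family"])
    return list(df["family"].iloc[:n_select])


def select_c0_parents(blues: pd.DataFrame, families: list[str],
                      n_per_family: int) -> list[str]:
    """The n_per_family highest-BLUE lines within each chosen family.
    ``blues`` columns: line, family, value."""
    out = []
    for fam in families:
        sub = blues[blues["family"] == fam]
        if len(sub) < n_per_family:
            raise ValueError(f"family {fam} has fewer than {n_per_family} lines")
        top = sub.sort_values(["value", "line"], ascending=[False, True])
        out.extend(top["line"].iloc[:n_per_family])
    return out


# ---------------------------------------------------------------------------
# Crossing plans


def make_cross_plan(
    parents_by_family: dict[str, list[str]],
    rng: np.random.Generator,
    crosses_within_per_family: int = 6,
    crosses_between_per_pair: int = 10,
    n_between_pairs: int = 11,
    min_intercross_uses: int = 3,
    pair_scores: dict[tuple[str, str], float] | None = None,
) -> CrossPlan:
    """Structured C1-style plan: ``crosses_within_per_family`` random
    non-self pairs inside every family plus ``crosses_between_per_pair``
    crosses for each of ``n_between_pairs`` family pairs, chosen by
    ``pair_scores`` (e.g. between-family prediction ability) where given
    and constrained so every family joins >= ``min_intercross_uses``
    intercross pairs."""
    fams = sorted(parents_by_family)
    for f in fams:
        if crosses_within_per_family > 0 and len(parents_by_family[f]) < 2:
            raise PlanError(f"family {f} needs >= 2 parents for within-family crosses")
    all_pairs = list(itertools.combinations(fams, 2))
    if n_between_pairs > len(all_pairs):
        raise PlanError(
            f"requested {n_between_pairs} between-family pairs but only "
            f"{len(all_pairs)} exist"
        )
    if min_intercross_uses * len(fams) > 2 * n_between_pairs:
        raise PlanError(
            "infeasible constraint: each family in >= "
            f"{min_intercross_uses} pairs requires more than {n_between_pairs} pairs"
        )

    def score(p):
        if pair_scores is None:
            return 0.0
        return pair_scores.get(p, pair_scores.get((p[1], p[0]), 0.0))

    # greedy pair selection: always take the remaining pair covering the
    # largest unmet intercross deficit, breaking ties by score (higher
    # prediction ability between the families); when the floor is exactly
    # tight the greedy can corner itself, so restart with a reshuffle
    chosen: list[tuple[str, str]] = []
    for _attempt in range(100):
        remaining = list(all_pairs)
        rng.shuffle(remaining)
        uses = {f: 0 for f in fams}
        chosen = []
        for _ in range(n_between_pairs):
            def priority(p):
                deficit = sum(max(min_intercross_uses - uses[f], 0) for f in p)
                return (deficit, score(p))
            best = max(remaining, key=priority)
            remaining.remove(best)
            chosen.append(best)
            uses[best[0]] += 1
            uses[best[1]] += 1
        if all(uses[f] >= min_intercross_uses for f in fams):
            break
    else:
        short = [f for f in fams if uses[f] < min_intercross_uses]
        raise PlanError(
            f"cannot satisfy >= {min_intercross_uses} intercross uses for "
            f"families {short}"
        )

    crosses: list[tuple[str, str, str]] = []
    for f in fams:
        parents = parents_by_family[f]
        for _ in range(crosses_within_per_family):
            a, b = rng.choice(len(parents), size=2, replace=False)
            crosses.append((parents[a], parents[b], "within"))
    for a, b in chosen:
        pa, pb = parents_by_family[a], parents_by_family[b]
        for _ in range(crosses_between_per_pair):
            crosses.append((pa[rng.integers(len(pa))], pb[rng.integers(len(pb))],
                            "between"))
    return CrossPlan(crosses)


def make_cycle_cross_plan(
    parents_by_family: dict[str, list[str]],
    n_within: int,
    n_between: int,
    rng: np.random.Generator,
) -> CrossPlan:
    """Recombination plan for cycles past C1, where a parent's family is
    its cross of origin and most families hold a single selected F1:
    within-family crosses are drawn from families with >= 2 parents and
    any infeasible remainder is shifted to between-family crosses."""
    fams = sorted(parents_by_family)
    if sum(len(v) for v in parents_by_family.values()) < 2:
        raise PlanError("need at least 2 parents")
    multi = [f for f in fams if len(parents_by_family[f]) >= 2]
    crosses: list[tuple[str, str, str]] = []
    n_within_feasible = n_within if multi else 0
    for _ in range(n_within_feasible):
        f = multi[rng.integers(len(multi))]
        parents = parents_by_family[f]
        a, b = rng.choice(len(parents), size=2, replace=False)
        crosses.append((parents[a], parents[b], "within"))
    shifted = n_within - n_within_feasible
    if len(fams) < 2 and n_between + shifted > 0:
        raise PlanError("between-family crosses need >= 2 families")
    for _ in range(n_between + shifted):
        fa, fb = rng.choice(len(fams), size=2, replace=False)
        pa = parents_by_family[fams[fa]]
        pb = parents_by_family[fams[fb]]
        crosses.append((pa[rng.integers(len(pa))], pb[rng.integers(len(pb))],
                        "between"))
    return CrossPlan(crosses)


# ---------------------------------------------------------------------------
# F1 realization and bulk genotyping


def bulk_f1_genotype(offspring: list[SimIndividual], n_plants: int | None = None) -> np.ndarray:
    """Mean allele dosage over sampled sibling F1 plants — the marker
    profile of pooled (bulk) DNA.  Real-valued; equals the deterministic
    F1 dosage when both parents are fully inbred."""
    if not offspring:
        raise ValueError("no offspring supplied")
    if n_plants is None:
        n_plants = len(offspring)
    if not 1 <= n_plants <= len(offspring):
        raise ValueError("n_plants out of range")
    return np.mean([o.dosage for o in offspring[:n_plants]], axis=0).astype(float)


def _realize_f1s(plan: CrossPlan, parent_lookup: dict[str, SimIndividual],
                 n_total: int, bulk_range: tuple, founders, rng,
                 label: str):
    """Draw sibling counts per cross to hit the planted total, keep one
    primary plant per cross slot as the candidate and bulk all siblings."""
    n_crosses = len(plan)
    base = n_total // n_crosses
    extra = rng.permutation(n_crosses) < (n_total - base * n_crosses)
    candidates, bulks, cross_of_origin = [], [], []
    k = 0
    for (pa_id, pb_id, kind), n_slots in zip(plan.crosses, base + extra.astype(int)):
        if n_slots == 0:
            continue
        pa, pb = parent_lookup[pa_id], parent_lookup[pb_id]
        cross_tag = f"{label}_{pa_id}x{pb_id}"
        for s in range(n_slots):
            k += 1
            n_sibs = int(rng.integers(bulk_range[0], bulk_range[1] + 1))
            sibs = _simpop.cross(pa, pb, n_sibs, rng, founders,
                                 id_prefix=f"{label}F1_{k}", family=cross_tag,
                                 generation=label)
            primary = sibs[0]
            primary.id = f"{label}F1_{k}"
            candidates.append(primary)
            bulks.append(bulk_f1_genotype(sibs))
            cross_of_origin.append(cross_tag)
    return candidates, np.array(bulks), cross_of_origin


# ---------------------------------------------------------------------------
# Prediction of candidates jointly with the training set


class _TrainingContext:
    """Frozen training data reused by every cycle (the training set is
    never updated during the scheme)."""

    def __init__(self, mm: MarkerMatrix, blues: pd.DataFrame, ped_tuples: list,
                 cfg: SchemeConfig, marker_index: np.ndarray | None = None):
        self.cfg = cfg
        self.marker_ids = mm.marker_ids
        #: columns of the ORIGINAL simulated marker panel that survived QC,
        #: applied to every candidate genotyped later
        self.marker_index = (np.arange(mm.n_markers) if marker_index is None
                             else marker_index)
        self.dosages = mm.dosages
        self.line_ids = mm.individual_ids
        self.blues = blues.set_index("line")["value"].reindex(self.line_ids).to_numpy()
        self.ped_tuples = list(ped_tuples)
        self.means = self.dosages.mean(axis=0)
        self.sds = self.dosages.std(axis=0)

    def predict(self, candidate_ids, candidate_dosages, candidate_parents,
                seed: int):
        """Joint fit over training lines + unphenotyped candidates."""
        cfg = self.cfg
        ids = np.concatenate([self.line_ids, np.asarray(candidate_ids, dtype=object)])
        X = np.vstack([self.dosages,
                       np.asarray(candidate_dosages)[:, self.marker_index]])
        structures = {}
        need = _models.MODEL_PRESETS[cfg.model_preset]
        if "G" in need:
            structures["G"] = genomic_matrix_from_dosages(ids, X, self.means, self.sds)
        if any(k.startswith("K") for k in need):
            ds = distance_summary_from_dosages(ids, X, self.means, self.sds,
                                               m_subset=self.line_ids)
            for name, K in zip(("K1", "K2", "K3"), gaussian_kernels(ds)):
                structures[name] = K
        if "A" in need:
            ped = Pedigree.from_tuples(
                self.ped_tuples
                + [(cid, p1, p2, 0) for cid, (p1, p2) in
                   zip(candidate_ids, candidate_parents)]
            )
            structures["A"] = pedigree_matrix(ped).align(ids)
        chain = dataclasses.replace(cfg.chain, seed=seed)
        spec = _models.build_spec(cfg.model_preset, structures, chain=chain)
        y = np.concatenate([self.blues, np.full(len(candidate_ids), np.nan)])
        fit_res = _models.fit(y, spec)
        return fit_res


def _family_summary(pheno: pd.DataFrame, families: pd.Series,
                    structures, cfg: SchemeConfig, rng) -> pd.DataFrame:
    """Per-family mean yield, a moment-based h2 estimate from replicate
    data and, when requested by the selection criteria, within- and
    between-family CV prediction abilities."""
    r = pheno.groupby("line")["rep"].nunique().iloc[0]
    line_means = pheno.groupby("line")["value"].mean()
    rows = []
    blues = pd.DataFrame({
        "line": line_means.index,
        "family": families.reindex(line_means.index).to_numpy(),
        "value": line_means.to_numpy(),
    })
    for fam, sub in blues.groupby("family"):
        fam_lines = sub["line"]
        obs = pheno[pheno["line"].isin(fam_lines)]
        sigma_e = obs.groupby("line")["value"].var().mean() if r > 1 else 0.0
        sigma_g = max(float(sub["value"].var()) - sigma_e / r, 0.0)
        denom = sigma_g + sigma_e / r
        h2 = sigma_g / denom if denom > 0 else 0.0
        rows.append((fam, float(sub["value"].mean()), h2, len(sub)))
    out = pd.DataFrame(rows, columns=["family", "mean_gy", "h2", "n_lines"])
    needs_cv = {"within_ability", "between_ability"} & set(cfg.family_criteria)
    if needs_cv and structures is not None:
        cv_chain = dataclasses.replace(cfg.chain, seed=int(rng.integers(2**31)))
        within = cross_validate(
            blues, structures, cfg.model_preset,
            CVScheme("within", cfg.cv_k_folds, cfg.cv_repeats),
            seed=int(rng.integers(2**31)), chain=cv_chain,
        )
        between = cross_validate(
            blues, structures, cfg.model_preset, CVScheme("between"),
            seed=int(rng.integers(2**31)), chain=cv_chain,
        )
        out = out.merge(
            pd.DataFrame([(r_.family, r_.mean_ability) for r_ in within],
                         columns=["family", "within_ability"]), on="family")
        out = out.merge(
            pd.DataFrame([(r_.family, r_.mean_ability) for r_ in between],
                         columns=["family", "between_ability"]), on="family")
    return out


# ---------------------------------------------------------------------------
# The cycle engine


def run_cycle(
    ctx: _TrainingContext,
    plan: CrossPlan,
    parent_lookup: dict[str, SimIndividual],
    n_f1: int,
    n_select: int | None,
    founders,
    arch,
    label: str,
    rng: np.random.Generator,
) -> CyclePopulation:
    """Execute one recombination cycle: realize F1s from the plan, bulk
    genotype, predict GEBVs jointly with the training set, truncation-
    select.  ``n_select=None`` skips selection (terminal cycle)."""
    candidates, bulks, origin = _realize_f1s(
        plan, parent_lookup, n_f1, ctx.cfg.bulk_plants, founders, rng, label
    )
    _simpop.true_breeding_values(candidates, arch)
    parents = [(c.parent1, c.parent2) for c in candidates]
    fit_res = ctx.predict([c.id for c in candidates], bulks, parents,
                          seed=int(rng.integers(2**31)))
    gebvs = _models.predict(fit_res, [c.id for c in candidates])
    selected = rank_and_select(gebvs, n_select) if n_select else []
    pop = CyclePopulation(label, candidates, gebvs, selected, plan)
    pop.training_gebv_mean = float(
        np.mean(fit_res.genetic_values[: len(ctx.line_ids)])
    )
    return pop


def run_scheme(cfg: SchemeConfig, seed: int) -> SchemeResult:
    """Run the full pipeline from training-population simulation through
    ``cfg.n_cycles`` recombination cycles to the realized-gain report.

    Deterministic given (cfg, seed). Gain on true breeding values is
    always reported; the simulated final yield trial (selfing to inbred
    lines, multi-year replicated evaluation) runs when
    ``cfg.do_final_trial`` is set."""
    rng = np.random.default_rng(seed)
    mm, ped, pheno, families, extras = _simpop.make_training_population(
        cfg.training, seed=int(rng.integers(2**31))
    )
    founders = extras["founders"]
    arch = extras["architecture"]
    lines = {l.id: l for l in extras["lines"]}

    # marker QC on the training matrix (simulated data are complete, so
    # imputation is a no-op; the MAF filter still bites)
    mm_qc, qc_report = filter_markers(mm, cfg.maf_threshold)
    line_means = pheno.groupby("line")["value"].mean()
    blues = pd.DataFrame({
        "line": line_means.index,
        "family": families.reindex(line_means.index).to_numpy(),
        "value": line_means.to_numpy(),
    })

    # family selection
    structures = None
    if {"within_ability", "between_ability"} & set(cfg.family_criteria):
        G = genomic_matrix_from_dosages(mm_qc.individual_ids, mm_qc.dosages)
        structures = {"G": G,
                      "A": pedigree_matrix(ped).align(mm_qc.individual_ids)}
        ds = distance_summary_from_dosages(mm_qc.individual_ids, mm_qc.dosages)
        for name, K in zip(("K1", "K2", "K3"), gaussian_kernels(ds)):
            structures[name] = K
    fam_summary = _family_summary(pheno, families, structures, cfg, rng)
    chosen_fams = select_families(fam_summary, cfg.n_families_select,
                                  cfg.family_criteria)
    parent_ids = select_c0_parents(blues, chosen_fams, cfg.n_top_lines_per_family)
    parents_by_family = {
        f: [l for l in parent_ids if lines[l].family == f] for f in chosen_fams
    }
    pair_scores = None
    if "between_ability" in fam_summary.columns:
        ability = fam_summary.set_index("family")["between_ability"]
        pair_scores = {
            (a, b): float((ability[a] + ability[b]) / 2.0)
            for a, b in itertools.combinations(sorted(chosen_fams), 2)
        }

    marker_pos = {m: k for k, m in enumerate(mm.marker_ids)}
    ctx = _TrainingContext(
        mm_qc, blues,
        [(r.id, r.parent1 or 0, r.parent2 or 0, r.selfing_generations)
         for r in ped.records],
        cfg,
        marker_index=np.array([marker_pos[m] for m in mm_qc.marker_ids]),
    )

    # C0 population record (the training lines)
    tbv_train = np.array([l.true_breeding_value for l in extras["lines"]])
    c0 = CyclePopulation("C0", extras["lines"], None, parent_ids, None)
    cycles = [c0]

    plan = make_cross_plan(
        parents_by_family, rng,
        cfg.crosses_within_per_family, cfg.crosses_between_per_pair,
        cfg.n_between_pairs, cfg.min_intercross_uses, pair_scores,
    )
    parent_lookup = {pid: lines[pid] for pid in parent_ids}
    for c in range(1, cfg.n_cycles + 1):
        n_f1 = cfg.n_f1_per_cycle[min(c - 1, len(cfg.n_f1_per_cycle) - 1)]
        n_sel = (cfg.n_select_per_cycle[c - 1]
                 if c - 1 < len(cfg.n_select_per_cycle) else None)
        pop = run_cycle(ctx, plan, parent_lookup, n_f1, n_sel, founders, arch,
                        f"C{c}", rng)
        cycles.append(pop)
        if c < cfg.n_cycles:
            sel = {i: ind for ind in pop.individuals for i in [ind.id]
                   if ind.id in pop.selected_ids}
            by_fam: dict[str, list[str]] = {}
            for sid in pop.selected_ids:
                fam = sel[sid].family
                by_fam.setdefault(fam, []).append(sid)
            n_within, n_between = cfg.cycle_crosses[
                min(c - 1, len(cfg.cycle_crosses) - 1)
            ]
            plan = make_cycle_cross_plan(by_fam, n_within, n_between, rng)
            parent_lookup = sel
            ctx.ped_tuples.extend(
                (ind.id, ind.parent1, ind.parent2, 0) for ind in pop.individuals
            )

    # gain on simulation truth
    means_true = [float(tbv_train.mean())] + [p.mean_tbv() for p in cycles[1:]]
    gain_true = GainReport.from_means(
        [p.label for p in cycles], [len(p.individuals) for p in cycles],
        means_true, basis="true_breeding_value",
    )

    # GEBV per-cycle summary (C0 = training-set GEBVs from the C1 fit)
    gebv_means = {"C0": [cycles[1].training_gebv_mean]}
    for p in cycles[1:]:
        gebv_means[p.label] = p.gebvs.table["gebv"].to_numpy()
    gebv_df = _models.gebv_cycle_summary(gebv_means)

    gain_pheno, trial_table = None, None
    if cfg.do_final_trial:
        gain_pheno, trial_table = _final_trial(cfg, cycles, founders, arch, rng)

    return SchemeResult(cycles, gain_true, gain_pheno, gebv_df, fam_summary,
                        trial_table)


def _final_trial(cfg: SchemeConfig, cycles, founders, arch, rng):
    """Advance a GEBV rank-band sample of each cycle's F1s to inbred
    lines and evaluate them with a sample of C0 parents in a replicated
    multi-year trial."""
    entries: list[tuple[str, SimIndividual]] = []
    c0 = cycles[0]
    checks = list(rng.choice(c0.selected_ids,
                             size=min(cfg.n_c0_checks, len(c0.selected_ids)),
                             replace=False))
    line_map = {l.id: l for l in c0.individuals}
    entries.extend(("C0", line_map[i]) for i in checks)
    for k, pop in enumerate(cycles[1:]):
        n_adv = cfg.n_advance_per_cycle[min(k, len(cfg.n_advance_per_cycle) - 1)]
        ranked = rank_and_select(pop.gebvs, min(cfg.advance_rank_band,
                                                len(pop.individuals)))
        picked = rng.choice(ranked, size=min(n_adv, len(ranked)), replace=False)
        ind_map = {i.id: i for i in pop.individuals}
        for pid in picked:
            line = _simpop.self_advance(ind_map[pid], cfg.selfing_to_line, rng,
                                        founders, bulk_policy=3,
                                        id_suffix="_F6")
            entries.append((pop.label, line))
    pop_all = [ind for _, ind in entries]
    g = _simpop.true_breeding_values(pop_all, arch)
    sigma_g = float(np.var(g))
    env_var = (sigma_g * (1 - cfg.trial_h2) / cfg.trial_h2 * cfg.trial_reps
               if 0 < cfg.trial_h2 < 1 else 0.0)
    trial_arch = dataclasses.replace(arch, env_variance=env_var,
                                     family_h2_targets=None)
    pheno = _simpop.assign_phenotypes(pop_all, trial_arch, r_reps=cfg.trial_reps,
                                      seed=int(rng.integers(2**31)),
                                      years=cfg.trial_years)
    cyc_of = {ind.id: lab for lab, ind in entries}
    pheno["cycle"] = pheno["line"].map(cyc_of)
    table = cycle_means(pheno)
    labels = [p.label for p in cycles]
    means = [float(table.loc[lab, "combined"]) for lab in labels]
    counts = [int(table.loc[lab, "n"]) for lab in labels]
    report = GainReport.from_means(labels, counts, means, basis="phenotype")
    return report, table
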