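"""Evaluation arithmetic for a recurrent genomic selection program:
line-mean heritability from variance components, within/between-family
cross-validation of prediction ability, cycle means, realized genetic
gain, LSD, and Nei-distance diversity summaries.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from . import models as _models
from .genotypes import MarkerMatrix
from .kinship import RelationshipMatrix, nei_distance
from .models import ChainSettings, ModelSpec

__all__ = [
    "VarianceComponents",
    "CVResult",
    "CVScheme",
    "GainReport",
    "heritability",
    "cross_validate",
    "cycle_means",
    "realized_gain",
    "gain_per_year",
    "lsd",
    "diversity_summary",
]


@dataclasses.dataclass
class VarianceComponents:
    """Trial variance components on the observation scale.

    sigma2_g : genotypic variance
    sigma2_ge : genotype-by-year (environment) interaction variance
    sigma2_e : residual variance
    r, e : replicate and environment (year) counts
    """

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    r: int = 1
    e: int = 1

    def __post_init__(self):
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValueError("variances must be >= 0")
        if self.r < 1 or self.e < 1:
            raise ValueError("r and e must be >= 1")


def heritability(vc: VarianceComponents) -> float:
    """Line-mean heritability

        h2 = sigma2_g / (sigma2_g + sigma2_ge/e + sigma2_e/(r*e))

    i.e. the genotypic share of the variance among entry means from a
    trial with r replicates in each of e environments (years)."""
    denom = vc.sigma2_g + vc.sigma2_ge / vc.e + vc.sigma2_e / (vc.r * vc.e)
    if denom <= 0:
        raise ValueError("total variance must be > 0")
    return vc.sigma2_g / denom


# ---------------------------------------------------------------------------
# Cross-validation


@dataclasses.dataclass
class CVScheme:
    mode: str = "within"  # within | between
    k_folds: int = 5
    n_repeats: int = 10
    include_other_families: bool = False  # within mode: train also on other families


@dataclasses.dataclass
class CVResult:
    family: str
    mode: str
    fold_correlations: list[float]
    mean_ability: float

    def __post_init__(self):
        for c in self.fold_correlations:
            if not -1.0 <= c <= 1.0:
                raise ValueError("correlation outside [-1, 1]")


def _fit_predict_masked(y, mask_predict, spec_template: ModelSpec, seed: int):
    """Refit with the target entries' phenotypes masked; return their
    predicted genetic values."""
    y_train = y.copy()
    y_train[mask_predict] = np.nan
    chain = dataclasses.replace(spec_template.chain, seed=seed)
    spec = dataclasses.replace(spec_template, chain=chain)
    fit_res = _models.fit(y_train, spec)
    return fit_res.genetic_values[mask_predict]


def cross_validate(
    pheno: pd.DataFrame,
    structures: dict[str, RelationshipMatrix],
    preset: str,
    scheme: CVScheme,
    seed: int,
    chain: ChainSettings | None = None,
) -> list[CVResult]:
    """Random cross-validation of genomic prediction ability within and
    between families.

    ``pheno`` is a line-level table with columns line, family, value
    (BLUEs).  Prediction ability is the Pearson correlation of predicted
    vs observed values.  Within mode: k-fold random partition inside each
    family, trained on the remainder of that family (plus, optionally,
    every other family).  Between mode: leave-one-family-out.
    Zero-variance folds are skipped.
    """
    lines = pheno["line"].to_numpy(dtype=object)
    fams = pheno["family"].to_numpy(dtype=object)
    y_all = pheno["value"].to_numpy(dtype=float)
    fam_list = sorted(set(fams))
    if scheme.mode == "between" and len(fam_list) < 2:
        raise ValueError("between-family CV needs at least 2 families")

    aligned = {k: v.align(lines) for k, v in structures.items()}
    template = _models.build_spec(preset, aligned, chain=chain)
    rng = np.random.default_rng(seed)
    results = []

    if scheme.mode == "between":
        for fam in fam_list:
            test = fams == fam
            pred = _fit_predict_masked(y_all, test, template,
                                       seed=int(rng.integers(2**31)))
            corrs = []
            if np.std(y_all[test]) > 0 and np.std(pred) > 0:
                corrs.append(float(np.corrcoef(pred, y_all[test])[0, 1]))
            results.append(CVResult(fam, "between", corrs,
                                    float(np.mean(corrs)) if corrs else float("nan")))
        return results

    if scheme.mode != "within":
        raise ValueError("mode must be 'within' or 'between'")

    for fam in fam_list:
        fam_idx = np.flatnonzero(fams == fam)
        corrs = []
        for _ in range(scheme.n_repeats):
            perm = rng.permutation(fam_idx)
            for fold in np.array_split(perm, scheme.k_folds):
                if fold.size < 2:
                    continue
                test = np.zeros(len(lines), dtype=bool)
                test[fold] = True
                if not scheme.include_other_families:
                    # train only on this family's remainder
                    sub_ids = lines[fams == fam]
                    sub_structs = {k: v.align(sub_ids) for k, v in aligned.items()}
                    sub_template = _models.build_spec(preset, sub_structs,
                                                      chain=template.chain)
                    sub_test = test[fams == fam]
                    pred = _fit_predict_masked(y_all[fams == fam], sub_test,
                                               sub_template,
                                               seed=int(rng.integers(2**31)))
                    obs_vals = y_all[test]
                else:
                    pred = _fit_predict_masked(y_all, test, template,
                                               seed=int(rng.integers(2**31)))
                    obs_vals = y_all[test]
                if np.std(obs_vals) == 0 or np.std(pred) == 0:
                    continue  # degenerate fold, skipped
                corrs.append(float(np.corrcoef(pred, obs_vals)[0, 1]))
        results.append(CVResult(fam, "within", corrs,
                                float(np.mean(corrs)) if corrs else float("nan")))
    return results


# ---------------------------------------------------------------------------
# Cycle means and genetic gain


def cycle_means(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-cycle mean phenotype by year plus a combined column.

    ``pheno`` needs columns cycle, year, value (one row per plot or per
    line-year mean).  The combined mean is the average of the per-year
    means — the balanced-design convention, under which e.g. year means
    6.11 and 7.65 combine to 6.88."""
    years = sorted(pheno["year"].unique())
    out = pheno.pivot_table(index="cycle", columns="year", values="value",
                            aggfunc="mean")
    out["combined"] = out[years].mean(axis=1)
    counts = pheno.groupby("cycle")["value"].size() // len(years)
    out.insert(0, "n", counts)
    return out


def realized_gain(first_mean: float, last_mean: float, n_cycles: int):
    """Realized genetic gain: per-cycle = (last - first)/n_cycles and
    percent = 100*(last - first)/first."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    per_cycle = (last_mean - first_mean) / n_cycles
    if first_mean <= 0:
        raise ValueError("first_mean must be > 0 for a percent gain")
    percent = 100.0 * (last_mean - first_mean) / first_mean
    return per_cycle, percent


def gain_per_year(per_cycle_gain: float, n_cycles: int, elapsed_years: float) -> float:
    """Gain per year = (n_cycles * per_cycle_gain) / elapsed_years."""
    if elapsed_years <= 0:
        raise ValueError("elapsed_years must be > 0")
    return n_cycles * per_cycle_gain / elapsed_years


def lsd(mse: float, df_error: int, r: int, alpha: float = 0.05) -> float:
    """Least significant difference between two entry means with r
    replicates: t(1-alpha/2, df) * sqrt(2*mse/r)."""
    if mse < 0 or r < 1 or df_error < 1:
        raise ValueError("invalid LSD inputs")
    return float(stats.t.ppf(1 - alpha / 2, df_error) * np.sqrt(2 * mse / r))


@dataclasses.dataclass
class GainReport:
    """Realized-gain bookkeeping across selection cycles."""

    cycle_labels: list[str]
    n_lines: list[int]
    cycle_mean: list[float]
    per_cycle_gain: float
    percent_gain: float
    per_year_gain: float | None = None
    basis: str = "phenotype"  # phenotype | true_breeding_value | gebv

    def __post_init__(self):
        if any(n <= 0 for n in self.n_lines):
            raise ValueError("cycle line counts must be > 0")
        first, last = self.cycle_mean[0], self.cycle_mean[-1]
        n_cyc = len(self.cycle_mean) - 1
        if n_cyc >= 1 and first > 0:
            pc, pct = realized_gain(first, last, n_cyc)
            if abs(pc - self.per_cycle_gain) > 1e-9 or abs(pct - self.percent_gain) > 1e-6:
                raise ValueError("gain fields inconsistent with cycle means")

    @classmethod
    def from_means(cls, labels, n_lines, means, basis="phenotype",
                   cycles_per_year: float | None = None,
                   elapsed_years: float | None = None) -> "GainReport":
        n_cyc = len(means) - 1
        pc, pct = realized_gain(means[0], means[-1], max(n_cyc, 1))
        py = None
        if elapsed_years:
            py = gain_per_year(pc, n_cyc, elapsed_years)
        return cls(list(labels), list(n_lines), [float(m) for m in means],
                   pc, pct, py, basis)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Diversity


def diversity_summary(mm_by_cycle: dict[str, MarkerMatrix]) -> pd.DataFrame:
    """Mean and SD of pairwise Nei standard distances within each cycle
    and between each cycle pair (lines as dosage/2 frequency profiles).

    Returns a long table (cycle_a, cycle_b, n_pairs, mean, sd) where
    cycle_a == cycle_b rows are within-cycle summaries. Infinite
    distances (disjoint fixation) propagate to the mean and are thereby
    flagged rather than dropped."""
    labels = list(mm_by_cycle)
    freqs = {k: mm.dosages / 2.0 for k, mm in mm_by_cycle.items()}
    rows = []
    for a_idx, a in enumerate(labels):
        Fa = freqs[a]
        # within
        ds = [
            nei_distance(Fa[i], Fa[j])
            for i in range(Fa.shape[0])
            for j in range(i + 1, Fa.shape[0])
        ]
        rows.append((a, a, len(ds), _mean_or_nan(ds), _sd_or_nan(ds)))
        for b in labels[a_idx + 1:]:
            Fb = freqs[b]
            ds = [
                nei_distance(Fa[i], Fb[j])
                for i in range(Fa.shape[0])
                for j in range(Fb.shape[0])
            ]
            rows.append((a, b, len(ds), _mean_or_nan(ds), _sd_or_nan(ds)))
    return pd.DataFrame(rows, columns=["cycle_a", "cycle_b", "n_pairs", "mean", "sd"])


def _mean_or_nan(xs):
    return float(np.mean(xs)) if xs else float("nan")


def _sd_or_nan(xs):
    if not xs:
        return float("nan")
    if np.isinf(xs).any():
        return float("nan")  # SD undefined once a distance is infinite
    return float(np.std(xs))
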