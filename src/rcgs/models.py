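"""Bayesian genomic prediction: one Gibbs engine for every model.

All four model presets share the form

    y = mu*1 + sum_t u_t + e,   u_t ~ N(0, sigma2_t K_t),  e ~ N(0, sigma2_e I)

with K_t a genomic relationship matrix (GBLUP), a pedigree numerator
relationship matrix A, or a Gaussian kernel from the kernel-averaging
set.  Presets:

* ``GBLUP``       — {G}
* ``P+GBLUP``     — {A, G}
* ``RKHS-KA``     — {K1, K2, K3}
* ``P+RKHS-KA``   — {A, K1, K2, K3}

Each term is sampled on the eigenbasis of its covariance matrix so that
its conditional update factorizes into independent normals; variance
components have scaled-inverse-chi-square full conditionals; missing
phenotypes are imputed from their conditional normal each sweep, which
is how unphenotyped selection candidates are predicted jointly with the
training set.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .kinship import RelationshipMatrix

__all__ = [
    "ChainSettings",
    "ModelTerm",
    "ModelSpec",
    "PosteriorFit",
    "GEBVTable",
    "MODEL_PRESETS",
    "build_spec",
    "fit",
    "predict",
    "rank_and_select",
    "gebv_cycle_summary",
]

MODEL_PRESETS = {
    "GBLUP": ("G",),
    "P+GBLUP": ("A", "G"),
    "RKHS-KA": ("K1", "K2", "K3"),
    "P+RKHS-KA": ("A", "K1", "K2", "K3"),
}


@dataclasses.dataclass
class ChainSettings:
    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclasses.dataclass
class ModelTerm:
    name: str
    matrix: RelationshipMatrix


@dataclasses.dataclass
class ModelSpec:
    """A list of covariance-structured random effects plus priors and
    chain settings.

    Priors: every variance gets a scaled-inverse-chi-square with df0
    degrees of freedom; scales are set from the phenotypic variance so
    that the random terms' prior modes share ``r2_prior`` of it equally
    and the error prior mode gets the remainder.
    """

    terms: list[ModelTerm]
    preset: str | None = None
    chain: ChainSettings = dataclasses.field(default_factory=ChainSettings)
    df0: float = 5.0
    r2_prior: float = 0.5

    def __post_init__(self):
        if not self.terms:
            raise ValueError("model needs at least one random term")
        ids0 = list(self.terms[0].matrix.ids)
        for t in self.terms[1:]:
            if list(t.matrix.ids) != ids0:
                raise ValueError(
                    f"term {t.name!r} ids differ from first term; align matrices first"
                )

    @property
    def ids(self) -> np.ndarray:
        return self.terms[0].matrix.ids


def build_spec(
    preset: str,
    structures: dict[str, RelationshipMatrix],
    chain: ChainSettings | None = None,
    **kwargs,
) -> ModelSpec:
    """Expand a named preset into a ModelSpec from a dict of available
    structures ('G', 'A', 'K1'...'K3')."""
    if preset not in MODEL_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(MODEL_PRESETS)}")
    missing = [k for k in MODEL_PRESETS[preset] if k not in structures]
    if missing:
        raise ValueError(f"preset {preset} needs structures {missing}")
    terms = [ModelTerm(k, structures[k]) for k in MODEL_PRESETS[preset]]
    return ModelSpec(terms=terms, preset=preset,
                     chain=chain or ChainSettings(), **kwargs)


@dataclasses.dataclass
class PosteriorFit:
    """Posterior summaries of a Gibbs run."""

    ids: np.ndarray
    mu_mean: float
    mu_sd: float
    variance_means: dict[str, float]
    variance_sds: dict[str, float]
    term_values: dict[str, np.ndarray]  # posterior-mean genetic value per term
    genetic_values: np.ndarray  # posterior mean of mu + sum_t u_t
    phenotyped: np.ndarray  # bool per individual
    samples: pd.DataFrame  # thinned draws of mu and variances
    ess: dict[str, float]
    preset: str | None = None

    def heritability(self, term: str | None = None) -> float:
        """Posterior-mean variance-ratio h2 = sum(sigma2_terms)/(sum + sigma2_e)
        (or a single term's share)."""
        s2e = self.variance_means["sigma2_e"]
        genetic = {k: v for k, v in self.variance_means.items() if k != "sigma2_e"}
        num = genetic[f"sigma2_{term}"] if term else sum(genetic.values())
        return num / (sum(genetic.values()) + s2e)


@dataclasses.dataclass
class GEBVTable:
    """Per-individual predicted genetic values on the trait scale."""

    table: pd.DataFrame  # columns: id, gebv, phenotyped
    preset: str | None = None

    def __post_init__(self):
        if not np.isfinite(self.table["gebv"].to_numpy()).all():
            raise ValueError("non-finite GEBV")

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial positive autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


def fit(
    y: np.ndarray,
    spec: ModelSpec,
    fixed_variances: dict[str, float] | None = None,
    fixed_mu: float | None = None,
    eig_floor: float = 1e-8,
) -> PosteriorFit:
    """Run the Gibbs sampler.

    Parameters
    ----------
    y : array of phenotypes aligned to ``spec.ids``; NaN marks
        unphenotyped individuals (predicted jointly).
    fixed_variances : clamp named variances ('sigma2_<term>' or
        'sigma2_e') instead of sampling them — used for oracle checks
        against closed-form BLUP.
    fixed_mu : clamp the intercept.
    eig_floor : relative eigenvalue floor below which eigenpairs of a
        term's covariance matrix are dropped.
    """
    y = np.asarray(y, dtype=float)
    ids = spec.ids
    n = len(ids)
    if y.shape != (n,):
        raise ValueError("y length does not match model ids")
    obs = ~np.isnan(y)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("all phenotypes missing")
    if n_obs < 10 and fixed_variances is None:
        raise ValueError("need at least 10 non-missing phenotypes")
    fixed_variances = fixed_variances or {}

    rng = np.random.default_rng(spec.chain.seed)
    vy = float(np.var(y[obs])) or 1.0
    df0 = spec.df0
    n_terms = len(spec.terms)
    # prior scale S0: mode df0*S0/(df0+2) equals the target variance share
    S0 = {
        t.name: (spec.r2_prior * vy / n_terms) * (df0 + 2.0) / df0
        for t in spec.terms
    }
    S0_e = (1.0 - spec.r2_prior) * vy * (df0 + 2.0) / df0

    # eigendecompositions (dropping near-null eigenpairs)
    bases, eigvals = [], []
    for t in spec.terms:
        w, V = np.linalg.eigh(t.matrix.values)
        keep = w > eig_floor * max(w[-1], 1.0)
        if not keep.any():
            raise ValueError(f"term {t.name!r}: covariance matrix is numerically null")
        bases.append(np.ascontiguousarray(V[:, keep]))
        eigvals.append(w[keep])

    # initial state
    mu = fixed_mu if fixed_mu is not None else float(np.mean(y[obs]))
    s2 = {
        t.name: fixed_variances.get(f"sigma2_{t.name}", spec.r2_prior * vy / n_terms)
        for t in spec.terms
    }
    s2e = fixed_variances.get("sigma2_e", (1.0 - spec.r2_prior) * vy)
    u = [np.zeros(n) for _ in spec.terms]
    total_u = np.zeros(n)
    ycur = y.copy()
    ycur[~obs] = mu

    n_iter, burn_in, thin = spec.chain.n_iter, spec.chain.burn_in, spec.chain.thin
    kept = 0
    mu_draws, var_draws = [], {f"sigma2_{t.name}": [] for t in spec.terms}
    var_draws["sigma2_e"] = []
    u_accum = [np.zeros(n) for _ in spec.terms]
    g_accum = np.zeros(n)

    for it in range(n_iter):
        # intercept (flat prior)
        if fixed_mu is None:
            r = ycur - total_u
            mu = rng.normal(float(np.mean(r)), np.sqrt(s2e / n))
        # each random term on its eigenbasis
        for t_idx, term in enumerate(spec.terms):
            V, d = bases[t_idx], eigvals[t_idx]
            r_t = ycur - mu - total_u + u[t_idx]
            w = V.T @ r_t
            c = 1.0 / (1.0 / s2e + 1.0 / (s2[term.name] * d))
            delta = c * w / s2e + np.sqrt(c) * rng.standard_normal(d.size)
            u_new = V @ delta
            total_u += u_new - u[t_idx]
            u[t_idx] = u_new
            key = f"sigma2_{term.name}"
            if key not in fixed_variances:
                ss = float(np.sum(delta * delta / d))
                s2[term.name] = (ss + df0 * S0[term.name]) / rng.chisquare(df0 + d.size)
        # error variance from observed residuals
        if "sigma2_e" not in fixed_variances:
            e_obs = ycur[obs] - mu - total_u[obs]
            ss_e = float(e_obs @ e_obs)
            s2e = (ss_e + df0 * S0_e) / rng.chisquare(df0 + n_obs)
        if not (np.isfinite(s2e) and all(np.isfinite(v) for v in s2.values())):
            raise RuntimeError(f"divergent chain: non-finite variance draw at iteration {it}")
        # impute missing phenotypes from their conditional normal
        n_miss = n - n_obs
        if n_miss:
            ycur[~obs] = mu + total_u[~obs] + np.sqrt(s2e) * rng.standard_normal(n_miss)

        if it >= burn_in and (it - burn_in) % thin == 0:
            kept += 1
            mu_draws.append(mu)
            for term in spec.terms:
                var_draws[f"sigma2_{term.name}"].append(s2[term.name])
            var_draws["sigma2_e"].append(s2e)
            for t_idx in range(n_terms):
                u_accum[t_idx] += u[t_idx]
            g_accum += mu + total_u

    samples = pd.DataFrame({"mu": mu_draws, **var_draws})
    variance_means = {k: float(np.mean(v)) for k, v in var_draws.items()}
    variance_sds = {k: float(np.std(v)) for k, v in var_draws.items()}
    ess = {col: _ess(samples[col].to_numpy()) for col in samples.columns}
    return PosteriorFit(
        ids=ids,
        mu_mean=float(np.mean(mu_draws)),
        mu_sd=float(np.std(mu_draws)),
        variance_means=variance_means,
        variance_sds=variance_sds,
        term_values={t.name: u_accum[k] / kept for k, t in enumerate(spec.terms)},
        genetic_values=g_accum / kept,
        phenotyped=obs,
        samples=samples,
        ess=ess,
        preset=spec.preset,
    )


def predict(fit_result: PosteriorFit, ids=None) -> GEBVTable:
    """Posterior-mean total genetic value (intercept included) for the
    requested individuals, phenotyped or not."""
    if ids is None:
        ids = fit_result.ids
    lookup = {i: k for k, i in enumerate(fit_result.ids)}
    unknown = [i for i in ids if i not in lookup]
    if unknown:
        raise KeyError(f"ids not in fit: {unknown[:5]}")
    idx = np.array([lookup[i] for i in ids])
    df = pd.DataFrame(
        {
            "id": np.asarray(ids, dtype=object),
            "gebv": fit_result.genetic_values[idx],
            "phenotyped": fit_result.phenotyped[idx],
        }
    )
    return GEBVTable(df, preset=fit_result.preset)


def rank_and_select(gebvs: GEBVTable, n_select: int) -> list[str]:
    """Ids of the n_select largest GEBVs; ties broken by lexicographic id
    order for reproducibility."""
    df = gebvs.table
    if n_select > len(df):
        raise ValueError("n_select exceeds table size")
    ordered = df.sort_values(["gebv", "id"], ascending=[False, True], kind="stable")
    return list(ordered["id"].iloc[:n_select])


def gebv_cycle_summary(gebvs_by_cycle: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean GEBV per cycle plus the mean per-cycle increment
    (last - first) / n_intervals, in cycle-label order as given."""
    labels = list(gebvs_by_cycle)
    means = [float(np.mean(np.asarray(v, dtype=float))) for v in gebvs_by_cycle.values()]
    n_int = max(len(labels) - 1, 1)
    increment = (means[-1] - means[0]) / n_int
    df = pd.DataFrame({"cycle": labels, "mean_gebv": means})
    df.attrs["mean_increment"] = increment
    return df
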