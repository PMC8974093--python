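"""Population-divergence statistics over genotypes and diversity indices.

Three analysis families:

* per-individual diversity indices compared among populations and among
  lakes x habitats -- over-dispersed (quasi-Poisson) count regressions with
  sequential scaled-deviance chi-square tests for allele/supertype counts,
  ordinary linear models with sequential F tests for the continuous
  indices, and Tukey HSD post-hocs;
* a multivariate "pool" test of allele (or supertype) composition -- one
  binomial GLM per allele, a sum-of-deviance likelihood-ratio statistic per
  model term, permutation p-values with restricted row permutation under
  the reduced model, and Westfall-Young step-down adjusted per-allele
  contributions;
* nonmetric multidimensional scaling of individuals on Jaccard
  dissimilarities of their presence/absence profiles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import GenotypeTable

__all__ = [
    "DiversityModelResult",
    "MultivariateTestResult",
    "OrdinationResult",
    "diversity_models",
    "multivariate_pool_test",
    "pairwise_pool_tests",
    "nmds",
]


# ---------------------------------------------------------------------------
# per-individual diversity models


@dataclass
class DiversityModelResult:
    table: pd.DataFrame                      # response, term, df, statistic, p_value, kind
    posthoc: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)


def _check_factors(df: pd.DataFrame, factors: Iterable[str]) -> None:
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")


def _sequential_quasipoisson(df: pd.DataFrame, response: str, terms: list[str]
                             ) -> list[dict]:
    """Sequential scaled-deviance chi-square tests for a quasi-Poisson GLM."""
    formulas = [f"{response} ~ 1"]
    for j in range(len(terms)):
        formulas.append(f"{response} ~ " + " + ".join(terms[: j + 1]))
    fits = [smf.glm(f, data=df, family=sm.families.Poisson()).fit() for f in formulas]
    full = fits[-1]
    scale = full.pearson_chi2 / full.df_resid  # quasi-likelihood dispersion
    rows = []
    for j, term in enumerate(terms):
        d_dev = fits[j].deviance - fits[j + 1].deviance
        d_df = fits[j].df_resid - fits[j + 1].df_resid
        chi2 = d_dev / scale
        rows.append({
            "term": term, "df": int(d_df), "statistic": float(chi2),
            "p_value": float(stats.chi2.sf(chi2, d_df)), "kind": "quasipoisson_chisq",
        })
    return rows


def _sequential_ols(df: pd.DataFrame, response: str, terms: list[str]) -> list[dict]:
    full = smf.ols(f"{response} ~ " + " + ".join(terms), data=df).fit()
    anova = sm.stats.anova_lm(full, typ=1)
    rows = []
    for term in terms:
        key = term.replace("*", ":")
        row = anova.loc[key]
        rows.append({
            "term": term, "df": int(row["df"]), "statistic": float(row["F"]),
            "p_value": float(row["PR(>F)"]), "kind": "lm_F",
        })
    return rows


def diversity_models(
    indices: pd.DataFrame,
    count_responses: Sequence[str] = ("n_alleles", "n_supertypes"),
    continuous_responses: Sequence[str] = ("pi", "dn", "ds"),
    design: Sequence[str] = ("population",),
    posthoc_factors: Sequence[str] = (),
) -> DiversityModelResult:
    """Compare per-individual diversity indices across the sampling design.

    ``indices`` is the output of
    :func:`midas_mhc.diversity.individual_diversity` (indices joined to the
    sample table).  ``design`` is the ordered term list, e.g.
    ``["population"]`` or ``["lake", "habitat", "lake:habitat"]``; terms are
    tested sequentially.  Count responses use a Poisson GLM with a
    quasi-likelihood dispersion (Pearson chi2 / df) and scaled-deviance
    chi-square tests; continuous responses use OLS with sequential F tests.
    """
    design = list(design)
    main_factors = [t for t in design if ":" not in t and "*" not in t]
    _check_factors(indices, main_factors)
    rows = []
    for resp in count_responses:
        if resp not in indices.columns:
            continue
        for r in _sequential_quasipoisson(indices, resp, design):
            rows.append({"response": resp, **r})
    for resp in continuous_responses:
        if resp not in indices.columns:
            continue
        df = indices.dropna(subset=[resp])
        for r in _sequential_ols(df, resp, design):
            rows.append({"response": resp, **r})
    posthoc = {}
    for factor in posthoc_factors:
        for resp in list(count_responses) + list(continuous_responses):
            if resp not in indices.columns:
                continue
            sub = indices.dropna(subset=[resp])
            res = pairwise_tukeyhsd(sub[resp], sub[factor])
            posthoc[(resp, factor)] = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
    return DiversityModelResult(table=pd.DataFrame(rows), posthoc=posthoc)


# ---------------------------------------------------------------------------
# multivariate pool test


def _design_matrix(samples: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    """Intercept + treatment-coded dummies for the given categorical terms."""
    n = len(samples)
    cols = [np.ones((n, 1))]
    for term in terms:
        parts = term.split(":")
        combo = samples[parts[0]].astype(str)
        for p in parts[1:]:
            combo = combo + "|" + samples[p].astype(str)
        d = pd.get_dummies(combo, drop_first=True).to_numpy(dtype=float)
        cols.append(d)
    X = np.hstack(cols)
    # drop exactly collinear columns (unbalanced crossed designs)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-9
    return X[:, keep]


def _binom_deviance(X: np.ndarray, Y: np.ndarray, max_iter: int = 50,
                    tol: float = 1e-9) -> np.ndarray:
    """Residual deviance of one binomial GLM per column of Y (batched IRLS)."""
    n, k = X.shape
    p = Y.shape[1]
    B = np.zeros((p, k))
    ybar = Y.mean(axis=0).clip(1e-6, 1 - 1e-6)
    B[:, 0] = np.log(ybar / (1 - ybar))
    prev = np.full(p, np.inf)
    eye = np.eye(k) * 1e-9
    for _ in range(max_iter):
        eta = X @ B.T                       # n x p
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = mu.clip(1e-9, 1 - 1e-9)
        W = mu * (1.0 - mu)                 # n x p
        z = eta + (Y - mu) / W
        XtWX = np.einsum("np,ni,nj->pij", W, X, X, optimize=True) + eye
        XtWz = np.einsum("ni,np->pi", X, W * z, optimize=True)
        B = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
        dev = _deviance_from_mu(Y, mu)
        if np.all(np.abs(dev - prev) < tol * (np.abs(dev) + 1)):
            break
        prev = dev
    eta = X @ B.T
    mu = (1.0 / (1.0 + np.exp(-eta))).clip(1e-12, 1 - 1e-12)
    return _deviance_from_mu(Y, mu)


def _deviance_from_mu(Y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = Y * np.log(mu) + (1 - Y) * np.log(1 - mu)
    return -2.0 * ll.sum(axis=0)


def _group_codes(samples: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    parts = [p for term in terms for p in term.split(":")]
    combo = samples[parts[0]].astype(str)
    for p in parts[1:]:
        combo = combo + "|" + samples[p].astype(str)
    return pd.factorize(combo)[0]


def _cell_mean_deviance(codes: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Deviance of the saturated-in-groups binomial model (closed form)."""
    G = codes.max() + 1
    n_g = np.bincount(codes, minlength=G).astype(float)
    S = np.zeros((G, Y.shape[1]))
    np.add.at(S, codes, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        phat = S / n_g[:, None]
        t1 = np.where(S > 0, S * np.log(phat), 0.0)
        F = n_g[:, None] - S
        t2 = np.where(F > 0, F * np.log(1 - phat), 0.0)
    return -2.0 * (t1 + t2).sum(axis=0)


def _is_cell_means(terms: Sequence[str]) -> bool:
    """True when the model is equivalent to per-group means (single term or
    a full factorial ending in the complete interaction)."""
    if len(terms) == 1:
        return True
    last = terms[-1]
    if ":" not in last:
        return False
    factors = set(last.split(":"))
    mains = {t for t in terms[:-1] if ":" not in t}
    others = [t for t in terms[:-1] if ":" in t and set(t.split(":")) - factors]
    return factors == mains and not others


def _term_deviance(samples: pd.DataFrame, Y: np.ndarray,
                   reduced: Sequence[str], full: Sequence[str]) -> np.ndarray:
    """Per-allele deviance drop from adding the last term of ``full``."""
    if reduced:
        if _is_cell_means(reduced):
            dev_red = _cell_mean_deviance(_group_codes(samples, reduced), Y)
        else:
            dev_red = _binom_deviance(_design_matrix(samples, reduced), Y)
    else:
        dev_red = _cell_mean_deviance(np.zeros(len(samples), dtype=int), Y)
    if _is_cell_means(full):
        dev_full = _cell_mean_deviance(_group_codes(samples, full), Y)
    else:
        dev_full = _binom_deviance(_design_matrix(samples, full), Y)
    return np.maximum(dev_red - dev_full, 0.0)


@dataclass
class MultivariateTestResult:
    terms: pd.DataFrame        # term, statistic, p_value
    univariate: dict[str, pd.DataFrame]  # term -> (allele, statistic, p_raw, p_adj)
    n_resamples: int
    seed: int | None
    dropped_alleles: list[str] = field(default_factory=list)


def _stepdown_adjust(obs: np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Westfall-Young step-down maxT adjusted p-values.

    ``obs``: (p,) observed per-allele statistics; ``perm``: (B, p) statistics
    under permutation.  Adjusted p is monotone in the observed ordering.
    """
    B, p = perm.shape
    order = np.argsort(-obs)
    # successive maxima over the permuted stats of alleles ranked at or below i
    succ_max = np.empty((B, p))
    running = np.full(B, -np.inf)
    for rank in range(p - 1, -1, -1):
        running = np.maximum(running, perm[:, order[rank]])
        succ_max[:, rank] = running
    adj = np.empty(p)
    for rank, j in enumerate(order):
        adj[j] = (1 + (succ_max[:, rank] >= obs[j]).sum()) / (B + 1)
    # enforce monotonicity along the ranking
    for rank in range(1, p):
        adj[order[rank]] = max(adj[order[rank]], adj[order[rank - 1]])
    return adj


def multivariate_pool_test(
    genotypes: GenotypeTable,
    terms: Sequence[str] = ("population",),
    n_resamples: int = 999,
    seed: int | None = None,
) -> MultivariateTestResult:
    """Test whether allele composition differs across the design terms.

    Per allele, a binomial GLM (presence ~ terms) is fit for the sequential
    nested models; each term's statistic is the sum over alleles of the
    deviance drop (a multivariate likelihood-ratio statistic).  P-values
    come from permuting individuals' presence profiles: freely for the
    first term, within the levels of the first reduced-model factor for
    later terms (an approximation to resampling residual structure under
    the reduced model).  Per-allele contributions are reported with
    Westfall-Young step-down adjusted p-values from the same permutations.
    """
    terms = list(terms)
    samples = genotypes.samples
    Y = genotypes.matrix.to_numpy(dtype=float)
    allele_ids = np.array(genotypes.allele_ids)
    const = (Y.std(axis=0) == 0)
    dropped = list(allele_ids[const])
    if dropped:
        warnings.warn(f"dropping alleles present in all or no individuals: {dropped}")
        Y = Y[:, ~const]
        allele_ids = allele_ids[~const]
    if Y.shape[1] == 0:
        raise ValueError("no variable alleles to test")
    for t in terms:
        for f in t.split(":"):
            if samples[f].nunique() < 2:
                raise ValueError(f"factor {f!r} has fewer than 2 levels")
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    term_rows = []
    univariate: dict[str, pd.DataFrame] = {}
    for j, term in enumerate(terms):
        reduced, full = terms[:j], terms[: j + 1]
        obs_uni = _term_deviance(samples, Y, reduced, full)
        obs_stat = float(obs_uni.sum())
        # restricted permutation strata under the reduced model
        if reduced:
            strata = pd.factorize(samples[reduced[0].split(":")[0]].astype(str))[0]
        else:
            strata = np.zeros(n, dtype=int)
        perm_uni = np.empty((n_resamples, Y.shape[1]))
        idx = np.arange(n)
        strata_groups = [np.nonzero(strata == s)[0] for s in np.unique(strata)]
        for b in range(n_resamples):
            perm = idx.copy()
            for g in strata_groups:
                perm[g] = g[rng.permutation(len(g))]
            perm_uni[b] = _term_deviance(samples, Y[perm], reduced, full)
        perm_stat = perm_uni.sum(axis=1)
        p = (1 + int((perm_stat >= obs_stat).sum())) / (n_resamples + 1)
        term_rows.append({"term": term, "statistic": obs_stat, "p_value": p})
        p_raw = (1 + (perm_uni >= obs_uni).sum(axis=0)) / (n_resamples + 1)
        p_adj = _stepdown_adjust(obs_uni, perm_uni)
        univariate[term] = pd.DataFrame({
            "allele": allele_ids, "statistic": obs_uni,
            "p_raw": p_raw, "p_adj": p_adj,
        }).sort_values("statistic", ascending=False, ignore_index=True)
    return MultivariateTestResult(
        terms=pd.DataFrame(term_rows), univariate=univariate,
        n_resamples=n_resamples, seed=seed, dropped_alleles=dropped,
    )


def pairwise_pool_tests(
    genotypes: GenotypeTable,
    factor: str,
    n_resamples: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise multivariate pool tests between the levels of ``factor``,
    with Benjamini-Hochberg correction across pairs."""
    samples = genotypes.samples
    levels = sorted(samples[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    ss = np.random.SeedSequence(seed).spawn(len(levels) * (len(levels) - 1) // 2)
    rows = []
    for k, (a, b) in enumerate(itertools.combinations(levels, 2)):
        ids = samples.loc[samples[factor].isin([a, b]), "individual_id"]
        sub = genotypes.subset_individuals(ids)
        sub_var = sub.drop_alleles(
            [al for al in sub.allele_ids if sub.matrix[al].std() == 0]
        )
        res = multivariate_pool_test(
            sub_var, terms=[factor], n_resamples=n_resamples,
            seed=int(ss[k].generate_state(1)[0] % 2**31),
        )
        rows.append({"level_a": a, "level_b": b,
                     "statistic": res.terms["statistic"].iloc[0],
                     "p_raw": res.terms["p_value"].iloc[0]})
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# NMDS


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame
    stress: float
    n_dims: int
    n_starts: int


def nmds(
    genotypes: GenotypeTable,
    n_dims: int = 6,
    n_starts: int = 30,
    max_iter: int = 1000,
    seed: int | None = None,
) -> OrdinationResult:
    """Nonmetric MDS of individuals on Jaccard dissimilarities.

    Runs ``n_starts`` random starts (Kruskal stress-1 minimisation) and
    returns the best, with centred coordinates.
    """
    Y = genotypes.matrix.to_numpy(dtype=bool)
    if Y.shape[0] < n_dims + 1:
        raise ValueError("need at least n_dims + 1 individuals")
    diss = squareform(pdist(Y, metric="jaccard"))
    if not np.any(diss > 0):
        raise ValueError("zero dissimilarity matrix: all individuals identical")
    mds = MDS(
        n_components=n_dims, metric=False, dissimilarity="precomputed",
        n_init=n_starts, max_iter=max_iter, random_state=seed,
        normalized_stress=True, eps=1e-9,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = mds.fit_transform(diss)
    coords = coords - coords.mean(axis=0)
    cols = [f"MDS{i + 1}" for i in range(n_dims)]
    df = pd.DataFrame(coords, index=genotypes.individuals, columns=cols)
    df.insert(0, "individual_id", df.index)
    df = df.reset_index(drop=True)
    return OrdinationResult(coordinates=df, stress=float(mds.stress_),
                            n_dims=n_dims, n_starts=n_starts)
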