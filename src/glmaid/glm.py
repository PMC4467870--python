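"""Three-way factorial GLM with Type-III term tests and Bonferroni subsets.

The model for one chemical parameter is

    y = mu + c_i + p_j + h_k + (cp)_ij + (ch)_ik + (ph)_jk + (cph)_ijk + e

with sum-to-zero level encoding.  Term significance is assessed by
marginal (Type-III) F-tests: the extra residual sum of squares incurred by
deleting the term's columns from the otherwise full design, on the rank
difference as numerator degrees of freedom.  This matches the default
behaviour of mainstream GLM procedures for unbalanced factorials and
coincides with sequential sums of squares on balanced ones.

Explained variance is the unadjusted model R^2 as a percentage.

Within a subgroup of samples some level combinations may be absent; terms
whose columns add no rank there are inestimable and reported as absent
(with a warning) rather than failing the whole fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from . import reference as ref

_RCOND = 1e-10


class SingletonLevelError(ValueError):
    """A factor level with fewer than 2 samples: means cannot be compared."""


@dataclass
class GLMResult:
    """Term-wise test results for one parameter on one sample subset."""

    parameter: str
    n: int
    terms_tested: tuple[str, ...]
    p_values: dict[str, float]          # absent (inestimable) terms omitted
    f_values: dict[str, float] = field(default_factory=dict)
    df: dict[str, int] = field(default_factory=dict)
    explained_variance_pct: float = float("nan")
    df_residual: int = 0
    inestimable: tuple[str, ...] = ()

    def significant_terms(self, alpha: float = 0.05) -> list[str]:
        return [t for t in self.terms_tested
                if t in self.p_values and self.p_values[t] < alpha]


def terms_for_factors(factors: tuple[str, ...] | list[str]) -> list[str]:
    """Canonical model terms (mains + all interactions) for a factor set."""
    present = set(factors)
    return [t for t in ref.TERMS
            if set(ref.TERM_FACTORS[t]) <= present]


def _term_formula(term: str) -> str:
    return ":".join(f"C({f}, Sum)" for f in ref.TERM_FACTORS[term])


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares of the least-squares fit and rank of X."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=_RCOND)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def explained_variance(ss_residual: float, ss_total: float) -> float:
    """100 x (1 - SS_residual / SS_total)."""
    if ss_total <= 0:
        raise ValueError("ss_total must be > 0 (constant response)")
    if not 0 <= ss_residual <= ss_total:
        raise ValueError("need 0 <= ss_residual <= ss_total")
    return 100.0 * (1.0 - ss_residual / ss_total)


def fit_factorial_glm(values, factors: pd.DataFrame,
                      terms: list[str] | None = None,
                      parameter: str = "") -> GLMResult:
    """Fit the factorial GLM of one parameter and test each term.

    Parameters
    ----------
    values : 1-d float array, the response.
    factors : DataFrame with a column per factor (any subset of
        cultivar / practice / harvest); only factors with >= 2 observed
        levels enter the model.
    terms : model terms to test; defaults to all mains and interactions
        of the supplied multi-level factors.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) != len(factors):
        raise ValueError("values and factors must have matching length")
    usable = [c for c in factors.columns if factors[c].nunique() >= 2]
    if not usable:
        raise ValueError("no factor with >= 2 levels")
    if terms is None:
        terms = terms_for_factors(tuple(usable))
    else:
        for t in terms:
            if t not in ref.TERMS:
                raise ValueError(f"unknown term {t!r}")
            if not set(ref.TERM_FACTORS[t]) <= set(usable):
                raise ValueError(
                    f"term {t!r} involves a factor without >= 2 levels here")

    data = factors.reset_index(drop=True)

    def build(term_list):
        design = dmatrix(
            "1 + " + " + ".join(_term_formula(t) for t in term_list),
            data, return_type="dataframe")
        return design.to_numpy(), design.design_info

    # prune fully aliased terms (highest interaction order first): a term
    # whose columns add no rank beyond the rest of the model is
    # inestimable on this subset and cannot be tested
    inestimable = []
    terms = list(terms)
    while True:
        X, info = build(terms)
        rank_full = np.linalg.matrix_rank(X, tol=_RCOND * max(X.shape))
        dropped = False
        for term in sorted(terms, key=lambda t: -len(ref.TERM_FACTORS[t])):
            sl = info.term_name_slices[
                info.term_names[1 + terms.index(term)]]
            keep = np.ones(X.shape[1], dtype=bool)
            keep[sl] = False
            rank_red = np.linalg.matrix_rank(X[:, keep],
                                             tol=_RCOND * max(X.shape))
            if rank_full - rank_red == 0:
                inestimable.append(term)
                warnings.warn(
                    f"term {term} is inestimable on this subset "
                    f"(aliased design columns); reported as absent",
                    stacklevel=2)
                terms.remove(term)
                dropped = True
                break
        if not dropped:
            break
        if not terms:
            raise ValueError("all model terms are inestimable")

    rss_full, rank_full = _rss(X, y)
    df_resid = len(y) - rank_full
    if df_resid < 1:
        raise ValueError(
            f"no residual degrees of freedom (n={len(y)}, model rank="
            f"{rank_full})")

    ss_total = float(np.sum((y - y.mean()) ** 2))
    result = GLMResult(
        parameter=parameter, n=len(y), terms_tested=tuple(terms),
        p_values={}, explained_variance_pct=explained_variance(
            min(rss_full, ss_total), ss_total) if ss_total > 0 else float("nan"),
        df_residual=df_resid)

    term_names = list(info.term_names)
    for term, tname in zip(terms, term_names[1:]):  # skip Intercept
        sl = info.term_name_slices[tname]
        keep = np.ones(X.shape[1], dtype=bool)
        keep[sl] = False
        rss_red, rank_red = _rss(X[:, keep], y)
        df_term = rank_full - rank_red
        if df_term == 0:   # partial aliasing survived pruning
            inestimable.append(term)
            warnings.warn(
                f"term {term} is inestimable on this subset "
                f"(aliased design columns); reported as absent",
                stacklevel=2)
            continue
        ss_term = max(rss_red - rss_full, 0.0)
        if rss_full == 0.0:
            # saturated fit: any extra SS is infinitely significant
            f_val = float("inf") if ss_term > 0 else 0.0
        else:
            f_val = (ss_term / df_term) / (rss_full / df_resid)
        result.f_values[term] = f_val
        result.df[term] = df_term
        result.p_values[term] = (0.0 if np.isinf(f_val) else
                                 float(f_dist.sf(f_val, df_term, df_resid)))
    result.inestimable = tuple(inestimable)
    return result


def fit_all_parameters(table: pd.DataFrame, parameters: list[str],
                       factors: tuple[str, ...] = ref.FACTORS,
                       terms: list[str] | None = None) -> list[GLMResult]:
    """Fit the factorial GLM for every parameter of a cohort table."""
    fac = table[list(factors)]
    return [fit_factorial_glm(table[p].to_numpy(), fac, terms=terms,
                              parameter=p) for p in parameters]


def results_to_frame(results: list[GLMResult]) -> pd.DataFrame:
    """Summary table mirroring the published layout: one row per
    parameter, per-term p-values and explained variance."""
    records = []
    for r in results:
        rec = {"parameter": r.parameter, "n": r.n}
        for t in ref.TERMS:
            rec[t] = r.p_values.get(t, float("nan"))
        rec["explained_variance"] = r.explained_variance_pct
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("parameter")


# ---------------------------------------------------------------------------
# Bonferroni homogeneous subsets

@dataclass
class SubsetPartition:
    """Homogeneous subsets of factor levels from pairwise Bonferroni tests.

    ``subsets`` is a compact-letter-display cover: every level belongs to
    at least one subset, and two levels share no subset exactly when their
    pairwise difference is significant at the Bonferroni-adjusted level.
    Subsets may overlap (pairwise non-significance is not transitive);
    :meth:`blocks` merges overlapping subsets into the disjoint partition
    used to form child nodes.
    """

    factor: str
    levels: tuple[str, ...]             # ordered by ascending mean
    means: dict[str, float]
    sds: dict[str, float]
    counts: dict[str, int]
    subsets: list[tuple[str, tuple[str, ...]]]   # (letter, levels)
    alpha: float
    pairwise_p: dict[frozenset, float]  # raw two-sided p, threshold alpha/m

    @property
    def n_comparisons(self) -> int:
        L = len(self.levels)
        return L * (L - 1) // 2

    def blocks(self) -> list[tuple[str, ...]]:
        """Disjoint level blocks: union of overlapping subsets."""
        parent = {lev: lev for lev in self.levels}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for _, members in self.subsets:
            for other in members[1:]:
                parent[find(other)] = find(members[0])
        groups: dict[str, list[str]] = {}
        for lev in self.levels:
            groups.setdefault(find(lev), []).append(lev)
        return [tuple(g) for g in groups.values()]


def bonferroni_subsets(values, factor_labels, alpha: float = 0.05,
                       factor: str = "") -> SubsetPartition:
    """Group factor levels into homogeneous subsets.

    All pairwise level comparisons use t statistics on the pooled
    within-group mean square (the one-way ANOVA MSE, df = N - L) with the
    Bonferroni-adjusted threshold alpha / m, m = L(L-1)/2.  Subsets are
    then formed by insert-and-absorb over mean-ordered levels (compact
    letter display), which makes the grouping deterministic.
    """
    y = np.asarray(values, dtype=float)
    labels = pd.Series(list(factor_labels))
    levels_present = labels.unique().tolist()
    if len(levels_present) < 2:
        raise ValueError("need >= 2 levels to form subsets")
    counts = labels.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise SingletonLevelError(
            f"level(s) {bad} of {factor or 'factor'} have a single sample; "
            "mean values cannot be compared")

    means = {lev: float(y[labels == lev].mean()) for lev in levels_present}
    sds = {lev: float(y[labels == lev].std(ddof=1)) for lev in levels_present}
    ns = {lev: int(counts[lev]) for lev in levels_present}
    N, L = len(y), len(levels_present)
    mse = sum(np.sum((y[labels == lev] - means[lev]) ** 2)
              for lev in levels_present) / (N - L)
    order = sorted(levels_present, key=lambda lev: (means[lev], lev))
    m = L * (L - 1) // 2

    pairwise: dict[frozenset, float] = {}
    for i in range(L):
        for j in range(i + 1, L):
            a, b = order[i], order[j]
            se = np.sqrt(mse * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0:
                p = 1.0 if means[a] == means[b] else 0.0
            else:
                tstat = (means[a] - means[b]) / se
                p = float(2 * t_dist.sf(abs(tstat), N - L))
            pairwise[frozenset((a, b))] = p

    threshold = alpha / m

    def differ(a, b):
        return pairwise[frozenset((a, b))] < threshold

    # maximal runs of mutually non-different mean-ordered levels
    runs: list[tuple[int, int]] = []
    i = 0
    while i < L:
        j = i
        while j + 1 < L and all(not differ(order[k], order[j + 1])
                                for k in range(i, j + 1)):
            j += 1
        if not runs or not (runs[-1][0] <= i and j <= runs[-1][1]):
            runs.append((i, j))
        i += 1
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    subsets = [(letters[k % 26] * (k // 26 + 1),
                tuple(order[a:b + 1])) for k, (a, b) in enumerate(runs)]

    return SubsetPartition(
        factor=factor, levels=tuple(order), means=means, sds=sds,
        counts=ns, subsets=subsets, alpha=alpha, pairwise_p=pairwise)
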