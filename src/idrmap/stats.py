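"""Statistical layer: Pearson correlation with significance bands, index
of dispersion, OLS multiple regression with sequential ANOVA and
diagnostics, and hypergeometric annotation-term enrichment.

The significance-star convention follows the figure legends of windowed
genome studies: ``***`` p < 0.005, ``**`` p < 0.01, ``*`` p < 0.05,
``ns`` otherwise (strict inequalities, so p = 0.005 earns ``**``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan
from statsmodels.stats.multitest import multipletests


def star_band(p: float) -> str:
    if p < 0.005:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    stars: str


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with a two-sided t-transform p-value.

    p is computed from t = r * sqrt((n-2) / (1-r^2)) against Student's t
    with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3, have {n}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    if np.ptp(y) == 0:
        raise ValueError("y has zero variance")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), n - 2)
    return CorrelationResult(r=r, n=n, p=p, stars=star_band(p))


def index_of_dispersion(counts) -> float:
    """Variance-to-mean ratio of per-window counts.

    1 under a Poisson (spatially random) distribution of genes across
    windows; > 1 indicates clustering.  Sample variance (ddof=1).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need a 1-D vector of at least 2 window counts")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be non-negative integers")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("all-zero counts: dispersion undefined")
    return float(counts.var(ddof=1) / mean)


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of disorder frequency on G+C and recombination.

    ``anova_p`` holds sequential (type I) ANOVA p-values per term;
    ``bp_*`` a Breusch–Pagan heteroscedasticity check and ``shapiro_*`` a
    residual-normality check — reported as diagnostics, never used to
    gate the fit.
    """

    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    multiple_r2: float
    anova_p: dict[str, float]
    bp_lm_stat: float
    bp_lm_p: float
    shapiro_w: float
    shapiro_p: float
    n: int


def multiple_regression(y, gc, rec) -> RegressionResult:
    """Fit ``y ~ intercept + gc + rec`` by ordinary least squares."""
    df = pd.DataFrame({
        "y": np.asarray(y, dtype=float),
        "gc": np.asarray(gc, dtype=float),
        "rec": np.asarray(rec, dtype=float),
    })
    if len(df) <= 3:
        raise ValueError(f"need n > 3 observations, have {len(df)}")
    if df.isna().any().any():
        raise ValueError("NaN in regression inputs; drop undefined windows first")
    X = sm.add_constant(df[["gc", "rec"]])
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = smf.ols("y ~ gc + rec", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    resid = model.resid.to_numpy()
    bp_stat, bp_p, _f, _fp = het_breuschpagan(resid, X.to_numpy())
    if np.ptp(resid) > 0:
        sw, swp = sps.shapiro(resid)
    else:  # perfectly flat residuals (exact fit)
        sw, swp = 1.0, 1.0
    names = {"Intercept": "intercept", "gc": "gc", "rec": "rec"}
    return RegressionResult(
        params={names[k]: float(v) for k, v in model.params.items()},
        bse={names[k]: float(v) for k, v in model.bse.items()},
        pvalues={names[k]: float(v) for k, v in model.pvalues.items()},
        multiple_r2=float(model.rsquared),
        anova_p={k: float(anova.loc[k, "PR(>F)"]) for k in ("gc", "rec")},
        bp_lm_stat=float(bp_stat),
        bp_lm_p=float(bp_p),
        shapiro_w=float(sw),
        shapiro_p=float(swp),
        n=len(df),
    )


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    study_count: int
    study_size: int
    population_count: int
    population_size: int
    p_raw: float
    p_corrected: float


def term_enrichment(
    study: set[str],
    population: set[str],
    annotations: dict[str, set[str]],
    correction: str = "bonferroni",
) -> list[EnrichmentResult]:
    """Hypergeometric (one-sided, upper tail) term over-representation.

    ``annotations`` maps each gene/protein id to its set of terms.  Every
    term annotating at least one population member is tested; correction
    is Bonferroni (default) or Benjamini–Hochberg (``'bh'``).  Results are
    sorted by ascending raw p.
    """
    if not study:
        raise ValueError("empty study set")
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in population:
        for term in annotations.get(gene, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1
    if not term_pop:
        raise ValueError("annotations cover no population member")
    terms = sorted(term_pop)
    M, n = len(population), len(study)
    raw = np.array([
        sps.hypergeom.sf(term_study.get(t, 0) - 1, M, term_pop[t], n)
        for t in terms
    ])
    method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[correction]
    corrected = multipletests(raw, method=method)[1]
    results = [
        EnrichmentResult(t, term_study.get(t, 0), n, term_pop[t], M,
                         float(p), float(pc))
        for t, p, pc in zip(terms, raw, corrected)
    ]
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results
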