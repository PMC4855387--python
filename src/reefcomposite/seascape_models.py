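"""Exhaustive AICc model selection of seascape drivers of genetic diversity.

Two fitting paths share one candidate enumeration (all predictor subsets of
size 1..max_terms plus the intercept-only reference):

* OLS on the per-island composite AR (n ~ 13 islands), with
  AICc = n ln(RSS/n) + n ln(2 pi) + n + 2K + 2K(K+1)/(n-K-1)
  where K counts the regression coefficients (incl. intercept) plus the
  residual variance;
* a random-intercept linear mixed model on species-level AR records
  (grouping label = species-by-marker), fitted by maximum likelihood so
  AICc is comparable across fixed-effect sets; K adds the group variance.

Candidates are ranked by AICc; the top set is ΔAICc < 2; Akaike weights are
w_i = exp(-Δ_i/2) / Σ exp(-Δ_j/2). Also here: the colinearity screen that
pre-selects predictors, the LGM habitat-loss metric, the quadratic
margin fit, and trait models of the species correlation profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

TOP_SET_DELTA = 2.0


def lgm_loss(area_lgm: float, area_present: float) -> float:
    """Habitat loss since the last glacial maximum: 1 - LGM/present area.

    A proxy for historical bottleneck severity; clamped to [0, 1] with a
    warning when the LGM area exceeds the present one.
    """
    if area_present <= 0:
        raise ValueError("present-day habitat area must be > 0")
    if area_lgm < 0:
        raise ValueError("LGM habitat area must be >= 0")
    loss = 1.0 - area_lgm / area_present
    if loss < 0:
        logger.warning("LGM area %.3g exceeds present area %.3g; loss clamped to 0",
                       area_lgm, area_present)
        return 0.0
    return min(loss, 1.0)


# ---------------------------------------------------------------------------
# single fits
# ---------------------------------------------------------------------------

class DegenerateModelError(ValueError):
    """Model cannot be scored (perfect fit, rank deficiency, or n too small)."""


@dataclass
class ModelFit:
    """One scored candidate model."""

    terms: tuple[str, ...]
    k: int
    aicc: float
    loglike: float
    coefficients: dict[str, float]
    adj_r2: float | None = None
    r2: float | None = None
    singular: bool = False
    group_var: float | None = None
    random_effects: dict | None = None


def _aicc_from_loglike(loglike: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise DegenerateModelError(
            f"n={n} too small for K={k} (AICc correction denominator <= 0)"
        )
    return -2.0 * loglike + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_ols_aicc(y: np.ndarray | pd.Series,
                 X: pd.DataFrame | None = None,
                 terms: Sequence[str] | None = None) -> ModelFit:
    """Gaussian OLS scored by small-sample AICc.

    ``X`` holds the predictor columns (an intercept is always added); pass
    ``X=None`` for the intercept-only model. K = #coefficients + 1 for the
    ML residual variance.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        names: list[str] = []
        design = np.ones((n, 1))
    else:
        names = list(X.columns) if terms is None else list(terms)
        design = np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
    p = design.shape[1]
    k = p + 1  # + residual variance
    if n - k - 1 <= 0:
        raise DegenerateModelError(f"n={n} too small for K={k}")
    beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p:
        raise DegenerateModelError(f"rank-deficient design for terms {names}")
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if not np.isfinite(rss) or rss <= 1e-12 * max(tss, 1.0):
        raise DegenerateModelError("perfect fit (RSS ~ 0); likelihood unbounded")
    loglike = -0.5 * n * (np.log(2 * np.pi) + np.log(rss / n) + 1.0)
    aicc = _aicc_from_loglike(loglike, k, n)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    n_pred = p - 1
    adj_r2 = (1.0 - (1.0 - r2) * (n - 1) / (n - n_pred - 1)) if n - n_pred - 1 > 0 else np.nan
    coefs = {"intercept": float(beta[0])}
    coefs.update({nm: float(b) for nm, b in zip(names, beta[1:])})
    return ModelFit(terms=tuple(names), k=k, aicc=aicc, loglike=loglike,
                    coefficients=coefs, adj_r2=float(adj_r2), r2=float(r2))


def fit_mixed_aicc(records: pd.DataFrame, terms: Sequence[str],
                   group_col: str = "group", response: str = "ar") -> ModelFit:
    """Random-intercept mixed model scored by ML AICc.

    ``records`` is the long table of species-by-marker x island AR values
    joined to island predictors; one random intercept per ``group_col``
    level. K = fixed coefficients (incl. intercept) + residual variance +
    group variance. A singular fit (group variance -> 0) is retained with
    ``singular=True``.
    """
    if records[group_col].isna().any():
        raise ValueError("grouping label must be non-null for every record")
    n_groups = records[group_col].nunique()
    if n_groups < 2:
        raise ValueError("need >= 2 groups for a random intercept")
    terms = list(terms)
    n = len(records)
    y = records[response].to_numpy(dtype=float)
    exog = sm.add_constant(records[terms].to_numpy(dtype=float)) if terms else np.ones((n, 1))
    k = (len(terms) + 1) + 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=records[group_col].to_numpy())
        fit = model.fit(reml=False)
    loglike = float(fit.llf)
    aicc = _aicc_from_loglike(loglike, k, n)
    group_var = float(np.asarray(fit.cov_re)[0, 0])
    singular = group_var < 1e-8
    if singular:
        logger.warning("mixed fit for terms %s is singular (group variance ~ 0)", terms)
    names = ["intercept"] + terms
    coefs = {nm: float(b) for nm, b in zip(names, np.asarray(fit.fe_params))}
    blups = {g: float(np.asarray(v).ravel()[0]) for g, v in fit.random_effects.items()}
    return ModelFit(terms=tuple(terms), k=k, aicc=aicc, loglike=loglike,
                    coefficients=coefs, singular=singular, group_var=group_var,
                    random_effects=blups)


# ---------------------------------------------------------------------------
# enumeration + results
# ---------------------------------------------------------------------------

def enumerate_candidates(names: Sequence[str], max_terms: int = 3
                         ) -> list[tuple[str, ...]]:
    """Intercept-only plus every predictor subset of size 1..max_terms."""
    out: list[tuple[str, ...]] = [()]
    for size in range(1, max_terms + 1):
        out.extend(combinations(names, size))
    return out


@dataclass
class ModelSelectionResults:
    """Ranked candidate table with AICc, ΔAICc, Akaike weights and coefficients.

    ``table`` rows are ordered by (AICc, fewer terms, lexicographic terms);
    weights sum to 1 over the fitted candidates; ``top_set`` is ΔAICc < 2.
    """

    table: pd.DataFrame
    fits: dict[tuple[str, ...], ModelFit]
    skipped: dict[tuple[str, ...], str]
    n_obs: int
    region: str = "ARCH"
    kind: str = "ols"

    @property
    def best(self) -> ModelFit:
        return self.fits[tuple(self.table.iloc[0]["terms"])]

    @property
    def top_set(self) -> pd.DataFrame:
        """Predictor models with ΔAICc < 2 (the reference row excluded)."""
        tbl = self.table
        return tbl[(tbl["delta_aicc"] < TOP_SET_DELTA) & ~tbl["reference"]]

    @property
    def reference_delta(self) -> float:
        """ΔAICc of the intercept-only reference from the best model."""
        ref = self.table[self.table["reference"]]
        return float(ref["delta_aicc"].iloc[0]) if len(ref) else np.nan

    def weight_of(self, terms: Sequence[str]) -> float:
        key = " + ".join(terms) if terms else "(intercept)"
        row = self.table[self.table["model"] == key]
        return float(row["w"].iloc[0]) if len(row) else 0.0

    def term_in_top_set(self, term: str) -> bool:
        return any(term in t for t in self.top_set["terms"])

    def summary(self) -> str:
        lines = [
            f"Exhaustive {self.kind.upper()} AICc model selection "
            f"(region={self.region}, n={self.n_obs}, "
            f"{len(self.table)} candidates, {len(self.skipped)} skipped)",
            "=" * 78,
        ]
        tbl = self.table.copy()
        tbl["coefficients"] = tbl["terms"].map(
            lambda t: ", ".join(f"{k}={v:+.3g}" for k, v in self.fits[t].coefficients.items()
                                if k != "intercept") or "-"
        )
        cols = ["model", "K", "aicc", "delta_aicc", "w"]
        if "adj_r2" in tbl.columns and tbl["adj_r2"].notna().any():
            cols.insert(2, "adj_r2")
        with pd.option_context("display.width", 120, "display.max_rows", 25):
            lines.append(tbl[cols + ["coefficients"]].head(15).to_string(index=False,
                         float_format=lambda v: f"{v:0.3f}"))
        lines.append(f"top set (ΔAICc < {TOP_SET_DELTA}): "
                     + "; ".join(self.top_set["model"]))
        return "\n".join(lines)


def _rank_table(fits: dict[tuple[str, ...], ModelFit], kind: str) -> pd.DataFrame:
    """Rank candidates by (AICc, parsimony, name). The intercept-only model is
    the no-driver reference: it gets a ΔAICc but stays outside the Akaike
    weight normalization, which runs over the predictor subsets only."""
    rows = []
    for terms, f in fits.items():
        rows.append({"terms": terms,
                     "model": " + ".join(terms) if terms else "(intercept)",
                     "n_terms": len(terms), "K": f.k, "aicc": f.aicc,
                     "adj_r2": f.adj_r2, "loglike": f.loglike,
                     "singular": f.singular, "reference": len(terms) == 0})
    tbl = pd.DataFrame(rows)
    tbl = tbl.sort_values(["aicc", "n_terms", "model"], kind="mergesort").reset_index(drop=True)
    tbl["delta_aicc"] = tbl["aicc"] - tbl["aicc"].min()
    cand = ~tbl["reference"]
    rel = np.where(cand, np.exp(-0.5 * tbl["delta_aicc"].to_numpy()), 0.0)
    tbl["w"] = np.where(cand, rel / rel.sum(), np.nan) if cand.any() else np.nan
    return tbl


class ModelSelection:
    """Exhaustive OLS model selection of a response on predictor subsets.

    Parameters
    ----------
    y : response aligned to ``predictors`` rows (per-island composite AR in
        the seascape analysis; per-species correlation r in trait models).
    predictors : DataFrame of candidate predictor columns.
    max_terms : largest subset size (1-3 terms for n ~ 13 islands).
    sign_hypotheses : optional map predictor -> +1/-1; when given, top-set
        models whose coefficient signs oppose the hypothesis can be filtered
        by ``fit(sign_filter=True)``.
    """

    def __init__(self, y: pd.Series | np.ndarray, predictors: pd.DataFrame,
                 max_terms: int = 3, region: str = "ARCH",
                 sign_hypotheses: Mapping[str, int] | None = None):
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != len(predictors):
            raise ValueError("y and predictors must have the same length")
        self.predictors = predictors.reset_index(drop=True)
        self.max_terms = max_terms
        self.region = region
        self.sign_hypotheses = dict(sign_hypotheses or {})

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       predictors: Sequence[str], **kw) -> "ModelSelection":
        sub = data.dropna(subset=[response, *predictors])
        return cls(sub[response], sub[list(predictors)], **kw)

    def fit(self, sign_filter: bool = False) -> ModelSelectionResults:
        fits: dict[tuple[str, ...], ModelFit] = {}
        skipped: dict[tuple[str, ...], str] = {}
        for terms in enumerate_candidates(list(self.predictors.columns), self.max_terms):
            try:
                fits[terms] = fit_ols_aicc(
                    self.y, self.predictors[list(terms)] if terms else None)
            except DegenerateModelError as e:
                skipped[terms] = str(e)
        if not fits:
            raise DegenerateModelError("every candidate model was skipped")
        if sign_filter and self.sign_hypotheses:
            fits = {t: f for t, f in fits.items()
                    if all(np.sign(f.coefficients[nm]) == self.sign_hypotheses.get(nm, np.sign(f.coefficients[nm]))
                           for nm in t)} or fits
        table = _rank_table(fits, "ols")
        return ModelSelectionResults(table=table, fits=fits, skipped=skipped,
                                     n_obs=len(self.y), region=self.region, kind="ols")


class MixedModelSelection:
    """Exhaustive random-intercept mixed-model selection on long AR records.

    Same candidate enumeration as :class:`ModelSelection`; records carry a
    ``group`` column (species-by-marker label) and per-record predictor
    values joined from the island table.
    """

    def __init__(self, records: pd.DataFrame, predictors: Sequence[str],
                 max_terms: int = 3, region: str = "ARCH",
                 group_col: str = "group", response: str = "ar"):
        self.records = records.dropna(subset=[response, *predictors]).reset_index(drop=True)
        self.predictor_names = list(predictors)
        self.max_terms = max_terms
        self.region = region
        self.group_col = group_col
        self.response = response

    def fit(self) -> ModelSelectionResults:
        fits: dict[tuple[str, ...], ModelFit] = {}
        skipped: dict[tuple[str, ...], str] = {}
        for terms in enumerate_candidates(self.predictor_names, self.max_terms):
            try:
                fits[terms] = fit_mixed_aicc(self.records, terms,
                                             group_col=self.group_col,
                                             response=self.response)
            except (DegenerateModelError, np.linalg.LinAlgError, ValueError) as e:
                skipped[terms] = str(e)
        if not fits:
            raise DegenerateModelError("every candidate mixed model was skipped")
        table = _rank_table(fits, "mixed")
        return ModelSelectionResults(table=table, fits=fits, skipped=skipped,
                                     n_obs=len(self.records), region=self.region,
                                     kind="mixed")


def exhaustive_model_selection(y, predictors: pd.DataFrame, max_terms: int = 3,
                               region: str = "ARCH",
                               sign_hypotheses: Mapping[str, int] | None = None,
                               sign_filter: bool = False) -> ModelSelectionResults:
    """Functional wrapper around :class:`ModelSelection`."""
    return ModelSelection(y, predictors, max_terms=max_terms, region=region,
                          sign_hypotheses=sign_hypotheses).fit(sign_filter=sign_filter)


# ---------------------------------------------------------------------------
# colinearity screen, quadratic fit, trait models
# ---------------------------------------------------------------------------

def colinearity_screen(data: "pd.DataFrame | object", predictors: Sequence[str],
                       threshold: float = 0.7
                       ) -> tuple[list[str], pd.DataFrame]:
    """Greedy colinearity pre-screen of candidate predictors.

    While any pair has |r| >= threshold, drop the member with the larger
    mean |r| to the other predictors. Returns the retained names and the
    full pairwise correlation matrix of the original set.
    """
    df = getattr(data, "data", data)
    if len(df) < 3:
        raise ValueError("need >= 3 islands for a correlation screen")
    sub = df[list(predictors)].dropna()
    corr = sub.corr()
    retained = list(predictors)
    while True:
        worst_pair, worst = None, threshold
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                if abs(corr.loc[a, b]) >= worst:
                    worst, worst_pair = abs(corr.loc[a, b]), (a, b)
        if worst_pair is None:
            break
        a, b = worst_pair
        others_a = [abs(corr.loc[a, c]) for c in retained if c not in (a, b)]
        others_b = [abs(corr.loc[b, c]) for c in retained if c not in (a, b)]
        mean_a = np.mean(others_a + [abs(corr.loc[a, b])])
        mean_b = np.mean(others_b + [abs(corr.loc[a, b])])
        drop = a if mean_a >= mean_b else b
        logger.info("colinearity screen: dropping %s (|r|=%.2f with %s)",
                    drop, worst, b if drop == a else a)
        retained.remove(drop)
    return retained, corr


@dataclass
class QuadraticFit:
    r2: float
    p: float
    coefficients: dict[str, float]


def quadratic_fit(y, x) -> QuadraticFit:
    """OLS of y on [x, x^2]: the margins-vs-centre curvature test.

    Returns unadjusted r^2, the overall-F p-value and the coefficients; a
    positive x^2 coefficient means higher values at both margins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError("need n >= 4 for a quadratic fit")
    if np.ptp(x) == 0:
        raise ValueError("constant x; quadratic fit undefined")
    X = sm.add_constant(np.column_stack([x, x ** 2]))
    fit = sm.OLS(y, X).fit()
    return QuadraticFit(r2=float(fit.rsquared), p=float(fit.f_pvalue),
                        coefficients={"intercept": float(fit.params[0]),
                                      "x": float(fit.params[1]),
                                      "x2": float(fit.params[2])})


def trait_models(profile, traits, drivers: Sequence[str] | None = None,
                 trait_columns: Sequence[str] | None = None,
                 covariates: Sequence[str] | None = None,
                 max_terms: int = 3) -> dict[str, ModelSelectionResults]:
    """Which species traits explain which species respond to which drivers.

    For each driver column of the correlation profile, runs the exhaustive
    OLS enumeration with species traits as predictors (listwise-complete
    species). When ``covariates`` are given, the response is first
    residualized on them (partial mode for sampling artefacts: number of
    islands, marker type, total marker diversity).
    """
    from .congruence import CorrelationProfile
    prof = profile.data if isinstance(profile, CorrelationProfile) else profile
    tdf = getattr(traits, "data", traits)
    trait_columns = list(trait_columns or [c for c in tdf.columns
                                           if c not in ("species",)])
    responses = drivers or [c[2:] for c in prof.columns if c.startswith("r_")]
    out: dict[str, ModelSelectionResults] = {}
    for drv in responses:
        col = f"r_{drv}" if f"r_{drv}" in prof.columns else drv
        merged = prof[[col]].join(tdf.set_index("species")
                                  if "species" in tdf.columns and tdf.index.name != "species"
                                  else tdf, how="inner")
        use_cols = [col] + trait_columns + list(covariates or [])
        merged = merged.dropna(subset=[c for c in use_cols if c in merged.columns])
        if len(merged) == 0:
            continue
        y = merged[col].to_numpy(dtype=float)
        if covariates:
            Z = sm.add_constant(merged[list(covariates)].to_numpy(dtype=float))
            y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        try:
            out[drv] = ModelSelection(y, merged[trait_columns],
                                      max_terms=max_terms, region="ARCH").fit()
        except DegenerateModelError as e:
            logger.warning("trait models for driver %s skipped: %s", drv, e)
    return out
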