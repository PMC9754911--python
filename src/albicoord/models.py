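"""Mixed-model selection, averaging, and the coordination report.

The stage-specific analysis fits linear mixed models of sqrt trip
duration on the focal and partner covariates, with random intercepts for
pair and year and a random slope of the partner's previous-trip
deviation by pair (so coordination strength may vary between pairs).
The crossed random structure is expressed through variance components in
a single statsmodels ``MixedLM`` group; the pair intercept and pair
slope are independent components (see the methods note).

Selection follows small-sample information-theoretic practice:

1. every fixed-effect subset of the global model that respects
   marginality (quadratics require their linear term, interactions their
   main effects) is fitted by maximum likelihood so likelihoods are
   comparable, and ranked by AICc;
2. the best-supported set is the models within ΔAICc < 2 of the top;
3. models that merely add terms to a lower-AICc model in the set
   (nested, more complex versions) are excluded;
4. the survivors are model-averaged with Akaike weights.  Averaging is
   conditional ("natural"): a term is averaged over the models that
   contain it, with its presence weight reported separately.  Terms
   participating in retained interactions are flagged and suppressed
   from the primary estimate table, as averaging across interaction
   structures is not interpretable.

Reported coefficients come from REML refits of the final set; ranking
always uses ML.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams, VCSpec

__all__ = [
    "GLOBAL_MAIN_TERMS",
    "GLOBAL_INTERACTIONS",
    "ModelSpec",
    "FitResult",
    "fit_lmm",
    "aicc",
    "enumerate_specs",
    "rank_all",
    "best_set",
    "exclude_nested",
    "akaike_weights",
    "model_average",
    "r2_nakagawa",
    "select_and_average",
    "coordination_report",
]

#: Fixed-effect mains of the global model (the coordination term is
#: ``partner_prev_dev``).
GLOBAL_MAIN_TERMS = (
    "focal_age",
    "focal_age2",
    "partner_age",
    "partner_age2",
    "focal_boldness",
    "partner_boldness",
    "date",
    "new_partner",
    "partner_prev_dev",
    "sex",
)

#: Interactions of the global model: trait modulation of the coordination
#: slope, age-by-own-boldness, and sex-specific boldness effects.
GLOBAL_INTERACTIONS = (
    "focal_boldness:focal_age",
    "focal_boldness:focal_age2",
    "focal_age:partner_prev_dev",
    "focal_age2:partner_prev_dev",
    "focal_boldness:partner_prev_dev",
    "new_partner:partner_prev_dev",
    "partner_boldness:partner_age",
    "partner_boldness:partner_age2",
    "partner_age:partner_prev_dev",
    "partner_age2:partner_prev_dev",
    "partner_boldness:partner_prev_dev",
    "focal_boldness:sex",
    "partner_boldness:sex",
)

_COLUMN_OF = {"sex": "sex_male"}
_QUADRATIC_OF = {"focal_age2": "focal_age", "partner_age2": "partner_age"}


def term_column(table: pd.DataFrame, term: str) -> np.ndarray:
    """Design column for a term; interactions are products of their parts."""
    if ":" in term:
        a, b = term.split(":")
        return term_column(table, a) * term_column(table, b)
    col = _COLUMN_OF.get(term, term)
    if col not in table.columns:
        raise KeyError(f"model table has no column for term {term!r}")
    return table[col].to_numpy(dtype=float)


def required_terms(term: str) -> set:
    """Marginality: terms that must accompany ``term`` in any model."""
    out = set()
    if ":" in term:
        for part in term.split(":"):
            out.add(part)
            out |= required_terms(part)
    elif term in _QUADRATIC_OF:
        out.add(_QUADRATIC_OF[term])
    return out


@dataclass(frozen=True)
class ModelSpec:
    """A candidate fixed-effect structure (random structure is fixed)."""

    terms: tuple
    stage: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(sorted(self.terms)))
        for t in self.terms:
            missing = required_terms(t) - set(self.terms)
            if missing:
                raise ValueError(
                    f"term {t!r} violates marginality; missing {sorted(missing)}"
                )

    def __contains__(self, term: str) -> bool:
        return term in self.terms


def enumerate_specs(
    global_terms, stage: str | None = None, limit: int | None = 200_000
) -> list[ModelSpec]:
    """All marginality-valid subsets of the global terms (incl. null model).

    ``limit`` guards against accidental combinatorial explosions with
    large global sets; pass ``None`` to lift it.
    """
    terms = list(dict.fromkeys(global_terms))
    for t in terms:
        missing = required_terms(t) - set(terms)
        if missing:
            raise ValueError(f"global set lacks {sorted(missing)} required by {t!r}")
    specs = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            chosen = set(combo)
            if all(required_terms(t) <= chosen for t in combo):
                specs.append(ModelSpec(terms=combo, stage=stage))
                if limit is not None and len(specs) > limit:
                    raise ValueError(
                        f"more than {limit} candidate models; reduce the "
                        "global set or raise `limit`"
                    )
    return specs


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: ``-2 logLik + 2k + 2k(k+1)/(n-k-1)``."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (needs n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class FitResult:
    """One fitted candidate: coefficients, variance components, AICc."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    vcomp: dict  # {"pair", "pair_slope", "year"} -> variance
    resid_var: float
    llf: float
    k: int
    n: int
    aicc: float
    converged: bool
    singular: bool
    method: str
    var_fixed: float
    mean_dev_sq: float
    results: object | None = field(default=None, repr=False)

    @property
    def delta(self) -> float:  # set by rank_all
        return getattr(self, "_delta", float("nan"))


_VC_NAMES = ("pair", "pair_slope", "year")


def _build_vcspec(table: pd.DataFrame) -> VCSpec:
    pair_d = pd.get_dummies(table["pair_id"]).to_numpy(dtype=float)
    pair_names = [str(c) for c in pd.get_dummies(table["pair_id"]).columns]
    year_d = pd.get_dummies(table["season"]).to_numpy(dtype=float)
    year_names = [str(c) for c in pd.get_dummies(table["season"]).columns]
    slope_d = pair_d * table["partner_prev_dev"].to_numpy(dtype=float)[:, None]
    return VCSpec(
        list(_VC_NAMES),
        [[pair_names], [pair_names], [year_names]],
        [[pair_d], [slope_d], [year_d]],
    )


def fit_lmm(
    table: pd.DataFrame,
    spec: ModelSpec | tuple,
    method: str = "ml",
    start: MixedLMParams | None = None,
    optimizer: str = "powell",
    store_results: bool = False,
    singular_tol: float = 1e-4,
    fit_kwargs: dict | None = None,
    _vcspec: VCSpec | None = None,
) -> FitResult:
    """Fit one candidate model with the fixed random structure.

    Random structure (identical for every spec): pair and year random
    intercepts plus a by-pair random slope on the scaled partner
    deviation, fitted as independent variance components.  ``method`` is
    "ml" for ranking (likelihoods comparable across fixed structures) or
    "reml" for reported coefficients.  A near-zero variance component
    marks the fit singular — retained, since a vanishing random-slope
    variance is itself a finding (little interpair variation in
    coordination strength) — while a non-converged fit is excluded from
    ranking by :func:`rank_all`.
    """
    if not isinstance(spec, ModelSpec):
        spec = ModelSpec(terms=tuple(spec))
    if method not in ("ml", "reml"):
        raise ValueError(f"method must be 'ml' or 'reml', got {method!r}")
    names = ["Intercept"] + list(spec.terms)
    X = np.column_stack(
        [np.ones(len(table))] + [term_column(table, t) for t in spec.terms]
    )
    y = table["resp_sqrt_h"].to_numpy(dtype=float)
    vcs = _vcspec if _vcspec is not None else _build_vcspec(table)
    model = MixedLM(y, X, groups=np.ones(len(table)), exog_vc=vcs)
    # an optimizer's line search can wander into variance values that make
    # the inner solver singular; fall back through optimizers/starts
    attempts = [
        (optimizer, start, fit_kwargs or {}),
        (optimizer, None, {}),
        ("nm", start, {}),
        ("bfgs", None, {}),
    ]
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for opt, st, kw in attempts:
            try:
                res = model.fit(
                    reml=(method == "reml"), method=opt, start_params=st, **kw
                )
                break
            except (np.linalg.LinAlgError, ValueError, OverflowError):
                continue
    if res is None:
        raise RuntimeError(
            f"mixed-model fit failed for terms {spec.terms} under every optimizer"
        )
    vcomp = {nm: float(v) for nm, v in zip(_VC_NAMES, res.vcomp)}
    k = X.shape[1] + len(_VC_NAMES) + 1
    n = len(table)
    llf = float(res.llf)
    converged = bool(res.converged) and np.isfinite(llf)
    singular = any(v < singular_tol * float(res.scale) for v in res.vcomp)
    params = pd.Series(np.asarray(res.fe_params), index=names)
    with warnings.catch_warnings():
        # bse is computed lazily; boundary variance estimates can make
        # single cov_params diagonal entries slightly negative
        warnings.simplefilter("ignore")
        bse = pd.Series(np.asarray(res.bse_fe), index=names)
    xb = X @ np.asarray(res.fe_params)
    dev = table["partner_prev_dev"].to_numpy(dtype=float)
    return FitResult(
        spec=spec,
        params=params,
        bse=bse,
        vcomp=vcomp,
        resid_var=float(res.scale),
        llf=llf,
        k=k,
        n=n,
        aicc=aicc(llf, k, n) if converged else float("nan"),
        converged=converged,
        singular=singular,
        method=method,
        var_fixed=float(np.var(xb)),
        mean_dev_sq=float(np.mean(dev**2)),
        results=res if store_results else None,
    )


@dataclass
class RankedModels:
    """All converged candidates, ranked by AICc."""

    fits: list  # FitResult, ascending AICc
    table: pd.DataFrame  # terms, k, llf, aicc, delta, weight, singular
    n_candidates: int
    n_nonconverged: int


def rank_all(
    table: pd.DataFrame,
    global_terms,
    stage: str | None = None,
    limit: int | None = 200_000,
    ranking_tol: float | None = 2e-3,
) -> RankedModels:
    """Fit and rank every marginality-valid submodel of the global set.

    The global model is fitted first; its variance parameters warm-start
    every submodel fit (the profiled ML surface is over the same three
    variance components whatever the fixed terms).  Ranking fits use a
    slightly relaxed optimizer tolerance (``ranking_tol``; the induced
    logLik error is orders of magnitude below the ΔAICc < 2 resolution);
    reported models are refitted at full precision downstream.
    Non-converged fits are dropped from the ranking with a count.
    """
    specs = enumerate_specs(global_terms, stage=stage, limit=limit)
    vcs = _build_vcspec(table)
    glob = fit_lmm(table, ModelSpec(tuple(global_terms), stage), _vcspec=vcs)
    start = None
    if glob.converged and glob.resid_var > 0:
        start = MixedLMParams.from_components(
            cov_re=np.empty((0, 0)),
            vcomp=np.array([glob.vcomp[nm] for nm in _VC_NAMES]) / glob.resid_var,
        )
    loose = dict(xtol=ranking_tol, ftol=ranking_tol) if ranking_tol else None
    fits = []
    n_bad = 0
    for spec in specs:
        if spec.terms == glob.spec.terms:
            fit = glob
        else:
            fit = fit_lmm(table, spec, start=start, fit_kwargs=loose, _vcspec=vcs)
        if fit.converged:
            fits.append(fit)
        else:
            n_bad += 1
    if not fits:
        raise RuntimeError("no candidate model converged")
    fits.sort(key=lambda f: f.aicc)
    amin = fits[0].aicc
    for f in fits:
        f._delta = f.aicc - amin
    weights = akaike_weights([f.aicc for f in fits])
    ranked = pd.DataFrame(
        {
            "terms": [" + ".join(f.spec.terms) or "(intercept only)" for f in fits],
            "n_terms": [len(f.spec.terms) for f in fits],
            "k": [f.k for f in fits],
            "llf": [f.llf for f in fits],
            "aicc": [f.aicc for f in fits],
            "delta": [f._delta for f in fits],
            "weight": weights,
            "singular": [f.singular for f in fits],
        }
    )
    return RankedModels(
        fits=fits, table=ranked, n_candidates=len(specs), n_nonconverged=n_bad
    )


def best_set(fits: list, delta: float = 2.0) -> list:
    """Fits within ``delta`` AICc of the best (strict <), ascending."""
    fits = sorted(fits, key=lambda f: f.aicc)
    amin = fits[0].aicc
    return [f for f in fits if f.aicc - amin < delta]


def exclude_nested(fits: list) -> list:
    """Drop models that are more complex versions of better simpler models.

    A model is removed iff the set contains another model whose terms
    are a strict subset of its terms and whose AICc is lower.
    """
    keep = []
    for f in fits:
        terms = set(f.spec.terms)
        dominated = any(
            set(g.spec.terms) < terms and g.aicc < f.aicc for g in fits
        )
        if not dominated:
            keep.append(f)
    return sorted(keep, key=lambda f: f.aicc)


def akaike_weights(aiccs) -> np.ndarray:
    """Normalized Akaike weights ``w_i = exp(-delta_i/2) / sum``."""
    a = np.asarray(aiccs, dtype=float)
    w = np.exp(-0.5 * (a - a.min()))
    return w / w.sum()


@dataclass
class AveragedEstimates:
    """Model-averaged coefficients over the post-exclusion best set."""

    table: pd.DataFrame  # term, estimate, unconditional_se, presence_weight,
    #                      n_models, suppressed
    weights: np.ndarray
    terms: tuple
    method: str  # "conditional" | "full"

    def estimate(self, term: str) -> tuple[float, float] | None:
        """(estimate, SE) for a term, or None when absent from the set."""
        row = self.table[self.table["term"] == term]
        if len(row) == 0:
            return None
        return float(row["estimate"].iloc[0]), float(row["unconditional_se"].iloc[0])


def model_average(fits: list, method: str = "conditional") -> AveragedEstimates:
    """Akaike-weighted averaging over a (post-exclusion) model set.

    ``conditional`` (default) averages each term over the models that
    contain it with renormalized weights; ``full`` substitutes zero
    (with zero SE) where a term is absent.  Unconditional standard
    errors combine within-model sampling variance with between-model
    spread: ``sqrt(sum_i w_i (se_i^2 + (b_i - b_bar)^2))``.  Terms in
    retained interactions (and those interactions' main effects) are
    flagged ``suppressed``.
    """
    if not fits:
        raise ValueError("cannot average an empty model set")
    if method not in ("conditional", "full"):
        raise ValueError(f"unknown averaging method {method!r}")
    weights = akaike_weights([f.aicc for f in fits])
    all_terms = ["Intercept"] + sorted(
        {t for f in fits for t in f.spec.terms}
    )
    in_interaction = set()
    for f in fits:
        for t in f.spec.terms:
            if ":" in t:
                in_interaction.add(t)
                in_interaction |= {p for p in t.split(":")}
    rows = []
    for term in all_terms:
        present = np.array(
            [term == "Intercept" or term in f.spec for f in fits]
        )
        presence_weight = float(weights[present].sum())
        if method == "conditional":
            w = weights[present] / weights[present].sum()
            b = np.array([f.params[term] for f, p in zip(fits, present) if p])
            se = np.array([f.bse[term] for f, p in zip(fits, present) if p])
        else:
            w = weights
            b = np.array(
                [f.params[term] if p else 0.0 for f, p in zip(fits, present)]
            )
            se = np.array([f.bse[term] if p else 0.0 for f, p in zip(fits, present)])
        est = float(np.sum(w * b))
        use = float(np.sqrt(np.sum(w * (se**2 + (b - est) ** 2))))
        rows.append(
            {
                "term": term,
                "estimate": est,
                "unconditional_se": use,
                "presence_weight": presence_weight,
                "n_models": int(present.sum()),
                "suppressed": term in in_interaction,
            }
        )
    return AveragedEstimates(
        table=pd.DataFrame(rows),
        weights=weights,
        terms=tuple(all_terms),
        method=method,
    )


def r2_nakagawa(fit: FitResult) -> tuple[float, float]:
    """Marginal and conditional R² for a mixed model.

    Marginal: variance of the fixed-effect predictor over the total
    (fixed + random + residual).  Conditional adds the random variances
    to the numerator.  The by-pair random slope contributes its variance
    weighted by the mean squared slope covariate.
    """
    var_random = (
        fit.vcomp["pair"]
        + fit.vcomp["pair_slope"] * fit.mean_dev_sq
        + fit.vcomp["year"]
    )
    total = fit.var_fixed + var_random + fit.resid_var
    return fit.var_fixed / total, (fit.var_fixed + var_random) / total


@dataclass
class SelectionResult:
    """Full selection pipeline output for one stage."""

    stage: str | None
    ranked: RankedModels
    best: list  # post-exclusion best set (ML fits)
    best_reml: list  # REML refits of the same specs
    averaged: AveragedEstimates
    delta: float


def select_and_average(
    table: pd.DataFrame,
    global_terms,
    stage: str | None = None,
    delta: float = 2.0,
    averaging: str = "conditional",
    reml_refit: bool = True,
    limit: int | None = 200_000,
) -> SelectionResult:
    """Rank all submodels, extract ΔAICc < delta, drop nested, average.

    Weights come from the ML AICc of the post-exclusion set; reported
    coefficients come from REML refits of those specs (standard practice
    for mixed models: ML for comparing fixed structures, REML for
    estimates).
    """
    ranked = rank_all(table, global_terms, stage=stage, limit=limit)
    best = exclude_nested(best_set(ranked.fits, delta=delta))
    if reml_refit:
        vcs = _build_vcspec(table)
        refits = []
        for f in best:
            r = fit_lmm(table, f.spec, method="reml", _vcspec=vcs, store_results=True)
            r.aicc = f.aicc  # weights stay on the ML scale
            refits.append(r)
    else:
        refits = best
    averaged = model_average(refits, method=averaging)
    return SelectionResult(
        stage=stage,
        ranked=ranked,
        best=best,
        best_reml=refits,
        averaged=averaged,
        delta=delta,
    )


def summary_table(sel: "SelectionResult", global_terms) -> pd.DataFrame:
    """Publication-style estimate table over the full global term set.

    One row per global term: whether any post-exclusion best model
    retained it, and the averaged estimate ± unconditional SE.  Terms
    suppressed because they participate in retained interactions show
    retained = "Y" with blank estimates, mirroring the convention of
    reporting such terms only in the per-model supplementary output.
    """
    rows = []
    for term in ["Intercept"] + list(global_terms):
        est = sel.averaged.estimate(term)
        sup = False
        if est is not None:
            sup = bool(
                sel.averaged.table.loc[
                    sel.averaged.table["term"] == term, "suppressed"
                ].iloc[0]
            )
        rows.append(
            {
                "term": term,
                "retained": "Y" if est is not None else "N",
                "estimate": np.nan if (est is None or sup) else est[0],
                "se": np.nan if (est is None or sup) else est[1],
                "suppressed": sup,
            }
        )
    return pd.DataFrame(rows)


def pair_slopes(fit: FitResult) -> pd.Series | None:
    """Per-pair predicted coordination slopes (fixed slope + pair BLUP).

    Requires a fit stored with ``store_results=True``; returns None when
    the coordination term is absent from the fixed structure (the random
    slope BLUPs alone are deviations around zero in that model).
    """
    if fit.results is None:
        raise ValueError("fit was not stored with store_results=True")
    if "partner_prev_dev" not in fit.params.index:
        return None
    fixed = float(fit.params["partner_prev_dev"])
    re = fit.results.random_effects
    (series,) = re.values()  # single group
    blups = {
        name.split("[", 1)[1].rstrip("]"): float(val) + fixed
        for name, val in series.items()
        if name.startswith("pair_slope[")
    }
    return pd.Series(blups).sort_index()


def coordination_report(
    stage_results: dict,
) -> pd.DataFrame:
    """Summarize coordination evidence per breeding stage.

    ``stage_results`` maps stage name to a :class:`SelectionResult`.
    Reports the averaged coordination slope ± unconditional SE (absent,
    not zero, when no best model retains the term), the SD of the
    by-pair random slope, and any retained interactions with the
    coordination term (evidence of trait-dependent coordination).
    """
    rows = []
    for stage, sel in stage_results.items():
        est = sel.averaged.estimate("partner_prev_dev")
        retained = est is not None
        dev_fits = [f for f in sel.best_reml if "partner_prev_dev" in f.spec]
        src = dev_fits[0] if dev_fits else sel.best_reml[0]
        inter = sorted(
            {
                t
                for f in sel.best
                for t in f.spec.terms
                if ":" in t and "partner_prev_dev" in t.split(":")
            }
        )
        marg, cond = r2_nakagawa(src)
        rows.append(
            {
                "stage": stage,
                "coordination_retained": retained,
                "coordination_slope": est[0] if retained else np.nan,
                "coordination_se": est[1] if retained else np.nan,
                "random_slope_sd": float(np.sqrt(src.vcomp["pair_slope"])),
                "retained_dev_interactions": ";".join(inter),
                "marginal_r2": marg,
                "conditional_r2": cond,
                "n_best_models": len(sel.best),
                "n_candidates": sel.ranked.n_candidates,
                "n_nonconverged": sel.ranked.n_nonconverged,
            }
        )
    return pd.DataFrame(rows)
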