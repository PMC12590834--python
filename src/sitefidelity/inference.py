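"""Mixed-model, model-averaging and survival inference.

Three layers mirror the study design:

1. `FidelityModelSet` — linear mixed models of ln(fidelity distance) on
   environmental predictability (spatial/temporal constancy), home-range
   quality (mean suitable biomass) and previous reproductive success,
   always controlling for home-range size, with a random intercept for
   animal (annual scale) or animal-year (finer scales).  Candidate
   sub-models are screened for collinearity (|r| > 0.6 splits a
   sub-model), fitted by maximum likelihood, and combined by AICc model
   averaging over the 95% confidence set.  Interaction sub-models are
   generated but excluded from the averaging set by default; inference
   rests on the additive set.
2. Condition models — autumn body fat (and spring-to-autumn fat accrual,
   with spring fat as the state variable) on fidelity and recruitment.
3. `NeonateSurvivalModel` — Andersen-Gill Cox proportional hazards of
   neonate mortality over [0, 120] days on maternal fidelity, with a
   cluster-robust (sandwich) variance on mother identity; a Mann-Whitney
   comparison serves where events are too few for the Cox model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

__all__ = [
    "CandidateModelSpec",
    "LMMFit",
    "ModelAveragingResult",
    "CoxResult",
    "assemble_table",
    "standardize_covariates",
    "screen_collinearity",
    "candidate_sets",
    "fit_lmm",
    "aicc_model_average",
    "FidelityModelSet",
    "fit_condition_models",
    "NeonateSurvivalModel",
    "fit_neonate_survival",
    "mann_whitney_fidelity",
]

PREDICTABILITY = ("spatial_C", "temporal_C")
QUALITY = ("mean_biomass",)
HR_SIZE = "hr_area_km2"
CONTINUOUS_COVARIATES = (*PREDICTABILITY, *QUALITY, HR_SIZE)
Z95 = 1.959963984540054


@dataclass(frozen=True)
class CandidateModelSpec:
    name: str
    terms: tuple  # main-effect columns; interactions written "a:b"
    set_name: str  # heterogeneity | success | combined
    additive: bool = True

    @property
    def main_terms(self) -> tuple:
        return tuple(t for t in self.terms if ":" not in t)

    def with_terms(self, terms, suffix: str) -> "CandidateModelSpec":
        return replace(self, name=f"{self.name}.{suffix}", terms=tuple(terms))


@dataclass(frozen=True)
class LMMFit:
    spec: CandidateModelSpec
    params: pd.Series  # fixed effects incl. Intercept
    bse: pd.Series
    llf: float
    k: int  # fixed effects + RE variance + residual variance
    n: int
    converged: bool
    singular: bool


def assemble_table(
    fidelity_df: pd.DataFrame,
    constancy_df: pd.DataFrame,
    recruitment_df: pd.DataFrame,
    homerange_df: pd.DataFrame,
    scale: str,
) -> pd.DataFrame:
    """Inner-join metric tables on (animal_id, year, index) for one scale.

    Rows with unknown recruitment are dropped; continuous covariates are
    standardized within scale x site; the grouping factor is animal at the
    annual scale and animal-year otherwise.
    """
    keys = ["animal_id", "year", "index"]
    for name, df in (
        ("fidelity", fidelity_df),
        ("constancy", constancy_df),
        ("recruitment", recruitment_df),
        ("homerange", homerange_df),
    ):
        if df.duplicated(keys).any():
            raise ValueError(f"duplicate {keys} keys in {name} table")
    out = (
        fidelity_df.merge(constancy_df, on=keys)
        .merge(recruitment_df, on=keys)
        .merge(homerange_df, on=keys)
    )
    if out.empty:
        warnings.warn("assembled table is empty (disjoint keys)")
        return out
    n0 = len(out)
    out = out[out["status"] != "unknown"].copy()
    if len(out) < n0:
        warnings.warn(f"dropped {n0 - len(out)} rows with unknown recruitment")
    out["recruit"] = (out["status"] == "success").astype(int)
    from .fidelity import log_distance

    out["log_distance"] = log_distance(out["distance_m"].to_numpy())
    if "site_id" not in out:
        out["site_id"] = "S1"
    out["scale"] = scale
    out["group"] = (
        out["animal_id"]
        if scale == "annual"
        else out["animal_id"].astype(str) + ":" + out["year"].astype(str)
    )
    return standardize_covariates(out.reset_index(drop=True))


def standardize_covariates(table: pd.DataFrame, columns=CONTINUOUS_COVARIATES):
    """Mean-0 / sd-1 scaling within scale x site; stats kept in attrs."""
    table = table.copy()
    stats_rec = {}
    for col in columns:
        if col not in table:
            continue
        grp = table.groupby(["scale", "site_id"])[col]
        mu, sd = grp.transform("mean"), grp.transform("std").replace(0, np.nan)
        stats_rec[col] = {
            "mean": grp.mean().to_dict(),
            "sd": grp.std().to_dict(),
        }
        table[col] = ((table[col] - mu) / sd).fillna(0.0)
    table.attrs["standardization"] = stats_rec
    return table


def candidate_sets(scale: str, include_interactions: bool = True):
    """The hypothesis-driven candidate sub-model sets (home-range size in all)."""
    pred = list(PREDICTABILITY)
    qual = list(QUALITY)
    specs = [
        CandidateModelSpec("het.predictability", (*pred,), "heterogeneity"),
        CandidateModelSpec("het.quality", (*qual,), "heterogeneity"),
        CandidateModelSpec("het.pred+qual", (*pred, *qual), "heterogeneity"),
        CandidateModelSpec(
            "het.predxqual",
            (*pred, *qual, *(f"{p}:{q}" for p in pred for q in qual)),
            "heterogeneity",
            additive=False,
        ),
        CandidateModelSpec("succ.recruit", ("recruit",), "success"),
        CandidateModelSpec("comb.pred+recruit", (*pred, "recruit"), "combined"),
        CandidateModelSpec("comb.qual+recruit", (*qual, "recruit"), "combined"),
        CandidateModelSpec(
            "comb.pred+qual+recruit", (*pred, *qual, "recruit"), "combined"
        ),
        CandidateModelSpec(
            "comb.predxrecruit",
            (*pred, "recruit", *(f"{p}:recruit" for p in pred)),
            "combined",
            additive=False,
        ),
        CandidateModelSpec(
            "comb.qualxrecruit",
            (*qual, "recruit", *(f"{q}:recruit" for q in qual)),
            "combined",
            additive=False,
        ),
        CandidateModelSpec(
            "comb.predxrecruit+qualxrecruit",
            (
                *pred,
                *qual,
                "recruit",
                *(f"{p}:recruit" for p in pred),
                *(f"{q}:recruit" for q in qual),
            ),
            "combined",
            additive=False,
        ),
    ]
    specs = [replace(s, terms=(*s.terms, HR_SIZE)) for s in specs]
    if not include_interactions:
        specs = [s for s in specs if s.additive]
    return specs


def screen_collinearity(table: pd.DataFrame, specs, r_max: float = 0.6):
    """Split sub-models whose covariate pairs exceed |r| > r_max.

    Constant covariates (undefined r) are removed from every sub-model
    with a warning.  Splitting removes one member of the first offending
    pair at a time and recurses; duplicate term sets are dropped.
    """
    continuous = [c for c in CONTINUOUS_COVARIATES if c in table.columns]
    constant = [c for c in continuous if table[c].nunique() <= 1]
    for c in constant:
        warnings.warn(f"covariate {c} is constant; removed from all sub-models")
    usable = [c for c in continuous if c not in constant]
    corr = table[usable].corr() if len(usable) >= 2 else pd.DataFrame()

    def offending_pair(terms):
        mains = [t for t in terms if ":" not in t and t in usable]
        for i, a in enumerate(mains):
            for b in mains[i + 1 :]:
                if abs(corr.loc[a, b]) > r_max:
                    return a, b
        return None

    def expand(spec: CandidateModelSpec):
        terms = tuple(
            t
            for t in spec.terms
            if not any(part in constant for part in t.split(":"))
        )
        spec = replace(spec, terms=terms)
        pair = offending_pair(spec.terms)
        if pair is None:
            return [spec]
        out = []
        for drop in pair:
            kept = tuple(
                t for t in spec.terms if drop not in t.split(":")
            )
            out.extend(expand(spec.with_terms(kept, f"no_{drop}")))
        return out

    seen, final = set(), []
    for spec in specs:
        for v in expand(spec):
            key = frozenset(v.terms)
            if key not in seen and v.terms:
                seen.add(key)
                final.append(v)
    return final


def _design_matrix(table: pd.DataFrame, terms) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    for t in terms:
        if ":" in t:
            a, b = t.split(":")
            X[t] = table[a].to_numpy() * table[b].to_numpy()
        else:
            X[t] = table[t].to_numpy(dtype=float)
    return sm.add_constant(X, has_constant="add").rename(columns={"const": "Intercept"})


def fit_lmm(
    spec: CandidateModelSpec, table: pd.DataFrame, group_col: str = "group"
) -> LMMFit:
    """Gaussian LMM with a single random intercept, fitted by ML.

    ML (not REML) keeps log-likelihoods comparable across fixed-effect
    structures for AICc.
    """
    X = _design_matrix(table, spec.terms)
    y = table["log_distance"].to_numpy(dtype=float)
    k = X.shape[1] + 2  # fixed effects + RE variance + residual variance
    if len(table) < k + 2:
        raise ValueError(f"{spec.name}: {len(table)} rows < k + 2 = {k + 2}")
    model = sm.MixedLM(y, X, groups=table[group_col])
    singular = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False)
            converged = bool(res.converged)
        except Exception:  # fall back to a more robust optimizer
            res = model.fit(reml=False, method="powell")
            converged = bool(res.converged)
        if float(np.asarray(res.cov_re).ravel()[0]) < 1e-8:
            singular = True
    return LMMFit(
        spec=spec,
        params=res.fe_params.copy(),
        bse=res.bse_fe.copy(),
        llf=float(res.llf),
        k=k,
        n=len(table),
        converged=converged,
        singular=singular,
    )


def _aicc(llf: float, k: int, n: int) -> float:
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass(frozen=True)
class ModelAveragingResult:
    """AICc table, 95% confidence set and model-averaged coefficients."""

    model_table: pd.DataFrame
    coefficients: pd.DataFrame
    fits: tuple = field(repr=False, default=())

    def summary(self) -> str:
        lines = ["AICc model comparison", "=" * 72]
        lines.append(
            self.model_table.to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            )
        )
        lines.append("")
        lines.append("Model-averaged coefficients (95% confidence set)")
        lines.append("=" * 72)
        lines.append(
            self.coefficients.to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            )
        )
        return "\n".join(lines)


def aicc_model_average(fits, conf_level: float = 0.95) -> ModelAveragingResult:
    """Akaike weights, minimal 95% confidence set and natural averaging.

    Per term, the average runs over confidence-set models containing the
    term with weights renormalized; the unconditional SE folds
    between-model coefficient spread into the within-model SE.  A term is
    flagged significant when the averaged 95% CI excludes zero.
    """
    fits = [f for f in fits if f.n > f.k + 1]
    if not fits:
        raise ValueError("no fittable models")
    n = {f.n for f in fits}
    if len(n) != 1:
        raise ValueError("model averaging requires identical data rows across fits")
    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.spec.name,
                "set": f.spec.set_name,
                "k": f.k,
                "logLik": f.llf,
                "AICc": _aicc(f.llf, f.k, f.n),
            }
        )
    tab = pd.DataFrame(rows)
    tab["delta_AICc"] = tab["AICc"] - tab["AICc"].min()
    raw = np.exp(-0.5 * tab["delta_AICc"])
    tab["weight"] = raw / raw.sum()
    tab = tab.sort_values("weight", ascending=False).reset_index(drop=True)
    cum = tab["weight"].cumsum()
    m = int(np.searchsorted(cum.to_numpy(), conf_level - 1e-12)) + 1
    tab["in_confidence_set"] = np.arange(len(tab)) < m

    by_name = {f.spec.name: f for f in fits}
    conf = tab[tab["in_confidence_set"]]
    terms = sorted(
        {t for name in conf["model"] for t in by_name[name].params.index if t != "Intercept"}
    )
    coef_rows = []
    for term in terms:
        members = conf[
            conf["model"].map(lambda name: term in by_name[name].params.index)
        ]
        w = members["weight"].to_numpy()
        w = w / w.sum()
        beta = np.array([by_name[name].params[term] for name in members["model"]])
        se = np.array([by_name[name].bse[term] for name in members["model"]])
        b_avg = float(np.sum(w * beta))
        se_u = float(np.sqrt(np.sum(w * (se**2 + (beta - b_avg) ** 2))))
        lo, hi = b_avg - Z95 * se_u, b_avg + Z95 * se_u
        coef_rows.append(
            {
                "term": term,
                "beta": b_avg,
                "se": se_u,
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(lo > 0 or hi < 0),
                "n_models": len(members),
            }
        )
    return ModelAveragingResult(
        model_table=tab, coefficients=pd.DataFrame(coef_rows), fits=tuple(fits)
    )


class FidelityModelSet:
    """Candidate LMMs of log fidelity distance; fit() -> ModelAveragingResult.

    Parameters
    ----------
    table : assembled analysis table (see `assemble_table`).
    scale : annual | month30 | biweek14; sets the random-intercept grouping.
    sets : which hypothesis sets to include.
    include_interactions : keep interaction sub-models in the averaging set
        (default False: additive-set inference).
    """

    def __init__(
        self,
        table: pd.DataFrame,
        scale: str,
        sets=("heterogeneity", "success", "combined"),
        include_interactions: bool = False,
        r_max: float = 0.6,
    ):
        self.table = table
        self.scale = scale
        self.sets = tuple(sets)
        self.include_interactions = include_interactions
        self.r_max = r_max

    def specs(self):
        specs = [
            s
            for s in candidate_sets(self.scale, include_interactions=self.include_interactions)
            if s.set_name in self.sets
        ]
        return screen_collinearity(self.table, specs, r_max=self.r_max)

    def fit(self) -> ModelAveragingResult:
        fits, skipped = [], []
        for spec in self.specs():
            try:
                fits.append(fit_lmm(spec, self.table))
            except ValueError as exc:
                skipped.append((spec.name, str(exc)))
        if skipped:
            warnings.warn(f"skipped models: {skipped}")
        return aicc_model_average(fits)


def fit_condition_models(
    condition: pd.DataFrame,
    min_recruits_for_interaction: int = 3,
) -> dict:
    """Autumn-fat and fat-accrual mixed models on fidelity and recruitment.

    ``condition`` needs columns animal_id, year, spring_fat_pct,
    autumn_fat_pct, distance_m (seasonal fidelity metric) and recruited
    (0/1).  The fidelity covariate is standardized ln(distance).  The
    fidelity x recruit interaction is dropped when fewer than
    `min_recruits_for_interaction` females recruited; the accrual model
    adds spring fat as the state variable.  Returns coefficient tables
    keyed by response.
    """
    df = condition.dropna(subset=["distance_m"]).copy()
    ld = np.log(df["distance_m"].to_numpy() + (1.0 if (df["distance_m"] == 0).any() else 0.0))
    df["fidelity_z"] = (ld - ld.mean()) / (ld.std(ddof=0) or 1.0)
    df["recruit"] = df["recruited"].astype(int)
    n_succ = int(df["recruit"].sum())
    use_interaction = n_succ >= min_recruits_for_interaction and n_succ < len(df)

    out = {}
    for response in ("autumn_fat_pct", "fat_accrual"):
        d = df.copy()
        if response == "fat_accrual":
            if "spring_fat_pct" not in d or d["spring_fat_pct"].isna().all():
                continue
            d["fat_accrual"] = d["autumn_fat_pct"] - d["spring_fat_pct"]
            terms = ["fidelity_z", "recruit", "spring_fat_pct"]
        else:
            terms = ["fidelity_z", "recruit"]
        if use_interaction:
            d["fidelity_z:recruit"] = d["fidelity_z"] * d["recruit"]
            terms.append("fidelity_z:recruit")
        X = sm.add_constant(d[terms], has_constant="add").rename(
            columns={"const": "Intercept"}
        )
        if len(d) < X.shape[1] + 3:
            warnings.warn(f"{response}: too few rows ({len(d)}); model skipped")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(
                d[response].to_numpy(dtype=float), X, groups=d["animal_id"]
            ).fit(reml=False)
        coefs = pd.DataFrame(
            {
                "term": res.fe_params.index,
                "beta": res.fe_params.to_numpy(),
                "se": res.bse_fe.to_numpy(),
            }
        )
        coefs["ci_low"] = coefs["beta"] - Z95 * coefs["se"]
        coefs["ci_high"] = coefs["beta"] + Z95 * coefs["se"]
        out[response] = coefs
    return out


@dataclass(frozen=True)
class CoxResult:
    beta: float
    hazard_ratio: float
    se_robust: float
    p: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int
    n_censored: int

    def summary(self) -> str:
        return (
            f"Cox PH (Andersen-Gill), cluster-robust on mother\n"
            f"  beta = {self.beta:.4f}  HR = {self.hazard_ratio:.4f}  "
            f"robust SE = {self.se_robust:.4f}  p = {self.p:.4f}\n"
            f"  95% CI on beta: [{self.ci_low:.4f}, {self.ci_high:.4f}]\n"
            f"  n = {self.n}, events = {self.n_events}, censored = {self.n_censored}"
        )


class NeonateSurvivalModel:
    """Cox proportional hazards of neonate mortality over [0, 120] days.

    The single covariate is maternal site fidelity; repeated neonates per
    mother are handled with a cluster-robust sandwich variance.  Ties use
    the Breslow approximation (lifelines' default).
    """

    def __init__(self, neonates, window_days: int = 120, min_events: int = 5):
        self.window_days = window_days
        self.min_events = min_events
        rows = []
        for r in neonates:
            days = min((r.end_date - r.birth_date).days, window_days)
            event = int(r.fate == "died" and days <= window_days)
            rows.append(
                {
                    "mother_id": r.mother_id,
                    "duration": max(days, 0.5),  # same-day deaths get half a day
                    "event": event,
                    "fidelity": r.maternal_fidelity_z,
                }
            )
        self.frame = pd.DataFrame(rows)

    def fit(self) -> CoxResult:
        from lifelines import CoxPHFitter

        events = int(self.frame["event"].sum())
        if events < self.min_events:
            raise ValueError(
                f"only {events} mortalities (< {self.min_events}); "
                "use mann_whitney_fidelity instead"
            )
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                self.frame,
                duration_col="duration",
                event_col="event",
                cluster_col="mother_id",
                robust=True,
                formula="fidelity",
            )
        s = cph.summary.loc["fidelity"]
        return CoxResult(
            beta=float(s["coef"]),
            hazard_ratio=float(np.exp(s["coef"])),
            se_robust=float(s["se(coef)"]),
            p=float(s["p"]),
            ci_low=float(s["coef lower 95%"]),
            ci_high=float(s["coef upper 95%"]),
            n=len(self.frame),
            n_events=events,
            n_censored=len(self.frame) - events,
        )


def fit_neonate_survival(neonates, window_days: int = 120) -> CoxResult:
    return NeonateSurvivalModel(neonates, window_days=window_days).fit()


def mann_whitney_fidelity(group_survived, group_died):
    """Two-sided rank-sum comparison of inter-annual fidelity distances."""
    a = np.asarray(group_survived, dtype=float)
    b = np.asarray(group_died, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
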