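"""Association and prediction analyses for clock validation.

Mortality associations use Cox proportional hazards (Efron ties, via
lifelines).  Incident-disease associations use the Fine-Gray
subdistribution hazard model to account for death as a competing event,
estimated as a weighted Cox partial likelihood on the Fine-Gray risk set:
participants with a competing event remain at risk after their death time
with inverse-probability-of-censoring weights G(t-)/G(s_i-) from the
Kaplan-Meier estimator of the censoring distribution (the Geskus
formulation).  The weighted risk-set sums are accumulated analytically
(cumulative sums over the natural risk set plus a censoring-weighted sum
over past competing events), so no expanded counting-process dataset is
ever materialized.

Multiple testing is controlled with Benjamini-Hochberg FDR across the
suite; discrimination is compared with Harrell's C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sksurv.metrics import concordance_index_censored
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AdjustmentTier",
    "AssociationResult",
    "ConcordanceResult",
    "default_tiers",
    "fit_cox",
    "fit_fine_gray",
    "bh_fdr",
    "harrell_c",
    "run_association_suite",
    "compare_models_c",
    "correlation_panel",
    "cumulative_incidence",
]


@dataclass(frozen=True)
class AdjustmentTier:
    """Named covariate set; tiers nest (age ⊂ partial ⊂ full)."""

    name: str
    covariates: tuple[str, ...]


def default_tiers(prevalent_columns: tuple[str, ...] = ()) -> list[AdjustmentTier]:
    age = ("age",)
    partial = age + ("sex", "education", "deprivation", "smoking", "bmi")
    full = partial + tuple(prevalent_columns)
    return [
        AdjustmentTier("age_adjusted", age),
        AdjustmentTier("partial", partial),
        AdjustmentTier("full", full),
    ]


@dataclass
class AssociationResult:
    outcome: str
    exposure: str
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    model_type: str  # "cox" | "fine_gray"
    tier: str = ""
    p_adj: float | None = None


@dataclass
class ConcordanceResult:
    label: str
    c: float
    n_pairs: int


# ---------------------------------------------------------------- Cox


def fit_cox(X: pd.DataFrame, time, event) -> pd.DataFrame:
    """Cox PH fit (Efron ties); one row per covariate.

    Returns a DataFrame with columns coef, se, hr, ci_low, ci_high, p.
    """
    df = X.copy()
    df["_time"] = np.asarray(time, dtype=float)
    df["_event"] = np.asarray(event, dtype=int)
    if df["_event"].sum() < 1:
        raise ValueError("need at least one event")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="_time", event_col="_event",
            fit_options={"precision": 1e-9})
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef"] - 1.959963984540054 * s["se(coef)"]),
            "ci_high": np.exp(s["coef"] + 1.959963984540054 * s["se(coef)"]),
            "p": s["p"],
        }
    )


# ---------------------------------------------------------------- Fine-Gray


def _censoring_km_left(times: np.ndarray, censored: np.ndarray):
    """Kaplan-Meier of the censoring distribution; returns G(t-) evaluator."""
    order = np.argsort(times, kind="stable")
    t_s = times[order]
    c_s = censored[order].astype(float)
    uniq, inv = np.unique(t_s, return_inverse=True)
    c_at = np.bincount(inv, weights=c_s, minlength=len(uniq))
    n_total = len(t_s)
    n_before = np.searchsorted(t_s, uniq, side="left")
    at_risk = n_total - n_before
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - np.where(at_risk > 0, c_at / at_risk, 0.0)
    surv = np.cumprod(factors)  # G(t) right-continuous at uniq

    def g_left(t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(uniq, np.asarray(t, dtype=float), side="left")
        out = np.where(idx == 0, 1.0, surv[np.maximum(idx - 1, 0)])
        return out

    return g_left


def fit_fine_gray(X: pd.DataFrame, time, status, max_iter: int = 100,
                  tol: float = 1e-10) -> pd.DataFrame:
    """Fine-Gray subdistribution-hazard regression.

    ``status``: 0 censored, 1 event of interest, 2 competing event (death
    before the event).  Returns the same per-covariate table as
    :func:`fit_cox`.  With zero competing events this reduces exactly to a
    Breslow Cox fit.
    """
    names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    t = np.asarray(time, dtype=float)
    s = np.asarray(status, dtype=int)
    if not set(np.unique(s)) <= {0, 1, 2}:
        raise ValueError("status must be coded 0/1/2")
    if (s == 1).sum() < 1:
        raise ValueError("no events of interest")
    n, p = Xv.shape

    order = np.argsort(t, kind="stable")
    t_s, s_s, X_s = t[order], s[order], Xv[order]
    center = X_s.mean(axis=0)
    X_s = X_s - center

    g_left = _censoring_km_left(t, (s == 0).astype(float))
    ev_times = np.unique(t_s[s_s == 1])
    G_ev = g_left(ev_times)  # G(t_k-)
    start = np.searchsorted(t_s, ev_times, side="left")  # natural risk set start
    # tie counts and tie-set covariate sums per unique event time
    is_ev = s_s == 1
    ev_idx = np.searchsorted(ev_times, t_s[is_ev])
    dk = np.bincount(ev_idx, minlength=len(ev_times)).astype(float)
    x_ev_sum = np.zeros((len(ev_times), p))
    np.add.at(x_ev_sum, ev_idx, X_s[is_ev])

    comp = s_s == 2
    G_own = g_left(t_s[comp])  # G(s_i-) for competing subjects
    if np.any(G_own <= 0):
        raise ValueError("censoring weights undefined (G = 0 at a competing event time)")
    # number of competing subjects with T_i < t_k
    n_comp_before = np.searchsorted(t_s[comp], ev_times, side="left")

    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X_s @ beta
        c = eta.max()
        r = np.exp(eta - c)
        rx = r[:, None] * X_s
        rxx = rx[:, :, None] * X_s[:, None, :]

        rev0 = np.concatenate([np.cumsum(r[::-1])[::-1], [0.0]])
        rev1 = np.concatenate([np.cumsum(rx[::-1], axis=0)[::-1], np.zeros((1, p))])
        rev2 = np.concatenate([np.cumsum(rxx[::-1], axis=0)[::-1], np.zeros((1, p, p))])

        wc = (r[comp] / G_own)
        cum0 = np.concatenate([[0.0], np.cumsum(wc)])
        cum1 = np.concatenate([np.zeros((1, p)), np.cumsum(wc[:, None] * X_s[comp], axis=0)])
        cum2 = np.concatenate([np.zeros((1, p, p)),
                               np.cumsum(wc[:, None, None] * rxx[comp] / r[comp, None, None], axis=0)])

        S0 = rev0[start] + G_ev * cum0[n_comp_before]
        S1 = rev1[start] + G_ev[:, None] * cum1[n_comp_before]
        S2 = rev2[start] + G_ev[:, None, None] * cum2[n_comp_before]

        mean1 = S1 / S0[:, None]
        U = x_ev_sum.sum(axis=0) - (dk[:, None] * mean1).sum(axis=0)
        info = (dk[:, None, None] * (S2 / S0[:, None, None]
                                     - mean1[:, :, None] * mean1[:, None, :])).sum(axis=0)
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular information matrix in Fine-Gray fit") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    else:
        if np.max(np.abs(U)) > 1e-6 * max(1.0, float(dk.sum())):
            raise RuntimeError("Fine-Gray Newton iteration did not converge")

    # final information for SEs
    se = np.sqrt(np.diag(np.linalg.inv(info)))
    from scipy import stats as _st

    z = beta / se
    pvals = 2 * _st.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - 1.959963984540054 * se),
            "ci_high": np.exp(beta + 1.959963984540054 * se),
            "p": pvals,
        },
        index=names,
    )


def cumulative_incidence(time, status, cause: int = 1):
    """Aalen-Johansen cumulative incidence function for one cause.

    Returns a DataFrame (index: time, column ``cif``).
    """
    from lifelines import AalenJohansenFitter

    ajf = AalenJohansenFitter(calculate_variance=False)
    ajf.fit(np.asarray(time, dtype=float), np.asarray(status, dtype=int), event_of_interest=cause)
    cif = ajf.cumulative_density_
    cif.columns = ["cif"]
    return cif


# ---------------------------------------------------------------- metrics


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def harrell_c(time, event, risk_score, label: str = "") -> ConcordanceResult:
    """Harrell's C over comparable pairs (risk ties count 1/2)."""
    t = np.asarray(time, dtype=float)
    d = np.asarray(event).astype(bool)
    r = np.asarray(risk_score, dtype=float)
    if not (len(t) == len(d) == len(r)):
        raise ValueError("equal lengths required")
    c, conc, disc, tied_risk, _ = concordance_index_censored(d, t, r)
    n_pairs = int(conc + disc + tied_risk)
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    return ConcordanceResult(label=label, c=float(c), n_pairs=n_pairs)


# ---------------------------------------------------------------- suites


def run_association_suite(data: pd.DataFrame, exposure: str, outcomes,
                          tiers: list[AdjustmentTier],
                          mortality_outcome: str = "mortality") -> pd.DataFrame:
    """Cox (mortality) and Fine-Gray (diseases) associations per tier.

    ``data`` holds the exposure, tier covariates, ``time_death``/``died``,
    per-disease ``time_<d>``/``status_<d>`` columns, and optionally
    ``prevalent_<d>`` flags (prevalent cases are excluded from that
    disease's model; the fully adjusted tier drops the modeled outcome's
    own pre-existing-disease covariate).  BH-FDR is applied across every
    test in the suite.
    """
    rows: list[AssociationResult] = []
    for tier in tiers:
        missing = [c for c in tier.covariates if c not in data.columns]
        if missing:
            raise ValueError(f"tier {tier.name!r} covariates missing from data: {missing}")
        for outcome in outcomes:
            covs = [c for c in tier.covariates if c != f"prevalent_{outcome}"]
            cols = [exposure, *covs]
            if outcome == mortality_outcome:
                sub = data.dropna(subset=cols + ["time_death", "died"])
                res = fit_cox(sub[cols], sub["time_death"], sub["died"])
                n_ev = int(sub["died"].sum())
                model_type = "cox"
            else:
                tcol, scol = f"time_{outcome}", f"status_{outcome}"
                sub = data
                prev = f"prevalent_{outcome}"
                if prev in sub.columns:
                    sub = sub[sub[prev] != 1]
                sub = sub.dropna(subset=cols + [tcol, scol])
                res = fit_fine_gray(sub[cols], sub[tcol], sub[scol])
                n_ev = int((sub[scol] == 1).sum())
                model_type = "fine_gray"
            r = res.loc[exposure]
            rows.append(AssociationResult(
                outcome=outcome, exposure=exposure, hr=float(r["hr"]),
                ci_low=float(r["ci_low"]), ci_high=float(r["ci_high"]),
                p=float(r["p"]), n=len(sub), n_events=n_ev,
                model_type=model_type, tier=tier.name,
            ))
    table = pd.DataFrame([vars(r) for r in rows])
    table["p_adj"] = bh_fdr(table["p"].to_numpy())
    return table


def compare_models_c(data: pd.DataFrame, score_columns, duration_col: str,
                     event_col: str) -> pd.DataFrame:
    """Harrell's C of single-covariate Cox models on the shared complete-case rows."""
    score_columns = list(score_columns)
    sub = data.dropna(subset=[*score_columns, duration_col, event_col])
    if len(sub) == 0:
        raise ValueError("empty complete-case set")
    out = []
    for col in score_columns:
        res = fit_cox(sub[[col]], sub[duration_col], sub[event_col])
        risk = float(res.loc[col, "coef"]) * sub[col].to_numpy(dtype=float)
        cr = harrell_c(sub[duration_col], sub[event_col], risk, label=col)
        out.append({"score": col, "c": cr.c, "n_pairs": cr.n_pairs, "n": len(sub)})
    return pd.DataFrame(out).set_index("score")


def correlation_panel(data: pd.DataFrame, columns, method: str = "spearman",
                      age_adjust: bool = False, age_col: str = "age") -> pd.DataFrame:
    """Pairwise correlation matrix; optionally of age-regression residuals."""
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    cols = list(columns)
    df = data[cols + ([age_col] if age_adjust and age_col not in cols else [])].copy()
    for c in cols:
        v = df[c].dropna()
        if len(v) and v.nunique() == 1:
            raise ValueError(f"column {c!r} is constant")
    if age_adjust:
        from .preprocess import age_adjusted_residuals

        res = {}
        for c in cols:
            ok = df[[c, age_col]].notna().all(axis=1)
            r = pd.Series(np.nan, index=df.index)
            r[ok] = age_adjusted_residuals(df.loc[ok, c], df.loc[ok, age_col])
            res[c] = r
        df = pd.DataFrame(res)
    return df[cols].corr(method=method, min_periods=3)
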