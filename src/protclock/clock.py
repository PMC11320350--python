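"""The proteomic aging clock: train, serialize, and score.

The clock pairs two Gompertz proportional-hazards models fitted on the same
training rows: a *full* model (chronological age + the LASSO-selected
proteins) and an *age-only* reference model.  A participant's proteomic age
is the chronological age at which the reference model's cumulative
mortality risk over a fixed horizon k equals the participant's full-model
risk — the standard risk-matching construction for second-generation
biological-age clocks.  Writing M for the full-model k-year risk and
(a0, b00, b_age) for the reference model, the inversion is closed-form:

    A = [ log(-log(1 - M) * a0 / (exp(a0*k) - 1)) - b00 ] / b_age

Deviation (proteomic age acceleration) is A minus chronological age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ProteinMatrix
from .gompertz import GompertzModel, fit_gompertz, gompertz_cuminc, _growth

__all__ = [
    "PACModel",
    "ProteomicAgeResult",
    "split_cohort",
    "build_pac",
    "proteomic_age",
    "score_cohort",
]

AGE_COL = "age"


@dataclass
class PACModel:
    full: GompertzModel
    age_only: GompertzModel
    horizon: float = 10.0  # years

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        if AGE_COL not in self.age_only.coef.index or self.age_only.coef[AGE_COL] <= 0:
            raise ValueError("age-only model must have a positive age coefficient")

    @property
    def proteins(self) -> list[str]:
        return [c for c in self.full.covariate_names if c != AGE_COL]

    def to_dict(self) -> dict:
        return {"full": self.full.to_dict(), "age_only": self.age_only.to_dict(),
                "horizon": float(self.horizon)}

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PACModel":
        return cls(full=GompertzModel.from_dict(d["full"]),
                   age_only=GompertzModel.from_dict(d["age_only"]),
                   horizon=float(d["horizon"]))

    @classmethod
    def load(cls, path) -> "PACModel":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class ProteomicAgeResult:
    participant_id: object
    proteomic_age: float
    deviation: float  # proteomic_age - chronological age
    risk_at_horizon: float


def split_cohort(ids, train_fraction: float = 0.7, seed: int = 0):
    """Random disjoint, exhaustive train/test split of participant ids.

    |train| = round(train_fraction * n); deterministic in the seed.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie in (0, 1)")
    ids = np.asarray(list(ids))
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two participants to split")
    n_train = int(math.floor(train_fraction * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    train = ids[np.sort(perm[:n_train])]
    test = ids[np.sort(perm[n_train:])]
    return list(train), list(test)


def build_pac(train_X: pd.DataFrame, time, event, selected_proteins,
              horizon_k: float = 10.0) -> PACModel:
    """Fit the paired Gompertz models and assemble the clock.

    ``train_X`` must contain an ``age`` column plus the selected protein
    columns; both models are fitted on the same rows.
    """
    selected_proteins = [p for p in selected_proteins if p != AGE_COL]
    cols = [AGE_COL, *selected_proteins]
    missing = [c for c in cols if c not in train_X.columns]
    if missing:
        raise ValueError(f"training matrix lacks columns: {missing[:5]}")
    full = fit_gompertz(train_X[cols], time, event)
    age_only = fit_gompertz(train_X[[AGE_COL]], time, event)
    return PACModel(full=full, age_only=age_only, horizon=float(horizon_k))


def _invert_age(pac: PACModel, cumhaz_full: np.ndarray) -> np.ndarray:
    """Closed-form risk-matching: the age whose reference k-year cumulative
    hazard equals ``cumhaz_full``."""
    a0 = pac.age_only.shape
    b00 = pac.age_only.lograte
    b_age = float(pac.age_only.coef[AGE_COL])
    growth = _growth(pac.horizon, a0)
    return (np.log(cumhaz_full / growth) - b00) / b_age


def proteomic_age(pac: PACModel, x_row) -> ProteomicAgeResult:
    """Score a single participant (mapping or Series of covariate values)."""
    x = pd.Series(x_row, dtype=float)
    risk = gompertz_cuminc(pac.full, x, pac.horizon)
    if not (0.0 < risk < 1.0):
        raise ValueError(f"degenerate full-model risk {risk}")
    cumhaz = -math.log1p(-risk)
    age_hat = float(_invert_age(pac, np.array([cumhaz]))[0])
    chron = float(x[AGE_COL])
    return ProteomicAgeResult(
        participant_id=x.get("participant_id", None),
        proteomic_age=age_hat,
        deviation=age_hat - chron,
        risk_at_horizon=risk,
    )


def score_cohort(pac: PACModel, matrix: ProteinMatrix | pd.DataFrame,
                 cohort: pd.DataFrame) -> pd.DataFrame:
    """Score every participant; returns id-indexed proteomic_age / deviation / risk.

    ``matrix`` must be imputed (no missing values among the clock proteins).
    """
    vals = matrix.values if isinstance(matrix, ProteinMatrix) else matrix
    need = pac.proteins
    missing = [p for p in need if p not in vals.columns]
    if missing:
        raise ValueError(f"matrix lacks clock proteins: {missing[:5]}")
    if AGE_COL not in cohort.columns:
        raise ValueError("cohort lacks an 'age' column")
    common = cohort.index.intersection(vals.index)
    X = pd.concat([cohort.loc[common, [AGE_COL]], vals.loc[common, need]], axis=1)
    if X.isna().any().any():
        raise ValueError("missing covariate values; impute before scoring")

    risk = gompertz_cuminc(pac.full, X[pac.full.covariate_names], pac.horizon)
    if np.any(risk <= 0) or np.any(risk >= 1):
        raise ValueError("degenerate full-model risks encountered")
    cumhaz = -np.log1p(-risk)
    age_hat = _invert_age(pac, cumhaz)
    out = pd.DataFrame(
        {
            "proteomic_age": age_hat,
            "deviation": age_hat - X[AGE_COL].to_numpy(),
            "risk_at_horizon": risk,
        },
        index=common,
    )
    out.index.name = cohort.index.name or "participant_id"
    return out
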