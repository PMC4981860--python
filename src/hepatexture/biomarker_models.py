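"""Logistic imaging-biomarker models: the published NASHMRI and FibroMRI
presets, patient scoring, and (re)fitting on new feature tables.

A model is a linear combination of per-protocol estimator aggregates
passed through the logistic function:

    eta = beta0 + sum_i beta_i * E_i(protocol_i)
    p   = 1 / (1 + exp(-eta))

A patient is called positive when p exceeds the decision threshold
strictly (the published cut-off is 0.5 for both presets).

The published presets store the printed slope coefficients.  Their
intercepts were never printed and are kept as an explicit free parameter
(default 0) that must be calibrated before absolute probabilities are
meaningful; ranking (and hence AUROC) does not depend on it.  The NASHMRI
model names three estimators but only two printed coefficients; the third
term (E73, FAST-STIR) ships with coefficient 0 and is flagged INCOMPLETE.
FibroMRI's mode coefficient (-115.737) is stored verbatim; its magnitude
implies the mode must be fed on the 0-1 window-normalised intensity scale.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .estimators import EstimatorVector
from .protocols import Protocol

__all__ = [
    "ModelTerm",
    "BiomarkerModel",
    "ScoreResult",
    "NASHMRI",
    "FIBROMRI",
    "get_preset",
    "score",
    "odds_ratio",
    "fit_logistic",
    "select_features",
    "FitResult",
]


@dataclass(frozen=True)
class ModelTerm:
    protocol: Protocol
    estimator_id: str
    coefficient: float
    incomplete: bool = False  # published term without a printed coefficient


@dataclass(frozen=True)
class BiomarkerModel:
    name: str
    terms: tuple[ModelTerm, ...]
    intercept: float = 0.0
    threshold: float = 0.5
    #: True for the shipped presets whose intercept is a free parameter.
    intercept_free: bool = False

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie strictly in (0, 1)")
        keys = [(t.protocol, t.estimator_id) for t in self.terms]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (protocol, estimator) term")

    def with_intercept(self, beta0: float) -> "BiomarkerModel":
        return replace(self, intercept=beta0, intercept_free=False)

    def to_json(self, path: str | os.PathLike) -> None:
        doc = {
            "name": self.name,
            "intercept": self.intercept,
            "intercept_free": self.intercept_free,
            "threshold": self.threshold,
            "terms": [
                {"protocol": str(t.protocol), "estimator": t.estimator_id,
                 "coefficient": t.coefficient, "incomplete": t.incomplete}
                for t in self.terms
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @staticmethod
    def from_json(path: str | os.PathLike) -> "BiomarkerModel":
        with open(path) as fh:
            doc = json.load(fh)
        return BiomarkerModel(
            name=doc["name"],
            terms=tuple(
                ModelTerm(Protocol(t["protocol"]), t["estimator"],
                          float(t["coefficient"]),
                          bool(t.get("incomplete", False)))
                for t in doc["terms"]),
            intercept=float(doc.get("intercept", 0.0)),
            threshold=float(doc.get("threshold", 0.5)),
            intercept_free=bool(doc.get("intercept_free", False)))


@dataclass(frozen=True)
class ScoreResult:
    patient_id: str
    model: str
    eta: float
    probability: float
    positive: bool
    features: dict[str, float] = field(default_factory=dict)


#: Steatohepatitis model: harmonic mean (SSFSE-T2), second-order contrast
#: (DYNAMIC) and averaged mean curvature (FAST-STIR).  Only two slope
#: coefficients were published; the curvature term ships with 0, flagged.
NASHMRI = BiomarkerModel(
    name="NASHMRI",
    terms=(
        ModelTerm(Protocol.SSFSE_T2, "E3", 0.079),
        ModelTerm(Protocol.DYNAMIC, "E57", 0.127),
        ModelTerm(Protocol.FAST_STIR, "E73", 0.0, incomplete=True),
    ),
    intercept=0.0, threshold=0.5, intercept_free=True)

#: Significant-fibrosis model: Pearson asymmetry (SSFSE-T2) plus harmonic
#: mean, mode, co-occurrence column marginal mean and maximum principal
#: curvature (all DYNAMIC).
FIBROMRI = BiomarkerModel(
    name="FibroMRI",
    terms=(
        ModelTerm(Protocol.SSFSE_T2, "E22", 1.101),
        ModelTerm(Protocol.DYNAMIC, "E3", -1.105),
        ModelTerm(Protocol.DYNAMIC, "E6", -115.737),
        ModelTerm(Protocol.DYNAMIC, "E31", 0.696),
        ModelTerm(Protocol.DYNAMIC, "E75", -0.825),
    ),
    intercept=0.0, threshold=0.5, intercept_free=True)

_PRESETS = {"nashmri": NASHMRI, "fibromri": FIBROMRI}


def get_preset(name: str) -> BiomarkerModel:
    try:
        return _PRESETS[name.lower()]
    except KeyError as exc:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from exc


def score(model: BiomarkerModel,
          aggregates: dict[Protocol, EstimatorVector],
          patient_id: str = "") -> ScoreResult:
    """Score one patient from per-protocol estimator aggregates.

    Every model term must be present and finite in the aggregates; a
    missing feature raises ``KeyError`` naming the absent term (no
    imputation is performed).
    """
    eta = model.intercept
    used: dict[str, float] = {}
    for t in model.terms:
        vec = aggregates.get(t.protocol)
        if vec is None or t.estimator_id not in vec.values:
            raise KeyError(
                f"missing feature ({t.protocol}, {t.estimator_id}) "
                f"required by {model.name}")
        v = vec.values[t.estimator_id]
        used[f"{t.protocol}:{t.estimator_id}"] = v
        eta += t.coefficient * v
    p = 1.0 / (1.0 + math.exp(-eta))
    p = min(max(p, np.nextafter(0.0, 1.0)), np.nextafter(1.0, 0.0))
    return ScoreResult(patient_id=patient_id, model=model.name, eta=eta,
                       probability=p, positive=p > model.threshold,
                       features=used)


def odds_ratio(coefficient: float) -> tuple[float, float]:
    """(full-precision, 2-decimal) odds ratio exp(beta) of a coefficient."""
    if not math.isfinite(coefficient):
        raise ValueError("coefficient must be finite")
    v = math.exp(coefficient)
    return v, round(v, 2)


@dataclass
class FitResult:
    model: BiomarkerModel
    coefficients: pd.DataFrame  # term, beta, se, z, p, OR, OR CI
    log_likelihood: float
    converged: bool
    separation_warning: bool


def _design(features: pd.DataFrame, columns: list[str]):
    X = features[columns].to_numpy(dtype=np.float64)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    return sm.add_constant(X, has_constant="add")


def _term_from_column(col: str, beta: float) -> ModelTerm:
    if ":" in col:
        proto, eid = col.split(":", 1)
        return ModelTerm(Protocol(proto), eid, beta)
    return ModelTerm(Protocol.UNKNOWN, col, beta)


def fit_logistic(features: pd.DataFrame, labels, columns: list[str] | None = None,
                 name: str = "custom") -> FitResult:
    """Maximum-likelihood logistic fit of a biomarker model.

    ``features`` columns are named ``"PROTOCOL:Eid"`` (or plain ids); the
    deterministic Newton solver of statsmodels is used.  Perfect
    separation is flagged rather than fatal; a rank-deficient design
    raises ``ValueError``.
    """
    y = np.asarray(labels, dtype=np.float64)
    if features.shape[0] < 10:
        raise ValueError("at least 10 patients are required")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    cols = columns or list(features.columns)
    X = _design(features, cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (duplicated/collinear predictor)")
    separation = False
    import warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    try:
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception:
        separation = True
        with warnings.catch_warnings(), np.errstate(all="ignore"):
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="bfgs")
    if not res.mle_retvals.get("converged", False) and not separation:
        raise RuntimeError("logistic fit did not converge")

    beta, se = res.params, res.bse
    rows = []
    for i, col in enumerate(["(intercept)"] + cols):
        b, s = float(beta[i]), float(se[i])
        z = b / s if s > 0 else np.inf
        rows.append({
            "term": col, "beta": b, "se": s, "z": z,
            "p": 2 * (1 - _norm_cdf(abs(z))),
            "or": math.exp(b) if abs(b) < 700 else math.inf,
            "or_ci_low": math.exp(b - 1.96 * s) if abs(b - 1.96 * s) < 700 else 0.0,
            "or_ci_high": math.exp(b + 1.96 * s) if abs(b + 1.96 * s) < 700 else math.inf,
        })
    table = pd.DataFrame(rows)
    model = BiomarkerModel(
        name=name,
        terms=tuple(_term_from_column(c, float(beta[i + 1]))
                    for i, c in enumerate(cols)),
        intercept=float(beta[0]), threshold=0.5)
    return FitResult(model=model, coefficients=table,
                     log_likelihood=float(res.llf),
                     converged=bool(res.mle_retvals.get("converged", separation)),
                     separation_warning=separation)


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def _loglik(features: pd.DataFrame, labels, cols: list[str]) -> float:
    y = np.asarray(labels, dtype=np.float64)
    X = sm.add_constant(features[cols].to_numpy(np.float64), has_constant="add") \
        if cols else np.ones((len(y), 1))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sm.Logit(y, X).fit(disp=0, maxiter=200).llf)


def select_features(features: pd.DataFrame, labels,
                    candidates: list[str], entry_p: float = 0.05,
                    adjust: str | None = "bonferroni",
                    name: str = "selected") -> tuple[list[str], FitResult]:
    """Forward selection by likelihood-ratio test.

    At each step the candidate whose addition gives the largest likelihood
    improvement enters if its LR p-value is below ``entry_p``; selection
    stops when no candidate qualifies.  Because the entering candidate is
    the best of the remaining pool, the raw LR p is multiplied by the pool
    size by default (``adjust="bonferroni"``) so the chance of any noise
    variable entering stays near ``entry_p``; pass ``adjust=None`` for the
    classical unadjusted procedure.  Returns the entry order and the final
    fitted model (intercept-only fit when nothing enters).
    """
    from scipy.stats import chi2

    if not candidates:
        raise ValueError("candidate set is empty")
    selected: list[str] = []
    ll_cur = _loglik(features, labels, [])
    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:
            try:
                ll = _loglik(features, labels, selected + [cand])
            except Exception:
                continue
            lr = 2.0 * (ll - ll_cur)
            p = float(chi2.sf(max(lr, 0.0), df=1))
            if adjust == "bonferroni":
                p = min(1.0, p * len(remaining))
            if best is None or ll > best[1]:
                best = (cand, ll, p)
        if best is None or best[2] >= entry_p:
            break
        selected.append(best[0])
        ll_cur = best[1]
        remaining.remove(best[0])
    if selected:
        fit = fit_logistic(features, labels, columns=selected, name=name)
    else:
        beta0 = _intercept_only(labels)
        fit = FitResult(
            model=BiomarkerModel(name=name, terms=(), intercept=beta0),
            coefficients=pd.DataFrame(
                [{"term": "(intercept)", "beta": beta0}]),
            log_likelihood=ll_cur, converged=True, separation_warning=False)
    return selected, fit


def _intercept_only(labels) -> float:
    y = np.asarray(labels, dtype=np.float64)
    p = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    return math.log(p / (1.0 - p))
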