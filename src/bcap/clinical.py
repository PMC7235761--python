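"""CAPRA-S post-surgical risk scoring and logistic combination models.

The logistic models combine the bCaP ratio score with serum PSA, DRE status
(positive = 1), and age on the linear-predictor scale, fit by iteratively
reweighted least squares on the training set only.  No feature is
standardized or transformed by default (a flag enables log2 PSA upstream).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .qpcr import ClinicalPathology, Finding


class SeparationWarning(UserWarning):
    """Raised when a logistic fit encounters (quasi-)perfect separation."""


@dataclass
class CapraScore:
    total: int
    psa_points: int
    gleason_points: int
    sm_points: int
    svi_points: int
    ece_points: int
    lni_points: int
    risk_group: str  # "low" | "intermediate" | "high"


def capra_s(path: ClinicalPathology) -> CapraScore:
    """CAPRA-S score: PSA at RP (<=6: 0, (6,10]: +1, (10,20]: +2, >20: +3),
    prostatectomy Gleason (<=3+3: 0, 3+4: +1, 4+3: +2, sum >=8: +3),
    SM+ +2, SVI+ +2, ECE+ +1, LNI+ +1.  Risk groups: [0,2] low,
    [3,5] intermediate, [6,12] high.
    """
    missing = []
    if path.psa_at_rp is None:
        missing.append("psa_at_rp")
    if path.gleason_primary is None or path.gleason_secondary is None:
        missing.append("gleason")
    for name in ("sm", "svi", "ece", "lni"):
        if getattr(path, name) == Finding.UNKNOWN:
            missing.append(name)
    if missing:
        raise ValueError(f"CAPRA-S requires known fields: {missing}")

    psa = path.psa_at_rp
    if psa <= 6:
        psa_pts = 0
    elif psa <= 10:
        psa_pts = 1
    elif psa <= 20:
        psa_pts = 2
    else:
        psa_pts = 3

    p, s = path.gleason_primary, path.gleason_secondary
    if p + s >= 8:
        gl_pts = 3
    elif (p, s) == (4, 3):
        gl_pts = 2
    elif (p, s) == (3, 4):
        gl_pts = 1
    else:
        gl_pts = 0

    sm_pts = 2 if path.sm == Finding.POSITIVE else 0
    svi_pts = 2 if path.svi == Finding.POSITIVE else 0
    ece_pts = 1 if path.ece == Finding.POSITIVE else 0
    lni_pts = 1 if path.lni == Finding.POSITIVE else 0
    total = psa_pts + gl_pts + sm_pts + svi_pts + ece_pts + lni_pts
    risk = "low" if total <= 2 else ("intermediate" if total <= 5 else "high")
    return CapraScore(total, psa_pts, gl_pts, sm_pts, svi_pts, ece_pts, lni_pts, risk)


@dataclass
class LogisticModelSpec:
    feature_names: list[str]
    coefficients: list[float]
    intercept: float
    n: int = 0
    seed: int | None = None
    converged: bool = True
    separation: bool = False
    loglik_path: list[float] = field(default_factory=list, repr=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "n": self.n,
            "seed": self.seed,
            "converged": self.converged,
            "separation": self.separation,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticModelSpec":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _as_matrix(features, feature_names) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != len(feature_names):
        raise ValueError(
            f"{X.shape[1]} feature columns but {len(feature_names)} names"
        )
    if not np.isfinite(X).all():
        raise ValueError("features contain missing values; exclude those samples upstream")
    return X


def fit_logistic(
    features,
    outcome,
    feature_names: list[str],
    max_iter: int = 100,
    tol: float = 1e-8,
    seed: int | None = None,
) -> tuple[LogisticModelSpec, np.ndarray]:
    """Logistic regression by IRLS (Newton-Raphson); returns (spec, cov).

    Converges when the deviance changes by less than ``tol``.  Perfect or
    quasi-perfect separation is flagged (SeparationWarning) and the current
    coefficients are returned.  ``cov`` is the Wald covariance (X'WX)^-1.
    """
    X = _as_matrix(features, feature_names)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    n, k = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(k + 1)
    dev_old = np.inf
    loglik_path: list[float] = []
    separation = False
    converged = False
    cov = np.full((k + 1, k + 1), np.nan)
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        loglik = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        loglik_path.append(loglik)
        w = mu * (1 - mu)
        if np.all(np.abs(mu - y) < 1e-6) or np.max(np.abs(beta)) > 1e3:
            separation = True
            warnings.warn(
                "perfect separation detected; coefficients are unstable",
                SeparationWarning,
                stacklevel=2,
            )
            break
        XtWX = Xd.T @ (Xd * w[:, None])
        try:
            step = np.linalg.solve(XtWX, Xd.T @ (y - mu))
        except np.linalg.LinAlgError:
            separation = True
            warnings.warn(
                "singular information matrix (separation or collinearity)",
                SeparationWarning,
                stacklevel=2,
            )
            break
        beta = beta + step
        dev = -2.0 * loglik
        if abs(dev_old - dev) < tol:
            converged = True
            cov = np.linalg.inv(XtWX)
            break
        dev_old = dev
    if not converged and not separation:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")
    spec = LogisticModelSpec(
        feature_names=list(feature_names),
        coefficients=[float(b) for b in beta[1:]],
        intercept=float(beta[0]),
        n=n,
        seed=seed,
        converged=converged,
        separation=separation,
        loglik_path=loglik_path,
    )
    return spec, cov


def predict_logistic(model: LogisticModelSpec, features) -> np.ndarray:
    """Inverse-logit of the linear predictor; deterministic."""
    X = _as_matrix(features, model.feature_names)
    eta = model.intercept + X @ np.asarray(model.coefficients)
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
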