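"""Transductive conformal scoring with class-weighted logistic models.

For one unclassified individual (UCI) and one predictor, two conformal scores
are computed:

* ASD score — the UCI is pooled with the reference sample under an assumed ASD
  label, a logistic model predicting the ASD label is fitted with ASD examples
  (including the UCI) carrying a very large class weight, and the score is the
  fraction of ASD *reference* individuals whose fitted value is <= the UCI's.
* NTC score — the mirrored procedure with NTC as the assumed and weighted class.

The large weight makes the model care almost exclusively about fitting the
assumed class, which is what pushes false-positive predictions down.  Ranks are
taken on the linear predictor: with the extreme weight the sigmoid outputs
saturate and tie at double precision, while ranks are identical under any
monotone link.

A small ridge penalty keeps the weighted fit well posed; the solver is a damped
Newton iteration, deterministic, with an automatic retry at a stronger penalty
if it fails to converge.  A scoring failure yields NaN scores and an abstention
rather than an exception.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScorerSpec", "ConformalResult", "conformal_scores", "decide"]

ABSTAIN = "abstain"

#: cap on the effective per-class weight ratio; the nominal 1e16 weight is
#: numerically indistinguishable in rank terms but overflows loss
#: accumulation, so weights are normalised and the ratio capped here.
MAX_WEIGHT_RATIO = 1e8


@dataclass(frozen=True)
class ScorerSpec:
    """Configuration of the class-weighted logistic scorer.

    class_weight   : nominal weight on the assumed class's examples (>= 1)
    regularization : ridge penalty on the slope coefficients
    mirrored       : if True (default) the NTC score weights NTC examples, the
                     exact mirror of the ASD score; if False both fits weight
                     ASD (the alternative reading of an "analogous" procedure)
    """

    class_weight: float = 1e16
    regularization: float = 1e-6
    mirrored: bool = True

    def __post_init__(self) -> None:
        if self.class_weight < 1:
            raise ValueError("class_weight must be >= 1")
        if self.regularization < 0:
            raise ValueError("regularization must be >= 0")

    @property
    def effective_ratio(self) -> float:
        return float(min(self.class_weight, MAX_WEIGHT_RATIO))


@dataclass
class ConformalResult:
    """Per-individual, per-predictor conformal outcome."""

    p_asd: float
    p_ntc: float
    decision: str
    predictor_id: str
    alpha: float


def _fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray,
    ridge: float,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> np.ndarray | None:
    """Ridge-penalised weighted logistic fit by damped Newton iteration.

    Returns the coefficient vector (intercept first) or None on failure.  The
    ridge applies to slopes only; weights are normalised to mean 1 so the loss
    stays on a float-safe scale regardless of the nominal class weight.
    """
    n, d = X.shape
    Xd = np.column_stack([np.ones(n), X])
    w = sample_weight / sample_weight.mean()
    pen = np.concatenate([[0.0], np.full(d, ridge)])
    beta = np.zeros(d + 1)

    def loss_grad(b: np.ndarray):
        z = Xd @ b
        # stable log-loss: log(1+exp(-|z|)) + max(z,0) - y*z
        ll = np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - y * z
        p = 1.0 / (1.0 + np.exp(-z))
        f = float(np.dot(w, ll) / n + 0.5 * np.dot(pen, b * b))
        g = Xd.T @ (w * (p - y)) / n + pen * b
        return f, g, p

    f, g, p = loss_grad(beta)
    for _ in range(max_iter):
        W = w * p * (1.0 - p) / n
        H = (Xd * W[:, None]).T @ Xd + np.diag(pen + 1e-14)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return None
        if not np.isfinite(step).all():
            return None
        t = 1.0
        for _ in range(40):
            cand = beta - t * step
            fc, gc, pc = loss_grad(cand)
            if fc <= f + 1e-14 * abs(f):
                break
            t *= 0.5
        else:
            break
        beta, f, g, p = cand, fc, gc, pc
        if np.abs(g).max() < tol:
            return beta
    return beta if np.abs(g).max() < 1e-4 else None


def rank_fraction(reference_fitted: np.ndarray, uci_fitted: float) -> float:
    """Fraction of reference fitted values <= the UCI's (ties count, per <=)."""
    reference_fitted = np.asarray(reference_fitted, dtype=float)
    if reference_fitted.size == 0:
        raise ValueError("empty reference class")
    return float(np.mean(reference_fitted <= uci_fitted))


def _one_class_score(
    X_ref: np.ndarray,
    labels_ref: np.ndarray,
    x_uci: np.ndarray,
    assumed: str,
    weighted: str,
    spec: ScorerSpec,
) -> float:
    """Conformal score of the UCI for ``assumed``; NaN if the fit fails."""
    X = np.vstack([X_ref, x_uci[None, :]])
    labels = np.append(labels_ref, assumed)
    y = (labels == assumed).astype(float)
    w = np.where(labels == weighted, spec.effective_ratio, 1.0)
    ridge = max(spec.regularization, 1e-12)
    beta = _fit_weighted_logistic(X, y, w, ridge)
    if beta is None:  # retry with stronger regularisation before giving up
        beta = _fit_weighted_logistic(X, y, w, ridge * 1e4)
    if beta is None:
        return float("nan")
    z = beta[0] + X @ beta[1:]
    ref_class = np.flatnonzero(labels_ref == assumed)
    return rank_fraction(z[ref_class], float(z[-1]))


def conformal_scores(
    uci_features: np.ndarray,
    reference_features: np.ndarray,
    reference_labels: np.ndarray,
    spec: ScorerSpec | None = None,
) -> tuple[float, float]:
    """(ASD score, NTC score) of one UCI against a labelled reference sample.

    Each call is self-contained: no state is shared across individuals.
    """
    spec = spec or ScorerSpec()
    X_ref = np.atleast_2d(np.asarray(reference_features, dtype=float))
    x_uci = np.asarray(uci_features, dtype=float).ravel()
    labels = np.asarray(reference_labels)
    if X_ref.shape[0] != labels.shape[0]:
        raise ValueError("reference features and labels misaligned")
    present = set(labels)
    if not {"ASD", "NTC"} <= present:
        raise ValueError(f"reference must contain both labels, found {sorted(present)}")
    if not (np.isfinite(X_ref).all() and np.isfinite(x_uci).all()):
        raise ValueError("features must be finite")
    p_asd = _one_class_score(X_ref, labels, x_uci, "ASD", "ASD", spec)
    ntc_weighted = "NTC" if spec.mirrored else "ASD"
    p_ntc = _one_class_score(X_ref, labels, x_uci, "NTC", ntc_weighted, spec)
    return p_asd, p_ntc


def decide(p_asd: float, p_ntc: float, alpha: float = 0.05) -> str:
    """Dual-threshold abstaining rule.

    Predict ASD iff the NTC label is rejected (p_ntc < alpha) *and* the ASD
    label is not (p_asd >= alpha); abstain otherwise, including when both
    labels are rejected, when neither is, or when a score is undefined.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if np.isnan(p_asd) or np.isnan(p_ntc):
        return ABSTAIN
    for name, p in (("p_asd", p_asd), ("p_ntc", p_ntc)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    return "ASD" if (p_ntc < alpha and p_asd >= alpha) else ABSTAIN
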