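"""Partial least-squares discriminant analysis via NIPALS.

PLS-DA regresses a dummy-coded class membership matrix Y (n x k) on the
spectral matrix X (n x p), extracting A latent components that maximise
covariance between X and Y scores, then assigns each sample to the class
with the largest predicted dummy response.

The component extraction is the classical NIPALS PLS2 iteration with
deflation of both X and Y:

    u   <- column of Y with maximal variance
    w   <- X'u / ||X'u||          (unit-norm weights)
    t   <- Xw                     (X scores)
    c   <- Y't / t't              (Y loadings)
    u   <- Yc / c'c
    ... until t stabilises ...
    p_a <- X't / t't              (X loadings)
    X   <- X - t p_a' ;  Y <- Y - t c_a'

The regression coefficients in the original (centred) variable space are
B = W (P'W)^-1 C', so that Yhat = Xc B + y_mean.

Mean-centring is always applied; unit-variance scaling (autoscale) is
optional and off by default — first-derivative spectra already share a
common intensity scale across channels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra_io import SpectraSet

__all__ = [
    "DummyCoding",
    "PLSDAModel",
    "encode_dummy",
    "nipals_pls2",
    "fit_plsda",
    "predict_scores",
    "predict_classes",
]


@dataclass(frozen=True)
class DummyCoding:
    """One-hot class membership matrix with a fixed label order."""

    class_labels: list[str]
    Y: np.ndarray  # n x k, rows sum to 1


def encode_dummy(labels, class_labels: list[str] | None = None) -> DummyCoding:
    """One-hot encode class labels in deterministic (lexicographic) order.

    ``class_labels`` may fix the column space explicitly (used inside
    cross-validation folds so every fold shares the full label set, even
    when a fold has lost a class).
    """
    labels = [str(l) for l in labels]
    if class_labels is None:
        class_labels = sorted(set(labels))
        if len(class_labels) < 2:
            raise ValueError("need at least 2 distinct class labels")
    index = {lab: j for j, lab in enumerate(class_labels)}
    unknown = sorted(set(labels) - set(class_labels))
    if unknown:
        raise ValueError(f"labels outside the class set: {unknown}")
    Y = np.zeros((len(labels), len(class_labels)))
    for i, lab in enumerate(labels):
        Y[i, index[lab]] = 1.0
    return DummyCoding(class_labels=list(class_labels), Y=Y)


@dataclass
class PLSDAModel:
    """Fitted PLS-DA state.

    Matrices follow the NIPALS conventions: ``W`` (p x A) unit-norm weight
    columns, ``P`` (p x A) X-loadings, ``C`` (k x A) Y-loadings, ``T``
    (n x A) training scores with mutually orthogonal columns, and ``B``
    (p x k) regression coefficients on the centred/scaled scale.
    """

    A: int
    class_labels: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    W: np.ndarray
    P: np.ndarray
    C: np.ndarray
    T: np.ndarray
    B: np.ndarray
    autoscale: bool = False
    convergence_tol: float = 1e-10
    max_iter: int = 500
    warnings_log: list[str] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def p(self) -> int:
        return int(self.x_mean.size)

    def component_y_variance(self) -> np.ndarray:
        """Per-component explained-Y sum of squares SS_a = (c_a'c_a)(t_a't_a)."""
        return np.einsum("ka,ka->a", self.C, self.C) * np.einsum(
            "na,na->a", self.T, self.T
        )

    # -- prediction ----------------------------------------------------------

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new spectra onto the latent components (scores)."""
        Xc = (np.asarray(X, float) - self.x_mean) / self.x_scale
        return Xc @ self.W @ np.linalg.inv(self.P.T @ self.W)

    def predict_response(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.p:
            raise ValueError(
                f"expected {self.p} channels, got {X.shape[1]}"
            )
        Xc = (X - self.x_mean) / self.x_scale
        return Xc @ self.B + self.y_mean

    def predict_labels(self, X: np.ndarray) -> list[str]:
        yhat = self.predict_response(X)
        # argmax returns the first maximum; labels are lexicographic, so
        # ties resolve to the lexicographically smallest label
        return [self.class_labels[j] for j in np.argmax(yhat, axis=1)]

    # -- serialisation -------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "A": self.A,
            "class_labels": self.class_labels,
            "autoscale": self.autoscale,
            "convergence_tol": self.convergence_tol,
            "max_iter": self.max_iter,
            "warnings": self.warnings_log,
        }
        for name in ("x_mean", "x_scale", "y_mean", "W", "P", "C", "T", "B"):
            payload[name] = getattr(self, name).tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PLSDAModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            A=payload["A"],
            class_labels=payload["class_labels"],
            x_mean=np.array(payload["x_mean"]),
            x_scale=np.array(payload["x_scale"]),
            y_mean=np.array(payload["y_mean"]),
            W=np.array(payload["W"]),
            P=np.array(payload["P"]),
            C=np.array(payload["C"]),
            T=np.array(payload["T"]),
            B=np.array(payload["B"]),
            autoscale=payload["autoscale"],
            convergence_tol=payload["convergence_tol"],
            max_iter=payload["max_iter"],
            warnings_log=payload["warnings"],
        )


def nipals_pls2(
    X: np.ndarray,
    Y: np.ndarray,
    A: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> dict:
    """NIPALS PLS2 on already centred/scaled matrices.

    Returns W, P, C, T, B and a list of convergence warnings.  Extraction
    stops early (with a warning) if X or Y deflates to numerical zero
    before A components are found.
    """
    X = np.array(X, float)
    Y = np.array(Y, float)
    n, p = X.shape
    if A < 1:
        raise ValueError("A must be >= 1")
    if A > min(n - 1, p):
        raise ValueError(f"A={A} exceeds min(n-1, p)={min(n - 1, p)}")
    x_norm0 = np.linalg.norm(X)
    y_norm0 = np.linalg.norm(Y)
    if x_norm0 == 0:
        raise ValueError("X has zero variance after centring")

    W = np.zeros((p, A))
    P = np.zeros((p, A))
    C = np.zeros((Y.shape[1], A))
    T = np.zeros((n, A))
    logs: list[str] = []
    n_extracted = 0
    for a in range(A):
        if np.linalg.norm(X) < 1e-12 * x_norm0 or np.linalg.norm(Y) < 1e-12 * max(y_norm0, 1.0):
            logs.append(f"component {a + 1}: X or Y exhausted; stopping early")
            break
        u = Y[:, int(np.argmax(Y.var(axis=0)))]
        t_old = None
        for it in range(max_iter):
            w = X.T @ u
            w_norm = np.linalg.norm(w)
            if w_norm == 0:
                raise ValueError(f"component {a + 1}: degenerate weights (X'u = 0)")
            w /= w_norm
            t = X @ w
            c = (Y.T @ t) / (t @ t)
            u = (Y @ c) / (c @ c)
            if t_old is not None:
                denom = np.linalg.norm(t)
                if denom == 0 or np.linalg.norm(t - t_old) / denom < tol:
                    break
            t_old = t
        else:
            logs.append(
                f"component {a + 1}: no convergence in {max_iter} iterations"
            )
        p_a = (X.T @ t) / (t @ t)
        X = X - np.outer(t, p_a)
        Y = Y - np.outer(t, c)
        W[:, a], P[:, a], C[:, a], T[:, a] = w, p_a, c, t
        n_extracted += 1

    if n_extracted < A:
        W, P, C, T = W[:, :n_extracted], P[:, :n_extracted], C[:, :n_extracted], T[:, :n_extracted]
    B = W @ np.linalg.solve(P.T @ W, C.T)
    return {"W": W, "P": P, "C": C, "T": T, "B": B, "A": n_extracted, "warnings": logs}


def fit_plsda(
    s: SpectraSet,
    A: int | None = None,
    autoscale: bool = False,
    tol: float = 1e-10,
    max_iter: int = 500,
    class_labels: list[str] | None = None,
) -> PLSDAModel:
    """Fit a PLS-DA model to a (processed) spectral dataset.

    ``A`` defaults to k - 1 where k is the number of origin classes — the
    standard component count for a k-class discriminant model.  Labels are
    taken from the ``origin`` metadata column.
    """
    coding = encode_dummy(s.origins, class_labels=class_labels)
    k = len(coding.class_labels)
    if A is None:
        A = k - 1
    if s.n <= A:
        raise ValueError(f"need n > A; got n={s.n}, A={A}")

    X = s.intensities.astype(float)
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    if autoscale:
        x_scale = Xc.std(axis=0, ddof=1)
        x_scale[x_scale == 0] = 1.0  # constant channels pass through unscaled
    else:
        x_scale = np.ones(s.p)
    Xc = Xc / x_scale
    y_mean = coding.Y.mean(axis=0)
    Yc = coding.Y - y_mean

    fit = nipals_pls2(Xc, Yc, A, tol=tol, max_iter=max_iter)
    for msg in fit["warnings"]:
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return PLSDAModel(
        A=fit["A"],
        class_labels=coding.class_labels,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        W=fit["W"],
        P=fit["P"],
        C=fit["C"],
        T=fit["T"],
        B=fit["B"],
        autoscale=autoscale,
        convergence_tol=tol,
        max_iter=max_iter,
        warnings_log=fit["warnings"],
    )


def predict_scores(m: PLSDAModel, s: SpectraSet) -> np.ndarray:
    """Predicted dummy-response matrix (n_new x k) for new spectra."""
    return m.predict_response(s.intensities)


def predict_classes(m: PLSDAModel, s: SpectraSet) -> list[str]:
    """Class assignment by maximum predicted dummy response."""
    return m.predict_labels(s.intensities)
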