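"""Thin SVM-RBF fit/predict backend.

The searchlight evaluates tens of thousands of tiny SVM problems
(~29 samples x ~171 features), where the public ``sklearn.svm.SVC``
estimator spends most of its time in input validation.  When available we
call scikit-learn's low-level libsvm binding directly — the exact same
solver ``SVC`` wraps — and fall back to the public estimator otherwise.
Unit tests assert prediction-level equivalence of the two paths.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

try:  # private but long-stable; guarded by an equivalence test
    from sklearn.svm import _libsvm as _ll

    _ll.set_verbosity_wrap(0)
    HAVE_FAST_BACKEND = True
except Exception:  # pragma: no cover - exercised only on unsupported versions
    _ll = None
    HAVE_FAST_BACKEND = False


def _fit_predict_fast(X_train, y_train, X_test, C: float, gamma: float) -> np.ndarray:
    out = _ll.fit(
        np.ascontiguousarray(X_train, dtype=np.float64),
        np.ascontiguousarray(y_train, dtype=np.float64),
        svm_type=0,
        kernel="rbf",
        gamma=gamma,
        C=C,
    )
    support, SV, nSV, sv_coef, intercept, probA, probB = out[:7]
    pred = _ll.predict(
        np.ascontiguousarray(X_test, dtype=np.float64),
        support,
        SV,
        nSV,
        sv_coef,
        intercept,
        probA,
        probB,
        svm_type=0,
        kernel="rbf",
        gamma=gamma,
    )
    return pred.astype(np.int64)


def _fit_predict_sklearn(X_train, y_train, X_test, C: float, gamma: float) -> np.ndarray:
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(X_train, y_train)
    return clf.predict(X_test).astype(np.int64)


def fit_predict(X_train, y_train, X_test, C: float, gamma: float,
                backend: str = "auto") -> np.ndarray:
    """Fit SVM-RBF on (X_train, y_train) and predict labels for X_test.

    backend: "auto" (fast path when available), "fast", or "sklearn".
    """
    if backend == "sklearn" or (backend == "auto" and not HAVE_FAST_BACKEND):
        return _fit_predict_sklearn(X_train, y_train, X_test, C, gamma)
    if backend in ("auto", "fast"):
        return _fit_predict_fast(X_train, y_train, X_test, C, gamma)
    raise ValueError(f"unknown SVM backend {backend!r}")
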