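"""Genomic annotation model: L2-penalized logistic regression.

Predicts binary outlier status from the standardized annotation vector G
alone. The objective is

    min_w  - sum_n log P(y_n | G_n; w0, w)  +  lambda ||w||^2

with the intercept unpenalized. Fitting is delegated to scikit-learn
(lbfgs, C = 1 / (2 lambda)).
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression


def fit_gam(G: np.ndarray, y: np.ndarray, penalty: float = 1.0) -> np.ndarray:
    """Fit the annotation-only model for one signal.

    Parameters
    ----------
    G : (n, P) standardized annotations
    y : (n,) binary outlier labels (1 = outlier in any direction)
    penalty : L2 weight lambda on the slope coefficients

    Returns
    -------
    (P + 1,) array: intercept followed by slopes.
    """
    G = np.asarray(G, float)
    y = np.asarray(y, int)
    if len(np.unique(y)) < 2:
        raise ValueError("GAM requires both outlier and non-outlier labels")
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    clf = LogisticRegression(
        C=1.0 / (2.0 * penalty), solver="lbfgs", max_iter=2000, tol=1e-10,
    )
    clf.fit(G, y)
    return np.concatenate([clf.intercept_, clf.coef_.ravel()])


def gam_predict(G: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Predicted outlier probabilities, strictly inside (0, 1)."""
    G = np.asarray(G, float)
    z = coef[0] + G @ coef[1:]
    return 1.0 / (1.0 + np.exp(-z))
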