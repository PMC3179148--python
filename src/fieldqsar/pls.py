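"""PLS regression with leave-one-out validation and QSAR model statistics.

The estimator follows the standard field-QSAR protocol: a partial
least-squares model (NIPALS, via scikit-learn) is fitted on the assembled
descriptor block with pKi as the response; the optimum number of latent
components (OPN) is the one maximizing the leave-one-out cross-validated

    q2 = 1 - PRESS_cv / sum_i (y_i - ybar)^2 ,

with the full-training-set mean in the denominator and centering recomputed
inside every fold.  The final model reports

    r2_ncv  — squared correlation of fitted vs. observed (training),
    SEE     — sqrt(RSS / (n - OPN - 1)),
    F       — (r2 / OPN) / ((1 - r2) / (n - OPN - 1)),
    r2_pred — 1 - PRESS_test / SD  (SD relative to the training mean),

and per-block relative contributions sum_j |coef_j| * sd_j normalized over
all columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.utils.validation import check_array, check_X_y

from .fields import DescriptorBlock


class PLSError(ValueError):
    pass


@dataclass
class ModelStats:
    """The statistics reported for a fitted field-QSAR model."""

    q2: float
    r2_ncv: float
    see: float
    f: float
    opn: int
    r2_pred: float | None = None
    block_contributions: dict[str, float] = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "q2": float(self.q2),
            "OPN": int(self.opn),
            "r2_ncv": float(self.r2_ncv),
            "SEE": float(self.see),
            "F": float(self.f),
        }
        if self.r2_pred is not None:
            out["r2_pred"] = float(self.r2_pred)
        if self.block_contributions:
            out["contributions"] = {k: float(v) for k, v in self.block_contributions.items()}
        return out


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, DescriptorBlock):
        return X.X
    return np.asarray(X, dtype=float)


def _fit_sk_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    # Rank-deficient X (or a fully deflated response) makes NIPALS degenerate
    # beyond the effective rank; extra components add nothing, so fall back to
    # the largest component count that fits cleanly.
    for a in range(n_components, 0, -1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = PLSRegression(n_components=a, scale=False)
            try:
                model.fit(X, y.reshape(-1, 1))
            except Exception:
                continue
        if not np.all(np.isfinite(model.coef_)):
            continue
        norms = (model.x_scores_**2).sum(axis=0)
        effective = int((norms > 1e-10 * max(norms[0], 1e-300)).sum())
        if effective < a:
            continue  # retry with fewer components
        return model
    raise PLSError("PLS fit failed for every component count")


class PLSQSAR(RegressorMixin, BaseEstimator):
    """PLS regressor for field-QSAR descriptor blocks.

    Parameters
    ----------
    n_components : int or "auto"
        Number of latent components; "auto" selects the OPN by LOO q2.
    max_components : int
        Upper bound scanned when ``n_components="auto"``.

    Attributes (after fit)
    ----------------------
    opn_ : selected number of components
    q2_, press_cv_ : LOO statistics at the OPN
    q2_by_component_ : q2 for 1..max scanned components
    r2_ncv_, see_, f_ : training statistics
    coef_, intercept_ : regression coefficients on the input columns
    """

    def __init__(self, n_components: int | str = "auto", max_components: int = 10):
        self.n_components = n_components
        self.max_components = max_components

    # -- core fitting --------------------------------------------------

    def fit(self, X, y) -> "PLSQSAR":
        block = X if isinstance(X, DescriptorBlock) else None
        Xm = _as_matrix(X)
        Xm, y = check_X_y(Xm, np.asarray(y, dtype=float))
        n, p = Xm.shape
        if np.std(y) == 0:
            raise PLSError("zero-variance activity vector")

        if self.n_components == "auto":
            max_a = int(min(self.max_components, n - 3, p))
            if max_a < 1:
                raise PLSError("too few samples for component selection")
            opn, table = select_opn(Xm, y, max_a)
            self.q2_by_component_ = table
        else:
            opn = int(self.n_components)
            if not 1 <= opn <= min(n - 1, p):
                raise PLSError(f"n_components={opn} outside [1, min(n-1, p)]")
            self.q2_by_component_ = None
        if n < opn + 2:
            raise PLSError("need n >= n_components + 2")

        self.opn_ = opn
        self.model_ = _fit_sk_pls(Xm, y, opn)
        self.coef_ = self.model_.coef_.ravel().copy()
        self.intercept_ = float(np.ravel(self.model_.intercept_)[0])
        self.n_features_in_ = p
        self._train_col_std_ = Xm.std(axis=0, ddof=1)
        self._train_y_mean_ = float(y.mean())
        self._block_ = block

        fitted = self.model_.predict(Xm).ravel()
        self.r2_ncv_ = _squared_correlation(fitted, y)
        rss = float(((y - fitted) ** 2).sum())
        dof = n - opn - 1
        self.see_ = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")
        self.f_ = _f_statistic(self.r2_ncv_, n, opn)
        if n >= opn + 3:
            self.q2_, self.press_cv_ = loo_q2(Xm, y, opn)
        else:
            self.q2_, self.press_cv_ = float("nan"), float("nan")
        return self

    def predict(self, X) -> np.ndarray:
        Xm = check_array(_as_matrix(X))
        return self.model_.predict(Xm).ravel()

    # -- statistics ----------------------------------------------------

    def r2_pred(self, X_test, y_test) -> float:
        """External predictivity 1 - PRESS/SD, SD about the training mean."""
        y_test = np.asarray(y_test, dtype=float)
        if len(y_test) == 0:
            raise PLSError("empty test set")
        pred = self.predict(X_test)
        press = float(((y_test - pred) ** 2).sum())
        sd = float(((y_test - self._train_y_mean_) ** 2).sum())
        if sd == 0:
            raise PLSError("test activities all equal the training mean")
        return 1.0 - press / sd

    def block_contributions(self, block: DescriptorBlock | None = None) -> dict[str, float]:
        """Per-block fraction of sum_j |coef_j| * sd_j (training column sd)."""
        block = block or self._block_
        if block is None:
            raise PLSError("no DescriptorBlock available for contributions")
        weight = np.abs(self.coef_) * self._train_col_std_
        total = weight.sum()
        out = {}
        for b in block.blocks:
            w = float(weight[b.cols].sum())
            out[b.name] = w / total if total > 0 else 0.0
        return out

    def stats(self, X_test=None, y_test=None) -> ModelStats:
        r2p = None
        if X_test is not None and y_test is not None and len(np.atleast_1d(y_test)):
            r2p = self.r2_pred(X_test, y_test)
        contributions = {}
        if self._block_ is not None:
            contributions = self.block_contributions()
        return ModelStats(
            q2=self.q2_,
            r2_ncv=self.r2_ncv_,
            see=self.see_,
            f=self.f_,
            opn=self.opn_,
            r2_pred=r2p,
            block_contributions=contributions,
        )


# --------------------------------------------------------------------------
# module-level operations (thin wrappers / building blocks)
# --------------------------------------------------------------------------

def _squared_correlation(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _f_statistic(r2: float, n: int, opn: int) -> float:
    dof = n - opn - 1
    if dof <= 0 or r2 >= 1.0:
        return float("inf")
    return (r2 / opn) / ((1.0 - r2) / dof)


def fit_pls(X, y, n_components: int) -> PLSQSAR:
    """Fit a PLS model with a fixed number of components."""
    return PLSQSAR(n_components=n_components).fit(X, y)


def loo_q2(X, y, n_components: int) -> tuple[float, float]:
    """Leave-one-out q2: every fold refits (centering included) from scratch.

    q2 = 1 - PRESS_cv / SS_tot with SS_tot about the full training mean.
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < n_components + 3:
        raise PLSError("need n >= n_components + 3 for LOO")
    press = 0.0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if np.std(y[mask]) == 0:
            raise PLSError(f"fold {i}: zero-variance activities")
        model = _fit_sk_pls(Xm[mask], y[mask], n_components)
        pred = float(model.predict(Xm[i : i + 1]).ravel()[0])
        press += (y[i] - pred) ** 2
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / ss_tot, press


def select_opn(X, y, max_components: int) -> tuple[int, list[dict]]:
    """Scan 1..max_components; OPN = argmax LOO q2 (ties: fewer components,
    then lower SEE)."""
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if max_components < 1:
        raise PLSError("max_components must be >= 1")
    table = []
    for a in range(1, max_components + 1):
        q2, press = loo_q2(Xm, y, a)
        model = _fit_sk_pls(Xm, y, a)
        fitted = model.predict(Xm).ravel()
        rss = float(((y - fitted) ** 2).sum())
        dof = len(y) - a - 1
        see = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")
        table.append({"components": a, "q2": q2, "press": press, "see": see})
    best = table[0]
    for row in table[1:]:
        if row["q2"] > best["q2"] + 1e-12:
            best = row
    return best["components"], table


def final_stats(model: PLSQSAR, X_train, y_train, X_test=None, y_test=None) -> ModelStats:
    """Assemble the reported statistics for a fitted model."""
    return model.stats(X_test, y_test)


def block_contributions(model: PLSQSAR, block: DescriptorBlock) -> dict[str, float]:
    return model.block_contributions(block)


def y_randomization(
    X, y, n_components: int, n_permutations: int = 100, seed: int = 0
) -> np.ndarray:
    """Diagnostic: LOO q2 under seeded random permutations of the response."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    out = np.empty(n_permutations)
    for k in range(n_permutations):
        out[k] = loo_q2(X, rng.permutation(y), n_components)[0]
    return out
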