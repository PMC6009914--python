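"""PLS1 regression, cross-validation, external validation and contour maps.

The regression is NIPALS-style PLS1 on column-centered (not variance-scaled)
descriptors, the standard choice for lattice-field QSAR where thousands of
collinear columns share one physical unit per field kind.  Internal validity
is the leave-one-out cross-validated coefficient

    q^2 = 1 - sum_i (y_i - yhat_(-i))^2 / sum_i (y_i - ybar)^2 ,

with ybar the full-training mean and the column mask held fixed across the
LOO loop.  External predictivity on held-out compounds is reported as RMSEP
and the squared Pearson correlation r^2_pred, together with the
Golbraikh-Tropsha through-origin checks ((R^2-R0^2)/R^2 < 0.1 and
0.85 <= K <= 1.15, with primed variants for the reversed regression).

Contour extraction ranks lattice columns by signed stdev x coefficient and
returns the smallest point sets covering a given share (default 80% favored /
20% disfavored) of the total positive and negative contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .fields import FieldMatrix


@dataclass
class PLSModelState:
    """Fitted latent-variable model on the active (unmasked) columns."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray  # (p, c)
    x_loadings: np.ndarray  # (p, c)
    y_loadings: np.ndarray  # (c,)
    coefficients: np.ndarray  # (p,) on centered X
    active_columns: np.ndarray | None = None  # global column ids if fit on a FieldMatrix
    column_kinds: np.ndarray | None = None
    point_index: np.ndarray | None = None
    column_sd: np.ndarray | None = None  # training stdev per active column

    def predict(self, X) -> np.ndarray:
        X = _as_design(X)
        return (X - self.x_mean) @ self.coefficients + self.y_mean


def _as_design(X) -> np.ndarray:
    if isinstance(X, FieldMatrix):
        return X.design_matrix()
    return np.asarray(X, dtype=float)


def fit_pls(X, y, n_components: int) -> PLSModelState:
    """NIPALS PLS1 on column-centered, unscaled descriptors (deterministic)."""
    meta = X if isinstance(X, FieldMatrix) else None
    Xd = _as_design(X)
    y = np.asarray(y, dtype=float)
    n, p = Xd.shape
    if p == 0:
        raise ValueError("no active columns to fit")
    if np.ptp(y) == 0:
        raise ValueError("activity vector has zero variance")
    if n_components < 1:
        raise ValueError("need at least one component")
    x_mean = Xd.mean(axis=0)
    y_mean = float(y.mean())
    E = Xd - x_mean
    f = y - y_mean
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-14:  # residual exhausted; stop early
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-14:
            W, P, q = W[:, :a], P[:, :a], q[:a]
            break
        pa = E.T @ t / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, pa)
        f = f - qa * t
        W[:, a], P[:, a], q[a] = w, pa, qa
    if W.shape[1] == 0:
        raise ValueError("PLS extracted no components (degenerate problem)")
    coef = W @ np.linalg.solve(P.T @ W, q)
    state = PLSModelState(
        n_components=W.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=coef,
    )
    if meta is not None:
        act = meta.active_indices()
        state.active_columns = act
        state.column_kinds = meta.kinds[act]
        state.point_index = meta.point_index[act]
        state.column_sd = Xd.std(axis=0, ddof=1)
    return state


def loo_q2(X, y, n_components: int) -> tuple[float, float]:
    """Leave-one-out q^2 (and the LOO RMS error) with a fixed column mask.

    Each left-out compound is predicted by a model refit (re-centered) on the
    remaining n-1; the denominator uses the full-sample mean.
    """
    Xd = _as_design(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("LOO needs at least 3 samples")
    if n_components >= n - 1:
        raise ValueError("n_components must be < n - 1 for LOO")
    preds = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        model = fit_pls(Xd[keep], y[keep], n_components)
        preds[i] = model.predict(Xd[i : i + 1])[0]
    press = float(np.sum((y - preds) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("activity vector has zero variance")
    return 1.0 - press / tss, math.sqrt(press / n)


def select_components(X, y, max_components: int) -> int:
    """Number of latent variables maximizing LOO q^2 (ties -> fewest)."""
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    best_c, best_q2 = 1, -np.inf
    for c in range(1, max_components + 1):
        q2, _ = loo_q2(X, y, c)
        if q2 > best_q2 + 1e-12:
            best_c, best_q2 = c, q2
    return best_c


@dataclass
class ExternalValidation:
    """Held-out predictivity and Golbraikh-Tropsha through-origin statistics."""

    rmsep: float
    r2_pred: float
    r0_sq: float
    r0_prime_sq: float
    k_slope: float
    k_prime_slope: float
    gt_ratio: float
    gt_ratio_prime: float

    @property
    def passes_golbraikh_tropsha(self) -> bool:
        slope_ok = 0.85 <= self.k_slope <= 1.15 or 0.85 <= self.k_prime_slope <= 1.15
        ratio_ok = self.gt_ratio < 0.1 or self.gt_ratio_prime < 0.1
        return slope_ok and ratio_ok


def external_validate(predicted, observed, training_mean: float | None = None
                      ) -> ExternalValidation:
    """RMSEP, squared-Pearson r^2_pred and through-origin regression checks."""
    yhat = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if yhat.shape != y.shape or y.ndim != 1 or len(y) < 3:
        raise ValueError("need equal-length 1D vectors with n >= 3")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        raise ValueError("zero variance in predicted or observed values")
    rmsep = float(np.sqrt(np.mean((y - yhat) ** 2)))
    r = float(np.corrcoef(yhat, y)[0, 1])
    r2 = r * r
    k = float(np.sum(y * yhat) / np.sum(yhat**2))
    kp = float(np.sum(y * yhat) / np.sum(y**2))
    r0 = 1.0 - np.sum((y - k * yhat) ** 2) / np.sum((y - y.mean()) ** 2)
    r0p = 1.0 - np.sum((yhat - kp * y) ** 2) / np.sum((yhat - yhat.mean()) ** 2)
    return ExternalValidation(
        rmsep=rmsep,
        r2_pred=r2,
        r0_sq=float(r0),
        r0_prime_sq=float(r0p),
        k_slope=k,
        k_prime_slope=kp,
        gt_ratio=(r2 - float(r0)) / r2,
        gt_ratio_prime=(r2 - float(r0p)) / r2,
    )


@dataclass
class TrainingStatistics:
    r2_ncv: float
    see: float
    f_value: float
    rmsec: float


def summary_statistics(model: PLSModelState, X, y) -> TrainingStatistics:
    """Non-cross-validated r^2, SEE, F and training RMS error.

    SEE = sqrt(RSS/(n-c-1)); F = [r^2/c] / [(1-r^2)/(n-c-1)] with c the
    number of latent variables (conventions mutually consistent).
    """
    y = np.asarray(y, dtype=float)
    n, c = len(y), model.n_components
    if n <= c + 1:
        raise ValueError("too few samples for SEE/F with this many components")
    yhat = model.predict(X)
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    see = math.sqrt(rss / (n - c - 1))
    f = math.inf if r2 >= 1.0 else (r2 / c) / ((1.0 - r2) / (n - c - 1))
    return TrainingStatistics(r2_ncv=r2, see=see, f_value=f, rmsec=math.sqrt(rss / n))


def _contributions(model: PLSModelState) -> np.ndarray:
    if model.column_sd is None:
        raise ValueError("model was not fit on a FieldMatrix (no column metadata)")
    return model.column_sd * model.coefficients


def field_fractions(model: PLSModelState) -> dict[str, float]:
    """Share of total stdev x |coefficient| contribution per field kind."""
    contrib = np.abs(_contributions(model))
    total = contrib.sum()
    kinds = model.column_kinds
    if total == 0:
        uniq = sorted(set(kinds))
        return {k: 1.0 / len(uniq) for k in uniq}
    return {
        str(k): float(contrib[kinds == k].sum() / total) for k in sorted(set(kinds))
    }


@dataclass
class ContourSet:
    """Favored / disfavored lattice points for one field kind."""

    field_kind: str
    favored_points: list[tuple[tuple[int, int, int], float]] = dc_field(
        default_factory=list
    )
    disfavored_points: list[tuple[tuple[int, int, int], float]] = dc_field(
        default_factory=list
    )
    levels: tuple[float, float] = (80.0, 20.0)


def _covering_prefix(points, contribs, level_pct):
    """Smallest descending-sorted prefix covering level_pct% of the total."""
    order = np.argsort(-contribs)
    total = contribs.sum()
    out = []
    acc = 0.0
    for j in order:
        if total > 0 and acc >= level_pct / 100.0 * total - 1e-12:
            break
        out.append((tuple(int(v) for v in points[j]), float(contribs[j])))
        acc += contribs[j]
    return out


def extract_contours(
    model: PLSModelState, favored_level: float = 80.0, disfavored_level: float = 20.0
) -> dict[str, ContourSet]:
    """Smallest point sets covering the requested contribution levels.

    Favored points have positive stdev x coefficient (activity-increasing
    field values under a +1 probe), disfavored points negative.
    """
    contrib = _contributions(model)
    out: dict[str, ContourSet] = {}
    for kind in sorted(set(model.column_kinds)):
        sel = model.column_kinds == kind
        c = contrib[sel]
        pts = model.point_index[sel]
        pos = c > 0
        neg = c < 0
        out[str(kind)] = ContourSet(
            field_kind=str(kind),
            favored_points=_covering_prefix(pts[pos], c[pos], favored_level),
            disfavored_points=_covering_prefix(pts[neg], -c[neg], disfavored_level),
            levels=(favored_level, disfavored_level),
        )
    return out
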