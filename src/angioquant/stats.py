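"""Classification and reader-study statistics.

Covers empirical ROC curves with bootstrap confidence intervals and operating
points, Kendall's coefficient of concordance for multi-reader ordinal
ratings, covariate-adjusted ROC regression through a probit link, simple
size-vs-metric regression, and ellipsoidal tumor geometry.

The ROC regression models the reader ROC curve as a function of tumor
diameter x:

    ROC_x(p) = Phi( alpha0_k + alpha1 * Phi^{-1}(p) + beta * x )

for reader k at false-positive rate p, where Phi is the standard normal CDF.
It is fitted by the placement-value approach: each tumor score is converted
to its placement in the reader's empirical control survival distribution, and
the binary indicators 1{placement <= p} over a grid of p are regressed with a
probit-link GLM on reader dummies, Phi^{-1}(p), and x. Standard errors come
from a bootstrap that resamples whole images (stratified by class) so that
within-image correlation across readers is respected.

The positive-class decision rule is score >= threshold throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCCurve",
    "ReaderPanel",
    "ROCRegressionFit",
    "TumorGeometry",
    "roc_curve",
    "auc_mann_whitney",
    "bootstrap_ci",
    "optimal_cutoff",
    "kendalls_w",
    "placement_values",
    "roc_regression",
    "predicted_roc",
    "size_metric_regression",
    "tumor_geometry",
]


@dataclass(frozen=True)
class ROCCurve:
    """Empirical ROC: thresholds (descending), fpr/tpr (nondecreasing), trapezoidal AUC."""

    thresholds: np.ndarray = field(repr=False)
    fpr: np.ndarray = field(repr=False)
    tpr: np.ndarray = field(repr=False)
    auc: float = 0.0
    ci: tuple | None = None


@dataclass(frozen=True)
class ReaderPanel:
    """K readers x N images of ordinal scores 1-6, with labels and tumor diameters."""

    scores: np.ndarray = field(repr=False)  # (K, N) int
    labels: np.ndarray = field(repr=False)  # (N,) bool, True = tumor
    diameters: np.ndarray = field(repr=False)  # (N,) float, NaN for controls
    reader_ids: tuple = ()

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        labels = np.asarray(self.labels, dtype=bool)
        diam = np.asarray(self.diameters, dtype=float)
        if scores.ndim != 2 or scores.shape[0] < 2:
            raise ValueError("need a (K >= 2, N) score matrix")
        if labels.shape != (scores.shape[1],) or diam.shape != labels.shape:
            raise ValueError("labels/diameters must align with score columns")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "diameters", diam)
        if not self.reader_ids:
            object.__setattr__(
                self, "reader_ids", tuple(f"R{k + 1}" for k in range(scores.shape[0]))
            )

    @property
    def n_readers(self) -> int:
        return self.scores.shape[0]

    @property
    def n_images(self) -> int:
        return self.scores.shape[1]


@dataclass(frozen=True)
class ROCRegressionFit:
    """Fitted probit ROC regression: per-reader intercepts, baseline slope, covariate beta."""

    alpha0: np.ndarray
    alpha1: float
    beta: float
    reader_ids: tuple
    p_grid: np.ndarray = field(repr=False)
    bootstrap_se: dict | None = None
    ci: dict | None = None
    n_boot: int = 0


@dataclass(frozen=True)
class TumorGeometry:
    """Ellipsoidal tumor: volume pi/6*d1*d2*d3, geometric-mean diameter."""

    axes: tuple
    volume: float
    mean_diameter: float


def roc_curve(scores, labels) -> ROCCurve:
    """Empirical ROC over all distinct score thresholds (score >= t is positive).

    The trapezoidal AUC equals the tie-corrected Mann-Whitney statistic
    U/(n1*n2).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def auc_mann_whitney(scores, labels) -> float:
    """AUC via midranks: (rank-sum form of the tie-corrected Mann-Whitney U)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bootstrap_ci(
    metric,
    data,
    labels=None,
    n_boot: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    max_redraws: int = 100,
):
    """Percentile bootstrap CI by case resampling, stratified by class if labels given.

    ``metric`` is called as ``metric(data[idx])`` or ``metric(data[idx],
    labels[idx])``. Degenerate resamples in the unstratified case (metric
    raises) are redrawn up to ``max_redraws`` times, then error. Returns
    ``(lo, hi)``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    data = np.asarray(data)
    n = data.shape[0]
    if labels is not None:
        labels = np.asarray(labels, dtype=bool)
        idx_pos = np.flatnonzero(labels)
        idx_neg = np.flatnonzero(~labels)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_redraws + 1):
            if labels is None:
                idx = rng.integers(0, n, n)
                try:
                    vals[b] = metric(data[idx])
                    break
                except ValueError:
                    if attempt == max_redraws:
                        raise ValueError("degenerate bootstrap resamples exhausted redraws")
            else:
                idx = np.concatenate(
                    [
                        rng.choice(idx_pos, idx_pos.size, replace=True),
                        rng.choice(idx_neg, idx_neg.size, replace=True),
                    ]
                )
                vals[b] = metric(data[idx], labels[idx])
                break
    lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def optimal_cutoff(roc: ROCCurve, mode: str = "youden", level: float = 0.9):
    """Operating point on an empirical ROC.

    mode='youden' maximizes sensitivity + specificity - 1 (ties resolved
    toward higher specificity); mode='fix_spec'/'fix_sens' returns the best
    partner value subject to specificity (sensitivity) >= ``level``, raising
    if the constraint is unattainable at any finite threshold. Returns
    ``(threshold, sensitivity, specificity)``.
    """
    finite = np.isfinite(roc.thresholds)
    thr = roc.thresholds[finite]
    sens = roc.tpr[finite]
    spec = 1.0 - roc.fpr[finite]
    if thr.size == 0:
        raise ValueError("ROC curve has no finite thresholds")
    if mode == "youden":
        j = sens + spec - 1.0
        best = np.flatnonzero(j == j.max())
        i = best[np.argmax(spec[best])]
    elif mode in ("fix_spec", "fix_sens"):
        constraint = spec if mode == "fix_spec" else sens
        partner = sens if mode == "fix_spec" else spec
        ok = np.flatnonzero(constraint >= level)
        if ok.size == 0:
            raise ValueError(f"{mode}({level}) unattainable: max is {constraint.max():.3f}")
        i = ok[np.argmax(partner[ok])]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(thr[i]), float(sens[i]), float(spec[i])


def kendalls_w(scores) -> float:
    """Kendall's coefficient of concordance W with the standard tie correction.

    ``scores`` is (K readers, N images). Within-reader midranks are used;
    W = 12 S / (K^2 (N^3 - N) - K * sum_k T_k) with T_k = sum over tie groups
    of (t^3 - t).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 2:
        raise ValueError("need at least 2 readers and 2 images")
    k, n = scores.shape
    ranks = np.vstack([sps.rankdata(row) for row in scores])
    r = ranks.sum(axis=0)
    s = float(((r - r.mean()) ** 2).sum())
    tie = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        tie += float((counts**3 - counts).sum())
    denom = k**2 * (n**3 - n) - k * tie
    if denom <= 0:
        return 0.0
    return 12.0 * s / denom


def placement_values(tumor_scores, control_scores) -> np.ndarray:
    """Placement of each tumor score in the control survival distribution.

    PV = P0(Y0 >= y) estimated empirically with midrank tie handling, clamped
    to the open interval (0, 1) at half a control mass unit so probit
    transforms stay finite even when supports do not overlap.
    """
    t = np.asarray(tumor_scores, dtype=float)
    c = np.asarray(control_scores, dtype=float)
    n0 = c.size
    if n0 == 0:
        raise ValueError("need control scores")
    greater = (c[None, :] > t[:, None]).sum(axis=1)
    equal = (c[None, :] == t[:, None]).sum(axis=1)
    pv = (greater + 0.5 * equal) / n0
    eps = 0.5 / n0
    return np.clip(pv, eps, 1.0 - eps)


def _rocreg_design(panel: ReaderPanel, p_grid: np.ndarray):
    """Stack the placement-value GLM design over readers, tumors and the p grid."""
    tumors = np.flatnonzero(panel.labels)
    controls = np.flatnonzero(~panel.labels)
    k, _ = panel.scores.shape
    q = sps.norm.ppf(p_grid)
    rows_y, rows_reader, rows_q, rows_x = [], [], [], []
    for r in range(k):
        pv = placement_values(panel.scores[r, tumors], panel.scores[r, controls])
        x = panel.diameters[tumors]
        # indicator 1{PV <= p} for each tumor × grid point
        y = (pv[:, None] <= p_grid[None, :] + 1e-12).astype(float).ravel()
        rows_y.append(y)
        rows_reader.append(np.full(y.size, r))
        rows_q.append(np.tile(q, tumors.size))
        rows_x.append(np.repeat(x, p_grid.size))
    y = np.concatenate(rows_y)
    reader = np.concatenate(rows_reader).astype(int)
    design = np.column_stack(
        [np.eye(k)[reader], np.concatenate(rows_q), np.concatenate(rows_x)]
    )
    return y, design


def _fit_rocreg_once(panel: ReaderPanel, p_grid: np.ndarray):
    y, design = _rocreg_design(panel, p_grid)
    model = sm.GLM(y, design, family=sm.families.Binomial(sm.families.links.Probit()))
    with warnings.catch_warnings():
        # small bootstrap panels often separate perfectly; the working GLM
        # still yields finite usable coefficients on the clamped design
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100)
    if not np.all(np.isfinite(res.params)):
        raise ValueError("singular design in ROC regression")
    k = panel.n_readers
    return res.params[:k], float(res.params[k]), float(res.params[k + 1])


def _control_pv_grid(panel: ReaderPanel, max_points: int = 50) -> np.ndarray:
    """FPR grid: distinct control placement values pooled over readers, capped."""
    controls = np.flatnonzero(~panel.labels)
    pvs = []
    for r in range(panel.n_readers):
        pvs.append(placement_values(panel.scores[r, controls], panel.scores[r, controls]))
    grid = np.unique(np.concatenate(pvs))
    grid = grid[(grid > 0.0) & (grid < 1.0)]
    if grid.size > max_points:
        grid = np.quantile(grid, np.linspace(0, 1, max_points))
        grid = np.unique(grid)
    if grid.size == 0:
        raise ValueError("no usable control placement values")
    return grid


def roc_regression(
    panel: ReaderPanel,
    n_boot: int = 1000,
    seed: int | None = None,
    p_grid: np.ndarray | None = None,
    max_grid: int = 50,
) -> ROCRegressionFit:
    """Fit the covariate-adjusted probit ROC regression to a reader panel.

    Tumor diameter (mm) is the covariate; coefficients are per-reader
    intercepts alpha0_k, the baseline-quantile slope alpha1, and the diameter
    effect beta (probit units per mm). Set ``n_boot=0`` to skip bootstrap
    standard errors; otherwise whole images are resampled, stratified by
    class, and percentile CIs are reported for alpha1 and beta.
    """
    if not panel.labels.any() or panel.labels.all():
        raise ValueError("panel needs both tumor and control images")
    if np.any(~np.isfinite(panel.diameters[panel.labels])):
        raise ValueError("all tumor images need a diameter")
    grid = np.asarray(p_grid, float) if p_grid is not None else _control_pv_grid(panel, max_grid)
    alpha0, alpha1, beta = _fit_rocreg_once(panel, grid)

    se = ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        idx_pos = np.flatnonzero(panel.labels)
        idx_neg = np.flatnonzero(~panel.labels)
        a1s, betas = [], []
        for _ in range(n_boot):
            idx = np.concatenate(
                [
                    rng.choice(idx_pos, idx_pos.size, replace=True),
                    rng.choice(idx_neg, idx_neg.size, replace=True),
                ]
            )
            bp = ReaderPanel(
                scores=panel.scores[:, idx],
                labels=panel.labels[idx],
                diameters=panel.diameters[idx],
                reader_ids=panel.reader_ids,
            )
            try:
                bgrid = _control_pv_grid(bp, max_grid)
                _, a1_b, beta_b = _fit_rocreg_once(bp, bgrid)
            except (ValueError, np.linalg.LinAlgError):
                continue
            a1s.append(a1_b)
            betas.append(beta_b)
        if len(betas) >= max(10, n_boot // 2):
            a1s, betas = np.array(a1s), np.array(betas)
            se = {"alpha1": float(a1s.std(ddof=1)), "beta": float(betas.std(ddof=1))}
            ci = {
                "alpha1": tuple(np.quantile(a1s, [0.025, 0.975])),
                "beta": tuple(np.quantile(betas, [0.025, 0.975])),
            }
    return ROCRegressionFit(
        alpha0=np.asarray(alpha0, float),
        alpha1=float(alpha1),
        beta=float(beta),
        reader_ids=panel.reader_ids,
        p_grid=grid,
        bootstrap_se=se,
        ci=ci,
        n_boot=n_boot,
    )


def predicted_roc(fit: ROCRegressionFit, x: float, p_grid=None) -> ROCCurve:
    """Model-implied ROC at tumor diameter ``x`` with reader effects averaged.

    ROC(p) = Phi(mean_k alpha0_k + alpha1 * Phi^{-1}(p) + beta * x); AUC by
    trapezoidal integration over the grid.
    """
    if x < 0:
        raise ValueError("diameter must be nonnegative")
    p = np.asarray(p_grid, float) if p_grid is not None else np.linspace(1e-6, 1 - 1e-6, 2001)
    if p.size == 0:
        raise ValueError("empty p grid")
    eta = float(np.mean(fit.alpha0)) + fit.alpha1 * sps.norm.ppf(p) + fit.beta * x
    tpr = sps.norm.cdf(eta)
    p_ext = np.concatenate([[0.0], p, [1.0]])
    tpr_ext = np.concatenate([[0.0], tpr, [1.0]])
    auc = float(np.trapezoid(tpr_ext, p_ext))
    return ROCCurve(thresholds=np.full(p_ext.size, np.nan), fpr=p_ext, tpr=tpr_ext, auc=auc)


def size_metric_regression(diameters, values):
    """OLS of a per-image metric on tumor diameter with a t-test on the slope.

    Returns ``(slope, intercept, r_squared, p_value)``.
    """
    x = np.asarray(diameters, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0:
        raise ValueError("zero variance in diameters")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


def tumor_geometry(axes) -> TumorGeometry:
    """Ellipsoid from three orthogonal diameters: volume and geometric-mean diameter."""
    d = tuple(float(a) for a in axes)
    if len(d) != 3 or any(a <= 0 for a in d):
        raise ValueError("need three positive axis diameters")
    prod = d[0] * d[1] * d[2]
    return TumorGeometry(axes=d, volume=math.pi / 6.0 * prod, mean_diameter=prod ** (1.0 / 3.0))
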