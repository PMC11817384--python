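"""PLS-DA (NIPALS), VIP wavelength selection, ANN-DA and model evaluation.

PLS-DA regresses one-hot class indicators on the spectra with NIPALS
partial least squares and classifies by the largest predicted indicator
column.  Variable importance in projection (VIP) summarises each band's
contribution to the explained indicator variance,

    VIP_i = sqrt( p * sum_f w_if^2 SS_f / sum_f SS_f ),   SS_f = ||c_f||^2 t_f^T t_f,

with p bands, X-weights w, Y-loadings c and scores t; mean(VIP^2) over
bands is exactly 1, and bands with VIP^2 >= 1 are selected as critical
wavelengths.  VIP-PLS-DA refits the model on the selected bands only.
ANN-DA is a single-hidden-layer feed-forward classifier; PLS-ANN-DA
trains the same network on the PLS score matrix instead of raw spectra.

Validation follows chemometric convention: venetian-blinds
cross-validation (every k-th sample in dataset order forms a fold, 10
splits by default), a stratified 80/20 train/test split, and a report of
per-class sensitivity/specificity plus class-averaged accuracy, together
with R^2/RMSE computed between the one-hot indicators and the continuous
predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

__all__ = [
    "PLSDAModel",
    "VIPResult",
    "PerformanceReport",
    "CVPlan",
    "ANNModel",
    "one_hot",
    "fit_pls",
    "predict_classes",
    "pls_scores",
    "vip",
    "refit_on_selected",
    "fit_ann",
    "predict_ann",
    "select_components",
    "venetian_cv",
    "holdout_split",
    "score_report",
    "plsda_model_fn",
    "vip_plsda_model_fn",
    "ann_model_fn",
    "pls_ann_model_fn",
]


def one_hot(y, classes=None) -> tuple[np.ndarray, np.ndarray]:
    """Indicator-code labels; returns (Y, classes in column order)."""
    y = np.asarray(y)
    if classes is None:
        classes = np.unique(y)
    classes = np.asarray(classes)
    Y = (y[:, None] == classes[None, :]).astype(float)
    return Y, classes


@dataclass
class PLSDAModel:
    """Fitted NIPALS factors and preprocessing state.

    ``W`` are the X-weights (p x F), ``P`` the X-loadings, ``T`` the
    training scores (n x F), ``C`` the Y-loadings (q x F).  ``band_indices``
    maps a reduced-band model back onto the full wavelength axis.
    """

    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    C: np.ndarray
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    classes: np.ndarray
    n_components: int
    autoscale: bool = False
    band_indices: np.ndarray | None = None

    @property
    def rotation(self) -> np.ndarray:
        """R = W (P^T W)^-1 such that T = X_centered R."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    @property
    def coef(self) -> np.ndarray:
        """Regression coefficients on the (centered, scaled) X scale."""
        return self.rotation @ self.C.T

    @property
    def component_ss(self) -> np.ndarray:
        """Per-component explained indicator sum of squares ||c_f||^2 t_f^T t_f."""
        return np.sum(self.C**2, axis=0) * np.sum(self.T**2, axis=0)


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int,
    classes: np.ndarray | None = None,
    autoscale: bool = False,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> PLSDAModel:
    """NIPALS PLS2 on mean-centered X (optionally autoscaled) and centered Y.

    ``Y`` may be one-hot indicators or a 1-D label vector (then indicator
    coded internally).  If the requested component count exceeds the
    effective rank of X the extraction stops early with a warning and the
    model keeps the components found.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y, classes = one_hot(Y, classes)
    elif classes is None:
        classes = np.arange(Y.shape[1])
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y row counts differ")
    if n_components < 1:
        raise ValueError("need at least one component")
    n, p = X.shape

    x_mean = X.mean(axis=0)
    if autoscale:
        x_scale = X.std(axis=0, ddof=1)
        x_scale[x_scale < 1e-12] = 1.0  # guard constant columns
    else:
        x_scale = np.ones(p)
    y_mean = Y.mean(axis=0)
    Xd = (X - x_mean) / x_scale
    Yd = Y - y_mean

    total_x_ss = np.sum(Xd**2)
    W, P, T, C = [], [], [], []
    for _ in range(n_components):
        if np.sum(Xd**2) < 1e-12 * max(total_x_ss, 1.0) or np.sum(Yd**2) < 1e-14:
            warnings.warn(
                f"rank exhausted after {len(W)} components (requested {n_components})"
            )
            break
        u = Yd[:, int(np.argmax(Yd.var(axis=0)))]
        t_old = np.zeros(n)
        for _ in range(max_iter):
            w = Xd.T @ u
            wn = np.linalg.norm(w)
            if wn < 1e-14:
                break
            w = w / wn
            t = Xd @ w
            c = Yd.T @ t / (t @ t)
            u = Yd @ c / (c @ c)
            if np.linalg.norm(t - t_old) < tol * max(np.linalg.norm(t), 1.0):
                break
            t_old = t
        tt = t @ t
        if tt < 1e-14:
            warnings.warn(f"degenerate component after {len(W)}; stopping")
            break
        p_load = Xd.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        Yd = Yd - np.outer(t, c)
        W.append(w)
        P.append(p_load)
        T.append(t)
        C.append(c)
    if not W:
        raise ValueError("no PLS component could be extracted (X or Y constant)")
    return PLSDAModel(
        W=np.column_stack(W),
        P=np.column_stack(P),
        T=np.column_stack(T),
        C=np.column_stack(C),
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        classes=classes,
        n_components=len(W),
        autoscale=autoscale,
    )


def _reduce_bands(model: PLSDAModel, X: np.ndarray) -> np.ndarray:
    if model.band_indices is not None and X.shape[1] != model.x_mean.size:
        return X[:, model.band_indices]
    return X


def pls_scores(model: PLSDAModel, X_new: np.ndarray) -> np.ndarray:
    """Project new spectra onto the latent components (n x F)."""
    X_new = _reduce_bands(model, np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"band count {X_new.shape[1]} does not match model ({model.x_mean.size})"
        )
    return ((X_new - model.x_mean) / model.x_scale) @ model.rotation


def predict_classes(model: PLSDAModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Continuous indicator predictions and argmax class labels.

    Ties go to the lowest class index (argmax keeps the first maximum).
    Returns ``(labels, Y_continuous)``.
    """
    X_new = _reduce_bands(model, np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"band count {X_new.shape[1]} does not match model ({model.x_mean.size})"
        )
    Yhat = ((X_new - model.x_mean) / model.x_scale) @ model.coef + model.y_mean
    labels = model.classes[np.argmax(Yhat, axis=1)]
    return labels, Yhat


@dataclass
class VIPResult:
    """Per-band VIP scores, the VIP^2 >= 1 selection, and its nm ranges."""

    vip: np.ndarray
    selected: np.ndarray
    ranges_nm: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def vip(model: PLSDAModel, wavelengths: np.ndarray | None = None) -> VIPResult:
    """Wold VIP scores from the fitted factors; selection at VIP^2 >= 1."""
    ss = model.component_ss
    total = ss.sum()
    if total <= 0:
        raise ValueError("model explains no indicator variance; VIP undefined")
    p = model.W.shape[0]
    vip_sq = p * (model.W**2 @ ss) / total
    scores = np.sqrt(vip_sq)
    selected = vip_sq >= 1.0
    ranges: list[tuple[float, float]] = []
    if wavelengths is not None:
        wavelengths = np.asarray(wavelengths, dtype=float)
        ranges = selected_ranges(selected, wavelengths)
    return VIPResult(vip=scores, selected=selected, ranges_nm=ranges)


def selected_ranges(selected: np.ndarray, wavelengths: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous runs of selected bands as (start_nm, end_nm) pairs."""
    ranges = []
    start = None
    for i, s in enumerate(selected):
        if s and start is None:
            start = i
        elif not s and start is not None:
            ranges.append((float(wavelengths[start]), float(wavelengths[i - 1])))
            start = None
    if start is not None:
        ranges.append((float(wavelengths[start]), float(wavelengths[-1])))
    return ranges


def refit_on_selected(
    X: np.ndarray,
    Y: np.ndarray,
    vip_result: VIPResult,
    n_components: int,
    classes: np.ndarray | None = None,
    autoscale: bool = False,
) -> PLSDAModel:
    """VIP-PLS-DA: refit on the critical-wavelength submatrix only."""
    idx = np.flatnonzero(vip_result.selected)
    if idx.size < 2:
        raise ValueError(f"only {idx.size} band(s) selected; need at least 2")
    model = fit_pls(
        np.asarray(X, dtype=float)[:, idx], Y,
        min(n_components, idx.size), classes=classes, autoscale=autoscale,
    )
    model.band_indices = idx
    return model


# ---------------------------------------------------------------------------
# ANN-DA


@dataclass
class ANNModel:
    """Feed-forward softmax classifier, optionally over PLS scores."""

    net: MLPClassifier
    pls: PLSDAModel | None = None  # set for PLS-ANN-DA
    converged: bool = True
    final_loss: float = float("nan")


def fit_ann(
    X: np.ndarray,
    y: np.ndarray,
    hidden: tuple[int, ...] = (10,),
    seed: int = 0,
    max_iter: int = 2000,
    pls_model: PLSDAModel | None = None,
) -> ANNModel:
    """Train the discriminant network (logistic hidden units, softmax output).

    With ``pls_model`` given, the network is trained on the PLS score
    matrix (PLS-ANN-DA).  Non-convergence is reported on the returned
    model, not raised.
    """
    X = np.asarray(X, dtype=float)
    if pls_model is not None:
        X = pls_scores(pls_model, X)
    net = MLPClassifier(
        hidden_layer_sizes=hidden,
        activation="logistic",
        solver="lbfgs",
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence reported via the model
        net.fit(X, np.asarray(y))
    converged = net.n_iter_ < max_iter
    return ANNModel(net=net, pls=pls_model, converged=converged, final_loss=float(net.loss_))


def predict_ann(model: ANNModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels and class probabilities from the trained network."""
    X_new = np.asarray(X_new, dtype=float)
    if model.pls is not None:
        X_new = pls_scores(model.pls, X_new)
    return model.net.predict(X_new), model.net.predict_proba(X_new)


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class CVPlan:
    """Venetian-blinds plan: fold f holds samples with index ≡ f (mod splits)."""

    n_splits: int = 10
    test_size: float = 0.2
    stratify: bool = True
    seed: int = 0

    def folds(self, n: int) -> list[np.ndarray]:
        if n < self.n_splits:
            raise ValueError(f"need at least {self.n_splits} samples, got {n}")
        idx = np.arange(n)
        return [idx[idx % self.n_splits == f] for f in range(self.n_splits)]


def holdout_split(
    X: np.ndarray, y: np.ndarray, plan: CVPlan = CVPlan()
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test split (default 80/20) with the plan's seed."""
    return train_test_split(
        np.asarray(X), np.asarray(y),
        test_size=plan.test_size,
        random_state=plan.seed,
        stratify=np.asarray(y) if plan.stratify else None,
    )


@dataclass
class PerformanceReport:
    """Confusion counts and the derived classification metrics.

    ``accuracy`` is the arithmetic mean over classes of the one-vs-rest
    accuracy (TP+TN)/n and ``error_rate`` is its complement.  R^2/RMSE
    compare one-hot indicators with the continuous predictions, per class
    and pooled over all indicator entries.
    """

    classes: np.ndarray
    confusion: np.ndarray  # true x predicted
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    per_class_accuracy: np.ndarray
    accuracy: float
    error_rate: float
    r2_per_class: np.ndarray | None = None
    rmse_per_class: np.ndarray | None = None
    r2_pooled: float | None = None
    rmse_pooled: float | None = None
    missing_classes: tuple = ()

    @property
    def fraction_correct(self) -> float:
        """Plain fraction of correctly labeled samples (diagonal mass)."""
        return float(np.trace(self.confusion) / self.confusion.sum())


def score_report(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_continuous: np.ndarray | None = None,
    classes: np.ndarray | None = None,
) -> PerformanceReport:
    """Per-class one-vs-rest confusion metrics plus indicator R^2/RMSE.

    A class present in ``classes`` but absent from ``y_true`` has
    undefined sensitivity (NaN) and is listed in ``missing_classes``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred lengths differ")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    n = y_true.size
    k = classes.size
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        confusion[np.flatnonzero(classes == t)[0], np.flatnonzero(classes == p)[0]] += 1

    tp = np.diag(confusion).astype(float)
    fn = confusion.sum(axis=1) - tp
    fp = confusion.sum(axis=0) - tp
    tn = n - tp - fn - fp

    with np.errstate(invalid="ignore", divide="ignore"):
        sensitivity = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        specificity = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
    per_class_acc = (tp + tn) / n
    accuracy = float(np.mean(per_class_acc))
    missing = tuple(classes[confusion.sum(axis=1) == 0])

    r2c = rmsec = r2p = rmsep = None
    if y_continuous is not None:
        y_continuous = np.asarray(y_continuous, dtype=float)
        Y, _ = one_hot(y_true, classes)
        if y_continuous.shape != Y.shape:
            raise ValueError("continuous predictions must be n x n_classes")
        resid = Y - y_continuous
        rmsec = np.sqrt(np.mean(resid**2, axis=0))
        ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2c = np.where(ss_tot > 0, 1 - np.sum(resid**2, axis=0) / ss_tot, np.nan)
        rmsep = float(np.sqrt(np.mean(resid**2)))
        tot = np.sum((Y - Y.mean(axis=0)) ** 2)
        r2p = float(1 - np.sum(resid**2) / tot) if tot > 0 else float("nan")

    return PerformanceReport(
        classes=classes,
        confusion=confusion,
        tp=tp.astype(int),
        tn=tn.astype(int),
        fp=fp.astype(int),
        fn=fn.astype(int),
        sensitivity=sensitivity,
        specificity=specificity,
        per_class_accuracy=per_class_acc,
        accuracy=accuracy,
        error_rate=1.0 - accuracy,
        r2_per_class=r2c,
        rmse_per_class=rmsec,
        r2_pooled=r2p,
        rmse_pooled=rmsep,
        missing_classes=missing,
    )


def venetian_cv(
    X: np.ndarray,
    y: np.ndarray,
    model_fn,
    plan: CVPlan = CVPlan(),
) -> PerformanceReport:
    """Venetian-blinds cross-validation pooled over folds.

    ``model_fn(X_train, y_train)`` must return a predictor
    ``predict(X_test) -> (labels, continuous)``.  The pooled report is
    built from all held-out predictions in original sample order.  A fold
    whose training remainder misses a class triggers a warning but is
    still scored.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = y.size
    classes = np.unique(y)
    pred = np.empty(n, dtype=y.dtype)
    cont = np.zeros((n, classes.size))
    for fold_idx in plan.folds(n):
        train_mask = np.ones(n, dtype=bool)
        train_mask[fold_idx] = False
        y_train = y[train_mask]
        if np.unique(y_train).size < classes.size:
            warnings.warn("a training remainder misses a class; fold scored anyway")
        predictor = model_fn(X[train_mask], y_train)
        labels, yc = predictor(X[fold_idx])
        pred[fold_idx] = labels
        yc = np.asarray(yc, dtype=float)
        if yc.shape[1] == classes.size:
            cont[fold_idx] = yc
    return score_report(y, pred, cont, classes=classes)


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 20,
    plan: CVPlan = CVPlan(),
    autoscale: bool = False,
) -> int:
    """Pick the PLS component count minimising venetian-blinds CV error.

    Ties break toward the smaller model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    limit = min(max_components, X.shape[0] - 1, X.shape[1])
    best_f, best_err = 1, np.inf
    for F in range(1, limit + 1):
        rep = venetian_cv(X, y, plsda_model_fn(F, autoscale=autoscale), plan)
        err = 1.0 - rep.fraction_correct
        if err < best_err - 1e-12:
            best_f, best_err = F, err
    return best_f


# ---------------------------------------------------------------------------
# model_fn factories for venetian_cv / the pipeline


def _constant_predictor(label):
    """Degenerate single-class training set: predict that class everywhere."""

    def predict(X_test):
        n = np.asarray(X_test).shape[0]
        return np.full(n, label), np.ones((n, 1))

    return predict


def plsda_model_fn(n_components: int, autoscale: bool = False):
    def fit(X_train, y_train):
        classes = np.unique(y_train)
        if classes.size < 2:
            return _constant_predictor(classes[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_pls(X_train, y_train, n_components, autoscale=autoscale)
        return lambda X_test: predict_classes(model, X_test)

    return fit


def vip_plsda_model_fn(n_components: int, autoscale: bool = False):
    def fit(X_train, y_train):
        classes = np.unique(y_train)
        if classes.size < 2:
            return _constant_predictor(classes[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = fit_pls(X_train, y_train, n_components, autoscale=autoscale)
            sel = vip(base)
            model = refit_on_selected(X_train, y_train, sel, n_components, autoscale=autoscale)
        return lambda X_test: predict_classes(model, X_test)

    return fit


def ann_model_fn(hidden: tuple[int, ...] = (10,), seed: int = 0):
    def fit(X_train, y_train):
        classes = np.unique(y_train)
        if classes.size < 2:
            return _constant_predictor(classes[0])
        model = fit_ann(X_train, y_train, hidden=hidden, seed=seed)
        return lambda X_test: predict_ann(model, X_test)

    return fit


def pls_ann_model_fn(n_components: int, hidden: tuple[int, ...] = (10,), seed: int = 0):
    def fit(X_train, y_train):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = fit_pls(X_train, y_train, n_components)
        model = fit_ann(X_train, y_train, hidden=hidden, seed=seed, pls_model=base)
        return lambda X_test: predict_ann(model, X_test)

    return fit
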