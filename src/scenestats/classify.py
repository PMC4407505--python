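"""Quadratic discriminant classification of preferred vs. non-preferred images.

Images are labeled high/low by a median split on mean preference. A
quadratic discriminant (QD) model fits one multivariate Gaussian per class
(separate covariance matrices, empirical priors); validation uses a
pairwise leave-one-out scheme: every (high, low) pair is held out, the
classifier is trained on the remaining n - 2 images, and both held-out
images are classified. Accuracy is the mean fraction correct over all
pairs. Backward elimination greedily drops features that do not help the
cross-validated accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HIGH, LOW = "high", "low"


class DegenerateSplitError(ValueError):
    pass


class SingularCovarianceError(ValueError):
    pass


def median_split(values: np.ndarray) -> np.ndarray:
    """Label values above the median ``high``, below ``low``.

    Values exactly at the median are assigned alternately (first tie to the
    currently smaller class, ``low`` first on a dead heat) so the two
    classes stay as balanced as possible; an odd count gives sizes
    {(n-1)/2, (n+1)/2}.
    """
    values = np.asarray(values, float)
    if values.size < 4:
        raise ValueError("need at least 4 values for a median split")
    if np.ptp(values) == 0:
        raise DegenerateSplitError("all values identical: median split degenerate")
    med = np.median(values)
    labels = np.empty(values.size, dtype=object)
    labels[values > med] = HIGH
    labels[values < med] = LOW
    n_high = int((values > med).sum())
    n_low = int((values < med).sum())
    for idx in np.flatnonzero(values == med):
        if n_high < n_low:
            labels[idx], n_high = HIGH, n_high + 1
        else:
            labels[idx], n_low = LOW, n_low + 1
    if n_high == 0 or n_low == 0:
        raise DegenerateSplitError("all values identical: median split degenerate")
    return labels


@dataclass
class QDModel:
    """Per-class Gaussian parameters of a quadratic discriminant."""

    classes: tuple[str, ...]
    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    log_priors: dict[str, float]
    feature_names: tuple[str, ...] | None = None


def _gaussian_params(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    return mean, np.atleast_2d(cov)


def qd_fit(
    X: np.ndarray, labels: np.ndarray, feature_names: tuple[str, ...] | None = None
) -> QDModel:
    """Fit class-conditional Gaussians with empirical priors."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    classes = tuple(sorted(np.unique(labels)))
    d = X.shape[1]
    means, covs, log_priors = {}, {}, {}
    for c in classes:
        Xc = X[labels == c]
        if len(Xc) < d + 2:
            raise SingularCovarianceError(
                f"class {c!r} has {len(Xc)} members; need >= d + 2 = {d + 2} "
                "(consider reducing the feature subset)"
            )
        mean, cov = _gaussian_params(Xc)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise SingularCovarianceError(
                f"singular covariance for class {c!r}; "
                "consider reducing the feature subset"
            ) from exc
        means[c], covs[c] = mean, cov
        log_priors[c] = float(np.log(len(Xc) / len(X)))
    return QDModel(classes, means, covs, log_priors, feature_names)


def _log_gaussian(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of N(mean, cov) at rows of x."""
    x = np.atleast_2d(x)
    d = x.shape[1]
    chol = np.linalg.cholesky(cov)
    diff = x - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (maha + logdet + d * np.log(2.0 * np.pi))


def qd_predict(model: QDModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classify rows of ``x``; returns (labels, posterior matrix).

    Posterior columns follow ``model.classes``; the predicted label is the
    argmax posterior (first class wins exact ties).
    """
    x = np.atleast_2d(np.asarray(x, float))
    scores = np.column_stack(
        [
            model.log_priors[c] + _log_gaussian(x, model.means[c], model.covariances[c])
            for c in model.classes
        ]
    )
    shifted = scores - scores.max(axis=1, keepdims=True)
    post = np.exp(shifted)
    post /= post.sum(axis=1, keepdims=True)
    labels = np.asarray(model.classes, dtype=object)[np.argmax(scores, axis=1)]
    return labels, post


@dataclass
class LOOResult:
    """Outcome of the pairwise leave-one-out cross-validation."""

    accuracy: float
    n_pairs: int
    pair_scores: np.ndarray  # n_high x n_low, entries in {0, 0.5, 1}
    per_image_rate: dict[str, float] = field(default_factory=dict)
    feature_names: tuple[str, ...] | None = None


def _loo_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out class means and covariances for each row of X."""
    n, d = X.shape
    total = X.sum(axis=0)
    scatter = X.T @ X
    means = np.empty((n, d))
    covs = np.empty((n, d, d))
    for i in range(n):
        mu = (total - X[i]) / (n - 1)
        sc = scatter - np.outer(X[i], X[i])
        covs[i] = (sc - (n - 1) * np.outer(mu, mu)) / (n - 2)
        means[i] = mu
    return means, covs


def loo_pairwise_accuracy(
    X: np.ndarray, labels: np.ndarray, feature_names: tuple[str, ...] | None = None
) -> LOOResult:
    """Pairwise leave-one-out accuracy of the QD classifier.

    For every (high, low) pair of images, a QD model is trained on the
    other n - 2 images and both held-out images are classified; the pair
    contributes 0, 0.5 or 1 correct. Implemented with downdated sufficient
    statistics — the held-out high image only affects the high-class
    Gaussian and vice versa — which is numerically identical to refitting
    from scratch for each pair.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    hi_idx = np.flatnonzero(labels == HIGH)
    lo_idx = np.flatnonzero(labels == LOW)
    nh, nl = len(hi_idx), len(lo_idx)
    d = X.shape[1]
    if nh < d + 3 or nl < d + 3:
        raise SingularCovarianceError(
            f"classes of size ({nh}, {nl}) too small for d = {d} after holdout"
        )
    Xh, Xl = X[hi_idx], X[lo_idx]
    mh, ch = _loo_stats(Xh)  # per held-out high image
    ml, cl = _loo_stats(Xl)
    n_train = nh + nl - 2
    lp_high = np.log((nh - 1) / n_train)
    lp_low = np.log((nl - 1) / n_train)

    # log-likelihood of each held-out point under each downdated model
    ll_h_own = np.array(
        [_log_gaussian(Xh[i], mh[i], ch[i])[0] for i in range(nh)]
    )  # x_i under high\i
    ll_l_own = np.array([_log_gaussian(Xl[j], ml[j], cl[j])[0] for j in range(nl)])
    ll_h_under_low = np.column_stack(
        [_log_gaussian(Xh, ml[j], cl[j]) for j in range(nl)]
    )  # (i, j): x_i under low\j
    ll_l_under_high = np.column_stack(
        [_log_gaussian(Xl, mh[i], ch[i]) for i in range(nh)]
    )  # (j, i): x_j under high\i

    # argmax with the same tie-break as qd_predict (classes sorted: high first)
    high_correct = (ll_h_own[:, None] + lp_high) >= (ll_h_under_low + lp_low)
    low_correct = (ll_l_under_high + lp_high) < (ll_l_own[:, None] + lp_low)
    pair_scores = 0.5 * high_correct + 0.5 * low_correct.T
    accuracy = float(pair_scores.mean())

    per_image = {}
    for pos, i in enumerate(hi_idx):
        per_image[int(i)] = float(high_correct[pos].mean())
    for pos, j in enumerate(lo_idx):
        per_image[int(j)] = float(low_correct[pos].mean())
    return LOOResult(
        accuracy=accuracy,
        n_pairs=nh * nl,
        pair_scores=pair_scores,
        per_image_rate=per_image,
        feature_names=feature_names,
    )


def backward_elimination(
    X: np.ndarray,
    labels: np.ndarray,
    feature_names: tuple[str, ...],
) -> tuple[tuple[str, ...], list[tuple[tuple[str, ...], float]]]:
    """Greedy backward feature elimination on pairwise LOO accuracy.

    Repeatedly drops the single feature whose removal yields the highest
    accuracy (ties broken by dropping the later-listed feature); stops when
    no removal strictly improves on the current subset. Returns the best
    subset and the (subset, accuracy) trace.
    """
    X = np.asarray(X, float)
    current = list(feature_names)
    idx = {f: i for i, f in enumerate(feature_names)}

    def acc_of(subset: list[str]) -> float:
        cols = [idx[f] for f in subset]
        try:
            return loo_pairwise_accuracy(X[:, cols], labels).accuracy
        except (SingularCovarianceError, np.linalg.LinAlgError):
            return -1.0

    trace = [(tuple(current), acc_of(current))]
    while len(current) > 1:
        best_acc, best_drop = -np.inf, None
        for pos in range(len(current)):  # later-listed wins ties via >=
            candidate = current[:pos] + current[pos + 1 :]
            a = acc_of(candidate)
            if a >= best_acc:
                best_acc, best_drop = a, pos
        if best_acc > trace[-1][1]:
            current.pop(best_drop)
            trace.append((tuple(current), best_acc))
        else:
            break
    return tuple(current), trace
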