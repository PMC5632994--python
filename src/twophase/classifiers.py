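"""Classifiers fitted on bias-corrected samples.

Four classifiers are supported: logistic regression (linear terms),
logistic regression with all two-way interaction terms, a naive Bayes
classifier with univariate Gaussian kernel-density class-conditionals, and
a random forest.  The stratum feature always enters as a predictor.

For the single-sample corrections (``none``, ``ip_oversampling``,
``smote``) the classifier is fitted once on the corrected sample; the
resampling-based corrections (``ip_bagging``, ``costing``,
``stochastic_ip_oversampling``, ``parametric_ip_bagging``) fit ``m``
models on ``m`` corrected samples and average their risk scores.  The
random forest instead folds the correction into its own resampling: each
tree is grown on one freshly drawn corrected sample, so bagging is not
nested inside bagging.

Every scorer exposes ``predict_score`` returning a continuous risk score
in [0, 1] (the probability of the positive class, or an average of such).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KernelDensity
from sklearn.preprocessing import PolynomialFeatures
from sklearn.tree import DecisionTreeClassifier

from . import correctors as corr_mod
from .correctors import CorrectionSpec, make_corrector
from .strata import StratifiedSample, StratumTable, assign_strata, build_stratum_table

__all__ = [
    "CLASSIFIERS",
    "ClassifierSpec",
    "TwoPhaseClassifier",
    "fit_logistic",
    "fit_logistic_interactions",
    "fit_naive_bayes_kde",
    "fit_random_forest_corrected",
    "fit_corrected",
]

CLASSIFIERS = ("logistic", "logistic_interactions", "naive_bayes_kde", "random_forest")

_PROB_FLOOR = 1e-12  # floor for categorical class-conditional frequencies


class ClassifierSpec:
    """Choice of classifier and its hyperparameters."""

    def __init__(self, kind: str = "logistic", n_trees: int = 500,
                 mtry: int | None = None, max_iter: int = 1000):
        if kind not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {kind!r}; choose one of {CLASSIFIERS}")
        self.kind = kind
        self.n_trees = n_trees
        self.mtry = mtry
        self.max_iter = max_iter


def _outcome_levels(sample: StratifiedSample) -> list:
    return sorted(pd.unique(sample.data[sample.outcome]))


def _y01(sample: StratifiedSample, levels: list) -> np.ndarray:
    return (sample.data[sample.outcome].to_numpy() == levels[-1]).astype(int)


class _Scorer:
    """Base scorer: remembers the training column layout for prediction."""

    def __init__(self, stratum_feature: str, features: list[str], xe_levels: list):
        self.stratum_feature = stratum_feature
        self.features = features
        self.xe_levels = xe_levels

    def _design(self, X) -> np.ndarray:
        """Encode input rows to [xe_code, main features] column order."""
        if isinstance(X, StratifiedSample):
            X = X.data
        if isinstance(X, pd.DataFrame):
            codes = X[self.stratum_feature].map(
                {lev: i for i, lev in enumerate(self.xe_levels)})
            if codes.isna().any():
                # unseen level: encode past the known range
                codes = codes.fillna(len(self.xe_levels)).astype(float)
            mat = np.column_stack(
                [codes.to_numpy(dtype=float)]
                + [X[c].to_numpy(dtype=float) for c in self.features])
            return mat
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 1 + len(self.features):
            raise ValueError(
                f"expected {1 + len(self.features)} columns "
                f"(stratum feature first), got shape {X.shape}")
        return X

    def predict_score(self, X) -> np.ndarray:
        raise NotImplementedError


class LogisticScorer(_Scorer):
    """Maximum-likelihood logistic regression, optionally with all two-way
    interactions among {stratum feature, main features}.

    ``separation_flagged_`` is set when the optimizer hit its iteration cap
    (the typical symptom of perfect separation); scores from the terminal
    iterate are still returned.
    """

    def __init__(self, stratum_feature, features, xe_levels,
                 interactions: bool = False, max_iter: int = 1000):
        super().__init__(stratum_feature, features, xe_levels)
        self.interactions = interactions
        self.max_iter = max_iter
        self.model_: LogisticRegression | None = None
        self.poly_: PolynomialFeatures | None = None
        self.separation_flagged_ = False
        self.constant_score_: float | None = None

    def fit(self, sample: StratifiedSample, y: np.ndarray,
            sample_weight=None) -> "LogisticScorer":
        D = self._design(sample.data)
        if self.interactions:
            self.poly_ = PolynomialFeatures(degree=2, interaction_only=True,
                                            include_bias=False)
            D = self.poly_.fit_transform(D)
        if D.shape[1] == 0 or len(np.unique(y)) < 2:
            # intercept-only / single-class degenerate fits
            self.constant_score_ = float(np.average(
                y, weights=sample_weight)) if len(y) else 0.5
            return self
        import warnings

        # C=inf -> unpenalized maximum likelihood
        self.model_ = LogisticRegression(C=np.inf, solver="lbfgs",
                                         max_iter=self.max_iter, tol=1e-8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model_.fit(D, y, sample_weight=sample_weight)
        # iteration cap or exploding coefficients both indicate separation;
        # the terminal iterate still yields usable (saturated) scores
        self.separation_flagged_ = bool(
            np.any(self.model_.n_iter_ >= self.max_iter)
            or np.max(np.abs(self.model_.coef_)) > 15.0)
        return self

    def predict_score(self, X) -> np.ndarray:
        D = self._design(X)
        if self.constant_score_ is not None:
            return np.full(D.shape[0], self.constant_score_)
        if self.poly_ is not None:
            D = self.poly_.transform(D)
        return self.model_.predict_proba(D)[:, 1]


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25)
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    h = 0.9 * spread * n ** (-1 / 5)
    floor = 1e-6 * (float(np.ptp(x)) + 1.0)
    return max(h, floor)


class KDENaiveBayesScorer(_Scorer):
    """Naive Bayes with per-feature Gaussian KDE class-conditionals.

    Main features contribute univariate kernel-density estimates (Silverman
    bandwidth, floored for degenerate features); the categorical stratum
    feature contributes class-conditional level frequencies.  Scores are
    class-1 posteriors normalized over the two classes.
    """

    def __init__(self, stratum_feature, features, xe_levels):
        super().__init__(stratum_feature, features, xe_levels)
        self.log_priors_: dict[int, float] = {}
        self.xe_logfreq_: dict[int, dict[float, float]] = {}
        self.kdes_: dict[int, list[KernelDensity]] = {}

    def fit(self, sample: StratifiedSample, y: np.ndarray) -> "KDENaiveBayesScorer":
        D = self._design(sample.data)
        xe, Xm = D[:, 0], D[:, 1:]
        for cls in (0, 1):
            rows = y == cls
            if rows.sum() < 2:
                raise ValueError("naive Bayes requires at least 2 rows per class")
            self.log_priors_[cls] = np.log(rows.mean())
            codes, counts = np.unique(xe[rows], return_counts=True)
            freq = dict(zip(codes, counts / counts.sum()))
            self.xe_logfreq_[cls] = {c: np.log(max(f, _PROB_FLOOR))
                                     for c, f in freq.items()}
            self.kdes_[cls] = [
                KernelDensity(kernel="gaussian",
                              bandwidth=_silverman_bandwidth(Xm[rows, k])
                              ).fit(Xm[rows, k][:, None])
                for k in range(Xm.shape[1])
            ]
        return self

    def predict_score(self, X) -> np.ndarray:
        D = self._design(X)
        xe, Xm = D[:, 0], D[:, 1:]
        logp = np.zeros((D.shape[0], 2))
        for cls in (0, 1):
            lp = np.full(D.shape[0], self.log_priors_[cls])
            lookup = self.xe_logfreq_[cls]
            lp += np.array([lookup.get(c, np.log(_PROB_FLOOR)) for c in xe])
            for k, kde in enumerate(self.kdes_[cls]):
                lp += kde.score_samples(Xm[:, k][:, None])
            logp[:, cls] = lp
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p[:, 1] / p.sum(axis=1)


class EnsembleScorer(_Scorer):
    """Arithmetic mean of member scorers' risk scores."""

    def __init__(self, members: list[_Scorer]):
        first = members[0]
        super().__init__(first.stratum_feature, first.features, first.xe_levels)
        self.members = members

    def predict_score(self, X) -> np.ndarray:
        return np.mean([mem.predict_score(X) for mem in self.members], axis=0)


class ForestScorer(_Scorer):
    """Average of fully grown CART trees' class-1 leaf frequencies."""

    def __init__(self, stratum_feature, features, xe_levels,
                 trees: list[DecisionTreeClassifier]):
        super().__init__(stratum_feature, features, xe_levels)
        self.trees = trees

    def predict_score(self, X) -> np.ndarray:
        D = self._design(X)
        score = np.zeros(D.shape[0])
        for tree in self.trees:
            proba = tree.predict_proba(D)
            col = int(np.flatnonzero(tree.classes_ == 1)[0])
            score += proba[:, col]
        return score / len(self.trees)


# ---------------------------------------------------------------------------
# fitting entry points


def fit_logistic(sample: StratifiedSample, max_iter: int = 1000) -> LogisticScorer:
    """Fit logistic regression on stratum feature + main features."""
    levels = _outcome_levels(sample)
    xe_levels = sorted(pd.unique(sample.data[sample.stratum_feature]))
    scorer = LogisticScorer(sample.stratum_feature, sample.features, xe_levels,
                            interactions=False, max_iter=max_iter)
    return scorer.fit(sample, _y01(sample, levels))


def fit_logistic_interactions(sample: StratifiedSample,
                              max_iter: int = 1000) -> LogisticScorer:
    """Logistic regression with every pairwise interaction term added."""
    levels = _outcome_levels(sample)
    xe_levels = sorted(pd.unique(sample.data[sample.stratum_feature]))
    scorer = LogisticScorer(sample.stratum_feature, sample.features, xe_levels,
                            interactions=True, max_iter=max_iter)
    return scorer.fit(sample, _y01(sample, levels))


def fit_naive_bayes_kde(sample: StratifiedSample) -> KDENaiveBayesScorer:
    """Kernel-density naive Bayes on stratum feature + main features."""
    levels = _outcome_levels(sample)
    xe_levels = sorted(pd.unique(sample.data[sample.stratum_feature]))
    scorer = KDENaiveBayesScorer(sample.stratum_feature, sample.features, xe_levels)
    return scorer.fit(sample, _y01(sample, levels))


def _fit_single(kind: str, sample: StratifiedSample, levels, xe_levels,
                max_iter: int) -> _Scorer:
    y = _y01(sample, levels)
    if kind == "logistic":
        return LogisticScorer(sample.stratum_feature, sample.features, xe_levels,
                              max_iter=max_iter).fit(sample, y)
    if kind == "logistic_interactions":
        return LogisticScorer(sample.stratum_feature, sample.features, xe_levels,
                              interactions=True, max_iter=max_iter).fit(sample, y)
    if kind == "naive_bayes_kde":
        return KDENaiveBayesScorer(sample.stratum_feature, sample.features,
                                   xe_levels).fit(sample, y)
    raise ValueError(f"unknown classifier kind {kind!r}")


def _tree_sample(method: str, sample: StratifiedSample, table: StratumTable | None,
                 smote_set: StratifiedSample | None, rng: np.random.Generator,
                 seedseq: np.random.SeedSequence) -> StratifiedSample:
    """Draw the corrected learning set for a single tree."""
    n = sample.n
    if method == "none":
        return sample.take(rng.integers(0, n, size=n))
    if method == "smote":
        ns = smote_set.n
        return smote_set.take(rng.integers(0, ns, size=ns))
    w_row = table.weight_of(sample.stratum_id).astype(float)
    if method in ("ip_oversampling", "ip_bagging"):
        # IP oversampling inside a forest is IP bagging with samples of
        # size n' instead of n
        size = table.n_prime if method == "ip_oversampling" else n
        probs = w_row / w_row.sum()
        return sample.take(rng.choice(n, size=size, replace=True, p=probs))
    if method == "costing":
        return corr_mod.CostingSampler(m=1).resample(
            sample, table, random_state=seedseq)[0]
    if method == "stochastic_ip_oversampling":
        return corr_mod.StochasticIPOversampler(m=1).resample(
            sample, table, random_state=seedseq)[0]
    if method == "parametric_ip_bagging":
        return corr_mod.ParametricIPBagger(m=1).resample(
            sample, table, random_state=seedseq)[0]
    raise ValueError(f"unknown correction method {method!r}")


def fit_random_forest_corrected(
    sample: StratifiedSample,
    table: StratumTable | None = None,
    correction: str | CorrectionSpec = "none",
    n_trees: int = 500,
    mtry: int | None = None,
    seed=None,
    max_redraws: int = 100,
    bootstrap: bool = True,
) -> ForestScorer:
    """Random forest with the bias correction folded into per-tree sampling.

    Each tree is grown fully (no depth limit, minimum leaf size 1) on one
    corrected sample drawn by the chosen method, with ``mtry`` features
    considered per split (default floor(sqrt(#predictors))).  Trees whose
    corrected sample contains a single outcome class are refit on a
    redrawn sample, up to ``max_redraws`` times.
    """
    method = correction.method if isinstance(correction, CorrectionSpec) else correction
    spec_k = correction.k if isinstance(correction, CorrectionSpec) else 5
    if method not in corr_mod.METHODS:
        raise ValueError(f"unknown correction method {method!r}")
    if method != "none" and table is None:
        raise ValueError("a stratum table is required for weighted corrections")
    levels = _outcome_levels(sample)
    xe_levels = sorted(pd.unique(sample.data[sample.stratum_feature]))
    if mtry is None:
        mtry = max(1, int(np.sqrt(1 + sample.n_features)))
    smote_set = None
    if method == "smote":
        smote_set = corr_mod.StratifiedSMOTE(k=spec_k).resample(
            sample, table, random_state=seed)[0]
    trees: list[DecisionTreeClassifier] = []
    for child in np.random.SeedSequence(seed).spawn(n_trees):
        rng = np.random.default_rng(child)
        sub_seqs = iter(child.spawn(max_redraws + 1))
        for _ in range(max_redraws + 1):
            if method == "none" and not bootstrap:
                drawn = sample  # diagnostic mode: every tree sees the raw sample
            else:
                drawn = _tree_sample(method, sample, table, smote_set, rng,
                                     next(sub_seqs))
            y = _y01(drawn, levels)
            if len(np.unique(y)) == 2:
                break
        else:
            raise RuntimeError(
                f"correction {method!r} kept producing single-class samples "
                f"after {max_redraws} redraws")
        tree = DecisionTreeClassifier(max_features=mtry,
                                      random_state=int(rng.integers(2 ** 31)))
        encoder = _Scorer(sample.stratum_feature, sample.features, xe_levels)
        tree.fit(encoder._design(drawn.data), y)
        trees.append(tree)
    return ForestScorer(sample.stratum_feature, sample.features, xe_levels, trees)


def fit_corrected(
    sample: StratifiedSample,
    table: StratumTable | None = None,
    correction: str | CorrectionSpec = "none",
    classifier: str | ClassifierSpec = "logistic",
    m: int = 100,
    k: int = 5,
    family: str = "normal",
    seed=None,
    n_trees: int = 500,
    mtry: int | None = None,
    max_iter: int = 1000,
) -> _Scorer:
    """Fit a classifier under a correction strategy (dispatch layer).

    Random forests delegate to :func:`fit_random_forest_corrected`; other
    classifiers are fitted once for the single-sample corrections and as a
    score-averaging ensemble of ``m`` fits for the resampling-based ones.
    """
    if isinstance(correction, CorrectionSpec):
        spec = correction
    else:
        spec = CorrectionSpec(method=correction, m=m, k=k, family=family, seed=seed)
    kind = classifier.kind if isinstance(classifier, ClassifierSpec) else classifier
    if isinstance(classifier, ClassifierSpec):
        n_trees, mtry, max_iter = classifier.n_trees, classifier.mtry, classifier.max_iter
    if kind == "random_forest":
        return fit_random_forest_corrected(sample, table, spec, n_trees=n_trees,
                                           mtry=mtry, seed=spec.seed if spec.seed is not None else seed)
    if kind not in CLASSIFIERS:
        raise ValueError(f"unknown classifier {kind!r}")
    if spec.method != "none" and table is None:
        raise ValueError("a stratum table is required for weighted corrections")
    levels = _outcome_levels(sample)
    xe_levels = sorted(pd.unique(sample.data[sample.stratum_feature]))
    corrector = make_corrector(spec.method, m=spec.m, k=spec.k, family=spec.family)
    use_seed = spec.seed if spec.seed is not None else seed
    if spec.method in corr_mod.SINGLE_SAMPLE_METHODS:
        corrected = corrector.resample(sample, table, random_state=use_seed)
        return _fit_single(kind, corrected[0], levels, xe_levels, max_iter)
    # resampling ensemble: m corrected samples, one fit each, score-averaged.
    # A member draw missing an outcome class (possible for the bootstrap
    # methods at extreme weights) is redrawn, as in the forest.
    min_per_class = 2 if kind == "naive_bayes_kde" else 1
    single = make_corrector(spec.method, m=1, k=spec.k, family=spec.family)
    members = []
    if isinstance(use_seed, np.random.SeedSequence):
        children = use_seed.spawn(spec.m)
    else:
        children = np.random.SeedSequence(use_seed).spawn(spec.m)
    for child in children:
        for sub in child.spawn(100):
            drawn = single.resample(sample, table, random_state=sub)[0]
            counts = np.bincount(_y01(drawn, levels), minlength=2)
            if counts.min() >= min_per_class:
                break
        else:
            raise RuntimeError(
                f"correction {spec.method!r} kept producing samples without "
                f"{min_per_class} rows per class after 100 redraws")
        members.append(_fit_single(kind, drawn, levels, xe_levels, max_iter))
    return EnsembleScorer(members) if len(members) > 1 else members[0]


class TwoPhaseClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn estimator wrapping correction + classifier fitting.

    Parameters
    ----------
    classifier : str
        One of ``logistic``, ``logistic_interactions``, ``naive_bayes_kde``,
        ``random_forest``.
    correction : str
        One of the seven correction strategies.
    stratum_col : str or int
        Which column of ``X`` holds the categorical stratum feature.
    population_counts, p_select : mapping or sequence, optional
        Per-stratum population sizes or selection probabilities, keyed by
        ``(stratum level, outcome)`` (required for every correction except
        ``none``).
    """

    def __init__(self, classifier: str = "logistic", correction: str = "none",
                 stratum_col=0, population_counts=None, p_select=None,
                 m: int = 100, k: int = 5, n_trees: int = 500,
                 mtry: int | None = None, family: str = "normal",
                 max_iter: int = 1000, random_state=None):
        self.classifier = classifier
        self.correction = correction
        self.stratum_col = stratum_col
        self.population_counts = population_counts
        self.p_select = p_select
        self.m = m
        self.k = k
        self.n_trees = n_trees
        self.mtry = mtry
        self.family = family
        self.max_iter = max_iter
        self.random_state = random_state

    def _to_frame(self, X) -> tuple[pd.DataFrame, str, list[str]]:
        if isinstance(X, pd.DataFrame):
            df = X.copy()
            stratum = (self.stratum_col if isinstance(self.stratum_col, str)
                       else df.columns[self.stratum_col])
        else:
            X = np.asarray(X)
            cols = [f"x{i}" for i in range(X.shape[1])]
            df = pd.DataFrame(X, columns=cols)
            stratum = cols[self.stratum_col]
        features = [c for c in df.columns if c != stratum]
        return df, stratum, features

    def fit(self, X, y) -> "TwoPhaseClassifier":
        df, stratum, features = self._to_frame(X)
        y = np.asarray(y)
        df["__outcome__"] = y
        self.classes_ = np.sort(np.unique(y))
        sample = assign_strata(df, "__outcome__", stratum, features)
        table = None
        if self.correction != "none":
            table = build_stratum_table(sample,
                                        population_counts=self.population_counts,
                                        p_select=self.p_select)
        self.sample_ = sample
        self.stratum_table_ = table
        self.scorer_ = fit_corrected(
            sample, table, correction=self.correction, classifier=self.classifier,
            m=self.m, k=self.k, family=self.family, seed=self.random_state,
            n_trees=self.n_trees, mtry=self.mtry, max_iter=self.max_iter)
        return self

    def predict_score(self, X) -> np.ndarray:
        if isinstance(X, (pd.DataFrame, np.ndarray)) and not isinstance(X, pd.DataFrame):
            X = np.asarray(X)
        if isinstance(X, pd.DataFrame):
            return self.scorer_.predict_score(X)
        X = np.asarray(X, dtype=float)
        # reorder so the stratum column comes first, as the scorer expects
        idx = (self.stratum_col if isinstance(self.stratum_col, int) else 0)
        order = [idx] + [i for i in range(X.shape[1]) if i != idx]
        return self.scorer_.predict_score(X[:, order])

    def predict_proba(self, X) -> np.ndarray:
        s = self.predict_score(X)
        return np.column_stack([1 - s, s])

    def predict(self, X) -> np.ndarray:
        s = self.predict_score(X)
        return self.classes_[(s >= 0.5).astype(int)]
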