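"""Seven bias-correction strategies for stratified learning samples.

Every corrector turns a :class:`~twophase.strata.StratifiedSample` plus its
:class:`~twophase.strata.StratumTable` into one or more corrected learning
samples:

``none``
    the sample unchanged.
``ip_oversampling``
    deterministic replication of every row of stratum h by its integer IP
    weight w_h, giving n' rows.
``ip_bagging``
    m bootstrap samples of size n with per-row selection probability
    proportional to w_h.
``costing``
    m rejection subsamples: each row enters at most once, accepted with
    probability w_h / max_h' w_h'; draws missing a nonempty stratum are
    discarded and redrawn.
``smote``
    stratified SMOTE: every stratum with w_h > 1 gains n_h*(w_h - 1)
    synthetic rows interpolated between stratum members and their k nearest
    neighbours, giving n' rows.
``stochastic_ip_oversampling``
    m copies of the IP-oversampled set with mean-zero Gaussian noise added
    to the main features, whose per-stratum covariance
    (w_h - 1)/(w_h*n_h - 1) * Sigma_h restores the stratum covariance in
    expectation.
``parametric_ip_bagging``
    m parametric bootstrap samples of size n': per stratum, n_h*w_h feature
    vectors drawn from the stratum-wise fitted distribution (multivariate
    normal with the empirical mean and covariance).

Randomness follows a master seed; repetition j always uses the j-th
spawned child of ``numpy.random.SeedSequence(seed)``, so enlarging m never
perturbs earlier repetitions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

from .strata import StratifiedSample, StratumTable

__all__ = [
    "METHODS",
    "CorrectionSpec",
    "NoCorrection",
    "IPOversampler",
    "IPBagger",
    "CostingSampler",
    "StratifiedSMOTE",
    "StochasticIPOversampler",
    "ParametricIPBagger",
    "make_corrector",
    "correct_none",
    "ip_oversample",
    "ip_bagging_samples",
    "costing_samples",
    "smote_stratified",
    "noise_covariance",
    "stochastic_ip_oversample",
    "parametric_ip_bag_samples",
]

METHODS = (
    "none",
    "ip_oversampling",
    "ip_bagging",
    "costing",
    "smote",
    "stochastic_ip_oversampling",
    "parametric_ip_bagging",
)

#: methods that produce a single corrected sample outside the random forest
SINGLE_SAMPLE_METHODS = ("none", "ip_oversampling", "smote")


@dataclass
class CorrectionSpec:
    """Serializable choice of correction strategy and hyperparameters."""

    method: str = "none"
    m: int = 100
    k: int = 5
    family: str = "normal"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown correction method {self.method!r}; "
                             f"choose one of {METHODS}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def build(self):
        return make_corrector(self.method, m=self.m, k=self.k,
                              family=self.family, random_state=self.seed)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "CorrectionSpec":
        return cls(**json.loads(text))


def _child_rngs(random_state, m: int) -> list[np.random.Generator]:
    if isinstance(random_state, np.random.SeedSequence):
        seq = random_state
    else:
        seq = np.random.SeedSequence(random_state)
    return [np.random.default_rng(c) for c in seq.spawn(m)]


class _BaseCorrector(BaseEstimator):
    """Common resampling interface; subclasses implement ``resample``."""

    name: str = ""

    def resample(self, sample: StratifiedSample, table: StratumTable | None,
                 random_state=None) -> list[StratifiedSample]:
        raise NotImplementedError

    def _seed(self, random_state):
        if random_state is None:
            return getattr(self, "_default_seed", None)
        return random_state


class NoCorrection(_BaseCorrector):
    """Ignore the bias: return the learning sample as-is."""

    name = "none"

    def resample(self, sample, table=None, random_state=None):
        out = sample.take(np.arange(sample.n), provenance="none")
        return [out]


class IPOversampler(_BaseCorrector):
    """Deterministic replication of each row by its stratum IP weight."""

    name = "ip_oversampling"

    def resample(self, sample, table, random_state=None):
        w_row = table.weight_of(sample.stratum_id)
        idx = np.repeat(np.arange(sample.n), w_row)
        return [sample.take(idx, provenance="ip_oversampling")]


class IPBagger(_BaseCorrector):
    """Weighted nonparametric bootstrap: n draws, row prob proportional to w_h."""

    name = "ip_bagging"

    def __init__(self, m: int = 100):
        self.m = m

    def resample(self, sample, table, random_state=None):
        w_row = table.weight_of(sample.stratum_id).astype(float)
        probs = w_row / w_row.sum()
        out = []
        for rng in _child_rngs(self._seed(random_state), self.m):
            idx = rng.choice(sample.n, size=sample.n, replace=True, p=probs)
            out.append(sample.take(idx, provenance="ip_bagging"))
        return out


class CostingSampler(_BaseCorrector):
    """Rejection subsampling: accept each row once with prob w_h / max w.

    Subsamples missing any nonempty stratum are discarded and redrawn
    (cap ``max_retries`` per subsample), so every learner sees all strata.
    ``filter_incomplete=False`` disables that completeness filter (a
    diagnostic mode exposing the raw acceptance-sampling law, whose
    expected subsample size is sum_h n_h w_h / max w).
    """

    name = "costing"

    def __init__(self, m: int = 100, max_retries: int = 1000,
                 filter_incomplete: bool = True):
        self.m = m
        self.max_retries = max_retries
        self.filter_incomplete = filter_incomplete
        self.rejection_counts_: list[int] | None = None

    def resample(self, sample, table, random_state=None):
        w_row = table.weight_of(sample.stratum_id).astype(float)
        accept_p = w_row / w_row.max()
        present = np.unique(sample.stratum_id)
        out = []
        self.rejection_counts_ = []
        for rng in _child_rngs(self._seed(random_state), self.m):
            for attempt in range(self.max_retries + 1):
                keep = rng.random(sample.n) < accept_p
                if not self.filter_incomplete or np.array_equal(
                        np.unique(sample.stratum_id[keep]), present):
                    break
            else:
                raise RuntimeError(
                    f"costing failed to draw a subsample covering all strata "
                    f"within {self.max_retries} retries; strata may be too small"
                )
            self.rejection_counts_.append(attempt)
            out.append(sample.take(np.flatnonzero(keep), provenance="costing"))
        return out


class StratifiedSMOTE(_BaseCorrector):
    """SMOTE per stratum: synthesize n_h*(w_h-1) rows where w_h > 1.

    Each original row of an enlarged stratum generates w_h - 1 synthetic
    rows as x + u*(x_nn - x), u ~ U(0,1), with x_nn one of its k Euclidean
    nearest neighbours inside the same stratum.  Outcome and stratum
    feature are copied, so labels are conserved and the output has n' rows.
    """

    name = "smote"

    def __init__(self, k: int = 5):
        self.k = k

    def resample(self, sample, table, random_state=None):
        (rng,) = _child_rngs(self._seed(random_state), 1)
        X = sample.feature_matrix()
        blocks_idx = [np.arange(sample.n)]
        blocks_feat = [X]
        for sid, w in zip(table.table.index, table.w_h):
            if w <= 1:
                continue
            rows = np.flatnonzero(sample.stratum_id == sid)
            n_h = len(rows)
            if self.k >= n_h:
                raise ValueError(
                    f"smote requires k < n_h; stratum {sid} has n_h={n_h} "
                    f"but k={self.k}"
                )
            Xh = X[rows]
            nn = NearestNeighbors(n_neighbors=self.k + 1).fit(Xh)
            neigh = nn.kneighbors(Xh, return_distance=False)[:, 1:]  # drop self
            base = np.repeat(np.arange(n_h), w - 1)
            pick = rng.integers(0, self.k, size=base.size)
            partner = neigh[base, pick]
            u = rng.random(base.size)[:, None]
            synth = Xh[base] + u * (Xh[partner] - Xh[base])
            blocks_idx.append(rows[base])
            blocks_feat.append(synth)
        idx = np.concatenate(blocks_idx)
        out = sample.take(idx, provenance="smote")
        feats = np.concatenate(blocks_feat, axis=0)
        return [out.with_features(feats, provenance="smote")]


def noise_covariance(sigma_hat: np.ndarray, w_h: int, n_h: int) -> np.ndarray:
    """Adjusted noise covariance (w-1)/(w*n-1) * Sigma for stratum noise.

    Adding mean-zero noise with this covariance to all n_h*w_h replicated
    rows makes the expected empirical covariance of the enlarged stratum
    equal the original stratum covariance.
    """
    sigma = np.asarray(sigma_hat, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("sigma_hat must be a square matrix")
    if not np.allclose(sigma, sigma.T, rtol=1e-8, atol=1e-12):
        raise ValueError("sigma_hat must be symmetric")
    if n_h < 2:
        raise ValueError("n_h must be >= 2 for a covariance estimate")
    if w_h < 1:
        raise ValueError("w_h must be >= 1")
    return ((w_h - 1.0) / (w_h * n_h - 1.0)) * sigma


def _ridge(sigma: np.ndarray) -> np.ndarray:
    """Tiny diagonal ridge so Cholesky-based sampling always succeeds."""
    lam = 1e-8 * float(np.mean(np.diag(sigma)))
    if lam <= 0:
        lam = 1e-8
    return sigma + lam * np.eye(sigma.shape[0])


def _mvn_draw(rng, mean, cov, size):
    cov = _ridge(np.asarray(cov, dtype=float))
    L = np.linalg.cholesky(cov)
    z = rng.standard_normal((size, cov.shape[0]))
    return np.asarray(mean) + z @ L.T


class StochasticIPOversampler(_BaseCorrector):
    """IP oversampling plus per-stratum Gaussian noise on the main features.

    Noise with covariance (w_h-1)/(w_h*n_h-1)*Sigma_hat_h is added to every
    replicated row of stratum h (originals included); strata with w_h = 1
    receive no noise, so the all-weights-one limit is the identity.
    """

    name = "stochastic_ip_oversampling"

    def __init__(self, m: int = 100, family: str = "normal"):
        self.m = m
        self.family = family

    def resample(self, sample, table, random_state=None):
        if self.family != "normal":
            raise ValueError(f"unsupported noise family {self.family!r}")
        counts = sample.stratum_counts()
        for sid, w in zip(table.table.index, table.w_h):
            if w > 1 and counts.get(sid, 0) < 2:
                raise ValueError(
                    f"stratum {sid} has fewer than 2 rows; its covariance "
                    "is undefined for stochastic IP oversampling"
                )
        base = IPOversampler().resample(sample, table)[0]
        X0 = base.feature_matrix()
        Xs = sample.feature_matrix()
        plans = []  # (rows in the oversampled set, adjusted covariance)
        for sid, w, n_h in zip(table.table.index, table.w_h, table.n_h):
            if w <= 1:
                continue
            sigma = np.atleast_2d(
                np.cov(Xs[sample.stratum_id == sid], rowvar=False, ddof=1))
            adj = noise_covariance(sigma, int(w), int(n_h))
            plans.append((np.flatnonzero(base.stratum_id == sid), adj))
        out = []
        for rng in _child_rngs(self._seed(random_state), self.m):
            X = X0.copy()
            for rows, adj in plans:
                X[rows] += _mvn_draw(rng, np.zeros(adj.shape[0]), adj, rows.size)
            out.append(base.with_features(X, provenance="stochastic_ip_oversampling"))
        return out


class ParametricIPBagger(_BaseCorrector):
    """Parametric bootstrap of size n' from stratum-wise fitted Gaussians.

    Per repetition and stratum h, n_h*w_h feature vectors are drawn from
    N(mu_hat_h, Sigma_hat_h) with the empirical stratum mean and covariance
    (a tiny ridge keeps degenerate covariances sampleable); the stratum's
    (x_e, y) pair is attached to every draw.
    """

    name = "parametric_ip_bagging"

    def __init__(self, m: int = 100, family: str = "normal"):
        self.m = m
        self.family = family

    def resample(self, sample, table, random_state=None):
        if self.family != "normal":
            raise ValueError(f"unsupported parametric family {self.family!r}")
        X = sample.feature_matrix()
        params = {}
        for sid, n_h in zip(table.table.index, table.n_h):
            rows = np.flatnonzero(sample.stratum_id == sid)
            if rows.size < 2:
                raise ValueError(
                    f"stratum {sid} has fewer than 2 rows; parametric "
                    "IP bagging needs a covariance estimate"
                )
            Xh = X[rows]
            params[sid] = (rows, Xh.mean(axis=0),
                           np.atleast_2d(np.cov(Xh, rowvar=False, ddof=1)))
        out = []
        for rng in _child_rngs(self._seed(random_state), self.m):
            idx_blocks, feat_blocks = [], []
            for sid, w, n_h in zip(table.table.index, table.w_h, table.n_h):
                rows, mu, sigma = params[sid]
                size = int(n_h * w)
                draws = _mvn_draw(rng, mu, sigma, size)
                # recycle original rows for the (x_e, y) metadata columns
                idx_blocks.append(np.resize(rows, size))
                feat_blocks.append(draws)
            idx = np.concatenate(idx_blocks)
            rep = sample.take(idx, provenance="parametric_ip_bagging")
            rep = rep.with_features(np.concatenate(feat_blocks, axis=0),
                                    provenance="parametric_ip_bagging")
            out.append(rep)
        return out


_CORRECTORS = {
    "none": NoCorrection,
    "ip_oversampling": IPOversampler,
    "ip_bagging": IPBagger,
    "costing": CostingSampler,
    "smote": StratifiedSMOTE,
    "stochastic_ip_oversampling": StochasticIPOversampler,
    "parametric_ip_bagging": ParametricIPBagger,
}


def make_corrector(method: str, m: int = 100, k: int = 5,
                   family: str = "normal", random_state=None) -> _BaseCorrector:
    """Instantiate a corrector by method name with its relevant parameters."""
    if method not in _CORRECTORS:
        raise ValueError(f"unknown correction method {method!r}; "
                         f"choose one of {METHODS}")
    cls = _CORRECTORS[method]
    kwargs = {}
    if method in ("ip_bagging", "costing"):
        kwargs["m"] = m
    elif method == "smote":
        kwargs["k"] = k
    elif method in ("stochastic_ip_oversampling", "parametric_ip_bagging"):
        kwargs.update(m=m, family=family)
    corr = cls(**kwargs)
    if random_state is not None:
        corr._default_seed = random_state
    return corr


# ---------------------------------------------------------------------------
# thin functional wrappers


def correct_none(sample: StratifiedSample) -> StratifiedSample:
    return NoCorrection().resample(sample)[0]


def ip_oversample(sample: StratifiedSample, table: StratumTable) -> StratifiedSample:
    return IPOversampler().resample(sample, table)[0]


def ip_bagging_samples(sample, table, m=100, seed=None):
    return IPBagger(m=m).resample(sample, table, random_state=seed)


def costing_samples(sample, table, m=100, seed=None, max_retries=1000):
    return CostingSampler(m=m, max_retries=max_retries).resample(
        sample, table, random_state=seed)


def smote_stratified(sample, table, k=5, seed=None):
    return StratifiedSMOTE(k=k).resample(sample, table, random_state=seed)[0]


def stochastic_ip_oversample(sample, table, m=100, family="normal", seed=None):
    return StochasticIPOversampler(m=m, family=family).resample(
        sample, table, random_state=seed)


def parametric_ip_bag_samples(sample, table, m=100, family="normal", seed=None):
    return ParametricIPBagger(m=m, family=family).resample(
        sample, table, random_state=seed)
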