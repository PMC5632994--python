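"""Synthetic two-phase case-control study: generation, sampling, evaluation.

The generator emulates a population of ``N`` individuals with a rare
binary exposure (``P(X_e = 1) = 0.1``) and ``p = 5`` main features drawn
independently from one of four families (normal, Student's t, Poisson,
Bernoulli) with per-replicate parameters drawn uniformly from fixed
ranges.  The outcome follows a logistic model with exposure effect
``beta_e = log 0.5``, slopes drawn uniformly from [-0.15, 0.15] and an
intercept calibrated by bisection so that the disease prevalence is
``P(Y = 1) = 0.1``.

A two-phase selection then draws a learning sample with four equally
sized ``(x_e, y)`` strata, so case and exposed fractions are exactly 0.5
in the sample while both are rare in the population.  Classifier quality
is measured by the rank-based AUC on an unbiased test set, and correction
strategies are compared by an OLS regression of AUC on correction dummies
with "no correction" as the reference, plus DeLong paired tests with a
Bonferroni threshold for families of comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .classifiers import CLASSIFIERS, fit_corrected
from .correctors import METHODS
from .strata import StratifiedSample, StratumTable, assign_strata, build_stratum_table

__all__ = [
    "ScenarioConfig",
    "StudyResult",
    "draw_replicate_params",
    "generate_population",
    "calibrate_intercept",
    "two_phase_sample",
    "auc",
    "delong_paired_test",
    "bonferroni_threshold",
    "compare_methods",
    "run_study",
]

log = logging.getLogger(__name__)

FAMILIES = ("normal", "student_t", "poisson", "bernoulli")


@dataclass
class ScenarioConfig:
    """Parameters of one simulation scenario.

    Defaults reproduce the reference study conditions: N = 1e5 population,
    1e4 test rows, four equal strata of a 2000-row learning sample and
    1000 replicates.  ``beta_0`` is always derived by calibration, never
    set by the user.
    """

    family: str = "normal"
    p: int = 5
    mu_range: tuple[float, float] = (1.0, 10.0)
    sigma_range: tuple[float, float] = (1.0, 5.0)
    nu_set: tuple[int, int] = (10, 100)          # integers, inclusive
    lambda_set: Sequence[int] = (1, 2, 3, 4, 5)
    pi_range: tuple[float, float] = (0.4, 0.6)
    beta_e: float = math.log(0.5)
    beta_range: tuple[float, float] = (-0.15, 0.15)
    prevalence: float = 0.1
    exposure_rate: float = 0.1
    n_population: int = 100_000
    n_test: int = 10_000
    n_learn: int = 2000
    replicates: int = 1000
    seed: int | None = None
    # supplementary scenario knobs (no headline claims attached)
    families: Sequence[str] | None = None        # per-feature family mix
    correlation: np.ndarray | None = None        # feature-copula correlation

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.families is not None:
            bad = set(self.families) - set(FAMILIES)
            if bad:
                raise ValueError(f"unknown families {sorted(bad)}")
            if len(self.families) != self.p:
                raise ValueError("families must list one family per feature")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class StudyResult:
    """Long AUC table plus per-classifier comparison statistics."""

    aucs: pd.DataFrame          # scenario, replicate, classifier, correction, auc
    comparisons: pd.DataFrame   # classifier, correction, coef, ci_low, ci_high, significant
    failures: list = field(default_factory=list)


def draw_replicate_params(config: ScenarioConfig, rng: np.random.Generator) -> dict:
    """Draw one replicate's feature-distribution parameters and slopes."""
    fams = list(config.families) if config.families is not None \
        else [config.family] * config.p
    per_feature = []
    for fam in fams:
        if fam == "normal":
            per_feature.append({"family": fam,
                                "mu": rng.uniform(*config.mu_range),
                                "sigma": rng.uniform(*config.sigma_range)})
        elif fam == "student_t":
            per_feature.append({"family": fam,
                                "nu": int(rng.integers(config.nu_set[0],
                                                       config.nu_set[1] + 1))})
        elif fam == "poisson":
            per_feature.append({"family": fam,
                                "lam": int(rng.choice(np.asarray(config.lambda_set)))})
        else:
            per_feature.append({"family": fam,
                                "pi": rng.uniform(*config.pi_range)})
    betas = rng.uniform(*config.beta_range, size=config.p)
    return {"features": per_feature, "beta": betas, "beta_e": config.beta_e}


def _feature_ppf(spec: Mapping, u: np.ndarray) -> np.ndarray:
    fam = spec["family"]
    if fam == "normal":
        return stats.norm.ppf(u, loc=spec["mu"], scale=spec["sigma"])
    if fam == "student_t":
        return stats.t.ppf(u, df=spec["nu"])
    if fam == "poisson":
        return stats.poisson.ppf(u, mu=spec["lam"])
    return stats.bernoulli.ppf(u, p=spec["pi"])


def _draw_features(config: ScenarioConfig, params: dict, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    specs = params["features"]
    if config.correlation is not None:
        # Gaussian copula for the supplementary dependent-feature scenario
        R = np.asarray(config.correlation, dtype=float)
        L = np.linalg.cholesky(R)
        z = rng.standard_normal((n, config.p)) @ L.T
        u = stats.norm.cdf(z)
        return np.column_stack([_feature_ppf(s, u[:, j])
                                for j, s in enumerate(specs)])
    cols = []
    for spec in specs:
        fam = spec["family"]
        if fam == "normal":
            cols.append(rng.normal(spec["mu"], spec["sigma"], size=n))
        elif fam == "student_t":
            cols.append(rng.standard_t(spec["nu"], size=n))
        elif fam == "poisson":
            cols.append(rng.poisson(spec["lam"], size=n).astype(float))
        else:
            cols.append((rng.random(n) < spec["pi"]).astype(float))
    return np.column_stack(cols)


def calibrate_intercept(linear_predictor: np.ndarray, target: float,
                        lo: float = -50.0, hi: float = 50.0,
                        tol: float = 1e-10) -> float:
    """Bisect for the intercept making mean(expit(b + lp)) hit the target."""
    if not 0 < target < 1:
        raise ValueError("target prevalence must lie in (0, 1)")
    lp = np.asarray(linear_predictor, dtype=float)

    def f(b: float) -> float:
        return float(np.mean(expit(b + lp))) - target

    flo, fhi = f(lo), f(hi)
    if flo > 0 or fhi < 0:
        raise ValueError("bisection bracket [-50, 50] does not contain the root")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm) < tol:
            return mid
        if fm < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_population(config: ScenarioConfig, seed=None, params: dict | None = None,
                        n: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Generate one population table (x_e, x1..xp, y) plus its parameters.

    If ``params`` is supplied (e.g. to generate a test set with the same
    replicate-specific distribution), its calibrated intercept is reused;
    otherwise parameters are drawn and the intercept calibrated here.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    n = config.n_population if n is None else n
    if params is None:
        params = draw_replicate_params(config, rng)
    xe = (rng.random(n) < config.exposure_rate).astype(int)
    X = _draw_features(config, params, n, rng)
    lp = xe * params["beta_e"] + X @ params["beta"]
    if "beta_0" not in params:
        params = dict(params)
        params["beta_0"] = calibrate_intercept(lp, config.prevalence)
    theta = expit(params["beta_0"] + lp)
    y = (rng.random(n) < theta).astype(int)
    df = pd.DataFrame(X, columns=[f"x{j + 1}" for j in range(config.p)])
    df.insert(0, "x_e", xe)
    df["y"] = y
    return df, params


def two_phase_sample(population: pd.DataFrame, n: int, seed=None,
                     outcome: str = "y", stratum_feature: str = "x_e",
                     ) -> tuple[StratifiedSample, StratumTable]:
    """Draw the stratified learning sample: n/4 rows per (x_e, y) cell.

    Population cell counts become N_h, so the stratum table carries the
    exact selection probabilities and IP weights of the design.
    """
    if n % 4 != 0:
        raise ValueError("the two-phase sample size n must be divisible by 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_cell = n // 4
    cells = sorted(set(zip(population[stratum_feature], population[outcome])))
    pieces, pop_counts = [], {}
    for cell in cells:
        mask = ((population[stratum_feature] == cell[0])
                & (population[outcome] == cell[1]))
        members = np.flatnonzero(mask.to_numpy())
        pop_counts[cell] = len(members)
        if len(members) < per_cell:
            raise ValueError(
                f"population cell {cell} holds {len(members)} rows; "
                f"{per_cell} are required")
        pieces.append(rng.choice(members, size=per_cell, replace=False))
    drawn = population.iloc[np.concatenate(pieces)].reset_index(drop=True)
    features = [c for c in population.columns if c not in (outcome, stratum_feature)]
    sample = assign_strata(drawn, outcome, stratum_feature, features)
    table = build_stratum_table(sample, population_counts=pop_counts)
    return sample, table


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC: P(score+ > score-) + 0.5 P(tie), via midranks."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    pos = y == classes[1]
    n1, n0 = int(pos.sum()), int((~pos).sum())
    r = stats.rankdata(s)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _delong_components(scores: np.ndarray, pos: np.ndarray):
    sp, sn = scores[pos], scores[~pos]
    m, n = len(sp), len(sn)
    tz = stats.rankdata(np.concatenate([sp, sn]))
    tx = stats.rankdata(sp)
    ty = stats.rankdata(sn)
    a = float((tz[:m].sum() - m * (m + 1) / 2) / (m * n))
    v01 = (tz[:m] - tx) / n           # structural components, cases
    v10 = 1.0 - (tz[m:] - ty) / m     # structural components, controls
    return a, v01, v10


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong paired test for equality of two correlated AUCs.

    Returns the normal test statistic and the two-sided p-value; identical
    scores (zero variance of the difference) give (0.0, 1.0) by convention.
    """
    sa, sb = np.asarray(scores_a, float), np.asarray(scores_b, float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned")
    pos = y == classes[1]
    auc_a, v01a, v10a = _delong_components(sa, pos)
    auc_b, v01b, v10b = _delong_components(sb, pos)
    m, n = len(v01a), len(v10a)
    d01 = v01a - v01b
    d10 = v10a - v10b
    var = (np.var(d01, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(d10, ddof=1) / n if n > 1 else 0.0)
    if var <= 0:
        return 0.0, 1.0
    z = (auc_a - auc_b) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 7) -> float:
    """Per-test p-value threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def compare_methods(auc_table: pd.DataFrame, classifier: str | None = None,
                    alpha: float = 0.05, reference: str = "none") -> pd.DataFrame:
    """OLS of AUC on correction dummies with "none" as reference.

    Coefficients equal mean-AUC differences versus no correction; an
    approach is flagged significant when its t-based (1-alpha) confidence
    interval excludes zero.
    """
    import statsmodels.formula.api as smf

    df = auc_table
    if classifier is not None:
        df = df[df["classifier"] == classifier]
    df = df.dropna(subset=["auc"])
    if reference not in set(df["correction"]):
        raise ValueError(f"reference category {reference!r} missing from the table")
    counts = df.groupby("correction")["auc"].count()
    if (counts < 2).any():
        raise ValueError("every correction needs at least 2 replicates")
    fit = smf.ols(
        f"auc ~ C(correction, Treatment(reference='{reference}'))", data=df
    ).fit()
    ci = fit.conf_int(alpha=alpha)
    rows = [{
        "correction": reference, "coef": 0.0, "ci_low": 0.0, "ci_high": 0.0,
        "significant": False, "mean_auc": df.loc[df["correction"] == reference,
                                                 "auc"].mean(),
    }]
    for name in fit.params.index:
        if name == "Intercept":
            continue
        level = name.split("[T.")[1].rstrip("]")
        lo, hi = ci.loc[name]
        rows.append({
            "correction": level,
            "coef": float(fit.params[name]),
            "ci_low": float(lo),
            "ci_high": float(hi),
            "significant": bool(lo > 0 or hi < 0),
            "mean_auc": df.loc[df["correction"] == level, "auc"].mean(),
        })
    out = pd.DataFrame(rows)
    if classifier is not None:
        out.insert(0, "classifier", classifier)
    return out


def plot_comparisons(comparisons: pd.DataFrame, path=None, classifier: str | None = None):
    """Plot per-correction mean-AUC-difference coefficients with 95% CIs.

    One panel per classifier: a point per correction at its OLS coefficient
    (difference in mean AUC versus no correction) with its confidence
    interval; the dashed line marks no effect.  Requires matplotlib.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = comparisons
    if classifier is not None:
        df = df[df["classifier"] == classifier]
    groups = (df.groupby("classifier") if "classifier" in df.columns
              else [("", df)])
    groups = list(groups)
    fig, axes = plt.subplots(1, len(groups), figsize=(4.5 * len(groups), 3.5),
                             squeeze=False)
    for ax, (name, sub) in zip(axes[0], groups):
        sub = sub[sub["correction"] != "none"]
        ypos = np.arange(len(sub))
        ax.errorbar(sub["coef"], ypos,
                    xerr=[sub["coef"] - sub["ci_low"],
                          sub["ci_high"] - sub["coef"]],
                    fmt="o", capsize=3)
        ax.axvline(0.0, linestyle="--", linewidth=1)
        ax.set_yticks(ypos, sub["correction"])
        ax.set_xlabel("AUC difference vs no correction")
        ax.set_title(str(name))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def run_study(
    config: ScenarioConfig,
    classifiers: Sequence[str] = ("logistic",),
    corrections: Sequence[str] | Mapping[str, Sequence[str]] = METHODS,
    m: int = 100,
    k: int = 5,
    n_trees: int = 500,
    mtry: int | None = None,
    include_population: bool = False,
    replicate_ids: Sequence[int] | None = None,
    progress: bool = False,
) -> StudyResult:
    """Run the (scenario x classifier x correction) study.

    Per replicate: draw parameters, generate the population and an
    independent test set with the same parameters, draw the stratified
    learning sample, fit every (classifier, correction) cell and record
    its test AUC.  With ``include_population`` an uncorrected fit on the
    full population is added under the correction label ``population``.
    Each replicate uses its own spawned seed stream, so subsets of
    replicates (``replicate_ids``) reproduce exactly the same cells as a
    full run.
    """
    for c in classifiers:
        if c not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {c!r}")
    corr_for = (dict(corrections) if isinstance(corrections, Mapping)
                else {c: list(corrections) for c in classifiers})
    for cls, meths in corr_for.items():
        bad = set(meths) - set(METHODS)
        if bad:
            raise ValueError(f"unknown corrections {sorted(bad)} for {cls!r}")
    reps = list(replicate_ids) if replicate_ids is not None \
        else list(range(config.replicates))
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    rows, failures = [], []
    for r in reps:
        seq = children[r]
        s_pop, s_test, s_learn, s_fit = seq.spawn(4)
        pop, params = generate_population(config, seed=np.random.default_rng(s_pop))
        test, _ = generate_population(config, seed=np.random.default_rng(s_test),
                                      params=params, n=config.n_test)
        learn, table = two_phase_sample(pop, config.n_learn,
                                        seed=np.random.default_rng(s_learn))
        test_y = test["y"].to_numpy()
        fit_children = iter(s_fit.spawn(len(classifiers) * (len(METHODS) + 1)))
        for cls in classifiers:
            cells = list(corr_for[cls]) + (["population"] if include_population else [])
            for method in cells:
                child = next(fit_children)
                try:
                    if method == "population":
                        pop_sample = assign_strata(pop, "y", "x_e")
                        scorer = fit_corrected(
                            pop_sample, None, correction="none", classifier=cls,
                            n_trees=n_trees, mtry=mtry,
                            seed=int(child.generate_state(1)[0] % 2**31))
                    else:
                        scorer = fit_corrected(
                            learn, table, correction=method, classifier=cls,
                            m=m, k=k, n_trees=n_trees, mtry=mtry,
                            seed=int(child.generate_state(1)[0] % 2**31))
                    value = auc(scorer.predict_score(test), test_y)
                except Exception as exc:  # pragma: no cover - defensive logging
                    log.warning("replicate %d cell (%s, %s) failed: %s",
                                r, cls, method, exc)
                    failures.append({"replicate": r, "classifier": cls,
                                     "correction": method, "error": str(exc)})
                    value = np.nan
                rows.append({"scenario": config.family, "replicate": r,
                             "classifier": cls, "correction": method,
                             "auc": value})
        if progress:
            log.info("replicate %d/%d done", r + 1, config.replicates)
    aucs = pd.DataFrame(rows)
    comp_frames = []
    for cls in classifiers:
        sub = aucs[aucs["classifier"] == cls]
        if sub["correction"].nunique() >= 2 and "none" in set(sub["correction"]) \
                and sub.groupby("correction")["auc"].count().min() >= 2:
            comp_frames.append(compare_methods(sub, classifier=cls))
    comparisons = (pd.concat(comp_frames, ignore_index=True)
                   if comp_frames else pd.DataFrame())
    return StudyResult(aucs=aucs, comparisons=comparisons, failures=failures)
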