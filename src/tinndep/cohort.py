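"""Synthetic tinnitus-patient cohort generator.

Simulates a cohort of chronic-tinnitus outpatients with pre- (T0) and
post-treatment (T1) depression scores and a full questionnaire battery, so
that the whole downstream pipeline (feature assembly, classifier tuning,
model-reliance feature selection) is testable without any clinical data.

The generative model
--------------------

1. **Depression scores.**  Each patient carries a pair of latent Gaussian
   depression traits ``(z0, z1)`` for the two time points, correlated with
   a copula correlation solved numerically so that the *joint* clinical /
   subclinical transition table matches the configured proportions.  Sex
   enters as an additive latent shift (solved from the configured female /
   male prevalence targets).  Each latent is mapped through its exact
   mixture CDF to a uniform variate and then through a Weibull quantile
   function whose two parameters are solved so that the discretised sum
   score reproduces the configured mean and clinical prevalence exactly.

2. **Rank heterogeneity.**  A Gaussian copula that reproduces the
   transition table implies a higher T0/T1 rank correlation than the
   configured Spearman target: concordance at the clinical threshold is
   stronger than global rank concordance.  To model this asymmetry, a
   fraction of patients have their T1 latent re-assigned by permutation
   *within* T1 outcome strata.  This leaves every marginal statistic and
   all four transition cells untouched while lowering the rank correlation
   continuously; the fraction has a closed quadrature solution because
   Spearman's rho is linear in it.

3. **Other instruments.**  Tinnitus-distress, perceived-stress and
   general-health traits are Gaussian with configured (Spearman) coupling
   to the post-treatment depression trait; instrument totals follow
   discretised, range-clipped normal marginals and are then distributed
   over their items with a capacity-constrained urn draw
   (``multivariate_hypergeometric``), which makes every stored scale score
   *exactly* recomputable from its items.  Items without a score-bearing
   total (TLQ, TINSKAL, the unscored TQ items) are produced by
   thresholding a noisy copy of the instrument trait (graded-response
   style).

All randomness derives from ``config.seed`` through named child streams
(see :mod:`tinndep._rng`), so regenerating with the same configuration is
byte-identical and adding a new stream never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rng import child_rng
from .schema import QuestionnaireSchema, default_schema

__all__ = [
    "GeneratorConfig",
    "CohortTable",
    "CohortCalibration",
    "calibrate",
    "sample_latent_traits",
    "discretize_to_likert",
    "generate_cohort",
    "inject_missingness",
    "make_planted_classification",
    "verify_scale_consistency",
]

#: integer sum score at or above which depression counts as clinical
CLINICAL_CUTOFF = 16


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _default_priors() -> dict[str, tuple[float, ...]]:
    return {
        "nationality": (0.95, 0.05),
        "graduation": (0.04, 0.33, 0.28, 0.14, 0.14, 0.07),
        "job": (0.52, 0.08, 0.07, 0.20, 0.04, 0.04, 0.05),
        "marital": (0.25, 0.55, 0.12, 0.05, 0.03),
        "partnership": (0.75, 0.25),
        "hearing_aid": (0.12, 0.88),
        "tlq_loc": (0.22, 0.22, 0.34, 0.17, 0.05),
    }


def _default_loadings() -> dict[str, float]:
    return {
        "depression": 0.8,
        "stress": 0.7,
        "tinnitus_distress": 0.7,
        "general_health": 0.7,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Targets and knobs of the cohort generator.

    The defaults encode the study conditions the generator is meant to
    emulate: a cohort of 1,490 outpatients, T0 depression sum 18.2 points
    on average with 52% clinical prevalence (58.6% among women, 45.7%
    among men), a mean treatment effect of 5.0 points, a T0/T1 Spearman
    correlation of 0.71, clinical-to-subclinical improvement in 22.7% of
    patients and worsening in 3.4%, and moderate coupling of the
    post-treatment depression score with tinnitus distress (0.53),
    perceived stress (0.53) and general health (-0.48).
    """

    n_patients: int = 1490
    seed: int = 0

    # T0 depression sum marginal
    target_t0_mean: float = 18.2
    target_t0_sd: float = 11.7          # descriptive; emerges from the solve
    prevalence_female: float = 0.586
    prevalence_male: float = 0.457
    p_female: float = 755 / 1490
    sex_effect: float | None = None     # latent shift; None = solve from prevalences
    t0_location_shift: float = 0.0      # additive shift on the T0 score scale

    # treatment effect and T0/T1 dependence
    treatment_effect_mean: float = 5.0
    treatment_effect_sd: float = 8.2    # descriptive; see docs/methods.md
    rho_t0_t1: float = 0.71             # Spearman target
    improvement_rate: float = 0.227     # clinical at T0, subclinical at T1
    worsening_rate: float = 0.034       # subclinical at T0, clinical at T1

    # coupling of other instruments to the T1 depression trait (Spearman)
    corr_t1_tq: float = 0.53
    corr_t1_psq: float = 0.53
    corr_t1_sf8: float = -0.48
    latent_loadings: Mapping[str, float] = field(default_factory=_default_loadings)

    # instrument total marginals
    tq_mean: float = 38.6
    tq_sd: float = 17.2
    psq_raw_mean: float = 75.0          # raw 30-120 scale; /90 - 1/3 gives 0-1
    psq_raw_sd: float = 18.0
    sf8_sum_mean: float = 24.0
    sf8_sum_sd: float = 7.9

    # socio-demographics
    age_mean: float = 49.8
    age_sd: float = 12.2
    categorical_priors: Mapping[str, tuple[float, ...]] = field(
        default_factory=_default_priors)

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not -1.0 < self.rho_t0_t1 < 1.0:
            raise ValueError("rho_t0_t1 must lie in (-1, 1)")
        for name in ("target_t0_sd", "treatment_effect_sd", "age_sd",
                     "tq_sd", "psq_raw_sd", "sf8_sum_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("prevalence_female", "prevalence_male", "p_female",
                     "improvement_rate", "worsening_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        for fld, probs in self.categorical_priors.items():
            p = np.asarray(probs, dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"categorical prior for {fld!r} must be a probability "
                    f"vector summing to 1 (got sum {p.sum():.12f})")

    @property
    def prevalence_t0(self) -> float:
        return (self.p_female * self.prevalence_female
                + (1.0 - self.p_female) * self.prevalence_male)

    @property
    def prevalence_t1(self) -> float:
        return self.prevalence_t0 - self.improvement_rate + self.worsening_rate

    @property
    def target_t1_mean(self) -> float:
        return self.target_t0_mean - self.treatment_effect_mean


# ---------------------------------------------------------------------------
# cohort container
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Per-patient raw responses plus derived sum scores.

    ``data`` holds one row per patient.  Missing responses are encoded as
    NaN / empty cells; a cell is "flagged missing" iff it is null.
    """

    data: pd.DataFrame

    ID_COLUMN = "patient_id"

    @property
    def n(self) -> int:
        return len(self.data)

    def value_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != self.ID_COLUMN]

    def missing_mask(self) -> pd.DataFrame:
        return self.data[self.value_columns()].isna()

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        df = pd.read_csv(path)
        return cls(df)


# ---------------------------------------------------------------------------
# low-level operations
# ---------------------------------------------------------------------------

def sample_latent_traits(n: int, trait_correlations, seed: int,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw ``n`` samples of zero-mean, unit-variance correlated traits.

    ``trait_correlations`` must be a symmetric positive semi-definite
    matrix with unit diagonal.  Sampling uses an eigendecomposition, so
    exactly singular (semi-definite) matrices are admissible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    corr = np.asarray(trait_correlations, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("trait correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("trait correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
        raise ValueError("trait correlation matrix must have unit diagonal")
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"trait correlation matrix is not positive semi-definite "
            f"(smallest eigenvalue {eigvals.min():.3e})")
    eigvals = np.clip(eigvals, 0.0, None)
    factor = eigvecs * np.sqrt(eigvals)
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.standard_normal((n, corr.shape[0])) @ factor.T


def discretize_to_likert(values, n_levels: int, thresholds) -> np.ndarray:
    """Map real values to ordinal levels ``0 .. n_levels-1`` by thresholding.

    ``thresholds`` must be strictly increasing with length ``n_levels - 1``;
    a value below the first threshold maps to 0, at or above the last to
    ``n_levels - 1``.  The mapping is monotone by construction.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if thresholds.shape != (n_levels - 1,):
        raise ValueError("need exactly n_levels - 1 thresholds")
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    return np.searchsorted(thresholds, np.asarray(values, dtype=float),
                           side="right").astype(np.int64)


# ---------------------------------------------------------------------------
# calibration solvers
# ---------------------------------------------------------------------------

def _solve_weibull(mean: float, p_tail: float, cut: float) -> tuple[float, float]:
    """Weibull (shape, scale) with given mean and ``P(X >= cut) = p_tail``.

    The scale follows from the tail condition for each shape; the shape is
    found by bracketing the mean equation.  Of the (up to two) roots the
    smaller, i.e. more right-skewed, shape is returned, which matches the
    skew of bounded symptom-sum scores.
    """
    if not 0.0 < p_tail < 1.0:
        raise ValueError("tail probability must lie in (0, 1)")
    log_tail = -math.log(p_tail)

    def f(c: float) -> float:
        lam = cut / log_tail ** (1.0 / c)
        return lam * math.gamma(1.0 + 1.0 / c) - mean

    grid = np.linspace(0.35, 30.0, 600)
    vals = [f(c) for c in grid]
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            c = float(a)
            break
        if fa * fb < 0:
            c = optimize.brentq(f, a, b)
            break
    else:
        raise ValueError(
            f"no Weibull marginal with mean {mean} and P(X >= {cut}) = "
            f"{p_tail}: targets are jointly infeasible")
    return float(c), float(cut / log_tail ** (1.0 / c))


def _solve_sex_shift(prev_f: float, prev_m: float,
                     p_female: float) -> tuple[float, float]:
    """Latent shifts (+d_f for women, -d_m for men) with zero mean.

    Solved so that, after mapping through the exact mixture CDF, the
    within-sex clinical prevalences equal the targets while the overall
    prevalence equals their population mix.
    """
    z_f = stats.norm.ppf(prev_f)
    z_m = stats.norm.ppf(prev_m)
    d_f = (z_f - z_m) / (1.0 + p_female / (1.0 - p_female))
    d_m = p_female * d_f / (1.0 - p_female)
    return float(d_f), float(d_m)


@dataclass(frozen=True)
class CohortCalibration:
    """Solved internal parameters of the depression-score model."""

    weibull_t0: tuple[float, float]
    weibull_t1: tuple[float, float]
    shift_f: float
    shift_m: float
    rho: float                  # latent copula correlation (pre-shuffle)
    c0: float                   # latent clinical threshold at T0
    c1: float                   # latent clinical threshold at T1
    shuffle_fraction: float
    p_female: float

    def mix_cdf(self, x) -> np.ndarray:
        """Exact CDF of the sex-shifted latent (mixture of two normals)."""
        x = np.asarray(x, dtype=float)
        return (self.p_female * stats.norm.cdf(x - self.shift_f)
                + (1.0 - self.p_female) * stats.norm.cdf(x + self.shift_m))

    def mix_ppf(self, q: float) -> float:
        return optimize.brentq(lambda x: self.mix_cdf(x) - q, -12.0, 12.0)


def _orthant(rho: float, c0: float, c1: float, cal_shifts) -> float:
    """P(z0' >= c0, z1' >= c1) under the sex-shifted bivariate normal."""
    total = 0.0
    for p_s, d in cal_shifts:
        bvn = stats.multivariate_normal(mean=[0.0, 0.0],
                                        cov=[[1.0, rho], [rho, 1.0]])
        # P(Z >= lo) = P(Z <= -lo) by symmetry
        total += p_s * bvn.cdf([-(c0 - d), -(c1 - d)])
    return total


_HERMITE_NODES = 100


def _spearman_quadrature(rho: float, cal: "CohortCalibration",
                         stratum_average: bool) -> float:
    """Model Spearman's rho of (T0, T1) via Gauss-Hermite quadrature.

    With ``stratum_average=True`` the T1 probability integral transform is
    replaced by its within-stratum mean, which is the large-n limit of a
    full within-stratum shuffle.  Spearman's rho equals ``12 E[F0 F1] - 3``
    for (effectively) continuous margins.
    """
    xs, ws = np.polynomial.hermite_e.hermegauss(_HERMITE_NODES)
    wn = ws / ws.sum()
    shifts = [(cal.p_female, cal.shift_f), (1.0 - cal.p_female, -cal.shift_m)]

    if stratum_average:
        num_hi = den_hi = num_lo = den_lo = 0.0
        for p_s, d in shifts:
            z = xs + d
            f1 = cal.mix_cdf(z)
            hi = z >= cal.c1
            num_hi += p_s * float((wn * f1 * hi).sum())
            den_hi += p_s * float((wn * hi).sum())
            num_lo += p_s * float((wn * f1 * ~hi).sum())
            den_lo += p_s * float((wn * ~hi).sum())
        g_hi = num_hi / den_hi
        g_lo = num_lo / den_lo

    total = 0.0
    z0 = xs[:, None]
    eps = xs[None, :]
    w2 = wn[:, None] * wn[None, :]
    for p_s, d in shifts:
        z1 = rho * z0 + math.sqrt(1.0 - rho * rho) * eps
        f0 = cal.mix_cdf(z0 + d)
        if stratum_average:
            f1 = np.where(z1 + d >= cal.c1, g_hi, g_lo)
        else:
            f1 = cal.mix_cdf(z1 + d)
        total += p_s * float((w2 * f0 * f1).sum())
    return 12.0 * total - 3.0


def calibrate(config: GeneratorConfig) -> CohortCalibration:
    """Solve all internal parameters from the configured targets.

    Raises ``ValueError`` with a diagnostic when the targets are jointly
    infeasible (e.g. a Spearman target above what the transition table
    allows, or marginal targets no Weibull can meet).
    """
    p0 = config.prevalence_t0
    p1 = config.prevalence_t1
    if not 0.0 < p1 < 1.0:
        raise ValueError(
            f"implied T1 prevalence {p1:.3f} outside (0, 1); check "
            "improvement_rate / worsening_rate")
    cut = CLINICAL_CUTOFF - 0.5
    weib_t0 = _solve_weibull(config.target_t0_mean, p0, cut)
    weib_t1 = _solve_weibull(config.target_t1_mean, p1, cut)

    if config.sex_effect is None:
        d_f, d_m = _solve_sex_shift(config.prevalence_female,
                                    config.prevalence_male, config.p_female)
    else:
        d_f = float(config.sex_effect)
        d_m = config.p_female * d_f / (1.0 - config.p_female)

    partial = CohortCalibration(
        weibull_t0=weib_t0, weibull_t1=weib_t1, shift_f=d_f, shift_m=d_m,
        rho=0.0, c0=0.0, c1=0.0, shuffle_fraction=0.0,
        p_female=config.p_female)
    c0 = partial.mix_ppf(1.0 - p0)
    c1 = partial.mix_ppf(1.0 - p1)

    both_clinical = p0 - config.improvement_rate
    if both_clinical <= 0:
        raise ValueError("improvement_rate exceeds the T0 prevalence")
    shifts = [(config.p_female, d_f), (1.0 - config.p_female, -d_m)]

    def gap(r: float) -> float:
        return _orthant(r, c0, c1, shifts) - both_clinical

    lo, hi = -0.999, 0.999
    if gap(lo) * gap(hi) > 0:
        raise ValueError(
            "transition-table targets are incompatible with the marginal "
            "prevalences: no copula correlation reproduces them")
    rho = optimize.brentq(gap, lo, hi, xtol=1e-10)

    partial = replace(partial, rho=rho, c0=c0, c1=c1)
    rs_full = _spearman_quadrature(rho, partial, stratum_average=False)
    rs_shuffled = _spearman_quadrature(rho, partial, stratum_average=True)
    target = config.rho_t0_t1
    if abs(rs_full - rs_shuffled) < 1e-12:
        pi = 0.0
    else:
        pi = (rs_full - target) / (rs_full - rs_shuffled)
    if pi < -1e-6 or pi > 1.0 + 1e-6:
        raise ValueError(
            f"Spearman target rho_t0_t1={target} is infeasible: the "
            f"transition table constrains the achievable range to "
            f"[{rs_shuffled:.3f}, {rs_full:.3f}]")
    pi = float(np.clip(pi, 0.0, 1.0))
    return replace(partial, shuffle_fraction=pi)


# ---------------------------------------------------------------------------
# item allocation
# ---------------------------------------------------------------------------

def _allocate_items(rng: np.random.Generator, totals: np.ndarray,
                    n_items: int, lo: int, hi: int) -> np.ndarray:
    """Distribute each integer total over ``n_items`` items in [lo, hi].

    Items receive the baseline ``lo`` plus a capacity-constrained urn
    allocation of the remaining ``total - n_items*lo`` points, which is
    exchangeable across items and reproduces the total exactly.
    """
    cap = hi - lo
    colors = [cap] * n_items
    out = np.empty((len(totals), n_items), dtype=np.int64)
    for i, t in enumerate(np.asarray(totals, dtype=np.int64)):
        surplus = int(t) - n_items * lo
        if surplus < 0 or surplus > n_items * cap:
            raise ValueError(f"total {t} not reachable with {n_items} items "
                             f"in [{lo}, {hi}]")
        out[i] = rng.multivariate_hypergeometric(colors, surplus)
    return out + lo


def _graded_items(rng: np.random.Generator, trait: np.ndarray, n_items: int,
                  loading: float, n_levels: int) -> np.ndarray:
    """Ordinal items from a noisy trait copy, thresholded at equal-mass cuts."""
    cuts = stats.norm.ppf(np.arange(1, n_levels) / n_levels)
    resid = math.sqrt(max(1.0 - loading * loading, 0.0))
    out = np.empty((trait.shape[0], n_items), dtype=np.int64)
    for j in range(n_items):
        latent = loading * trait + resid * rng.standard_normal(trait.shape[0])
        out[:, j] = discretize_to_likert(latent, n_levels, cuts)
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _depression_scores(config: GeneratorConfig, cal: CohortCalibration,
                       sex_is_f: np.ndarray, seed: int
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """T0/T1 integer sum scores plus the standardized post-shuffle T1 trait."""
    n = sex_is_f.shape[0]
    d = np.where(sex_is_f, cal.shift_f, -cal.shift_m)

    rng_dep = child_rng(seed, "depression")
    z = rng_dep.standard_normal((n, 2))
    z0 = z[:, 0] + d
    z1 = cal.rho * z[:, 0] + math.sqrt(1.0 - cal.rho ** 2) * z[:, 1] + d

    # within-stratum shuffle of the T1 latent (see module docstring)
    rng_sh = child_rng(seed, "shuffle")
    selected = rng_sh.random(n) < cal.shuffle_fraction
    hi = z1 >= cal.c1
    for mask in (hi & selected, (~hi) & selected):
        idx = np.flatnonzero(mask)
        if idx.size > 1:
            z1[idx] = z1[rng_sh.permutation(idx)]

    u0 = cal.mix_cdf(z0)
    u1 = cal.mix_cdf(z1)
    c0w, l0 = cal.weibull_t0
    c1w, l1 = cal.weibull_t1
    x0_cont = stats.weibull_min.ppf(u0, c0w, scale=l0) + config.t0_location_shift
    x1_cont = stats.weibull_min.ppf(u1, c1w, scale=l1)
    x0 = np.clip(np.round(x0_cont), 0, 60).astype(np.int64)
    x1 = np.clip(np.round(x1_cont), 0, 60).astype(np.int64)
    z1_std = stats.norm.ppf(np.clip(u1, 1e-12, 1.0 - 1e-12))
    return x0, x1, z1_std


def generate_cohort(config: GeneratorConfig,
                    schema: QuestionnaireSchema | None = None) -> CohortTable:
    """Generate a complete synthetic cohort under ``config`` and ``schema``.

    Deterministic given ``config`` (including its seed).  Every stored
    scale score is exactly recomputable from the generated items.
    """
    if schema is None:
        schema = default_schema()
    n = config.n_patients
    seed = config.seed
    cal = calibrate(config)

    rng_sex = child_rng(seed, "sex")
    sex_is_f = rng_sex.random(n) < config.p_female

    x0, x1, z1_std = _depression_scores(config, cal, sex_is_f, seed)

    # instrument traits, conditioned on the post-treatment depression trait
    spearman_to_pearson = lambda rs: 2.0 * math.sin(math.pi * rs / 6.0)
    b_tq = spearman_to_pearson(config.corr_t1_tq)
    b_psq = spearman_to_pearson(config.corr_t1_psq)
    b_sf8 = spearman_to_pearson(config.corr_t1_sf8)
    resid_corr = np.array([
        [1.00, 0.20, -0.15],
        [0.20, 1.00, -0.30],
        [-0.15, -0.30, 1.00],
    ])
    rng_traits = child_rng(seed, "traits")
    eta = sample_latent_traits(n, resid_corr, seed=0, rng=rng_traits)
    z_tin = b_tq * z1_std + math.sqrt(1 - b_tq ** 2) * eta[:, 0]
    z_stress = b_psq * z1_std + math.sqrt(1 - b_psq ** 2) * eta[:, 1]
    z_health = b_sf8 * z1_std + math.sqrt(1 - b_sf8 ** 2) * eta[:, 2]

    # instrument totals (discretised, range-clipped normal marginals)
    tq_total = np.clip(np.round(config.tq_mean + config.tq_sd * z_tin),
                       0, 84).astype(np.int64)
    psq_raw = np.clip(np.round(config.psq_raw_mean
                               + config.psq_raw_sd * z_stress),
                      30, 120).astype(np.int64)
    sf8_sum = np.clip(np.round(config.sf8_sum_mean
                               + config.sf8_sum_sd * z_health),
                      0, 40).astype(np.int64)

    # items: allocate score-bearing totals; grade the rest from the trait
    loadings = dict(_default_loadings(), **dict(config.latent_loadings))
    rng_items = child_rng(seed, "items")
    adsl_t0 = _allocate_items(rng_items, x0, 20, 0, 3)
    adsl_t1 = _allocate_items(rng_items, x1, 20, 0, 3)
    tq_scored = _allocate_items(rng_items, tq_total, 42, 0, 2)
    tq_rest = _graded_items(rng_items, z_tin, 10,
                            loadings["tinnitus_distress"], 3)
    psq_items = _allocate_items(rng_items, psq_raw, 30, 1, 4)
    sf8_items = _allocate_items(rng_items, sf8_sum, 8, 0, 5)
    tlq_items = _graded_items(rng_items, z_tin, 15,
                              0.6 * loadings["tinnitus_distress"], 4)

    lam_vas = loadings["tinnitus_distress"]

    def vas(coupling: float) -> np.ndarray:
        latent = (coupling * z_tin
                  + math.sqrt(1 - coupling ** 2) * rng_items.standard_normal(n))
        return np.clip(np.round(5.5 + 2.3 * latent), 0, 10).astype(np.int64)

    tin_loudness = vas(0.5 * lam_vas)
    tin_frequency = vas(0.45 * lam_vas)
    tin_distress = vas(lam_vas)

    # socio-demographics
    rng_cov = child_rng(seed, "covariates")
    priors = dict(_default_priors(), **dict(config.categorical_priors))

    def draw_cat(field_name: str, levels: Sequence[str]) -> np.ndarray:
        p = np.asarray(priors[field_name], dtype=float)
        if p.shape[0] != len(levels):
            raise ValueError(
                f"prior for {field_name!r} has {p.shape[0]} entries but the "
                f"schema declares {len(levels)} levels")
        return rng_cov.choice(np.asarray(levels, dtype=object), size=n, p=p)

    cat_cols: dict[str, np.ndarray] = {}
    for cat in schema.categoricals:
        if cat.column == "sex":
            cat_cols["sex"] = np.where(sex_is_f, "F", "M").astype(object)
        else:
            cat_cols[cat.column] = draw_cat(cat.column, cat.levels)

    age = np.round(np.clip(
        config.age_mean + config.age_sd * rng_cov.standard_normal(n),
        18.0, 95.0), 1)
    # log-normal tinnitus duration with mode ~5 years
    tindur = np.round(np.clip(
        np.exp(math.log(5.0) + 0.64 + 0.8 * rng_cov.standard_normal(n)),
        0.3, 40.0), 1)
    days_to_treatment = np.round(np.clip(
        np.exp(1.6 + 1.1 * rng_cov.standard_normal(n)), 0.0, 365.0), 0)

    data: dict[str, np.ndarray] = {
        CohortTable.ID_COLUMN: np.array(
            [f"P{i:05d}" for i in range(1, n + 1)], dtype=object),
    }
    for cat in schema.categoricals:
        data[cat.column] = cat_cols[cat.column]
    data["age"] = age
    data["tindur"] = tindur
    data["days_to_treatment"] = days_to_treatment

    def add_items(prefix_cols: Sequence[str], matrix: np.ndarray) -> None:
        for j, col in enumerate(prefix_cols):
            data[col] = matrix[:, j]

    ins = {i.name: i for i in schema.instruments}
    add_items(ins["ADSL"].items, adsl_t0)
    add_items(ins["PSQ"].items, psq_items)
    add_items(ins["SF8"].items, sf8_items)
    add_items(ins["TQ"].items, np.hstack([tq_scored, tq_rest]))
    data["loudness"] = tin_loudness
    data["frequency"] = tin_frequency
    data["distress"] = tin_distress
    add_items(ins["TLQ"].items, tlq_items)
    add_items([f"adsl_t1_{i:02d}" for i in range(1, 21)], adsl_t1)

    # derived sums, recomputed from the items they summarise
    data["adsl_sum_t0"] = adsl_t0.sum(axis=1)
    data["adsl_sum_t1"] = adsl_t1.sum(axis=1)
    data["tq_total"] = tq_scored.sum(axis=1)
    data["psq_total"] = (psq_items.sum(axis=1) - 30) / 90.0

    return CohortTable(pd.DataFrame(data))


def inject_missingness(table: CohortTable, rate: float,
                       seed: int) -> CohortTable:
    """Flag a random ``rate`` fraction of value cells as missing (NaN)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("missingness rate must lie in [0, 1]")
    out = table.copy()
    if rate == 0.0:
        return out
    cols = out.value_columns()
    rng = child_rng(seed, "missingness")
    mask = rng.random((out.n, len(cols))) < rate
    block = out.data[cols].astype(object).to_numpy()
    block[mask] = np.nan
    for j, c in enumerate(cols):
        out.data[c] = block[:, j]
    return out


def verify_scale_consistency(table: CohortTable) -> None:
    """Assert that every stored sum score matches its items exactly."""
    df = table.data
    adsl_t0 = df[[f"adsl{i:02d}" for i in range(1, 21)]].to_numpy(float)
    adsl_t1 = df[[f"adsl_t1_{i:02d}" for i in range(1, 21)]].to_numpy(float)
    tq = df[[f"tq{i:02d}" for i in range(1, 43)]].to_numpy(float)
    psq = df[[f"psq{i:02d}" for i in range(1, 31)]].to_numpy(float)
    checks = {
        "adsl_sum_t0": adsl_t0.sum(axis=1),
        "adsl_sum_t1": adsl_t1.sum(axis=1),
        "tq_total": tq.sum(axis=1),
        "psq_total": (psq.sum(axis=1) - 30) / 90.0,
    }
    for col, expected in checks.items():
        stored = df[col].to_numpy(float)
        if not np.allclose(stored, expected, atol=1e-12, equal_nan=True):
            raise AssertionError(f"stored {col} disagrees with its items")


# ---------------------------------------------------------------------------
# planted-truth generator for feature-selection experiments
# ---------------------------------------------------------------------------

def make_planted_classification(n: int = 1000, n_signal: int = 5,
                                n_noise: int = 45, beta: float = 0.9,
                                seed: int = 0
                                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Binary outcome driven by ``n_signal`` planted features plus pure noise.

    Features are i.i.d. standard normal; the outcome follows a logistic
    model with coefficient ``beta`` on every planted feature and 0 on the
    noise block.  Used to probe whether the feature-selection wrapper
    recovers the planted features and discards the noise.
    """
    rng = child_rng(seed, "planted")
    cols = ([f"signal{i:02d}" for i in range(1, n_signal + 1)]
            + [f"noise{i:02d}" for i in range(1, n_noise + 1)])
    X = pd.DataFrame(rng.standard_normal((n, len(cols))), columns=cols)
    eta = beta * X.iloc[:, :n_signal].sum(axis=1).to_numpy()
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(np.int64)
    if y.min() == y.max():  # pragma: no cover - vanishingly unlikely
        y[0] = 1 - y[0]
    return X, y
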