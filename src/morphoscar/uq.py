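"""Age-group Monte Carlo feasibility machinery.

Spatial heterogeneity of skin is modeled by giving a subset of parameters
lognormal random fields: a zero-mean, approximately unit-variance Gaussian
process is drawn from a normalized truncated Karhunen-Loeve sine expansion,

    u_hat(X) = sum_{j=1..n} Z_j * sqrt(2/n) * sin((2j-1) * pi/(2*|O|) * X),

with iid standard-normal Z_j, and a parameter with arithmetic mean mu and
sd sigma becomes exp(M + S*u_hat(X)) where (M, S) are the log-scale moments
matching (mu, sigma).  Cohorts of patients are simulated per age group and
compared with an equal-sample-size two-group t statistic, kernel density
estimates, empirical CDFs, and confidence intervals for the mean.

Reproducibility contract: every sample's random stream is derived from
(base seed, group id, sample index), so cohort results are bit-identical
regardless of worker count or scheduling.
"""

from __future__ import annotations

import importlib.resources as importlib_resources
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .fem import NumericsConfig, build_mesh, simulate
from .observables import summarize_trajectory
from .params import (ParameterSet, InvalidParameterError, validate_parameters)

logger = logging.getLogger(__name__)

__all__ = [
    "KLSpec", "AgeGroupSpec", "CohortResult", "kl_realization",
    "lognormal_moments", "heterogeneous_field", "sample_patient",
    "run_cohort", "kde_and_ecdf", "group_t_test", "confidence_interval",
    "load_age_groups", "TTestResult",
]


@dataclass
class KLSpec:
    """Truncation and geometry of the Karhunen-Loeve sine expansion."""

    n_terms: int = 60
    domain_length: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 1:
            raise ValueError("n_terms must be >= 1")


def kl_realization(spec: KLSpec, X: np.ndarray,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One realization of the normalized KL field at coordinates ``X``.

    The field is exactly zero at X = 0 for every draw (all sine terms
    vanish), has zero mean over draws, and unit variance when the pointwise
    variance is averaged over the domain.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    X = np.asarray(X, dtype=float)
    j = np.arange(1, spec.n_terms + 1)
    Z = rng.standard_normal(spec.n_terms)
    phases = (2 * j - 1) * np.pi / (2.0 * spec.domain_length)
    return np.sqrt(2.0 / spec.n_terms) * np.sin(np.outer(X, phases)) @ Z


def lognormal_moments(mu_arith: float, sigma_arith: float) -> tuple:
    """Log-scale (M, S) of a lognormal with arithmetic mean and sd given.

    Round-trip property: exp(M + S*Z), Z ~ N(0,1), has arithmetic mean
    ``mu_arith`` and arithmetic sd ``sigma_arith``.
    """
    mu_arith = np.asarray(mu_arith, dtype=float)
    if np.any(mu_arith <= 0):
        raise InvalidParameterError("lognormal mean must be positive")
    if np.any(np.asarray(sigma_arith) < 0):
        raise InvalidParameterError("lognormal sd must be non-negative")
    cv2 = np.asarray(sigma_arith, dtype=float) ** 2 / mu_arith ** 2
    M = np.log(mu_arith / np.sqrt(1.0 + cv2))
    S = np.sqrt(np.log(1.0 + cv2))
    if M.ndim == 0:
        return float(M), float(S)
    return M, S


def heterogeneous_field(mu_arith: float, sigma_arith: float,
                        u_hat: np.ndarray) -> np.ndarray:
    """Lognormal parameter field exp(M + S*u_hat); strictly positive,
    constant mu for sigma = 0."""
    M, S = lognormal_moments(mu_arith, sigma_arith)
    return np.exp(M + S * np.asarray(u_hat, dtype=float))


@dataclass
class AgeGroupSpec:
    """Means, heterogeneity sds, and the heterogeneous-parameter list for
    one age group."""

    group_id: int
    age_range: tuple
    means: ParameterSet
    sd: dict = dc_field(default_factory=dict)   # arithmetic sd per field name
    heterogeneous: Sequence[str] = ()

    def __post_init__(self):
        for name, val in self.sd.items():
            if val < 0:
                raise InvalidParameterError(f"sd for {name} must be >= 0")


def load_age_groups(path: str | Path | None = None,
                    base: ParameterSet = None) -> dict:
    """Build the four AgeGroupSpec objects from the (editable) YAML table.

    Group means are the healthy-adult defaults scaled by per-group
    multipliers; the equilibrium collagen concentration declines
    exponentially with the group's collagen age.  Wound values (including
    the initial wound collagen, 20% of the adult mean) and the secretion
    rate k_c are shared by all groups.
    """
    base = base or ParameterSet()
    if path is None:
        ref = importlib_resources.files("morphoscar") / "data/age_groups.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    ref_age = raw["reference_age"]
    decline = raw["collagen_decline_per_year"]
    het_names = tuple(raw["heterogeneous"]["parameters"])
    sd_frac = raw["heterogeneous"]["sd_fraction"]
    groups = {}
    for gid, g in raw["groups"].items():
        gid = int(gid)
        changes = {name: getattr(base, name) * mult
                   for name, mult in (g.get("multipliers") or {}).items()}
        age = g["collagen_age"]
        changes["rho_bar"] = base.rho_bar * (1.0 - decline) ** (age - ref_age)
        means = base.replace(**changes)
        sd = {name: sd_frac * float(np.asarray(getattr(means, name)).mean())
              for name in het_names}
        groups[gid] = AgeGroupSpec(group_id=gid,
                                   age_range=tuple(g["age_range"]),
                                   means=means, sd=sd,
                                   heterogeneous=het_names)
    return groups


def sample_patient(group: AgeGroupSpec, kl: KLSpec, seed,
                   x: np.ndarray = None,
                   numerics: NumericsConfig = None,
                   shared_field: bool = False) -> ParameterSet:
    """Draw one patient: heterogeneous parameters become nodal lognormal
    fields on the simulation mesh, the rest take the group means.

    Independent KL fields are drawn per parameter by default
    (``shared_field=True`` reuses one field for all).  Realizations that
    violate a hard stability bound are resampled, at most 10 times.
    """
    if x is None:
        numerics = numerics or NumericsConfig()
        x = build_mesh(group.means.L, group.means.L_w, numerics)
    rng = np.random.default_rng(
        np.random.SeedSequence(_as_entropy(seed)))
    for attempt in range(10):
        changes = {}
        u_shared = kl_realization(kl, x, rng) if shared_field else None
        for name in group.heterogeneous:
            sigma = group.sd.get(name, 0.0)
            mu = float(np.asarray(getattr(group.means, name)).mean())
            if sigma == 0.0:
                continue
            u_hat = u_shared if shared_field else kl_realization(kl, x, rng)
            changes[name] = heterogeneous_field(mu, sigma, u_hat)
        p = group.means.replace(**changes)
        report = validate_parameters(p)
        if report.ok:
            return p
        logger.info("patient resample %d for group %d: %s", attempt + 1,
                    group.group_id, report.violations)
    raise InvalidParameterError(
        f"could not draw a stable parameter field for group "
        f"{group.group_id} after 10 attempts")


def _as_entropy(seed):
    if isinstance(seed, (tuple, list)):
        return [int(s) for s in seed]
    return int(seed)


@dataclass
class CohortResult:
    """Per-sample summaries of one simulated age-group cohort."""

    group_id: int
    n_b: int
    base_seed: int
    summaries: pd.DataFrame   # one row per sample, the five scalar outputs
    failures: int = 0


def _one_patient(group: AgeGroupSpec, kl: KLSpec, seed_tuple,
                 numerics: NumericsConfig, shared_field: bool) -> dict:
    try:
        x = build_mesh(group.means.L, group.means.L_w, numerics)
        p = sample_patient(group, kl, seed_tuple, x=x,
                          shared_field=shared_field)
        traj = simulate(p, numerics)
        row = summarize_trajectory(traj).to_dict()
        row["error"] = ""
    except Exception as exc:
        logger.warning("cohort sample %s failed: %s", seed_tuple, exc)
        row = {k: np.nan for k in
               ("RSA_min", "RSA_day", "RSA_365", "SED_max", "SED_day")}
        row["error"] = str(exc)
    return row


def run_cohort(group: AgeGroupSpec, n_b: int, base_seed: int,
               numerics: NumericsConfig = None, kl: KLSpec = None,
               n_jobs: int = 1, shared_field: bool = False) -> CohortResult:
    """Simulate ``n_b`` patients of one age group on the half domain.

    Per-sample seeds are derived from (base_seed, group id, index), so the
    result is bit-identical for any worker count.  Failed samples are
    excluded with a logged count.
    """
    numerics = numerics or NumericsConfig()
    kl = kl or KLSpec(domain_length=group.means.L)
    seeds = [(base_seed, group.group_id, i) for i in range(n_b)]
    if n_jobs != 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=n_jobs)(
            delayed(_one_patient)(group, kl, s, numerics, shared_field)
            for s in seeds)
    else:
        rows = [_one_patient(group, kl, s, numerics, shared_field)
                for s in seeds]
    df = pd.DataFrame(rows)
    df.insert(0, "sample", np.arange(n_b))
    failures = int((df["error"] != "").sum())
    return CohortResult(group_id=group.group_id, n_b=n_b,
                        base_seed=base_seed, summaries=df, failures=failures)


# --- statistical reporting -------------------------------------------------

def kde_and_ecdf(samples: np.ndarray, grid: np.ndarray = None) -> dict:
    """Gaussian-kernel density (Silverman bandwidth) and right-continuous
    ECDF of a sample.

    A degenerate (zero-variance) sample gets an ECDF only; the KDE is
    refused because its bandwidth is undefined.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    xs = np.sort(samples)
    ecdf_y = np.arange(1, xs.size + 1) / xs.size
    out = {"ecdf_x": xs, "ecdf_y": ecdf_y, "grid": None, "pdf": None}
    if np.ptp(samples) == 0.0:
        return out
    kde = stats.gaussian_kde(samples, bw_method="silverman")
    if grid is None:
        lo, hi = xs[0], xs[-1]
        pad = 0.25 * (hi - lo)
        grid = np.linspace(lo - pad, hi + pad, 512)
    out["grid"] = grid
    out["pdf"] = kde(grid)
    return out


@dataclass
class TTestResult:
    t: float
    critical: float
    df: int
    alpha: float
    reject: bool

    def to_dict(self) -> dict:
        return {"t": self.t, "critical": self.critical, "df": self.df,
                "alpha": self.alpha, "reject": self.reject}


def group_t_test(A: np.ndarray, B: np.ndarray,
                 alpha: float = 0.001) -> TTestResult:
    """Equal-sample-size two-group t statistic.

    t = (mean(A) - mean(B)) / s_p with s_p = sqrt((s_a^2 + s_b^2)/n_b),
    rejected when |t| exceeds the upper alpha/2 quantile of the
    t-distribution with 2*(n_b - 1) degrees of freedom.  With n_b = 1950
    and alpha = 0.001 the critical value is 3.293.
    """
    A, B = np.asarray(A, dtype=float), np.asarray(B, dtype=float)
    if A.size != B.size:
        raise ValueError("the test assumes equal sample sizes")
    n_b = A.size
    if n_b < 2:
        raise ValueError("need at least 2 samples per group")
    s_p = np.sqrt((A.var(ddof=1) + B.var(ddof=1)) / n_b)
    t = float((A.mean() - B.mean()) / s_p) if s_p > 0 else (
        0.0 if A.mean() == B.mean() else float("inf"))
    df = 2 * (n_b - 1)
    crit = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    return TTestResult(t=t, critical=crit, df=df, alpha=alpha,
                       reject=bool(abs(t) > crit))


def confidence_interval(samples: np.ndarray, level: float = 0.95) -> tuple:
    """t-based confidence interval for the mean: m +/- t_{n-1} * sd/sqrt(n)."""
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    m = samples.mean()
    half = (stats.t.ppf(0.5 + level / 2.0, n - 1)
            * samples.std(ddof=1) / np.sqrt(n))
    return float(m - half), float(m + half)
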