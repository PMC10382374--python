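"""Synthetic stand-in for the 20-patient transdermal-fentanyl sample cohort.

The original cohort of cancer patients on fentanyl patches is available only
as printed summary statistics: per-covariate means and standard deviations,
a 10/10 gender split, ages between 40 and 68 years, and three pairwise
correlations (gender-height 0.87, gender-weight 0.43, weight-height 0.38,
with gender coded 1 = male, 0 = female).  ``generate_sample_cohort`` builds a
cohort whose *empirical* moments and Pearson correlations equal those targets
exactly: gender is fixed at half male / half female, residuals orthogonal
to gender (Gaussian, except an edge-weighted age residual implied by the
printed age range) are rotated to the target residual correlation
structure, and an affine rescaling pins the sample means and SDs.  The
construction is deterministic given the seed; a whole-cohort rejection loop
enforces the printed age range and physiological weight/height/BMI bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AGE_BOUNDS = (18.0, 100.0)
WEIGHT_BOUNDS = (30.0, 150.0)
HEIGHT_BOUNDS = (1.2, 2.2)
BMI_BOUNDS = (15.0, 45.0)

#: Printed sample summary: mean and SD for age [y], weight [kg], height [m].
SAMPLE_MOMENTS = {
    "age": (56.75, 9.82),
    "weight": (72.8, 14.8),
    "height": (1.70, 0.12),
}
#: Printed point-biserial correlations of the 0/1 gender code with the
#: continuous covariates; the gender-age correlation is not printed and is
#: taken as zero.
SAMPLE_GENDER_CORR = {"age": 0.0, "weight": 0.43, "height": 0.87}
#: Printed weight-height correlation; the age-weight and age-height
#: correlations are not printed and are taken as zero.
SAMPLE_CROSS_CORR = {("age", "weight"): 0.0, ("age", "height"): 0.0, ("weight", "height"): 0.38}
SAMPLE_AGE_RANGE = (40.0, 68.0)

_CONTINUOUS = ("age", "weight", "height")
COHORT_COLUMNS = ("id", "age_years", "gender", "weight_kg", "height_m")


@dataclass(frozen=True)
class PatientProfile:
    """One virtual patient's covariates.

    gender is an indicator: 1 = male, 0 = female.
    """

    age: float
    gender: int
    weight: float
    height: float

    def __post_init__(self) -> None:
        if not AGE_BOUNDS[0] <= self.age <= AGE_BOUNDS[1]:
            raise ValueError(f"age {self.age} outside {AGE_BOUNDS}")
        if self.gender not in (0, 1):
            raise ValueError(f"gender must be 0 or 1, got {self.gender}")
        if not WEIGHT_BOUNDS[0] <= self.weight <= WEIGHT_BOUNDS[1]:
            raise ValueError(f"weight {self.weight} outside {WEIGHT_BOUNDS}")
        if not HEIGHT_BOUNDS[0] <= self.height <= HEIGHT_BOUNDS[1]:
            raise ValueError(f"height {self.height} outside {HEIGHT_BOUNDS}")

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2


@dataclass
class CohortSummary:
    """Exact sample moments of a cohort (SD uses denominator n-1).

    ``pearson`` is the 4x4 Pearson matrix over (age, gender, weight, height)
    with gender treated as 0/1 numeric; entries involving a zero-variance
    column are reported as missing (NaN), never as zero.
    """

    n: int
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    male_count: int = 0
    female_count: int = 0
    pearson: pd.DataFrame | None = None


def cohort_to_frame(cohort: Sequence[PatientProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": [p.age for p in cohort],
            "gender": [p.gender for p in cohort],
            "weight": [p.weight for p in cohort],
            "height": [p.height for p in cohort],
        }
    )


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientProfile]:
    return [
        PatientProfile(
            age=float(r.age), gender=int(r.gender), weight=float(r.weight), height=float(r.height)
        )
        for r in frame.itertuples()
    ]


def write_cohort_csv(cohort: Sequence[PatientProfile], path: str | Path) -> None:
    """Write a cohort as CSV with header id,age_years,gender,weight_kg,height_m."""
    frame = cohort_to_frame(cohort)
    out = pd.DataFrame(
        {
            "id": np.arange(len(frame)),
            "age_years": frame["age"],
            "gender": frame["gender"],
            "weight_kg": frame["weight"],
            "height_m": frame["height"],
        }
    )
    out.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[PatientProfile]:
    raw = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"cohort CSV {path} is missing columns {sorted(missing)}")
    frame = raw.rename(
        columns={"age_years": "age", "weight_kg": "weight", "height_m": "height"}
    )
    return frame_to_cohort(frame)


def _target_correlation() -> tuple[np.ndarray, np.ndarray]:
    """Gender-vs-continuous correlation vector and continuous block."""
    r_g = np.array([SAMPLE_GENDER_CORR[c] for c in _CONTINUOUS])
    r_xx = np.eye(3)
    for (a, b), rho in SAMPLE_CROSS_CORR.items():
        i, j = _CONTINUOUS.index(a), _CONTINUOUS.index(b)
        r_xx[i, j] = r_xx[j, i] = rho
    return r_g, r_xx


def _residual_cholesky(r_g: np.ndarray, r_xx: np.ndarray) -> np.ndarray:
    residual = r_xx - np.outer(r_g, r_g)
    try:
        return np.linalg.cholesky(residual)
    except np.linalg.LinAlgError as exc:
        eigs = np.linalg.eigvalsh(residual)
        raise ValueError(
            "target correlation matrix is not positive semi-definite after "
            f"conditioning on the 0/1 gender code (residual eigenvalues {eigs})"
        ) from exc


def generate_sample_cohort(seed: int, n: int = 20) -> list[PatientProfile]:
    """Deterministically synthesize an n-patient cohort matching the printed
    sample summary exactly (means, SDs, and the three printed correlations).

    The cohort has exactly n/2 males and n/2 females and all ages inside the
    printed 40-68 y range.
    """
    if n % 2:
        raise ValueError("n must be even (half male, half female)")
    if n < 6:
        raise ValueError("need at least 3 patients per gender to pin 3 correlations")
    rng = np.random.default_rng(seed)
    gender = np.repeat([1, 0], n // 2)
    g_std = (gender - gender.mean()) / gender.std(ddof=1)
    r_g, r_xx = _target_correlation()
    chol = _residual_cholesky(r_g, r_xx)
    means = np.array([SAMPLE_MOMENTS[c][0] for c in _CONTINUOUS])
    sds = np.array([SAMPLE_MOMENTS[c][1] for c in _CONTINUOUS])

    # The printed age mean/SD must live inside the printed 40-68 y range;
    # the moment-implied Beta shape has both parameters < 1, i.e. the age
    # distribution of the real cohort is necessarily edge-heavy.  Drawing
    # the age residual from that Beta shape (the other residuals stay
    # Gaussian) makes the bounded rejection step well-conditioned.
    lo, hi = SAMPLE_AGE_RANGE
    mu = (SAMPLE_MOMENTS["age"][0] - lo) / (hi - lo)
    var = (SAMPLE_MOMENTS["age"][1] / (hi - lo)) ** 2
    nu = mu * (1 - mu) / var - 1
    if nu <= 0:
        raise ValueError("printed age SD is incompatible with the printed age range")
    alpha, beta = mu * nu, (1 - mu) * nu

    for _ in range(10_000):
        raw = rng.standard_normal((n, 3))
        raw[:, 0] = rng.beta(alpha, beta, size=n)
        # Project out the constant and gender directions, then whiten so the
        # residual columns are exactly orthonormal (scaled to ddof=1).
        raw -= raw.mean(axis=0)
        raw -= np.outer(g_std, g_std @ raw) / (n - 1)
        cov = raw.T @ raw
        try:
            basis = raw @ np.linalg.inv(np.linalg.cholesky(cov)).T * np.sqrt(n - 1)
        except np.linalg.LinAlgError:  # degenerate draw; retry
            continue
        x_std = np.outer(g_std, r_g) + basis @ chol.T
        values = means + sds * x_std
        age, weight, height = values.T
        bmi = weight / height**2
        if (
            (age >= SAMPLE_AGE_RANGE[0]).all()
            and (age <= SAMPLE_AGE_RANGE[1]).all()
            and (weight >= WEIGHT_BOUNDS[0]).all()
            and (weight <= WEIGHT_BOUNDS[1]).all()
            and (height >= HEIGHT_BOUNDS[0]).all()
            and (height <= HEIGHT_BOUNDS[1]).all()
            and (bmi >= BMI_BOUNDS[0]).all()
            and (bmi <= BMI_BOUNDS[1]).all()
        ):
            return [
                PatientProfile(age=float(a), gender=int(g), weight=float(w), height=float(h))
                for a, g, w, h in zip(age, gender, weight, height)
            ]
    raise RuntimeError(
        "could not draw a cohort satisfying the age/weight/height/BMI bounds; "
        "the requested moments may be incompatible with the bounds"
    )


def summarize_cohort(cohort: Sequence[PatientProfile]) -> CohortSummary:
    """Exact sample moments and Pearson matrix of a cohort.

    Correlations involving a constant column (e.g. gender in a single-gender
    cohort) are undefined and reported as NaN.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    frame = cohort_to_frame(cohort)[["age", "gender", "weight", "height"]].astype(float)
    mean = frame.mean()
    sd = frame.std(ddof=1) if len(frame) > 1 else frame.std(ddof=0) * np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        pearson = frame.corr()
    male = int((frame["gender"] == 1).sum())
    return CohortSummary(
        n=len(frame),
        mean=mean.to_dict(),
        sd=sd.to_dict(),
        male_count=male,
        female_count=len(frame) - male,
        pearson=pearson,
    )
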