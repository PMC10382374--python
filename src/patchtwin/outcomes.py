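"""Per-patient outcome metrics and population-level therapy comparison.

"Time without pain" is the cumulative duration with VAS strictly below 3
over the horizon, computed by linear interpolation of the hourly series
at threshold crossings (so it is insensitive to the output-grid step).
The replacement controller, by contrast, triggers on VAS strictly above
3, so values exactly at the target neither count as pain-free nor trigger
a patch change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .therapy import SimulationResult


@dataclass
class OutcomeSummary:
    """One patient's therapy outcome over the simulation horizon."""

    max_c_p: float
    min_vas: float
    mean_vas: float
    min_ventilation: float
    mean_ventilation: float
    time_without_pain_total: float
    time_without_pain_longest: float
    n_patches: int
    exceeded_toxicity: bool
    hypoventilation: bool


def _below_threshold_intervals(
    t: np.ndarray, v: np.ndarray, threshold: float
) -> list[tuple[float, float]]:
    """Maximal intervals where the piecewise-linear v(t) is strictly below
    the threshold, with crossing times located by linear interpolation."""
    below = v < threshold
    intervals: list[tuple[float, float]] = []
    start: float | None = None
    for i in range(len(t) - 1):
        t0, t1, v0, v1 = t[i], t[i + 1], v[i], v[i + 1]
        if below[i] and start is None:
            start = t0
        if below[i] != below[i + 1]:
            # locate the crossing inside [t0, t1]
            tc = t0 + (threshold - v0) / (v1 - v0) * (t1 - t0)
            if below[i]:  # leaving the pain-free region
                intervals.append((start if start is not None else t0, tc))
                start = None
            else:  # entering it
                start = tc
    if below[-1]:
        intervals.append((start if start is not None else t[-1], t[-1]))
    return [(a, b) for a, b in intervals if b > a]


def time_without_pain(
    t: np.ndarray, vas: np.ndarray, threshold: float = 3.0
) -> tuple[float, float]:
    """(total, longest-contiguous) duration with VAS below the threshold."""
    intervals = _below_threshold_intervals(np.asarray(t, float), np.asarray(vas, float), threshold)
    if not intervals:
        return 0.0, 0.0
    lengths = [b - a for a, b in intervals]
    return float(sum(lengths)), float(max(lengths))


def patient_outcomes(result: SimulationResult, thresholds: dict) -> OutcomeSummary:
    """Extrema over the hourly grid plus interpolated pain-free durations."""
    s = result.series
    pain_threshold = float(thresholds.get("pain_free_vas", 3.0))
    toxicity = float(thresholds.get("toxicity_ng_ml", 2.0))
    hypovent = float(thresholds.get("hypoventilation_L_min", 4.0))
    total, longest = time_without_pain(
        s["time_h"].to_numpy(), s["vas"].to_numpy(), pain_threshold
    )
    return OutcomeSummary(
        max_c_p=float(s["c_p_ng_ml"].max()),
        min_vas=float(s["vas"].min()),
        mean_vas=float(s["vas"].mean()),
        min_ventilation=float(s["ventilation_L_min"].min()),
        mean_ventilation=float(s["ventilation_L_min"].mean()),
        time_without_pain_total=total,
        time_without_pain_longest=longest,
        n_patches=result.n_patches,
        exceeded_toxicity=bool(s["c_p_ng_ml"].max() > toxicity),
        hypoventilation=bool(s["ventilation_L_min"].min() < hypovent),
    )


def outcomes_table(
    patients: pd.DataFrame, summaries: list[OutcomeSummary]
) -> pd.DataFrame:
    """Join patient covariates with their outcome summaries.

    ``patients`` needs columns age, gender, weight, height (one row per
    summary, in order).
    """
    if len(patients) != len(summaries):
        raise ValueError("one covariate row per outcome summary required")
    out = patients.reset_index(drop=True).copy()
    out["bmi"] = out["weight"] / out["height"] ** 2
    for name in OutcomeSummary.__dataclass_fields__:
        out[name] = [getattr(s, name) for s in summaries]
    return out


def _dispersion(x: pd.Series) -> dict:
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "mean": float(x.mean()),
        "sd": float(x.std(ddof=1)),
        "median": float(x.median()),
        "iqr": float(q3 - q1),
    }


def population_compare(
    conventional: pd.DataFrame,
    twin: pd.DataFrame,
    horizon_h: float = 72.0,
) -> dict:
    """Paired conventional-vs-twin comparison over the same patients.

    Reports percent changes of population mean/SD of the average VAS,
    median and IQR of time without pain per arm, the fraction of patients
    pain-free for more than half the horizon, Pearson correlations of
    outcomes with the covariates, and the heavy-user subgroup analysis.
    """
    if len(conventional) != len(twin) or not conventional.index.equals(twin.index):
        raise ValueError("arms must cover the same patients in the same order")
    for col in ("age", "gender", "weight", "height"):
        if not np.allclose(conventional[col], twin[col]):
            raise ValueError(f"arms disagree on patient covariate {col!r}")

    report: dict = {"n": int(len(twin)), "horizon_h": horizon_h, "arms": {}}
    for name, table in (("conventional", conventional), ("twin_assisted", twin)):
        frac_pain_free = float((table["time_without_pain_total"] > horizon_h / 2).mean())
        report["arms"][name] = {
            "mean_vas": _dispersion(table["mean_vas"]),
            "time_without_pain_h": _dispersion(table["time_without_pain_total"]),
            "max_c_p_ng_ml": _dispersion(table["max_c_p"]),
            "mean_ventilation_L_min": _dispersion(table["mean_ventilation"]),
            "fraction_pain_free_half_horizon": frac_pain_free,
            "mean_n_patches": float(table["n_patches"].mean()),
        }
    conv_arm, twin_arm = report["arms"]["conventional"], report["arms"]["twin_assisted"]

    def pct_change(new: float, old: float) -> float | None:
        return None if old == 0 else 100.0 * (new - old) / old

    report["percent_change"] = {
        "mean_vas": pct_change(twin_arm["mean_vas"]["mean"], conv_arm["mean_vas"]["mean"]),
        "sd_vas": pct_change(twin_arm["mean_vas"]["sd"], conv_arm["mean_vas"]["sd"]),
        "mean_c_p": pct_change(
            twin_arm["max_c_p_ng_ml"]["mean"], conv_arm["max_c_p_ng_ml"]["mean"]
        ),
        "mean_ventilation": pct_change(
            twin_arm["mean_ventilation_L_min"]["mean"],
            conv_arm["mean_ventilation_L_min"]["mean"],
        ),
        "iqr_time_without_pain": pct_change(
            twin_arm["time_without_pain_h"]["iqr"], conv_arm["time_without_pain_h"]["iqr"]
        ),
    }
    report["median_time_without_pain_gain_h"] = (
        twin_arm["time_without_pain_h"]["median"] - conv_arm["time_without_pain_h"]["median"]
    )

    covariates = ["age", "weight", "height", "bmi"]
    with np.errstate(divide="ignore", invalid="ignore"):
        # constant outcomes (e.g. n_patches = 1 everywhere under the
        # conventional policy) have undefined correlations -> NaN
        report["correlations"] = {
            arm_name: {
                outcome: {
                    cov: float(table[outcome].corr(table[cov])) for cov in covariates
                }
                for outcome in ("time_without_pain_total", "n_patches", "max_c_p")
            }
            for arm_name, table in (("conventional", conventional), ("twin_assisted", twin))
        }
    report["subgroup_heavy_users"] = subgroup_heavy_users(twin, horizon_h=horizon_h)
    return report


def subgroup_heavy_users(
    twin: pd.DataFrame,
    horizon_h: float = 72.0,
    patches_per_day: float = 1.0,
) -> dict:
    """Patients needing more than ``patches_per_day`` patches per day under
    twin-assisted therapy, compared with the full population.

    Reports both a Welch t-test and a two-sample Kolmogorov-Smirnov test
    per continuous covariate; an empty subgroup yields missing tests, not
    a failure.
    """
    threshold = patches_per_day * horizon_h / 24.0
    subgroup = twin[twin["n_patches"] > threshold]
    report: dict = {
        "threshold_n_patches": threshold,
        "n_subgroup": int(len(subgroup)),
        "n_population": int(len(twin)),
    }

    def fm_ratio(table: pd.DataFrame) -> float | None:
        males = int((table["gender"] == 1).sum())
        return None if males == 0 else float((table["gender"] == 0).sum() / males)

    report["female_male_ratio_population"] = fm_ratio(twin)
    report["female_male_ratio_subgroup"] = fm_ratio(subgroup) if len(subgroup) else None
    tests: dict = {}
    for cov in ("age", "weight", "height"):
        if len(subgroup) < 2:
            tests[cov] = None
            continue
        welch = stats.ttest_ind(subgroup[cov], twin[cov], equal_var=False)
        ks = stats.ks_2samp(subgroup[cov], twin[cov])
        tests[cov] = {
            "mean_shift": float(subgroup[cov].mean() - twin[cov].mean()),
            "welch_p": float(welch.pvalue),
            "ks_p": float(ks.pvalue),
        }
    report["tests"] = tests
    return report
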