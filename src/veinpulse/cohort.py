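"""Subject-level summaries and cohort comparisons.

Vessel-level pulsatility distributions are skewed, so each subject is
summarised by the median across that subject's vessels (pulsatile vessels
only, for PI and lag), and group inference runs on the subject summaries:
one-sample t-tests of lag against zero (Bonferroni over the four vessel
groupings), a paired t-test of PI between small and surface veins, one-way
ANOVAs over vascular territories, and a paired t-test of time-averaged
speed between pulsatile and non-pulsatile veins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["SubjectSummary", "summarize_subject", "group_tests",
           "VEIN_CLASSES", "LAG_GROUPS"]

VEIN_CLASSES = ("small_vein", "surface_vein")
#: vessel groupings for the lag-vs-zero tests (Bonferroni over these four)
LAG_GROUPS = ("small_vein", "surface_vein", "all_veins", "artery")
_TERRITORIES = ("ACA", "L_MCA", "R_MCA", "PCA")


def _median_or_nan(values: pd.Series) -> float:
    values = values.dropna()
    return float(values.median()) if len(values) else float("nan")


@dataclass
class SubjectSummary:
    """Per-subject vessel counts and median pulsatility measures.

    ``median_pi`` and ``median_lag_ms`` are medians over *pulsatile*
    vessels only and are NaN when a grouping has none (missing data).
    ``territory_lag_veins/arteries`` and ``territory_pi_veins`` hold one
    median per territory for the ANOVAs, NaN where the subject has no
    pulsatile vessel in that territory.
    """

    subject: str
    n_vessels: dict[str, int]
    n_pulsatile: dict[str, int]
    median_pi: dict[str, float]
    median_lag_ms: dict[str, float]
    mean_abs_speed_pulsatile: float
    mean_abs_speed_nonpulsatile: float
    territory_lag_veins: dict[str, float]
    territory_lag_arteries: dict[str, float]
    territory_pi_veins: dict[str, float]


def summarize_subject(results: pd.DataFrame, subject: str) -> SubjectSummary:
    """Summarise one subject's per-vessel results table.

    ``results`` needs columns class_label, territory, pcnr, pi, lag_ms,
    pulsatile, mean_abs_speed.  Sinus and discarded clusters are ignored.
    """
    df = results[results["class_label"].isin(("small_vein", "surface_vein",
                                              "artery"))].copy()
    if df.empty:
        raise ValueError(f"no vessels for subject {subject!r}")
    veins = df[df["class_label"].isin(VEIN_CLASSES)]
    puls = df[df["pulsatile"]]
    puls_veins = puls[puls["class_label"].isin(VEIN_CLASSES)]

    def group(frame: pd.DataFrame, name: str) -> pd.DataFrame:
        if name == "all_veins":
            return frame[frame["class_label"].isin(VEIN_CLASSES)]
        return frame[frame["class_label"] == name]

    n_vessels = {g: len(group(df, g)) for g in LAG_GROUPS}
    n_pulsatile = {g: len(group(puls, g)) for g in LAG_GROUPS}
    median_pi = {g: _median_or_nan(group(puls, g)["pi"])
                 for g in ("small_vein", "surface_vein", "all_veins")}
    median_lag = {g: _median_or_nan(group(puls, g)["lag_ms"])
                  for g in LAG_GROUPS}

    nonpuls_veins = veins[~veins["pulsatile"]]
    speed_p = (float(puls_veins["mean_abs_speed"].mean())
               if len(puls_veins) else float("nan"))
    speed_np = (float(nonpuls_veins["mean_abs_speed"].mean())
                if len(nonpuls_veins) else float("nan"))

    terr_lag_v = {t: _median_or_nan(
        puls_veins.loc[puls_veins["territory"] == t, "lag_ms"])
        for t in _TERRITORIES}
    terr_lag_a = {t: _median_or_nan(
        puls.loc[(puls["class_label"] == "artery") &
                 (puls["territory"] == t), "lag_ms"])
        for t in _TERRITORIES}
    terr_pi_v = {t: _median_or_nan(
        puls_veins.loc[puls_veins["territory"] == t, "pi"])
        for t in _TERRITORIES}

    return SubjectSummary(
        subject=subject, n_vessels=n_vessels, n_pulsatile=n_pulsatile,
        median_pi=median_pi, median_lag_ms=median_lag,
        mean_abs_speed_pulsatile=speed_p,
        mean_abs_speed_nonpulsatile=speed_np,
        territory_lag_veins=terr_lag_v, territory_lag_arteries=terr_lag_a,
        territory_pi_veins=terr_pi_v)


def _one_sample(values: np.ndarray) -> tuple[float, int, float]:
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError("one-sample t-test needs >= 2 subjects")
    if np.ptp(values) == 0 and values[0] == 0:
        return 0.0, len(values) - 1, 1.0  # null exactly true, zero variance
    t, p = sps.ttest_1samp(values, 0.0)
    return float(t), len(values) - 1, float(p)


def _paired(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 2:
        raise ValueError("paired t-test needs >= 2 complete pairs")
    if np.allclose(a, b):
        return 0.0, len(a) - 1, 1.0
    t, p = sps.ttest_rel(a, b)
    return float(t), len(a) - 1, float(p)


def _anova(groups: list[np.ndarray]) -> tuple[float, tuple[int, int], float]:
    groups = [g[np.isfinite(g)] for g in groups]
    groups = [g for g in groups if len(g)]
    n_obs = sum(len(g) for g in groups)
    df = (len(groups) - 1, n_obs - len(groups))
    if len(groups) < 2 or df[1] < 1:
        raise ValueError("ANOVA needs >= 2 non-empty groups and residual df")
    if all(np.ptp(g) == 0 for g in groups) and \
            np.ptp([g[0] for g in groups]) == 0:
        return 0.0, df, 1.0
    f, p = sps.f_oneway(*groups)
    return float(f), df, float(p)


def group_tests(summaries: list[SubjectSummary]) -> pd.DataFrame:
    """Cohort-level comparisons on the per-subject medians.

    Returns one row per test with statistic, degrees of freedom, raw p and
    (for the lag-vs-zero family) Bonferroni-corrected p, corrected for the
    four vessel groupings and capped at 1.  Territory ANOVAs omit missing
    subject-territory cells (a subject with no pulsatile vessel in a
    territory contributes no value there).
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 subjects")
    rows = []

    for g in LAG_GROUPS:
        lags = np.array([s.median_lag_ms[g] for s in summaries])
        t, df, p = _one_sample(lags)
        rows.append({"test": f"lag_vs_zero[{g}]", "statistic": t,
                     "df": str(df), "p_raw": p,
                     "p_corrected": min(1.0, 4 * p)})

    pi_small = np.array([s.median_pi["small_vein"] for s in summaries])
    pi_surf = np.array([s.median_pi["surface_vein"] for s in summaries])
    t, df, p = _paired(pi_small, pi_surf)
    rows.append({"test": "pi_small_vs_surface", "statistic": t,
                 "df": str(df), "p_raw": p, "p_corrected": p})

    for name, attr in (("anova_lag_veins", "territory_lag_veins"),
                       ("anova_lag_arteries", "territory_lag_arteries"),
                       ("anova_pi_veins", "territory_pi_veins")):
        groups = [np.array([getattr(s, attr)[t_] for s in summaries])
                  for t_ in _TERRITORIES]
        f, df2, p = _anova(groups)
        rows.append({"test": name, "statistic": f,
                     "df": f"{df2[0]},{df2[1]}", "p_raw": p,
                     "p_corrected": p})

    sp = np.array([s.mean_abs_speed_pulsatile for s in summaries])
    sn = np.array([s.mean_abs_speed_nonpulsatile for s in summaries])
    t, df, p = _paired(sp, sn)
    rows.append({"test": "speed_pulsatile_vs_nonpulsatile", "statistic": t,
                 "df": str(df), "p_raw": p, "p_corrected": p})

    return pd.DataFrame(rows, columns=["test", "statistic", "df", "p_raw",
                                       "p_corrected"])
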