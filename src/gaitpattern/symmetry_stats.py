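"""Left/right gait symmetry index and the nonparametric statistical battery.

The symmetry index compares the mean movement waveform of the two body
sides within one subject and condition.  With the nine angle blocks
concatenated (1809 points by default), the left mean waveform is subtracted
from the right, each point is divided by the pooled standard deviation of
the two sides at that point, the normalized differences are summed over all
points, and the absolute value is taken:

    S = | sum_t (mean_R(t) - mean_L(t)) / sd_pool(t) |,
    sd_pool(t) = sqrt((var_L(t) + var_R(t)) / 2).

Dividing by the pooled SD weights each time point by how repeatable the
movement is there, and makes the index dimensionless; 0 means perfect
symmetry.  Signed differences are summed before the absolute value, so
asymmetries of opposite sign across the cycle may cancel.

Group comparisons use the field's standard nonparametric tests
(Kruskal-Wallis across the four conditions, Friedman within sex subgroups,
Wilcoxon-Mann-Whitney between sexes) with Rosenthal's r = |Z| / sqrt(N) as
the effect size, plus Holm-corrected paired t-tests for the running-speed
control (speeds are normally distributed, so ANOVA applies there).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ParameterError
from .waveform_prep import ANGLES, DEFAULT_N_TIME, TrialSet, time_normalize

#: Pooled-SD floor (deg): points below it are excluded from the index sum.
SD_FLOOR = 1e-9

EFFECT_THRESHOLDS = (0.1, 0.3, 0.5)  # low / medium / large


def effect_label(r: float) -> str:
    if r >= 0.5:
        return "large"
    if r >= 0.3:
        return "medium"
    if r >= 0.1:
        return "low"
    return "sub-low"


@dataclass
class StatTestResult:
    test: str
    statistic: float
    df: int | None
    n: int
    p: float
    effect_size_r: float | None = None

    @property
    def effect(self) -> str | None:
        return None if self.effect_size_r is None else effect_label(self.effect_size_r)


def _stack_trials(trial_rows: list[np.ndarray]) -> np.ndarray:
    arr = np.asarray(trial_rows, dtype=float)
    if arr.ndim != 2:
        raise ParameterError("trials must share one concatenated-waveform layout")
    return arr


def symmetry_index(
    left_trials: list[np.ndarray] | np.ndarray, right_trials: list[np.ndarray] | np.ndarray
) -> float:
    """Dimensionless left/right symmetry value of one subject x condition.

    Inputs are per-trial concatenated waveform rows (same layout on both
    sides, at least 2 trials per side so the pooled SD is defined).
    """
    L = _stack_trials(list(left_trials))
    R = _stack_trials(list(right_trials))
    if L.shape[1] != R.shape[1]:
        raise ParameterError("left/right waveform layouts differ")
    if L.shape[0] < 2 or R.shape[0] < 2:
        raise InsufficientDataError("need >= 2 trials per side for the pooled SD")
    diff = R.mean(axis=0) - L.mean(axis=0)
    pooled_sd = np.sqrt((L.var(axis=0, ddof=1) + R.var(axis=0, ddof=1)) / 2.0)
    ok = pooled_sd > SD_FLOOR
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} zero-variance point(s) from the symmetry sum",
            stacklevel=2,
        )
    if not ok.any():
        return 0.0
    return float(abs(np.sum(diff[ok] / pooled_sd[ok])))


@dataclass
class SymmetryTable:
    """One symmetry value per subject x condition, plus per-condition medians."""

    values: pd.DataFrame  # subjects x conditions
    sex: dict[str, str]

    @property
    def medians(self) -> pd.Series:
        return self.values.median(axis=0, skipna=True)

    def by_sex(self, sex: str) -> pd.DataFrame:
        subjects = [s for s in self.values.index if self.sex.get(s) == sex]
        return self.values.loc[subjects]


def symmetry_table(
    trials: TrialSet,
    n_time: int = DEFAULT_N_TIME,
    angles: tuple[str, ...] = ANGLES,
) -> SymmetryTable:
    """Symmetry index for every subject x condition with both sides present.

    ``angles`` selects which blocks enter the concatenated waveform (the
    full nine-angle set by default; a lower-limb subset is a valid choice).
    """
    bad = [a for a in angles if a not in ANGLES]
    if bad:
        raise ParameterError(f"unknown angle(s) {bad}")
    subjects = trials.subjects
    conditions = trials.conditions
    table = pd.DataFrame(np.nan, index=subjects, columns=conditions)
    grouped: dict[tuple, dict[str, list[np.ndarray]]] = {}
    for t in trials:
        row = np.concatenate([time_normalize(t.angles[a], n_time) for a in angles])
        grouped.setdefault((t.subject, t.condition), {"L": [], "R": []})[t.side].append(row)
    for (subject, condition), sides in grouped.items():
        if len(sides["L"]) < 2 or len(sides["R"]) < 2:
            warnings.warn(
                f"{subject}/{condition}: missing or single-trial side, cell left empty",
                stacklevel=2,
            )
            continue
        table.loc[subject, condition] = symmetry_index(sides["L"], sides["R"])
    return SymmetryTable(values=table, sex=dict(trials.sex))


def kruskal_wallis(groups: list[list[float] | np.ndarray]) -> StatTestResult:
    """Tie-corrected Kruskal-Wallis H across >= 2 groups (chi-square p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ParameterError("need >= 2 nonempty groups")
    n = int(sum(g.size for g in groups))
    if n < 3:
        raise ParameterError("need >= 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return StatTestResult("kruskal_wallis", 0.0, len(groups) - 1, n, 1.0)
    h, p = stats.kruskal(*groups)
    return StatTestResult("kruskal_wallis", float(h), len(groups) - 1, n, float(p))


def friedman(blocked: pd.DataFrame | np.ndarray) -> StatTestResult:
    """Friedman chi-square over a subjects x conditions table.

    Rows with any missing value (incomplete blocks) are dropped with a
    warning; identical columns give statistic 0, p 1.
    """
    df = pd.DataFrame(blocked)
    complete = df.dropna()
    if len(complete) < len(df):
        warnings.warn(f"dropping {len(df) - len(complete)} incomplete block(s)", stacklevel=2)
    if complete.shape[1] < 2:
        raise ParameterError("need >= 2 conditions")
    if complete.shape[0] < 2:
        raise InsufficientDataError("need >= 2 complete blocks")
    arr = complete.to_numpy(dtype=float)
    k = arr.shape[1]
    if np.all(arr == arr[:, :1]):
        return StatTestResult("friedman", 0.0, k - 1, arr.shape[0], 1.0)
    if k == 2:
        # scipy requires >= 3 conditions; fall back to the rank formula
        ranks = np.apply_along_axis(stats.rankdata, 1, arr)
        n = arr.shape[0]
        chi2 = 12.0 * n / (k * (k + 1)) * np.sum((ranks.mean(axis=0) - (k + 1) / 2) ** 2)
        p = float(stats.chi2.sf(chi2, k - 1))
        return StatTestResult("friedman", float(chi2), k - 1, n, p)
    chi2, p = stats.friedmanchisquare(*[arr[:, j] for j in range(k)])
    return StatTestResult("friedman", float(chi2), k - 1, arr.shape[0], float(p))


def mann_whitney_effect(x, y) -> StatTestResult:
    """Mann-Whitney U with tie-corrected normal Z and Rosenthal effect size.

    U is the statistic of the first sample; Z uses the normal approximation
    with the tie-corrected variance (no continuity correction); the effect
    size is r = |Z| / sqrt(n_x + n_y) with the 0.1/0.3/0.5 low/medium/large
    convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ParameterError("both samples must be nonempty")
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = stats.rankdata(np.concatenate([x, y]))
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    mu = nx * ny / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (u_x - mu) / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(z)))
    r = abs(z) / np.sqrt(n)
    return StatTestResult("mann_whitney", u_x, None, n, min(p, 1.0), effect_size_r=float(r))


def holm_correct(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down decisions and monotone adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


def pairwise_mann_whitney(
    table: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise condition comparisons of a subjects x conditions table,
    Mann-Whitney with Holm correction (the post-hoc follow-up to a
    significant Kruskal-Wallis)."""
    import itertools

    conds = list(table.columns)
    rows = []
    for a, b in itertools.combinations(conds, 2):
        res = mann_whitney_effect(table[a].dropna(), table[b].dropna())
        rows.append((f"{a} vs {b}", res.statistic, res.p, res.effect_size_r, res.effect))
    out = pd.DataFrame(rows, columns=["comparison", "U", "p", "effect_r", "effect"])
    reject, p_adj = holm_correct(out["p"].to_numpy(), alpha)
    out["p_holm"] = p_adj
    out["significant"] = reject
    return out


def compare_running_speed(
    speeds: pd.DataFrame, alpha: float = 0.05
) -> dict[str, object]:
    """Running-speed control: normality check, repeated-measures ANOVA
    across conditions, and Holm-corrected paired t-tests.

    ``speeds`` is a long table with columns subject, condition, speed (one
    row per trial); trials are averaged to subject x condition means first.
    """
    required = {"subject", "condition", "speed"}
    if not required.issubset(speeds.columns):
        raise ParameterError(f"speeds table needs columns {sorted(required)}")
    means = (
        speeds.groupby(["subject", "condition"], sort=False)["speed"].mean().reset_index()
    )
    wide = means.pivot(index="subject", columns="condition", values="speed").dropna()
    conds = list(wide.columns)
    if len(conds) < 2 or len(wide) < 2:
        raise InsufficientDataError("need >= 2 conditions and >= 2 complete subjects")
    resid = wide.to_numpy() - wide.to_numpy().mean(axis=1, keepdims=True)
    if np.allclose(resid, 0.0):
        anova = StatTestResult("anova", 0.0, len(conds) - 1, len(wide), 1.0)
        lillie_p = None
    else:
        from statsmodels.stats.anova import AnovaRM
        from statsmodels.stats.diagnostic import lilliefors

        _, lillie_p = lilliefors(resid.ravel(), dist="norm")
        fit = AnovaRM(means, depvar="speed", subject="subject", within=["condition"]).fit()
        row = fit.anova_table.iloc[0]
        anova = StatTestResult(
            "anova",
            float(row["F Value"]),
            int(row["Num DF"]),
            len(wide),
            float(row["Pr > F"]),
        )
    import itertools

    pairs, stats_rows = [], []
    for a, b in itertools.combinations(conds, 2):
        d = wide[a] - wide[b]
        if np.allclose(d, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(wide[a], wide[b])
        pairs.append(f"{a} vs {b}")
        stats_rows.append((float(t), float(p)))
    reject, p_adj = holm_correct([p for _, p in stats_rows], alpha)
    posthoc = pd.DataFrame(
        {
            "comparison": pairs,
            "t": [t for t, _ in stats_rows],
            "p": [p for _, p in stats_rows],
            "p_holm": p_adj,
            "significant": reject,
        }
    )
    return {"normality_p": lillie_p, "anova": anova, "posthoc": posthoc}
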