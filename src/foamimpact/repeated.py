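"""Repeated-loading analysis: force at the reference energy across strikes.

For every layer count, the force reached at the reference energy E_ref is
tabulated per specimen and repetition (the five-strike block at the highest
drop height), summarised as mean +/- SD and percentage increase over the
first strike, and tested with a one-way repeated-measures ANOVA followed by
one-sided paired t tests on consecutive repetitions (alternative: the later
strike shows the higher force, i.e. the mat has degraded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import StudyConfig

__all__ = [
    "RepeatedLoadingResult",
    "force_increase_table",
    "shapiro_wilk",
    "rm_anova",
    "posthoc_consecutive_t",
    "build_table1",
]


@dataclass(frozen=True)
class RepeatedLoadingResult:
    """Per-layer summary of the repeated-loading block."""

    layer: int
    force_matrix: np.ndarray  # specimens x repetitions, N
    means: np.ndarray  # per repetition, N
    stds: np.ndarray  # per repetition, N (ddof=1)
    increase_pct: np.ndarray  # vs repetition 1, unrounded %
    anova_F: float
    anova_p: float
    eta_squared: float
    posthoc_p: np.ndarray  # p for rep r vs r-1, r = 2..R
    posthoc_t: np.ndarray
    shapiro_p: np.ndarray  # per repetition cell (across specimens)


def force_increase_table(means: np.ndarray | list[float]) -> np.ndarray:
    """Percentage force increase of each repetition over repetition 1.

    Computed from unrounded means; round only when rendering.
    """
    means = np.asarray(means, dtype=float)
    if len(means) < 1:
        raise ValueError("means must be non-empty")
    if means[0] <= 0:
        raise ValueError("repetition-1 mean must be > 0")
    return 100.0 * (means / means[0] - 1.0)


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W, p); requires 3 <= n <= 50."""
    x = np.asarray(sample, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if len(x) > 50:
        raise ValueError("Shapiro-Wilk supported here for n <= 50")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values identical")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def rm_anova(force_matrix: np.ndarray) -> tuple[float, float, float]:
    """One-way repeated-measures ANOVA on a specimens x repetitions matrix.

    Returns ``(F, p, eta_squared)`` where F = MS_treatment / MS_error after
    removing the between-specimen effect, and
    eta_squared = SS_treatment / (SS_treatment + SS_error) (partial).
    """
    import pingouin as pg

    m = np.asarray(force_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete matrix with >= 2 specimens and >= 2 repetitions")
    if np.isnan(m).any():
        raise ValueError("incomplete force matrix")
    n_subj, n_rep = m.shape
    long = pd.DataFrame(
        {
            "force": m.ravel(),
            "specimen": np.repeat(np.arange(n_subj), n_rep),
            "repetition": np.tile(np.arange(1, n_rep + 1), n_subj),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.rm_anova(
            data=long,
            dv="force",
            within="repetition",
            subject="specimen",
            effsize="np2",
            detailed=False,
        )
    row = aov.iloc[0]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return float(row["F"]), float(row[p_col]), float(row["np2"])


def posthoc_consecutive_t(force_matrix: np.ndarray) -> pd.DataFrame:
    """One-sided paired t tests between consecutive repetitions.

    Alternative hypothesis: the force at repetition r exceeds that at r-1
    (degraded mats are stiffer at the same absorbed energy).  No multiplicity
    correction is applied; p values are reported raw.  Zero-variance
    difference vectors are flagged with ``degenerate=True`` and NaN p.
    """
    m = np.asarray(force_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 repetitions")
    rows = []
    for r in range(1, m.shape[1]):
        later, earlier = m[:, r], m[:, r - 1]
        d = later - earlier
        if np.ptp(d) == 0:
            # identical samples: no effect, t = 0 and one-sided p = 1/2;
            # a constant nonzero shift has zero-variance differences and an
            # undefined t statistic -> flagged
            zero = d[0] == 0
            rows.append(
                {
                    "rep": r + 1,
                    "vs_rep": r,
                    "t": 0.0 if zero else np.nan,
                    "p": 0.5 if zero else np.nan,
                    "mean_diff": float(d.mean()),
                    "degenerate": not zero,
                }
            )
            continue
        res = sps.ttest_rel(later, earlier, alternative="greater")
        rows.append(
            {
                "rep": r + 1,
                "vs_rep": r,
                "t": float(res.statistic),
                "p": float(res.pvalue),
                "mean_diff": float(d.mean()),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)


def _repeated_block(metrics: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Select the five-repetition block at the repeated-loading drop height."""
    at_height = metrics[
        np.isclose(metrics["drop_height_m"], config.extra_drop_height)
    ]
    reps_per_specimen = at_height.groupby("specimen_id")["repetition"].max()
    full = reps_per_specimen[reps_per_specimen >= config.repetitions_extra].index
    return at_height[at_height["specimen_id"].isin(full)]


def build_table1(
    metrics: pd.DataFrame,
    e_ref: float,
    config: StudyConfig,
) -> dict[int, RepeatedLoadingResult]:
    """Assemble the repeated-loading summary for every layer count.

    ``metrics`` must hold one row per test with columns ``drop_height_m``,
    ``n_layers``, ``specimen_id``, ``repetition`` and ``force_at_eref_n``
    (the force at ``e_ref`` absorbed energy).  Only specimens with the full
    extra-repetition count at the repeated-loading drop height are used.
    """
    block = _repeated_block(metrics, config)
    if block.empty:
        raise ValueError(
            f"no specimens with {config.repetitions_extra} repetitions at "
            f"{config.extra_drop_height} m in metrics"
        )
    results: dict[int, RepeatedLoadingResult] = {}
    for layer, sub in block.groupby("n_layers"):
        pivot = sub.pivot_table(
            index="specimen_id",
            columns="repetition",
            values="force_at_eref_n",
        )
        reps = list(range(1, config.repetitions_extra + 1))
        missing = [
            (sid, r)
            for sid in pivot.index
            for r in reps
            if r not in pivot.columns or pd.isna(pivot.loc[sid].get(r, np.nan))
        ]
        if missing:
            raise ValueError(f"layer {layer}: missing cells {missing}")
        m = pivot[reps].to_numpy()
        means = m.mean(axis=0)
        stds = m.std(axis=0, ddof=1)
        increase = force_increase_table(means)
        F, p, eta2 = rm_anova(m)
        post = posthoc_consecutive_t(m)
        shapiro_p = np.array(
            [
                shapiro_wilk(m[:, j])[1]
                if (m.shape[0] >= 3 and np.ptp(m[:, j]) > 0)
                else np.nan
                for j in range(m.shape[1])
            ]
        )
        results[int(layer)] = RepeatedLoadingResult(
            layer=int(layer),
            force_matrix=m,
            means=means,
            stds=stds,
            increase_pct=increase,
            anova_F=F,
            anova_p=p,
            eta_squared=eta2,
            posthoc_p=post["p"].to_numpy(),
            posthoc_t=post["t"].to_numpy(),
            shapiro_p=shapiro_p,
        )
    return results


def table1_frame(results: dict[int, RepeatedLoadingResult]) -> pd.DataFrame:
    """Render the repeated-loading table (means, SDs, increases, p values)."""
    rows = []
    for layer in sorted(results):
        r = results[layer]
        for j, rep in enumerate(range(1, len(r.means) + 1)):
            rows.append(
                {
                    "layer": layer,
                    "repetition": rep,
                    "mean_n": round(float(r.means[j])),
                    "std_n": round(float(r.stds[j])),
                    "increase_pct": (
                        round(float(r.increase_pct[j])) if rep > 1 else None
                    ),
                    "p_value": float(r.posthoc_p[j - 1]) if rep > 1 else None,
                }
            )
    return pd.DataFrame(rows)


def anova_frame(results: dict[int, RepeatedLoadingResult]) -> pd.DataFrame:
    rows = [
        {
            "layer": layer,
            "F": results[layer].anova_F,
            "p": results[layer].anova_p,
            "eta_squared": results[layer].eta_squared,
        }
        for layer in sorted(results)
    ]
    return pd.DataFrame(rows)
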