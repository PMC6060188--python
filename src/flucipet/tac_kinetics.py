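"""Time-activity-curve extraction and equilibrium (plateau) analysis.

A TAC is one uptake statistic (SUV_max, SUV_mean, TB_max, or TB_mean) sampled
at the frame mid-times.  Equilibrium is assessed over the late window (frames
with mid-time >= 30 min, i.e. 30/40/50/60 min on the default schedule): an
unbalanced two-way ANOVA (time, group; type-II sums of squares) followed by
Tukey HSD over time points within each group.  A group is flagged as plateaued
when no within-group time-pair difference is significant at alpha.

Missing late frames (patient attrition) are carried as NaN and never imputed;
group averages report the per-point n so attrition is visible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import DynamicImage
from .roi_metrics import VoxelMask

__all__ = [
    "TAC",
    "EquilibriumResult",
    "extract_tac",
    "group_average_tac",
    "equilibrium_anova",
    "plot_group_tacs",
    "EQUILIBRIUM_WINDOW_START_MIN",
]

#: Frames with mid-time at or after this (minutes) form the equilibrium window.
EQUILIBRIUM_WINDOW_START_MIN = 30.0

_STATISTICS = ("suv_max", "suv_mean", "tb_max", "tb_mean")


@dataclass(frozen=True)
class TAC:
    """One uptake statistic versus frame mid-time for one ROI (NaN = missing)."""

    roi_id: str
    statistic: str
    times_min: np.ndarray
    values: np.ndarray
    group_label: str | None = None
    n_per_point: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


def extract_tac(
    img: DynamicImage,
    mask: VoxelMask,
    statistic: str,
    bg_series: np.ndarray | None = None,
    roi_id: str = "",
    group_label: str | None = None,
) -> TAC:
    """Sample one statistic over a fixed mask at every frame mid-time.

    TB statistics divide each frame's value by the *same frame's* background
    (``bg_series``, one SUV per frame), which is therefore required for them.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}; choose from {_STATISTICS}")
    if mask.count == 0:
        raise ValueError("mask is empty")
    if mask.mask.shape != img.spatial_shape:
        raise ValueError("mask shape does not match image spatial shape")
    needs_bg = statistic.startswith("tb_")
    if needs_bg:
        if bg_series is None:
            raise ValueError(f"statistic {statistic!r} requires bg_series")
        bg_series = np.asarray(bg_series, dtype=float)
        if bg_series.shape != (img.schedule.n_frames,):
            raise ValueError("bg_series must hold one value per frame")

    sel = img.voxels[mask.mask, :]  # (n_voxels, n_frames)
    if statistic in ("suv_max", "tb_max"):
        vals = sel.max(axis=0)
    else:
        vals = sel.mean(axis=0)
    if needs_bg:
        vals = vals / bg_series
    return TAC(roi_id, statistic, img.schedule.frame_mid_times_min, vals, group_label)


def group_average_tac(tacs: list[TAC], group_label: str | None = None) -> TAC:
    """Pointwise mean TAC over lesions, ignoring missing values.

    All inputs must share the same time grid (to 1e-6 min).  The per-point
    number of contributing lesions is attached so late-frame attrition is
    explicit; a point missing in every input stays NaN.
    """
    if not tacs:
        raise ValueError("need at least one TAC")
    ref = tacs[0]
    for t in tacs[1:]:
        if t.times_min.shape != ref.times_min.shape or not np.allclose(
            t.times_min, ref.times_min, atol=1e-6
        ):
            raise ValueError("TACs are not on a shared time grid")
        if t.statistic != ref.statistic:
            raise ValueError("TACs mix statistics")
    stack = np.vstack([t.values for t in tacs])
    n = np.sum(~np.isnan(stack), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(stack, axis=0)
    return TAC(
        roi_id=group_label or "group",
        statistic=ref.statistic,
        times_min=ref.times_min,
        values=mean,
        group_label=group_label,
        n_per_point=n,
    )


@dataclass(frozen=True)
class EquilibriumResult:
    """Two-way ANOVA + per-group Tukey HSD over the equilibrium window.

    ``tukey_pairs`` maps group -> DataFrame (time_a, time_b, meandiff, p_adj)
    or None when unavailable (a single lesion leaves no residual df).
    ``plateau`` maps group -> True/False/None (None = unavailable).
    """

    window_min: tuple[float, ...]
    anova_table: pd.DataFrame
    tukey_pairs: dict[str, pd.DataFrame | None]
    plateau: dict[str, bool | None]
    alpha: float
    degenerate: bool = field(default=False)  # zero-variance input


def _tukey_within_group(sub: pd.DataFrame, alpha: float) -> pd.DataFrame | None:
    """Tukey HSD across time points for one group; None if no residual df."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    counts = sub.groupby("time_point")["value"].count()
    if (sub.shape[0] - counts.size) < 1 or counts.min() < 1 or counts.size < 2:
        return None
    if np.ptp(sub["value"].to_numpy()) == 0.0:
        # all identical: every pairwise difference is exactly zero
        times = sorted(sub["time_point"].unique())
        pairs = [(a, b) for i, a in enumerate(times) for b in times[i + 1 :]]
        return pd.DataFrame(
            {"time_a": [p[0] for p in pairs], "time_b": [p[1] for p in pairs],
             "meandiff": 0.0, "p_adj": 1.0}
        )
    with np.errstate(divide="ignore", invalid="ignore"):  # zero within-cell variance
        res = pairwise_tukeyhsd(sub["value"].to_numpy(), sub["time_point"].to_numpy(), alpha=alpha)
    tbl = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return pd.DataFrame(
        {
            "time_a": tbl["group1"].astype(float),
            "time_b": tbl["group2"].astype(float),
            "meandiff": tbl["meandiff"].astype(float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
        }
    )


def equilibrium_anova(
    obs: pd.DataFrame,
    window_start_min: float = EQUILIBRIUM_WINDOW_START_MIN,
    alpha: float = 0.05,
) -> EquilibriumResult:
    """Assess TAC flattening over the late window.

    ``obs`` is a long table with columns (lesion, group, time_point, value);
    rows with mid-time before the window or NaN values are dropped.  The ANOVA
    uses type-II sums of squares, appropriate for the unbalanced designs that
    patient attrition produces; with a single group the group factor is
    dropped (one-way in time).  Results are invariant to lesion relabeling and
    row order.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    required = {"lesion", "group", "time_point", "value"}
    if not required.issubset(obs.columns):
        raise ValueError(f"obs must have columns {sorted(required)}")
    df = obs.dropna(subset=["value"]).copy()
    df = df[df["time_point"] >= window_start_min - 1e-9]
    window = tuple(sorted(df["time_point"].unique()))
    if len(window) < 2:
        raise ValueError("need >= 2 time points in the equilibrium window")

    groups = sorted(df["group"].unique())
    degenerate = bool(np.ptp(df["value"].to_numpy()) == 0.0)
    if degenerate:
        # no variance anywhere: F undefined, nothing is significant
        anova = pd.DataFrame(
            {"sum_sq": [0.0, 0.0, 0.0], "df": [np.nan] * 3,
             "F": [np.nan] * 3, "PR(>F)": [1.0, 1.0, 1.0]},
            index=["C(time_point)", "C(group)", "Residual"],
        )
    else:
        formula = "value ~ C(time_point)"
        if len(groups) > 1:
            formula += " + C(group)"
        fit = smf.ols(formula, data=df).fit()
        anova = sm.stats.anova_lm(fit, typ=2)

    tukey: dict[str, pd.DataFrame | None] = {}
    plateau: dict[str, bool | None] = {}
    for g in groups:
        sub = df[df["group"] == g]
        if sub["lesion"].nunique() < 2:
            tukey[g] = None
            plateau[g] = None
            continue
        pairs = _tukey_within_group(sub, alpha)
        tukey[g] = pairs
        plateau[g] = None if pairs is None else bool((pairs["p_adj"] >= alpha).all())

    return EquilibriumResult(
        window_min=window,
        anova_table=anova,
        tukey_pairs=tukey,
        plateau=plateau,
        alpha=alpha,
        degenerate=degenerate,
    )


def plot_group_tacs(tacs: list[TAC], path, display_start_min: float = 4.5) -> None:
    """Save a PNG of group-average TACs (one line per group).

    Curves are drawn from ``display_start_min`` onward (the early infusion
    frames compress the plateau visually); the underlying TAC data always
    keeps every frame.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for tac in tacs:
        keep = tac.times_min >= display_start_min - 1e-9
        label = tac.group_label or tac.roi_id
        ax.plot(tac.times_min[keep], tac.values[keep], marker="o", label=label)
    ax.set_xlabel("time post-injection (min)")
    ax.set_ylabel(tacs[0].statistic if tacs else "value")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
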