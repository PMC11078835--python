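"""Within-subject statistics: participant z-scores, 2x3 repeated-measures
ANOVA with generalized eta squared, paired post-hocs, IQR outlier flags.

Trial values of each dependent variable are first z-scored within
participant (the measures are highly idiosyncratic), then reduced to
participant x size x weight cell means, and entered into a classical
two-way fully-within ANOVA. Each effect is tested against its own
effect-by-subject interaction; generalized eta squared follows the
manipulated-factors convention,

    ges = SS_effect / (SS_effect + SS_subjects + sum of all error SS),

which makes effect sizes comparable across within- and between-subject
designs. Degrees of freedom are reported uncorrected (no sphericity
correction), and post-hoc paired t-tests between weight levels (averaging
over size) come with the paired Cohen's d (mean difference over the SD of
the differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DV_PARTICIPANT_COLUMN",
    "EffectResult",
    "AnovaResult",
    "PosthocResult",
    "zscore_by_participant",
    "aggregate_cells",
    "rm_anova_2way",
    "posthoc_weight",
    "iqr_outliers",
    "analyze_features",
]

SIZE_LEVELS = ["small", "big"]
WEIGHT_LEVELS = ["light", "medium", "heavy"]
WEIGHT_PAIRS = [("light", "medium"), ("light", "heavy"), ("medium", "heavy")]

#: Which actor each dependent variable belongs to: the giver produces the
#: kinematic measures and their own grip-force rate; the receiver's grip
#: force rate belongs to the receiver.
DV_PARTICIPANT_COLUMN = {
    "lift_delay": "giver_id",
    "max_lift_velocity": "giver_id",
    "giver_pgfr": "giver_id",
    "receiver_pgfr": "receiver_id",
}


@dataclass(frozen=True)
class EffectResult:
    F: float
    df_num: int
    df_den: int
    p: float
    ges: float
    degenerate: bool = False


@dataclass(frozen=True)
class AnovaResult:
    """Two-way within-subject ANOVA summary for one dependent variable."""

    weight: EffectResult
    size: EffectResult
    interaction: EffectResult
    n_participants: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, eff in (
            ("weight", self.weight),
            ("size", self.size),
            ("weight_x_size", self.interaction),
        ):
            rows.append(
                {
                    "effect": name,
                    "df_num": eff.df_num,
                    "df_den": eff.df_den,
                    "F": eff.F,
                    "p": eff.p,
                    "ges": eff.ges,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PosthocResult:
    """Paired t-tests and Cohen's d for the three weight-level pairs.

    Differences are taken as (second level - first level), so a measure that
    grows with weight has positive d throughout.
    """

    comparisons: pd.DataFrame  # columns: pair, t, p, cohens_d, n

    def __getitem__(self, pair: tuple[str, str]) -> pd.Series:
        key = f"{pair[0]}-{pair[1]}"
        row = self.comparisons[self.comparisons["pair"] == key]
        if row.empty:
            raise KeyError(pair)
        return row.iloc[0]


def zscore_by_participant(
    table: pd.DataFrame, dv: str, participant_col: str = "participant"
) -> pd.DataFrame:
    """Standardize ``dv`` within each participant (sample SD, ddof=1).

    Returns a copy with the dv column replaced; each participant's values
    then have mean 0 and SD 1. Raises if a participant has fewer than two
    trials or zero variance.
    """
    out = table.copy()
    for pid, grp in out.groupby(participant_col, sort=False):
        x = grp[dv].to_numpy(dtype=float)
        if x.shape[0] < 2:
            raise ValueError(f"participant {pid!r} has fewer than 2 trials for {dv}")
        sd = x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(
                f"participant {pid!r} has zero within-participant variance for {dv}"
            )
        out.loc[grp.index, dv] = (x - x.mean()) / sd
    return out


def aggregate_cells(
    table: pd.DataFrame, dv: str, participant_col: str = "participant"
) -> pd.DataFrame:
    """Reduce trials to participant x size x weight cell means of ``dv``.

    Every participant must contribute at least one trial to each of the six
    cells (balanced design entry requirement for the within-subject ANOVA).
    """
    cells = (
        table.groupby([participant_col, "size", "weight"], sort=False, observed=True)[dv]
        .mean()
        .reset_index()
    )
    n_p = cells[participant_col].nunique()
    if len(cells) != n_p * len(SIZE_LEVELS) * len(WEIGHT_LEVELS):
        counts = cells.groupby(participant_col, observed=True).size()
        bad = counts[counts != 6].index.tolist()
        raise ValueError(f"empty design cell(s) for participant(s) {bad}")
    return cells


def _cell_cube(
    cells: pd.DataFrame, dv: str, participant_col: str
) -> tuple[np.ndarray, list]:
    """Arrange cell means as Y[subject, size, weight]."""
    participants = list(pd.unique(cells[participant_col]))
    y = np.full((len(participants), len(SIZE_LEVELS), len(WEIGHT_LEVELS)), np.nan)
    p_idx = {p: i for i, p in enumerate(participants)}
    s_idx = {s: i for i, s in enumerate(SIZE_LEVELS)}
    w_idx = {w: i for i, w in enumerate(WEIGHT_LEVELS)}
    for row in cells.itertuples(index=False):
        d = row._asdict()
        y[p_idx[d[participant_col]], s_idx[str(d["size"])], w_idx[str(d["weight"])]] = d[dv]
    if np.isnan(y).any():
        raise ValueError("incomplete design: missing participant x size x weight cell")
    return y, participants


def rm_anova_2way(
    cells: pd.DataFrame, dv: str, participant_col: str = "participant"
) -> AnovaResult:
    """Two-way (size x weight) fully-within repeated-measures ANOVA.

    Expects one value per participant x size x weight cell (see
    :func:`aggregate_cells`). Effects are tested against their own
    effect-by-subject error terms; p-values use the uncorrected F
    distribution.
    """
    y, participants = _cell_cube(cells, dv, participant_col)
    n, a, b = y.shape  # participants, size levels, weight levels
    if n < 2:
        raise ValueError("at least 2 participants required")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))        # subject means
    m_a = y.mean(axis=(0, 2))        # size means
    m_b = y.mean(axis=(0, 1))        # weight means
    m_ab = y.mean(axis=0)            # size x weight means
    m_as = y.mean(axis=2)            # subject x size means
    m_bs = y.mean(axis=1)            # subject x weight means

    ss_subj = a * b * np.sum((m_s - grand) ** 2)
    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum(
        (m_as - m_a[None, :] - m_s[:, None] + grand) ** 2
    )
    ss_bs = a * np.sum(
        (m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2
    )
    ss_total = np.sum((y - grand) ** 2)
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)

    ss_error_all = ss_as + ss_bs + ss_abs

    def effect(ss_eff: float, df_num: int, ss_err: float, df_den: int) -> EffectResult:
        ges_denom = ss_eff + ss_subj + ss_error_all
        ges = ss_eff / ges_denom if ges_denom > 0 else 0.0
        if ss_err <= 1e-300 * max(1.0, ss_eff):
            # no residual variability: F undefined
            return EffectResult(
                F=float("nan"),
                df_num=df_num,
                df_den=df_den,
                p=float("nan"),
                ges=ges,
                degenerate=True,
            )
        F = (ss_eff / df_num) / (ss_err / df_den)
        p = float(sps.f.sf(F, df_num, df_den))
        return EffectResult(F=float(F), df_num=df_num, df_den=df_den, p=p, ges=float(ges))

    return AnovaResult(
        size=effect(ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        weight=effect(ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        interaction=effect(ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
        n_participants=n,
    )


def posthoc_weight(
    cells: pd.DataFrame, dv: str, participant_col: str = "participant"
) -> PosthocResult:
    """Paired t-tests between weight levels on participant means (averaged
    over size), with paired Cohen's d = mean(diff) / sd(diff)."""
    y, participants = _cell_cube(cells, dv, participant_col)
    per_weight = y.mean(axis=1)  # (n, 3), averaged over size
    w_idx = {w: i for i, w in enumerate(WEIGHT_LEVELS)}
    rows = []
    for first, second in WEIGHT_PAIRS:
        diff = per_weight[:, w_idx[second]] - per_weight[:, w_idx[first]]
        sd = diff.std(ddof=1)
        if sd == 0:
            if np.allclose(diff, 0):
                t, p, d = 0.0, 1.0, 0.0
            else:
                raise ValueError(f"zero-variance differences for pair {first}-{second}")
        else:
            t, p = sps.ttest_rel(
                per_weight[:, w_idx[second]], per_weight[:, w_idx[first]]
            )
            d = diff.mean() / sd
        rows.append(
            {
                "pair": f"{first}-{second}",
                "t": float(t),
                "p": float(p),
                "cohens_d": float(d),
                "n": len(participants),
            }
        )
    return PosthocResult(comparisons=pd.DataFrame(rows))


def iqr_outliers(values: np.ndarray) -> np.ndarray:
    """Boolean mask of values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation. Requires at least 4 values.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 4:
        raise ValueError("iqr_outliers requires at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def analyze_features(
    features: pd.DataFrame,
    dvs: tuple[str, ...] = tuple(DV_PARTICIPANT_COLUMN),
    drop_outliers: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, AnovaResult]]:
    """Run the full statistical stage on a long-format feature table.

    For each dependent variable: attribute each trial to the actor who
    produced the measure, z-score within participant, flag 1.5-IQR outliers
    on the z-scores (optionally dropping them), aggregate to cell means and
    fit the 2x3 within-subject ANOVA plus weight post-hocs.

    Returns ``(anova_table, posthoc_table, results_by_dv)``.
    """
    anova_rows, posthoc_rows = [], []
    results: dict[str, AnovaResult] = {}
    for dv in dvs:
        pcol = DV_PARTICIPANT_COLUMN.get(dv, "giver_id")
        sub = features[[pcol, "size", "weight", dv]].rename(
            columns={pcol: "participant"}
        )
        sub = zscore_by_participant(sub, dv)
        if drop_outliers:
            sub = sub[~iqr_outliers(sub[dv].to_numpy())]
        cells = aggregate_cells(sub, dv)
        res = rm_anova_2way(cells, dv)
        results[dv] = res
        tab = res.to_frame()
        tab.insert(0, "dv", dv)
        anova_rows.append(tab)
        ph = posthoc_weight(cells, dv).comparisons
        ph.insert(0, "dv", dv)
        posthoc_rows.append(ph)
    return (
        pd.concat(anova_rows, ignore_index=True),
        pd.concat(posthoc_rows, ignore_index=True),
        results,
    )
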