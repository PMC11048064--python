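"""Group x cognitive-load statistics for instrumented-test features.

The central object is :class:`MixedAnova`: a two-way mixed-design analysis
of variance with one between-subject factor (group: stroke vs control) and
one within-subject factor (cognitive load: single vs dual task), the design
the reference protocol analysed for each of its 25 measures. ``fit()``
returns a :class:`MixedAnovaResults` carrying the full sums-of-squares
decomposition, F tests, partial eta-squared per effect with its
small/medium/large class, and a ``summary()`` table.

The decomposition uses observation-weighted (sequential) sums of squares,
which are additive — ``SS_total = sum of effect SS + sum of error SS`` —
for any group sizes, and coincide with the usual mixed-ANOVA tables when
the groups are balanced. Partial eta-squared is
``SS_effect / (SS_effect + SS_error_of_that_stratum)``: the between-subject
stratum (subjects within groups) tests the group effect; the
within-subject stratum tests cognitive load and the interaction.

Also here: Shapiro-Wilk normality screening per design cell, the
cell-mean percent contrasts behind the headline group differences, and the
per-subject dual-task cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    InvalidSpecError,
    UnbalancedDesignError,
    UndefinedContrastError,
)

__all__ = [
    "MixedAnova",
    "MixedAnovaResults",
    "ContrastResult",
    "classify_effect_size",
    "normality_screen",
    "group_contrast_percent",
    "dual_task_cost",
    "anova_by_feature",
    "validate_feature_table",
]

FEATURE_TABLE_COLUMNS = ("subject_id", "group", "condition", "feature", "value")

#: Partial eta-squared class boundaries: small below 0.06, medium from 0.06
#: to 0.14, large above 0.14.
ETA2_SMALL = 0.06
ETA2_MEDIUM = 0.14


def classify_effect_size(eta2: float) -> str:
    """Classify a partial eta-squared as S (< 0.06), M (0.06-0.14) or L (> 0.14)."""
    if not 0.0 <= eta2 <= 1.0 or not np.isfinite(eta2):
        raise InvalidSpecError(f"partial eta-squared must be in [0, 1], got {eta2}")
    if eta2 < ETA2_SMALL:
        return "S"
    if eta2 <= ETA2_MEDIUM:
        return "M"
    return "L"


def validate_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format feature table contract and return it.

    Required columns: subject_id, group, condition, feature, value. Every
    subject must appear in both conditions for each of its features.
    """
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidSpecError(f"feature table is missing columns: {missing}")
    return table


# ---------------------------------------------------------------------------
# Mixed ANOVA model / results
# ---------------------------------------------------------------------------


class MixedAnova:
    """Two-way mixed ANOVA: between-subject group, within-subject condition.

    Parameters
    ----------
    data:
        Long-format DataFrame with one row per subject x condition.
    dv, subject, between, within:
        Column names of the response, the subject identifier, the
        between-subject factor and the (two-level) within-subject factor.

    Examples
    --------
    >>> res = MixedAnova(df, dv="value").fit()
    >>> res.p["group"], res.eta2["condition"]
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str = "value",
        subject: str = "subject_id",
        between: str = "group",
        within: str = "condition",
    ) -> None:
        for col in (dv, subject, between, within):
            if col not in data.columns:
                raise InvalidSpecError(f"column {col!r} not in data")
        self.data = data
        self.dv = dv
        self.subject = subject
        self.between = between
        self.within = within

        d = data[[subject, between, within, dv]].dropna()
        conds = sorted(d[within].unique())
        if len(conds) != 2:
            raise InvalidSpecError(
                f"the within factor must have exactly 2 levels, got {conds}"
            )
        counts = d.groupby(subject)[within].nunique()
        incomplete = counts[counts < 2]
        if len(incomplete):
            raise UnbalancedDesignError(
                f"subjects missing a condition: {list(incomplete.index)[:5]}"
            )
        dup = d.groupby([subject, within]).size()
        if (dup > 1).any():
            raise UnbalancedDesignError("duplicate subject x condition rows")
        wide = d.pivot(index=subject, columns=within, values=dv)
        grp = d.groupby(subject)[between].first()
        if grp.groupby(grp).size().min() < 2 or grp.nunique() < 2:
            raise InsufficientDataError("need >= 2 subjects in each of >= 2 groups")

        self._conds = conds
        self._y = wide[conds].to_numpy(dtype=float)  # (n_subjects, 2)
        self._groups = grp.loc[wide.index].to_numpy()
        self._subjects = wide.index.to_numpy()

    def fit(self) -> "MixedAnovaResults":
        ss, df, F, p = _mixed_anova_arrays(self._y, self._groups)
        return MixedAnovaResults(self, ss, df, F, p)


def _mixed_anova_arrays(
    y: np.ndarray, groups: np.ndarray
) -> tuple[dict, dict, dict, dict]:
    """Core decomposition on a (n_subjects, 2) response array.

    Returns dicts of SS, df, F and p keyed by
    group / subjects_within_groups / condition / interaction / within_error.
    """
    n, b = y.shape
    levels, inverse = np.unique(groups, return_inverse=True)
    a = len(levels)
    n_j = np.bincount(inverse)

    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    if ss_total == 0.0:
        raise DegenerateDataError("the response has zero total variance")

    subj_means = y.mean(axis=1)
    group_means = np.array([subj_means[inverse == j].mean() for j in range(a)])

    ss_between = b * float(((subj_means - grand) ** 2).sum())
    ss_group = b * float((n_j * (group_means - grand) ** 2).sum())
    ss_subj = ss_between - ss_group

    cond_means = y.mean(axis=0)  # observation-weighted
    ss_cond = n * float(((cond_means - grand) ** 2).sum())
    cell_means = np.array(
        [[y[inverse == j, i].mean() for i in range(b)] for j in range(a)]
    )
    ss_inter = float(
        (
            n_j[:, None]
            * (cell_means - group_means[:, None] - cond_means[None, :] + grand) ** 2
        ).sum()
    )
    ss_within_total = ss_total - ss_between
    ss_err_w = ss_within_total - ss_cond - ss_inter

    df = {
        "group": a - 1,
        "subjects_within_groups": n - a,
        "condition": b - 1,
        "interaction": (a - 1) * (b - 1),
        "within_error": (n - a) * (b - 1),
    }
    ss = {
        "group": ss_group,
        "subjects_within_groups": ss_subj,
        "condition": ss_cond,
        "interaction": ss_inter,
        "within_error": ss_err_w,
    }

    ms_subj = ss_subj / df["subjects_within_groups"]
    ms_err_w = ss_err_w / df["within_error"]

    def _f(ss_eff: float, df_eff: int, ms_err: float, df_err: int) -> tuple[float, float]:
        if ms_err == 0.0:
            return float("inf"), 0.0
        f = (ss_eff / df_eff) / ms_err
        return f, float(_st.f.sf(f, df_eff, df_err))

    F: dict[str, float] = {}
    p: dict[str, float] = {}
    F["group"], p["group"] = _f(ss_group, df["group"], ms_subj, df["subjects_within_groups"])
    F["condition"], p["condition"] = _f(ss_cond, df["condition"], ms_err_w, df["within_error"])
    F["interaction"], p["interaction"] = _f(
        ss_inter, df["interaction"], ms_err_w, df["within_error"]
    )
    return ss, df, F, p


_EFFECT_ERROR = {
    "group": "subjects_within_groups",
    "condition": "within_error",
    "interaction": "within_error",
}


class MixedAnovaResults:
    """Fitted mixed-ANOVA results.

    Attributes
    ----------
    ss, df, F, p : dict
        Per-effect (and per-error-stratum, for ``ss``/``df``) statistics.
    eta2 : dict
        Partial eta-squared per effect.
    size_class : dict
        S/M/L class of each effect's partial eta-squared.
    """

    effects = ("group", "condition", "interaction")

    def __init__(self, model: MixedAnova, ss: dict, df: dict, F: dict, p: dict) -> None:
        self.model = model
        self.ss = ss
        self.df = df
        self.F = F
        self.p = p
        self.eta2 = {}
        for eff in self.effects:
            denom = ss[eff] + ss[_EFFECT_ERROR[eff]]
            self.eta2[eff] = ss[eff] / denom if denom > 0 else 0.0
        self.size_class = {eff: classify_effect_size(self.eta2[eff]) for eff in self.effects}

    @property
    def ss_total(self) -> float:
        return sum(self.ss.values())

    def anova_table(self) -> pd.DataFrame:
        rows = []
        for eff in self.effects:
            rows.append(
                {
                    "effect": eff,
                    "SS": self.ss[eff],
                    "df": self.df[eff],
                    "F": self.F[eff],
                    "p": self.p[eff],
                    "eta2_partial": self.eta2[eff],
                    "size_class": self.size_class[eff],
                }
            )
        for err in ("subjects_within_groups", "within_error"):
            rows.append(
                {
                    "effect": err,
                    "SS": self.ss[err],
                    "df": self.df[err],
                    "F": np.nan,
                    "p": np.nan,
                    "eta2_partial": np.nan,
                    "size_class": "",
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable ANOVA table."""
        tbl = self.anova_table().copy()
        with pd.option_context("display.float_format", "{:0.4g}".format):
            body = tbl.to_string(index=False)
        header = (
            "Mixed ANOVA (between: {b}; within: {w}; dv: {dv}; n = {n})".format(
                b=self.model.between,
                w=self.model.within,
                dv=self.model.dv,
                n=len(self.model._subjects),
            )
        )
        return header + "\n" + "-" * len(header) + "\n" + body

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        bits = ", ".join(
            f"{e}: p={self.p[e]:.3g}, eta2={self.eta2[e]:.3g} ({self.size_class[e]})"
            for e in self.effects
        )
        return f"<MixedAnovaResults {bits}>"


def anova_by_feature(
    table: pd.DataFrame,
    dv: str = "value",
    feature_col: str = "feature",
) -> pd.DataFrame:
    """Run :class:`MixedAnova` per feature of a long-format feature table.

    Returns one row per feature with p-values, partial eta-squared and size
    classes for the group, cognitive-load and interaction effects, mirroring
    the reference report's per-measure layout.
    """
    validate_feature_table(table.rename(columns={dv: "value"}) if dv != "value" else table)
    rows = []
    for feature, sub in table.groupby(feature_col, sort=True):
        try:
            res = MixedAnova(sub, dv=dv).fit()
        except (DegenerateDataError, InsufficientDataError, UnbalancedDesignError) as exc:
            rows.append({"feature": feature, "error": str(exc)})
            continue
        rows.append(
            {
                "feature": feature,
                "p_group": res.p["group"],
                "eta2_group": res.eta2["group"],
                "class_group": res.size_class["group"],
                "p_cl": res.p["condition"],
                "eta2_cl": res.eta2["condition"],
                "class_cl": res.size_class["condition"],
                "p_interaction": res.p["interaction"],
                "eta2_interaction": res.eta2["interaction"],
                "class_interaction": res.size_class["interaction"],
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Normality screening
# ---------------------------------------------------------------------------


def normality_screen(
    table: pd.DataFrame,
    feature: str | None = None,
    dv: str = "value",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Shapiro-Wilk normality check per group x condition cell.

    Returns a DataFrame with one row per cell (``group``, ``condition``,
    ``n``, ``shapiro_p``, ``flagged``); cells with ``shapiro_p < alpha`` are
    flagged. Constant cells raise
    :class:`~mobiseg.errors.DegenerateDataError`, cells with fewer than 3
    values :class:`~mobiseg.errors.InsufficientDataError`.
    """
    d = table
    if feature is not None:
        d = d[d["feature"] == feature]
    rows = []
    for (grp, cond), cell in d.groupby(["group", "condition"], sort=True):
        vals = cell[dv].to_numpy(dtype=float)
        if len(vals) < 3:
            raise InsufficientDataError(
                f"cell ({grp}, {cond}) has {len(vals)} < 3 values"
            )
        if np.ptp(vals) == 0.0:
            raise DegenerateDataError(f"cell ({grp}, {cond}) is constant")
        p = float(_st.shapiro(vals).pvalue)
        rows.append(
            {
                "group": grp,
                "condition": cond,
                "n": len(vals),
                "shapiro_p": p,
                "flagged": p < alpha,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Contrasts and dual-task cost
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastResult:
    """Percent difference of stroke vs control cell means."""

    feature_name: str
    percent_difference: float  # signed; positive = stroke higher
    direction: str  # "stroke_higher" | "stroke_lower"
    averaging: str  # "pooled_over_CL" | "ST_only" | "DT_only"


def group_contrast_percent(
    cell_means: dict[tuple[str, str], float],
    averaging: str = "pooled_over_CL",
    feature_name: str = "",
) -> ContrastResult:
    """Stroke-vs-control percent contrast from the four cell means.

    ``cell_means`` maps ``(group, condition)`` to the cell mean. With
    ``pooled_over_CL`` the contrast is
    ``100 * (mean(stroke_ST, stroke_DT) - mean(control_ST, control_DT)) /
    mean(control_ST, control_DT)``; ``ST_only``/``DT_only`` compare within a
    single load condition. Rounding to a whole percent is left to reporting.
    """
    if averaging == "pooled_over_CL":
        need = [("stroke", "ST"), ("stroke", "DT"), ("control", "ST"), ("control", "DT")]
    elif averaging == "ST_only":
        need = [("stroke", "ST"), ("control", "ST")]
    elif averaging == "DT_only":
        need = [("stroke", "DT"), ("control", "DT")]
    else:
        raise InvalidSpecError(f"unknown averaging {averaging!r}")
    missing = [k for k in need if k not in cell_means]
    if missing:
        raise InvalidSpecError(f"missing cell means: {missing}")

    stroke = float(np.mean([cell_means[k] for k in need if k[0] == "stroke"]))
    control = float(np.mean([cell_means[k] for k in need if k[0] == "control"]))
    if control == 0.0:
        raise UndefinedContrastError("control mean is zero; contrast undefined")
    pct = 100.0 * (stroke - control) / control
    if not np.isfinite(pct):
        raise UndefinedContrastError("contrast is not finite")
    return ContrastResult(
        feature_name=feature_name,
        percent_difference=pct,
        direction="stroke_higher" if pct >= 0 else "stroke_lower",
        averaging=averaging,
    )


def cell_means(table: pd.DataFrame, feature: str, dv: str = "value") -> dict[tuple[str, str], float]:
    """Group x condition cell means of one feature from a feature table."""
    d = table[table["feature"] == feature]
    out = {
        (g, c): float(cell[dv].mean())
        for (g, c), cell in d.groupby(["group", "condition"], sort=True)
    }
    return out


def dual_task_cost(st_value: float, dt_value: float) -> float:
    """Per-subject dual-task cost, percent: ``100 * (DT - ST) / ST``.

    The package convention is to compute this per subject and average the
    per-subject costs across a group.
    """
    if st_value <= 0:
        raise UndefinedContrastError(
            f"dual-task cost undefined for non-positive ST value {st_value}"
        )
    return 100.0 * (dt_value - st_value) / st_value


def mean_dual_task_cost(
    table: pd.DataFrame, feature: str, group: str | None = None, dv: str = "value"
) -> float:
    """Mean per-subject dual-task cost of one feature (optionally per group)."""
    d = table[table["feature"] == feature]
    if group is not None:
        d = d[d["group"] == group]
    wide = d.pivot(index="subject_id", columns="condition", values=dv).dropna()
    if wide.empty:
        raise InsufficientDataError("no complete subject pairs for dual-task cost")
    costs = [dual_task_cost(st, dt) for st, dt in zip(wide["ST"], wide["DT"])]
    return float(np.mean(costs))
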