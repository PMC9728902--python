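"""Cross-species statistics on segmentation performance.

Ties a train x test performance grid to phylogeny: pairwise divergence
times (Mya, 0.0 for conspecifics), sample-size-weighted mean divergence for
multi-species training sets, univariate OLS regressions of performance on
divergence / training seconds / diversity with a Bonferroni-corrected
alpha, and one-way ANOVA with Tukey HSD for species-level differences.

All models are univariate (one predictor, one response).  Training seconds
and sample sizes vary over orders of magnitude and are log-transformed
(natural log) before regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import METRIC_NAMES, SpeciesSummary

__all__ = [
    "DivergenceTable",
    "ModelSpec",
    "RegressionFit",
    "AnovaResult",
    "weighted_mean_divergence",
    "bonferroni_alpha",
    "fit_univariate_ols",
    "one_way_anova",
    "tukey_hsd",
    "performance_analysis",
    "render_report",
]


class DivergenceTable:
    """Symmetric pairwise species divergence times in Mya, zero diagonal."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.astype(float)
        if list(frame.index) != list(frame.columns):
            raise ValueError("divergence table must be square with matching labels")
        m = frame.to_numpy()
        finite = np.isfinite(m)
        if not np.allclose(np.where(finite & finite.T, m, 0.0),
                           np.where(finite & finite.T, m.T, 0.0), atol=1e-9):
            raise ValueError("divergence table must be symmetric")
        if np.nanmin(m) < 0:
            raise ValueError("divergence times must be non-negative")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal (conspecific) divergences must be 0.0")
        self.frame = frame

    @property
    def species(self) -> list[str]:
        return list(self.frame.index)

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame | list[tuple[str, str, float]]) -> "DivergenceTable":
        """Build from long-form (speciesA, speciesB, mya) records."""
        if not isinstance(pairs, pd.DataFrame):
            pairs = pd.DataFrame(pairs, columns=["speciesA", "speciesB", "mya"])
        names = sorted(set(pairs["speciesA"]) | set(pairs["speciesB"]))
        frame = pd.DataFrame(np.nan, index=names, columns=names)
        for name in names:
            frame.loc[name, name] = 0.0
        for _, row in pairs.iterrows():
            a, b, d = row["speciesA"], row["speciesB"], float(row["mya"])
            frame.loc[a, b] = d
            frame.loc[b, a] = d
        return cls(frame)

    @classmethod
    def from_csv(cls, path) -> "DivergenceTable":
        return cls.from_pairs(pd.read_csv(path))

    def to_pairs(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.species):
            for b in self.species[i + 1:]:
                d = self.frame.loc[a, b]
                if np.isfinite(d):
                    rows.append((a, b, float(d)))
        return pd.DataFrame(rows, columns=["speciesA", "speciesB", "mya"])

    def divergence(self, a: str, b: str) -> float:
        try:
            d = float(self.frame.loc[a, b])
        except KeyError as exc:
            raise KeyError(f"species pair ({a!r}, {b!r}) not in divergence table") from exc
        if math.isnan(d):
            raise KeyError(f"divergence for ({a!r}, {b!r}) is unknown")
        return d


@dataclass(frozen=True)
class ModelSpec:
    """A trained model: its training species and seconds-proportional weights."""

    weights: tuple[tuple[str, float], ...]
    name: str = "multi"

    @classmethod
    def from_dict(cls, weights: dict[str, float], name: str = "multi") -> "ModelSpec":
        return cls(tuple(sorted(weights.items())), name=name)

    @classmethod
    def equal(cls, species: list[str], name: str = "multi") -> "ModelSpec":
        w = 1.0 / len(species)
        return cls.from_dict({sp: w for sp in species}, name=name)

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.weights)
        if any(w < 0 for _, w in self.weights):
            raise ValueError("weights must be non-negative")
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")

    @property
    def trained_species(self) -> list[str]:
        return [sp for sp, _ in self.weights]


def weighted_mean_divergence(
    model: ModelSpec, test_species: str, table: DivergenceTable
) -> float:
    """Sample-size-weighted mean divergence of a training set to a test taxon.

    Conspecific comparisons contribute 0.0 Mya (the table's zero diagonal),
    so the result is 0 exactly when all weight lies on the test species.
    """
    return sum(w * table.divergence(sp, test_species) for sp, w in model.weights)


def bonferroni_alpha(alpha: float = 0.05, m: int = 1) -> float:
    """Familywise alpha/m for m univariate models."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    adjusted_r2: float
    p_slope: float
    n: int
    stderr_slope: float = math.nan

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope (t, n-2 df)."""
        half = stats.t.ppf(0.5 + level / 2, self.n - 2) * self.stderr_slope
        return self.slope - half, self.slope + half


def fit_univariate_ols(
    x: np.ndarray,
    y: np.ndarray,
    log_x: bool = False,
    log_y: bool = False,
) -> RegressionFit:
    """Univariate OLS with optional natural-log transforms.

    NaN pairs are dropped pairwise; the slope p-value is two-sided from the
    t distribution with n-2 df; adjusted R^2 = 1 - (1 - R^2)(n-1)/(n-2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if log_x:
        if np.any(x <= 0):
            raise ValueError("log transform requested for non-positive x")
        x = np.log(x)
    if log_y:
        if np.any(y <= 0):
            raise ValueError("log transform requested for non-positive y")
        y = np.log(y)
    if np.var(x) == 0:
        raise ValueError("zero variance in predictor")
    if np.var(y) == 0:
        # degenerate response: flat line fits with nothing to explain
        adj = 1 - (n - 1) / (n - 2)
        return RegressionFit(0.0, float(y[0]), adj, 1.0, n, 0.0)
    res = stats.linregress(x, y)
    r2 = res.rvalue ** 2
    adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        adjusted_r2=float(adj),
        p_slope=float(res.pvalue),
        n=n,
        stderr_slope=float(res.stderr),
    )


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    p: float


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Standard between/within sums-of-squares decomposition and F test."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = all_vals.size - len(groups)
    f_stat = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f_stat, df_between, df_within))
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        p=p,
    )


def tukey_hsd(groups: list[np.ndarray], labels: list[str] | None = None) -> pd.DataFrame:
    """All-pairs Tukey Honest Significant Differences comparisons.

    Adjusted p-values come from the studentized-range distribution at the
    within-group df.  Returns a tidy frame (group_a, group_b, mean_diff,
    p_adj) with mean_diff = mean(a) - mean(b).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    one_way_anova(groups)  # shares preconditions
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append(
                (
                    labels[i],
                    labels[j],
                    float(res.statistic[i, j]),
                    float(min(1.0, max(0.0, res.pvalue[i, j]))),
                )
            )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "mean_diff", "p_adj"])


def performance_analysis(
    grid: dict[tuple[object, str], SpeciesSummary] | pd.DataFrame,
    divergence_table: DivergenceTable,
    diversity_table: pd.DataFrame | None = None,
    sizes: dict[object, float] | None = None,
    responses: tuple[str, ...] = ("accuracy", "precision", "recall", "f_score", "ser_abs"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fit every univariate (predictor, response) regression over a grid.

    ``grid`` maps (trained, tested) to a :class:`SpeciesSummary` (trained
    is a species name or a :class:`ModelSpec` for multi-species models), or
    is an equivalent tidy frame with ``trained``/``tested``/``divergence_mya``
    and metric columns.  Predictors are divergence (Mya), log training
    seconds when ``sizes`` is given, and any diversity columns keyed by
    tested species.  Significance is flagged at the Bonferroni-corrected
    alpha; on the full 11 x 11 layout the correction uses m = 121.
    """
    if isinstance(grid, pd.DataFrame):
        tidy = grid.copy()
        n_cells = len(tidy)
    else:
        if len(grid) < 3:
            raise ValueError("need at least 3 grid cells")
        rows = []
        for (trained, tested), summary in grid.items():
            if isinstance(trained, ModelSpec):
                div = weighted_mean_divergence(trained, tested, divergence_table)
                trained_name = trained.name
            else:
                div = divergence_table.divergence(trained, tested)
                trained_name = trained
            row = {"trained": trained_name, "tested": tested, "divergence_mya": div}
            row.update(summary.pooled.metrics())
            if sizes is not None:
                row["training_s"] = sizes[trained]
            rows.append(row)
        tidy = pd.DataFrame(rows)
        n_cells = len(tidy)
    if n_cells < 3:
        raise ValueError("need at least 3 grid cells")

    predictors: dict[str, tuple[np.ndarray, bool]] = {
        "divergence_mya": (tidy["divergence_mya"].to_numpy(float), False)
    }
    if "training_s" in tidy.columns:
        predictors["training_s"] = (tidy["training_s"].to_numpy(float), True)
    if diversity_table is not None:
        div_tab = diversity_table.set_index("species") if "species" in diversity_table.columns else diversity_table
        for col in div_tab.columns:
            vals = tidy["tested"].map(div_tab[col]).to_numpy(float)
            predictors[f"diversity_{col}"] = (vals, False)

    fits = []
    for pname, (x, log_x) in predictors.items():
        for rname in responses:
            if rname not in tidy.columns:
                continue
            y = tidy[rname].to_numpy(float)
            try:
                fit = fit_univariate_ols(x, y, log_x=log_x)
            except ValueError:
                continue  # degenerate predictor/response after NaN drop
            fits.append({"predictor": pname, "response": rname, **fit.__dict__})
    if not fits:
        raise ValueError("no regressions could be fitted")
    report = pd.DataFrame(fits)
    m = 121 if n_cells == 121 else len(report)
    a_corr = bonferroni_alpha(alpha, m)
    report["m_models"] = m
    report["alpha_bonferroni"] = a_corr
    report["significant"] = report["p_slope"] < a_corr
    return report


def render_report(report: pd.DataFrame) -> str:
    """Human-readable summary of a performance_analysis frame."""
    a = report["alpha_bonferroni"].iloc[0]
    m = int(report["m_models"].iloc[0])
    lines = [
        f"Univariate OLS fits: {len(report)} models, "
        f"Bonferroni alpha = {a:.3g} (0.05/{m})",
        "",
    ]
    for _, row in report.iterrows():
        star = " *" if row["significant"] else ""
        lines.append(
            f"{row['response']} ~ {row['predictor']}: slope={row['slope']:.4g}, "
            f"adjR2={row['adjusted_r2']:.3f}, p={row['p_slope']:.3g}, n={int(row['n'])}{star}"
        )
    return "\n".join(lines) + "\n"
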