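"""Group-level validation layer: dose-response tests and correlations.

The study table has one row per animal (group label, dose, Dm, HDFm and
optional covariates: Ashcroft score, micro-CT HU peak, dynamic compliance
Cdyn, forced vital capacity FVC, lung wet weight, body weight).

Dose-response contrasts against the control group use one-way ANOVA followed
by Dunnett's multiple-comparison test for parametric readouts, or
Kruskal-Wallis followed by Dunn's test (rank z contrasts vs control,
Bonferroni-adjusted over the control contrasts, tie-corrected) for ordinal
readouts such as the Ashcroft score.  Correlations between indexes and
external readouts are Spearman rank correlations, with an ordinary
least-squares line reported alongside for plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "STAR_THRESHOLDS",
    "DoseResponseResult",
    "CorrelationResult",
    "stars",
    "aggregate",
    "dose_response",
    "correlate",
    "percent_change",
]

#: Significance thresholds for star annotation: * ** *** ****
STAR_THRESHOLDS = (0.05, 0.01, 0.001, 0.0001)


def stars(p: float) -> str:
    """Encode a p-value as '', '*', '**', '***' or '****'."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value outside [0, 1]: {p}")
    return "*" * sum(p < t for t in STAR_THRESHOLDS)


@dataclass
class DoseResponseResult:
    """Per-dose contrasts against the control group."""

    test: str  # "anova+dunnett" or "kruskal+dunn"
    omnibus_p: float
    contrasts: pd.DataFrame  # columns: group, n, mean, p, stars


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation plus an OLS line for the scatter panel."""

    r: float
    p: float
    slope: float
    intercept: float
    n: int


def aggregate(per_section_indexes, how: str = "mean") -> pd.DataFrame:
    """Per-animal Dm/HDFm from per-section indexes.

    Parameters
    ----------
    per_section_indexes
        Iterable of ``(animal_id, DensityIndexes)`` pairs, one per section.
    how
        ``"mean"`` averages section indexes per animal; ``"pool"`` weights
        each section by its tile count (tile-pooled Dm/HDFm).
    """
    rows = [
        {"animal_id": aid, "Dm": ix.Dm, "HDFm": ix.HDFm, "n_tiles": ix.n_tiles}
        for aid, ix in per_section_indexes
    ]
    if not rows:
        raise ValueError("no section indexes to aggregate")
    df = pd.DataFrame(rows)
    if how == "mean":
        out = df.groupby("animal_id", sort=False).agg(
            Dm=("Dm", "mean"), HDFm=("HDFm", "mean"), n_sections=("Dm", "size"),
            n_tiles=("n_tiles", "sum"),
        )
    elif how == "pool":
        def _pool(g: pd.DataFrame) -> pd.Series:
            w = g["n_tiles"] / g["n_tiles"].sum()
            return pd.Series({
                "Dm": float((g["Dm"] * w).sum()),
                "HDFm": float((g["HDFm"] * w).sum()),
                "n_sections": len(g),
                "n_tiles": int(g["n_tiles"].sum()),
            })
        out = df.groupby("animal_id", sort=False).apply(_pool, include_groups=False)
    else:
        raise ValueError(f"how must be 'mean' or 'pool', got {how!r}")
    return out.reset_index()


def _group_samples(table: pd.DataFrame, column: str, group_col: str, control: str):
    if control not in set(table[group_col]):
        raise ValueError(f"control group {control!r} not present in table")
    sub = table[[group_col, column]].dropna()
    groups = list(dict.fromkeys(sub[group_col]))  # preserve first-appearance order
    samples = {g: sub.loc[sub[group_col] == g, column].to_numpy(dtype=float) for g in groups}
    for g, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations for {column!r}")
    treated = [g for g in groups if g != control]
    if not treated:
        raise ValueError("dose-response needs at least one non-control group")
    return samples, treated


def _dunn_vs_control(samples: dict, control: str, treated: list) -> np.ndarray:
    """Dunn's rank z-test of each treated group vs control, Bonferroni over contrasts."""
    order = [control] + treated
    values = np.concatenate([samples[g] for g in order])
    ranks = sps.rankdata(values)
    n_total = values.size
    # tie correction to the rank variance
    _, counts = np.unique(values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1))
    s2 = n_total * (n_total + 1) / 12.0 - tie_term
    mean_ranks, sizes = {}, {}
    pos = 0
    for g in order:
        n_g = samples[g].size
        mean_ranks[g] = ranks[pos : pos + n_g].mean()
        sizes[g] = n_g
        pos += n_g
    m = len(treated)
    pvals = []
    for g in treated:
        se = np.sqrt(s2 * (1.0 / sizes[g] + 1.0 / sizes[control]))
        if se == 0:
            pvals.append(1.0)
            continue
        z = (mean_ranks[g] - mean_ranks[control]) / se
        pvals.append(min(1.0, 2.0 * sps.norm.sf(abs(z)) * m))
    return np.asarray(pvals)


def dose_response(
    table: pd.DataFrame,
    column: str,
    group_col: str = "group",
    control: str = "control",
    parametric: bool = True,
) -> DoseResponseResult:
    """Omnibus test plus per-dose contrasts vs the control group.

    Parametric: one-way ANOVA, Dunnett contrasts.  Nonparametric (ordinal
    readouts): Kruskal-Wallis, Dunn contrasts.  A column that is constant
    across all groups is degenerate: every p is reported as 1 with a warning.
    """
    samples, treated = _group_samples(table, column, group_col, control)
    values = [samples[g] for g in [control] + treated]
    if np.ptp(np.concatenate(values)) == 0:
        warnings.warn(f"column {column!r} is constant across groups; reporting p = 1", stacklevel=2)
        omnibus_p = 1.0
        pvals = np.ones(len(treated))
        test = "degenerate"
    elif parametric:
        omnibus_p = float(sps.f_oneway(*values).pvalue)
        res = sps.dunnett(*[samples[g] for g in treated], control=samples[control])
        pvals = np.atleast_1d(res.pvalue)
        test = "anova+dunnett"
    else:
        omnibus_p = float(sps.kruskal(*values).pvalue)
        pvals = _dunn_vs_control(samples, control, treated)
        test = "kruskal+dunn"
    contrasts = pd.DataFrame({
        "group": treated,
        "n": [samples[g].size for g in treated],
        "mean": [samples[g].mean() for g in treated],
        "p": pvals,
        "stars": [stars(float(p)) for p in pvals],
    })
    return DoseResponseResult(test=test, omnibus_p=omnibus_p, contrasts=contrasts)


def correlate(table: pd.DataFrame, x: str, y: str) -> CorrelationResult:
    """Spearman correlation of two per-animal columns, pairwise-complete."""
    sub = table[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError(f"need at least 3 paired values for {x!r} vs {y!r}, got {len(sub)}")
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError(f"correlation of {x!r} vs {y!r} undefined: zero-variance column")
    rho, p = sps.spearmanr(xv, yv)
    fit = sps.linregress(xv, yv)
    return CorrelationResult(r=float(rho), p=float(p), slope=float(fit.slope),
                             intercept=float(fit.intercept), n=len(sub))


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Relative change of a treated group mean over the control mean, in percent."""
    if control_mean <= 0:
        raise ValueError(f"control mean must be positive, got {control_mean}")
    return 100.0 * (treated_mean - control_mean) / control_mean
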