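"""Summary statistics: thresholds, refractive gain, RM-ANOVA, post-hocs.

The three-way repeated-measures ANOVA is the univariate within-subject
decomposition on cell means: for each effect (3 main effects, 3 two-way
interactions, 1 three-way), ``F = MS_effect / MS_(effect x subject)``,
with ``df_effect = prod(levels - 1)`` over the effect's factors and
``df_error = df_effect * (n_subjects - 1)``.  Effect size is partial
eta squared, ``SS_effect / (SS_effect + SS_error)``.  No sphericity
correction is applied by default (a Greenhouse-Geisser option exists),
matching the convention of reporting uncorrected degrees of freedom.

Refractive gain is the per-subject, per-location ratio
``Rx = MAD_blur / MAD_clear`` with MAD first averaged over the cue
factor within each blur level.  Gains are tested against 1.0 per
location (one-sample t) and between the horizontal (nasal + temporal)
and vertical (superior + inferior) meridians (paired t on per-subject
meridian means).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import BLUR_LEVELS, CUE_LEVELS, HORIZONTAL, LOCATIONS, VERTICAL
from .experiment import Dataset

__all__ = [
    "IncompleteDesignError",
    "InvalidDataError",
    "RmAnovaResult",
    "TTestResult",
    "compute_tables",
    "refractive_gain",
    "rm_anova_threeway",
    "posthoc_pairwise",
    "gain_tests",
    "format_report",
    "write_results",
]

FACTORS = ("location", "blur", "cue")
_DEFAULT_LEVELS = {"location": LOCATIONS, "blur": BLUR_LEVELS, "cue": CUE_LEVELS}


class IncompleteDesignError(ValueError):
    """The factorial table is missing cells or is unbalanced."""


class InvalidDataError(ValueError):
    """Data cannot support the requested statistic."""


@dataclass(frozen=True)
class RmAnovaResult:
    effect: str
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class TTestResult:
    label: str
    t: float
    df: int
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float


def compute_tables(dataset: Dataset) -> pd.DataFrame:
    """Per-cell summary: MAD averaged over sessions, RT over correct trials."""
    mad = (
        dataset.estimates.groupby(["subject", *FACTORS], as_index=False)["mad_arcmin"]
        .mean()
        .rename(columns={"mad_arcmin": "mad"})
    )
    correct = dataset.trials[dataset.trials["correct"]]
    rt = (
        correct.groupby(["subject", *FACTORS], as_index=False)["rt_ms"]
        .mean()
        .rename(columns={"rt_ms": "rt"})
    )
    table = mad.merge(rt, on=["subject", *FACTORS], how="left")
    n_cells = int(
        np.prod([dataset.estimates[c].nunique() for c in ("subject", *FACTORS)])
    )
    if len(table) != n_cells or table[["mad", "rt"]].isna().any().any():
        raise IncompleteDesignError("threshold table is missing cells")
    return table


def _pivot(table: pd.DataFrame, dv: str) -> tuple[np.ndarray, list, dict[str, list]]:
    """Stack a long factorial table into y[subject, location, blur, cue]."""
    subjects = list(pd.unique(table["subject"]))
    levels = {}
    for f in FACTORS:
        default = [l for l in _DEFAULT_LEVELS[f] if l in set(table[f])]
        extra = [l for l in pd.unique(table[f]) if l not in default]
        levels[f] = default + extra
    shape = (len(subjects), *(len(levels[f]) for f in FACTORS))
    expected = int(np.prod(shape))
    if len(table) != expected or table.duplicated(["subject", *FACTORS]).any():
        raise IncompleteDesignError(
            f"need exactly one observation per subject x cell ({expected} rows)"
        )
    y = np.full(shape, np.nan)
    index = {
        "subject": {s: i for i, s in enumerate(subjects)},
        **{f: {l: i for i, l in enumerate(levels[f])} for f in FACTORS},
    }
    for row in table.itertuples(index=False):
        d = row._asdict()
        y[
            index["subject"][d["subject"]],
            index["location"][d["location"]],
            index["blur"][d["blur"]],
            index["cue"][d["cue"]],
        ] = d[dv]
    if np.isnan(y).any():
        raise IncompleteDesignError("incomplete factorial design")
    return y, subjects, levels


def _effect_deviation(y: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Inclusion-exclusion deviation term for the effect on ``axes``."""
    all_axes = tuple(range(y.ndim))
    e = np.zeros([y.shape[a] if a in axes else 1 for a in all_axes])
    for r in range(len(axes) + 1):
        for sub in itertools.combinations(axes, r):
            keep = tuple(a for a in all_axes if a not in sub)
            sign = (-1) ** (len(axes) - len(sub))
            e = e + sign * y.mean(axis=keep, keepdims=True)
    return e


def _subset_ss(y: np.ndarray, axes: tuple[int, ...]) -> float:
    e = _effect_deviation(y, axes)
    return float((e**2).sum() * (y.size / e.size))


def rm_anova_threeway(
    table: pd.DataFrame,
    dv: str = "mad",
    sphericity_correction: bool = False,
) -> dict[str, RmAnovaResult]:
    """Three-way within-subject ANOVA of a complete factorial table.

    Returns one :class:`RmAnovaResult` per effect, keyed by effect name
    (``"location"``, ..., ``"location:blur:cue"``).  With
    ``sphericity_correction`` the Greenhouse-Geisser epsilon of each
    effect's subject-by-effect covariance adjusts the degrees of freedom
    used for the p-value (F is unchanged).
    """
    y, subjects, levels = _pivot(table, dv)
    n = len(subjects)
    if n < 2:
        raise InvalidDataError("repeated-measures ANOVA needs >= 2 subjects")
    results: dict[str, RmAnovaResult] = {}
    factor_axes = {f: i + 1 for i, f in enumerate(FACTORS)}  # axis 0 = subject
    for r in range(1, len(FACTORS) + 1):
        for combo in itertools.combinations(FACTORS, r):
            axes = tuple(factor_axes[f] for f in combo)
            ss_effect = _subset_ss(y, axes)
            ss_error = _subset_ss(y, (0, *axes))
            df_effect = int(np.prod([len(levels[f]) - 1 for f in combo]))
            df_error = df_effect * (n - 1)
            if ss_error == 0.0:
                f_stat, p = (0.0, 1.0) if ss_effect == 0.0 else (np.inf, 0.0)
            else:
                f_stat = (ss_effect / df_effect) / (ss_error / df_error)
                df1, df2 = df_effect, df_error
                if sphericity_correction:
                    eps = _gg_epsilon(y, axes)
                    df1, df2 = df1 * eps, df2 * eps
                p = float(stats.f.sf(f_stat, df1, df2))
            denom = ss_effect + ss_error
            eta = ss_effect / denom if denom > 0 else 0.0
            results[":".join(combo)] = RmAnovaResult(
                effect=":".join(combo),
                F=float(f_stat),
                df_effect=df_effect,
                df_error=df_error,
                p=p,
                partial_eta_sq=float(eta),
                ss_effect=ss_effect,
                ss_error=ss_error,
            )
    return results


def _gg_epsilon(y: np.ndarray, axes: tuple[int, ...]) -> float:
    """Greenhouse-Geisser epsilon of one within-subject effect.

    Computed on the covariance of per-subject scores along orthonormal
    contrasts spanning the effect subspace, so a single-df effect always
    has epsilon exactly 1.
    """
    all_axes = tuple(range(y.ndim))
    other = tuple(a for a in all_axes[1:] if a not in axes)
    m = y.mean(axis=other) if other else y  # subjects x effect-factor levels
    m = m.reshape(m.shape[0], -1)

    def centered_basis(levels: int) -> np.ndarray:
        u = np.linalg.svd(np.eye(levels) - 1.0 / levels)[0]
        return u[:, : levels - 1]

    contrasts = np.ones((1, 1))
    for a in axes:
        contrasts = np.kron(contrasts, centered_basis(y.shape[a]))
    scores = m @ contrasts  # subjects x df
    d = scores.shape[1]
    cov = np.atleast_2d(np.cov(scores, rowvar=False))
    denom = d * float((cov * cov.T).sum())
    if denom == 0:
        return 1.0
    eps = float(np.trace(cov)) ** 2 / denom
    return float(min(1.0, max(eps, 1.0 / d)))


def refractive_gain(table: pd.DataFrame) -> pd.DataFrame:
    """Per subject x location gain ``Rx = MAD_blur / MAD_clear``.

    MAD is first averaged over the cue factor within each blur level.
    """
    mean_over_cue = table.groupby(["subject", "location", "blur"], as_index=False)[
        "mad"
    ].mean()
    wide = mean_over_cue.pivot(index=["subject", "location"], columns="blur", values="mad")
    if wide.isna().any().any() or not {"clear", "blurred"} <= set(wide.columns):
        raise IncompleteDesignError("gain computation needs both blur levels everywhere")
    if (wide["clear"] <= 0).any():
        raise InvalidDataError("clear MAD must be positive to form a ratio")
    out = wide.reset_index()
    out["rx"] = out["blurred"] / out["clear"]
    return out[["subject", "location", "rx"]]


def _t_ci(diffs: np.ndarray, label: str, popmean: float = 0.0) -> TTestResult:
    n = len(diffs)
    if n < 2:
        raise InvalidDataError("t-test needs >= 2 subjects")
    mean = float(np.mean(diffs)) - popmean
    sem = float(stats.sem(diffs))
    df = n - 1
    if sem == 0.0:
        t_stat, p = (0.0, 1.0) if mean == 0.0 else (np.inf * np.sign(mean), 0.0)
        half = 0.0
    else:
        t_stat = mean / sem
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
        half = float(stats.t.ppf(0.975, df)) * sem
    return TTestResult(
        label=label,
        t=float(t_stat),
        df=df,
        p=p,
        mean_diff=mean,
        ci_low=mean - half,
        ci_high=mean + half,
    )


def posthoc_pairwise(
    table: pd.DataFrame, factor: str, dv: str = "mad"
) -> list[TTestResult]:
    """Bonferroni-corrected paired t-tests on subject marginal means."""
    if factor not in table.columns:
        raise InvalidDataError(f"unknown factor {factor!r}")
    levels = [l for l in _DEFAULT_LEVELS.get(factor, ()) if l in set(table[factor])]
    levels += [l for l in pd.unique(table[factor]) if l not in levels]
    if len(levels) < 2:
        raise InvalidDataError("post-hoc comparisons need >= 2 levels")
    marginals = (
        table.groupby(["subject", factor])[dv].mean().unstack(factor)
    )
    if len(marginals) < 2:
        raise InvalidDataError("post-hoc comparisons need >= 2 subjects")
    pairs = list(itertools.combinations(levels, 2))
    results = []
    for a, b in pairs:
        res = _t_ci((marginals[a] - marginals[b]).to_numpy(), label=f"{a} vs {b}")
        corrected = min(1.0, res.p * len(pairs))
        results.append(
            TTestResult(
                label=res.label,
                t=res.t,
                df=res.df,
                p=corrected,
                mean_diff=res.mean_diff,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
            )
        )
    return results


def gain_tests(gains: pd.DataFrame) -> list[TTestResult]:
    """One-sample t of Rx against 1.0 per location, plus the
    horizontal-vs-vertical meridian paired t on per-subject means."""
    missing = set(LOCATIONS) - set(gains["location"])
    if missing:
        raise IncompleteDesignError(f"gains missing locations: {sorted(missing)}")
    wide = gains.pivot(index="subject", columns="location", values="rx")
    if len(wide) < 2:
        raise InvalidDataError("gain tests need >= 2 subjects")
    results = [
        _t_ci(wide[loc].to_numpy(), label=f"rx[{loc}] vs 1.0", popmean=1.0)
        for loc in LOCATIONS
    ]
    horizontal = wide[list(HORIZONTAL)].mean(axis=1)
    vertical = wide[list(VERTICAL)].mean(axis=1)
    results.append(
        _t_ci((horizontal - vertical).to_numpy(), label="horizontal vs vertical meridian")
    )
    return results


def format_report(
    anova: dict[str, dict[str, RmAnovaResult]],
    posthocs: dict[str, list[TTestResult]] | None = None,
    gains: list[TTestResult] | None = None,
) -> str:
    """Plain-text report in conventional notation:
    ``F(df1,df2) = x, p = y, partial eta^2 = z``."""
    lines = []
    for dv, results in anova.items():
        lines.append(f"== Repeated-measures ANOVA ({dv}) ==")
        for name, res in results.items():
            lines.append(
                f"  {name}: F({res.df_effect},{res.df_error}) = {res.F:.3f}, "
                f"p = {res.p:.4g}, partial eta^2 = {res.partial_eta_sq:.3f}"
            )
    for section, tests in (posthocs or {}).items():
        lines.append(f"== Post-hoc pairwise ({section}, Bonferroni) ==")
        for res in tests:
            lines.append(
                f"  {res.label}: diff = {res.mean_diff:.4f} "
                f"[{res.ci_low:.4f}, {res.ci_high:.4f}], "
                f"t({res.df}) = {res.t:.3f}, p = {res.p:.4g}"
            )
    if gains:
        lines.append("== Refractive gain tests ==")
        for res in gains:
            lines.append(
                f"  {res.label}: diff = {res.mean_diff:.4f} "
                f"[{res.ci_low:.4f}, {res.ci_high:.4f}], "
                f"t({res.df}) = {res.t:.3f}, p = {res.p:.4g}"
            )
    return "\n".join(lines) + "\n"


def _anova_frame(results: dict[str, RmAnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "F": r.F,
                "df_effect": r.df_effect,
                "df_error": r.df_error,
                "p": r.p,
                "partial_eta_sq": r.partial_eta_sq,
            }
            for r in results.values()
        ]
    )


def _ttest_frame(results: list[TTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "comparison": r.label,
                "t": r.t,
                "df": r.df,
                "p": r.p,
                "mean_diff": r.mean_diff,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
            }
            for r in results
        ]
    )


def write_results(dataset: Dataset, out_dir) -> Path:
    """Full analysis of a dataset written as CSV tables plus a report.

    Produces ``anova_mad.csv``, ``anova_rt.csv``,
    ``posthoc_location_mad.csv``, ``gains.csv``, ``gain_tests.csv`` and
    ``report.txt``; returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = compute_tables(dataset)
    anova = {dv: rm_anova_threeway(table, dv) for dv in ("mad", "rt")}
    posthoc = posthoc_pairwise(table, "location", "mad")
    gains = refractive_gain(table)
    g_tests = gain_tests(gains)
    table.to_csv(out / "threshold_table.csv", index=False)
    for dv, results in anova.items():
        _anova_frame(results).to_csv(out / f"anova_{dv}.csv", index=False)
    _ttest_frame(posthoc).to_csv(out / "posthoc_location_mad.csv", index=False)
    gains.to_csv(out / "gains.csv", index=False)
    _ttest_frame(g_tests).to_csv(out / "gain_tests.csv", index=False)
    report = format_report(anova, {"location (mad)": posthoc}, g_tests)
    (out / "report.txt").write_text(report)
    return out
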