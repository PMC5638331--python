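"""Repeated-measures inference on TBV-corrected ratio tables.

The machinery is the one-sample Hotelling T² test applied to within-subject
contrast vectors. For a factor with L levels, each subject contributes the
(L−1)-vector of differences from the first level of their per-level cell
means; for the step × ROI interaction each subject contributes the
(L_step−1)(L_roi−1) double differences. Under the null of no factor effect
the contrast vectors have zero mean, and

    T² = n · d̄ᵀ S⁻¹ d̄,      T² ~ (νp/(ν−p+1)) F(p, ν−p+1),  ν = n − 1,

with d̄ the mean contrast vector, S its unbiased sample covariance, p the
contrast dimension and n the number of subjects. The critical value at
level α is CV = νp/(ν−p+1) · F_{1−α}(p, ν−p+1); the test rejects iff
T² > CV. This is exact under multivariate normality of the contrasts and
needs no sphericity assumption.

Effect sizes use generalized eta squared for fully within-subject designs
(Olejnik–Algina convention): the effect sum of squares divided by the
effect SS plus every subject-level error SS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .volumetrics import validate_crossing

__all__ = [
    "FACTORS",
    "PAIRWISE_COMPARISONS",
    "HotellingResult",
    "PairwiseResult",
    "hotelling_one_sample",
    "hotelling_critical",
    "repeated_measures_test",
    "generalized_eta_squared",
    "within_subject_ss",
    "pairwise_step_tests",
]

logger = logging.getLogger(__name__)

FACTORS = ("step", "roi", "step_x_roi", "run", "day")

#: The seven pipeline comparisons tested pairwise per ROI. FS is compared
#: only to N4SS, the step whose pipeline it most resembles.
PAIRWISE_COMPARISONS: tuple[tuple[str, str], ...] = (
    ("ORIG", "RROT"),
    ("ORIG", "N4BC"),
    ("ORIG", "N4SS"),
    ("RROT", "N4BC"),
    ("RROT", "N4SS"),
    ("N4BC", "N4SS"),
    ("N4SS", "FS"),
)


@dataclass(frozen=True)
class HotellingResult:
    factor: str
    t2: float
    p_contrasts: int
    n_subjects: int
    alpha: float
    critical_value: float
    eta2_g: float
    reject: bool

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "t2": self.t2,
            "p_contrasts": self.p_contrasts,
            "n_subjects": self.n_subjects,
            "alpha": self.alpha,
            "critical_value": self.critical_value,
            "eta2_g": self.eta2_g,
            "reject": self.reject,
        }


@dataclass(frozen=True)
class PairwiseResult:
    comparison: str
    roi: str
    t: float
    df: int
    p_value: float
    alpha: float
    n_comparisons: int
    significant: bool

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "roi": self.roi,
            "t": self.t,
            "df": self.df,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "n_comparisons": self.n_comparisons,
            "significant": self.significant,
        }


def hotelling_one_sample(D) -> float:
    """One-sample Hotelling T² statistic n·d̄ᵀS⁻¹d̄ of a contrast matrix.

    ``D`` is an n × p matrix of per-subject contrast scores. An all-zero
    matrix (identical repeated measurements, the exact-null case) returns
    0.0; otherwise a singular contrast covariance raises.
    """
    D = np.atleast_2d(np.asarray(D, dtype=float))
    if D.ndim != 2:
        raise ValueError("D must be a 2D (subjects x contrasts) matrix")
    n, p = D.shape
    if p < 1:
        raise ValueError("at least one contrast column is required")
    if n <= p:
        raise ValueError(f"need n > p subjects, got n={n}, p={p}")
    if not np.any(D):
        return 0.0
    dbar = D.mean(axis=0)
    variances = D.var(axis=0)
    if np.any((variances == 0) & (dbar != 0)):
        # a contrast that is nonzero yet identical for every subject (the
        # noise-free limit): the discrepancy is certain, T2 diverges
        return float("inf")
    S = np.atleast_2d(np.cov(D, rowvar=False, ddof=1))
    try:
        sol = np.linalg.solve(S, dbar)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular contrast covariance (collinear contrasts)") from exc
    if not np.all(np.isfinite(sol)):
        raise ValueError("singular contrast covariance (collinear contrasts)")
    return float(n * dbar @ sol)


def hotelling_critical(p: int, n: int | None = None, alpha: float = 0.05, *, df: int | None = None) -> float:
    """Critical value of the one-sample T² law: νp/(ν−p+1) · F_{1−α}(p, ν−p+1).

    ``df`` is the T² degrees of freedom ν; by default ν = n − 1 for a
    sample of n subjects (equivalently p(n−1)/(n−p) · F_{1−α}(p, n−p)).
    Passing ``df`` explicitly recomputes a critical value from a reported
    (p, ν) pair.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    if df is None:
        if n is None:
            raise ValueError("provide either n or df")
        if n <= p:
            raise ValueError(f"need n > p, got n={n}, p={p}")
        df = n - 1
    if df < p:
        raise ValueError(f"need df >= p, got df={df}, p={p}")
    return float(df * p / (df - p + 1) * stats.f.ppf(1 - alpha, p, df - p + 1))


def _cell_means(ratios: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    return ratios.groupby(["participant_id", *by], sort=False, observed=True)["ratio"].mean()


def _level_order(ratios: pd.DataFrame, column: str) -> list:
    return list(dict.fromkeys(ratios[column]))


def _eta_or_zero(ss: dict[str, float], effect: str) -> float:
    # a table with zero total SS (every cell identical, the noise-free
    # exact null) carries no effect; the strict public function raises
    if ss.get("total", 0.0) == 0.0:
        return 0.0
    return generalized_eta_squared(ss, effect)


def _wide(cells: pd.Series, column: str, order: list) -> np.ndarray:
    wide = cells.unstack(column).reindex(columns=order)
    if wide.isna().any().any():
        raise ValueError(f"incomplete cells for factor {column!r}")
    return wide.to_numpy()


def repeated_measures_test(
    ratios: pd.DataFrame,
    factor: str,
    alpha: float = 0.05,
) -> HotellingResult:
    """Hotelling T² test for one within-subject factor of the ratio table.

    ``factor`` is one of ``step``, ``roi``, ``step_x_roi`` (computed on
    per-subject step × ROI cell means collapsed over scans and runs),
    ``run`` (algorithmic consistency; scan 1 only, collapsed over steps and
    ROIs) or ``day`` (scan-rescan consistency; run 1 only, collapsed over
    steps and ROIs). Contrasts are differences from the first factor level
    in order of appearance; the interaction uses double differences, giving
    contrast dimensions L−1 and (L_step−1)(L_roi−1).

    The table must be a complete crossing; partial tables are refused.
    """
    if factor not in FACTORS:
        raise ValueError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    report = validate_crossing(ratios)
    if not report.is_complete:
        raise ValueError(f"incomplete design: {report.summary()}")

    steps = _level_order(ratios, "step")
    rois = _level_order(ratios, "roi")

    if factor in ("step", "roi", "step_x_roi"):
        cells = _cell_means(ratios, ["step", "roi"])
        y = (
            cells.unstack(["step", "roi"])
            .reindex(columns=pd.MultiIndex.from_product([steps, rois]))
            .to_numpy()
            .reshape(-1, len(steps), len(rois))
        )  # (n, L_step, L_roi)
        if np.isnan(y).any():
            raise ValueError("incomplete step x roi cells")
        if factor == "step":
            levels = y.mean(axis=2)  # (n, L_step)
            D = levels[:, 1:] - levels[:, [0]]
            eta = _eta_or_zero(within_subject_ss(y), "A")
        elif factor == "roi":
            levels = y.mean(axis=1)  # (n, L_roi)
            D = levels[:, 1:] - levels[:, [0]]
            eta = _eta_or_zero(within_subject_ss(y), "B")
        else:
            dd = y - y[:, [0], :] - y[:, :, [0]] + y[:, [0], [0]][:, :, None]
            D = dd[:, 1:, 1:].reshape(y.shape[0], -1)
            eta = _eta_or_zero(within_subject_ss(y), "AB")
    elif factor == "run":
        sub = ratios[ratios["scan_index"] == 1]
        if sub.empty:
            raise ValueError("no scan_index == 1 records for the run factor")
        order = sorted(sub["run_index"].unique())
        cells = _cell_means(sub, ["run_index"])
        levels = _wide(cells, "run_index", order)
        D = levels[:, 1:] - levels[:, [0]]
        eta = _eta_or_zero(within_subject_ss(levels[:, :, None]), "A")
    else:  # day
        sub = ratios[ratios["run_index"] == 1]
        if sub.empty:
            raise ValueError("no run_index == 1 records for the day factor")
        order = sorted(sub["scan_index"].unique())
        cells = _cell_means(sub, ["scan_index"])
        levels = _wide(cells, "scan_index", order)
        D = levels[:, 1:] - levels[:, [0]]
        eta = _eta_or_zero(within_subject_ss(levels[:, :, None]), "A")

    n, p = D.shape
    if p < 1:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    t2 = hotelling_one_sample(D)
    cv = hotelling_critical(p, n, alpha)
    logger.info("factor=%s: n=%d, p=%d contrasts, T2=%.4f, CV=%.2f", factor, n, p, t2, cv)
    return HotellingResult(
        factor=factor,
        t2=t2,
        p_contrasts=p,
        n_subjects=n,
        alpha=alpha,
        critical_value=cv,
        eta2_g=eta,
        reject=bool(t2 > cv),
    )


def within_subject_ss(y: np.ndarray) -> dict[str, float]:
    """Sums of squares of a fully within-subject (subject × A × B) cell array.

    ``y`` has shape (n_subjects, a, b); pass b = 1 for a one-way design.
    Returns the decomposition {A, B, AB, subject, subject_x_A, subject_x_B,
    subject_x_AB} (interaction terms with B are 0 when b = 1).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("y must have shape (subjects, A levels, B levels)")
    n, a, b = y.shape
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)
    ss = {
        "A": float(n * b * ((m_a - grand) ** 2).sum()),
        "B": float(n * a * ((m_b - grand) ** 2).sum()),
        "subject": float(a * b * ((m_s - grand) ** 2).sum()),
        "AB": float(n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()),
        "subject_x_A": float(
            b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
        ),
        "subject_x_B": float(
            a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
        ),
    }
    ss_total = float(((y - grand) ** 2).sum())
    ss["subject_x_AB"] = max(ss_total - sum(ss.values()), 0.0)
    ss["total"] = ss_total
    return ss


def generalized_eta_squared(ss: dict[str, float], effect: str) -> float:
    """Generalized eta squared of one effect in a fully within-subject design.

    ``ss`` is the decomposition from :func:`within_subject_ss`; ``effect``
    is ``"A"``, ``"B"`` or ``"AB"``. The denominator adds every
    subject-level variance source (subject main effect and all
    subject-by-factor interactions) to the effect SS, so values are
    comparable across designs. A zero effect SS returns 0 even when the
    error SS is 0 (the exact-null, noise-free case); a design with zero
    total SS is degenerate and raises.
    """
    if effect not in ("A", "B", "AB"):
        raise ValueError(f"effect must be 'A', 'B' or 'AB', got {effect!r}")
    if ss.get("total", 0.0) == 0.0:
        raise ValueError("zero total sum of squares: all cells identical")
    ss_effect = ss[effect]
    if ss_effect == 0.0:
        return 0.0
    denom = ss_effect + ss["subject"] + ss["subject_x_A"] + ss["subject_x_B"] + ss["subject_x_AB"]
    return float(ss_effect / denom)


def pairwise_step_tests(ratios: pd.DataFrame, alpha: float = 0.05) -> list[PairwiseResult]:
    """The seven paired step comparisons, per ROI, Bonferroni-corrected.

    For each ROI, per-subject mean ratios (over scans and runs) at the two
    steps are compared with a two-sided paired t-test (df = n − 1);
    significance is declared at alpha / 7. Returns 7 × n_rois results in
    comparison-major order.
    """
    report = validate_crossing(ratios)
    if not report.is_complete:
        raise ValueError(f"incomplete design: {report.summary()}")
    steps = set(ratios["step"].unique())
    needed = {s for pair in PAIRWISE_COMPARISONS for s in pair}
    missing = needed - steps
    if missing:
        raise ValueError(f"missing step level(s) for pairwise tests: {sorted(missing)}")
    rois = _level_order(ratios, "roi")
    cells = _cell_means(ratios, ["step", "roi"])
    m = len(PAIRWISE_COMPARISONS)
    results = []
    for step_a, step_b in PAIRWISE_COMPARISONS:
        for roi in rois:
            a = cells.xs((step_a, roi), level=("step", "roi"))
            b = cells.xs((step_b, roi), level=("step", "roi"))
            b = b.reindex(a.index)
            diff = a.to_numpy() - b.to_numpy()
            if not np.any(diff):
                # identical paired samples: zero difference with zero
                # variance is the exact null, not an indeterminate 0/0
                t, p_value = 0.0, 1.0
            else:
                t, p_value = stats.ttest_rel(a.to_numpy(), b.to_numpy())
            results.append(
                PairwiseResult(
                    comparison=f"{step_a} vs {step_b}",
                    roi=roi,
                    t=float(t),
                    df=len(a) - 1,
                    p_value=float(p_value),
                    alpha=alpha,
                    n_comparisons=m,
                    significant=bool(p_value < alpha / m),
                )
            )
    return results
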