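"""Agreement and association statistics for the two timing methods.

Three statistics quantify how well the broad (meal-slot) method reproduces
per-participant architecture variables computed from precise times:

* **ICC(3,1)** — the individual-measure, two-way mixed-effects *consistency*
  intraclass correlation (Shrout & Fleiss), which treats the two methods as
  fixed and ignores a constant shift between them.  From the two-way ANOVA
  decomposition over participants x methods with k = 2 methods::

      ICC = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)

  with an exact F-based confidence interval from
  F = MS_subjects / MS_error on (n-1, (n-1)(k-1)) degrees of freedom.

* **Bland-Altman** — mean difference d = precise - broad, limits of
  agreement mean(d) +/- z sd(d) (z = 1.96 by default), and the share of
  pairs strictly outside the limits.  The precise-minus-broad sign
  convention makes an *under*estimate of frequency by the broad method a
  *positive* mean difference.

* **Pearson r with Fisher-z CI** — tanh(atanh(r) +/- z_(1-a/2)/sqrt(n-3)),
  used both for method-vs-method association and for associations of
  architecture variables with participant outcomes (TEI, BMI, WC, ODP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .architecture_metrics import (
    VARIABLES,
    ParticipantArchitecture,
    architecture_frame,
)
from .occasion_builder import BROAD, PRECISE


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05  # two-sided CI level 1 - alpha
    z: float = 1.96  # normal quantile for the limits of agreement
    k: int = 2  # number of methods compared (fixed)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.z <= 0:
            raise ValueError("z must be positive")
        if self.k != 2:
            raise ValueError("exactly two methods are compared")


@dataclass
class PairedSeries:
    """Complete-case paired per-participant values: x = precise, y = broad."""

    variable: str
    x: np.ndarray
    y: np.ndarray
    n_excluded: int = 0

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")

    @property
    def n(self) -> int:
        return len(self.x)

    @classmethod
    def from_architecture(
        cls, participants: list[ParticipantArchitecture], variable: str
    ) -> "PairedSeries":
        """Pair precise/broad values by participant id, dropping (and
        counting) pairs where either side is undefined."""
        frame = architecture_frame(participants)
        wide = frame.pivot(index="participant_id", columns="method", values=variable)
        if PRECISE not in wide or BROAD not in wide:
            raise ValueError("both methods are required to form pairs")
        complete = wide.dropna(subset=[PRECISE, BROAD])
        return cls(
            variable=variable,
            x=complete[PRECISE].to_numpy(),
            y=complete[BROAD].to_numpy(),
            n_excluded=len(wide) - len(complete),
        )


@dataclass
class AgreementResult:
    """ICC, Bland-Altman summary, and sample size for one variable."""

    variable: str
    n: int
    icc: float
    icc_ci: tuple[float, float]
    mean_diff: float
    sd_diff: float
    loa: tuple[float, float]
    pct_outside: float
    n_excluded: int = 0
    ba_points: pd.DataFrame | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "variable": self.variable,
            "n": self.n,
            "icc": self.icc,
            "icc_ci_low": self.icc_ci[0],
            "icc_ci_high": self.icc_ci[1],
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa[0],
            "loa_high": self.loa[1],
            "pct_outside": self.pct_outside,
            "n_excluded": self.n_excluded,
        }


def icc_consistency(
    s: PairedSeries, cfg: StatsConfig = StatsConfig()
) -> tuple[float, float, float]:
    """ICC(3,1) with its exact F-based confidence interval.

    Returns ``(icc, ci_low, ci_high)``.  Raises on fewer than three pairs or
    a degenerate (zero total variance) series.
    """
    n, k = s.n, cfg.k
    if n < 3:
        raise ValueError("ICC requires at least 3 pairs")
    data = np.column_stack([s.x, s.y])
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite values in paired series")
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("degenerate series: zero total variance")
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_err == 0:
        return 1.0, 1.0, 1.0
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
    f_obs = ms_rows / ms_err
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_hi = sps.f.ppf(1 - cfg.alpha / 2, df1, df2)
    f_lo = sps.f.ppf(cfg.alpha / 2, df1, df2)
    lower = (f_obs / f_hi - 1) / (f_obs / f_hi + k - 1)
    upper = (f_obs / f_lo - 1) / (f_obs / f_lo + k - 1)
    return float(icc), float(lower), float(upper)


def bland_altman(
    s: PairedSeries, cfg: StatsConfig = StatsConfig()
) -> tuple[float, float, tuple[float, float], float, pd.DataFrame]:
    """Mean difference, SD, limits of agreement and share outside them.

    Differences are ``precise - broad``; SD uses the n-1 denominator;
    ``pct_outside`` counts pairs *strictly* beyond either limit, as a
    fraction in [0, 1].  Also returns the (pair mean, difference) points
    for the classic scatter plot.
    """
    if s.n < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    d = s.x - s.y
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa = (mean_diff - cfg.z * sd, mean_diff + cfg.z * sd)
    outside = np.count_nonzero((d < loa[0]) | (d > loa[1]))
    points = pd.DataFrame({"mean": (s.x + s.y) / 2.0, "diff": d})
    return mean_diff, sd, loa, outside / s.n, points


def pearson_ci(
    x: np.ndarray, y: np.ndarray, cfg: StatsConfig = StatsConfig()
) -> tuple[float, float, float]:
    """Sample Pearson correlation with a Fisher-transform CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("Pearson CI requires >= 4 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    zq = sps.norm.ppf(1 - cfg.alpha / 2)
    half = zq / math.sqrt(len(x) - 3)
    zr = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    return r, math.tanh(zr - half), math.tanh(zr + half)


def agreement_analysis(
    participants: list[ParticipantArchitecture],
    cfg: StatsConfig = StatsConfig(),
    variables: tuple[str, ...] = VARIABLES,
    keep_points: bool = False,
) -> list[AgreementResult]:
    """ICC + Bland-Altman for every architecture variable."""
    out = []
    for variable in variables:
        s = PairedSeries.from_architecture(participants, variable)
        icc, lo, hi = icc_consistency(s, cfg)
        mean_diff, sd, loa, pct, points = bland_altman(s, cfg)
        out.append(
            AgreementResult(
                variable=variable,
                n=s.n,
                icc=icc,
                icc_ci=(lo, hi),
                mean_diff=mean_diff,
                sd_diff=sd,
                loa=loa,
                pct_outside=pct,
                n_excluded=s.n_excluded,
                ba_points=points if keep_points else None,
            )
        )
    return out


def agreement_frame(results: list[AgreementResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


DEFAULT_OUTCOMES = ("TEI", "BMI", "WC", "ODP")


def association_table(
    participants: list[ParticipantArchitecture],
    outcomes: pd.DataFrame,
    cfg: StatsConfig = StatsConfig(),
    variables: tuple[str, ...] = VARIABLES,
) -> pd.DataFrame:
    """Pearson r (CI) of each architecture variable with each outcome, per method.

    ``outcomes`` must carry a ``participant_id`` column plus one column per
    outcome.  Cells are pairwise complete (complete cases per cell); each row
    reports the cell's own n.  Raises if no participants overlap.
    """
    outcome_cols = [c for c in outcomes.columns if c != "participant_id"]
    if not outcome_cols:
        raise ValueError("outcome table has no outcome columns")
    arch = architecture_frame(participants)
    merged = arch.merge(outcomes, on="participant_id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping participants between diaries and outcomes")
    rows = []
    for method in (PRECISE, BROAD):
        sub = merged[merged["method"] == method]
        for variable in variables:
            for outcome in outcome_cols:
                cell = sub[[variable, outcome]].dropna()
                if len(cell) < 4:
                    continue
                try:
                    r, lo, hi = pearson_ci(
                        cell[variable].to_numpy(), cell[outcome].to_numpy(), cfg
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "method": method,
                        "variable": variable,
                        "outcome": outcome,
                        "n": len(cell),
                        "r": r,
                        "ci_low": lo,
                        "ci_high": hi,
                    }
                )
    return pd.DataFrame(
        rows, columns=["method", "variable", "outcome", "n", "r", "ci_low", "ci_high"]
    )
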