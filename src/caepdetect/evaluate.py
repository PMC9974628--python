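"""Assessment machinery for detector performance.

Covers the standard toolkit of a specificity/sensitivity study: empirical
rejection rates with exact binomial confidence intervals, recalibration of
the nominal significance level so each method's false-positive rate matches
a target, Fisher's exact test for comparing detection counts between
methods, and Cohen's kappa (with its standard error) for intra- and
inter-test reliability of binary detection decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class RateEstimate:
    """An empirical proportion with a Clopper-Pearson confidence interval."""

    rate: float
    m: int
    ci: tuple[float, float]
    level: float

    def __post_init__(self):
        lo, hi = self.ci
        if not (0 <= lo <= self.rate <= hi <= 1):
            raise ValueError("confidence interval must bracket the rate")


@dataclass(frozen=True)
class AgreementTable:
    """2x2 agreement counts between two binary decision sequences.

    ``c11``: detected by both; ``c10``: first only; ``c01``: second only;
    ``c00``: neither.
    """

    c11: int
    c10: int
    c01: int
    c00: int

    def __post_init__(self):
        if min(self.c11, self.c10, self.c01, self.c00) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.c11 + self.c10 + self.c01 + self.c00

    @classmethod
    def from_decisions(cls, first, second) -> "AgreementTable":
        """Cross-tabulate two equal-length boolean decision sequences.

        Ambiguous outcomes should be mapped to non-detections before calling.
        """
        a = np.asarray(first, dtype=bool)
        b = np.asarray(second, dtype=bool)
        if a.shape != b.shape:
            raise ValueError("decision sequences must have equal length")
        return cls(
            c11=int(np.sum(a & b)),
            c10=int(np.sum(a & ~b)),
            c01=int(np.sum(~a & b)),
            c00=int(np.sum(~a & ~b)),
        )

    def transpose(self) -> "AgreementTable":
        return AgreementTable(self.c11, self.c01, self.c10, self.c00)


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its components and (optionally) a standard error."""

    kappa: float
    p_o: float
    p_c: float
    n: int
    se: float | None = None
    ci95: tuple[float, float] | None = None


def empirical_rate(decisions, level: float = 0.95) -> RateEstimate:
    """Rejection (or detection) proportion with an exact binomial CI."""
    d = np.asarray(decisions, dtype=bool).ravel()
    m = d.size
    if m < 1:
        raise ValueError("no decisions supplied")
    k = int(d.sum())
    ci = stats.binomtest(k, m).proportion_ci(confidence_level=level, method="exact")
    return RateEstimate(rate=k / m, m=m, ci=(float(ci.low), float(ci.high)), level=level)


def binomial_ci(m: int, p0: float, level: float = 0.99) -> tuple[float, float]:
    """Exact binomial interval for an observed proportion under p0.

    Endpoints are mid-distribution quantiles of Binomial(M, p0): the smallest
    count k whose mid-CDF, P(X < k) + P(X = k)/2, reaches the tail mass
    (1 - level)/2, respectively its upper-tail mirror, divided by M. The
    mid-CDF is the standard way to invert a discrete CDF without the
    systematic overshoot of plain quantiles. For M = 10,000 trials at
    p0 = 0.01 and 99% confidence this gives [0.0076, 0.0127] — the
    acceptance band for a calibrated test with that trial count.
    """
    if m < 1:
        raise ValueError("need at least one trial")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    tail = (1.0 - level) / 2.0
    k = np.arange(m + 1)
    fmid = stats.binom.cdf(k, m, p0) - 0.5 * stats.binom.pmf(k, m, p0)
    lo = int(k[np.searchsorted(fmid, tail)]) if fmid[-1] >= tail else m
    hi_idx = np.searchsorted(fmid, 1.0 - tail)
    hi = int(k[hi_idx]) if hi_idx <= m else m
    return lo / m, hi / m


def adjust_alpha(null_stats, target_fpr: float = 0.01, tail: str = "upper") -> float:
    """Decision threshold giving the target rejection rate on a null sample.

    With ``tail="upper"`` (raw statistics; reject when statistic > threshold)
    the threshold is the midpoint between the order statistics bracketing the
    empirical (1 - target) quantile, so re-applying it to the same sample
    rejects at most ``target_fpr`` and within one count of it. With
    ``tail="lower"`` (p-values; reject when p <= threshold) the threshold is
    the analogous lower-tail cut — the adjusted nominal alpha.
    """
    x = np.sort(np.asarray(null_stats, dtype=float).ravel())
    b = x.size
    if b < int(round(1.0 / target_fpr)):
        raise ValueError(
            f"need at least {int(round(1.0 / target_fpr))} null values to calibrate at {target_fpr}"
        )
    k = int(np.floor(b * target_fpr))
    if tail == "upper":
        if k == 0:
            return float(x[-1])
        return float(0.5 * (x[b - k - 1] + x[b - k]))
    elif tail == "lower":
        if k == 0:
            return float(x[0]) / 2.0
        return float(0.5 * (x[k - 1] + x[k]))
    raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p-value (point-probability rule) for a 2x2 table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if t.sum() == 0:
        raise ValueError("empty table")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def cohens_kappa(table: AgreementTable) -> KappaResult:
    """Chance-corrected agreement between two binary raters.

    P_o = (c11 + c00) / n is the observed agreement; the chance agreement
    P_c = (A + B) / n combines the margin products
    A = (c11 + c10)(c11 + c01) / n and B = (c01 + c00)(c10 + c00) / n;
    kappa = (P_o - P_c) / (1 - P_c).
    """
    n = table.n
    if n < 1:
        raise ValueError("empty agreement table")
    p_o = (table.c11 + table.c00) / n
    a = (table.c11 + table.c10) * (table.c11 + table.c01) / n
    b = (table.c01 + table.c00) * (table.c10 + table.c00) / n
    p_c = (a + b) / n
    if p_c >= 1.0:
        raise ValueError("chance agreement is 1: kappa undefined")
    kappa = (p_o - p_c) / (1.0 - p_c)
    return KappaResult(kappa=float(kappa), p_o=float(p_o), p_c=float(p_c), n=n)


def kappa_se(res: KappaResult, n: int | None = None) -> KappaResult:
    """Attach the large-sample standard error and 95% CI to a kappa estimate.

    SE = sqrt(P_o (1 - P_o) / (n (1 - P_c)^2)); CI = kappa +/- 1.96 SE.
    """
    n = res.n if n is None else n
    if n < 1:
        raise ValueError("need n >= 1")
    se = float(np.sqrt(res.p_o * (1.0 - res.p_o) / (n * (1.0 - res.p_c) ** 2)))
    ci = (res.kappa - 1.96 * se, res.kappa + 1.96 * se)
    return KappaResult(
        kappa=res.kappa, p_o=res.p_o, p_c=res.p_c, n=n, se=se, ci95=ci
    )
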