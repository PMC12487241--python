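"""Iterative two-sided Grubbs outlier filtering for control wells.

Segmentation failures (empty or debris-filled wells) occasionally land in
the control populations; a Grubbs test removes one extreme value at a time
until no value exceeds the critical bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class GrubbsStep:
    """One iteration: statistic, critical value and what (if anything) was removed."""

    n: int
    g: float
    g_crit: float
    removed_index: int | None
    removed_value: float | None


@dataclass
class OutlierReport:
    """Audit trail of an iterative Grubbs filter run."""

    values: np.ndarray
    alpha: float
    removed_indices: list[int] = field(default_factory=list)
    steps: list[GrubbsStep] = field(default_factory=list)
    warning: str | None = None

    @property
    def cleaned(self) -> np.ndarray:
        keep = np.ones(len(self.values), dtype=bool)
        keep[self.removed_indices] = False
        return self.values[keep]

    @property
    def n_removed(self) -> int:
        return len(self.removed_indices)


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values,
    alpha: float = 0.05,
    max_removals: int | None = None,
) -> OutlierReport:
    """Iteratively remove the most extreme value while it fails Grubbs.

    At each step G = max|x_i - mean| / sd (sample sd, n-1) is computed on the
    current sample; the extreme value is removed iff G > G_crit(n, alpha).
    Stops when no rejection occurs, when fewer than 3 values remain, or after
    ``max_removals`` removals. n < 3 or zero-spread samples are a no-op with
    a warning flag.
    """
    if not 0 < alpha <= 0.2:
        raise ValueError("alpha must be in (0, 0.2]")
    x = np.asarray(values, dtype=float)
    report = OutlierReport(values=x, alpha=alpha)
    if x.size < 3:
        report.warning = "too_few_values"
        return report
    if max_removals is None:
        max_removals = x.size - 3
    active = list(range(x.size))
    while len(active) >= 3:
        if max_removals is not None and len(report.removed_indices) >= max_removals:
            break
        sub = x[active]
        mean = sub.mean()
        sd = sub.std(ddof=1)
        if sd == 0:
            if not report.steps:
                report.warning = "zero_spread"
            break
        dev = np.abs(sub - mean)
        j = int(np.argmax(dev))
        g = dev[j] / sd
        g_crit = grubbs_critical_value(len(sub), alpha)
        if g > g_crit:
            idx = active.pop(j)
            report.removed_indices.append(idx)
            report.steps.append(GrubbsStep(len(sub), float(g), float(g_crit), idx, float(x[idx])))
        else:
            report.steps.append(GrubbsStep(len(sub), float(g), float(g_crit), None, None))
            break
    return report
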