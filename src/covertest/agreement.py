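"""Repeatability and method-comparison statistics for paired phoria data.

Bland–Altman limits of agreement (mean difference ± 1.96 SD of the paired
differences), within-subject standard deviation of repeated measurements,
direction-concordance tables, and the Bonferroni significance-level helper.
Inferential machinery (t tests, ANOVA, non-parametric batteries) is out of
scope: these are the descriptive effect summaries one plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

__all__ = [
    "BlandAltmanResult",
    "bland_altman",
    "within_subject_sd",
    "direction_concordance",
    "bonferroni_alpha",
]

DIRECTION_LABELS = ("eso", "ortho", "exo")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement summary between two paired series of measurements."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    r_diff_vs_mean: Optional[float]
    n: int
    multiplier: float = 1.96

    @property
    def loa_halfwidth(self) -> float:
        return self.multiplier * self.sd_diff


def bland_altman(
    a: Sequence[float], b: Sequence[float], multiplier: float = 1.96
) -> BlandAltmanResult:
    """Bland–Altman analysis of paired measurements ``a`` and ``b``.

    mean_diff = mean(a−b); sd_diff uses the n−1 denominator; limits of
    agreement are mean_diff ± multiplier·sd_diff; r_diff_vs_mean is the
    Pearson correlation of the differences against the pair means (None when
    either series is constant, where the correlation is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("paired series must have equal length")
    if a.size < 2:
        raise ParameterError("need at least 2 pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ParameterError("pairs must be finite")
    diff = a - b
    mean = (a + b) / 2.0
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    if np.var(mean) == 0.0 or np.var(diff) == 0.0:
        r = None
    else:
        r = float(stats.pearsonr(diff, mean).statistic)
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - multiplier * sd_diff,
        loa_high=mean_diff + multiplier * sd_diff,
        r_diff_vs_mean=r,
        n=int(a.size),
        multiplier=multiplier,
    )


def within_subject_sd(groups) -> float:
    """Within-subject SD: sqrt of the mean per-subject sample variance.

    ``groups`` is a mapping subject → repeated values, or an iterable of
    per-subject sequences.  Subjects with fewer than two values are excluded
    with a warning.  Adding a per-subject constant leaves the result
    unchanged: between-subject spread does not leak in.
    """
    if isinstance(groups, Mapping):
        seqs = list(groups.values())
    else:
        seqs = [np.asarray(g, dtype=float) for g in groups]
    variances = []
    n_excluded = 0
    for g in seqs:
        g = np.asarray(g, dtype=float)
        if g.size < 2:
            n_excluded += 1
            continue
        variances.append(np.var(g, ddof=1))
    if n_excluded:
        warnings.warn(
            f"{n_excluded} subject(s) with fewer than 2 values excluded",
            stacklevel=2,
        )
    if not variances:
        raise ParameterError("no subject has 2 or more repeated values")
    return float(np.sqrt(np.mean(variances)))


def direction_concordance(
    dirs_a: Sequence[str], dirs_b: Sequence[str]
) -> Tuple[float, pd.DataFrame]:
    """Fraction of matching direction labels plus the 3×3 contingency table.

    Rows index the first list's labels, columns the second's; all nine
    eso/ortho/exo combinations are tabulated even when empty.
    """
    dirs_a = list(dirs_a)
    dirs_b = list(dirs_b)
    if len(dirs_a) != len(dirs_b):
        raise ParameterError("label lists must have equal length")
    if not dirs_a:
        raise ParameterError("label lists must be non-empty")
    for lab in dirs_a + dirs_b:
        if lab not in DIRECTION_LABELS:
            raise ParameterError(f"unknown direction label {lab!r}")
    table = pd.DataFrame(
        0, index=list(DIRECTION_LABELS), columns=list(DIRECTION_LABELS), dtype=int
    )
    agree = 0
    for la, lb in zip(dirs_a, dirs_b):
        table.loc[la, lb] += 1
        agree += la == lb
    return agree / len(dirs_a), table


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison significance level after Bonferroni correction."""
    if not 0.0 < family_alpha < 1.0:
        raise ParameterError("family_alpha must lie in (0, 1)")
    if m < 1:
        raise ParameterError("m must be >= 1")
    return family_alpha / m
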