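"""Group comparisons: one-way ANOVA, Duncan's multiple range test with a
compact letter display, and reference-gene-normalised qPCR expression.

Duncan's multiple range test is the step-down procedure on sorted group
means used throughout the feeding-trial literature to attach superscript
letters to treatment means.  For a stretch of p adjacent ordered means the
critical range is

    R_p = q(alpha_p, p, df_error) * sqrt(MSE / n_h)

with the protection level ``alpha_p = 1 - (1 - alpha)**(p - 1)`` (Duncan's
original increasing levels), q the studentized-range quantile, MSE the
pooled within-group variance from the ANOVA, and n_h the harmonic mean
group size (the Kramer adjustment for unbalanced designs; with balanced
groups it is just n).  A stretch whose observed range does not exceed its
critical range is declared homogeneous, and — as in every step-down range
procedure — all of its sub-stretches are then declared homogeneous too
without further testing.  Homogeneous maximal stretches share a letter;
the highest mean gets "a".

With two groups the protection level is alpha and q(alpha, 2, df) =
sqrt(2) * t(alpha/2, df), so the procedure reduces exactly to the pooled
two-sample t-test.

qPCR relative quantities follow the multi-reference-gene normalisation of
the geNorm framework: each sample's target quantity ``E**(-Ct)`` is
divided by the geometric mean of its reference-gene quantities, then
scaled so the calibrator group averages 1.
"""

from __future__ import annotations

import math
import string
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError

__all__ = [
    "GroupData",
    "AnovaResult",
    "DuncanResult",
    "QpcrSample",
    "one_way_anova",
    "duncan_mrt",
    "levene_test",
    "relative_expression",
]


@dataclass(frozen=True)
class GroupData:
    """Labelled groups of replicate observations."""

    groups: Mapping[str, Sequence[float]]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for label, vals in self.groups.items():
            arr = np.asarray(vals, dtype=float).ravel()
            if arr.size < 2:
                raise ValidationError(
                    f"group {label!r} has {arr.size} observation(s); "
                    "at least 2 are needed to estimate within-group variance"
                )
            if not np.isfinite(arr).all():
                raise ValidationError(f"group {label!r} contains non-finite values")
            clean[str(label)] = arr
        if len(clean) < 2:
            raise ValidationError("need at least 2 groups")
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_long(cls, data: pd.DataFrame, group_col: str, value_col: str) -> "GroupData":
        """Build from a long-format table with a group and a value column."""
        if group_col not in data.columns or value_col not in data.columns:
            raise ValidationError(f"columns {group_col!r} and {value_col!r} are required")
        return cls({g: sub[value_col].to_numpy() for g, sub in data.groupby(group_col, sort=False)})

    def labels(self) -> list[str]:
        return list(self.groups)

    def means(self) -> dict[str, float]:
        return {g: float(v.mean()) for g, v in self.groups.items()}


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA decomposition."""

    f: float
    p: float
    mse: float
    df_error: int
    df_between: int
    degenerate: bool = False  # zero within- and between-group variance


def one_way_anova(g: GroupData) -> AnovaResult:
    """Standard between/within sum-of-squares decomposition.

    Returns the F statistic, its p-value, the pooled error variance (MSE)
    and the error degrees of freedom — the latter two feed Duncan's test.
    All-identical data make F 0/0; the result is flagged ``degenerate``
    with p = 1.
    """
    arrays = list(g.groups.values())
    grand = np.concatenate(arrays)
    n_total = grand.size
    k = len(arrays)
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between, df_error = k - 1, n_total - k
    mse = ss_within / df_error
    if mse == 0:
        if ss_between == 0:
            return AnovaResult(math.nan, 1.0, 0.0, df_error, df_between, degenerate=True)
        return AnovaResult(math.inf, 0.0, 0.0, df_error, df_between)
    f = (ss_between / df_between) / mse
    p = float(stats.f.sf(f, df_between, df_error))
    return AnovaResult(float(f), p, float(mse), df_error, df_between)


@dataclass(frozen=True)
class DuncanResult:
    """Duncan's multiple range test outcome with a compact letter display.

    ``means`` is sorted descending; ``letters`` maps each group to its
    letter string ("a" marks the stretch containing the highest mean).
    Two groups are significantly different at ``alpha`` iff they share no
    letter.
    """

    means: "pd.Series"
    letters: Mapping[str, str]
    mse: float
    df_error: int
    alpha: float
    anova: AnovaResult = field(repr=False, default=None)

    def different(self, a: str, b: str) -> bool:
        """True if groups *a* and *b* share no letter."""
        return not (set(self.letters[a]) & set(self.letters[b]))

    def summary(self) -> pd.DataFrame:
        """Means (descending) with their letters, Table-style."""
        return pd.DataFrame(
            {"mean": self.means, "letters": [self.letters[g] for g in self.means.index]}
        )


def _critical_range(alpha: float, p: int, df: int, mse: float, n_h: float) -> float:
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    q = stats.studentized_range.isf(alpha_p, p, df)
    return float(q * math.sqrt(mse / n_h))


def duncan_mrt(g: GroupData, alpha: float = 0.05) -> DuncanResult:
    """Duncan's multiple range test with compact letters.

    Step-down over stretches of adjacent ordered means, longest first; a
    homogeneous stretch protects all of its sub-stretches.  Letters are
    invariant to group input order and to adding a constant to every
    observation.
    """
    if not (0 < alpha < 0.5):
        raise ValidationError(f"alpha must be in (0, 0.5), got {alpha}")
    anova = one_way_anova(g)
    means = pd.Series(g.means()).sort_values(ascending=False, kind="mergesort")
    labels = list(means.index)
    k = len(labels)
    sizes = np.array([g.groups[lab].size for lab in labels], dtype=float)
    n_h = k / (1.0 / sizes).sum()  # harmonic mean group size

    if anova.degenerate or anova.mse == 0.0:
        # Zero within-group variance: any nonzero difference is significant.
        sig = lambda i, j: means.iloc[i] - means.iloc[j] > 0  # noqa: E731
        significant = [[sig(i, j) for j in range(k)] for i in range(k)]
    else:
        # significant[i][j]: stretch of ordered means i..j (i < j) exceeds
        # its critical range.  Filled longest-first so protected (contained)
        # stretches can be cleared without testing.
        significant = [[False] * k for _ in range(k)]
        protected = [[False] * k for _ in range(k)]
        for span in range(k, 1, -1):
            r_crit = _critical_range(alpha, span, anova.df_error, anova.mse, n_h)
            for i in range(0, k - span + 1):
                j = i + span - 1
                if protected[i][j]:
                    continue
                if means.iloc[i] - means.iloc[j] > r_crit:
                    significant[i][j] = True
                else:
                    for a in range(i, j + 1):
                        for b in range(a + 1, j + 1):
                            protected[a][b] = True

    # Compact letter display: maximal non-significant stretches get letters.
    stretches: list[tuple[int, int]] = []
    i = 0
    for i in range(k):
        j = i
        while j + 1 < k and not significant[i][j + 1]:
            j += 1
        if not any(a <= i and j <= b for a, b in stretches):
            stretches.append((i, j))
    alphabet = string.ascii_lowercase
    if len(stretches) > len(alphabet):
        raise DomainError("more homogeneous stretches than letters available")
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    for idx, (a, b) in enumerate(stretches):
        for pos in range(a, b + 1):
            letters[labels[pos]].append(alphabet[idx])
    return DuncanResult(
        means=means,
        letters={lab: "".join(ls) for lab, ls in letters.items()},
        mse=anova.mse,
        df_error=anova.df_error,
        alpha=alpha,
        anova=anova,
    )


def levene_test(g: GroupData) -> tuple[float, float]:
    """Median-centred Levene (Brown-Forsythe) homogeneity-of-variance test.

    Reported alongside the ANOVA but not used to gate it.
    """
    stat, p = stats.levene(*g.groups.values(), center="median")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# qPCR relative expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QpcrSample:
    """One qPCR observation: target Ct, reference-gene Cts, efficiency.

    ``efficiency`` is the amplification factor per cycle (2.0 = perfect
    doubling), shared by target and references.
    """

    ct_target: float
    ct_refs: Sequence[float]
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        refs = tuple(float(c) for c in self.ct_refs)
        if not refs:
            raise ValidationError("a qPCR sample needs at least one reference-gene Ct")
        for ct in (self.ct_target, *refs):
            if not (0 < ct < 45):
                raise ValidationError(f"Ct values must lie in (0, 45), got {ct}")
        if not (1.0 < self.efficiency <= 2.2):
            raise ValidationError(f"efficiency must be in (1, 2.2], got {self.efficiency}")
        object.__setattr__(self, "ct_refs", refs)

    def normalized_quantity(self) -> float:
        """Target quantity over the geometric mean of reference quantities.

        Computed on the log (cycle) scale: E**(mean(ct_refs) - ct_target).
        """
        mean_ref = sum(self.ct_refs) / len(self.ct_refs)
        return float(self.efficiency ** (mean_ref - self.ct_target))


def relative_expression(
    samples: Sequence[QpcrSample], calibrator: Sequence[QpcrSample]
) -> np.ndarray:
    """Reference-normalised relative quantities, calibrator group mean = 1."""
    if not samples or not calibrator:
        raise ValidationError("samples and calibrator must be non-empty")
    cal = np.array([s.normalized_quantity() for s in calibrator])
    scale = cal.mean()
    if scale <= 0:
        raise DomainError("calibrator quantities must be positive")
    return np.array([s.normalized_quantity() for s in samples]) / scale
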