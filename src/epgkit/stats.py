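"""Group-comparison statistics for EPG parameters.

The workflow mirrors standard practice for EPG parameter batteries,
whose raw values are strongly right-skewed or proportion-valued:

1. **Transformation selection.**  Each parameter is Box-Cox power
   transformed, with the exponent chosen from a fixed grid
   (-3 ... 3 in steps of 0.25) by maximizing the profile
   log-likelihood; lambda = 0 means log.  Proportion-typed parameters
   (percentages in [0, 100]) are first arcsine-square-root transformed,
   because no power transform can approximate the needed S-curve.
   Values <= 0 are handled by a recorded additive shift (half the
   smallest positive value).  A Shapiro-Wilk statistic on the
   transformed values is reported for audit.

2. **All-pairs comparison.**  A one-way fixed-effects model on the
   transformed scale; pairwise differences are tested with the
   studentized range using the Kramer correction for unequal group
   sizes, with the pooled error variance on N - k degrees of freedom.

3. **Compact letter display.**  Letters are assigned with the
   insert-and-absorb algorithm, which — unlike line-based displays —
   remains correct when the standard error of a difference varies
   between pairs; discontinuous letter strings such as "ac" are a
   legitimate outcome.  The defining display property: two groups share
   at least one letter if and only if their adjusted p-value is >= alpha.

Group means are reported on the original scale (the transformed-scale
means and confidence intervals travel in a supplementary table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import MetadataTable

__all__ = [
    "TransformSpec",
    "GroupComparison",
    "select_transform",
    "tukey_kramer",
    "piepho_letters",
    "group_compare",
    "LAMBDA_GRID",
]

#: Box-Cox exponent search grid.
LAMBDA_GRID = np.arange(-3.0, 3.0 + 1e-9, 0.25)


@dataclass(frozen=True)
class TransformSpec:
    """A fitted parameter transformation.

    ``apply`` maps original-scale values onto the analysis scale:
    optional arcsine-sqrt for proportions, then a recorded positive
    shift if needed, then the Box-Cox power with exponent ``lam``.
    """

    arcsine_first: bool
    lam: float
    shift: float
    selection_score: float
    shapiro_w: float = math.nan

    def apply(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        if self.arcsine_first:
            x = np.arcsin(np.sqrt(x / 100.0))
        x = x + self.shift
        if self.lam == 0:
            return np.log(x)
        return (x**self.lam - 1.0) / self.lam


def select_transform(values, proportion_typed: bool = False) -> TransformSpec:
    """Choose the best normalizing transformation for one parameter.

    Raises ``ValueError`` for degenerate (constant) samples, fewer than
    4 values, or negative input (percentages outside [0, 100] when
    proportion-typed).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 4:
        raise ValueError(f"select_transform needs >=4 finite values, got {x.size}")
    if np.min(x) < 0:
        raise ValueError("negative values are not valid for this parameter typing")
    orig = x
    if proportion_typed:
        if np.max(x) > 100:
            raise ValueError("proportion-typed values must lie in [0, 100]")
        x = np.arcsin(np.sqrt(x / 100.0))
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values identical")

    shift = 0.0
    if np.min(x) <= 0:
        positive = x[x > 0]
        if positive.size == 0:
            raise ValueError("degenerate sample: no positive values to set a shift")
        shift = 0.5 * float(np.min(positive))
    shifted = x + shift

    lls = np.array([sps.boxcox_llf(lam, shifted) for lam in LAMBDA_GRID])
    best = int(np.argmax(lls))
    lam = float(LAMBDA_GRID[best])
    spec = TransformSpec(
        arcsine_first=proportion_typed, lam=lam, shift=shift,
        selection_score=float(lls[best]),
    )
    transformed = spec.apply(orig)
    transformed = transformed[np.isfinite(transformed)]
    w = sps.shapiro(transformed).statistic if transformed.size >= 3 else math.nan
    return TransformSpec(
        arcsine_first=spec.arcsine_first, lam=spec.lam, shift=spec.shift,
        selection_score=spec.selection_score, shapiro_w=float(w),
    )


def tukey_kramer(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs comparison with the studentized range.

    Parameters
    ----------
    groups
        Mapping group label -> 1-D array of (transformed) values; every
        group needs at least 2 values; unequal sizes are allowed (the
        Kramer correction uses the harmonic pair term).
    alpha
        Significance level, recorded for the caller; p-values are
        returned unthresholded.

    Returns
    -------
    A symmetric DataFrame of adjusted p-values with unit diagonal.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("tukey_kramer needs at least 2 groups")
    arrays = {}
    for lab in labels:
        a = np.asarray(groups[lab], dtype=float)
        a = a[np.isfinite(a)]
        if a.size < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")
        arrays[lab] = a

    k = len(labels)
    ns = np.array([arrays[lab].size for lab in labels])
    means = np.array([arrays[lab].mean() for lab in labels])
    N = int(ns.sum())
    df = N - k
    sse = sum(((arrays[lab] - arrays[lab].mean()) ** 2).sum() for lab in labels)
    mse = sse / df

    p = np.eye(k)
    np.fill_diagonal(p, 1.0)
    for i, j in combinations(range(k), 2):
        se = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0:
            pij = 1.0 if means[i] == means[j] else 0.0
        else:
            q = abs(means[i] - means[j]) / se
            pij = float(sps.studentized_range.sf(q, k, df))
        p[i, j] = p[j, i] = min(1.0, pij)
    return pd.DataFrame(p, index=labels, columns=labels)


def piepho_letters(labels: list[str], significant: np.ndarray) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Parameters
    ----------
    labels
        Group labels in display order.
    significant
        Square boolean matrix; ``significant[i, j]`` is True when the
        pair differs significantly.  Must be symmetric with a False
        diagonal.

    Returns
    -------
    Mapping label -> letter string.  Two labels share at least one
    letter iff their pair is non-significant; strings may be
    discontinuous (e.g. ``"ac"``).
    """
    sig = np.asarray(significant, dtype=bool)
    k = len(labels)
    if sig.shape != (k, k):
        raise ValueError(f"significance matrix must be {k}x{k}")
    if not np.array_equal(sig, sig.T):
        raise ValueError("significance matrix must be symmetric")
    if np.diagonal(sig).any():
        raise ValueError("significance matrix diagonal must be False")

    # insert: split every column containing a significant pair
    columns: list[set[int]] = [set(range(k))]
    for i, j in combinations(range(k), 2):
        if not sig[i, j]:
            continue
        nxt: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                nxt.append(col - {i})
                nxt.append(col - {j})
            else:
                nxt.append(col)
        # absorb: drop empty columns, duplicates and proper subsets
        uniq: list[set[int]] = []
        for c in nxt:
            if c and c not in uniq:
                uniq.append(c)
        columns = [c for c in uniq if not any(c < d for d in uniq)]

    # letters in first-appearance order: columns sorted by membership
    columns.sort(key=lambda c: sorted(c))
    letters = {lab: "" for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for c, col in enumerate(columns):
        ch = alphabet[c] if c < len(alphabet) else f"({c})"
        for idx in sorted(col):
            letters[labels[idx]] += ch
    return letters


@dataclass
class GroupComparison:
    """Statistical result for one parameter across groups."""

    parameter: str
    transform: TransformSpec | None
    alpha: float
    summary: pd.DataFrame  # index group; n, mean_original, mean_transformed,
    #                        ci_low, ci_high, letter
    pairwise_p: pd.DataFrame | None
    skipped: str | None = None  # reason, when the comparison could not run


def group_compare(
    table: pd.DataFrame,
    metadata: MetadataTable,
    factor: str,
    alpha: float = 0.05,
    proportion_params: list[str] | None = None,
) -> list[GroupComparison]:
    """Run the full per-parameter comparison across one grouping factor.

    `table` is the per-insect parameter table (index insect_id, storage
    units); `factor` names a metadata column.  Per parameter: missing
    values are dropped, a transformation is selected on the pooled
    values, groups are compared with Tukey-Kramer on the transformed
    scale, and compact letters are assigned.  A parameter that cannot
    be analyzed (a whole group missing or degenerate values) is
    reported with a ``skipped`` reason instead of raising.
    """
    if factor not in metadata.frame.columns:
        raise ValueError(f"factor {factor!r} not in metadata columns")
    proportion_params = list(proportion_params or [])
    grouping = metadata.frame.set_index("insect_id")[factor]
    missing_ids = [i for i in table.index if i not in grouping.index]
    if missing_ids:
        raise ValueError(f"insects absent from metadata: {missing_ids[:5]}")
    levels = sorted(grouping.loc[table.index].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")

    out: list[GroupComparison] = []
    for param in table.columns:
        col = table[param]
        groups_orig = {
            lev: col[grouping.loc[col.index] == lev].dropna().to_numpy(dtype=float)
            for lev in levels
        }
        thin = [lev for lev, v in groups_orig.items() if v.size < 2]
        if thin:
            out.append(GroupComparison(
                parameter=param, transform=None, alpha=alpha,
                summary=pd.DataFrame(index=levels), pairwise_p=None,
                skipped=f"group(s) with <2 non-missing values: {thin}",
            ))
            continue
        pooled = np.concatenate(list(groups_orig.values()))
        try:
            spec = select_transform(pooled, param in proportion_params)
        except ValueError as exc:
            out.append(GroupComparison(
                parameter=param, transform=None, alpha=alpha,
                summary=pd.DataFrame(index=levels), pairwise_p=None,
                skipped=f"transformation failed: {exc}",
            ))
            continue
        groups_t = {lev: spec.apply(v) for lev, v in groups_orig.items()}
        pvals = tukey_kramer(groups_t, alpha=alpha)
        sig = pvals.to_numpy() < alpha
        np.fill_diagonal(sig, False)
        letters = piepho_letters(levels, sig)

        ns = np.array([groups_t[lev].size for lev in levels])
        N, kk = int(ns.sum()), len(levels)
        mse = sum(((groups_t[lev] - groups_t[lev].mean()) ** 2).sum()
                  for lev in levels) / (N - kk)
        tcrit = sps.t.ppf(1 - alpha / 2, N - kk)
        rows = {}
        for lev, n in zip(levels, ns):
            mt = groups_t[lev].mean()
            half = tcrit * math.sqrt(mse / n)
            rows[lev] = {
                "n": n,
                "mean_original": groups_orig[lev].mean(),
                "mean_transformed": mt,
                "ci_low": mt - half,
                "ci_high": mt + half,
                "letter": letters[lev],
            }
        out.append(GroupComparison(
            parameter=param, transform=spec, alpha=alpha,
            summary=pd.DataFrame.from_dict(rows, orient="index"),
            pairwise_p=pvals,
        ))
    return out
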