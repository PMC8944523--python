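"""Expression-matrix transformation, 2^-ΔΔCt relative expression, and
Duncan's multiple range test.

The heatmap transform is log2(FPKM + 1) followed by per-gene mean
centering, matching the usual tissue-profile visualisation.  Relative
qPCR expression follows the standard ΔΔCt convention: technical
replicates are collapsed to one Ct by their mean, ΔCt is target minus
reference per biological replicate, ΔΔCt subtracts the mean ΔCt of the
calibrator condition (same treatment, 0 h), and expression is 2^(-ΔΔCt)
summarised as mean ± sd over biological replicates.

Duncan's multiple range test runs after a one-way ANOVA: means are
sorted descending and a span of p ordered means differs significantly
when its range reaches R_p = q(alpha_p, p, df) * sqrt(MSE/n), with the
protection level alpha_p = 1 - (1 - alpha)^(p-1) and q the studentized
range quantile (computed numerically via scipy, not from printed
tables).  Letters are assigned by the standard sweep over maximal
non-significant runs; the largest mean gets 'a'.  The test is liberal by
construction — its family-wise error with all-null groups exceeds the
nominal alpha.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats


@lru_cache(maxsize=None)
def _duncan_q(alpha: float, p: int, df: int) -> float:
    """Studentized-range quantile at Duncan's protection level
    alpha_p = 1 - (1 - alpha)^(p-1).  Cached: the quantile function is
    expensive and the test re-uses a handful of (p, df) combinations."""
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(stats.studentized_range.ppf(1.0 - alpha_p, p, df))


# ---------------------------------------------------------------------------
# expression matrix


def heatmap_matrix(fpkm: pd.DataFrame) -> pd.DataFrame:
    """log2(FPKM + 1), then per-gene (row) mean centering."""
    if (fpkm.values < 0).any():
        raise ValueError("FPKM values must be non-negative")
    logged = np.log2(fpkm.astype(float) + 1.0)
    return logged.sub(logged.mean(axis=1), axis=0)


def tissue_profile_report(
    fpkm: pd.DataFrame, members: list[str] | None = None, margin: float = 1.0
) -> pd.DataFrame:
    """Per-gene tissue ranking on the transformed scale.

    Flags genes whose top tissue exceeds the runner-up by ``margin``
    log2 units (default 1.0, i.e. a two-fold gap).
    """
    if fpkm.empty:
        return pd.DataFrame(columns=["gene", "top_tissue", "second_tissue",
                                     "gap_log2", "flagged"])
    mat = heatmap_matrix(fpkm)
    if members is not None:
        mat = mat.loc[[m for m in members if m in mat.index]]
    rows = []
    for gene, row in mat.iterrows():
        ranked = row.sort_values(ascending=False)
        gap = float(ranked.iloc[0] - ranked.iloc[1]) if len(ranked) > 1 else 0.0
        rows.append(
            dict(gene=gene, top_tissue=ranked.index[0],
                 second_tissue=ranked.index[1] if len(ranked) > 1 else "",
                 gap_log2=gap, flagged=gap >= margin)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR


def relative_expression(
    table: pd.DataFrame,
    gene: str,
    reference: str,
    treatment: str,
    calibrator_timepoint: int = 0,
) -> pd.DataFrame:
    """Per-timepoint mean ± sd of 2^-ΔΔCt over biological replicates.

    The table needs columns gene, treatment, timepoint, bio_rep,
    tech_rep, ct.  A missing reference measurement fails naming the
    offending design cell.
    """
    sub = table[table["treatment"] == treatment]
    tech_mean = (
        sub.groupby(["gene", "timepoint", "bio_rep"])["ct"].mean().reset_index()
    )

    def _ct(g: str, tp: int, bio: int) -> float:
        row = tech_mean[
            (tech_mean["gene"] == g)
            & (tech_mean["timepoint"] == tp)
            & (tech_mean["bio_rep"] == bio)
        ]
        if row.empty:
            raise ValueError(
                f"missing Ct for gene={g!r}, treatment={treatment!r}, "
                f"timepoint={tp}, bio_rep={bio}"
            )
        return float(row["ct"].iloc[0])

    timepoints = sorted(sub["timepoint"].unique())
    bio_reps = sorted(sub[sub["gene"] == gene]["bio_rep"].unique())
    if calibrator_timepoint not in timepoints:
        raise ValueError(f"calibrator timepoint {calibrator_timepoint} absent")
    calib_dct = np.mean(
        [
            _ct(gene, calibrator_timepoint, b) - _ct(reference, calibrator_timepoint, b)
            for b in bio_reps
        ]
    )
    out = []
    for tp in timepoints:
        rel = [
            2.0 ** -((_ct(gene, tp, b) - _ct(reference, tp, b)) - calib_dct)
            for b in bio_reps
        ]
        out.append(
            dict(timepoint=tp, mean=float(np.mean(rel)),
                 sd=float(np.std(rel, ddof=1)) if len(rel) > 1 else 0.0,
                 n=len(rel))
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Duncan's multiple range test


@dataclass
class DuncanGrouping:
    groups: list[str]  # ordered by descending mean
    means: list[float]
    letters: list[str]  # letter set per group, aligned with ``groups``
    alpha: float

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.groups, self.letters))


def duncan_mrt(
    groups: dict[str, np.ndarray | list[float]],
    alpha: float = 0.05,
    f_protect: bool = True,
) -> DuncanGrouping:
    """Duncan's multiple range test over replicate groups.

    By default the range test is applied as a post-hoc: when the one-way
    ANOVA F-test is not significant at ``alpha`` all groups share one
    letter.  ``f_protect=False`` gives the unprotected test, whose
    family-wise error under the complete null is the top protection
    level 1 - (1-alpha)^(k-1) rather than alpha.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    sizes = [len(v) for v in data.values()]
    if min(sizes) < 2:
        raise ValueError("each group needs at least two replicates")
    k = len(names)
    n_total = sum(sizes)
    df_err = n_total - k
    sse = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    mse = sse / df_err
    if len(set(sizes)) > 1:
        warnings.warn("unbalanced groups: using the harmonic mean group size",
                      stacklevel=2)
        n_h = k / sum(1.0 / s for s in sizes)
    else:
        n_h = float(sizes[0])
    order = sorted(names, key=lambda g: -data[g].mean())
    means = [float(data[g].mean()) for g in order]
    se = np.sqrt(mse / n_h)

    if f_protect:
        grand = np.concatenate(list(data.values())).mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
        if mse == 0.0:
            f_significant = ssb > 0
        else:
            f_stat = (ssb / (k - 1)) / mse
            f_significant = stats.f.sf(f_stat, k - 1, df_err) <= alpha
        if not f_significant:
            return DuncanGrouping(groups=order, means=means,
                                  letters=["a"] * k, alpha=alpha)

    def lsr(p: int) -> float:
        if se == 0.0:
            return 0.0
        return _duncan_q(alpha, p, df_err) * se

    def significant(i: int, j: int) -> bool:
        # span of p = j - i + 1 ordered means
        diff = means[i] - means[j]
        r = lsr(j - i + 1)
        if r == 0.0:  # zero within-group variance: any real difference counts
            return diff > 0
        return diff >= r

    # maximal non-significant runs -> letters
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and not significant(i, j + 1):
            j += 1
        runs.append((i, j))
    maximal = [r for r in runs
               if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    maximal = sorted(set(maximal))
    letters = ["" for _ in range(k)]
    for idx, (s, e) in enumerate(maximal):
        letter = chr(ord("a") + idx)
        for g in range(s, e + 1):
            letters[g] += letter
    return DuncanGrouping(groups=order, means=means, letters=letters, alpha=alpha)
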