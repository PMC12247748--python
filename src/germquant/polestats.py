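"""Pole-cell scoring summaries and hypothesis tests.

Stage-5 embryos are scored into three mutually exclusive categories —
``negative``, ``attempt`` (pole-bud initiation without completed,
germ-cell-fated cells), and ``anterior_pole_cells`` — with anterior and
posterior pole cells counted per embryo.  Two tests accompany the
summaries:

* a pooled-bootstrap test on the difference in means between two groups of
  per-embryo values (counts or enrichment scores), 10,000 iterations by
  default, p = fraction of null statistics at least as extreme as the
  observed difference (equality counts);
* a one-sided Fisher's exact test on the 2x2 table of embryos with /
  without the anterior-pole-cell phenotype, the penetrance comparison.
  Significance is declared at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CATEGORIES

__all__ = [
    "GroupSummary",
    "BootstrapResult",
    "validate_score_table",
    "summarize_scores",
    "bootstrap_diff_means",
    "fisher_one_sided",
    "compare_penetrance",
]

DEFAULT_B = 10_000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class GroupSummary:
    """Per-genotype phenotype bookkeeping.

    ``penetrance`` = positives / embryos.  ``mean_anterior_count`` averages
    over positive embryos only and is NaN (undefined) when there are none;
    ``mean_posterior_count`` averages over every embryo.
    """

    genotype: str
    n_embryos: int
    n_attempts: int
    n_positive: int
    penetrance: float
    mean_anterior_count: float
    mean_posterior_count: float


@dataclass(frozen=True)
class BootstrapResult:
    observed_diff: float
    p_value: float
    n_iterations: int
    seed: int
    sidedness: str


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a score table's columns, categories, and count consistency."""
    required = {"embryo_id", "genotype", "category", "n_anterior", "n_posterior"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    bad = set(table["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}; expected {CATEGORIES}")
    if (table[["n_anterior", "n_posterior"]] < 0).any().any():
        raise ValueError("pole-cell counts must be >= 0")
    pos = table["category"] == "anterior_pole_cells"
    if (table.loc[pos, "n_anterior"] < 1).any():
        raise ValueError("anterior_pole_cells embryos must have n_anterior >= 1")
    return table


def summarize_scores(table: pd.DataFrame, genotype: str) -> GroupSummary:
    """Summarize one genotype: penetrance, attempts, and mean counts."""
    validate_score_table(table)
    grp = table[table["genotype"] == genotype]
    if grp.empty:
        raise ValueError(f"genotype {genotype!r} not present in table")
    n = len(grp)
    n_pos = int((grp["category"] == "anterior_pole_cells").sum())
    n_att = int((grp["category"] == "attempt").sum())
    mean_ant = (
        float(grp.loc[grp["category"] == "anterior_pole_cells", "n_anterior"].mean())
        if n_pos
        else float("nan")
    )
    return GroupSummary(
        genotype=genotype,
        n_embryos=n,
        n_attempts=n_att,
        n_positive=n_pos,
        penetrance=n_pos / n,
        mean_anterior_count=mean_ant,
        mean_posterior_count=float(grp["n_posterior"].mean()),
    )


def bootstrap_diff_means(
    x,
    y,
    n_iterations: int = DEFAULT_B,
    seed: int = 0,
    sidedness: str = "two-sided",
    plus_one_correction: bool = False,
) -> BootstrapResult:
    """Pooled-bootstrap test on the difference in means, mean(x) - mean(y).

    The null distribution pools both samples and redraws |x| and |y| values
    with replacement ``n_iterations`` times.  ``sidedness`` is
    ``"two-sided"`` (|null| >= |observed|), ``"greater"`` or ``"less"``
    (one-tailed on the signed statistic); equality with the observed value
    always counts as extreme.  At finite B the p-value may be 0;
    ``plus_one_correction`` applies the (k+1)/(B+1) convention instead.
    Deterministic for a given seed.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if sidedness not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    observed = float(x.mean() - y.mean())
    rng = np.random.default_rng(seed)
    pool = np.concatenate([x, y]) if x.size <= y.size else np.concatenate([y, x])
    pool.sort()  # draws depend only on the pooled multiset, not argument order
    # draw in size-canonical order so swapping x and y only flips the sign of
    # the null statistic — the two-sided p is then exactly swap-invariant
    small, large = sorted((x.size, y.size))
    bs = rng.choice(pool, size=(n_iterations, small), replace=True).mean(axis=1)
    bl = rng.choice(pool, size=(n_iterations, large), replace=True).mean(axis=1)
    null = bs - bl if x.size <= y.size else bl - bs
    if sidedness == "two-sided":
        k = int((np.abs(null) >= abs(observed)).sum())
    elif sidedness == "greater":
        k = int((null >= observed).sum())
    else:
        k = int((null <= observed).sum())
    p = (k + 1) / (n_iterations + 1) if plus_one_correction else k / n_iterations
    return BootstrapResult(
        observed_diff=observed,
        p_value=float(p),
        n_iterations=n_iterations,
        seed=seed,
        sidedness=sidedness,
    )


def fisher_one_sided(table, direction: str = "less") -> float:
    """One-sided Fisher's exact p for a 2x2 table [[a, b], [c, d]].

    Rows are groups, columns are (with phenotype, without phenotype);
    ``direction="less"`` tests whether row 1's phenotype proportion is
    lower than row 2's (the usual variant-vs-control comparison),
    ``"greater"`` the reverse.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("contingency table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be >= 0")
    if t.sum(axis=0).max() == 0 and t.sum(axis=1).max() == 0:
        raise ValueError("table is all zeros")
    if direction not in ("less", "greater"):
        raise ValueError(f"direction must be 'less' or 'greater', got {direction!r}")
    _, p = stats.fisher_exact(t, alternative=direction)
    return float(p)


def compare_penetrance(
    summary_a: GroupSummary,
    summary_b: GroupSummary,
    direction: str = "less",
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Fisher penetrance comparison of group A (variant) vs group B (control).

    Builds the 2x2 table of (positive, non-positive) embryos per group and
    returns the table, the one-sided p, and the significance flag at
    ``alpha``.  ``direction="less"`` asks whether A's penetrance is lower.
    """
    for s in (summary_a, summary_b):
        if s.n_embryos == 0:
            raise ValueError(f"group {s.genotype!r} has zero embryos")
    table = [
        [summary_a.n_positive, summary_a.n_embryos - summary_a.n_positive],
        [summary_b.n_positive, summary_b.n_embryos - summary_b.n_positive],
    ]
    p = fisher_one_sided(table, direction=direction)
    return {
        "group_a": summary_a.genotype,
        "group_b": summary_b.genotype,
        "table": table,
        "direction": direction,
        "p_value": p,
        "alpha": alpha,
        "significant": p < alpha,
    }
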