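"""Count normalization, differential expression and qPCR quantification.

Counts are scaled to reads-per-million of each library's clean (retained)
total, compared between conditions with a classical pooled-variance
two-sample Student's t-test at raw thresholds 0.05 and 0.01 (no
multiple-testing correction), and summarised as
log2((mean_treated + pc) / (mean_control + pc)).

qPCR support implements the comparative 2^-ddCt method against a reference
gene and a pair-wise fixed-reallocation randomization test on replicate
dCt values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

NORMALIZATION_CONSTANT = 1_000_000
DEFAULT_PSEUDOCOUNT = 0.01


def normalize_per_million(counts: pd.DataFrame, totals: pd.Series | None = None) -> pd.DataFrame:
    """Scale each library column to reads-per-million of its clean total.

    *totals* defaults to the column sums; pass the library clean-read totals
    when the table holds a subset of tags.
    """
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValidationError(f"zero clean-read total in libraries {bad}")
    return counts / totals * NORMALIZATION_CONSTANT


def log2_ratio(mean_treated: float, mean_control: float,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((T + pc) / (C + pc)); the pseudocount guards zero means."""
    if mean_treated < 0 or mean_control < 0:
        raise ValidationError("negative mean expression")
    return float(np.log2((mean_treated + pseudocount) / (mean_control + pseudocount)))


def student_t_test(control: np.ndarray, treated: np.ndarray, welch: bool = False) -> float:
    """Two-sided two-sample t-test p-value (pooled variance by default).

    Degenerate zero-variance input: p = 1 when the means agree, 0 otherwise.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.size < 2 or treated.size < 2:
        raise ValidationError("need at least 2 replicates per condition")
    if control.var(ddof=1) == 0 and treated.var(ddof=1) == 0:
        return 1.0 if control.mean() == treated.mean() else 0.0
    _, p = stats.ttest_ind(control, treated, equal_var=not welch)
    return float(p)


def t_test_table(control: np.ndarray, treated: np.ndarray, welch: bool = False) -> np.ndarray:
    """Row-wise two-sample t-test over matrices (features x replicates)."""
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(control, treated, axis=1, equal_var=not welch)
    p = np.asarray(p)
    degenerate = (control.var(axis=1, ddof=1) == 0) & (treated.var(axis=1, ddof=1) == 0)
    if degenerate.any():
        equal = control.mean(axis=1) == treated.mean(axis=1)
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0
    return p


def call_de(table: pd.DataFrame, alpha_low: float = 0.05, alpha_high: float = 0.01) -> pd.DataFrame:
    """Add strict-inequality significance flags to a table with a p_value column."""
    out = table.copy()
    out["significant_05"] = out["p_value"] < alpha_low
    out["significant_01"] = out["p_value"] < alpha_high
    return out


def differential_expression(
    counts: pd.DataFrame,
    conditions: dict[str, str],
    clean_totals: pd.Series | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    welch: bool = False,
) -> pd.DataFrame:
    """Full DE table from a feature x library count table.

    *conditions* maps library name -> "control" | "treated". Returns one row
    per feature with normalized means, log2 ratio, p-value and significance
    flags, sorted by p-value.
    """
    control_libs = [lib for lib in counts.columns if conditions[lib] == "control"]
    treated_libs = [lib for lib in counts.columns if conditions[lib] == "treated"]
    if len(control_libs) < 2 or len(treated_libs) < 2:
        raise ValidationError("need at least 2 libraries per condition")
    norm = normalize_per_million(counts, clean_totals)
    c = norm[control_libs].to_numpy()
    t = norm[treated_libs].to_numpy()
    p = t_test_table(c, t, welch=welch)
    mean_c = c.mean(axis=1)
    mean_t = t.mean(axis=1)
    table = pd.DataFrame(
        {
            **{f"norm_{lib}": norm[lib] for lib in counts.columns},
            "mean_control": mean_c,
            "mean_treated": mean_t,
            "log2_ratio": np.log2((mean_t + pseudocount) / (mean_c + pseudocount)),
            "p_value": p,
        },
        index=counts.index,
    )
    return call_de(table).sort_values("p_value", kind="stable")


# ---------------------------------------------------------------------------
# qPCR

@dataclass
class QpcrSample:
    """Replicate Ct values for one gene and the reference gene, per condition."""

    gene: str
    target_control: np.ndarray
    target_treated: np.ndarray
    reference_control: np.ndarray
    reference_treated: np.ndarray

    def __post_init__(self):
        for attr in ("target_control", "target_treated",
                     "reference_control", "reference_treated"):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.size < 2:
                raise ValidationError(f"{self.gene}: {attr} needs >= 2 replicates")
            if not np.isfinite(arr).all():
                raise ValidationError(f"{self.gene}: non-finite Ct in {attr}")
            setattr(self, attr, arr)

    @property
    def dct_control(self) -> np.ndarray:
        return self.target_control - self.reference_control.mean()

    @property
    def dct_treated(self) -> np.ndarray:
        return self.target_treated - self.reference_treated.mean()


def ddct_fold_change(sample: QpcrSample) -> float:
    """Comparative 2^-ddCt relative expression (treated vs control)."""
    ddct = sample.dct_treated.mean() - sample.dct_control.mean()
    return float(2.0 ** (-ddct))


def reallocation_randomization_test(
    sample: QpcrSample,
    n_permutations: int = 2000,
    seed: int | None = None,
    exhaustive: bool | None = None,
) -> float:
    """Pair-wise fixed-reallocation randomization p-value on replicate dCt.

    Condition labels are reallocated across the pooled replicate dCt values;
    the statistic is |ddCt|. In exhaustive mode every distinct relabeling is
    enumerated: with N = C(n+m, n) labelings, p = (b + 1) / (N + 1) where b
    counts non-observed relabelings at least as extreme as the observed
    statistic. In sampled mode n_permutations random relabelings are drawn
    (seeded) with the same plus-one correction.
    """
    c = sample.dct_control
    t = sample.dct_treated
    pooled = np.concatenate([c, t])
    n_c = c.size
    observed = abs(t.mean() - c.mean())
    total = comb(pooled.size, n_c)
    if exhaustive is None:
        exhaustive = total <= n_permutations

    if exhaustive:
        observed_idx = frozenset(range(n_c))
        b = 0
        for idx in combinations(range(pooled.size), n_c):
            if frozenset(idx) == observed_idx:
                continue
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(idx)] = True
            stat = abs(pooled[~mask].mean() - pooled[mask].mean())
            if stat >= observed - 1e-12:
                b += 1
        return (b + 1) / (total + 1)

    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = abs(perm[n_c:].mean() - perm[:n_c].mean())
        if stat >= observed - 1e-12:
            b += 1
    return (b + 1) / (n_permutations + 1)
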