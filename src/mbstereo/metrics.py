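"""Stereotypy metrics on individuals x odors response tables.

Two complementary measures of cross-individual response stereotypy are
provided.  *Correlation stereotypy* is the Pearson correlation between two
individuals' odor-indexed response vectors: it captures whether the relative
pattern of responses across odors is shared, but ignores absolute response
differences.  *PRED* (pairwise relative distance) works on a pair of odors in
a pair of individuals and asks whether the two individuals differ more for
different odors than for the same odor:

    D1 = (a1 - b1)^2 + (a2 - b2)^2        same-odor squared distances
    D2 = (a1 - b2)^2 + (a2 - b1)^2        cross-odor squared distances
    PRED = (D2 - D1) / (D2 + D1)          in [-1, 1]; 0 if D1 + D2 = 0

where ``a1, a2`` are one individual's responses to the two odors and
``b1, b2`` the other's.  PRED is averaged over all unordered individual
pairs x odor pairs of a table.  Unlike correlation it stays graded for
two-odor data sets and is defined when one individual's responses are
constant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResponseTable",
    "PredComponents",
    "StereotypySignificance",
    "PredResult",
    "CorrelationResult",
    "GroupedPredResult",
    "PermutationResult",
    "pred_pair",
    "pred_stereotypy",
    "correlation_stereotypy",
    "grouped_pred",
    "permutation_null",
    "one_sample_t",
    "pairwise_pred_values",
]

# Relative floor below which D1 + D2 is treated as exactly zero (all four
# responses equal up to rounding), in units of the largest squared term.
_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class ResponseTable:
    """Trial-averaged responses: rows = individuals, columns = odors.

    Units are arbitrary (spike counts, dF/F, model output); every stereotypy
    operation requires at least two individuals and two odors.
    """

    values: np.ndarray
    individuals: tuple[str, ...]
    odors: tuple[str, ...]

    def __init__(self, values, individuals=None, odors=None):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValueError("response table must be 2-D (individuals x odors)")
        if not np.all(np.isfinite(arr)):
            raise ValueError("response table contains non-finite entries")
        n_i, n_o = arr.shape
        inds = tuple(str(x) for x in (individuals if individuals is not None
                                      else (f"ind{i+1}" for i in range(n_i))))
        ods = tuple(str(x) for x in (odors if odors is not None
                                     else (f"odor{j+1}" for j in range(n_o))))
        if len(inds) != n_i:
            raise ValueError("individual labels do not match the number of rows")
        if len(ods) != n_o:
            raise ValueError("odor labels do not match the number of columns")
        if len(set(inds)) != n_i:
            raise ValueError("duplicate individual labels")
        if len(set(ods)) != n_o:
            raise ValueError("duplicate odor labels")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "individuals", inds)
        object.__setattr__(self, "odors", ods)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_odors(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ResponseTable":
        return cls(df.to_numpy(dtype=float), df.index, df.columns)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.individuals),
                            columns=list(self.odors))

    def require_pairs(self) -> None:
        """Raise unless the table supports pairwise stereotypy analysis."""
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals for stereotypy")
        if self.n_odors < 2:
            raise ValueError("need at least 2 odors for stereotypy")


@dataclass(frozen=True)
class PredComponents:
    """Same-odor (d1) and cross-odor (d2) squared distances and their PRED."""

    d1: float
    d2: float
    pred: float


@dataclass(frozen=True)
class StereotypySignificance:
    mean: float
    n: int
    t_statistic: float
    p_value: float
    test_name: str


@dataclass
class PredResult:
    mean: float
    per_pair: pd.DataFrame  # columns: individual_pair, odor_pair, pred
    n: int = field(init=False)

    def __post_init__(self):
        self.n = len(self.per_pair)


@dataclass
class CorrelationResult:
    mean: float  # NaN when every pair is undefined
    per_pair: pd.DataFrame  # columns: individual_pair, r (NaN = undefined)
    n_defined: int
    n_undefined: int

    @property
    def all_undefined(self) -> bool:
        return self.n_defined == 0


@dataclass
class GroupedPredResult:
    within_mean: float  # NaN when no within pairs exist
    across_mean: float  # NaN when no across pairs exist
    n_within: int
    n_across: int
    per_pair: pd.DataFrame  # adds group_1, group_2, relation columns


@dataclass
class PermutationResult:
    observed: float
    null_distribution: np.ndarray
    p_value: float
    n_resamples: int


def _finite_scalar(name: str, x) -> float:
    x = float(x)
    if not np.isfinite(x):
        raise ValueError(f"{name} must be finite, got {x}")
    return x


def pred_pair(a1, a2, b1, b2) -> PredComponents:
    """PRED for one odor pair (1, 2) in one individual pair (a, b).

    d1 sums the two same-odor squared differences, d2 the two cross-odor
    ones; the ratio is identical under averaging instead of summing.
    """
    a1 = _finite_scalar("a1", a1)
    a2 = _finite_scalar("a2", a2)
    b1 = _finite_scalar("b1", b1)
    b2 = _finite_scalar("b2", b2)
    d1 = (a1 - b1) ** 2 + (a2 - b2) ** 2
    d2 = (a1 - b2) ** 2 + (a2 - b1) ** 2
    top = max((a1 - b1) ** 2, (a2 - b2) ** 2, (a1 - b2) ** 2, (a2 - b1) ** 2)
    if d1 + d2 <= _ZERO_TOL * top or top == 0.0:
        pred = 0.0
    else:
        pred = (d2 - d1) / (d2 + d1)
    return PredComponents(d1=d1, d2=d2, pred=pred)


def pairwise_pred_values(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Condensed PRED values for all odor pairs of two response vectors.

    ``x`` and ``y`` are two individuals' responses over the same odors
    (1-D, length O); returns C(O, 2) PRED values ordered like
    ``itertools.combinations(range(O), 2)``.  Vectorized core shared by the
    table-level operations and the simulator reports.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i, j = np.triu_indices(x.shape[-1], k=1)
    s1 = (x[..., i] - y[..., i]) ** 2  # same odor i
    s2 = (x[..., j] - y[..., j]) ** 2  # same odor j
    c1 = (x[..., i] - y[..., j]) ** 2  # cross
    c2 = (x[..., j] - y[..., i]) ** 2
    d1 = s1 + s2
    d2 = c1 + c2
    top = np.max(np.stack([s1, s2, c1, c2]), axis=0)
    denom = d1 + d2
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = np.where(denom > _ZERO_TOL * np.maximum(top, 1e-300),
                        (d2 - d1) / np.where(denom == 0, 1.0, denom), 0.0)
    return pred


def pred_stereotypy(table: ResponseTable) -> PredResult:
    """Mean PRED over all unordered individual pairs x odor pairs."""
    table.require_pairs()
    odor_pairs = list(itertools.combinations(range(table.n_odors), 2))
    rows = []
    for ia, ib in itertools.combinations(range(table.n_individuals), 2):
        preds = pairwise_pred_values(table.values[ia], table.values[ib])
        pair_label = f"{table.individuals[ia]}|{table.individuals[ib]}"
        for (o1, o2), p in zip(odor_pairs, preds):
            rows.append((pair_label, f"{table.odors[o1]}|{table.odors[o2]}", p))
    df = pd.DataFrame(rows, columns=["individual_pair", "odor_pair", "pred"])
    return PredResult(mean=float(df["pred"].mean()), per_pair=df)


def correlation_stereotypy(table: ResponseTable) -> CorrelationResult:
    """Mean Pearson r between individuals' odor response vectors.

    Pairs where either vector is constant have an undefined correlation;
    they are excluded from the mean and counted, never coerced to 0.
    """
    table.require_pairs()
    rows = []
    for ia, ib in itertools.combinations(range(table.n_individuals), 2):
        x, y = table.values[ia], table.values[ib]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = np.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
        rows.append((f"{table.individuals[ia]}|{table.individuals[ib]}", r))
    df = pd.DataFrame(rows, columns=["individual_pair", "r"])
    defined = df["r"].dropna()
    mean = float(defined.mean()) if len(defined) else float("nan")
    return CorrelationResult(mean=mean, per_pair=df,
                             n_defined=int(len(defined)),
                             n_undefined=int(df["r"].isna().sum()))


def grouped_pred(table: ResponseTable, odor_groups: dict) -> GroupedPredResult:
    """Partition PRED pair values by whether the two odors share a group.

    ``odor_groups`` maps every odor label to a group label (e.g. a
    concentration level).  With 6 odors in 2 groups of 3 and 6 individuals
    this yields 90 within-group and 135 across-group values.
    """
    missing = [o for o in table.odors if o not in odor_groups]
    if missing:
        raise ValueError(f"odors without a group assignment: {missing}")
    base = pred_stereotypy(table)
    df = base.per_pair.copy()
    o1 = df["odor_pair"].str.split("|").str[0]
    o2 = df["odor_pair"].str.split("|").str[1]
    df["group_1"] = o1.map(odor_groups)
    df["group_2"] = o2.map(odor_groups)
    df["relation"] = np.where(df["group_1"] == df["group_2"], "within", "across")
    within = df.loc[df["relation"] == "within", "pred"]
    across = df.loc[df["relation"] == "across", "pred"]
    return GroupedPredResult(
        within_mean=float(within.mean()) if len(within) else float("nan"),
        across_mean=float(across.mean()) if len(across) else float("nan"),
        n_within=int(len(within)),
        n_across=int(len(across)),
        per_pair=df,
    )


def permutation_null(table: ResponseTable, n_resamples: int,
                     seed=None) -> PermutationResult:
    """Permutation test for mean PRED > 0.

    The null shuffles each individual's odor labels independently (sampled
    with replacement from the permutation group) and recomputes the mean
    PRED; the one-sided p-value uses the +1 small-sample correction:
    p = (1 + #{null >= observed}) / (n_resamples + 1).
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    table.require_pairs()
    rng = np.random.default_rng(seed)
    observed = _mean_pred_fast(table.values)
    null = np.empty(n_resamples)
    vals = table.values
    for k in range(n_resamples):
        shuffled = np.stack([row[rng.permutation(vals.shape[1])] for row in vals])
        null[k] = _mean_pred_fast(shuffled)
    p = (1.0 + np.count_nonzero(null >= observed)) / (n_resamples + 1.0)
    return PermutationResult(observed=observed, null_distribution=null,
                             p_value=float(p), n_resamples=n_resamples)


def _mean_pred_fast(values: np.ndarray) -> float:
    """Mean PRED over all individual/odor pairs without label bookkeeping."""
    acc, n = 0.0, 0
    for ia, ib in itertools.combinations(range(values.shape[0]), 2):
        preds = pairwise_pred_values(values[ia], values[ib])
        acc += preds.sum()
        n += preds.size
    return acc / n


def one_sample_t(values, baseline: float = 0.0) -> StereotypySignificance:
    """Two-tailed one-sample t-test of the mean against a baseline."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a t-test")
    if np.ptp(arr) == 0:
        raise ValueError(
            "zero variance: the t-test is undefined; use permutation_null")
    res = stats.ttest_1samp(arr, popmean=baseline)
    return StereotypySignificance(
        mean=float(arr.mean()), n=int(arr.size),
        t_statistic=float(res.statistic), p_value=float(res.pvalue),
        test_name="one-sample-t")
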