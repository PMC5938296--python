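"""Observer reliability (weighted kappa) and score-distribution summaries.

Inter-observer reliability compares every pair of observers on the original
(non-replicated) assessments they share; intra-observer reliability pairs
each replicated presentation with its original.  Agreement beyond chance is
quantified with the weighted kappa for ordered categories, penalizing large
disagreements more than adjacent ones (linear weights by default, quadratic
selectable), with the standard large-sample variance for the confidence
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import ImageCondition, SCORE_LEVELS


@dataclass
class KappaResult:
    """Weighted kappa with percent agreement for one rater pairing."""

    kappa_w: float
    ci_low: float
    ci_high: float
    se: float
    percent_agreement: float
    weights: str
    n: int
    pair_label: str = ""
    note: str = ""

    @property
    def defined(self) -> bool:
        return not np.isnan(self.kappa_w)


@dataclass
class ScoreDistribution:
    """Percentage of each relative score assigned to one image condition.

    Scores are re-signed so that positive always favours the condition in
    question: a record keeps its score when the condition sat on the right
    monitor and is negated when it sat on the left.
    """

    condition: ImageCondition
    percentages: dict
    n: int

    def favourable_percent(self) -> float:
        return sum(v for s, v in self.percentages.items() if s > 0)

    def unfavourable_percent(self) -> float:
        return sum(v for s, v in self.percentages.items() if s < 0)


def weighted_kappa(
    x,
    y,
    weights: str = "linear",
    categories=SCORE_LEVELS,
    level: float = 0.95,
    pair_label: str = "",
) -> KappaResult:
    """Two-rater weighted kappa on ordered categories.

    Builds the contingency table over ``categories``, applies disagreement
    weights w_ij = |i-j|/(K-1) (linear) or ((i-j)/(K-1))^2 (quadratic) and
    returns kappa_w = 1 - sum(w * observed) / sum(w * expected), the exact-match
    percent agreement, and a large-sample Wald confidence interval
    (Fleiss-Cohen-Everitt variance).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("rating vectors must have the same length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired ratings")
    cats = list(categories)
    K = len(cats)
    lookup = {c: i for i, c in enumerate(cats)}
    try:
        xi = np.array([lookup[v] for v in x])
        yi = np.array([lookup[v] for v in y])
    except KeyError as exc:
        raise ValueError(f"rating {exc} outside the category set") from None

    table = np.zeros((K, K))
    np.add.at(table, (xi, yi), 1.0)
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    agreement = 100.0 * float(np.trace(table)) / n

    if (row > 0).sum() < 2 and (col > 0).sum() < 2:
        return KappaResult(
            kappa_w=np.nan, ci_low=np.nan, ci_high=np.nan, se=np.nan,
            percent_agreement=agreement, weights=weights, n=n,
            pair_label=pair_label,
            note="kappa undefined: fewer than 2 categories observed",
        )

    i = np.arange(K)[:, None]
    j = np.arange(K)[None, :]
    if weights == "linear":
        w = np.abs(i - j) / (K - 1)
    elif weights == "quadratic":
        w = ((i - j) / (K - 1)) ** 2
    else:
        raise ValueError("weights must be 'linear' or 'quadratic'")
    v = 1.0 - w  # agreement weights

    po = float(np.sum(p * v))
    pe = float(np.sum(np.outer(row, col) * v))
    if pe >= 1.0 - 1e-15:
        kappa = np.nan
        se = np.nan
        note = "kappa undefined: chance agreement is 1"
    else:
        kappa = (po - pe) / (1.0 - pe)
        # Fleiss, Cohen & Everitt large-sample variance
        v_row = v @ col          # \bar v_{i.} with column-margin weights
        v_col = row @ v          # \bar v_{.j} with row-margin weights
        term = v - (v_row[:, None] + v_col[None, :]) * (1.0 - kappa)
        var = (
            float(np.sum(p * term**2)) - (kappa - pe * (1.0 - kappa)) ** 2
        ) / (n * (1.0 - pe) ** 2)
        se = float(np.sqrt(max(var, 0.0)))
        note = ""
    z = norm.ppf(0.5 + level / 2.0)
    return KappaResult(
        kappa_w=float(kappa) if not np.isnan(kappa) else np.nan,
        ci_low=kappa - z * se if not np.isnan(kappa) else np.nan,
        ci_high=kappa + z * se if not np.isnan(kappa) else np.nan,
        se=se,
        percent_agreement=agreement,
        weights=weights,
        n=n,
        pair_label=pair_label,
        note=note,
    )


def _canonical_key_and_sign(df: pd.DataFrame) -> tuple[pd.Series, np.ndarray]:
    """Orientation-free pair key plus the sign mapping scores onto it."""
    left = list(zip(df["left_mAs"].astype(float), df["left_algo"]))
    right = list(zip(df["right_mAs"].astype(float), df["right_algo"]))
    keys = []
    signs = np.empty(len(df))
    for k, (l, r) in enumerate(zip(left, right)):
        if l <= r:
            keys.append((l, r))
            signs[k] = 1.0
        else:
            keys.append((r, l))
            signs[k] = -1.0
    return pd.Series(keys, index=df.index), signs


@dataclass
class ReliabilitySummary:
    """Collection of kappa results with their observed range."""

    results: list = field(default_factory=list)
    skipped: list = field(default_factory=list)

    def _vals(self, attr):
        return [getattr(r, attr) for r in self.results if r.defined]

    @property
    def kappa_range(self) -> tuple[float, float]:
        vals = self._vals("kappa_w")
        return (min(vals), max(vals)) if vals else (np.nan, np.nan)

    @property
    def agreement_range(self) -> tuple[float, float]:
        vals = self._vals("percent_agreement")
        return (min(vals), max(vals)) if vals else (np.nan, np.nan)


def interobserver_summary(
    records: pd.DataFrame, weights: str = "linear"
) -> ReliabilitySummary:
    """Weighted kappa for every observer pair on their shared assessments.

    Uses original assessments only (``replicate_index`` 0), matched on
    (patient, pair, criterion) with scores mapped to a common pair
    orientation.  Pairs of observers with no shared cells are skipped with a
    notice.
    """
    df = records[records["replicate_index"] == 0].copy()
    key, sign = _canonical_key_and_sign(df)
    df["_pair"] = key
    df["_cscore"] = df["score"].to_numpy() * sign
    observers = sorted(df["observer_id"].unique())
    summary = ReliabilitySummary()
    cell = ["patient_id", "_pair", "criterion"]
    by_obs = {o: df[df["observer_id"] == o].set_index(cell) for o in observers}
    for i, o1 in enumerate(observers):
        for o2 in observers[i + 1:]:
            a = by_obs[o1]
            b = by_obs[o2]
            shared = a.index.intersection(b.index)
            label = f"{o1} vs {o2}"
            if not len(shared):
                summary.skipped.append(f"{label}: no shared assessments")
                continue
            summary.results.append(
                weighted_kappa(
                    a.loc[shared, "_cscore"].to_numpy(int),
                    b.loc[shared, "_cscore"].to_numpy(int),
                    weights=weights,
                    pair_label=label,
                )
            )
    return summary


def intraobserver_summary(
    records: pd.DataFrame, weights: str = "linear"
) -> ReliabilitySummary:
    """Weighted kappa per observer between replicated and original readings.

    Each ``replicate_index`` >= 1 row is paired with its original (same
    patient, observer, pair orientation, criterion); all criteria pool into
    one kappa per observer.  Without replicates the result is empty with a
    notice.
    """
    summary = ReliabilitySummary()
    reps = records[records["replicate_index"] >= 1]
    if not len(reps):
        summary.skipped.append("no replicated assessments present")
        return summary
    orig = records[records["replicate_index"] == 0]
    cell = ["patient_id", "left_mAs", "left_algo", "right_mAs", "right_algo",
            "criterion"]
    for obs in sorted(reps["observer_id"].unique()):
        r = reps[reps["observer_id"] == obs]
        o = orig[orig["observer_id"] == obs].set_index(cell)
        xs, ys = [], []
        for row in r.itertuples(index=False):
            d = row._asdict()
            k = (d["patient_id"], d["left_mAs"], d["left_algo"],
                 d["right_mAs"], d["right_algo"], d["criterion"])
            if k in o.index:
                matched = o.loc[k, "score"]
                first = int(matched.iloc[0]) if hasattr(matched, "iloc") else int(matched)
                xs.append(first)
                ys.append(int(d["score"]))
        if not xs:
            summary.skipped.append(f"{obs}: replicates without originals")
            continue
        summary.results.append(
            weighted_kappa(xs, ys, weights=weights, pair_label=str(obs))
        )
    return summary


def score_distribution(
    records: pd.DataFrame, condition: ImageCondition
) -> ScoreDistribution:
    """Distribution of scores assigned to one image condition.

    Every record presenting the condition contributes once: with its score
    when the condition was on the right monitor, negated when on the left
    (so positive percentages always favour the condition).
    """
    on_right = (
        (records["right_mAs"].astype(float) == condition.tube_load)
        & (records["right_algo"] == condition.algorithm)
    )
    on_left = (
        (records["left_mAs"].astype(float) == condition.tube_load)
        & (records["left_algo"] == condition.algorithm)
    )
    scores = np.concatenate([
        records.loc[on_right, "score"].to_numpy(int),
        -records.loc[on_left, "score"].to_numpy(int),
    ])
    if scores.size == 0:
        raise ValueError(f"condition {condition.label()!r} absent from records")
    pct = {
        s: 100.0 * float(np.mean(scores == s)) for s in SCORE_LEVELS
    }
    return ScoreDistribution(condition=condition, percentages=pct, n=scores.size)


def score_distribution_table(records: pd.DataFrame, conditions) -> pd.DataFrame:
    """Score distribution for every condition, one row per condition."""
    rows = []
    for cond in conditions:
        try:
            d = score_distribution(records, cond)
        except ValueError:
            continue
        row = {"tube_load": cond.tube_load, "algorithm": cond.algorithm,
               "n": d.n}
        for s in SCORE_LEVELS:
            row[f"score_{s:+d}_pct"] = d.percentages[s]
        row["favourable_pct"] = d.favourable_percent()
        row["unfavourable_pct"] = d.unfavourable_percent()
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "KappaResult",
    "ScoreDistribution",
    "ReliabilitySummary",
    "weighted_kappa",
    "interobserver_summary",
    "intraobserver_summary",
    "score_distribution",
    "score_distribution_table",
]
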