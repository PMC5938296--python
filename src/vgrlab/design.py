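"""Pairwise comparison design and grading-record data model.

A visual grading study presents pairs of reconstructed image stacks side by
side and asks each observer to grade, per image-quality criterion, which side
is better on a 5-point relative scale (-2 .. +2, 0 = equivalent).  This module
defines the image conditions (tube load x reconstruction algorithm), the
pairwise comparison design, the grading-record table, and CSV/YAML round-trip
I/O with validation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

#: default reconstruction-algorithm labels; FBP (filtered back projection) is
#: the reference level, IR3/IR5 are iterative reconstruction strengths 3 and 5.
DEFAULT_ALGORITHMS: tuple[str, ...] = ("FBP", "IR3", "IR5")
DEFAULT_REFERENCE: str = "FBP"

#: quality-reference mAs levels of the default three-dose protocol
DEFAULT_TUBE_LOADS: tuple[float, ...] = (42.0, 98.0, 140.0)

#: registered image-quality criteria (integer codes with display names)
DEFAULT_CRITERIA: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
CRITERION_NAMES: Mapping[int, str] = {
    1: "Liver parenchyma",
    2: "Pancreatic contours",
    3: "Kidneys and proximal ureters",
    4: "Lymph nodes < 15 mm",
    5: "Image noise",
    6: "Overall image quality",
}

SCORE_LEVELS: tuple[int, ...] = (-2, -1, 0, 1, 2)

#: canonical CSV column order for grading tables
RECORD_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "observer_id",
    "criterion",
    "left_mAs",
    "left_algo",
    "right_mAs",
    "right_algo",
    "score",
    "replicate_index",
)


@dataclass(frozen=True)
class ImageCondition:
    """One reconstructed image stack's acquisition/reconstruction label.

    Parameters
    ----------
    tube_load : float
        Quality-reference mAs (proxy for radiation dose), > 0.
    algorithm : str
        Reconstruction algorithm label, e.g. ``"FBP"``, ``"IR3"``, ``"IR5"``.
    """

    tube_load: float
    algorithm: str

    def __post_init__(self) -> None:
        if not self.tube_load > 0:
            raise ValueError(f"tube_load must be positive, got {self.tube_load}")

    def dose_fraction(self, max_tube_load: float) -> float:
        """Percent of the full-protocol tube load this condition uses."""
        return 100.0 * self.tube_load / max_tube_load

    def label(self) -> str:
        g = f"{self.tube_load:g}"
        return f"{g} mAs {self.algorithm}"


@dataclass(frozen=True)
class ComparisonPair:
    """An ordered (left monitor, right monitor) pair of image conditions."""

    left: ImageCondition
    right: ImageCondition

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise ValueError("a comparison pair must differ in tube load or algorithm")

    def mirrored(self) -> "ComparisonPair":
        return ComparisonPair(self.right, self.left)

    def unordered_key(self) -> frozenset:
        """Key identifying the pair irrespective of left/right orientation."""
        return frozenset([self.left, self.right])

    def label(self) -> str:
        return f"{self.left.label()} vs {self.right.label()}"


@dataclass(frozen=True)
class ComparisonDesign:
    """The set of pairwise comparisons presented for every patient.

    Invariants: no duplicate pairs (a pair and its mirror count as the same
    comparison) and every condition referenced by a pair is registered.
    """

    pairs: tuple[ComparisonPair, ...]
    conditions: tuple[ImageCondition, ...]

    def __post_init__(self) -> None:
        keys = [p.unordered_key() for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("design contains duplicate pairs (up to mirroring)")
        registered = set(self.conditions)
        for p in self.pairs:
            for cond in (p.left, p.right):
                if cond not in registered:
                    raise ValueError(f"pair references unregistered condition {cond}")

    @property
    def algorithms(self) -> tuple[str, ...]:
        seen: list[str] = []
        for c in self.conditions:
            if c.algorithm not in seen:
                seen.append(c.algorithm)
        return tuple(seen)

    @property
    def tube_loads(self) -> tuple[float, ...]:
        return tuple(sorted({c.tube_load for c in self.conditions}))

    def contains_pair(self, pair: ComparisonPair) -> bool:
        """True if the pair (or its mirror) belongs to the design."""
        key = pair.unordered_key()
        return any(p.unordered_key() == key for p in self.pairs)

    def to_dict(self) -> dict:
        return {
            "conditions": [
                {"tube_load": c.tube_load, "algorithm": c.algorithm}
                for c in self.conditions
            ],
            "pairs": [
                {
                    "left": {"tube_load": p.left.tube_load, "algorithm": p.left.algorithm},
                    "right": {"tube_load": p.right.tube_load, "algorithm": p.right.algorithm},
                }
                for p in self.pairs
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ComparisonDesign":
        conds = tuple(
            ImageCondition(float(c["tube_load"]), str(c["algorithm"]))
            for c in d["conditions"]
        )
        pairs = tuple(
            ComparisonPair(
                ImageCondition(float(p["left"]["tube_load"]), str(p["left"]["algorithm"])),
                ImageCondition(float(p["right"]["tube_load"]), str(p["right"]["algorithm"])),
            )
            for p in d["pairs"]
        )
        return cls(pairs=pairs, conditions=conds)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ComparisonDesign":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True, eq=True)
class GradingRecord:
    """One ordinal pairwise assessment by one observer.

    ``score`` is relative: negative favours the left image, positive the
    right, 0 means the two are judged equivalent.  ``replicate_index`` 0 marks
    the original assessment; >= 1 marks re-presentations of the same hanging
    used for intra-observer reliability.
    """

    patient_id: str
    observer_id: str
    criterion: int
    pair: ComparisonPair
    score: int
    replicate_index: int = 0
    meta: tuple = ()  # extra (key, value) columns preserved opaquely


def build_default_design(
    tube_loads: Sequence[float] = DEFAULT_TUBE_LOADS,
    algorithms: Sequence[str] = DEFAULT_ALGORITHMS,
) -> ComparisonDesign:
    """Build the default 12-pair comparison design.

    Over 3 tube loads x 3 algorithms: six within-algorithm dose comparisons
    (low vs mid and mid vs high dose for each algorithm) plus six
    cross-algorithm comparisons at matched dose (each algorithm pair at the
    low and mid tube loads).  Left/right presentation sides are randomized at
    simulation time, not in the design, so this function is deterministic.
    """
    lo, mid, hi = sorted(tube_loads)
    conditions = tuple(
        ImageCondition(t, g) for t in sorted(tube_loads) for g in algorithms
    )
    pairs: list[ComparisonPair] = []
    for g in algorithms:
        pairs.append(ComparisonPair(ImageCondition(lo, g), ImageCondition(mid, g)))
        pairs.append(ComparisonPair(ImageCondition(mid, g), ImageCondition(hi, g)))
    for i, g1 in enumerate(algorithms):
        for g2 in algorithms[i + 1:]:
            for t in (lo, mid):
                pairs.append(
                    ComparisonPair(ImageCondition(t, g1), ImageCondition(t, g2))
                )
    return ComparisonDesign(pairs=tuple(pairs), conditions=conditions)


# ---------------------------------------------------------------------------
# record <-> DataFrame conversion
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[GradingRecord]) -> pd.DataFrame:
    """Convert grading records to the canonical tabular layout."""
    rows = []
    extra_cols: list[str] = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "observer_id": r.observer_id,
            "criterion": r.criterion,
            "left_mAs": r.pair.left.tube_load,
            "left_algo": r.pair.left.algorithm,
            "right_mAs": r.pair.right.tube_load,
            "right_algo": r.pair.right.algorithm,
            "score": r.score,
            "replicate_index": r.replicate_index,
        }
        for k, v in r.meta:
            row[k] = v
            if k not in extra_cols:
                extra_cols.append(k)
        rows.append(row)
    cols = list(RECORD_COLUMNS) + extra_cols
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df["criterion"] = df["criterion"].astype(int)
        df["score"] = df["score"].astype(int)
        df["replicate_index"] = df["replicate_index"].astype(int)
    return df


def frame_to_records(df: pd.DataFrame) -> list[GradingRecord]:
    """Convert a grading table back to ``GradingRecord`` objects."""
    extra = [c for c in df.columns if c not in RECORD_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        pair = ComparisonPair(
            ImageCondition(float(d["left_mAs"]), str(d["left_algo"])),
            ImageCondition(float(d["right_mAs"]), str(d["right_algo"])),
        )
        records.append(
            GradingRecord(
                patient_id=str(d["patient_id"]),
                observer_id=str(d["observer_id"]),
                criterion=int(d["criterion"]),
                pair=pair,
                score=int(d["score"]),
                replicate_index=int(d["replicate_index"]),
                meta=tuple((k, d[k]) for k in extra),
            )
        )
    return records


class RecordParseError(ValueError):
    """Raised when a grading CSV contains malformed rows or missing columns."""


def read_records(path, as_frame: bool = True):
    """Read a grading CSV.

    Parameters
    ----------
    path : path-like
        CSV file with header naming at least the canonical record columns
        (``patient_id, observer_id, criterion, left_mAs, left_algo,
        right_mAs, right_algo, score, replicate_index``).  Unknown columns
        are preserved.
    as_frame : bool
        Return a :class:`pandas.DataFrame` (default) or a list of
        :class:`GradingRecord`.

    Raises
    ------
    RecordParseError
        Naming the missing column, or the 1-based file line and field of the
        first malformed value.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordParseError(f"missing mandatory column(s): {', '.join(missing)}")
    converters = {
        "criterion": int,
        "score": int,
        "replicate_index": int,
        "left_mAs": float,
        "right_mAs": float,
    }
    for col, conv in converters.items():
        parsed = []
        for idx, raw in enumerate(df[col].tolist()):
            try:
                parsed.append(conv(raw))
            except (TypeError, ValueError):
                # +2: one for the header line, one for 1-based numbering
                raise RecordParseError(
                    f"line {idx + 2}: cannot parse field '{col}' value {raw!r}"
                ) from None
        df[col] = parsed
    ordered = list(RECORD_COLUMNS) + [c for c in df.columns if c not in RECORD_COLUMNS]
    df = df[ordered]
    return df if as_frame else frame_to_records(df)


def write_records(records, path) -> None:
    """Write grading records (DataFrame or record list) as CSV (UTF-8, header)."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    kind: str
    row: int | None
    message: str


@dataclass
class ValidationReport:
    """Bookkeeping and rule violations for a grading dataset.

    ``pairs_per_observer`` counts distinct original (patient, pair)
    presentations per observer; ``total_pair_assessments`` sums them across
    observers (a complete 50-patient, 12-pair, 5-observer study yields
    600 per observer and 3,000 in total, each covering every criterion).
    """

    n_records: int
    n_patients: int
    n_observers: int
    pairs_per_observer: dict = field(default_factory=dict)
    total_pair_assessments: int = 0
    missing_cells: int = 0
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_records(records, design: ComparisonDesign) -> ValidationReport:
    """Check a grading dataset against the scale, criteria and design.

    Reports (never raises): out-of-range scores, unknown criteria, pairs
    absent from the design modulo left/right mirroring, and per-cell
    completeness over patients x observers x pairs x criteria (original
    assessments only).
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    violations: list[Violation] = []
    if not len(df):
        return ValidationReport(n_records=0, n_patients=0, n_observers=0)

    design_keys = {p.unordered_key() for p in design.pairs}
    score_set = set(SCORE_LEVELS)
    criteria_set = set(DEFAULT_CRITERIA)

    pair_keys = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        if int(d["score"]) not in score_set:
            violations.append(
                Violation("score_out_of_range", i, f"score {d['score']} outside -2..+2")
            )
        if int(d["criterion"]) not in criteria_set:
            violations.append(
                Violation("unknown_criterion", i, f"criterion {d['criterion']} not registered")
            )
        key = frozenset(
            [
                ImageCondition(float(d["left_mAs"]), str(d["left_algo"])),
                ImageCondition(float(d["right_mAs"]), str(d["right_algo"])),
            ]
        )
        pair_keys.append(key)
        if key not in design_keys:
            violations.append(
                Violation(
                    "pair_not_in_design",
                    i,
                    f"pair {sorted((c.label() for c in key))} not in design",
                )
            )

    originals = df[df["replicate_index"] == 0]
    pair_key_series = pd.Series(pair_keys, index=df.index)[originals.index]
    per_obs = {}
    for obs, sub in originals.groupby("observer_id"):
        keys = pair_key_series[sub.index]
        per_obs[str(obs)] = len(
            {(p, k) for p, k in zip(sub["patient_id"], keys)}
        )
    total = sum(per_obs.values())

    # completeness over the full crossing at replicate 0
    patients = originals["patient_id"].unique()
    observers = originals["observer_id"].unique()
    criteria = sorted(set(originals["criterion"]) & criteria_set)
    expected = len(patients) * len(observers) * len(design.pairs) * len(criteria)
    observed_cells = len(
        {
            (p, o, k, c)
            for p, o, k, c in zip(
                originals["patient_id"],
                originals["observer_id"],
                pair_key_series,
                originals["criterion"],
            )
            if k in design_keys
        }
    )
    missing = max(expected - observed_cells, 0)

    # order-independence: violations sorted by (kind, row) for stable reporting
    violations.sort(key=lambda v: (v.kind, -1 if v.row is None else v.row))
    return ValidationReport(
        n_records=len(df),
        n_patients=len(patients),
        n_observers=len(observers),
        pairs_per_observer=per_obs,
        total_pair_assessments=total,
        missing_cells=missing,
        violations=violations,
    )
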