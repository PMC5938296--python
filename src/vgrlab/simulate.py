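"""Synthetic grading cohorts with the latent structure the VGR model assumes.

Scores arise from a latent-variable cumulative-logit model: for a presented
pair the latent quality difference is

    eta = a * (ln mAs_right - ln mAs_left) + b[right algo] - b[left algo]
          + u_patient + v_observer

with u, v centred normal random intercepts drawn per (subject, criterion) and
a standard-logistic residual.  Nondecreasing thresholds theta_1..theta_4 cut
the latent scale into the five ordered score categories -2..+2.  This is the
exact generative inverse of the model fitted in :mod:`vgrlab.model`, so every
downstream stage is testable without real ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import (
    ComparisonDesign,
    ComparisonPair,
    DEFAULT_CRITERIA,
    RECORD_COLUMNS,
    build_default_design,
)

#: default ground truth; magnitudes chosen so that most probability mass sits
#: on scores -1..+1 and fitted effects resemble a realistic reading study.
DEFAULT_TRUE_A = 2.3
DEFAULT_TRUE_B: Mapping[str, float] = {"FBP": 0.0, "IR3": 1.0, "IR5": 1.7}
DEFAULT_THRESHOLDS: tuple[float, ...] = (-3.0, -1.0, 1.0, 3.0)
DEFAULT_SIGMA = 0.5


@dataclass
class SimulationConfig:
    """Ground truth and study dimensions for a simulated grading study.

    Parameters
    ----------
    n_patients : int
        Number of scanned patients (default 50).
    observer_ids : sequence of str
        Reader labels (default five radiologists O1..O5).
    criteria : sequence of int
        Image-quality criteria graded per hanging (default 1..6).
    design : ComparisonDesign
        Pairwise comparison design (default 12-pair, 3 doses x 3 algorithms).
    true_a : float
        Latent effect per unit natural-log tube load.
    true_b : mapping algorithm -> float
        Latent algorithm effects; the reference algorithm must be 0.
    sigma_patient, sigma_observer : float
        SDs of the patient and observer random intercepts (>= 0), drawn
        independently per criterion.
    thresholds : 4-vector
        Nondecreasing cut points on the latent scale.
    n_replicates : int
        Number of (patient, pair) hangings re-presented to each observer for
        intra-observer reliability (default 5).
    seed : int
        Seed for all randomness.
    """

    n_patients: int = 50
    observer_ids: Sequence[str] = ("O1", "O2", "O3", "O4", "O5")
    criteria: Sequence[int] = DEFAULT_CRITERIA
    design: ComparisonDesign = field(default_factory=build_default_design)
    true_a: float = DEFAULT_TRUE_A
    true_b: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_B))
    sigma_patient: float = DEFAULT_SIGMA
    sigma_observer: float = DEFAULT_SIGMA
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.sigma_patient < 0 or self.sigma_observer < 0:
            raise ValueError("random-intercept SDs must be nonnegative")
        th = np.asarray(self.thresholds, dtype=float)
        if th.ndim != 1 or np.any(np.diff(th) < 0):
            raise ValueError("thresholds must be a nondecreasing vector")
        algos = set(self.design.algorithms)
        unknown = set(self.true_b) - algos
        if unknown:
            raise ValueError(f"true_b refers to unregistered algorithm(s): {unknown}")
        for g in algos:
            self.true_b.setdefault(g, 0.0)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "design" in d:
            d["design"] = ComparisonDesign.from_dict(d["design"])
        if "thresholds" in d:
            d["thresholds"] = tuple(float(t) for t in d["thresholds"])
        return cls(**d)


def _category_probs(eta, thresholds) -> np.ndarray:
    """P(score category | eta) under the latent-logistic model.

    Probabilities are differences of the standard-logistic CDF evaluated at
    the thresholds shifted by ``eta``; rows are guaranteed nonnegative and
    sum to 1.
    """
    from scipy.special import expit

    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    th = np.asarray(thresholds, dtype=float)
    cdf = expit(th[None, :] - eta[:, None])
    cum = np.concatenate(
        [np.zeros((len(eta), 1)), cdf, np.ones((len(eta), 1))], axis=1
    )
    return np.diff(cum, axis=1)


def category_probabilities(
    pair: ComparisonPair,
    config: SimulationConfig,
    patient_effect: float = 0.0,
    observer_effect: float = 0.0,
) -> np.ndarray:
    """Probability of each score -2..+2 for one presented pair.

    The latent mean combines the tube-load effect on the natural-log scale,
    the algorithm effects (right minus left), and the supplied random
    intercepts.
    """
    for cond in (pair.left, pair.right):
        if cond.algorithm not in config.true_b:
            raise ValueError(f"unregistered algorithm {cond.algorithm!r}")
    eta = (
        config.true_a * (np.log(pair.right.tube_load) - np.log(pair.left.tube_load))
        + config.true_b[pair.right.algorithm]
        - config.true_b[pair.left.algorithm]
        + patient_effect
        + observer_effect
    )
    return _category_probs(eta, config.thresholds)[0]


def simulate_study(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a full pairwise grading study.

    Left/right orientation is randomized per (patient, pair) hanging — every
    observer sees the same hanging, as in a reading room.  Scores are sampled
    per (patient, observer, criterion, hanging) from the latent model.  For
    each observer, ``n_replicates`` hangings are re-presented (same
    orientation, same random intercepts, fresh residual draws) with
    ``replicate_index`` = 1.

    Returns the canonical grading table; fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    design = config.design
    n_pat = config.n_patients
    observers = list(config.observer_ids)
    criteria = list(config.criteria)
    n_obs = len(observers)
    n_crit = len(criteria)
    n_pairs = len(design.pairs)
    patients = [f"P{i + 1:03d}" for i in range(n_pat)]

    log_mas = {c: np.log(c.tube_load) for c in design.conditions}
    b = config.true_b

    # orientation flip per (patient, pair) hanging, shared across observers
    flip = rng.random((n_pat, n_pairs)) < 0.5

    # per-(subject, criterion) random intercepts
    u = rng.normal(0.0, config.sigma_patient, size=(n_pat, n_crit))
    v = rng.normal(0.0, config.sigma_observer, size=(n_obs, n_crit))

    # fixed latent difference per pair in design (canonical) orientation
    dx = np.array(
        [log_mas[p.right] - log_mas[p.left] for p in design.pairs]
    )
    db = np.array(
        [b[p.right.algorithm] - b[p.left.algorithm] for p in design.pairs]
    )
    fixed = config.true_a * dx + db  # (n_pairs,)
    sign = np.where(flip, -1.0, 1.0)  # (n_pat, n_pairs)
    fixed_pres = sign * fixed[None, :]  # latent fixed part as presented

    th = np.asarray(config.thresholds, dtype=float)

    def sample_scores(eta: np.ndarray) -> np.ndarray:
        probs = _category_probs(eta.ravel(), th)
        uni = rng.random(probs.shape[0])
        cat = (uni[:, None] >= np.cumsum(probs, axis=1)).sum(axis=1)
        return cat - 2  # categories 0..4 -> scores -2..+2

    # main grid: patient x observer x criterion x pair
    P, O, C, K = np.meshgrid(
        np.arange(n_pat), np.arange(n_obs), np.arange(n_crit), np.arange(n_pairs),
        indexing="ij",
    )
    eta = fixed_pres[P, K] + u[P, C] + v[O, C]
    scores = sample_scores(eta)

    left_mas = np.empty(n_pairs)
    right_mas = np.empty(n_pairs)
    left_algo = np.empty(n_pairs, dtype=object)
    right_algo = np.empty(n_pairs, dtype=object)
    for k, p in enumerate(design.pairs):
        left_mas[k], left_algo[k] = p.left.tube_load, p.left.algorithm
        right_mas[k], right_algo[k] = p.right.tube_load, p.right.algorithm

    fl = flip[P, K]
    rows = {
        "patient_id": np.array(patients, dtype=object)[P.ravel()],
        "observer_id": np.array(observers, dtype=object)[O.ravel()],
        "criterion": np.array(criteria)[C.ravel()],
        "left_mAs": np.where(fl.ravel(), right_mas[K.ravel()], left_mas[K.ravel()]),
        "left_algo": np.where(fl.ravel(), right_algo[K.ravel()], left_algo[K.ravel()]),
        "right_mAs": np.where(fl.ravel(), left_mas[K.ravel()], right_mas[K.ravel()]),
        "right_algo": np.where(fl.ravel(), left_algo[K.ravel()], right_algo[K.ravel()]),
        "score": scores.ravel(),
        "replicate_index": np.zeros(scores.size, dtype=int),
    }
    df = pd.DataFrame(rows, columns=list(RECORD_COLUMNS))

    # replicated hangings: per observer, re-present n_replicates random
    # (patient, pair) hangings across all criteria with fresh residuals
    rep_frames = []
    if config.n_replicates > 0:
        n_hang = n_pat * n_pairs
        for oi in range(n_obs):
            chosen = rng.choice(n_hang, size=min(config.n_replicates, n_hang),
                                replace=False)
            pi, ki = np.unravel_index(chosen, (n_pat, n_pairs))
            Pr, Cr = np.meshgrid(np.arange(len(chosen)), np.arange(n_crit),
                                 indexing="ij")
            eta_r = (
                fixed_pres[pi[Pr.ravel()], ki[Pr.ravel()]]
                + u[pi[Pr.ravel()], Cr.ravel()]
                + v[oi, Cr.ravel()]
            )
            sc = sample_scores(eta_r)
            flr = flip[pi[Pr.ravel()], ki[Pr.ravel()]]
            kr = ki[Pr.ravel()]
            rep_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": np.array(patients, dtype=object)[pi[Pr.ravel()]],
                        "observer_id": observers[oi],
                        "criterion": np.array(criteria)[Cr.ravel()],
                        "left_mAs": np.where(flr, right_mas[kr], left_mas[kr]),
                        "left_algo": np.where(flr, right_algo[kr], left_algo[kr]),
                        "right_mAs": np.where(flr, left_mas[kr], right_mas[kr]),
                        "right_algo": np.where(flr, left_algo[kr], right_algo[kr]),
                        "score": sc,
                        "replicate_index": 1,
                    },
                    columns=list(RECORD_COLUMNS),
                )
            )
    if rep_frames:
        df = pd.concat([df] + rep_frames, ignore_index=True)

    df["criterion"] = df["criterion"].astype(int)
    df["score"] = df["score"].astype(int)
    df["replicate_index"] = df["replicate_index"].astype(int)
    df["left_mAs"] = df["left_mAs"].astype(float)
    df["right_mAs"] = df["right_mAs"].astype(float)
    return df
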