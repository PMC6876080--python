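"""The LRRGD ensemble: feature bagging, ridge logistic regression by
Newton's method, and gradient-descent refinement of a relaxed protein
indicator vector.

With ~30 disease samples and ~1600 protein features the regression is badly
under-determined, so the random-forest trick of feature bagging is borrowed:
many rounds, each fitting a model on a small random subset of proteins
(default round(sqrt(n_features))).  Per round:

1. sample a bag of protein columns without replacement (the pool is
   restored between rounds);
2. fit a ridge-penalised logistic regression of normalised disease
   similarity on the bag, by damped Newton steps;
3. relax the target disease's bag indicator vector x in [0, 1]^bag and run
   projected gradient descent on f(x) = (h_theta(x) - 1)^2, pulling the
   predicted similarity toward the self-similarity of 1.  The descent is
   initialised from the known related proteins ("informed initialisation"),
   which keeps the trajectory near the intended optimum and, together with
   the early stop |f_{n+1} - f_n| < eps, acts as an implicit weight-
   magnitude filter;
4. binarise at 0.5; proteins at 1 are this round's "related" calls.

Calls are tallied over all rounds; proteins called at least the vote
threshold (default 7, mirroring a ~10-selections-per-protein regime) are
reported as related to the target disease.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .associations import FeatureMatrix

logger = logging.getLogger(__name__)


class OptimizationError(RuntimeError):
    """Raised when a model fit cannot proceed (e.g. singular Hessian)."""


@dataclass
class LogisticModel:
    theta: np.ndarray  # intercept first, then one weight per bag feature
    feature_ids: tuple[str, ...]
    converged: bool
    final_loss: float

    @property
    def intercept(self) -> float:
        return float(self.theta[0])

    @property
    def weights(self) -> np.ndarray:
        return self.theta[1:]


@dataclass(frozen=True)
class BagConfig:
    """Feature-bagging schedule: rounds, bag size, master seed.

    ``bag_size=None`` derives round(sqrt(n_features)) at run time.  Sampling
    is without replacement within a round; the full pool is restored between
    rounds.
    """

    n_rounds: int = 400
    bag_size: int | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        if self.bag_size is not None and self.bag_size < 1:
            raise ValueError("bag_size must be >= 1")


@dataclass(frozen=True)
class GDConfig:
    """Projected-gradient-descent settings for the indicator refinement."""

    step: float = 0.1
    tol: float = 1e-6
    max_iter: int = 10_000
    init_seed_proteins: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("descent rate must be positive")
        if self.tol <= 0:
            raise ValueError("stopping tolerance must be positive")


@dataclass
class IndicatorVector:
    """Relaxed per-feature relatedness in [0, 1] plus its 0/1 view."""

    values: np.ndarray

    @property
    def binarized(self) -> np.ndarray:
        return (self.values >= 0.5).astype(np.int8)


@dataclass
class VoteTally:
    """Per-protein counts of bag selections and positive ("related") calls."""

    protein_index: tuple[str, ...]
    times_selected: np.ndarray
    times_called_related: np.ndarray
    n_rounds: int
    bag_size: int
    failed_rounds: int = 0

    def per_protein(self) -> dict[str, tuple[int, int]]:
        return {
            p: (int(s), int(c))
            for p, s, c in zip(
                self.protein_index, self.times_selected, self.times_called_related
            )
        }


def feature_subset_size(n_features: int) -> int:
    """Bag size rule borrowed from random forests: round(sqrt(n_features))."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return max(1, round(math.sqrt(n_features)))


def expected_selections(n_rounds: int, bag_size: int, n_features: int) -> float:
    """Expected number of rounds in which any given protein is sampled."""
    if min(n_rounds, bag_size, n_features) < 1:
        raise ValueError("all arguments must be positive")
    if bag_size > n_features:
        raise ValueError("bag_size cannot exceed n_features")
    return n_rounds * bag_size / n_features


def sample_features(
    n_features: int, bag_size: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample of distinct feature indices for one round."""
    if bag_size > n_features:
        raise ValueError("bag_size cannot exceed n_features")
    return rng.choice(n_features, size=bag_size, replace=False)


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _penalized_loss(Xa, y, theta, ridge):
    m = Xa.shape[0]
    z = Xa @ theta
    # numerically stable cross-entropy: log(1+e^z) - y*z
    ce = np.logaddexp(0.0, z) - y * z
    pen = 0.5 * ridge * float(theta[1:] @ theta[1:]) / m
    return float(ce.mean() + pen)


def fit_logistic_newton(
    X_bag: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    ridge: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Minimise the ridge-penalised cross-entropy by damped Newton steps.

    The loss is J(theta) = -(1/m) sum_i [y_i log h + (1-y_i) log(1-h)]
    + (ridge/2m) ||theta_without_intercept||^2.  Labels may be fractional in
    [0, 1] (cross-entropy is a proper scoring rule there); the intercept is
    not penalised.  Steps are halved until the loss does not increase, so
    the objective decreases monotonically.
    """
    X_bag = np.asarray(X_bag, dtype=float)
    y = np.asarray(y, dtype=float)
    if X_bag.ndim != 2 or X_bag.shape[0] != y.shape[0]:
        raise ValueError("X_bag rows must match label length")
    if X_bag.shape[1] < 1:
        raise ValueError("bag must contain at least one feature")
    if not (np.isfinite(X_bag).all() and np.isfinite(y).all()):
        raise ValueError("non-finite entries in design matrix or labels")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("labels must lie in [0, 1]")
    if ridge < 0:
        raise ValueError("ridge penalty must be >= 0")

    m, k = X_bag.shape
    Xa = np.hstack([np.ones((m, 1)), X_bag])
    pen_mask = np.ones(k + 1)
    pen_mask[0] = 0.0  # intercept unpenalised
    theta = np.zeros(k + 1)
    loss = _penalized_loss(Xa, y, theta, ridge)
    converged = False
    for _ in range(max_iter):
        p = _sigmoid(Xa @ theta)
        grad = Xa.T @ (p - y) / m + (ridge / m) * pen_mask * theta
        w = p * (1.0 - p)
        H = (Xa * w[:, None]).T @ Xa / m + (ridge / m) * np.diag(pen_mask)
        if ridge == 0.0 and np.linalg.matrix_rank(H) < k + 1:
            raise OptimizationError(
                "singular Hessian with ridge=0; set a positive ridge penalty"
            )
        try:
            direction = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            if ridge == 0.0:
                raise OptimizationError(
                    "singular Hessian with ridge=0; set a positive ridge penalty"
                ) from exc
            raise OptimizationError("Newton step failed") from exc
        # damping: halve the step until the objective does not increase
        t = 1.0
        for _ in range(40):
            cand = theta - t * direction
            cand_loss = _penalized_loss(Xa, y, cand, ridge)
            if cand_loss <= loss:
                break
            t *= 0.5
        else:
            break  # no improving step found; stop at current theta
        theta, loss = cand, cand_loss
        if float(np.linalg.norm(t * direction)) < tol:
            converged = True
            break
    ids = tuple(feature_ids) if feature_ids is not None else tuple(
        f"f{i}" for i in range(k)
    )
    return LogisticModel(theta=theta, feature_ids=ids, converged=converged, final_loss=loss)


def gd_refine_indicator(
    model: LogisticModel, x_init: np.ndarray, cfg: GDConfig
) -> IndicatorVector:
    """Projected gradient descent of f(x) = (h_theta(x) - 1)^2 over [0, 1]^k.

    x starts at the known-protein indicator pattern; each step moves along
    -k * grad f and projects back onto the box.  The step is halved within an
    iteration whenever it would increase f, so f is non-increasing along the
    trajectory; iteration stops when |f_{n+1} - f_n| < tol or at max_iter.
    """
    if cfg.step <= 0:
        raise ValueError("descent rate must be positive")
    w = model.weights
    b = model.intercept
    x = np.clip(np.asarray(x_init, dtype=float), 0.0, 1.0)
    if x.shape != w.shape:
        raise ValueError("x_init length must equal the bag size")

    def f(v: np.ndarray) -> float:
        h = _sigmoid(b + float(w @ v))
        return (h - 1.0) ** 2

    fx = f(x)
    for _ in range(cfg.max_iter):
        h = _sigmoid(b + float(w @ x))
        grad = 2.0 * (h - 1.0) * h * (1.0 - h) * w
        step = cfg.step
        x_new = np.clip(x - step * grad, 0.0, 1.0)
        f_new = f(x_new)
        while f_new > fx and step > 1e-15:
            step *= 0.5
            x_new = np.clip(x - step * grad, 0.0, 1.0)
            f_new = f(x_new)
        delta = abs(f_new - fx)
        x, fx = x_new, f_new
        if delta < cfg.tol:
            break
    return IndicatorVector(values=x)


def run_ensemble(
    fm: FeatureMatrix,
    target_row: str,
    seed_proteins: Iterable[str],
    bag_cfg: BagConfig = BagConfig(),
    gd_cfg: GDConfig = GDConfig(),
    ridge: float = 1.0,
) -> VoteTally:
    """The full bagged LR + GD ensemble; deterministic given ``rng_seed``.

    Each round fits on every disease row restricted to the bag, refines the
    target disease's indicator from the seed-protein initialisation, and
    tallies selections and positive calls.  Rounds whose fit fails still
    count toward ``times_selected`` (the denominator stays honest) but make
    no calls.
    """
    if target_row not in fm.disease_index:
        raise KeyError(f"target disease {target_row!r} not in the feature matrix")
    n_features = len(fm.protein_index)
    bag_size = bag_cfg.bag_size or feature_subset_size(n_features)
    if bag_size > n_features:
        raise ValueError("bag_size cannot exceed the number of features")

    pset = set(fm.protein_index)
    seeds = set(seed_proteins)
    outside = sorted(seeds - pset)
    if outside:
        logger.warning("seed proteins not in the feature pool ignored: %s", outside)
    seed_mask = np.array([p in seeds for p in fm.protein_index], dtype=float)

    X = fm.X.astype(float)
    times_selected = np.zeros(n_features, dtype=np.int64)
    times_called = np.zeros(n_features, dtype=np.int64)
    failed = 0
    for r in range(bag_cfg.n_rounds):
        # per-round substream keyed by (master seed, round index): results do
        # not depend on execution order
        rng = np.random.default_rng([bag_cfg.rng_seed, r])
        idx = sample_features(n_features, bag_size, rng)
        times_selected[idx] += 1
        feature_ids = tuple(fm.protein_index[j] for j in idx)
        try:
            model = fit_logistic_newton(
                X[:, idx], fm.y, feature_ids=feature_ids, ridge=ridge
            )
        except (OptimizationError, np.linalg.LinAlgError) as exc:
            failed += 1
            logger.warning("round %d fit failed (%s); no calls recorded", r, exc)
            continue
        refined = gd_refine_indicator(model, seed_mask[idx], gd_cfg)
        times_called[idx[refined.binarized == 1]] += 1
    return VoteTally(
        protein_index=fm.protein_index,
        times_selected=times_selected,
        times_called_related=times_called,
        n_rounds=bag_cfg.n_rounds,
        bag_size=bag_size,
        failed_rounds=failed,
    )


def select_related(tally: VoteTally, vote_threshold: int = 7) -> list[str]:
    """Proteins (selected at least once) called related in at least
    ``vote_threshold`` rounds, sorted by call count descending then accession.
    """
    if vote_threshold < 0:
        raise ValueError("vote threshold must be >= 0")
    picked = [
        (int(c), p)
        for p, s, c in zip(
            tally.protein_index, tally.times_selected, tally.times_called_related
        )
        if s > 0 and c >= vote_threshold
    ]
    picked.sort(key=lambda cp: (-cp[0], cp[1]))
    return [p for _, p in picked]


def known_fraction(n_identified: int, n_novel: int) -> float:
    """Percentage of identified proteins that were already known related."""
    if n_identified == 0:
        raise ValueError("no proteins identified")
    if not 0 <= n_novel <= n_identified:
        raise ValueError("novel count outside [0, identified]")
    return 100.0 * (n_identified - n_novel) / n_identified


VOTES_COLUMNS = [
    "protein_accession",
    "times_selected",
    "times_called_related",
    "called_fraction",
    "is_seed",
    "selected_flag",
]


def votes_frame(
    tally: VoteTally,
    seed_proteins: Iterable[str] = (),
    vote_threshold: int = 7,
) -> pd.DataFrame:
    seeds = set(seed_proteins)
    selected = set(select_related(tally, vote_threshold))
    rows = []
    for p, s, c in zip(
        tally.protein_index, tally.times_selected, tally.times_called_related
    ):
        rows.append(
            {
                "protein_accession": p,
                "times_selected": int(s),
                "times_called_related": int(c),
                "called_fraction": float(c) / s if s else 0.0,
                "is_seed": int(p in seeds),
                "selected_flag": int(p in selected),
            }
        )
    return pd.DataFrame(rows, columns=VOTES_COLUMNS)


def write_votes(
    path: str | Path,
    tally: VoteTally,
    seed_proteins: Iterable[str] = (),
    vote_threshold: int = 7,
) -> None:
    votes_frame(tally, seed_proteins, vote_threshold).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_votes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_accession": str})
    missing = set(VOTES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"votes table missing columns: {sorted(missing)}")
    return df


def write_manifest(path: str | Path, entries: Mapping) -> None:
    """Record every parameter needed to reproduce a run bit-for-bit."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dict(entries), fh, indent=2, sort_keys=True)
        fh.write("\n")
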