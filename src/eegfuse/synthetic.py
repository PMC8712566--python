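"""Synthetic cohorts: VAR-coupled signals, MST feature tables, score ensembles.

Three generators exercise every stage of the pipeline without clinical data.

* :func:`gen_var_cohort` draws two classes of multichannel signals from
  stable VAR(2) processes that differ only in their directed coupling
  topology, emulating two groups whose functional networks are organized
  differently (the downstream GC → MST features must separate them).
* :func:`gen_feature_table` draws the subjects × (bands × metrics) table
  directly, with per-feature effect sizes, for experiments that start at the
  classification stage.
* :func:`gen_classifier_scores` draws per-classifier class-probability
  vectors with controlled marginal accuracies and error correlation, via a
  Gaussian copula on latent correctness: classifier ``j`` is correct when its
  latent normal falls below the ``acc_j`` quantile, and latents are
  correlated as requested, so redundant ensembles (high correlation) and
  diverse ones (low correlation) can both be produced.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from eegfuse.brain_network import BANDS, EpochSignal, feature_names

__all__ = [
    "SyntheticSpec",
    "gen_var_cohort",
    "gen_feature_table",
    "gen_classifier_scores",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Cohort dimensions and effect parameters.

    Defaults mirror a small resting-state EEG study: 20 subjects per class,
    19 channels at 512 Hz, 25 artifact-free epochs of 4096 samples each.
    """

    n_per_class: int = 20
    n_channels: int = 19
    fs: float = 512.0
    n_epochs: int = 25
    epoch_len: int = 4096
    coupling_strength: float = 0.35
    n_couplings_class0: int = 4
    n_couplings_class1: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_per_class", "n_channels", "n_epochs", "epoch_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _stable_var2(
    rng: np.random.Generator,
    n_channels: int,
    couplings: Sequence[tuple[int, int]],
    strength: float,
) -> tuple[np.ndarray, np.ndarray]:
    """VAR(2) coefficient matrices: damped-oscillator diagonal + couplings.

    Each channel is an AR(2) with poles well inside the unit circle; each
    coupling (src, dst) adds a lag-1 term src → dst.  The companion-matrix
    spectral radius is checked and the coupling block scaled down if needed.
    """
    k = n_channels
    A1 = np.diag(rng.uniform(0.4, 0.6, size=k))
    A2 = np.diag(rng.uniform(-0.35, -0.15, size=k))
    C = np.zeros((k, k))
    for src, dst in couplings:
        C[dst, src] = strength * rng.choice([-1.0, 1.0])
    for _ in range(20):
        top = np.hstack([A1 + C, A2])
        bottom = np.hstack([np.eye(k), np.zeros((k, k))])
        companion = np.vstack([top, bottom])
        radius = np.max(np.abs(np.linalg.eigvals(companion)))
        if radius < 0.97:
            return A1 + C, A2
        C *= 0.8
    raise ValueError(
        f"could not stabilize VAR: companion spectral radius {radius:.3f} >= 0.97"
    )


def _simulate_var2(
    rng: np.random.Generator, A1: np.ndarray, A2: np.ndarray, n_samples: int, burn: int = 200
) -> np.ndarray:
    k = A1.shape[0]
    T = n_samples + burn
    x = np.zeros((k, T))
    eps = rng.standard_normal((k, T))
    for t in range(2, T):
        x[:, t] = A1 @ x[:, t - 1] + A2 @ x[:, t - 2] + eps[:, t]
    return x[:, burn:]


def _coupling_edges(
    rng: np.random.Generator, n_channels: int, n_edges: int
) -> list[tuple[int, int]]:
    pairs = [(i, j) for i in range(n_channels) for j in range(n_channels) if i != j]
    idx = rng.choice(len(pairs), size=min(n_edges, len(pairs)), replace=False)
    return [pairs[i] for i in idx]


def gen_var_cohort(spec: SyntheticSpec) -> tuple[list[list[EpochSignal]], np.ndarray]:
    """Two-class cohort of VAR-coupled epochs.

    Returns (subjects, labels): ``subjects[s]`` is the list of epochs of
    subject ``s``; classes share channel dynamics but differ in coupling
    topology/density, so only the network structure separates them.
    """
    rng = np.random.default_rng(spec.seed)
    topo_rng = np.random.default_rng(rng.integers(2**31))
    edges0 = _coupling_edges(topo_rng, spec.n_channels, spec.n_couplings_class0)
    edges1 = _coupling_edges(topo_rng, spec.n_channels, spec.n_couplings_class1)
    subjects: list[list[EpochSignal]] = []
    labels = []
    for label, edges in ((0, edges0), (1, edges1)):
        for _ in range(spec.n_per_class):
            subj_rng = np.random.default_rng(rng.integers(2**31))
            A1, A2 = _stable_var2(subj_rng, spec.n_channels, edges, spec.coupling_strength)
            epochs = [
                EpochSignal(
                    _simulate_var2(subj_rng, A1, A2, spec.epoch_len), spec.fs
                )
                for _ in range(spec.n_epochs)
            ]
            subjects.append(epochs)
            labels.append(label)
    return subjects, np.asarray(labels)


#: Plausible baseline (mean, sd) per tree metric for a 19-node MST.
_METRIC_BASELINES = {
    "max_degree": (4.0, 1.0),
    "max_bc": (0.6, 0.08),
    "leaf_fraction": (0.6, 0.07),
    "diameter": (8.0, 1.5),
    "hierarchy": (0.45, 0.06),
}


def gen_feature_table(
    n_per_class: int = 20,
    effect_sizes: Optional[dict[str, float]] = None,
    bands: Sequence[str] = tuple(BANDS),
    seed: int = 0,
) -> pd.DataFrame:
    """Subjects × (bands × 5 metrics) table with Gaussian class shifts.

    ``effect_sizes`` maps feature names (e.g. ``"theta_leaf_fraction"``) to
    standardized mean differences (class 1 − class 0, in within-class sd
    units).  Metric-range constraints are respected: degrees and diameters
    are rounded to integers and floored at their tree minima, leaf fraction
    is clipped to (0, 1], betweenness and hierarchy to (0, 1].
    """
    rng = np.random.default_rng(seed)
    effect_sizes = effect_sizes or {}
    cols = feature_names(bands)
    unknown = set(effect_sizes) - set(cols)
    if unknown:
        raise ValueError(f"unknown feature names in effect_sizes: {sorted(unknown)}")
    n = 2 * n_per_class
    labels = np.repeat([0, 1], n_per_class)
    data = {}
    for col in cols:
        metric = next(m for m in _METRIC_BASELINES if col.endswith(m))
        mean, sd = _METRIC_BASELINES[metric]
        shift = effect_sizes.get(col, 0.0) * sd
        values = rng.normal(mean, sd, size=n) + shift * labels
        if metric in ("max_degree", "diameter"):
            values = np.clip(np.round(values), 2, None)
        elif metric == "leaf_fraction":
            values = np.clip(values, 2.0 / 19.0, 1.0)
        else:
            values = np.clip(values, 1e-3, 1.0)
        data[col] = values
    frame = pd.DataFrame(data)
    frame["label"] = labels
    return frame


def gen_classifier_scores(
    n_samples: int,
    accuracies: Sequence[float],
    error_correlation: "float | np.ndarray" = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated classifier-score ensemble for one batch of samples.

    Returns ``(scores, truth)`` with ``scores`` of shape
    (n_samples, n_classifiers, 2): per-classifier probabilities of the two
    classes, summing to 1.  Classifier ``j`` assigns the larger probability
    to the true class with probability ``accuracies[j]``; correctness events
    are correlated across classifiers through a Gaussian copula with the
    requested latent correlation (scalar = equicorrelation, or a full PSD
    matrix).  Confidence of the winning class is ``0.5 + 0.5·Beta(5, 2)``
    when correct and ``0.5 + 0.5·Beta(2, 5)`` when wrong — informative but
    imperfect scores whose 0.5 threshold reproduces the marginal accuracies.
    """
    acc = np.asarray(accuracies, dtype=float)
    if np.any((acc <= 0.0) | (acc > 1.0)):
        raise ValueError("accuracies must lie in (0, 1]")
    n_clf = len(acc)
    if np.isscalar(error_correlation):
        R = np.full((n_clf, n_clf), float(error_correlation))
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(error_correlation, dtype=float)
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3e})"
        )
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R + 1e-12 * np.eye(n_clf))
    Z = rng.standard_normal((n_samples, n_clf)) @ L.T
    correct = Z <= norm.ppf(np.clip(acc, None, 1 - 1e-12))
    truth = rng.integers(0, 2, size=n_samples)

    conf_correct = 0.5 + 0.5 * rng.beta(5.0, 2.0, size=(n_samples, n_clf))
    conf_wrong = 0.5 + 0.5 * rng.beta(2.0, 5.0, size=(n_samples, n_clf))
    winner_conf = np.where(correct, conf_correct, conf_wrong)
    # class predicted = truth where correct, 1-truth where wrong
    predicted = np.where(correct, truth[:, None], 1 - truth[:, None])
    scores = np.empty((n_samples, n_clf, 2))
    scores[..., 0] = np.where(predicted == 0, winner_conf, 1.0 - winner_conf)
    scores[..., 1] = 1.0 - scores[..., 0]
    return scores, truth
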