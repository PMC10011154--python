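"""Binary particle swarm optimization for feature-subset selection.

Each particle is a binary mask over the feature vector; velocities live in
a continuous space and are squashed through a sigmoid to bit-flip
probabilities (the standard binary-PSO transfer).  The fitness rewards
cross-validated classification accuracy and mildly penalizes mask size, so
the swarm does not trivially select everything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 20
    iterations: int = 50
    inertia: float = 0.7
    cognitive: float = 1.49
    social: float = 1.49
    sparsity_penalty: float = 0.01   # lambda on the selected fraction
    cv_folds: int = 5
    seed: int = 0
    v_max: float = 4.0

    def __post_init__(self) -> None:
        if self.swarm_size <= 0 or self.iterations < 0:
            raise ValueError("swarm_size must be > 0 and iterations >= 0")
        if not 0.0 < self.inertia < 1.0:
            raise ValueError("inertia must lie in (0, 1)")


def _cv_accuracy(features: np.ndarray, labels: np.ndarray, mask: np.ndarray,
                 folds: int, rng: np.random.Generator) -> float:
    x = features[:, mask]
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                         random_state=int(rng.integers(2**31 - 1)))
    correct = 0
    for train, test in skf.split(x, labels):
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto",
                                         priors=[0.5, 0.5])
        clf.fit(x[train], labels[train])
        correct += int(np.sum(clf.predict(x[test]) == labels[test]))
    return correct / len(labels)


def _best_univariate(features: np.ndarray, labels: np.ndarray) -> int:
    """Index of the feature with the largest absolute two-class t-statistic."""
    a, b = features[labels == labels.min()], features[labels == labels.max()]
    num = np.abs(a.mean(0) - b.mean(0))
    den = np.sqrt(a.var(0, ddof=1) / len(a) + b.var(0, ddof=1) / len(b))
    t = np.where(den > 0, num / np.maximum(den, 1e-30), 0.0)
    return int(np.argmax(t))


@dataclass
class PSOResult:
    mask: np.ndarray
    fitness: float
    trace: np.ndarray  # best-so-far fitness per iteration (index 0 = init)


def pso_select(features: np.ndarray, labels: np.ndarray,
               config: PSOConfig = PSOConfig()) -> PSOResult:
    """Select a feature subset maximizing CV accuracy minus a sparsity term.

    Reproducible for a fixed ``config.seed``; the best-so-far fitness trace
    is monotone non-decreasing.  All-zero candidate masks are repaired to
    contain the single best univariate feature.
    """
    features = np.asarray(features, float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2 or counts.min() < 2:
        raise ValueError("need two classes with >= 2 samples each")
    n_feat = features.shape[1]
    folds = min(config.cv_folds, int(counts.min()))

    rng = np.random.default_rng(config.seed)
    fallback = _best_univariate(features, labels)

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[fallback] = True
        return mask

    def fitness(mask: np.ndarray) -> float:
        acc = _cv_accuracy(features, labels, mask, folds, rng)
        return acc - config.sparsity_penalty * mask.mean()

    positions = rng.random((config.swarm_size, n_feat)) < 0.5
    positions = np.array([repair(p) for p in positions])
    velocities = rng.uniform(-1, 1, (config.swarm_size, n_feat))

    pbest = positions.copy()
    pbest_fit = np.array([fitness(p) for p in positions])
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    trace = [gbest_fit]

    for _ in range(config.iterations):
        r1 = rng.random((config.swarm_size, n_feat))
        r2 = rng.random((config.swarm_size, n_feat))
        velocities = (
            config.inertia * velocities
            + config.cognitive * r1 * (pbest.astype(float) - positions)
            + config.social * r2 * (gbest.astype(float) - positions)
        )
        np.clip(velocities, -config.v_max, config.v_max, out=velocities)
        prob = 1.0 / (1.0 + np.exp(-velocities))
        positions = rng.random((config.swarm_size, n_feat)) < prob
        positions = np.array([repair(p) for p in positions])
        for i in range(config.swarm_size):
            f = fitness(positions[i])
            if f > pbest_fit[i]:
                pbest_fit[i] = f
                pbest[i] = positions[i]
                if f > gbest_fit:
                    gbest_fit = float(f)
                    gbest = positions[i].copy()
        trace.append(gbest_fit)

    return PSOResult(mask=gbest, fitness=gbest_fit, trace=np.asarray(trace))
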