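"""Performance scoring and Markov-chain surrogate significance testing.

Predictions are scored against expert (or generator ground-truth) labels
with a 4x4 confusion matrix, per-type sensitivity TP/(TP+FN) and positive
predictive value TP/(TP+FP), macro-averaged over the types for which the
metric is defined.

Significance is assessed against a classifier-free null: surrogate label
sequences are simulated from a discrete-time, time-homogeneous Markov
chain whose transition matrix is estimated from the true label sequence,
and scored against the true labels exactly like the real predictions.
The p-value is the fraction of realizations — the 1000 surrogates plus
the original — that reach the observed metric or better, so the smallest
attainable p is 1/1001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_TYPES",
    "ConfusionMatrix",
    "PerformanceReport",
    "TransitionMatrix",
    "SurrogateTestResult",
    "confusion",
    "sensitivity_ppv",
    "estimate_transitions",
    "simulate_chain",
    "surrogate_test",
    "group_test",
]

N_TYPES = 4


@dataclass
class ConfusionMatrix:
    """counts[t-1][p-1] = number of segments with true type t predicted p."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (N_TYPES, N_TYPES) or (self.counts < 0).any():
            raise ValueError("confusion matrix must be 4x4 with non-negative counts")

    @property
    def n_segments(self) -> int:
        return int(self.counts.sum())


@dataclass
class PerformanceReport:
    """Per-type and type-averaged sensitivity and PPV.

    Undefined entries (zero denominator) are NaN and excluded from the
    type averages.
    """

    per_type_sensitivity: np.ndarray
    per_type_ppv: np.ndarray
    mean_sensitivity: float
    mean_ppv: float
    n_segments: int
    types_present: list[int]


@dataclass
class TransitionMatrix:
    """Row-stochastic 4x4 transition matrix over brain-state types.

    Rows of never-visited states are flagged in ``unvisited`` and left at
    zero.
    """

    probs: np.ndarray
    unvisited: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_TYPES, N_TYPES) or (self.probs < 0).any():
            raise ValueError("transition matrix must be 4x4 non-negative")
        visited = [i for i in range(N_TYPES) if i not in self.unvisited]
        if visited and not np.allclose(self.probs[visited].sum(axis=1), 1.0):
            raise ValueError("rows of visited states must sum to 1")

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution over visited states (eigenvector of P')."""
        visited = [i for i in range(N_TYPES) if i not in self.unvisited]
        P = self.probs[np.ix_(visited, visited)]
        # renormalize in case mass leaks to unvisited states
        rs = P.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        P = P / rs
        vals, vecs = np.linalg.eig(P.T)
        k = np.argmin(np.abs(vals - 1.0))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
        full = np.zeros(N_TYPES)
        full[visited] = pi
        return full


@dataclass
class SurrogateTestResult:
    """Observed metric, its surrogate null distribution and p-value."""

    metric: str
    observed_metric: float
    surrogate_metrics: np.ndarray
    p_value: float
    initial_distribution: np.ndarray | None = None


def _as_labels(seq) -> np.ndarray:
    arr = np.asarray(getattr(seq, "labels", seq), dtype=int)
    if arr.ndim != 1:
        raise ValueError("label sequence must be one-dimensional")
    if ((arr < 1) | (arr > N_TYPES)).any():
        raise ValueError("labels must be in 1..4")
    return arr


def confusion(true, predicted) -> ConfusionMatrix:
    """Confusion matrix of true versus predicted type labels."""
    t = _as_labels(true)
    p = _as_labels(predicted)
    if len(t) != len(p):
        raise ValueError("true and predicted sequences must have equal length")
    counts = np.bincount((t - 1) * N_TYPES + (p - 1), minlength=N_TYPES * N_TYPES)
    return ConfusionMatrix(counts.reshape(N_TYPES, N_TYPES))


def sensitivity_ppv(cm: ConfusionMatrix) -> PerformanceReport:
    """Per-type and macro-averaged sensitivity and PPV from a confusion matrix.

    Sensitivity of type t is cm[t][t] / row-sum(t) (undefined when the
    type never occurs in the truth); PPV is cm[t][t] / column-sum(t)
    (undefined when the type is never predicted).  Averages run over the
    defined types only.
    """
    c = cm.counts.astype(float)
    diag = np.diag(c)
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    if row.sum() == 0:
        raise ValueError("empty confusion matrix")
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, diag / np.where(row > 0, row, 1), np.nan)
        ppv = np.where(col > 0, diag / np.where(col > 0, col, 1), np.nan)
    return PerformanceReport(
        per_type_sensitivity=sens,
        per_type_ppv=ppv,
        mean_sensitivity=float(np.nanmean(sens)),
        mean_ppv=float(np.nanmean(ppv)),
        n_segments=cm.n_segments,
        types_present=(np.flatnonzero(row > 0) + 1).tolist(),
    )


def estimate_transitions(true) -> TransitionMatrix:
    """Empirical transition matrix of a type label sequence.

    probs[i][j] = count(i -> j) / count(i -> anything) for visited i.  A
    constant single-label sequence yields self-transition probability 1
    for that label.
    """
    t = _as_labels(true)
    if len(t) < 2:
        raise ValueError("need at least 2 labels to estimate transitions")
    counts = np.zeros((N_TYPES, N_TYPES))
    np.add.at(counts, (t[:-1] - 1, t[1:] - 1), 1)
    row = counts.sum(axis=1)
    unvisited = np.flatnonzero(row == 0).tolist()
    probs = counts / np.where(row > 0, row, 1)[:, None]
    return TransitionMatrix(probs, unvisited=unvisited)


def simulate_chain(
    tm: TransitionMatrix,
    length: int,
    n_chains: int,
    rng: np.random.Generator,
    initial_distribution: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate ``n_chains`` label sequences of ``length`` from the chain.

    Vectorized over chains; returns an (n_chains, length) integer array of
    labels in 1..4.  The initial state defaults to the chain's stationary
    distribution.
    """
    if length < 1 or n_chains < 1:
        raise ValueError("length and n_chains must be >= 1")
    pi = (
        tm.stationary_distribution()
        if initial_distribution is None
        else np.asarray(initial_distribution, float)
    )
    if pi.sum() <= 0:
        raise ValueError("degenerate initial distribution")
    pi = pi / pi.sum()
    # guard rows of unvisited states: self-transition so chains stay valid
    P = tm.probs.copy()
    for i in range(N_TYPES):
        if P[i].sum() == 0:
            P[i, i] = 1.0
    cum = np.cumsum(P, axis=1)
    cum_pi = np.cumsum(pi)

    out = np.empty((n_chains, length), dtype=np.int64)
    state = np.searchsorted(cum_pi, rng.random(n_chains), side="right")
    out[:, 0] = state + 1
    for t in range(1, length):
        u = rng.random(n_chains)
        state = (cum[state] < u[:, None]).sum(axis=1)
        out[:, t] = state + 1
    return out


def _batch_metrics(true: np.ndarray, preds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean sensitivity and mean PPV of each row of ``preds`` vs ``true``.

    Vectorized confusion-matrix computation for a batch of predicted
    sequences; NaN-aware macro averages as in :func:`sensitivity_ppv`.
    """
    n, L = preds.shape
    codes = (true[None, :] - 1) * N_TYPES + (preds - 1)
    offs = (np.arange(n) * N_TYPES * N_TYPES)[:, None]
    flat = (codes + offs).ravel()
    cms = np.bincount(flat, minlength=n * N_TYPES * N_TYPES).reshape(n, N_TYPES, N_TYPES)
    diag = cms[:, np.arange(N_TYPES), np.arange(N_TYPES)].astype(float)
    row = cms.sum(axis=2).astype(float)
    col = cms.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(row > 0, diag / np.where(row > 0, row, 1), np.nan)
        ppv = np.where(col > 0, diag / np.where(col > 0, col, 1), np.nan)
    return np.nanmean(sens, axis=1), np.nanmean(ppv, axis=1)


def _p_value(observed: float, surrogates: np.ndarray) -> float:
    # realizations = surrogates + the original; the original always counts
    return float((np.sum(surrogates >= observed) + 1) / (len(surrogates) + 1))


def surrogate_test(
    true,
    observed_report: PerformanceReport,
    tm: TransitionMatrix,
    n: int = 1000,
    seed: int | None = None,
) -> dict[str, SurrogateTestResult]:
    """Test observed mean sensitivity and PPV against Markov surrogates.

    Each surrogate is a label sequence of the same length as ``true``
    simulated from ``tm``, scored against ``true``.  Returns one result
    per metric ('sensitivity', 'ppv').
    """
    if n < 1:
        raise ValueError("need at least one surrogate")
    t = _as_labels(true)
    rng = np.random.default_rng(seed)
    pi = tm.stationary_distribution()
    chains = simulate_chain(tm, len(t), n, rng, initial_distribution=pi)
    sens, ppv = _batch_metrics(t, chains)
    return {
        "sensitivity": SurrogateTestResult(
            "sensitivity",
            observed_report.mean_sensitivity,
            sens,
            _p_value(observed_report.mean_sensitivity, sens),
            initial_distribution=pi,
        ),
        "ppv": SurrogateTestResult(
            "ppv",
            observed_report.mean_ppv,
            ppv,
            _p_value(observed_report.mean_ppv, ppv),
            initial_distribution=pi,
        ),
    }


def group_test(
    individuals: list[tuple[object, PerformanceReport, TransitionMatrix]],
    n: int = 1000,
    seed: int | None = None,
) -> dict[str, SurrogateTestResult]:
    """Group-level surrogate test over several individuals.

    Each surrogate realization draws one chain per individual; the group
    statistic is the unweighted mean of the individual type-averaged
    metrics.  With a single individual this reduces to
    :func:`surrogate_test`.
    """
    if not individuals:
        raise ValueError("need at least one individual")
    rng = np.random.default_rng(seed)
    obs_sens = float(np.mean([r.mean_sensitivity for _, r, _ in individuals]))
    obs_ppv = float(np.mean([r.mean_ppv for _, r, _ in individuals]))
    sens_acc = np.zeros(n)
    ppv_acc = np.zeros(n)
    for true, _, tm in individuals:
        t = _as_labels(true)
        chains = simulate_chain(tm, len(t), n, rng)
        s, p = _batch_metrics(t, chains)
        sens_acc += s
        ppv_acc += p
    sens_acc /= len(individuals)
    ppv_acc /= len(individuals)
    return {
        "sensitivity": SurrogateTestResult(
            "sensitivity", obs_sens, sens_acc, _p_value(obs_sens, sens_acc)
        ),
        "ppv": SurrogateTestResult("ppv", obs_ppv, ppv_acc, _p_value(obs_ppv, ppv_acc)),
    }
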