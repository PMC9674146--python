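"""Post-hoc analyses of network structure and synaptic weight space.

Covers receptive-field reconstruction, the Particle Responsiveness Metric
(PRM), task-relevant synapse extraction, SVM classification of weight
configurations, PCA/kernel-PCA trajectory embeddings, solution-manifold
distances, and 2-D weight-movement histograms.  All weight-space analyses
operate on flattened hidden->output excitatory weight snapshots (6272
dimensions at default network size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA, KernelPCA
from sklearn.svm import SVC

from .environment import DIRECTIONS, ORIENTATION_OFFSETS, Orientation

__all__ = [
    "WeightSnapshotSet", "receptive_field_hidden", "receptive_field_output",
    "hidden_receptive_fields", "prm", "prm_from_receptive_fields",
    "particle_masks", "direction_mask", "task_relevant_synapses",
    "svm_weight_classifier", "embed_trajectory", "Embedding",
    "manifold_distance", "manifold_point_set", "weight_histogram_2d",
    "Histogram2D",
]


@dataclass
class WeightSnapshotSet:
    """Ordered flattened weight snapshots with (trial, phase, aeon) labels."""

    weights: np.ndarray           # (n_snapshots, n_synapses)
    trials: np.ndarray
    phases: np.ndarray
    aeons: np.ndarray

    def __post_init__(self):
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        n = self.weights.shape[0]
        for name in ("trials", "phases", "aeons"):
            arr = np.asarray(getattr(self, name))
            if arr.shape[0] != n:
                raise ValueError(f"{name} length does not match snapshots")
            setattr(self, name, arr)

    @classmethod
    def from_records(cls, records, labels=None) -> "WeightSnapshotSet":
        ws, trials, phases, aeons = [], [], [], []
        for rec in records:
            for phase, aeon, w in rec.snapshots(labels):
                ws.append(w)
                trials.append(rec.trial)
                phases.append(phase)
                aeons.append(aeon)
        if not ws:
            raise ValueError("no snapshots matched")
        return cls(np.asarray(ws, dtype=float), np.asarray(trials),
                   np.asarray(phases), np.asarray(aeons))

    def select(self, mask: np.ndarray) -> "WeightSnapshotSet":
        return WeightSnapshotSet(self.weights[mask], self.trials[mask],
                                 self.phases[mask], self.aeons[mask])


# -- receptive fields -------------------------------------------------------


def receptive_field_hidden(wiring: np.ndarray, w_ih: np.ndarray,
                           hidden_id: int,
                           input_shape: tuple[int, int] = (7, 7)) -> np.ndarray:
    """Afferent weights of one hidden neuron placed at their visual-field
    coordinates (zeros elsewhere)."""
    rf = np.zeros(input_shape)
    cols = input_shape[1]
    for k in range(wiring.shape[1]):
        src = int(wiring[hidden_id, k])
        rf[src // cols, src % cols] += w_ih[hidden_id, k]
    return rf


def hidden_receptive_fields(wiring: np.ndarray, w_ih: np.ndarray,
                            input_shape: tuple[int, int] = (7, 7)) -> np.ndarray:
    """Stack of all hidden receptive fields, shape (n_hidden, rows, cols)."""
    n_h = wiring.shape[0]
    rf = np.zeros((n_h, input_shape[0] * input_shape[1]))
    rows = np.repeat(np.arange(n_h), wiring.shape[1])
    np.add.at(rf, (rows, wiring.ravel()), w_ih.ravel())
    return rf.reshape(n_h, *input_shape)


def receptive_field_output(wiring: np.ndarray, w_ih: np.ndarray,
                           w_ho: np.ndarray, output_id: int,
                           input_shape: tuple[int, int] = (7, 7)) -> np.ndarray:
    """Weighted average of hidden receptive fields, weights = W(H->output)."""
    w = w_ho[:, output_id]
    total = w.sum()
    if total <= 0:
        raise ValueError("output neuron has zero total excitatory weight")
    rfs = hidden_receptive_fields(wiring, w_ih, input_shape)
    return np.tensordot(w, rfs, axes=(0, 0)) / total


# -- particle responsiveness metric -----------------------------------------


def particle_masks(orientation: Orientation | str,
                   fov: int = 7) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Pixel-coordinate pairs for every placement of a particle in the field
    (fully inside, no wrapping)."""
    dr, dc = ORIENTATION_OFFSETS[Orientation(orientation)]
    masks = []
    for r in range(fov):
        for c in range(fov):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < fov and 0 <= c2 < fov:
                masks.append(((r, c), (r2, c2)))
    return masks


def direction_mask(direction: tuple[int, int], fov: int = 7) -> np.ndarray:
    """3x3 block of ones in the region of the field the direction points to.

    Cardinal directions center the block on the middle of the matching
    edge; diagonals sit in the corner (e.g. up-left -> the top-left 3x3).
    """
    half = fov // 2

    def start(d: int) -> int:
        if d < 0:
            return 0
        if d == 0:
            return half - 1
        return fov - 3

    dr, dc = direction
    m = np.zeros((fov, fov))
    m[start(dr):start(dr) + 3, start(dc):start(dc) + 3] = 1.0
    return m


def prm_from_receptive_fields(rfs: np.ndarray, w_ho: np.ndarray,
                              orientation: Orientation | str,
                              directions=DIRECTIONS) -> float:
    """PRM evaluated from precomputed hidden receptive fields.

    Implements, per output neuron O with direction mask D_O::

        PRM = sum_O grand( D_O ⊙ sum_H W_{H->O} * sum_P (W_H ⊙ P) * grand(W_H ⊙ P)^2 )

    where P ranges over every placement of the particle orientation in the
    field, W_H is hidden neuron H's receptive field, and grand() sums all
    entries of a matrix.
    """
    fov = rfs.shape[1]
    masks = particle_masks(orientation, fov)
    n_h = rfs.shape[0]
    m = np.zeros((n_h, fov, fov))
    for (r1, c1), (r2, c2) in masks:
        grand = rfs[:, r1, c1] + rfs[:, r2, c2]
        g2 = grand * grand
        m[:, r1, c1] += rfs[:, r1, c1] * g2
        m[:, r2, c2] += rfs[:, r2, c2] * g2
    total = 0.0
    for o, d in enumerate(directions):
        s_o = np.tensordot(w_ho[:, o], m, axes=(0, 0))
        total += float((direction_mask(d, fov) * s_o).sum())
    return total


def prm(wiring: np.ndarray, w_ih: np.ndarray, w_ho: np.ndarray,
        orientation: Orientation | str,
        input_shape: tuple[int, int] = (7, 7)) -> float:
    """Particle Responsiveness Metric for one particle orientation.

    Quantifies how strongly particles of that orientation, at any field
    location, drive output neurons toward the matching movement direction.
    """
    rfs = hidden_receptive_fields(wiring, w_ih, input_shape)
    return prm_from_receptive_fields(rfs, w_ho, orientation)


# -- weight-space analyses ---------------------------------------------------


def task_relevant_synapses(snapshot: np.ndarray, quantile: float = 0.9) -> np.ndarray:
    """Ids of the weights in the top ``(1-quantile)`` tail of a snapshot.

    The set size is ``ceil((1-quantile) * N)`` (628 of 6272 at the default
    10%); ties at the threshold are broken by synapse index.
    """
    flat = np.asarray(snapshot, dtype=float).ravel()
    n_top = math.ceil((1.0 - quantile) * flat.size)
    order = np.argsort(-flat, kind="stable")
    return np.sort(order[:n_top])


def svm_weight_classifier(train_t1: np.ndarray, train_t2: np.ndarray,
                          query: np.ndarray, C: float = 1.0,
                          gamma: str | float = "scale") -> np.ndarray:
    """RBF-kernel SVM decision values for weight-configuration queries.

    Trained on labelled Task-1 / Task-2 snapshot sets; returns the signed
    distance to the decision boundary per query row.  Sign convention:
    Task-1-like states are negative, Task-2-like positive.
    """
    train_t1 = np.atleast_2d(train_t1)
    train_t2 = np.atleast_2d(train_t2)
    if len(train_t1) == 0 or len(train_t2) == 0:
        raise ValueError("both training classes must be non-empty")
    X = np.vstack([train_t1, train_t2])
    y = np.concatenate([np.zeros(len(train_t1)), np.ones(len(train_t2))])
    clf = SVC(kernel="rbf", C=C, gamma=gamma)
    clf.fit(X, y)
    return clf.decision_function(np.atleast_2d(query))


@dataclass
class Embedding:
    coords: np.ndarray
    method: str
    degenerate: bool = False


def embed_trajectory(snapshots: np.ndarray, method: str = "pca",
                     dims: int = 2) -> Embedding:
    """Deterministic low-dimensional embedding of weight snapshots.

    ``"pca"`` is ordinary principal components; ``"kpca"`` uses an RBF
    kernel with a median-heuristic bandwidth.  Identical snapshots (zero
    variance) yield a flagged all-zero embedding rather than noise.
    """
    X = np.atleast_2d(np.asarray(snapshots, dtype=float))
    if X.shape[0] < dims + 1:
        raise ValueError("need at least dims+1 snapshots")
    if np.allclose(X.var(axis=0), 0.0):
        return Embedding(np.zeros((X.shape[0], dims)), method, degenerate=True)
    if method == "pca":
        coords = PCA(n_components=dims, random_state=0).fit_transform(X)
    elif method == "kpca":
        sq = cdist(X, X, metric="sqeuclidean")
        med = np.median(sq[np.triu_indices_from(sq, k=1)])
        gamma = 1.0 / med if med > 0 else 1.0
        coords = KernelPCA(n_components=dims, kernel="rbf", gamma=gamma,
                           random_state=0).fit_transform(X)
    else:
        raise ValueError("method must be 'pca' or 'kpca'")
    return Embedding(coords, method)


def manifold_distance(point: np.ndarray, manifold_points: np.ndarray) -> float:
    """Distance from a weight state to a sampled solution manifold:
    the minimum Euclidean distance over the point set."""
    pts = np.atleast_2d(np.asarray(manifold_points, dtype=float))
    if pts.shape[0] == 0:
        raise ValueError("manifold point set is empty")
    point = np.asarray(point, dtype=float).reshape(1, -1)
    if point.shape[1] != pts.shape[1]:
        raise ValueError("point dimension does not match manifold set")
    return float(cdist(point, pts).min())


def manifold_point_set(records, phase_labels) -> np.ndarray:
    """Stack the snapshots from the last fifth of the named phases.

    The membership rule for a solution manifold: weight states from the
    final 20% of a phase's snapshots (after performance has plateaued),
    pooled over trials.
    """
    labels = [phase_labels] if isinstance(phase_labels, str) else list(phase_labels)
    points = []
    for rec in records:
        for label in labels:
            try:
                ph = rec.phase(label)
            except KeyError:
                continue
            snaps = ph.snap_weights
            if not snaps:
                continue
            start = min(math.ceil(0.8 * len(snaps)), len(snaps) - 1)
            points.extend(snaps[start:])
    if not points:
        raise ValueError("no snapshots found for the requested phases")
    return np.asarray(points, dtype=float)


@dataclass
class Histogram2D:
    counts: np.ndarray          # raw per-bin synapse counts
    capped: np.ndarray          # counts clipped at the display cap
    x_edges: np.ndarray
    y_edges: np.ndarray
    marginal_x: np.ndarray
    marginal_y: np.ndarray


def weight_histogram_2d(snapshot_a: np.ndarray, snapshot_b: np.ndarray,
                        n_bins: int = 50, count_cap: int = 50) -> Histogram2D:
    """Joint histogram of per-synapse strengths at two time slices.

    Synapses that kept their strength fall on the diagonal; the x (y) axis
    collects synapses that lost (gained) all strength.  ``capped`` clips
    bin counts at ``count_cap`` for display scaling; ``counts`` conserves
    total mass (= number of synapses).
    """
    a = np.asarray(snapshot_a, dtype=float).ravel()
    b = np.asarray(snapshot_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("snapshots must have equal length")
    hi = max(a.max(), b.max(), 1e-12)
    edges = np.linspace(0.0, hi * (1 + 1e-9), n_bins + 1)
    counts, xe, ye = np.histogram2d(a, b, bins=(edges, edges))
    return Histogram2D(
        counts=counts,
        capped=np.minimum(counts, count_cap),
        x_edges=xe, y_edges=ye,
        marginal_x=np.histogram(a, bins=edges)[0],
        marginal_y=np.histogram(b, bins=edges)[0],
    )
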