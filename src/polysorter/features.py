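"""Low-dimensional waveform features: variance-ranked points + PCA.

Each event contributes a data vector of voltages at up to M = 100
(channel, tau) coordinates chosen by ranking the across-event variance
at every time point of the waveform on the cluster's assigned channels.
The principal components of those vectors (mean-centered covariance
eigendecomposition) give the 2-3 dimensional space in which clustering
and pair-overlap tests run.  Scores inherit the microvolt scale of the
waveforms, which is what makes the clustering kernel width (sigma in
microvolts) meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

M_POINTS = 100  # max number of variance-ranked time points


@dataclass
class FeatureSet:
    """PCA scores and basis for a set of event waveforms."""

    scores: np.ndarray          # (N, n_components)
    basis: np.ndarray           # (M, n_components), orthonormal columns
    eigenvalues: np.ndarray     # all M, nonincreasing
    selected_points: list       # [(channel, tau), ...] in vector order
    mean: np.ndarray            # (M,) center removed before projection


def select_timepoints(W: np.ndarray, channels: np.ndarray,
                      taus: np.ndarray, m_points: int = M_POINTS) -> list:
    """Rank (channel, tau) coordinates by across-event variance.

    ``W`` is (n_events, n_channels, n_taus).  Returns up to ``m_points``
    coordinates with the highest variance; exact ties break by
    (channel, tau) lexicographic order.  Degenerate all-identical input
    falls back to returning every coordinate.
    """
    if W.shape[0] < 2:
        raise ValueError("need at least 2 events to rank variances")
    var = W.var(axis=0)                       # (n_channels, n_taus)
    flat = var.ravel()
    order = np.lexsort((np.tile(taus, len(channels)),
                        np.repeat(channels, len(taus)),
                        -flat))
    if flat.max() > 0:
        order = order[: m_points]
    ci, ti = np.unravel_index(order, var.shape)
    return [(int(channels[c]), int(taus[t])) for c, t in zip(ci, ti)]


def data_vectors(W: np.ndarray, channels: np.ndarray, taus: np.ndarray,
                 selected: list) -> np.ndarray:
    """(N, M) matrix of voltages at the selected coordinates."""
    ch_pos = {int(c): i for i, c in enumerate(channels)}
    tau_pos = {int(t): i for i, t in enumerate(taus)}
    cols = [(ch_pos[c], tau_pos[t]) for c, t in selected]
    return np.stack([W[:, c, t] for c, t in cols], axis=1)


def compute_pcs(X: np.ndarray, n_components: int = 2) -> FeatureSet:
    """Principal components of mean-centered data vectors.

    The covariance matrix is eigendecomposed; scores are dot products of
    the centered vectors with the top eigenvectors.  Eigenvector sign is
    fixed by making each column's largest-magnitude loading positive.
    Rank-deficient input simply yields trailing ~zero eigenvalues.
    """
    X = np.asarray(X, dtype=float)
    N, M = X.shape
    if N < n_components + 1:
        raise ValueError("need more observations than components")
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = Xc.T @ Xc / (N - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.maximum(evals, 0.0)
    basis = evecs[:, :n_components].copy()
    for j in range(basis.shape[1]):
        i = np.argmax(np.abs(basis[:, j]))
        if basis[i, j] < 0:
            basis[:, j] = -basis[:, j]
    return FeatureSet(scores=Xc @ basis, basis=basis, eigenvalues=evals,
                      selected_points=[], mean=mean)


def waveform_features(W: np.ndarray, channels: np.ndarray, taus: np.ndarray,
                      n_components: int = 3,
                      m_points: int = M_POINTS) -> FeatureSet:
    """Variance-ranked point selection followed by PCA, in one call."""
    selected = select_timepoints(W, channels, taus, m_points)
    X = data_vectors(W, channels, taus, selected)
    fs = compute_pcs(X, n_components=min(n_components, X.shape[1], X.shape[0] - 1))
    fs.selected_points = selected
    return fs
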