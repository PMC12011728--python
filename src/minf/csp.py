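"""Common Spatial Patterns for left- vs right-hand motor imagery.

Class covariances are per-trial trace-normalized and averaged, then lightly
shrunk toward a scaled identity. Filters solve the generalized eigenproblem

    C_left w = lambda (C_left + C_right) w,

so each eigenvalue in (0, 1) is the fraction of pooled band-power variance
the filter attributes to left-hand trials. Because motor imagery suppresses
the contralateral rhythm, the filter selected for a hand is the one whose
output variance is minimal on that hand's trials (lambda extreme): left-hand
filter at the low-lambda extreme, right-hand filter at the high end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from minf.preprocessing import EpochSet
from minf.simulate import sensorimotor_clusters


@dataclass
class CSPModel:
    W: np.ndarray                  # filters x channels, rows sorted by desc eigenvalue
    eigenvalues: np.ndarray        # in (0, 1), descending
    patterns: np.ndarray           # channels x filters (pinv of W)
    selected: dict                 # {'left': filter index, 'right': filter index}
    channel_subset: list[str]      # channel labels the model was fit on
    channel_positions: np.ndarray

    @property
    def n_filters(self) -> int:
        return self.W.shape[0]


def trial_covariances(ep: EpochSet, window: tuple[float, float],
                      normalize: bool = True) -> np.ndarray:
    """Per-trial channel covariance over the MI window (trace-normalized)."""
    sl = ep.sample_slice(window)
    segs = ep.data[:, :, sl]
    covs = np.einsum("tcs,tds->tcd", segs, segs) / segs.shape[-1]
    if normalize:
        traces = np.trace(covs, axis1=1, axis2=2)
        covs = covs / traces[:, None, None]
    return covs


def class_covariances(ep: EpochSet, window: tuple[float, float] = (0.5, 4.5),
                      shrinkage: float = 0.05
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Shrunk average covariance per class over non-rejected trials."""
    out = []
    for hand in ("left", "right"):
        mask = (ep.labels == hand) & ep.kept
        if mask.sum() < 2:
            raise ValueError(f"need >= 2 usable {hand!r} trials, got {mask.sum()}")
        c = trial_covariances(ep.select(mask), window).mean(axis=0)
        n = c.shape[0]
        c = (1 - shrinkage) * c + shrinkage * np.trace(c) / n * np.eye(n)
        out.append(c)
    return out[0], out[1]


def csp_from_covariances(c_left: np.ndarray, c_right: np.ndarray,
                         channel_labels: list[str] | None = None,
                         channel_positions: np.ndarray | None = None) -> CSPModel:
    """Solve C_left w = lambda (C_left + C_right) w; rows of W by desc lambda."""
    pooled = c_left + c_right
    try:
        eigvals, eigvecs = linalg.eigh(c_left, pooled)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            f"pooled covariance singular even after regularization: {err}"
        ) from err
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    W = eigvecs.T
    n = c_left.shape[0]
    if channel_labels is None:
        channel_labels = [f"C{i}" for i in range(n)]
    if channel_positions is None:
        channel_positions = np.zeros((n, 2))
    model = CSPModel(
        W=W,
        eigenvalues=eigvals,
        patterns=np.linalg.pinv(W),
        selected={},
        channel_subset=list(channel_labels),
        channel_positions=channel_positions,
    )
    return select_filters(model, 1, mode="eigenvalue")


def fit_csp(ep: EpochSet, window: tuple[float, float] = (0.5, 4.5),
            shrinkage: float = 0.05) -> CSPModel:
    """Fit CSP on band-filtered epochs over the MI window.

    Expects data already band-pass filtered to 8-30 Hz and restricted to the
    channel subset the model should use.
    """
    c_left, c_right = class_covariances(ep, window, shrinkage)
    return csp_from_covariances(c_left, c_right, ep.channel_labels,
                                ep.channel_positions)


def _plausibility_score(pattern: np.ndarray, positions: np.ndarray) -> float:
    """Spatial smoothness x sensorimotor-cluster weight of one pattern.

    Automates the manual 'neurophysiologically plausible' criterion: a
    plausible pattern concentrates energy over a hand area and varies
    smoothly across neighboring sensors.
    """
    p2 = pattern**2
    total = p2.sum()
    if total <= 0:
        return 0.0
    left_idx, right_idx = sensorimotor_clusters(positions)
    cluster = np.union1d(left_idx, right_idx)
    cluster_weight = p2[cluster].sum() / total if cluster.size else 0.0
    # roughness: squared deviation from the mean of the 4 nearest neighbors
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1)[:, :4]
    rough = np.mean((pattern - pattern[nn].mean(axis=1)) ** 2) / (pattern.var() + 1e-12)
    smooth = 1.0 / (1.0 + rough)
    return cluster_weight * smooth


def select_filters(model: CSPModel, n_per_class: int = 1,
                   mode: str = "eigenvalue", n_candidates: int = 3) -> CSPModel:
    """Pick one (or n) filter per hand at the eigenvalue extremes.

    eigenvalue mode: the most extreme filters (right hand at high lambda,
    left hand at low lambda). scored mode: among ``n_candidates`` extreme
    filters per side, takes the one with the best plausibility score.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if 2 * n_per_class > model.n_filters:
        raise ValueError("fewer filters than requested")
    if mode == "eigenvalue":
        right = list(range(n_per_class))
        left = list(range(model.n_filters - n_per_class, model.n_filters))
    elif mode == "scored":
        k = min(n_candidates, model.n_filters // 2)
        high = list(range(k))
        low = list(range(model.n_filters - k, model.n_filters))
        score = lambda i: _plausibility_score(
            model.patterns[:, i], model.channel_positions
        )
        right = sorted(high, key=score, reverse=True)[:n_per_class]
        left = sorted(low, key=score, reverse=True)[:n_per_class]
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    sel = {"right": right[0], "left": left[0]} if n_per_class == 1 else \
        {"right": right, "left": left}
    return dataclasses.replace(model, selected=sel)


def apply_csp(ep: EpochSet, model: CSPModel, laterality: str = "contra"
              ) -> EpochSet:
    """Project each trial onto its hand's filter (one virtual channel).

    contra: a trial's own hand's filter (left-hand filter on left-hand EEG);
    ipsi: the opposite hand's filter.
    """
    if not model.selected:
        raise ValueError("model.selected not populated; run select_filters")
    if laterality not in ("contra", "ipsi"):
        raise ValueError(f"laterality must be contra or ipsi, got {laterality!r}")
    if ep.channel_labels != model.channel_subset:
        raise ValueError("epoch channel set does not match the CSP model")
    out = np.empty((ep.n_trials, 1, ep.data.shape[-1]))
    for i in range(ep.n_trials):
        hand = ep.labels[i]
        key = hand if laterality == "contra" else \
            ("left" if hand == "right" else "right")
        w = model.W[model.selected[key]]
        out[i, 0] = w @ ep.data[i]
    return dataclasses.replace(
        ep.copy(),
        data=out,
        channel_labels=[f"CSP-{laterality}"],
        channel_positions=np.zeros((1, 2)),
    )


def project_selected(ep: EpochSet, model: CSPModel) -> EpochSet:
    """Project every trial onto both selected filters (left, right).

    Unlike :func:`apply_csp` the projection does not depend on the trial
    label, giving the fixed two-dimensional feature space the neurofeedback
    classifiers operate in.
    """
    if not model.selected:
        raise ValueError("model.selected not populated; run select_filters")
    if ep.channel_labels != model.channel_subset:
        raise ValueError("epoch channel set does not match the CSP model")
    w = model.W[[model.selected["left"], model.selected["right"]]]
    data = np.einsum("fc,tcs->tfs", w, ep.data)
    return dataclasses.replace(
        ep.copy(),
        data=data,
        channel_labels=["CSP-left", "CSP-right"],
        channel_positions=np.zeros((2, 2)),
    )


def serialize_model(model: CSPModel, path: str) -> None:
    """Write filters, eigenvalues, selection and channel subset as text."""
    import json

    payload = dict(
        W=model.W.tolist(),
        eigenvalues=model.eigenvalues.tolist(),
        patterns=model.patterns.tolist(),
        selected=model.selected,
        channel_subset=model.channel_subset,
        channel_positions=model.channel_positions.tolist(),
    )
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path: str) -> CSPModel:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    return CSPModel(
        W=np.array(payload["W"]),
        eigenvalues=np.array(payload["eigenvalues"]),
        patterns=np.array(payload["patterns"]),
        selected=payload["selected"],
        channel_subset=payload["channel_subset"],
        channel_positions=np.array(payload["channel_positions"]),
    )
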