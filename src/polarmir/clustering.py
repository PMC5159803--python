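"""Fuzzy c-means clustering of DE-gene time profiles.

Profiles are the concatenated per-timepoint log2 mean expressions in M1 and
then M2 (8 values for a 4-point course), optionally expressed relative to
the unstimulated (M0) baseline, standardized per gene to mean 0 / sd 1.
Soft clustering follows the classic fuzzy c-means alternating updates with
Euclidean distance on standardized profiles; genes are assigned to the
cluster of maximum membership only when that membership strictly exceeds a
threshold (a threshold above 0.5 guarantees uniqueness).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils import check_random_state

from .design import SampleDesign

log = logging.getLogger(__name__)


def build_profiles(
    normalized: pd.DataFrame,
    design: SampleDesign,
    de_genes,
    relative_to_m0: bool = False,
) -> pd.DataFrame:
    """Standardized time profiles for the given genes.

    Returns a DataFrame (gene x 2T) of per-gene standardized vectors of
    log2(mean normalized count + 1) at each time point, M1 block first then
    M2.  With ``relative_to_m0``, the log2 M0 mean is subtracted before
    standardization (an affine shift, so the standardized profile is
    unchanged unless genes are later compared on the raw scale).  Genes with
    zero variance across the profile are excluded with a logged reason.
    """
    genes = [g for g in de_genes if g in normalized.index]
    missing = len(list(de_genes)) - len(genes)
    if missing:
        raise ValueError(f"{missing} requested genes absent from the expression matrix")
    cols, blocks = [], []
    for cond in ("M1", "M2"):
        for tp in design.timepoints:
            samples = design.samples(cond, tp)
            if not samples:
                raise ValueError(f"no samples for {cond} at {tp} h")
            blocks.append(np.log2(normalized.loc[genes, samples].mean(axis=1) + 1.0))
            cols.append(f"{cond}_{tp:g}h")
    prof = pd.concat(blocks, axis=1)
    prof.columns = cols
    if relative_to_m0:
        m0_samples = design.samples("M0")
        if not m0_samples:
            raise ValueError("relative_to_m0 requires M0 control samples in the design")
        m0 = np.log2(normalized.loc[genes, m0_samples].mean(axis=1) + 1.0)
        prof = prof.sub(m0, axis=0)
    sd = prof.std(axis=1, ddof=0)
    flat = sd == 0
    if flat.any():
        log.info("excluding %d constant gene profiles from clustering: %s",
                 int(flat.sum()), list(prof.index[flat][:10]))
        prof = prof.loc[~flat]
        sd = sd.loc[~flat]
    return prof.sub(prof.mean(axis=1), axis=0).div(sd, axis=0)


class FuzzyCMeans(BaseEstimator, ClusterMixin):
    """Fuzzy c-means (soft k-means) with Euclidean distance.

    Parameters
    ----------
    n_clusters : int
        Number of clusters c.
    m : float
        Fuzzifier (> 1).  Large m drives all memberships toward 1/c.
    tol : float
        Convergence threshold on the maximum center shift.
    max_iter : int
        Iteration cap; non-convergence logs a warning, never raises.
    n_init : int
        Number of seeded random restarts; the run with the lowest final
        objective is kept (fuzzy c-means converges to local optima, so
        restarts are the standard guard, as in k-means).
    random_state : int, RandomState or None
        Seeds the initializations (c distinct profiles sampled as centers).

    Fitted attributes: ``cluster_centers_`` (c x d), ``membership_``
    (n x c, rows sum to 1), ``labels_`` (argmax membership),
    ``objective_history_`` (sum u^m d^2 per iteration, non-increasing),
    ``n_iter_``, ``converged_``.
    """

    def __init__(self, n_clusters: int = 4, m: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 500, n_init: int = 10, random_state=None):
        self.n_clusters = n_clusters
        self.m = m
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init
        self.random_state = random_state

    def _memberships(self, X: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u = np.zeros_like(d2)
        zero = d2 <= 0
        has_zero = zero.any(axis=1)
        # a profile coinciding with a center gets full membership there
        if has_zero.any():
            z = zero[has_zero]
            u[has_zero] = z / z.sum(axis=1, keepdims=True)
        rest = ~has_zero
        if rest.any():
            inv = d2[rest] ** (-1.0 / (self.m - 1.0))
            u[rest] = inv / inv.sum(axis=1, keepdims=True)
        return u, d2

    def fit(self, X, y=None) -> "FuzzyCMeans":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        n = X.shape[0]
        if n <= self.n_clusters:
            raise ValueError("need more profiles than clusters")
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        rng = check_random_state(self.random_state)
        best = None
        for _ in range(self.n_init):
            run = self._fit_once(X, rng)
            if best is None or run["objective"] < best["objective"]:
                best = run
        self.cluster_centers_ = best["centers"]
        self.membership_ = best["membership"]
        self.labels_ = best["membership"].argmax(axis=1)
        self.objective_history_ = best["history"]
        self.n_iter_ = len(best["history"])
        self.converged_ = best["converged"]
        return self

    def _fit_once(self, X: np.ndarray, rng) -> dict:
        n = X.shape[0]
        centers = X[rng.choice(n, size=self.n_clusters, replace=False)].copy()
        history = []
        converged = False
        u, d2 = self._memberships(X, centers)
        for it in range(1, self.max_iter + 1):
            um = u**self.m
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            u, d2 = self._memberships(X, centers)
            history.append(float((u**self.m * d2).sum()))
            if shift < self.tol:
                converged = True
                break
        if not converged:
            log.warning("fuzzy c-means did not converge in %d iterations", self.max_iter)
        return {"centers": centers, "membership": u, "history": np.asarray(history),
                "converged": converged, "objective": history[-1] if history else np.inf}

    def predict(self, X) -> np.ndarray:
        u, _ = self._memberships(np.asarray(X, dtype=float), self.cluster_centers_)
        return u.argmax(axis=1)

    def predict_membership(self, X) -> np.ndarray:
        u, _ = self._memberships(np.asarray(X, dtype=float), self.cluster_centers_)
        return u


def fuzzy_cmeans(profiles: pd.DataFrame, c: int = 4, m: float = 2.0, seed=None,
                 tol: float = 1e-6, max_iter: int = 500, n_init: int = 10) -> FuzzyCMeans:
    """Cluster a profile table; thin wrapper over :class:`FuzzyCMeans`."""
    return FuzzyCMeans(n_clusters=c, m=m, tol=tol, max_iter=max_iter, n_init=n_init,
                       random_state=seed).fit(profiles.to_numpy())


def assign_clusters(fc: FuzzyCMeans, profiles: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Hard assignments at a strict membership threshold.

    Returns a table indexed by gene with the argmax cluster, its membership
    and the assignment (cluster id, or -1 for unassigned when the maximum
    membership does not strictly exceed the threshold).  The assigned
    fraction is stored in ``table.attrs['assigned_fraction']``.
    """
    if not 0 < threshold < 1:
        raise ValueError("membership threshold must be in (0, 1)")
    u = fc.membership_
    best = u.argmax(axis=1)
    best_u = u[np.arange(len(u)), best]
    assigned = np.where(best_u > threshold, best, -1)
    out = pd.DataFrame(
        {"cluster": best, "membership": best_u, "assigned": assigned},
        index=profiles.index,
    )
    out.attrs["assigned_fraction"] = float((assigned >= 0).mean()) if len(out) else 0.0
    return out
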