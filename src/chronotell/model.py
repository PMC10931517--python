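"""Time-indexed probability model of the circadian clock transcriptome.

For each training timepoint t_i the normalised expression vectors over the
gene panel are reduced by a *local* principal component analysis to d = 3
coordinates.  All training data are projected through each local basis and a
multivariate normal is fitted per training time, giving means mu_{i,j} and
covariances Sigma_{i,j}.  Periodic PCHIP splines through the per-time means
and the d(d+1)/2 distinct covariance entries extend each timepoint's family
of Gaussians to every time of day, with eigenvalue-clipping repair wherever
interpolation leaves a covariance indefinite.  The resulting family of MVN
distributions indexed by clock time is the probability model: the likelihood
of a single test sample as a function of time of day is read off from it.

:class:`ClockModel` wraps the whole construction as a scikit-learn style
estimator (``fit`` / ``predict`` / ``score_samples``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator

from .dataset import ExpressionSet, GenePanel, extract_revs
from .normalize import NormalisationRecipe, fit_timecourse, normalise
from .spline import PeriodicPchip, nearest_pd

__all__ = [
    "LocalProjection",
    "TimepointMVN",
    "fit_local_projection",
    "fit_timepoint_mvn",
    "mvn_logpdf",
    "ClockModel",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class LocalProjection:
    """Top-d principal subspace of the normalised vectors at one timepoint."""

    timepoint: int
    basis: np.ndarray  # G x d, orthonormal columns
    explained_variance_ratio: np.ndarray  # length d
    centre: np.ndarray  # G, timepoint mean used for centring

    def project(self, g: np.ndarray) -> np.ndarray:
        """Linear projection U_d^T g (no centring at evaluation time)."""
        return self.basis.T @ g


@dataclass
class TimepointMVN:
    """Gaussian fitted to the projected vectors of one training time."""

    timepoint: int
    mean: np.ndarray  # d
    cov: np.ndarray  # d x d, symmetric PD (after regularisation)
    regularised: bool = False


def fit_local_projection(revs_at_t: np.ndarray, d: int) -> LocalProjection:
    """PCA basis of the columns of a G x N_s matrix of normalised vectors.

    Centring is by the timepoint mean; the returned basis spans the top-d
    principal subspace.  Component signs are fixed so that the
    largest-magnitude loading of each component is positive, making fitted
    archives reproducible.
    """
    X = np.asarray(revs_at_t, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in projection input")
    G, n = X.shape
    if n <= d:
        raise ValueError(
            f"need more than d={d} samples at a timepoint to fit the local "
            f"projection (got {n}); lower d or pool more instances"
        )
    centre = X.mean(axis=1)
    Xc = X - centre[:, None]
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    ratios = var[:d] / total if total > 0 else np.zeros(d)
    basis = U[:, :d].copy()
    if basis.shape[1] < d:  # rank-deficient beyond available columns
        pad = np.zeros((G, d - basis.shape[1]))
        basis = np.hstack([basis, pad])
        ratios = np.pad(ratios, (0, d - len(ratios)))
    for k in range(d):
        j = int(np.argmax(np.abs(basis[:, k])))
        if basis[j, k] < 0:
            basis[:, k] = -basis[:, k]
    if total > 0 and np.any(var[:d] <= 1e-12 * total):
        warnings.warn("degenerate rank: some components have zero explained variance")
    return LocalProjection(
        timepoint=-1, basis=basis, explained_variance_ratio=np.asarray(ratios), centre=centre
    )


def fit_timepoint_mvn(
    projected: np.ndarray,
    timepoint: int = -1,
    cond_cap: float = 1e8,
    ridge_tau: float = 1e-4,
) -> TimepointMVN:
    """Fit a Gaussian (sample mean, n-1 covariance) to d x N_s projections.

    If the sample covariance is ill-conditioned (condition number above
    ``cond_cap``, including singular), a ridge ``ridge_tau * trace/d`` is
    added to the diagonal.
    """
    P = np.asarray(projected, dtype=float)
    d, n = P.shape
    if n < 2:
        raise ValueError("need at least 2 points to fit a timepoint Gaussian")
    mean = P.mean(axis=1)
    cov = np.cov(P, ddof=1)
    cov = np.atleast_2d(cov)
    w = np.linalg.eigvalsh(0.5 * (cov + cov.T))
    regularised = False
    # a degenerate cluster (coincident points) has covariance at round-off
    # level; its ridge must be set by the data scale, not the trace
    ref = max(float(np.mean(P**2)), np.finfo(float).tiny)
    if w[-1] <= 1e-12 * ref:
        cov = cov + (ridge_tau * ref) * np.eye(d)
        regularised = True
    elif w[0] <= 0 or w[-1] / max(w[0], np.finfo(float).tiny) > cond_cap:
        cov = cov + (ridge_tau * (np.trace(cov) / d)) * np.eye(d)
        regularised = True
    return TimepointMVN(timepoint=timepoint, mean=mean, cov=0.5 * (cov + cov.T), regularised=regularised)


def mvn_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Multivariate normal log-density, via Cholesky factorisation."""
    x = np.asarray(x, dtype=float)
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    d = len(mean)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance is not positive definite") from e
    z = np.linalg.solve(L, x - mean)
    return float(-0.5 * z @ z - np.log(np.diag(L)).sum() - 0.5 * d * _LOG_2PI)


class ClockModel(BaseEstimator):
    """Estimator of internal circadian phase from single expression vectors.

    Parameters
    ----------
    panel : GenePanel, list of str, or None
        Gene panel; ``None`` uses all genes of the training set, in order.
    d : int
        Projection dimension of the local PCA (3 captures the dominant
        clock correlations for typical panels).
    normalisation : {"timecourse", "intergene", "both"}
        How training and test vectors are normalised.
    l_thresh : float
        Log-likelihood floor applied per timepoint curve before averaging;
        protects the combined curve from unreliable extreme-low densities.
    eta, eps : float
        Parameters of the cosine reference curve C(t|T) used by the theta
        dysfunction metric; must satisfy 0 < eta*eps < eta*(2+eps) < 1.
    grid_size : int
        Number of evaluation times per day (1440 = 1-minute resolution).
    timepoint_tol : float
        Tolerance in hours when grouping sample times onto timepoints.
    allow_unequal_ns : bool
        Tolerate unequal numbers of samples per timepoint (used by
        leave-one-sample-out cross-validation).

    Attributes
    ----------
    panel_ : GenePanel
    recipe_ : NormalisationRecipe or None
    timepoint_times_ : array, training times t_i
    projections_ : list of LocalProjection
    mvn_means_ : array (N_t, N_t, d), mu_{i,j}
    mvn_covs_ : array (N_t, N_t, d, d), Sigma_{i,j}
    grid_times_ : array, dense evaluation times
    repair_count_ : int, number of PD repairs on the dense grid
    training_ml_, training_theta_ : arrays of in-sample training metrics
    """

    def __init__(
        self,
        panel=None,
        d: int = 3,
        normalisation: str = "timecourse",
        l_thresh: float = -5.0,
        eta: float = 0.35,
        eps: float = 0.15,
        grid_size: int = 1440,
        timepoint_tol: float = 0.25,
        cond_cap: float = 1e8,
        ridge_tau: float = 1e-4,
        pd_eps_scale: float = 1e-8,
        allow_unequal_ns: bool = False,
        compute_training_summary: bool = True,
    ):
        self.panel = panel
        self.d = d
        self.normalisation = normalisation
        self.l_thresh = l_thresh
        self.eta = eta
        self.eps = eps
        self.grid_size = grid_size
        self.timepoint_tol = timepoint_tol
        self.cond_cap = cond_cap
        self.ridge_tau = ridge_tau
        self.pd_eps_scale = pd_eps_scale
        self.allow_unequal_ns = allow_unequal_ns
        self.compute_training_summary = compute_training_summary

    # ------------------------------------------------------------------
    def fit(self, X: ExpressionSet, y=None) -> "ClockModel":
        es = X
        if self.panel is None:
            panel = GenePanel(list(es.gene_ids))
        elif isinstance(self.panel, GenePanel):
            panel = self.panel
        else:
            panel = GenePanel(list(self.panel))
        self.panel_ = panel
        if not self.d < len(panel):
            raise ValueError("projection dimension d must be < panel size")

        if self.normalisation in ("timecourse", "both"):
            self.recipe_ = fit_timecourse(es, panel)
        else:
            self.recipe_ = None
        revs = extract_revs(es, panel)
        g_norm = normalise(self.normalisation, revs, es.instances, self.recipe_)

        tp_idx = es.timepoint_index
        counts = np.bincount(tp_idx)
        if not self.allow_unequal_ns and len(set(counts)) > 1:
            raise ValueError(
                f"unequal number of samples per timepoint {counts.tolist()}; "
                "set allow_unequal_ns=True to tolerate this"
            )
        times = es.timepoint_times
        order = np.argsort(times)
        self.timepoint_times_ = times[order]
        n_t = len(order)
        if n_t < 3:
            raise ValueError("need at least 3 training timepoints for periodic splines")

        d = self.d
        self.projections_ = []
        self.mvn_means_ = np.empty((n_t, n_t, d))
        self.mvn_covs_ = np.empty((n_t, n_t, d, d))
        self.mvn_regularised_ = np.zeros((n_t, n_t), dtype=bool)
        for a, i in enumerate(order):
            cols_i = tp_idx == i
            proj = fit_local_projection(g_norm[:, cols_i], d)
            proj.timepoint = a
            self.projections_.append(proj)
            P_all = proj.basis.T @ g_norm  # d x N, linear projection of everything
            for b, j in enumerate(order):
                mvn = fit_timepoint_mvn(
                    P_all[:, tp_idx == j], timepoint=b,
                    cond_cap=self.cond_cap, ridge_tau=self.ridge_tau,
                )
                self.mvn_means_[a, b] = mvn.mean
                self.mvn_covs_[a, b] = mvn.cov
                self.mvn_regularised_[a, b] = mvn.regularised

        self._build_grid_cache()
        self._g_norm_training = g_norm
        self._training_summary()
        return self

    # ------------------------------------------------------------------
    def _build_grid_cache(self) -> None:
        """Spline means/covariances onto the dense grid and factorise."""
        n_t, d = len(self.timepoint_times_), self.d
        grid = np.arange(self.grid_size) * (24.0 / self.grid_size)
        self.grid_times_ = grid
        iu = np.triu_indices(d)
        self.grid_means_ = np.empty((n_t, self.grid_size, d))
        self.grid_covs_ = np.empty((n_t, self.grid_size, d, d))
        repair = 0
        for a in range(n_t):
            mean_spline = PeriodicPchip(self.timepoint_times_, self.mvn_means_[a])
            self.grid_means_[a] = mean_spline(grid)
            cov_entries = self.mvn_covs_[a][:, iu[0], iu[1]]  # N_t x d(d+1)/2
            cov_spline = PeriodicPchip(self.timepoint_times_, cov_entries)
            vals = cov_spline(grid)  # grid x d(d+1)/2
            covs = np.zeros((self.grid_size, d, d))
            covs[:, iu[0], iu[1]] = vals
            covs[:, iu[1], iu[0]] = vals
            # batched PD screen; eigenvalue-clipping repair only where needed
            w = np.linalg.eigvalsh(covs)
            tr = np.trace(covs, axis1=1, axis2=2)
            floor = self.pd_eps_scale * np.where(tr > 0, tr / d, 1.0)
            bad = np.flatnonzero(w[:, 0] < floor)
            for k in bad:
                covs[k], _ = nearest_pd(covs[k], self.pd_eps_scale)
            repair += len(bad)
            self.grid_covs_[a] = covs
        self.repair_count_ = repair
        chol = np.linalg.cholesky(self.grid_covs_)  # (n_t, grid, d, d)
        self._grid_inv_chol = np.linalg.inv(chol)
        diag = np.einsum("abii->abi", chol)
        self._grid_half_logdet = np.log(diag).sum(axis=-1)  # (n_t, grid)

    def _training_summary(self) -> None:
        if not self.compute_training_summary:
            self.training_ml_ = np.empty(0)
            self.training_log_ml_ = np.empty(0)
            self.training_theta_ = np.empty(0)
            del self._g_norm_training
            return
        profs = self.score_samples(self._g_norm_training, already_normalised=True)
        self.training_ml_ = np.array([p.ml for p in profs])
        self.training_log_ml_ = np.array([p.log_ml for p in profs])
        self.training_theta_ = np.array([p.theta for p in profs])
        del self._g_norm_training

    # ------------------------------------------------------------------
    def mu_sigma_at(self, i: int, times) -> tuple[np.ndarray, np.ndarray]:
        """Splined (mean, covariance) of timepoint i's family at given times.

        Evaluated directly from the spline knots with PD repair; independent
        of the cached grid factorisation.
        """
        d = self.d
        iu = np.triu_indices(d)
        times = np.atleast_1d(np.asarray(times, dtype=float))
        mu = PeriodicPchip(self.timepoint_times_, self.mvn_means_[i])(times)
        vals = PeriodicPchip(
            self.timepoint_times_, self.mvn_covs_[i][:, iu[0], iu[1]]
        )(times)
        covs = np.zeros((len(times), d, d))
        covs[:, iu[0], iu[1]] = vals
        covs[:, iu[1], iu[0]] = vals
        for k in range(len(times)):
            covs[k], _ = nearest_pd(covs[k], self.pd_eps_scale)
        return mu, covs

    def _normalise_input(self, X, instances=None, already_normalised=False) -> np.ndarray:
        if isinstance(X, ExpressionSet):
            revs = extract_revs(X, self.panel_)
            labels = X.instances
        else:
            revs = np.asarray(X, dtype=float)
            if revs.ndim == 1:
                revs = revs[:, None]
            labels = instances
        if already_normalised:
            return revs
        return normalise(self.normalisation, revs, labels, self.recipe_)

    def per_timepoint_loglik(self, g_norm: np.ndarray) -> np.ndarray:
        """Log L_{g,i}(t): array (N_t, grid_size, N) of per-timepoint curves.

        ``g_norm`` is a G-vector or G x N matrix already normalised with the
        model's recipe/mode.
        """
        g = np.asarray(g_norm, dtype=float)
        single = g.ndim == 1
        if single:
            g = g[:, None]
        bases = np.stack([p.basis for p in self.projections_])  # (n_t, G, d)
        proj = np.einsum("igd,gn->idn", bases, g)  # (n_t, d, N)
        diff = proj[:, None, :, :] - self.grid_means_[..., None]  # (n_t, grid, d, N)
        z = np.einsum("abde,aben->abdn", self._grid_inv_chol, diff)
        quad = np.einsum("abdn,abdn->abn", z, z)
        ll = -0.5 * quad - self._grid_half_logdet[..., None] - 0.5 * self.d * _LOG_2PI
        return ll

    def max_log_density(self, grid_index) -> np.ndarray:
        """Log of the model's maximum density at grid times, per the
        truncated-average convention used for the likelihood curve.

        This is the density each timepoint family assigns to its own mean,
        floored at l_thresh and averaged over timepoints; used as M in the
        likelihood-ratio statistic lambda = log(ML/M).
        """
        peak = -self._grid_half_logdet[:, grid_index] - 0.5 * self.d * _LOG_2PI
        return np.mean(np.maximum(peak, self.l_thresh), axis=0)

    # ------------------------------------------------------------------
    def score_samples(
        self, X, instances=None, already_normalised=False, l_thresh=None
    ) -> list:
        """Full likelihood profile (T, ML, LRF, theta, peaks, flags) per sample."""
        from .profile import ThetaConfig, build_profile

        g_norm = self._normalise_input(X, instances, already_normalised)
        ll = self.per_timepoint_loglik(g_norm)
        lt = self.l_thresh if l_thresh is None else l_thresh
        cfg = ThetaConfig(eta=self.eta, eps=self.eps)
        sample_ids = (
            X.sample_ids if isinstance(X, ExpressionSet) else list(range(g_norm.shape[1]))
        )
        out = []
        for n, sid in enumerate(sample_ids):
            out.append(
                build_profile(
                    ll[:, :, n], self.grid_times_, lt, cfg,
                    model=self, sample_id=sid,
                )
            )
        return out

    def predict(self, X, instances=None, already_normalised=False) -> np.ndarray:
        """Estimated internal phase T (hours in [0, 24)) per sample."""
        return np.array(
            [p.t for p in self.score_samples(X, instances, already_normalised)]
        )

    # ------------------------------------------------------------------
    # archive
    def save(self, path) -> None:
        """Write the fitted model to a self-describing JSON archive."""
        obj = {
            "schema": "chronotell-model-1",
            "params": self.get_params(),
            "panel": list(self.panel_),
            "panel_provenance": self.panel_.provenance,
            "recipe": None
            if self.recipe_ is None
            else {
                "mode": self.recipe_.mode,
                "table": self.recipe_.to_table().to_dict(orient="list"),
            },
            "timepoint_times": self.timepoint_times_.tolist(),
            "projections": [
                {
                    "basis": p.basis.tolist(),
                    "explained_variance_ratio": p.explained_variance_ratio.tolist(),
                    "centre": p.centre.tolist(),
                }
                for p in self.projections_
            ],
            "mvn_means": self.mvn_means_.tolist(),
            "mvn_covs": self.mvn_covs_.tolist(),
            "mvn_regularised": self.mvn_regularised_.tolist(),
            "training_ml": self.training_ml_.tolist(),
            "training_log_ml": self.training_log_ml_.tolist(),
            "training_theta": self.training_theta_.tolist(),
            "repair_count": int(self.repair_count_),
        }
        params = obj["params"]
        if isinstance(params.get("panel"), GenePanel):
            params["panel"] = list(params["panel"])
        with open(path, "w") as fh:
            json.dump(obj, fh, sort_keys=True, indent=None, separators=(",", ":"))

    @classmethod
    def load(cls, path) -> "ClockModel":
        with open(path) as fh:
            obj = json.load(fh)
        if obj.get("schema") != "chronotell-model-1":
            raise ValueError("unrecognised model archive schema")
        model = cls(**obj["params"])
        model.panel_ = GenePanel(obj["panel"], provenance=obj.get("panel_provenance", ""))
        rec = obj["recipe"]
        model.recipe_ = (
            None
            if rec is None
            else NormalisationRecipe.from_table(pd.DataFrame(rec["table"]), rec["mode"])
        )
        model.timepoint_times_ = np.asarray(obj["timepoint_times"])
        model.projections_ = [
            LocalProjection(
                timepoint=a,
                basis=np.asarray(p["basis"]),
                explained_variance_ratio=np.asarray(p["explained_variance_ratio"]),
                centre=np.asarray(p["centre"]),
            )
            for a, p in enumerate(obj["projections"])
        ]
        model.mvn_means_ = np.asarray(obj["mvn_means"])
        model.mvn_covs_ = np.asarray(obj["mvn_covs"])
        model.mvn_regularised_ = np.asarray(obj["mvn_regularised"], dtype=bool)
        model.training_ml_ = np.asarray(obj["training_ml"])
        model.training_log_ml_ = np.asarray(obj["training_log_ml"])
        model.training_theta_ = np.asarray(obj["training_theta"])
        model._build_grid_cache()
        model.repair_count_ = int(obj["repair_count"])
        return model
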