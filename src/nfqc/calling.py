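"""Empty-droplet and damaged-cell calling from nuclear fraction and UMI count.

Two statistical components drive the calls:

* **Empty droplets** sit at distinctly low nuclear fraction because ambient
  RNA is predominantly mature, spliced mRNA.  A Gaussian kernel density
  estimate of the per-droplet NF scores is computed on a fixed grid over
  [0, 1]; the first local minimum of the density following its first peak —
  found via sign changes of the numerical first derivative — is the cutoff
  below which barcodes are flagged as empty.  Manual overrides are provided:
  a fixed NF threshold, and a UMI count above which a barcode is always
  kept as a cell.

* **Damaged cells** are partially lysed: depleted of cytoplasmic RNA, they
  show a higher NF and a lower UMI total than intact cells of the same
  type.  Per cell type, a two-component Gaussian mixture with diagonal
  covariance,

      P(x | mu, sigma, alpha) = alpha_1 N(x | mu_1, sigma_1^2)
                              + alpha_2 N(x | mu_2, sigma_2^2),

  is fitted by expectation-maximization on x = (log10 UMI, NF).  Initial
  parameters come from a deterministic median split on NF: component means,
  (biased) variances and weights alpha_k = N_k / N are computed from the two
  halves, then E-steps (posterior responsibilities, Bayes' rule) alternate
  with M-steps (responsibility-weighted refits) until the log-likelihood
  stabilizes.  The Bayesian information criterion decides whether a second
  component is warranted at all (k=2 vs k=1); when it is, the component
  with higher mean NF *and* lower mean UMI is the damaged-cell candidate,
  and droplets are labelled damaged only if the separation passes two gates
  (mean NF difference >= ``delta_nf``, default 0.15; candidate mean UMI at
  most ``umi_ratio`` of the intact mean, default 50%).

The estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and compose with
sklearn model selection; the module-level functions are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .counting import STATUS_CELL, STATUS_DAMAGED, STATUS_EMPTY, STATUS_UNASSIGNED

logger = logging.getLogger(__name__)

__all__ = [
    "CallConfig",
    "EmptyThreshold",
    "MixtureFit",
    "EmptyDropletDetector",
    "DiagonalGaussianMixture",
    "DamagedCellDetector",
    "estimate_empty_threshold",
    "flag_empty",
    "fit_mixture",
    "identify_damaged",
    "call_all",
]


@dataclass
class CallConfig:
    """Knobs for empty-droplet and damaged-cell calling.

    ``nf_rescue`` replaces the automatic KDE cutoff with a manual NF
    threshold; ``umi_rescue`` marks every barcode above that UMI total as a
    cell regardless of NF.  ``delta_nf`` and ``umi_ratio`` are the
    separation gates for damaged-cell labelling.
    """

    nf_rescue: float | None = None
    umi_rescue: float | None = None
    delta_nf: float = 0.15
    umi_ratio: float = 0.5
    min_droplets_per_type: int = 100
    em_tol: float = 1e-6
    em_max_iter: int = 1000
    seed: int = 0
    # empty-threshold estimation
    bandwidth: str | float = "silverman"
    grid_size: int = 512
    prominence: float = 0.05
    min_nf_values: int = 50
    # mixture details
    variance_floor: float = 1e-6
    posterior_cutoff: float = 0.5
    umi_center: str = "geometric"

    def __post_init__(self) -> None:
        if not 0 < self.delta_nf < 1:
            raise ValueError("delta_nf must be in (0, 1)")
        if not 0 < self.umi_ratio < 1:
            raise ValueError("umi_ratio must be in (0, 1)")


@dataclass
class EmptyThreshold:
    """KDE of the NF distribution and the detected empty-droplet cutoff."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    peak_position: float
    valley_position: float | None
    cutoff: float | None


@dataclass
class MixtureFit:
    """A fitted k-component diagonal-Gaussian mixture on (log10 UMI, NF)."""

    k: int
    means: np.ndarray  # (k, d)
    variances: np.ndarray  # (k, d)
    weights: np.ndarray  # (k,)
    responsibilities: np.ndarray  # (n, k)
    loglik: float
    bic: float
    n_iter: int
    converged: bool
    loglik_path: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# empty-droplet detection


def _reflected_kde(values: np.ndarray, bandwidth, grid_size: int):
    """Gaussian KDE on [0, 1] with boundary reflection at both edges.

    Reflection keeps the probability mass of modes near 0 or 1 inside the
    unit interval, so the returned density integrates to ~1 over the grid.
    """
    kde = stats.gaussian_kde(values, bw_method=bandwidth)
    grid = np.linspace(0.0, 1.0, grid_size)
    density = kde(grid) + kde(-grid) + kde(2.0 - grid)
    bw = kde.factor * values.std(ddof=1)
    return grid, density, bw


def _peaks_and_valleys(density: np.ndarray):
    """Local maxima/minima via sign changes of the finite first difference.

    Flat stretches inherit the preceding slope sign so a plateau counts as a
    single extremum; boundary extrema are detected by padding.
    """
    sign = np.sign(np.diff(density))
    for i in range(1, len(sign)):  # carry slope through flats
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    sign = np.concatenate([[1.0], sign, [-1.0]])  # boundary extrema
    peaks, valleys = [], []
    for i in range(1, len(sign)):
        if sign[i - 1] > 0 and sign[i] < 0:
            peaks.append(i - 1)
        elif sign[i - 1] < 0 and sign[i] > 0:
            valleys.append(i - 1)
    return peaks, valleys


class EmptyDropletDetector(BaseEstimator):
    """Flag empty droplets by a KDE-valley threshold on the nuclear fraction.

    Parameters
    ----------
    bandwidth : str or float, default="silverman"
        Bandwidth rule (or scipy ``bw_method`` factor) for the Gaussian KDE.
    grid_size : int, default=512
        Number of evaluation points on [0, 1].
    prominence : float, default=0.05
        A mode must reach this fraction of the global density maximum to
        count as a peak; suppresses noise wiggles.
    min_samples : int, default=50
        Minimum number of defined NF values for automatic thresholding.
    nf_rescue : float, optional
        Manual NF cutoff overriding the automatic one.
    umi_rescue : float, optional
        UMI total above which a barcode is always called a cell.

    ``fit`` expects ``X`` with the NF scores in the first column; a second
    column, when present, holds UMI totals and is used only by ``predict``
    for the rescue rule.
    """

    def __init__(self, bandwidth="silverman", grid_size=512, prominence=0.05,
                 min_samples=50, nf_rescue=None, umi_rescue=None):
        self.bandwidth = bandwidth
        self.grid_size = grid_size
        self.prominence = prominence
        self.min_samples = min_samples
        self.nf_rescue = nf_rescue
        self.umi_rescue = umi_rescue

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=False, ensure_min_samples=1)
        nf = np.sort(np.asarray(X if X.ndim == 1 else X[:, 0], dtype=float))
        if np.any((nf < 0) | (nf > 1)):
            raise ValueError("nuclear fraction values must lie in [0, 1]")
        self.n_features_in_ = 1 if X.ndim == 1 else X.shape[1]
        if len(nf) < self.min_samples:
            if self.nf_rescue is None:
                raise ValueError(
                    f"only {len(nf)} defined nuclear-fraction values "
                    f"(minimum {self.min_samples} for automatic thresholding); "
                    "set nf_rescue to threshold manually"
                )
            self.grid_ = self.density_ = None
            self.bandwidth_ = None
            self.peak_position_ = self.valley_position_ = self.cutoff_ = None
            self.threshold_ = self.nf_rescue
            return self
        grid, density, bw = _reflected_kde(nf, self.bandwidth, self.grid_size)
        peaks, valleys = _peaks_and_valleys(density)
        floor = self.prominence * density.max()
        major = [p for p in peaks if density[p] >= floor]
        self.grid_, self.density_, self.bandwidth_ = grid, density, bw
        self.peak_position_ = float(grid[major[0]]) if major else float(grid[int(np.argmax(density))])
        if len(major) >= 2:
            # first valley strictly between the first two qualifying peaks
            between = [v for v in valleys if major[0] < v < major[1]]
            vi = between[0] if between else int(major[0] + np.argmin(density[major[0]:major[1] + 1]))
            self.valley_position_ = float(grid[vi])
            self.cutoff_ = self.valley_position_
        else:  # unimodal: no interior valley after smoothing
            self.valley_position_ = None
            self.cutoff_ = None
        self.threshold_ = self.nf_rescue if self.nf_rescue is not None else self.cutoff_
        return self

    def predict(self, X):
        """Label droplets ``empty_droplet`` / ``cell`` by the fitted cutoff."""
        check_is_fitted(self, "threshold_")
        if self.threshold_ is None:
            raise ValueError(
                "no empty-droplet cutoff: the NF density is unimodal and "
                "nf_rescue is unset; provide nf_rescue to threshold manually"
            )
        X = check_array(X, ensure_2d=False, ensure_all_finite=False)
        if X.ndim == 1:
            nf, umi = X.astype(float), None
        else:
            nf = X[:, 0].astype(float)
            umi = X[:, 1].astype(float) if X.shape[1] > 1 else None
        empty = nf < self.threshold_
        if self.umi_rescue is not None and umi is not None:
            empty &= ~(umi > self.umi_rescue)
        return np.where(empty, STATUS_EMPTY, STATUS_CELL)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)


# ---------------------------------------------------------------------------
# diagonal-Gaussian mixture via EM


class DiagonalGaussianMixture(BaseEstimator):
    """k-component Gaussian mixture with per-dimension variances, fit by EM.

    Initialization is deterministic: observations are split at the median of
    ``split_feature`` (default: last column, the NF axis), and each half
    provides a component's initial mean, biased variance and weight
    N_k / N.  The E-step computes posterior responsibilities by Bayes' rule;
    the M-step refits means, variances and weights with those weights.
    Iteration stops when the relative log-likelihood change drops below
    ``tol``.  ``bic_`` is ``-2 loglik + p ln n`` with ``p = 2kd + (k-1)``
    free parameters.

    A variance floor guards against component collapse; a collapse triggers
    a bounded number of re-initializations at random quantile splits before
    failing.
    """

    def __init__(self, n_components=2, tol=1e-6, max_iter=1000,
                 variance_floor=1e-6, split_feature=-1, n_retries=3,
                 random_state=0):
        self.n_components = n_components
        self.tol = tol
        self.max_iter = max_iter
        self.variance_floor = variance_floor
        self.split_feature = split_feature
        self.n_retries = n_retries
        self.random_state = random_state

    # log N(x | mu, sigma^2) summed over dimensions, per component
    def _log_components(self, X, means, variances, weights):
        n, d = X.shape
        out = np.empty((n, len(weights)))
        for k in range(len(weights)):
            out[:, k] = np.log(weights[k]) - 0.5 * np.sum(
                np.log(2.0 * np.pi * variances[k])
                + (X - means[k]) ** 2 / variances[k],
                axis=1,
            )
        return out

    def _initial_partition(self, X, split_q):
        k = self.n_components
        if k == 1:
            return np.zeros(len(X), dtype=int)
        pivot = np.quantile(X[:, self.split_feature], split_q)
        assign = (X[:, self.split_feature] > pivot).astype(int)
        if assign.min() == assign.max():  # degenerate split: halve by rank
            order = np.argsort(X[:, self.split_feature], kind="stable")
            assign = np.zeros(len(X), dtype=int)
            assign[order[len(X) // 2:]] = 1
        return assign

    def _init_params(self, X, assign):
        k, d = self.n_components, X.shape[1]
        means = np.empty((k, d))
        variances = np.empty((k, d))
        weights = np.empty(k)
        for j in range(k):
            sub = X[assign == j]
            means[j] = sub.mean(axis=0)
            variances[j] = np.maximum(sub.var(axis=0), self.variance_floor)
            weights[j] = len(sub) / len(X)
        return means, variances, weights

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        if self.n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        n, d = X.shape
        rng = np.random.default_rng(self.random_state)
        last_err = None
        for attempt in range(self.n_retries + 1):
            split_q = 0.5 if attempt == 0 else rng.uniform(0.2, 0.8)
            try:
                self._fit_once(X, split_q)
                break
            except _ComponentCollapse as err:
                last_err = err
        else:
            raise RuntimeError(
                f"EM failed after {self.n_retries} restarts: {last_err}"
            )
        self.n_features_in_ = d
        p = 2 * self.n_components * d + (self.n_components - 1)
        self.bic_ = -2.0 * self.loglik_ + p * np.log(n)
        return self

    def _fit_once(self, X, split_q):
        assign = self._initial_partition(X, split_q)
        means, variances, weights = self._init_params(X, assign)
        path: list[float] = []
        prev = -np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            log_comp = self._log_components(X, means, variances, weights)
            log_norm = logsumexp(log_comp, axis=1)
            loglik = float(log_norm.sum())
            resp = np.exp(log_comp - log_norm[:, None])
            path.append(loglik)
            if np.isfinite(prev) and abs(loglik - prev) <= self.tol * abs(prev):
                converged = True
                break
            prev = loglik
            # M-step: responsibility-weighted refits
            nk = resp.sum(axis=0)
            if np.any(nk < 1e-8):
                raise _ComponentCollapse("a component lost all responsibility")
            weights = nk / len(X)
            means = (resp.T @ X) / nk[:, None]
            variances = np.empty_like(means)
            for j in range(len(nk)):
                variances[j] = (resp[:, j] @ (X - means[j]) ** 2) / nk[j]
            if np.any(variances < self.variance_floor / 10):
                raise _ComponentCollapse("component variance collapsed")
            variances = np.maximum(variances, self.variance_floor)
        self.means_, self.variances_, self.weights_ = means, variances, weights
        self.responsibilities_ = resp
        self.loglik_ = path[-1]
        self.loglik_path_ = path
        self.n_iter_ = len(path)
        self.converged_ = converged

    def score_samples(self, X):
        """Per-sample log density under the fitted mixture (Eq. of the model)."""
        check_is_fitted(self, "means_")
        X = check_array(X)
        return logsumexp(
            self._log_components(X, self.means_, self.variances_, self.weights_),
            axis=1,
        )

    def score(self, X, y=None):
        return float(np.mean(self.score_samples(X)))

    def predict_proba(self, X):
        """Posterior P(x in component k | x) — Bayes' rule over components."""
        check_is_fitted(self, "means_")
        X = check_array(X)
        log_comp = self._log_components(X, self.means_, self.variances_, self.weights_)
        return np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)

    def to_fit(self) -> MixtureFit:
        check_is_fitted(self, "means_")
        return MixtureFit(
            k=self.n_components,
            means=self.means_.copy(),
            variances=self.variances_.copy(),
            weights=self.weights_.copy(),
            responsibilities=self.responsibilities_.copy(),
            loglik=self.loglik_,
            bic=self.bic_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            loglik_path=list(self.loglik_path_),
        )


class _ComponentCollapse(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# damaged-cell detection


class DamagedCellDetector(BaseEstimator):
    """Flag damaged cells within one cell type via a 2-component mixture.

    ``fit`` expects ``X`` with columns ``(nuclear_fraction, umi_count)`` on
    the linear UMI scale; the mixture itself is fitted on
    ``(log10 UMI, NF)``.  Candidate selection and gating follow the damaged
    -cell phenotype: the flagged component must have **both** a higher mean
    NF and a lower mean UMI than the other, the NF means must differ by at
    least ``delta_nf``, and the candidate's mean UMI (geometric, i.e.
    ``10**mean(log10 UMI)``, by default) must be at most ``umi_ratio`` of
    the intact component's.  If BIC prefers a single component, or any gate
    fails, nothing is flagged.
    """

    def __init__(self, delta_nf=0.15, umi_ratio=0.5, min_droplets=100,
                 posterior_cutoff=0.5, umi_center="geometric",
                 em_tol=1e-6, em_max_iter=1000, variance_floor=1e-6,
                 random_state=0):
        self.delta_nf = delta_nf
        self.umi_ratio = umi_ratio
        self.min_droplets = min_droplets
        self.posterior_cutoff = posterior_cutoff
        self.umi_center = umi_center
        self.em_tol = em_tol
        self.em_max_iter = em_max_iter
        self.variance_floor = variance_floor
        self.random_state = random_state

    def _features(self, X):
        X = check_array(X)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: (nuclear_fraction, umi_count)")
        nf, umi = X[:, 0].astype(float), X[:, 1].astype(float)
        if np.any(umi <= 0):
            raise ValueError("umi_count must be positive (log10 undefined otherwise)")
        return np.column_stack([np.log10(umi), nf])

    def _umi_center(self, mean_log10_umi: float) -> float:
        if self.umi_center == "geometric":
            return 10.0 ** mean_log10_umi
        raise ValueError(f"unknown umi_center {self.umi_center!r}")

    def fit(self, X, y=None):
        feats = self._features(X)
        self.n_features_in_ = 2
        if len(feats) < self.min_droplets:
            logger.warning(
                "only %d droplets (< min_droplets=%d); skipping damaged-cell "
                "detection for this group", len(feats), self.min_droplets,
            )
            self.k_ = None
            self.mixtures_ = {}
            self.candidate_ = None
            self.gates_passed_ = False
            return self

        def _mix(k):
            return DiagonalGaussianMixture(
                n_components=k, tol=self.em_tol, max_iter=self.em_max_iter,
                variance_floor=self.variance_floor, split_feature=1,
                random_state=self.random_state,
            ).fit(feats)

        self.mixtures_ = {1: _mix(1), 2: _mix(2)}
        self.k_ = 2 if self.mixtures_[2].bic_ < self.mixtures_[1].bic_ else 1
        self.candidate_ = None
        self.gates_passed_ = False
        if self.k_ == 2:
            m = self.mixtures_[2]
            # NF is feature 1, log10 UMI is feature 0
            hi_nf = int(np.argmax(m.means_[:, 1]))
            lo_umi = int(np.argmin(m.means_[:, 0]))
            if hi_nf == lo_umi:  # damaged phenotype: high NF AND low UMI
                other = 1 - hi_nf
                dnf = m.means_[hi_nf, 1] - m.means_[other, 1]
                umi_cand = self._umi_center(m.means_[hi_nf, 0])
                umi_other = self._umi_center(m.means_[other, 0])
                if dnf >= self.delta_nf and umi_cand <= self.umi_ratio * umi_other:
                    self.candidate_ = hi_nf
                    self.gates_passed_ = True
        return self

    def predict(self, X):
        """Boolean mask: True where the droplet is called damaged."""
        check_is_fitted(self, "k_")
        feats = self._features(X)
        if self.k_ != 2 or not self.gates_passed_:
            return np.zeros(len(feats), dtype=bool)
        post = self.mixtures_[2].predict_proba(feats)[:, self.candidate_]
        return post > self.posterior_cutoff

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)


# ---------------------------------------------------------------------------
# functional wrappers over the estimators


def estimate_empty_threshold(nf_values, cfg: CallConfig | None = None) -> EmptyThreshold:
    """KDE + first-derivative valley detection on the NF distribution."""
    cfg = cfg or CallConfig()
    det = EmptyDropletDetector(
        bandwidth=cfg.bandwidth, grid_size=cfg.grid_size,
        prominence=cfg.prominence, min_samples=cfg.min_nf_values,
    ).fit(np.asarray(nf_values, dtype=float).reshape(-1, 1))
    return EmptyThreshold(
        grid=det.grid_, density=det.density_, bandwidth=det.bandwidth_,
        peak_position=det.peak_position_, valley_position=det.valley_position_,
        cutoff=det.cutoff_,
    )


def flag_empty(table: pd.DataFrame, thr: EmptyThreshold | None,
               cfg: CallConfig | None = None) -> pd.DataFrame:
    """Mark ``empty_droplet``/``cell`` status on rows with a defined NF.

    ``cfg.nf_rescue`` overrides the automatic cutoff; rows with
    ``umi_count > cfg.umi_rescue`` are always cells.  Rows with undefined NF
    keep ``unassigned``.
    """
    cfg = cfg or CallConfig()
    cutoff = cfg.nf_rescue if cfg.nf_rescue is not None else (thr.cutoff if thr else None)
    if cutoff is None:
        raise ValueError(
            "no empty-droplet cutoff available: automatic detection found no "
            "valley and nf_rescue is unset"
        )
    out = table.copy()
    defined = out["nuclear_fraction"].notna()
    empty = defined & (out["nuclear_fraction"] < cutoff)
    if cfg.umi_rescue is not None:
        empty &= ~(out["umi_count"] > cfg.umi_rescue)
    out.loc[defined, "qc_status"] = STATUS_CELL
    out.loc[empty, "qc_status"] = STATUS_EMPTY
    return out


def fit_mixture(X, k: int, cfg: CallConfig | None = None) -> MixtureFit:
    """Fit a k-component diagonal-Gaussian mixture on (log10 UMI, NF) pairs."""
    cfg = cfg or CallConfig()
    est = DiagonalGaussianMixture(
        n_components=k, tol=cfg.em_tol, max_iter=cfg.em_max_iter,
        variance_floor=cfg.variance_floor, split_feature=1,
        random_state=cfg.seed,
    ).fit(check_array(X))
    return est.to_fit()


def identify_damaged(table: pd.DataFrame, cell_type: str,
                     cfg: CallConfig | None = None) -> pd.DataFrame:
    """Flag damaged cells among status-``cell`` rows of one cell type."""
    cfg = cfg or CallConfig()
    out = table.copy()
    mask = (
        (out["qc_status"] == STATUS_CELL)
        & (out["cell_type"] == cell_type)
        & out["nuclear_fraction"].notna()
        & (out["umi_count"] > 0)
    )
    sub = out.loc[mask, ["nuclear_fraction", "umi_count"]].to_numpy(dtype=float)
    det = _damaged_detector(cfg).fit(sub)
    if det.k_ == 2 and det.gates_passed_:
        flags = det.predict(sub)
        out.loc[mask[mask].index[flags], "qc_status"] = STATUS_DAMAGED
    return out


def _damaged_detector(cfg: CallConfig) -> DamagedCellDetector:
    return DamagedCellDetector(
        delta_nf=cfg.delta_nf, umi_ratio=cfg.umi_ratio,
        min_droplets=cfg.min_droplets_per_type,
        posterior_cutoff=cfg.posterior_cutoff, umi_center=cfg.umi_center,
        em_tol=cfg.em_tol, em_max_iter=cfg.em_max_iter,
        variance_floor=cfg.variance_floor, random_state=cfg.seed,
    )


def call_all(table: pd.DataFrame, cfg: CallConfig | None = None):
    """Run the full calling pipeline: empty-droplet flags, then damaged
    cells per cell type.

    Statuses are reset first, so repeated calls are idempotent.  Rows are
    only ever flagged, never removed.  Returns ``(table, report)`` where the
    report records the threshold and, per cell type, the BIC-selected model
    and its parameters.
    """
    cfg = cfg or CallConfig()
    out = table.copy()
    out["qc_status"] = STATUS_UNASSIGNED
    defined = out["nuclear_fraction"].notna()
    nf = out.loc[defined, "nuclear_fraction"].to_numpy(dtype=float)

    thr = None
    if cfg.nf_rescue is None or len(nf) >= cfg.min_nf_values:
        thr = estimate_empty_threshold(nf, cfg)
    out = flag_empty(out, thr, cfg)
    report: dict = {
        "empty_threshold": {
            "cutoff": None if thr is None else thr.cutoff,
            "effective": cfg.nf_rescue if cfg.nf_rescue is not None else thr.cutoff,
            "peak_position": None if thr is None else thr.peak_position,
            "n_empty": int((out["qc_status"] == STATUS_EMPTY).sum()),
        },
        "cell_types": {},
    }

    if out["cell_type"].notna().any():
        for cell_type in sorted(out.loc[out["cell_type"].notna(), "cell_type"].unique()):
            mask = (
                (out["qc_status"] == STATUS_CELL)
                & (out["cell_type"] == cell_type)
                & out["nuclear_fraction"].notna()
                & (out["umi_count"] > 0)
            )
            sub = out.loc[mask, ["nuclear_fraction", "umi_count"]].to_numpy(dtype=float)
            det = _damaged_detector(cfg).fit(sub)
            entry = {"n": int(mask.sum()), "k": det.k_, "n_damaged": 0}
            if det.k_ is not None:
                entry["bic"] = {k: det.mixtures_[k].bic_ for k in det.mixtures_}
                if det.k_ == 2:
                    m = det.mixtures_[2]
                    entry["means"] = m.means_.tolist()
                    entry["variances"] = m.variances_.tolist()
                    entry["weights"] = m.weights_.tolist()
                    entry["gates_passed"] = det.gates_passed_
                if det.k_ == 2 and det.gates_passed_:
                    flags = det.predict(sub)
                    out.loc[mask[mask].index[flags], "qc_status"] = STATUS_DAMAGED
                    entry["n_damaged"] = int(flags.sum())
            report["cell_types"][str(cell_type)] = entry
    else:
        logger.warning("no cell_type labels provided; skipping damaged-cell calling")
    return out, report
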