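"""Non-negative matrix factorization of the effect matrix.

X (trait components x variants) is factorized as X ~ H W with H holding
trait loadings (rows x K) and W holding variant weights (K x variants), all
entries non-negative. The reference algorithm is Lee-Seung multiplicative
updates for the Frobenius loss, with best-of-restarts selection; the rank K
is chosen over a candidate range by mean silhouette width and Frobenius
error (cophenetic correlation and consensus dispersion are reported as
diagnostics); a Bayesian NMF with automatic relevance determination (ARD)
cross-validates the chosen rank by counting surviving components.

Estimators follow the scikit-learn protocol (``fit``, fitted attributes with
a trailing underscore, ``get_params``/``set_params``) so they compose with
sklearn model selection; the module-level functions ``factorize``,
``select_rank`` and ``bnmf_ard`` are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.metrics import silhouette_score
from sklearn.utils import check_array, check_random_state

logger = logging.getLogger(__name__)

_EPS = 1e-10


def multiplicative_update(
    H: np.ndarray, W: np.ndarray, X: np.ndarray, eps: float = _EPS
) -> tuple[np.ndarray, np.ndarray]:
    """One Lee-Seung step for the Frobenius loss ||X - HW||_F^2.

    H' = H * (X W^T) / (H W W^T + eps), then W' = W * (H'^T X) /
    (H'^T H' W + eps). The objective never increases; eps guards division.
    """
    Wt = W.T
    H = H * (X @ Wt) / (H @ (W @ Wt) + eps)
    Ht = H.T
    W = W * (Ht @ X) / ((Ht @ H) @ W + eps)
    return H, W


def _init_factors(
    X: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    # uniform random init scaled so E[HW] ~ mean(X)
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    H = rng.uniform(_EPS, 2 * scale, size=(X.shape[0], k))
    W = rng.uniform(_EPS, 2 * scale, size=(k, X.shape[1]))
    return H, W


@dataclass
class FactorizationResult:
    """Best-of-restarts factorization X ~ H W at a fixed rank."""

    H: np.ndarray
    W: np.ndarray
    K: int
    frobenius_error: float
    n_iter_run: int
    init_seed: int
    objective_trace: np.ndarray
    row_labels: list[str] | None = None
    variant_ids: list[str] | None = None

    def normalized(self) -> "FactorizationResult":
        """Resolve scale indeterminacy: unit-max columns of H, compensated W."""
        scale = self.H.max(axis=0)
        scale[scale == 0] = 1.0
        return FactorizationResult(
            H=self.H / scale,
            W=self.W * scale[:, None],
            K=self.K,
            frobenius_error=self.frobenius_error,
            n_iter_run=self.n_iter_run,
            init_seed=self.init_seed,
            objective_trace=self.objective_trace,
            row_labels=self.row_labels,
            variant_ids=self.variant_ids,
        )


class FrobeniusNMF(BaseEstimator):
    """Multiplicative-update NMF with restarts and patience-based stopping.

    Parameters
    ----------
    n_components : rank K of the factorization (number of clusters).
    n_init : random restarts; the lowest-error restart is kept.
    max_iter : iteration cap per restart.
    conv_window : a restart stops early once the relative objective change
        stays below ``tol`` for this many consecutive iterations.
    tol : relative-change convergence tolerance.
    random_state : seed; fits are deterministic under a fixed seed.

    Attributes
    ----------
    trait_loadings_ : H, (rows x K).
    variant_weights_ : W, (K x variants).
    reconstruction_err_ : final Frobenius error ||X - HW||_F.
    objective_trace_ : per-iteration error of the winning restart.
    n_iter_ : iterations used by the winning restart.
    """

    def __init__(
        self,
        n_components: int = 9,
        n_init: int = 30,
        max_iter: int = 10_000,
        conv_window: int = 80,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.n_init = n_init
        self.max_iter = max_iter
        self.conv_window = conv_window
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if (X < 0).any():
            raise ValueError("X must be non-negative")
        k = self.n_components
        if not 1 <= k <= min(X.shape):
            raise ValueError(f"n_components={k} outside [1, {min(X.shape)}]")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        seed = check_random_state(self.random_state).randint(0, 2**31 - 1)
        best = None
        for restart in range(self.n_init):
            rng = np.random.default_rng(seed + restart)
            H, W, trace = self._run_restart(X, k, rng)
            err = trace[-1]
            if best is None or err < best[2][-1]:
                best = (H, W, trace, restart)
        H, W, trace, restart = best
        self.trait_loadings_ = H
        self.variant_weights_ = W
        self.reconstruction_err_ = float(trace[-1])
        self.objective_trace_ = trace
        self.n_iter_ = len(trace)
        self.init_seed_ = seed + restart
        return self

    def _run_restart(self, X, k, rng):
        H, W = _init_factors(X, k, rng)
        trace = np.empty(self.max_iter)
        prev = np.linalg.norm(X - H @ W)
        patience = 0
        n = 0
        for it in range(self.max_iter):
            H, W = multiplicative_update(H, W, X)
            err = np.linalg.norm(X - H @ W)
            trace[it] = err
            n = it + 1
            rel = (prev - err) / prev if prev > 0 else 0.0
            patience = patience + 1 if abs(rel) < self.tol else 0
            if patience >= self.conv_window:
                break
            prev = err
        return H, W, trace[:n].copy()

    def transform(self, X):
        """Project new rows onto the fitted variant weights (H for new X)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "variant_weights_")
        X = check_array(X, dtype=float)
        W = self.variant_weights_
        rng = np.random.default_rng(self.init_seed_)
        H = rng.uniform(_EPS, 1.0, size=(X.shape[0], W.shape[0]))
        for _ in range(200):
            H = H * (X @ W.T) / (H @ (W @ W.T) + _EPS)
        return H

    def result_(self, row_labels=None, variant_ids=None) -> FactorizationResult:
        return FactorizationResult(
            H=self.trait_loadings_,
            W=self.variant_weights_,
            K=self.n_components,
            frobenius_error=self.reconstruction_err_,
            n_iter_run=self.n_iter_,
            init_seed=self.init_seed_,
            objective_trace=self.objective_trace_,
            row_labels=row_labels,
            variant_ids=variant_ids,
        )


def factorize(
    X,
    K: int,
    n_init: int = 30,
    max_iter: int = 10_000,
    conv_window: int = 80,
    tol: float = 1e-6,
    seed: int | None = None,
) -> FactorizationResult:
    """Factorize X at rank K; thin wrapper over :class:`FrobeniusNMF`."""
    row_labels = variant_ids = None
    if isinstance(X, pd.DataFrame):
        row_labels, variant_ids = list(X.index), list(X.columns)
        X = X.to_numpy(dtype=float)
    est = FrobeniusNMF(
        n_components=K,
        n_init=n_init,
        max_iter=max_iter,
        conv_window=conv_window,
        tol=tol,
        random_state=seed,
    ).fit(X)
    return est.result_(row_labels=row_labels, variant_ids=variant_ids)


def _variant_labels(W: np.ndarray) -> np.ndarray:
    return np.argmax(W, axis=0)


def _cosine_distance_matrix(W: np.ndarray) -> np.ndarray:
    cols = W.T
    norms = np.linalg.norm(cols, axis=1)
    norms[norms == 0] = 1.0
    unit = cols / norms[:, None]
    d = 1.0 - unit @ unit.T
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


class NMFRankSelector(BaseEstimator):
    """Choose the factorization rank over a candidate range.

    Per candidate K this runs ``n_restarts`` multiplicative-update fits and
    computes: mean silhouette width of the variants (assigned to clusters by
    argmax column of W, distance 1 - cosine similarity between W columns),
    best-of-restarts Frobenius error, and two consensus diagnostics
    (cophenetic correlation and dispersion of the restart consensus matrix).
    The chosen K is the Pareto-optimal candidate on (max silhouette, min
    error); with several Pareto points the highest silhouette wins, ties
    going to the smaller K.
    """

    def __init__(
        self,
        k_range=range(2, 21),
        n_restarts: int = 10,
        max_iter: int = 2_000,
        conv_window: int = 40,
        tol: float = 1e-5,
        random_state: int | None = None,
    ):
        self.k_range = k_range
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.conv_window = conv_window
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if (X < 0).any():
            raise ValueError("X must be non-negative")
        if not X.any():
            raise ValueError("X is identically zero; rank selection is undefined")
        ks = sorted(set(int(k) for k in self.k_range))
        if not ks:
            raise ValueError("empty K range")
        if ks[-1] > min(X.shape):
            raise ValueError(f"K range exceeds matrix dimensions {X.shape}")
        seed = check_random_state(self.random_state).randint(0, 2**31 - 1)
        rows = []
        self.results_ = {}
        for k in ks:
            errs, labelings = [], []
            best = None
            for r in range(self.n_restarts):
                est = FrobeniusNMF(
                    n_components=k,
                    n_init=1,
                    max_iter=self.max_iter,
                    conv_window=self.conv_window,
                    tol=self.tol,
                    random_state=seed + 7919 * k + r,
                ).fit(X)
                errs.append(est.reconstruction_err_)
                labelings.append(_variant_labels(est.variant_weights_))
                if best is None or est.reconstruction_err_ < best.reconstruction_err_:
                    best = est
            self.results_[k] = best
            sil = self._silhouette(best.variant_weights_)
            coph, disp = _consensus_stats(labelings)
            rows.append(
                {
                    "K": k,
                    "silhouette": sil,
                    "frobenius_error": min(errs),
                    "cophenetic": coph,
                    "dispersion": disp,
                }
            )
        self.report_ = pd.DataFrame(rows)
        self.chosen_k_, self.rule_trace_ = _pareto_choice(self.report_)
        return self

    @staticmethod
    def _silhouette(W: np.ndarray) -> float:
        labels = _variant_labels(W)
        if len(np.unique(labels)) < 2:
            return -1.0
        d = _cosine_distance_matrix(W)
        return float(silhouette_score(d, labels, metric="precomputed"))


def _consensus_stats(labelings: list[np.ndarray]) -> tuple[float, float]:
    """Cophenetic correlation and dispersion of the restart consensus matrix."""
    n = labelings[0].shape[0]
    consensus = np.zeros((n, n))
    for lab in labelings:
        consensus += (lab[:, None] == lab[None, :]).astype(float)
    consensus /= len(labelings)
    dispersion = float(np.mean(4.0 * (consensus - 0.5) ** 2))
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, condensed[0]):
        return 1.0, dispersion  # degenerate: all restarts identical partition
    z = linkage(condensed, method="average")
    coph, _ = cophenet(z, condensed)
    return float(coph), dispersion


def _pareto_choice(report: pd.DataFrame, sil_tol: float = 0.01) -> tuple[int, list[str]]:
    """Pick K by highest silhouette and lowest error.

    Silhouette plateaus once clusters are merely being merged or split, so
    candidates within ``sil_tol`` of the best silhouette count as tied; the
    tie is broken by the sharpest relative drop in reconstruction error from
    the previous K (the error elbow), remaining ties by the smaller K.
    """
    trace = []
    sil = report["silhouette"].to_numpy()
    err = report["frobenius_error"].to_numpy()
    ks = report["K"].to_numpy()
    pareto = []
    for i in range(len(ks)):
        dominated = np.any(
            (sil >= sil[i]) & (err <= err[i]) & ((sil > sil[i]) | (err < err[i]))
        )
        if not dominated:
            pareto.append(i)
    trace.append(f"Pareto-optimal K on (silhouette, error): {[int(ks[i]) for i in pareto]}")
    best_sil = max(sil[i] for i in pareto)
    tied = [i for i in pareto if sil[i] >= best_sil - sil_tol]
    trace.append(
        f"silhouette within {sil_tol} of best ({best_sil:.4f}): K={[int(ks[i]) for i in tied]}"
    )
    # relative error improvement over the previous evaluated K; the smallest
    # K in range gets the maximal gain (nothing to improve on)
    gains = np.ones(len(ks))
    for i in range(1, len(ks)):
        gains[i] = (err[i - 1] - err[i]) / err[i - 1] if err[i - 1] > 0 else 0.0
    best_gain = max(gains[i] for i in tied)
    final = [i for i in tied if gains[i] == best_gain]
    choice = int(min(ks[i] for i in final))
    trace.append(
        f"sharpest error drop {best_gain:.3f} at K={[int(ks[i]) for i in final]}; "
        f"chosen K = {choice}"
    )
    return choice, trace


def select_rank(
    X,
    k_range=range(2, 21),
    restarts: int = 10,
    seed: int | None = None,
    max_iter: int = 2_000,
) -> tuple[int, pd.DataFrame, list[str]]:
    """Rank selection wrapper; returns (chosen K, metrics table, rule trace)."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    sel = NMFRankSelector(
        k_range=k_range, n_restarts=restarts, random_state=seed, max_iter=max_iter
    ).fit(X)
    return sel.chosen_k_, sel.report_, sel.rule_trace_


class ARDNMF(BaseEstimator):
    """Bayesian NMF with automatic relevance determination.

    Gaussian likelihood with half-normal priors on the columns of H and rows
    of W; each component k has a shared relevance scale lambda_k updated in
    closed form (inverse-gamma hyperprior a, b). MAP multiplicative updates
    shrink irrelevant components toward zero; a component is pruned when the
    maximum element of its rank-1 contribution falls below
    ``prune_tol * max(X)``. Run many times from random starts, the most
    frequent surviving component count estimates the rank.

    Attributes
    ----------
    n_components_ : modal surviving component count across runs.
    runs_ : one row per run (surviving K, final objective, iterations).
    """

    def __init__(
        self,
        k_max: int = 20,
        n_runs: int = 1_000,
        max_iter: int = 200_000,
        tol: float = 1e-8,
        prune_tol: float = 1e-8,
        a: float = 2.0,
        b: float = 1e-2,
        noise_floor: float = 3e-2,
        burn_in: int = 100,
        random_state: int | None = None,
    ):
        self.k_max = k_max
        self.n_runs = n_runs
        self.max_iter = max_iter
        self.tol = tol
        self.prune_tol = prune_tol
        self.a = a
        self.b = b
        self.noise_floor = noise_floor
        self.burn_in = burn_in
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        if (X < 0).any():
            raise ValueError("X must be non-negative")
        seed = check_random_state(self.random_state).randint(0, 2**31 - 1)
        rows = []
        best = None
        for run in range(self.n_runs):
            H, W, obj, iters = self._run_once(X, np.random.default_rng(seed + run))
            k_surv = H.shape[1]
            rows.append({"run": run, "K": k_surv, "objective": obj, "n_iter": iters})
            if best is None or obj < best[2]:
                best = (H, W, obj)
        self.runs_ = pd.DataFrame(rows)
        counts = self.runs_["K"].value_counts()
        top = counts.max()
        self.n_components_ = int(min(counts[counts == top].index))
        self.trait_loadings_, self.variant_weights_, _ = best
        return self

    def _run_once(self, X, rng):
        n, m = X.shape
        k = min(self.k_max, min(n, m))
        H, W = _init_factors(X, k, rng)
        x_max = X.max() if X.max() > 0 else 1.0
        prune_level = self.prune_tol * x_max
        # noise power never drops below a fraction of the signal power: keeps
        # the ARD pull alive on (near-)noiseless inputs, where the estimated
        # residual variance would otherwise collapse and freeze redundant
        # degenerate components
        sigma2_floor = max(self.noise_floor * float(np.mean(X**2)), _EPS)
        shape = self.a + (n + m) / 2.0 + 1.0
        prev_obj = np.inf
        it = 0
        for it in range(1, self.max_iter + 1):
            if it <= self.burn_in:
                # plain multiplicative updates first, so shrinkage acts on
                # factors that already fit the data
                H, W = multiplicative_update(H, W, X)
                continue
            lam = (0.5 * ((H**2).sum(axis=0) + (W**2).sum(axis=1)) + self.b) / shape
            resid = X - H @ W
            sigma2 = max(float(np.mean(resid**2)), sigma2_floor)
            inv_lam = sigma2 / lam
            H = H * (X @ W.T) / (H @ (W @ W.T) + H * inv_lam[None, :] + _EPS)
            W = W * (H.T @ X) / ((H.T @ H) @ W + W * inv_lam[:, None] + _EPS)
            # drop components whose rank-1 contribution is numerically zero
            contrib = H.max(axis=0) * W.max(axis=1)
            alive = contrib > prune_level
            if not alive.all():
                if not alive.any():
                    alive[np.argmax(contrib)] = True
                H, W = H[:, alive], W[alive, :]
            if it % 20 == 0:
                # convergence on the MAP objective: the data term alone is
                # flat across degenerate component splits that ARD is still
                # merging
                lam = (0.5 * ((H**2).sum(axis=0) + (W**2).sum(axis=1)) + self.b) / shape
                obj = float(
                    np.linalg.norm(X - H @ W) ** 2 / (2 * sigma2)
                    + shape * np.sum(np.log(lam))
                )
                if abs(prev_obj - obj) < self.tol * max(abs(prev_obj), _EPS) and it > self.burn_in + 100:
                    break
                prev_obj = obj
        obj = float(np.linalg.norm(X - H @ W) ** 2)
        contrib = H.max(axis=0) * W.max(axis=1)
        alive = contrib > prune_level
        if alive.any():
            H, W = H[:, alive], W[alive, :]
        return H, W, obj, it


def bnmf_ard(
    X,
    K_max: int = 20,
    runs: int = 1_000,
    max_iter: int = 200_000,
    seed: int | None = None,
    tol: float = 1e-7,
) -> tuple[int, pd.DataFrame]:
    """ARD Bayesian NMF wrapper; returns (modal surviving K, run table)."""
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    est = ARDNMF(k_max=K_max, n_runs=runs, max_iter=max_iter, random_state=seed, tol=tol).fit(X)
    return est.n_components_, est.runs_


@dataclass
class ClusterSummary:
    """Per-cluster top-decile traits and variants with effect directions."""

    clusters: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            for t in c["top_traits"]:
                rows.append(
                    {
                        "cluster": c["cluster"],
                        "trait": t["trait"],
                        "direction": t["direction"],
                        "activity": t["loading"],
                    }
                )
        return pd.DataFrame(rows, columns=["cluster", "trait", "direction", "activity"])

    def weight_summary(self, zero_floor: float = 1e-40) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster": c["cluster"],
                    "n_snps": c["n_variants_nonzero"],
                    "q90_weight": c["q90_weight"],
                }
                for c in self.clusters
            ]
        )


def summarize_clusters(
    result: FactorizationResult,
    sign_registry: dict[str, str] | None = None,
    top_n_traits: int = 7,
    zero_floor: float = 1e-40,
) -> ClusterSummary:
    """Top-decile traits and variants per cluster with directions.

    The 90th-percentile threshold (linear-interpolation percentile) is taken
    per cluster over all variant weights and over all trait-component
    loadings; boundary ties are included. Sign-split trait components are
    collapsed to one entry per trait whose direction is the sign of the
    larger component loading. Variants with weight below ``zero_floor``
    count as zero-weight.
    """
    H, W, K = result.H, result.W, result.K
    row_labels = result.row_labels or [f"row_{i}" for i in range(H.shape[0])]
    variant_ids = result.variant_ids or [f"v_{j}" for j in range(W.shape[1])]
    sign_registry = sign_registry or {}
    clusters = []
    for k in range(K):
        w_k, h_k = W[k], H[:, k]
        if not w_k.any() and not h_k.any():
            logger.warning("cluster %d is all-zero; empty summary", k)
            clusters.append(
                {
                    "cluster": k,
                    "top_traits": [],
                    "top_variants": [],
                    "q90_weight": 0.0,
                    "n_variants_nonzero": 0,
                }
            )
            continue
        q90_w = float(np.percentile(w_k, 90))
        top_var = [
            {"variant_id": variant_ids[j], "weight": float(w_k[j])}
            for j in np.argsort(-w_k)
            if w_k[j] >= q90_w
        ]
        # collapse trait +/- components: direction = sign of larger loading
        per_trait: dict[str, dict] = {}
        for i, label in enumerate(row_labels):
            trait = label.rsplit("|", 1)[0] if "|" in label else label
            direction = sign_registry.get(label, "+")
            cur = per_trait.get(trait)
            if cur is None or h_k[i] > cur["loading"]:
                per_trait[trait] = {"trait": trait, "direction": direction, "loading": float(h_k[i])}
        q90_h = float(np.percentile(h_k, 90))
        ranked = sorted(per_trait.values(), key=lambda d: -d["loading"])
        top_traits = [t for t in ranked if t["loading"] >= q90_h][:top_n_traits]
        clusters.append(
            {
                "cluster": k,
                "top_traits": top_traits,
                "top_variants": top_var,
                "q90_weight": q90_w,
                "n_variants_nonzero": int((w_k > zero_floor).sum()),
            }
        )
    return ClusterSummary(clusters=clusters)
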