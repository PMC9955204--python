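"""Markov state model estimation, validation and coarse-graining.

The workflow mirrors standard MSM practice on molecular trajectories:
frames discretized into microstates (k-means in tICA space), sliding-window
transition counts at a lag time, a reversible maximum-likelihood transition
matrix on the largest connected set, implied timescales
``t_i = −τ/ln|λ_{i+1}|`` checked for lag-convergence, a Bayesian
(Dirichlet) transition-matrix ensemble for uncertainty bands, the
Chapman–Kolmogorov test for Markovianity, PCCA++ coarse-graining into
metastable macrostates, mean first-passage times between macrostates, and
the stationary-weight-reweighted free-energy surface.

The reversible estimator is the default because PCCA++ requires a real
spectrum; the Bayesian sampler is the conjugate non-reversible Dirichlet
posterior (exact, simple), a documented deviation from reversible samplers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse.csgraph

__all__ = [
    "Discretization",
    "CountMatrix",
    "MarkovModel",
    "BayesianEnsemble",
    "CoarseGraining",
    "FESGrid",
    "kmeans",
    "count_matrix",
    "estimate_msm",
    "implied_timescales",
    "ck_test",
    "bayesian_sample",
    "pcca",
    "mfpt",
    "macrostate_transition_times",
    "frame_weights",
    "free_energy_surface",
]

logger = logging.getLogger(__name__)


@dataclass
class Discretization:
    centers: np.ndarray          # (k, d)
    assignments: np.ndarray      # per-frame center index
    k: int
    seed: int
    inertia: float


@dataclass
class CountMatrix:
    counts: np.ndarray
    lag: int
    mode: str = "sliding"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class MarkovModel:
    transition_matrix: np.ndarray
    lag: int
    stationary: np.ndarray
    eigenvalues: np.ndarray
    active_set: np.ndarray       # original state indices of the connected set
    frame_stride_ns: float = 1.0
    reversible: bool = True

    def __post_init__(self) -> None:
        t = self.transition_matrix
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix rows must sum to 1 within 1e-10")
        pi = self.stationary
        if np.any(pi < -1e-12) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("stationary distribution must be a probability vector")
        if np.max(np.abs(pi @ t - pi)) > 1e-8:
            raise ValueError("stationary distribution must satisfy πT = π within 1e-8")
        if self.reversible:
            flux = pi[:, None] * t
            if np.max(np.abs(flux - flux.T)) > 1e-8:
                raise ValueError("detailed balance violated beyond 1e-8")

    @property
    def lag_ns(self) -> float:
        return self.lag * self.frame_stride_ns

    def timescales(self, n: int | None = None) -> np.ndarray:
        """Implied timescales in ns; +inf where |λ| ≥ 1, NaN where λ ≤ 0 is
        too fast to resolve (|λ| ~ 0)."""
        lam = self.eigenvalues[1:]
        if n is not None:
            lam = lam[:n]
        out = np.empty(lam.shape)
        for i, lv in enumerate(np.abs(lam)):
            if lv >= 1.0:
                out[i] = np.inf
            elif lv <= 0.0:
                out[i] = np.nan
            else:
                out[i] = -self.lag_ns / np.log(lv)
        return out


@dataclass
class BayesianEnsemble:
    samples: list[np.ndarray]
    lag: int
    active_set: np.ndarray
    frame_stride_ns: float = 1.0

    def timescale_ci(self, n_its: int = 3, level: float = 0.95) -> np.ndarray:
        """(n_its, 2) lower/upper CI bounds on the implied timescales (ns)."""
        vals = []
        for t in self.samples:
            lam = np.sort(np.abs(np.linalg.eigvals(t)))[::-1][1 : n_its + 1]
            with np.errstate(divide="ignore"):
                ts = -self.lag * self.frame_stride_ns / np.log(np.clip(lam, 1e-15, 1 - 1e-15))
            vals.append(ts)
        vals = np.asarray(vals)
        alpha = (1.0 - level) / 2.0
        return np.stack([
            np.quantile(vals, alpha, axis=0),
            np.quantile(vals, 1.0 - alpha, axis=0),
        ], axis=1)


@dataclass
class CoarseGraining:
    memberships: np.ndarray      # (k, m), rows sum to 1
    assignments: np.ndarray      # crisp argmax per microstate
    m: int

    def __post_init__(self) -> None:
        chi = self.memberships
        if np.any(chi < -1e-10) or np.any(chi > 1 + 1e-10):
            raise ValueError("memberships must lie in [0, 1]")
        if not np.allclose(chi.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("membership rows must sum to 1 within 1e-10")


@dataclass
class FESGrid:
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray      # kT; NaN marks empty bins

    @property
    def minimum(self) -> float:
        return float(np.nanmin(self.free_energy))


# ---------------------------------------------------------------------------
# Discretization


def kmeans(
    points: np.ndarray,
    k: int = 100,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> Discretization:
    """K-means (k-means++ seeding, Lloyd iterations), deterministic by seed."""
    from sklearn.cluster import KMeans

    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    if k > points.shape[0]:
        raise ValueError(f"k={k} exceeds the number of points ({points.shape[0]})")
    km = KMeans(n_clusters=k, n_init=1, init="k-means++", random_state=seed,
                max_iter=max_iter, tol=tol)
    labels = km.fit_predict(points)
    return Discretization(
        centers=km.cluster_centers_,
        assignments=labels.astype(int),
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


def count_matrix(assignments, lag: int, n_states: int | None = None) -> CountMatrix:
    """Sliding-window transition counts at integer ``lag``.

    ``assignments`` may be a single state sequence or a list of sequences
    (counts never cross trajectory boundaries).
    """
    if lag < 1:
        raise ValueError("lag must be ≥ 1")
    seqs = assignments
    if np.ndim(seqs[0]) == 0:
        seqs = [assignments]
    seqs = [np.asarray(s, dtype=int) for s in seqs]
    if n_states is None:
        n_states = max(int(s.max()) for s in seqs) + 1
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    any_pairs = False
    for s in seqs:
        if len(s) <= lag:
            continue
        any_pairs = True
        np.add.at(counts, (s[:-lag], s[lag:]), 1)
    if not any_pairs:
        warnings.warn("lag ≥ trajectory length: count matrix is all zero", stacklevel=2)
    return CountMatrix(counts=counts, lag=lag)


# ---------------------------------------------------------------------------
# Estimation


def _largest_connected_set(counts: np.ndarray) -> np.ndarray:
    """Indices of the largest strongly connected component of the count graph."""
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        counts > 0, directed=True, connection="strong"
    )
    sizes = np.bincount(labels, minlength=n_comp)
    # among equally sized components prefer the one with more counts
    best = None
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        key = (sizes[c], counts[np.ix_(idx, idx)].sum())
        if best is None or key > best[0]:
            best = (key, idx)
    return best[1]


def estimate_msm(
    counts: CountMatrix,
    reversible: bool = True,
    frame_stride_ns: float = 1.0,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> MarkovModel:
    """Maximum-likelihood transition matrix on the largest connected set.

    The reversible estimator uses the standard self-consistent fixed-point
    iteration on the symmetrized flux matrix; the non-reversible variant is
    simple row normalization.  Disconnected states are dropped with a log
    entry; their indices are recoverable through ``active_set``.
    """
    c = np.asarray(counts.counts, dtype=float)
    active = _largest_connected_set(c)
    if active.size == 0 or c[np.ix_(active, active)].sum() == 0:
        raise ValueError("count matrix has no connected set with transitions")
    if active.size < c.shape[0]:
        logger.info("dropping %d disconnected states", c.shape[0] - active.size)
    c = c[np.ix_(active, active)]
    n = c.shape[0]
    if not reversible:
        t = c / c.sum(axis=1, keepdims=True)
        pi = _stationary_distribution(t)
        eigvals = np.sort(np.linalg.eigvals(t).real)[::-1]
        return MarkovModel(t, counts.lag, pi, eigvals, active,
                           frame_stride_ns, reversible=False)
    # reversible MLE: iterate x_ij = (c_ij + c_ji) / (c_i/x_i + c_j/x_j)
    c_sym = c + c.T
    c_row = c.sum(axis=1)
    x = c_sym / c_sym.sum()
    prev_ll = -np.inf
    for _ in range(max_iter):
        x_row = x.sum(axis=1)
        denom = (c_row / x_row)[:, None] + (c_row / x_row)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_new = np.where(c_sym > 0, c_sym / denom, 0.0)
        x_new /= x_new.sum()
        x = x_new
        t = x / x.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            ll = float(np.sum(c[c > 0] * np.log(t[c > 0])))
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    x_row = x.sum(axis=1)
    t = x / x_row[:, None]
    pi = x_row / x_row.sum()
    # symmetric similarity transform gives a numerically real spectrum
    sqrt_pi = np.sqrt(pi)
    sym = (sqrt_pi[:, None] * t) / sqrt_pi[None, :]
    eigvals = np.sort(scipy.linalg.eigvalsh(0.5 * (sym + sym.T)))[::-1]
    # clean round-off so the model invariants hold exactly enough
    t = t / t.sum(axis=1, keepdims=True)
    pi = _stationary_distribution(t)
    return MarkovModel(t, counts.lag, pi, eigvals, active, frame_stride_ns,
                       reversible=True)


def _stationary_distribution(t: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(t.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.abs(v[:, i].real)
    return pi / pi.sum()


def implied_timescales(
    assignments,
    lags,
    n_its: int = 3,
    frame_stride_ns: float = 1.0,
    n_bayes_samples: int = 0,
    seed: int = 0,
):
    """Implied timescales (ns) per lag, optionally with Bayesian 95% CIs.

    Returns a list of dicts ``{lag, lag_ns, timescales, ci}``; ``ci`` is
    None unless ``n_bayes_samples > 0``.  Timescales that are undefined at
    a lag (non-positive eigenvalue) come out as NaN, never fabricated.
    """
    out = []
    for lag in lags:
        cm = count_matrix(assignments, lag)
        model = estimate_msm(cm, frame_stride_ns=frame_stride_ns)
        ts = model.timescales(n_its)
        ci = None
        if n_bayes_samples > 0:
            ens = bayesian_sample(cm, n_samples=n_bayes_samples, seed=seed,
                                  frame_stride_ns=frame_stride_ns)
            ci = ens.timescale_ci(n_its)
        out.append({"lag": int(lag), "lag_ns": lag * frame_stride_ns,
                    "timescales": ts, "ci": ci})
    return out


# ---------------------------------------------------------------------------
# Bayesian ensemble


def bayesian_sample(
    counts: CountMatrix,
    n_samples: int = 100,
    seed: int = 0,
    frame_stride_ns: float = 1.0,
    prior: float = 0.0,
) -> BayesianEnsemble:
    """Dirichlet-conjugate posterior sampling of the transition matrix.

    Each row of T is sampled independently from a Dirichlet over the
    observed transitions of that row (concentration counts + prior),
    restricted to the largest connected set.  Unobserved transitions stay
    zero so sparse count matrices are not swamped by pseudo-counts
    (non-reversible sampler).
    """
    c = np.asarray(counts.counts, dtype=float)
    active = _largest_connected_set(c)
    c = c[np.ix_(active, active)]
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n_samples):
        t = np.zeros_like(c)
        for i, row in enumerate(c):
            obs = np.flatnonzero(row > 0)
            t[i, obs] = rng.dirichlet(row[obs] + prior)
        samples.append(t)
    return BayesianEnsemble(samples=samples, lag=counts.lag, active_set=active,
                            frame_stride_ns=frame_stride_ns)


# ---------------------------------------------------------------------------
# Chapman–Kolmogorov test


def _set_occupation_curve(t: np.ndarray, pi: np.ndarray, sets: list[np.ndarray],
                          power: int) -> np.ndarray:
    """P(in set A at k·τ | started π-distributed in A), for every set A."""
    tk = np.linalg.matrix_power(t, power)
    out = np.empty(len(sets))
    for a, idx in enumerate(sets):
        w = np.zeros(t.shape[0])
        w[idx] = pi[idx]
        w /= w.sum()
        out[a] = (w @ tk)[idx].sum()
    return out


def ck_test(
    model: MarkovModel,
    ensemble: BayesianEnsemble,
    assignments,
    grouping: CoarseGraining,
    factors=(2, 3, 4, 5),
    level: float = 0.95,
    min_fraction: float = 0.95,
):
    """Chapman–Kolmogorov test on macrostate occupation curves.

    For each factor k, compares the model propagated k steps
    (``T(τ)^k``) against a model re-estimated at lag kτ, per macrostate.
    The Bayesian ensemble supplies a ``level`` credible band around the
    prediction; the test passes when at least ``min_fraction`` of the
    (factor × macrostate) points fall inside their band.

    Returns a dict with per-factor predicted/estimated curves, the bands,
    and the boolean ``passed``.
    """
    sets = [np.flatnonzero(grouping.assignments == a) for a in range(grouping.m)]
    sets = [s for s in sets if s.size > 0]
    seqs = assignments if np.ndim(assignments[0]) else [assignments]
    max_len = max(len(np.asarray(s)) for s in seqs)
    results = {"factors": [], "predicted": [], "estimated": [], "band": []}
    n_inside = 0
    n_total = 0
    alpha = (1.0 - level) / 2.0
    for k in factors:
        if k * model.lag >= max_len:
            logger.info("CK factor %d skipped: insufficient data at lag %d",
                        k, k * model.lag)
            continue
        predicted = _set_occupation_curve(model.transition_matrix,
                                          model.stationary, sets, k)
        try:
            cm_k = count_matrix(assignments, k * model.lag,
                                n_states=int(np.max([np.max(s) for s in seqs])) + 1)
            model_k = estimate_msm(cm_k, frame_stride_ns=model.frame_stride_ns)
        except ValueError:
            logger.info("CK factor %d skipped: no connected model at lag %d",
                        k, k * model.lag)
            continue
        # map the re-estimated model back onto the reference active set
        full_to_k = {s: i for i, s in enumerate(model_k.active_set)}
        est = np.full(len(sets), np.nan)
        t_k, pi_k = model_k.transition_matrix, model_k.stationary
        for a, idx in enumerate(sets):
            orig = model.active_set[idx]
            kidx = np.array([full_to_k[s] for s in orig if s in full_to_k], dtype=int)
            if kidx.size == 0:
                continue
            w = np.zeros(t_k.shape[0])
            w[kidx] = pi_k[kidx]
            w /= w.sum()
            est[a] = (w @ t_k)[kidx].sum()
        band_samples = np.array([
            _set_occupation_curve(s, _stationary_distribution(s), sets, k)
            for s in ensemble.samples
        ])
        lo = np.quantile(band_samples, alpha, axis=0)
        hi = np.quantile(band_samples, 1.0 - alpha, axis=0)
        for a in range(len(sets)):
            if np.isnan(est[a]):
                continue
            n_total += 1
            if lo[a] - 1e-12 <= est[a] <= hi[a] + 1e-12:
                n_inside += 1
        results["factors"].append(k)
        results["predicted"].append(predicted)
        results["estimated"].append(est)
        results["band"].append((lo, hi))
    results["fraction_inside"] = n_inside / n_total if n_total else np.nan
    results["passed"] = bool(n_total and n_inside / n_total >= min_fraction)
    return results


# ---------------------------------------------------------------------------
# PCCA++


def pcca(model: MarkovModel, m: int = 4) -> CoarseGraining:
    """PCCA++ coarse-graining into ``m`` metastable macrostates.

    Runs the inner-simplex vertex search on the top-m right eigenvectors
    (π-weighted), producing fuzzy memberships χ that are clipped to the
    probability simplex; the crisp assignment is the row argmax.
    """
    if not model.reversible:
        raise ValueError("PCCA++ requires a reversible model (real spectrum); "
                         "estimate with reversible=True")
    t = model.transition_matrix
    n = t.shape[0]
    if m > n:
        raise ValueError(f"m={m} exceeds the number of microstates ({n})")
    if m == 1:
        chi = np.ones((n, 1))
        return CoarseGraining(memberships=chi, assignments=np.zeros(n, dtype=int), m=1)
    pi = model.stationary
    sqrt_pi = np.sqrt(pi)
    sym = (sqrt_pi[:, None] * t) / sqrt_pi[None, :]
    w, v = scipy.linalg.eigh(0.5 * (sym + sym.T))
    order = np.argsort(w)[::-1]
    v = v[:, order[:m]]
    # right eigenvectors of T, normalized so the first is constant 1
    x = v / sqrt_pi[:, None]
    x /= x[0, 0] if abs(x[0, 0]) > 1e-12 else 1.0
    x[:, 0] = 1.0
    # inner simplex algorithm: pick the m states spanning the largest simplex
    y = x.copy()
    vertices = [int(np.argmax(np.linalg.norm(y, axis=1)))]
    y = y - y[vertices[0]]
    for j in range(1, m):
        direction = y[vertices[j - 1]] if j > 1 else None
        if j > 1:
            direction = direction / np.linalg.norm(direction)
            y = y - np.outer(y @ direction, direction)
        norms = np.linalg.norm(y, axis=1)
        norms[vertices] = -1.0
        vertices.append(int(np.argmax(norms)))
    chi = x @ np.linalg.solve(x[vertices], np.eye(m))
    # feasibility: clip tiny negatives from the linear map, renormalize
    chi = np.clip(chi, 0.0, None)
    rows = chi.sum(axis=1)
    rows[rows == 0] = 1.0
    chi = chi / rows[:, None]
    return CoarseGraining(memberships=chi, assignments=np.argmax(chi, axis=1), m=m)


# ---------------------------------------------------------------------------
# Macrostate kinetics


def mfpt(model: MarkovModel, target: np.ndarray, source: np.ndarray | None = None) -> float:
    """Mean first-passage time (ns) into ``target`` by first-step analysis.

    Solves h = 1 + T h with h = 0 on the target; the source average is
    π-weighted over ``source`` (restricted and renormalized).  Returns 0
    when the source lies inside the target, +inf when unreachable.
    """
    t = model.transition_matrix
    n = t.shape[0]
    target = np.asarray(target, dtype=int)
    if source is None:
        source = np.setdiff1d(np.arange(n), target)
    source = np.asarray(source, dtype=int)
    if np.all(np.isin(source, target)):
        return 0.0
    free = np.setdiff1d(np.arange(n), target)
    a = np.eye(free.size) - t[np.ix_(free, free)]
    try:
        h_free = np.linalg.solve(a, np.ones(free.size))
    except np.linalg.LinAlgError:
        return float("inf")
    if np.any(h_free < -1e-9):
        return float("inf")
    h = np.zeros(n)
    h[free] = h_free
    w = model.stationary[source]
    if w.sum() == 0:
        w = np.ones(source.size)
    w = w / w.sum()
    steps = float(w @ h[source])
    return steps * model.lag_ns


def macrostate_transition_times(
    model: MarkovModel,
    grouping: CoarseGraining,
) -> tuple[np.ndarray, np.ndarray]:
    """Directed m × m MFPT table (ns) and net transition rates (1/ns).

    Entry (a, b) is the mean first-passage time from macrostate a to
    macrostate b; diagonal entries are 0.  Rates are 1/MFPT (0 where the
    MFPT is infinite).
    """
    m = grouping.m
    times = np.zeros((m, m))
    for a in range(m):
        src = np.flatnonzero(grouping.assignments == a)
        for b in range(m):
            if a == b:
                continue
            tgt = np.flatnonzero(grouping.assignments == b)
            if src.size == 0 or tgt.size == 0:
                times[a, b] = np.inf
                continue
            times[a, b] = mfpt(model, tgt, src)
    with np.errstate(divide="ignore"):
        rates = np.where(np.isfinite(times) & (times > 0), 1.0 / times, 0.0)
    return times, rates


# ---------------------------------------------------------------------------
# Free-energy surface


def frame_weights(assignments: np.ndarray, model: MarkovModel) -> np.ndarray:
    """Stationary weight per frame: π(microstate)/count(frames in microstate).

    Frames in microstates outside the active set get weight 0.
    """
    assignments = np.asarray(assignments, dtype=int)
    weights = np.zeros(assignments.shape[0])
    for i, state in enumerate(model.active_set):
        mask = assignments == state
        n = int(mask.sum())
        if n:
            weights[mask] = model.stationary[i] / n
    s = weights.sum()
    if s > 0:
        weights /= s
    return weights


def free_energy_surface(
    projection: np.ndarray,
    weights: np.ndarray,
    bins: int | tuple = 50,
    temperature_kT: float = 1.0,
) -> FESGrid:
    """Reweighted 2-D free-energy surface: F(bin) = −kT ln Σ weights, min 0.

    Empty bins are NaN (flagged, never zero).
    """
    projection = np.asarray(projection, dtype=float)
    if projection.size == 0:
        raise ValueError("empty projection")
    if projection.ndim != 2 or projection.shape[1] < 2:
        raise ValueError("projection must be (frames, ≥2); the first two "
                         "components are binned")
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be ≥ 0")
    hist, x_edges, y_edges = np.histogram2d(
        projection[:, 0], projection[:, 1], bins=bins, weights=weights
    )
    logh = np.full_like(hist, np.nan)
    np.log(hist, out=logh, where=hist > 0)
    f = -temperature_kT * logh
    f = f - np.nanmin(f)
    return FESGrid(x_edges=x_edges, y_edges=y_edges, free_energy=f)
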