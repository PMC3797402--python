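"""Joint independent component analysis with a shared mixing matrix.

The generative model: n sections of paired observations share one n x n
mixing matrix A,

    X_fnirs = A · S_fnirs        (n x T temporal block)
    X_fmri  = A · S_fmri         (n x V spatial block)

equivalently, stacking the two feature blocks row-wise,

    [X_fnirs | X_fmri] = A · [S_fnirs | S_fmri].

Because the two blocks share A, unmixing the stacked matrix yields
*paired* components: each independent source has a temporal signature
(when the hemodynamic signal changes) and a spatial map (where).

Estimation is infomax ICA: gradient ascent on the entropy of
g(W·x) with the logistic nonlinearity g(x) = 1/(1+e^-x), implemented
as the natural-gradient update

    ΔW = η · (I + (1 − 2 g(u)) uᵀ / m) · W,    u = W·X,

averaged over the m stacked feature columns, with PCA whitening as a
preconditioner and an annealed learning rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import gamma as gamma_dist

from .io import StimulusParadigm, VolumeGrid
from .preprocess import SectionTrace, SpatialMapSet


# ---------------------------------------------------------------------------
# joint dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointDataset:
    """The stacked n x (T+V) joint data matrix.

    Row i = [fNIRS trace of section i | fMRI map of section i], each
    modality block row-centered and the whole block rescaled so that
    both blocks carry equal mean-square power (so neither modality
    dominates the entropy objective).  ``split`` = T, the column index
    separating the blocks; ``modality_scales`` records the two scale
    factors for undoing.
    """

    X: np.ndarray
    split: int
    modality_scales: tuple[float, float]
    section_ids: tuple[int, ...]
    time_axis: np.ndarray | None = None
    grid: VolumeGrid | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "section_ids", tuple(int(s) for s in self.section_ids))
        if X.ndim != 2:
            raise ValueError("X must be 2-D (sections x features)")
        if not (0 < self.split < X.shape[1]):
            raise ValueError("split must lie strictly inside the feature axis")
        if len(self.section_ids) != X.shape[0]:
            raise ValueError("section_ids must match row count")

    @property
    def n_sections(self) -> int:
        return self.X.shape[0]

    @property
    def fnirs_block(self) -> np.ndarray:
        return self.X[:, : self.split]

    @property
    def fmri_block(self) -> np.ndarray:
        return self.X[:, self.split :]


def stack_joint(traces: list[SectionTrace], maps: SpatialMapSet) -> JointDataset:
    """Row-concatenate section traces and maps into one joint matrix.

    Each modality block is centered per row, then scaled by one scalar
    per modality so the two blocks have equal (unit) mean square.
    """
    n = len(traces)
    if n < 2:
        raise ValueError("square jICA needs at least 2 sections")
    if maps.n_maps != n:
        raise ValueError(f"{n} traces but {maps.n_maps} maps")
    trace_ids = [tr.section_id for tr in traces]
    if tuple(trace_ids) != maps.section_ids:
        raise ValueError(
            f"section ids disagree: traces {trace_ids} vs maps {list(maps.section_ids)}"
        )
    T = traces[0].n_samples
    if any(tr.n_samples != T for tr in traces):
        raise ValueError("all traces must have equal length")
    Xf = np.stack([tr.trace for tr in traces])
    Xm = np.array(maps.maps, copy=True)
    Xf = Xf - Xf.mean(axis=1, keepdims=True)
    Xm = Xm - Xm.mean(axis=1, keepdims=True)
    rms_f = np.sqrt(np.mean(Xf**2))
    rms_m = np.sqrt(np.mean(Xm**2))
    if rms_f == 0 or rms_m == 0:
        raise ValueError("a modality block is identically zero after centering")
    sf, sm = 1.0 / rms_f, 1.0 / rms_m
    X = np.hstack([Xf * sf, Xm * sm])
    return JointDataset(
        X=X,
        split=T,
        modality_scales=(sf, sm),
        section_ids=tuple(trace_ids),
        time_axis=traces[0].time_axis,
        grid=maps.grid,
    )


# ---------------------------------------------------------------------------
# whitening
# ---------------------------------------------------------------------------

def whiten(
    X: np.ndarray, section_ids: tuple[int, ...] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA-whiten row-centered data: returns (Z, K, K_inv) with Z = K·X.

    The n x n sample covariance of Z's rows over the feature columns is
    the identity.  Rank deficiency is diagnosed with the offending
    (near-duplicate) section pairs named.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    C = X @ X.T / m
    evals, evecs = np.linalg.eigh(C)
    if evals[0] < 1e-10 * max(evals[-1], 1e-300):
        ids = section_ids or tuple(range(1, n + 1))
        sd = np.sqrt(np.clip(np.diag(C), 1e-300, None))
        R = C / np.outer(sd, sd)
        pairs = [
            (ids[i], ids[j])
            for i in range(n)
            for j in range(i + 1, n)
            if abs(R[i, j]) > 0.999
        ]
        hint = f"; near-duplicate section pairs: {pairs}" if pairs else ""
        raise ValueError(f"rank-deficient joint data (covariance is singular){hint}")
    K = (evecs / np.sqrt(evals)).T  # rows scaled -> K = D^{-1/2} E^T
    K_inv = evecs * np.sqrt(evals)
    return K @ X, K, K_inv


# ---------------------------------------------------------------------------
# infomax
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InfomaxConfig:
    learning_rate: float = 0.2
    anneal_factor: float = 0.9
    max_iterations: int = 2000
    tolerance: float = 1e-7
    seed: int = 0
    use_natural_gradient: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0 < self.anneal_factor <= 1):
            raise ValueError("anneal_factor must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


def infomax_step(W: np.ndarray, X_batch: np.ndarray, eta: float) -> np.ndarray:
    """One natural-gradient infomax update ΔW for the logistic network.

    ΔW = η · (I + (1 − 2 y) uᵀ / m) · W with u = W·X, y = g(u), m the
    batch column count.  Passing the fNIRS and fMRI blocks separately
    and summing their (un-normalized) contributions equals the pooled
    update on the concatenated columns.
    """
    X_batch = np.atleast_2d(np.asarray(X_batch, dtype=float))
    if X_batch.shape[1] == 0:
        raise ValueError("empty batch")
    n, m = W.shape[0], X_batch.shape[1]
    u = W @ X_batch
    y = expit(u)
    grad = np.eye(n) + (1.0 - 2.0 * y) @ u.T / m
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError(
            "non-finite values in the infomax update (divergence); reduce the learning rate"
        )
    return eta * (grad @ W)


def infomax_loglik(W: np.ndarray, X: np.ndarray) -> float:
    """Per-sample infomax objective log|det W| + mean Σ log g'(u).

    g'(u) = g(u)(1−g(u)); the natural-gradient update ascends this.
    Exposed for diagnostics and gradient checks.
    """
    u = W @ X
    # log g'(u) = -u - 2 log(1 + e^-u), computed stably
    log_gprime = -u - 2.0 * np.logaddexp(0.0, -u)
    sign, logdet = np.linalg.slogdet(W)
    if sign <= 0 and abs(np.linalg.det(W)) == 0:
        return -np.inf
    return logdet + float(log_gprime.sum(axis=0).mean())


@dataclass
class MixingModel:
    """Result of a jICA fit: unmixing W (on whitened data), mixing A, sources."""

    W: np.ndarray
    A: np.ndarray
    whitener: np.ndarray
    whitener_inv: np.ndarray
    u_fnirs: np.ndarray
    u_fmri: np.ndarray
    n_iterations: int
    converged: bool
    seed: int
    final_update_norm: float = np.nan
    eta_history: tuple[float, ...] = field(default_factory=tuple)

    @property
    def unmixing_total(self) -> np.ndarray:
        """W composed with the whitener: maps centered scaled data to sources."""
        return self.W @ self.whitener


def _random_orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    Q, R = np.linalg.qr(rng.standard_normal((n, n)))
    return Q * np.sign(np.diag(R))


def fit_jica(X: JointDataset, cfg: InfomaxConfig = InfomaxConfig()) -> MixingModel:
    """Fit the shared-mixing model by whitened infomax gradient ascent.

    Starts from a seeded random W(0), iterates :func:`infomax_step` on
    the whitened joint data until ‖ΔW‖_F < tolerance·‖W‖_F or the
    iteration budget runs out (then ``converged=False`` with a warning).
    The learning rate is annealed when an update norm jumps by more than
    10x, and the fit restarts from a fresh seeded W(0) after three
    divergences.  Deterministic given ``cfg.seed``.
    """
    n = X.n_sections
    if n < 2:
        raise ValueError("need at least 2 sections")
    Xc = X.X - X.X.mean(axis=1, keepdims=True)
    Z, K, K_inv = whiten(Xc, X.section_ids)
    rng = np.random.default_rng(cfg.seed)
    W = _random_orthogonal(n, rng)
    eta = cfg.learning_rate
    eta_history = [eta]
    prev_norm = np.inf
    diverged = 0
    restarts = 0
    converged = False
    it = 0
    d_norm = np.nan
    for it in range(1, cfg.max_iterations + 1):
        try:
            dW = infomax_step(W, Z, eta)
        except FloatingPointError:
            diverged += 1
            if diverged > 3:
                restarts += 1
                if restarts > 3:
                    raise FloatingPointError(
                        "infomax diverged repeatedly despite annealing; "
                        "reduce learning_rate"
                    )
                W = _random_orthogonal(n, rng)
                diverged = 0
                prev_norm = np.inf
            eta *= cfg.anneal_factor
            eta_history.append(eta)
            continue
        d_norm = float(np.linalg.norm(dW))
        if d_norm > 10.0 * prev_norm:
            eta *= cfg.anneal_factor
            eta_history.append(eta)
        W = W + dW
        if d_norm < cfg.tolerance * np.linalg.norm(W):
            converged = True
            break
        prev_norm = d_norm
    if not converged:
        warnings.warn(
            f"infomax did not converge in {cfg.max_iterations} iterations "
            f"(last ‖ΔW‖={d_norm:.3e})",
            stacklevel=2,
        )
    W_total = W @ K
    A = np.linalg.inv(W_total)
    u = W_total @ Xc
    return MixingModel(
        W=W,
        A=A,
        whitener=K,
        whitener_inv=K_inv,
        u_fnirs=u[:, : X.split],
        u_fmri=u[:, X.split :],
        n_iterations=it,
        converged=converged,
        seed=cfg.seed,
        final_update_norm=d_norm,
        eta_history=tuple(eta_history),
    )


# ---------------------------------------------------------------------------
# task regressor and component extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFParams:
    """Double-gamma hemodynamic response: SPM-like canonical defaults.

    Response gamma peaks at ``peak_delay`` s, the undershoot gamma at
    ``undershoot_delay`` s with relative amplitude ``ratio``.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 1.0 / 6.0
    duration: float = 32.0


def double_gamma_hrf(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times t (s); 0 for t < 0."""
    t = np.asarray(t, dtype=float)
    p = params
    pos = gamma_dist.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    neg = gamma_dist.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    h = np.where(t >= 0, pos - p.ratio * neg, 0.0)
    return h


def task_regressor(
    p: StimulusParadigm,
    time_axis: np.ndarray,
    hrf_params: HRFParams = HRFParams(),
) -> np.ndarray:
    """Expected task response on an epoch time axis (0 = task onset).

    A boxcar over [0, task_duration] convolved with the double-gamma
    HRF, then demeaned and scaled to unit norm.  Errors if the task
    interval does not overlap the window.
    """
    t = np.asarray(time_axis, dtype=float)
    if len(t) < 2:
        raise ValueError("time_axis too short")
    dt = float(np.median(np.diff(t)))
    box = ((t >= 0) & (t < p.task_duration)).astype(float)
    if not box.any():
        raise ValueError("task interval [0, task_duration) does not overlap the window")
    kernel_t = np.arange(0.0, hrf_params.duration + dt, dt)
    kernel = double_gamma_hrf(kernel_t, hrf_params)
    reg = np.convolve(box, kernel)[: len(t)] * dt
    reg = reg - reg.mean()
    norm = np.linalg.norm(reg)
    if norm == 0:
        raise ValueError("degenerate regressor (identically zero)")
    return reg / norm


@dataclass(frozen=True)
class JointComponents:
    """Paired temporal/spatial independent components, ordered and labeled.

    ``temporal`` is T x n (columns t_i), ``spatial`` is V x n z-scored
    columns s_i.  Components are ordered by |task correlation|
    descending; task-labeled columns are sign-fixed to correlate
    positively with the task regressor, noise columns so their largest
    |spatial| value is positive.  ``order`` records the permutation from
    the fit's native component order.
    """

    temporal: np.ndarray
    spatial: np.ndarray
    labels: tuple[str, ...]
    task_correlations: np.ndarray
    order: tuple[int, ...]
    time_axis: np.ndarray | None = None
    grid: VolumeGrid | None = None

    @property
    def n_components(self) -> int:
        return self.temporal.shape[1]


def extract_components(
    model: MixingModel,
    X: JointDataset,
    regressor: np.ndarray,
    label_threshold: float = 0.4,
) -> JointComponents:
    """Turn fitted sources into labeled, ordered component pairs.

    Temporal components are the fNIRS source estimates (T x n), spatial
    components the z-scored fMRI source estimates (V x n).  Each
    component's Pearson correlation with the task regressor decides its
    label (|r| >= label_threshold -> "task") and the ordering.
    """
    regressor = np.asarray(regressor, dtype=float).ravel()
    if len(regressor) != X.split:
        raise ValueError(f"regressor length {len(regressor)} != T = {X.split}")
    temporal = np.array(model.u_fnirs.T, dtype=float)  # T x n
    spatial = np.array(model.u_fmri.T, dtype=float)  # V x n
    n = temporal.shape[1]
    t_sd = temporal.std(axis=0)
    s_sd = spatial.std(axis=0)
    if np.any(t_sd == 0) or np.any(s_sd == 0):
        raise ValueError("constant (zero-variance) component; fit is degenerate")
    spatial = (spatial - spatial.mean(axis=0)) / s_sd
    r_sd = regressor.std()
    if r_sd == 0:
        raise ValueError("constant task regressor")
    rc = (regressor - regressor.mean()) / r_sd
    r = np.array(
        [np.mean(rc * (temporal[:, i] - temporal[:, i].mean()) / t_sd[i]) for i in range(n)]
    )
    order = tuple(int(i) for i in np.argsort(-np.abs(r), kind="stable"))
    temporal = temporal[:, order]
    spatial = spatial[:, order]
    r = r[list(order)]
    labels = tuple("task" if abs(ri) >= label_threshold else "noise" for ri in r)
    signs = np.ones(n)
    for i in range(n):
        if labels[i] == "task":
            signs[i] = 1.0 if r[i] >= 0 else -1.0
        else:
            v = spatial[:, i]
            signs[i] = 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0
    temporal = temporal * signs
    spatial = spatial * signs
    r = r * signs
    return JointComponents(
        temporal=temporal,
        spatial=spatial,
        labels=labels,
        task_correlations=r,
        order=order,
        time_axis=X.time_axis,
        grid=X.grid,
    )
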