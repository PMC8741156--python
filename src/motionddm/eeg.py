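"""From continuous EEG to the per-subject pre-response slope measure.

Pipeline: response-locked epoching with a random-motion baseline ->
Reliable Components Analysis (RCA) spatial filtering -> FIR time-expanded
deconvolution of overlapping stimulus- and response-locked activity, with
sliding-window artifact masking and ridge regularisation (cross-validated
penalty, constrained to the modal value across participants) -> OLS slope
of the deconvolved response-locked waveform over the last 200 ms before the
response, in microvolts/second.

The FIR design has one boxcar predictor per (event type, difficulty, lag)
over the half-open lag window [-1000, 1000) ms; at 250 Hz this is exactly
500 lags per event type x difficulty.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, sparse

from motionddm.io import EEGRecording

__all__ = [
    "EpochSet",
    "RCModel",
    "TimeExpandedDesign",
    "DeconvolvedERP",
    "SlopeMeasure",
    "epoch_and_baseline",
    "rca_fit",
    "rca_project",
    "build_design",
    "mask_artifacts",
    "deconvolve",
    "select_lambda",
    "extract_slope",
]


@dataclass
class EpochSet:
    """Epoched data: trials x channels x time, times relative to the lock event."""

    data: np.ndarray
    times: np.ndarray
    sfreq: float
    difficulty: list
    n_dropped: int = 0


@dataclass
class RCModel:
    """Reliable-components spatial filters (channels x components), their
    forward-model projections and reliability coefficients (descending)."""

    weights: np.ndarray
    forward: np.ndarray
    reliability: np.ndarray


@dataclass
class TimeExpandedDesign:
    X: sparse.csr_matrix
    conditions: list  # (event_type, difficulty), one per block of lag columns
    lags_s: np.ndarray
    sfreq: float

    @property
    def n_lags(self) -> int:
        return len(self.lags_s)


@dataclass
class DeconvolvedERP:
    """FIR regression weights per (event type, difficulty), microvolts."""

    betas: dict
    lags_s: np.ndarray
    sfreq: float
    lam: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class SlopeMeasure:
    """Pre-response build-up slope per difficulty (microvolts/s) and the
    derived EEG.mean (average over difficulties) and EEG.diff (easy - hard)."""

    slope_easy: float
    slope_hard: float

    @property
    def eeg_mean(self) -> float:
        return 0.5 * (self.slope_easy + self.slope_hard)

    @property
    def eeg_diff(self) -> float:
        return self.slope_easy - self.slope_hard


# ---------------------------------------------------------------------------


def epoch_and_baseline(
    rec: EEGRecording,
    lock: str = "response",
    window: tuple[float, float] = (-0.6, 0.2),
    baseline_window: tuple[float, float] = (-0.1, 0.0),
) -> EpochSet:
    """Epoch around each `lock` event and subtract, channel-wise, the mean of
    the baseline interval taken relative to the trial's stimulus onset (the
    last 100 ms of the random-motion period by default). Epochs that exceed
    the recording are dropped and counted."""
    sf = rec.sfreq
    lo = int(round(window[0] * sf))
    hi = int(round(window[1] * sf))
    stim_times = [e["time_s"] for e in rec.events if e["type"] == "stimulus"]
    if not stim_times:
        raise ValueError("no stimulus events: baseline interval cannot be resolved")
    stim_times = np.asarray(stim_times)
    epochs, diffs = [], []
    dropped = 0
    for ev in rec.events:
        if ev["type"] != lock:
            continue
        samp = int(round(ev["time_s"] * sf))
        prior = stim_times[stim_times <= ev["time_s"] + 1e-9]
        if len(prior) == 0:
            dropped += 1
            continue
        stim_samp = int(round(prior[-1] * sf))
        b0 = stim_samp + int(round(baseline_window[0] * sf))
        b1 = stim_samp + int(round(baseline_window[1] * sf))
        if samp + lo < 0 or samp + hi > rec.n_samples or b0 < 0 or b1 > rec.n_samples or b1 <= b0:
            dropped += 1
            continue
        seg = rec.data[:, samp + lo : samp + hi]
        base = rec.data[:, b0:b1].mean(axis=1, keepdims=True)
        epochs.append(seg - base)
        diffs.append(ev.get("difficulty"))
    if not epochs:
        raise ValueError("no usable epochs")
    times = (np.arange(lo, hi)) / sf
    return EpochSet(
        data=np.stack(epochs), times=times, sfreq=sf, difficulty=diffs, n_dropped=dropped
    )


def rca_fit(epochs: EpochSet | np.ndarray, n_components: int | None = None) -> RCModel:
    """Reliable Components Analysis on pooled epochs.

    Spatial filters w maximize across-trial reliability via the generalized
    eigenproblem R_between w = lambda R_within w, where R_within is the
    trial-averaged spatial covariance and R_between the average cross-trial
    covariance. Components are ordered by reliability; weights are
    unit-norm; forward projections are covariance-mapped (R_within w) with
    the sign fixed so each projection's largest-magnitude entry is positive.
    """
    X = epochs.data if isinstance(epochs, EpochSet) else np.asarray(epochs)
    if X.ndim != 3:
        raise ValueError("epochs must be trials x channels x time")
    n, C, T = X.shape
    if n < 2 or C < 2:
        raise ValueError("RCA needs at least 2 trials and 2 channels")
    Xc = X - X.mean(axis=2, keepdims=True)
    S = Xc.sum(axis=0)  # channels x time
    Rw = np.einsum("ict,idt->cd", Xc, Xc) / (n * T)
    Rb = (S @ S.T / T - Rw * n) / (n * (n - 1))
    Rb = 0.5 * (Rb + Rb.T)
    load = 0.0
    try:
        evals, evecs = linalg.eigh(Rb, Rw)
    except linalg.LinAlgError:
        load = 1e-9 * np.trace(Rw) / C
        warnings.warn("rank-deficient within-trial covariance; applying diagonal loading")
        evals, evecs = linalg.eigh(Rb, Rw + load * np.eye(C))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k = n_components or C
    W = evecs[:, :k]
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    A = (Rw + load * np.eye(C)) @ W
    # fix signs: largest-|entry| of each forward projection positive
    for j in range(A.shape[1]):
        i = np.argmax(np.abs(A[:, j]))
        if A[i, j] < 0:
            A[:, j] *= -1
            W[:, j] *= -1
    return RCModel(weights=W, forward=A, reliability=evals[:k])


def rca_project(rec: EEGRecording, model: RCModel, component: int = 0) -> np.ndarray:
    """Project continuous data through one spatial filter -> component waveform."""
    return model.weights[:, component] @ rec.data


def build_design(
    events: list,
    sfreq: float,
    n_samples: int,
    window: tuple[float, float] = (-1.0, 1.0),
    difficulties: tuple[str, str] = ("easy", "hard"),
    difficulty_map: dict | None = None,
    event_types: tuple[str, str] = ("stimulus", "response"),
) -> TimeExpandedDesign:
    """Time-expanded FIR design matrix.

    One boxcar predictor per (event type, difficulty, lag); the lag window is
    half-open [window[0], window[1]) so 250 Hz over [-1, 1) s gives exactly
    500 lags per condition. Events are snapped to the nearest sample.
    """
    if not events:
        raise ValueError("empty event list")
    difficulty_map = {"catch": difficulties[0]} if difficulty_map is None else difficulty_map
    lag0 = int(round(window[0] * sfreq))
    n_lags = int(round((window[1] - window[0]) * sfreq))
    lags = np.arange(lag0, lag0 + n_lags)
    conditions = [(et, d) for et in event_types for d in difficulties]
    cond_index = {c: i for i, c in enumerate(conditions)}
    rows, cols = [], []
    for ev in sorted(events, key=lambda e: e["time_s"]):
        d = difficulty_map.get(ev.get("difficulty"), ev.get("difficulty"))
        key = (ev["type"], d)
        if key not in cond_index:
            continue
        samp = int(round(ev["time_s"] * sfreq))
        r = samp + lags
        ok = (r >= 0) & (r < n_samples)
        rows.append(r[ok])
        cols.append(cond_index[key] * n_lags + np.flatnonzero(ok) )
    X = sparse.csr_matrix(
        (np.ones(sum(len(r) for r in rows)), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_samples, len(conditions) * n_lags),
    )
    X.data[:] = 1.0  # duplicate (row, col) pairs collapse to a single boxcar
    return TimeExpandedDesign(X=X, conditions=conditions, lags_s=lags / sfreq, sfreq=sfreq)


def mask_artifacts(
    waveform: np.ndarray,
    sfreq: float,
    threshold: float = 250.0,
    segment_s: float = 2.0,
    step_s: float = 0.1,
):
    """Sliding-window artifact exclusion: any `segment_s` window (stepped by
    `step_s`) containing an excursion beyond +/-threshold has all its samples
    marked excluded. Returns (excluded mask, excluded fraction)."""
    x = np.asarray(waveform).ravel()
    n = len(x)
    L = int(round(segment_s * sfreq))
    step = max(int(round(step_s * sfreq)), 1)
    excluded = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(np.abs(x) > threshold):
        k_first = max(int(np.ceil((i - L + 1) / step)), 0)
        k_last = i // step
        excluded[k_first * step : min(k_last * step + L, n)] = True
    return excluded, float(excluded.mean())


def deconvolve(
    design: TimeExpandedDesign,
    signal: np.ndarray,
    lam: float = 0.0,
    mask: np.ndarray | None = None,
) -> DeconvolvedERP:
    """Penalized FIR deconvolution: beta = argmin ||y - X beta||^2 + lam ||beta||^2.

    lam = 0 reduces to OLS (raises on a singular system, pointing to ridge);
    `mask` marks samples to exclude (artifact windows)."""
    if lam < 0:
        raise ValueError("ridge penalty must be >= 0")
    y = np.asarray(signal).ravel()
    X = design.X
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        X = X[keep]
        y = y[keep]
    XtX = (X.T @ X).toarray()
    Xty = X.T @ y
    A = XtX + lam * np.eye(XtX.shape[0])
    try:
        cf = linalg.cho_factor(A)
        beta = linalg.cho_solve(cf, Xty)
    except linalg.LinAlgError as err:
        if lam == 0:
            raise linalg.LinAlgError(
                "singular FIR system at lam=0 (overlapping predictors); "
                "use ridge regularisation (lam > 0)"
            ) from err
        raise
    n_lags = design.n_lags
    betas = {
        cond: beta[i * n_lags : (i + 1) * n_lags] for i, cond in enumerate(design.conditions)
    }
    resid = y - X @ beta
    return DeconvolvedERP(
        betas=betas,
        lags_s=design.lags_s,
        sfreq=design.sfreq,
        lam=lam,
        diagnostics={
            "rss": float(resid @ resid),
            "n_samples": int(X.shape[0]),
            "excluded_fraction": float(mask.mean()) if mask is not None else 0.0,
        },
    )


def _cv_mse(design, y, keep_idx, grid, k):
    """Held-out MSE per lambda with contiguous-time folds, sharing one
    eigendecomposition of each fold's normal matrix across the grid."""
    folds = np.array_split(keep_idx, k)
    mse = np.zeros(len(grid))
    for f in range(k):
        test = folds[f]
        train = np.concatenate([folds[g] for g in range(k) if g != f])
        Xtr, ytr = design.X[train], y[train]
        Xte, yte = design.X[test], y[test]
        XtX = (Xtr.T @ Xtr).toarray()
        Xty = Xtr.T @ ytr
        e, V = linalg.eigh(XtX)
        VtXty = V.T @ Xty
        for i, lam in enumerate(grid):
            beta = V @ (VtXty / (e + lam)) if lam > 0 else V @ (VtXty / np.maximum(e, 1e-12))
            r = yte - Xte @ beta
            mse[i] += float(r @ r)
    return mse


def select_lambda(
    participants: list,
    grid: np.ndarray | None = None,
    k: int = 5,
):
    """Cross-validated common ridge penalty.

    `participants` is a list of (design, signal, mask-or-None). Each
    participant's best lambda minimizes k-fold held-out MSE over contiguous
    time segments; the returned common penalty is the mode across
    participants (smallest value on ties), applied to everyone so that
    regularisation differences cannot masquerade as group differences.
    Returns (modal_lambda, per-participant bests).
    """
    if grid is None:
        grid = np.arange(0.0, 30.5, 0.5)
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    if k < 2:
        raise ValueError("need at least 2 folds")
    best = []
    for design, signal, mask in participants:
        y = np.asarray(signal).ravel()
        keep = np.arange(len(y)) if mask is None else np.flatnonzero(~np.asarray(mask, bool))
        if min(len(chunk) for chunk in np.array_split(keep, k)) < 2:
            raise ValueError("degenerate folds: too few usable samples")
        mse = _cv_mse(design, y, keep, np.asarray(grid, float), k)
        best.append(float(grid[int(np.argmin(mse))]))
    return modal_lambda(best), best


def modal_lambda(best: list) -> float:
    """Mode of the per-participant penalties; ties resolve to the smallest
    (least regularisation) among the most frequent values."""
    counts = Counter(best)
    top = max(counts.values())
    return min(lam for lam, c in counts.items() if c == top)


def extract_slope(
    erp: DeconvolvedERP,
    window: tuple[float, float] = (-0.2, 0.0),
    event_type: str = "response",
) -> SlopeMeasure:
    """OLS slope (microvolts/s) of the response-locked deconvolved waveform
    per difficulty over `window` (inclusive), plus EEG.mean / EEG.diff."""
    sel = (erp.lags_s >= window[0] - 1e-9) & (erp.lags_s <= window[1] + 1e-9)
    if not sel.any():
        raise ValueError(f"lag axis does not cover the slope window {window}")
    t = erp.lags_s[sel]
    slopes = {}
    for diff in ("easy", "hard"):
        y = erp.betas[(event_type, diff)][sel]
        slopes[diff] = float(np.polyfit(t, y, 1)[0])
    return SlopeMeasure(slope_easy=slopes["easy"], slope_hard=slopes["hard"])
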