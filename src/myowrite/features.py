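"""Sliding-window extraction of the 26 time- and frequency-domain EMG features.

Windows of 150 ms advancing by 75 ms are cut from each activation segment
and, per channel, summarised by 16 time-domain features (amplitude
statistics, threshold-gated counts, two entropies, a 10-bin histogram and a
4th-order autoregressive model with its cepstrum) and 10 frequency-domain
features derived from a Hamming-tapered periodogram. Five canonical
myoelectric feature sets (Hudgins, Du, Phinyomark 1/2, TDAR) are defined as
sub-selections of the full set.

All extractors are implemented batch-first (``(n_windows, n_samples)``
arrays); the per-window functions are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
from scipy import signal

from .synth import ActivationSegment, EmgRecording

logger = logging.getLogger(__name__)


class FeatureError(ValueError):
    """Window unsuitable for the requested feature (too short, degenerate)."""


@dataclass(frozen=True)
class FeatureParams:
    """Tunable parameters of the feature extractors.

    ``eps`` is the amplitude deadzone (mV) shared by ZC, SSC, WAMP and MYOP;
    when ``None`` it is resolved per recording as
    ``eps_rms_factor x baseline RMS``. Fuzzy entropy uses embedding
    dimension ``fuzen_m``, tolerance ``fuzen_r_factor x window SD`` and
    exponent ``fuzen_n``; weighted permutation entropy uses ordinal patterns
    of ``wpe_order`` with ``wpe_delay``. The periodogram is Hamming-tapered,
    one-sided, zero-padded to ``nfft``. The frequency ratio splits the
    35-450 Hz band at ``fr_split`` Hz; the power-spectrum ratio sums
    ``psr_halfwidth`` bins either side of the spectral peak.
    """

    eps: float | None = None
    eps_rms_factor: float = 0.01
    fuzen_m: int = 2
    fuzen_r_factor: float = 0.15
    fuzen_n: float = 2.0
    wpe_order: int = 3
    wpe_delay: int = 1
    ar_order: int = 4
    hist_bins: int = 10
    nfft: int = 256
    band: tuple[float, float] = (35.0, 450.0)
    fr_split: float = 135.0
    psr_halfwidth: int = 10

    def resolve_eps(self, baseline_rms: float) -> float:
        return self.eps if self.eps is not None else self.eps_rms_factor * baseline_rms

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class AnalysisWindow:
    """One channels x samples analysis window cut from a segment."""

    samples: np.ndarray  # (n_channels, W)
    start_sample: int
    word_label: int


# --- feature registry: name -> output width -------------------------------

TD_SCALARS = [
    "IEMG", "MAV", "VAR", "RMS", "WL", "DAMV", "DASDV",
    "ZC", "MYOP", "WAMP", "SSC", "FuzEN", "WPermEN",
]
FD_SCALARS = ["MNF", "MDF", "PKF", "TTP", "SM1", "SM2", "SM3", "FR", "PSR", "VCF"]

FEATURE_WIDTHS: dict[str, int] = {
    **{f: 1 for f in TD_SCALARS},
    "HIST": 10,
    "AR": 4,
    "CC": 4,
    **{f: 1 for f in FD_SCALARS},
}

ALL_FEATURES = list(FEATURE_WIDTHS)  # TD scalars, HIST, AR, CC, then FD

FEATURE_SETS: dict[str, list[str]] = {
    "Hudgins": ["MAV", "WL", "SSC", "ZC"],
    "Du": ["IEMG", "VAR", "WAMP", "WL", "SSC", "ZC"],
    "Phinyomark1": ["MAV", "WL", "WAMP", "ZC", "AR", "MNF", "PSR"],
    "Phinyomark2": ["WPermEN", "CC", "RMS", "WL"],
    "TDAR": ["MAV", "SSC", "WL", "VAR", "WAMP", "AR", "ZC"],
    "ALL": ALL_FEATURES,
}


@dataclass(frozen=True)
class FeatureSetSpec:
    name: str
    members: tuple[str, ...]

    @classmethod
    def named(cls, name: str) -> "FeatureSetSpec":
        if name not in FEATURE_SETS:
            raise KeyError(f"unknown feature set {name!r}; choose from {list(FEATURE_SETS)}")
        return cls(name, tuple(FEATURE_SETS[name]))

    @property
    def width_per_channel(self) -> int:
        return sum(FEATURE_WIDTHS[f] for f in self.members)


def set_column_names(spec: FeatureSetSpec, n_channels: int) -> list[str]:
    """Channel-major column schema: ``<FEAT>[_k]_ch<i>``."""
    cols = []
    for ch in range(1, n_channels + 1):
        for feat in spec.members:
            w = FEATURE_WIDTHS[feat]
            if w == 1:
                cols.append(f"{feat}_ch{ch}")
            else:
                cols.extend(f"{feat}_{k}_ch{ch}" for k in range(1, w + 1))
    return cols


# --- windowing -------------------------------------------------------------

def make_windows(
    recording: EmgRecording,
    segments: list[ActivationSegment],
    win: float = 0.150,
    step: float = 0.075,
) -> list[AnalysisWindow]:
    """Cut fixed-length sliding windows from each activation segment.

    A segment of L samples yields ``floor((L - W)/S) + 1`` windows (W, S the
    window and step in samples); windows never straddle segment boundaries.
    """
    if not (win > step > 0):
        raise ValueError("require win > step > 0")
    W = int(round(win * recording.fs))
    S = int(round(step * recording.fs))
    windows = []
    for seg in segments:
        start = seg.start_sample
        while start + W <= seg.end_sample:
            windows.append(
                AnalysisWindow(
                    samples=recording.data[:, start : start + W],
                    start_sample=start,
                    word_label=recording.word_label,
                )
            )
            start += S
    return windows


# --- time-domain batch extractors -----------------------------------------

def td_features_batch(X: np.ndarray, eps: float) -> dict[str, np.ndarray]:
    """Scalar time-domain features for a (n_windows, N) batch."""
    X = np.asarray(X, dtype=float)
    n, N = X.shape
    if N < 2:
        raise FeatureError("time-domain features need windows of >= 2 samples")
    absx = np.abs(X)
    d = np.diff(X, axis=1)
    absd = np.abs(d)

    out: dict[str, np.ndarray] = {}
    out["IEMG"] = absx.sum(axis=1)
    out["MAV"] = out["IEMG"] / N
    out["VAR"] = (X**2).sum(axis=1) / (N - 1)
    out["RMS"] = np.sqrt((X**2).mean(axis=1))
    out["WL"] = absd.sum(axis=1)
    out["DAMV"] = out["WL"] / (N - 1)
    out["DASDV"] = np.sqrt((d**2).sum(axis=1) / (N - 1))
    out["ZC"] = ((X[:, :-1] * X[:, 1:] < 0) & (absd >= eps)).sum(axis=1).astype(float)
    out["MYOP"] = (absx >= eps).mean(axis=1)
    out["WAMP"] = (absd >= eps).sum(axis=1).astype(float)
    # slope-sign change: local extremum at i with at least one flank >= eps
    slope_prod = d[:, :-1] * d[:, 1:]
    flank = (absd[:, :-1] >= eps) | (absd[:, 1:] >= eps)
    out["SSC"] = ((slope_prod < 0) & flank).sum(axis=1).astype(float)
    return out


def hist_batch(X: np.ndarray, bins: int = 10) -> np.ndarray:
    """Per-window histogram counts over that window's [min, max] range."""
    n, N = X.shape
    out = np.empty((n, bins))
    for i in range(n):
        out[i], _ = np.histogram(X[i], bins=bins)
    return out


def fuzzy_entropy_batch(
    X: np.ndarray, m: int = 2, r_factor: float = 0.15, n_exp: float = 2.0
) -> np.ndarray:
    """Fuzzy entropy with exponential membership exp(-(d/r)^n).

    Template vectors are locally demeaned; similarity uses the Chebyshev
    distance; the tolerance is ``r_factor`` times the window SD. Degenerate
    (constant) windows return 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape[0])
    for i, x in enumerate(X):
        out[i] = _fuzzy_entropy_1d(x, m, r_factor, n_exp)
    return out


def _phi(x: np.ndarray, m: int, r: float, n_exp: float, n_templates: int) -> float:
    idx = np.arange(m)[None, :] + np.arange(n_templates)[:, None]
    tpl = x[idx]
    tpl = tpl - tpl.mean(axis=1, keepdims=True)
    dist = np.max(np.abs(tpl[:, None, :] - tpl[None, :, :]), axis=2)
    sim = np.exp(-((dist / r) ** n_exp))
    np.fill_diagonal(sim, 0.0)
    return sim.sum() / (n_templates * (n_templates - 1))


def _fuzzy_entropy_1d(x: np.ndarray, m: int, r_factor: float, n_exp: float) -> float:
    sd = float(np.std(x))
    if sd == 0.0:
        logger.debug("constant window: FuzEN = 0 by convention")
        return 0.0
    r = r_factor * sd
    n_templates = len(x) - m  # shared by orders m and m+1
    if n_templates < 2:
        raise FeatureError("window too short for fuzzy entropy embedding")
    phi_m = _phi(x, m, r, n_exp, n_templates)
    phi_m1 = _phi(x, m + 1, r, n_exp, n_templates)
    if phi_m <= 0 or phi_m1 <= 0:
        return 0.0
    return float(np.log(phi_m) - np.log(phi_m1))


def weighted_permutation_entropy_batch(
    X: np.ndarray, order: int = 3, delay: int = 1
) -> np.ndarray:
    """Variance-weighted permutation entropy, normalised to [0, 1] by log(order!).

    Each embedded vector votes for its ordinal pattern with weight equal to
    its sample variance, so flat (noise-floor) stretches contribute little.
    Constant windows return 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    n, N = X.shape
    n_vec = N - (order - 1) * delay
    if n_vec < 2:
        raise FeatureError("window too short for permutation embedding")
    idx = np.arange(0, order * delay, delay)[None, :] + np.arange(n_vec)[:, None]
    out = np.empty(n)
    radix = np.power(order, np.arange(order))
    for i in range(n):
        vec = X[i][idx]  # (n_vec, order)
        weights = vec.var(axis=1)
        total = weights.sum()
        if total == 0.0:
            out[i] = 0.0
            continue
        patterns = np.argsort(vec, axis=1, kind="stable") @ radix
        pw = np.bincount(patterns, weights=weights)
        p = pw[pw > 0] / total
        h = float(-(p * np.log(p)).sum() / np.log(factorial(order)))
        out[i] = max(h, 0.0)  # guard float noise when one pattern dominates
    return out


# --- autoregressive / cepstral --------------------------------------------

def ar_coefficients_batch(X: np.ndarray, order: int = 4) -> np.ndarray:
    """Yule-Walker AR coefficients (biased autocorrelation), batched.

    Sign convention: the returned a_1..a_p satisfy
    ``x_t + a_1 x_{t-1} + ... + a_p x_{t-p} = e_t``, i.e. an AR(1) process
    ``x_t = 0.5 x_{t-1} + e_t`` gives a_1 ~= -0.5. Windows are demeaned
    before autocorrelation. Degenerate (zero-variance) windows raise.
    """
    X = np.asarray(X, dtype=float)
    n, N = X.shape
    if N <= 2 * order:
        raise FeatureError(f"AR({order}) needs windows longer than {2 * order} samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    # biased autocorrelation r_k = (1/N) sum_t x_t x_{t+k}, k = 0..order
    r = np.empty((n, order + 1))
    for k in range(order + 1):
        r[:, k] = (Xc[:, : N - k] * Xc[:, k:]).sum(axis=1) / N
    if np.any(r[:, 0] <= 0):
        raise FeatureError("constant window: autocorrelation matrix singular")
    lag_diff = np.abs(np.arange(order)[:, None] - np.arange(order)[None, :])
    R = r[:, lag_diff]  # (n, order, order) Toeplitz
    rho = np.linalg.solve(R, r[:, 1:, None])[:, :, 0]  # predictor coefficients
    return -rho


def cepstral_from_ar(a: np.ndarray) -> np.ndarray:
    """Cepstral coefficients of an AR model via the standard recursion.

    ``c_1 = -a_1``; ``c_p = -a_p - sum_{l=1}^{p-1} (1 - l/p) a_l c_{p-l}``.
    Accepts (order,) or (n, order) arrays.
    """
    a_arr = np.asarray(a, dtype=float)
    squeeze = a_arr.ndim == 1
    a2 = np.atleast_2d(a_arr)
    n, order = a2.shape
    c = np.zeros_like(a2)
    c[:, 0] = -a2[:, 0]
    for p in range(2, order + 1):
        acc = np.zeros(n)
        for l in range(1, p):
            acc += (1 - l / p) * a2[:, l - 1] * c[:, p - l - 1]
        c[:, p - 1] = -a2[:, p - 1] - acc
    return c[0] if squeeze else c


# --- frequency-domain ------------------------------------------------------

def fd_features_batch(
    X: np.ndarray, fs: float, params: FeatureParams = FeatureParams()
) -> dict[str, np.ndarray]:
    """Periodogram-based spectral features for a (n_windows, N) batch."""
    X = np.asarray(X, dtype=float)
    n, N = X.shape
    if N < 64:
        raise FeatureError("frequency-domain features need >= 64 samples")
    f, P = signal.periodogram(
        X, fs=fs, window="hamming", nfft=max(params.nfft, N), axis=1
    )
    ttp = P.sum(axis=1)
    if np.any(ttp <= 0):
        raise FeatureError("all-zero window: spectral ratios undefined")

    out: dict[str, np.ndarray] = {}
    sm1 = (P * f).sum(axis=1)
    sm2 = (P * f**2).sum(axis=1)
    sm3 = (P * f**3).sum(axis=1)
    out["TTP"] = ttp
    out["SM1"] = sm1
    out["SM2"] = sm2
    out["SM3"] = sm3
    out["MNF"] = sm1 / ttp
    out["VCF"] = sm2 / ttp - (sm1 / ttp) ** 2

    cum = np.cumsum(P, axis=1)
    half = ttp / 2.0
    mdf_idx = (cum < half[:, None]).sum(axis=1)
    out["MDF"] = f[np.minimum(mdf_idx, len(f) - 1)]

    pk_idx = P.argmax(axis=1)
    out["PKF"] = f[pk_idx]

    low = (f >= params.band[0]) & (f < params.fr_split)
    high = (f >= params.fr_split) & (f <= params.band[1])
    hp = P[:, high].sum(axis=1)
    lp = P[:, low].sum(axis=1)
    fr = np.zeros(n)
    bad = hp <= 0
    if bad.any():
        logger.warning("FR denominator zero in %d windows; reported as 0", bad.sum())
    fr[~bad] = lp[~bad] / hp[~bad]
    out["FR"] = fr

    w = params.psr_halfwidth
    psr = np.empty(n)
    for i in range(n):
        lo = max(pk_idx[i] - w, 0)
        hi = min(pk_idx[i] + w + 1, P.shape[1])
        psr[i] = P[i, lo:hi].sum() / ttp[i]
    out["PSR"] = psr
    return out


# --- single-window conveniences -------------------------------------------

def td_features(x: np.ndarray, eps: float = 0.0) -> dict[str, float]:
    """Time-domain features (incl. HIST) of one 1-D window."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out = {k: float(v[0]) for k, v in td_features_batch(x, eps).items()}
    out["HIST"] = hist_batch(x)[0]
    return out


def entropy_features(
    x: np.ndarray, params: FeatureParams = FeatureParams()
) -> dict[str, float]:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return {
        "FuzEN": float(
            fuzzy_entropy_batch(x, params.fuzen_m, params.fuzen_r_factor, params.fuzen_n)[0]
        ),
        "WPermEN": float(
            weighted_permutation_entropy_batch(x, params.wpe_order, params.wpe_delay)[0]
        ),
    }


def ar_cc_features(x: np.ndarray, order: int = 4) -> dict[str, np.ndarray]:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    a = ar_coefficients_batch(x, order)
    return {"AR": a[0], "CC": cepstral_from_ar(a)[0]}


def fd_features(
    x: np.ndarray, fs: float, params: FeatureParams = FeatureParams()
) -> dict[str, float]:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return {k: float(v[0]) for k, v in fd_features_batch(x, fs, params).items()}


# --- feature-matrix assembly ----------------------------------------------

@dataclass
class FeatureMatrix:
    """Windows x (features x channels) table with labels and provenance."""

    X: pd.DataFrame
    y: np.ndarray
    provenance: pd.DataFrame  # recording_id, subject_id, window_start
    feature_set: FeatureSetSpec
    feature_params: FeatureParams
    resolved_eps: dict[str, float] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.X)

    def select(self, feature_set: str | FeatureSetSpec) -> "FeatureMatrix":
        """Slice out a named sub-set's columns (requires a superset matrix)."""
        spec = (
            feature_set
            if isinstance(feature_set, FeatureSetSpec)
            else FeatureSetSpec.named(feature_set)
        )
        missing = set(spec.members) - set(self.feature_set.members)
        if missing:
            raise KeyError(f"features {sorted(missing)} not in this matrix")
        n_channels = _n_channels_from_columns(self.X.columns)
        cols = set_column_names(spec, n_channels)
        return FeatureMatrix(
            X=self.X[cols].copy(),
            y=self.y,
            provenance=self.provenance,
            feature_set=spec,
            feature_params=self.feature_params,
            resolved_eps=self.resolved_eps,
        )

    def to_csv(self, path) -> None:
        out = self.provenance.copy()
        out["label"] = self.y
        pd.concat([out, self.X], axis=1).to_csv(path, index=False)

    def write_params(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.feature_params.as_dict().items():
                fh.write(f"{k}={v}\n")
            for rec, eps in self.resolved_eps.items():
                fh.write(f"eps[{rec}]={eps:.6g}\n")


def _n_channels_from_columns(columns) -> int:
    return max(int(c.rsplit("_ch", 1)[1]) for c in columns)


def compute_window_features(
    W: np.ndarray, fs: float, members: tuple[str, ...], eps: float,
    params: FeatureParams,
) -> np.ndarray:
    """Feature block for one channel's (n_windows, N) batch, column order per set."""
    needed_td = [m for m in members if m in TD_SCALARS[:11]]
    td = td_features_batch(W, eps) if needed_td else {}
    fd = fd_features_batch(W, fs, params) if any(m in FD_SCALARS for m in members) else {}
    ar = (
        ar_coefficients_batch(W, params.ar_order)
        if ("AR" in members or "CC" in members)
        else None
    )
    blocks = []
    for m in members:
        if m in td:
            blocks.append(td[m][:, None])
        elif m in fd:
            blocks.append(fd[m][:, None])
        elif m == "HIST":
            blocks.append(hist_batch(W, params.hist_bins))
        elif m == "FuzEN":
            blocks.append(
                fuzzy_entropy_batch(
                    W, params.fuzen_m, params.fuzen_r_factor, params.fuzen_n
                )[:, None]
            )
        elif m == "WPermEN":
            blocks.append(
                weighted_permutation_entropy_batch(
                    W, params.wpe_order, params.wpe_delay
                )[:, None]
            )
        elif m == "AR":
            blocks.append(ar)
        elif m == "CC":
            blocks.append(cepstral_from_ar(ar))
        else:
            raise KeyError(f"unknown feature {m!r}")
    return np.hstack(blocks)


def build_feature_matrix(
    recordings: list[EmgRecording],
    segments: list[list[ActivationSegment]],
    feature_set: str | FeatureSetSpec = "ALL",
    params: FeatureParams = FeatureParams(),
    win: float = 0.150,
    step: float = 0.075,
) -> FeatureMatrix:
    """Assemble the labelled windows x (features x channels) matrix.

    The amplitude deadzone is resolved per recording from the baseline
    (outside-segment) RMS unless ``params.eps`` pins it; resolved values are
    recorded for reproducibility.
    """
    spec = (
        feature_set
        if isinstance(feature_set, FeatureSetSpec)
        else FeatureSetSpec.named(feature_set)
    )
    if len({r.fs for r in recordings}) > 1:
        raise FeatureError("recordings have mismatched sampling rates")
    fs = recordings[0].fs
    n_channels = recordings[0].n_channels
    cols = set_column_names(spec, n_channels)

    rows, labels, prov = [], [], []
    resolved: dict[str, float] = {}
    for rec_idx, (rec, segs) in enumerate(zip(recordings, segments)):
        windows = make_windows(rec, segs, win=win, step=step)
        rec_id = f"{rec.subject_id}/w{rec.word_label:02d}"
        eps = params.resolve_eps(_baseline_rms(rec, segs))
        resolved[rec_id] = eps
        if not windows:
            continue
        stack = np.stack([w.samples for w in windows])  # (n_win, ch, W)
        per_channel = [
            compute_window_features(stack[:, ch, :], fs, spec.members, eps, params)
            for ch in range(n_channels)
        ]
        rows.append(np.hstack(per_channel))
        labels.extend(w.word_label for w in windows)
        prov.extend(
            (rec_id, rec.subject_id, w.start_sample) for w in windows
        )

    X = (
        pd.DataFrame(np.vstack(rows), columns=cols)
        if rows
        else pd.DataFrame(np.empty((0, len(cols))), columns=cols)
    )
    provenance = pd.DataFrame(
        prov, columns=["recording_id", "subject_id", "window_start"]
    )
    return FeatureMatrix(
        X=X,
        y=np.asarray(labels, dtype=int),
        provenance=provenance,
        feature_set=spec,
        feature_params=params,
        resolved_eps=resolved,
    )


def _baseline_rms(rec: EmgRecording, segs: list[ActivationSegment]) -> float:
    mask = np.ones(rec.n_samples, dtype=bool)
    for s in segs:
        mask[s.start_sample : s.end_sample] = False
    base = rec.data[:, mask] if mask.any() else rec.data
    return float(np.sqrt(np.mean(base**2)))
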