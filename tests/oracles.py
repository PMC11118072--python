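"""Independent direct-definition oracles for the EMG window features.

Every function here recomputes a feature from its textbook definition with
plain loops / direct sums, deliberately avoiding the package's vectorised
implementations, so the two can be compared as independent routes.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_td(x: np.ndarray, eps: float) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    N = len(x)
    iemg = sum(abs(v) for v in x)
    wl = sum(abs(x[i + 1] - x[i]) for i in range(N - 1))
    zc = sum(
        1
        for i in range(N - 1)
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= eps
    )
    myop = sum(1 for v in x if abs(v) >= eps) / N
    wamp = sum(1 for i in range(N - 1) if abs(x[i + 1] - x[i]) >= eps)
    ssc = 0
    for i in range(1, N - 1):
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > 0 and (
            abs(x[i] - x[i + 1]) >= eps or abs(x[i] - x[i - 1]) >= eps
        ):
            ssc += 1
    return {
        "IEMG": iemg,
        "MAV": iemg / N,
        "VAR": sum(v * v for v in x) / (N - 1),
        "RMS": math.sqrt(sum(v * v for v in x) / N),
        "WL": wl,
        "DAMV": wl / (N - 1),
        "DASDV": math.sqrt(
            sum((x[i + 1] - x[i]) ** 2 for i in range(N - 1)) / (N - 1)
        ),
        "ZC": float(zc),
        "MYOP": myop,
        "WAMP": float(wamp),
        "SSC": float(ssc),
    }


def oracle_hist(x: np.ndarray, bins: int = 10) -> np.ndarray:
    counts, _ = np.histogram(np.asarray(x, dtype=float), bins=bins)
    return counts.astype(float)


def oracle_fuzzy_entropy(
    x: np.ndarray, m: int = 2, r_factor: float = 0.15, n_exp: float = 2.0
) -> float:
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = r_factor * sd
    n_t = len(x) - m

    def phi(mm: int) -> float:
        tpl = []
        for i in range(n_t):
            seg = x[i : i + mm]
            tpl.append(seg - seg.mean())
        total = 0.0
        for i in range(n_t):
            for j in range(n_t):
                if i == j:
                    continue
                d = max(abs(a - b) for a, b in zip(tpl[i], tpl[j]))
                total += math.exp(-((d / r) ** n_exp))
        return total / (n_t * (n_t - 1))

    return math.log(phi(m)) - math.log(phi(m + 1))


def oracle_wpe(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    x = np.asarray(x, dtype=float)
    n_vec = len(x) - (order - 1) * delay
    weights: dict[tuple, float] = {}
    total = 0.0
    for i in range(n_vec):
        vec = x[i : i + order * delay : delay]
        pattern = tuple(np.argsort(vec, kind="stable"))
        w = float(np.var(vec))
        weights[pattern] = weights.get(pattern, 0.0) + w
        total += w
    if total == 0.0:
        return 0.0
    h = -sum(
        (w / total) * math.log(w / total) for w in weights.values() if w > 0
    )
    return h / math.log(math.factorial(order))


def oracle_ar_yule_walker(x: np.ndarray, order: int = 4) -> np.ndarray:
    """AR coefficients via explicit biased-autocorrelation Toeplitz solve.

    Returns the polynomial-convention coefficients a_1..a_p of
    ``x_t + sum a_k x_{t-k} = e_t`` (negated predictor coefficients).
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    N = len(x)
    r = [float(np.dot(x[: N - k], x[k:])) / N for k in range(order + 1)]
    R = np.array([[r[abs(i - j)] for j in range(order)] for i in range(order)])
    rho = np.linalg.solve(R, np.array(r[1:]))
    return -rho


def oracle_cepstrum_from_ar(a: np.ndarray, n_coeffs: int = 4) -> np.ndarray:
    """Cepstral coefficients of the AR model 1/A(z) via the FFT route.

    The complex cepstrum of the minimum-phase AR transfer function is the
    inverse transform of log(1/A(e^{jw})), evaluated on a dense grid —
    independent of the package's recursion.
    """
    a = np.asarray(a, dtype=float)
    nfft = 8192
    poly = np.zeros(nfft)
    poly[0] = 1.0
    poly[1 : len(a) + 1] = a
    A = np.fft.fft(poly)
    c = np.fft.ifft(np.log(1.0 / A)).real
    return c[1 : n_coeffs + 1]


def oracle_periodogram(x: np.ndarray, fs: float, nfft: int) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hamming-tapered periodogram with scipy's density scaling."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()  # constant detrend, as in the implementation's PSD
    n = len(x)
    # periodic (DFT-even) Hamming window, written out from its definition
    win = 0.54 - 0.46 * np.cos(2.0 * np.pi * np.arange(n) / n)
    xw = x * win
    X = np.fft.rfft(xw, n=nfft)
    scale = 1.0 / (fs * float(np.sum(win**2)))
    P = scale * np.abs(X) ** 2
    P[1:-1] *= 2.0  # fold negative frequencies (DC and Nyquist excluded)
    f = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return f, P


def oracle_fd(
    x: np.ndarray,
    fs: float,
    nfft: int = 256,
    band=(35.0, 450.0),
    fr_split: float = 135.0,
    psr_halfwidth: int = 10,
) -> dict[str, float]:
    f, P = oracle_periodogram(x, fs, nfft)
    ttp = float(np.sum(P))
    sm = [float(np.sum(P * f**k)) for k in (1, 2, 3)]
    cum = 0.0
    mdf = f[-1]
    for fi, pi in zip(f, P):
        cum += pi
        if cum >= ttp / 2.0:
            mdf = fi
            break
    pk = int(np.argmax(P))
    low = float(np.sum(P[(f >= band[0]) & (f < fr_split)]))
    high = float(np.sum(P[(f >= fr_split) & (f <= band[1])]))
    lo, hi = max(pk - psr_halfwidth, 0), min(pk + psr_halfwidth + 1, len(P))
    return {
        "TTP": ttp,
        "SM1": sm[0],
        "SM2": sm[1],
        "SM3": sm[2],
        "MNF": sm[0] / ttp,
        "MDF": float(mdf),
        "PKF": float(f[pk]),
        "FR": low / high if high > 0 else 0.0,
        "PSR": float(np.sum(P[lo:hi])) / ttp,
        "VCF": sm[1] / ttp - (sm[0] / ttp) ** 2,
    }


def oracle_mcc(tp: float, tn: float, fp: float, fn: float) -> float:
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / den if den > 0 else 0.0
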