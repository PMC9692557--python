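"""Independent brute-force reference implementations used only by tests.

Every function here recomputes a feature from its mathematical definition
with naive loops, direct DFTs or explicit convolution-decimation — no
shared code with the package implementations they check.
"""

import math

import numpy as np


def tm(x, m):
    return abs(sum(float(v) ** m for v in x) / len(x))


def lcard(x, threshold=0.001):
    s = sorted(float(v) for v in x)
    classes = 1
    for a, b in zip(s, s[1:]):
        if b - a > threshold:
            classes += 1
    return math.log(1 + classes)


def lrmsv(x, gamma):
    p = (sum(abs(float(v)) ** gamma for v in x) / len(x)) ** (1.0 / gamma)
    return math.log(p)


def asm(x):
    n = len(x)
    total = 0.0
    for i, v in enumerate(x, start=1):
        e = 0.5 if 0.25 * n <= i <= 0.75 * n else 0.75
        total += abs(float(v)) ** e
    return total / n


def asr(x):
    return sum(abs(float(v)) ** 0.5 for v in x)


def aac(x):
    return sum(abs(float(b) - float(a)) for a, b in zip(x, x[1:])) / len(x)


def ssi(x):
    return sum(float(v) ** 2 for v in x)


def kurtosis(x):
    n = len(x)
    mean = sum(x) / n
    s = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    g = sum(((v - mean) / s) ** 4 for v in x)
    return n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * g - 3 * (n - 1) ** 2 / (
        (n - 2) * (n - 3)
    )


def sd_pop(x):
    n = len(x)
    mean = sum(x) / n
    return math.sqrt(sum((v - mean) ** 2 for v in x) / n)


def mfl(x):
    return math.log10(math.sqrt(sum((a - b) ** 2 for a, b in zip(x, x[1:]))))


def wl(x, threshold=0.05):
    diffs = [abs(b - a) for a, b in zip(x, x[1:])]
    mx = max(diffs)
    return sum(d for d in diffs if d > threshold * mx)


def mmav2(x):
    n = len(x)
    total = 0.0
    for i, v in enumerate(x, start=1):
        if 0.25 * n <= i <= 0.75 * n:
            w = 1.0
        elif i < 0.25 * n:
            w = 4 * i / n
        else:
            w = 4 * (n - i) / n
        total += w * abs(float(v))
    return total / n


def mmav5(x):
    n = len(x)
    total = 0.0
    for i, v in enumerate(x, start=1):
        r = 4 * i / n
        if i < 0.25 * n:
            w = r
        elif i <= 0.5 * n:
            w = r - 1
        elif i <= 0.75 * n:
            w = r - 2
        else:
            w = r - 3
        total += w * abs(float(v))
    return total / n


def mhw(x):
    n = len(x)
    # Hamming window by definition
    w = [0.54 - 0.46 * math.cos(2 * math.pi * i / (n - 1)) for i in range(n)]
    return sum((wi * float(v)) ** 2 for wi, v in zip(w, x))


def hjorth_complexity(x):
    def var(y):
        m = sum(y) / len(y)
        return sum((v - m) ** 2 for v in y) / len(y)

    def mob(y):
        dy = [b - a for a, b in zip(y, y[1:])]
        return math.sqrt(var(dy) / var(y))

    dx = [b - a for a, b in zip(x, x[1:])]
    return mob(dx) / mob(x)


def _dft(x):
    n = len(x)
    return [
        sum(x[t] * np.exp(-2j * np.pi * k * t / n) for t in range(n))
        for k in range(n // 2 + 1)
    ]


def spectral(x, fs):
    """Direct-DFT MMDF, SMD, SMN, MMNF, MASP."""
    n = len(x)
    xd = [v - sum(x) / n for v in x]
    X = _dft(xd)
    m = len(X)
    f = [k * fs / n for k in range(m)]
    amp, psd = [], []
    for k in range(1, m):
        scale = 1.0 if (n % 2 == 0 and k == m - 1) else 2.0
        amp.append(scale * abs(X[k]) / n)
        psd.append(scale * abs(X[k]) ** 2 / n**2)
    fq = f[1:]
    a_sum, p_sum = sum(amp), sum(psd)
    mags = [abs(v) for v in _dft(xd)]
    bands = np.array_split(np.asarray(mags), 5)
    return {
        "MMDF": 0.5 * a_sum,
        "SMD": 0.5 * p_sum,
        "SMN": sum(fi * pi for fi, pi in zip(fq, psd)) / p_sum if p_sum else 0.0,
        "MMNF": sum(fi * ai for fi, ai in zip(fq, amp)) / a_sum if a_sum else 0.0,
        "MASP": np.array([b.sum() / n for b in bands]),
    }


def yule_walker(x, order=3):
    """AR coefficients by explicit Toeplitz solve (no Levinson)."""
    from scipy.linalg import toeplitz

    xd = np.asarray(x, float)
    xd = xd - xd.mean()
    n = xd.size
    r = np.array([np.dot(xd[: n - k], xd[k:]) / n for k in range(order + 1)])
    return np.linalg.solve(toeplitz(r[:order]), r[1 : order + 1])


def lpc(x, order=3):
    from scipy.linalg import toeplitz

    xr = np.asarray(x, float)
    n = xr.size
    r = np.array([np.dot(xr[: n - k], xr[k:]) / n for k in range(order + 1)])
    b = np.linalg.solve(toeplitz(r[:order]), r[1 : order + 1])
    err = r[0] - np.dot(b, r[1 : order + 1])
    return np.concatenate(([np.sqrt(max(err, 0.0))], b))


def stft_mean(x, fs, win_frac=4):
    n = len(x)
    wlen = max(n // win_frac, 8)
    hop = max(wlen // 2, 1)
    w = [0.54 - 0.46 * math.cos(2 * math.pi * i / (wlen - 1)) for i in range(wlen)]
    mags = []
    for s in range(0, n - wlen + 1, hop):
        frame = [x[s + i] * w[i] for i in range(wlen)]
        for k in range(wlen // 2 + 1):
            mags.append(
                abs(sum(frame[t] * np.exp(-2j * np.pi * k * t / wlen) for t in range(wlen)))
            )
    return float(np.mean(mags))


def stockwell_mean(x):
    """Direct double-loop discrete S-transform mean magnitude."""
    x = np.asarray(x, float)
    n = x.size
    X = np.fft.fft(x)
    m = np.fft.fftfreq(n) * n
    rows = [np.full(n, np.mean(x), dtype=complex)]
    for k in range(1, n // 2 + 1):
        gauss = np.exp(-2 * np.pi**2 * m**2 / k**2)
        shifted = np.array([X[(k + j) % n] for j in range(n)])
        voice = np.array(
            [np.sum(shifted * gauss * np.exp(2j * np.pi * m * tau / n)) / n for tau in range(n)]
        )
        rows.append(voice)
    return float(np.mean(np.abs(np.vstack(rows))))


def wavelet_packet_energies(x, wavelet_name, level):
    """Convolution-decimation cascade with zero extension (packet tree)."""
    import pywt

    w = pywt.Wavelet(wavelet_name)

    def split(y):
        lo = np.convolve(y, w.dec_lo)[1::2]
        hi = np.convolve(y, w.dec_hi)[1::2]
        return lo, hi

    nodes = [np.asarray(x, float)]
    for _ in range(level):
        nxt = []
        for y in nodes:
            lo, hi = split(y)
            nxt.extend([lo, hi])
        nodes = nxt
    return np.array([np.mean(y**2) for y in nodes])


def higuchi_fd(x, kmax=8):
    x = [float(v) for v in x]
    n = len(x)
    logs = []
    for k in range(1, kmax + 1):
        lm = []
        for m in range(k):
            idx = list(range(m, n, k))
            if len(idx) < 2:
                continue
            dist = sum(abs(x[idx[i]] - x[idx[i - 1]]) for i in range(1, len(idx)))
            lm.append(dist * (n - 1) / ((len(idx) - 1) * k) / k)
        if lm and sum(lm) > 0:
            logs.append((math.log(1.0 / k), math.log(sum(lm) / len(lm))))
    xs = [p[0] for p in logs]
    ys = [p[1] for p in logs]
    xm, ym = sum(xs) / len(xs), sum(ys) / len(ys)
    slope = sum((a - xm) * (b - ym) for a, b in zip(xs, ys)) / sum((a - xm) ** 2 for a in xs)
    return min(max(slope, 1.0), 2.0)  # same clamp convention as the feature


def fer4(seg_x, channel_names=("FCR", "FCU", "APB", "EDC")):
    mav = [np.mean(np.abs(ch)) for ch in seg_x]
    edc = mav[channel_names.index("EDC")]
    ratios = [m / edc for m in mav]
    mx = max(ratios)
    return [r / mx for r in ratios]


def hilbert_weighted_freq(imf, fs):
    """Analytic signal by direct DFT construction, then the weighted mean
    instantaneous frequency — independent of scipy.signal.hilbert."""
    imf = np.asarray(imf, float)
    n = imf.size
    X = np.fft.fft(imf)
    h = np.zeros(n)
    h[0] = 1
    if n % 2 == 0:
        h[n // 2] = 1
        h[1 : n // 2] = 2
    else:
        h[1 : (n + 1) // 2] = 2
    analytic = np.fft.ifft(X * h)
    a = np.abs(analytic)
    phase = np.unwrap(np.angle(analytic))
    inst_f = np.diff(phase) * fs / (2 * np.pi)
    wts = (0.5 * (a[:-1] + a[1:])) ** 2
    return float(np.sum(wts * inst_f) / np.sum(wts))
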