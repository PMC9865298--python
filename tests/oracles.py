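"""Independent brute-force oracles used by the test suite.

Deliberately written in plain Python loops, straight off the feature and
metric definitions, with no shared code with the package implementation.
"""

import math


def brute_force_features(window, static_window):
    """All 13 feature families of one per-axis sample list."""
    a = [float(x) for x in window]
    s = [float(x) for x in static_window]
    n = len(a)
    mu = sum(a) / n
    var = sum((x - mu) ** 2 for x in a) / n
    std = math.sqrt(var)
    mav = sum(abs(x) for x in a) / n
    mx = max(a)
    mn = min(a)
    ssi = sum(x * x for x in a)
    rms = math.sqrt(ssi / n)
    if ssi > 0:
        went = 0.0
        for x in a:
            p = x * x / ssi
            if p > 0:
                went -= p * math.log(p)
    else:
        went = 0.0
    if std > 1e-12:
        skew = sum((x - mu) ** 3 for x in a) / n / std**3
        kurt = sum((x - mu) ** 4 for x in a) / n / std**4
    else:
        skew = 0.0
        kurt = 0.0
    dac = mx - mn
    sac = max(s) - min(s)
    lee = sum(math.log2(x * x + 1e-12) for x in a)
    return {
        "MAV": mav, "STD": std, "VAR": var, "MAX": mx, "MIN": mn,
        "RMS": rms, "SSI": ssi, "WENT": went, "SKEW": skew, "KURT": kurt,
        "DAC": dac, "SAC": sac, "LEE": lee,
    }


def brute_force_binary_metrics(tp, tn, fp, fn):
    """Accuracy/precision/recall/F1 straight from the one-vs-rest counts."""
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "f1": 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0,
    }


def butterworth_magnitude(f, cutoff, order):
    """Closed-form analog Butterworth |H(jf)|."""
    return 1.0 / math.sqrt(1.0 + (f / cutoff) ** (2 * order))
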