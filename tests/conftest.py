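import numpy as np
import pytest

from shiftdiscrim import load_builtin_fixtures, evaluate_candidate

PW91 = "B3PW91/DGDZVP"
B3LYP = "B3LYP/6-31+G(d,p)"
B3LYP_31G = "B3LYP/6-31G(d,p)"


@pytest.fixture(scope="session")
def builtin():
    return load_builtin_fixtures()


@pytest.fixture(scope="session")
def builtin_scores(builtin):
    return [evaluate_candidate(t) for t in builtin]


def loo_press_explicit(x, y):
    """Independent leave-one-out oracle: literally refit n separate
    regressions with numpy.polyfit and sum the squared prediction errors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    press = 0.0
    preds = []
    for i in range(len(x)):
        keep = np.ones(len(x), dtype=bool)
        keep[i] = False
        slope, intercept = np.polyfit(x[keep], y[keep], 1)
        pred = slope * x[i] + intercept
        preds.append(pred)
        press += (y[i] - pred) ** 2
    return press, np.asarray(preds)
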