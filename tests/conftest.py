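import numpy as np
import pytest

uM = 1e-6
nM = 1e-9


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def write_titration_csv(path, x, signals, x_blank=None, blanks=None):
    """Write a long-format titration CSV (x, signal, replicate [, blank])."""
    import pandas as pd

    rows = []
    for i, xv in enumerate(np.asarray(x)):
        for j in range(np.asarray(signals).shape[1]):
            rows.append({"x": xv, "signal": signals[i, j], "replicate": j + 1,
                         "blank": 0})
    if blanks is not None:
        for j, b in enumerate(np.asarray(blanks)):
            rows.append({"x": 0.0 if x_blank is None else x_blank,
                         "signal": b, "replicate": j + 1, "blank": 1})
    df = pd.DataFrame(rows)
    if blanks is None:
        df = df.drop(columns=["blank"])
    df.to_csv(path, index=False)
    return path
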