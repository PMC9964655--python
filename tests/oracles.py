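"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the classifier
oracle evaluates the Boolean equations literally, the correlation oracle
is an O(N^2) double loop, and the ANOVA oracle computes sequential sums
of squares by explicit least-squares fits of nested design matrices.
"""

import numpy as np
import pandas as pd


def classify_oracle(nemg_ed, nemg_fds, epsilon, mu):
    """Literal truth-table evaluation of REST/OPEN/CLOSE (strict comparisons)."""
    a = nemg_ed > epsilon
    b = nemg_fds > mu
    c = nemg_ed > nemg_fds
    rest = (not a) and (not b)
    open_ = a and ((not b) or c)
    close = b and ((not a) or (not c))
    assert rest + open_ + close == 1, "outputs must be mutually exclusive"
    if rest:
        return 0
    return -1 if open_ else 1


def xcorr_oracle(x, y):
    """r_xy(h) = sum_n x(n+h) y(n) for h = 0..N-1, by double loop."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    out = np.zeros(n)
    for h in range(n):
        s = 0.0
        for i in range(n - h):
            s += x[i + h] * y[i]
        out[h] = s
    return out


def _dummies(labels):
    labels = pd.Series(labels).astype(str)
    levels = sorted(labels.unique())
    return np.column_stack([(labels == lv).to_numpy(float) for lv in levels[1:]])


def sequential_ss_oracle(table):
    """Type I sums of squares for d_l2 ~ test + order + subject via nested fits."""
    y = table["d_l2"].to_numpy(float)
    n = len(y)
    blocks = [
        np.ones((n, 1)),
        _dummies(table["test"]),
        _dummies(table["order"]),
        _dummies(table["subject"]),
    ]

    def rss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        r = y - x @ beta
        return float(r @ r)

    ss = []
    prev = rss(blocks[0])
    x = blocks[0]
    for blk in blocks[1:]:
        x = np.hstack([x, blk])
        cur = rss(x)
        ss.append(prev - cur)
        prev = cur
    return {"Test": ss[0], "Order": ss[1], "Individual": ss[2], "Residuals": prev}
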