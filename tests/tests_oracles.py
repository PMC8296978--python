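"""Shared independent oracles for the test suite.

These deliberately avoid the library code paths they verify.
"""

import numpy as np


def spearman_oracle(x, y):
    """Average-tie ranks, then Pearson by hand."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        sv = np.asarray(v)[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2)))
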