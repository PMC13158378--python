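"""Shared test utilities."""

import numpy as np

from falff.io import BoldRun


def run_from_series(series, tr=0.8):
    """Wrap (n_series, t) rows as a degenerate spatial BoldRun."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    v, t = series.shape
    data = series.reshape(v, 1, 1, t)
    return BoldRun(data, tr, np.eye(4), np.ones((v, 1, 1), bool))
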