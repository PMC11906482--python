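"""IC50 <-> score transform and threshold labelling.

Binding-affinity assays report half-maximal inhibitory concentrations
(IC50, nanomolar; lower = stronger binding).  Regression targets use the
log-transform

    score = 1 - ln(IC50) / ln(50000)

which maps 50000 nM -> 0 and 1 nM -> 1 and is strictly decreasing in
IC50.  Scores are deliberately not clipped to [0, 1]: the transform is
unbounded and clipping would bias the mean-squared-error target.

Classification labels use the conventional 500 nM cut-off: IC50 < 500 nM
is a binder (label 1), IC50 >= 500 nM a non-binder (label 0).
"""

from __future__ import annotations

import math

import numpy as np

#: Reference concentration (nM) mapped to score 0.
IC50_MAX = 50000.0
#: Binder/non-binder IC50 threshold in nM.
BINDER_THRESHOLD_NM = 500.0

_LN_MAX = math.log(IC50_MAX)


def ic50_to_score(ic50):
    """Transform IC50 (nM) to the log-affinity score.

    Accepts scalars or arrays; rejects non-positive concentrations.
    """
    arr = np.asarray(ic50, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("IC50 must be positive (nM)")
    out = 1.0 - np.log(arr) / _LN_MAX
    return float(out) if np.isscalar(ic50) or arr.ndim == 0 else out


def score_to_ic50(score):
    """Inverse transform: IC50 = 50000^(1 - score) nM."""
    arr = np.asarray(score, dtype=np.float64)
    out = np.exp(_LN_MAX * (1.0 - arr))
    return float(out) if np.isscalar(score) or arr.ndim == 0 else out


def label_by_threshold(ic50, threshold: float = BINDER_THRESHOLD_NM):
    """Binary binder label: 1 iff IC50 < *threshold* (nM)."""
    arr = np.asarray(ic50, dtype=np.float64)
    if np.any(arr <= 0):
        raise ValueError("IC50 must be positive (nM)")
    out = (arr < threshold).astype(np.int64)
    return int(out) if np.isscalar(ic50) or arr.ndim == 0 else out


#: Score corresponding to the 500 nM binder threshold (~0.4256); the
#: default cut-off for pruning implausible decoy negatives in curation.
BINDER_SCORE = ic50_to_score(BINDER_THRESHOLD_NM)
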