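"""TMM between-sample normalization and detection flags.

Implements the trimmed mean of M-values at formula level: for each sample
against a reference sample, log ratios M and average intensities A are
computed over features nonzero in both libraries, doubly trimmed (30% of M
on each side, 5% of A), and combined into a precision-weighted mean whose
antilog is the sample's scaling factor.  Factors are rescaled to geometric
mean 1.  Expression is reported as TMM-scaled counts per million.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

TRIM_M = 0.30
TRIM_A = 0.05


@dataclass
class NormalizationFactors:
    factors: pd.Series        # per-sample factor, geometric mean 1
    reference: str            # reference sample id

    def report(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": self.factors.index,
            "factor": self.factors.to_numpy(),
            "is_reference": [s == self.reference for s in self.factors.index],
        })


def _choose_reference(counts: pd.DataFrame) -> str:
    """Sample whose 75th-percentile count fraction is closest to the mean."""
    frac = counts.to_numpy(dtype=float) / counts.sum(axis=0).to_numpy(dtype=float)
    q75 = np.percentile(frac, 75, axis=0)
    return counts.columns[int(np.argmin(np.abs(q75 - q75.mean())))]


def _pair_factor(x: np.ndarray, xr: np.ndarray, n: float, nr: float) -> float:
    """log2 TMM factor of one sample against the reference."""
    keep = (x > 0) & (xr > 0)
    x, xr = x[keep], xr[keep]
    if x.size == 0:
        return 0.0
    p, pr = x / n, xr / nr
    m = np.log2(p / pr)
    a = 0.5 * np.log2(p * pr)
    nfeat = m.size
    lo_m = np.floor(nfeat * TRIM_M) + 1
    hi_m = nfeat + 1 - lo_m
    lo_a = np.floor(nfeat * TRIM_A) + 1
    hi_a = nfeat + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not sel.any():
        return 0.0
    w = 1.0 / ((n - x[sel]) / (n * x[sel]) + (nr - xr[sel]) / (nr * xr[sel]))
    return float(np.sum(w * m[sel]) / np.sum(w))


def tmm_factors(counts: pd.DataFrame) -> NormalizationFactors:
    """Compute per-sample TMM factors for a feature x sample count matrix.

    Requires at least two samples; a sample with all-zero counts is an error
    (its library size is undefined).
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    libsize = counts.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has all-zero counts")
    ref = _choose_reference(counts)
    xr = counts[ref].to_numpy(dtype=float)
    nr = float(libsize[ref])
    logf = {}
    for s in counts.columns:
        if s == ref:
            logf[s] = 0.0
        else:
            logf[s] = _pair_factor(counts[s].to_numpy(dtype=float), xr,
                                   float(libsize[s]), nr)
    f = pd.Series({s: 2.0 ** v for s, v in logf.items()})[counts.columns]
    f /= np.exp(np.mean(np.log(f)))   # geometric mean 1
    return NormalizationFactors(f, ref)


def normalize(counts: pd.DataFrame, factors: NormalizationFactors) -> pd.DataFrame:
    """TMM-scaled counts per million: e_ij = x_ij / (N_j * f_j) * 1e6."""
    libsize = counts.sum(axis=0).astype(float)
    denom = libsize * factors.factors[counts.columns]
    return counts / denom * 1e6


def detection_flags(counts: pd.DataFrame, min_count: int = 5) -> pd.DataFrame:
    """A locus is detected in a sample when its count reaches ``min_count``."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return counts >= min_count
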