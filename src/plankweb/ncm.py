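"""Sloan neutral community model: occupancy-abundance fitting.

The model predicts the occurrence frequency of a taxon across local
communities from its mean relative abundance p in the metacommunity.  With
community size N (reads) and migration rate m, the stationary local relative
abundance of the taxon is Beta(N m p, N m (1 - p)); the taxon is detected
when its abundance exceeds a detection limit d, so

    predicted_freq(p) = 1 - I_d(N m p, N m (1 - p))

with I the regularized incomplete beta function.  m is estimated by
nonlinear least squares of observed frequencies against this curve and N is
the mean library size.  The default detection limit is d = ln(2)/N: under
binomial sampling of N reads a taxon at local relative abundance a appears
with probability 1 - (1 - a)^N, which crosses one half at a = ln(2)/N, so
this d is the median-detection threshold the step-function model
approximates (the one-read convention d = 1/N overstates the limit and
biases m upward; it remains available via ``detection_limit``).  Fit
quality is
R^2 = 1 - SSE/SStot; taxa are classified against a binomial (Wilson)
confidence band around the predicted frequency at the number of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .otu import OtuTable


@dataclass
class NcmFit:
    m: float
    n_reads: float                  # community size N used in the fit
    nm: float                       # N * m
    detection_limit: float          # d, relative abundance of one read
    r_squared: float
    ci_level: float
    per_otu: pd.DataFrame           # p, freq, predicted, lower, upper, otu_class
    n_excluded: int                 # taxa with p = 0 or freq = 0

    @property
    def class_counts(self) -> dict:
        return self.per_otu["otu_class"].value_counts().to_dict()

    def to_json_dict(self) -> dict:
        return {
            "m": self.m,
            "N": self.n_reads,
            "Nm": self.nm,
            "d": self.detection_limit,
            "R2": self.r_squared,
            "ci_level": self.ci_level,
            "n_otus": int(len(self.per_otu)),
            "n_excluded": self.n_excluded,
            "class_counts": {k: int(v) for k, v in self.class_counts.items()},
        }


def occupancy_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-taxon mean relative abundance ``p`` and occurrence frequency
    ``freq`` (fraction of samples with a positive count)."""
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rel = table.relative_abundance()
    return pd.DataFrame(
        {"p": rel.mean(axis=1), "freq": (table.counts > 0).mean(axis=1)}
    )


def ncm_predict(p, n_reads: float, m: float, detection_limit: float):
    """Predicted occurrence frequency under the neutral model.

    ``p`` may be a scalar or array of metacommunity relative abundances in
    (0, 1).
    """
    p = np.asarray(p, float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1)")
    if not 0 < detection_limit < 1:
        raise ValueError("detection limit must lie in (0, 1)")
    if n_reads * m <= 0:
        raise ValueError("N*m must be positive")
    nm = n_reads * m
    return beta_dist.sf(detection_limit, nm * p, nm * (1.0 - p))


def _wilson_band(freq_hat: np.ndarray, n: int, ci_level: float):
    """Wilson score interval around a predicted binomial proportion."""
    z = norm.ppf(0.5 + ci_level / 2.0)
    denom = 1.0 + z**2 / n
    center = (freq_hat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(freq_hat * (1 - freq_hat) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


def ncm_fit(
    table: OtuTable,
    ci_level: float = 0.95,
    detection_limit: float | None = None,
) -> NcmFit:
    """Fit the neutral model to a count table and classify taxa against the
    confidence band.

    ``detection_limit`` defaults to ln(2)/N, the median-detection abundance
    of a library of N reads; pass 1/N for the one-read convention.  Taxa
    with zero mean abundance or zero occurrence carry no information on the
    occupancy curve and are excluded (their number is reported).
    """
    occ = occupancy_abundance(table)
    n_total = len(occ)
    usable = occ[(occ["p"] > 0) & (occ["p"] < 1) & (occ["freq"] > 0)]
    n_excluded = n_total - len(usable)
    if len(usable) < 20:
        warnings.warn(f"only {len(usable)} informative taxa; fit may be unstable")
    if len(usable) < 2 or usable["freq"].nunique() == 1:
        raise ValueError("no variation in occurrence frequencies; cannot fit")

    n_reads = float(table.sample_totals().mean())
    d = float(detection_limit) if detection_limit is not None else np.log(2.0) / n_reads
    p = usable["p"].to_numpy()
    freq = usable["freq"].to_numpy()

    def sse(m: float) -> float:
        return float(np.sum((freq - ncm_predict(p, n_reads, m, d)) ** 2))

    result = minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded",
                             options={"xatol": 1e-8})
    if not result.success:
        raise RuntimeError(f"neutral-model fit did not converge (last m={result.x})")
    m_hat = float(result.x)
    predicted = ncm_predict(p, n_reads, m_hat, d)
    ss_res = float(np.sum((freq - predicted) ** 2))
    ss_tot = float(np.sum((freq - freq.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot

    lower, upper = _wilson_band(predicted, table.n_samples, ci_level)
    tol = 1e-9  # guard float round-off at the band edges (upper is exactly 1 when predicted is 1)
    otu_class = np.where(
        freq > upper + tol, "above", np.where(freq < lower - tol, "below", "within")
    )
    per_otu = usable.assign(
        predicted=predicted, lower=lower, upper=upper, otu_class=otu_class
    )
    return NcmFit(
        m=m_hat,
        n_reads=n_reads,
        nm=n_reads * m_hat,
        detection_limit=d,
        r_squared=r_squared,
        ci_level=ci_level,
        per_otu=per_otu,
        n_excluded=n_excluded,
    )
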