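"""Colour/intensity outlier exclusion.

A normal model is fitted to the *relative* colour intensities of objects
that were not split out of a cluster (cluster_size == 1) — these are the
detections least likely to be false positives.  Each object's relative
intensity is its per-channel median divided by the channel sum, which
cancels overall illumination scale.  Objects whose likelihood under the
fitted model falls below a user-controlled quantile cutoff are flagged
as excluded (they remain in the detailed output, marked).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import PostfilterParams

log = logging.getLogger(__name__)

__all__ = ["ColourModel", "relative_intensity", "fit_colour_model",
           "filter_by_likelihood"]


@dataclass
class ColourModel:
    mean: np.ndarray   #: per-channel mean of relative intensities
    sd: np.ndarray     #: per-channel sd, floored at sd_floor
    n_fit: int         #: number of (non-split) objects used
    usable: bool       #: False -> the filter passes everything


def relative_intensity(medians) -> np.ndarray:
    """Channel medians normalised by their sum (illumination-scale-free).

    An all-zero object (no measurable colour) maps to the uniform vector.
    """
    m = np.asarray(medians, dtype=np.float64)
    s = m.sum()
    if s <= 0:
        return np.full(m.shape, 1.0 / m.size)
    return m / s


def fit_colour_model(median_colours, cluster_sizes,
                     params: PostfilterParams | None = None) -> ColourModel:
    """Fit per-channel independent normals on non-split objects.

    Parameters
    ----------
    median_colours : (N, C) array of per-object channel medians
    cluster_sizes : (N,) array; only rows with cluster size 1 are used

    With fewer than 3 non-split objects the model is marked unusable and
    the downstream filter passes everything (with a warning).
    """
    params = params or PostfilterParams()
    medians = np.atleast_2d(np.asarray(median_colours, dtype=np.float64))
    sizes = np.asarray(cluster_sizes)
    if medians.shape[0] == 0:
        return ColourModel(np.zeros(3), np.ones(3), 0, usable=False)
    rel = np.vstack([relative_intensity(m) for m in medians])
    fit = rel[sizes == 1]
    if fit.shape[0] < 3:
        log.warning("colour filter disabled: only %d non-split objects",
                    fit.shape[0])
        return ColourModel(np.zeros(rel.shape[1]), np.ones(rel.shape[1]),
                           int(fit.shape[0]), usable=False)
    mean = fit.mean(axis=0)
    sd = np.maximum(fit.std(axis=0, ddof=0), params.sd_floor)
    return ColourModel(mean=mean, sd=sd, n_fit=int(fit.shape[0]), usable=True)


def filter_by_likelihood(median_colours, model: ColourModel,
                         cutoff: float) -> np.ndarray:
    """Boolean mask of objects to EXCLUDE at the given quantile cutoff.

    The likelihood of an object is the product of the per-channel normal
    densities at its relative intensity; because that product decreases
    monotonically in the squared Mahalanobis distance
    ``s = sum(((x - mean) / sd)**2)``, thresholding it at the cutoff
    quantile of the model's own density is equivalent to excluding
    objects with ``chi2.sf(s, df=C) < cutoff``.  ``cutoff = 0`` excludes
    nothing; an object exactly at the model mean is never excluded for
    any cutoff < 1.
    """
    medians = np.atleast_2d(np.asarray(median_colours, dtype=np.float64))
    if not model.usable or medians.shape[0] == 0:
        return np.zeros(medians.shape[0], dtype=bool)
    if not 0.0 <= cutoff < 1.0:
        raise ValueError("cutoff must be in [0, 1)")
    rel = np.vstack([relative_intensity(m) for m in medians])
    z2 = (((rel - model.mean) / model.sd) ** 2).sum(axis=1)
    tail = stats.chi2.sf(z2, df=rel.shape[1])
    return tail < cutoff
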