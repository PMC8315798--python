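"""Functional connectivity statistics: FC, GBC, loading, E/I ratio.

GBC (global brain connectivity) summarizes each parcel's mean functional
coupling: off-diagonal Pearson correlations are Fisher r-to-Z transformed
and averaged along rows. The change map (perturbed minus baseline GBC) is
compared to an empirical target through its "loading" — the dot product
with the target divided by the target's squared norm — which is sensitive
to both topography and magnitude of the perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import SteadyState

__all__ = [
    "BrainMap",
    "cov_to_fc",
    "gbc",
    "delta_gbc",
    "loading",
    "ei_ratio",
    "spearman",
]

_FISHER_CLIP = 1.0 - 1e-12


@dataclass
class BrainMap:
    """A parcel-keyed scalar map (expression, GBC, PC, beta, ...)."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be a 1-D vector")
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != self.values.size:
            raise ValueError("labels length must match values")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    def align_to(self, labels: list[str]) -> "BrainMap":
        """Reorder values to match a reference label order."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"labels not in map: {missing[:5]}")
        vals = self.values[[index[lab] for lab in labels]]
        return BrainMap(values=vals, labels=list(labels))


def _check_labels(a: BrainMap, b: BrainMap) -> None:
    if a.labels != b.labels:
        raise ValueError("brain maps have mismatched parcel labels")


def cov_to_fc(cov: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix from a covariance matrix."""
    cov = np.asarray(cov, dtype=float)
    d = np.diag(cov)
    if np.any(d <= 0):
        raise ValueError("covariance has non-positive variance on the diagonal")
    s = np.sqrt(d)
    r = cov / np.outer(s, s)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


def gbc(fc: np.ndarray, labels: list[str] | None = None) -> BrainMap:
    """Mean Fisher-Z off-diagonal correlation per parcel (row means)."""
    fc = np.asarray(fc, dtype=float)
    n = fc.shape[0]
    if n < 2:
        raise ValueError("GBC needs at least two parcels")
    z = np.arctanh(np.clip(fc, -_FISHER_CLIP, _FISHER_CLIP))
    np.fill_diagonal(z, 0.0)
    vals = z.sum(axis=1) / (n - 1)
    if labels is None:
        labels = [f"parcel{i:03d}" for i in range(n)]
    return BrainMap(values=vals, labels=list(labels))


def delta_gbc(perturbed: BrainMap, baseline: BrainMap) -> BrainMap:
    """Perturbed-minus-baseline GBC difference map."""
    _check_labels(perturbed, baseline)
    return BrainMap(values=perturbed.values - baseline.values, labels=perturbed.labels)


def loading(model_map: BrainMap, empirical_map: BrainMap) -> float:
    """<model, empirical> / <empirical, empirical>."""
    _check_labels(model_map, empirical_map)
    denom = float(empirical_map.values @ empirical_map.values)
    if denom == 0:
        raise ValueError("empirical map is identically zero")
    return float(model_map.values @ empirical_map.values) / denom


def ei_ratio(perturbed: SteadyState, baseline: SteadyState) -> float:
    """E/I firing-rate ratio of the perturbed state relative to baseline.

    E/I ratio is mean excitatory rate across nodes over mean inhibitory
    rate; the return value is the perturbed ratio divided by the baseline
    ratio (1.0 means unchanged).
    """
    for ss in (perturbed, baseline):
        if np.mean(ss.r_I) == 0:
            raise ValueError("mean inhibitory rate is zero")
    rp = np.mean(perturbed.r_E) / np.mean(perturbed.r_I)
    rb = np.mean(baseline.r_E) / np.mean(baseline.r_I)
    return float(rp / rb)


def spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("inputs must be equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)
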