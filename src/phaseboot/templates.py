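"""Cosine template bank and maximal-correlation peak-time estimation.

A gene whose baseline expression oscillates with period ``T`` (24 h for a
circadian gene) is approximated by an ideal cosine wave

    C_phi(t) = cos(2*pi*t/T - phi),

whose first peak falls at theta = phi*T/(2*pi) hours.  With ``2k`` templates
at phases phi_i = i*pi/k the template peaks land exactly on the grid
{i*T/(2k)}; at the defaults (T=24 h, k=3) this is {0,4,8,12,16,20} h, i.e.
the sampling grid of a 4-h design, which is the whole point: the method asks
whether a gene's peak can be pinned to one observation time.

The peak-time estimate is the peak of the best-correlated template
(arg-max of the Pearson correlation between the series and each template).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DegenerateSeriesError",
    "ExpressionSeries",
    "CosineTemplate",
    "TemplateSet",
    "PhaseEstimate",
    "PhaseBin",
    "default_timepoints",
    "generate_templates",
    "phase_bins",
    "correlation_vector",
    "estimate_phase",
]


class DegenerateSeriesError(ValueError):
    """Raised when a series has zero variance, so correlation is undefined."""


def default_timepoints(n: int = 12, spacing: float = 4.0) -> np.ndarray:
    """Sampling times 0, spacing, ..., spacing*(n-1) hours (default 0..44 h)."""
    return np.arange(n, dtype=float) * spacing


@dataclass(frozen=True)
class ExpressionSeries:
    """One gene's ordered measurements with their sampling times (hours)."""

    gene_id: str
    values: np.ndarray
    timepoints: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        tp = self.timepoints
        tp = default_timepoints(len(values)) if tp is None else np.asarray(tp, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "timepoints", tp)
        if values.ndim != 1 or len(values) != len(tp):
            raise ValueError("values and timepoints must be 1-D and the same length")
        if len(values) < 4:
            raise ValueError("need at least 4 timepoints")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite values in series {self.gene_id!r}")
        if not np.all(np.diff(tp) > 0):
            raise ValueError("timepoints must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CosineTemplate:
    """An ideal cosine wave cos(2*pi*t/T - phi) evaluated on the sampling grid."""

    phase_phi: float
    peak_time: float
    values: np.ndarray


@dataclass(frozen=True)
class TemplateSet:
    """The bank of 2k cosine templates with phases i*pi/k, i = 0..2k-1."""

    period_T: float
    k: int
    timepoints: np.ndarray
    templates: tuple[CosineTemplate, ...]

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def phases(self) -> np.ndarray:
        return np.array([t.phase_phi for t in self.templates])

    @property
    def peak_times(self) -> np.ndarray:
        return np.array([t.peak_time for t in self.templates])

    @property
    def matrix(self) -> np.ndarray:
        """(2k, n) array of template values; rows follow template order."""
        return np.vstack([t.values for t in self.templates])

    def standardized_matrix(self) -> np.ndarray:
        """Rows centred and scaled to unit norm, for fast batch Pearson."""
        m = self.matrix - self.matrix.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(m, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise DegenerateSeriesError("a template is constant on this grid")
        return m / norms


@dataclass(frozen=True)
class PhaseEstimate:
    """Best correlation rho_hat, its template phase phi_hat, peak time theta_hat (h)."""

    rho_hat: float
    phi_hat: float
    theta_hat: float


@dataclass(frozen=True)
class PhaseBin:
    """A peak-time bin G_i = [i*T/(2k) - T/(4k), i*T/(2k) + T/(4k)] hours."""

    label: str
    lower: float
    upper: float

    @property
    def center(self) -> float:
        return 0.5 * (self.lower + self.upper)


def generate_templates(
    timepoints: Sequence[float] | None = None,
    period_T: float = 24.0,
    k: int = 3,
) -> TemplateSet:
    """Build the bank of 2k cosine templates evaluated at ``timepoints``.

    Parameters
    ----------
    timepoints : sequence of hours, default 0,4,...,44
    period_T : oscillation period in hours (24 for circadian)
    k : resolution; phases are {i*pi/k}, giving 2k templates whose peak
        times i*T/(2k) are spaced T/(2k) hours apart.
    """
    if period_T <= 0:
        raise ValueError(f"period_T must be positive, got {period_T}")
    if not (isinstance(k, (int, np.integer)) and k >= 1):
        raise ValueError(f"k must be a positive integer, got {k!r}")
    tp = default_timepoints() if timepoints is None else np.asarray(timepoints, dtype=float)
    if tp.size == 0:
        raise ValueError("timepoints must be nonempty")
    templates = []
    for i in range(2 * k):
        phi = i * np.pi / k
        values = np.cos(2.0 * np.pi * tp / period_T - phi)
        peak = phi * period_T / (2.0 * np.pi)
        templates.append(CosineTemplate(phase_phi=phi, peak_time=peak, values=values))
    return TemplateSet(period_T=float(period_T), k=int(k), timepoints=tp,
                       templates=tuple(templates))


def phase_bins(period_T: float = 24.0, k: int = 3) -> list[PhaseBin]:
    """Peak-time bins G0..G(2k-1), width T/(2k), centred on the template peaks.

    Defaults reproduce G0=[-2,2], G1=[2,6], ..., G5=[18,22].  G0 straddles
    zero; containment tests treat it circularly (see inference.assign_phase).
    """
    if period_T <= 0 or k < 1:
        raise ValueError("period_T must be positive and k >= 1")
    half = period_T / (4.0 * k)
    bins = []
    for i in range(2 * k):
        center = i * period_T / (2.0 * k)
        bins.append(PhaseBin(label=f"G{i}", lower=center - half, upper=center + half))
    return bins


def _as_values(series) -> np.ndarray:
    if isinstance(series, ExpressionSeries):
        return series.values
    return np.asarray(series, dtype=float)


def correlation_vector(
    series, templates: TemplateSet, method: str = "pearson"
) -> np.ndarray:
    """Correlation of the series with each template, in template order.

    Pearson by default (a cosine-template Pearson fit is the correlation
    analogue of cosinor fitting); ``method="spearman"`` is available but
    not the default.  Raises :class:`DegenerateSeriesError` for a constant
    series, where correlation is undefined.
    """
    x = _as_values(series)
    tmat = templates.matrix
    if x.shape[0] != tmat.shape[1]:
        raise ValueError(
            f"series length {x.shape[0]} does not match template length {tmat.shape[1]}"
        )
    if np.ptp(x) == 0:
        raise DegenerateSeriesError("constant series: correlation undefined")
    if method == "pearson":
        xc = x - x.mean()
        xc = xc / np.linalg.norm(xc)
        return np.clip(templates.standardized_matrix() @ xc, -1.0, 1.0)
    if method == "spearman":
        return np.array([stats.spearmanr(x, row).statistic for row in tmat])
    raise ValueError(f"unknown correlation method {method!r}")


def estimate_phase(
    series, templates: TemplateSet, method: str = "pearson"
) -> PhaseEstimate:
    """Peak-time estimate from the best-correlated template.

    rho_hat = max_i corr(series, template_i); phi_hat is the arg-max phase
    (ties broken toward the smallest phase); theta_hat = phi_hat*T/(2*pi).
    """
    corr = correlation_vector(series, templates, method=method)
    i = int(np.argmax(corr))  # argmax takes the first maximum -> smallest phi
    best = templates.templates[i]
    return PhaseEstimate(rho_hat=float(corr[i]), phi_hat=best.phase_phi,
                         theta_hat=best.peak_time)
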