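"""Longitudinal study designs: measurement occasions and sample size.

A design is the half of a latent growth curve power analysis that the
investigator controls: *when* the M measurement occasions happen (in years,
relative to an arbitrary origin; the intercept is defined at time 0) and how
many subjects are observed. Two occasions suffice for the closed-form
precision indices; model fitting additionally requires M >= 3 for
identification, which is enforced at the fitting layer, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

__all__ = ["StudyDesign", "shift_design", "scale_design", "center_design"]


@dataclass(frozen=True)
class StudyDesign:
    """Measurement occasions ``times`` (years) and optional sample size.

    Parameters
    ----------
    times
        Strictly increasing, finite occasion times ``t_1 < ... < t_M`` with
        M >= 2. Units are years throughout the package.
    n_subjects
        Number of subjects N. Optional: precision and reliability indices do
        not depend on N; it is required once power or simulation is requested.
    """

    times: tuple[float, ...]
    n_subjects: Optional[int] = None

    def __init__(self, times: Iterable[float], n_subjects: Optional[int] = None):
        times = tuple(float(t) for t in times)
        if len(times) < 2:
            raise ValueError(f"a design needs at least 2 occasions, got {len(times)}")
        if not all(math.isfinite(t) for t in times):
            raise ValueError("occasion times must be finite")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("occasion times must be strictly increasing")
        if n_subjects is not None:
            n_subjects = int(n_subjects)
            if n_subjects < 1:
                raise ValueError("n_subjects must be a positive integer")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "n_subjects", n_subjects)

    @property
    def n_occasions(self) -> int:
        """Number of measurement occasions M."""
        return len(self.times)

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def mean_time(self) -> float:
        """Mean occasion time t-bar (years)."""
        return float(np.mean(self.times_array))

    @property
    def sst(self) -> float:
        """Sum of squared deviations of occasion times about their mean (years^2)."""
        t = self.times_array
        return float(np.sum((t - t.mean()) ** 2))

    @property
    def dispersion(self) -> float:
        """Sample variance of the occasion times, SST/(M-1) (years^2)."""
        return self.sst / (self.n_occasions - 1)

    def with_n(self, n_subjects: int) -> "StudyDesign":
        return StudyDesign(self.times, n_subjects)

    def require_n(self) -> int:
        if self.n_subjects is None:
            raise ValueError("this operation needs a sample size; use design.with_n(N)")
        return self.n_subjects

    def shift(self, delta: float) -> "StudyDesign":
        return shift_design(self, delta)

    def scale(self, factor: float) -> "StudyDesign":
        return scale_design(self, factor)

    def center(self) -> "StudyDesign":
        return center_design(self)


def shift_design(design: StudyDesign, delta: float) -> StudyDesign:
    """Translate all occasions by ``delta`` years (t -> t + delta).

    Shifting moves the time origin, i.e. redefines which occasion anchors the
    latent intercept; it changes effective error and ECR but not SST or GRR.
    """
    return StudyDesign((t + delta for t in design.times), design.n_subjects)


def scale_design(design: StudyDesign, factor: float) -> StudyDesign:
    """Stretch (factor > 1) or compress (factor < 1) the study duration."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return StudyDesign((t * factor for t in design.times), design.n_subjects)


def center_design(design: StudyDesign) -> StudyDesign:
    """Shift so the mean occasion time is 0 (t -> t - t_bar).

    The centered design has the largest effective error over all shifts of a
    given design, hence the smallest ECR and power, whenever ICC2 < 1.
    """
    return shift_design(design, -design.mean_time)
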