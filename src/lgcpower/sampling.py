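"""Simulation of complete-data longitudinal samples from an LGCM."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .design import StudyDesign
from .moments import implied_moments
from .params import GrowthParams

__all__ = ["LongitudinalSample", "simulate_sample", "replication_rng"]


@dataclass(frozen=True)
class LongitudinalSample:
    """An N x M table of observed scores plus the design that indexes its columns."""

    values: np.ndarray
    design: StudyDesign

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-d array (subjects x occasions)")
        if values.shape[1] != self.design.n_occasions:
            raise ValueError(
                f"sample has {values.shape[1]} columns but the design has "
                f"{self.design.n_occasions} occasions"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("sample contains missing or non-finite cells; "
                             "only complete-data designs are supported")
        object.__setattr__(self, "values", values)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Wide data frame with one row per subject, columns named t<time>."""
        cols = [f"t{t:g}" for t in self.design.times]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "id", np.arange(1, self.n_subjects + 1))
        return df

    def mean_vector(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def covariance(self) -> np.ndarray:
        """Maximum-likelihood (divide by N) sample covariance."""
        centered = self.values - self.values.mean(axis=0)
        return centered.T @ centered / self.n_subjects


def replication_rng(seed: int, replication: int) -> np.random.Generator:
    """Counter-based per-replication generator.

    Replication ``r`` of a batch run draws from ``SeedSequence((seed, r))``,
    so any single replication is reproducible in isolation.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(replication))))


def simulate_sample(
    design: StudyDesign,
    params: GrowthParams,
    n_subjects: Optional[int] = None,
    seed: Union[int, np.random.Generator, None] = None,
) -> LongitudinalSample:
    """Draw N independent subjects from the multivariate normal implied by the model.

    Parameters
    ----------
    design, params
        Study design and population parameters; the implied moments are
        computed exactly and passed to the multivariate-normal sampler.
    n_subjects
        Overrides ``design.n_subjects`` when given.
    seed
        Integer seed or an existing :class:`numpy.random.Generator`. Required
        for reproducibility; ``None`` draws fresh entropy.
    """
    n = int(n_subjects) if n_subjects is not None else design.require_n()
    if n < 1:
        raise ValueError("n_subjects must be >= 1")
    mom = implied_moments(design, params)
    eigvals = np.linalg.eigvalsh(mom.covariance)
    if eigvals[0] < -1e-10 * max(1.0, abs(eigvals[-1])):
        raise ValueError("implied covariance is not positive semidefinite")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = rng.multivariate_normal(
        mom.mean, mom.covariance, size=n, check_valid="ignore", method="eigh"
    )
    return LongitudinalSample(values=values, design=design.with_n(n))
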