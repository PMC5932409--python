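"""Readers and writers: wide/long CSV samples and YAML scenario files."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .design import StudyDesign
from .params import GrowthParams
from .sampling import LongitudinalSample

__all__ = [
    "read_wide_csv",
    "read_long_csv",
    "write_wide_csv",
    "Scenario",
    "load_scenario",
]

PathLike = Union[str, Path]


def read_wide_csv(path: PathLike) -> LongitudinalSample:
    """Read a wide sample: header ``id,t<time1>,...,t<timeM>``, one row per subject."""
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("wide CSV must have an 'id' column")
    time_cols = [c for c in df.columns if c != "id"]
    try:
        times = [float(str(c).lstrip("t")) for c in time_cols]
    except ValueError as exc:
        raise ValueError(
            f"cannot parse occasion times from columns {time_cols}; "
            "expected names like t0, t2.5"
        ) from exc
    values = df[time_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("wide CSV contains missing cells; complete data required")
    return LongitudinalSample(values=values, design=StudyDesign(times, len(df)))


def read_long_csv(path: PathLike) -> LongitudinalSample:
    """Read a long sample: header ``id,time,value``; occasion grid must be shared."""
    df = pd.read_csv(path)
    required = {"id", "time", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"long CSV must have columns {sorted(required)}")
    wide = df.pivot(index="id", columns="time", values="value")
    if wide.isna().any().any():
        raise ValueError(
            "long CSV is incomplete or subjects are measured on different "
            "occasion grids; complete balanced data required"
        )
    times = [float(t) for t in wide.columns]
    return LongitudinalSample(
        values=wide.to_numpy(dtype=float), design=StudyDesign(times, len(wide))
    )


def write_wide_csv(sample: LongitudinalSample, path: PathLike) -> None:
    sample.to_frame().to_csv(path, index=False)


class Scenario:
    """A design x parameters x seed triple loaded from a YAML scenario file."""

    def __init__(self, design: StudyDesign, params: GrowthParams,
                 seed: Optional[int] = None):
        self.design = design
        self.params = params
        self.seed = seed

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"Scenario(design={self.design!r}, params={self.params!r}, "
                f"seed={self.seed!r})")


_PARAM_KEYS = {
    "mu_i": "mu_intercept",
    "mu_s": "mu_slope",
    "var_i": "var_intercept",
    "var_s": "var_slope",
    "cov_is": "cov_intercept_slope",
    "var_e": "var_residual",
}


def load_scenario(path: PathLike) -> Scenario:
    """Load a YAML scenario.

    Expected keys::

        design:
          times: [0, 1, 2, 3, 4]
          n: 100            # optional
        params:
          mu_i: 0.0         # optional, default 0
          mu_s: 0.0         # optional, default 0
          var_i: 10.0
          var_s: 1.0
          cov_is: 0.0       # optional, default 0
          var_e: 50.0
        seed: 1             # optional
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "design" not in raw or "params" not in raw:
        raise ValueError("scenario YAML needs top-level 'design' and 'params' keys")
    dsec = raw["design"]
    design = StudyDesign(dsec["times"], dsec.get("n"))
    psec = raw["params"]
    unknown = set(psec) - set(_PARAM_KEYS)
    if unknown:
        raise ValueError(f"unknown parameter keys in scenario: {sorted(unknown)}")
    kwargs = {_PARAM_KEYS[k]: float(v) for k, v in psec.items()}
    params = GrowthParams(**kwargs)
    seed = raw.get("seed")
    return Scenario(design, params, None if seed is None else int(seed))
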