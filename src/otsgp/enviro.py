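"""Environmental covariates and the enviromic kernel.

Daily weather records per trial environment are summarized over crop phenology
windows (defaults 0-14, 15-35, 36-60, 61-90 and 91-120 days after emergence)
into an environments x covariates matrix W.  Intensive variables (temperature,
humidity, day length) are averaged within a window; accumulative ones
(rainfall, radiation totals) are summed.  After column standardization the
enviromic similarity kernel is the normalized linear kernel

    K_E = W W' / (tr(W W') / q),

a q x q PSD matrix with trace exactly q, playing for environments the role a
genomic relationship matrix plays for genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_WINDOWS",
    "WeatherTable",
    "EnviroCovariates",
    "EnvKernel",
    "summarize_env_covariates",
    "scale_ec_matrix",
    "env_kernel",
    "read_weather_csv",
]

DEFAULT_WINDOWS: tuple[tuple[int, int], ...] = ((0, 14), (15, 35), (36, 60), (61, 90), (91, 120))

#: window aggregation defaults by variable-name keyword
ACCUMULATIVE_KEYWORDS = ("rain", "precip", "radiation", "flux", "insolation")


@dataclass
class WeatherTable:
    """Daily weather per environment: long table (env, day, variable columns)."""

    data: pd.DataFrame  # columns: env, day, <variables...>

    def __post_init__(self) -> None:
        need = {"env", "day"}
        if not need.issubset(self.data.columns):
            raise ValueError("weather table needs 'env' and 'day' columns")
        if (self.data["day"] < 0).any():
            raise ValueError("day index must be >= 0 (days after emergence)")
        dup = self.data.duplicated(subset=["env", "day"])
        if dup.any():
            raise ValueError("duplicate (env, day) rows in weather table")

    @property
    def variables(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("env", "day")]

    @property
    def environment_ids(self) -> list[str]:
        return sorted(self.data["env"].astype(str).unique())


@dataclass
class EnviroCovariates:
    environment_ids: list[str]
    covariate_ids: list[str]
    matrix: np.ndarray  # q x m
    scaled: bool = False
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.environment_ids), len(self.covariate_ids)):
            raise ValueError("EC matrix shape does not match id lists")

    @property
    def q(self) -> int:
        return len(self.environment_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.environment_ids, columns=self.covariate_ids)


@dataclass
class EnvKernel:
    environment_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.matrix, dtype=float)
        q = len(self.environment_ids)
        if k.shape != (q, q):
            raise ValueError("kernel dimension must equal number of environments")
        if not np.allclose(k, k.T, atol=1e-10):
            raise ValueError("enviromic kernel must be symmetric")
        self.matrix = (k + k.T) / 2.0
        w = np.linalg.eigvalsh(self.matrix)
        if w.min() < -1e-8 * max(1.0, abs(w.max())):
            raise ValueError("enviromic kernel not PSD")
        if abs(np.trace(self.matrix) - q) > 1e-8 * max(1.0, q):
            raise ValueError("enviromic kernel trace must equal number of environments")


def _is_accumulative(variable: str, accumulative: set[str] | None) -> bool:
    if accumulative is not None:
        return variable in accumulative
    v = variable.lower()
    return any(k in v for k in ACCUMULATIVE_KEYWORDS)


def summarize_env_covariates(
    w: WeatherTable,
    windows: tuple[tuple[int, int], ...] = DEFAULT_WINDOWS,
    accumulative: set[str] | None = None,
) -> EnviroCovariates:
    """One covariate per variable x window, named ``<variable>_<start>_<end>``.

    ``accumulative`` lists variables to sum within a window; everything else is
    averaged.  When omitted, variables whose names mention rainfall/radiation
    are summed.  Windows are inclusive day intervals and must be ordered and
    non-overlapping; a window reaching past an environment's recorded days is
    an error naming that environment.
    """
    for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
        if a1 >= b0 or a0 > a1:
            raise ValueError("windows must be ordered and non-overlapping")
    if windows and windows[0][0] > windows[0][1]:
        raise ValueError("windows must be ordered and non-overlapping")
    envs = w.environment_ids
    variables = w.variables
    last_needed = max(end for _, end in windows)
    rows = []
    for env in envs:
        sub = w.data[w.data["env"].astype(str) == env].set_index("day")
        if sub.index.max() < last_needed:
            raise ValueError(
                f"environment {env}: weather ends at day {int(sub.index.max())}, "
                f"window needs day {last_needed}"
            )
        row = []
        for var in variables:
            for start, end in windows:
                vals = sub.loc[(sub.index >= start) & (sub.index <= end), var]
                row.append(vals.sum() if _is_accumulative(var, accumulative) else vals.mean())
        rows.append(row)
    cov_ids = [f"{var}_{start}_{end}" for var in variables for start, end in windows]
    return EnviroCovariates(envs, cov_ids, np.array(rows, dtype=float))


def scale_ec_matrix(w: EnviroCovariates) -> EnviroCovariates:
    """Center and unit-variance-scale each covariate column (sample sd, ddof=1).

    Zero-variance columns carry no environmental contrast and are dropped with
    a log entry.  Idempotent: scaling an already-scaled matrix is a no-op.
    """
    if w.q < 2:
        raise ValueError("need at least 2 environments to scale covariates")
    x = w.matrix
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all covariate columns constant")
    log = list(w.log)
    dropped = [c for c, k in zip(w.covariate_ids, keep) if not k]
    if dropped:
        log.append(f"scale: dropped {len(dropped)} constant covariates: {dropped[:5]}")
    xs = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    return EnviroCovariates(
        environment_ids=list(w.environment_ids),
        covariate_ids=[c for c, k in zip(w.covariate_ids, keep) if k],
        matrix=xs,
        scaled=True,
        log=log,
    )


def env_kernel(w: EnviroCovariates) -> EnvKernel:
    """Normalized linear kernel K_E = WW' / (tr(WW')/q); trace(K_E) = q."""
    if w.q < 2:
        raise ValueError("need at least 2 environments for an enviromic kernel")
    if not w.scaled:
        warnings.warn("building K_E from unscaled covariates", stacklevel=2)
    ww = w.matrix @ w.matrix.T
    tr = np.trace(ww)
    if tr <= 0:
        raise ValueError("EC matrix has zero norm")
    return EnvKernel(list(w.environment_ids), ww / (tr / w.q))


def read_weather_csv(path) -> WeatherTable:
    return WeatherTable(pd.read_csv(path))
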