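"""Synthetic trial generation from the covariate-adjusted random-intercept model.

Outcomes follow the two-level linear mixed model

    y_ij = beta0 + beta1 * x_j + beta2 * z_j + u_j + e_ij

with cluster effects ``u_j ~ N(0, sigma_u^2)`` and subject errors
``e_ij ~ N(0, sigma_e^2)``, all mutually independent.  Treatment ``x_j`` and
the binary covariate ``z_j`` live at the cluster level and are fixed by the
design: each simulated condition conditions on a fixed degree of imbalance,
so ``z`` is not resampled across replicates.

Seeding uses :class:`numpy.random.SeedSequence` with the replicate coordinates
``(master_seed, condition_index, replicate_index)`` as entropy, so replicate
streams are reproducible, non-overlapping across conditions and independent
of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .design import TrialDesign

__all__ = ["ModelParams", "TrialData", "generate_trial", "replicate_stream"]


@dataclass(frozen=True)
class ModelParams:
    """Fixed effects and variance components of the generating model.

    ``beta1`` and ``beta2`` are in outcome-SD units when the total variance
    ``sigma_u2 + sigma_e2`` is 1, the study's default normalization.  The
    intercept defaults to 0; every quantity evaluated downstream is invariant
    to location shifts.
    """

    beta1: float
    beta2: float
    sigma_u2: float
    sigma_e2: float
    beta0: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_u2 < 0.0:
            raise ValueError(f"sigma_u2 must be >= 0, got {self.sigma_u2}")
        if self.sigma_e2 <= 0.0 and not (self.sigma_e2 == 0.0 and self.sigma_u2 == 0.0):
            raise ValueError(f"sigma_e2 must be > 0, got {self.sigma_e2}")

    @classmethod
    def from_icc(
        cls, rho: float, beta1: float, beta2: float, beta0: float = 0.0
    ) -> "ModelParams":
        """Unit-total-variance parameters with intraclass correlation ``rho``."""
        if not 0.0 <= rho < 1.0:
            raise ValueError(f"ICC rho must lie in [0, 1), got {rho}")
        return cls(
            beta1=beta1, beta2=beta2, sigma_u2=rho, sigma_e2=1.0 - rho, beta0=beta0
        )

    @property
    def icc(self) -> float:
        total = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / total if total > 0 else 0.0


@dataclass(frozen=True)
class TrialData:
    """One generated trial: an ``(n2, n1)`` outcome matrix plus its design."""

    design: TrialDesign
    y: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=np.float64)
        object.__setattr__(self, "y", y)
        if y.shape != (self.design.n2, self.design.n1):
            raise ValueError(
                f"y must have shape (n2, n1) = ({self.design.n2}, {self.design.n1}), "
                f"got {y.shape}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("y contains non-finite values")

    def to_frame(self):
        """Long-format view (cluster, subject, x, z, y), for CSV export or
        fitting with external mixed-model software."""
        import pandas as pd

        n2, n1 = self.y.shape
        return pd.DataFrame(
            {
                "cluster": np.repeat(np.arange(n2), n1),
                "subject": np.tile(np.arange(n1), n2),
                "x": np.repeat(self.design.x, n1),
                "z": np.repeat(self.design.z, n1),
                "y": self.y.ravel(),
            }
        )


def generate_trial(
    design: TrialDesign,
    params: ModelParams,
    seed: int | np.random.SeedSequence | np.random.Generator,
) -> TrialData:
    """Draw one trial from the adjusted mixed model.

    The same seed always yields bitwise-identical outcomes.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    n2, n1 = design.n2, design.n1
    mean = (
        params.beta0 + params.beta1 * design.x + params.beta2 * design.z
    )  # (n2,)
    u = rng.normal(0.0, np.sqrt(params.sigma_u2), size=n2)
    e = rng.normal(0.0, np.sqrt(params.sigma_e2), size=(n2, n1))
    y = mean[:, None] + u[:, None] + e
    return TrialData(design=design, y=y)


def replicate_seed(
    master_seed: int, condition_index: int, replicate_index: int
) -> np.random.SeedSequence:
    """Seed for one replicate of one condition; stable across run orders."""
    return np.random.SeedSequence((master_seed, condition_index, replicate_index))


def replicate_stream(
    design: TrialDesign,
    params: ModelParams,
    reps: int,
    master_seed: int,
    condition_index: int = 0,
) -> Iterator[TrialData]:
    """Yield ``reps`` independent replicate trials of one condition."""
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    for r in range(reps):
        yield generate_trial(
            design, params, replicate_seed(master_seed, condition_index, r)
        )
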