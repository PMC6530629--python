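"""Clonogenic-survival datasets and their CSV dialect.

The on-disk format is a plain comma-separated table with header
``cell_line,dose_gy,surviving_fraction,sd,n_replicates`` (dot decimal,
UTF-8).  ``sd`` is the standard deviation of the surviving fraction on
the linear scale and may be empty; ``n_replicates`` defaults to 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalObservation",
    "SurvivalDataset",
    "read_survival_csv",
    "write_survival_csv",
    "CSV_COLUMNS",
]

CSV_COLUMNS = ["cell_line", "dose_gy", "surviving_fraction", "sd", "n_replicates"]


@dataclass
class SurvivalObservation:
    """One dose point of a clonogenic assay.

    surviving_fraction must lie in (0, 1]; values > 1 (plating-efficiency
    noise in the unirradiated control) are clamped to 1 with a warning.
    """

    dose: float
    surviving_fraction: float
    sd: float = math.nan
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.dose) or self.dose < 0:
            raise ValueError(f"dose must be finite and >= 0, got {self.dose!r}")
        if not math.isfinite(self.surviving_fraction) or self.surviving_fraction <= 0:
            raise ValueError(
                f"surviving_fraction must be in (0, 1], got {self.surviving_fraction!r}"
            )
        if self.surviving_fraction > 1.0:
            warnings.warn(
                f"surviving_fraction {self.surviving_fraction:.4g} > 1 clamped to 1",
                stacklevel=2,
            )
            self.surviving_fraction = 1.0
        if math.isfinite(self.sd) and self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd!r}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates!r}")


@dataclass
class SurvivalDataset:
    """Ordered dose/surviving-fraction observations for one cell line."""

    label: str
    observations: list[SurvivalObservation] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def doses(self) -> np.ndarray:
        return np.array([o.dose for o in self.observations], dtype=float)

    @property
    def survival(self) -> np.ndarray:
        return np.array([o.surviving_fraction for o in self.observations], dtype=float)

    @property
    def sd(self) -> np.ndarray:
        return np.array([o.sd for o in self.observations], dtype=float)

    def validate_for_fit(self, min_points: int) -> None:
        """Check the dataset can support a fit with the given parameter count."""
        if len(self) < min_points:
            raise ValueError(
                f"dataset '{self.label}' has {len(self)} points; "
                f"at least {min_points} are required for this fit"
            )
        doses = self.doses
        if np.all(doses == doses[0]):
            raise ValueError(
                f"dataset '{self.label}' is degenerate: all doses identical"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_line": self.label,
                "dose_gy": self.doses,
                "surviving_fraction": self.survival,
                "sd": self.sd,
                "n_replicates": [o.n_replicates for o in self.observations],
            }
        )


def read_survival_csv(path) -> list[SurvivalDataset]:
    """Read survival datasets from CSV, one dataset per cell line.

    Malformed rows raise ValueError naming the offending row number
    (1-based, excluding the header).
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty or header-less CSV") from exc
    missing = [c for c in CSV_COLUMNS[:3] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    datasets: dict[str, SurvivalDataset] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            obs = SurvivalObservation(
                dose=float(row.dose_gy),
                surviving_fraction=float(row.surviving_fraction),
                sd=float(getattr(row, "sd", math.nan))
                if not pd.isna(getattr(row, "sd", math.nan))
                else math.nan,
                n_replicates=int(getattr(row, "n_replicates", 1))
                if not pd.isna(getattr(row, "n_replicates", 1))
                else 1,
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from exc
        label = str(row.cell_line)
        datasets.setdefault(label, SurvivalDataset(label=label)).observations.append(obs)
    if not datasets:
        raise ValueError(f"{path}: no data rows")
    return list(datasets.values())


def write_survival_csv(datasets, path) -> None:
    if isinstance(datasets, SurvivalDataset):
        datasets = [datasets]
    pd.concat([d.to_frame() for d in datasets], ignore_index=True).to_csv(
        path, index=False
    )
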