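"""The LR(ITA) protocol: per-descriptor ordinary-least-squares models.

Each model regresses the post-Hartree-Fock correlation energy (hartree)
against a single descriptor column. Summary statistics follow the published
conventions: R^2 = 1 - SSR/SST and RMSD = sqrt(SSR/n) over the fitted points,
reported in millihartree. Training-set fits (``fit_lr``/``fit_all``) and
extrapolation metrics (``evaluate``) are distinct: the former summarize the
fit within the training data, the latter gauge predictions on held-out
systems.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ContractError, DegenerateFitError, InsufficientDataError

__all__ = [
    "LinearModel",
    "DataTable",
    "fit_lr",
    "predict",
    "fit_all",
    "evaluate",
    "load_table",
    "packaged_tables",
    "summary_frame",
]

TARGET_COLUMN = "eps_mp2"


@dataclass(frozen=True)
class LinearModel:
    """OLS fit of correlation energy (hartree) against one descriptor column."""

    slope: float  # hartree per descriptor unit (as tabulated, scale included)
    intercept: float  # hartree
    n_points: int
    r_squared: float
    rmsd: float  # in the units of y (hartree when y is a correlation energy)

    @property
    def rmsd_mh(self) -> float:
        """RMSD in millihartree."""
        return self.rmsd * 1.0e3

    def to_dict(self) -> dict[str, float | int]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(**{k: d[k] for k in ("slope", "intercept", "n_points", "r_squared", "rmsd")})


def fit_lr(x: np.ndarray, y: np.ndarray) -> LinearModel:
    """Ordinary least squares with intercept; RMSD = sqrt(SSR/n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ContractError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 points to fit; got {n}")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("descriptor column is constant; cannot fit")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    ssr = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    return LinearModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_points=n,
        r_squared=r2,
        rmsd=float(np.sqrt(ssr / n)),
    )


def predict(model: LinearModel, x: float | np.ndarray) -> float | np.ndarray:
    """Correlation energy (hartree) predicted for descriptor value(s) x."""
    out = model.slope * np.asarray(x, dtype=float) + model.intercept
    return float(out) if out.ndim == 0 else out


def evaluate(model: LinearModel, x: np.ndarray, y_ref: np.ndarray) -> tuple[float, float]:
    """Extrapolation quality on held-out data: (R^2, RMSD in y units).

    Differs from the training-set statistics stored on the model: here the
    model is applied as-is to new descriptor values and compared against
    reference energies.
    """
    x = np.asarray(x, dtype=float)
    y_ref = np.asarray(y_ref, dtype=float)
    if x.shape != y_ref.shape:
        raise ContractError("x and y_ref must have equal shape")
    pred = predict(model, x)
    ssr = float(np.sum((y_ref - pred) ** 2))
    sst = float(np.sum((y_ref - y_ref.mean()) ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    return r2, float(np.sqrt(ssr / len(x)))


@dataclass
class DataTable:
    """Descriptor columns plus a correlation-energy target column.

    ``scales`` records any scale factor applied to a column as printed (for
    example a column stored as IF/10^3 has scale 1e3). Scaling a column leaves
    R^2 and RMSD invariant (the slope absorbs it), so fits may be done on the
    values exactly as tabulated.
    """

    frame: pd.DataFrame
    target: str = TARGET_COLUMN
    scales: dict[str, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.target not in self.frame.columns:
            raise ContractError(f"target column {self.target!r} missing")
        if self.frame[self.target].isna().any():
            raise ContractError("target column contains missing values")

    @property
    def descriptor_columns(self) -> list[str]:
        skip = {self.target, "n", "label", "system"}
        return [c for c in self.frame.columns if c not in skip]


def fit_all(table: DataTable) -> dict[str, LinearModel]:
    """One linear model per descriptor column of the table."""
    y = table.frame[table.target].to_numpy(dtype=float)
    return {
        col: fit_lr(table.frame[col].to_numpy(dtype=float), y)
        for col in table.descriptor_columns
    }


def summary_frame(models: dict[str, LinearModel]) -> pd.DataFrame:
    """Per-descriptor summary in the layout of the published R^2/RMSD rows.

    R^2 rounded to 3 decimals, RMSD in mH rounded to 1 decimal.
    """
    return pd.DataFrame(
        {
            "descriptor": list(models),
            "slope": [m.slope for m in models.values()],
            "intercept": [m.intercept for m in models.values()],
            "R2": [round(m.r_squared, 3) for m in models.values()],
            "RMSD_mH": [round(m.rmsd_mh, 1) for m in models.values()],
        }
    ).set_index("descriptor")


_PACKAGED = {
    "table02_polyyne": "table02_polyyne.csv",
    "table03_polyene": "table03_polyene.csv",
    "table04_polymethineimine": "table04_polymethineimine.csv",
    "table05_acene": "table05_acene.csv",
    "table10_co2": "table10_co2.csv",
    "table11_benzene": "table11_benzene.csv",
}


def packaged_tables() -> tuple[str, ...]:
    return tuple(_PACKAGED)


def load_table(name_or_path: str | Path, target: str = TARGET_COLUMN) -> DataTable:
    """Load a packaged descriptor/energy table (by short name) or a CSV path.

    Lines starting with '#' are provenance/metadata; a '# scales:' line (JSON)
    records per-column scale factors as printed.
    """
    name = str(name_or_path)
    if name in _PACKAGED:
        text = resources.files("itacorr.data.tables").joinpath(_PACKAGED[name]).read_text()
        label = name
    else:
        p = Path(name_or_path)
        if not p.exists():
            raise ConfigurationError(f"no packaged table or file named {name!r}")
        text = p.read_text()
        label = p.stem
    scales: dict[str, float] = {}
    data_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("scales:"):
                scales = json.loads(body[len("scales:") :])
            continue
        if line.strip():
            data_lines.append(line)
    from io import StringIO

    frame = pd.read_csv(StringIO("\n".join(data_lines)))
    return DataTable(frame=frame, target=target, scales=scales or None, label=label)
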