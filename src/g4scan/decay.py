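"""Distance dependence of transcription-induced G-quadruplex formation.

G4 formation in double-stranded DNA, quantified as the percentage of
DNA molecules carrying a quadruplex (%qDNA), decays with the separation
X (bp) between the quadruplex-forming motif and the promoter as a
single-phase exponential

    Y = max * exp(-k * X) + plateau

where ``max`` (%) is the inducible amplitude, ``k`` (1/bp) the decay
rate and ``plateau`` (%) the residual distance-independent level.  The
half-decay distance D_1/2 — the separation at which formation drops to
the midpoint between its maximum (max + plateau, at X = 0) and its
minimum (plateau) — equals ln(2)/k.

The model is exposed statsmodels-style: build :class:`ExponentialDecayModel`
from data, call :meth:`~ExponentialDecayModel.fit`, inspect the returned
:class:`DecayFitResults` (estimates, standard errors, ``summary()``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import bisect, curve_fit

__all__ = [
    "percent_qdna",
    "DecayDataset",
    "ExponentialDecayModel",
    "DecayFitResults",
    "fit_decay",
    "d_half_definition_check",
    "UnidentifiableDecayError",
]


class UnidentifiableDecayError(ValueError):
    """The decay rate cannot be identified from the data (constant y)."""


def percent_qdna(g4_band_intensity: float, total_intensity: float) -> float:
    """Quadruplex-bearing DNA as a percentage of total DNA.

    Band intensities are arbitrary densitometry units; requires
    0 <= g4 <= total and total > 0.
    """
    if total_intensity <= 0:
        raise ValueError("total_intensity must be > 0")
    if not (0 <= g4_band_intensity <= total_intensity):
        raise ValueError("need 0 <= g4_band_intensity <= total_intensity")
    return 100.0 * g4_band_intensity / total_intensity


@dataclass(frozen=True)
class DecayDataset:
    """Paired (distance bp, %qDNA) observations."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")
        if len(self.x) < 3:
            raise ValueError("need at least 3 observations")
        if np.any(self.x < 0):
            raise ValueError("distances must be >= 0")
        if np.any((self.y < 0) | (self.y > 100)):
            raise ValueError("%qDNA values must lie in [0, 100]")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "DecayDataset":
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"distance_bp", "pct_qdna"} <= set(df.columns):
            raise ValueError("TSV must have columns distance_bp, pct_qdna")
        return cls(df["distance_bp"].to_numpy(), df["pct_qdna"].to_numpy())

    def to_tsv(self, path: Union[str, Path]) -> None:
        pd.DataFrame({"distance_bp": self.x, "pct_qdna": self.y}).to_csv(
            path, sep="\t", index=False
        )


def _decay(x, max_, k, plateau):
    return max_ * np.exp(-k * x) + plateau


class ExponentialDecayModel:
    """Single-phase exponential decay of %qDNA with promoter distance.

    Fitted by nonlinear least squares with the constraints max >= 0 and
    k >= 0 (plateau unconstrained), initialized at plateau0 = min(y),
    max0 = max(y) - min(y), k0 = ln(2) / (x-range / 2).
    """

    def __init__(self, x: Sequence[float], y: Sequence[float]):
        self.data = DecayDataset(np.asarray(x, float), np.asarray(y, float))
        if len(np.unique(self.data.x)) < 3:
            raise ValueError("need >= 3 distinct x values")
        if np.allclose(self.data.y, self.data.y[0]):
            raise UnidentifiableDecayError(
                "y is constant: the decay rate k is unidentifiable"
            )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, x: str = "distance_bp", y: str = "pct_qdna"
    ) -> "ExponentialDecayModel":
        return cls(df[x].to_numpy(), df[y].to_numpy())

    @classmethod
    def from_dataset(cls, data: DecayDataset) -> "ExponentialDecayModel":
        return cls(data.x, data.y)

    def fit(self, maxiter: int = 10_000) -> "DecayFitResults":
        x, y = self.data.x, self.data.y
        xr = float(x.max() - x.min())
        p0 = [float(y.max() - y.min()), math.log(2) / (xr / 2), float(y.min())]
        popt, pcov = curve_fit(
            _decay,
            x,
            y,
            p0=p0,
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=maxiter,
            ftol=1e-12,
            xtol=1e-12,
            gtol=1e-12,
        )
        resid = y - _decay(x, *popt)
        sse = float(resid @ resid)
        with np.errstate(invalid="ignore"):
            bse = np.sqrt(np.diag(pcov))
        return DecayFitResults(
            model=self,
            max_=float(popt[0]),
            k=float(popt[1]),
            plateau=float(popt[2]),
            residual_sse=sse,
            bse=bse,
        )


@dataclass(frozen=True)
class DecayFitResults:
    """Estimates and diagnostics of an exponential-decay fit."""

    model: Optional[ExponentialDecayModel]
    max_: float
    k: float
    plateau: float
    residual_sse: float
    bse: Optional[np.ndarray] = None

    #: k below which the fit is flagged as non-decaying (boundary hit)
    K_BOUNDARY = 1e-12

    @property
    def non_decaying(self) -> bool:
        return self.k <= self.K_BOUNDARY

    @property
    def d_half(self) -> float:
        """Half-decay distance ln(2)/k, bp (NaN when non-decaying)."""
        if self.non_decaying:
            return float("nan")
        return math.log(2) / self.k

    def predict(self, x) -> np.ndarray:
        return _decay(np.asarray(x, float), self.max_, self.k, self.plateau)

    def params_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "max": [self.max_],
                "k": [self.k],
                "plateau": [self.plateau],
                "d_half": [self.d_half],
                "sse": [self.residual_sse],
            }
        )

    def summary(self) -> str:
        lines = [
            "Single-phase exponential decay  Y = max*exp(-k*X) + plateau",
            f"  n observations : {len(self.model.data.x) if self.model else 'n/a'}",
            f"  max (amplitude): {self.max_:10.4f} %",
            f"  k (decay rate) : {self.k:10.6g} 1/bp",
            f"  plateau        : {self.plateau:10.4f} %",
            f"  D_1/2 = ln2/k  : {self.d_half:10.4f} bp",
            f"  residual SSE   : {self.residual_sse:10.6g}",
        ]
        if self.bse is not None and np.all(np.isfinite(self.bse)):
            lines.append(
                "  std. errors    : max {:.4g}, k {:.4g}, plateau {:.4g}".format(
                    *self.bse
                )
            )
        if self.non_decaying:
            lines.append("  WARNING: k at zero boundary — non-decaying fit, D_1/2 undefined")
        return "\n".join(lines)


def fit_decay(data: DecayDataset) -> DecayFitResults:
    """Convenience wrapper: fit the decay model to a dataset."""
    return ExponentialDecayModel.from_dataset(data).fit()


def d_half_definition_check(fit: DecayFitResults, tol: float = 1e-9) -> float:
    """Solve the verbal definition of D_1/2 numerically.

    Finds X with max*exp(-k X) + plateau = plateau + max/2 by bisection
    on [0, 50/k]; exists to assert the closed form ln(2)/k against the
    midvalue definition.
    """
    if fit.k <= 0:
        raise ValueError("requires k > 0")
    if fit.max_ <= 0:
        raise ValueError("requires max > 0")
    target = fit.plateau + fit.max_ / 2.0

    def f(xx):
        return fit.max_ * math.exp(-fit.k * xx) + fit.plateau - target

    return float(bisect(f, 0.0, 50.0 / fit.k, xtol=tol))
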