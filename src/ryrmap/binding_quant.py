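"""Densitometry normalization and competition-binding IC50 estimation.

Specific probe binding of a lane is the streptavidin fluorescence (800 nm)
over the total-protein stain (700 nm), with the same ratio measured in the
presence of excess competitor subtracted:

    specific = (F800/F700)_noATP - (F800/F700)_ATP

Competition curves are normalized as y = (F - F0)/Fmax and fitted with a
one-site competition model

    y = 1 / (1 + (c / IC50)^h)

by unweighted nonlinear least squares (Hill slope h fixed at 1 by default,
optionally free). The starting IC50 is the geometric mean of the non-zero
concentrations, which makes the fit deterministic for given data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class QuantError(ValueError):
    pass


class FitError(RuntimeError):
    """Nonlinear regression failed (non-convergence or degenerate data)."""


@dataclass(frozen=True)
class DensitometryRecord:
    """One lane of a two-channel near-infrared gel scan.

    ``f800``: streptavidin fluorescence (800 nm channel, arbitrary units);
    ``f700``: total-protein stain intensity (700 nm channel); ``atp_mM``:
    competitor concentration; ``plus_crosslinker``: whether the photoprobe
    was UV-activated in this lane.
    """

    lane: str
    f800: float
    f700: float
    atp_mM: float = 0.0
    plus_crosslinker: bool = True

    def __post_init__(self) -> None:
        if self.f700 <= 0:
            raise QuantError(f"lane {self.lane!r}: F700 must be positive")
        if self.f800 < 0:
            raise QuantError(f"lane {self.lane!r}: F800 must be non-negative")
        if self.atp_mM < 0:
            raise QuantError(f"lane {self.lane!r}: negative ATP concentration")

    @property
    def ratio(self) -> float:
        return self.f800 / self.f700


@dataclass(frozen=True)
class CompetitionCurve:
    """Concentration-response points (atp_mM, normalized signal y)."""

    atp_mM: tuple
    y: tuple
    replicate: tuple = ()

    def __post_init__(self) -> None:
        if len(self.atp_mM) != len(self.y):
            raise QuantError("atp_mM and y must have equal length")
        arr = np.asarray(self.y, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise QuantError("non-finite normalized signal")
        if any(c < 0 for c in self.atp_mM):
            raise QuantError("negative concentration")


@dataclass(frozen=True)
class FitResult:
    ic50_mM: float
    se: float
    hill_slope: float
    hill_fixed: bool
    rss: float
    n_points: int

    def to_dict(self) -> dict:
        return {
            "ic50_mM": self.ic50_mM,
            "se": self.se,
            "hill_slope": self.hill_slope,
            "hill_fixed": self.hill_fixed,
            "rss": self.rss,
            "n_points": self.n_points,
        }


def specific_signal(
    no_atp: DensitometryRecord, with_atp: DensitometryRecord
) -> float:
    """Specific probe binding: (F800/F700)_noATP - (F800/F700)_ATP.

    A negative value (competitor lane brighter than the no-competitor lane)
    is reported but flagged with a warning — it usually indicates a
    normalization or lane-matching problem.
    """
    value = no_atp.ratio - with_atp.ratio
    if value < 0:
        warnings.warn(
            f"negative specific binding ({value:.4g}) for lanes "
            f"{no_atp.lane!r}/{with_atp.lane!r}",
            stacklevel=2,
        )
    return value


def normalize_curve(records, f0: float, fmax: float) -> CompetitionCurve:
    """Normalize raw signals to y = (F - F0)/Fmax.

    ``records`` is an iterable of (atp_mM, F) pairs or
    :class:`DensitometryRecord` objects (whose F is the F800/F700 ratio).
    """
    if fmax <= 0:
        raise QuantError(f"Fmax must be positive, got {fmax}")
    conc, y = [], []
    for rec in records:
        if isinstance(rec, DensitometryRecord):
            c, f = rec.atp_mM, rec.ratio
        else:
            c, f = rec
        conc.append(float(c))
        y.append((float(f) - f0) / fmax)
    return CompetitionCurve(atp_mM=tuple(conc), y=tuple(y))


def _model_fixed(c, ic50):
    return 1.0 / (1.0 + c / ic50)


def _model_free(c, ic50, h):
    return 1.0 / (1.0 + (c / ic50) ** h)


def fit_ic50(curve: CompetitionCurve, hill: str = "fixed") -> FitResult:
    """Least-squares one-site competition fit of a normalized curve.

    ``hill='fixed'`` fits IC50 only (h = 1); ``hill='free'`` also fits the
    Hill slope. Requires at least 4 distinct non-zero concentrations. The
    standard error comes from the fit covariance. Raises :class:`FitError`
    on non-convergence or on a degenerate (flat) curve.
    """
    if hill not in {"fixed", "free"}:
        raise ValueError(f"hill must be 'fixed' or 'free', got {hill!r}")
    conc = np.asarray(curve.atp_mM, dtype=float)
    y = np.asarray(curve.y, dtype=float)
    nonzero = conc > 0
    if len(set(conc[nonzero])) < 4:
        raise FitError("need at least 4 distinct non-zero concentrations")
    if np.ptp(y) < 1e-3:
        raise FitError("degenerate flat curve: no concentration dependence")
    # zero-concentration points carry no information about IC50 under the
    # model (y(0) == 1 exactly); keep them, they anchor the plateau
    ic50_start = float(np.exp(np.mean(np.log(conc[nonzero]))))
    try:
        if hill == "fixed":
            popt, pcov = curve_fit(
                _model_fixed, conc, y, p0=[ic50_start],
                bounds=([1e-9], [np.inf]), maxfev=10000,
            )
            ic50, h = float(popt[0]), 1.0
            se = float(np.sqrt(pcov[0, 0]))
            fitted = _model_fixed(conc, ic50)
        else:
            popt, pcov = curve_fit(
                _model_free, conc, y, p0=[ic50_start, 1.0],
                bounds=([1e-9, 0.05], [np.inf, 20.0]), maxfev=10000,
            )
            ic50, h = float(popt[0]), float(popt[1])
            se = float(np.sqrt(pcov[0, 0]))
            fitted = _model_free(conc, ic50, h)
    except RuntimeError as exc:
        raise FitError(f"nonlinear regression did not converge: {exc}") from exc
    rss = float(np.sum((y - fitted) ** 2))
    if not np.isfinite(ic50) or ic50 <= 0:
        raise FitError(f"implausible IC50 estimate: {ic50}")
    return FitResult(
        ic50_mM=ic50, se=se, hill_slope=h, hill_fixed=(hill == "fixed"),
        rss=rss, n_points=len(conc),
    )


# ---------------------------------------------------------------------------
# Tabular I/O

def read_densitometry_tsv(path) -> list[DensitometryRecord]:
    """Read lanes from TSV with columns lane, atp_mM, F800, F700
    (optional plus_crosslinker)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.itertuples():
        out.append(
            DensitometryRecord(
                lane=str(row.lane),
                f800=float(row.F800),
                f700=float(row.F700),
                atp_mM=float(row.atp_mM),
                plus_crosslinker=bool(getattr(row, "plus_crosslinker", True)),
            )
        )
    return out


def curve_from_records(records) -> CompetitionCurve:
    """Build a normalized curve from raw lanes.

    F0 is the mean ratio of non-crosslinked (no-UV) background lanes when
    present, otherwise the minimum F800/F700 ratio across lanes (the
    lowest-signal lane approximates background). Fmax is the mean ratio of
    crosslinked no-competitor lanes, after background subtraction.
    """
    records = list(records)
    background = [r.ratio for r in records if not r.plus_crosslinker]
    if background:
        f0 = float(np.mean(background))
    else:
        f0 = min(r.ratio for r in records)
    crosslinked = [r for r in records if r.plus_crosslinker]
    no_atp = [r.ratio for r in crosslinked if r.atp_mM == 0]
    if not no_atp:
        raise QuantError("no zero-ATP lane to define Fmax")
    fmax = float(np.mean(no_atp)) - f0
    if fmax <= 0:
        raise QuantError("Fmax (no-ATP signal above background) is not positive")
    return normalize_curve(
        [(r.atp_mM, r.ratio) for r in crosslinked if r.atp_mM > 0], f0=f0, fmax=fmax
    )
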