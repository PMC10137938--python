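"""ACE inhibition rates from HPLC peak areas and IC50 dose-response fitting.

ACE cleaves the substrate HHL to hippuric acid, quantified by its HPLC peak
area at 228 nm.  With peak areas a (experimental), b (blank, uninhibited)
and c (control, no enzyme), the inhibition percentage is

    inhibition = ((b - c) - (a - c)) / (b - c) * 100 = (b - a) / (b - c) * 100

IC50 is the inhibitor concentration giving half-maximal inhibition, obtained
from a four-parameter log-logistic (4PL) fit to a dilution series:

    y(x) = bottom + (top - bottom) / (1 + 10**(hill * (log10(IC50) - log10(x))))

with bottom constrained to >= 0 and top to <= 100 percent by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .peptides import validate_peptide

#: Average residue masses (g/mol) for peptide molar-mass conversions.
_RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}
_WATER_MASS = 18.0153


def molar_mass(peptide: str) -> float:
    """Average molar mass of a tetrapeptide in g/mol."""
    validate_peptide(peptide)
    return sum(_RESIDUE_MASS[aa] for aa in peptide) + _WATER_MASS


def mg_per_l_to_um(mass_conc_mg_l: float, peptide: str) -> float:
    """Convert a mg/L mass concentration to uM for a given sequence."""
    return mass_conc_mg_l / molar_mass(peptide) * 1000.0


def inhibition_rate(a: float, b: float, c: float) -> float:
    """ACE inhibition percentage from hippuric-acid peak areas.

    a: experimental group; b: blank (uninhibited) group; c: control group.
    Invariant under rescaling all three areas by a common factor.
    """
    for name, v in (("a", a), ("b", b), ("c", c)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"peak area {name} must be finite and >= 0")
    if b == c:
        raise ValueError("degenerate assay: blank and control areas are equal")
    return ((b - c) - (a - c)) / (b - c) * 100.0


def four_param_logistic(
    x: np.ndarray, bottom: float, top: float, log_ic50: float, hill: float
) -> np.ndarray:
    """4PL response at concentrations x (same units as 10**log_ic50)."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_ic50 - np.log10(x))))


@dataclass
class IC50Results:
    """Fitted 4PL parameters; ``ic50`` is NaN when the fit did not converge."""

    ic50: float
    hill_slope: float
    bottom: float
    top: float
    ci_half_width: float
    converged: bool
    rmse: float = np.nan
    n_points: int = 0
    message: str = ""
    model: "DoseResponseModel | None" = field(default=None, repr=False)

    def predict(self, concentrations) -> np.ndarray:
        x = np.asarray(concentrations, dtype=float)
        return four_param_logistic(
            x, self.bottom, self.top, np.log10(self.ic50), self.hill_slope
        )

    def summary(self) -> str:
        if not self.converged:
            return (
                "4PL dose-response fit: NOT converged "
                f"({self.message or 'no dose dependence detected'})"
            )
        return "\n".join(
            [
                "4PL dose-response fit",
                f"  n points        {self.n_points}",
                f"  IC50            {self.ic50:.4g} uM (+/- {self.ci_half_width:.3g},"
                " 95% CI half-width)",
                f"  hill slope      {self.hill_slope:.3f}",
                f"  bottom / top    {self.bottom:.2f} / {self.top:.2f} %",
                f"  rmse            {self.rmse:.3f} % inhibition",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "ic50_uM": self.ic50,
            "hill_slope": self.hill_slope,
            "bottom_pct": self.bottom,
            "top_pct": self.top,
            "ci_half_width_uM": self.ci_half_width,
            "converged": self.converged,
            "rmse_pct": self.rmse,
            "n_points": self.n_points,
        }

    def plot(self, ax=None):
        """Data points and fitted curve on a log concentration axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        m = self.model
        if m is not None:
            ax.semilogx(m.concentrations, m.inhibition, "o", label="data")
        if self.converged and m is not None:
            grid = np.geomspace(m.concentrations.min() / 3,
                                m.concentrations.max() * 3, 200)
            ax.semilogx(grid, self.predict(grid), "-",
                        label=f"4PL, IC50 = {self.ic50:.3g} uM")
            ax.axvline(self.ic50, ls=":", color="grey")
        ax.set_xlabel("concentration (uM)")
        ax.set_ylabel("ACE inhibition (%)")
        ax.legend()
        return ax


class DoseResponseModel:
    """Dose-response series (concentrations in uM, inhibition in percent)."""

    def __init__(self, concentrations, inhibition):
        x = np.asarray(concentrations, dtype=float)
        y = np.asarray(inhibition, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("concentrations and inhibition must be 1-D, same length")
        if np.any(x <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(x)) < 4:
            raise ValueError("need >= 4 distinct concentrations")
        if np.any(y < -10) or np.any(y > 110):
            raise ValueError("inhibition outside plausible [-10, 110] % range")
        order = np.argsort(x)
        self.concentrations = x[order]
        self.inhibition = y[order]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DoseResponseModel":
        """Build from a CSV-style frame.

        Accepts either ``concentration_uM, inhibition_pct`` or raw peak areas
        ``concentration_uM, a, b, c`` (converted with the inhibition formula).
        """
        if "inhibition_pct" in df.columns:
            return cls(df["concentration_uM"], df["inhibition_pct"])
        if {"a", "b", "c"} <= set(df.columns):
            y = [inhibition_rate(r.a, r.b, r.c) for r in df.itertuples()]
            return cls(df["concentration_uM"], y)
        raise ValueError("need inhibition_pct or a,b,c columns")

    def fit(self, constrain: bool = True) -> IC50Results:
        """Least-squares 4PL fit.

        Starting values: bottom 0, top 100, IC50 at the geometric mean of the
        concentrations, hill slope 1.  With ``constrain`` (default) bottom is
        bounded to [0, 100] and top to [0, 100].  The fit is flagged
        non-converged when the optimizer fails, the covariance is singular,
        or the fitted amplitude (top - bottom) is under 1 percentage point —
        a flat series carries no IC50 information.
        """
        x, y = self.concentrations, self.inhibition
        if np.ptp(y) < 5.0:
            return IC50Results(
                ic50=np.nan, hill_slope=np.nan, bottom=np.nan, top=np.nan,
                ci_half_width=np.nan, converged=False, n_points=x.size,
                model=self,
                message=f"flat response (range {np.ptp(y):.2g}% inhibition)",
            )
        p0 = [0.0, 100.0, np.log10(np.exp(np.mean(np.log(x)))), 1.0]
        if constrain:
            bounds = ([0.0, 0.0, -12.0, 0.05], [100.0, 100.0, 12.0, 10.0])
        else:
            bounds = ([-np.inf, -np.inf, -12.0, 0.05], [np.inf, np.inf, 12.0, 10.0])
        failure = dict(
            ic50=np.nan, hill_slope=np.nan, bottom=np.nan, top=np.nan,
            ci_half_width=np.nan, converged=False, n_points=x.size, model=self,
        )
        try:
            popt, pcov = curve_fit(
                four_param_logistic, x, y, p0=p0, bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError) as err:
            return IC50Results(message=f"optimizer failure: {err}", **failure)
        bottom, top, log_ic50, hill = popt
        se_log = np.sqrt(pcov[2, 2]) if np.all(np.isfinite(pcov)) else np.inf
        amplitude = top - bottom
        if amplitude < 1.0:
            return IC50Results(
                message=f"no dose dependence (amplitude {amplitude:.2g}%)",
                **failure,
            )
        if not np.isfinite(se_log):
            return IC50Results(message="singular covariance", **failure)
        ic50 = 10.0 ** log_ic50
        resid = y - four_param_logistic(x, *popt)
        return IC50Results(
            ic50=float(ic50),
            hill_slope=float(hill),
            bottom=float(bottom),
            top=float(top),
            ci_half_width=float(1.96 * ic50 * np.log(10.0) * se_log),
            converged=True,
            rmse=float(np.sqrt(np.mean(resid**2))),
            n_points=int(x.size),
            model=self,
        )
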