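"""MM/GBSA + interaction-entropy binding free energy assembly.

The binding free energy of a protein-peptide complex is split as

    dG_bind = dG_gas + dG_solv + (-T dS)
    dG_gas  = dE_ele + dE_vdW
    dG_solv = dG_gb + dG_np,      dG_np = gamma * SASA + beta

with the enthalpy dH = dE_vdW + dE_ele + dG_gb + dG_np averaged over MD
frames, and the entropic penalty estimated by the interaction-entropy (IE)
formula

    -T dS = kT * ln < exp(beta_T * dE_int) >,   beta_T = 1/(kT)

where dE_int is the fluctuation of the protein-ligand gas-phase interaction
energy about its mean.  By Jensen's inequality the IE term is always
non-negative; for Gaussian fluctuations of standard deviation sigma it
converges to sigma**2 / (2 kT).

Per-frame component tables are consumed as inputs; computing GB polar
solvation or SASA from coordinates is out of scope for this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

#: Boltzmann constant in kcal/(mol K).
BOLTZMANN_KCAL: float = 0.0019872

#: Production-run temperature in K.
DEFAULT_TEMPERATURE: float = 300.0

#: Nonpolar solvation surface-tension coefficient, kcal/(mol A^2).
GAMMA_NONPOLAR: float = 0.005

#: Nonpolar solvation offset, kcal/mol.
BETA_NONPOLAR: float = 0.0

#: Default frame counts: enthalpy components are averaged over ~100 frames,
#: the exponential IE average needs far more (~10,000) to converge.
N_FRAMES_ENTHALPY: int = 100
N_FRAMES_ENTROPY: int = 10_000

COMPONENT_COLUMNS = ("e_vdw", "e_ele", "g_gb", "g_np")


def nonpolar_solvation(
    sasa: float | np.ndarray,
    gamma: float = GAMMA_NONPOLAR,
    beta: float = BETA_NONPOLAR,
) -> float | np.ndarray:
    """Nonpolar solvation term gamma * SASA + beta (SASA in A^2, result kcal/mol).

    For a complex-minus-parts difference the caller supplies the SASA
    difference; a buried interface gives a negative value.
    """
    sasa = np.asarray(sasa, dtype=float)
    if np.any(sasa < 0):
        raise ValueError("SASA must be non-negative")
    out = gamma * sasa + beta
    return float(out) if out.ndim == 0 else out


def interaction_entropy(
    e_int: np.ndarray,
    temperature: float = DEFAULT_TEMPERATURE,
    boltzmann_k: float = BOLTZMANN_KCAL,
) -> float:
    """Entropic penalty -T dS = kT ln<exp(beta dE_int)> in kcal/mol.

    ``e_int`` is the per-frame protein-ligand interaction energy; its
    fluctuation about the series mean enters the exponential average, so the
    estimate is invariant under additive shifts of the raw series.  The
    average is evaluated in log space (max-shifted) because exp(beta*dE)
    overflows double precision for fluctuations of a few kcal/mol.

    Always >= 0; exactly 0 for a constant series.
    """
    e = np.asarray(e_int, dtype=float)
    if e.ndim != 1 or e.size < 2:
        raise ValueError("interaction-entropy estimate needs >= 2 frames")
    if not np.all(np.isfinite(e)):
        raise ValueError("interaction energies must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kt = boltzmann_k * temperature
    if np.ptp(e) == 0:  # constant series: no fluctuation, exactly zero
        return 0.0
    de = e - e.mean()
    value = kt * (logsumexp(de / kt) - np.log(e.size))
    if not np.isfinite(value):
        raise FloatingPointError(
            f"IE exponential average did not stay finite "
            f"(max |dE| = {np.abs(de).max():.3g} kcal/mol over {e.size} frames)"
        )
    # Jensen guarantees >= 0; clip float-precision residue on constant input
    return max(float(value), 0.0)


def mean_components(frames: pd.DataFrame) -> pd.Series:
    """Arithmetic mean of the four energy components over frames (kcal/mol)."""
    if frames.empty:
        raise ValueError("energy series has no frames")
    missing = set(COMPONENT_COLUMNS) - set(frames.columns)
    if missing:
        raise ValueError(f"frames missing component columns: {sorted(missing)}")
    sub = frames.loc[:, list(COMPONENT_COLUMNS)].astype(float)
    if not np.all(np.isfinite(sub.to_numpy())):
        raise ValueError("energy components must be finite")
    return sub.mean()


@dataclass
class BindingFreeEnergy:
    """One assembled free-energy row (all fields kcal/mol).

    ``d_h`` is the sum of the four component means and ``d_gbind`` is
    ``d_h + minus_t_ds``; ``minus_t_ds`` is the (non-negative) IE penalty.
    """

    d_evdw: float
    d_eele: float
    d_ggb: float
    d_gnp: float
    d_h: float
    minus_t_ds: float
    d_gbind: float
    complex_id: str = ""

    @property
    def d_ggas(self) -> float:
        return self.d_evdw + self.d_eele

    @property
    def d_gsolv(self) -> float:
        return self.d_ggb + self.d_gnp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "complex": self.complex_id,
                    "d_evdw": self.d_evdw,
                    "d_eele": self.d_eele,
                    "d_ggb": self.d_ggb,
                    "d_gnp": self.d_gnp,
                    "d_h": self.d_h,
                    "minus_t_ds": self.minus_t_ds,
                    "d_gbind": self.d_gbind,
                }
            ]
        )


def assemble_binding_free_energy(
    components, minus_t_ds: float, complex_id: str = ""
) -> BindingFreeEnergy:
    """Combine component means and the IE penalty into a free-energy row.

    ``components`` is any mapping with keys e_vdw, e_ele, g_gb, g_np
    (kcal/mol).  dH is their sum and dG_bind = dH + (-T dS).
    """
    values = {k: float(components[k]) for k in COMPONENT_COLUMNS}
    if not all(np.isfinite(v) for v in values.values()) or not np.isfinite(minus_t_ds):
        raise ValueError("all energy terms must be finite")
    if minus_t_ds < 0:
        raise ValueError("-T dS must be non-negative (entropy is a penalty)")
    d_h = sum(values.values())
    return BindingFreeEnergy(
        d_evdw=values["e_vdw"],
        d_eele=values["e_ele"],
        d_ggb=values["g_gb"],
        d_gnp=values["g_np"],
        d_h=d_h,
        minus_t_ds=float(minus_t_ds),
        d_gbind=d_h + float(minus_t_ds),
        complex_id=complex_id,
    )


def _subsample(values: np.ndarray, n: int) -> np.ndarray:
    """Evenly strided subsample of at most n points, keeping temporal order."""
    if n >= values.size:
        return values
    idx = np.linspace(0, values.size - 1, n).round().astype(int)
    return values[np.unique(idx)]


class BindingEnergyModel:
    """MM/GBSA + IE estimator over a per-frame energy table.

    Parameters
    ----------
    frames : DataFrame
        Per-frame components ``e_vdw, e_ele, g_gb, g_np`` (or ``sasa``, which
        is converted with gamma * SASA + beta) and the protein-ligand
        interaction energy ``e_int``.
    temperature : float
        Simulation temperature in K, used by the IE estimator.
    complex_id : str
        Label carried into the results row.
    """

    def __init__(
        self,
        frames: pd.DataFrame,
        temperature: float = DEFAULT_TEMPERATURE,
        complex_id: str = "",
        gamma: float = GAMMA_NONPOLAR,
        beta: float = BETA_NONPOLAR,
    ):
        frames = frames.copy()
        if "g_np" not in frames.columns:
            if "sasa" not in frames.columns:
                raise ValueError("frames need a g_np or sasa column")
            frames["g_np"] = nonpolar_solvation(frames["sasa"].to_numpy(), gamma, beta)
        if "e_int" not in frames.columns:
            raise ValueError("frames need an e_int column for the IE estimate")
        if len(frames) < 2:
            raise ValueError("need >= 2 frames")
        self.frames = frames
        self.temperature = float(temperature)
        self.complex_id = complex_id

    @classmethod
    def from_csv(cls, path, **kwargs) -> "BindingEnergyModel":
        return cls(pd.read_csv(path), **kwargs)

    def fit(
        self,
        n_frames_enthalpy: int = N_FRAMES_ENTHALPY,
        n_frames_entropy: int = N_FRAMES_ENTROPY,
    ) -> "BindingEnergyResults":
        """Estimate component means, the IE penalty, and dG_bind.

        Enthalpy components are averaged over an evenly strided subsample of
        ``n_frames_enthalpy`` frames; the IE exponential average uses up to
        ``n_frames_entropy`` frames.  Component uncertainties are standard
        errors of the frame means.
        """
        comp_frames = self.frames.iloc[
            np.unique(
                np.linspace(0, len(self.frames) - 1,
                            min(n_frames_enthalpy, len(self.frames)))
                .round().astype(int)
            )
        ]
        means = mean_components(comp_frames)
        sems = comp_frames.loc[:, list(COMPONENT_COLUMNS)].astype(float).sem()
        e_int = _subsample(self.frames["e_int"].to_numpy(dtype=float),
                           n_frames_entropy)
        minus_t_ds = interaction_entropy(e_int, self.temperature)
        energy = assemble_binding_free_energy(means, minus_t_ds, self.complex_id)
        return BindingEnergyResults(
            model=self,
            energy=energy,
            component_sems=sems,
            n_frames_enthalpy=len(comp_frames),
            n_frames_entropy=e_int.size,
        )


class BindingEnergyResults:
    """Fitted binding free energy with per-component uncertainties."""

    def __init__(self, model, energy, component_sems, n_frames_enthalpy,
                 n_frames_entropy):
        self.model = model
        self.energy = energy
        self.component_sems = component_sems
        self.n_frames_enthalpy = n_frames_enthalpy
        self.n_frames_entropy = n_frames_entropy

    @property
    def d_gbind(self) -> float:
        return self.energy.d_gbind

    def to_frame(self) -> pd.DataFrame:
        return self.energy.to_frame()

    def summary(self) -> str:
        e = self.energy
        lines = [
            f"MM/GBSA + interaction entropy"
            + (f" — {e.complex_id}" if e.complex_id else ""),
            f"  frames: {self.n_frames_enthalpy} (enthalpy), "
            f"{self.n_frames_entropy} (entropy); T = {self.model.temperature:g} K",
            "  term          kcal/mol      sem",
            f"  dE_vdW      {e.d_evdw:10.2f}  {self.component_sems['e_vdw']:7.2f}",
            f"  dE_ele      {e.d_eele:10.2f}  {self.component_sems['e_ele']:7.2f}",
            f"  dG_GB       {e.d_ggb:10.2f}  {self.component_sems['g_gb']:7.2f}",
            f"  dG_np       {e.d_gnp:10.2f}  {self.component_sems['g_np']:7.2f}",
            f"  dH          {e.d_h:10.2f}",
            f"  -T dS       {e.minus_t_ds:10.2f}",
            f"  dG_bind     {e.d_gbind:10.2f}",
        ]
        return "\n".join(lines)

    def plot_components(self, ax=None):
        """Bar chart of the assembled energy terms."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        e = self.energy
        labels = ["dE_vdW", "dE_ele", "dG_GB", "dG_np", "dH", "-TdS", "dG_bind"]
        values = [e.d_evdw, e.d_eele, e.d_ggb, e.d_gnp, e.d_h, e.minus_t_ds,
                  e.d_gbind]
        ax.bar(labels, values, color=["#4878d0"] * 4 + ["#ee854a", "#6acc64",
                                                        "#d65f5f"])
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("kcal/mol")
        if e.complex_id:
            ax.set_title(e.complex_id)
        return ax
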