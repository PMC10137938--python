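"""Synthetic inputs with the statistical structure the pipeline assumes.

Docking engines and MD codes are not part of this package; these generators
stand in for them so every analysis stage is testable end-to-end:

* a docking-score landscape over all 160,000 tetrapeptides, additive in
  position-specific residue effects plus Gaussian noise, calibrated to the
  published score range;
* per-frame MM/GBSA component series with Gaussian (optionally
  AR(1)-autocorrelated) fluctuations;
* alanine-scan contribution tables with planted hotspot residues and exact
  per-complex decomposition totals;
* 4PL dose-response dilution series with Gaussian noise on the inhibition.

Everything is deterministic per seed.  The additive score model reproduces
positional enrichment patterns; it makes no claim of emulating docking
physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assay import four_param_logistic
from .energetics import DEFAULT_TEMPERATURE
from .peptides import PEPTIDE_LENGTH, POSITIONS, STANDARD_ALPHABET


class ConfigError(ValueError):
    """Raised for an infeasible or incomplete generator configuration."""


# ---------------------------------------------------------------------------
# Docking-score landscape
# ---------------------------------------------------------------------------

#: Published extremes of the docking scoring function over the full library.
SCORE_RANGE: tuple[float, float] = (-12.125, -1.536)

#: Default per-position residue effects (same at all four positions), chosen
#: to reproduce the observed enrichment: Trp strongly favourable, other
#: aromatics and basics favourable, short side chains unfavourable.
DEFAULT_EFFECTS: dict[str, float] = {
    **{aa: 0.0 for aa in STANDARD_ALPHABET},
    "W": -1.2, "Y": -0.7, "F": -0.7, "R": -0.6, "H": -0.5,
    **{aa: 0.4 for aa in "IVATCLPGS"},
}


def uniform_effects(per_residue: dict[str, float]) -> dict[str, dict[str, float]]:
    """Expand a residue->effect map to all four positions."""
    return {pos: dict(per_residue) for pos in POSITIONS}


@dataclass
class ScoreLandscapeConfig:
    seed: int = 0
    effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: uniform_effects(DEFAULT_EFFECTS)
    )
    baseline: float = -6.8
    noise_sd: float = 0.5
    score_range: tuple[float, float] | None = SCORE_RANGE

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for pos in POSITIONS:
            table = self.effects.get(pos)
            if table is None:
                raise ConfigError(f"effect map missing position {pos}")
            missing = set(STANDARD_ALPHABET) - set(table)
            if missing:
                raise ConfigError(f"effect map at {pos} missing residues {sorted(missing)}")
            if not all(np.isfinite(v) for v in table.values()):
                raise ConfigError("effects must be finite")


def gen_score_landscape(cfg: ScoreLandscapeConfig | None = None) -> pd.DataFrame:
    """Score every tetrapeptide: baseline + sum of positional effects + noise.

    Returns a DataFrame (peptide, score) covering the full enumeration in
    lexicographic order.  When ``cfg.score_range`` is set, scores are mapped
    affinely (order-preserving) onto that range, mimicking the span of the
    published scoring function.
    """
    cfg = cfg or ScoreLandscapeConfig()
    rng = np.random.default_rng(cfg.seed)
    ordered = sorted(STANDARD_ALPHABET)
    n = 20 ** PEPTIDE_LENGTH
    # residue index of each peptide at each position (mixed-radix digits)
    k = np.arange(n)
    scores = np.full(n, cfg.baseline, dtype=float)
    for j, pos in enumerate(POSITIONS):
        digits = (k // 20 ** (PEPTIDE_LENGTH - 1 - j)) % 20
        eff = np.array([cfg.effects[pos][aa] for aa in ordered])
        scores += eff[digits]
    if cfg.noise_sd > 0:
        scores += rng.normal(0.0, cfg.noise_sd, size=n)
    if cfg.score_range is not None:
        lo, hi = cfg.score_range
        span = scores.max() - scores.min()
        if span > 0:
            scores = lo + (scores - scores.min()) * (hi - lo) / span
    from .peptides import enumerate_tetrapeptides

    return pd.DataFrame({"peptide": enumerate_tetrapeptides(), "score": scores})


# ---------------------------------------------------------------------------
# MD energy series
# ---------------------------------------------------------------------------

@dataclass
class EnergySeriesConfig:
    seed: int = 0
    n_frames: int = 10_000
    component_means: dict[str, float] = field(
        default_factory=lambda: {"e_vdw": -36.32, "e_ele": -43.52,
                                 "g_gb": 41.12, "g_np": -2.84}
    )
    component_sds: dict[str, float] = field(
        default_factory=lambda: {"e_vdw": 3.0, "e_ele": 5.0,
                                 "g_gb": 4.0, "g_np": 0.3}
    )
    e_int_mean: float = -79.84  # e_vdw + e_ele of the defaults
    e_int_sd: float = 3.0
    temperature: float = DEFAULT_TEMPERATURE
    ar1: float = 0.0  # lag-1 autocorrelation of every series
    complex_id: str = ""

    def __post_init__(self):
        if self.n_frames < 2:
            raise ConfigError("need n_frames >= 2")
        if any(sd < 0 for sd in self.component_sds.values()) or self.e_int_sd < 0:
            raise ConfigError("standard deviations must be >= 0")
        if abs(self.ar1) >= 1:
            raise ConfigError("AR(1) coefficient must satisfy |phi| < 1")


def _ar1_series(rng, mean, sd, n, phi):
    """Stationary AR(1) with the requested marginal mean and sd."""
    if sd == 0:
        return np.full(n, mean)
    if phi == 0:
        return rng.normal(mean, sd, size=n)
    innov_sd = sd * math.sqrt(1 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return mean + x


def gen_energy_series(cfg: EnergySeriesConfig | None = None) -> pd.DataFrame:
    """Per-frame component table (frame, e_vdw, e_ele, g_gb, g_np, e_int)."""
    cfg = cfg or EnergySeriesConfig()
    rng = np.random.default_rng(cfg.seed)
    data = {"frame": np.arange(cfg.n_frames)}
    for comp, mean in cfg.component_means.items():
        data[comp] = _ar1_series(rng, mean, cfg.component_sds[comp],
                                 cfg.n_frames, cfg.ar1)
    data["e_int"] = _ar1_series(rng, cfg.e_int_mean, cfg.e_int_sd,
                                cfg.n_frames, cfg.ar1)
    df = pd.DataFrame(data)
    df.attrs["temperature"] = cfg.temperature
    df.attrs["complex_id"] = cfg.complex_id
    return df


# ---------------------------------------------------------------------------
# Alanine-scan contribution tables
# ---------------------------------------------------------------------------

#: ACE active-site neighbourhood used as the default scanned-residue universe
#: (binding-pocket, zinc-coordinating and lid residues).
DEFAULT_RESIDUE_UNIVERSE: tuple[str, ...] = (
    "Q281", "H353", "A354", "S355", "A356", "W357", "H383", "E384", "H387",
    "H410", "E411", "F457", "K511", "H513", "V518", "Y520", "R522", "Y523",
)

#: Recurrent hotspot set used as the default planting target.
DEFAULT_HOTSPOTS: tuple[str, ...] = (
    "Q281", "H353", "W357", "E411", "H513", "Y520", "R522", "Y523",
)


def gen_alanine_scan_table(
    seed: int = 0,
    hotspots: tuple[str, ...] = DEFAULT_HOTSPOTS,
    n_complexes: int = 10,
    n_replicas: int = 3,
    residues: tuple[str, ...] = DEFAULT_RESIDUE_UNIVERSE,
    pass_fraction: float = 0.5,
    total_dgbind=None,
    replica_sd: float = 0.1,
) -> pd.DataFrame:
    """Long-format alanine-scan table with planted hotspots.

    Each planted residue receives a replica-mean contribution <= -1.3
    kcal/mol in at least ``pass_fraction`` of the complexes; all other
    residue/complex means stay above -0.6.  Replica noise is double-centred
    so per-residue means and per-complex totals are exact.  When
    ``total_dgbind`` is given (scalar or complex->value mapping) the rows of
    each complex are adjusted to sum exactly to it; the realised totals are
    stored in ``df.attrs['totals']`` either way.
    """
    hotspots = tuple(hotspots)
    if not set(hotspots) <= set(residues):
        raise ConfigError("planted hotspots must be a subset of the residue universe")
    if n_complexes < 1 or n_replicas < 1:
        raise ConfigError("need >= 1 complex and >= 1 replica")
    rng = np.random.default_rng(seed)
    complexes = [f"complex_{i+1}" for i in range(n_complexes)]
    n_res = len(residues)
    min_pass = math.ceil(pass_fraction * n_complexes)

    # planned replica-mean per (complex, residue)
    means = rng.uniform(-0.5, 0.2, size=(n_complexes, n_res))
    res_index = {r: j for j, r in enumerate(residues)}
    for residue in hotspots:
        n_pass = int(rng.integers(min_pass, n_complexes + 1))
        which = rng.choice(n_complexes, size=n_pass, replace=False)
        means[which, res_index[residue]] = rng.uniform(-4.5, -1.3, size=n_pass)

    if total_dgbind is not None:
        if np.isscalar(total_dgbind):
            targets = {c: float(total_dgbind) for c in complexes}
        else:
            targets = {c: float(total_dgbind[c]) for c in complexes}
        for i, c in enumerate(complexes):
            residual = targets[c] - means[i].sum()
            passing = means[i] <= -1.3
            if residual <= 0:
                pool = np.flatnonzero(passing)
                if pool.size == 0:
                    # spreading a favourable residual over non-hotspot rows
                    # must not push any of them past the hotspot threshold
                    if np.any(means[i] + residual / n_res <= -0.95):
                        raise ConfigError(
                            f"cannot absorb residual {residual:.2f} for {c} "
                            "without creating spurious hotspots"
                        )
                    pool = np.arange(n_res)
                means[i, pool] += residual / pool.size
            else:
                pool = np.flatnonzero(~passing)
                if pool.size == 0:
                    raise ConfigError(
                        f"no non-hotspot residues to absorb +{residual:.2f} for {c}"
                    )
                means[i, pool] += residual / pool.size
                if np.any(means[i, pool] <= -1.0):
                    raise ConfigError("residual adjustment broke hotspot margins")
    totals = {c: float(means[i].sum()) for i, c in enumerate(complexes)}

    rows = []
    for i, c in enumerate(complexes):
        noise = rng.normal(0.0, replica_sd, size=(n_res, n_replicas))
        # double-centre: zero row means (residue means exact) and zero column
        # sums (per-replica decomposition totals exact)
        noise = (noise - noise.mean(axis=1, keepdims=True)
                 - noise.mean(axis=0, keepdims=True)
                 + noise.mean())
        for j, residue in enumerate(residues):
            for rep in range(n_replicas):
                rows.append(
                    (c, residue, rep + 1, means[i, j] + noise[j, rep])
                )
    df = pd.DataFrame(rows, columns=["complex_id", "residue_id", "replica", "ddg"])
    df.attrs["totals"] = totals
    df.attrs["planted_hotspots"] = hotspots
    return df


# ---------------------------------------------------------------------------
# Dose-response curves
# ---------------------------------------------------------------------------

def gen_dose_response(
    seed: int = 0,
    true_ic50: float = 19.98,
    hill: float = 1.0,
    noise_sd: float = 3.0,
    n_points: int = 7,
    dilution_factor: float = 2.0,
    top: float = 100.0,
    bottom: float = 0.0,
) -> pd.DataFrame:
    """Serial-dilution dose-response series around ``true_ic50`` (uM).

    ``n_points`` concentrations in a geometric series (factor
    ``dilution_factor``) centred on the true IC50, with Gaussian noise of
    ``noise_sd`` percentage points added to the 4PL inhibition.
    """
    if true_ic50 <= 0:
        raise ConfigError("true_ic50 must be positive")
    if noise_sd < 0 or dilution_factor <= 1:
        raise ConfigError("need noise_sd >= 0 and dilution_factor > 1")
    rng = np.random.default_rng(seed)
    offsets = np.arange(n_points) - (n_points - 1) / 2
    conc = true_ic50 * dilution_factor ** offsets
    y = four_param_logistic(conc, bottom, top, np.log10(true_ic50), hill)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_points)
    y = np.clip(y, -9.9, 109.9)
    return pd.DataFrame({"concentration_uM": conc, "inhibition_pct": y})
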