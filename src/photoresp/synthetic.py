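"""Synthetic leaf gas-exchange generator.

Emulates the measurement design the analysis assumes: per species, CO2
response curves over 12 ambient CO2 levels (0–1200 μmol mol⁻¹), at
21 % and 2 % O2, under saturating light (PAR 2000 μmol m⁻² s⁻¹) and in
darkness (PAR 0), with 5 replicates.

Ground truth per species:

* R_p(C_a): unimodal quadratic anchored at its zero-CO2 value
  (``rp_min``) with vertex ``rp_max`` at ``rp_peak_ca``, truncated
  below at ``rp_min`` so asymmetric peaks cannot push it negative.
* R_n(C_a): linear decline between ``rn_at_zero`` and ``rn_at_max_ca``.
* R_d(C_a): derived self-consistently from the recycling relation
  R_d = R_n·(1 − ratio), with ratio = (R_p,max − R_p)/R_p,max — the same
  relation the partitioning pipeline inverts, so noiseless data round-
  trip exactly. The emergent R_d profile is unimodal with a peak below
  the R_p peak.

Observed fluxes (pre-noise):

    P_n(21 %, light) = G(C_a) − R_p − R_d
    P_n(2 %, light)  = G(C_a) − R_d          (photorespiration suppressed)
    P_n(dark)        = −R_n                   (both O2 levels)

with gross assimilation G from a modified-rectangular-hyperbola (or
biochemical) shape, C_i = ci_ratio·C_a, and independent homoscedastic
Gaussian noise. Replicates are generated independently; real leaves
would show replicate-level correlation and heteroscedastic noise, which
this generator deliberately omits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence

import numpy as np

from .fitting import GasExchangeCurve
from .models import FvCBParams, ModRectHyperbolaParams, eval_fvcb, eval_mod_rect_hyperbola

__all__ = [
    "SpeciesProfile",
    "SimulationConfig",
    "DEFAULT_CA_LEVELS",
    "default_config",
    "true_profiles",
    "simulate_dataset",
    "config_to_dict",
    "config_from_dict",
]

# the default 12-level ambient CO2 sequence (μmol mol⁻¹)
DEFAULT_CA_LEVELS = (0.0, 50.0, 80.0, 100.0, 150.0, 200.0, 380.0, 400.0,
                     600.0, 800.0, 1000.0, 1200.0)


@dataclass(frozen=True)
class SpeciesProfile:
    """Ground-truth respiratory profiles and gross-assimilation shape.

    Fluxes in μmol CO2 m⁻² s⁻¹, CO2 in μmol mol⁻¹. ``gross`` holds the
    gross-assimilation parameters (respiration term zero); either a
    :class:`ModRectHyperbolaParams` or an :class:`FvCBParams`.
    """

    name: str
    rp_min: float
    rp_max: float
    rp_peak_ca: float
    rn_at_zero: float
    rn_at_max_ca: float
    gross: object

    def validate(self, ca_levels: Sequence[float]) -> None:
        ca = np.asarray(ca_levels, dtype=float)
        if not (0 < self.rp_min < self.rp_max):
            raise ValueError(f"{self.name}: need 0 < rp_min < rp_max")
        if not (ca.min() < self.rp_peak_ca < ca.max()):
            raise ValueError(f"{self.name}: rp_peak_ca must lie inside the C_a grid")
        if self.rn_at_zero <= 0 or self.rn_at_max_ca <= 0:
            raise ValueError(f"{self.name}: rn endpoints must be positive")
        resp = getattr(self.gross, "rp", getattr(self.gross, "rd", 0.0))
        if resp != 0:
            raise ValueError(f"{self.name}: gross params must carry no respiration term")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the generator.

    Defaults reproduce the measured design: the 12-level C_a grid,
    n = 5 replicates, saturating PAR 2000, C_i = 0.75·C_a (no stomatal
    model is attempted), homoscedastic Gaussian noise sd 0.3
    μmol m⁻² s⁻¹ (of the order of the replicate SDs the design
    targets), and identical dark respiration at both O2 levels.
    """

    species: tuple = ()
    ca_levels: tuple = DEFAULT_CA_LEVELS
    n_replicates: int = 5
    ci_ratio: float = 0.75
    noise_sd: float = 0.3
    noise_cv: float = 0.0  # optional heteroscedastic term: sd += cv·|pn|
    par_light: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ci_ratio <= 1):
            raise ValueError("ci_ratio must lie in (0, 1]")
        if self.noise_sd < 0 or self.noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if len(self.ca_levels) < 3:
            raise ValueError("need at least 3 C_a levels")
        for sp in self.species:
            sp.validate(self.ca_levels)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Two-species default emulating wheat/bean field-measurement conditions.

    R_p ranges and peak locations, and the R_n endpoints (21 % O2),
    match the reference magnitudes: wheat R_p 4.923→12.307 peaking at
    600 μmol mol⁻¹, R_n 3.862→1.453; bean R_p 4.686→11.673 peaking at
    1000, R_n 4.040→1.210.
    """
    wheat = SpeciesProfile(
        name="wheat", rp_min=4.923, rp_max=12.307, rp_peak_ca=600.0,
        rn_at_zero=3.862, rn_at_max_ca=1.453,
        gross=ModRectHyperbolaParams(a=0.08, b=0.0002, c=0.0015, rp=0.0),
    )
    bean = SpeciesProfile(
        name="bean", rp_min=4.686, rp_max=11.673, rp_peak_ca=1000.0,
        rn_at_zero=4.040, rn_at_max_ca=1.210,
        gross=ModRectHyperbolaParams(a=0.075, b=0.00025, c=0.0012, rp=0.0),
    )
    return SimulationConfig(species=(wheat, bean), seed=seed, **overrides)


def config_to_dict(config: SimulationConfig) -> dict:
    """Plain-dict form of a config, suitable for YAML/JSON round-trip."""
    d = asdict(config)
    d["species"] = []
    for sp in config.species:
        sd = {k: v for k, v in asdict(sp).items() if k != "gross"}
        g = dict(vars(sp.gross))
        g["type"] = "fvcb" if isinstance(sp.gross, FvCBParams) else "modrect"
        sd["gross"] = g
        d["species"].append(sd)
    d["ca_levels"] = list(config.ca_levels)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    """Inverse of :func:`config_to_dict`."""
    d = dict(d)
    species = []
    for sd in d.pop("species", []):
        sd = dict(sd)
        g = dict(sd.pop("gross"))
        kind = g.pop("type", "modrect")
        cls = FvCBParams if kind == "fvcb" else ModRectHyperbolaParams
        species.append(SpeciesProfile(gross=cls(**g), **sd))
    d["species"] = tuple(species)
    if "ca_levels" in d:
        d["ca_levels"] = tuple(float(c) for c in d["ca_levels"])
    return SimulationConfig(**d)


def _gross(profile: SpeciesProfile, ca: np.ndarray) -> np.ndarray:
    g = np.zeros_like(ca)
    pos = ca > 0
    if isinstance(profile.gross, ModRectHyperbolaParams):
        g[pos] = eval_mod_rect_hyperbola(profile.gross, ca[pos])
    elif isinstance(profile.gross, FvCBParams):
        g[pos] = eval_fvcb(profile.gross, ca[pos])
    else:
        raise TypeError("gross must be ModRectHyperbolaParams or FvCBParams")
    return g


def true_profiles(config: SimulationConfig) -> Dict[str, Dict[str, np.ndarray]]:
    """Ground-truth R_p, R_d, R_n, recycling ratio and gross G on the grid.

    Returns, per species, a dict with keys ``ca``, ``rp``, ``rd``,
    ``rn``, ``ratio``, ``gross``. Raises on profiles that dip below
    zero anywhere on the grid.
    """
    ca = np.asarray(config.ca_levels, dtype=float)
    ca_max = ca.max()
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for sp in config.species:
        rel = (ca - sp.rp_peak_ca) / sp.rp_peak_ca
        rp = np.maximum(sp.rp_max + (sp.rp_min - sp.rp_max) * rel ** 2, sp.rp_min)
        rn = sp.rn_at_zero + (sp.rn_at_max_ca - sp.rn_at_zero) * ca / ca_max
        rp_max = float(rp.max())
        ratio = (rp_max - rp) / rp_max
        rd = rn * (1.0 - ratio)
        for name, prof in (("rp", rp), ("rn", rn), ("rd", rd)):
            if np.any(prof < 0):
                raise ValueError(f"{sp.name}: {name} profile dips below zero on the grid")
        out[sp.name] = {"ca": ca.copy(), "rp": rp, "rd": rd, "rn": rn,
                        "ratio": ratio, "gross": _gross(sp, ca)}
    return out


def simulate_dataset(config: SimulationConfig,
                     seed: Optional[int] = None) -> List[GasExchangeCurve]:
    """Generate the full four-class measurement set for every species.

    Per species × replicate: light curves at 21 % and 2 % O2 and dark
    curves at both O2 levels, on the shared C_a grid. Bit-identical
    for the same seed (``seed`` overrides ``config.seed``).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = true_profiles(config)
    curves: List[GasExchangeCurve] = []
    for sp in config.species:
        t = truth[sp.name]
        ca = t["ca"]
        ci = config.ci_ratio * ca
        pure = {
            (0.21, config.par_light): t["gross"] - t["rp"] - t["rd"],
            (0.02, config.par_light): t["gross"] - t["rd"],
            (0.21, 0.0): -t["rn"],
            (0.02, 0.0): -t["rn"],
        }
        for rep in range(1, config.n_replicates + 1):
            for (o2, par), pn0 in pure.items():
                sd = config.noise_sd + config.noise_cv * np.abs(pn0)
                noise = rng.normal(0.0, 1.0, size=ca.size) * sd
                curves.append(GasExchangeCurve(
                    species=sp.name, replicate=rep, o2_fraction=o2, par=par,
                    ca=ca.copy(), pn=pn0 + noise, ci=ci.copy()))
    return curves
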