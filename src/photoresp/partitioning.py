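"""Partitioning light respiration into photorespiration and day respiration.

The differential-O2 method: at 2 % O2 Rubisco oxygenation (and hence
photorespiration) is suppressed, so at matched CO2 and irradiance

    R_p = P_n(2 %) − P_n(21 %)

isolates the photorespiratory flux. At zero ambient CO2 the 21 % O2 net
flux is pure respiration, so −P_n(21 %) measures total light respiration
R_L = R_p + R_d and −P_n(2 %) measures day respiration R_d directly.

Because respired CO2 is released inside the mesophyll, a fraction of it
is re-assimilated by the chloroplast before escaping the leaf.  That
recycling weakens as ambient CO2 rises and photorespiration is then
competitively inhibited.  Both regimes are quantified against the peak
photorespiration rate R_p,max:

    recovery ratio / inhibition ratio = (R_p,max − R_p,i) / R_p,max

(recovery below the peak CO2, inhibition above it).  Mitochondrial CO2
is assumed to be recycled with the same efficiency, which converts the
dark respiration rate R_n into day respiration:

    R_d,i = R_n,i · (1 − ratio_i).

Sign convention throughout: P_n is signed (negative = net efflux);
R_L, R_d, R_p and R_n are positive magnitudes, in μmol CO2 m⁻² s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fitting import GasExchangeCurve

__all__ = [
    "RespirationSeries",
    "RecoveryProfile",
    "MissingCurveClassError",
    "photorespiration_rate",
    "recovery_inhibition",
    "rd_in_light",
    "build_respiration_series",
]


class MissingCurveClassError(ValueError):
    """A required measurement class (O2 × light level) is absent."""

    def __init__(self, species: str, missing: Sequence[str]):
        self.species = species
        self.missing = list(missing)
        super().__init__(f"species {species!r}: missing curve class(es): "
                         + ", ".join(self.missing))


def photorespiration_rate(pn_2pct, pn_21pct):
    """Photorespiration rate R_p = P_n(2 % O2) − P_n(21 % O2).

    Both fluxes must be measured at the same CO2 and irradiance. At
    zero CO2 and saturating light this equals R_L − R_d. Noise can make
    the result negative; values are returned un-clamped so that
    replicate averaging stays unbiased.
    """
    out = np.asarray(pn_2pct, dtype=float) - np.asarray(pn_21pct, dtype=float)
    return out if out.ndim else float(out)


@dataclass
class RecoveryProfile:
    """Recovery/inhibition ratios of photorespiratory CO2 versus C_a."""

    species: str
    ca: np.ndarray
    ratio: np.ndarray
    phase: List[str]
    rp_max: float
    ca_at_peak: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "species": self.species, "ca": self.ca,
            "ratio": self.ratio, "phase": self.phase,
        })


def recovery_inhibition(rp_by_ca: Sequence[Tuple[float, float]],
                        species: str = "") -> RecoveryProfile:
    """Recovery/inhibition profile from an ordered (C_a, R_p) series.

    ratio_i = (R_p,max − R_p,i)/R_p,max with R_p,max the series maximum
    (ties broken toward the lowest C_a). Points below the peak C_a are
    the recovery phase, points above it the inhibition phase.
    """
    arr = np.asarray(rp_by_ca, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need an ordered series of at least 3 (ca, rp) pairs")
    ca, rp = arr[:, 0], arr[:, 1]
    order = np.argsort(ca, kind="stable")
    ca, rp = ca[order], rp[order]
    if np.any(rp < 0):
        raise ValueError("photorespiration rates must be non-negative")
    rp_max = float(np.max(rp))
    if rp_max == 0:
        raise ValueError("all-zero photorespiration series: profile undefined")
    i_peak = int(np.argmax(rp))  # argmax takes the first (lowest-ca) maximum
    ca_peak = float(ca[i_peak])
    ratio = (rp_max - rp) / rp_max
    phase = ["recovery" if c <= ca_peak else "inhibition" for c in ca]
    return RecoveryProfile(species=species, ca=ca, ratio=ratio, phase=phase,
                           rp_max=rp_max, ca_at_peak=ca_peak)


def rd_in_light(rn_i, ratio_i):
    """Day respiration R_d,i = R_n,i · (1 − ratio_i).

    ``ratio_i`` is the recovery (below the peak) or inhibition (above
    it) ratio, a fraction in [0, 1]; ``rn_i`` the dark respiration
    magnitude at the same C_a.
    """
    rn = np.asarray(rn_i, dtype=float)
    ratio = np.asarray(ratio_i, dtype=float)
    if np.any(rn < 0):
        raise ValueError("rn must be non-negative")
    if np.any((ratio < 0) | (ratio > 1)):
        raise ValueError("ratio must lie in [0, 1]")
    out = rn * (1.0 - ratio)
    return out if out.ndim else float(out)


@dataclass
class RespirationSeries:
    """Per-C_a respiratory fluxes with replicate dispersion.

    Means and sample SDs (ddof = 1; NaN SD when n = 1) of R_p, R_d,
    R_L = R_p + R_d, and dark respiration R_n per O2 level.
    ``qc_negative_rp`` lists (replicate, ca) pairs where noise drove a
    per-replicate R_p below zero (retained, not clamped).
    """

    species: str
    ca: np.ndarray
    rp_mean: np.ndarray
    rp_sd: np.ndarray
    rd_mean: np.ndarray
    rd_sd: np.ndarray
    rl_mean: np.ndarray
    rl_sd: np.ndarray
    rn_mean: Dict[float, np.ndarray]
    rn_sd: Dict[float, np.ndarray]
    n_replicates: int
    qc_negative_rp: List[Tuple[object, float]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: species, ca, quantity, mean, sd, n."""
        rows = []
        quantities = [("rp", self.rp_mean, self.rp_sd),
                      ("rd", self.rd_mean, self.rd_sd),
                      ("rl", self.rl_mean, self.rl_sd)]
        for o2, m in self.rn_mean.items():
            quantities.append((f"rn_{int(round(o2 * 100))}pct", m, self.rn_sd[o2]))
        for name, mean, sd in quantities:
            for i, c in enumerate(self.ca):
                rows.append({"species": self.species, "ca": float(c),
                             "quantity": name, "mean": float(mean[i]),
                             "sd": float(sd[i]), "n": self.n_replicates})
        return pd.DataFrame(rows)


_CLASS_LABELS = {
    (0.21, True): "light (PAR > 0, 21% O2)",
    (0.02, True): "light (PAR > 0, 2% O2)",
    (0.21, False): "dark (PAR 0, 21% O2)",
    (0.02, False): "dark (PAR 0, 2% O2)",
}


def _mean_sd(stack: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mean = stack.mean(axis=0)
    if stack.shape[0] > 1:
        sd = stack.std(axis=0, ddof=1)
    else:
        sd = np.full_like(mean, np.nan)
    return mean, sd


def build_respiration_series(curves: Sequence[GasExchangeCurve],
                             rn_o2: float = 0.21) -> Dict[str, RespirationSeries]:
    """Run the full partitioning scheme on a set of measured curves.

    Requires, per species, curves in all four measurement classes
    (21 %/2 % O2 × light/dark) on a shared C_a grid with matching
    replicate ids across classes. Per replicate: R_p from the
    differential-O2 subtraction, R_n from the dark flux magnitude,
    recovery/inhibition ratios from that replicate's own R_p series,
    and R_d = R_n·(1 − ratio) using the ``rn_o2`` dark series (default
    21 % O2; the O2 level has no significant effect on R_n).
    Replicate series are then averaged into means ± sample SDs.
    """
    by_species: Dict[str, Dict[Tuple[float, bool], Dict[object, GasExchangeCurve]]] = {}
    for c in curves:
        key = (round(c.o2_fraction, 4), c.par > 0)
        if key not in _CLASS_LABELS:
            raise ValueError(f"unsupported O2 fraction {c.o2_fraction} (expected 0.21 or 0.02)")
        by_species.setdefault(c.species, {}).setdefault(key, {})[c.replicate] = c

    out: Dict[str, RespirationSeries] = {}
    for species, classes in sorted(by_species.items()):
        required = [(0.21, True), (0.02, True), (round(rn_o2, 4), False)]
        missing = [_CLASS_LABELS[k] for k in required if k not in classes]
        if missing:
            raise MissingCurveClassError(species, missing)

        light21 = classes[(0.21, True)]
        light2 = classes[(0.02, True)]
        dark = classes[(round(rn_o2, 4), False)]
        reps = sorted(light21, key=str)
        for label, group in (("light (PAR > 0, 2% O2)", light2),
                             (_CLASS_LABELS[(round(rn_o2, 4), False)], dark)):
            if sorted(group, key=str) != reps:
                raise ValueError(f"species {species!r}: replicate ids of class "
                                 f"'{label}' do not match the 21% O2 light class")

        ca = light21[reps[0]].ca
        for group in classes.values():
            for c in group.values():
                if c.ca.shape != ca.shape or not np.allclose(c.ca, ca):
                    raise ValueError(f"species {species!r}: curves do not share a C_a grid")

        rp_rows, rd_rows, rl_rows, qc = [], [], [], []
        rn_rows = {k[0]: [] for k in classes if not k[1]}
        for r in reps:
            rp_r = photorespiration_rate(light2[r].pn, light21[r].pn)
            neg = np.nonzero(rp_r < 0)[0]
            qc.extend((r, float(ca[i])) for i in neg)
            prof = recovery_inhibition(list(zip(ca, np.maximum(rp_r, 0.0))), species)
            rn_r = -dark[r].pn
            rd_r = rd_in_light(np.maximum(rn_r, 0.0), prof.ratio)
            rp_rows.append(rp_r)
            rd_rows.append(rd_r)
            rl_rows.append(rp_r + rd_r)
            for o2 in rn_rows:
                rn_rows[o2].append(-classes[(o2, False)][r].pn)

        rp_mean, rp_sd = _mean_sd(np.vstack(rp_rows))
        rd_mean, rd_sd = _mean_sd(np.vstack(rd_rows))
        rl_mean, rl_sd = _mean_sd(np.vstack(rl_rows))
        rn_mean, rn_sd = {}, {}
        for o2, rows in rn_rows.items():
            rn_mean[o2], rn_sd[o2] = _mean_sd(np.vstack(rows))
        out[species] = RespirationSeries(
            species=species, ca=ca.copy(),
            rp_mean=rp_mean, rp_sd=rp_sd, rd_mean=rd_mean, rd_sd=rd_sd,
            rl_mean=rl_mean, rl_sd=rl_sd, rn_mean=rn_mean, rn_sd=rn_sd,
            n_replicates=len(reps), qc_negative_rp=qc,
        )
    return out
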