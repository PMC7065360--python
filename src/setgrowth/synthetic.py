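"""Seeded generator of tomato-like high-throughput phenotyping experiments.

The generator emulates a greenhouse conveyor experiment: 32 potted plants
in a randomized complete-block design (4 blocks x 8 treatments, the
treatments being 4 zinc levels crossed with +/- mycorrhizal inoculation),
imaged daily from 17 to 51 days after planting — 1120 projected-shoot-area
(PSA, kilopixels) records.

Data-generating model, per plant i at day t:

    PSA_i(t) = m_i(t) * exp( sigma(t) * z_i(t) + A * s(t) )

* ``m_i(t)`` — a three-parameter logistic mean curve with plant-level
  parameters drawn around treatment means; asymptotes span roughly
  95–185 kpx and the day-17 values sit near 2 kpx, so trajectories cover
  about two orders of magnitude. A watering-interruption dip multiplies the
  day-to-day AGR of the mean curve by a factor < 1 during the interruption,
  recovering linearly over the following days (continuity preserved).
* ``z_i(t)`` — a standardized AR(1) Gaussian process (lag-1 correlation
  rho), independent across plants; ``sigma(t)`` scales its marginal SD and
  grows with the mean curve, widening the replicate spread over time.
* ``s(t)`` — a deterministic alternating "sawtooth" sign with amplitude
  ``A`` on the log scale: invisible in the PSA profile but producing the
  characteristic sign-alternating pattern in the raw growth rates.

Ground truth (latent parameters, noiseless curves, noise paths) is returned
alongside the dataset, so simulation studies can score recovery exactly.
The same seed always reproduces the same experiment byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from ._errors import ParameterError
from .longdata import LongitudinalDataset

__all__ = ["LogisticParams", "SimConfig", "GroundTruth", "generate_experiment",
           "null_experiment"]


@dataclass(frozen=True)
class LogisticParams:
    """Treatment-mean logistic curve: phi1 asymptote (kpx), phi2 time of
    half-asymptote (DAP), phi3 scale (days)."""

    phi1: float
    phi2: float = 34.0
    phi3: float = 3.8

    def curve(self, t: np.ndarray) -> np.ndarray:
        return self.phi1 / (1.0 + np.exp(-(t - self.phi2) / self.phi3))


def _default_curves() -> dict:
    # +AMF: zinc-insensitive asymptotes; -AMF: growth depends on added Zn
    plus = {0: 172.0, 10: 176.0, 40: 180.0, 90: 178.0}
    minus = {0: 95.0, 10: 105.0, 40: 160.0, 90: 135.0}
    curves = {}
    for zn, p1 in plus.items():
        curves[(zn, "+")] = LogisticParams(phi1=p1)
    for zn, p1 in minus.items():
        curves[(zn, "-")] = LogisticParams(phi1=p1)
    return curves


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment.

    Defaults reproduce the tomato-style design: 4 blocks x (4 Zn levels x
    2 AMF levels), daily imaging DAP 17-51, AR(1) rho = 0.88, log-scale SD
    ramping 0.04 -> 0.08 with mean size, sawtooth amplitude 0.015 (period
    2 d), and an AGR dip (multiplier 0.3) for the 3-day watering
    interruption starting DAP 39 with a 2-day linear recovery.
    """

    n_blocks: int = 4
    zn_levels: tuple = (0, 10, 40, 90)
    amf_levels: tuple = ("+", "-")
    day_start: int = 17
    day_end: int = 51
    curves: Mapping | None = None        # (zn, amf) -> LogisticParams
    phi1_log_sd: float = 0.06            # plant-level lognormal CV on phi1
    phi2_sd: float = 0.5                 # days
    phi3_sd: float = 0.15                # days
    block_log_sd: float = 0.03           # multiplicative block effect on phi1
    rho: float = 0.88
    sigma_min: float = 0.04              # log-scale SD at small plants
    sigma_max: float = 0.08              # ... at the asymptote
    sawtooth_amplitude: float = 0.015    # log scale
    sawtooth_period: int = 2             # days
    dip_enabled: bool = True
    dip_onset: int = 39
    dip_duration: int = 3
    dip_agr_multiplier: float = 0.3
    dip_recovery_days: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ParameterError(f"|rho| must be < 1, got {self.rho}")
        if self.sigma_min < 0 or self.sigma_max < 0:
            raise ParameterError("sigma profile must be nonnegative")
        if self.day_end <= self.day_start:
            raise ParameterError("day_end must exceed day_start")
        if self.sawtooth_period < 2 or self.sawtooth_period % 2:
            raise ParameterError("sawtooth_period must be an even integer >= 2")
        if self.curves is None:
            object.__setattr__(self, "curves", _default_curves())
        for key in ((z, a) for z in self.zn_levels for a in self.amf_levels):
            cp = self.curves.get(key)
            if cp is None:
                raise ParameterError(f"no logistic parameters for treatment {key}")
            if cp.phi1 <= 0 or cp.phi3 <= 0:
                raise ParameterError(f"phi1 and phi3 must be positive for {key}")

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.day_start, self.day_end + 1)

    @property
    def n_subjects(self) -> int:
        return self.n_blocks * len(self.zn_levels) * len(self.amf_levels)


@dataclass
class GroundTruth:
    """Latent state of a simulated experiment.

    plants: per-subject drawn parameters and design; mean: noiseless mean
    curves (subjects x days); noise: the standardized AR(1) paths z.
    """

    plants: pd.DataFrame
    mean: pd.DataFrame
    noise: pd.DataFrame
    config: SimConfig


def _apply_dip(m: np.ndarray, days: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Scale the day-to-day AGR of the mean curve inside the dip window.

    Multiplier = dip_agr_multiplier during the interruption, then ramps
    linearly back to 1 over dip_recovery_days; the curve is rebuilt by
    cumulative summation so it stays continuous.
    """
    if not cfg.dip_enabled:
        return m
    inc = np.diff(m)
    mult = np.ones_like(inc)
    for i, d in enumerate(days[1:]):  # increment i ends at day d
        if cfg.dip_onset <= d < cfg.dip_onset + cfg.dip_duration:
            mult[i] = cfg.dip_agr_multiplier
        elif (
            cfg.dip_recovery_days > 0
            and cfg.dip_onset + cfg.dip_duration
            <= d
            < cfg.dip_onset + cfg.dip_duration + cfg.dip_recovery_days
        ):
            frac = (d - (cfg.dip_onset + cfg.dip_duration) + 1) / (
                cfg.dip_recovery_days + 1
            )
            mult[i] = cfg.dip_agr_multiplier + frac * (1.0 - cfg.dip_agr_multiplier)
    return m[0] + np.concatenate([[0.0], np.cumsum(inc * mult)])


def _ar1_path(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Standardized stationary AR(1): unit marginal variance, lag-1
    correlation rho."""
    z = np.empty(n)
    z[0] = rng.standard_normal()
    innov_sd = np.sqrt(1.0 - rho * rho)
    eps = rng.standard_normal(n - 1)
    for i in range(1, n):
        z[i] = rho * z[i - 1] + innov_sd * eps[i - 1]
    return z


def _sawtooth(days: np.ndarray, period: int) -> np.ndarray:
    half = period // 2
    return np.where(((days - days[0]) // half) % 2 == 0, 1.0, -1.0)


def generate_experiment(cfg: SimConfig | None = None) -> tuple[LongitudinalDataset, GroundTruth]:
    """Simulate one complete experiment under ``cfg`` (seeded).

    Returns the long-format dataset (columns subject, Lane, Position,
    Block, Zn, AMF, DAP, PSA) and the :class:`GroundTruth`.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    days = cfg.days
    nd = days.size
    treatments = [(z, a) for z in cfg.zn_levels for a in cfg.amf_levels]
    n_trt = len(treatments)

    block_mult = np.exp(rng.normal(0.0, cfg.block_log_sd, cfg.n_blocks))
    saw = cfg.sawtooth_amplitude * _sawtooth(days, cfg.sawtooth_period)

    plant_rows, data_rows = [], []
    mean_rows, noise_rows = {}, {}
    sid = 0
    for b in range(cfg.n_blocks):
        order = rng.permutation(n_trt)  # randomization within the block
        for pos, trt_idx in enumerate(order):
            zn, amf = treatments[trt_idx]
            base = cfg.curves[(zn, amf)]
            phi1 = base.phi1 * block_mult[b] * np.exp(
                rng.normal(0.0, cfg.phi1_log_sd)
            )
            phi2 = base.phi2 + rng.normal(0.0, cfg.phi2_sd)
            phi3 = max(base.phi3 + rng.normal(0.0, cfg.phi3_sd), 0.5)
            m = LogisticParams(phi1, phi2, phi3).curve(days.astype(float))
            m = _apply_dip(m, days, cfg)
            z = _ar1_path(rng, nd, cfg.rho)
            sigma = cfg.sigma_min + (cfg.sigma_max - cfg.sigma_min) * (m / phi1)
            psa = m * np.exp(sigma * z + saw)

            sid += 1
            subject = f"cart{sid:02d}"
            lane = 1 + (sid - 1) // 16
            position = 1 + (sid - 1) % 16
            plant_rows.append(
                {
                    "subject": subject,
                    "Block": f"B{b + 1}",
                    "Lane": lane,
                    "Position": position,
                    "Zn": zn,
                    "AMF": amf,
                    "phi1": phi1,
                    "phi2": phi2,
                    "phi3": phi3,
                }
            )
            mean_rows[subject] = m
            noise_rows[subject] = z
            for t, v in zip(days, psa):
                data_rows.append(
                    {
                        "subject": subject,
                        "Lane": lane,
                        "Position": position,
                        "Block": f"B{b + 1}",
                        "Zn": zn,
                        "AMF": amf,
                        "DAP": int(t),
                        "PSA": float(v),
                    }
                )

    data = pd.DataFrame(data_rows)
    ds = LongitudinalDataset(
        data=data,
        subject="subject",
        time="DAP",
        block="Block",
        factors=("Zn", "AMF"),
        traits=("PSA",),
    )
    truth = GroundTruth(
        plants=pd.DataFrame(plant_rows).set_index("subject"),
        mean=pd.DataFrame(mean_rows, index=days).T,
        noise=pd.DataFrame(noise_rows, index=days).T,
        config=cfg,
    )
    return ds, truth


def null_experiment(cfg: SimConfig | None = None) -> tuple[LongitudinalDataset, GroundTruth]:
    """As :func:`generate_experiment` but with *identical* treatment means:
    every Zn x AMF combination gets the same logistic parameters, so any
    downstream treatment significance is a type-I error."""
    cfg = cfg or SimConfig()
    common = cfg.curves[(cfg.zn_levels[0], cfg.amf_levels[0])]
    flat = {
        (z, a): common for z in cfg.zn_levels for a in cfg.amf_levels
    }
    return generate_experiment(replace(cfg, curves=flat))
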