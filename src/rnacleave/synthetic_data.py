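"""Seeded synthetic kinetic data emulating the RP-HPLC experiments.

Every input the analysis consumes — mole-fraction time courses, pH-rate
profiles and catalyst-concentration series — can be generated from stated
ground-truth parameters, so the whole pipeline is testable without any
laboratory data.  Observation noise is multiplicative lognormal: rate
constants and peak-area shares are positive quantities whose HPLC
measurement error is roughly relative.  The default experiment design
mirrors the study conditions: pH grid 3.0-8.5, catalyst 0-7 mM, eight
aliquots per time course spanning about three half-lives.

The isomerization and cyclic-phosphate/monophosphate hydrolysis rate
constants of the default network are plausible assumptions of the same
order as the cleavage constant (no printed values exist for them); they
are recorded as assumptions in the generated metadata.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, field_validator

from rnacleave.fitting import ConcSeries, PHProfile
from rnacleave.kinetic_network import KineticNetwork, TimeCourse, propagate
from rnacleave.ph_rate_model import Conditions, RateParams, eq1_rate

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "gen_ph_profile",
    "gen_conc_series",
    "gen_timecourse",
    "default_network",
]


class NoiseModel(BaseModel):
    """Multiplicative lognormal observation noise, or none.

    ``cv`` is the relative standard deviation of the multiplicative
    factor; the factor has mean 1 (the lognormal mu is offset by
    -sigma^2/2).  Identical seeds give identical draws.
    """

    model_config = {"frozen": True}

    kind: str = "multiplicative-lognormal"
    cv: float = Field(0.1, ge=0.0)
    seed: int = 0

    @field_validator("kind")
    @classmethod
    def _known_kind(cls, v: str) -> str:
        if v not in ("none", "multiplicative-lognormal"):
            raise ValueError(f"unknown noise kind: {v!r}")
        return v

    def factors(self, shape, rng: np.random.Generator | None = None) -> np.ndarray:
        """Mean-one multiplicative noise factors of the given shape."""
        if self.kind == "none" or self.cv == 0.0:
            return np.ones(shape)
        if rng is None:
            rng = np.random.default_rng(self.seed)
        sigma = np.sqrt(np.log1p(self.cv**2))
        return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


class ExperimentDesign(BaseModel):
    """Grids and schedules of the emulated experiments."""

    model_config = {"frozen": True}

    ph_min: float = 3.0
    ph_max: float = 8.5
    ph_step: float = Field(0.5, gt=0.0)
    cat_max_M: float = Field(7e-3, ge=0.0)
    cat_step_M: float = Field(1e-3, gt=0.0)
    n_times: int = Field(8, ge=4)
    n_half_lives: float = Field(3.0, gt=0.0)
    replicates: int = Field(1, ge=1)

    def ph_grid(self) -> np.ndarray:
        n = int(round((self.ph_max - self.ph_min) / self.ph_step)) + 1
        grid = self.ph_min + self.ph_step * np.arange(n)
        return grid[grid <= self.ph_max + 1e-12]

    def cat_grid(self) -> np.ndarray:
        n = int(round(self.cat_max_M / self.cat_step_M)) + 1
        return self.cat_step_M * np.arange(n)

    def sampling_times(self, k_ref: float) -> np.ndarray:
        """Aliquot times: t=0 plus log-spaced points to ~n half-lives.

        ``k_ref`` is the dominant decay rate (s^-1); for a dormant system
        (k_ref = 0) an arbitrary uniform schedule is returned.
        """
        if k_ref <= 0.0:
            return np.arange(self.n_times, dtype=float)
        t_end = self.n_half_lives * np.log(2.0) / k_ref
        inner = np.geomspace(t_end / 2 ** (self.n_times - 2), t_end,
                             self.n_times - 1)
        return np.concatenate([[0.0], inner])


def gen_ph_profile(
    truth: RateParams,
    design: ExperimentDesign = ExperimentDesign(),
    cat_conc: float = 0.0,
    noise: NoiseModel = NoiseModel(kind="none", cv=0.0),
    rng: np.random.Generator | None = None,
) -> PHProfile:
    """Synthetic pH-rate profile from the forward rate law.

    ``k_obs`` is the rate law evaluated on the design's pH grid times a
    multiplicative noise factor; the reported standard error is
    ``cv * k_obs`` (zero for noise-free data).
    """
    grid = design.ph_grid()
    k_true = np.array([
        eq1_rate(truth, Conditions(pH=float(p), cat_conc=cat_conc))
        for p in grid
    ])
    k_obs = k_true * noise.factors(grid.shape, rng)
    se = noise.cv * k_obs if noise.kind != "none" else np.zeros_like(k_obs)
    return PHProfile(
        pH=grid, k_obs=k_obs, se=se, cat_conc=cat_conc,
        meta={"truth": truth.model_dump(), "noise": noise.model_dump()},
    )


def gen_conc_series(
    truth: RateParams,
    design: ExperimentDesign = ExperimentDesign(),
    pH: float = 7.0,
    noise: NoiseModel = NoiseModel(kind="none", cv=0.0),
    rng: np.random.Generator | None = None,
) -> ConcSeries:
    """Synthetic catalyst-concentration series at fixed pH.

    The rate law is affine in catalyst concentration, so the noise-free
    series is exactly linear with slope kcat times the speciation
    fraction at the series pH.
    """
    grid = design.cat_grid()
    k_true = np.array([
        eq1_rate(truth, Conditions(pH=pH, cat_conc=float(c))) for c in grid
    ])
    k_obs = k_true * noise.factors(grid.shape, rng)
    se = noise.cv * k_obs if noise.kind != "none" else np.zeros_like(k_obs)
    return ConcSeries(
        cat_conc=grid, k_obs=k_obs, se=se, pH=pH,
        meta={"truth": truth.model_dump(), "noise": noise.model_dump()},
    )


#: Ratio of assumed isomerization rate to the cleavage rate in the default
#: synthetic network (assumption; not a measured value).
_ISO_TO_CL = 0.5
#: Assumed hydrolysis rates of the cyclic and acyclic monophosphates
#: relative to the cleavage rate (assumption).
_HYD_TO_CL = 2.0


def default_network(k_cl: float) -> KineticNetwork:
    """Plausible full network around a given pooled cleavage constant.

    Both isomers cleave at ``k_cl``; isomerization runs at half and the
    two downstream hydrolyses at twice that rate.  These side-reaction
    magnitudes are assumptions — the study reports no values for them —
    chosen to be of the same order as the cleavage they accompany.
    """
    return KineticNetwork(
        k_iso_45=_ISO_TO_CL * k_cl,
        k_iso_54=_ISO_TO_CL * k_cl,
        k_cl_4=k_cl,
        k_cl_5=k_cl,
        k_h_cAMP=_HYD_TO_CL * k_cl,
        k_h_AMP=_HYD_TO_CL * k_cl,
    )


def gen_timecourse(
    network: KineticNetwork,
    design: ExperimentDesign = ExperimentDesign(),
    noise: NoiseModel = NoiseModel(kind="none", cv=0.0),
    initial: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> TimeCourse:
    """Synthetic aliquot time course with HPLC-style multiplicative noise.

    The exact network solution is perturbed entry-wise and each row is
    renormalized the way peak-area shares are: the monophosphate lineage
    (N4, N5, cAMP, AMP, Ado) is rescaled to sum to one and the released
    nucleoside N6 is the complement of the uncleaved pool.  Noise-free
    rows therefore sum to one exactly.
    """
    if initial is None:
        initial = np.array([1.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    k_ref = 0.5 * (network.k_cl_4 + network.k_cl_5)
    if k_ref <= 0.0:
        k_ref = max(network.k_iso_45 + network.k_iso_54, 0.0)
    times = design.sampling_times(k_ref)
    tc = propagate(network, initial, times)

    frac = tc.fractions * noise.factors(tc.fractions.shape, rng)
    lineage = [0, 1, 3, 4, 5]
    frac[:, lineage] /= frac[:, lineage].sum(axis=1, keepdims=True)
    frac[:, 2] = 1.0 - frac[:, 0] - frac[:, 1]
    return TimeCourse(
        times=times, fractions=frac, noisy=noise.kind != "none",
        meta={
            "network": network.model_dump(),
            "noise": noise.model_dump(),
            "assumed_side_reactions": True,
        },
    )
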