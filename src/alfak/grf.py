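"""Gaussian-random-field ground-truth fitness landscapes.

Synthetic landscapes over 22-dimensional karyotype space, used as known ground
truth when benchmarking the inference pipeline. The field is synthesized from
random plane waves (random Fourier features):

    f(k) = offset + (amplitude / sqrt(n_basis)) * sum_j sin(2*pi*<k, u_j>/lambda + phi_j)

with unit directions u_j drawn uniformly on the 21-sphere and phases
phi_j ~ U(0, 2*pi). The characteristic wavelength ``lambda`` (Euclidean
distance in copy-number space) controls topography: large lambda gives smooth,
gently varying landscapes; small lambda gives rugged ones where even single
missegregations reshuffle fitness. For fixed k the field value over random
seeds is asymptotically Gaussian with variance amplitude**2 / 2.

Fitness here is a net growth rate in units of 1/day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


@dataclass(frozen=True, eq=False)
class GRFLandscape:
    """Frozen random-plane-wave fitness landscape.

    Deterministic given (seed, wavelength, n_basis, amplitude, offset):
    the basis directions and phases are drawn once at construction and then
    fixed, so two evaluations of the same karyotype agree bit-for-bit.
    """

    wavelength: float
    n_basis: int
    amplitude: float
    offset: float
    seed: int
    directions: np.ndarray = field(repr=False)  # (n_basis, 22) unit rows
    phases: np.ndarray = field(repr=False)  # (n_basis,)

    def fitness(self, k: Sequence[int]) -> float:
        """Evaluate fitness (1/day) at a single karyotype."""
        return float(self.batch_fitness(np.asarray(k, dtype=float)[None, :])[0])

    __call__ = fitness

    def batch_fitness(self, K: np.ndarray) -> np.ndarray:
        """Evaluate fitness at each row of a (n, 22) matrix of karyotypes."""
        K = np.atleast_2d(np.asarray(K, dtype=float))
        phase = 2.0 * np.pi * (K @ self.directions.T) / self.wavelength
        waves = np.sin(phase + self.phases[None, :])
        return self.offset + self.amplitude / np.sqrt(self.n_basis) * waves.sum(axis=1)

    def with_founder_fitness(self, founder: Sequence[int], value: float) -> "GRFLandscape":
        """Return a copy whose offset is shifted so f(founder) == value."""
        delta = value - self.fitness(founder)
        return replace(self, offset=self.offset + delta)

    def to_config(self) -> dict:
        """Serializable spec sufficient to regenerate the landscape."""
        return {
            "wavelength": self.wavelength,
            "n_basis": self.n_basis,
            "amplitude": self.amplitude,
            "offset": self.offset,
            "seed": self.seed,
        }

    @classmethod
    def from_config(cls, config: dict) -> "GRFLandscape":
        offset = config.get("offset", 0.0)
        land = generate_grf(
            wavelength=config["wavelength"],
            n_basis=config["n_basis"],
            amplitude=config["amplitude"],
            seed=config["seed"],
        )
        return replace(land, offset=offset)


def generate_grf(
    wavelength: float,
    n_basis: int = 64,
    amplitude: float = 0.3,
    seed: int = 0,
    offset: float = 0.0,
) -> GRFLandscape:
    """Draw a frozen GRF landscape.

    Parameters
    ----------
    wavelength
        Characteristic length scale lambda (> 0) in Euclidean copy-number
        units; fitness decorrelates over roughly this distance.
    n_basis
        Number of random plane-wave components (>= 1); larger values give a
        better Gaussian-field approximation.
    amplitude
        Overall fitness fluctuation scale (1/day); the pointwise standard
        deviation of the field is amplitude / sqrt(2).
    seed
        RNG seed; regeneration with the same arguments is bit-identical.
    offset
        Constant added to the field (mean fitness level).
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be > 0")
    if n_basis < 1:
        raise ValueError("n_basis must be >= 1")
    rng = np.random.default_rng(seed)
    directions = rng.normal(size=(n_basis, 22))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_basis)
    return GRFLandscape(
        wavelength=float(wavelength),
        n_basis=int(n_basis),
        amplitude=float(amplitude),
        offset=float(offset),
        seed=int(seed),
        directions=directions,
        phases=phases,
    )


def grf_fitness(landscape: GRFLandscape, k: Sequence[int]) -> float:
    """Functional alias for :meth:`GRFLandscape.fitness`."""
    return landscape.fitness(k)
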