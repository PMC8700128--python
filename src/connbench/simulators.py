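"""Synthetic five-variate systems with known connectivity structure.

Three stochastic nonlinear systems are hard-coded:

* **S1** — purely contemporaneous dependencies (i.i.d. over time): X3, X5 are
  instantaneous functions of X2 and X4 of X1; no lagged influence exists.
* **S2** — a nonlinear VAR(3): only lagged (causal) dependencies, no
  contemporaneous ones.
* **S3** — both: X2 depends on X1 at lag 0, and a causal chain
  X2 -> X3 -> {X4, X5} runs through lags 1..3.

Noise terms are deliberately non-Gaussian (exponential, chi-squared, beta,
gamma) so that marginals are skewed, which is what makes the rank- and
information-based measures interesting. Every realization is reproducible
from an integer seed; independent noise streams come from spawned
``numpy.random.SeedSequence`` substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NoiseLaw",
    "TruthNetwork",
    "SystemSpec",
    "TimeSeriesPanel",
    "SYSTEMS",
    "get_system",
    "draw_noise",
    "simulate",
    "truth_of",
]

#: default number of initial points discarded for the recursive systems
DEFAULT_BURN_IN = 1000

#: treat the gamma "b" parameter as a scale (mean 4, variance 1) rather than a
#: rate (mean 64, variance 256); the scale reading keeps the X3^2 -> X5 signal
#: visible above the noise, consistent with the systems' intended structure.
GAMMA_B_IS_RATE_DEFAULT = False


class SimulationError(RuntimeError):
    """Raised when a generated panel contains non-finite values."""


class ConfigurationError(ValueError):
    """Raised for unknown noise families or invalid system ids."""


@dataclass(frozen=True)
class NoiseLaw:
    """Descriptor of a marginal noise distribution.

    family is one of ``gaussian``, ``exponential``, ``chisq``, ``beta``,
    ``gamma``; ``params`` holds the family's natural parameters
    (gaussian: mean, sd; exponential: rate; chisq: df; beta: a, b;
    gamma: shape, b where b is scale unless ``gamma_b_is_rate``).
    """

    family: str
    params: tuple[float, ...]


@dataclass(frozen=True)
class TruthNetwork:
    """Known structure of a system.

    ``contemporaneous``: unordered 1-based variable pairs (stored sorted).
    ``lagged``: ordered 1-based (source, destination) pairs. Self-dependencies
    are never part of the truth. ``equation_implied`` marks lagged edges that
    are not written explicitly but follow by substitution of one equation
    into another (S3: X1 -> X2 at lag 2).
    """

    contemporaneous: frozenset[tuple[int, int]]
    lagged: frozenset[tuple[int, int]]
    equation_implied: frozenset[tuple[int, int]] = frozenset()

    def __post_init__(self) -> None:
        for a, b in self.contemporaneous:
            if a == b:
                raise ValueError("self-pair in contemporaneous truth")
            if a > b:
                raise ValueError("contemporaneous pairs must be stored sorted")
        for a, b in self.lagged | self.equation_implied:
            if a == b:
                raise ValueError("self-edge in lagged truth")


@dataclass(frozen=True)
class SystemSpec:
    id: str
    K: int
    max_lag: int
    noise_laws: tuple[NoiseLaw, ...]
    truth: TruthNetwork
    var_order: int  # VAR order P used by the model-based measures

    def __post_init__(self) -> None:
        if self.K != 5:
            raise ValueError("all benchmark systems are five-variate")
        if len(self.noise_laws) != self.K:
            raise ValueError("one noise law per variable required")


@dataclass
class TimeSeriesPanel:
    """An n x K multivariate series plus generation metadata."""

    data: np.ndarray
    labels: list[str]
    system_id: str | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def K(self) -> int:
        return self.data.shape[1]

    def column(self, i: int) -> np.ndarray:
        """Return variable ``i`` (1-based, matching the X1..X5 naming)."""
        return self.data[:, i - 1]


_GAUSS = NoiseLaw("gaussian", (0.0, 1.0))

SYSTEMS: dict[str, SystemSpec] = {
    "S1": SystemSpec(
        id="S1",
        K=5,
        max_lag=0,
        noise_laws=(
            NoiseLaw("exponential", (2.0,)),
            NoiseLaw("chisq", (1.0,)),
            _GAUSS,
            _GAUSS,
            _GAUSS,
        ),
        truth=TruthNetwork(
            contemporaneous=frozenset({(2, 3), (1, 4), (2, 5)}),
            lagged=frozenset(),
        ),
        var_order=1,
    ),
    "S2": SystemSpec(
        id="S2",
        K=5,
        max_lag=3,
        noise_laws=(
            _GAUSS,
            NoiseLaw("exponential", (2.0,)),
            NoiseLaw("beta", (1.0, 2.0)),
            NoiseLaw("beta", (2.0, 1.0)),
            _GAUSS,
        ),
        truth=TruthNetwork(
            contemporaneous=frozenset(),
            lagged=frozenset({(1, 2), (1, 3), (4, 5), (5, 4)}),
        ),
        var_order=3,
    ),
    "S3": SystemSpec(
        id="S3",
        K=5,
        max_lag=3,
        noise_laws=(
            _GAUSS,
            NoiseLaw("beta", (1.0, 2.0)),
            NoiseLaw("beta", (1.0, 2.0)),
            _GAUSS,
            NoiseLaw("gamma", (16.0, 0.25)),
        ),
        truth=TruthNetwork(
            contemporaneous=frozenset({(1, 2)}),
            lagged=frozenset({(2, 3), (3, 4), (3, 5)}),
            equation_implied=frozenset({(1, 2)}),
        ),
        var_order=3,
    ),
}


def get_system(system_id: str) -> SystemSpec:
    try:
        return SYSTEMS[system_id.upper()]
    except KeyError:
        raise ConfigurationError(
            f"unknown system {system_id!r}; expected one of {sorted(SYSTEMS)}"
        ) from None


def draw_noise(
    law: NoiseLaw,
    m: int,
    rng: np.random.Generator,
    *,
    gamma_b_is_rate: bool = GAMMA_B_IS_RATE_DEFAULT,
) -> np.ndarray:
    """Draw ``m`` i.i.d. values from ``law`` using ``rng``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    fam = law.family
    if fam == "gaussian":
        mean, sd = law.params
        return rng.normal(mean, sd, size=m)
    if fam == "exponential":
        (rate,) = law.params
        return rng.exponential(1.0 / rate, size=m)
    if fam == "chisq":
        (df,) = law.params
        return rng.chisquare(df, size=m)
    if fam == "beta":
        a, b = law.params
        return rng.beta(a, b, size=m)
    if fam == "gamma":
        shape, b = law.params
        scale = 1.0 / b if gamma_b_is_rate else b
        return rng.gamma(shape, scale, size=m)
    raise ConfigurationError(f"unknown noise family {fam!r}")


def _noise_streams(
    spec: SystemSpec,
    m: int,
    seed: int,
    gamma_b_is_rate: bool,
) -> np.ndarray:
    """m x K matrix of mutually independent noise streams."""
    children = np.random.SeedSequence(seed).spawn(spec.K)
    cols = [
        draw_noise(
            law,
            m,
            np.random.Generator(np.random.PCG64(child)),
            gamma_b_is_rate=gamma_b_is_rate,
        )
        for law, child in zip(spec.noise_laws, children)
    ]
    return np.column_stack(cols)


def _simulate_s1(e: np.ndarray) -> np.ndarray:
    x = np.empty_like(e)
    x[:, 0] = e[:, 0]
    x[:, 1] = e[:, 1]
    x[:, 2] = 0.8 * x[:, 1] + e[:, 2]
    x1 = x[:, 0]
    x[:, 3] = 0.7 * x1 * (x1**2 - 1.0) * np.exp(-(x1**2) / 2.0) + e[:, 3]
    x[:, 4] = 0.3 * x[:, 1] + 0.05 * x[:, 1] ** 2 + e[:, 4]
    return x


def _simulate_s2(e: np.ndarray) -> np.ndarray:
    m = e.shape[0]
    x = np.zeros_like(e)
    for t in range(m):
        x1l1 = x[t - 1, 0] if t >= 1 else 0.0
        x1l2 = x[t - 2, 0] if t >= 2 else 0.0
        x1l3 = x[t - 3, 0] if t >= 3 else 0.0
        x3l2 = x[t - 2, 2] if t >= 2 else 0.0
        x4l1 = x[t - 1, 3] if t >= 1 else 0.0
        x5l1 = x[t - 1, 4] if t >= 1 else 0.0
        x5l2 = x[t - 2, 4] if t >= 2 else 0.0
        x[t, 0] = 0.7 * x1l1 + e[t, 0]
        x[t, 1] = 0.3 * x1l2**2 + e[t, 1]
        x[t, 2] = 0.4 * x1l3 - 0.3 * x3l2 + e[t, 2]
        x[t, 3] = 0.7 * x4l1 - 0.3 * x5l1 * np.exp(-(x5l1**2) / 2.0) + e[t, 3]
        x[t, 4] = 0.5 * x4l1 + 0.2 * x5l2 + e[t, 4]
    return x


def _simulate_s3(e: np.ndarray) -> np.ndarray:
    m = e.shape[0]
    x = np.zeros_like(e)
    for t in range(m):
        x1l2 = x[t - 2, 0] if t >= 2 else 0.0
        x2l1 = x[t - 1, 1] if t >= 1 else 0.0
        x2l3 = x[t - 3, 1] if t >= 3 else 0.0
        x3l1 = x[t - 1, 2] if t >= 1 else 0.0
        x3l2 = x[t - 2, 2] if t >= 2 else 0.0
        x[t, 0] = 0.6 * x1l2 + e[t, 0]
        x[t, 1] = x[t, 0] + 0.3 * x2l1 + e[t, 1]
        x[t, 2] = 0.3 * x3l1 + np.sin(x2l3) + e[t, 2]
        x[t, 3] = 0.4 * x3l2 + e[t, 3]
        x[t, 4] = -3.2 + 0.5 * x3l1**2 + e[t, 4]
    return x


_SIMULATORS = {"S1": _simulate_s1, "S2": _simulate_s2, "S3": _simulate_s3}


def simulate(
    spec: SystemSpec | str,
    n: int = 2000,
    seed: int = 0,
    burn_in: int | None = None,
    *,
    gamma_b_is_rate: bool = GAMMA_B_IS_RATE_DEFAULT,
) -> TimeSeriesPanel:
    """Generate one realization of a benchmark system.

    Parameters
    ----------
    spec : SystemSpec or str
        The system (or its id, one of ``S1``, ``S2``, ``S3``).
    n : int
        Sample size after burn-in (default 2000).
    seed : int
        Seed for the realization; noise streams use independent substreams.
    burn_in : int, optional
        Initial points discarded. Defaults to 0 for S1 (i.i.d. over time)
        and 1000 for the recursive systems; must be >= the system's max lag.
    """
    if isinstance(spec, str):
        spec = get_system(spec)
    if n < 100:
        raise ValueError("n must be >= 100")
    if burn_in is None:
        burn_in = 0 if spec.max_lag == 0 else DEFAULT_BURN_IN
    if burn_in < spec.max_lag:
        raise ValueError(f"burn_in must be >= max_lag ({spec.max_lag})")
    m = n + burn_in
    e = _noise_streams(spec, m, seed, gamma_b_is_rate)
    x = _SIMULATORS[spec.id](e)
    x = x[burn_in:]
    if not np.all(np.isfinite(x)):
        raise SimulationError(f"non-finite values generated for {spec.id}")
    return TimeSeriesPanel(
        data=x,
        labels=[f"X{i}" for i in range(1, spec.K + 1)],
        system_id=spec.id,
        seed=seed,
        meta={
            "burn_in": burn_in,
            "gamma_b_is_rate": gamma_b_is_rate,
            "var_order": spec.var_order,
        },
    )


def truth_of(spec: SystemSpec | str) -> TruthNetwork:
    """Known connectivity structure of a system."""
    if isinstance(spec, str):
        spec = get_system(spec)
    return spec.truth
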