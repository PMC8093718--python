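"""Configuration objects for the simulation and pipeline stages.

The simulation configuration fixes the *study conditions*: two male tactics
(courter, sneaker) with dimorphic trait distributions, a microsatellite locus
panel, per-tactic selection surfaces acting on standardized traits, and
landmark consensus shapes.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

TACTICS = ("courter", "sneaker")
TRAIT_NAMES = ("standard_length", "body_depth", "sword_length")

MISSING = -1  # sentinel allele code for missing calls


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SelectionSurface:
    """Per-tactic fitness surface on tactic-standardized traits.

    Expected offspring count for a male with standardized traits ``z`` is

        lambda = exp(intercept + beta . z + 0.5 * gamma . z**2)

    so that realized (Poisson) fitness is a nonnegative integer, zeros
    included.  ``gamma`` follows the reporting convention in which the
    quadratic regression coefficient is half of gamma; the factor 1/2 in the
    exponent makes the analytic surface and the doubled regression estimate
    agree.
    """

    intercept: float
    beta: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.beta.shape != self.gamma.shape:
            raise ConfigError("beta and gamma must have the same length")
        if np.any(self.gamma >= 1.0):
            # E[exp(0.5*g*z^2)] diverges for g >= 1 under standard normal z
            raise ConfigError("gamma components must be < 1 for finite mean fitness")

    def log_lambda(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return self.intercept + z @ self.beta + 0.5 * (z**2) @ self.gamma

    def expected_mean_fitness(self) -> float:
        """Analytic E[lambda] under z ~ N(0, I)."""
        g = self.gamma
        b = self.beta
        log_m = self.intercept + np.sum(
            b**2 / (2.0 * (1.0 - g)) - 0.5 * np.log1p(-g)
        )
        return float(np.exp(log_m))


def calibrated_intercept(
    mean_fitness: float,
    beta: np.ndarray,
    gamma: np.ndarray,
    mean: np.ndarray | float = 0.0,
    sd: np.ndarray | float = 1.0,
) -> float:
    """Intercept such that E[lambda] = mean_fitness when each standardized
    trait is N(mean_j, sd_j^2) (independent traits).

    The defaults (mean 0, sd 1) cover surfaces evaluated on a group's own
    standard scale; pass the group's moments *on the evaluation scale* when
    the surface acts on population-standardized traits.
    """
    beta = np.asarray(beta, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    m = np.broadcast_to(np.asarray(mean, dtype=float), beta.shape)
    s = np.broadcast_to(np.asarray(sd, dtype=float), beta.shape)
    if mean_fitness <= 0:
        raise ConfigError("mean_fitness must be positive")
    if np.any(gamma * s**2 >= 1.0):
        raise ConfigError("gamma * sd^2 must be < 1 for finite mean fitness")
    gs2 = gamma * s**2
    # E[exp(b z + g/2 z^2)] for z ~ N(m, s^2), per trait
    log_e = (
        beta * m
        + 0.5 * gamma * m**2
        + (beta * s + gamma * m * s) ** 2 / (2.0 * (1.0 - gs2))
        - 0.5 * np.log1p(-gs2)
    )
    return float(np.log(mean_fitness) - np.sum(log_e))


@dataclass
class LocusModel:
    """A microsatellite locus: visible allele pool plus null-allele and
    per-allele typing-error rates."""

    name: str
    allele_sizes: list[int]
    allele_freqs: np.ndarray
    null_freq: float = 0.0
    typing_error: float = 0.0

    def __post_init__(self) -> None:
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if len(self.allele_sizes) != len(self.allele_freqs):
            raise ConfigError(f"{self.name}: sizes and freqs length mismatch")
        if abs(self.allele_freqs.sum() - 1.0) > 1e-12:
            raise ConfigError(f"{self.name}: allele frequencies must sum to 1")
        if np.any(self.allele_freqs < 0):
            raise ConfigError(f"{self.name}: negative allele frequency")
        if not (0.0 <= self.null_freq <= 1.0):
            raise ConfigError(f"{self.name}: null_freq outside [0, 1]")
        if not (0.0 <= self.typing_error <= 1.0):
            raise ConfigError(f"{self.name}: typing_error outside [0, 1]")
        if len(set(self.allele_sizes)) != len(self.allele_sizes):
            raise ConfigError(f"{self.name}: duplicate allele sizes")


@dataclass
class SimulationConfig:
    """Full generator parameterization; see :func:`default_config` for the
    study-condition defaults."""

    n_courter: int
    n_sneaker: int
    n_dams: int
    trait_means: dict[str, np.ndarray]
    trait_sds: dict[str, np.ndarray]
    trait_corr: dict[str, np.ndarray]
    surface: dict[str, SelectionSurface]
    loci: list[LocusModel]
    landmark_consensus: dict[str, np.ndarray]
    landmark_noise_sd: float
    sliders: tuple[tuple[int, int, int], ...]
    seed: int
    trait_names: tuple[str, ...] = TRAIT_NAMES
    # scale on which each tactic's selection surface is evaluated:
    # "tactic"     -- z = (x - mu_tactic) / sigma_tactic (selection on a
    #                 male's trait value relative to his own tactic)
    # "population" -- z = (x - mu_mix) / sigma_mix using the analytic
    #                 two-tactic mixture moments (the same scale on which
    #                 the selection module standardizes, so surface
    #                 coefficients are directly comparable to estimates)
    surface_scale: str = "tactic"

    def __post_init__(self) -> None:
        for n, label in (
            (self.n_courter, "n_courter"),
            (self.n_sneaker, "n_sneaker"),
            (self.n_dams, "n_dams"),
        ):
            if n <= 0:
                raise ConfigError(f"{label} must be > 0")
        p = len(self.trait_names)
        for tactic in TACTICS:
            for d, label in (
                (self.trait_means, "trait_means"),
                (self.trait_sds, "trait_sds"),
            ):
                d[tactic] = np.asarray(d[tactic], dtype=float)
                if d[tactic].shape != (p,):
                    raise ConfigError(f"{label}[{tactic}] must have length {p}")
            if np.any(self.trait_sds[tactic] <= 0):
                raise ConfigError(f"trait_sds[{tactic}] must be positive")
            corr = np.asarray(self.trait_corr[tactic], dtype=float)
            self.trait_corr[tactic] = corr
            if corr.shape != (p, p) or not np.allclose(corr, corr.T):
                raise ConfigError(f"trait_corr[{tactic}] must be symmetric {p}x{p}")
            if np.min(np.linalg.eigvalsh(corr)) <= 0:
                raise ConfigError(f"trait_corr[{tactic}] is not positive-definite")
            if len(self.surface[tactic].beta) != p:
                raise ConfigError(f"surface[{tactic}] dimension != number of traits")
            lm = np.asarray(self.landmark_consensus[tactic], dtype=float)
            self.landmark_consensus[tactic] = lm
            if lm.ndim != 2 or lm.shape[1] != 2 or lm.shape[0] < 3:
                raise ConfigError(f"landmark_consensus[{tactic}] must be k x 2, k >= 3")
        k0 = self.landmark_consensus["courter"].shape[0]
        if self.landmark_consensus["sneaker"].shape[0] != k0:
            raise ConfigError("tactic consensus shapes must share the same k")
        if self.surface_scale not in ("tactic", "population"):
            raise ConfigError("surface_scale must be 'tactic' or 'population'")

    def population_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Analytic mean and sd of each trait over the two-tactic mixture
        (weighted by the configured tactic sizes)."""
        n_c, n_s = self.n_courter, self.n_sneaker
        w_c = n_c / (n_c + n_s)
        w_s = 1.0 - w_c
        mu = w_c * self.trait_means["courter"] + w_s * self.trait_means["sneaker"]
        var = (
            w_c * (self.trait_sds["courter"] ** 2
                   + (self.trait_means["courter"] - mu) ** 2)
            + w_s * (self.trait_sds["sneaker"] ** 2
                     + (self.trait_means["sneaker"] - mu) ** 2)
        )
        return mu, np.sqrt(var)


def default_loci(n_alleles: int = 10, with_null_locus: bool = True) -> list[LocusModel]:
    """Five-locus panel; one locus optionally carries a substantial null
    allele (0.17) and all loci a 0.01 typing-error rate, mirroring the kind
    of panel quality typical of wild-population microsatellite studies."""
    rng = np.random.default_rng(20140301)  # panel is a fixed constant, not per-run
    loci = []
    for i in range(5):
        freqs = rng.dirichlet(np.full(n_alleles, 3.0))
        sizes = [150 + 10 * i + 2 * j for j in range(n_alleles)]
        loci.append(
            LocusModel(
                name=f"msat{i + 1:02d}",
                allele_sizes=sizes,
                allele_freqs=freqs,
                null_freq=0.17 if (with_null_locus and i == 0) else 0.0,
                typing_error=0.01,
            )
        )
    return loci


def _fish_consensus(depth_scale: float, sword: float) -> np.ndarray:
    """Stylized 10-point lateral fish outline in mm-like units.

    Points (1-based): 1 rostrum tip, 2 forehead (semilandmark), 3 anterior
    dorsal-fin insertion, 4 posterior dorsal-fin insertion, 5 dorsal caudal
    insertion, 6 midline last scale (semilandmark), 7 ventral caudal
    insertion, 8 gonopodium insertion, 9 abdomen (semilandmark),
    10 operculum ventral occlusion.
    """
    base = np.array(
        [
            [0.0, 0.0],  # 1 rostrum
            [3.0, 2.2],  # 2 forehead
            [9.0, 4.0],  # 3 ant. dorsal
            [15.0, 3.6],  # 4 post. dorsal
            [22.0, 1.8],  # 5 dorsal caudal
            [23.0 + sword * 0.1, 0.0],  # 6 midline
            [22.0, -1.8],  # 7 ventral caudal
            [14.0, -3.2],  # 8 gonopodium
            [8.0, -3.8],  # 9 abdomen
            [4.0, -2.4],  # 10 operculum
        ]
    )
    out = base.copy()
    out[:, 1] *= depth_scale
    return out


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-condition defaults: 36 courters, 44 sneakers, 43 dams; dimorphic
    trait means (courters ~11.2 mm longer, ~4.5 mm deeper, ~8.6 mm longer
    swords); mean fitness ~6 fry for courters and ~3 for sneakers with
    directional sword selection of opposite sign between tactics."""
    cfg = dict(
        n_courter=36,
        n_sneaker=44,
        n_dams=43,
        trait_means={
            "courter": np.array([39.2, 12.0, 17.6]),
            "sneaker": np.array([28.0, 7.5, 9.0]),
        },
        trait_sds={
            "courter": np.array([2.8, 1.1, 2.5]),
            "sneaker": np.array([2.2, 0.8, 1.5]),
        },
        trait_corr={
            "courter": np.array(
                [[1.0, 0.6, 0.4], [0.6, 1.0, 0.3], [0.4, 0.3, 1.0]]
            ),
            "sneaker": np.array(
                [[1.0, 0.6, 0.4], [0.6, 1.0, 0.3], [0.4, 0.3, 1.0]]
            ),
        },
        surface={
            # traits ordered (standard length, body depth, sword length);
            # courters gain fitness with longer swords, sneakers lose
            "courter": SelectionSurface(
                intercept=calibrated_intercept(6.0, [0.3, 0.0, 0.5], [0.0] * 3),
                beta=np.array([0.3, 0.0, 0.5]),
                gamma=np.zeros(3),
            ),
            "sneaker": SelectionSurface(
                intercept=calibrated_intercept(3.0, [0.0, 0.0, -0.3], [0.0] * 3),
                beta=np.array([0.0, 0.0, -0.3]),
                gamma=np.zeros(3),
            ),
        },
        loci=default_loci(),
        landmark_consensus={
            "courter": _fish_consensus(depth_scale=1.25, sword=17.6),
            "sneaker": _fish_consensus(depth_scale=0.85, sword=9.0),
        },
        landmark_noise_sd=0.15,
        sliders=((0, 1, 2), (4, 5, 6), (7, 8, 9)),  # points 2, 6, 9 slide
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def simulation_config_from_yaml(path: str, seed: int | None = None) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file, overlaying the study-
    condition defaults.

    Recognized keys mirror the dataclass fields; per-tactic mappings
    (trait_means, trait_sds, trait_corr, landmark_consensus) take
    {courter: ..., sneaker: ...} of lists; ``surface`` entries are
    {intercept | mean_fitness, beta, gamma}; ``loci`` is a list of
    {name, allele_sizes, allele_freqs, null_freq, typing_error}.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    overrides: dict = {}
    simple = {
        "n_courter", "n_sneaker", "n_dams", "landmark_noise_sd",
        "surface_scale", "seed",
    }
    for key in simple & set(data):
        overrides[key] = data.pop(key)
    for key in ("trait_means", "trait_sds", "trait_corr",
                "landmark_consensus"):
        if key in data:
            overrides[key] = {
                t: np.asarray(v, dtype=float) for t, v in data.pop(key).items()
            }
    if "sliders" in data:
        overrides["sliders"] = tuple(
            tuple(int(i) for i in trip) for trip in data.pop("sliders")
        )
    if "surface" in data:
        surf = {}
        for tactic, spec in data.pop("surface").items():
            beta = np.asarray(spec.get("beta", [0.0, 0.0, 0.0]), dtype=float)
            gamma = np.asarray(spec.get("gamma", np.zeros_like(beta)),
                               dtype=float)
            if "intercept" in spec:
                intercept = float(spec["intercept"])
            else:
                intercept = calibrated_intercept(
                    float(spec.get("mean_fitness", 4.0)), beta, gamma)
            surf[tactic] = SelectionSurface(intercept, beta, gamma)
        overrides["surface"] = surf
    if "loci" in data:
        overrides["loci"] = [
            LocusModel(
                name=l["name"],
                allele_sizes=[int(s) for s in l["allele_sizes"]],
                allele_freqs=np.asarray(l["allele_freqs"], dtype=float),
                null_freq=float(l.get("null_freq", 0.0)),
                typing_error=float(l.get("typing_error", 0.0)),
            )
            for l in data.pop("loci")
        ]
    if data:
        raise ConfigError(f"unknown simulation config keys: {sorted(data)}")
    if seed is not None:
        overrides["seed"] = seed
    return default_config(**overrides) if "seed" in overrides else \
        default_config(seed=0, **overrides)


@dataclass
class RunConfig:
    """End-to-end pipeline settings.  Defaults follow the published analysis
    protocol: 0.01 genotyping error, 0.95/0.80 assignment confidence, 9,999
    fitness permutations, >= 10% PC-axis retention, and a 1,000/5,000/1,000
    Markov-chain schedule for the Hardy-Weinberg exact test."""

    seed: int = 0
    error_rate: float = 0.01
    strict_level: float = 0.95
    relaxed_level: float = 0.80
    sim_offspring: int = 10_000
    n_candidates: int | None = None  # None -> use number of genotyped males
    prop_sampled: float = 0.87
    prop_typed: float = 1.0
    min_typed_loci: int = 2
    max_dam_mismatch_loci: int = 0
    n_perm: int = 9_999
    alpha: float = 0.05
    retain_threshold: float = 0.10
    hwe_dememorization: int = 1_000
    hwe_batches: int = 5_000
    hwe_iter_per_batch: int = 1_000
    ld_permutations: int = 2_000
    art_coding: str = "sum"  # "sum" (-1/2, +1/2) or "treatment"
    within_tactic_z: bool = False
    plus_one_p: bool = False
    p_method: str = "two_sided"  # or "directional" (sign-picked tail)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}
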