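"""Ground-truth population generator.

Emulates the data a wild-population selection study collects: per-male
traits drawn from tactic-specific multivariate normals, offspring counts
from known per-tactic selection surfaces (Poisson, log link), Mendelian
microsatellite inheritance with null alleles and typing error, and landmark
configurations scattered around tactic consensus shapes then pushed through
random similarity transforms.

Every operation takes or derives an explicit seed; a fixed seed yields
identical output (numpy Generator with the default PCG64 bit generator).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import MISSING, TACTICS, ConfigError, LocusModel, SimulationConfig
from .datatypes import GenotypeTable, LandmarkSet, Pedigree

__all__ = [
    "simulate_population",
    "simulate_genotypes",
    "simulate_landmarks",
    "simulate_study",
]


def simulate_population(config: SimulationConfig) -> tuple[pd.DataFrame, Pedigree]:
    """Draw males, their traits and their realized reproductive success.

    Traits for each tactic come from N(mu_t, D_t C_t D_t) (D = diag of sds,
    C = correlation matrix).  A male's expected offspring count is his
    tactic's surface evaluated on his standardized traits -- standardized by
    his own tactic's configured moments, or by the analytic population
    mixture moments, per ``config.surface_scale``.  Realized counts are
    Poisson.  Each offspring is assigned a uniformly random dam and the sire
    that produced it.

    Returns a trait table (one row per male: id, tactic, trait columns,
    n_offspring) and the pedigree with ground-truth paternity.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    counts = {"courter": config.n_courter, "sneaker": config.n_sneaker}
    male_ids: list[str] = []
    lam_all = []
    for tactic in TACTICS:
        n = counts[tactic]
        mu = config.trait_means[tactic]
        sd = config.trait_sds[tactic]
        cov = np.outer(sd, sd) * config.trait_corr[tactic]
        x = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
        if config.surface_scale == "population":
            mu_mix, sd_mix = config.population_moments()
            zeta = (x - mu_mix) / sd_mix
        else:
            zeta = (x - mu) / sd
        lam = np.exp(config.surface[tactic].log_lambda(zeta))
        ids = [f"{tactic[0].upper()}{i + 1:03d}" for i in range(n)]
        male_ids.extend(ids)
        lam_all.append(lam)
        for j, mid in enumerate(ids):
            rows.append(
                {"id": mid, "tactic": tactic}
                | dict(zip(config.trait_names, x[j]))
            )
    traits = pd.DataFrame(rows)
    lam_all = np.concatenate(lam_all)
    n_off = rng.poisson(lam_all)
    traits["n_offspring"] = n_off
    # sword "extension beyond the caudal fin": a fixed 12 mm visibility
    # threshold sits between the tactic sword means, so courters nearly all
    # show an extension and most sneakers do not
    traits["sword_extension"] = traits["sword_length"] > 12.0

    dam_ids = [f"D{i + 1:03d}" for i in range(config.n_dams)]
    links = []
    total = int(n_off.sum())
    dams_for_offspring = rng.integers(0, config.n_dams, size=total)
    j = 0
    for mid, c in zip(male_ids, n_off):
        for _ in range(int(c)):
            links.append(
                {
                    "offspring_id": f"F{j + 1:04d}",
                    "dam_id": dam_ids[dams_for_offspring[j]],
                    "sire_id": mid,
                }
            )
            j += 1
    pedigree = Pedigree(
        male_ids=male_ids,
        dam_ids=dam_ids,
        links=pd.DataFrame(links, columns=["offspring_id", "dam_id", "sire_id"]),
    )
    return traits, pedigree


def _draw_founder_alleles(rng, locus: LocusModel, n: int) -> np.ndarray:
    """(n, 2) *true* allele indices; index len(alleles) encodes the null."""
    m = len(locus.allele_sizes)
    probs = np.append(locus.allele_freqs * (1.0 - locus.null_freq), locus.null_freq)
    return rng.choice(m + 1, size=(n, 2), p=probs)


def _observe(rng, locus: LocusModel, true_idx: np.ndarray) -> np.ndarray:
    """Apply null-allele masking and typing error to true allele indices,
    returning observed fragment sizes with MISSING for dropouts.

    A heterozygote carrying one null shows as an apparent homozygote for the
    visible allele; a null/null genotype fails to amplify entirely.  Typing
    error independently replaces each observed allele with a draw from the
    population frequencies (the error class the likelihood model assumes).
    """
    m = len(locus.allele_sizes)
    idx = true_idx.copy()
    null = idx == m
    both_null = null.all(axis=1)
    one_null = null.any(axis=1) & ~both_null
    # visible allele duplicated over the null one
    vis = np.where(null[one_null, 0], idx[one_null, 1], idx[one_null, 0])
    idx[one_null, 0] = vis
    idx[one_null, 1] = vis

    if locus.typing_error > 0:
        err = rng.random(idx.shape) < locus.typing_error
        replacements = rng.choice(m, size=idx.shape, p=locus.allele_freqs)
        idx = np.where(err, replacements, idx)

    sizes = np.asarray(locus.allele_sizes, dtype=int)
    out = np.where(both_null[:, None], MISSING, sizes[np.minimum(idx, m - 1)])
    out[both_null] = MISSING
    return out


def simulate_genotypes(
    pedigree: Pedigree, loci: list[LocusModel], seed: int
) -> GenotypeTable:
    """Founder genotypes from the allele-frequency models; offspring inherit
    one uniformly chosen allele per parent.  Null alleles and typing error
    corrupt only the *observed* calls; inheritance acts on true alleles.
    """
    rng = np.random.default_rng(seed)
    males, dams = pedigree.male_ids, pedigree.dam_ids
    links = pedigree.links
    dam_row = {d: i for i, d in enumerate(dams)}
    sire_row = {s: i for i, s in enumerate(males)}
    missing_parents = (set(links["dam_id"]) - set(dams)) | (
        set(links["sire_id"]) - set(males)
    )
    if missing_parents:
        raise ValueError(f"offspring reference unknown parents: {sorted(missing_parents)[:5]}")

    n_off = len(links)
    ids = males + dams + pedigree.offspring_ids
    roles = ["sire"] * len(males) + ["dam"] * len(dams) + ["offspring"] * n_off
    dam_col = [None] * (len(males) + len(dams)) + list(links["dam_id"])

    calls: dict[str, np.ndarray] = {}
    for locus in loci:
        true_sires = _draw_founder_alleles(rng, locus, len(males))
        true_dams = _draw_founder_alleles(rng, locus, len(dams))
        pick = rng.integers(0, 2, size=(n_off, 2))
        di = np.array([dam_row[d] for d in links["dam_id"]], dtype=int)
        si = np.array([sire_row[s] for s in links["sire_id"]], dtype=int)
        true_off = np.stack(
            [
                true_dams[di, pick[:, 0]],
                true_sires[si, pick[:, 1]],
            ],
            axis=1,
        )
        obs = np.concatenate(
            [
                _observe(rng, locus, true_sires),
                _observe(rng, locus, true_dams),
                _observe(rng, locus, true_off),
            ]
        )
        calls[locus.name] = obs
    return GenotypeTable(ids=ids, roles=roles, dam_ids=dam_col, calls=calls)


def simulate_landmarks(
    n_per_tactic: dict[str, int],
    consensus: dict[str, np.ndarray],
    noise_sd: float,
    seed: int,
    sliders: tuple[tuple[int, int, int], ...] = (),
    ids: dict[str, list[str]] | None = None,
) -> LandmarkSet:
    """Configurations = tactic consensus + isotropic Gaussian landmark noise,
    then a random rotation, translation and positive scale per specimen, so
    superimposition has genuine work to do."""
    rng = np.random.default_rng(seed)
    all_coords, all_ids = [], []
    for tactic in sorted(n_per_tactic):
        n = n_per_tactic[tactic]
        base = np.asarray(consensus[tactic], dtype=float)
        if base.ndim != 2 or base.shape[0] < 3 or base.shape[1] != 2:
            raise ConfigError("consensus must be k x 2 with k >= 3")
        for i in range(n):
            cfg = base + rng.normal(0.0, noise_sd, size=base.shape)
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            scale = np.exp(rng.normal(0.0, 0.3))
            shift = rng.normal(0.0, 50.0, size=2)
            all_coords.append(scale * cfg @ rot.T + shift)
            if ids is not None:
                all_ids.append(ids[tactic][i])
            else:
                all_ids.append(f"{tactic}_{i + 1:03d}")
    return LandmarkSet(
        ids=all_ids, coords=np.stack(all_coords), sliders=tuple(sliders)
    )


def simulate_study(config: SimulationConfig):
    """One full synthetic study: traits+pedigree, genotypes, landmarks.

    Genotype and landmark seeds are derived deterministically from the
    config seed so the three artifacts are jointly reproducible.
    """
    traits, pedigree = simulate_population(config)
    genotypes = simulate_genotypes(
        pedigree, config.loci, seed=(config.seed * 1_000_003 + 1) % (2**31)
    )
    per_tactic_ids = {
        t: list(traits.loc[traits["tactic"] == t, "id"]) for t in TACTICS
    }
    landmarks = simulate_landmarks(
        n_per_tactic={t: len(v) for t, v in per_tactic_ids.items()},
        consensus=config.landmark_consensus,
        noise_sd=config.landmark_noise_sd,
        seed=(config.seed * 1_000_003 + 2) % (2**31),
        sliders=config.sliders,
        ids=per_tactic_ids,
    )
    return traits, pedigree, genotypes, landmarks
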