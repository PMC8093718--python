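import numpy as np
import pytest

import tactsel as ts


@pytest.fixture(scope="session")
def small_study():
    """One fixed synthetic study at the default (field-study-sized)
    conditions; shared across read-only tests."""
    cfg = ts.default_config(seed=42)
    traits, pedigree, genotypes, landmarks = ts.simulate_study(cfg)
    return {
        "config": cfg,
        "traits": traits,
        "pedigree": pedigree,
        "genotypes": genotypes,
        "landmarks": landmarks,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def clean_loci(n_loci: int = 5, n_alleles: int = 10) -> list[ts.LocusModel]:
    """Equifrequent multi-allele panel with no nulls and no typing error."""
    return [
        ts.LocusModel(
            name=f"L{i}",
            allele_sizes=[100 + 10 * i + 2 * j for j in range(n_alleles)],
            allele_freqs=np.full(n_alleles, 1.0 / n_alleles),
            null_freq=0.0,
            typing_error=0.0,
        )
        for i in range(n_loci)
    ]


def uniform_config(n_per_tactic: int, beta, gamma=None, mean_fitness=4.0,
                   seed=0, **kw) -> ts.SimulationConfig:
    """Config where both tactics share trait moments and surface, so the
    population behaves as one homogeneous group (handy for closed-form
    checks against single-group theory)."""
    beta = np.asarray(beta, dtype=float)
    gamma = np.zeros_like(beta) if gamma is None else np.asarray(gamma, float)
    surface = ts.SelectionSurface(
        intercept=ts.calibrated_intercept(mean_fitness, beta, gamma),
        beta=beta,
        gamma=gamma,
    )
    means = np.array([30.0, 8.0, 10.0])
    sds = np.array([2.0, 1.0, 1.5])
    eye = np.eye(3)
    return ts.default_config(
        seed=seed,
        n_courter=n_per_tactic,
        n_sneaker=n_per_tactic,
        n_dams=max(40, n_per_tactic // 5),
        trait_means={"courter": means, "sneaker": means.copy()},
        trait_sds={"courter": sds, "sneaker": sds.copy()},
        trait_corr={"courter": eye, "sneaker": eye.copy()},
        surface={"courter": surface,
                 "sneaker": ts.SelectionSurface(surface.intercept,
                                                beta.copy(), gamma.copy())},
        **kw,
    )
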