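import numpy as np
import pytest

import netcomm as nc


@pytest.fixture(scope="session")
def toy():
    """The six-node demonstration network plus a label→index map."""
    net = nc.toy_network()
    return net, {lab: k for k, lab in enumerate(net.labels)}


@pytest.fixture(scope="session")
def small_geometric():
    """A small connected geometric network for generic numeric checks."""
    spec = nc.CohortSpec(n_nodes=12, n_subjects=2, target_density=0.35,
                         noise_sd=0.0, seed=7)
    _, group = nc.generate_geometric_cohort(spec)
    return group


def random_connected_network(n, density, seed):
    spec = nc.CohortSpec(n_nodes=n, n_subjects=1, target_density=density,
                         noise_sd=0.0, seed=seed)
    _, group = nc.generate_geometric_cohort(spec)
    return group


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def planted_navigation_benchmark(n_null, seed, n_nodes=24, n_subjects=12,
                                 noise_sd=0.1):
    """Observed vs rewired-null asymmetry correlations.

    A geometric group network's navigation asymmetry is the planted
    directionality: two independent noisy cohorts built around its
    navigation-efficiency matrix yield an observed correlation of their
    asymmetry t-statistics, while degree-preserving rewired surrogates of
    the group network (navigation recomputed, same cohort noise) yield the
    null distribution.  Returns ``(r_observed, null_correlations)``.
    """
    spec = nc.CohortSpec(n_nodes=n_nodes, n_subjects=n_subjects,
                         target_density=0.22, noise_sd=0.05, seed=seed)
    _, group = nc.generate_geometric_cohort(spec)
    E0 = nc.compute_measure(group, "nav").eff
    A_ref = nc.pairwise_asymmetry_test(
        nc.noisy_tensor_from_matrix(E0, n_subjects, noise_sd=noise_sd,
                                    seed=seed + 1)).A
    A_obs = nc.pairwise_asymmetry_test(
        nc.noisy_tensor_from_matrix(E0, n_subjects, noise_sd=noise_sd,
                                    seed=seed + 2)).A
    r_obs = nc.asymmetry_correlation(A_obs, A_ref)[0]
    null_rs = []
    for k in range(n_null):
        rewired, _ = nc.rewire_degree_preserving(group, seed=seed + 100 + k)
        E_null = nc.compute_measure(rewired, "nav").eff
        A_null = nc.pairwise_asymmetry_test(
            nc.noisy_tensor_from_matrix(E_null, n_subjects, noise_sd=noise_sd,
                                        seed=seed + 2)).A
        null_rs.append(nc.asymmetry_correlation(A_null, A_ref)[0])
    return r_obs, null_rs
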