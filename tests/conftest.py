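import pytest

import tmtpanel as tp


@pytest.fixture(scope="session")
def default_config() -> tp.SimConfig:
    return tp.SimConfig(seed=0)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """Full synthetic dataset under the default study conditions, seed 0."""
    catalog = tp.make_proteome(default_config)
    truth = tp.plan_truth(catalog, default_config)
    exp = tp.simulate_tmt(truth, default_config, catalog)
    return default_config, catalog, truth, exp


@pytest.fixture(scope="session")
def default_ratios(default_dataset):
    _, _, _, exp = default_dataset
    retained = tp.filter_min_replicates(exp, k=2)
    return retained, tp.compute_normalized_ratios(exp, retained)


def brute_force_regions(dep_sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Independent Venn oracle: per-protein signature enumeration by set algebra."""
    mutants = sorted(dep_sets)
    counts: dict[tuple[str, ...], int] = {}
    union = set().union(*dep_sets.values())
    for protein in union:
        sig = tuple(m for m in mutants if protein in dep_sets[m])
        counts[sig] = counts.get(sig, 0) + 1
    return counts


def hypergeom_tail_exact(k: int, N: int, K: int, n: int) -> float:
    """Exact upper-tail P(X >= k) via integer arithmetic (oracle)."""
    from math import comb

    denom = comb(N, n)
    total = 0
    for i in range(k, min(n, K) + 1):
        if n - i <= N - K:
            total += comb(K, i) * comb(N - K, n - i)
    return total / denom
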