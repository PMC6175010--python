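"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from repeatgate import CcsRead, SimulationSpec, get_design, simulate_sample


def brute_force_min_edits(sequence: str, site: str) -> int:
    """Independent oracle: minimum Levenshtein distance of the site to any
    substring of the sequence, by full per-start dynamic programming.

    For each start offset a standard edit-distance DP over the suffix is
    run; the minimum over its final row is the cheapest alignment beginning
    there.  O(len(site) * len(sequence)^2) — fine at test scale, and
    structurally unlike the semi-global suffix DP under test.
    """
    n, m = len(sequence), len(site)
    best = m  # aligning against the empty substring deletes the whole site
    for start in range(n):
        prev = list(range(m + 1))  # dist(sequence[start:start], site[:j]) = j
        local_best = prev[m]
        for i in range(start, n):
            ci = sequence[i]
            cur = [i - start + 1] + [0] * m
            for j in range(1, m + 1):
                cur[j] = min(prev[j - 1] + (ci != site[j - 1]),
                             prev[j] + 1,
                             cur[j - 1] + 1)
            prev = cur
            if prev[m] < local_best:
                local_best = prev[m]
        if local_best < best:
            best = local_best
    return best


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT")) for _ in range(n))


def perfect_htt_read(cag: int = 21, ccg: int = 7, l1: int = 913,
                     l2: int = 155, seed: int = 0) -> tuple[CcsRead, str]:
    """Error-free HTT-design read plus its expected repeat tract."""
    design = get_design("HTT")
    rng = np.random.default_rng(seed)
    tract = "CAG" * cag + design.linker + "CCG" * ccg
    up = random_dna(rng, l1 - len(design.upstream_site)) + design.upstream_site
    down = design.downstream_site + random_dna(rng, l2 - len(design.downstream_site))
    return CcsRead("perfect", up + tract + down), tract


@pytest.fixture(scope="session")
def htt_design():
    return get_design("HTT")


@pytest.fixture(scope="session")
def fmr1_design():
    return get_design("FMR1")


@pytest.fixture(scope="session")
def noisy_htt_sample(htt_design):
    """One seeded 1%-indel HTT sample with truth, shared across tests."""
    spec = SimulationSpec(design=htt_design,
                          genotype={"CAG": (21, 29), "CCG": (7, 7)},
                          n_reads=300, error_rates=(0.0, 0.005, 0.005),
                          seed=42)
    reads, truth = simulate_sample(spec)
    return spec, reads, truth
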