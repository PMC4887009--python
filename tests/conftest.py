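import numpy as np
import pandas as pd
import pytest

from refstab import SimConfig, simulate_cohort

CANDIDATE_PANEL = [
    "CHCHD1", "GNB2L1", "IPO8", "LASP1", "RPL27A", "RPS12", "SOD1", "SRSF9", "TMBIM6",
]
STABLE_TRIO = ["CHCHD1", "SRSF9", "TMBIM6"]
TARGET_GENES = ["DDIT3", "ERO1A", "STC2"]


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic patient cohort shared by read-only tests."""
    return simulate_cohort(SimConfig(seed=20))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_log_matrix(rng, n_genes, n_samples, sd=0.5):
    """Random complete gene x sample log2 matrix with alphabetical gene ids."""
    genes = [f"G{chr(65 + i)}" for i in range(n_genes)]
    samples = [f"S{j}" for j in range(n_samples)]
    vals = rng.normal(8.0, sd, size=(n_genes, n_samples))
    return pd.DataFrame(vals, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# Independent brute-force geNorm oracle (deliberately naive; used only to
# cross-check the implementation).
# ---------------------------------------------------------------------------

def brute_pairwise_sd(m, g1, g2):
    diffs = [m.at[g1, s] - m.at[g2, s] for s in m.columns]
    mean = sum(diffs) / len(diffs)
    return (sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1)) ** 0.5


def brute_m_values(m):
    out = {}
    for g in m.index:
        others = [k for k in m.index if k != g]
        out[g] = sum(brute_pairwise_sd(m, g, k) for k in others) / len(others)
    return out


def brute_stepwise(m):
    """Removal order + final pair by full recomputation each step."""
    remaining = m.copy()
    removed = []
    while remaining.shape[0] > 2:
        mv = brute_m_values(remaining)
        worst_val = max(mv.values())
        worst = max(g for g, v in mv.items() if v == worst_val)
        removed.append(worst)
        remaining = remaining.drop(index=worst)
    return sorted(remaining.index) + removed[::-1]
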