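import numpy as np
import pandas as pd
import pytest

import loopshift as ls


@pytest.fixture(scope="session")
def genome():
    return ls.GenomeModel.from_sizes({"chr1": 10_000_000, "chr2": 10_000_000}, 25_000)


@pytest.fixture(scope="session")
def sim_map():
    """One simulated contact map with planted structure, balanced + expected.

    Session-scoped: several test modules reuse it read-only.
    """
    cfg = ls.SimulationConfig(seed=1)
    mats, truth = ls.simulate_contact_map(cfg)
    bal = {c: ls.ice_balance(ls.filter_min_distance(m, 20_000)) for c, m in mats.items()}
    exp = {c: ls.expected_by_distance(m) for c, m in bal.items()}
    return {"cfg": cfg, "raw": mats, "bal": bal, "exp": exp, "truth": truth}


@pytest.fixture(scope="session")
def perturbation():
    """One simulated depletion experiment (untreated/treated pair)."""
    return ls.simulate_perturbation_experiment(ls.SimulationConfig(seed=1))


def random_peakset(genome, rng, n, max_len=50_000):
    chroms = np.asarray(genome.chrom_names)[rng.integers(0, len(genome.chrom_names), n)]
    starts = rng.integers(0, 9_000_000, n)
    lengths = rng.integers(1, max_len, n)
    return ls.PeakSet(
        pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + lengths}), genome
    )
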