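import numpy as np
import pandas as pd
import pytest

import polwave.simulate as sim


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(n_genes=8, seed=101)


@pytest.fixture(scope="session")
def small_genome(small_config):
    genes, sizes = sim.make_genome(small_config)
    pas = sim.make_pas(genes, small_config)
    return genes, pas, sizes


def brute_force_assign(ends: pd.DataFrame, pas: pd.DataFrame, window: int) -> np.ndarray:
    """Exhaustive nearest-PAS search with the distal-ward tie rule.

    Deliberately written as plain loops, independent of the vectorized
    implementation it checks.
    """
    pas = pas.reset_index(drop=True)
    sites = list(
        zip(pas.index, pas["chrom"], pas["pos"].astype(int), pas["strand"])
    )
    out = np.full(len(ends), -1, dtype=int)
    for ei, e in enumerate(ends.itertuples(index=False)):
        epos = int(e.start)
        best, best_pos, best_dist = -1, None, None
        for pi, chrom, pos, strand in sites:
            if chrom != e.chrom or strand != e.strand:
                continue
            d = abs(epos - pos)
            if d > window:
                continue
            if best_dist is None or d < best_dist:
                best, best_pos, best_dist = pi, pos, d
            elif d == best_dist:
                # tie: prefer the transcriptionally downstream (distal-ward) site
                if e.strand == "+" and pos > best_pos:
                    best, best_pos = pi, pos
                if e.strand == "-" and pos < best_pos:
                    best, best_pos = pi, pos
        out[ei] = best
    return out


@pytest.fixture(scope="session")
def brute_assign():
    return brute_force_assign
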