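import numpy as np
import pandas as pd
import pytest

import erna_scout as es


@pytest.fixture(scope="session")
def study():
    """One full synthetic study at the default conditions, run end to end.

    Shared across test modules because fragment-level simulation dominates
    suite runtime; everything downstream is deterministic given the seed.
    """
    cfg = es.SimConfig(seed=1)
    genome, sim, surv, truth = es.simulate_dataset(cfg)
    union = es.merge_peak_sets([genome.peaks], 250)
    zones = es.build_exclusion_zones(genome.annotation)
    intergenic = es.filter_intergenic_peaks(union, zones)
    cm = es.build_count_matrix(intergenic, sim.fragment_sets)
    mask, cand = es.filter_candidates(cm)
    cand_regions = es.RegionSet(
        [iv for iv, k in zip(intergenic, mask) if k], sorted=True, merged=True
    )
    fpm = pd.DataFrame(
        es.compute_fpm(cand), index=cand.region_ids, columns=cand.sample_ids
    )
    de = es.run_differential(cand, sim.metadata["cohort"].to_numpy())
    return {
        "cfg": cfg,
        "genome": genome,
        "sim": sim,
        "surv": surv,
        "truth": truth,
        "union": union,
        "zones": zones,
        "intergenic": intergenic,
        "cm": cm,
        "mask": mask,
        "cand": cand,
        "cand_regions": cand_regions,
        "fpm": fpm,
        "de": de,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
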