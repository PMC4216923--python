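import numpy as np
import pandas as pd
import pytest

from maepi import SimulationConfig, generate_genome


def make_records(site_counts, contexts=None):
    """Build a wide cytosine table from per-sample (meth, unmeth) lists.

    ``site_counts`` maps sample -> list of (meth, unmeth) tuples, one per
    site; sites are placed 100 bp apart on chr1, + strand, context CG
    unless ``contexts`` overrides.
    """
    n = len(next(iter(site_counts.values())))
    df = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, n + 1) * 100,
        "strand": "+",
        "context": contexts if contexts is not None else ["CG"] * n,
        "tri": "CGA",
    })
    for sample, counts in site_counts.items():
        arr = np.asarray(counts)
        df[f"{sample}:meth"] = arr[:, 0]
        df[f"{sample}:unmeth"] = arr[:, 1]
    return df


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, chromosome_lengths=(50_000, 50_000))


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def dmp_study():
    """DMP calls from two default-rate simulations (different seeds),
    for treatment-contrast and enrichment checks."""
    from maepi import (MethylationCallPolicy, call_dmps, generate_genome,
                       remove_parental_dmps, simulate_bisulfite_counts,
                       simulate_pedigree, site_universe)

    policy = MethylationCallPolicy()
    runs = []
    for seed in (21, 22):
        cfg = SimulationConfig(seed=seed,
                               chromosome_lengths=(250_000, 250_000))
        genome, annotation = generate_genome(cfg)
        truth, _ = simulate_pedigree(cfg, genome, annotation)
        records, _ = simulate_bisulfite_counts(truth, cfg)
        parental = [s.sample_id for s in truth.bisulfite_samples
                    if s.role == "parental"]
        derived = [s.sample_id for s in truth.bisulfite_samples
                   if s.role == "derived"]
        _, analyzable = site_universe(records, parental, derived, policy)
        mask, _ = remove_parental_dmps(records, parental, policy, analyzable)
        dmps = call_dmps(records, parental, derived, policy, mask)
        runs.append({
            "config": cfg, "annotation": annotation, "records": records,
            "dmps": dmps, "parental": parental, "derived": derived,
            "analyzable": analyzable,
            "treatments": {s.sample_id: s.treatment
                           for s in truth.bisulfite_samples},
        })
    return runs


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete on-disk synthetic input set, built once per session."""
    from maepi import make_fixture

    out = tmp_path_factory.mktemp("fixture")
    config = SimulationConfig(seed=7, chromosome_lengths=(50_000, 50_000))
    run_cfg = make_fixture(config, out)
    return out, run_cfg, config
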