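"""Shared fixtures: one synthetic cohort (default study conditions) built
once per session and reused across module tests and acceptance tests."""

from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from jxpepdb.genome_io import classify_junctions
from jxpepdb.junctiondb import build_junction_database
from jxpepdb.search_postprocess import assemble_combined_db, read_psm_table
from jxpepdb.synthetic_data import (
    SimConfig,
    generate_genome_and_models,
    generate_junctions,
    generate_psms,
    generate_reference_proteins,
)


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def sim_data(default_cfg):
    """Synthetic genome, gene models, junctions with planted truth, and the
    junction-peptide database built from them."""
    genome, models = generate_genome_and_models(default_cfg)
    junctions, truth, genome = generate_junctions(default_cfg, models, genome)
    classified = classify_junctions(junctions, models)
    entries, stats = build_junction_database(classified, genome, models)
    return SimpleNamespace(
        cfg=default_cfg,
        genome=genome,
        models=models,
        junctions=junctions,
        classified=classified,
        truth=truth,
        entries=entries,
        stats=stats,
    )


@pytest.fixture(scope="session")
def psm_data(default_cfg, sim_data, tmp_path_factory):
    """Simulated PSM table over the combined target+decoy database, parsed
    back through the PSM reader."""
    reference = generate_reference_proteins(default_cfg)
    combined = assemble_combined_db(reference, sim_data.entries)
    psm_df, truth = generate_psms(default_cfg, combined, sim_data.entries)
    path = tmp_path_factory.mktemp("psms") / "psms.tsv"
    psm_df.to_csv(path, sep="\t", index=False)
    psms = read_psm_table(path, combined)
    labels = dict(zip(truth.spectrum_id, truth.label))
    return SimpleNamespace(
        reference=reference,
        combined=combined,
        psm_df=psm_df,
        truth=truth,
        labels=labels,
        psms=psms,
    )
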