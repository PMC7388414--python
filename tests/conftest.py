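import pytest

from venomics import datasets
from venomics.assembly import build_coverage, is_fully_sequenced
from venomics.io import PipelineConfig
from venomics.synthetic import (
    SyntheticConfig,
    generate_toxins,
    simulate_evidence,
    simulate_ion_map,
)
from venomics.validation import cluster_ions, filter_ions, match_toxins
from venomics.chemistry import ToxinRecord


@pytest.fixture(scope="session")
def reference_toxins():
    return datasets.load_reference_toxins()


@pytest.fixture(scope="session")
def reference_toxin_table():
    return datasets.load_reference_toxin_table()


def run_synthetic_recovery(seed: int):
    """End-to-end synthetic run: returns (sensitivity, false_validations).

    Sensitivity: fraction of planted toxins validated from the full ion
    map plus digest evidence.  False validations: toxins validated when
    matching against the decoy-only ion subset.
    """
    config = SyntheticConfig(seed=seed)
    toxins = generate_toxins(config)
    evidence = simulate_evidence(toxins, config)
    ions = simulate_ion_map(toxins, config)
    pipeline = PipelineConfig(seed=seed)

    candidates = [
        ToxinRecord(t.id, t.mature, t.ss_bonds) for t in toxins
    ]
    by_parent = {}
    for ev in evidence:
        by_parent.setdefault(ev.parent_id, []).append(ev)
    msms = {}
    for t in toxins:
        cov = build_coverage(by_parent.get(t.id, []), t.precursor)
        span = (t.mature_start, t.mature_start + len(t.mature) - 1)
        msms[t.id], _ = is_fully_sequenced(cov, span)

    kept = filter_ions(ions, pipeline.min_intensity)
    clusters = cluster_ions(kept, pipeline.tolerance_ppm)
    reports = match_toxins(
        candidates, clusters, pipeline.tolerance_ppm, msms_supported=msms
    )
    sensitivity = sum(r.validated for r in reports) / len(reports)

    n_true = len(toxins) * config.ions_per_toxin
    decoy_only = filter_ions(ions[n_true:], pipeline.min_intensity)
    decoy_clusters = cluster_ions(decoy_only, pipeline.tolerance_ppm)
    decoy_reports = match_toxins(
        candidates, decoy_clusters, pipeline.tolerance_ppm, msms_supported=msms
    )
    false_validations = sum(r.validated for r in decoy_reports)
    return sensitivity, false_validations
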