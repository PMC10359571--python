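import json
from pathlib import Path

import pytest

from lynchledger.report import PipelineConfig, run_pipeline
from lynchledger.synthgen import GeneratorConfig, generate_patients

KEY = "unit-test-key"


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7, n_patients=400)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_patients(small_config)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline execution shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(generator=GeneratorConfig(seed=11, n_patients=800),
                         key=KEY, outdir=str(outdir))
    manifest = run_pipeline(cfg)
    return cfg, outdir, manifest


def read_truth(outdir: Path):
    meta = None
    patients = []
    with open(outdir / "synthetic" / "truth_ledger.jsonl") as fh:
        for line in fh:
            rec = json.loads(line)
            if rec["type"] == "meta":
                meta = rec
            else:
                patients.append(rec)
    return meta, patients
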