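"""Shared fixtures: a desk-scale synthetic run and the headline-scale preset.

Both are session-scoped — generation and the full pipeline are deterministic,
so every test sees the same objects.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from snpcircuit import SyntheticConfig, generate_bundle, paper_scale_bundle
from snpcircuit.pipeline import RunConfig, run_pipeline

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """Desk-scale synthetic bundle (seed 0), written out and piped end to end."""
    indir = tmp_path_factory.mktemp("desk_in")
    outdir = tmp_path_factory.mktemp("desk_out")
    panel, truth, bundle = generate_bundle(SyntheticConfig(seed=0))
    bundle.write_dir(panel, indir)
    result = run_pipeline(RunConfig(indir=str(indir), outdir=str(outdir)))
    return {
        "panel": panel,
        "truth": truth,
        "bundle": bundle,
        "result": result,
        "indir": indir,
        "outdir": outdir,
    }


@pytest.fixture(scope="session")
def paper_run(tmp_path_factory):
    """Headline-scale preset (seed 1) run end to end."""
    indir = tmp_path_factory.mktemp("paper_in")
    outdir = tmp_path_factory.mktemp("paper_out")
    panel, truth, bundle = paper_scale_bundle(1)
    bundle.write_dir(panel, indir)
    result = run_pipeline(RunConfig(indir=str(indir), outdir=str(outdir)))
    return {"panel": panel, "truth": truth, "bundle": bundle, "result": result,
            "indir": indir, "outdir": outdir}
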