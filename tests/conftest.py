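from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory) -> Path:
    """One full synthetic fixture bundle shared across tests."""
    from sculpin import synth

    out = tmp_path_factory.mktemp("fixtures")
    synth.simulate_all(seed=11, out_dir=out)
    return out


@pytest.fixture(scope="session")
def rnr_inputs(fixture_bundle):
    """Parsed RNR inputs (gene map, PSL per organism, NT hits, quant)."""
    from sculpin import read_blast_tab, read_gene_map, read_psl, read_quant, synth
    from sculpin.synth import ORGANISMS, TISSUES

    ev = fixture_bundle / "evidence"
    return {
        "gene_map": read_gene_map(fixture_bundle / "transcriptome" / "transcripts.gtf"),
        "psl": {o: read_psl(ev / f"refseq_{o}.psl") for o in ORGANISMS},
        "nt": read_blast_tab(ev / "nt_blastn.tsv"),
        "quant": read_quant({t: ev / f"quant_{t}.tsv" for t in TISSUES}),
        "truth": synth.TruthSet.from_json(
            fixture_bundle / "transcriptome" / "truth.json"
        ),
    }
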