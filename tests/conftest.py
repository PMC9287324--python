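import pytest

from hybridtrace.simulate import SimConfig, generate_hybrids, generate_panel


@pytest.fixture(scope="session")
def small_bundle():
    """A small noise-free simulated survey: 4 species, 10 F1s, 3 three-ways,
    with the diagnostic 1-bp indel between fluitans and circinatus."""
    cfg = SimConfig(
        seed=7, n_f1=10, n_threeway=3, indel_between=("fluitans", "circinatus")
    )
    panel, refsets, truth = generate_panel(cfg)
    its, plastid, records, truth_df = generate_hybrids(panel, refsets, truth, cfg)
    return {
        "config": cfg,
        "panel": panel,
        "refsets": refsets,
        "truth": truth,
        "its": its,
        "plastid": plastid,
        "records": records,
        "truth_df": truth_df,
    }
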